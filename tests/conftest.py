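"""Shared fixtures: synthetic corpora and trained models.

Training is done once per session with small model configurations (2 CNN
ensemble members, small hidden sizes) so the whole suite stays desk-scale;
the corpora sizes match the recovery checks (1000 mixed records for
screening, 1500 all-RCT records for extraction/bias with 500 held out).
"""

from __future__ import annotations

import pytest

from trialscope import bias, pico, screening, sizeextract, synth
from trialscope.store import PipelineModels


@pytest.fixture(scope="session")
def vocab():
    v = synth.make_vocabulary(seed=7, n_concepts=60)
    v.assert_acyclic()
    return v


@pytest.fixture(scope="session")
def corpus_mixed(vocab):
    """1000 records, half RCT, 90% human: screening train/eval corpus."""
    return synth.generate_corpus(synth.GeneratorConfig(n_records=1000, seed=11), vocab)


@pytest.fixture(scope="session")
def corpus_rct(vocab):
    """1500 all-RCT records: extraction and bias train/eval corpus."""
    return synth.generate_corpus(
        synth.GeneratorConfig(n_records=1500, rct_fraction=1.0, seed=13), vocab
    )


@pytest.fixture(scope="session")
def rct_model(corpus_mixed):
    return screening.train_rct_ensemble(
        corpus_mixed[:800], screening.RctTrainConfig(n_cnn=2, seed=0)
    )


@pytest.fixture(scope="session")
def human_model(corpus_mixed):
    return screening.train_human_model(
        corpus_mixed[:800], seed=0, labels=[g.is_human for _, g in corpus_mixed[:800]]
    )


@pytest.fixture(scope="session")
def size_model(corpus_rct):
    return sizeextract.train_size_model(
        corpus_rct[:1000], sizeextract.SizeTrainConfig(seed=0)
    )


@pytest.fixture(scope="session")
def tagger(corpus_rct):
    return pico.train_span_tagger(corpus_rct[:800], pico.TaggerTrainConfig(epochs=5, seed=0))


@pytest.fixture(scope="session")
def bias_model(corpus_rct):
    return bias.train_bias_model(corpus_rct[:1000], seed=0)


@pytest.fixture(scope="session")
def pipeline_models(rct_model, human_model, size_model, tagger, bias_model, vocab):
    return PipelineModels(
        rct=rct_model, human=human_model, size=size_model,
        tagger=tagger, bias=bias_model, vocab=vocab,
    )
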