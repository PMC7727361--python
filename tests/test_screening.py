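"""RCT/human screening: threshold selection, ensemble behavior, bootstrap."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from trialscope import screening
from trialscope.metrics import c_statistic
from trialscope.screening import (bootstrap_threshold_stability, predict_human,
                                  predict_rct, predict_rct_batch,
                                  select_balanced_threshold, train_human_model,
                                  train_rct_ensemble, RctTrainConfig)


def brute_force_best_j(scores, labels) -> float:
    """Exhaustive scan over all cuts: max sensitivity + specificity."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    cuts = np.unique(scores)
    candidates = np.concatenate([cuts, [cuts.max() + 1.0]])
    best = -np.inf
    for t in candidates:
        pred = scores >= t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        best = max(best, sens + spec)
    return best


def achieved_j(threshold, scores, labels) -> float:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pred = scores >= threshold
    return (pred & labels).sum() / labels.sum() + (~pred & ~labels).sum() / (~labels).sum()


def test_balanced_threshold_separable_midpoint():
    thr = select_balanced_threshold([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
    assert 0.2 < thr <= 0.8
    assert thr == pytest.approx(0.5)
    assert achieved_j(thr, [0.1, 0.2, 0.8, 0.9], [False, False, True, True]) == 2.0


def test_balanced_threshold_degenerate_equal_scores_tie_to_highest():
    scores = [0.4] * 6
    labels = [True, False, True, False, True, False]
    thr = select_balanced_threshold(scores, labels)
    assert thr > 0.4  # highest candidate: classify everything negative
    assert achieved_j(thr, scores, labels) == pytest.approx(1.0)


def test_balanced_threshold_one_class_rejected():
    with pytest.raises(ValueError):
        select_balanced_threshold([0.1, 0.9], [True, True])


def test_balanced_threshold_matches_exhaustive_oracle_on_random_instances():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = int(rng.integers(5, 500))
        scores = rng.random(n).round(3)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        thr = select_balanced_threshold(scores, labels)
        assert achieved_j(thr, scores, labels) == pytest.approx(
            brute_force_best_j(scores, labels))


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.tuples(st.integers(0, 100), st.booleans()), min_size=4, max_size=60))
def test_balanced_threshold_property_equals_oracle(items):
    scores = [s / 100 for s, _ in items]
    labels = [l for _, l in items]
    if all(labels) or not any(labels):
        return
    thr = select_balanced_threshold(scores, labels)
    assert achieved_j(thr, scores, labels) == pytest.approx(brute_force_best_j(scores, labels))


def test_perfect_scorer_threshold_gives_sens_spec_one():
    rng = np.random.default_rng(4)
    labels = rng.random(100) < 0.5
    scores = np.where(labels, 0.6 + 0.4 * rng.random(100), 0.4 * rng.random(100))
    thr = select_balanced_threshold(scores, labels)
    assert achieved_j(thr, scores, labels) == 2.0


# -- ensemble ---------------------------------------------------------------


def test_ensemble_probability_is_mean_of_members(rct_model, corpus_mixed):
    records = [r for r, _ in corpus_mixed[800:810]]
    ens = predict_rct_batch(rct_model, records)
    X = screening._features(rct_model.vectorizer, [r.text for r in records],
                           [r.publication_types for r in records],
                           rct_model.ptyp_feature_enabled)
    member = [rct_model.linear_member.predict_proba(X)[:, 1]]
    extra = np.vstack([screening.ptype_indicator(r.publication_types) for r in records])
    for cnn in rct_model.cnn_members:
        member.append(cnn.predict_proba([r.text for r in records], extra=extra))
    np.testing.assert_allclose(ens, np.mean(member, axis=0))
    # permutation invariance in member order
    np.testing.assert_allclose(ens, np.mean(member[::-1], axis=0))


def test_ensemble_heldout_auc(rct_model, corpus_mixed):
    test = corpus_mixed[800:]
    probs = predict_rct_batch(rct_model, [r for r, _ in test])
    auc = c_statistic(probs, [g.is_rct for _, g in test])
    assert auc >= 0.9


def test_rct_probability_deterministic(rct_model, corpus_mixed):
    record = corpus_mixed[805][0]
    assert predict_rct(rct_model, record) == predict_rct(rct_model, record)


def test_training_deterministic_under_seed(corpus_mixed):
    small = corpus_mixed[:150]
    cfg = RctTrainConfig(n_cnn=1, seed=9, cnn_epochs=2)
    a = train_rct_ensemble(small, cfg)
    b = train_rct_ensemble(small, cfg)
    records = [r for r, _ in corpus_mixed[150:170]]
    np.testing.assert_allclose(predict_rct_batch(a, records), predict_rct_batch(b, records))


def test_ptyp_feature_improves_auc_with_informative_tags(corpus_mixed):
    """With publication-type tags present, the indicator cannot hurt."""
    small = corpus_mixed[:400]
    test = corpus_mixed[400:600]
    labels = [g.is_rct for _, g in test]
    with_t = train_rct_ensemble(small, RctTrainConfig(n_cnn=1, seed=1, cnn_epochs=3))
    without = train_rct_ensemble(
        small, RctTrainConfig(n_cnn=1, seed=1, cnn_epochs=3, ptyp_feature_enabled=False))
    auc_with = c_statistic(predict_rct_batch(with_t, [r for r, _ in test]), labels)
    auc_without = c_statistic(predict_rct_batch(without, [r for r, _ in test]), labels)
    assert auc_with >= auc_without - 0.01


def test_single_class_corpus_raises(corpus_mixed):
    rct_only = [(r, g) for r, g in corpus_mixed if g.is_rct][:50]
    with pytest.raises(ValueError):
        train_rct_ensemble(rct_only, RctTrainConfig(n_cnn=1))


def test_synthetic_rct_records_clear_threshold(rct_model, corpus_mixed):
    probe = [(r, g) for r, g in corpus_mixed[800:] if g.is_rct]
    probs = predict_rct_batch(rct_model, [r for r, _ in probe])
    thresholds = np.array([rct_model.threshold_for(r) for r, _ in probe])
    assert np.mean(probs >= thresholds) >= 0.95


def test_empty_text_record_scored_without_crash(rct_model):
    from trialscope.records import StudyRecord

    rec = StudyRecord(record_id="empty", source="pubmed", title="", abstract="")
    p = predict_rct(rct_model, rec)
    assert 0.0 <= p <= 1.0


# -- bootstrap threshold stability ------------------------------------------


def test_bootstrap_perfectly_separable_precision_ci_is_one():
    labels = np.array([False] * 30 + [True] * 30)
    scores = np.where(labels, 0.9, 0.1)
    report = bootstrap_threshold_stability(scores, labels, n_iter=50, seed=0)
    assert report.intervals["precision"] == (1.0, 1.0)
    assert report.intervals["recall"] == (1.0, 1.0)


def test_bootstrap_reproducible_with_fixed_seed():
    rng = np.random.default_rng(8)
    labels = rng.random(80) < 0.5
    scores = np.clip(labels * 0.4 + rng.random(80) * 0.6, 0, 1)
    a = bootstrap_threshold_stability(scores, labels, n_iter=25, seed=3)
    b = bootstrap_threshold_stability(scores, labels, n_iter=25, seed=3)
    assert a.intervals == b.intervals


def test_bootstrap_interval_covers_population_recall():
    """95% out-of-bag recall interval covers the population recall in >=90%
    of replicate experiments under a known generating model."""
    mu_pos, mu_neg, sd = 0.65, 0.35, 0.12
    pop_threshold = 0.5  # symmetric classes -> balanced cut at the midpoint
    pop_recall = 1 - norm.cdf(pop_threshold, loc=mu_pos, scale=sd)
    rng = np.random.default_rng(12)
    covered = 0
    n_rep = 100
    for rep in range(n_rep):
        labels = rng.random(300) < 0.5
        scores = np.where(labels, rng.normal(mu_pos, sd, 300), rng.normal(mu_neg, sd, 300))
        report = bootstrap_threshold_stability(scores, labels, n_iter=120, seed=rep)
        lo, hi = report.intervals["recall"]
        covered += lo <= pop_recall <= hi
    assert covered >= 0.90 * n_rep


# -- human classifier -------------------------------------------------------


def test_human_model_separates_animal_templates(human_model, corpus_mixed):
    test = corpus_mixed[800:]
    animal = [r for r, g in test if not g.is_human]
    human = [r for r, g in test if g.is_human]
    p_animal = np.array([predict_human(human_model, r) for r in animal])
    p_human = np.array([predict_human(human_model, r) for r in human])
    assert np.mean(p_animal < 0.5) >= 0.95
    assert np.mean(p_human > 0.5) >= 0.95


def test_human_prediction_deterministic(human_model, corpus_mixed):
    record = corpus_mixed[0][0]
    assert predict_human(human_model, record) == predict_human(human_model, record)


def test_human_labels_default_to_mesh_presence(corpus_mixed):
    from trialscope.screening import human_label

    for record, gold in corpus_mixed[:50]:
        assert human_label(record) == gold.is_human
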