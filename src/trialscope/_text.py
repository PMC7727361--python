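"""Text utilities: offset-preserving tokenization, a light part-of-speech
tagger, and normalization of English cardinal number words to numerals.

Number normalization replaces contiguous cardinal phrases ("one hundred and
twelve", "sixty-six", "two thousand and five") with decimal numerals while
keeping an offset map back to the original text. Ordinals and fractions are
left alone (they are not in the cardinal lexicon), as is a bare "one"
directly before "of" ("one of the arms"), which is a determiner-like use.
Parsing is capped at 0..999999; longer phrases stay verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

TOKEN_RE = re.compile(r"[A-Za-z]+|\d+(?:\.\d+)?|[^\sA-Za-z\d]")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Tokens with (text, start, end) character offsets, 0-based half-open."""
    return [(m.group(0), m.start(), m.end()) for m in TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# Light part-of-speech tagging (closed-class lexicons + suffix heuristics).

_DETS = {"a", "an", "the", "this", "that", "these", "those", "each", "every", "all", "both", "some"}
_PREPS = {
    "of", "in", "on", "at", "to", "for", "with", "from", "by", "over", "after",
    "before", "during", "between", "among", "versus", "vs", "per", "than",
}
_CONJ = {"and", "or", "but", "nor", "whereas", "while"}
_PRON = {"we", "they", "it", "he", "she", "who", "which", "our", "their", "its"}
_VERBS = {
    "was", "were", "is", "are", "be", "been", "had", "have", "has", "did", "do",
    "randomized", "randomised", "assigned", "allocated", "received", "underwent",
    "compared", "enrolled", "recruited", "included", "treated", "measured",
    "assessed", "observed", "reported", "showed", "found", "conducted", "performed",
}
_ADJ_SUFFIX = ("ous", "ive", "ble", "ic", "al", "ary", "less", "ful")
_VERB_SUFFIX = ("ized", "ised", "ated", "ing")


def pos_tag(token: str) -> str:
    """Coarse tag in {NUM, DET, PREP, CONJ, PRON, VERB, ADJ, NOUN, PUNCT}."""
    if not token:
        return "PUNCT"
    if token[0].isdigit():
        return "NUM"
    if not token[0].isalnum():
        return "PUNCT"
    low = token.lower()
    if low in _DETS:
        return "DET"
    if low in _PREPS:
        return "PREP"
    if low in _CONJ:
        return "CONJ"
    if low in _PRON:
        return "PRON"
    if low in _VERBS or low.endswith(_VERB_SUFFIX):
        return "VERB"
    if low.endswith(_ADJ_SUFFIX):
        return "ADJ"
    return "NOUN"


POS_TAGS = ("NUM", "DET", "PREP", "CONJ", "PRON", "VERB", "ADJ", "NOUN", "PUNCT")


# ---------------------------------------------------------------------------
# Cardinal number words.

_UNITS = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11, "twelve": 12,
    "thirteen": 13, "fourteen": 14, "fifteen": 15, "sixteen": 16,
    "seventeen": 17, "eighteen": 18, "nineteen": 19,
}
_TENS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
    "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90,
}
NUMBER_WORDS = set(_UNITS) | set(_TENS) | {"hundred", "thousand", "and"}

MAX_NUMWORD_VALUE = 999_999


def _parse_below_hundred(words: list[str], i: int) -> tuple[int, int] | None:
    """Parse tens/units starting at i; return (value, next_i) or None."""
    if i >= len(words):
        return None
    w = words[i]
    if w in _TENS:
        if i + 1 < len(words) and words[i + 1] in _UNITS and 1 <= _UNITS[words[i + 1]] <= 9:
            return _TENS[w] + _UNITS[words[i + 1]], i + 2
        return _TENS[w], i + 1
    if w in _UNITS:
        return _UNITS[w], i + 1
    return None


def _parse_below_thousand(words: list[str], i: int) -> tuple[int, int] | None:
    got = _parse_below_hundred(words, i)
    if got is None:
        return None
    value, j = got
    if 1 <= value <= 9 and j < len(words) and words[j] == "hundred":
        value *= 100
        j += 1
        k = j
        if k < len(words) and words[k] == "and":
            k += 1
        rest = _parse_below_hundred(words, k)
        if rest is not None and 1 <= rest[0] <= 99:
            return value + rest[0], rest[1]
        return value, j
    return value, j


def parse_cardinal(words: list[str]) -> tuple[int, int] | None:
    """Parse the longest valid cardinal prefix of lowercase ``words``.

    Returns (value, number of words consumed) or None. "and" is accepted only
    after "hundred"/"thousand"; the leading word must itself be a number word.
    """
    got = _parse_below_thousand(words, 0)
    if got is None:
        return None
    value, j = got
    if 1 <= value <= 999 and j < len(words) and words[j] == "thousand":
        total = value * 1000
        j += 1
        k = j
        if k < len(words) and words[k] == "and":
            k += 1
            rest = _parse_below_hundred(words, k)
        else:
            rest = _parse_below_thousand(words, k)
        if rest is not None and 1 <= rest[0] <= 999:
            return total + rest[0], rest[1]
        return total, j
    if value > MAX_NUMWORD_VALUE:
        return None
    return value, j


@dataclass
class NormalizedAbstract:
    """Abstract with number words rewritten as numerals plus an offset map.

    ``segments`` is a list of (norm_start, norm_end, orig_start, orig_end)
    covering the normalized text in order; unchanged stretches map 1:1 and
    each rewritten numeral maps to the whole original phrase.
    """

    text: str
    original: str
    segments: list[tuple[int, int, int, int]]

    def to_original(self, start: int, end: int) -> tuple[int, int]:
        """Map a normalized [start, end) interval to original coordinates."""
        if not (0 <= start <= end <= len(self.text)):
            raise ValueError("interval outside normalized text")
        if start == end:
            return (self._point(start), self._point(start))
        lo = hi = None
        for ns, ne, os_, oe in self.segments:
            if ns <= start < ne:
                lo = os_ + (start - ns) if oe - os_ == ne - ns else os_
            if ns < end <= ne:
                hi = os_ + (end - ns) if oe - os_ == ne - ns else oe
        assert lo is not None and hi is not None
        return lo, hi

    def _point(self, pos: int) -> int:
        for ns, ne, os_, oe in self.segments:
            if ns <= pos <= ne:
                return os_ + (pos - ns) if oe - os_ == ne - ns else os_
        return len(self.original)


def normalize_numwords(text: str) -> NormalizedAbstract:
    """Replace contiguous English cardinal phrases with decimal numerals."""
    tokens = tokenize(text)
    out: list[str] = []
    segments: list[tuple[int, int, int, int]] = []
    norm_pos = 0
    orig_pos = 0  # start of the not-yet-copied original suffix
    i = 0

    def copy_through(orig_end: int) -> None:
        nonlocal norm_pos, orig_pos
        if orig_end > orig_pos:
            chunk = text[orig_pos:orig_end]
            out.append(chunk)
            segments.append((norm_pos, norm_pos + len(chunk), orig_pos, orig_end))
            norm_pos += len(chunk)
            orig_pos = orig_end

    while i < len(tokens):
        tok, start, _ = tokens[i]
        low = tok.lower()
        if low in _UNITS or low in _TENS:
            # Collect the maximal run of cardinal words (joined by spaces,
            # hyphens, or "and"), then parse its longest valid prefix.
            run: list[str] = []
            run_tok_idx: list[int] = []
            j = i
            while j < len(tokens):
                w = tokens[j][0].lower()
                if w in NUMBER_WORDS:
                    run.append(w)
                    run_tok_idx.append(j)
                    j += 1
                elif w == "-" and run and j + 1 < len(tokens) and tokens[j + 1][0].lower() in NUMBER_WORDS:
                    j += 1  # hyphen joining number words
                else:
                    break
            parsed = parse_cardinal(run)
            if parsed is not None:
                value, consumed = parsed
                last_idx = run_tok_idx[consumed - 1]
                phrase_end = tokens[last_idx][2]
                next_word = tokens[last_idx + 1][0].lower() if last_idx + 1 < len(tokens) else ""
                if consumed == 1 and run[0] == "one" and next_word == "of":
                    i += 1  # "one of the ..." — determiner-like, leave verbatim
                    continue
                copy_through(start)
                numeral = str(value)
                out.append(numeral)
                segments.append((norm_pos, norm_pos + len(numeral), start, phrase_end))
                norm_pos += len(numeral)
                orig_pos = phrase_end
                i = last_idx + 1
                continue
        i += 1
    copy_through(len(text))
    return NormalizedAbstract(text="".join(out), original=text, segments=segments)
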