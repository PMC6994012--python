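"""String-similarity baselines for mention ranking.

Two primitives live here: a padded character n-gram overlap score (the
unlearned ranking baseline) and the Jaro-Winkler similarity used both as a
corpus statistic (how lexically similar are gold synonym pairs?) and as a
per-model diagnostic (how lexically similar are the synonyms a model finds?).
"""

from __future__ import annotations

from .corpus import normalize_surface

# Reserved pad sentinels: non-printing characters that cannot occur in
# normalized clinical text.
PAD_START = "\x02"
PAD_END = "\x03"


class UndefinedScoreError(ValueError):
    """The n-gram overlap score is undefined for an empty query gram set."""


def char_ngrams(
    surface: str, n: int, *, pad_start: str = PAD_START, pad_end: str = PAD_END
) -> frozenset[str]:
    """Set of padded character n-grams of a mention string.

    The string is split on spaces; each word is padded with one reserved
    start and one reserved end symbol, and all contiguous length-``n``
    substrings of the padded words are unioned.  Padding is per word, so no
    gram bridges a word boundary.  Set semantics: duplicates collapse.
    """
    if n < 1:
        raise ValueError(f"ngram length must be >= 1, got {n}")
    if pad_start in surface or pad_end in surface:
        raise ValueError("surface contains a reserved pad symbol")
    grams: set[str] = set()
    for word in surface.split():
        padded = pad_start + word + pad_end
        grams.update(padded[i : i + n] for i in range(len(padded) - n + 1))
    return frozenset(grams)


def ngram_overlap_score(query_surface: str, cand_surface: str, n: int) -> float:
    """|grams(candidate) ∩ grams(query)| / |grams(query)|.

    Asymmetric by construction: the denominator is the query's gram count, so
    a candidate that contains the query scores 1.0 while the reverse pairing
    generally does not.
    """
    q = char_ngrams(query_surface, n)
    if not q:
        raise UndefinedScoreError("query mention has no ngrams")
    c = char_ngrams(cand_surface, n)
    return len(c & q) / len(q)


def jaro_winkler(s1: str, s2: str) -> float:
    """Jaro-Winkler similarity of two strings (1.0 = identical).

    Inputs are normalized (lowercase, collapsed whitespace) first, since all
    string-equality tests in the pipeline use the normalized form.  Standard
    parameters: match window floor(max(len)/2) - 1, prefix scale p = 0.1,
    common-prefix length capped at 4.  Two empty strings score 1.0 by
    convention.
    """
    s1 = normalize_surface(s1)
    s2 = normalize_surface(s2)
    if not s1 and not s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    jaro = _jaro(s1, s2)
    prefix = 0
    for a, b in zip(s1, s2):
        if a != b or prefix == 4:
            break
        prefix += 1
    return jaro + prefix * 0.1 * (1.0 - jaro)


def _jaro(s1: str, s2: str) -> float:
    len1, len2 = len(s1), len(s2)
    window = max(max(len1, len2) // 2 - 1, 0)
    match1 = [False] * len1
    match2 = [False] * len2
    matches = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not match2[j] and s2[j] == c:
                match1[i] = match2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # transpositions: matched characters in order of appearance
    m1 = [c for c, f in zip(s1, match1) if f]
    m2 = [c for c, f in zip(s2, match2) if f]
    half_transpositions = sum(a != b for a, b in zip(m1, m2))
    t = half_transpositions // 2
    m = matches
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


# Alias matching the similarity-scaled reading of the reported statistic.
jw_score = jaro_winkler
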