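"""Fuzzy string matching: Gestalt pattern-matching and Levenshtein distance.

Two classical similarity measures over cleaned name strings, implemented
from first principles:

* **Gestalt pattern-matching (GPM)**, the Ratcliff-Obershelp similarity:
  recursively anchor on the longest common substring, match what remains
  to its left and right, and score
  ``GPM(X, Y) = 2 * (|s1| + ... + |sn|) / (|X| + |Y|)``
  where the ``s_i`` are the matched blocks. Higher is more similar, 1
  means identical.
* **Normalized Levenshtein distance (LED)**: minimum number of
  single-character edits divided by the longer string's length. Lower is
  more similar, 0 means identical.

No popularity ("autojunk") heuristics are applied: every character counts,
so the score is exactly the recursive definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import BothEmpty


class Method(str, Enum):
    """A similarity method name."""

    GPM = "gpm"
    LED = "led"
    SM = "sm"

    @property
    def higher_is_better(self) -> bool:
        return self is Method.GPM


@dataclass(frozen=True)
class MatchBlock:
    """A maximal common substring matched between two strings.

    ``x[pos_x : pos_x + length] == y[pos_y : pos_y + length]``.
    """

    pos_x: int
    pos_y: int
    length: int


@dataclass(frozen=True)
class SimilarityScore:
    """A similarity value in [0, 1] tagged with the method that produced it.

    For GPM higher means more similar; for LED (a normalized *distance*)
    lower means more similar.
    """

    method: Method
    value: float


@dataclass
class RankedMatches:
    """Top-k candidates for one query under one method, best first."""

    query: str
    method: Method
    k: int
    entries: list[tuple[str, float, int]] = field(default_factory=list)
    """``(candidate, score, rank)`` with ranks consecutive from 1."""

    @property
    def candidates(self) -> list[str]:
        return [c for c, _, _ in self.entries]


def _longest_common_block(
    x: str, y: str, xlo: int, xhi: int, ylo: int, yhi: int
) -> MatchBlock | None:
    """Longest common substring of ``x[xlo:xhi]`` and ``y[ylo:yhi]``.

    Ties are broken by the smallest start in ``x``, then in ``y``, which
    makes the recursive decomposition deterministic. Returns ``None`` when
    the windows share no character.
    """
    best_len = 0
    best_i = best_j = -1
    # lengths[j] = length of common suffix ending at (i, j); rolling row
    lengths = [0] * (yhi - ylo + 1)
    for i in range(xlo, xhi):
        prev_diag = 0
        ci = x[i]
        for j in range(ylo, yhi):
            cur = lengths[j - ylo + 1]
            if ci == y[j]:
                new = prev_diag + 1
                lengths[j - ylo + 1] = new
                if new > best_len:
                    best_len = new
                    best_i = i - new + 1
                    best_j = j - new + 1
            else:
                lengths[j - ylo + 1] = 0
            prev_diag = cur
    if best_len == 0:
        return None
    return MatchBlock(best_i, best_j, best_len)


def gpm_blocks(x: str, y: str) -> list[MatchBlock]:
    """Recursive Gestalt decomposition of ``x`` and ``y`` into match blocks.

    The longest common substring serves as an anchor; the regions to its
    left and to its right are matched recursively. Blocks are returned in
    increasing position order and never overlap. Disjoint strings yield an
    empty list.
    """
    blocks: list[MatchBlock] = []

    def recurse(xlo: int, xhi: int, ylo: int, yhi: int) -> None:
        if xlo >= xhi or ylo >= yhi:
            return
        anchor = _longest_common_block(x, y, xlo, xhi, ylo, yhi)
        if anchor is None:
            return
        recurse(xlo, anchor.pos_x, ylo, anchor.pos_y)
        blocks.append(anchor)
        recurse(anchor.pos_x + anchor.length, xhi, anchor.pos_y + anchor.length, yhi)

    recurse(0, len(x), 0, len(y))
    return blocks


def gpm_similarity(x: str, y: str) -> SimilarityScore:
    """Gestalt pattern-matching similarity of two non-empty strings."""
    matched = sum(b.length for b in gpm_blocks(x, y))
    value = 2.0 * matched / (len(x) + len(y))
    return SimilarityScore(Method.GPM, value)


def levenshtein(x: str, y: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions transforming ``x`` into ``y``.

    Dynamic programming over a rolling row; equivalent to the classic
    recursion with base cases ``lev(x, "") = |x|`` and ``lev("", y) = |y|``.
    """
    if not x:
        return len(y)
    if not y:
        return len(x)
    prev = list(range(len(y) + 1))
    for i, cx in enumerate(x, start=1):
        cur = [i] + [0] * len(y)
        for j, cy in enumerate(y, start=1):
            cur[j] = min(
                prev[j] + 1,  # delete from x
                cur[j - 1] + 1,  # insert into x
                prev[j - 1] + (cx != cy),  # substitute / keep
            )
        prev = cur
    return prev[-1]


def normalized_levenshtein(x: str, y: str) -> SimilarityScore:
    """Levenshtein distance divided by the longer string's length.

    Raises
    ------
    BothEmpty
        If both strings are empty (0/0 is undefined).
    """
    if not x and not y:
        raise BothEmpty("normalized Levenshtein undefined for two empty strings")
    value = levenshtein(x, y) / max(len(x), len(y))
    return SimilarityScore(Method.LED, value)


def _score(query: str, candidate: str, method: Method) -> float:
    if method is Method.GPM:
        return gpm_similarity(query, candidate).value
    if method is Method.LED:
        return normalized_levenshtein(query, candidate).value
    raise ValueError(f"method {method} is not a string-based matcher")


def top_k(
    query: str,
    corpus: Sequence[str] | Iterable[str],
    method: Method | str,
    k: int = 20,
    cutoff: float = 0.0,
) -> RankedMatches:
    """Rank a corpus against one query and keep the best ``k`` candidates.

    GPM candidates are sorted by descending similarity, LED candidates by
    ascending normalized distance. ``cutoff`` excludes candidates with GPM
    similarity below it (resp. LED distance above ``1 - cutoff``); the
    default 0.0 keeps everything. Score ties break by ascending candidate
    string so output order is reproducible.
    """
    method = Method(method)
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [(c, _score(query, c, method)) for c in corpus]
    if cutoff > 0.0:
        if method.higher_is_better:
            scored = [(c, s) for c, s in scored if s >= cutoff]
        else:
            scored = [(c, s) for c, s in scored if s <= 1.0 - cutoff]
    sign = -1.0 if method.higher_is_better else 1.0
    scored.sort(key=lambda cs: (sign * cs[1], cs[0]))
    entries = [(c, s, rank) for rank, (c, s) in enumerate(scored[:k], start=1)]
    return RankedMatches(query=query, method=method, k=k, entries=entries)


def top_k_batch(
    queries: Sequence[str],
    corpus: Sequence[str],
    method: Method | str,
    k: int = 20,
    cutoff: float = 0.0,
) -> list[RankedMatches]:
    """:func:`top_k` applied to each query in turn."""
    return [top_k(q, corpus, method, k=k, cutoff=cutoff) for q in queries]


def gpm_similarity_matrix(queries: Sequence[str], corpus: Sequence[str]) -> np.ndarray:
    """Dense GPM similarity matrix, queries as rows. Convenience for evaluation."""
    out = np.empty((len(queries), len(corpus)))
    for i, q in enumerate(queries):
        for j, c in enumerate(corpus):
            out[i, j] = gpm_similarity(q, c).value
    return out
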