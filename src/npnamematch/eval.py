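"""Retrieval and agreement metrics.

Mean reciprocal rank (MRR) over top-k retrieval, in two modes: *exact*
(the literal target string must appear) and *equivalent* (any name in the
target's synonym group counts). A query whose answer is absent from the
top-k contributes a reciprocal rank of 0. Also: threshold accuracy for
labeled pairs under a model distance, and Cohen's kappa for two-annotator
2x2 agreement tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateMarginals, EmptyOutcomes, ModelMissing
from .fuzzy import Method, RankedMatches, top_k
from .pairgen import LabeledPair, Lexicon

#: Sentinel rank for "target not in the top-k".
ABSENT = None


@dataclass(frozen=True)
class RankOutcome:
    """Where the correct answer landed for one query (or ABSENT)."""

    query: str
    rank: int | None
    k: int


@dataclass(frozen=True)
class MRRResult:
    """Mean reciprocal rank, its per-query SD, query count and mode."""

    value: float
    sd: float
    n: int
    mode: str


def rank_of_target(
    ranked: RankedMatches,
    target: str | None = None,
    equivalents: Iterable[str] | None = None,
    mode: str = "exact",
) -> RankOutcome:
    """Rank of the first correct entry in a ranked list.

    ``exact`` mode looks for the literal target; ``equivalent`` mode for
    any member of the target's synonym set (which must contain the target).
    """
    if mode == "exact":
        if target is None:
            raise ValueError("exact mode requires a target")
        accept = {target}
    elif mode == "equivalent":
        eq = set(equivalents or ())
        if not eq:
            raise ValueError("equivalent mode requires a non-empty equivalents set")
        if target is not None and target not in eq:
            raise ValueError("equivalents must contain the target")
        accept = eq
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for candidate, _, rank in ranked.entries:
        if candidate in accept:
            return RankOutcome(ranked.query, rank, ranked.k)
    return RankOutcome(ranked.query, ABSENT, ranked.k)


def mean_reciprocal_rank(outcomes: Sequence[RankOutcome], mode: str = "exact") -> MRRResult:
    """``MRR = (1/n) * sum(1/rank_i)`` with ABSENT contributing 0.

    The SD is the population standard deviation of the per-query
    reciprocal ranks.
    """
    if not outcomes:
        raise EmptyOutcomes("MRR over an empty outcome list")
    rr = np.array([0.0 if o.rank is ABSENT else 1.0 / o.rank for o in outcomes])
    return MRRResult(float(rr.mean()), float(rr.std()), len(rr), mode)


def pair_accuracy(model, pairs: Sequence[LabeledPair], threshold: float = 0.5) -> float:
    """Fraction of pairs where ``(distance >= threshold)`` equals the label."""
    from .siamese import pair_distances

    if not pairs:
        raise ValueError("pairs must be non-empty")
    d = pair_distances(model, pairs)
    labels = np.array([p.label for p in pairs])
    return float(((d >= threshold).astype(int) == labels).mean())


@dataclass(frozen=True)
class AgreementTable:
    """2x2 cross-tabulation of two annotators' match/non-match verdicts.

    ``counts[i][j]`` is the number of items rater 1 put in category ``i``
    and rater 2 in category ``j``.
    """

    counts: tuple[tuple[int, int], tuple[int, int]]

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)

    @property
    def p0(self) -> float:
        """Relative observed agreement among raters."""
        return (self.counts[0][0] + self.counts[1][1]) / self.total

    @property
    def pe(self) -> float:
        """Hypothetical probability of chance agreement (marginal product)."""
        n = self.total
        r1 = [sum(self.counts[0]), sum(self.counts[1])]
        r2 = [self.counts[0][0] + self.counts[1][0], self.counts[0][1] + self.counts[1][1]]
        return (r1[0] * r2[0] + r1[1] * r2[1]) / (n * n)


def cohens_kappa(table: AgreementTable) -> float:
    """Chance-corrected agreement ``kappa = (p0 - pe) / (1 - pe)``.

    Raises
    ------
    DegenerateMarginals
        If chance agreement is 1 (both raters constant and identical).
    """
    if table.total == 0:
        raise ValueError("empty agreement table")
    pe = table.pe
    if pe >= 1.0:
        raise DegenerateMarginals("kappa undefined when chance agreement is 1")
    return (table.p0 - pe) / (1.0 - pe)


def compare_methods(
    lexicon: Lexicon,
    holdout_pairs: Sequence[LabeledPair],
    methods: Sequence[Method | str] = (Method.GPM, Method.LED, Method.SM),
    k: int = 20,
    model=None,
    *,
    n_queries: int | None = None,
    corpus: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exact and equivalent MRR for each method over holdout matching pairs.

    Each matching pair contributes its first element as the query and its
    second as the correct answer; the retrieval corpus defaults to every
    name in the lexicon. Returns a tidy frame with columns
    ``method, mode, mrr, sd, n``.
    """
    from .siamese import sm_top_k

    methods = [Method(m) for m in methods]
    matching = [p for p in holdout_pairs if p.label == 0]
    if n_queries is not None:
        matching = matching[:n_queries]
    if not matching:
        raise ValueError("no matching pairs to evaluate")
    if corpus is None:
        corpus = lexicon.all_names()
    corpus = list(dict.fromkeys(corpus))
    group_of = lexicon.group_of()
    names_by_group: dict[str, set[str]] = {}
    for name, gid in group_of.items():
        names_by_group.setdefault(gid, set()).add(name)

    sm_vectors = None
    if Method.SM in methods:
        if model is None:
            raise ModelMissing("SM requested without a model")
        sm_vectors = model.embed_names(corpus)

    rows = []
    for method in methods:
        exact_outcomes, equiv_outcomes = [], []
        for pair in matching:
            if method is Method.SM:
                ranked = sm_top_k(model, pair.query, corpus, k=k, corpus_vectors=sm_vectors)
            else:
                ranked = top_k(pair.query, corpus, method, k=k)
            exact_outcomes.append(rank_of_target(ranked, target=pair.target, mode="exact"))
            gid = group_of.get(pair.target)
            equivalents = names_by_group.get(gid, {pair.target}) | {pair.target}
            equiv_outcomes.append(
                rank_of_target(ranked, target=pair.target, equivalents=equivalents,
                               mode="equivalent")
            )
        for mode, outcomes in (("exact", exact_outcomes), ("equivalent", equiv_outcomes)):
            res = mean_reciprocal_rank(outcomes, mode)
            rows.append(
                {"method": method.value, "mode": mode, "mrr": res.value,
                 "sd": res.sd, "n": res.n}
            )
    return pd.DataFrame(rows)
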