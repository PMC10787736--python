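"""Candidate-mining pipeline over an unmapped-name corpus.

Given a query set of natural-product names (one Latin binomial and one
preferred common name per product) and a large corpus of unmapped
free-text strings, the pipeline:

1. filters the corpus (clean, drop empties, drop over-length strings,
   drop exact duplicates) with full bookkeeping of what was removed;
2. mines the top-20 corpus strings per query under Gestalt
   pattern-matching and/or the Siamese model;
3. exports the merged candidates as an annotation sheet for two human
   reviewers (match / non-match), re-imports their verdicts, and
   summarizes per-method totals, uniques and overlap;
4. counts how many reports a name list captures before and after adding
   the newly validated names.

The adjudication of disagreements is a human step; the sheet embeds the
review rules as guidance (a Latin-binomial query matched to only a genus
or a general common name is a non-match; a common-name query colliding
with another medical term is a non-match).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import normalize
from .errors import (
    EmptyAfterCleaning,
    ModelMissing,
    SchemaMismatch,
    TooLong,
    UnreviewedCandidates,
)
from .fuzzy import Method, top_k

ADJUDICATION_RULES = (
    "If the query term is a Latin binomial and the result is a general common "
    "name or only a genus name, mark non-match. If the query term is a common "
    "name and the result could collide with another medical term, mark non-match."
)

_VERDICTS = {"match", "non-match", ""}


@dataclass(frozen=True)
class QueryTerm:
    """One query name: a product id plus one of its two name kinds."""

    np_id: str
    name: str
    name_kind: str  # "latin_binomial" | "preferred_term"

    def __post_init__(self) -> None:
        if self.name_kind not in {"latin_binomial", "preferred_term"}:
            raise ValueError(f"bad name_kind {self.name_kind!r}")


@dataclass
class UnmappedCorpus:
    """De-duplicated, length-filtered clean strings plus a removal log."""

    strings: list[str]
    filter_log: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CandidateMapping:
    """A proposed (query, corpus string) link awaiting human review."""

    query: QueryTerm
    candidate: str
    method: Method
    score: float
    rank: int
    annotation: str = "unreviewed"  # unreviewed | match | non-match
    annotator1: str = ""
    annotator2: str = ""


@dataclass(frozen=True)
class CaptureReport:
    """Report counts before/after extending the name list."""

    reports_before: int
    reports_after: int

    @property
    def difference(self) -> int:
        return self.reports_after - self.reports_before


def query_terms_from_lexicon(lexicon) -> list[QueryTerm]:
    """Two queries per product: the Latin binomial and the preferred term."""
    out = []
    for g in lexicon.groups:
        out.append(QueryTerm(g.group_id, g.latin_binomial, "latin_binomial"))
        out.append(QueryTerm(g.group_id, g.preferred_term, "preferred_term"))
    return out


def filter_corpus(raw: Iterable[str], max_len: int = normalize.MAX_LEN) -> UnmappedCorpus:
    """Clean and filter raw strings, logging every removal by reason.

    Conservation invariant: ``len(raw) == len(kept) + sum(filter_log)``.
    """
    log = {"empty_after_cleaning": 0, "too_long": 0, "duplicate": 0}
    kept: list[str] = []
    seen: set[str] = set()
    n = 0
    for s in raw:
        n += 1
        try:
            cleaned = normalize.clean_name(s, max_len=max_len)
        except EmptyAfterCleaning:
            log["empty_after_cleaning"] += 1
            continue
        except TooLong:
            log["too_long"] += 1
            continue
        if cleaned in seen:
            log["duplicate"] += 1
            continue
        seen.add(cleaned)
        kept.append(cleaned)
    if not n:
        raise ValueError("raw corpus must be non-empty")
    log["input"] = n
    return UnmappedCorpus(kept, log)


def mine_candidates(
    queries: Sequence[QueryTerm],
    corpus: UnmappedCorpus,
    *,
    gpm_on: bool = True,
    sm_model=None,
    k: int = 20,
) -> list[CandidateMapping]:
    """Top-k corpus strings per query under each enabled method."""
    if not gpm_on and sm_model is None:
        raise ModelMissing("enable GPM and/or supply a Siamese model")
    out: list[CandidateMapping] = []
    sm_vectors = None
    if sm_model is not None:
        sm_vectors = sm_model.embed_names(corpus.strings)
    for q in queries:
        if gpm_on:
            ranked = top_k(q.name, corpus.strings, Method.GPM, k=k)
            out.extend(
                CandidateMapping(q, c, Method.GPM, s, r) for c, s, r in ranked.entries
            )
        if sm_model is not None:
            from .siamese import sm_top_k

            ranked = sm_top_k(sm_model, q.name, corpus.strings, k=k,
                              corpus_vectors=sm_vectors)
            out.extend(
                CandidateMapping(q, c, Method.SM, s, r) for c, s, r in ranked.entries
            )
    return out


def overlap_accounting(candidates: Sequence[CandidateMapping]) -> dict:
    """Per-method totals, uniques and overlap of correct candidates.

    "Total" counts correct candidate names per method (a name found by
    both methods counts in both); "unique" counts names only one method
    found. Broken down by query name kind as well as overall.

    Raises
    ------
    UnreviewedCandidates
        If any candidate is still unreviewed.
    """
    if any(c.annotation == "unreviewed" for c in candidates):
        raise UnreviewedCandidates("annotate every candidate before accounting")
    methods = (Method.GPM, Method.SM)
    kinds = ("latin_binomial", "preferred_term")

    def correct_names(method: Method, kind: str | None) -> set[str]:
        return {
            c.candidate
            for c in candidates
            if c.method is method
            and c.annotation == "match"
            and (kind is None or c.query.name_kind == kind)
        }

    summary: dict = {"by_kind": {}, "rules": ADJUDICATION_RULES}
    for kind in (*kinds, None):
        gpm = correct_names(Method.GPM, kind)
        sm = correct_names(Method.SM, kind)
        entry = {
            "gpm_total": len(gpm),
            "sm_total": len(sm),
            "combined_total": len(gpm) + len(sm),
            "gpm_unique": len(gpm - sm),
            "sm_unique": len(sm - gpm),
            "overlap": len(gpm & sm),
            "combined_unique": len(gpm | sm),
        }
        if kind is None:
            summary["overall"] = entry
        else:
            summary["by_kind"][kind] = entry
    return summary


_SHEET_COLUMNS = [
    "query", "query_kind", "np_id", "candidate", "method", "rank", "score",
    "annotator1", "annotator2", "adjudicated",
]


def export_annotation_sheet(candidates: Sequence[CandidateMapping], path: str | Path) -> None:
    """Write a review sheet (CSV) with two annotator columns.

    The adjudication rules are embedded as a comment line for reviewers.
    """
    if not candidates:
        raise ValueError("no candidates to export")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# Review guidance: {ADJUDICATION_RULES}\n")
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_SHEET_COLUMNS)
        for c in candidates:
            w.writerow(
                [c.query.name, c.query.name_kind, c.query.np_id, c.candidate,
                 c.method.value, c.rank, f"{c.score:.6f}", c.annotator1, c.annotator2,
                 "" if c.annotation == "unreviewed" else c.annotation]
            )


def import_annotations(
    candidates: Sequence[CandidateMapping], path: str | Path
) -> list[CandidateMapping]:
    """Re-attach reviewed verdicts from an annotation sheet.

    Rows are matched on ``(query, candidate, method)``; the adjudicated
    column (falling back to agreement of the two annotators) becomes the
    candidate's annotation.

    Raises
    ------
    SchemaMismatch
        On missing columns, unknown verdict vocabulary, or rows that do
        not correspond to any candidate.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None or not set(_SHEET_COLUMNS) <= set(reader.fieldnames):
        raise SchemaMismatch(f"sheet must have columns {_SHEET_COLUMNS}")
    by_key = {(c.query.name, c.candidate, c.method.value): c for c in candidates}
    out = dict(by_key)
    for row in reader:
        key = (row["query"], row["candidate"], row["method"])
        if key not in by_key:
            raise SchemaMismatch(f"sheet row {key} matches no candidate")
        for col in ("annotator1", "annotator2", "adjudicated"):
            if row[col] not in _VERDICTS:
                raise SchemaMismatch(f"verdict {row[col]!r} not in {{match, non-match}}")
        verdict = row["adjudicated"]
        if not verdict and row["annotator1"] and row["annotator1"] == row["annotator2"]:
            verdict = row["annotator1"]
        out[key] = replace(
            by_key[key],
            annotation=verdict or "unreviewed",
            annotator1=row["annotator1"],
            annotator2=row["annotator2"],
        )
    return list(out.values())


def agreement_table(candidates: Sequence[CandidateMapping]):
    """2x2 annotator agreement table over doubly-annotated candidates."""
    from .eval import AgreementTable

    counts = [[0, 0], [0, 0]]
    for c in candidates:
        if c.annotator1 in ("match", "non-match") and c.annotator2 in ("match", "non-match"):
            i = 0 if c.annotator1 == "match" else 1
            j = 0 if c.annotator2 == "match" else 1
            counts[i][j] += 1
    return AgreementTable(((counts[0][0], counts[0][1]), (counts[1][0], counts[1][1])))


def capture_gain(
    reports: Sequence[tuple[str, Sequence[str]]],
    names_before: set[str],
    names_after: set[str],
    *,
    substring: bool = False,
) -> CaptureReport:
    """Count reports mentioning any name from each set.

    A report is a ``(report_id, [name strings])`` record; matching is
    exact equality on cleaned strings (substring containment behind the
    ``substring`` flag). ``names_after`` must contain ``names_before``.
    """
    if not names_after >= names_before:
        raise ValueError("names_after must be a superset of names_before")

    def mentions(strings: Sequence[str], names: set[str]) -> bool:
        cleaned = []
        for s in strings:
            try:
                cleaned.append(normalize.clean_name(s))
            except EmptyAfterCleaning:
                continue
        if substring:
            return any(n in c for c in cleaned for n in names)
        return any(c in names for c in cleaned)

    before = sum(1 for _, strings in reports if mentions(strings, names_before))
    after = sum(1 for _, strings in reports if mentions(strings, names_after))
    return CaptureReport(before, after)


def write_candidates_jsonl(candidates: Sequence[CandidateMapping], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for c in candidates:
            fh.write(json.dumps({
                "query": c.query.name, "query_kind": c.query.name_kind,
                "np_id": c.query.np_id, "candidate": c.candidate,
                "method": c.method.value, "score": c.score, "rank": c.rank,
                "annotation": c.annotation,
            }) + "\n")
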