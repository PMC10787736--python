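import numpy as np
import pytest

from npnamematch import fuzzy, mine, pairgen
from npnamematch.errors import SchemaMismatch, UnreviewedCandidates


@pytest.fixture(scope="module")
def mined():
    """A small seeded mining run with planted perturbations of the queries."""
    lexicon = pairgen.synth_lexicon(4, seed=31)
    queries = mine.query_terms_from_lexicon(lexicon)
    config = pairgen.PerturbationConfig(rng_seed=31)
    rng = np.random.default_rng(31)
    planted = {
        q.name: pairgen.perturb_name(q.name, config, rng) for q in queries
    }
    decoys = pairgen.synth_decoy_corpus(
        300, seed=32, avoid=set(planted.values()) | set(planted)
    )
    raw = decoys + list(planted.values())
    corpus = mine.filter_corpus(raw)
    candidates = mine.mine_candidates(queries, corpus, gpm_on=True, k=20)
    return {
        "lexicon": lexicon,
        "queries": queries,
        "planted": planted,
        "corpus": corpus,
        "candidates": candidates,
    }


class TestFilterCorpus:
    def test_removals_logged_by_reason(self):
        raw = ["ginger", "GINGER!", "123", "x" * 70, "cinnamon"]
        corpus = mine.filter_corpus(raw)
        assert corpus.strings == ["GINGER", "CINNAMON"]
        assert corpus.filter_log["duplicate"] == 1
        assert corpus.filter_log["empty_after_cleaning"] == 1
        assert corpus.filter_log["too_long"] == 1

    def test_conservation_invariant(self, rng):
        decoys = pairgen.synth_decoy_corpus(200, seed=5)
        noisy = decoys + [d.lower() for d in decoys[:37]] + ["!!!", "y" * 66]
        order = rng.permutation(len(noisy))
        corpus = mine.filter_corpus([noisy[i] for i in order])
        removed = sum(v for k, v in corpus.filter_log.items() if k != "input")
        assert corpus.filter_log["input"] == len(noisy)
        assert len(corpus.strings) + removed == len(noisy)

    def test_clean_unique_corpus_unchanged(self):
        strings = ["ALPHA", "BETA", "GAMMA"]
        corpus = mine.filter_corpus(strings)
        assert corpus.strings == strings
        assert sum(v for k, v in corpus.filter_log.items() if k != "input") == 0


class TestMineCandidates:
    def test_planted_perturbations_found_by_gpm(self, mined):
        by_query = {}
        for c in mined["candidates"]:
            by_query.setdefault(c.query.name, []).append(c.candidate)
        for qname, plant in mined["planted"].items():
            assert plant in by_query[qname]

    def test_gpm_only_when_sm_disabled(self, mined):
        assert {c.method for c in mined["candidates"]} == {fuzzy.Method.GPM}

    def test_single_candidate_identity(self, toy_model):
        q = mine.QueryTerm("NP0", "GINGER", "preferred_term")
        corpus = mine.UnmappedCorpus(["GINGER"], {})
        out = mine.mine_candidates([q], corpus, gpm_on=True, sm_model=toy_model, k=1)
        assert len(out) == 2  # one per method
        assert all(c.rank == 1 and c.candidate == "GINGER" for c in out)

    def test_both_methods_contribute_unique_candidates(self, mined, trained_toy):
        """With spelling noise and cross-name equivalences, each matcher
        finds candidates the other misses (in both directions)."""
        model = trained_toy["model"]
        out = mine.mine_candidates(
            mined["queries"], mined["corpus"], gpm_on=True, sm_model=model, k=20
        )
        gpm = {(c.query.name, c.candidate) for c in out if c.method is fuzzy.Method.GPM}
        sm = {(c.query.name, c.candidate) for c in out if c.method is fuzzy.Method.SM}
        assert gpm - sm and sm - gpm


class TestAnnotationSheet:
    def test_round_trip_lossless(self, mined, tmp_path):
        path = tmp_path / "sheet.csv"
        mine.export_annotation_sheet(mined["candidates"], path)
        back = mine.import_annotations(mined["candidates"], path)
        key = lambda c: (c.query.name, c.candidate, c.method.value)
        assert sorted(map(key, back)) == sorted(map(key, mined["candidates"]))
        assert all(c.annotation == "unreviewed" for c in back)

    def test_verdicts_applied_and_agreement_counted(self, mined, tmp_path):
        path = tmp_path / "sheet.csv"
        cands = mined["candidates"][:8]
        mine.export_annotation_sheet(cands, path)
        text = path.read_text().splitlines()
        rows = []
        for i, line in enumerate(text):
            if i >= 2:  # alternate annotator verdicts, agree on half
                a1 = "match" if i % 2 else "non-match"
                a2 = "match"
                line = line.replace(",,,", f",{a1},{a2},")
            rows.append(line)
        path.write_text("\n".join(rows) + "\n")
        back = mine.import_annotations(cands, path)
        annotated = [c for c in back if c.annotator1]
        assert annotated
        table = mine.agreement_table(back)
        assert table.total == len(annotated)
        # agreement -> verdict adopted; disagreement -> left for adjudication
        for c in annotated:
            if c.annotator1 == c.annotator2:
                assert c.annotation == c.annotator1
            else:
                assert c.annotation == "unreviewed"

    def test_bad_verdict_vocabulary_rejected(self, mined, tmp_path):
        path = tmp_path / "sheet.csv"
        cands = mined["candidates"][:2]
        mine.export_annotation_sheet(cands, path)
        text = path.read_text().replace(",,,\n", ",maybe,match,\n", 1)
        path.write_text(text)
        with pytest.raises(SchemaMismatch):
            mine.import_annotations(cands, path)

    def test_missing_columns_rejected(self, mined, tmp_path):
        path = tmp_path / "sheet.csv"
        path.write_text("query,candidate\nA,B\n")
        with pytest.raises(SchemaMismatch):
            mine.import_annotations(mined["candidates"], path)


class TestOverlapAccounting:
    def make(self, qname, cand, method, annotation):
        q = mine.QueryTerm("NP0", qname, "preferred_term")
        return mine.CandidateMapping(q, cand, method, 0.5, 1, annotation)

    def test_set_arithmetic(self):
        cands = [
            self.make("Q", c, fuzzy.Method.GPM, "match") for c in ("A", "B", "C")
        ] + [
            self.make("Q", c, fuzzy.Method.SM, "match") for c in ("B", "D")
        ]
        summary = mine.overlap_accounting(cands)["overall"]
        assert summary["gpm_total"] == 3 and summary["sm_total"] == 2
        assert summary["combined_total"] == 5
        assert summary["gpm_unique"] == 2 and summary["sm_unique"] == 1
        assert summary["overlap"] == 1 and summary["combined_unique"] == 4

    def test_disjoint_methods_sum(self):
        cands = [self.make("Q", "A", fuzzy.Method.GPM, "match"),
                 self.make("Q", "B", fuzzy.Method.SM, "match")]
        s = mine.overlap_accounting(cands)["overall"]
        assert s["combined_total"] == s["gpm_unique"] + s["sm_unique"]

    def test_all_non_match_gives_zero(self):
        cands = [self.make("Q", "A", fuzzy.Method.GPM, "non-match")]
        s = mine.overlap_accounting(cands)["overall"]
        assert s["combined_total"] == 0

    def test_unreviewed_rejected(self):
        cands = [self.make("Q", "A", fuzzy.Method.GPM, "unreviewed")]
        with pytest.raises(UnreviewedCandidates):
            mine.overlap_accounting(cands)


class TestCaptureGain:
    reports = [
        ("r1", ["GINGER", "ASPIRIN"]),
        ("r2", ["likorice"]),
        ("r3", ["unknown herb"]),
        ("r4", ["GINGER", "LIKORICE"]),
    ]

    def test_no_new_names_no_difference(self):
        before = {"GINGER"}
        gain = mine.capture_gain(self.reports, before, set(before))
        assert gain.difference == 0 and gain.reports_before == 2

    def test_novel_names_add_reports(self):
        before = {"GINGER"}
        after = before | {"LIKORICE"}
        gain = mine.capture_gain(self.reports, before, after)
        assert gain.reports_before == 2
        assert gain.reports_after == 3
        assert gain.difference == 1

    def test_report_matching_both_sets_counts_once(self):
        before = {"GINGER"}
        after = before | {"ASPIRIN"}
        gain = mine.capture_gain(self.reports, before, after)
        assert gain.reports_after == 2  # r1 matches both names but counts once
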