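"""Sliding-window mining, deduplication, ranking, domain annotation."""

import numpy as np
import pytest

import acpmine as am
from acpmine.mining import (DomainHit, MiningConfig, Provenance,
                            annotate_candidates, deduplicate,
                            enumerate_windows, mine_reads, parse_domtblout,
                            window_count, windows_from_fragments)
from acpmine.seqio import SequenceRecord, six_frame_translate

DOMTBLOUT_FIXTURE = """\
#                                                                            --- full sequence --- -------------- this domain -------------  hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ -----   -- --- --------- --------- ------ -----  ----- ----- ----- ----- ----- ----- ---- ---------------------
Homeodomain          PF00046.24    57 cand1                -             30   1.2e-08   33.9   0.1   1   1   1.9e-12   1.1e-08   33.7   0.1      2    31     1    30     1    30 0.95 Homeodomain
Homeodomain          PF00046.24    57 ghost                -             30   5.0e-03   10.0   0.0   1   1   1.0e-05   5.0e-01   9.0    0.0      2    31     1    30     1    30 0.80 Homeodomain
"""


class TestWindows:
    def test_count_formula_small(self):
        wins = list(enumerate_windows("ABCDEFG".replace("B", "C"), 5, 7))
        assert len(wins) == 3 + 2 + 1

    def test_exact_single_window(self):
        assert [w for _, w in enumerate_windows("AAEKE", 5, 5)] == ["AAEKE"]

    def test_ordering_contract(self):
        wins = list(enumerate_windows("AAEKEF", 5, 6))
        assert wins == [(0, "AAEKE"), (1, "AEKEF"), (0, "AAEKEF")]

    def test_count_matches_closed_form(self, rng):
        from conftest import random_peptides
        for frag in random_peptides(rng, 20, 1, 60):
            n = len(list(enumerate_windows(frag, 5, 50)))
            assert n == window_count(len(frag), 5, 50)

    def test_short_fragment_empty(self):
        assert list(enumerate_windows("AAK", 5, 50)) == []


class TestDeduplicate:
    def test_merges_identical_windows(self):
        prov1 = Provenance("r1", 1, 0, 5)
        prov2 = Provenance("r2", -2, 3, 5)
        out = deduplicate([("AAEKE", prov1), ("AAEKE", prov2)])
        assert len(out) == 1 and len(out[0].provenance) == 2

    def test_distinct_preserved_and_provenance_conserved(self, rng):
        from conftest import random_peptides
        peps = random_peptides(rng, 30, 5, 10)
        items = [(p, Provenance(f"r{i}", 1, 0, len(p))) for i, p in enumerate(peps)]
        out = deduplicate(items)
        assert len(out) == len(set(peps))
        assert sum(len(c.provenance) for c in out) == len(items)


class TestMineReads:
    def test_planted_recall(self, trained_model):
        acp = am.default_profile("acp")
        planted = [r.sequence for r in am.sample_peptides(acp, 30, seed=21)]
        reads, manifest = am.generate_reads(planted, 50, 300, seed=22)
        report, counts = mine_reads(reads, trained_model)
        predicted = set(report.loc[report["label"] == "ACP", "peptide"])
        recall = np.mean([p in predicted for p in manifest.entries["peptide"]])
        assert recall >= 0.9
        assert counts["candidates"] <= counts["windows"]

    def test_no_orf_reads_empty_report(self, trained_model):
        # a 12-nt read cannot encode a stop-free stretch of >= 5 residues
        reads = [SequenceRecord("r1", "ACGTACGTACGT", "dna")]
        report, counts = mine_reads(reads, trained_model)
        assert len(report) == 0 and counts["candidates"] == 0

    def test_ranking_deterministic(self, trained_model):
        reads, _ = am.generate_reads(
            [r.sequence for r in am.sample_peptides(am.default_profile("acp"), 3, seed=31)],
            5, 300, seed=32)
        r1, _ = mine_reads(reads, trained_model)
        r2, _ = mine_reads(reads, trained_model)
        assert r1.equals(r2)
        # sorted by score desc, ties shorter-first then lexicographic
        s = r1["score"].to_numpy()
        assert (np.diff(s) <= 1e-15).all()

    def test_candidates_are_verbatim_substrings(self, trained_model):
        reads, _ = am.generate_reads(
            [r.sequence for r in am.sample_peptides(am.default_profile("acp"), 2, seed=41)],
            3, 300, seed=42)
        frags = [f for rec in reads for f in six_frame_translate(rec, 5)]
        cands = windows_from_fragments(frags, MiningConfig())
        frag_by_key = {(f.read_id, f.frame, f.nt_start): f for f in frags}
        for cand in cands:
            for prov in cand.provenance:
                frag = frag_by_key[(prov.read_id, prov.frame, prov.frag_nt_start)]
                assert frag.peptide[prov.offset: prov.offset + prov.length] == cand.peptide

    def test_empty_read_set_rejected(self, trained_model):
        with pytest.raises(ValueError):
            mine_reads([], trained_model)


class TestDomainAnnotation:
    def test_parse_fixture(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBLOUT_FIXTURE)
        hits = parse_domtblout(p)
        assert len(hits) == 2
        h = hits[0]
        assert h.accession == "PF00046.24" and h.candidate_id == "cand1"
        # printed 1..30 becomes 0-based half-open 0..30
        assert (h.ali_start, h.ali_end) == (0, 30)

    def test_comment_only_file(self, tmp_path):
        p = tmp_path / "empty.domtblout"
        p.write_text("# nothing here\n\n")
        assert parse_domtblout(p) == []

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.domtblout"
        p.write_text("too few columns\n")
        with pytest.raises(ValueError, match=":1:"):
            parse_domtblout(p)

    def test_annotation_threshold_and_separation(self, tmp_path):
        import pandas as pd
        report = pd.DataFrame({"peptide": ["cand1", "ghost"], "length": [30, 30],
                               "score": [0.9, 0.8], "label": ["ACP", "ACP"],
                               "n_sources": [1, 1]})
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBLOUT_FIXTURE)
        hits = parse_domtblout(p)
        out = annotate_candidates(report, hits, e_max=0.01)
        assert out.loc[0, "domains"] == "Homeodomain(PF00046.24)"
        assert out.loc[1, "domains"] == ""  # i-Evalue 0.5 above the cutoff
        # annotation never touches scores or ranking
        assert out["score"].equals(report["score"])

    def test_unknown_candidate_skipped(self, tmp_path):
        import pandas as pd
        report = pd.DataFrame({"peptide": ["other"], "length": [5], "score": [0.5],
                               "label": ["nonACP"], "n_sources": [1]})
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBLOUT_FIXTURE)
        out = annotate_candidates(report, parse_domtblout(p))
        assert out.loc[0, "domains"] == ""
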