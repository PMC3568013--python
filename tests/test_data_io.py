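"""Evidence-table parsing, validation and round-trip exports."""

import numpy as np
import pandas as pd
import pytest

import apmscreen as aps
from conftest import evidence_frame

TSV_HEADER = "replicate_id\tprotein_id\tpeptide_seq\tscore\tprobability\tspectral_count\n"


def write_tsv(tmp_path, body, header=TSV_HEADER, name="ev.tsv"):
    p = tmp_path / name
    p.write_text(header + body)
    return p


class TestReadEvidenceTable:
    def test_three_rows_two_replicates(self, tmp_path):
        p = write_tsv(tmp_path,
                      "R1\tA\tPEPK\t30\t0.9\t2\n"
                      "R1\tB\tSEQK\t20\t0.5\t1\n"
                      "R2\tA\tPEPK\t25\t0.8\t1\n")
        es = aps.read_evidence_table(p, role="bait")
        assert es.k == 2
        assert len(es.evidence) == 3
        assert es.replicate_ids == ["R1", "R2"]

    def test_header_only_is_an_error(self, tmp_path):
        p = write_tsv(tmp_path, "")
        with pytest.raises(aps.ValidationError, match="no evidence rows"):
            aps.read_evidence_table(p, role="bait")

    def test_missing_column_names_the_column(self, tmp_path):
        p = write_tsv(tmp_path, "R1\tA\t30\n",
                      header="replicate_id\tprotein_id\tscore\n")
        with pytest.raises(aps.FormatError, match="peptide_seq"):
            aps.read_evidence_table(p, role="bait")

    @pytest.mark.parametrize("body,match", [
        ("R1\tA\tPEPK\t-1\t0.5\t1\n", "negative score at row 2"),
        ("R1\tA\tPEPK\t30\t0.5\t1\nR2\tA\tPEPK\t10\t1.5\t1\n",
         r"probability outside \[0, 1\] at row 3"),
        ("R1\tA\t\t30\t0.5\t1\n", "empty peptide sequence"),
    ])
    def test_row_level_validation(self, tmp_path, body, match):
        p = write_tsv(tmp_path, body)
        with pytest.raises(aps.ValidationError, match=match):
            aps.read_evidence_table(p, role="bait")

    def test_absent_probability_column_reads_as_missing(self, tmp_path):
        p = write_tsv(tmp_path, "R1\tA\tPEPK\t30\n",
                      header="replicate_id\tprotein_id\tpeptide_seq\tscore\n")
        es = aps.read_evidence_table(p, role="bait")
        assert es.evidence["probability"].isna().all()

    def test_duplicate_rows_are_kept_as_distinct_spectra(self, tmp_path):
        p = write_tsv(tmp_path, "R1\tA\tPEPK\t30\t0.9\t1\n" * 3)
        es = aps.read_evidence_table(p, role="bait")
        assert len(es.evidence) == 3

    def test_round_trip_preserves_records(self, tmp_path):
        p = write_tsv(tmp_path,
                      "R1\tA\tPEPK\t30.25\t0.9\t2\n"
                      "R2\tB\tSEQK\t20.5\t\t\n")
        es = aps.read_evidence_table(p, role="control")
        out = tmp_path / "out.tsv"
        aps.write_evidence_table(es, out)
        es2 = aps.read_evidence_table(out, role="control")
        pd.testing.assert_frame_equal(es.evidence, es2.evidence)

    def test_missing_file(self, tmp_path):
        with pytest.raises(aps.FormatError):
            aps.read_evidence_table(tmp_path / "nope.tsv", role="bait")


class TestExperimentSet:
    def test_rejects_unknown_replicates_and_duplicates(self):
        ev = evidence_frame([("R9", "A", "PEPK", 10.0)])
        with pytest.raises(aps.ValidationError, match="unknown replicates"):
            aps.ExperimentSet("bait", "", ["R1"], ev)
        with pytest.raises(aps.ValidationError, match="not unique"):
            aps.ExperimentSet("bait", "", ["R1", "R1"],
                              evidence_frame([("R1", "A", "PEPK", 10.0)]))

    def test_row_order_does_not_affect_downstream_counts(self):
        rng = np.random.default_rng(0)
        rows = [(f"R{k}", f"P{j}", "PEPK", 30.0 + j)
                for j in range(6) for k in range(3) if (j + k) % 2 == 0]
        ev = evidence_frame(rows)
        shuffled = ev.sample(frac=1.0, random_state=1).reset_index(drop=True)
        reps = ["R0", "R1", "R2"]
        m1 = aps.PresenceMatrix.from_evidence(ev, reps)
        m2 = aps.PresenceMatrix.from_evidence(shuffled, reps)
        assert (m1.matrix == m2.matrix).all()
        assert (m1.max_score == m2.max_score).all()


class TestPeptideEvidence:
    def test_invariants(self):
        aps.PeptideEvidence("R1", "A", "PEPK", 10.0, 0.5, 1)
        with pytest.raises(aps.ValidationError):
            aps.PeptideEvidence("R1", "A", "PEPK", -1.0)
        with pytest.raises(aps.ValidationError):
            aps.PeptideEvidence("R1", "A", "PEPK", 1.0, probability=1.5)
        with pytest.raises(aps.ValidationError):
            aps.PeptideEvidence("R1", "A", "", 1.0)


class TestScoreList:
    def test_posterior_range_checked(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("protein_id\tscore\nA\t0.9\nB\t1.2\n")
        aps.read_score_list(p)  # plain scores: fine
        with pytest.raises(aps.ValidationError):
            aps.read_score_list(p, is_posterior=True)


class TestWriteResults:
    def _results(self):
        bait, control, _ = aps.generate_apms(aps.SynthConfig(
            k_bait=4, k_control=6, n_specific=5, n_contaminant=30, seed=3))
        return aps.InteractionScreen(bait, control, adjust_pmin=True).fit(
            cs_cutoff=0.15, seed=3)

    def test_manifest_lists_five_files(self, tmp_path):
        res = self._results()
        manifest = res.save(tmp_path / "out")
        assert len(manifest) == 5
        assert any(m.endswith("summary.json") for m in manifest)

    def test_cs_table_round_trips(self, tmp_path):
        res = self._results()
        res.save(tmp_path / "out")
        back = pd.read_csv(tmp_path / "out" / "confidence_scores.tsv", sep="\t")
        orig = res.cs_table.frame.reset_index()
        pd.testing.assert_frame_equal(back, orig, check_exact=False)

    def test_empty_table_written_with_header_only(self, tmp_path):
        empty = pd.DataFrame(columns=["protein_id", "cs"])
        manifest = aps.write_results({"specific_preys": empty}, {"n": 0},
                                     tmp_path / "o")
        text = (tmp_path / "o" / "specific_preys.tsv").read_text()
        assert text.strip() == "protein_id\tcs"
        assert len(manifest) == 2
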