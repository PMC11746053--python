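"""Cohort ingestion, the 40-cycle cap, QC gating and diagnostic contrasts."""

import numpy as np
import pandas as pd
import pytest

from cqtriage import (
    CQ_CAP,
    CqCohort,
    default_panel,
    make_contrast,
    qc_filter,
    read_cq_table,
)
from cqtriage.cohort import write_exclusion_log
from cqtriage.errors import (
    DegenerateContrastError,
    DuplicateMeasurementError,
    ParseError,
)


def _write(tmp_path, text, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadWide:
    def test_reference_table_shape(self, ref_cohort):
        assert ref_cohort.n_samples == 9
        assert len(ref_cohort.measurements) == 45

    def test_na_cell_becomes_capped_expression_negative(self, ref_cohort):
        m = ref_cohort.measurements
        hela_mal = m[(m.sample_id == "HeLa") & (m.target == "MAL")].iloc[0]
        assert hela_mal.cq == pytest.approx(40.00)
        assert bool(hela_mal.expression_negative)

    def test_value_above_cap_is_capped(self, tmp_path):
        path = _write(tmp_path, "sample_id,diagnosis,G1\ns1,NILM,41.3\n")
        cohort = read_cq_table(path, "wide")
        row = cohort.measurements.iloc[0]
        assert row.cq == CQ_CAP and bool(row.expression_negative)

    def test_header_only_file_gives_empty_cohort(self, tmp_path):
        path = _write(tmp_path, "sample_id,diagnosis,G1\n")
        cohort = read_cq_table(path, "wide")
        assert cohort.n_samples == 0

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = _write(tmp_path, "sample_id,diagnosis,G1\ns1,NILM,oops\n")
        with pytest.raises(ParseError, match="G1"):
            read_cq_table(path, "wide")

    def test_diagnosis_case_insensitive(self, tmp_path):
        path = _write(tmp_path, "sample_id,diagnosis,G1\ns1,hsil,30\n")
        assert read_cq_table(path, "wide").diagnosis_of("s1") == "HSIL"

    def test_duplicate_sample_rejected(self, tmp_path):
        path = _write(
            tmp_path, "sample_id,diagnosis,G1\ns1,NILM,30\ns1,NILM,31\n"
        )
        with pytest.raises(DuplicateMeasurementError):
            read_cq_table(path, "wide")


class TestReadLong:
    def test_multiple_replicates(self, tmp_path):
        text = (
            "sample_id,diagnosis,target,replicate,cq\n"
            "s1,NILM,G1,1,30.1\ns1,NILM,G1,2,30.3\n"
        )
        cohort = read_cq_table(_write(tmp_path, text), "long")
        assert len(cohort.measurements) == 2
        assert cohort.mean_cq().at["s1", "G1"] == pytest.approx(30.2)

    def test_duplicate_replicate_rejected(self, tmp_path):
        text = (
            "sample_id,diagnosis,target,replicate,cq\n"
            "s1,NILM,G1,1,30.1\ns1,NILM,G1,1,30.3\n"
        )
        with pytest.raises(DuplicateMeasurementError):
            read_cq_table(_write(tmp_path, text), "long")


@pytest.mark.parametrize("format", ["wide", "long"])
def test_round_trip_preserves_values_and_flags(tmp_path, ref_cohort, format):
    path = tmp_path / f"rt.{format}.csv"
    ref_cohort.write_csv(path, format=format)
    back = read_cq_table(path, format)
    merged = ref_cohort.measurements.merge(
        back.measurements, on=["sample_id", "target", "replicate"], suffixes=("", "_rt")
    )
    assert len(merged) == len(ref_cohort.measurements)
    assert np.allclose(merged.cq, merged.cq_rt, atol=0.005)
    assert (merged.expression_negative == merged.expression_negative_rt).all()


class TestQcFilter:
    @staticmethod
    def _cohort(hmbs, pgk1):
        frame = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "diagnosis": ["NILM"],
                "HMBS": [str(hmbs)],
                "PGK1": [str(pgk1)],
            }
        )
        return CqCohort.from_wide_frame(frame, panel=default_panel())

    def test_dna_boundary_inclusive(self):
        filtered, log = qc_filter(self._cohort(35.0, 30.0))
        assert filtered.n_samples == 0
        assert log == [("s1", "excluded_dna", 35.0)]

    def test_just_below_both_thresholds_passes(self):
        filtered, log = qc_filter(self._cohort(34.99, 34.99))
        assert filtered.n_samples == 1 and log == []

    def test_dna_checked_before_rna(self):
        _, log = qc_filter(self._cohort(36.0, 36.0))
        assert log[0][1] == "excluded_dna"

    def test_rna_exclusion(self):
        _, log = qc_filter(self._cohort(30.0, 36.0))
        assert log == [("s1", "excluded_rna", 36.0)]

    def test_idempotent_on_synthetic_cohort(self, cohort):
        filtered, _ = qc_filter(cohort)
        again, log2 = qc_filter(filtered)
        assert log2 == []
        assert again.sample_ids == filtered.sample_ids

    def test_exclusion_log_written_as_tsv(self, tmp_path):
        _, log = qc_filter(self._cohort(36.0, 30.0))
        path = tmp_path / "log.tsv"
        write_exclusion_log(log, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "sample_id\treason\tcq"
        assert lines[1].split("\t") == ["s1", "excluded_dna", "36.00"]


class TestMakeContrast:
    @staticmethod
    def _study_cohort():
        rows = []
        for group, n in (("NILM", 61), ("LSIL", 28), ("HSIL", 42), ("CC", 36)):
            for i in range(n):
                rows.append((f"{group}{i}", group, "30.0"))
        frame = pd.DataFrame(rows, columns=["sample_id", "diagnosis", "G1"])
        return CqCohort.from_wide_frame(frame)

    def test_screening_contrast_counts(self):
        labels, retained, dropped = make_contrast(
            self._study_cohort(), "LSILminus_vs_HSILplus"
        )
        assert int(labels.sum()) == 78
        assert int((labels == 0).sum()) == 89
        assert dropped == []

    def test_nilm_vs_cc_drops_intermediate_grades(self):
        labels, retained, dropped = make_contrast(self._study_cohort(), "NILM_vs_CC")
        assert int(labels.sum()) == 36
        assert int((labels == 0).sum()) == 61
        assert len(dropped) == 70

    def test_single_group_is_degenerate(self):
        frame = pd.DataFrame(
            {"sample_id": ["a", "b"], "diagnosis": ["NILM", "NILM"], "G1": ["30", "31"]}
        )
        with pytest.raises(DegenerateContrastError):
            make_contrast(CqCohort.from_wide_frame(frame), "NILM_vs_CC")
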