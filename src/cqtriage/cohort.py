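"""Cq cohorts: per-sample, per-target quantification cycles with diagnoses.

The universal input of the pipeline is a cohort of cytological specimens,
each with a Bethesda diagnosis (NILM / LSIL / HSIL / CC, or unknown for
cell lines and unlabeled material) and one or more replicate Cq values per
assay target. Instrument values above the 40-cycle detection limit (or
non-amplifying wells) are *expression-negative* and stored capped at exactly
40.00 so that downstream ΔCq features stay finite.

Two CSV dialects are supported:

* wide  — ``sample_id, diagnosis, <target>, <target>, ...`` one replicate
  per cell; expression-negative wells written as ``N/A``;
* long  — ``sample_id, diagnosis, target, replicate, cq,
  expression_negative`` with any number of replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateContrastError,
    DuplicateMeasurementError,
    ParseError,
)
from .panel import BiomarkerPanel, Role

#: Detection limit of the instrument in PCR cycles; values beyond it are
#: expression-negative and stored at exactly this cap.
CQ_CAP = 40.0

#: Default sample-adequacy exclusion threshold (inclusive), in Cq cycles.
ADEQUACY_MAX_CQ = 35.0


class Diagnosis(str, Enum):
    NILM = "NILM"
    LSIL = "LSIL"
    HSIL = "HSIL"
    CC = "CC"
    UNKNOWN = "UNKNOWN"


class QCStatus(str, Enum):
    PASS = "pass"
    EXCLUDED_DNA = "excluded_dna"
    EXCLUDED_RNA = "excluded_rna"


_MEASUREMENT_COLS = ["sample_id", "target", "replicate", "cq", "expression_negative"]


def _parse_diagnosis(value, row=None) -> str:
    text = str(value).strip().upper()
    if text in ("", "NAN", "NONE", "UNKNOWN", "NA"):
        return Diagnosis.UNKNOWN.value
    try:
        return Diagnosis(text).value
    except ValueError:
        where = f" (row {row})" if row is not None else ""
        raise ParseError(f"unrecognized diagnosis {value!r}{where}") from None


def _parse_cq_cell(raw, row, column) -> tuple[float, bool]:
    """Parse one Cq cell -> (cq, expression_negative)."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return CQ_CAP, True
    text = str(raw).strip()
    if text == "" or text.upper() in ("N/A", "NA", "NAN"):
        return CQ_CAP, True
    try:
        value = float(text)
    except ValueError:
        raise ParseError(
            f"malformed Cq value {raw!r} at row {row}, column {column!r}"
        ) from None
    if value > CQ_CAP:
        return CQ_CAP, True
    if value <= 0:
        raise ParseError(
            f"Cq must be positive, got {value} at row {row}, column {column!r}"
        )
    return value, False


@dataclass
class CqCohort:
    """Samples × targets Cq matrix in long form, plus per-sample metadata.

    ``measurements`` columns: sample_id, target, replicate (int ≥ 1), cq,
    expression_negative. ``samples`` is indexed by sample_id with columns
    ``diagnosis`` and ``qc_status``.
    """

    measurements: pd.DataFrame
    samples: pd.DataFrame
    panel: BiomarkerPanel | None = None
    exclusion_log: list = field(default_factory=list)

    def __post_init__(self):
        m = self.measurements
        if list(m.columns) != _MEASUREMENT_COLS:
            self.measurements = m = m.reindex(columns=_MEASUREMENT_COLS)
        dup = m.duplicated(subset=["sample_id", "target", "replicate"])
        if dup.any():
            offending = m.loc[dup, ["sample_id", "target", "replicate"]]
            raise DuplicateMeasurementError(
                "duplicate (sample, target, replicate) rows: "
                + offending.to_string(index=False)
            )
        if (m["cq"] > CQ_CAP + 1e-12).any():
            raise DataError("stored Cq values must not exceed the 40.00 cap")

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def targets(self) -> list[str]:
        return list(pd.unique(self.measurements["target"]))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def diagnosis_of(self, sample_id: str) -> str:
        return self.samples.at[sample_id, "diagnosis"]

    def subset(self, sample_ids) -> "CqCohort":
        keep = list(sample_ids)
        return CqCohort(
            self.measurements[self.measurements["sample_id"].isin(keep)].reset_index(
                drop=True
            ),
            self.samples.loc[keep].copy(),
            panel=self.panel,
        )

    def mean_cq(self) -> pd.DataFrame:
        """Samples × targets matrix of replicate-averaged Cq values."""
        wide = self.measurements.pivot_table(
            index="sample_id", columns="target", values="cq", aggfunc="mean"
        )
        return wide.reindex(index=self.sample_ids)

    # -- construction --------------------------------------------------------

    @classmethod
    def from_wide_frame(
        cls, frame: pd.DataFrame, panel: BiomarkerPanel | None = None
    ) -> "CqCohort":
        required = {"sample_id", "diagnosis"}
        missing = required - set(frame.columns)
        if missing:
            raise ParseError(f"wide table missing columns: {sorted(missing)}")
        target_cols = [c for c in frame.columns if c not in required]
        records = []
        sample_rows = []
        for row_idx, row in frame.iterrows():
            sid = str(row["sample_id"]).strip()
            sample_rows.append((sid, _parse_diagnosis(row["diagnosis"], row_idx)))
            for col in target_cols:
                cq, neg = _parse_cq_cell(row[col], row_idx, col)
                records.append((sid, col, 1, cq, neg))
        measurements = pd.DataFrame(records, columns=_MEASUREMENT_COLS)
        samples = pd.DataFrame(
            sample_rows, columns=["sample_id", "diagnosis"]
        ).set_index("sample_id")
        if samples.index.duplicated().any():
            dupes = sorted(samples.index[samples.index.duplicated()])
            raise DuplicateMeasurementError(f"duplicate sample rows: {dupes}")
        samples["qc_status"] = QCStatus.PASS.value
        return cls(measurements, samples, panel=panel)

    @classmethod
    def from_long_frame(
        cls, frame: pd.DataFrame, panel: BiomarkerPanel | None = None
    ) -> "CqCohort":
        required = {"sample_id", "diagnosis", "target", "replicate", "cq"}
        missing = required - set(frame.columns)
        if missing:
            raise ParseError(f"long table missing columns: {sorted(missing)}")
        records = []
        diag_by_sample: dict[str, str] = {}
        order: list[str] = []
        for row_idx, row in frame.iterrows():
            sid = str(row["sample_id"]).strip()
            diagnosis = _parse_diagnosis(row["diagnosis"], row_idx)
            if sid not in diag_by_sample:
                diag_by_sample[sid] = diagnosis
                order.append(sid)
            try:
                replicate = int(row["replicate"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"malformed replicate {row['replicate']!r} at row {row_idx}"
                ) from None
            if replicate < 1:
                raise ParseError(f"replicate index must be ≥ 1 at row {row_idx}")
            cq, neg = _parse_cq_cell(row["cq"], row_idx, "cq")
            if "expression_negative" in frame.columns and not neg:
                flag = str(row["expression_negative"]).strip().lower()
                if flag in ("true", "1", "yes"):
                    neg, cq = True, CQ_CAP
            records.append((sid, str(row["target"]).strip(), replicate, cq, neg))
        measurements = pd.DataFrame(records, columns=_MEASUREMENT_COLS)
        samples = pd.DataFrame(
            {"diagnosis": [diag_by_sample[s] for s in order]},
            index=pd.Index(order, name="sample_id"),
        )
        samples["qc_status"] = QCStatus.PASS.value
        return cls(measurements, samples, panel=panel)

    # -- persistence ---------------------------------------------------------

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide table with one replicate per cell; requires single-replicate data."""
        if (self.measurements["replicate"] != 1).any():
            raise DataError("wide format supports single-replicate cohorts only")
        out = pd.DataFrame({"sample_id": self.sample_ids})
        out["diagnosis"] = [self.diagnosis_of(s) for s in self.sample_ids]
        pivot_cq = self.measurements.pivot(
            index="sample_id", columns="target", values="cq"
        ).reindex(self.sample_ids)
        pivot_neg = self.measurements.pivot(
            index="sample_id", columns="target", values="expression_negative"
        ).reindex(self.sample_ids)
        for target in pivot_cq.columns:
            cells = []
            for sid in self.sample_ids:
                if bool(pivot_neg.at[sid, target]):
                    cells.append("N/A")
                else:
                    cells.append(f"{pivot_cq.at[sid, target]:.2f}")
            out[target] = cells
        return out

    def to_long_frame(self) -> pd.DataFrame:
        out = self.measurements.copy()
        out.insert(1, "diagnosis", out["sample_id"].map(self.samples["diagnosis"]))
        out["cq"] = out["cq"].map(lambda v: f"{v:.2f}")
        return out

    def write_csv(self, path, format: str = "wide") -> None:
        frame = self.to_wide_frame() if format == "wide" else self.to_long_frame()
        frame.to_csv(path, index=False)


def read_cq_table(
    path, format: str = "wide", panel: BiomarkerPanel | None = None
) -> CqCohort:
    """Read a Cq cohort from a wide or long CSV file.

    Empty cells, ``N/A`` and raw values above 40 become expression-negative
    measurements capped at 40.00. Diagnosis strings are case-insensitive.
    """
    path = Path(path)
    if format not in ("wide", "long"):
        raise ConfigurationError(f"unknown table format {format!r}")
    frame = pd.read_csv(path, dtype=str)
    if format == "wide":
        return CqCohort.from_wide_frame(frame, panel=panel)
    return CqCohort.from_long_frame(frame, panel=panel)


# -- QC gating ----------------------------------------------------------------


def qc_filter(
    cohort: CqCohort,
    dna_max: float = ADEQUACY_MAX_CQ,
    rna_max: float = ADEQUACY_MAX_CQ,
) -> tuple[CqCohort, list[tuple[str, str, float]]]:
    """Exclude samples with insufficient DNA or RNA template.

    A sample is excluded when its DNA-adequacy control (HMBS in the default
    panel) has mean Cq ≥ ``dna_max``, or failing that, when its RNA-adequacy
    control (PGK1) has mean Cq ≥ ``rna_max``; the DNA check takes precedence.
    Thresholds are inclusive. Returns the filtered cohort and an exclusion
    log of ``(sample_id, reason, offending mean Cq)`` tuples.
    """
    if cohort.panel is None:
        raise ConfigurationError("qc_filter requires a cohort with a panel")
    dna_target = cohort.panel.adequacy_target(Role.DNA_ADEQUACY).name
    rna_target = cohort.panel.adequacy_target(Role.RNA_ADEQUACY).name
    mean_cq = cohort.mean_cq()
    for target, kind in ((dna_target, "DNA"), (rna_target, "RNA")):
        if target not in mean_cq.columns:
            raise ConfigurationError(
                f"{kind}-adequacy target {target!r} absent from cohort"
            )
    log: list[tuple[str, str, float]] = []
    status = {}
    for sid in cohort.sample_ids:
        dna_cq = mean_cq.at[sid, dna_target]
        rna_cq = mean_cq.at[sid, rna_target]
        if not np.isnan(dna_cq) and dna_cq >= dna_max:
            status[sid] = QCStatus.EXCLUDED_DNA.value
            log.append((sid, QCStatus.EXCLUDED_DNA.value, float(dna_cq)))
        elif not np.isnan(rna_cq) and rna_cq >= rna_max:
            status[sid] = QCStatus.EXCLUDED_RNA.value
            log.append((sid, QCStatus.EXCLUDED_RNA.value, float(rna_cq)))
        else:
            status[sid] = QCStatus.PASS.value
    keep = [s for s in cohort.sample_ids if status[s] == QCStatus.PASS.value]
    filtered = cohort.subset(keep)
    filtered.exclusion_log = log
    annotated = cohort.samples.copy()
    annotated["qc_status"] = [status[s] for s in cohort.sample_ids]
    cohort.samples = annotated
    return filtered, log


def write_exclusion_log(log, path) -> None:
    """Tab-separated exclusion log: sample_id, reason, offending Cq."""
    with open(path, "w") as fh:
        fh.write("sample_id\treason\tcq\n")
        for sid, reason, cq in log:
            fh.write(f"{sid}\t{reason}\t{cq:.2f}\n")


# -- diagnostic contrasts ------------------------------------------------------


class ContrastScheme(str, Enum):
    #: NILM specimens vs invasive cancer; LSIL and HSIL are dropped.
    NILM_VS_CC = "NILM_vs_CC"
    #: ≤LSIL (NILM + LSIL) vs ≥HSIL (HSIL + CC) — the screening contrast.
    LSILMINUS_VS_HSILPLUS = "LSILminus_vs_HSILplus"


@dataclass(frozen=True)
class Contrast:
    scheme: ContrastScheme
    positive_group: frozenset
    negative_group: frozenset

    @classmethod
    def from_scheme(cls, scheme) -> "Contrast":
        scheme = ContrastScheme(scheme)
        if scheme is ContrastScheme.NILM_VS_CC:
            return cls(scheme, frozenset({"CC"}), frozenset({"NILM"}))
        return cls(scheme, frozenset({"HSIL", "CC"}), frozenset({"NILM", "LSIL"}))


def make_contrast(
    cohort: CqCohort, scheme
) -> tuple[pd.Series, list[str], list[str]]:
    """Binary labels for a classification contrast.

    Returns ``(labels, retained, dropped)`` where labels is a 0/1 Series
    indexed by sample_id (1 = positive group), retained lists the samples in
    either group in cohort order, and dropped lists samples outside both.
    """
    contrast = Contrast.from_scheme(scheme)
    labels = {}
    dropped = []
    for sid in cohort.sample_ids:
        diagnosis = cohort.diagnosis_of(sid)
        if diagnosis in contrast.positive_group:
            labels[sid] = 1
        elif diagnosis in contrast.negative_group:
            labels[sid] = 0
        else:
            dropped.append(sid)
    retained = [s for s in cohort.sample_ids if s in labels]
    values = pd.Series([labels[s] for s in retained], index=retained, dtype=int)
    n_pos = int(values.sum())
    if n_pos == 0 or n_pos == len(values):
        raise DegenerateContrastError(
            f"contrast {contrast.scheme.value} has {n_pos} positives of "
            f"{len(values)} retained samples"
        )
    return values, retained, dropped
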