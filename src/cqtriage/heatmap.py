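"""Aberrancy heat-map scaling and assembly.

Each biomarker column (normalized mRNA or miRNA level, HPV load,
lactobacilli fraction) is mapped onto a common 0–100 aberrancy scale with a
two-segment linear transform anchored at the column's minimum (→ 0), median
P50 (→ 50, the white point) and maximum (→ 100). Markers whose values *fall*
with disease (downregulated mRNAs, lactobacilli) are inverted on the 0–100
scale (u → 100 − u) so that red always means aberrant.

Rows are grouped for display: discrepant samples first — false negatives
(cytology ≥HSIL but classifier low-risk) then false positives — followed by
the concordant NILM, LSIL, HSIL and CC blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateScaleError

GROUP_ORDER = ["FN", "FP", "NILM", "LSIL", "HSIL", "CC"]


@dataclass(frozen=True)
class HeatmapScale:
    biomarker: str
    min_value: float
    p50: float
    max_value: float
    invert: bool

    @property
    def degenerate(self) -> bool:
        return self.min_value == self.max_value


def fit_scale(values, invert: bool, biomarker: str = "") -> HeatmapScale:
    """Anchor a column scale at the min, median and max of its values."""
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 3:
        raise DegenerateScaleError(
            f"scale for {biomarker!r} needs ≥ 3 distinct values"
        )
    return HeatmapScale(
        biomarker,
        float(values.min()),
        float(np.median(values)),
        float(values.max()),
        invert,
    )


def scale_value(scale: HeatmapScale, v: float) -> float:
    """Map a native value onto [0, 100] with the P50 white point at 50.

    Piecewise linear: [min, p50] → [0, 50] and [p50, max] → [50, 100],
    clipped. A flat segment (p50 equal to an extreme) maps onto its P50
    endpoint, keeping the white point fixed at 50. Inversion flips the
    mapped value u to 100 − u.
    """
    if scale.degenerate:
        raise DegenerateScaleError(f"degenerate scale for {scale.biomarker!r}")
    v = float(np.clip(v, scale.min_value, scale.max_value))
    if v <= scale.p50:
        if scale.p50 == scale.min_value:
            u = 50.0
        else:
            u = 50.0 * (v - scale.min_value) / (scale.p50 - scale.min_value)
    else:
        if scale.p50 == scale.max_value:
            u = 50.0
        else:
            u = 50.0 + 50.0 * (v - scale.p50) / (scale.max_value - scale.p50)
    if scale.invert:
        u = 100.0 - u
    return float(u)


def build_heatmap(
    values: pd.DataFrame,
    diagnoses: pd.Series,
    calls: pd.Series,
    invert_flags: dict,
) -> tuple[pd.DataFrame, pd.Series, list[HeatmapScale]]:
    """Assemble the grouped 0–100 heat-map matrix.

    ``values`` is samples × biomarkers on each biomarker's native normalized
    scale; ``diagnoses`` Bethesda labels; ``calls`` the classifier risk
    calls (low_risk / increased_risk); ``invert_flags`` maps biomarker name
    to its inversion flag. Returns the scaled matrix (rows reordered into
    the FN / FP / NILM / LSIL / HSIL / CC blocks), the per-sample block
    label, and the fitted column scales.
    """
    missing = [s for s in values.index if s not in diagnoses or s not in calls]
    if missing:
        raise DataError(f"samples missing diagnosis or call: {missing}")
    unknown = set(values.columns) - set(invert_flags)
    if unknown:
        raise DataError(f"biomarkers without invert flag: {sorted(unknown)}")

    scales = [
        fit_scale(values[c].to_numpy(), bool(invert_flags[c]), c)
        for c in values.columns
    ]
    scaled = pd.DataFrame(
        {
            s.biomarker: [scale_value(s, v) for v in values[s.biomarker]]
            for s in scales
        },
        index=values.index,
    )

    def _block(sid: str) -> str:
        diagnosis = diagnoses[sid]
        call = calls[sid]
        severe = diagnosis in ("HSIL", "CC")
        if severe and call == "low_risk":
            return "FN"
        if not severe and call == "increased_risk":
            return "FP"
        return diagnosis

    blocks = pd.Series({sid: _block(sid) for sid in values.index})
    bad = sorted(set(blocks) - set(GROUP_ORDER))
    if bad:
        raise DataError(f"samples with unassignable groups: {bad}")
    order = [
        sid
        for group in GROUP_ORDER
        for sid in values.index
        if blocks[sid] == group
    ]
    return scaled.loc[order], blocks.loc[order], scales


def write_heatmap(matrix: pd.DataFrame, blocks: pd.Series, scales, path, meta_path=None):
    out = matrix.copy()
    out.insert(0, "group", blocks)
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.2f")
    if meta_path is not None:
        meta = pd.DataFrame(
            [
                (s.biomarker, s.invert, s.min_value, s.p50, s.max_value)
                for s in scales
            ],
            columns=["biomarker", "invert", "min", "p50", "max"],
        )
        meta.to_csv(meta_path, index=False)
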