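"""Bundled reference data: the prototype-assay worked example.

Nine specimens measured with the two-tube multiplex prototype test — two
NILM, two LSIL, two HSIL and two CC cytological smears plus cultured HeLa
cells — with replicate-averaged Cq values for the five classifier-1 mRNAs,
the published DF value of classifier 1 and the resulting risk call. In the
HeLa cell line the three downregulated epithelial mRNAs do not amplify and
enter at the 40.00 expression-negative cap.

The classifier-1 weights are not published; :func:`recover_reference_weights`
reconstructs them by ordinary least squares, exploiting that the nine
(feature, DF) rows are consistent with a single affine function to within
rounding of the printed values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import LinearClassifier
from .cohort import CqCohort
from .pairs import PairDef, feature_matrix

#: Classifier-1 pair set: four downregulated mRNAs each paired with CDKN2A.
CLASSIFIER1_PAIRS = [
    PairDef("MAL", "CDKN2A", "DU"),
    PairDef("TMPRSS4", "CDKN2A", "DU"),
    PairDef("CRNN", "CDKN2A", "DU"),
    PairDef("ECM1", "CDKN2A", "DU"),
]

#: sample -> (diagnosis, Cq CDKN2A, MAL, TMPRSS4, CRNN, ECM1, DF, CV%, call)
_REFERENCE_ROWS = [
    ("NILM-1", "NILM", 34.66, 31.09, 32.07, 33.35, 29.69, -0.1797, 10.7, "low_risk"),
    ("NILM-2", "NILM", 33.20, 30.67, 28.85, 31.38, 29.07, -0.2377, 12.4, "low_risk"),
    ("LSIL-1", "LSIL", 35.57, 32.36, 32.02, 32.75, 31.34, -0.2781, 12.6, "low_risk"),
    ("LSIL-2", "LSIL", 31.79, 25.08, 29.80, 25.57, 24.64, -0.6364, 7.1, "low_risk"),
    ("HSIL-1", "HSIL", 26.43, 25.83, 27.03, 29.16, 25.23, 0.5122, 3.2, "increased_risk"),
    ("HSIL-2", "HSIL", 25.07, 29.28, 25.56, 31.20, 23.79, 0.8935, 1.2, "increased_risk"),
    ("CC-1", "CC", 27.02, 28.49, 26.13, 32.37, 25.36, 0.6370, 2.8, "increased_risk"),
    ("CC-2", "CC", 30.22, 27.87, 32.47, 28.84, 27.44, 0.2475, 8.9, "increased_risk"),
    ("HeLa", "UNKNOWN", 20.44, 40.00, 40.00, 40.00, 28.85, 3.8160, 0.3, "increased_risk"),
]

_TARGETS = ["CDKN2A", "MAL", "TMPRSS4", "CRNN", "ECM1"]


def reference_frame() -> pd.DataFrame:
    """The worked-example table as a DataFrame indexed by sample_id."""
    frame = pd.DataFrame(
        _REFERENCE_ROWS,
        columns=["sample_id", "diagnosis", *_TARGETS, "df", "cv_percent", "call"],
    )
    return frame.set_index("sample_id")


def reference_cohort() -> CqCohort:
    """The nine reference specimens as a CqCohort (HeLa N/A wells capped)."""
    frame = reference_frame()
    wide = frame.reset_index()[["sample_id", "diagnosis", *_TARGETS]].astype(str)
    # the three non-amplifying HeLa mRNAs are expression-negative
    for target in ("MAL", "TMPRSS4", "CRNN"):
        wide.loc[wide["sample_id"] == "HeLa", target] = "N/A"
    return CqCohort.from_wide_frame(wide)


def reference_df() -> pd.Series:
    """Published classifier-1 DF values of the nine specimens."""
    return reference_frame()["df"]


def recover_reference_weights(
    exclude: str | None = None,
) -> tuple[LinearClassifier, float]:
    """Reconstruct classifier-1 weights from the worked-example table.

    Ordinary least squares of the published DF values on the four pair
    features over the nine specimens (optionally holding one out) yields an
    intercept and four weights; the returned residual is the maximum
    absolute misfit over the samples used, a consistency check that the
    published values derive from a single affine decision function.
    """
    cohort = reference_cohort()
    features = feature_matrix(cohort, CLASSIFIER1_PAIRS)
    target = reference_df()
    if exclude is not None:
        features = features.drop(index=exclude)
        target = target.drop(index=exclude)
    design = np.column_stack(
        [np.ones(len(features)), features.to_numpy(dtype=float)]
    )
    coef, *_ = np.linalg.lstsq(design, target.to_numpy(dtype=float), rcond=None)
    clf = LinearClassifier(
        CLASSIFIER1_PAIRS,
        coef[1:],
        float(coef[0]),
        contrast="LSILminus_vs_HSILplus",
    )
    residual = float(np.abs(design @ coef - target.to_numpy()).max())
    return clf, residual
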