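"""Exhaustive pair screening: rank every ΔCq pair by discriminatory power."""

from __future__ import annotations

import pandas as pd

from .cohort import ContrastScheme, CqCohort, make_contrast
from .errors import ConfigurationError
from .evaluation import bonferroni_threshold, mann_whitney, roc_auc
from .pairs import enumerate_pairs, feature_matrix


def screen_pairs(
    cohort: CqCohort,
    include_housekeeping: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """AUC and Mann–Whitney p for every pair under both contrasts.

    One row per enumerated pair with, per contrast, the ROC AUC of the
    ΔCq feature and the two-sided Mann–Whitney p-value, plus the Bonferroni
    per-comparison threshold for the full screen (pairs × contrasts) and a
    significance flag. Discriminatory power is orientation-free (a trained
    weight absorbs the sign), so the reported AUC is max(a, 1 − a) of the
    raw feature AUC ``a``, with the feature's direction recorded as +1 when
    ΔCq rises with severity and −1 when it falls. Sorted by AUC on the
    ≤LSIL vs ≥HSIL contrast, descending.
    """
    if cohort.panel is None:
        raise ConfigurationError("screen_pairs requires a cohort with a panel")
    pairs = enumerate_pairs(cohort.panel, include_housekeeping=include_housekeeping)
    features = feature_matrix(cohort, pairs)
    schemes = [ContrastScheme.LSILMINUS_VS_HSILPLUS, ContrastScheme.NILM_VS_CC]
    threshold = bonferroni_threshold(alpha, len(pairs) * len(schemes))
    rows = []
    for pair in pairs:
        row = {"pair": pair.name, "pair_type": pair.pair_type}
        for scheme in schemes:
            labels, retained, _ = make_contrast(cohort, scheme)
            values = features.loc[retained, pair.name]
            auc = roc_auc(values, labels)
            test = mann_whitney(
                values[labels == 1], values[labels == 0], label=pair.name
            )
            tag = "hsil" if scheme is ContrastScheme.LSILMINUS_VS_HSILPLUS else "cc"
            row[f"auc_{tag}"] = max(auc, 1.0 - auc)
            row[f"direction_{tag}"] = 1 if auc >= 0.5 else -1
            row[f"p_{tag}"] = test.p_value
            row[f"significant_{tag}"] = test.p_value < threshold
        row["bonferroni_threshold"] = threshold
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("auc_hsil", ascending=False)
    return out.reset_index(drop=True)
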