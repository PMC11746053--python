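"""ΔCq pair-ratio features.

The core normalization trick of the assay: instead of referencing every
mRNA to a housekeeping gene, two oppositely deregulated mRNAs are combined
into a pair (X; Y) and the feature is

    ΔCq(X, Y) = Cq(Y) − Cq(X) = log2( C(X) / C(Y) )

i.e. the log2 concentration ratio of X over Y. For a pair of one down- and
one up-regulated mRNA the two expression shifts add, amplifying the disease
signal without consuming a housekeeping channel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .cohort import CqCohort
from .errors import ConfigurationError, MissingFeatureError
from .panel import BiomarkerPanel, Regulation, Role


def delta_cq(cq_x: float, cq_y: float) -> float:
    """ΔCq(X, Y) = Cq(Y) − Cq(X); antisymmetric under swapping X and Y."""
    return cq_y - cq_x


def relative_expression(cq_target: float, cq_reference: float) -> float:
    """Fold expression of *target* relative to *reference*: 2^−(Cq_t − Cq_r).

    Assumes perfect doubling per cycle, so one cycle of delay halves the
    estimated concentration.
    """
    return 2.0 ** (-(cq_target - cq_reference))


#: Pair-type codes by (regulation of X, regulation of Y) after
#: canonical orientation. U = up, D = down, H = housekeeping.
PairType = str

_REG_CODE = {
    Regulation.UP: "U",
    Regulation.DOWN: "D",
    Regulation.HOUSEKEEPING: "H",
}


@dataclass(frozen=True)
class PairDef:
    """A canonical, oriented biomarker pair (X first, the ratio numerator)."""

    x_target: str
    y_target: str
    pair_type: PairType

    def __post_init__(self):
        if self.x_target == self.y_target:
            raise ConfigurationError("a pair must combine two distinct targets")

    @property
    def name(self) -> str:
        return f"{self.x_target}-{self.y_target}"

    def swapped(self) -> "PairDef":
        """The same pair with reversed orientation (feature sign flips)."""
        return PairDef(self.y_target, self.x_target, self.pair_type[::-1])


def _canonical_orientation(a, b) -> tuple:
    """Order two panel targets into the conventional X-Y orientation.

    Down-regulated mRNAs are named first (DU pairs, e.g. MAL-CDKN2A);
    biomarkers precede housekeeping references (UH / DH); within the same
    regulation class the panel order is kept.
    """
    rank = {Regulation.DOWN: 0, Regulation.UP: 1, Regulation.HOUSEKEEPING: 2}
    if rank[a.regulation] <= rank[b.regulation]:
        return a, b
    return b, a


def enumerate_pairs(
    panel: BiomarkerPanel, include_housekeeping: bool = True
) -> list[PairDef]:
    """All unordered target pairs of the panel, canonically oriented.

    Eligible targets are the diagnostic biomarkers plus, when
    ``include_housekeeping`` is set, the RNA-adequacy housekeeping mRNA
    (the DNA-adequacy control gauges genomic template, not expression, and
    never enters pair features). For k eligible targets, k(k−1)/2 pairs.
    Housekeeping–housekeeping pairs would be typed HH and are
    non-diagnostic; the default panel has only one eligible housekeeping
    target so none arise.
    """
    eligible = panel.by_role(Role.BIOMARKER)
    if include_housekeeping:
        eligible += panel.by_role(Role.RNA_ADEQUACY)
    if len(eligible) < 2:
        raise ConfigurationError("pair enumeration needs at least 2 eligible targets")
    pairs = []
    for a, b in itertools.combinations(eligible, 2):
        x, y = _canonical_orientation(a, b)
        pair_type = _REG_CODE[x.regulation] + _REG_CODE[y.regulation]
        pairs.append(PairDef(x.name, y.name, pair_type))
    return pairs


def feature_matrix(
    cohort: CqCohort,
    pairs: list[PairDef],
    replicate_policy: str = "mean_cq",
) -> pd.DataFrame:
    """Samples × pairs matrix of ΔCq features.

    ``mean_cq`` (default) averages replicate Cq per target before
    differencing — the geometric mean on the concentration scale.
    Expression-negative measurements enter at the 40.00 cap.
    """
    if replicate_policy != "mean_cq":
        raise ConfigurationError(f"unknown replicate policy {replicate_policy!r}")
    if cohort.n_samples == 0:
        out = pd.DataFrame(columns=[p.name for p in pairs], dtype=float)
        out.index.name = "sample_id"
        return out
    mean_cq = cohort.mean_cq()
    needed = {p.x_target for p in pairs} | {p.y_target for p in pairs}
    missing_targets = needed - set(mean_cq.columns)
    if missing_targets:
        raise MissingFeatureError(
            f"targets absent from cohort: {sorted(missing_targets)}"
        )
    incomplete = mean_cq[sorted(needed)].isna()
    if incomplete.any().any():
        bad = sorted(incomplete.index[incomplete.any(axis=1)])
        raise MissingFeatureError(f"samples missing pair targets: {bad}")
    data = {
        p.name: mean_cq[p.y_target] - mean_cq[p.x_target] for p in pairs
    }
    out = pd.DataFrame(data, index=mean_cq.index)
    out.index.name = "sample_id"
    return out


def write_feature_matrix(features: pd.DataFrame, cohort: CqCohort, path) -> None:
    out = features.copy()
    out.insert(0, "diagnosis", [cohort.diagnosis_of(s) for s in out.index])
    out.to_csv(path)
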