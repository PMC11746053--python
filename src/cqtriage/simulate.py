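"""Synthetic Cq cohort generator.

Emulates the statistical structure of a cervical-screening RT-qPCR study:
four diagnosis groups (default sizes 61 NILM / 28 LSIL / 42 HSIL / 36 CC)
with per-target group mean Cq values that shift monotonically with lesion
severity — down for upregulated mRNAs (more template, earlier
amplification), up for downregulated ones, flat for housekeeping controls.

The noise model is Gaussian on the Cq scale (the log2 concentration scale,
the standard qPCR error model), split into a biological within-group
component and a technical replicate component. A per-sample latent severity
score couples the biomarker shifts to the optional covariates (HPV viral
load on the 2^-ΔCq relative scale, and lactobacilli fraction of total
bacterial DNA) so that the decision function correlates positively with
viral load and negatively with lactobacilli dominance, as observed
clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CQ_CAP, Contrast, CqCohort, QCStatus
from .errors import ConfigurationError
from .panel import BiomarkerPanel, Regulation, default_panel

GROUPS = ["NILM", "LSIL", "HSIL", "CC"]

#: severity direction of each regulation class on the Cq scale:
#: severe disease lowers Cq of upregulated targets and raises it for
#: downregulated ones.
_DIRECTION = {Regulation.UP: -1.0, Regulation.DOWN: +1.0, Regulation.HOUSEKEEPING: 0.0}

_DEFAULT_MEANS = {
    #            NILM  LSIL  HSIL   CC
    "CDKN2A":   (34.0, 32.5, 27.5, 26.5),
    "TOP2A":    (33.5, 32.5, 30.0, 28.5),
    "MAL":      (29.5, 30.0, 31.5, 32.5),
    "CRNN":     (31.5, 32.0, 33.5, 34.5),
    "CRISP3":   (30.0, 30.5, 32.0, 33.0),
    "SPINK5":   (29.5, 30.0, 31.0, 32.0),
    "ECM1":     (28.5, 29.0, 30.0, 30.5),
    "TMPRSS4":  (30.5, 30.7, 31.3, 31.7),
    "PGK1":     (27.0, 27.0, 27.0, 27.0),
    "HMBS":     (28.0, 28.0, 28.0, 28.0),
}

DEFAULT_GROUP_SIZES = {"NILM": 61, "LSIL": 28, "HSIL": 42, "CC": 36}


@dataclass
class GroupEffectConfig:
    """Per-target, per-group Cq distribution parameters.

    ``means`` is a targets × groups DataFrame of mean Cq cycles;
    ``within_sd`` the biological between-sample SD per target (cycles);
    ``replicate_sd`` the technical SD added per replicate measurement;
    ``severity_loading`` the share of within-group SD driven by the shared
    latent severity score (0 decouples targets within a group).
    """

    panel: BiomarkerPanel
    means: pd.DataFrame
    within_sd: pd.Series
    replicate_sd: float = 0.15
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    severity_loading: float = 0.4
    check_monotone: bool = True

    def __post_init__(self):
        self.means = self.means.reindex(columns=GROUPS)
        if self.means.isna().any().any():
            raise ConfigurationError("means must cover all four diagnosis groups")
        if ((self.means <= 0) | (self.means > CQ_CAP)).any().any():
            raise ConfigurationError("mean Cq values must lie in (0, 40]")
        if (self.within_sd < 0).any() or self.replicate_sd < 0:
            raise ConfigurationError("standard deviations must be ≥ 0")
        if not 0 <= self.severity_loading <= 1:
            raise ConfigurationError("severity_loading must lie in [0, 1]")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be ≥ 0")
        if self.check_monotone:
            self._check_monotone()

    def _check_monotone(self):
        for target in self.means.index:
            reg = self.panel[target].regulation
            values = self.means.loc[target, GROUPS].to_numpy()
            diffs = np.diff(values)
            if reg is Regulation.UP and (diffs > 1e-9).any():
                raise ConfigurationError(
                    f"upregulated target {target!r}: mean Cq must be "
                    "non-increasing with severity"
                )
            if reg is Regulation.DOWN and (diffs < -1e-9).any():
                raise ConfigurationError(
                    f"downregulated target {target!r}: mean Cq must be "
                    "non-decreasing with severity"
                )
            if reg is Regulation.HOUSEKEEPING and not np.allclose(values, values[0]):
                raise ConfigurationError(
                    f"housekeeping target {target!r}: group means must be equal"
                )

    @classmethod
    def default(cls, **overrides) -> "GroupEffectConfig":
        panel = overrides.pop("panel", default_panel())
        means = pd.DataFrame(_DEFAULT_MEANS, index=GROUPS).T
        means = means.loc[[t for t in panel.names if t in means.index]]
        within = pd.Series(2.0, index=means.index)
        return cls(panel, means, within, **overrides)

    @classmethod
    def null(cls, **overrides) -> "GroupEffectConfig":
        """A no-signal configuration: every target keeps its NILM mean in all
        groups. Used for calibration checks (any feature's AUC ≈ 0.5)."""
        cfg = cls.default(**overrides)
        for target in cfg.means.index:
            cfg.means.loc[target] = cfg.means.at[target, "NILM"]
        return cfg

    def direction(self, target: str) -> float:
        return _DIRECTION[self.panel[target].regulation]


@dataclass
class CovariateConfig:
    """Group-level parameters for HPV load and lactobacilli fraction.

    HPV load is emitted directly on the 2^-ΔCq relative scale (copies per
    genomic-reference copy); HPV-negative samples carry load 0.
    ``log2_load_mean/sd`` parameterize the positive samples' log2 loads.
    Lactobacilli fraction is a clipped Gaussian on [0, 1]. The severity
    loadings couple both covariates to the latent per-sample severity.
    """

    log2_load_mean: dict = field(
        default_factory=lambda: {"NILM": 1.0, "LSIL": 3.0, "HSIL": 4.5, "CC": 5.0}
    )
    log2_load_sd: dict = field(
        default_factory=lambda: {g: 2.0 for g in GROUPS}
    )
    # HPV-negative probabilities from typical screening positivity by grade
    hpv_negative_prob: dict = field(
        default_factory=lambda: {
            "NILM": 44 / 60,
            "LSIL": 6 / 22,
            "HSIL": 1 / 32,
            "CC": 3 / 33,
        }
    )
    lb_fraction_mean: dict = field(
        default_factory=lambda: {"NILM": 0.70, "LSIL": 0.60, "HSIL": 0.35, "CC": 0.25}
    )
    lb_fraction_sd: dict = field(default_factory=lambda: {g: 0.25 for g in GROUPS})
    hpv_severity_loading: float = 1.0
    lb_severity_loading: float = -0.08

    def __post_init__(self):
        for g in GROUPS:
            if not 0 <= self.hpv_negative_prob[g] <= 1:
                raise ConfigurationError("HPV-negative probability must be in [0, 1]")
            if not 0 <= self.lb_fraction_mean[g] <= 1:
                raise ConfigurationError("lactobacilli fraction mean must be in [0, 1]")


def generate_cohort(
    effects: GroupEffectConfig,
    covariates: CovariateConfig | None = None,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[CqCohort, pd.DataFrame | None]:
    """Draw a synthetic cohort; bit-reproducible for a given seed.

    Per sample, a latent severity z ~ N(0,1) is drawn; each target's true
    Cq is ``mean + sd·(c·(±z) + sqrt(1−c²)·ε)`` with c the severity loading
    signed by the target's regulation direction, so the marginal stays
    Normal(mean, sd). Each replicate adds Normal(0, replicate_sd) technical
    noise. Values above 40 are capped and flagged expression-negative.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be ≥ 1")
    rng = np.random.default_rng(seed)
    targets = list(effects.means.index)
    records = []
    sample_rows = []
    covariate_rows = []
    for group in GROUPS:
        n = int(effects.group_sizes.get(group, 0))
        for i in range(n):
            sid = f"{group}-{i + 1:03d}"
            sample_rows.append((sid, group))
            z = rng.standard_normal()
            for target in targets:
                sd = float(effects.within_sd[target])
                c = effects.severity_loading * effects.direction(target)
                eps = rng.standard_normal()
                true_cq = (
                    effects.means.at[target, group]
                    + sd * (c * z + np.sqrt(max(0.0, 1.0 - c * c)) * eps)
                )
                for rep in range(1, n_replicates + 1):
                    value = true_cq + rng.normal(0.0, effects.replicate_sd)
                    negative = value > CQ_CAP
                    cq = CQ_CAP if negative else max(value, 1e-2)
                    records.append((sid, target, rep, round(cq, 2), negative))
            if covariates is not None:
                covariate_rows.append(
                    _draw_covariates(sid, group, z, covariates, rng)
                )
    measurements = pd.DataFrame(
        records,
        columns=["sample_id", "target", "replicate", "cq", "expression_negative"],
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "diagnosis"]
    ).set_index("sample_id")
    samples["qc_status"] = QCStatus.PASS.value
    cohort = CqCohort(measurements, samples, panel=effects.panel)
    table = None
    if covariates is not None:
        table = pd.DataFrame(
            covariate_rows, columns=["sample_id", "hpv_load", "lb_fraction"]
        ).set_index("sample_id")
    return cohort, table


def _draw_covariates(sid, group, z, cfg: CovariateConfig, rng):
    if rng.uniform() < cfg.hpv_negative_prob[group]:
        load = 0.0
    else:
        log2_load = (
            cfg.log2_load_mean[group]
            + cfg.hpv_severity_loading * z
            + rng.normal(0.0, cfg.log2_load_sd[group])
        )
        load = float(2.0 ** log2_load)
    lb = (
        cfg.lb_fraction_mean[group]
        + cfg.lb_severity_loading * z
        + rng.normal(0.0, cfg.lb_fraction_sd[group])
    )
    return (sid, load, float(np.clip(lb, 0.0, 1.0)))


def design_auc(
    effects: GroupEffectConfig,
    pair: tuple,
    contrast: Contrast | str,
    n_replicates: int = 1,
) -> float:
    """Analytic ROC AUC of a pair's ΔCq feature under the generator.

    Within each diagnosis group, ΔCq(X, Y) = Cq(Y) − Cq(X) is Gaussian with
    mean μ_Y − μ_X and variance σ_X² + σ_Y² − 2σ_Xσ_Y·c_X·c_Y (the latent
    severity induces the covariance term) plus the technical term
    2·replicate_sd²/r for r-replicate-averaged features. The AUC is the
    probability that a positive-group draw exceeds a negative-group draw,
    summed exactly over the group mixture with Φ closed forms.
    """
    if isinstance(contrast, str):
        contrast = Contrast.from_scheme(contrast)
    x, y = pair
    rho = effects.severity_loading
    c_x = rho * effects.direction(x)
    c_y = rho * effects.direction(y)
    sd_x = float(effects.within_sd[x])
    sd_y = float(effects.within_sd[y])
    if sd_x <= 0 or sd_y <= 0:
        raise ConfigurationError("design_auc requires within-group SDs > 0")
    var = (
        sd_x**2
        + sd_y**2
        - 2.0 * sd_x * sd_y * c_x * c_y
        + 2.0 * effects.replicate_sd**2 / n_replicates
    )

    def _mixture(group_set):
        members = [g for g in GROUPS if g in group_set]
        sizes = np.array([effects.group_sizes.get(g, 0) for g in members], float)
        if sizes.sum() == 0:
            raise ConfigurationError(f"empty contrast group: {sorted(group_set)}")
        weights = sizes / sizes.sum()
        means = np.array(
            [effects.means.at[y, g] - effects.means.at[x, g] for g in members]
        )
        return weights, means

    w_pos, m_pos = _mixture(contrast.positive_group)
    w_neg, m_neg = _mixture(contrast.negative_group)
    auc = 0.0
    for wp, mp in zip(w_pos, m_pos):
        for wn, mn in zip(w_neg, m_neg):
            auc += wp * wn * stats.norm.cdf((mp - mn) / np.sqrt(2.0 * var))
    return float(auc)
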