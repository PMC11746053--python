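"""Biomarker panel registry.

A panel lists the RT-qPCR targets of the assay together with their expected
regulation direction across lesion progression (``up`` = overexpressed in
severe lesions, hence *lower* Cq; ``down`` = silenced, hence *higher* Cq;
``housekeeping`` = stable) and their role: diagnostic ``biomarker``, or a
sample-adequacy control for DNA (``dna_adequacy``) or RNA (``rna_adequacy``)
amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ConfigurationError


class Regulation(str, Enum):
    UP = "up"
    DOWN = "down"
    HOUSEKEEPING = "housekeeping"


class Role(str, Enum):
    BIOMARKER = "biomarker"
    DNA_ADEQUACY = "dna_adequacy"
    RNA_ADEQUACY = "rna_adequacy"


@dataclass(frozen=True)
class BiomarkerTarget:
    """A single assay target.

    Adequacy controls must be housekeeping-regulated: they gauge template
    amount, not disease state.
    """

    name: str
    regulation: Regulation
    role: Role = Role.BIOMARKER

    def __post_init__(self):
        if self.role in (Role.DNA_ADEQUACY, Role.RNA_ADEQUACY):
            if self.regulation is not Regulation.HOUSEKEEPING:
                raise ConfigurationError(
                    f"adequacy target {self.name!r} must be housekeeping-regulated"
                )


@dataclass
class BiomarkerPanel:
    """An ordered collection of targets with unique names."""

    targets: list[BiomarkerTarget] = field(default_factory=list)

    def __post_init__(self):
        names = [t.name for t in self.targets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate target names in panel: {dupes}")

    def __iter__(self):
        return iter(self.targets)

    def __len__(self):
        return len(self.targets)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.targets]

    def __getitem__(self, name: str) -> BiomarkerTarget:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(t.name == name for t in self.targets)

    def by_role(self, role: Role) -> list[BiomarkerTarget]:
        return [t for t in self.targets if t.role is role]

    def by_regulation(self, regulation: Regulation) -> list[BiomarkerTarget]:
        return [t for t in self.targets if t.regulation is regulation]

    def adequacy_target(self, role: Role) -> BiomarkerTarget:
        """The unique adequacy control for *role*, or raise."""
        found = self.by_role(role)
        if len(found) != 1:
            raise ConfigurationError(
                f"panel must declare exactly one {role.value} target, found {len(found)}"
            )
        return found[0]


def default_panel() -> BiomarkerPanel:
    """The ten-target cervical triage panel.

    Two mRNAs upregulated with lesion severity (CDKN2A, TOP2A), six
    downregulated (MAL, CRNN, CRISP3, SPINK5, ECM1, TMPRSS4), PGK1 mRNA as
    the RNA-adequacy housekeeping control and the HMBS gene as the
    DNA-adequacy control.
    """
    up = ["CDKN2A", "TOP2A"]
    down = ["MAL", "CRNN", "CRISP3", "SPINK5", "ECM1", "TMPRSS4"]
    targets = [BiomarkerTarget(n, Regulation.UP) for n in up]
    targets += [BiomarkerTarget(n, Regulation.DOWN) for n in down]
    targets.append(
        BiomarkerTarget("PGK1", Regulation.HOUSEKEEPING, Role.RNA_ADEQUACY)
    )
    targets.append(
        BiomarkerTarget("HMBS", Regulation.HOUSEKEEPING, Role.DNA_ADEQUACY)
    )
    return BiomarkerPanel(targets)
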