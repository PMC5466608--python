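"""Gene-panel configuration.

The study panel is 26 known or proposed breast cancer susceptibility
genes, each assigned to one risk group used for group-level carrier
rates, and one region mode (whether intronic calls were assessable or
only exonic ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field


RISK_GROUPS = ("high", "moderate", "proposed", "lynch", "mutyh")
REGION_MODES = ("introns+exons", "exons_only")

_DEFAULT_GROUPS: dict[str, str] = {
    # High-risk / syndromic breast cancer genes
    "PALB2": "high", "TP53": "high", "CDH1": "high", "PTEN": "high", "STK11": "high",
    # Moderate-risk breast cancer genes
    "CHEK2": "moderate", "ATM": "moderate", "NBN": "moderate",
    # Proposed / candidate breast cancer genes
    "BARD1": "proposed", "FANCM": "proposed", "BLM": "proposed",
    "RAD50": "proposed", "RAD51D": "proposed", "RAD51C": "proposed",
    "BRIP1": "proposed", "PPM1D": "proposed", "FANCC": "proposed",
    "MRE11A": "proposed", "RINT1": "proposed", "XRCC2": "proposed",
    "BAP1": "proposed",
    # Lynch syndrome (mismatch repair) genes
    "MSH6": "lynch", "MSH2": "lynch", "PMS2": "lynch", "MLH1": "lynch",
    # Monoallelic MUTYH, analyzed as its own group
    "MUTYH": "mutyh",
}

# Exon-only assessment was available for these five genes; the rest had
# introns and exons on target.
_EXON_ONLY = frozenset({"BAP1", "FANCC", "FANCM", "PPM1D", "RINT1"})


@dataclass(frozen=True)
class PanelConfig:
    """The gene panel: symbols, risk-group and region-mode assignments.

    Every gene must have exactly one risk group and one region mode;
    violations raise ``ValueError`` at construction.
    """

    genes: tuple[str, ...] = tuple(sorted(_DEFAULT_GROUPS))
    risk_group: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS))
    region_mode: dict[str, str] = field(default_factory=lambda: {
        g: ("exons_only" if g in _EXON_ONLY else "introns+exons")
        for g in _DEFAULT_GROUPS})

    def __post_init__(self) -> None:
        for g in self.genes:
            grp = self.risk_group.get(g)
            if grp not in RISK_GROUPS:
                raise ValueError(f"gene {g!r} has no valid risk group: {grp!r}")
            if self.region_mode.get(g) not in REGION_MODES:
                raise ValueError(f"gene {g!r} has no valid region mode")

    def __contains__(self, gene: str) -> bool:
        return gene in self.risk_group and gene in set(self.genes)

    def genes_in_group(self, group: str) -> list[str]:
        return [g for g in self.genes if self.risk_group[g] == group]


def default_panel() -> PanelConfig:
    """The 26-gene study panel with its standard group assignments."""
    return PanelConfig()
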