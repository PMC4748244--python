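"""Built-in 8-color immunophenotyping panel designs.

Four standardized lyophilized-reagent panels (T-cell, Treg, B-cell,
DC/Mono/NK) are described here twice over:

* as *cell types* — mutually exclusive generative mixture components with a
  full sign vector over the panel's markers, used by the synthetic-data
  module; and
* as *populations* — the reported cell subsets, each a marker-sign predicate
  plus the denominator convention under which its proportion is reported
  (parent gate, total-Treg, or the pre-gated root).

A cell type *matches* a population predicate when every predicate sign is
consistent with the type's sign vector ('+' accepts '+' or 'high', '-'
accepts '-' or 'low'; 'high'/'low' are exact). Ground-truth proportions and
per-event truth masks both derive from this matching rule, so gates and
truth refer to the same definitions.

The Th1/2/17 helper panel is deliberately out of scope: chemokine-receptor
staining is too variable across sites for threshold gating to be reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import FLUORO, SCATTER, VIABILITY, ChannelInfo

# sign -> default mean position in transformed (asinh) units
SIGN_MEANS = {"+": 2.0, "-": -2.0, "high": 3.5, "low": -2.0}
NEGATIVE_DEFAULT = -2.0

#: scatter cluster profiles: (FSC-A mean, FSC-A sd, SSC-A mean, SSC-A sd)
SCATTER_PROFILES = {
    "lymphocyte": (55_000.0, 6_000.0, 25_000.0, 5_000.0),
    "monocyte": (90_000.0, 8_000.0, 60_000.0, 9_000.0),
    "debris": (10_000.0, 3_000.0, 8_000.0, 3_000.0),
}


@dataclass
class CellType:
    """Exclusive generative mixture component.

    ``signs`` maps marker -> one of {+, -, high, low}; markers absent from
    the map are drawn from the negative mode. ``baseline`` is the expected
    fraction of live singlet cells, on the linear scale; the synthetic
    module perturbs its logit with sample/center/residual effects.
    """

    name: str
    signs: dict[str, str]
    baseline: float
    scatter: str = "lymphocyte"

    def mean_vector(self, markers: list[str]) -> np.ndarray:
        return np.array(
            [SIGN_MEANS.get(self.signs.get(m, "-"), NEGATIVE_DEFAULT) for m in markers]
        )

    def matches(self, predicate: dict[str, str]) -> bool:
        for marker, want in predicate.items():
            have = self.signs.get(marker, "-")
            if want == "+":
                if have not in ("+", "high"):
                    return False
            elif want == "-":
                if have not in ("-", "low"):
                    return False
            elif want != have:  # 'high' / 'low' exact
                return False
        return True


@dataclass
class Population:
    """A reported cell subset: predicate + reporting denominator.

    ``denominator`` is another predicate (dict) or None, meaning the
    pre-gated root. ``reliable`` mirrors the panel's published reliability
    flag: subsets markable by automated gating are True.
    """

    name: str
    predicate: dict[str, str]
    denominator: dict[str, str] | None
    reliable: bool


@dataclass
class PanelDesign:
    name: str
    channels: list[ChannelInfo]
    cell_types: list[CellType] = field(default_factory=list)
    populations: list[Population] = field(default_factory=list)
    pregate_scope: str = "lymphocyte"  # or "mononuclear"

    def __post_init__(self) -> None:
        markers = set(self.fluoro_markers)
        for ct in self.cell_types:
            unknown = set(ct.signs) - markers
            if unknown:
                raise ValueError(f"{self.name}/{ct.name}: unknown markers {unknown}")
        for pop in self.populations:
            unknown = set(pop.predicate) - markers
            if pop.denominator:
                unknown |= set(pop.denominator) - markers
            if unknown:
                raise ValueError(f"{self.name}/{pop.name}: unknown markers {unknown}")
        total = sum(ct.baseline for ct in self.cell_types)
        if total > 1.0:
            raise ValueError(f"{self.name}: cell-type baselines sum to {total} > 1")

    @property
    def fluoro_markers(self) -> list[str]:
        return [c.marker for c in self.channels if c.role == FLUORO]

    @property
    def fluoro_detectors(self) -> list[str]:
        return [c.detector for c in self.channels if c.role == FLUORO]

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"{self.name}: no population {name!r}")

    def truth_proportion(
        self, pop: Population, leaf_proportions: dict[str, float]
    ) -> float:
        """True reported proportion implied by leaf-level proportions.

        The unnamed all-negative remainder counts toward any predicate
        satisfied by an all-negative event (every requested sign '-'/'low').
        """
        p_other = max(1.0 - sum(leaf_proportions[ct.name] for ct in self.cell_types), 0.0)

        def mass(predicate: dict[str, str] | None) -> float:
            if predicate is None:
                return 1.0
            m = sum(
                leaf_proportions[ct.name]
                for ct in self.cell_types
                if ct.matches(predicate)
            )
            if all(s in ("-", "low") for s in predicate.values()):
                m += p_other
            return m

        den = mass(pop.denominator)
        return mass(pop.predicate) / den if den > 0 else float("nan")


def _channels(marker_by_detector: dict[str, str]) -> list[ChannelInfo]:
    chans = [
        ChannelInfo("FSC-A", "FSC-A", SCATTER),
        ChannelInfo("FSC-H", "FSC-H", SCATTER),
        ChannelInfo("SSC-A", "SSC-A", SCATTER),
        ChannelInfo("FITC-A", "Live/Dead", VIABILITY),
    ]
    for det, marker in marker_by_detector.items():
        chans.append(ChannelInfo(det, marker, FLUORO))
    return chans


# Detector stains per panel (FITC carries the fixable green live/dead stain
# in every cocktail and is modelled as the viability channel).
_TCELL_STAINS = {
    "PE-A": "CCR7",
    "PerCP-Cy5-5-A": "CD4",
    "PE-Cy7-A": "CD45RA",
    "APC-A": "CD38",
    "APC-H7-A": "CD8",
    "V450-A": "CD3",
    "V500-A": "HLA-DR",
}
_TREG_STAINS = {
    "PE-A": "CD25",
    "PerCP-Cy5-5-A": "CD4",
    "PE-Cy7-A": "CCR4",
    "APC-A": "CD127",
    "APC-H7-A": "CD45RO",
    "V450-A": "CD3",
    "V500-A": "HLA-DR",
}
_BCELL_STAINS = {
    "PE-A": "CD24",
    "PerCP-Cy5-5-A": "CD19",
    "PE-Cy7-A": "CD27",
    "APC-A": "CD38",
    "APC-H7-A": "CD20",
    "V450-A": "CD3",
    "V500-A": "IgD",
}
_DC_STAINS = {
    "PE-A": "CD56",
    "PerCP-Cy5-5-A": "CD123",
    "PE-Cy7-A": "CD11c",
    "APC-A": "CD16",
    "APC-H7-A": "Lin",  # dump channel: CD3 + CD19 + CD20
    "V450-A": "CD14",
    "V500-A": "HLA-DR",
}


def _tcell_panel() -> PanelDesign:
    mem = {  # CCR7/CD45RA memory grid, shared between CD4 and CD8 branches
        "naive": {"CCR7": "+", "CD45RA": "+"},
        "cm": {"CCR7": "+", "CD45RA": "-"},
        "eff": {"CCR7": "-", "CD45RA": "+"},
        "em": {"CCR7": "-", "CD45RA": "-"},
    }
    cts = []
    for lineage, other, frac in (("CD4", "CD8", 1.0), ("CD8", "CD4", 1.0)):
        base = {"CD3": "+", lineage: "+", other: "-"}
        weights = (
            {"naive": 0.16, "cm": 0.12, "eff": 0.03, "em": 0.07}
            if lineage == "CD4"
            else {"naive": 0.08, "cm": 0.03, "eff": 0.05, "em": 0.04}
        )
        for sub, signs in mem.items():
            cts.append(CellType(f"{lineage.lower()}_{sub}", {**base, **signs}, weights[sub]))
        cts.append(
            CellType(
                f"{lineage.lower()}_act",
                {**base, "CCR7": "-", "CD45RA": "-", "CD38": "+", "HLA-DR": "+"},
                0.02 if lineage == "CD4" else 0.01,
            )
        )
    cd4 = {"CD3": "+", "CD4": "+", "CD8": "-"}
    cd8 = {"CD3": "+", "CD8": "+", "CD4": "-"}
    pops = [
        Population("CD8 Activated", {**cd8, "CD38": "+", "HLA-DR": "+"}, cd8, False),
        Population("CD4 Activated", {**cd4, "CD38": "+", "HLA-DR": "+"}, cd4, True),
        Population("CD4 Central Memory", {**cd4, "CCR7": "+", "CD45RA": "-"}, cd4, False),
        Population("CD8 Central Memory", {**cd8, "CCR7": "+", "CD45RA": "-"}, cd8, False),
        Population("CD4 Effector", {**cd4, "CCR7": "-", "CD45RA": "+"}, cd4, True),
        Population("CD8 Effector", {**cd8, "CCR7": "-", "CD45RA": "+"}, cd8, True),
        Population("CD4 Effector Memory", {**cd4, "CCR7": "-", "CD45RA": "-"}, cd4, True),
        Population("CD8 Effector Memory", {**cd8, "CCR7": "-", "CD45RA": "-"}, cd8, False),
        Population("CD4 Naive", {**cd4, "CCR7": "+", "CD45RA": "+"}, cd4, True),
        Population("CD8 Naive", {**cd8, "CCR7": "+", "CD45RA": "+"}, cd8, True),
    ]
    return PanelDesign("T-cell", _channels(_TCELL_STAINS), cts, pops)


def _treg_panel() -> PanelDesign:
    treg_core = {"CD3": "+", "CD4": "+", "CD127": "low", "CD25": "high"}
    cts = [
        CellType("cd4_naive_conv", {"CD3": "+", "CD4": "+", "CD127": "+"}, 0.20),
        CellType(
            "cd4_mem_conv",
            {"CD3": "+", "CD4": "+", "CD127": "+", "CCR4": "+", "CD45RO": "+"},
            0.12,
        ),
        CellType("treg_mem", {**treg_core, "CCR4": "+", "CD45RO": "+"}, 0.014),
        CellType("treg_naive", {**treg_core, "CCR4": "+"}, 0.008),
        CellType(
            "treg_act", {**treg_core, "CCR4": "+", "CD45RO": "+", "HLA-DR": "+"}, 0.004
        ),
        CellType("treg_ccr4neg_ro_neg", dict(treg_core), 0.003),
        CellType("treg_ccr4neg_ro_pos", {**treg_core, "CD45RO": "+"}, 0.002),
        CellType("cd8_t", {"CD3": "+"}, 0.18),
    ]
    cd4 = {"CD3": "+", "CD4": "+"}
    gate = treg_core  # the LoCD127/HiCD25 parent
    treg = {**treg_core, "CCR4": "+"}  # total Treg
    pops = [
        Population("Total CD4", cd4, {"CD3": "+"}, True),
        Population("LoCD127/HiCD25", gate, cd4, True),
        Population("Total T-regulatory", treg, cd4, True),
        Population("Memory T-regulatory", {**treg, "CD45RO": "+"}, treg, True),
        Population("Naive T-regulatory", {**treg, "CD45RO": "-"}, treg, True),
        Population("Activated", {**treg, "HLA-DR": "+"}, treg, True),
        Population("CCR4-/CD45RO-", {**gate, "CCR4": "-", "CD45RO": "-"}, gate, False),
        Population("CCR4-CD45RO+", {**gate, "CCR4": "-", "CD45RO": "+"}, gate, False),
        Population("CCR4+/CD45RO-", {**gate, "CCR4": "+", "CD45RO": "-"}, gate, False),
        Population("CCR4-HLADR-", {**gate, "CCR4": "-", "HLA-DR": "-"}, gate, True),
        Population("CCR4-/HLADR+", {**gate, "CCR4": "-", "HLA-DR": "+"}, gate, False),
        Population("CCR4+/HLADR+", {**gate, "CCR4": "+", "HLA-DR": "+"}, gate, True),
    ]
    return PanelDesign("Treg", _channels(_TREG_STAINS), cts, pops)


def _bcell_panel() -> PanelDesign:
    b = {"CD3": "-", "CD19": "+", "CD20": "+"}
    cts = [
        CellType("tcell", {"CD3": "+"}, 0.55),
        CellType("naive_b", {**b, "IgD": "+"}, 0.055),
        CellType("mem_igd_pos", {**b, "IgD": "+", "CD27": "+"}, 0.015),
        CellType("mem_igd_neg", {**b, "CD27": "+"}, 0.02),
        CellType("dn_b", dict(b), 0.006),
        CellType(
            "transitional", {**b, "IgD": "+", "CD24": "high", "CD38": "high"}, 0.005
        ),
        CellType(
            "plasmablast",
            {"CD3": "-", "CD19": "+", "CD20": "-", "CD27": "+", "CD24": "high", "CD38": "high"},
            0.003,
        ),
        # CD20-negative B lineage that is not CD24hi/CD38hi, so the
        # plasmablast denominator (CD19+/CD20-) is not degenerate
        CellType(
            "plasma_cell",
            {"CD3": "-", "CD19": "+", "CD20": "-", "CD27": "+", "CD38": "+"},
            0.002,
        ),
    ]
    pops = [
        Population("CD19", {"CD3": "-", "CD19": "+"}, None, True),
        Population("CD20", {"CD3": "-", "CD20": "+"}, None, True),
        Population("IgD-/CD27-", {**b, "IgD": "-", "CD27": "-"}, b, False),
        Population("Naive B", {**b, "IgD": "+", "CD27": "-"}, b, True),
        Population("Memory IgD+", {**b, "IgD": "+", "CD27": "+"}, b, True),
        Population("Memory IgD-", {**b, "IgD": "-", "CD27": "+"}, b, True),
        Population("Transitional", {**b, "CD24": "high", "CD38": "high"}, b, True),
        Population(
            "Plasmablasts",
            {"CD3": "-", "CD19": "+", "CD20": "-", "CD24": "high", "CD38": "high"},
            {"CD3": "-", "CD19": "+", "CD20": "-"},
            False,
        ),
    ]
    return PanelDesign("B-cell", _channels(_BCELL_STAINS), cts, pops)


def _dc_panel() -> PanelDesign:
    dc_gate = {"Lin": "-", "CD14": "-", "HLA-DR": "+"}
    nk_gate = {"Lin": "-", "CD14": "-", "HLA-DR": "-"}
    cts = [
        CellType("lymph", {"Lin": "+"}, 0.42),
        CellType("nk_dim", {"CD16": "+", "CD56": "+"}, 0.08),
        CellType("nk_bright", {"CD56": "+"}, 0.012),
        CellType("nk_cd16", {"CD16": "+"}, 0.010),
        CellType(
            "mono_classical",
            {"CD14": "+", "HLA-DR": "+", "CD11c": "+"},
            0.17,
            scatter="monocyte",
        ),
        CellType(
            "mono_inflammatory",
            {"CD14": "+", "CD16": "+", "HLA-DR": "+", "CD11c": "+"},
            0.03,
            scatter="monocyte",
        ),
        CellType(
            "mdc", {"HLA-DR": "+", "CD11c": "+"}, 0.010, scatter="monocyte"
        ),
        CellType("pdc", {"HLA-DR": "+", "CD123": "+"}, 0.005),
    ]
    lin_neg = {"Lin": "-"}
    lin_cd14_neg = {"Lin": "-", "CD14": "-"}
    pops = [
        Population("Lin-/CD14+", {"Lin": "-", "CD14": "+"}, lin_neg, True),
        Population("Lin-CD14-", lin_cd14_neg, lin_neg, True),
        Population("CD14+/CD16+", {"Lin": "-", "CD14": "+", "CD16": "+"}, lin_neg, False),
        Population("HLADR+", dc_gate, lin_cd14_neg, False),
        Population("CD11c+/CD123-", {**dc_gate, "CD11c": "+", "CD123": "-"}, dc_gate, True),
        Population("CD11c-/CD123+", {**dc_gate, "CD11c": "-", "CD123": "+"}, dc_gate, True),
        Population("CD11c+/CD123+", {**dc_gate, "CD11c": "+", "CD123": "+"}, dc_gate, False),
        Population("CD11c-/CD123-", {**dc_gate, "CD11c": "-", "CD123": "-"}, dc_gate, False),
        Population("CD16+/CD56+", {**nk_gate, "CD16": "+", "CD56": "+"}, nk_gate, True),
        Population("CD16-/CD56+", {**nk_gate, "CD16": "-", "CD56": "+"}, nk_gate, True),
        Population("CD16+/CD56-", {**nk_gate, "CD16": "+", "CD56": "-"}, nk_gate, False),
        Population("CD16-/CD56-", {**nk_gate, "CD16": "-", "CD56": "-"}, nk_gate, False),
    ]
    return PanelDesign(
        "DC-Mono-NK", _channels(_DC_STAINS), cts, pops, pregate_scope="mononuclear"
    )


_BUILDERS = {
    "T-cell": _tcell_panel,
    "Treg": _treg_panel,
    "B-cell": _bcell_panel,
    "DC-Mono-NK": _dc_panel,
}

PANEL_NAMES = tuple(_BUILDERS)


def builtin_panel(name: str) -> PanelDesign:
    """Return a fresh built-in panel design by name."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown panel {name!r}; available: {PANEL_NAMES}") from None


def builtin_panels() -> list[PanelDesign]:
    return [b() for b in _BUILDERS.values()]
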