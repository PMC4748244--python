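"""Synthetic multi-center cytometry experiments with known ground truth.

Emulates a standardized cross-laboratory immunophenotyping study: a crossed
design of centers x biological samples x staining replicates, four 8-color
panels, and event-level files in which every event carries a true cell-type
label. Population proportions vary on the logit scale with separate
sample-level, center-level, and residual components,

    y = logit(p) = mu + alpha_i + beta_j + eps_rij,
    alpha_i ~ N(0, sigma_sample^2), beta_j ~ N(0, sigma_center^2),
    eps_rij ~ N(0, sigma_residual^2),

which is exactly the crossed random-effects model the downstream variance
decomposition fits; the generator runs it forwards. Technical center effects
on *intensities* are modelled as per-channel affine distortions (gain and
offset on the raw scale), mimicking PMT/voltage differences between
instruments, applied before fluorescence spillover mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import FLUORO, VIABILITY, EventFrame, SpilloverMatrix
from .panels import SCATTER_PROFILES, PANEL_NAMES, PanelDesign, builtin_panel

#: minimum fraction of events reserved for the unnamed "other" remainder
MIN_OTHER = 0.01

#: live / dead viability modes in transformed units
VIABILITY_LIVE = 0.0
VIABILITY_DEAD = 3.5

#: FSC-H ~ FSC-A singlet relation
FSC_H_SLOPE = 0.98
FSC_H_NOISE = 1_500.0


def logit(p):
    p = np.asarray(p, dtype=np.float64)
    return np.log(p / (1.0 - p))


def inv_logit(y):
    y = np.asarray(y, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-y))


@dataclass
class SimulationConfig:
    """Full generative specification of one multi-center experiment.

    Defaults mirror the cryopreserved-PBMC study arm: nine centers staining
    three replicates of each of three samples. Logit-scale variance
    components default to (0.5, 0.3, 0.2) for sample/center/residual.
    """

    n_centers: int = 9
    n_samples: int = 3
    n_replicates: int = 3
    events_per_file: int = 20_000
    panels: tuple[str, ...] = PANEL_NAMES
    sigma_sample: float = 0.5
    sigma_center: float = 0.3
    sigma_residual: float = 0.2
    marker_sd: float = 0.5  # per-marker SD in transformed units
    gain_sd: float = 0.08  # tau_g: per-channel lognormal gain SD (log scale)
    offset_sd: float = 3.0  # tau_b: per-channel additive offset SD (raw units)
    doublet_frac: float = 0.03
    dead_frac: float = 0.05
    debris_frac: float = 0.05
    cofactor: float = 150.0
    spillover: SpilloverMatrix | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_sample", "sigma_center", "sigma_residual", "gain_sd", "offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("doublet_frac", "dead_frac", "debris_frac"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.marker_sd < 0 or self.cofactor <= 0:
            raise ValueError("marker_sd must be >= 0 and cofactor positive")
        if self.events_per_file < 1:
            raise ValueError("events_per_file must be >= 1")
        unknown = set(self.panels) - set(PANEL_NAMES)
        if unknown:
            raise ValueError(f"unknown panels {unknown}")

    def rng_for(self, *key: int) -> np.random.Generator:
        """Counter-derived per-file stream: order-independent generation."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


def default_spillover(detectors: list[str]) -> SpilloverMatrix:
    """Mild nearest-neighbour spillover: 4% to adjacent, 1% two away."""
    n = len(detectors)
    S = np.eye(n)
    for i in range(n):
        for j in range(n):
            d = abs(i - j)
            if d == 1:
                S[i, j] = 0.04
            elif d == 2:
                S[i, j] = 0.01
    return SpilloverMatrix(S, list(detectors))


# ---------------------------------------------------------------------------
# proportion-level generator (the logit-normal crossed model, run forwards)
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Realized effects and per-file truth for one panel of one experiment.

    ``leaf_proportions`` has one row per (center, sample, replicate, cell
    type); ``alpha``/``beta`` hold the shared sample/center effects (same
    draw for every replicate of a given sample or center).
    """

    panel: str
    leaf_proportions: pd.DataFrame
    alpha: pd.DataFrame  # columns: sample, cell_type, alpha
    beta: pd.DataFrame  # columns: center, cell_type, beta

    def file_leaf_proportions(self, center: int, sample: int, replicate: int) -> dict[str, float]:
        df = self.leaf_proportions
        sel = df[
            (df["center"] == center)
            & (df["sample"] == sample)
            & (df["replicate"] == replicate)
        ]
        return dict(zip(sel["cell_type"], sel["p_true"]))

    def population_truth(self, panel: PanelDesign) -> pd.DataFrame:
        """True reported proportion per file and published population."""
        rows = []
        for (c, s, r), grp in self.leaf_proportions.groupby(
            ["center", "sample", "replicate"]
        ):
            leaves = dict(zip(grp["cell_type"], grp["p_true"]))
            for pop in panel.populations:
                rows.append(
                    {
                        "center": c,
                        "sample": s,
                        "replicate": r,
                        "panel": panel.name,
                        "population": pop.name,
                        "proportion": panel.truth_proportion(pop, leaves),
                    }
                )
        return pd.DataFrame(rows)


def draw_population_proportions(
    config: SimulationConfig, panel: PanelDesign, rng: np.random.Generator
) -> GroundTruth:
    """Draw per-file true leaf proportions under the logit-normal model.

    Each leaf cell type receives independent sample effects alpha_i, center
    effects beta_j and residuals eps_rij on the logit of its baseline. Leaf
    proportions are then renormalized per file to leave at least
    ``MIN_OTHER`` of events in the unnamed remainder, preserving hierarchy
    consistency (internal populations are sums of leaves).
    """
    types = panel.cell_types
    mu = logit(np.array([ct.baseline for ct in types]))
    k = len(types)
    alpha = rng.normal(0.0, config.sigma_sample, size=(config.n_samples, k))
    beta = rng.normal(0.0, config.sigma_center, size=(config.n_centers, k))
    rows = []
    for j in range(config.n_centers):
        for i in range(config.n_samples):
            for r in range(config.n_replicates):
                eps = rng.normal(0.0, config.sigma_residual, size=k)
                p = inv_logit(mu + alpha[i] + beta[j] + eps)
                total = p.sum()
                if total > 1.0 - MIN_OTHER:
                    p *= (1.0 - MIN_OTHER) / total
                for ct, pv in zip(types, p):
                    rows.append(
                        {
                            "center": j,
                            "sample": i,
                            "replicate": r,
                            "cell_type": ct.name,
                            "p_true": float(pv),
                        }
                    )
    alpha_df = pd.DataFrame(
        [
            {"sample": i, "cell_type": ct.name, "alpha": alpha[i, t]}
            for i in range(config.n_samples)
            for t, ct in enumerate(types)
        ]
    )
    beta_df = pd.DataFrame(
        [
            {"center": j, "cell_type": ct.name, "beta": beta[j, t]}
            for j in range(config.n_centers)
            for t, ct in enumerate(types)
        ]
    )
    return GroundTruth(panel.name, pd.DataFrame(rows), alpha_df, beta_df)


def simulate_proportion_model(
    mu: float,
    sigma_sample: float,
    sigma_center: float,
    sigma_residual: float,
    n_samples: int = 3,
    n_centers: int = 9,
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one balanced crossed dataset directly at the observation level.

    Returns columns (sample, center, replicate, y, p, alpha, beta): the
    proportion-scale view of a single population, used to validate the
    variance-decomposition machinery against known components.
    """
    rng = np.random.default_rng() if rng is None else rng
    alpha = rng.normal(0.0, sigma_sample, n_samples)
    beta = rng.normal(0.0, sigma_center, n_centers)
    rows = []
    for j in range(n_centers):
        for i in range(n_samples):
            for r in range(n_replicates):
                y = mu + alpha[i] + beta[j] + rng.normal(0.0, sigma_residual)
                rows.append(
                    {
                        "sample": i,
                        "center": j,
                        "replicate": r,
                        "y": y,
                        "p": float(inv_logit(y)),
                        "alpha": alpha[i],
                        "beta": beta[j],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# event-level synthesis
# ---------------------------------------------------------------------------


def _scatter_block(profile: str, n: int, rng: np.random.Generator) -> np.ndarray:
    fa_m, fa_s, ssc_m, ssc_s = SCATTER_PROFILES[profile]
    fsc_a = np.clip(rng.normal(fa_m, fa_s, n), 1.0, None)
    fsc_h = np.clip(FSC_H_SLOPE * fsc_a + rng.normal(0.0, FSC_H_NOISE, n), 1.0, None)
    ssc_a = np.clip(rng.normal(ssc_m, ssc_s, n), 1.0, None)
    return np.column_stack([fsc_a, fsc_h, ssc_a])


def synthesize_events(
    proportions: dict[str, float],
    panel: PanelDesign,
    n_events: int,
    rng: np.random.Generator,
    config: SimulationConfig,
    center_gain: np.ndarray | None = None,
    center_offset: np.ndarray | None = None,
) -> tuple[EventFrame, pd.DataFrame]:
    """Synthesize one file of raw-scale events plus per-event truth labels.

    Events are a mixture over the panel's cell types (plus an all-negative
    "other" remainder), with doublets (two cells acquired as one), debris
    and dead cells mixed in. Fluorescence is drawn in transformed units,
    mapped to the raw scale, distorted by the center's affine law, and
    finally passed through the spillover forward model by the caller.
    """
    markers = panel.fluoro_markers
    type_names = [ct.name for ct in panel.cell_types]
    p_leaf = np.array([proportions[t] for t in type_names])
    if (p_leaf < 0).any() or p_leaf.sum() > 1.0 + 1e-9:
        raise ValueError("leaf proportions must be non-negative and sum to <= 1")
    means = np.stack([ct.mean_vector(markers) for ct in panel.cell_types])
    other_mean = np.full(len(markers), -2.0)

    # event categories
    u = rng.random(n_events)
    is_doublet = u < config.doublet_frac
    is_debris = (~is_doublet) & (u < config.doublet_frac + config.debris_frac)
    is_cell = ~(is_doublet | is_debris)

    def draw_cells(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """n single live-or-dead cells: component ids, fluoro, scatter."""
        probs = np.append(p_leaf, max(1.0 - p_leaf.sum(), 0.0))
        comp = rng.choice(len(probs), size=n, p=probs / probs.sum())
        mu = np.vstack([means, other_mean])[comp]
        x = rng.normal(mu, config.marker_sd)
        profiles = np.array(
            [ct.scatter for ct in panel.cell_types] + ["lymphocyte"], dtype=object
        )[comp]
        scatter = np.empty((n, 3))
        for prof in np.unique(profiles):
            m = profiles == prof
            scatter[m] = _scatter_block(str(prof), int(m.sum()), rng)
        return comp, x, scatter

    n_cell = int(is_cell.sum())
    n_dbl = int(is_doublet.sum())
    n_deb = int(is_debris.sum())

    comp_c, x_c, sc_c = draw_cells(n_cell)
    raw_c = np.sinh(x_c) * config.cofactor

    # doublets: two cells acquired as one event; areas add, height saturates
    comp_a, x_a, sc_a = draw_cells(n_dbl)
    comp_b, x_b, sc_b = draw_cells(n_dbl)
    raw_d = (np.sinh(x_a) + np.sinh(x_b)) * config.cofactor
    sc_d = np.empty((n_dbl, 3))
    sc_d[:, 0] = sc_a[:, 0] + sc_b[:, 0]  # FSC-A
    sc_d[:, 1] = np.maximum(sc_a[:, 1], sc_b[:, 1])  # FSC-H
    sc_d[:, 2] = sc_a[:, 2] + sc_b[:, 2]  # SSC-A

    raw_deb = np.sinh(rng.normal(-2.0, config.marker_sd, (n_deb, len(markers)))) * config.cofactor
    sc_deb = _scatter_block("debris", n_deb, rng)

    # viability: dead cells (among true cells) sit in the high mode
    dead = np.zeros(n_events, dtype=bool)
    dead_cells = rng.random(n_cell) < config.dead_frac
    via_c = np.where(
        dead_cells,
        rng.normal(VIABILITY_DEAD, config.marker_sd, n_cell),
        rng.normal(VIABILITY_LIVE, config.marker_sd, n_cell),
    )
    via_d = rng.normal(VIABILITY_LIVE, config.marker_sd, n_dbl)
    via_deb = rng.normal(VIABILITY_LIVE, config.marker_sd, n_deb)

    # assemble in event order: cells, doublets, debris interleaved by masks
    n_chan = len(panel.channels)
    data = np.empty((n_events, n_chan))
    labels = np.empty(n_events, dtype=object)
    det_index = {c.detector: k for k, c in enumerate(panel.channels)}
    sc_cols = [det_index["FSC-A"], det_index["FSC-H"], det_index["SSC-A"]]
    via_col = next(k for k, c in enumerate(panel.channels) if c.role == VIABILITY)
    fl_cols = [k for k, c in enumerate(panel.channels) if c.role == FLUORO]

    names = np.array(type_names + ["other"], dtype=object)
    for mask, sc, raw, via, lab in (
        (is_cell, sc_c, raw_c, via_c, names[comp_c]),
        (is_doublet, sc_d, raw_d, via_d, np.full(n_dbl, "doublet", dtype=object)),
        (is_debris, sc_deb, raw_deb, via_deb, np.full(n_deb, "debris", dtype=object)),
    ):
        idx = np.flatnonzero(mask)
        data[np.ix_(idx, sc_cols)] = sc
        data[np.ix_(idx, fl_cols)] = raw
        data[idx, via_col] = np.sinh(via) * config.cofactor
        labels[idx] = lab
    dead[np.flatnonzero(is_cell)] = dead_cells

    # center-specific affine distortion on raw fluorescence + viability
    if center_gain is not None:
        cols = fl_cols + [via_col]
        data[:, cols] = data[:, cols] * center_gain + center_offset

    frame = EventFrame(data, list(panel.channels))
    lab_df = pd.DataFrame(
        {
            "cell_type": labels,
            "is_doublet": is_doublet,
            "is_debris": is_debris,
            "is_dead": dead,
        }
    )
    return frame, lab_df


def apply_spillover(frame: EventFrame, S: SpilloverMatrix) -> EventFrame:
    """Forward spillover mixing on raw fluorescence: observed = true @ S."""
    fl = frame.roles(FLUORO)
    if [frame.channels[i].detector for i in fl] != S.detectors:
        raise ValueError("spillover detectors do not match frame fluorescence channels")
    if frame.transformed[fl].any():
        raise ValueError("spillover applies to raw intensities only")
    out = frame.copy()
    out.data[:, fl] = out.data[:, fl] @ S.matrix
    return out


def center_distortion(
    config: SimulationConfig, panel: PanelDesign, center: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel affine distortion for one center (gain, offset).

    Gains are lognormal(0, gain_sd), offsets normal(0, offset_sd); drawn
    from a center-keyed stream so every file from a center shares them.
    """
    rng = config.rng_for(0xD15, PANEL_NAMES.index(panel.name), center)
    n = len(panel.fluoro_markers) + 1  # + viability
    gain = rng.lognormal(0.0, config.gain_sd, n) if config.gain_sd > 0 else np.ones(n)
    offset = rng.normal(0.0, config.offset_sd, n) if config.offset_sd > 0 else np.zeros(n)
    return gain, offset


# ---------------------------------------------------------------------------
# whole-experiment driver
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFile:
    center: int
    sample: int
    replicate: int
    panel: str
    frame: EventFrame  # raw, distorted, spillover-mixed (as acquired)
    labels: pd.DataFrame
    leaf_proportions: dict[str, float]


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    panels: dict[str, PanelDesign]
    truth: dict[str, GroundTruth]
    files: list[SimulatedFile]
    spillover: SpilloverMatrix

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "center": f.center,
                    "sample": f.sample,
                    "replicate": f.replicate,
                    "panel": f.panel,
                }
                for f in self.files
            ]
        )

    def truth_table(self) -> pd.DataFrame:
        """Population-level true proportions, one row per file x population."""
        parts = [
            self.truth[name].population_truth(panel)
            for name, panel in self.panels.items()
        ]
        out = pd.concat(parts, ignore_index=True)
        out["method"] = "truth"
        return out


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate the full crossed experiment for the configured panels.

    Deterministic given ``config.seed``: proportions, effects, and each
    file's events come from counter-derived independent streams, so file
    order never influences content.
    """
    panels = {name: builtin_panel(name) for name in config.panels}
    first = next(iter(panels.values()))
    spill = config.spillover or default_spillover(first.fluoro_detectors)
    truth: dict[str, GroundTruth] = {}
    files: list[SimulatedFile] = []
    for p_idx, (name, panel) in enumerate(panels.items()):
        gt = draw_population_proportions(config, panel, config.rng_for(0xB10, p_idx))
        truth[name] = gt
        for j in range(config.n_centers):
            gain, offset = center_distortion(config, panel, j)
            for i in range(config.n_samples):
                for r in range(config.n_replicates):
                    leaves = gt.file_leaf_proportions(j, i, r)
                    rng = config.rng_for(0xF11E, p_idx, j, i, r)
                    frame, labels = synthesize_events(
                        leaves, panel, config.events_per_file, rng, config, gain, offset
                    )
                    frame = apply_spillover(frame, spill)
                    files.append(SimulatedFile(j, i, r, name, frame, labels, leaves))
    return SimulatedExperiment(config, panels, truth, files, spill)


def truth_masks(
    panel: PanelDesign, labels: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Per-population ground-truth event masks (live singlet cells only)."""
    ok = ~(labels["is_doublet"] | labels["is_debris"] | labels["is_dead"])
    ok = ok.to_numpy()
    by_type = {ct.name: (labels["cell_type"] == ct.name).to_numpy() for ct in panel.cell_types}
    other = (labels["cell_type"] == "other").to_numpy()
    out = {}
    for pop in panel.populations:
        m = np.zeros(len(labels), dtype=bool)
        for ct in panel.cell_types:
            if ct.matches(pop.predicate):
                m |= by_type[ct.name]
        # the all-negative remainder satisfies purely negative predicates
        if all(s in ("-", "low") for s in pop.predicate.values()):
            m |= other
        out[pop.name] = m & ok
    return out


def write_experiment(exp: SimulatedExperiment, out_dir, fmt: str = "fcs") -> pd.DataFrame:
    """Write files as {center}_{sample}_{replicate}_{panel}.{fcs,csv} plus
    manifest, ground-truth and spillover CSVs. Returns the manifest."""
    from . import fcsio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in exp.files:
        stem = f"C{f.center}_S{f.sample}_R{f.replicate}_{f.panel}"
        if fmt == "fcs":
            path = out / f"{stem}.fcs"
            fcsio.write_fcs(path, f.frame)
        elif fmt == "csv":
            path = out / f"{stem}.csv"
            fcsio.write_events_csv(path, f.frame)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        rows.append(
            {
                "center": f.center,
                "sample": f.sample,
                "replicate": f.replicate,
                "panel": f.panel,
                "path": str(path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    exp.truth_table().to_csv(out / "ground_truth.csv", index=False)
    exp.spillover.to_csv(out / "spillover.csv")
    return manifest
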