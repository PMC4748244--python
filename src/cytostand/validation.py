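"""Self-validation studies: the package run against its own ground truth.

Each function here executes one headline check of the pipeline on synthetic
data with known generating parameters and returns the measured quantities:
variance-component recovery, gating accuracy against per-event truth
labels, confidence-interval coverage, bias detection operating
characteristics, and power-formula self-consistency. Both the test suite
and the reproduction script call these, so the numbers they report are
always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gating import ROOT
from .panels import PanelDesign
from .pipeline import gate_experiment
from .power import min_detectable_effect, monte_carlo_power, scenario_variance
from .simulate import (
    SimulationConfig,
    simulate_experiment,
    simulate_proportion_model,
    truth_masks,
)
from .variance import bias, fit_variance_components, sample_level_estimates

STUDY_SIGMAS = (0.5, 0.3, 0.2)  # (sample, center, residual), logit SD scale


def variance_recovery(
    n_datasets: int = 2500,
    sigmas: tuple[float, float, float] = STUDY_SIGMAS,
    mu: float = -1.5,
    seed: int = 0,
) -> dict[str, float]:
    """Median REML estimates (SD scale) over replicated crossed datasets.

    Each dataset is the study design (9 centers x 3 samples x 3
    replicates) drawn from the logit-normal crossed model at ``sigmas``.
    Reported medians carry the intrinsic small-sample skew of a variance
    estimate with 2 degrees of freedom for the 3-sample component.
    """
    rng = np.random.default_rng(seed)
    ests = np.empty((n_datasets, 3))
    for k in range(n_datasets):
        df = simulate_proportion_model(mu, *sigmas, rng=rng)
        c = fit_variance_components(df)
        ests[k] = [c.sigma2_sample, c.sigma2_center, c.sigma2_residual]
    med = np.sqrt(np.median(ests, axis=0))
    out = {
        "sigma_sample_median": float(med[0]),
        "sigma_center_median": float(med[1]),
        "sigma_residual_median": float(med[2]),
    }
    for name, m, t in zip(("sample", "center", "residual"), med, sigmas):
        out[f"rel_err_{name}"] = float(abs(m - t) / t)
    return out


def null_component_shrinkage(n_datasets: int = 50, seed: int = 0) -> dict[str, float]:
    """How often a zero center component is estimated below 0.01."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_datasets):
        df = simulate_proportion_model(-1.0, 0.5, 0.0, 0.2, rng=rng)
        hits += fit_variance_components(df).sigma2_center < 0.01
    return {"shrunk": int(hits), "total": int(n_datasets)}


def _f1(gated: np.ndarray, truth: np.ndarray) -> float:
    tp = int((gated & truth).sum())
    denom = 2 * tp + int((gated & ~truth).sum()) + int((~gated & truth).sum())
    return 2 * tp / denom if denom else float("nan")


def gating_accuracy(
    n_centers: int = 3,
    events_per_file: int = 30_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Event-level F1 of every published population vs. truth labels.

    Runs the full pipeline (simulate, compensate, transform, pre-gate,
    template gating) on one sample replicated across centers for all four
    panels; also verifies count conservation along every gate path.
    Returns one row per (panel, population, file).
    """
    cfg = SimulationConfig(
        n_centers=n_centers,
        n_samples=1,
        n_replicates=1,
        events_per_file=events_per_file,
        seed=seed,
    )
    exp = simulate_experiment(cfg)
    records = gate_experiment(exp)
    files = {(f.center, f.sample, f.replicate, f.panel): f for f in exp.files}
    rows = []
    for meta, tree in records:
        f = files[(meta["center"], meta["sample"], meta["replicate"], meta["panel"])]
        panel: PanelDesign = exp.panels[f.panel]
        masks = truth_masks(panel, f.labels)
        for res in tree.results.values():
            if res.alias != ROOT:
                parent = tree.results[res.parent]
                if res.count > parent.count or (res.mask & ~parent.mask).any():
                    raise AssertionError(
                        f"count conservation violated at {f.panel}/{res.alias}"
                    )
        for pop in panel.populations:
            rows.append(
                {
                    "panel": f.panel,
                    "population": pop.name,
                    "center": f.center,
                    "reliable": pop.reliable,
                    "f1": _f1(tree.mask(pop.name), masks[pop.name]),
                }
            )
    return pd.DataFrame(rows)


def ci_coverage(
    n_datasets: int = 200,
    sigmas: tuple[float, float, float] = STUDY_SIGMAS,
    mu: float = -1.5,
    seed: int = 0,
) -> dict[str, float]:
    """Coverage of the 95% sample-level CIs for the true logit means."""
    rng = np.random.default_rng(seed)
    covered = total = 0
    for _ in range(n_datasets):
        df = simulate_proportion_model(mu, *sigmas, rng=rng)
        est = sample_level_estimates(df)
        truth = df.groupby("sample")["alpha"].first() + mu
        for _, r in est.iterrows():
            total += 1
            covered += bool(truth[r["sample"]] >= r["y_lo"] and truth[r["sample"]] <= r["y_hi"])
    return {"coverage": covered / total, "n": total}


def bias_operating_characteristics(
    n_seeds: int = 50, shift: float = 0.5, seed: int = 0
) -> dict[str, float]:
    """False-significance under the null and recovery of an injected shift.

    Null: two independent gating simulations of the same truth (shared
    sample effects, independent center/residual noise). Shift: the same
    dataset offset by ``shift`` on the logit scale — both methods then see
    identical cells, as when two pipelines gate the same files.
    """
    rng = np.random.default_rng(seed)
    false_sig = detected = covered = 0
    for _ in range(n_seeds):
        alpha = rng.normal(0, 0.5, 3)

        def draw() -> pd.DataFrame:
            d = simulate_proportion_model(-1.5, 0.0, 0.3, 0.2, rng=rng)
            d["y"] = d["y"] + alpha[d["sample"].to_numpy()]
            return d

        d1, d2 = draw(), draw()
        e1, e2 = sample_level_estimates(d1), sample_level_estimates(d2)
        false_sig += bool(bias(e1, e2)["significant"].any())
        d3 = d1.copy()
        d3["y"] = d3["y"] + shift
        b = bias(sample_level_estimates(d3), e1)
        detected += bool(b["significant"].all())
        covered += bool(((b["lo"] <= shift) & (shift <= b["hi"])).all())
    return {
        "false_significance_rate": false_sig / n_seeds,
        "shift_detection_rate": detected / n_seeds,
        "shift_ci_coverage": covered / n_seeds,
        "n_seeds": n_seeds,
    }


def power_self_consistency(
    n_per_group: int = 16, n_trials: int = 500, seed: int = 0
) -> dict[str, float]:
    """Monte-Carlo rejection rate at the closed-form delta_min."""
    comp = {
        "sigma2_sample": STUDY_SIGMAS[0] ** 2,
        "sigma2_center": STUDY_SIGMAS[1] ** 2,
        "sigma2_residual": STUDY_SIGMAS[2] ** 2,
    }
    delta = min_detectable_effect(comp, n_per_group, scenario="central")
    V = scenario_variance(comp, "central")
    rej = monte_carlo_power(
        delta, V, n_per_group, n_trials=n_trials, rng=np.random.default_rng(seed)
    )
    return {"delta_min": delta, "mc_rejection_rate": rej, "n_trials": n_trials}
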