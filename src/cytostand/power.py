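"""Minimum-detectable-effect-size power analysis on the logit scale.

For a two-group comparison of logit proportions with n subjects per group,
the per-subject variance depends on the study design scenario:

* ``single-center`` — all data from one site: V = sigma2_sample +
  sigma2_residual / r;
* ``central`` — multi-center data, centrally (or automated) gated:
  V adds sigma2_center;
* ``local`` — multi-center data gated at each site: V further adds the
  excess variance attributable to site-specific gating.

The minimum detectable effect at significance alpha (two-sided) and the
stated power is the familiar closed form

    delta_min = (z_{1-alpha/2} + z_{power}) * sqrt(2 V / n).

Monte-Carlo self-consistency (simulating the two-group study at delta_min
and counting t-test rejections) is provided as an empirical check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .variance import VarianceComponents

SCENARIOS = ("single-center", "central", "local")


def scenario_variance(
    components: VarianceComponents | dict,
    scenario: str,
    extra_local_variance: float = 0.0,
    replicates: int = 1,
) -> float:
    """Per-subject logit-scale variance under a design scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    c = components.as_dict() if isinstance(components, VarianceComponents) else components
    V = c["sigma2_sample"] + c["sigma2_residual"] / replicates
    if scenario != "single-center":
        V += c["sigma2_center"]
    if scenario == "local":
        V += extra_local_variance
    return float(V)


def min_detectable_effect(
    components,
    n_per_group: int,
    power: float = 0.80,
    alpha: float = 0.05,
    scenario: str = "central",
    extra_local_variance: float = 0.0,
    replicates: int = 1,
) -> float:
    """Smallest logit-scale group difference detectable at the stated power."""
    if not (0 < power < 1) or not (0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    V = scenario_variance(components, scenario, extra_local_variance, replicates)
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return float(z * np.sqrt(2.0 * V / n_per_group))


def power_curve(
    components,
    n_grid,
    scenarios=SCENARIOS,
    power: float = 0.80,
    alpha: float = 0.05,
    extra_local_variance: float = 0.0,
    replicates: int = 1,
) -> pd.DataFrame:
    """delta_min over a grid of group sizes, one curve per scenario.

    Verifies the structural guarantees: each curve decreases in n, and at
    every n the ordering single-center <= central <= local holds.
    """
    n_grid = np.asarray(list(n_grid), dtype=int)
    if not (np.diff(n_grid) > 0).all():
        raise ValueError("n_grid must be strictly increasing")
    rows = []
    for scen in scenarios:
        for n in n_grid:
            rows.append(
                {
                    "scenario": scen,
                    "n_per_group": int(n),
                    "delta_min": min_detectable_effect(
                        components, int(n), power, alpha, scen, extra_local_variance, replicates
                    ),
                }
            )
    df = pd.DataFrame(rows)
    for scen, grp in df.groupby("scenario"):
        d = grp.sort_values("n_per_group")["delta_min"].to_numpy()
        if not (np.diff(d) < 0).all():
            raise AssertionError(f"delta_min not decreasing in n for {scen}")
    wide = df.pivot(index="n_per_group", columns="scenario", values="delta_min")
    if {"single-center", "central"} <= set(wide.columns):
        assert (wide["single-center"] <= wide["central"] + 1e-12).all()
    if {"central", "local"} <= set(wide.columns):
        assert (wide["central"] <= wide["local"] + 1e-12).all()
    return df


def extra_local_variance(
    components_local: VarianceComponents, components_central: VarianceComponents
) -> float:
    """Excess (center + residual) variance of local over central gating.

    The local-gating power scenario charges this excess on top of the
    central-gating variance; clipped at zero.
    """
    extra = (
        components_local.sigma2_center
        + components_local.sigma2_residual
        - components_central.sigma2_center
        - components_central.sigma2_residual
    )
    return float(max(extra, 0.0))


def monte_carlo_power(
    delta: float,
    variance: float,
    n_per_group: int,
    alpha: float = 0.05,
    n_trials: int = 500,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical two-sample t-test rejection rate at group difference delta."""
    rng = np.random.default_rng() if rng is None else rng
    sd = np.sqrt(variance)
    a = rng.normal(0.0, sd, size=(n_trials, n_per_group))
    b = rng.normal(delta, sd, size=(n_trials, n_per_group))
    _, p = stats.ttest_ind(a, b, axis=1)
    return float((p < alpha).mean())
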