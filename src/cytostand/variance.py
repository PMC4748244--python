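"""Logit-scale crossed random-effects variance decomposition and bias.

The measurement model for a fixed panel, population and gating method is

    y_rij = logit(p_rij) = mu + alpha_i + beta_j + eps_rij

with sample effects alpha_i ~ N(0, sigma_sample^2), center effects
beta_j ~ N(0, sigma_center^2) and residual technical error
eps_rij ~ N(0, sigma_residual^2). Components are estimated by REML —
direct maximization of the restricted log-likelihood over the non-negative
orthant, with the balanced-design ANOVA moment estimator as the starting
point and as an independent cross-check. Sample-level estimates come from
the companion fit in which alpha_i is replaced by fixed per-sample means
(generalized least squares under the fitted covariance), and bias between
two gating methods is the difference of those fixed-effect estimates with
a summed-variance Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

Z95 = 1.959963984540054  # standard normal 97.5% quantile

_LOG_FLOOR = np.log(1e-10)


def logit(p):
    """Log-odds; rejects values outside (0, 1)."""
    p = np.asarray(p, dtype=np.float64)
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("logit requires 0 < p < 1; apply count correction first")
    return np.log(p / (1.0 - p))


def inv_logit(y):
    y = np.asarray(y, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-y))


def corrected_proportion(count, denominator):
    """Empirical-count continuity correction p' = (k + 0.5) / (n + 1)."""
    count = np.asarray(count, dtype=np.float64)
    denominator = np.asarray(denominator, dtype=np.float64)
    if (denominator <= 0).any():
        raise ValueError("denominator counts must be positive")
    return (count + 0.5) / (denominator + 1.0)


def observations_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """PopulationTable rows -> (sample, center, replicate, y) observations."""
    p = corrected_proportion(table["count"], table["denominator_count"])
    out = table[["sample", "center", "replicate"]].copy()
    out["y"] = logit(p)
    return out


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _design(obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = obs["y"].to_numpy(dtype=np.float64)
    s_codes = pd.Categorical(obs["sample"]).codes
    c_codes = pd.Categorical(obs["center"]).codes
    Zs = np.eye(s_codes.max() + 1)[s_codes]
    Zc = np.eye(c_codes.max() + 1)[c_codes]
    return y, Zs, Zc


def _reml_neg_loglik(
    log_s2: np.ndarray, y: np.ndarray, X: np.ndarray, parts: list[np.ndarray]
) -> float:
    """-2 x restricted log-likelihood (up to a constant)."""
    n = len(y)
    V = np.zeros((n, n))
    for s2, G in zip(np.exp(log_s2), parts):
        V += s2 * G
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_V = 2.0 * np.log(np.diag(L)).sum()
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    return logdet_V + logdet_X + quad


@dataclass
class VarianceComponents:
    sigma2_sample: float
    sigma2_center: float
    sigma2_residual: float
    mu: float
    converged: bool
    boundary: dict[str, bool]
    moment: dict[str, float]  # ANOVA cross-check (NaN when design unbalanced)
    n_obs: int

    @property
    def total(self) -> float:
        return self.sigma2_sample + self.sigma2_center + self.sigma2_residual

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_sample": self.sigma2_sample,
            "sigma2_center": self.sigma2_center,
            "sigma2_residual": self.sigma2_residual,
            "mu": self.mu,
        }


def anova_components(obs: pd.DataFrame) -> dict[str, float]:
    """Balanced-design method-of-moments (ANOVA) estimator.

    For a samples x b centers x r replicates without interaction:
    E[MS_sample] = sigma_e^2 + b r sigma_s^2, E[MS_center] = sigma_e^2 +
    a r sigma_c^2, and the additive-model residual mean square estimates
    sigma_e^2. Returns NaNs when the design is unbalanced.
    """
    counts = obs.groupby(["sample", "center"])["y"].count()
    a = obs["sample"].nunique()
    b = obs["center"].nunique()
    if counts.nunique() != 1 or len(counts) != a * b:
        return {k: float("nan") for k in ("sigma2_sample", "sigma2_center", "sigma2_residual")}
    r = int(counts.iloc[0])
    y = obs["y"].to_numpy()
    grand = y.mean()
    m_s = obs.groupby("sample")["y"].mean().to_numpy()
    m_c = obs.groupby("center")["y"].mean().to_numpy()
    ss_s = b * r * ((m_s - grand) ** 2).sum()
    ss_c = a * r * ((m_c - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_res = ss_tot - ss_s - ss_c
    df_res = a * b * r - a - b + 1
    ms_s = ss_s / (a - 1)
    ms_c = ss_c / (b - 1)
    ms_e = ss_res / df_res
    return {
        "sigma2_sample": (ms_s - ms_e) / (b * r),
        "sigma2_center": (ms_c - ms_e) / (a * r),
        "sigma2_residual": ms_e,
    }


def fit_variance_components(obs: pd.DataFrame) -> VarianceComponents:
    """REML estimates of (sigma2_sample, sigma2_center, sigma2_residual).

    ``obs`` needs columns (sample, center, y); the intercept is profiled
    out. Deterministic: quasi-Newton on log-variances from the moment
    start. Components driven to the lower bound are reported as 0 and
    flagged ``boundary``.
    """
    if obs["sample"].nunique() < 2 or obs["center"].nunique() < 2:
        raise ValueError("need at least 2 samples and 2 centers")
    y, Zs, Zc = _design(obs)
    n = len(y)
    X = np.ones((n, 1))
    parts = [Zs @ Zs.T, Zc @ Zc.T, np.eye(n)]

    mom = anova_components(obs)
    var_y = max(float(np.var(y)), 1e-8)

    def _start(key: str) -> float:
        v = mom[key]
        if not np.isfinite(v):
            v = var_y / 3.0
        return max(v, 1e-4 * var_y)

    start = np.array([_start("sigma2_sample"), _start("sigma2_center"), _start("sigma2_residual")])
    res = optimize.minimize(
        _reml_neg_loglik,
        np.log(start),
        args=(y, X, parts),
        method="L-BFGS-B",
        bounds=[(_LOG_FLOOR, np.log(100.0 * var_y + 1e-6))] * 3,
    )
    s2 = np.exp(res.x)
    boundary = {
        name: bool(res.x[i] < _LOG_FLOOR + 2.0)
        for i, name in enumerate(("sample", "center", "residual"))
    }
    s2 = np.where([boundary["sample"], boundary["center"], boundary["residual"]], 0.0, s2)
    # GLS intercept under the fitted covariance
    V = s2[0] * parts[0] + s2[1] * parts[1] + max(s2[2], 1e-12) * parts[2]
    Vi_y = np.linalg.solve(V, y)
    Vi_1 = np.linalg.solve(V, X)
    mu = float((X.T @ Vi_y).item() / (X.T @ Vi_1).item())
    return VarianceComponents(
        float(s2[0]),
        float(s2[1]),
        float(s2[2]),
        mu,
        bool(res.success),
        boundary,
        mom,
        n,
    )


# ---------------------------------------------------------------------------
# sample-level fixed effects, CIs, bias
# ---------------------------------------------------------------------------


def sample_level_estimates(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fixed-effect estimates with 95% Wald CIs.

    Refits y = mu_i + beta_j + eps with fixed per-sample means and random
    center effects (REML for sigma2_center, sigma2_residual with the
    sample-mean design matrix), then GLS under the fitted covariance.
    Intervals use a t quantile with n_centers - 1 degrees of freedom: the
    center-level variance that dominates the standard error is estimated
    from few centers, and a normal quantile visibly under-covers there.
    Returns one row per sample with logit-scale and proportion-scale
    estimates; the back-transform is monotone so CI endpoints map in order.
    """
    y, Zs, Zc = _design(obs)
    n = len(y)
    X = Zs  # per-sample fixed means
    parts = [Zc @ Zc.T, np.eye(n)]
    var_y = max(float(np.var(y)), 1e-10)
    start = np.log(np.array([var_y / 2, var_y / 2]))
    res = optimize.minimize(
        _reml_neg_loglik,
        start,
        args=(y, X, parts),
        method="L-BFGS-B",
        bounds=[(_LOG_FLOOR, np.log(100.0 * var_y + 1e-6))] * 2,
    )
    s2c, s2e = np.exp(res.x)
    V = s2c * parts[0] + max(s2e, 1e-12) * parts[1]
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, Vi_X.T @ y)
    cov = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))

    samples = pd.Categorical(obs["sample"]).categories
    n_centers = obs.groupby("sample")["center"].nunique()
    df_t = max(int(obs["center"].nunique()) - 1, 1)
    q = float(stats.t.ppf(0.975, df_t))
    rows = []
    for i, s in enumerate(samples):
        lo, hi = beta[i] - q * se[i], beta[i] + q * se[i]
        rows.append(
            {
                "sample": s,
                "y_hat": float(beta[i]),
                "se": float(se[i]),
                "y_lo": float(lo),
                "y_hi": float(hi),
                "p_hat": float(inv_logit(beta[i])),
                "p_lo": float(inv_logit(lo)),
                "p_hi": float(inv_logit(hi)),
                "df": df_t,
                "unstable": bool(n_centers.get(s, 0) < 2),
            }
        )
    return pd.DataFrame(rows)


def bias(est_auto: pd.DataFrame, est_manual: pd.DataFrame) -> pd.DataFrame:
    """Bias between gating methods: difference of sample-level estimates.

    Delta_i = y_hat_i(auto) - y_hat_i(manual) on the logit scale, with a
    Wald CI from summed variances (independent-estimate approximation).
    ``significant`` is True iff the CI of the difference excludes 0; the
    more conservative CI-overlap rule is also reported. Samples present in
    only one method are flagged missing.
    """
    merged = est_auto.merge(
        est_manual, on="sample", how="outer", suffixes=("_auto", "_manual"), indicator=True
    )
    rows = []
    for rec in merged.to_dict("records"):
        if rec["_merge"] != "both":
            rows.append(
                {"sample": rec["sample"], "delta": np.nan, "missing": True,
                 "se": np.nan, "lo": np.nan, "hi": np.nan,
                 "significant": False, "overlap_rule_significant": False,
                 "delta_proportion": np.nan}
            )
            continue
        d = rec["y_hat_auto"] - rec["y_hat_manual"]
        se = float(np.hypot(rec["se_auto"], rec["se_manual"]))
        dfs = [rec.get("df_auto"), rec.get("df_manual")]
        dfs = [v for v in dfs if v is not None and np.isfinite(v)]
        q = float(stats.t.ppf(0.975, max(int(min(dfs)), 1))) if dfs else Z95
        lo, hi = d - q * se, d + q * se
        overlap = not (rec["y_lo_auto"] > rec["y_hi_manual"] or rec["y_lo_manual"] > rec["y_hi_auto"])
        rows.append(
            {
                "sample": rec["sample"],
                "delta": float(d),
                "se": se,
                "lo": float(lo),
                "hi": float(hi),
                "significant": bool(lo > 0 or hi < 0),
                "overlap_rule_significant": not overlap,
                "delta_proportion": float(
                    inv_logit(rec["y_hat_auto"]) - inv_logit(rec["y_hat_manual"])
                ),
                "missing": False,
            }
        )
    return pd.DataFrame(rows)
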