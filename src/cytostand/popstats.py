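"""Tidy population tables and coefficient-of-variation summaries.

The PopulationTable is the tidy record of every measurement: one row per
(center, sample, replicate, panel, population, gating method) with the
event count, the declared denominator count, and the reported proportion.
CV summaries compare within-site spread (across staining replicates) to
between-site spread (across center means), the standard reproducibility
view for cross-laboratory immunophenotyping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

KEY = ["center", "sample", "replicate", "panel", "population", "method"]


def extract_proportions(records: list[tuple[dict, "object"]], method: str) -> pd.DataFrame:
    """Assemble a PopulationTable from evaluated gating trees.

    ``records`` pairs a metadata dict (center, sample, replicate, panel)
    with the file's GatingTree. Unresolvable populations keep their rows
    (count 0, flagged), they are never dropped silently.
    """
    parts = []
    for meta, tree in records:
        props = tree.proportions()
        for col, val in meta.items():
            props[col] = val
        parts.append(props)
    table = pd.concat(parts, ignore_index=True)
    table["method"] = method
    dup = table.duplicated(subset=KEY)
    if dup.any():
        raise ValueError("duplicate (file, population, method) rows in PopulationTable")
    return table


def validate_population_table(table: pd.DataFrame) -> None:
    ok = table["proportion"].dropna()
    if ((ok < 0) | (ok > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    if "count" in table and "denominator_count" in table:
        bad = table["count"] > table["denominator_count"]
        if bad.any():
            raise ValueError("count exceeds denominator count")
    if table.duplicated(subset=[k for k in KEY if k in table.columns]).any():
        raise ValueError("duplicate measurement rows")


def cv(values) -> float:
    """Percent coefficient of variation, sample SD (n-1) over the mean.

    Undefined (NaN) for fewer than two finite values or a zero mean.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


def cv_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Within-site vs between-site CV per (panel, population, method).

    Within-site: the CV across replicates, per center, averaged (arithmetic
    mean) over centers. Between-site: the CV across centers of the
    per-center mean proportion. Both groupings for the between/within
    comparison are emitted: per biological sample (``grouping='sample'``)
    and pooled over samples (``grouping='pooled'``). ``reduction_pct`` is
    the percent reduction of within- relative to between-site CV.
    """
    validate_population_table(table)
    rows = []

    def summarize(grp: pd.DataFrame, keys: dict) -> None:
        per_center = grp.groupby("center")["proportion"]
        within = per_center.apply(cv)
        between = cv(per_center.mean())
        w = float(np.nanmean(within)) if len(within) else float("nan")
        imbalanced = grp.groupby(["center"])["replicate"].count().nunique() > 1
        rows.append(
            {
                **keys,
                "within_site_cv": w,
                "between_site_cv": between,
                "reduction_pct": 100.0 * (1.0 - w / between) if between else np.nan,
                "n_centers": grp["center"].nunique(),
                "imbalanced": bool(imbalanced),
            }
        )

    for (panel, pop, method, sample), grp in table.groupby(
        ["panel", "population", "method", "sample"]
    ):
        summarize(
            grp,
            {
                "panel": panel,
                "population": pop,
                "method": method,
                "sample": sample,
                "grouping": "sample",
            },
        )
    for (panel, pop, method), grp in table.groupby(["panel", "population", "method"]):
        summarize(
            grp,
            {
                "panel": panel,
                "population": pop,
                "method": method,
                "sample": -1,
                "grouping": "pooled",
            },
        )
    return pd.DataFrame(rows)


def predicted_between_site_cv(
    p: float, sigma2_center: float, sigma2_residual: float, n_replicates: int
) -> float:
    """Delta-method between-site CV on the proportion scale.

    A center mean averages ``n_replicates`` logits, so its logit-scale
    variance is sigma2_center + sigma2_residual / n_replicates; the
    proportion-scale SD follows from dp/dy = p(1-p).
    """
    var_y = sigma2_center + sigma2_residual / n_replicates
    sd_p = p * (1.0 - p) * np.sqrt(var_y)
    return float(100.0 * sd_p / p)
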