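"""Template-driven hierarchical density gating.

The engine reproduces the supervised sequential strategy of density-based
automated gating frameworks: each gate operates only on its parent gate's
events, choosing 1-D cut-points from characteristics of the kernel density
estimate (valley between the two tallest modes; a robust-SD offset from the
main mode when the distribution is effectively unimodal). Two-marker
quadrant gates, tail ("high") gates and Boolean combination gates complete
the vocabulary needed by the four built-in panel hierarchies.

Templates are plain CSV files (one row per gate) so a hierarchy is data,
not code; the four built-in templates are reconstructions of the published
panel phenotypes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, median_abs_deviation

from .frames import EventFrame

GRID_SIZE = 512
GRID_PAD = 0.05
PEAK_FRAC = 0.05
MIN_EVENTS_DENSITY = 200
MIN_EVENTS_TAIL = 50
FALLBACK_K = 3.0


# ---------------------------------------------------------------------------
# density machinery
# ---------------------------------------------------------------------------


def density_grid(
    values: np.ndarray,
    bandwidth_factor: float = 1.0,
    grid_size: int = GRID_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE (Silverman bandwidth x factor) on a padded linear grid."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    pad = GRID_PAD * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    kde = gaussian_kde(values, bw_method="silverman")
    if bandwidth_factor != 1.0:
        kde.set_bandwidth(kde.factor * bandwidth_factor)
    return grid, kde(grid)


def _local_maxima(density: np.ndarray) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima (plateau-safe)."""
    n = len(density)
    idx = []
    i = 1
    while i < n - 1:
        if density[i] > density[i - 1]:
            j = i
            while j < n - 1 and density[j + 1] == density[j]:
                j += 1
            if j == n - 1 or density[j + 1] < density[j]:
                idx.append(i)  # leftmost point of the plateau
            i = j + 1
        else:
            i += 1
    if n >= 2 and density[0] > density[1]:
        idx.insert(0, 0)
    if n >= 2 and density[-1] > density[-2]:
        idx.append(n - 1)
    return np.array(sorted(idx), dtype=int)


def robust_sd(values: np.ndarray) -> float:
    """Normal-consistent MAD scale estimate."""
    return float(median_abs_deviation(values, scale="normal"))


def density_cutpoint(
    values: np.ndarray,
    bandwidth_factor: float = 1.0,
    peak_frac: float = PEAK_FRAC,
    fallback_k: float = FALLBACK_K,
    fallback_side: str = "auto",
    min_events: int = MIN_EVENTS_DENSITY,
    grid_size: int = GRID_SIZE,
) -> float:
    """Choose a 1-D threshold from the shape of the density estimate.

    With two or more modes of height >= ``peak_frac`` x the global maximum,
    the threshold is the leftmost minimizer of the KDE on the grid between
    the two tallest modes. With a single qualifying mode the threshold
    falls back to mode + / - ``fallback_k`` robust SDs, on ``fallback_side``
    ('+' above the mode, '-' below, 'auto' = the side with the longer tail).
    Below ``min_events`` events the median is used (with a warning); a
    constant input is degenerate and rejected.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0 or values.min() == values.max():
        raise ValueError("degenerate distribution: constant or empty input")
    if values.size < min_events:
        warnings.warn(
            f"only {values.size} events (<{min_events}); falling back to the median"
        )
        return float(np.quantile(values, 0.5))
    grid, dens = density_grid(values, bandwidth_factor, grid_size)
    peaks = _local_maxima(dens)
    peaks = peaks[dens[peaks] >= peak_frac * dens.max()]
    # peaks closer than a couple of bandwidths are ripples on one mode, not
    # distinct modes: keep the tallest representative of each cluster
    bw = np.std(values, ddof=1) * gaussian_kde(values, bw_method="silverman").factor
    min_sep = 2.5 * bw * bandwidth_factor
    order = np.argsort(-dens[peaks], kind="stable")
    selected: list[int] = []
    for idx in peaks[order]:
        if all(abs(grid[idx] - grid[j]) >= min_sep for j in selected):
            selected.append(int(idx))
    if len(selected) >= 2:
        # the two tallest remaining peaks; leftmost wins height ties
        a, b = sorted(selected[:2])
        between = slice(a, b + 1)
        return float(grid[a + int(np.argmin(dens[between]))])
    mode = float(grid[int(np.argmax(dens))])
    sd = robust_sd(values)
    if sd == 0:
        sd = float(values.std())
    side = fallback_side
    if side == "auto":
        q01, q99 = np.quantile(values, [0.01, 0.99])
        side = "+" if (q99 - mode) >= (mode - q01) else "-"
    return mode + fallback_k * sd if side == "+" else mode - fallback_k * sd


def quadrant_gate(
    x: np.ndarray, y: np.ndarray, cut_x: float, cut_y: float
) -> dict[str, np.ndarray]:
    """Partition events into the four quadrants; value >= cut counts as '+'.

    Keys are two-character sign strings, x first: '++', '+-', '-+', '--'.
    """
    if not (np.isfinite(cut_x) and np.isfinite(cut_y)):
        raise ValueError("quadrant cuts must be finite")
    xp = np.asarray(x) >= cut_x
    yp = np.asarray(y) >= cut_y
    return {
        "++": xp & yp,
        "+-": xp & ~yp,
        "-+": ~xp & yp,
        "--": ~xp & ~yp,
    }


def tail_gate(
    values: np.ndarray,
    k: float = 3.0,
    side: str = "+",
    grid_size: int = GRID_SIZE,
) -> float:
    """Threshold for 'high' (or 'low') phenotypes: main mode +/- k robust SDs.

    With fewer than ``MIN_EVENTS_TAIL`` events the KDE mode is unstable and
    the threshold widens to the fixed 0.99 (or 0.01) quantile.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0 or values.min() == values.max():
        raise ValueError("degenerate distribution: constant or empty input")
    if values.size < MIN_EVENTS_TAIL:
        warnings.warn(
            f"only {values.size} events (<{MIN_EVENTS_TAIL}); using fixed quantile"
        )
        return float(np.quantile(values, 0.99 if side == "+" else 0.01))
    grid, dens = density_grid(values, grid_size=grid_size)
    mode = float(grid[int(np.argmax(dens))])
    sd = robust_sd(values)
    if sd == 0:
        sd = float(values.std())
    return mode + k * sd if side == "+" else mode - k * sd


_TOKEN = re.compile(r"\s*([&|!()])\s*")


def boolean_gate(masks: dict[str, np.ndarray], expression: str) -> np.ndarray:
    """Event-wise Boolean combination of named masks with & | ! and parens."""
    tokens = [t for t in _TOKEN.split(expression) if t and not t.isspace()]
    tokens = [t.strip() for t in tokens if t.strip()]
    pos = 0

    def parse_or() -> np.ndarray:
        nonlocal pos
        left = parse_and()
        while pos < len(tokens) and tokens[pos] == "|":
            pos += 1
            left = left | parse_and()
        return left

    def parse_and() -> np.ndarray:
        nonlocal pos
        left = parse_not()
        while pos < len(tokens) and tokens[pos] == "&":
            pos += 1
            left = left & parse_not()
        return left

    def parse_not() -> np.ndarray:
        nonlocal pos
        if pos < len(tokens) and tokens[pos] == "!":
            pos += 1
            return ~parse_not()
        return parse_atom()

    def parse_atom() -> np.ndarray:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"truncated boolean expression: {expression!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            inner = parse_or()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced parentheses in {expression!r}")
            pos += 1
            return inner
        pos += 1
        if tok not in masks:
            raise ValueError(f"unknown alias {tok!r} in boolean expression")
        return masks[tok]

    out = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in boolean expression {expression!r}")
    return out


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

METHODS = ("density_cut", "quadrant", "rectangle", "tail", "boolean")
ROOT = "root"


@dataclass
class TemplateRow:
    alias: str
    parent: str
    dims: list[str]
    method: str
    args: dict[str, str]
    signs: list[str]
    denominator: str  # '' = parent
    report: bool = True


@dataclass
class GatingTemplate:
    panel: str
    rows: list[TemplateRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = {ROOT}
        for n, row in enumerate(self.rows, start=1):
            if row.alias in seen:
                raise ValueError(f"row {n}: duplicate alias {row.alias!r}")
            if row.parent not in seen:
                raise ValueError(
                    f"row {n}: parent {row.parent!r} not defined before {row.alias!r}"
                )
            if row.method not in METHODS:
                raise ValueError(f"row {n}: unknown method {row.method!r}")
            if row.method in ("quadrant", "rectangle") and len(row.dims) != 2:
                raise ValueError(f"row {n}: {row.method} needs two dims")
            if row.method == "density_cut" and len(row.dims) != 1:
                raise ValueError(f"row {n}: density_cut needs one dim")
            seen.add(row.alias)
        # denominators must be ancestors (or root)
        parents = {r.alias: r.parent for r in self.rows}
        for n, row in enumerate(self.rows, start=1):
            if not row.denominator:
                continue
            anc = row.parent
            chain = {row.alias}
            while anc != ROOT:
                chain.add(anc)
                anc = parents[anc]
            chain.add(ROOT)
            if row.denominator not in chain:
                raise ValueError(
                    f"row {n}: denominator {row.denominator!r} is not an ancestor of {row.alias!r}"
                )

    @property
    def aliases(self) -> list[str]:
        return [r.alias for r in self.rows]


def parse_template(path_or_df, panel: str = "") -> GatingTemplate:
    """Parse a template CSV with columns
    alias,parent,dims,method,args,signs,denominator,report ."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    df = df.fillna("")
    rows = []
    for n, rec in enumerate(df.to_dict("records"), start=1):
        args = {}
        for item in str(rec.get("args", "")).split(";"):
            if "=" in item:
                key, val = item.split("=", 1)
                args[key.strip()] = val.strip()
        dims = [d for d in str(rec["dims"]).split("|") if d]
        signs = list(str(rec.get("signs", "")))
        try:
            rows.append(
                TemplateRow(
                    alias=str(rec["alias"]).strip(),
                    parent=str(rec["parent"]).strip() or ROOT,
                    dims=dims,
                    method=str(rec["method"]).strip(),
                    args=args,
                    signs=signs,
                    denominator=str(rec.get("denominator", "")).strip(),
                    report=str(rec.get("report", "1")).strip() in ("1", "true", "True"),
                )
            )
        except Exception as err:
            raise ValueError(f"template row {n}: {err}") from err
    return GatingTemplate(panel, rows)


def builtin_template(panel_name: str) -> GatingTemplate:
    """Load one of the four shipped panel templates."""
    fname = f"{panel_name}.csv".replace("/", "-")
    ref = resources.files(__package__) / "templates" / fname
    with resources.as_file(ref) as path:
        if not Path(path).exists():
            raise KeyError(f"no built-in template for panel {panel_name!r}")
        return parse_template(path, panel_name)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class GateResult:
    alias: str
    parent: str
    mask: np.ndarray
    thresholds: dict[str, float]
    denominator: str
    report: bool
    unresolvable: bool = False

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class GatingTree:
    panel: str
    results: dict[str, GateResult]

    def mask(self, alias: str) -> np.ndarray:
        return self.results[alias].mask

    def count(self, alias: str) -> int:
        return self.results[alias].count

    def proportions(self) -> pd.DataFrame:
        """One row per reported gate, proportion under its declared denominator."""
        rows = []
        for res in self.results.values():
            if res.alias == ROOT or not res.report:
                continue
            denom_alias = res.denominator or res.parent
            denom = self.results[denom_alias].count
            rows.append(
                {
                    "population": res.alias,
                    "count": res.count,
                    "denominator": denom_alias,
                    "denominator_count": denom,
                    "proportion": res.count / denom if denom > 0 else np.nan,
                    "unresolvable": res.unresolvable or denom == 0,
                }
            )
        return pd.DataFrame(rows)


def _marker_values(frame: EventFrame, marker: str) -> np.ndarray:
    return frame.values(marker)


def apply_template(
    frame: EventFrame,
    template: GatingTemplate,
    root_mask: np.ndarray,
    bandwidth_factor: float = 1.0,
    peak_frac: float = PEAK_FRAC,
) -> GatingTree:
    """Evaluate a template top-down on one preprocessed frame.

    1-D cut-points are computed once per (parent, marker) pair and shared,
    so sibling gates with opposite signs and quadrant rows partition their
    parent exactly. A parent with zero events marks all its descendants
    unresolvable (empty masks, no exception).
    """
    results: dict[str, GateResult] = {
        ROOT: GateResult(ROOT, "", np.asarray(root_mask, dtype=bool), {}, "", True)
    }
    cut_cache: dict[tuple[str, str], float] = {}

    def cut_for(parent: str, marker: str, row: TemplateRow) -> float:
        key = (parent, marker)
        if key not in cut_cache:
            vals = _marker_values(frame, marker)[results[parent].mask]
            cut_cache[key] = density_cutpoint(
                vals,
                bandwidth_factor=bandwidth_factor,
                peak_frac=float(row.args.get("peak_frac", peak_frac)),
                fallback_k=float(row.args.get("k", FALLBACK_K)),
                fallback_side=row.args.get("side", "auto"),
            )
        return cut_cache[key]

    for row in template.rows:
        parent_res = results[row.parent]
        pmask = parent_res.mask
        if parent_res.count == 0 or parent_res.unresolvable:
            results[row.alias] = GateResult(
                row.alias,
                row.parent,
                np.zeros_like(pmask),
                {},
                row.denominator,
                row.report,
                unresolvable=True,
            )
            continue
        thresholds: dict[str, float] = {}
        if row.method in ("density_cut", "quadrant", "rectangle"):
            mask = pmask.copy()
            for marker, sign in zip(row.dims, row.signs):
                thr = cut_for(row.parent, marker, row)
                thresholds[marker] = thr
                vals = _marker_values(frame, marker)
                mask &= (vals >= thr) if sign == "+" else (vals < thr)
        elif row.method == "tail":
            k = float(row.args.get("k", 3.0))
            mask = pmask.copy()
            for i, marker in enumerate(row.dims):
                sign = row.signs[i] if i < len(row.signs) else "+"
                vals = _marker_values(frame, marker)[pmask]
                thr = tail_gate(vals, k=k, side=sign)
                thresholds[marker] = thr
                allv = _marker_values(frame, marker)
                mask &= (allv >= thr) if sign == "+" else (allv < thr)
        elif row.method == "boolean":
            expr = row.args.get("expr", "")
            mask = pmask & boolean_gate(
                {a: r.mask for a, r in results.items()}, expr
            )
        else:  # pragma: no cover - guarded by template validation
            raise AssertionError(row.method)
        results[row.alias] = GateResult(
            row.alias, row.parent, mask, thresholds, row.denominator, row.report
        )
    return GatingTree(template.panel, results)
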