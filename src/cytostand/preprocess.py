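"""Compensation, display transformation, and universal pre-gates.

Every panel-specific gating hierarchy sits on top of the same three nested
pre-gates: intact cells (scatter cluster on FSC-A/SSC-A), singlets (robust
band around the FSC-H ~ FSC-A relation), and viable cells (below a density
cut-point on the viability channel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .frames import FLUORO, VIABILITY, EventFrame, SpilloverMatrix, TransformSpec


def compensate(frame: EventFrame, S: SpilloverMatrix) -> EventFrame:
    """Invert spillover mixing: fluorescence columns become observed @ S^-1.

    Scatter and viability channels are untouched. Rejects ill-conditioned
    matrices (condition number above :attr:`SpilloverMatrix.MAX_CONDITION`).
    """
    fl = frame.roles(FLUORO)
    if [frame.channels[i].detector for i in fl] != S.detectors:
        raise ValueError("spillover detectors do not match frame fluorescence channels")
    if frame.transformed[fl].any():
        raise ValueError("compensation must run on raw intensities")
    S.validate_invertible()
    out = frame.copy()
    # observed = true @ S  =>  true = observed @ S^-1, via a linear solve
    out.data[:, fl] = np.linalg.solve(S.matrix.T, out.data[:, fl].T).T
    out.compensated = True
    return out


def transform_channels(frame: EventFrame, spec: TransformSpec | None = None) -> EventFrame:
    """Apply the display transform to fluorescence and viability channels."""
    spec = spec or TransformSpec()
    cols = frame.roles(FLUORO) + frame.roles(VIABILITY)
    if frame.transformed[cols].any():
        raise ValueError("channels already transformed; refusing to transform twice")
    out = frame.copy()
    out.data[:, cols] = spec.apply(out.data[:, cols])
    out.transformed[cols] = True
    return out


@dataclass
class PregateMasks:
    cells: np.ndarray
    singlets: np.ndarray
    viable: np.ndarray
    info: dict

    def __post_init__(self) -> None:
        # nesting is part of the contract: viable <= singlets <= cells
        assert not (self.singlets & ~self.cells).any()
        assert not (self.viable & ~self.singlets).any()


#: a mixture component is debris when its FSC-A mean falls below this
#: fraction of the largest component mean
DEBRIS_RATIO = 0.55


def _cells_mask(
    fsc_a: np.ndarray, ssc_a: np.ndarray, mononuclear: bool, seed: int
) -> tuple[np.ndarray, dict]:
    """Scatter gate: Gaussian-mixture clustering of FSC-A/SSC-A.

    Lymphoid panels model debris + lymphocytes; the mononuclear panel also
    keeps the monocyte cluster. One extra component absorbs the doublet
    cloud (high FSC-A), which would otherwise steal a component and leave
    debris merged with cells; doublets are removed by the singlet gate, not
    here. A component only counts as debris when its FSC-A mean is well
    below the heaviest cluster's, so a single-cluster input keeps
    everything.
    """
    X = np.column_stack([fsc_a, ssc_a])
    n_comp = 4 if mononuclear else 3
    try:
        gm = GaussianMixture(
            n_components=n_comp,
            covariance_type="full",
            random_state=seed,
            n_init=5,  # deterministic restarts; best likelihood wins
            init_params="k-means++",
        ).fit(X)
        means = gm.means_[:, 0]
        # the heaviest component is always cells; anything well below its
        # FSC-A mean is debris (a doublet cluster sits *above* and is kept
        # here, to be removed by the singlet gate)
        anchor = means[int(np.argmax(gm.weights_))]
        keep = np.flatnonzero(means >= DEBRIS_RATIO * anchor)
        # tie-break guarantee: the highest-FSC-A component is always cells
        resp = gm.predict(X)
        mask = np.isin(resp, keep)
        info = {"method": "gmm", "component_fsc_means": means.tolist(), "kept": keep.tolist()}
    except Exception as err:  # pragma: no cover - convergence fallback
        warnings.warn(f"scatter mixture fit failed ({err}); quantile-box fallback")
        lo_f, hi_f = np.quantile(fsc_a, [0.05, 0.995])
        lo_s, hi_s = np.quantile(ssc_a, [0.0, 0.995])
        mask = (fsc_a >= lo_f) & (fsc_a <= hi_f) & (ssc_a >= lo_s) & (ssc_a <= hi_s)
        info = {"method": "quantile-box"}
    return mask, info


def _singlet_mask(
    fsc_a: np.ndarray, fsc_h: np.ndarray, cells: np.ndarray, k_mad: float, seed: int
) -> tuple[np.ndarray, dict]:
    """Keep events within k * MAD of the robust FSC-H ~ FSC-A line.

    The Theil-Sen slope is computed on a (deterministic) subsample of the
    cell events; doublets sit far below the line (area doubles, height does
    not) and drop out of the band.
    """
    idx = np.flatnonzero(cells)
    sub = idx
    if len(idx) > 2000:
        sub = np.random.default_rng(seed).choice(idx, 2000, replace=False)
    slope, intercept, *_ = stats.theilslopes(fsc_h[sub], fsc_a[sub])
    resid = fsc_h - (slope * fsc_a + intercept)
    mad = stats.median_abs_deviation(resid[idx], scale="normal")
    band = k_mad * mad if mad > 0 else np.inf
    mask = cells & (np.abs(resid) <= band)
    return mask, {"slope": float(slope), "intercept": float(intercept), "band": float(band)}


def pregate(
    frame: EventFrame,
    mononuclear: bool = False,
    k_mad: float = 4.0,
    seed: int = 0,
) -> PregateMasks:
    """Compute the nested cells / singlets / viable masks.

    Expects a compensated, transformed frame (the viability cut-point is a
    density cut in transformed units). Deterministic for a given seed.
    """
    from .gating import density_cutpoint  # local import to avoid a cycle

    fsc_a = frame.values("FSC-A")
    fsc_h = frame.values("FSC-H")
    ssc_a = frame.values("SSC-A")
    via_col = frame.roles(VIABILITY)
    if not via_col:
        raise ValueError("frame has no viability channel")
    viability = frame.data[:, via_col[0]]

    cells, cells_info = _cells_mask(fsc_a, ssc_a, mononuclear, seed)
    singlets, singlet_info = _singlet_mask(fsc_a, fsc_h, cells, k_mad, seed)
    vals = viability[singlets]
    thr = density_cutpoint(vals, fallback_side="+")
    viable = singlets & (viability < thr)
    return PregateMasks(
        cells,
        singlets,
        viable,
        {
            "cells": cells_info,
            "singlets": singlet_info,
            "viability_threshold": float(thr),
        },
    )
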