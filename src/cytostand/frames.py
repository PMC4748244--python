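"""Event-level data containers and intensity transforms.

The :class:`EventFrame` is the currency passed between every pipeline stage:
an events x channels intensity matrix plus channel metadata (detector name,
marker name, role) and a per-channel flag recording whether the channel is on
the raw (linear) or transformed (asinh/logicle) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCATTER = "scatter"
FLUORO = "fluorescence"
VIABILITY = "viability"

ROLES = (SCATTER, FLUORO, VIABILITY)


@dataclass
class ChannelInfo:
    detector: str
    marker: str
    role: str  # one of ROLES

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class EventFrame:
    """Events x channels intensity matrix with channel metadata.

    Parameters
    ----------
    data
        float64 array of shape (n_events, n_channels).
    channels
        One :class:`ChannelInfo` per column, in column order.
    transformed
        Per-channel flag; True once a display transform has been applied.
    compensated
        True once spillover has been inverted.
    """

    data: np.ndarray
    channels: list[ChannelInfo]
    transformed: np.ndarray = field(default=None)  # type: ignore[assignment]
    compensated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (events x channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel metadata does not match data width")
        if not np.isfinite(self.data).all():
            raise ValueError("EventFrame contains non-finite intensities")
        names = [c.detector for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("detector names must be unique")
        if self.transformed is None:
            self.transformed = np.zeros(len(self.channels), dtype=bool)
        else:
            self.transformed = np.asarray(self.transformed, dtype=bool).copy()

    # -- lookup ------------------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def detectors(self) -> list[str]:
        return [c.detector for c in self.channels]

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    def index_of(self, name: str) -> int:
        """Column index by detector or marker name (detector wins on clash)."""
        for i, c in enumerate(self.channels):
            if c.detector == name:
                return i
        for i, c in enumerate(self.channels):
            if c.marker == name:
                return i
        raise KeyError(f"no channel named {name!r}")

    def values(self, name: str) -> np.ndarray:
        return self.data[:, self.index_of(name)]

    def roles(self, role: str) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.role == role]

    def copy(self) -> "EventFrame":
        return EventFrame(
            self.data.copy(),
            [replace(c) for c in self.channels],
            self.transformed.copy(),
            self.compensated,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.detectors)


@dataclass
class SpilloverMatrix:
    """Square spillover matrix over fluorescence detectors.

    Row = emitting fluorochrome, column = detector: ``observed = true @ S``.
    """

    matrix: np.ndarray
    detectors: list[str]

    MAX_CONDITION = 1e8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.detectors)
        if self.matrix.shape != (n, n):
            raise ValueError("spillover matrix must be square over its detectors")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover diagonal must be 1")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def validate_invertible(self) -> None:
        cond = self.condition_number
        if not np.isfinite(cond) or cond > self.MAX_CONDITION:
            raise ValueError(
                f"spillover matrix ill-conditioned (cond={cond:.3g} > {self.MAX_CONDITION:g})"
            )

    @classmethod
    def identity(cls, detectors: list[str]) -> "SpilloverMatrix":
        return cls(np.eye(len(detectors)), list(detectors))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.detectors).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy(dtype=np.float64), list(df.columns))


@dataclass
class TransformSpec:
    """Monotone display transform for fluorescence channels.

    asinh with a per-channel cofactor c maps x -> asinh(x / c); the logicle
    family (T, W, M, A) is provided for fidelity with real instrument files.
    """

    family: str = "asinh"
    cofactor: float = 150.0
    # logicle parameters
    T: float = 262144.0
    W: float = 0.5
    M: float = 4.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("asinh", "logicle"):
            raise ValueError(f"unknown transform family {self.family!r}")
        if self.family == "asinh" and self.cofactor <= 0:
            raise ValueError("asinh cofactor must be positive")
        if self.family == "logicle" and (self.T <= 0 or self.M <= 0 or self.W < 0):
            raise ValueError("invalid logicle parameters")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.family == "asinh":
            return np.arcsinh(x / self.cofactor)
        return _logicle(x, self.T, self.W, self.M, self.A)

    def invert(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        if self.family == "asinh":
            return np.sinh(y) * self.cofactor
        return _logicle_inverse(y, self.T, self.W, self.M, self.A)


# -- logicle ---------------------------------------------------------------
# Biexponential display scale of Parks, Roederer & Moore; implemented through
# its closed-form inverse and a vectorised bisection for the forward map.


def _logicle_params(T: float, W: float, M: float, A: float):
    ln10 = np.log(10.0)
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    b = (M + A) * ln10
    # d solves 2 ln(d/b)/(b+d) = -w on (0, b]; unique root, found by brentq
    if w == 0:
        d = b
    else:
        from scipy.optimize import brentq

        d = brentq(
            lambda dd: 2.0 * np.log(dd / b) / (b + dd) + w, 1e-9 * b, b * (1 - 1e-12)
        )
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
    a = T / (np.exp(b) - mf_a - c_a / np.exp(d))
    return a, b, c_a * a, d, a * mf_a, x1


def _logicle_inverse(y: np.ndarray, T: float, W: float, M: float, A: float) -> np.ndarray:
    a, b, c, d, f, x1 = _logicle_params(T, W, M, A)
    y = np.asarray(y, dtype=np.float64)
    sign = np.where(y >= x1, 1.0, -1.0)
    ya = np.where(y >= x1, y, 2.0 * x1 - y)
    return sign * (a * np.exp(b * ya) - c * np.exp(-d * ya) - f)


def _logicle(x: np.ndarray, T: float, W: float, M: float, A: float) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    lo = np.full(x.shape, -0.5)
    hi = np.full(x.shape, 1.5)
    for _ in range(80):  # bisection to ~1e-24 interval; plenty below 1e-10
        mid = 0.5 * (lo + hi)
        val = _logicle_inverse(mid, T, W, M, A)
        lo = np.where(val < x, mid, lo)
        hi = np.where(val < x, hi, mid)
    out = 0.5 * (lo + hi)
    return out if out.shape else float(out)
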