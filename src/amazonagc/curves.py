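"""Response curves used throughout the bookkeeping model.

Three families:

* :class:`CalibrationCurve` -- a four-parameter logistic mapping an annual
  L-VOD index to above-ground carbon density (Mg C ha-1), with the overflow
  sentinel convention used when the curve evaluates to a non-finite value.
* :class:`GrowthCurve` -- Chapman-Richards secondary-forest regrowth,
  AGC(age) = A * (1 - exp(-k*age))**theta.
* :class:`EdgeLossCurve` -- saturating-exponential cumulative fraction of the
  old-growth reference density lost at a forest edge,
  loss(age) = L_inf * (1 - exp(-r*age)).

All three are plain callables over NumPy arrays so they can be swapped for
alternative parameterisations without touching the flux code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OVERFLOW_SENTINEL",
    "CalibrationCurve",
    "GrowthCurve",
    "EdgeLossCurve",
]

#: Value substituted for non-finite curve evaluations ("Inf was set to 1e10").
OVERFLOW_SENTINEL = 1e10


def _logistic(vod, a, b, c, d):
    """Four-parameter logistic: d + (a - d) / (1 + exp(-b*(v - c)))."""
    with np.errstate(over="ignore", under="ignore"):
        return d + (a - d) / (1.0 + np.exp(-b * (np.asarray(vod, dtype=float) - c)))


@dataclass
class CalibrationCurve:
    """VOD -> AGC calibration curve with fit metadata.

    ``a`` is the upper asymptote and ``d`` the floor (both Mg C ha-1);
    ``b`` is the slope and ``c`` the inflection point in VOD units.
    The fitted curve is monotonically non-decreasing in VOD for b >= 0.
    """

    a: float
    b: float
    c: float
    d: float
    se_a: float = float("nan")
    se_b: float = float("nan")
    se_c: float = float("nan")
    se_d: float = float("nan")
    index_method: str = ""
    overflow_sentinel: float = OVERFLOW_SENTINEL
    rss: float = float("nan")
    n_fit: int = 0

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    @property
    def standard_errors(self) -> tuple[float, float, float, float]:
        return (self.se_a, self.se_b, self.se_c, self.se_d)

    def __call__(self, vod) -> np.ndarray:
        """Evaluate the curve; non-finite output -> overflow sentinel."""
        out = np.asarray(_logistic(vod, self.a, self.b, self.c, self.d), dtype=float)
        scalar = out.ndim == 0
        out = np.atleast_1d(out)
        out[~np.isfinite(out)] = self.overflow_sentinel
        return out[0] if scalar else out

    def inverse(self, agc) -> np.ndarray:
        """VOD value whose curve image is ``agc``.

        Defined only on the open interval (d, a); raises ValueError if any
        requested density falls outside the invertible range.
        """
        y = np.atleast_1d(np.asarray(agc, dtype=float))
        lo, hi = min(self.a, self.d), max(self.a, self.d)
        if np.any(y <= lo) or np.any(y >= hi):
            raise ValueError(
                "calibration curve not invertible over the requested density range "
                f"({np.min(y):.2f}..{np.max(y):.2f} vs open interval ({lo:.2f}, {hi:.2f}))"
            )
        v = self.c - np.log((self.a - self.d) / (y - self.d) - 1.0) / self.b
        return v if np.ndim(agc) else float(v[0])

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "se_a": self.se_a, "se_b": self.se_b, "se_c": self.se_c, "se_d": self.se_d,
            "index_method": self.index_method,
            "overflow_sentinel": self.overflow_sentinel,
            "rss": self.rss, "n_fit": self.n_fit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(**d)


@dataclass(frozen=True)
class GrowthCurve:
    """Chapman-Richards secondary-forest carbon accumulation.

    AGC(age) = asymptote * (1 - exp(-rate * age)) ** shape, Mg C ha-1.
    AGC(0) = 0, non-decreasing, bounded above by ``asymptote``.
    """

    asymptote: float = 90.0
    rate: float = 0.06
    shape: float = 1.5

    def __call__(self, age) -> np.ndarray:
        t = np.asarray(age, dtype=float)
        out = self.asymptote * (1.0 - np.exp(-self.rate * np.maximum(t, 0.0))) ** self.shape
        return out if np.ndim(age) else float(out)

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.asymptote, self.rate, self.shape)


@dataclass(frozen=True)
class EdgeLossCurve:
    """Cumulative fractional AGC loss as a function of forest-edge age.

    loss(age) = max_loss * (1 - exp(-rate * age)); loss(0) = 0,
    non-decreasing, asymptote max_loss < 1.
    """

    max_loss: float = 0.4
    rate: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_loss < 1.0):
            raise ValueError("edge-loss asymptote must lie in [0, 1)")

    def __call__(self, age) -> np.ndarray:
        t = np.asarray(age, dtype=float)
        out = self.max_loss * (1.0 - np.exp(-self.rate * np.maximum(t, 0.0)))
        return out if np.ndim(age) else float(out)

    @property
    def params(self) -> tuple[float, float]:
        return (self.max_loss, self.rate)
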