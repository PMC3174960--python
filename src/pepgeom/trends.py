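"""Trend fits for the planarity survey.

Two fits cover the observed regularities:

* a fixed-period harmonic of psi for delta-omega and theta_C — the
  planarity deviation alternates sign every 60 deg of psi, i.e. three full
  sine periods per turn (period 120 deg, k = 3); the fit estimates
  amplitude, phase and offset but never searches the period;
* an ordinary linear regression of theta_C on delta-omega, quantifying the
  coupling between bond twist and carbonyl-carbon pyramidalization.

Both fits treat the angular deviations as real numbers, which is valid
because the surveyed values are confined to a few degrees (documented
validity bound |y| < 90 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HarmonicFit",
    "LinearFit",
    "InsufficientDataError",
    "RankDeficiencyError",
    "DegenerateRegressorError",
    "fit_harmonic",
    "fit_linear",
    "zero_crossings",
]


class InsufficientDataError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    pass


class DegenerateRegressorError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonicFit:
    """y(psi) = amplitude * sin(k * (psi - phase)) + offset, k = 360/period.

    ``amplitude`` >= 0 (degrees); ``phase`` normalized to [0, period);
    zeros of the centered (offset-free) model are spaced period/2 apart.
    """

    amplitude: float
    phase: float
    offset: float
    period: float
    r_squared: float
    n: int

    @property
    def k(self) -> float:
        return 360.0 / self.period

    def predict(self, psi) -> np.ndarray:
        psi = np.asarray(psi, dtype=float)
        return self.amplitude * np.sin(np.radians(self.k * (psi - self.phase))) + self.offset


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float
    n: int
    constant_y: bool = False

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_harmonic(psi: Sequence[float], y: Sequence[float], period: float = 120.0) -> HarmonicFit:
    """Least-squares harmonic fit of y on the basis {sin(k psi), cos(k psi), 1}.

    Exact (zero residual) on any noiseless input generated from the model
    family.  Raises :class:`InsufficientDataError` for n < 4 and
    :class:`RankDeficiencyError` when the psi values cannot separate the
    basis functions (e.g. all psi identical).
    """
    psi = np.asarray(psi, dtype=float)
    y = np.asarray(y, dtype=float)
    if psi.shape != y.shape:
        raise ValueError("psi and y must have the same length")
    n = psi.size
    if n < 4:
        raise InsufficientDataError(f"harmonic fit needs n >= 4, got {n}")
    k = 360.0 / period
    arg = np.radians(k * psi)
    design = np.column_stack([np.sin(arg), np.cos(arg), np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise RankDeficiencyError("psi values do not span the harmonic basis")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b, offset = coef
    amplitude = math.hypot(a, b)
    # a sin + b cos == amplitude * sin(k(psi - phase)) with phase below
    phase = math.degrees(math.atan2(-b, a)) / k % period if amplitude > 0 else 0.0
    resid = y - design @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r_squared = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r_squared = 1.0 - ss_res / ss_tot
    return HarmonicFit(
        amplitude=float(amplitude),
        phase=float(phase),
        offset=float(offset),
        period=float(period),
        r_squared=float(r_squared),
        n=int(n),
    )


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y = slope*x + intercept with Pearson r.

    Raises :class:`DegenerateRegressorError` for constant x; a constant y
    gives r = 0 with the ``constant_y`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise InsufficientDataError(f"linear fit needs n >= 3, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateRegressorError("x is constant")
    if np.ptp(y) == 0.0:
        slope, intercept = 0.0, float(y[0])
        return LinearFit(slope, intercept, r=0.0, n=int(x.size), constant_y=True)
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=int(x.size),
    )


def zero_crossings(fit: HarmonicFit) -> Optional[List[float]]:
    """Roots of the fitted model in [0, 360), ascending.

    For |offset| > amplitude the model never crosses zero (empty list).
    With offset 0 the 2k roots are exactly period/2 apart (60 deg for the
    default period).  Returns ``None`` for an identically-zero model
    (amplitude 0, offset 0): every psi is a root.
    """
    if fit.amplitude == 0.0:
        return None if fit.offset == 0.0 else []
    s = -fit.offset / fit.amplitude
    if abs(s) > 1.0:
        return []
    alpha = math.degrees(math.asin(s))
    k = int(round(fit.k))
    roots = set()
    for m in range(k):
        for base in (alpha, 180.0 - alpha):
            roots.add(round((fit.phase + (base + 360.0 * m) / fit.k) % 360.0, 9))
    return sorted(roots)
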