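"""Legendre polynomial basis on a time interval.

Sampling hours are mapped onto the standard interval through
``x(t) = 2 (t - t_min) / (t_max - t_min) - 1`` and each column n evaluates
the degree-n Legendre polynomial P_n(x), optionally normalized as
``phi_n(x) = sqrt((2n + 1) / 2) P_n(x)`` so the columns have unit L2 norm
on [-1, 1]. "Order" means the highest degree included: order 6 yields 7
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["LegendreBasis", "legendre_basis"]


@dataclass(frozen=True)
class LegendreBasis:
    order: int
    t_min: float
    t_max: float
    normalized: bool = True
    log_time: bool = False  # standardize on log-hours instead of raw hours

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if not self.t_max > self.t_min:
            raise ValueError("need t_max > t_min")
        if self.log_time and self.t_min <= 0:
            raise ValueError("log-time standardization needs t_min > 0")

    def x(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        if self.log_time:
            t, lo, hi = np.log(t), np.log(self.t_min), np.log(self.t_max)
        else:
            lo, hi = self.t_min, self.t_max
        x = 2.0 * (t - lo) / (hi - lo) - 1.0
        if np.any((x < -1 - 1e-9) | (x > 1 + 1e-9)):
            raise ValueError("time outside basis bounds")
        return np.clip(x, -1.0, 1.0)

    def evaluate(self, times_h) -> np.ndarray:
        """Matrix with order+1 columns, one row per time."""
        x = np.atleast_1d(self.x(times_h))
        phi = npleg.legvander(x, self.order)
        if self.normalized:
            n = np.arange(self.order + 1)
            phi = phi * np.sqrt((2 * n + 1) / 2.0)
        return phi

    def row(self, time_h: float) -> np.ndarray:
        """The basis row vector t_t at a single hour."""
        return self.evaluate([time_h])[0]


def legendre_basis(times_h, order: int, t_min: float, t_max: float,
                   normalized: bool = True) -> np.ndarray:
    """Functional form of :meth:`LegendreBasis.evaluate`."""
    return LegendreBasis(order, t_min, t_max, normalized).evaluate(times_h)
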