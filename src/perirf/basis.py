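"""Tensor-product quadratic B-spline basis over stimulus delay and trial time.

A neuron's time-varying stimulus kernel k_xy(t, tau) is parameterized as a
weighted sum of separable basis functions B_ij(t, tau) = U_i(tau) V_j(t),
where U_i are quadratic B-splines over the delay tau between a probe and the
response, and V_j are quadratic B-splines over trial time t relative to
saccade onset.  Knots are uniform with 7 ms spacing (the probe frame
duration) on both axes: 33 delay knots {-13, -6, ..., 211} ms giving 30
basis functions, and 159 time knots {-554, -547, ..., 552} ms giving 156.
Knots are *not* clamped at the ends, so edge functions are partial and the
partition of unity holds only on the interior of each knot span.

One (location, delay-basis, time-basis) triple is a spatiotemporal unit
(STU); the full lattice over a 9x9 grid has 81 * 30 * 156 = 379,080 STUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSet",
    "STUIndex",
    "build_basis",
    "eval_tensor",
    "enumerate_stus",
    "DELAY_KNOTS",
    "TIME_KNOTS",
    "ORDER",
]

ORDER = 2  # quadratic (degree-2) B-splines
DELAY_KNOTS = np.arange(-13, 212, 7, dtype=float)   # 33 knots
TIME_KNOTS = np.arange(-554, 553, 7, dtype=float)   # 159 knots


def _basis_matrix(knots: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Dense (len(grid), n_funcs) matrix of quadratic B-splines on ``knots``."""
    n_funcs = len(knots) - ORDER - 1
    out = np.zeros((len(grid), n_funcs))
    for i in range(n_funcs):
        b = BSpline.basis_element(knots[i : i + ORDER + 2], extrapolate=False)
        vals = b(grid)
        out[:, i] = np.nan_to_num(vals, nan=0.0)
    # basis_element includes the right endpoint of the last interval; values
    # there belong to the next function's support on a uniform grid, but on
    # our integer-ms grid the knot points themselves evaluate consistently.
    return out


@dataclass(frozen=True)
class BasisSet:
    """Cached quadratic B-spline families over delay and trial time.

    Attributes
    ----------
    delay_knots, time_knots : ndarray
        Uniform knot grids (ms), 7 ms spacing.
    delay_grid, time_grid : ndarray
        The 1 ms evaluation grids spanning the knot ranges.
    U : ndarray, (len(delay_grid), n_delay)
        Delay basis sampled on the 1 ms grid.
    V : ndarray, (len(time_grid), n_time)
        Time basis sampled on the 1 ms grid.
    """

    delay_knots: np.ndarray
    time_knots: np.ndarray
    order: int
    delay_grid: np.ndarray
    time_grid: np.ndarray
    U: np.ndarray
    V: np.ndarray

    @property
    def n_delay(self) -> int:
        return self.U.shape[1]

    @property
    def n_time(self) -> int:
        return self.V.shape[1]

    @property
    def t_min(self) -> int:
        return int(self.time_grid[0])

    @property
    def t_max(self) -> int:
        return int(self.time_grid[-1])

    @property
    def n_bins(self) -> int:
        """Number of 1 ms bins in the trial span."""
        return len(self.time_grid)

    def t_index(self, t: np.ndarray | float) -> np.ndarray:
        """Bin index on the 1 ms trial clock for time(s) ``t`` (ms)."""
        idx = np.asarray(t) - self.t_min
        return idx.astype(np.intp)

    def delay_support(self, i: int) -> tuple[float, float]:
        """Support interval (ms) of delay basis function ``i``."""
        self._check_delay(i)
        return float(self.delay_knots[i]), float(self.delay_knots[i + self.order + 1])

    def time_support(self, j: int) -> tuple[float, float]:
        self._check_time(j)
        return float(self.time_knots[j]), float(self.time_knots[j + self.order + 1])

    def delay_center(self, i: int) -> float:
        """Center of mass of delay basis ``i`` (ms); peak of the symmetric spline."""
        lo, hi = self.delay_support(i)
        return (lo + hi) / 2

    def time_center(self, j: int) -> float:
        lo, hi = self.time_support(j)
        return (lo + hi) / 2

    def eval_delay(self, i: int, tau: np.ndarray | float) -> np.ndarray:
        """U_i evaluated at arbitrary delays (ms); zero outside support."""
        self._check_delay(i)
        b = BSpline.basis_element(
            self.delay_knots[i : i + self.order + 2], extrapolate=False
        )
        return np.nan_to_num(b(np.asarray(tau, dtype=float)), nan=0.0)

    def eval_time(self, j: int, t: np.ndarray | float) -> np.ndarray:
        self._check_time(j)
        b = BSpline.basis_element(
            self.time_knots[j : j + self.order + 2], extrapolate=False
        )
        return np.nan_to_num(b(np.asarray(t, dtype=float)), nan=0.0)

    def _check_delay(self, i: int) -> None:
        if not 0 <= i < self.n_delay:
            raise IndexError(f"delay basis index {i} outside [0, {self.n_delay})")

    def _check_time(self, j: int) -> None:
        if not 0 <= j < self.n_time:
            raise IndexError(f"time basis index {j} outside [0, {self.n_time})")


def build_basis(
    delay_knots: np.ndarray | None = None,
    time_knots: np.ndarray | None = None,
) -> BasisSet:
    """Build the quadratic B-spline basis families, cached on the 1 ms clock.

    Defaults produce 30 delay and 156 time functions from the standard knot
    grids.  Custom knot grids must be uniform with 7 ms spacing.
    """
    dk = DELAY_KNOTS if delay_knots is None else np.asarray(delay_knots, dtype=float)
    tk = TIME_KNOTS if time_knots is None else np.asarray(time_knots, dtype=float)
    for name, k in (("delay", dk), ("time", tk)):
        if len(k) < ORDER + 2:
            raise ValueError(f"too few {name} knots")
        if not np.allclose(np.diff(k), 7.0):
            raise ValueError(f"{name} knots must be uniform with 7 ms spacing")
    delay_grid = np.arange(dk[0], dk[-1] + 1.0)
    time_grid = np.arange(tk[0], tk[-1] + 1.0)
    return BasisSet(
        delay_knots=dk,
        time_knots=tk,
        order=ORDER,
        delay_grid=delay_grid,
        time_grid=time_grid,
        U=_basis_matrix(dk, delay_grid),
        V=_basis_matrix(tk, time_grid),
    )


def eval_tensor(
    basis: BasisSet, i: int, j: int, t: np.ndarray | float, tau: np.ndarray | float
) -> np.ndarray:
    """B_ij(t, tau) = U_i(tau) * V_j(t); zero outside the product support."""
    return basis.eval_delay(i, tau) * basis.eval_time(j, t)


@dataclass(frozen=True, order=True)
class STUIndex:
    """One spatiotemporal unit: (probe cell, delay-basis i, time-basis j)."""

    cell: int
    delay_index: int
    time_index: int


def enumerate_stus(grid, basis: BasisSet) -> np.ndarray:
    """Full STU lattice as a structured array, location-major then delay then time.

    Returns a structured ndarray with fields ``cell``, ``i``, ``j`` of length
    ``n_cells * n_delay * n_time`` in a deterministic order.
    """
    n_c, n_i, n_j = grid.n_cells, basis.n_delay, basis.n_time
    out = np.empty(n_c * n_i * n_j, dtype=[("cell", "i4"), ("i", "i4"), ("j", "i4")])
    cells = np.repeat(np.arange(n_c), n_i * n_j)
    ii = np.tile(np.repeat(np.arange(n_i), n_j), n_c)
    jj = np.tile(np.arange(n_j), n_c * n_i)
    out["cell"], out["i"], out["j"] = cells, ii, jj
    return out
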