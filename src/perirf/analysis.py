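"""Perisaccadic analyses: RF estimation, saccade-modulated STUs, nulling,
integration-relevant STUs, shared sensitivity, and the perisaccadic
modulation index (PMI).

Modulated STUs are found by comparing the local prevalence of selected
STUs on the (delay, time) lattice against its pre- and post-saccadic
fixation baselines:

    sqrt(|p(tau_n, t_m) - p1(tau_n)| * |p(tau_n, t_m) - p2(tau_n)|) > h

with p the selected fraction in a 3x3 lattice window, p1 the mean over
time bins 1-60 (540-120 ms before saccade onset) and p2 over bins 120-156
(280-540 ms after).  Nulling replaces modulated weights either with zero
or with their fixation values; an STU is integration-relevant when
zero-nulling it decreases the shared sensitivity

    delta = sum_{t=-500}^{+500} min(h1(t), h2(t)),

where h1, h2 are the mean absolute kernel values over the 9 cells around
the RF1/RF2 centers and delays 1..200 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import convolve2d

from .encoder import DT_S, SModel, reconstruct_kernels
from .grid import ProbeGrid

__all__ = [
    "PrevalenceMap",
    "RFEstimate",
    "ModulationResult",
    "estimate_rf",
    "probe_aligned_response",
    "stu_prevalence",
    "find_modulated",
    "null_stus",
    "spatial_sensitivity",
    "shared_sensitivity",
    "find_integration_relevant",
    "pmi",
]

FWHM_MS = 5.0
PRE_FIX_BINS = (0, 60)     # time-basis bins 1..60 (1-based), 540-120 ms before
POST_FIX_BINS = (119, 156)  # bins 120..156, 280-540 ms after
SENS_T_RANGE = (-500, 500)
SENS_DELAY_MS = 200


# ---------------------------------------------------------------------------
# RF estimation from probe-aligned responses
# ---------------------------------------------------------------------------

@dataclass
class RFEstimate:
    """Probe-aligned fixation responses and the argmax RF cells.

    ``pre`` / ``post`` are (n_cells, 201) mean rates (sp/s) over 0..200 ms
    after probe onset, smoothed with a 5 ms FWHM Gaussian; NaN rows mark
    cells never probed in that epoch.
    """

    rf1_cell: int
    rf2_cell: int
    pre: np.ndarray
    post: np.ndarray
    tied: bool = False


def probe_aligned_response(
    trials, epoch: str, window_ms: int = 200, min_offset_ms: float = 100.0,
    smooth: bool = True,
) -> np.ndarray:
    """Mean spike rate (sp/s) aligned to probe onset, per grid cell.

    ``epoch`` selects probes presented more than ``min_offset_ms`` before
    ("pre") or after ("post") saccade onset.  Returns (n_cells,
    window_ms + 1); cells with no qualifying probes are NaN.
    """
    if epoch not in ("pre", "post"):
        raise ValueError("epoch must be 'pre' or 'post'")
    n_cells = trials.grid.n_cells
    win = window_ms + 1
    acc = np.zeros((n_cells, win))
    cnt = np.zeros(n_cells, dtype=int)
    ev = trials.events
    t_on = ev["t_on"].astype(int)
    keep = (t_on < -min_offset_ms) if epoch == "pre" else (t_on > min_offset_ms)
    for tr, t0, cell in zip(ev["trial"][keep], t_on[keep], ev["cell"][keep]):
        b0 = t0 - trials.t_min
        if b0 + win > trials.n_bins:
            continue
        acc[cell] += trials.spikes[tr, b0 : b0 + win]
        cnt[cell] += 1
    out = np.full((n_cells, win), np.nan)
    probed = cnt > 0
    out[probed] = acc[probed] / cnt[probed, None] / DT_S
    if smooth:
        sigma = FWHM_MS / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out[probed] = gaussian_filter1d(out[probed], sigma, axis=1)
    return out


def estimate_rf(trials) -> RFEstimate:
    """RF1/RF2 = cells with the maximum probe-aligned fixation response
    before/after the saccade.  Ties break to the lowest cell index
    (flagged)."""
    pre = probe_aligned_response(trials, "pre")
    post = probe_aligned_response(trials, "post")
    unprobed = np.isnan(pre).all(axis=1) | np.isnan(post).all(axis=1)
    if unprobed.any():
        warnings.warn(
            f"{int(unprobed.sum())} cells were never probed in one epoch and "
            "are excluded from RF estimation"
        )
    if np.nansum(pre) == 0 and np.nansum(post) == 0:
        raise ValueError("all probe-aligned responses are zero")

    def argmax_cell(resp):
        peaks = np.where(np.isnan(resp).all(axis=1), -np.inf, np.nanmax(resp, axis=1))
        best = float(np.max(peaks))
        cands = np.flatnonzero(peaks == best)
        return int(cands[0]), len(cands) > 1

    rf1, tie1 = argmax_cell(pre)
    rf2, tie2 = argmax_cell(post)
    tied = tie1 or tie2
    if tied:
        warnings.warn("RF argmax tie; lowest cell index chosen")
    return RFEstimate(rf1_cell=rf1, rf2_cell=rf2, pre=pre, post=post, tied=tied)


# ---------------------------------------------------------------------------
# modulated STUs (prevalence statistic)
# ---------------------------------------------------------------------------

@dataclass
class PrevalenceMap:
    """Local selected-STU prevalence on the (delay, time) lattice.

    ``p[n, m]``: selected fraction in the (edge-clipped) 3x3 window around
    delay bin n, time bin m; ``p1[n]``, ``p2[n]``: its means over the pre-
    and post-saccadic fixation time-bin ranges.
    """

    p: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    def statistic(self) -> np.ndarray:
        """sqrt(|p - p1| * |p - p2|), in [0, 1]."""
        return np.sqrt(
            np.abs(self.p - self.p1[:, None]) * np.abs(self.p - self.p2[:, None])
        )


def stu_prevalence(selected_2d: np.ndarray) -> PrevalenceMap:
    """Prevalence map of one (n_delay, n_time) selection mask.

    Windows are clipped at lattice edges with the denominator equal to the
    actual window size.
    """
    m = np.asarray(selected_2d, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D (delay, time) mask")
    ones = np.ones((3, 3))
    count = convolve2d(m, ones, mode="same")
    size = convolve2d(np.ones_like(m), ones, mode="same")
    p = count / size
    n_time = m.shape[1]
    pre = slice(PRE_FIX_BINS[0], min(PRE_FIX_BINS[1], n_time))
    post = slice(min(POST_FIX_BINS[0], n_time), min(POST_FIX_BINS[1], n_time))
    p1 = p[:, pre].mean(axis=1) if pre.stop > pre.start else np.zeros(m.shape[0])
    p2 = p[:, post].mean(axis=1) if post.stop > post.start else np.zeros(m.shape[0])
    return PrevalenceMap(p=p, p1=p1, p2=p2)


def find_modulated(
    selected: np.ndarray, h: float = 0.3, per_location: bool = True
) -> np.ndarray:
    """Boolean mask of saccade-modulated STUs.

    ``selected`` is the dense (n_cells, n_delay, n_time) selection mask.
    With ``per_location`` (default) the prevalence statistic is computed on
    each location's own (delay, time) slice; otherwise on the pooled
    (any-location) mask, applied back to every selected STU.
    """
    if not 0 <= h <= 1:
        raise ValueError("threshold h must be in [0, 1]")
    selected = np.asarray(selected, dtype=bool)
    out = np.zeros_like(selected)
    if per_location:
        for c in range(selected.shape[0]):
            if not selected[c].any():
                continue
            stat = stu_prevalence(selected[c]).statistic()
            out[c] = selected[c] & (stat > h)
    else:
        pooled = selected.any(axis=0)
        stat = stu_prevalence(pooled).statistic()
        out = selected & (stat > h)[None, :, :]
    return out


# ---------------------------------------------------------------------------
# nulling and shared sensitivity
# ---------------------------------------------------------------------------

def null_stus(model: SModel, mask: np.ndarray, mode: str = "zero") -> SModel:
    """New model with the masked STU weights nulled; the original is
    untouched.

    ``mode='zero'`` sets the weights to zero.  ``mode='fixation'`` replaces
    each masked weight with the mean weight over selected STUs sharing the
    same (cell, delay-basis) whose time-basis centers fall in the
    pre-saccadic fixation window (zero if there are none).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != model.kappa.shape:
        raise ValueError("mask shape does not match the model lattice")
    if np.any(mask & ~model.selected):
        raise ValueError("mask includes STUs outside the selected set")
    kappa = model.kappa.copy()
    if mode == "zero":
        kappa[mask] = 0.0
        selected = model.selected & ~mask
    elif mode == "fixation":
        basis = model.basis
        t_centers = np.array([basis.time_center(j) for j in range(basis.n_time)])
        fix = (t_centers >= basis.t_min) & (
            t_centers <= basis.time_knots[PRE_FIX_BINS[1]]
        )
        for c, i in {(c, i) for c, i, _ in np.argwhere(mask)}:
            donors = model.selected[c, i] & fix
            val = model.kappa[c, i, donors].mean() if donors.any() else 0.0
            jj = mask[c, i]
            kappa[c, i, jj] = val
        selected = model.selected | (kappa != 0)
    else:
        raise ValueError(f"unknown nulling mode {mode!r}")
    return model.with_kappa(kappa, selected=selected)


def spatial_sensitivity(
    kernels, rf_center: int, grid: ProbeGrid | None = None,
    t_values: np.ndarray | None = None, T: int = SENS_DELAY_MS,
) -> np.ndarray:
    """h_rf(t): mean |K| over the 9 cells around ``rf_center`` and delays
    1..T ms, per 1 ms of t.

    ``kernels`` is an SModel (kernels are reconstructed as needed) or a
    KernelMap covering the neighborhood.  Edge RF centers use the clipped
    neighborhood with a renormalized denominator (warned).
    """
    if t_values is None:
        t_values = np.arange(SENS_T_RANGE[0], SENS_T_RANGE[1] + 1.0)
    if isinstance(kernels, SModel):
        model = kernels
        grid = model.grid
        cells = grid.neighborhood(rf_center)
        tau = np.arange(1.0, T + 1.0)
        km = reconstruct_kernels(model, cells=cells, tau=tau, t=t_values)
        vals = km.values
    else:
        if grid is None:
            raise ValueError("a ProbeGrid is required with a KernelMap input")
        cells = grid.neighborhood(rf_center)
        km = kernels
        tau_sel = (km.tau_grid >= 1) & (km.tau_grid <= T)
        t_idx = np.searchsorted(km.t_grid, t_values)
        if np.any(t_idx >= len(km.t_grid)) or np.any(km.t_grid[t_idx] != t_values):
            raise ValueError("kernel map does not cover the requested t grid")
        rows = [np.flatnonzero(km.cells == c)[0] for c in cells]
        vals = km.values[np.ix_(rows, np.flatnonzero(tau_sel), t_idx)]
    if len(cells) < 9:
        warnings.warn(
            f"RF center {rf_center} is on the grid edge; using a clipped "
            f"{len(cells)}-cell neighborhood"
        )
    return np.abs(vals).sum(axis=(0, 1)) / (len(cells) * T)


def shared_sensitivity(h1: np.ndarray, h2: np.ndarray) -> float:
    """delta = sum_t min(h1(t), h2(t)) over the common 1 ms grid."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("sensitivity traces must share one time grid")
    return float(np.minimum(h1, h2).sum())


@dataclass
class ModulationResult:
    modulated: np.ndarray
    integration_relevant: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    delta: float


def find_integration_relevant(
    model: SModel,
    modulated: np.ndarray,
    rf1_cell: int | None = None,
    rf2_cell: int | None = None,
    rel_tol: float = 1e-9,
) -> ModulationResult:
    """One-at-a-time screen: a modulated STU is integration-relevant when
    zero-nulling it (from the intact model) decreases delta = sum min(h1, h2)
    by more than ``rel_tol`` relative.

    Each STU is tested independently against the intact model, so the result
    does not depend on evaluation order.
    """
    modulated = np.asarray(modulated, dtype=bool)
    grid = model.grid
    rf1 = grid.rf1_index if rf1_cell is None else rf1_cell
    rf2 = grid.rf2_index if rf2_cell is None else rf2_cell
    t_values = np.arange(SENS_T_RANGE[0], SENS_T_RANGE[1] + 1.0)
    h1 = spatial_sensitivity(model, rf1, t_values=t_values)
    h2 = spatial_sensitivity(model, rf2, t_values=t_values)
    delta = shared_sensitivity(h1, h2)
    relevant = np.zeros_like(modulated)
    if delta == 0:
        warnings.warn("shared sensitivity is zero; no STU can be relevant")
        return ModulationResult(modulated, relevant, h1, h2, delta)

    nb1 = set(grid.neighborhood(rf1).tolist())
    nb2 = set(grid.neighborhood(rf2).tolist())
    basis = model.basis
    tau = np.arange(1.0, SENS_DELAY_MS + 1.0)
    # cache per-neighborhood |K| stacks for incremental single-STU updates
    km1 = reconstruct_kernels(model, cells=grid.neighborhood(rf1), tau=tau, t=t_values)
    km2 = reconstruct_kernels(model, cells=grid.neighborhood(rf2), tau=tau, t=t_values)
    sum_abs1 = np.abs(km1.values).sum(axis=(0, 1))
    sum_abs2 = np.abs(km2.values).sum(axis=(0, 1))
    denom1 = len(km1.cells) * SENS_DELAY_MS
    denom2 = len(km2.cells) * SENS_DELAY_MS
    U_tau = np.column_stack([basis.eval_delay(i, tau) for i in range(basis.n_delay)])
    V_t = np.column_stack([basis.eval_time(j, t_values) for j in range(basis.n_time)])
    thresh = delta * (1 - rel_tol)
    for c, i, j in np.argwhere(modulated):
        if model.kappa[c, i, j] == 0:
            continue
        in1, in2 = c in nb1, c in nb2
        if not (in1 or in2):
            continue
        duv = model.kappa[c, i, j] * np.outer(U_tau[:, i], V_t[:, j])
        h1n, h2n = h1, h2
        if in1:
            row = int(np.flatnonzero(km1.cells == c)[0])
            old = np.abs(km1.values[row]).sum(axis=0)
            new = np.abs(km1.values[row] - duv).sum(axis=0)
            h1n = (sum_abs1 - old + new) / denom1
        if in2:
            row = int(np.flatnonzero(km2.cells == c)[0])
            old = np.abs(km2.values[row]).sum(axis=0)
            new = np.abs(km2.values[row] - duv).sum(axis=0)
            h2n = (sum_abs2 - old + new) / denom2
        if shared_sensitivity(h1n, h2n) < thresh:
            relevant[c, i, j] = True
    return ModulationResult(modulated, relevant, h1, h2, delta)


# ---------------------------------------------------------------------------
# perisaccadic modulation index
# ---------------------------------------------------------------------------

def pmi(
    rate_saccade: np.ndarray,
    rate_fixation: np.ndarray,
    window_ms: tuple[float, float] = (75.0, 105.0),
    time_grid: np.ndarray | None = None,
) -> float:
    """(S - F) / (S + F) with S, F the mean probe-aligned rates in the
    window (default 75-105 ms after probe onset).

    Scalars are taken as already-windowed mean rates; arrays are averaged
    over ``window_ms`` on ``time_grid`` (default 0..len-1 ms after probe).
    """

    def windowed(r):
        r = np.asarray(r, dtype=float)
        if r.ndim == 0:
            return float(r)
        tg = np.arange(len(r)) if time_grid is None else np.asarray(time_grid)
        sel = (tg >= window_ms[0]) & (tg <= window_ms[1])
        if not sel.any():
            raise ValueError("window outside the response grid")
        return float(r[sel].mean())

    s, f = windowed(rate_saccade), windowed(rate_fixation)
    if s < 0 or f < 0:
        raise ValueError("mean rates must be nonnegative")
    if s == 0 and f == 0:
        raise ValueError("PMI undefined: both responses are zero")
    return (s - f) / (s + f)
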