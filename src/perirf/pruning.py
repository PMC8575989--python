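"""STU pruning: marginal screening of spatiotemporal units against shuffled
controls.

Each candidate STU gets a one-STU Bernoulli point-process GLM,
lambda_t = f(kappa * x_t + c) with x_t the STU's stimulus feature
(delay-basis-filtered probe history times the time-basis envelope) and c a
free intercept so the baseline rate cannot masquerade as stimulus drive.
The scalar weight kappa is fit on 100 random 35% trial subsets of the
original data and on 100 subsets in which spike trains are permuted across
trials (derangement), breaking the stimulus-response correspondence while
preserving within-trial spike statistics.  An STU is kept when

    |mu - mu_tilde| >= 1.5 * sigma_tilde

with mu the mean original weight and mu_tilde, sigma_tilde the mean and SD
of the control weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .basis import BasisSet
from .encoder import DT_S, _boxcar_profiles, estimate_rate_bounds

__all__ = [
    "PruningConfig",
    "PruningResult",
    "SingleSTUFit",
    "shuffle_control",
    "fit_single_stu_weight",
    "prune_stus",
    "STUPruner",
]


@dataclass(frozen=True)
class PruningConfig:
    n_resamples: int = 100
    subset_fraction: float = 0.35
    sigma_multiplier: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subset_fraction <= 1:
            raise ValueError("subset_fraction must be in (0, 1]")
        if self.n_resamples < 2:
            raise ValueError("need at least 2 resamples")


@dataclass
class PruningResult:
    """Per-STU screening outcome.

    ``table`` has one row per candidate STU with columns cell, i, j, mu
    (mean original weight), mu_ctrl, sigma_ctrl, selected, degenerate.
    """

    table: pd.DataFrame
    sigma_multiplier: float

    @property
    def selected(self) -> np.ndarray:
        return self.table["selected"].to_numpy()

    def selected_mask(self, grid, basis) -> np.ndarray:
        """Dense boolean (n_cells, n_delay, n_time) mask of kept STUs."""
        mask = np.zeros((grid.n_cells, basis.n_delay, basis.n_time), dtype=bool)
        kept = self.table[self.table["selected"]]
        mask[kept["cell"], kept["i"], kept["j"]] = True
        return mask


def shuffle_control(trials, seed: int):
    """Permute whole spike trains across trials (derangement: no trial keeps
    its own spikes), leaving stimulus sequences untouched."""
    n = trials.n_trials
    if n < 2:
        raise ValueError("shuffle control needs at least 2 trials")
    perm = _derangement(n, np.random.default_rng(seed))
    return trials.with_spikes(trials.spikes[perm])


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


# ---------------------------------------------------------------------------
# one-STU GLM fit (Newton with damping)
# ---------------------------------------------------------------------------

@dataclass
class SingleSTUFit:
    kappa: float
    intercept: float
    degenerate: bool
    converged: bool


def _newton_fit(x, r, n0, s0, a, max_iter=50, tol=1e-6, ridge=1.0):
    """Fit lambda = (a/dt) * sigmoid(kappa x + c) by Newton's method.

    ``x``, ``r``: feature and spike values at the feature's nonzero bins;
    ``n0``, ``s0``: bin and spike counts where the feature is zero (their
    likelihood contribution depends on c only and is aggregated in closed
    form).  ``a`` = rmax * dt.  A weak ridge on kappa keeps the estimate
    finite under complete separation (subsets where no spike coincides with
    the feature's support).
    """
    # intercept init from the marginal spike probability
    tot_bins = len(x) + n0
    pbar = np.clip((r.sum() + s0) / max(tot_bins, 1), 1e-6, a * (1 - 1e-6))
    theta = np.array([0.0, float(np.log(pbar / (a - pbar)))])

    def nll_grad_hess(theta):
        kap, c = theta
        u = kap * x + c
        s = expit(u)
        p = np.clip(a * s, 1e-12, 1 - 1e-9)
        nll = -(r @ np.log(p) + (1 - r) @ np.log1p(-p))
        gu = -(r * (1 - s) - (1 - r) * a * s * (1 - s) / (1 - p))
        sp = s * (1 - s)
        hu = r * sp + (1 - r) * a * (sp * (1 - 2 * s) * (1 - p) + a * sp**2) / (
            1 - p
        ) ** 2
        g = np.array([gu @ x, gu.sum()])
        h = np.array([[hu @ x**2, hu @ x], [hu @ x, hu.sum()]])
        # zero-feature bins: u = c
        s = expit(c)
        p = min(max(a * s, 1e-12), 1 - 1e-9)
        nll -= s0 * np.log(p) + (n0 - s0) * np.log1p(-p)
        gu1 = -(1 - s)                       # spike bins
        gu0 = a * s * (1 - s) / (1 - p)      # no-spike bins
        g[1] += s0 * gu1 + (n0 - s0) * gu0
        sp = s * (1 - s)
        hu1 = sp
        hu0 = a * (sp * (1 - 2 * s) * (1 - p) + a * sp**2) / (1 - p) ** 2
        h[1, 1] += s0 * hu1 + (n0 - s0) * hu0
        nll += 0.5 * ridge * kap**2
        g[0] += ridge * kap
        h[0, 0] += ridge
        return nll, g, h

    nll, g, h = nll_grad_hess(theta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(h + 1e-8 * np.eye(2), g)
        except np.linalg.LinAlgError:
            break
        alpha = 1.0
        for _ in range(20):
            cand = theta - alpha * step
            new_nll, new_g, new_h = nll_grad_hess(cand)
            if new_nll <= nll + 1e-12:
                break
            alpha *= 0.5
        else:
            break
        rel = abs(nll - new_nll) / max(abs(nll), 1.0)
        theta, nll, g, h = cand, new_nll, new_g, new_h
        if rel < tol:
            converged = True
            break
    return theta[0], theta[1], converged


def _stu_features(trials, basis: BasisSet, cell: int, i: int):
    """Per-trial nonzero bins of conv_ci(t) = sum_tau U_i(tau) s_cell(t-tau),
    before the time-basis envelope is applied."""
    g = _boxcar_profiles(basis)[i]
    u0 = int(basis.delay_grid[0])
    n_bins = basis.n_bins
    conv = np.zeros((trials.n_trials, n_bins))
    ev = trials.events
    sel = ev[ev["cell"] == cell]
    for tr, t_on in zip(sel["trial"], sel["t_on"]):
        start = int(t_on) - basis.t_min + u0
        lo, hi = start, start + len(g)
        plo, phi = max(0, -lo), len(g) - max(0, hi - n_bins)
        if phi > plo:
            conv[tr, lo + plo : lo + phi] += g[plo:phi]
    return conv


def fit_single_stu_weight(
    trials, stu, basis: BasisSet, rmax: float | None = None
) -> SingleSTUFit:
    """Maximum-likelihood scalar weight of one STU (plus a free intercept).

    ``stu`` is an STUIndex, a (cell, i, j) tuple, or a structured row with
    those fields.  A stimulus that never overlaps the STU's spatiotemporal
    support yields kappa = 0 flagged degenerate.
    """
    cell, i, j = _stu_fields(stu)
    if rmax is None:
        _, rmax = estimate_rate_bounds(trials.spikes)
    conv = _stu_features(trials, basis, cell, i)
    v = basis.V[:, j]
    x_full = conv * v[None, :]
    idx = np.nonzero(x_full)
    x = x_full[idx]
    if len(x) == 0 or np.ptp(x) == 0 and np.all(x == 0):
        return SingleSTUFit(0.0, float("nan"), degenerate=True, converged=True)
    r = trials.spikes[idx].astype(float)
    n_bins_tot = trials.n_trials * trials.n_bins
    n0 = n_bins_tot - len(x)
    s0 = int(trials.spikes.sum() - r.sum())
    a = min(rmax * DT_S, 1 - 1e-9)
    kap, c, conv_flag = _newton_fit(x, r, n0, s0, a)
    return SingleSTUFit(float(kap), float(c), degenerate=False, converged=conv_flag)


def _stu_fields(stu):
    if hasattr(stu, "cell") and not isinstance(stu, np.void):
        return int(stu.cell), int(stu.delay_index), int(stu.time_index)
    if isinstance(stu, np.void):
        return int(stu["cell"]), int(stu["i"]), int(stu["j"])
    cell, i, j = stu
    return int(cell), int(i), int(j)


def prune_stus(trials, lattice, cfg: PruningConfig, basis: BasisSet | None = None) -> PruningResult:
    """Screen every candidate STU against its shuffled-trial control.

    ``lattice`` is the structured array from ``enumerate_stus`` (or any list
    of (cell, i, j) candidates — sweeping a reduced candidate set is the
    intended way to run at desk scale).  For each STU, ``n_resamples``
    weights are fit on random ``subset_fraction`` trial subsets and the same
    number on spike-deranged subsets; selection follows the
    |mu - mu_tilde| >= multiplier * sigma_tilde rule.  Per-STU fit failures
    are recorded, not raised.  Deterministic given ``cfg.seed``.
    """
    if trials.n_trials < 2:
        raise ValueError("pruning needs at least 2 trials")
    basis = basis if basis is not None else trials.basis()
    stus = [_stu_fields(s) for s in lattice]
    _, rmax = estimate_rate_bounds(trials.spikes)
    a = min(rmax * DT_S, 1 - 1e-9)

    n = trials.n_trials
    k = max(2, int(round(cfg.subset_fraction * n)))
    rng = np.random.default_rng(cfg.seed)
    subsets = [rng.choice(n, size=k, replace=False) for _ in range(cfg.n_resamples)]
    ctrl_subsets = [rng.choice(n, size=k, replace=False) for _ in range(cfg.n_resamples)]
    # spike-source derangement within each control subset
    ctrl_pairing = []
    for sub in ctrl_subsets:
        d = _derangement(len(sub), rng)
        ctrl_pairing.append(sub[d])

    spikes = trials.spikes
    tot_spikes = spikes.sum(axis=1).astype(float)
    n_bins = trials.n_bins

    rows = []
    by_pair: dict[tuple[int, int], list[int]] = {}
    for idx, (c, i, j) in enumerate(stus):
        by_pair.setdefault((c, i), []).append(idx)
    results = [None] * len(stus)
    for (c, i), members in by_pair.items():
        conv = _stu_features(trials, basis, c, i)
        for idx in members:
            _, _, j = stus[idx]
            v = basis.V[:, j]
            x_full = conv * v[None, :]
            # per-trial nonzero bins
            per_trial_idx = [np.flatnonzero(x_full[l]) for l in range(n)]
            per_trial_x = [x_full[l, bi] for l, bi in enumerate(per_trial_idx)]
            nnz_counts = np.array([len(b) for b in per_trial_idx])
            if nnz_counts.sum() == 0:
                results[idx] = (0.0, np.nan, np.nan, False, True)
                continue

            def fit_on(stim_trials, spike_trials):
                xs, rs = [], []
                n0 = 0
                s0 = 0.0
                for a_tr, b_tr in zip(stim_trials, spike_trials):
                    bi = per_trial_idx[a_tr]
                    xs.append(per_trial_x[a_tr])
                    rb = spikes[b_tr, bi].astype(float)
                    rs.append(rb)
                    n0 += n_bins - len(bi)
                    s0 += tot_spikes[b_tr] - rb.sum()
                x = np.concatenate(xs)
                if len(x) == 0:
                    return np.nan
                r = np.concatenate(rs)
                kap, _, _ = _newton_fit(x, r, n0, s0, a)
                return kap

            orig = np.array([fit_on(sub, sub) for sub in subsets])
            ctrl = np.array(
                [fit_on(sub, pair) for sub, pair in zip(ctrl_subsets, ctrl_pairing)]
            )
            mu = float(np.nanmean(orig))
            mu_c = float(np.nanmean(ctrl))
            sd_c = float(np.nanstd(ctrl, ddof=1))
            keep = abs(mu - mu_c) >= cfg.sigma_multiplier * sd_c
            results[idx] = (mu, mu_c, sd_c, bool(keep), False)

    for (c, i, j), res in zip(stus, results):
        mu, mu_c, sd_c, keep, degen = res
        rows.append(
            dict(
                cell=c, i=i, j=j, mu=mu, mu_ctrl=mu_c, sigma_ctrl=sd_c,
                selected=keep, degenerate=degen,
            )
        )
    table = pd.DataFrame(rows)
    return PruningResult(table=table, sigma_multiplier=cfg.sigma_multiplier)


class STUPruner(BaseEstimator):
    """Estimator wrapper: ``fit(trials)`` runs the screening sweep.

    Attributes after fit: ``result_`` (PruningResult), ``selected_mask_``
    (dense boolean lattice mask).
    """

    def __init__(self, lattice=None, n_resamples=100, subset_fraction=0.35,
                 sigma_multiplier=1.5, seed=0):
        self.lattice = lattice
        self.n_resamples = n_resamples
        self.subset_fraction = subset_fraction
        self.sigma_multiplier = sigma_multiplier
        self.seed = seed

    def fit(self, trials, y=None):
        from .basis import enumerate_stus

        basis = trials.basis()
        lattice = (
            self.lattice
            if self.lattice is not None
            else enumerate_stus(trials.grid, basis)
        )
        cfg = PruningConfig(
            n_resamples=self.n_resamples,
            subset_fraction=self.subset_fraction,
            sigma_multiplier=self.sigma_multiplier,
            seed=self.seed,
        )
        self.result_ = prune_stus(trials, lattice, cfg, basis)
        self.selected_mask_ = self.result_.selected_mask(trials.grid, basis)
        return self
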