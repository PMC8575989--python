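"""The S-model: a sparse-variable point-process GLM encoder.

The conditional intensity (instantaneous firing rate, sp/s) of a neuron on
trial l is

    lambda(t) = f( sum_{x,y,tau} k_xy(t,tau) s_xy(t-tau)
                   + sum_tau h(tau) r(t-tau) + b(t) + b0 )

with f(u) = rmax / (1 + exp(-u)) a saturating sigmoid, k_xy the
time-varying stimulus kernels parameterized on the selected STU lattice
(weights kappa), h a post-spike kernel capturing refractoriness, b(t) a
saccade-locked offset on the time basis, and b0 = f^{-1}(r0) fixed at the
measured mean rate r0.  Spikes are modeled as per-millisecond Bernoulli
draws with probability lambda(t) * 1 ms, and parameters are obtained by
maximizing the Bernoulli point-process log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .basis import BasisSet, build_basis, _basis_matrix
from .grid import ProbeGrid

__all__ = [
    "SModel",
    "KernelMap",
    "SparseVariableGLM",
    "nonlinearity",
    "inverse_nonlinearity",
    "predict_rate",
    "fit_smodel",
    "reconstruct_kernels",
    "build_history_basis",
    "estimate_rate_bounds",
]

DT_S = 1e-3  # bin width in seconds (1 ms clock)

# Post-spike kernel basis: 8 quadratic B-splines, 7 ms uniform knots
# {-14, -7, ..., 56}, evaluated on the causal grid tau = 1..56 ms.
HISTORY_KNOTS = np.arange(-14.0, 57.0, 7.0)
HISTORY_LEN = 56


def build_history_basis() -> tuple[np.ndarray, np.ndarray]:
    """(tau_grid, H) with H of shape (56, 8): post-spike basis on tau=1..56 ms."""
    tau_grid = np.arange(1.0, HISTORY_LEN + 1.0)
    full = _basis_matrix(HISTORY_KNOTS, tau_grid)
    return tau_grid, full


def nonlinearity(u, rmax: float):
    """f(u) = rmax / (1 + exp(-u)); maps drive to firing rate (sp/s)."""
    return rmax * expit(np.asarray(u, dtype=float))


def inverse_nonlinearity(r, rmax: float):
    """Exact inverse of :func:`nonlinearity`; defined for 0 < r < rmax."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(r >= rmax):
        raise ValueError("inverse nonlinearity requires 0 < r < rmax")
    return logit(r / rmax)


@dataclass
class SModel:
    """Fitted (or planted) S-model parameters.

    ``kappa`` is a dense (n_cells, n_delay, n_time) weight array, zero
    outside ``selected``; ``h_weights`` lives on the 8-function post-spike
    basis; ``b_weights`` on the time basis V_j.
    """

    grid: ProbeGrid
    basis: BasisSet
    kappa: np.ndarray
    selected: np.ndarray
    h_weights: np.ndarray
    b_weights: np.ndarray
    b0: float
    r0: float
    rmax: float

    def __post_init__(self) -> None:
        shape = (self.grid.n_cells, self.basis.n_delay, self.basis.n_time)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.kappa.shape != shape or self.selected.shape != shape:
            raise ValueError(f"kappa/selected must have shape {shape}")
        if not np.all(np.isfinite(self.kappa)):
            raise ValueError("non-finite STU weights")
        if self.rmax <= 0:
            raise ValueError("rmax must be positive")
        if np.any(self.kappa[~self.selected] != 0):
            raise ValueError("kappa must be zero outside the selected mask")

    @property
    def history_kernel(self) -> np.ndarray:
        """h(tau) on the 1 ms grid tau = 1..56 ms."""
        _, H = build_history_basis()
        return H @ self.h_weights

    @property
    def offset(self) -> np.ndarray:
        """b(t) on the trial's 1 ms clock."""
        return self.basis.V @ self.b_weights

    def with_kappa(self, kappa: np.ndarray, selected: np.ndarray | None = None) -> "SModel":
        """Copy with replaced stimulus weights (the original is untouched)."""
        return replace(
            self,
            kappa=np.array(kappa, dtype=float),
            selected=self.selected.copy() if selected is None else selected,
            h_weights=self.h_weights.copy(),
            b_weights=self.b_weights.copy(),
        )


@dataclass
class KernelMap:
    """Dense stimulus kernels k_xy(t, tau) on the 1 ms grid.

    ``values[c, a, b]`` is the kernel of cell ``c`` at ``tau = tau_grid[a]``,
    ``t = t_grid[b]``.
    """

    cells: np.ndarray
    tau_grid: np.ndarray
    t_grid: np.ndarray
    values: np.ndarray

    def cell_kernel(self, cell: int) -> np.ndarray:
        pos = np.flatnonzero(self.cells == cell)
        if len(pos) == 0:
            raise KeyError(f"cell {cell} not in this map")
        return self.values[pos[0]]


def reconstruct_kernels(
    model: SModel,
    cells: np.ndarray | None = None,
    tau: np.ndarray | None = None,
    t: np.ndarray | None = None,
) -> KernelMap:
    """k_xy(t, tau) = sum_ij kappa_xyij U_i(tau) V_j(t) for the given cells.

    Defaults evaluate every cell on the cached 1 ms grids.  The map is zero
    wherever no selected STU has support.
    """
    basis = model.basis
    cells = np.arange(model.grid.n_cells) if cells is None else np.asarray(cells)
    if tau is None:
        tau = basis.delay_grid
        Umat = basis.U
    else:
        tau = np.asarray(tau, dtype=float)
        Umat = np.column_stack(
            [basis.eval_delay(i, tau) for i in range(basis.n_delay)]
        )
    if t is None:
        t = basis.time_grid
        Vmat = basis.V
    else:
        t = np.asarray(t, dtype=float)
        Vmat = np.column_stack([basis.eval_time(j, t) for j in range(basis.n_time)])
    vals = np.empty((len(cells), len(tau), len(t)))
    for a, c in enumerate(cells):
        vals[a] = Umat @ model.kappa[c] @ Vmat.T
    return KernelMap(cells=cells, tau_grid=np.asarray(tau), t_grid=np.asarray(t), values=vals)


# ---------------------------------------------------------------------------
# stimulus features
# ---------------------------------------------------------------------------

def _boxcar_profiles(basis: BasisSet) -> np.ndarray:
    """g_i(u) = sum_{d=0..6} U_i(u - d): delay basis convolved with the 7 ms
    probe boxcar, sampled at integer lags u = delay_grid[0] .. delay_grid[-1]+6.
    """
    n_u = len(basis.delay_grid) + 6
    g = np.zeros((basis.n_delay, n_u))
    for d in range(7):
        g[:, d : d + len(basis.delay_grid)] += basis.U.T
    return g


def stimulus_drive(
    model_or_parts,
    trial_events: list[np.ndarray],
    kappa: np.ndarray | None = None,
) -> np.ndarray:
    """Stimulus drive sum_{c,tau} k_c(t,tau) s_c(t-tau) per trial.

    ``trial_events`` is a list (one entry per trial) of structured arrays or
    2-column int arrays (t_on_ms, cell) of probe onsets.  Returns an array
    (n_trials, n_bins).
    """
    model = model_or_parts
    basis = model.basis
    W = model.kappa if kappa is None else kappa
    g = _boxcar_profiles(basis)
    u0 = int(basis.delay_grid[0])
    n_bins = basis.n_bins
    # w_ci(t) = sum_j kappa[c,i,j] V_j(t), only for (c,i) rows with weight
    used = np.argwhere(np.any(W != 0, axis=2))  # rows of (c, i)
    wct = {(int(c), int(i)): basis.V @ W[c, i] for c, i in used}
    out = np.zeros((len(trial_events), n_bins))
    for l, ev in enumerate(trial_events):
        if len(ev) == 0:
            continue
        t_on, cell = _unpack_events(ev)
        conv: dict[tuple[int, int], np.ndarray] = {}
        for (c, i), w in wct.items():
            sel = cell == c
            if not np.any(sel):
                continue
            key = (c, i)
            acc = conv.get(key)
            if acc is None:
                acc = np.zeros(n_bins)
                conv[key] = acc
            for onset in t_on[sel]:
                _add_profile(acc, g[i], onset - int(basis.t_min) + u0)
        for key, acc in conv.items():
            out[l] += acc * wct[key]
    return out


def _unpack_events(ev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if ev.dtype.names:
        return ev["t_on"].astype(int), ev["cell"].astype(int)
    ev = np.asarray(ev)
    return ev[:, 0].astype(int), ev[:, 1].astype(int)


def _add_profile(acc: np.ndarray, profile: np.ndarray, start: int) -> None:
    """acc[start : start+len(profile)] += profile, clipped to bounds."""
    n = len(acc)
    lo, hi = start, start + len(profile)
    plo = max(0, -lo)
    phi = len(profile) - max(0, hi - n)
    if phi <= plo:
        return
    acc[lo + plo : lo + phi] += profile[plo:phi]


def history_drive(model: SModel, spikes: np.ndarray) -> np.ndarray:
    """sum_tau h(tau) r(t - tau) per trial; ``spikes`` is (n_trials, n_bins)."""
    h = model.history_kernel
    spikes = np.atleast_2d(spikes)
    out = np.zeros_like(spikes, dtype=float)
    kern = np.concatenate([[0.0], h])  # tau = 0 excluded (strictly causal)
    for l in range(spikes.shape[0]):
        out[l] = np.convolve(spikes[l].astype(float), kern)[: spikes.shape[1]]
    return out


def predict_rate(
    model: SModel,
    trial_events: list[np.ndarray],
    spikes: np.ndarray | None = None,
) -> np.ndarray:
    """lambda(t) per trial (sp/s), strictly inside (0, rmax).

    ``spikes`` supplies the spike history; omit it (or pass zeros) for a
    stimulus-only readout.
    """
    drive = stimulus_drive(model, trial_events)
    if spikes is not None:
        spikes = np.atleast_2d(np.asarray(spikes))
        if spikes.shape != drive.shape:
            raise ValueError(
                f"spike array shape {spikes.shape} does not match the model "
                f"clock {drive.shape}"
            )
        drive += history_drive(model, spikes)
    u = drive + model.offset[None, :] + model.b0
    lam = nonlinearity(u, model.rmax)
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError("non-finite conditional intensity")
    return lam


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def bernoulli_loglik(lam: np.ndarray, spikes: np.ndarray) -> float:
    """Point-process Bernoulli log-likelihood with p = lambda * 1 ms (clipped)."""
    p = np.clip(lam * DT_S, 1e-12, 1 - 1e-9)
    r = np.asarray(spikes, dtype=float)
    return float(np.sum(r * np.log(p) + (1 - r) * np.log1p(-p)))


def estimate_rate_bounds(
    spikes: np.ndarray, headroom: float = 1.25, fwhm_ms: float = 5.0
) -> tuple[float, float]:
    """(r0, rmax) from data: mean rate, and the smoothed trial-averaged peak
    rate times a headroom factor."""
    from scipy.ndimage import gaussian_filter1d

    spikes = np.atleast_2d(spikes)
    r0 = float(spikes.mean() / DT_S)
    psth = spikes.mean(axis=0) / DT_S
    sigma = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    peak = float(gaussian_filter1d(psth, sigma).max())
    rmax = max(peak, r0 * 2, 1.0) * headroom
    return r0, rmax


def _adjacency_differences(stu_list, n_cols: int) -> sp.csr_matrix:
    """Sparse first-difference operator between lattice-adjacent selected
    STUs (same cell, delay or time index differing by one)."""
    pos = {stu: k for k, stu in enumerate(stu_list)}
    rows, cols, vals = [], [], []
    n = 0
    for (c, i, j), k in pos.items():
        for nb in ((c, i + 1, j), (c, i, j + 1)):
            if nb in pos:
                rows += [n, n]
                cols += [k, pos[nb]]
                vals += [1.0, -1.0]
                n += 1
    return sp.csr_matrix((vals, (rows, cols)), shape=(max(n, 1), n_cols))


class SparseVariableGLM(BaseEstimator):
    """Scikit-learn-style estimator for the S-model encoder.

    Parameters
    ----------
    selected : bool ndarray (n_cells, n_delay, n_time)
        STU selection mask from pruning; kappa is estimated only there.
    grid : ProbeGrid
    basis : BasisSet, optional
        Defaults to the standard 30 x 156 basis.
    l2 : float
        Ridge penalty on kappa for conditioning (not on h or b).
    smoothness : float
        First-difference penalty between kappa weights of lattice-adjacent
        selected STUs (same cell, neighboring delay or time basis).
        Overlapping B-spline features are strongly collinear at
        session-sized data; this penalty regularizes exactly those
        near-null directions while leaving the reconstructed kernel's
        smooth structure untouched.
    tol : float
        Relative log-likelihood convergence tolerance.
    max_iter : int
    r0, rmax : float, optional
        Fix the baseline / saturation rates; estimated from the data when
        None.
    fit_history, fit_offset : bool
        Include the post-spike kernel / time-varying offset.

    Attributes (after ``fit``)
    ----------
    kappa_, h_, b_, b0_, r0_, rmax_, loglik_, null_loglik_, converged_, n_iter_
    model_ : SModel
    """

    def __init__(
        self,
        selected=None,
        grid=None,
        basis=None,
        l2: float = 0.5,
        smoothness: float = 4.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        r0: float | None = None,
        rmax: float | None = None,
        rmax_headroom: float = 1.25,
        fit_history: bool = True,
        fit_offset: bool = True,
    ):
        self.selected = selected
        self.grid = grid
        self.basis = basis
        self.l2 = l2
        self.smoothness = smoothness
        self.tol = tol
        self.max_iter = max_iter
        self.r0 = r0
        self.rmax = rmax
        self.rmax_headroom = rmax_headroom
        self.fit_history = fit_history
        self.fit_offset = fit_offset

    # -- design matrix ----------------------------------------------------
    def _design(self, trial_events, spikes, basis, stu_list):
        """Sparse design matrix: columns = [kappa terms | h terms | b terms]."""
        n_trials, n_bins = spikes.shape
        g = _boxcar_profiles(basis)
        u0 = int(basis.delay_grid[0])
        pairs = sorted({(int(c), int(i)) for c, i, _ in stu_list})
        pair_pos = {p: k for k, p in enumerate(pairs)}
        _, H = build_history_basis()
        n_h = H.shape[1] if self.fit_history else 0
        n_b = basis.n_time if self.fit_offset else 0

        rows, cols, vals = [], [], []
        col_of_stu = {}
        for k, (c, i, j) in enumerate(stu_list):
            col_of_stu[(c, i, j)] = k
        Vsupp = [np.flatnonzero(basis.V[:, j]) for j in range(basis.n_time)]

        for l in range(n_trials):
            ev = trial_events[l]
            conv = np.zeros((len(pairs), n_bins))
            if len(ev):
                t_on, cell = _unpack_events(ev)
                for (c, i), k in pair_pos.items():
                    sel = cell == c
                    for onset in t_on[sel]:
                        _add_profile(conv[k], g[i], onset - basis.t_min + u0)
            base = l * n_bins
            for (c, i, j), k in col_of_stu.items():
                supp = Vsupp[j]
                x = conv[pair_pos[(c, i)], supp] * basis.V[supp, j]
                nz = np.flatnonzero(x)
                if len(nz):
                    rows.append(base + supp[nz])
                    cols.append(np.full(len(nz), k))
                    vals.append(x[nz])
            if self.fit_history:
                r = spikes[l].astype(float)
                for m in range(n_h):
                    kern = np.concatenate([[0.0], H[:, m]])
                    x = np.convolve(r, kern)[:n_bins]
                    nz = np.flatnonzero(x)
                    if len(nz):
                        rows.append(base + nz)
                        cols.append(np.full(len(nz), len(stu_list) + m))
                        vals.append(x[nz])
            if self.fit_offset:
                for j in range(n_b):
                    supp = Vsupp[j]
                    rows.append(base + supp)
                    cols.append(np.full(len(supp), len(stu_list) + n_h + j))
                    vals.append(basis.V[supp, j])
        n_cols = len(stu_list) + n_h + n_b
        X = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_trials * n_bins, n_cols),
        )
        return X, n_h, n_b

    def fit(self, trials, y=None):
        """Fit to a TrialSet (see perirf.synth); returns self."""
        basis = self.basis if self.basis is not None else trials.basis()
        grid = self.grid if self.grid is not None else trials.grid
        selected = np.asarray(self.selected, dtype=bool)
        if selected.shape != (grid.n_cells, basis.n_delay, basis.n_time):
            raise ValueError("selected mask shape does not match grid/basis")
        if not selected.any():
            raise ValueError("selected mask is empty")
        spikes = trials.spikes
        if spikes.shape[1] != basis.n_bins:
            raise ValueError("trial clock does not match the basis time grid")
        r0 = self.r0
        rmax = self.rmax
        if r0 is None or rmax is None:
            r0_est, rmax_est = estimate_rate_bounds(spikes, self.rmax_headroom)
            r0 = r0_est if r0 is None else r0
            rmax = rmax_est if rmax is None else rmax
        if not 0 < r0 < rmax:
            raise ValueError("need 0 < r0 < rmax")
        b0 = float(inverse_nonlinearity(r0, rmax))

        stu_list = [tuple(idx) for idx in np.argwhere(selected)]
        trial_events = trials.events_by_trial()
        X, n_h, n_b = self._design(trial_events, spikes, basis, stu_list)
        r = spikes.reshape(-1).astype(float)
        a = rmax * DT_S
        if a >= 1.0:
            a = 1.0 - 1e-9  # lambda*dt must stay a probability
        n_kappa = len(stu_list)
        l2_vec = np.zeros(X.shape[1])
        l2_vec[:n_kappa] = self.l2
        D = _adjacency_differences(stu_list, X.shape[1]) if self.smoothness else None

        def negloglik(theta):
            u = X @ theta + b0
            s = expit(u)
            p = np.clip(a * s, 1e-12, 1 - 1e-9)
            nll = -(r @ np.log(p) + (1 - r) @ np.log1p(-p))
            # d/du of -loglik
            gu = -(r * (1 - s) - (1 - r) * a * s * (1 - s) / (1 - p))
            grad = X.T @ gu
            nll += 0.5 * np.sum(l2_vec * theta**2)
            grad += l2_vec * theta
            if D is not None:
                d = D @ theta
                nll += 0.5 * self.smoothness * float(d @ d)
                grad += self.smoothness * (D.T @ d)
            return nll, grad

        theta0 = np.zeros(X.shape[1])
        f0 = negloglik(theta0)[0]
        res = minimize(
            negloglik,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": self.max_iter,
                "ftol": self.tol,
                "gtol": 1e-8,
            },
        )
        if not np.all(np.isfinite(res.x)):
            raise FloatingPointError("non-finite parameters after optimization")
        theta = res.x
        kappa = np.zeros_like(selected, dtype=float)
        for k, (c, i, j) in enumerate(stu_list):
            kappa[c, i, j] = theta[k]
        _, H = build_history_basis()
        h_w = theta[n_kappa : n_kappa + n_h] if n_h else np.zeros(H.shape[1])
        b_w = (
            theta[n_kappa + n_h :]
            if n_b
            else np.zeros(basis.n_time)
        )
        self.kappa_ = kappa
        self.h_ = h_w
        self.b_ = b_w
        self.b0_ = b0
        self.r0_ = float(r0)
        self.rmax_ = float(rmax)
        u_final = X @ theta + b0
        p_final = np.clip(a * expit(u_final), 1e-12, 1 - 1e-9)
        self.loglik_ = float(r @ np.log(p_final) + (1 - r) @ np.log1p(-p_final))
        p_null = np.clip(a * expit(b0), 1e-12, 1 - 1e-9)
        self.null_loglik_ = float(
            r.sum() * np.log(p_null) + (len(r) - r.sum()) * np.log1p(-p_null)
        )
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.model_ = SModel(
            grid=grid,
            basis=basis,
            kappa=kappa,
            selected=selected.copy(),
            h_weights=h_w,
            b_weights=b_w,
            b0=b0,
            r0=float(r0),
            rmax=float(rmax),
        )
        return self

    def predict_rate(self, trial_events, spikes=None):
        """Conditional intensity lambda(t) per trial for new stimuli."""
        return predict_rate(self.model_, trial_events, spikes)


def fit_smodel(trials, selected, basis=None, **kwargs) -> SModel:
    """Functional wrapper: fit the S-model and return the fitted SModel."""
    est = SparseVariableGLM(selected=selected, basis=basis, **kwargs)
    est.fit(trials)
    return est.model_
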