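"""Model-based readout of the visual scene: detectability and
discriminability AUC maps and the RF1/RF2 temporal-overlap statistic.

The fitted encoder is probed with arbitrary stimulus sequences it never
saw: a target probe is embedded in a 200 ms random sequence of filler
probes, and the predicted response lambda(t*) to sequences with the target
ON at t* - tau* is compared against sequences without it, using the
rank-based area under the ROC curve.  Sweeping response time t* (relative
to saccade onset) and probe-to-response delay tau* yields a decoding map;
thresholding it and projecting onto the response-time axis gives the window
over which a location is readable, and the signed overlap of the RF1 and
RF2 windows quantifies the continuity of the visuospatial representation
across the saccade (negative overlap = representational gap).

During readout the spike-history drive is zero: the readout conditions
only on the stimulus sequence, the saccade-locked offset, and the bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .encoder import SModel, nonlinearity, reconstruct_kernels

__all__ = [
    "DecodingGrid",
    "DecodingMap",
    "make_embeddings",
    "auc",
    "detectability_map",
    "discriminability_map",
    "threshold_region",
    "temporal_overlap",
    "THRESHOLD_DETECT",
    "THRESHOLD_DISCRIMINATE",
    "THRESHOLD_POPULATION",
]

THRESHOLD_DETECT = 0.61
THRESHOLD_DISCRIMINATE = 0.57
THRESHOLD_POPULATION = 0.55  # population-contour variant

FRAME_MS = 7


def _default_t() -> np.ndarray:
    return np.arange(-50.0, 301.0, 10.0)


def _default_tau() -> np.ndarray:
    return np.arange(30.0, 191.0, 10.0)


@dataclass(frozen=True)
class DecodingGrid:
    """Sweep configuration for the decoding maps.

    Response times t: -50..+300 ms re saccade (10 ms steps); delays tau:
    30..190 ms before the response (10 ms steps); each target embedded in a
    200 ms random probe sequence; 100 ON + 100 OFF sequences per point; AUC
    averaged over 20 repeats on random 80% subsamples.
    """

    t_values: np.ndarray = field(default_factory=_default_t)
    tau_values: np.ndarray = field(default_factory=_default_tau)
    embedding_ms: int = 200
    n_sequences: int = 100
    n_repeats: int = 20
    subsample_fraction: float = 0.80
    seed: int = 0
    exclude_rf_fillers: bool = True
    off_excludes_target_everywhere: bool = True
    allow_edge_center: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if np.max(self.tau_values) >= self.embedding_ms:
            raise ValueError("delays must be shorter than the embedding")


@dataclass
class DecodingMap:
    """AUC per (response time, delay); ``auc[a, b]`` at ``t_values[a]``,
    ``tau_values[b]``."""

    probe: int
    t_values: np.ndarray
    tau_values: np.ndarray
    auc: np.ndarray
    kind: str = "detectability"

    def __post_init__(self) -> None:
        if np.any(self.auc < 0) or np.any(self.auc > 1):
            raise ValueError("AUC outside [0, 1]")


def _frame_onsets(t_star: float, tau_star: float, embedding_ms: int) -> np.ndarray:
    """7 ms frame onsets tiling [t* - embedding, t*), aligned so one frame
    starts exactly at t* - tau*."""
    k_lo = int(np.ceil((tau_star - embedding_ms - (FRAME_MS - 1)) / FRAME_MS))
    k_hi = int(np.floor((tau_star - 1) / FRAME_MS))
    k = np.arange(k_lo, k_hi + 1)
    return (t_star - tau_star + FRAME_MS * k).astype(int)


def make_embeddings(
    model_grid,
    probe: int,
    t_star: float,
    tau_star: float,
    cfg: DecodingGrid,
    seed,
    versus: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ON / OFF stimulus sets for one decoding-grid point.

    Returns ``(onsets, on_cells, off_cells)``: frame onset times (ms) and two
    (n_sequences, n_frames) cell-index arrays.  In every ON sequence the
    target ``probe`` occupies the frame starting at t* - tau*; OFF sequences
    never contain it (or, for discriminability, contain ``versus`` there
    instead).  Filler frames draw uniformly from non-target cells, by
    default also excluding the RF1/RF2 cells so the two maps do not
    cross-contaminate.
    """
    grid = model_grid
    rng = np.random.default_rng(seed)
    onsets = _frame_onsets(t_star, tau_star, cfg.embedding_ms)
    target_frame = int(np.flatnonzero(onsets == int(t_star - tau_star))[0])
    excluded = {probe}
    if versus is not None:
        excluded.add(versus)
    if cfg.exclude_rf_fillers:
        excluded |= {grid.rf1_index, grid.rf2_index}
    fillers = np.array([c for c in range(grid.n_cells) if c not in excluded])
    if len(fillers) == 0:
        raise ValueError("no filler cells available")
    shape = (cfg.n_sequences, len(onsets))
    on_cells = fillers[rng.integers(0, len(fillers), size=shape)]
    on_cells[:, target_frame] = probe
    if cfg.off_excludes_target_everywhere or versus is not None:
        off_cells = fillers[rng.integers(0, len(fillers), size=shape)]
    else:
        # weaker reading: target may appear as a filler elsewhere in OFF
        pool = np.array(sorted(set(fillers.tolist()) | {probe}))
        off_cells = pool[rng.integers(0, len(pool), size=shape)]
        off_cells[:, target_frame] = fillers[
            rng.integers(0, len(fillers), size=cfg.n_sequences)
        ]
    if versus is not None:
        off_cells[:, target_frame] = versus
    return onsets, on_cells, off_cells


def auc(on_values, off_values) -> float:
    """Rank-based (Mann-Whitney) AUC of ON vs OFF values, ties counted 0.5."""
    on_values = np.asarray(on_values, dtype=float)
    off_values = np.asarray(off_values, dtype=float)
    if len(on_values) == 0 or len(off_values) == 0:
        raise ValueError("both value sets must be nonempty")
    y = np.concatenate([np.ones(len(on_values)), np.zeros(len(off_values))])
    return float(roc_auc_score(y, np.concatenate([on_values, off_values])))


class _ReadoutEngine:
    """Precomputed probe-response table for fast lambda(t*) evaluation.

    ``contrib[c, u, a]`` is the drive at response time ``t_values[a]`` from a
    7 ms probe at cell ``c`` whose frame starts ``u`` ms before the response
    (the kernel convolved with the probe boxcar along delay).
    """

    def __init__(self, model: SModel, t_values: np.ndarray):
        self.model = model
        self.t_values = np.asarray(t_values, dtype=float)
        km = reconstruct_kernels(model, t=self.t_values)
        K = km.values  # (n_cells, n_tau, n_t)
        tau = km.tau_grid.astype(int)
        self.u_min = int(tau[0])
        n_u = len(tau) + FRAME_MS - 1
        contrib = np.zeros((K.shape[0], n_u, K.shape[2]))
        for d in range(FRAME_MS):
            contrib[:, d : d + len(tau), :] += K
        self.contrib = contrib
        self.n_u = n_u
        V = model.basis
        self.offset_at_t = np.array(
            [model.offset[V.t_index(t)] for t in self.t_values]
        )

    def responses(self, onsets: np.ndarray, cells: np.ndarray, t_idx: int) -> np.ndarray:
        """lambda(t*) for each sequence; cells is (n_seq, n_frames)."""
        t_star = self.t_values[t_idx]
        u = (t_star - onsets).astype(int) - self.u_min
        ok = (u >= 0) & (u < self.n_u)
        drive = self.contrib[cells[:, ok], u[None, ok], t_idx].sum(axis=1)
        utot = drive + self.offset_at_t[t_idx] + self.model.b0
        return nonlinearity(utot, self.model.rmax)


def _mean_auc(on, off, cfg: DecodingGrid, rng) -> float:
    n_on = max(1, int(round(cfg.subsample_fraction * len(on))))
    n_off = max(1, int(round(cfg.subsample_fraction * len(off))))
    vals = []
    for _ in range(cfg.n_repeats):
        i = rng.choice(len(on), n_on, replace=False)
        j = rng.choice(len(off), n_off, replace=False)
        vals.append(auc(on[i], off[j]))
    return float(np.mean(vals))


def detectability_map(model: SModel, probe: int, cfg: DecodingGrid | None = None) -> DecodingMap:
    """AUC map for detecting ``probe`` from the model-predicted response."""
    cfg = cfg if cfg is not None else DecodingGrid()
    engine = _ReadoutEngine(model, cfg.t_values)
    out = np.zeros((len(cfg.t_values), len(cfg.tau_values)))
    for a, t_star in enumerate(cfg.t_values):
        for b, tau_star in enumerate(cfg.tau_values):
            seed = [cfg.seed, int(probe), a, b]
            onsets, on_c, off_c = make_embeddings(
                model.grid, probe, t_star, tau_star, cfg, seed
            )
            lam_on = engine.responses(onsets, on_c, a)
            lam_off = engine.responses(onsets, off_c, a)
            rng = np.random.default_rng(seed + [1])
            out[a, b] = _mean_auc(lam_on, lam_off, cfg, rng)
    return DecodingMap(
        probe=probe, t_values=cfg.t_values, tau_values=cfg.tau_values,
        auc=out, kind="detectability",
    )


def discriminability_map(
    model: SModel, center_probe: int, cfg: DecodingGrid | None = None
) -> DecodingMap:
    """Mean AUC for discriminating ``center_probe`` from each of its 8 grid
    neighbors presented at the same delay; errors on edge cells unless
    ``cfg.allow_edge_center`` averages over the existing neighbors."""
    cfg = cfg if cfg is not None else DecodingGrid()
    grid = model.grid
    if grid.is_interior(center_probe):
        neighbors = grid.neighbors(center_probe)
    elif cfg.allow_edge_center:
        neighbors = grid.neighborhood(center_probe, include_center=False)
    else:
        raise ValueError(
            f"cell {center_probe} is on the grid edge; set allow_edge_center "
            "to average over existing neighbors"
        )
    engine = _ReadoutEngine(model, cfg.t_values)
    out = np.zeros((len(cfg.t_values), len(cfg.tau_values)))
    for a, t_star in enumerate(cfg.t_values):
        for b, tau_star in enumerate(cfg.tau_values):
            accs = []
            for q, nb in enumerate(neighbors):
                seed = [cfg.seed, int(center_probe), int(nb), a, b]
                onsets, on_c, off_c = make_embeddings(
                    grid, center_probe, t_star, tau_star, cfg, seed, versus=int(nb)
                )
                lam_on = engine.responses(onsets, on_c, a)
                lam_off = engine.responses(onsets, off_c, a)
                rng = np.random.default_rng(seed + [1])
                accs.append(_mean_auc(lam_on, lam_off, cfg, rng))
            out[a, b] = float(np.mean(accs))
    return DecodingMap(
        probe=center_probe, t_values=cfg.t_values, tau_values=cfg.tau_values,
        auc=out, kind="discriminability",
    )


def threshold_region(dmap: DecodingMap, thr: float) -> tuple[np.ndarray, np.ndarray]:
    """(mask, projection): boolean auc > thr, and its any-delay projection
    onto the response-time axis."""
    mask = dmap.auc > thr
    return mask, mask.any(axis=1)


def _largest_run_interval(proj: np.ndarray, t_values: np.ndarray) -> tuple[float, float]:
    """[start, end] interval (ms) of the largest contiguous above-threshold
    run; each grid point covers one grid step."""
    proj = np.asarray(proj, dtype=bool)
    if not proj.any():
        raise ValueError("empty projection: overlap undefined")
    t_values = np.asarray(t_values, dtype=float)
    dt = float(np.diff(t_values)[0]) if len(t_values) > 1 else 1.0
    padded = np.concatenate([[False], proj, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    lengths = ends - starts
    k = int(np.argmax(lengths))
    return float(t_values[starts[k]]), float(t_values[ends[k] - 1] + dt)


def temporal_overlap(region_rf1, region_rf2, t_values: np.ndarray | None = None) -> float:
    """Signed temporal overlap (ms) between two response-time regions.

    Regions may be (start, end) intervals in ms, or boolean projections on a
    common ``t_values`` grid (the largest contiguous run of each is used).
    Positive: length of the intersection; negative: gap between the nearest
    endpoints when disjoint.
    """

    def as_interval(region):
        if isinstance(region, (tuple, list)) and len(region) == 2 and np.isscalar(region[0]):
            return float(region[0]), float(region[1])
        if t_values is None:
            raise ValueError("boolean projections require t_values")
        return _largest_run_interval(np.asarray(region), t_values)

    a1, b1 = as_interval(region_rf1)
    a2, b2 = as_interval(region_rf2)
    return float(min(b1, b2) - max(a1, a2))
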