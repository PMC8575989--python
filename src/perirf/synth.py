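"""Synthetic saccade-task stimuli and ground-truth neurons.

Emulates the visually guided saccade task: on each trial a complete
pseudorandom sequence ("condition") of 81 probes — one per grid cell — is
flashed at 7 ms per probe, one probe on screen at a time, while the neuron
emits Bernoulli spikes from its conditional intensity on a 1 ms clock.
Saccade onset is t = 0; trials span [-554, +552] ms, matching the time-basis
knot span.  Ground-truth neurons are S-models with planted, configurable
kernel dynamics (RF1 response at a fixed latency, perisaccadic late
response enhancement at RF1, RF2 emergence after the saccade, optional
early suppression), so every downstream stage is testable by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .basis import BasisSet, build_basis
from .encoder import (
    DT_S,
    SModel,
    build_history_basis,
    inverse_nonlinearity,
    nonlinearity,
    stimulus_drive,
)
from .grid import ProbeGrid

__all__ = [
    "Condition",
    "TrialSet",
    "GroundTruthConfig",
    "make_conditions",
    "render_stimulus",
    "make_ground_truth_model",
    "simulate_spikes",
    "simulate_trials",
]

FRAME_MS = 7
EVENT_DTYPE = np.dtype([("trial", "i4"), ("t_on", "i4"), ("cell", "i4")])


@dataclass(frozen=True)
class Condition:
    """One complete probe sequence: each grid cell exactly once, 7 ms frames."""

    sequence: np.ndarray
    n_cells: int
    frame_ms: int = FRAME_MS

    def __post_init__(self) -> None:
        seq = np.asarray(self.sequence, dtype=np.intp)
        object.__setattr__(self, "sequence", seq)
        if len(seq) and (
            len(np.unique(seq)) != len(seq)
            or seq.min() < 0
            or seq.max() >= self.n_cells
        ):
            raise ValueError("sequence must list distinct in-range cells")

    @property
    def duration_ms(self) -> int:
        return len(self.sequence) * self.frame_ms


@dataclass
class TrialSet:
    """Saccade-aligned stimulus events and binary spike trains, 1 ms clock.

    ``events`` is a structured array (trial, t_on, cell) of probe onsets,
    sorted by (trial, t_on); each probe is ON for 7 consecutive 1 ms bins
    starting at t_on.  ``spikes`` is (n_trials, n_bins) in {0, 1}, bin b
    covering time t_min + b.
    """

    grid: ProbeGrid
    events: np.ndarray
    spikes: np.ndarray
    t_min: int = -554
    t_max: int = 552

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=np.uint8)
        if self.spikes.ndim != 2 or self.spikes.shape[1] != self.n_bins:
            raise ValueError("spikes must be (n_trials, n_bins)")
        if np.any(self.spikes > 1):
            raise ValueError("spikes must be binary")
        ev = np.asarray(self.events)
        if ev.dtype != EVENT_DTYPE:
            ev = np.array(
                [tuple(row) for row in ev], dtype=EVENT_DTYPE
            ) if len(ev) else np.empty(0, dtype=EVENT_DTYPE)
        order = np.lexsort((ev["t_on"], ev["trial"]))
        self.events = ev[order]
        self._check_events()

    def _check_events(self) -> None:
        ev = self.events
        if len(ev) == 0:
            return
        if ev["trial"].min() < 0 or ev["trial"].max() >= self.n_trials:
            raise ValueError("event trial index out of range")
        if ev["t_on"].min() < self.t_min or ev["t_on"].max() + FRAME_MS - 1 > self.t_max:
            raise ValueError("probe event extends outside the trial span")
        if ev["cell"].min() < 0 or ev["cell"].max() >= self.grid.n_cells:
            raise ValueError("event cell outside the probe grid")
        same = ev["trial"][1:] == ev["trial"][:-1]
        if np.any(same & (np.diff(ev["t_on"]) < FRAME_MS)):
            raise ValueError("overlapping probe events within a trial")

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.t_max - self.t_min + 1

    def basis(self) -> BasisSet:
        b = build_basis()
        if b.n_bins != self.n_bins or b.t_min != self.t_min:
            raise ValueError("trial span does not match the standard time basis")
        return b

    def events_by_trial(self) -> list[np.ndarray]:
        out = [
            np.empty(0, dtype=[("t_on", "i4"), ("cell", "i4")])
            for _ in range(self.n_trials)
        ]
        ev = self.events
        for l in np.unique(ev["trial"]):
            sel = ev[ev["trial"] == l]
            rec = np.empty(len(sel), dtype=[("t_on", "i4"), ("cell", "i4")])
            rec["t_on"], rec["cell"] = sel["t_on"], sel["cell"]
            out[int(l)] = rec
        return out

    def subset(self, trial_idx: np.ndarray) -> "TrialSet":
        """New TrialSet with the given trials, renumbered 0..k-1."""
        trial_idx = np.asarray(trial_idx, dtype=np.intp)
        pieces = []
        for new_l, l in enumerate(trial_idx):
            sel = self.events[self.events["trial"] == l].copy()
            sel["trial"] = new_l
            pieces.append(sel)
        ev = (
            np.concatenate(pieces)
            if pieces
            else np.empty(0, dtype=EVENT_DTYPE)
        )
        return TrialSet(
            grid=self.grid,
            events=ev,
            spikes=self.spikes[trial_idx].copy(),
            t_min=self.t_min,
            t_max=self.t_max,
        )

    def with_spikes(self, spikes: np.ndarray) -> "TrialSet":
        return TrialSet(
            grid=self.grid,
            events=self.events.copy(),
            spikes=spikes,
            t_min=self.t_min,
            t_max=self.t_max,
        )


def make_conditions(grid: ProbeGrid, n_trials: int, seed: int) -> list[Condition]:
    """Balanced pseudorandom probe sequences, one per trial.

    Uses a cyclic Latin-square scheme per block of ``n_cells`` trials: within
    each block, every cell occupies every ordinal position exactly once, so
    with a multiple of 81 trials the (cell, position) counts are exactly
    balanced.  Deterministic for a given seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n = grid.n_cells
    out: list[Condition] = []
    while len(out) < n_trials:
        perm = rng.permutation(n)
        rows = rng.permutation(n)
        for r in rows[: n_trials - len(out)]:
            seq = perm[(int(r) + np.arange(n)) % n]
            out.append(Condition(sequence=seq, n_cells=n))
    return out


def render_stimulus(
    condition: Condition,
    saccade_onset_offset: int,
    span: tuple[int, int] = (-554, 552),
) -> np.ndarray:
    """Binary stimulus tensor (n_cells, n_bins) for one trial.

    The sequence's first probe turns ON at ``saccade_onset_offset`` ms
    relative to saccade onset; frames tile contiguously at 7 ms each.
    """
    t_min, t_max = span
    n_bins = t_max - t_min + 1
    s = np.zeros((condition.n_cells, n_bins), dtype=np.uint8)
    dur = condition.duration_ms
    if dur and (
        saccade_onset_offset < t_min or saccade_onset_offset + dur - 1 > t_max
    ):
        raise ValueError(
            f"sequence of {dur} ms at offset {saccade_onset_offset} does not "
            f"fit the span [{t_min}, {t_max}]"
        )
    for k, cell in enumerate(condition.sequence):
        b = saccade_onset_offset + k * condition.frame_ms - t_min
        s[cell, b : b + condition.frame_ms] = 1
    return s


@dataclass
class GroundTruthConfig:
    """Planted S-model parameters for a synthetic extrastriate neuron.

    Kernel amplitudes are in drive units (the sigmoid's argument); a probe
    inside a region of amplitude ``g`` contributes roughly ``7 g`` of drive
    (7 ON milliseconds).  Defaults produce a fixation baseline of 20 sp/s,
    an RF1 probe response peaking near 80 sp/s at ~55 ms latency, a
    perisaccadic late response at RF1 near 45 sp/s (delays 75-130 ms, times
    0-100 ms), and RF2 sensitivity emerging at saccade onset — matching the
    response magnitudes reported for extrastriate neurons in this task.
    """

    r0: float = 20.0
    rmax: float = 100.0
    # RF1 main response during (pre-saccadic) fixation
    rf1_latency: float = 55.0
    rf1_delay_halfwidth: float = 12.0
    rf1_gain: float = 0.4
    rf1_time_range: tuple[float, float] = (-554.0, 0.0)
    # perisaccadic late response enhancement at RF1 (weaker than the main
    # RF responses: it is a memory trace, and it must be the binding
    # minimum of the shared-sensitivity bridge)
    late_gain: float = 0.15
    late_delay_range: tuple[float, float] = (75.0, 130.0)
    late_time_range: tuple[float, float] = (0.0, 100.0)
    # RF2 sensitivity after the saccade
    rf2_gain: float = 0.4
    rf2_latency: float = 55.0
    rf2_delay_halfwidth: float = 12.0
    rf2_emergence: float = 0.0
    # optional early perisaccadic suppression at RF1 (added at RF1 latency)
    suppression_gain: float = 0.0
    suppression_time_range: tuple[float, float] = (-50.0, 0.0)
    # post-spike basis weights (8 functions, tau in (0, 56] ms)
    history_weights: tuple[float, ...] = (-5.0, -2.5, -1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.rmax <= self.r0:
            raise ValueError("need 0 < r0 < rmax")

    def to_dict(self) -> dict:
        return asdict(self)


def _centers_in(centers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.flatnonzero((centers >= lo) & (centers <= hi))


def make_ground_truth_model(
    cfg: GroundTruthConfig,
    basis: BasisSet | None = None,
    grid: ProbeGrid | None = None,
) -> SModel:
    """Plant the configured kernel dynamics as STU weights on the basis."""
    basis = basis if basis is not None else build_basis()
    grid = grid if grid is not None else ProbeGrid()
    d_centers = np.array([basis.delay_center(i) for i in range(basis.n_delay)])
    t_centers = np.array([basis.time_center(j) for j in range(basis.n_time)])
    kappa = np.zeros((grid.n_cells, basis.n_delay, basis.n_time))

    def plant(cell, d_lo, d_hi, t_lo, t_hi, gain, label):
        if gain == 0:
            return
        di = _centers_in(d_centers, d_lo, d_hi)
        tj = _centers_in(t_centers, t_lo, t_hi)
        if len(di) == 0 or len(tj) == 0:
            raise ValueError(f"{label} window lies outside the basis support")
        kappa[np.ix_([cell], di, tj)] += gain

    plant(
        grid.rf1_index,
        cfg.rf1_latency - cfg.rf1_delay_halfwidth,
        cfg.rf1_latency + cfg.rf1_delay_halfwidth,
        *cfg.rf1_time_range,
        cfg.rf1_gain,
        "RF1",
    )
    plant(
        grid.rf1_index,
        *cfg.late_delay_range,
        *cfg.late_time_range,
        cfg.late_gain,
        "late enhancement",
    )
    plant(
        grid.rf2_index,
        cfg.rf2_latency - cfg.rf2_delay_halfwidth,
        cfg.rf2_latency + cfg.rf2_delay_halfwidth,
        cfg.rf2_emergence,
        float(t_centers[-1]),
        cfg.rf2_gain,
        "RF2",
    )
    plant(
        grid.rf1_index,
        cfg.rf1_latency - cfg.rf1_delay_halfwidth,
        cfg.rf1_latency + cfg.rf1_delay_halfwidth,
        *cfg.suppression_time_range,
        cfg.suppression_gain,
        "suppression",
    )
    _, H = build_history_basis()
    return SModel(
        grid=grid,
        basis=basis,
        kappa=kappa,
        selected=kappa != 0,
        h_weights=np.asarray(cfg.history_weights, dtype=float),
        b_weights=np.zeros(basis.n_time),
        b0=float(inverse_nonlinearity(cfg.r0, cfg.rmax)),
        r0=cfg.r0,
        rmax=cfg.rmax,
    )


def simulate_spikes(
    model: SModel,
    trial_events: list[np.ndarray],
    seed: int,
) -> np.ndarray:
    """Bernoulli spike trains from the model's own conditional intensity.

    Per-bin spike probability is min(1, lambda(t) * 1 ms), with lambda
    including spike-history feedback when the post-spike kernel is nonzero.
    Returns (n_trials, n_bins) uint8; identical seeds give identical trains.
    """
    rng = np.random.default_rng(seed)
    drive = stimulus_drive(model, trial_events)
    base = drive + model.offset[None, :] + model.b0
    if not np.all(np.isfinite(base)):
        raise FloatingPointError("non-finite drive in simulation")
    n_trials, n_bins = base.shape
    h = model.history_kernel
    if np.all(h == 0):
        lam = nonlinearity(base, model.rmax)
        p = np.minimum(lam * DT_S, 1.0)
        return (rng.random(base.shape) < p).astype(np.uint8)
    H = len(h)
    hist = np.zeros((n_trials, n_bins + H))
    spikes = np.zeros((n_trials, n_bins), dtype=np.uint8)
    draws = rng.random((n_trials, n_bins))
    from scipy.special import expit as _expit

    for t in range(n_bins):
        lam = model.rmax * _expit(base[:, t] + hist[:, t])
        fired = draws[:, t] < np.minimum(lam * DT_S, 1.0)
        if np.any(fired):
            spikes[fired, t] = 1
            hist[fired, t + 1 : t + 1 + H] += h
    return spikes


def simulate_trials(
    model: SModel,
    n_trials: int,
    seed: int,
    alignment_offsets: np.ndarray | None = None,
) -> TrialSet:
    """Full synthetic session: balanced conditions, random saccade alignment
    (uniform over offsets that keep the 567 ms sequence inside the span,
    so probes tile all times relative to the saccade across trials), and
    model-simulated spikes.  All randomness flows from ``seed``.
    """
    grid, basis = model.grid, model.basis
    rng = np.random.default_rng(seed)
    conditions = make_conditions(grid, n_trials, seed=int(rng.integers(2**31)))
    t_min, t_max = basis.t_min, basis.t_max
    dur = conditions[0].duration_ms
    if alignment_offsets is None:
        alignment_offsets = rng.integers(t_min, t_max - dur + 2, size=n_trials)
    else:
        alignment_offsets = np.asarray(alignment_offsets, dtype=int)
    events = []
    for l, (cond, off) in enumerate(zip(conditions, alignment_offsets)):
        for k, cell in enumerate(cond.sequence):
            events.append((l, int(off) + k * cond.frame_ms, int(cell)))
    ev = np.array(events, dtype=EVENT_DTYPE)
    by_trial = []
    for l in range(n_trials):
        sel = ev[ev["trial"] == l]
        rec = np.empty(len(sel), dtype=[("t_on", "i4"), ("cell", "i4")])
        rec["t_on"], rec["cell"] = sel["t_on"], sel["cell"]
        by_trial.append(rec)
    spikes = simulate_spikes(model, by_trial, seed=int(rng.integers(2**31)))
    return TrialSet(grid=grid, events=ev, spikes=spikes, t_min=t_min, t_max=t_max)
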