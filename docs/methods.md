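# Methods

## Model and assumptions

`perirf` models a single extrastriate neuron as a Bernoulli point process
on a 1 ms clock. The conditional intensity is

λ⁽ˡ⁾(t) = f( Σ_{x,y,τ} k_xy(t,τ) s⁽ˡ⁾_xy(t−τ) + Σ_τ h(τ) r⁽ˡ⁾(t−τ) + b(t) + b0 ),
  f(u) = rmax / (1 + e^(−u)),

where s is the binary probe indicator per grid location, r the neuron's own
spike train, h a post-spike kernel (refractoriness), b(t) a saccade-locked
offset, and b0 = f⁻¹(r0) fixed at the measured mean rate. The per-bin spike
probability is λ·Δ with Δ = 1 ms; rmax·Δ < 1 keeps it a probability. All
trials are aligned to saccade onset (t = 0) and span [−554, +552] ms — the
knot span of the time basis.

Kernels are separable expansions k_xy(t,τ) = Σ_ij κ_xyij U_i(τ) V_j(t) over
quadratic (degree-2) B-splines on plain uniform knots with 7 ms spacing (the
probe frame duration): 33 delay knots {−13, …, 211} ms → 30 functions, 159
time knots {−554, …, 552} ms → 156 functions. Plain (unclamped) knots are
the only reading consistent with both counts (n_knots − order − 1); the
price is that edge functions are partial, so the partition of unity holds
only on the interior of each knot span and the usable delay range is
effectively τ ∈ [0, 200] ms, with the outer knots acting as boundary
padding.

## Synthetic task and ground-truth neurons

The generator emulates the visually guided saccade task: each trial presents
one *condition* — a pseudorandom permutation of all 81 (or n_cells) probe
locations at 7 ms per probe, exactly one probe on screen at a time. A cyclic
Latin-square scheme guarantees that over any multiple of n_cells trials,
every location occupies every ordinal position equally often. The sequence's
alignment to the saccade is drawn uniformly (seeded) over all offsets that
keep it inside the trial span, so probes tile all perisaccadic times across
trials. Saccade kinematics are not simulated; their retinal consequences are
planted directly in the kernels.

Ground-truth neurons plant κ on rectangular regions of (delay-center,
time-center) space:

| component | delays (ms) | times (ms) | gain | effect |
|---|---|---|---|---|
| RF1 response | 55 ± 12 | −554 … 0 | 0.40 | ~80 sp/s peak at 55 ms latency |
| late enhancement | 75–130 | 0 … 100 | 0.15 | ~45 sp/s delayed RF1 response near saccade |
| RF2 response | 55 ± 12 | 0 … 545 | 0.40 | post-saccadic RF at the new location |
| baseline / saturation | — | — | r0 = 20, rmax = 100 sp/s | fixation rates in the 20–40 sp/s range |

Gains are drive-units: a 7 ms probe inside a region of amplitude g
contributes ≈ 7g to the sigmoid argument. The values were chosen once so the
simulated rates match the range reported for extrastriate neurons in this
task (fixation responses of tens of sp/s, perisaccadic late responses near
50 sp/s), and so the late enhancement is *weaker* than the main RF
responses — it is a memory trace, and it must be the binding minimum of the
shared-sensitivity bridge (below). The default post-spike kernel is a strong
brief suppression (weights −5, −2.5, −1 on the first three of 8 quadratic
B-splines spanning τ ∈ (0, 56] ms).

What the generator does *not* emulate: eye-position traces and microsaccades,
latency jitter across trials, direction tuning, adaptation, non-Poisson
count statistics beyond refractoriness, and across-neuron correlations.
Passing tests therefore demonstrate correctness of the *analysis chain* on
data whose generative process matches the model class; they do not certify
performance on real recordings, where model mismatch is the dominant error
source.

## Pruning

Each candidate STU is screened marginally: a one-STU GLM
λ_t = f(κ·x_t + c) is fit by damped Newton iteration, where x_t is the
STU's feature (probe history filtered by U_i, windowed by V_j) and c a free
intercept so the baseline rate cannot masquerade as stimulus drive. Weights
are estimated on 100 random 35 % trial subsets of the original pairing and
on 100 subsets in which whole spike trains are permuted across trials
(derangement — no trial keeps its own spikes — preserving within-trial
autostructure). Selection: |μ − μ̃| ≥ 1.5 σ̃.

Numerical choices: the one-STU fit carries a ridge of 1.0 on κ. Without it,
subsets in which no spike lands in the feature's support have their maximum
likelihood at κ = −∞ (complete separation), and the control SD σ̃ inflates
to the signal scale, destroying the rule's power. The ridge bounds those
excursions at roughly the per-subset information scale and leaves genuine
signal estimates essentially untouched. Subsets are drawn without
replacement, independently per resample; each STU's result is independent of
the others, so the sweep may be restricted to any candidate subset of the
lattice (a full 379,080-STU sweep is a cluster-scale job; the test suite
sweeps planted-plus-null candidate sets).

Session size matters: an STU's feature occupies a ~45 ms acceptance window,
so each trial's single probe at that location lands inside it ~3 % of the
time. The packaged recovery demonstrations use 1200-trial sessions, giving
each 35 % subset ~15 informative trials — enough for the 1.5 σ̃ rule to
separate a planted cluster from nulls with margin.

## Encoder estimation

The S-model likelihood is maximized by L-BFGS with analytic gradients over
κ (selected STUs only), 8 post-spike weights, and 156 offset weights; b0 is
fixed at f⁻¹(r0). r0 is the mean rate; rmax defaults to the 5 ms-FWHM
smoothed trial-averaged peak rate × 1.25 headroom. Initialization is the
homogeneous model (all zeros); convergence at 1e−6 relative log-likelihood
or 500 iterations.

Regularization: overlapping B-spline features are strongly collinear at
session-sized data — neighboring κ can swing by ±3 in compensating
directions with almost no likelihood cost. The fitter therefore combines a
mild ridge (0.5) with a first-difference penalty (4.0) between
lattice-adjacent selected STUs (same location, neighboring delay or time
index). The difference penalty acts exactly on the near-null directions and
leaves the reconstructed kernel's smooth structure untouched; with it,
planted-kernel recovery at 600 trials reaches r ≈ 0.92 versus ≈ 0.15 with a
near-zero ridge alone. Both weights are exposed as estimator parameters.

## Decoder readout

Detectability of a probe at response time t* and delay τ*: 100 sequences
with the target ON for its 7 ms frame at t* − τ* and 100 without it, all
other frames drawn uniformly from filler locations; the model's predicted
λ(t*) for ON versus OFF sets is summarized by the rank-based AUC (ties
0.5), averaged over 20 repeats on random 80 % subsamples. Discriminability
replaces the OFF set with sequences in which one of the 8 grid neighbors
occupies the target frame, averaged over neighbors. Defaults follow the
standard sweep (t*: −50…+300 ms step 10; τ*: 30…190 ms step 10; 200 ms
embeddings; thresholds 0.61 detect / 0.57 discriminate / 0.55 population
contour).

Choices: the readout conditions only on the stimulus — spike-history drive
is zero during decoding. OFF sequences exclude the target everywhere in the
embedding (the stronger reading; a flag restores the weaker frame-only
exclusion). Fillers exclude both RF cells by default so the RF1 and RF2 maps
cannot contaminate each other. The response-time projection of a
thresholded map takes the largest contiguous above-threshold run (removing
speckle) before the signed overlap is computed; each above-threshold grid
point counts as one 10 ms step, and disjoint projections yield minus the
gap between nearest endpoints. With the planted gains the fixation-period
detectability saturates at AUC = 1.0 across τ ≈ 40–60 ms; the reported peak
delay is the midpoint of the argmax plateau (a deterministic tie-break).

## Modulated and integration-relevant STUs

The prevalence p(τ_n, t_m) is the selected fraction inside the 3 × 3 lattice
window around (n, m), computed per location (windows clipped at edges with
the true window size as denominator); baselines p1, p2 average p over time
bins 1–60 (540–120 ms before saccade) and 120–156 (280–540 ms after). An STU
is modulated when √(|p − p1|·|p − p2|) > h, h = 0.3 for analysis (0.7 for
display). Nulling either zeroes the masked weights or replaces them with the
mean weight of fixation-window STUs sharing the same (location, delay basis)
— the intact/nulled overlap contrast uses fixation replacement, the
relevance screen uses zeroing, each matching its analysis's definition.

Spatial sensitivity h_rf(t) averages |k| over the 9 cells around the RF
center and delays 1…200 ms (edge RFs use the clipped neighborhood with a
renormalized denominator, with a warning); the shared sensitivity is
δ = Σ_{t=−500}^{+500} min(h1, h2). A modulated STU is integration-relevant
when zero-nulling it alone (from the intact model, one at a time — not a
combinatorial subset search) decreases δ by more than 1e−9 relative, the
tolerance guarding against floating-point false positives. The screen is
order-independent by construction.

PMI = (S − F)/(S + F) with S, F the mean probe-aligned rates in the
75–105 ms post-probe window for perisaccadic (|t_on| ≤ 10 ms) versus
fixation (t_on < −100 ms) probes.

## Problem sizes and determinism

The packaged tests and the acceptance script run on reduced lattices chosen
as the smallest sizes at which each effect is unambiguous: 3 × 3 probe grids
(the planted RF cells sit on edges; sensitivity neighborhoods clip and warn),
600-trial sessions for encoder recovery, 1200 for pruning recovery, 3000 for
the PMI estimate. Full 9 × 9 runs are supported through the same interfaces.
Every stochastic step takes an explicit seed; pipeline stages derive theirs
from the master seed and the stage name (SHA-256), so identical configs
reproduce identical artifacts byte for byte.

## Known limitations

- The pruning sweep is marginal (one STU at a time, as the screening rule
  defines it); strongly correlated STUs can mask one another, and the
  1.5 σ̃ rule has no multiplicity control.
- The fixation-replacement nulling assumes fixation weights at the same
  (location, delay) exist; when none do, the replacement is zero.
- Selection-prevalence baselines use fixed bin ranges; shorter custom time
  bases fall back to clipped ranges.
- The decoder assumes the model generalizes to stimulus sequences never
  shown during fitting — true by construction for planted models, an
  approximation for fitted ones.
- Condition balance is exact only over multiples of n_cells trials;
  remainders use partial Latin-square blocks.
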