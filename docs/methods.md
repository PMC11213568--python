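# Methods

## Behavior model

Choices in the probabilistic learning task are modeled with a Q-learning
agent.  For the pair of cues shown on trial *t*, the chosen cue's value is
updated as

    Q_{t+1} = Q_t + α δ_t,        δ_t = R_t − Q_t,

with outcomes R ∈ {−1, 0, +1} euros.  Q-values start at 0 — the mean of the
possible outcomes — at the beginning of every pair, so the first prediction
error of a pair equals its outcome and |δ| ≤ 2 always.  Choice probabilities
follow a softmax on (Q + θ·1[chosen previously]) / β, where the perseveration
bonus θ applies to the option chosen on the previous trial *of the same
pair* (pairs interleave within a session, and pair ids are globally unique
across sessions, which also makes any between-session θ carry-over moot).

Fitting minimizes the negative log-likelihood of the observed choices with
L-BFGS-B from multiple uniform random starts inside the bounds
α ∈ [0, 1], β ∈ (10⁻⁶, 10], θ ∈ [−2, 2] (10 starts by default).  These
bounds are a design choice — wide enough to cover behaviorally plausible
agents, tight enough to keep β away from the degenerate β → 0 limit.
Choice probabilities are floored at 10⁻¹² so the objective stays finite;
the floor only matters for near-deterministic parameter proposals and does
not move optima.  The likelihood is reported in nats; all information
measures elsewhere are in bits.  The sequential likelihood kernel is JIT
compiled with numba when available, with an identical pure-Python fallback.

Parameter recovery at the defaults (α = 0.3, β = 0.2, θ = 0.1, 30 sessions
of 96 trials) is verified by the test suite: medians over 50 synthetic
subjects fall within ±25 % of the generating values.

## Synthetic data: the stated world

The generator reproduces the task as specified: per session 4 cue pairs
(2 reward, 2 punishment), 24 repetitions each in randomly intermingled
order, left/right position counterbalanced within pair, and reciprocal
0.75/0.25 outcome contingencies; a training session has 2 pairs × 8 trials.
Outcomes for both cues of every trial are pre-drawn so that simulated
choices resolve deterministically.

Neural epochs are outcome-locked (−0.5 to +1.5 s at 256 Hz, the analysis
rate of the spectral stage) and consist of AR(1) background noise
(coefficient 0.9 per sample, scaled to unit stationary variance) plus a
Gaussian temporal kernel at 0.5 s latency, 0.15 s width — the post-outcome
gamma response timing the pipeline is built to resolve.  The kernel's
per-trial amplitude is `gain · z(PE)` where z is the prediction error
z-scored within the coupled condition; the coupling function is the
identity since the rank-based estimators detect any monotone relation.
Coupling modes and their ground truth:

* **redundant pair** — amplitudes `gain·(f·z + (1−f)·eᵢ)` share one
  PE-driven latent source (f = 0.8 by default); interaction information at
  the latency is negative by construction and vanishes at f = 0.
* **synergistic pair** — contact 1 = `gain·z + N`, contact 2 = `N`, with
  trial-wise common noise N (SD 1) and reduced background (SD 0.5);
  conditioning on contact 2 denoises contact 1, giving positive interaction
  information (≈ +0.4 bits at the latency in the Gaussian limit) even
  though contact 2 alone is uninformative.
* **directed pair** — Y(t) = 0.8·X(t − 150 ms) + noise within each trial,
  where X is AR(1).  Because AR(1) is Markov, the reverse transfer entropy
  is exactly zero in expectation while the forward delay profile peaks at
  the generating lag; the coupling can be gated to one condition.
* **raw LFP surrogate** — a 75 Hz carrier with per-trial random phase,
  amplitude-modulated by a known envelope over 1/f background, for testing
  the spectral chain against ground truth.

The demo cohort (16 subjects, 2 sessions each) instantiates the qualitative
network summary the analysis is designed to detect: a redundant RPE-coupled
vmPFC–lOFC pair, a redundant PPE-coupled aINS–dlPFC pair, a
punishment-gated aINS→dlPFC lagged drive, and a synergistic full-PE
dlPFC–vmPFC pair (whose noise-only contact additionally gets a small early
local response at 150 ms, narrow enough to leave the 500 ms synergy window
untouched, so that the selectivity categorization can label it).

What the generator does **not** emulate: volume conduction and common
reference artifacts, non-stationary noise, epileptic activity, 1/f power
spectra in the power surrogate (AR(1) is used instead — cheap and
sufficient for the estimators' conditioning structure), heterogeneous
latencies across contacts, and session-level drift.  A green test therefore
establishes estimator correctness and calibration on exchangeable
trial structure, not robustness to every pathology of clinical recordings.

## Spectral stage

Bipolar derivations are adjacent-contact differences within an electrode
(n−1 derivations for n contacts).  Gamma power uses 9 Slepian tapers on
200 ms windows (15 cycles of the 75 Hz center; time–bandwidth product 5,
i.e. ±25 Hz, spanning 50–100 Hz), demodulated at the center frequency and
averaged over tapers — the mean-vs-sum choice is irrelevant downstream
because the estimators are rank-based.  Power is decimated to 256 Hz with
polyphase anti-aliasing (512 and 1024 Hz inputs are integer ratios; other
rates resample with a warning) and smoothed with an 11-point order-3
Savitzky–Golay filter — the classical odd-window form of a nominal
"10-point" filter.  Samples within half a taper window of the epoch edges
are invalid and returned as NaN; all operations are strictly per-trial.

## Information estimators

Every variable is copula-normalized per time sample across trials: average
ranks mapped to r/(n+1), then through the inverse normal CDF.  Estimates
are Gaussian-model information quantities on the normalized scores,
computed from log-determinants of covariance blocks, with the analytic
digamma-based small-sample bias correction; estimates are exactly invariant
under strictly monotone transforms of each variable, lower-bound the true
information, and (bias-corrected) may be slightly negative.  Degenerate
covariances (duplicated signals, constant columns) raise rather than being
silently regularized.  A minimum of 8 samples is enforced for
normalization and 20 trials for the time-resolved measures.

Transfer entropy uses the single sample at lag d as the "past" of both
source and target — no multi-sample embedding — and averages TE_d over the
delay window d ∈ [116, 236] ms in one-sample steps at 256 Hz; temporal
breadth comes from the delay average.  Output time points whose largest
delay reaches before the epoch start are NaN.

Permutation nulls re-apply the identical estimator to shuffled inputs: the
PE is shuffled across trials for MI and II; the source signal's trials are
shuffled for TE.  Nulls are seeded and bit-reproducible.

## Group statistics

Units (contacts for MI, pairs for II/TE, within subject only) are
random-effects replicates.  At each time point a one-sample t-test compares
unit values minus their own permutation means against zero; the same
statistic on every permutation slice yields the null t-distribution.  The
cluster-forming threshold is the 95th percentile of all permutation
t-values; contiguous supra-threshold runs form clusters whose mass (summed
t) is compared with the distribution of each permutation's largest cluster
mass, with a +1 guard so corrected p > 0.  Redundancy-direction tests
(II < 0) negate the t series; condition contrasts use paired t-tests with
within-unit sign-flip nulls, reported separately per direction.  Clustering
is one-dimensional temporal adjacency — per ROI or ROI pair, no spatial
clustering.

Per-contact selectivity uses the contact-level analog of the group rule
(threshold at the 95th percentile of the contact's own null pooled over
time and permutations, cluster-mass correction against its per-permutation
maxima at α = 0.05); the combination of RPE/PPE significance yields the
labels RPE-specific, PPE-specific, Both, Irrelevant.  Full-PE interaction
information of pairs is binned by the contacts' time-collapsed labels into
RPE-RPE, PPE-PPE, PPE-RPE and Mixed (a "Both" contact involved); pairs with
an Irrelevant contact are excluded, each populated category is tested
against zero with a one-sample t-test, and p-values are Benjamini–Hochberg
corrected across the populated categories only.

Type-I calibration is part of the acceptance suite: on fully uncoupled
cohorts the family-wise cluster error of the MI → group-t → cluster chain
stays within [0.01, 0.10] at nominal 0.05 over 200 runs (with 200
permutations and a shortened time axis purely for runtime).

## Numerical and design notes

* Ties in ranks take the average rank, keeping the copula map
  deterministic; prediction errors do tie (e.g. every first trial of a
  pair), and the estimators remain exchangeable under trial shuffles.
* One master seed spawns named per-stage substreams
  (`numpy.random.SeedSequence`), so stages re-run independently yet
  reproducibly; derived seeds stay below 2³¹.
* The sign-recovery fixtures are evaluated at n = 200 trials (two
  4-pair × 25-repetition sessions); the directed fixture at 200 trials of
  AR(1) epochs.
* The pipeline stores permutation nulls alongside observed values
  (HDF5), so group statistics can be re-run without re-estimating.
* Known limitations: no frequency-resolved scan (the 50–100 Hz band is
  fixed), no spatial clustering, no alternative learning models or model
  comparison, single-lag TE (no embedding dimension selection), and no
  handling of missing trials within a session.
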