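# Methods

This note documents the models, conventions and design choices behind
`attngate`: what the synthetic data emulates, how each stage is computed,
and what the test suite does and does not establish about real EEG.

## The generative model of a session

A session is a plan of alternating phases: *external* attention while
reading a text, *internal* attention while thinking about a question on
it. One reading + one task phase form a trial; the canonical calibration
protocol is four trials of 50 s + 50 s (eight parts, 400 s).

### Band-power mode

The generator's native quantity is **log₁₀ band power** per electrode and
band, matching the "absolute" band values streamed by consumer headset
bridges (whose true units and scale are not documented anywhere
authoritative; the log-power reading of those values is an assumption of
this package, chosen because it stabilises the additive-normal noise
model and suits a linear classifier; linear power is available as an
export). Each 100 ms frame is drawn i.i.d. as

  log₁₀ P_{e,b} ~ N( B_{e,b} + s_{e,b}·1[internal], σ² )

with defaults:

* baseline `B` (per band, same across electrodes): δ 1.0, θ 0.7, α 0.6,
  β 0.3, γ 0.0 — a 1/f-like decay of power with frequency;
* noise SD σ = 0.25 log₁₀ units;
* internal-attention shift `s`: alpha band only, (TP9, AF7, AF8, TP10) =
  (0.2, 0.1, 0.1, 0.4). Internal focus raises posterior alpha, strongest
  over the right temporoparietal site, so TP10 carries the largest shift
  and the frontal sites the smallest.

These standardised effects (0.8, 0.4, 0.4, 1.6 σ) give a Mahalanobis
class separation of ≈ 1.9 and hence a Bayes accuracy of ≈ 83%, placing
the synthetic calibration accuracy in the low-80s% regime typical of
person-dependent internal/external classification with consumer
headsets. `GeneratorParams.null()` zeroes the shift (chance-level data);
`with_effect_scale(c)` scales it for dose-response experiments.

What the generator does **not** emulate: 1/f spectral detail within
bands, temporal autocorrelation of band power, ocular/muscle artifacts,
blinks and jaw clenches, electrode-fit drift, or line noise (a 50 Hz
notch lives upstream in the real bridge). Frames are i.i.d. given the
phase, so shuffled and contiguous cross-validation agree here; on real
data, with 90%-overlapping windows, shuffled folds are optimistic —
which is why the contiguous scheme exists and is documented as the
leakage-safe option. Passing tests therefore validate the *machinery*
(extraction, training, voting, evaluation), not classifier performance
on real EEG.

### Raw-signal mode

Raw mode synthesises 4-channel 256 Hz signal whose *extracted* band
powers hit the same targets, exercising the spectral extractor end to
end. Each phase segment is, per channel, a sum over bands of band-limited
Gaussian noise (white noise FFT-masked to the band, flat spectrum,
variance-normalised). Choosing component variances is not trivial because
the canonical band definitions overlap (θ 4–8 Hz and α 7.5–13 Hz share
7.5–8 Hz) and adjacent bands share integer-bin edges, so a component's
power leaks into neighbouring band sums. The generator therefore computes
the exact expected **band-power transfer matrix** M of the downstream
analysis — M[b,j] is the expected window-power-normalised Hamming
periodogram band-b sum for a unit-variance component flat over band j's
synthesis interval, evaluated from the taper's squared DTFT — and solves
M·v = T for the component variances v given targets T. This makes the
extracted band powers unbiased by construction (residual < 0.025 log₁₀
on a 100 s check, dominated by estimation noise). Synthesis intervals
keep a 0.5 Hz interior margin per edge so components stay attributable
to their own band. Phase boundaries are joined by a 50 ms raised-cosine
cross-fade to avoid spectral splatter from discontinuities. Within a
phase the log-power target is constant; frame-to-frame variability in
raw mode comes from the periodogram's own sampling distribution rather
than from σ.

### Stream corruption

`corrupt_stream` mimics consumer-Bluetooth behaviour: samples dropped
independently (default rate 0.03%, within the reported 0.01–0.05%
range), Gaussian timestamp jitter (default SD 5 ms), optional constant
block delay; the stream is re-sorted after perturbation. Readers of
corrupted files re-sort with a warning.

## Feature extraction

Every 100 ms the most recent 256 samples are Hamming-tapered
(w_m = 0.54 − 0.46·cos(2πm/255)), Fourier transformed, and the
periodogram P_k = |X_k|²/Σw² summed over the bins whose centre frequency
lies in the closed interval [low, high] of each band. Conventions,
each a deliberate choice where the field's tooling is ambiguous:

* **Hop size.** 256 Hz / 10 Hz = 25.6 samples is not an integer; frames
  are scheduled on the exact 100 ms timestamp grid and the realised hop
  alternates 25/26 samples, honouring both the 256-sample window and the
  10 Hz rate literally. Mean overlap is exactly 90%.
* **Left-edge padding.** The first nine frames (t < 1 s) use a
  zero-padded partial window, so a T-second recording yields exactly
  10·T frames — the convention under which 400 s gives 4000 vectors with
  no warm-up loss. `pad_start=False` restores strict full-window frames
  (3991 from 400 s).
* **Band sums, closed edges.** Band values are bin *sums* (not per-bin
  means), both edges inclusive; the printed θ/α overlap at 7.5–8 Hz is
  honoured, so those bands share the 8 Hz bin rather than being forced
  orthogonal.
* **Normalisation and floor.** Window-power normalisation (divide by
  Σw²) keeps amplitudes taper-consistent; linear powers clamp at 1e-12
  before log₁₀ so silent channels cannot produce −∞.

Feature vectors flatten electrode-major — (TP9, AF7, AF8, TP10) ×
(δ, θ, α, β, γ) — so feature 5e+b is electrode e, band b; TP10-alpha is
index 17.

**Frame labels** follow majority coverage of the frame's 1 s analysis
window, ties to external (the same bias as the pause rule). Boundary
frames thus skew external: the canonical 400 s plan labels 2008 frames
external and 1992 internal, not 2000/2000.

## Classifier

Standard two-class LDA: Gaussian classes, shared pooled covariance,
empirical priors, no shrinkage (fitting is delegated to
scikit-learn's default `LinearDiscriminantAnalysis`; whether a real
deployment would use empirical or uniform priors is unknowable from the
outside, and empirical priors are the toolkit default, so that is the
documented assumption). The fitted discriminant is stored explicitly
(w, b, class means, Σ, priors) and prediction is the package's own
affine rule: internal iff wᵀx + b > 0, with the boundary score 0 going
to external. Zero-variance features are dropped with a warning before
fitting (their weights restored as zeros) so degenerate fixtures cannot
crash the covariance inversion; the SVD solver handles remaining
singularity via pseudo-inversion.

Cross-validation is 5-fold; `shuffled` (seeded, default 0) mirrors the
common toolkit default, `contiguous` provides block folds. Per-fold and
mean accuracies are both reported.

## Pause decision

A ring buffer of the last n = 40 predictions; pause iff
#internal ≥ ⌈0.6·40⌉ = 24. "At least 60%" is read inclusively. The vote
re-evaluates on every prediction (sliding window) rather than once per
disjoint 4 s block: sub-4 s pause/unpause blocks are observable in
practice, which only a sliding rule can produce; the disjoint `block`
mode is provided for comparison. Warm-up (< 40 predictions) emits
unpaused, consistent with the bias against pausing. An optional
`max_pause_s` cap (off by default) forces unpause after overly long
pauses.

## Adaptive-app simulation

Update events are scheduled with i.i.d. uniform [0.3, 3.0] s intervals,
the timer restarting when an update fires. Updates due during a pause
are **deferred** to the pause's end, not dropped — the interface
"resumes", and nothing suggests pending work is discarded; deferral is
the package's documented choice. Invariants checked on every simulated
log: no update falls strictly inside a pause interval, pause events
alternate, and paused time from the event log matches the timeline's
frame count within one frame period per block.

## Offline evaluation

Accuracy is the fraction of frames whose prediction matches the
phase-derived label, computed per reading phase, per task phase, and
overall. For trials flagged as "thinking and rereading" the task phase
is split into 5 equal-duration bins and bins whose external-predicted
fraction exceeds 0.5 (configurable) are excluded before re-scoring —
operationalising "high probability for external attention", for which no
exact threshold is documented. The rereading flag itself is an input: an
optional heuristic (task duration above the participant median) exists
but is off by default, since silently guessing the identification rule
would bake an assumption into results.

Pause blocks are maximal runs of constant pause state (length = run
length × 0.1 s); categories use half-open bins [0, 3), [3, 10),
[10, 30), [30, ∞) s. Category shares are computed per participant first
and then averaged with equal weights, so long recordings or many short
blocks do not dominate. Correlations use scipy's Pearson (and Spearman)
with two-sided p-values; constant inputs raise rather than returning
NaN.

## Numerical and testing choices

* One global integer seed drives named child streams (plan / signal /
  corruption / cv / updater) via `SeedSequence` spawn keys, so
  components are independently reproducible.
* The raw-mode fidelity test compares the *linear* mean of extracted
  powers over a 200 s segment against targets within 0.05 log₁₀ —
  linear averaging avoids the Jensen bias of averaging logs of
  chi-squared-distributed periodogram sums.
* Property tests use fixed seeds (hypothesis derandomised) so the suite
  is deterministic; Monte-Carlo assertions (chance level, effect-size
  monotonicity) aggregate ≥ 20 seeded replicates with one-standard-error
  tolerances.
* Problem sizes in tests and the acceptance script (400 s sessions,
  100–200 s raw segments, 20 replicates) were chosen so each check is
  statistically meaningful yet the whole suite completes in well under a
  minute on one CPU.

## Known limitations

The synthetic generator's i.i.d.-given-phase frames make cross-validated
accuracy an honest estimate here but an optimistic one on real,
autocorrelated EEG; no artifact model means robustness to blinks or
motion is untested; the headset stream dialect ships as editable data
because real bridge path strings vary by version and are not asserted as
truth; and the live network listener is out of scope — the dialect is
exercised through message-list parsing and file replay.
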