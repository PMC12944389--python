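# Methods

`semgdenoise` implements an adaptive denoising chain for single-channel
surface EMG (sEMG) recorded during rapid, repetitive tasks such as
keystrokes: variational mode decomposition (VMD) whose hyperparameters
are selected by a walrus-optimizer (WO) search on an envelope-entropy
criterion, followed by physiological-band mode screening and
zero-crossing interval thresholding with a threshold calibrated on a
resting segment. This note records the model, the parameters that
matter, the numerical choices, and what the synthetic test bed does and
does not establish.

## Problem setting

sEMG during high-rate repetitive motion is *high duty cycle*: the muscle
is active a large fraction of the time. Classical wavelet-style
denoising estimates the noise level σ from a robust statistic of the
whole record and applies the universal threshold `σ√(2 ln N)`. When
most of the record is genuine activity, that whole-record statistic is
inflated by the signal itself, the threshold is overestimated, and
shrinkage operators attenuate genuine myoelectric components. The
pipeline addresses this by (i) decomposing adaptively rather than with
fixed filters, and (ii) estimating σ only from a known resting segment
(the protocol's 5-second relaxed prefix), scaled by an
operator-dependent calibration coefficient C.

## Pipeline stages

**Preprocessing.** Fourth-order Butterworth band-pass 10–500 Hz plus a
50 Hz IIR notch (Q = 30). Both are applied zero-phase
(forward–backward), doubling the effective order; the phase handling is
a package choice made so burst timing — which the interval partition
depends on — is not delayed. Edges are protected by reflective padding
of several settling lengths.

**VMD.** The record is split into K band-limited modes u_k with
adaptive center frequencies ω_k by minimising the summed bandwidth of
the analytic-demodulated modes subject to Σ u_k = f, handled via a
quadratic penalty α and a Lagrange multiplier with dual-ascent step τ.
ADMM sweeps run in the one-sided frequency domain with the update

    û_k ← (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²),

power-weighted-mean updates of ω_k, and λ̂ ← λ̂ + τ(f̂ − Σ û_k).
Iteration stops when the summed relative squared spectrum change drops
below ε = 1e-6 or at the iteration cap. The input is mirror-extended by
half its length per side; center frequencies initialise uniformly over
(0, fs/4], making the solver fully deterministic. The factor 2α in the
Wiener denominator follows the formulation adopted here; it simply
rescales α relative to implementations that use 1 + α(·)², and α is
searched anyway.

**τ (reconstruction enforcement).** The library default for a bare
decomposition is τ = 0, but the *pipeline* runs with τ = 0.5. This was
a genuinely open design point and the deciding observation is
structural: with τ = 0 the multiplier never activates, the Wiener-type
mode updates leave an unassigned residual, and the mode sum silently
discards part of a broadband signal (≈3 dB of a flat-spectrum burst
carrier in our test bed) — so even the zero-threshold scheme T1 would
not be an identity, and the threshold comparison of §“Threshold
schemes” would be confounded by decomposition loss. With τ = 0.5 the
reconstruction constraint is enforced essentially exactly (residual
−60 dB and below), T1 is a true identity, and all denoising is
attributable to mode screening and thresholding, which is the design
being studied. Values of τ between 0.5 and 1 behave identically here.

**Hyperparameter search (WO on MMEE).** WO searches K ∈ [2, 15]
(integer) and α ∈ [500, 2000] with population 10 over 10 iterations by
default (a desk-scale budget; both are exposed). The fitness is the
*minimum mode envelope entropy*: each mode's Hilbert envelope a_k(t) is
normalised to a probability sequence and scored by Shannon entropy
(bits); burst-structured activity concentrates its envelope and scores
low, noise scores near the log2 N maximum. Only modes carrying ≥1% of
total mode energy enter the minimisation (energy gating), so trivial
near-empty modes cannot win; if nothing passes the gate the minimum is
taken over all modes. The envelope is the standard analytic-signal
magnitude |u + jH(u)|; a variant that squares the argument of the
Hilbert transform was considered and rejected as inconsistent with the
analytic-signal construction.

WO itself follows the danger/safety-signal design: a danger signal
`2γ·U(−1,1)` with γ decaying 1 → 0 gates each iteration between
migration (steps along the span of two random members, sigmoidally
damped) and role-based reproduction. Females blend attraction to a
paired male and the global best (weights γ and 1−γ). The source
description leaves two points open, resolved here as: males perform a
bounded random walk mixing attraction to the best and a random partner
(step scaled by γ); juveniles drift toward the best with a small Lévy
perturbation unless the safety signal drops below 0.5, in which case
they flee toward `O = X_best + X·LF` via `X ← (O − X)·P`. Lévy steps
use Mantegna's method with exponent 1.5. Positions are clamped to the
box; K stays continuous inside the search and is rounded only at
evaluation. The whole population is re-evaluated every iteration
(N·I + N objective calls), and best-so-far bookkeeping makes the
fitness history non-increasing for every seed.

Search-stage economics: fitness values only need to *rank* (K, α)
pairs. The ranking is stable well before full ADMM convergence (the
gated minimum entropy changes by <0.01 bits between 20 and 50 sweeps on
representative records), so search evaluations run under a 30-sweep
cap, and the final decomposition at the optimum uses the full 500-sweep
budget. Fitness values are cached on (K, round(α)); α resolution of 1.0
is far below any scale at which the decomposition changes.

**Mode screening.** Modes whose mean instantaneous frequency (mean
derivative of the unwrapped analytic phase, trimmed 5% per edge against
Hilbert edge artifacts) falls outside 10–500 Hz are discarded. The band
defaults to the preprocessing passband — the screening band is not
prescribed more precisely by the underlying design. If the screen would
discard everything, all modes are retained and a warning is issued:
fail-safe beats silently deleting the record.

**Interval thresholding.** Each retained mode is partitioned at its
zero crossings (exact zeros attach to the preceding interval; the
stretches before the first and after the last crossing are intervals
too). Each interval is kept or killed based on its single extremum
u(q): hard keeps the interval verbatim iff |u(q)| > T; soft
additionally scales it by (|u(q)| − T)/|u(q)|. Decisions per lobe, not
per sample, avoid Gibbs-type ringing. Four threshold schemes:

| scheme | σ estimated from | threshold |
|---|---|---|
| T1 | — | 0 (identity baseline) |
| T2 | whole record | σ√(2 ln N) (universal) |
| T3 | resting segment | σ√(2 ln N_rest) |
| T4 | resting segment | C·σ√(2 ln N_rest) |

σ_i is computed per mode as `median(|u_i over rest|)/0.6745`. The
absolute value matters: a signed median of zero-mean noise is ≈0 and
would nullify the threshold, so the standard robust MAD-type estimator
is used. C defaults to 0.3 for soft (small, to limit shrinkage bias)
and 0.7 for hard (midpoint of the 0.6–0.8 guidance for
amplitude-preserving operators). For records without a designed rest
period, `detect_rest` flags the windows whose 0.5-s RMS falls in the
lowest decile and returns the longest contiguous quiet run.

**Metrics.** SNR (dB, whole record, rest prefix included), RMSE, and
median frequency (MDF) from a Welch PSD (1-s Hann windows, 50% overlap,
cumulative power interpolated linearly between bins). Improvements are
ΔSNR = SNR_out − SNR_in, ΔRMSE% = 100·(RMSE_noisy −
RMSE_denoised)/RMSE_noisy, ΔMDF% = 100·(MDF_denoised −
MDF_ref)/MDF_ref.

## Synthetic test bed

Human keystroke recordings of the kind this pipeline targets are not
publicly available, so the package ships a generator emulating the
acquisition protocol: 5 s rest, then 20 keystrokes at 60 BPM at
fs = 1500 Hz (25 s, 37,500 samples). Each keystroke is a 0.3-s burst of
band-limited Gaussian noise (4th-order Butterworth, 20–450 Hz)
amplitude-modulated by a Hann envelope, with lognormal burst-to-burst
amplitude jitter (cv = 0.15) and a rest noise floor of 1% of mean burst
RMS so σ estimators see non-degenerate input. The 0.3-s burst length
puts ≈26% of task-period samples under an envelope above 5% of peak —
the high-duty-cycle regime the rest-calibrated threshold targets.
Noise is injected as white Gaussian scaled analytically to an exact
target input SNR.

What the generator does *not* emulate: motor-unit action potential
trains (the carrier is Gaussian, so within-burst amplitudes are
light-tailed), the peaked PSD of real sEMG (the carrier is flat across
20–450 Hz), tonic postural activity between strokes, motion artifacts,
and ECG crosstalk. Consequences for interpreting results are discussed
under Limitations.

## Numerical choices and degenerate inputs

* Convergence tolerance ε = 1e-6 on the summed relative squared
  spectrum change; caps of 500 (final) / 30 (search) sweeps.
* All-zero modes: envelope entropy falls back to the log2 N maximum,
  mean instantaneous frequency to 0 Hz, both with warnings.
* An all-zero rest segment gives σ = 0 and T = 0 (the denoiser becomes
  the identity on that mode).
* Non-finite objective values in WO are treated as +∞: the individual
  survives but can never become the incumbent; a fully non-finite
  initial population is an error.
* Degenerate search boxes (lower = upper) are honoured and return the
  fixed point.
* Benchmark replicate seeds derive from one master seed via
  `SeedSequence`; every stage is deterministic given its seed.

## Problem sizes

Default experiment sizes were chosen at desk scale: benchmark sweeps
run 4 input SNR levels (0/5/10/15 dB) × 20 seeded replicates on 25-s
records with the WO budget N = 10, I = 10; all thresholding schemes
under comparison share the single decomposition of each record, since
the decomposition does not depend on the scheme. One record's full
pipeline takes seconds on one core; a full sweep takes minutes.

## Limitations

* The soft-vs-hard operator ordering under the rest-calibrated
  threshold is *not* resolved by this test bed. On the generator's
  light-tailed, silence-separated bursts, hard thresholding has a
  slight (≈0.5–1 dB) median advantage, because nearly all genuine lobes
  sit far above T_hard and the inter-burst signal is exactly zero. The
  reported advantage of soft shrinkage on real recordings plausibly
  rests on amplitude features the generator deliberately omits
  (heavy-tailed MUAP amplitudes, sustained low-level activity near the
  threshold). Passing the shipped comparisons therefore shows the
  scheme ordering T4 > T2 and the SNR-gain trends, not the fine
  operator ordering on real sEMG.
* The MMEE criterion rewards envelope concentration, not parsimony: on
  stationary multi-tone signals its landscape is nearly flat in K with
  a mild preference for more modes. It is a burst-signal criterion and
  is validated here only in that regime.
* Thresholds calibrated on a resting prefix assume the noise is
  stationary across the trial; recordings whose noise level drifts
  need re-calibration or sliding rest detection.
* The parameter search costs N·I VMD runs per record and is the
  dominant runtime; real-time use would need a reduced budget or
  offline optimisation.
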