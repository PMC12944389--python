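# semgdenoise

Adaptive denoising for single-channel surface EMG (sEMG) recorded
during rapid repetitive tasks — keystrokes, typing-like industrial
operations, tremor-like contractions — where *sustained high-duty-cycle
activation* breaks the classical universal-threshold assumption that
most of the record is noise.

The pipeline is **WO-VMD + rest-calibrated interval thresholding**:

1. **Preprocess** — 4th-order Butterworth band-pass 10–500 Hz +
   50 Hz notch, zero-phase.
2. **Decompose** — variational mode decomposition (VMD): the record is
   split into K band-limited modes u_k with adaptive center
   frequencies ω_k by an ADMM solver in the frequency domain,

       min_{u_k, ω_k}  Σ_k ‖∂_t[(δ(t) + j/πt) ∗ u_k(t)] e^{−jω_k t}‖²₂
       s.t.  Σ_k u_k = f .

   The mode count K and bandwidth penalty α are *not* set by hand: a
   Walrus Optimizer (WO) — a population metaheuristic with
   danger/safety-gated migration and role-based position updates —
   searches K ∈ [2, 15], α ∈ [500, 2000], minimising the **minimum
   mode envelope entropy** (MMEE): the smallest Shannon entropy of the
   normalised Hilbert envelopes across energy-gated modes. Bursty,
   physiologically structured modes score low; noise scores near the
   log₂N maximum.
3. **Screen** — modes whose mean instantaneous frequency falls outside
   the physiological band (10–500 Hz) are discarded.
4. **Threshold** — each retained mode is partitioned at its zero
   crossings and each interval is kept, shrunk (soft) or zeroed based
   on its single extremum, with the *improved threshold*

       T_i = C · σ_i · √(2 ln N_rest),     σ_i = median(|u_i^rest|)/0.6745,

   where σ_i is estimated from a resting segment (the protocol's 5-s
   relaxed prefix, or one found automatically by RMS-window search)
   instead of the activity-inflated whole record, and C calibrates the
   operator (0.3 soft / 0.7 hard). The classical universal threshold
   σ√(2 ln N) and a zero-threshold identity are available for
   comparison (schemes T1–T4).
5. **Reconstruct** — the thresholded selected modes are summed.

Because the human keystroke dataset this method targets is not publicly
available, the package includes a synthetic generator emulating the
acquisition protocol (5 s rest + 20 keystrokes at 60 BPM, fs = 1500 Hz,
band-limited 20–450 Hz Hann-enveloped bursts) with calibrated white
Gaussian noise injection, plus the evaluation metrics ΔSNR, ΔRMSE% and
ΔMDF%.

## Worked example

```bash
semgdenoise simulate --seed 7 --snr 10 --out clean.csv --out-noisy noisy.csv
semgdenoise denoise --input noisy.csv --scheme T4 --operator soft --seed 7 \
                    --out denoised.csv --report report.json
semgdenoise evaluate --reference clean.csv --noisy noisy.csv --denoised denoised.csv
```

prints (abridged):

```
wrote clean.csv: 37500 samples at 1500.0 Hz, rest (0, 7500)
K_opt=12 alpha_opt=527.6 selected modes [0, 1, ..., 11] -> denoised.csv
{
  "snr_input": 10.0,
  "snr_output": 14.495,
  "delta_snr": 4.495,
  "delta_rmse_pct": 40.400,
  "mdf_reference": 243.867,
  "mdf_processed": 234.639,
  "delta_mdf_pct": -3.784
}
```

Reading: the optimizer settled on a 12-mode decomposition with a wide
mode bandwidth (α ≈ 528); rest-calibrated soft interval thresholding
then raised the SNR of the 10 dB noisy record by 4.5 dB and cut the
RMSE by 40%, while shifting the median frequency by under 4% — i.e.
noise removed, spectral structure preserved.

The same chain is available as a library:

```python
from semgdenoise import (SyntheticConfig, generate_keystroke_semg, add_wgn,
                         PipelineConfig, denoise_pipeline, evaluate)

clean = generate_keystroke_semg(SyntheticConfig(seed=7))
noisy = add_wgn(clean, 10.0, seed=8)
result = denoise_pipeline(noisy, PipelineConfig(seed=7))
print(evaluate(clean, noisy, result.denoised))
```

`semgdenoise benchmark` sweeps input SNR levels × seeded replicates and
tabulates median metrics per thresholding scheme.

## Layout

```
src/semgdenoise/
  signal_model.py    Signal container, CSV + JSON-sidecar I/O
  preprocessing.py   band-pass + notch front end
  vmd.py             ADMM variational mode decomposition
  walrus.py          walrus optimizer
  mmee.py            envelope-entropy fitness
  wovmd.py           hyperparameter search glue
  mode_selection.py  instantaneous-frequency mode screening
  thresholding.py    interval thresholding, σ estimation, rest detection
  metrics.py         SNR / RMSE / MDF and Δ metrics
  synthetic.py       keystroke-sEMG generator, WGN injection
  pipeline.py        end-to-end chain + benchmark harness
  cli.py             simulate / denoise / evaluate / benchmark commands
docs/methods.md      model, parameter and design notes
```
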