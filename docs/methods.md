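# Methods

This note documents the models, parameter choices and numerical behavior
of `nmrmodal`: what each stage computes, which knobs matter, what the
synthetic cohorts do and do not emulate, and where the method's known
limits are.

## Signal model for synthetic FIDs

A free induction decay is modeled as the standard sum of damped complex
sinusoids (Lorentzian lines in the frequency domain):

    x(n) = Σ_p A_p · exp(i(2π ν_p n Δt + φ_p)) · exp(−n Δt / T2_p)
           + a_w · A_w · exp(i 2π·0·n Δt) · exp(−n Δt / T2_w)
           + σ (ε_re(n) + i ε_im(n)),   ε ~ N(0, 1) i.i.d.

with dwell time `Δt = 1/spectral_width`.  Defaults mirror a typical
400 MHz single-pulse serum acquisition: 16,384 complex points, 10,016 Hz
spectral width (1.636 s acquisition).  Parameters and units:

| parameter | meaning | default |
| --- | --- | --- |
| `amplitude` A_p | line amplitude, arbitrary signal units | per resonance |
| `frequency_hz` ν_p | offset from the carrier; must satisfy \|ν\| < sw/2 | per resonance |
| `t2_s` T2_p | mono-exponential transverse decay, seconds | per resonance |
| `attenuation` a_w | residual-water suppression factor ∈ [0, 1] | 0.02 |
| `noise_sd` σ | per-channel SD of complex Gaussian noise per point | 0.05 |
| `amplitude_jitter` | per-sample multiplicative SD on each amplitude | 0.05 |

Water suppression (a pulse-train presaturation step during acquisition
in real instruments) is modeled purely as the amplitude attenuation
`a_w` on a 0 Hz line; no pulse sequence is simulated.  Noise is circular
complex Gaussian, the quadrature-detection thermal-noise model.  Per-sample
biological variability is i.i.d. multiplicative jitter (5%) on every
resonance amplitude, clipped at zero.

The default serum-like resonance set places broad, short-T2 lipoprotein
lipid envelopes and sharp, long-T2 small metabolites (lactate, alanine,
acetate) between −1.5 kHz and +0.3 kHz of the water carrier, with a
dominant glucose envelope — amplitudes and T2 values chosen to give a
spectrogram with both fast-decaying broad ridges and persistent narrow
ones.  The built-in two-state cohort ("precursor" vs "progressed")
doubles the lipid CH2 amplitude (with a 20% T2 shortening, i.e. line
broadening) and raises the glucose envelope by 50% in the progressed
state — a dyslipidemia-plus-hyperglycemia serum phenotype.  Both effects
are 10–20× the within-group jitter, so the states are genuinely
separable by design.

What the generator does **not** emulate: J-coupling multiplets, chemical
exchange, field drift and shim instability, baseline distortions,
sample-to-sample variation in water-suppression efficiency, and the
hundreds of minor metabolites of real serum.  Passing recovery tests on
these cohorts therefore demonstrates that the pipeline's machinery is
correct and sensitive, not that real serum cohorts of this size would
separate as cleanly.

## STFT and spectrogram

Frame `m` is the unnormalized `N_DFT`-point DFT of the Hann-windowed
length-`M` segment starting at sample `mR` (zero-padded after
windowing).  Geometry defaults: `M = 64`, overlap `L = 32`, hop
`R = M − L = 32`, `N_DFT = 1024`.  The frame count is
`k = ⌊(N_x − L)/R⌋`, which is 511 at the default acquisition size; the
power spectrogram `|X|²` is cropped to its first `n_frames_out = 256`
frames so every sample lands on one fixed 256 × 1024 grid.  The crop is
a configuration choice, recorded in output metadata: since the FID
decays with T2 ≤ 0.25 s and frame `m` starts at `mR·Δt ≈ m·3.2 ms`,
frames beyond ~0.8 s are noise-only, and keeping the first 256 retains
essentially all signal energy.  Signals yielding fewer than
`n_frames_out` frames are zero-padded instead.

Numerical conventions, chosen once and asserted by tests:

- **DFT normalization** — unnormalized forward DFT (no 1/N), so the
  per-frame Parseval identity reads
  `Σ_f |X_m(f)|² = N_DFT · Σ_n |g(n) x(n+mR)|²` (held to 1e−9 relative).
- **Sidedness** — the signal is complex, so the full 1024-bin two-sided
  transform is kept, reordered to a centered physical axis
  (−sw/2 … +sw/2); a one-sided mode exists for real inputs.
- **Window sampling** — symmetric Hann of length M (not periodic);
  zero-padding happens after windowing.
- **Frame timestamps** — frame `m` is reported at its window center,
  `(mR + M/2)·Δt`.

Exports: single-channel 32-bit-float uncompressed TIFF of the
log10-scaled power (display dynamic range), and an ASCII matrix (one
frame per line, single spaces, `%.17g`, C-locale) that re-parses to the
power matrix exactly.

## Feature matrix and SNV

Spectrograms are flattened row-major (cell `(i, j)` → column
`i·N_DFT + j`, invertible via the retained grid shape) and stacked in
input order.  SNV normalizes each row to mean 0 and SD 1; the SD uses
the n−1 (sample) denominator — with 262,144 variables the n vs n−1
difference is far below any tolerance in use, but the choice is
explicit and configurable.  Constant rows are an error (naming the
sample), not a silent NaN.

## PCA and PLS-DA (NIPALS)

With a handful of samples against 262,144 variables and only a few
latent components needed, both models use NIPALS, whose per-iteration
cost is O(n·p); a dense SVD of the wide matrix would be wasteful, and
an exact eigendecomposition path exists in the test oracles for
cross-checking.  Columns are always mean-centered internally; no column
scaling is applied (rows are already SNV-normalized, and scaling
262,144 mostly-noise columns would inflate noise).

- **PCA** — power iteration per component with deflation; convergence
  when the score vector changes by less than `tol = 1e−10` relative,
  `max_iter = 10,000` (near-degenerate eigenvalue pairs converge
  slowly; non-convergence warns with the iteration count rather than
  failing silently).  Explained variance fractions are `tᵀt` over the
  total centered sum of squares and sum to 1 over a full-rank fit.
- **PLS-DA** — the two classes (alphabetical order) are coded −1/+1 in
  a single dummy response, mean-centered; PLS1 NIPALS extracts factors
  with closed-form weights per factor, deflating both X and y.
- **Sign conventions** (for run-to-run reproducible plots) — every PCA
  loading column is flipped so its largest-magnitude element is
  positive; PLS Factor-1 is oriented so the +1-coded class has the
  higher mean score (relabeling the classes therefore exactly negates
  Factor-1); later PLS factors follow the loading-sign rule.
- **Degenerate inputs** — too many components for `min(n−1, p)`, a
  zero-variance matrix, fewer or more than 2 classes, and constant
  score vectors are all typed errors; a single-sample class warns.

Subgroup regrouping assigns each sample by the sign of a chosen PC's
score; a score of exactly 0 goes to the negative-side label (any fixed
tie-break beats an undocumented one).

## Correlation loadings and the 0.4 mask

The correlation loading of variable `j` for a score column `t` is the
plain Pearson correlation `r_j = corr(t, x_j)`, back-projected onto the
256 × 1024 grid.  Zero-variance cells are undefined (NaN) and never
masked.  Cells with |r| ≥ 0.4 (threshold inclusive, configurable in
(0, 1]) are flagged as relevant to the separation.

**Which matrix the correlations are taken against matters.**  The
models are fit on the SNV matrix, but the pipeline correlates scores
against the **raw** power matrix.  SNV is a per-row affine transform:
when two groups differ in overall spectral shape, each row's mean/SD
normalizer shifts systematically with the group, so after SNV *every*
cell — including pure-noise cells far from any resonance — acquires a
group-correlated offset.  On the built-in two-state cohort this
saturates the SNV-reference map (≈98% of all cells exceed |r| ≥ 0.4)
and even erodes recall at genuinely differing cells (the global shift
partially cancels moderate positive power differences).  Against the
raw matrix the map localizes: recall of the detectably-different cells
is 1.0 at the default conditions.  `correlation_loadings` itself is
reference-agnostic — it correlates whatever matrix it is given.

**Ground truth for recovery experiments.**  The "injected ridge" of a
two-state design is defined by a 3-sigma detectability rule: a cell
belongs to the ridge when half the noiseless between-group power
difference is at least 3× the per-cell SD of a 16-sample no-effect
cohort simulated with the same jitter and noise.  This is computed
directly from the simulator's resonance structure, independent of the
correlation/PLS code path it judges (~6.7k of 262,144 cells at the
default conditions).

**Known limitation — mask precision at small n.**  With 12 training
samples, the null distribution of a Pearson correlation has SD
≈ 1/√11 ≈ 0.30, so ≈20% of cells whose variation is independent of the
group axis (per-cell thermal noise) clear |r| ≥ 0.4 by chance — and
this is scale-invariant, so no noise level avoids it.  With ~6.7k true
ridge cells against ~255k background cells, the expected mask is
~60k cells and its precision ~0.1, which is what the recovery
experiment measures.  The 0.4 threshold is a discriminability heuristic
inherited from small-cohort chemometrics practice, not a false-positive
control; at these cohort sizes the mask should be read as "every
detectable difference is flagged, together with a fifth of the noise
floor", and any cell-level claim should be confirmed on an independent
cohort or with an explicitly FDR-controlled statistic (out of scope
here).

## Problem sizes and tolerances in the test suite

The suite exercises full-size acquisition geometry (16,384-point FIDs,
256 × 1024 grids) for the cohort-level checks — one simulated 2 × 6
cohort is shared across tests — while transform-correctness oracles run
on small random instances (signals ≤ 512 points, M ≤ 16, N_DFT ≤ 32 for
the brute-force STFT; 6–9 × 10–12 matrices for the model oracles), where
exhaustive reference evaluation is exact and cheap.  Stated tolerances:
STFT vs brute force 1e−10 absolute; Parseval 1e−9 relative; NIPALS vs
eigendecomposition / textbook PLS1 1e−6 up to sign; SNV postconditions
1e−9; FID text round-trips ≥ 12 significant digits (binary round-trips
bit-exact).
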