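# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `steerdecode`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Lagged linear regression

The core estimator is ridge regression over a time-lag expansion of the
predictor. With predictor *x* (possibly multichannel) and target *y*, the
canonical convention throughout the package is

    y(t) = Σ_τ w(τ) · x(t − τ),   τ ∈ [t_min, t_max] (signed, seconds)

so negative lags mean the predictor is read from the *future* of the
target's clock. Forward (encoding) models use x = steering, y = EEG and the
window [−1.5, 0.5] s: negative lags capture EEG preceding the action.
Backward (decoding) models use x = EEG, y = steering; their window is
specified on the steering–EEG *latency* axis as [−(a + 1.5), −a] s for
anticipation *a* and converted to canonical predictor lags [a, a + 1.5] by
a single sign-flip helper (`latency_to_lags`), so the decoder sees only EEG
recorded at least *a* seconds before the steering sample it predicts.

Design matrices are built by integer-sample shifting with zero padding at
the edges (an edge-trim variant exists; the first/last kernel-length
samples of generated sessions are flagged in `Session.meta` for it).
Columns are ordered channel-major, lag-minor.

### Ridge solution and cross-validation

`ridge_solve` computes w = (DᵀD + λM)⁻¹Dᵀy after removing column means
(bias restores them), M being the identity by default; a first-difference
penalty is available because ridge regularisation of TRFs acts as temporal
smoothing of the weights. A singular system at λ = 0 falls back to the
pseudo-inverse with a warning.

`cross_validated_fit` uses 10 contiguous, equal-size (±1 sample) folds.
Contiguity matters: the steering signal is strongly serially correlated,
and randomly interleaved folds would leak training information into the
test fold through that autocorrelation. λ is searched on a log grid
(default 13 decades, 10⁻³…10⁹). Two selection protocols are implemented:

- `nested` (default): for each outer fold, λ is chosen by
  leave-one-training-fold-out validation inside the training folds only,
  the model is refit on the whole training set, and r is computed on the
  held-out fold; the final reported model is refit on all data at the modal
  selected λ. This avoids the optimistic bias of tuning λ on test folds.
- `global`: one λ maximising the plain K-fold mean r. Cheaper and matches
  simpler published protocols; used here for null distributions and large
  sweeps.

Internally the CV caches per-fold Gram matrices (DᵀD, Dᵀy, sums), so any
union of training folds is assembled without touching the raw design, and
an eigendecomposition of each training Gram makes the λ search essentially
free. Design columns are standardized using training-set statistics before
solving (weights are un-standardized on output); standardization is off in
`ridge_solve` itself so that its output matches the plain normal equations
exactly.

Decoding quality is the Pearson correlation between reconstructed and
actual steering per test fold, averaged over folds. Multi-output fits
(encoder) average the per-channel correlations; a constant prediction
scores 0 by convention.

## CCA denoising

The noise matrix X concatenates, in order: 4 EMG channels preprocessed like
the EEG, 4 EMG sliding-RMS envelopes, 12 accelerometer axes, 3 bipolar EOG
channels (23 real columns), plus unit-variance white-noise columns drawn
from a recorded seed until X has as many columns as the EEG (J1 = J2).
The padding is what makes the denoising *reversible*: the EEG-side
transform W2 becomes square and invertible, so back-projection with no
components removed is the identity, and with J1 < J2 the mapping would
compress (and hence alter) the EEG even for unrelated noise.

CCA itself is computed by SVD whitening of each centered block (relative
singular-value cutoff 1e−10) followed by an SVD of the cross product of the
whitened bases; canonical variates have unit variance, canonical
correlations are clipped to [0, 1] and non-increasing, and the sign of each
W2 column is fixed (largest-magnitude element positive) for deterministic
output. Column means are removed before the rotation and restored after
back-projection.

Components are removed when their canonical correlation *strictly exceeds*
the 90th percentile (linear interpolation between order statistics — the
one percentile definition used everywhere in the package) of all canonical
correlations of that decomposition; since ρ is sorted, the removed set is
always a prefix. The percentile is a config parameter; 90 is a pragmatic
default, not a derived quantity.

Only instantaneous correlations are targeted — no lagged copies of the
nuisances enter X. Anticipatory cortical signal, which leads rather than
accompanies the action, therefore largely survives; signal that genuinely
co-varies with the nuisances at zero lag is removed with them, which makes
the procedure conservative for the scientific claim (surviving decoding is
not artifact).

## Null baselines and statistics

- **Shuffled-fold null**: the session is truncated to a fold-size multiple,
  the EEG fold blocks are re-ordered by a uniform random permutation
  (identity allowed; negligible mass at 10 folds), and the full CV decoding
  is rerun; 100 iterations by default. Baselines are linear-interpolated
  percentiles (95th by default; the 99th is also reported).
- **Permutation p-values** use the add-one estimator
  p = (1 + #{|null| ≥ |observed|}) / (n_iter + 1), so p is never 0.
- **Group TRF significance**: Wilcoxon signed-rank across subjects against
  zero at each (lag, channel), exact distribution below 10 subjects and the
  continuity-corrected normal approximation otherwise; BH-FDR is applied
  across latencies within each channel.
- **Repeated-measures ANOVA** is delegated to pingouin (one- and two-way,
  within-subject). Sphericity is checked with Mauchly's test;
  Greenhouse–Geisser-corrected p-values are used when it fails (p < .05,
  ≥ 3 levels). Effect size is partial eta squared,
  SS_effect/(SS_effect + SS_error). For the two-way design, where no
  omnibus Mauchly test exists, sphericity is assessed per factor on data
  collapsed over the other factor, and the interaction inherits a violation
  from either factor.

## Preprocessing

EEG: zero-phase Butterworth band-pass 0.1–24 Hz, order 4 per direction
(forward–backward, second-order sections). The filter's padding is
extended to ~3 cycles of the low edge (scipy's default padding is far too
short for a 0.1 Hz high-pass and leaks edge transients across the record).
Downsampling to 100 Hz is plain sample-picking for integer ratios —
anti-aliasing is the band-pass's job — and polyphase otherwise. Average
re-referencing precedes variance-based channel rejection (variance > 3×
the channel mean flags a channel); rejected channels are dropped from all
later stages and logged. EMG gets the EEG treatment *and* a 20–250 Hz
band-pass + 250 ms centered sliding-RMS envelope (edge windows truncated;
at analysis rates below ~100 Hz the envelope band scales down with the
Nyquist so the path remains well-posed). Accelerometers are z-scored
(sample sd, n−1). Steering passes through untouched. The 250 Hz EMG edge
is clipped to 249 Hz at a 500 Hz rate — a band edge exactly at Nyquist is
ill-posed.

## Synthetic sessions

The generator emulates the structure, not the physiology, of a driving
recording:

- **Steering**: low-pass filtered Gaussian noise (2nd-order zero-phase
  Butterworth, default cutoff 0.5 Hz), unit variance. Only smoothness and
  autocorrelation matter to the analyses; the cutoff is configurable since
  real steering spectra vary with track and driver.
- **EEG**: per-channel anticipatory kernels (sums of Gaussian bumps,
  default biphasic with peaks at −0.8/−0.45 s; the decoding studies use
  support hard-limited to [−1.0, −0.3] s) convolved with the steering,
  plus 1/f noise (spectral shaping, power exponent 1, configurable), plus
  artifact projections.
- **Nuisances**: accelerometers follow smoothed |dS/dt| (zero lag with the
  action) with per-axis loadings and noise; EMG is broadband noise
  amplitude-modulated by |dS/dt|; EOG is smoothed steering *advanced* by
  0.5 s — gaze leads the action, making the ocular artifact the genuinely
  anticipatory confound a decoder could exploit.
- **Artifact projections** are rank-1 and instantaneous: each stream's
  summary signal enters every EEG channel through a fixed mixing vector
  drawn once from the ground-truth seed. Low rank is deliberate: on the
  scalp a handful of nuisance components dominate, and the percentile rule
  removes a fixed fraction of components, so the removable subspace must be
  small relative to the channel count (at 111 channels the 90th-percentile
  rule removes ~11 components; the scaled-down sessions here use 24
  channels and remove 2–4).

Everything is deterministic given the two seeds (ground truth and session);
mixing vectors come from the former so repeated sessions share a stationary
artifact subspace for CCA to find.

What the generator does *not* emulate: event-related non-stationarity,
eye blinks as discrete events, electrode drift and pops, volume-conduction
geometry, spectral peaks (mu/alpha), or any vehicle dynamics. Passing
tests therefore demonstrate that the *pipeline* recovers planted structure
and rejects planted confounds under realistic noise levels — not that real
EEG contains such structure.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down configurations chosen to
keep full fidelity of the procedure while remaining desk-size: sessions of
1–10 minutes at 20–50 Hz with 4–24 EEG channels, a 7-point λ grid over the
same 10⁻³…10⁹ interval, 20-iteration nulls for single comparisons and
100-iteration nulls for calibration studies. The λ-grid density, fold
count, percentiles and window parameters are the reference settings
(`PipelineConfig` defaults: 0.1–24 Hz, 100 Hz, 90th CCA percentile,
[−1.5, 0.5] s encoder window, 13 anticipations, 10 folds, 100 null
iterations, 95th-percentile baseline).

Degenerate inputs: zero-variance channels make Pearson r undefined — CV
scoring treats constant predictions as r = 0, while `pearson_r` itself
raises; constant columns are rejected by the z-scorer with the column
index named; rank-deficient CCA blocks are whitened at reduced rank and
removal then refuses to proceed (non-square W2) rather than silently
compressing the EEG.

## Known limitations

- The shuffled-fold null shares λ-selection with the observed decoding but
  not the temporal adjacency of fold boundaries; at very short sessions
  the baseline is noticeably optimistic (wide), which is conservative.
- Group-level TRF significance spreads beyond the true kernel support
  because serial correlation of the steering correlates TRF estimates
  across lags; the group mask should be read as "signal present", not as a
  support estimator.
- The EDF reader is a thin optional wrapper (mne) and is not exercised by
  the test suite; the HDF5 session container is the tested interchange
  format.
- Decoding r on synthetic sessions is far higher than one should expect
  from real scalp EEG: the generator's SNR (unit kernels over unit 1/f
  noise) is a study condition, not a claim about recordings.
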