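# Methods

This note documents the models, conventions and defaults implemented in
`scapekit`, the choices made where the design was genuinely open, and what
the synthetic tests do and do not establish about real data.

## Recordings and spectra

A recording is a fixed-length mono PCM signal (stereo is averaged to mono;
the recorder is effectively a single measurement point). 16-bit integers
are scaled by 1/32768, so negative full scale maps exactly to −1.0.

Two spectrum estimators are provided:

- `fullfft` — a single periodogram of the whole recording with a
  rectangular window. The PSD integrates to the signal mean square
  (Parseval) to float precision; frequency resolution is `fs/N`.
- `welch` (default) — Hann-windowed segments of 1 s with 50% overlap,
  averaged. On 3-minute recordings this trades frequency resolution for an
  estimator variance roughly 1/180 of the periodogram's, which matters
  because downstream statistics correlate *per-bin averages* over time.

Both return a one-sided PSD; bins then average PSD values, so the scale
convention cancels out of every normalised quantity (evenness,
correlations, min–max spectrograms).

## Binning and the bin-count scan

Bins are contiguous runs of spectral points: with `n` points and `B` bins,
each bin holds ⌊n/B⌋ or ⌈n/B⌉ points and the first `n mod B` bins take the
extra point. This remainder rule is arbitrary but deterministic and
recorded; bin *frequency* edges follow from the point edges.

Mean intra-bin variance uses the **population** variance (divide by bin
size). The scan's two diagnostics move oppositely: v̄(B) falls as bins
shrink (law of total variance — for nested binnings the decrease is exact
and monotone, which the tests verify against a brute-force oracle), while
evenness rises toward the unbinned spectrum's evenness. Saturation is
declared at the smallest scanned B beyond which the successive relative
change (normalised by the maximum change over the scan) of **both** series
stays below the threshold (default 0.1). The first scan point has no
predecessor; its change value is undefined and excluded. The selected
count is rounded up to the nearest power of two by default (bit
convention). Requiring *both* measures below threshold is deliberate: a
variance-only rule can trigger early on spectra whose evenness is still
climbing.

Shannon evenness treats the binned spectrum as a probability distribution:
p_b = s_b/Σs, H = −Σ p_b ln p_b / ln B ∈ [0, 1], with H ≡ 1 for B = 1 and
an error for an all-zero spectrum. A variant that collapses the whole
spectrum to its grand mean before the −x ln x kernel is exposed as
`literal_entropy_term` for comparison only; it is not an evenness and is
not used by the pipeline.

The Cochran sample size is n₀ = z²·0.25/e² (worst-case proportion 0.5, z
the two-sided normal quantile), with finite-population correction
n = n₀/(1 + (n₀−1)/N); the implementation returns both the exact ceiling
and a nearest-thousand convenience value.

## Denoising

PCA is applied **per frequency bin** to that bin's time series folded into
a days × slots-per-day matrix (`daily` layout). Rationale: the dominant
low-rank structure of environmental power series is diurnal, and the daily
fold makes it the leading subspace; a delay-embedding (`lag`, SSA-style)
alternative is available for series without a daily grid. Columns are
centred, the covariance eigendecomposed (via SVD), and the smallest k
components whose cumulative explained variance reaches the threshold
(default 0.95) are retained; reconstruction is standard truncated PCA
(scores already carry eigenvalue scale). A literal extra
eigenvalue-weighting of retained components is available behind a flag for
comparison; it distorts amplitudes and is off by default.

Missing slots, short days and missing values are imputed with the bin
median *for the decomposition only* — after reconstruction every imputed
cell is restored to its original (possibly missing) value, so imputation
never fabricates data.

Outlier removal blanks values strictly above the per-bin empirical
99.95% quantile (type-7/linear order statistics, per site). Values become
missing rather than clipped or row-deleted, and downstream statistics use
available data per bin or per pair. On a constant series nothing is ever
removed. Expected removals are ≈ (1−q)·n per bin; the report records exact
counts.

Pipeline order is fixed and recorded in each ensemble's provenance list:
`bin → log → pca_denoise → remove_outliers`. Denoising on raw (unlogged)
power is possible by skipping the log stage; the relative order is still
enforced. Log transform is log₁₀ with a floor of 1e−12 × the spectrum
maximum, so silence maps to a large negative constant.

## Summaries

Median spectrum: per-bin median with 5% and 95% quantiles (type-7
throughout, for cross-module consistency) over non-missing values; a
warning is emitted below 20 recordings where the band is degenerate.

Normalised spectrogram: recordings are averaged per local calendar date
(no timezone arithmetic), dates without recordings stay as missing rows so
the calendar remains contiguous, and each bin's daily series is min–max
scaled over its observed dates. Min–max (rather than divide-by-maximum)
is used so that 1 is the period maximum *and* 0 the period minimum of each
bin; a constant bin maps to 0 by convention. The operation is idempotent
and invariant to per-bin affine rescaling of its input.

## Frequency correlation matrices

R²[a,b] is the squared Pearson correlation of bins a and b over
pairwise-complete recordings — computed exactly (per-pair means via mask
algebra), not by imputation. Entries with fewer than `min_pairs` (default
30) joint observations, and rows of zero-variance bins, are NaN
(undefined, never 0). Analyses are capped at 13 kHz by default, where
environmental spectra carry little power; configurable. The signed
correlation matrix can be retained for diagnostics since R² discards
anti-correlation structure. FCMs default to per-recording spectra; a
daily-mean variant is available by flag. The R² histogram covers the
strict upper triangle only (the diagonal of 1s carries no information),
with 50 equal bins on [0, 1], last bin closed.

`block_contrast` evaluates a candidate community partition as
(mean within-block R², mean between-block R²) over off-diagonal entries;
partitions indexed on the full band may be applied to a capped FCM —
out-of-range bins are ignored.

## Synthetic soundscapes

The generator defines the study conditions for all end-to-end tests.

- **Spectral tier** (`simulate_ensemble`): values are log₁₀-power per bin;
  a flat noise floor (−8) plus, for each active source, its level added to
  all bins whose centre lies in its band, plus i.i.d. Gaussian noise
  (sd 0.25 log units). Activity is an independent Bernoulli draw per slot,
  gated by hour window, weekday mask and date window. Shared activity
  across a band's bins is what creates within-band correlation: for a
  binary signal of variance σ²ₛ against noise σ²ₙ, pairwise r → σ²ₛ/(σ²ₛ+σ²ₙ).
- **Waveform tier** (`synthesize_wav`): the same sources rendered as
  band-passed white noise (FFT-domain masking with 100 Hz raised-cosine
  edges) over a broadband floor, deterministic per (seed, timestamp).
  It exists so WAV I/O and spectrum estimation are exercised end to end;
  unit tests use the fast spectral tier.
- **Default urban scenario**: 30 days × 50 slots (the cadence of a
  26-minute duty cycle), B = 128 bins to 22.05 kHz, three communities —
  weekday-only traffic ≤ 2.5 kHz (p = 0.9), morning bird chorus
  2.5–8.5 kHz in the first 15 days (p = 0.8), evening crickets 9–11 kHz
  (p = 0.7) — level 2.0 log units each, i.e. a 100× power contrast over
  the floor, comfortably above the 0.25 noise sd.
- **Spectrum-sample generator** (`simulate_spectrum_sample`), used by the
  bin-count scan: a decaying broadband continuum times a random gain, plus
  a random subset of a shared pool of 200 Gaussian peaks (centres ≤ 13 kHz,
  widths 30–300 Hz — narrowband sources such as birdsong, hums and engine
  orders), with ±10% multiplicative measurement noise. The shared pool
  gives the sample across-recording spectral structure at a finite
  frequency scale, which is what makes both scan diagnostics saturate
  smoothly; 65,536-point spectra keep bin-size discretisation negligible
  at 4,000 bins while the 60-spectrum scan completes in ~1 s.

What the synthetic data do **not** emulate: amplitude heterogeneity within
a source's band, spectral overlap between sources, autocorrelated weather
noise, propagation effects, or recorder self-noise structure. Passing the
planted-community tests therefore shows the *machinery* recovers known
block structure under realistic scheduling, not that real soundscapes
decompose this cleanly.

## Numerical conventions and degenerate inputs

- Quantiles: type-7 (linear interpolation) everywhere.
- Population variance in the binning diagnostics; SVD-based PCA.
- All-zero spectra: evenness errors; log transform floors; QC flags
  silence.
- Zero-variance embeddings return unchanged with k = 0; zero-variance
  bins yield NaN FCM rows.
- Random draws use `numpy.random.default_rng` seeded explicitly; nothing
  is seeded from the clock. Waveform slots derive their stream from
  (seed, timestamp) so any slot can be regenerated independently.

## Problem sizes

Default test and reproduction runs use 30 days × 50 slots × 128 bins for
the scenario pipeline, 60 × 65,536-point spectra for the bin-count scan,
10,000 × 4 ensembles for outlier counts and n = 5,000 for correlation
bounds — sizes at which every stochastic check is stable across seeds
while the full suite runs in a few seconds.

## Known limitations

- The daily PCA layout assumes a fixed number of slots per day; recordings
  beyond `width` on a given day are ignored by the embedding (restored
  untouched afterwards).
- `build_index` loads metadata from filenames only; a corrupt file body is
  caught at read time, not at indexing.
- FCM memory is O(B′²) and time O(n·B′²); at the default 13 kHz cap and
  1024-bin schemes (B′ ≈ 604) this is still inexpensive, but pairwise-
  complete handling materialises several B′ × B′ intermediates.
- Community structure is *evaluated* against a given partition
  (`block_contrast`); the package deliberately does not detect communities.
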