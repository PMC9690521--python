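# scapekit

Analysis of the time–frequency dynamics of long-term acoustic-environment
recordings: data-driven spectral binning, PCA time-series denoising, median
power spectra, normalised long-duration spectrograms, and **frequency
correlation matrices (FCMs)** — plus a synthetic soundscape simulator that
provides ground truth for every stage.

## Who this is for

Passive acoustic monitoring (PAM) campaigns record a few minutes of audio
every half hour, at several sites, for months. The resulting corpus (here
nominally 3-minute, 44.1 kHz, 16-bit WAV files every 26 minutes per site)
is far too large to listen to or to display as an ordinary spectrogram.
`scapekit` condenses such a corpus into a handful of per-site objects that
expose the structure of the acoustic environment — which frequency bands
carry power, how they evolve over days and seasons, and which bands rise
and fall *together*, indicating shared sound sources (traffic, bird chorus,
crickets, wind).

## The method

1. **Spectra and binning.** Each recording's one-sided power spectrum
   (full-length FFT, or Welch averaging) is averaged within *B* equal-width
   frequency bins. *B* is chosen by scanning candidate counts over a random
   sample of recordings and tracking two complexity measures:

   - mean intra-bin variance  v̄(B) = (1/n) Σᵢ (1/B) Σ_b var(s_ib) —
     spectral detail destroyed by binning;
   - mean Shannon evenness    H̄(B) = (1/n) Σᵢ [ −Σ_b p_b ln p_b / ln B ] —
     flatness of the normalised binned spectrum.

   The selected B\* is the smallest scanned count beyond which the relative
   change of **both** series stays below 10% of its maximum change, rounded
   up to a power of two. The sample size for the scan comes from Cochran's
   formula with finite-population correction (margin 1%, confidence 99%,
   N = 416,797 → 15,953, i.e. 16,000 recordings).

2. **Denoising.** Each bin's log-power time series is folded into a
   days × slots-per-day matrix and reconstructed from the leading principal
   components explaining ≥ 95% of its variance; the residual ~5% is treated
   as noise. Rare loud events are then blanked per bin above the 99.95%
   quantile (set to missing, never clipped).

3. **Summaries.** Per site: the median spectrum with a 5–95% quantile band;
   and a date × frequency matrix of daily mean spectra, min–max normalised
   to [0, 1] per bin, which makes faint high-frequency seasonal and weekly
   patterns visible next to the energetic low bands.

4. **FCM.** The squared Pearson correlation R² between every pair of bin
   power series (pairwise-complete over missing values, bins capped at
   13 kHz) forms a symmetric B′ × B′ matrix. Blocks of mutually high R²
   ("frequency communities") mark co-occurring sources; the histogram of
   the strict upper triangle exposes their multimodality.

## Worked example

The default synthetic scenario plants three independently scheduled
band-limited sources — weekday traffic below 2.5 kHz, a morning bird chorus
at 2.5–8.5 kHz during a breeding-season window, evening crickets at
9–11 kHz — over 30 days × 50 recording slots per day:

```python
import scapekit as sk
from scapekit import denoising as dn, fcm as fc

sources, settings = sk.default_urban_scenario(seed=7)
ens, truth = sk.simulate_ensemble(sources, **settings)
den, report = dn.denoise_ensemble(ens, var_threshold=0.95)
den, report = dn.remove_outliers(den, q=0.9995, report=report)
mat = fc.compute_fcm(den, fmax=13_000.0, min_pairs=30)
within, between = fc.block_contrast(mat, truth.partition)
```

prints (via the accompanying report fields):

```
ensemble: 1500 recordings x 128 bins
PCA components kept per bin: 14-23 (min explained 0.950)
outliers removed per bin: 1-1
FCM: 75 bins <= 13 kHz
mean within-community R^2:  0.661
mean between-community R^2: 0.003
```

Bins sharing a planted source correlate strongly (R² ≈ 0.66 on average)
while independently scheduled bands do not (R² ≈ 0.003) — the block
structure an FCM is designed to reveal. The normalised spectrogram of the
same run shows the low band dropping on weekends and the mid band confined
to its date window.

The same pipeline runs from the shell:

```bash
scape simulate --days 30 --slots 50 --seed 7 --out sim/
scape denoise sim/ensemble.npz --out sim/denoised.npz
scape fcm sim/denoised.npz --fmax 13000 --plot
scape run --seed 7 --out results/   # everything, with a hashed manifest
```

For real data, point `scape index` / `scape run` at a directory of WAV
files named `SITE_YYYYMMDD_HHMMSS.wav` (template configurable).

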