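"""Site summaries: median power spectra and normalised long-duration spectrograms.

The median spectrum (with a 5-95% quantile band) summarises the power
distribution per frequency bin over all recordings of a site; the median is
preferred over the mean for robustness against loud outliers.  The
normalised spectrogram averages binned spectra per calendar date and
min-max scales each frequency bin's daily series to [0, 1] over the study
period, so faint high-frequency patterns (bird chorus, crickets, weekday
traffic rhythms) become visible alongside the energetic low bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scapekit.ensemble import SpectrumEnsemble
from scapekit.spectral import BinningScheme

__all__ = [
    "MedianSpectrumSummary", "NormalizedSpectrogram",
    "median_power_spectrum", "daily_mean_spectra", "normalize_per_bin",
]


@dataclass
class MedianSpectrumSummary:
    """Per-bin median and 5/95% quantiles over all recordings of a site."""

    median: np.ndarray
    q05: np.ndarray
    q95: np.ndarray
    scheme: BinningScheme
    site_id: str
    n_recordings: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_hz": self.scheme.centers(),
            "median": self.median,
            "q05": self.q05,
            "q95": self.q95,
        })


@dataclass
class NormalizedSpectrogram:
    """[dates x B] matrix in [0, 1]; dates without recordings are NaN rows."""

    matrix: np.ndarray
    dates: pd.DatetimeIndex
    scheme: BinningScheme
    site_id: str = ""


def median_power_spectrum(ensemble: SpectrumEnsemble) -> MedianSpectrumSummary:
    """Median and 5-95% quantile band per bin over non-missing values."""
    if ensemble.n_recordings == 0:
        raise ValueError("empty ensemble")
    if ensemble.n_recordings < 20:
        warnings.warn(
            "fewer than 20 recordings: 5/95% quantiles are degenerate"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(ensemble.values, axis=0)
        q05 = np.nanquantile(ensemble.values, 0.05, axis=0, method="linear")
        q95 = np.nanquantile(ensemble.values, 0.95, axis=0, method="linear")
    return MedianSpectrumSummary(
        median=med, q05=q05, q95=q95, scheme=ensemble.scheme,
        site_id=ensemble.site_id, n_recordings=ensemble.n_recordings,
    )


def daily_mean_spectra(ensemble: SpectrumEnsemble
                       ) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Mean binned spectrum per calendar date, on a continuous date axis.

    Dates inside the recording period without any recording (maintenance
    days) appear as all-NaN rows so the calendar stays contiguous.
    """
    dates = ensemble.timestamps.normalize()
    df = pd.DataFrame(ensemble.values, index=dates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        daily = df.groupby(level=0, sort=True).mean()
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(full)
    return full, daily.to_numpy()


def normalize_per_bin(daily: np.ndarray,
                      dates: pd.DatetimeIndex | None = None,
                      scheme: BinningScheme | None = None,
                      site_id: str = "") -> NormalizedSpectrogram:
    """Min-max scale each frequency bin's daily series to [0, 1].

    Per bin, over non-missing dates: (x - min) / (max - min); a constant
    bin maps to 0 by convention.  An all-missing bin is an error.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.ndim != 2:
        raise ValueError("daily matrix must be 2-D [dates x B]")
    out = np.full_like(daily, np.nan)
    for b in range(daily.shape[1]):
        col = daily[:, b]
        finite = np.isfinite(col)
        if not finite.any():
            raise ValueError(f"bin {b} has no non-missing values")
        lo, hi = col[finite].min(), col[finite].max()
        if hi > lo:
            out[finite, b] = (col[finite] - lo) / (hi - lo)
        else:
            out[finite, b] = 0.0
    if dates is None:
        dates = pd.date_range("1970-01-01", periods=daily.shape[0], freq="D")
    return NormalizedSpectrogram(matrix=out, dates=pd.DatetimeIndex(dates),
                                 scheme=scheme, site_id=site_id)
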