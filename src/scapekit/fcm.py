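"""Frequency correlation matrices: squared Pearson r between bin power series.

For one site, every pair of frequency bins yields one Pearson correlation
between their power time series over all recordings; the FCM stores the
square, R^2 — the proportion of one bin's power variance linearly explained
by the other's.  Blocks of mutually high R^2 ("frequency communities")
indicate sound sources that occupy several bins and come and go together;
the histogram of the strict upper triangle exposes multimodality when
several such communities coexist.

Missing values (from outlier removal) are handled by pairwise-complete
observations: each entry uses exactly the recordings where both bins are
observed, with per-entry effective sample sizes retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scapekit.ensemble import SpectrumEnsemble
from scapekit.spectral import BinningScheme

__all__ = [
    "FrequencyCorrelationMatrix", "R2Histogram",
    "compute_fcm", "r2_histogram", "block_contrast",
]


@dataclass
class FrequencyCorrelationMatrix:
    """Symmetric [B' x B'] matrix of R^2 with per-entry sample sizes.

    B' counts the bins under the frequency cap.  Entries with too few
    pairwise-complete observations, or involving a zero-variance bin, are
    NaN (undefined, not zero).  ``r`` optionally keeps the signed
    correlations for diagnostics.
    """

    r2: np.ndarray
    scheme: BinningScheme
    site_id: str
    n_pairs_used: np.ndarray
    fmax: float
    r: np.ndarray | None = None


@dataclass
class R2Histogram:
    """Histogram of the strict-upper-triangle R^2 values on [0, 1]."""

    edges: np.ndarray
    counts: np.ndarray
    n_missing: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lo": self.edges[:-1], "hi": self.edges[1:], "count": self.counts,
        })


def _pairwise_pearson(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlation matrix of the columns of X.

    NaN cells are excluded pair by pair via mask algebra, so each entry is
    the exact Pearson r over the rows where both columns are observed.
    Returns (r, n_pairs).
    """
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    Mf = M.astype(float)
    N = Mf.T @ Mf
    Sxy = X0.T @ X0
    Sx = X0.T @ Mf          # Sx[a,b] = sum of x_a over rows valid in both
    Sxx = (X0 * X0).T @ Mf
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * Sxy - Sx * Sx.T
        varx = N * Sxx - Sx ** 2
        vary = N * Sxx.T - Sx.T ** 2
        denom = np.sqrt(varx * vary)
        r = cov / denom
    r[~np.isfinite(r)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    return r, N.astype(int)


def compute_fcm(ensemble: SpectrumEnsemble, fmax: float = 13_000.0,
                min_pairs: int = 30, keep_signed: bool = False,
                daily_mean: bool = False) -> FrequencyCorrelationMatrix:
    """FCM of an ensemble: R^2 between all bin pairs under ``fmax``.

    Bins whose centre exceeds ``fmax`` are dropped.  Entries backed by fewer
    than ``min_pairs`` pairwise-complete recordings are NaN.  Zero-variance
    bins give NaN rows/columns.  The diagonal of defined bins is exactly 1.
    ``daily_mean`` correlates per-date mean spectra instead of individual
    recordings.
    """
    sl = ensemble.bin_slice_under(fmax)
    if daily_mean:
        from scapekit.summaries import daily_mean_spectra
        _, X = daily_mean_spectra(ensemble)
        X = X[:, sl]
    else:
        X = ensemble.values[:, sl]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 bins under the frequency cap")
    r, n_pairs = _pairwise_pearson(X)
    r[n_pairs < min_pairs] = np.nan
    r2 = r ** 2
    # exact 1.0 on the diagonal of defined bins
    diag_ok = np.isfinite(np.diag(r2))
    idx = np.where(diag_ok)[0]
    r2[idx, idx] = 1.0
    capped = _capped_scheme(ensemble.scheme, sl.stop)
    return FrequencyCorrelationMatrix(
        r2=r2, scheme=capped, site_id=ensemble.site_id,
        n_pairs_used=n_pairs, fmax=fmax,
        r=r if keep_signed else None,
    )


def _capped_scheme(scheme: BinningScheme, n_keep: int) -> BinningScheme:
    return BinningScheme(
        B=n_keep,
        n_points=int(scheme.point_edges[n_keep]),
        edges=scheme.edges[: n_keep + 1],
        point_edges=scheme.point_edges[: n_keep + 1],
    )


def r2_histogram(fcm: FrequencyCorrelationMatrix, n_bins: int = 50
                 ) -> R2Histogram:
    """Histogram of strict-upper-triangle R^2 values (diagonal 1s removed).

    Bins are equal-width on [0, 1], half-open with the last closed (numpy
    convention).  NaN entries are excluded and counted separately.
    """
    iu = np.triu_indices_from(fcm.r2, k=1)
    vals = fcm.r2[iu]
    missing = int(np.sum(~np.isfinite(vals)))
    counts, edges = np.histogram(vals[np.isfinite(vals)], bins=n_bins,
                                 range=(0.0, 1.0))
    return R2Histogram(edges=edges, counts=counts, n_missing=missing)


def block_contrast(fcm: FrequencyCorrelationMatrix,
                   blocks: dict[str, np.ndarray] | list[np.ndarray]
                   ) -> tuple[float, float]:
    """Mean within-block vs between-block off-diagonal R^2.

    ``blocks`` partitions the bin indices of the (capped) FCM; indices
    beyond the cap are ignored, so a full-band truth partition can be
    applied directly to a capped matrix.  A planted community structure
    shows up as within >> between.  Returns ``(mean_within, mean_between)``;
    within is NaN for a singleton-only partition.
    """
    if isinstance(blocks, dict):
        parts = [np.asarray(v, dtype=int) for v in blocks.values()]
    else:
        parts = [np.asarray(v, dtype=int) for v in blocks]
    B = fcm.r2.shape[0]
    parts = [p[p < B] for p in parts]
    parts = [p for p in parts if len(p)]
    covered = np.concatenate(parts) if parts else np.array([], dtype=int)
    if len(np.unique(covered)) != B:
        raise ValueError("blocks must partition all bin indices")
    label = np.empty(B, dtype=int)
    for i, p in enumerate(parts):
        label[p] = i
    iu = np.triu_indices(B, k=1)
    same = label[iu[0]] == label[iu[1]]
    vals = fcm.r2[iu]
    ok = np.isfinite(vals)
    within = vals[same & ok]
    between = vals[~same & ok]
    mean_within = float(within.mean()) if len(within) else float("nan")
    mean_between = float(between.mean()) if len(between) else float("nan")
    return mean_within, mean_between
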