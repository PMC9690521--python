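"""Power spectra, equal-width frequency binning and data-driven bin-count selection.

A per-recording one-sided power spectral density is averaged within B
equal-width frequency bins.  The bin count is chosen by scanning candidate
counts and tracking two complexity measures over a random sample of
recordings:

* mean intra-bin variance  v_B = (1/n) sum_i (1/B) sum_b var(s_ib) —
  the spectral variability destroyed by averaging within bins;
* mean Shannon evenness    H_B = (1/n) sum_i [ -sum_b p_b ln p_b / ln B ]
  of the sum-normalised binned spectrum — the flatness retained.

Both measures saturate as B grows; the selected B* is the smallest scanned
count beyond which the relative change of BOTH series stays below a
threshold (default 10% of the maximum observed change), optionally rounded
up to the nearest power of two.  The sample size for the scan comes from
Cochran's formula with finite-population correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from scapekit.recording_io import AudioRecording

__all__ = [
    "RawSpectrum", "BinningScheme", "BinnedSpectrum", "BinSelectionCurve",
    "power_spectrum", "make_binning", "bin_spectrum", "log_transform",
    "mean_intra_bin_variance", "spectral_evenness", "literal_entropy_term",
    "bin_selection_curve", "select_bin_count", "cochran_sample_size",
]


@dataclass
class RawSpectrum:
    """One-sided power spectrum of a single recording.

    ``power`` is a PSD (power per Hz) on the ascending frequency grid
    ``freqs`` running from 0 to Nyquist.
    """

    power: np.ndarray
    freqs: np.ndarray
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.power) != len(self.freqs):
            raise ValueError("power and freqs must have equal length")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power must be finite and nonnegative")


@dataclass(frozen=True)
class BinningScheme:
    """B contiguous equal-width bins over spectral points.

    Bins are defined on point indices: each bin holds floor(n/B) or
    ceil(n/B) consecutive points, the first ``n mod B`` bins taking the
    extra point.  ``edges`` are the B+1 frequency values delimiting the
    bins ([lo, hi) per bin, last bin closed).
    """

    B: int
    n_points: int
    edges: np.ndarray
    point_edges: np.ndarray  # B+1 point indices

    def bin_slices(self) -> list[slice]:
        pe = self.point_edges
        return [slice(int(pe[b]), int(pe[b + 1])) for b in range(self.B)]

    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class BinnedSpectrum:
    """Per-bin mean power for one recording (linear or log10 scale)."""

    values: np.ndarray
    scheme: BinningScheme
    scale: str = "linear"  # "linear" | "log10"
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.scheme.B:
            raise ValueError("values length must equal scheme.B")


@dataclass
class BinSelectionCurve:
    """Complexity measures versus bin count, with relative-change series.

    ``rel_change_v[k]`` (and ``_h``) is |x_k - x_{k-1}| normalised by the
    maximum successive change over the scan; index 0 has no predecessor and
    is NaN.  ``selected_B`` is filled by :func:`select_bin_count`.
    """

    bin_counts: np.ndarray
    v_bar: np.ndarray
    h_bar: np.ndarray
    rel_change_v: np.ndarray = field(default=None)  # type: ignore[assignment]
    rel_change_h: np.ndarray = field(default=None)  # type: ignore[assignment]
    selected_B: int | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        self.v_bar = np.asarray(self.v_bar, dtype=float)
        self.h_bar = np.asarray(self.h_bar, dtype=float)
        if self.rel_change_v is None:
            self.rel_change_v = _relative_change(self.v_bar)
        else:
            self.rel_change_v = np.asarray(self.rel_change_v, dtype=float)
        if self.rel_change_h is None:
            self.rel_change_h = _relative_change(self.h_bar)
        else:
            self.rel_change_h = np.asarray(self.rel_change_h, dtype=float)
        n = len(self.bin_counts)
        if not (len(self.v_bar) == len(self.h_bar)
                == len(self.rel_change_v) == len(self.rel_change_h) == n):
            raise ValueError("curve arrays must share the bin_counts length")


def power_spectrum(rec: AudioRecording, method: str = "welch",
                   window: str | None = None,
                   segment_length: int | None = None) -> RawSpectrum:
    """One-sided PSD of a recording by full-length FFT or Welch averaging.

    ``fullfft`` takes a single periodogram of the whole recording
    (rectangular window by default) so that the integral of the PSD equals
    the signal mean square (Parseval).  ``welch`` averages modified
    periodograms (Hann window, 1-s segments, 50% overlap by default) for a
    lower-variance estimate on multi-minute recordings.
    """
    x = np.asarray(rec.samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    fs = rec.sample_rate
    if method == "fullfft":
        f, p = sps.periodogram(x, fs=fs, window=window or "boxcar",
                               detrend=False)
    elif method == "welch":
        # default: 1-s segments, capped at the recording length
        nperseg = (segment_length if segment_length is not None
                   else min(int(fs), len(x)))
        if nperseg > len(x):
            raise ValueError(
                f"segment_length {nperseg} exceeds recording length {len(x)}"
            )
        f, p = sps.welch(x, fs=fs, window=window or "hann", nperseg=nperseg,
                         noverlap=nperseg // 2, detrend=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    # tiny negative round-off can appear in scipy's PSD output
    p = np.maximum(p, 0.0)
    return RawSpectrum(power=p, freqs=f, recording_id=rec.source_path)


def make_binning(n_points: int, nyquist: float, B: int) -> BinningScheme:
    """Split ``n_points`` spectral points into B contiguous near-equal bins.

    When ``n_points`` is not divisible by B the first ``n_points mod B``
    bins receive the extra point (deterministic remainder rule).
    """
    if not (1 <= B <= n_points):
        raise ValueError(f"need 1 <= B <= n_points, got B={B}, n={n_points}")
    base, extra = divmod(n_points, B)
    counts = np.full(B, base, dtype=int)
    counts[:extra] += 1
    point_edges = np.concatenate([[0], np.cumsum(counts)])
    edges = point_edges * (nyquist / n_points)
    return BinningScheme(B=B, n_points=n_points, edges=edges,
                         point_edges=point_edges)


def bin_spectrum(raw: RawSpectrum, scheme: BinningScheme) -> BinnedSpectrum:
    """Average raw power within each bin of the scheme."""
    if len(raw.power) != scheme.n_points:
        raise ValueError(
            f"scheme built for {scheme.n_points} points, spectrum has "
            f"{len(raw.power)}"
        )
    sums = np.add.reduceat(raw.power, scheme.point_edges[:-1])
    counts = np.diff(scheme.point_edges)
    return BinnedSpectrum(values=sums / counts, scheme=scheme,
                          recording_id=raw.recording_id)


def log_transform(bs: BinnedSpectrum, floor_eps: float | None = None
                  ) -> BinnedSpectrum:
    """log10 of the binned power, flooring at ``floor_eps``.

    The default floor is 1e-12 times the spectrum maximum (or 1e-300 for an
    all-zero spectrum), so silence maps to a large negative constant rather
    than -inf.  Applying the transform twice is a contract error.
    """
    if bs.scale != "linear":
        raise ValueError("log_transform requires a linear-scale spectrum")
    if floor_eps is None:
        mx = float(np.max(bs.values)) if len(bs.values) else 0.0
        floor_eps = 1e-12 * mx if mx > 0 else 1e-300
    vals = np.log10(np.maximum(bs.values, floor_eps))
    return replace(bs, values=vals, scale="log10")


def mean_intra_bin_variance(raw: RawSpectrum, scheme: BinningScheme) -> float:
    """Mean over bins of the population variance of power inside each bin.

    This is the spectral complexity destroyed by binning: 0 for a constant
    spectrum or for single-point bins (B == n_points).
    """
    if len(raw.power) != scheme.n_points:
        raise ValueError("scheme/spectrum length mismatch")
    p = raw.power
    pe = scheme.point_edges
    counts = np.diff(pe)
    s1 = np.add.reduceat(p, pe[:-1])
    s2 = np.add.reduceat(p * p, pe[:-1])
    var = s2 / counts - (s1 / counts) ** 2
    return float(np.mean(np.maximum(var, 0.0)))


def spectral_evenness(bs: BinnedSpectrum) -> float:
    """Shannon evenness of the sum-normalised binned power, in [0, 1].

    With p_b = values_b / sum(values): H = -sum p_b ln p_b / ln B.  1 for a
    flat spectrum, 0 when a single bin carries all power; defined as 1 for
    B == 1.  Requires linear-scale, nonnegative, not-all-zero input.
    """
    if bs.scale != "linear":
        raise ValueError("evenness is defined on linear-scale power")
    v = bs.values
    if np.any(v < 0):
        raise ValueError("power must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("evenness undefined for an all-zero spectrum")
    B = len(v)
    if B == 1:
        return 1.0
    p = v / total
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return float(h / np.log(B))


def literal_entropy_term(bs: BinnedSpectrum) -> float:
    """-x ln x of the grand mean of the binned power (diagnostic only).

    Collapses the whole binned spectrum to its single mean before the
    entropy kernel; exposed for comparison with :func:`spectral_evenness`,
    which treats the bins as a probability distribution.
    """
    m = float(np.mean(bs.values))
    if m <= 0:
        return 0.0
    return -m * np.log(m)


def _relative_change(x: np.ndarray) -> np.ndarray:
    """|successive difference| / max |successive difference|; index 0 is NaN."""
    x = np.asarray(x, dtype=float)
    out = np.full(len(x), np.nan)
    if len(x) < 2:
        return out
    d = np.abs(np.diff(x))
    mx = d.max()
    out[1:] = d / mx if mx > 0 else 0.0
    return out


def bin_selection_curve(sample: Sequence[RawSpectrum],
                        bin_counts: Sequence[int],
                        nyquist: float | None = None) -> BinSelectionCurve:
    """Scan candidate bin counts over a sample of spectra.

    For each B, mean intra-bin variance and Shannon evenness are averaged
    over all sample recordings; relative-change series are attached.
    """
    if not len(sample):
        raise ValueError("sample must be nonempty")
    bin_counts = np.asarray(sorted(bin_counts), dtype=int)
    n_pts = len(sample[0].power)
    if bin_counts[-1] > n_pts:
        raise ValueError(
            f"bin count {bin_counts[-1]} exceeds spectrum length {n_pts}"
        )
    nyq = nyquist if nyquist is not None else float(sample[0].freqs[-1])
    v_bar = np.zeros(len(bin_counts))
    h_bar = np.zeros(len(bin_counts))
    for j, B in enumerate(bin_counts):
        scheme = make_binning(n_pts, nyq, int(B))
        vs = np.empty(len(sample))
        hs = np.empty(len(sample))
        for i, raw in enumerate(sample):
            vs[i] = mean_intra_bin_variance(raw, scheme)
            hs[i] = spectral_evenness(bin_spectrum(raw, scheme))
        v_bar[j] = vs.mean()
        h_bar[j] = hs.mean()
    return BinSelectionCurve(bin_counts=bin_counts, v_bar=v_bar, h_bar=h_bar)


def select_bin_count(curve: BinSelectionCurve, threshold: float = 0.1,
                     round_to_power_of_two: bool = True) -> int | None:
    """Smallest scanned B beyond which both measures stop changing.

    B* is the first scanned count such that every subsequent relative-change
    value of BOTH the variance and evenness series is strictly below
    ``threshold``.  With ``round_to_power_of_two`` the result is the nearest
    power of two >= B* (bit convention).  Returns None when the criterion is
    never met.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    rv, rh = curve.rel_change_v, curve.rel_change_h
    n = len(curve.bin_counts)
    for k in range(n):
        tail = slice(max(k, 1), n)  # index 0 has no change value
        # normalised changes are <= 1, so threshold 1.0 is vacuously met
        if threshold >= 1.0 or (np.all(rv[tail] < threshold)
                                and np.all(rh[tail] < threshold)):
            b_star = int(curve.bin_counts[k])
            curve.selected_B = (_next_power_of_two(b_star)
                                if round_to_power_of_two else b_star)
            curve.threshold = threshold
            return curve.selected_B
    curve.selected_B = None
    curve.threshold = threshold
    return None


def _next_power_of_two(b: int) -> int:
    return 1 << (b - 1).bit_length()


def cochran_sample_size(margin: float, confidence: float,
                        population: int | None = None
                        ) -> tuple[int, int]:
    """Cochran sample size with optional finite-population correction.

    n0 = z^2 * 0.25 / margin^2 with z the two-sided normal quantile of the
    given confidence (worst-case proportion 0.5); with finite population N,
    n = n0 / (1 + (n0 - 1)/N).  Returns ``(ceil(n), nearest_thousand)``.
    """
    if not (0 < margin < 1) or not (0 < confidence < 1):
        raise ValueError("margin and confidence must be in (0, 1)")
    z = spst.norm.ppf(0.5 + confidence / 2.0)
    n0 = z * z * 0.25 / (margin * margin)
    n = n0 if population is None else n0 / (1.0 + (n0 - 1.0) / population)
    exact = int(np.ceil(n - 1e-9))
    return exact, int(round(exact / 1000.0)) * 1000
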