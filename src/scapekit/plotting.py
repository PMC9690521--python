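"""Matplotlib renderings: median spectra, normalised spectrograms, FCM heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from scapekit.fcm import FrequencyCorrelationMatrix, R2Histogram
from scapekit.summaries import MedianSpectrumSummary, NormalizedSpectrogram


def plot_median_spectrum(summary: MedianSpectrumSummary, path: str,
                         fmax: float | None = None) -> str:
    fig, ax = plt.subplots(figsize=(8, 4))
    f = summary.scheme.centers()
    ax.fill_between(f, summary.q05, summary.q95, alpha=0.3,
                    label="5-95% quantile")
    ax.plot(f, summary.median, lw=1, label="median")
    if fmax:
        ax.set_xlim(0, fmax)
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel("log10 power")
    ax.legend(frameon=False)
    ax.set_title(summary.site_id or "median power spectrum")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_spectrogram(spg: NormalizedSpectrogram, path: str,
                     fmax: float | None = None) -> str:
    fig, ax = plt.subplots(figsize=(10, 4))
    mat = spg.matrix.T  # frequency on y, dates on x
    # missing dates render as black columns
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    extent = None
    if spg.scheme is not None:
        extent = (0, mat.shape[1], spg.scheme.edges[0], spg.scheme.edges[-1])
    ax.imshow(np.ma.masked_invalid(mat), aspect="auto", origin="lower",
              cmap=cmap, vmin=0, vmax=1, extent=extent)
    if fmax and spg.scheme is not None:
        ax.set_ylim(0, fmax)
    ax.set_xlabel("date index")
    ax.set_ylabel("frequency [Hz]")
    ax.set_title(spg.site_id or "normalised spectrogram")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_fcm(fcm: FrequencyCorrelationMatrix, hist: R2Histogram | None,
             path: str) -> str:
    fig, ax = plt.subplots(figsize=(6, 5))
    edges_khz = fcm.scheme.edges / 1000.0
    im = ax.imshow(fcm.r2, origin="lower", cmap="magma", vmin=0, vmax=1,
                   extent=(edges_khz[0], edges_khz[-1],
                           edges_khz[0], edges_khz[-1]))
    ax.set_xlabel("frequency [kHz]")
    ax.set_ylabel("frequency [kHz]")
    fig.colorbar(im, ax=ax, label=r"$R^2$")
    if hist is not None:
        inset = ax.inset_axes([0.08, 0.65, 0.3, 0.3])
        centers = 0.5 * (hist.edges[:-1] + hist.edges[1:])
        inset.bar(centers, hist.counts, width=np.diff(hist.edges),
                  color="white", edgecolor="none")
        inset.set_yticks([])
        inset.set_xlabel(r"$R^2$", fontsize=7)
        inset.tick_params(labelsize=7)
        inset.patch.set_alpha(0.2)
    ax.set_title(fcm.site_id or "frequency correlation matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
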