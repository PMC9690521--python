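"""SpectrumEnsemble: the time-ordered stack of binned spectra for one site.

Every downstream stage (denoising, summaries, FCM) consumes this container:
a [n_recordings x B] matrix of (log) bin power with NaN for missing values,
aligned timestamps, the binning scheme and an append-only provenance list
recording which transforms have been applied, in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from scapekit.spectral import BinningScheme, BinnedSpectrum

__all__ = ["SpectrumEnsemble"]

#: Canonical pipeline stage names, in the order they must be applied.
STAGE_ORDER = ["bin", "log", "pca_denoise", "remove_outliers"]


@dataclass
class SpectrumEnsemble:
    """[n_recordings x B] (log) bin power for one site, rows sorted by time."""

    values: np.ndarray
    timestamps: pd.DatetimeIndex
    scheme: BinningScheme
    site_id: str = ""
    scale: str = "linear"
    provenance: list[str] = field(default_factory=lambda: ["bin"])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D [n_recordings x B]")
        if self.values.shape[0] != len(self.timestamps):
            raise ValueError("one timestamp per recording row required")
        if self.values.shape[1] != self.scheme.B:
            raise ValueError("column count must equal scheme.B")
        if not self.timestamps.is_monotonic_increasing:
            order = np.argsort(self.timestamps)
            self.values = self.values[order]
            self.timestamps = self.timestamps[order]

    @property
    def n_recordings(self) -> int:
        return self.values.shape[0]

    @property
    def B(self) -> int:
        return self.values.shape[1]

    def record_stage(self, stage: str) -> None:
        """Append a pipeline stage, enforcing the canonical relative order.

        Stages may be skipped (e.g. denoising raw rather than log power)
        but never applied twice or out of order.
        """
        if stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}")
        applied = [s for s in self.provenance if s in STAGE_ORDER]
        if stage in applied:
            raise ValueError(f"stage {stage!r} already applied")
        last = max((STAGE_ORDER.index(s) for s in applied), default=-1)
        if STAGE_ORDER.index(stage) < last:
            raise ValueError(
                f"pipeline order violated: {stage!r} after "
                f"{STAGE_ORDER[last]!r}"
            )
        self.provenance.append(stage)

    def copy(self) -> "SpectrumEnsemble":
        return SpectrumEnsemble(
            values=self.values.copy(),
            timestamps=self.timestamps.copy(),
            scheme=self.scheme,
            site_id=self.site_id,
            scale=self.scale,
            provenance=list(self.provenance),
        )

    def bin_slice_under(self, fmax: float) -> slice:
        """Columns whose bin centre lies at or below ``fmax`` Hz."""
        centers = self.scheme.centers()
        n_keep = int(np.sum(centers <= fmax))
        return slice(0, n_keep)

    @classmethod
    def from_binned(cls, spectra: list[BinnedSpectrum],
                    timestamps, site_id: str = "") -> "SpectrumEnsemble":
        if not spectra:
            raise ValueError("need at least one binned spectrum")
        scheme = spectra[0].scheme
        scale = spectra[0].scale
        vals = np.vstack([bs.values for bs in spectra])
        prov = ["bin"] if scale == "linear" else ["bin", "log"]
        return cls(values=vals, timestamps=pd.DatetimeIndex(timestamps),
                   scheme=scheme, site_id=site_id, scale=scale,
                   provenance=prov)

    # --- persistence (named-array container) -------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(
            path,
            values=self.values,
            timestamps=self.timestamps.asi8,
            bin_edges=self.scheme.edges,
            point_edges=self.scheme.point_edges,
            n_points=self.scheme.n_points,
            site_id=np.array(self.site_id),
            scale=np.array(self.scale),
            provenance=np.array(self.provenance),
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "SpectrumEnsemble":
        with np.load(path, allow_pickle=False) as z:
            scheme = BinningScheme(
                B=len(z["bin_edges"]) - 1,
                n_points=int(z["n_points"]),
                edges=z["bin_edges"],
                point_edges=z["point_edges"],
            )
            return cls(
                values=z["values"],
                timestamps=pd.DatetimeIndex(z["timestamps"].astype("datetime64[ns]")),
                scheme=scheme,
                site_id=str(z["site_id"]),
                scale=str(z["scale"]),
                provenance=[str(s) for s in z["provenance"]],
            )
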