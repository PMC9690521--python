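"""WAV ingestion, filename metadata, dataset indexing and recording QC.

Recorders in long-term deployments write fixed-length files (here nominally
3-minute mono/stereo PCM WAV at 44.1 kHz) whose site and start time are
encoded in the filename, Wildlife-Acoustics style: ``SITE_YYYYMMDD_HHMMSS.wav``.
This module reads those files into :class:`AudioRecording` objects, indexes a
directory tree into a :class:`RecordingIndex`, summarises the dataset, and
flags implausible recordings (clipping, silence, statistical outliers).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioRecording", "RecordingIndex", "DatasetSummary", "QCReport",
    "read_wav", "write_wav", "parse_metadata", "build_index",
    "summarize_index", "qc_flags", "DEFAULT_FILENAME_PATTERN",
]

#: Default filename template: ``{site}_{datetime}.wav`` with the datetime
#: written as ``YYYYMMDD_HHMMSS`` (common field-recorder convention).
DEFAULT_FILENAME_PATTERN = "{site}_{datetime}.wav"

_DATETIME_RE = r"(?P<datetime>\d{8}_\d{6})"
_SITE_RE = r"(?P<site>[^_/\\]+?)"


class MetadataParseError(ValueError):
    """Filename does not match the metadata template."""


class WavFormatError(ValueError):
    """WAV file has an unsupported encoding."""


@dataclass
class AudioRecording:
    """One fixed-length recording: PCM samples plus site/time metadata.

    ``samples`` are dimensionless amplitudes in [-1, 1] (16-bit PCM is
    scaled by 1/32768), mono after optional channel averaging.
    """

    samples: np.ndarray
    sample_rate: float
    site_id: str = ""
    timestamp: datetime | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        """Length in seconds (== len(samples)/sample_rate)."""
        return len(self.samples) / self.sample_rate


@dataclass
class RecordingIndex:
    """Sorted catalogue of (site_id, timestamp, path, duration_s) entries."""

    entries: list[tuple[str, datetime, str, float]] = field(default_factory=list)

    @property
    def sites(self) -> set[str]:
        return {e[0] for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_rows(self) -> list[dict]:
        return [
            {"site_id": s, "timestamp": t.isoformat(), "path": p, "duration_s": d}
            for s, t, p, d in self.entries
        ]


@dataclass(frozen=True)
class DatasetSummary:
    """Closed-form dataset bookkeeping: counts, total minutes and days."""

    n_recordings: int
    recording_length_min: float
    total_minutes: float
    total_days: int
    n_sites: int
    date_range: tuple[datetime, datetime] | None


@dataclass
class QCReport:
    """Per-recording plausibility flags with the thresholds that produced them.

    ``flags`` maps a recording identifier to a dict with boolean entries
    ``clipped``, ``silent`` and ``stat_outlier``.
    """

    flags: dict[str, dict[str, bool]]
    thresholds: dict[str, float]

    def flagged_ids(self) -> list[str]:
        return [k for k, v in self.flags.items() if any(v.values())]


def read_wav(path: str | Path, mixdown: bool = True) -> AudioRecording:
    """Read a RIFF/WAVE PCM file into an :class:`AudioRecording`.

    16-bit integer data are scaled by 1/32768 so full negative scale maps to
    -1.0 exactly; IEEE-float data are taken as-is.  Stereo channels are
    averaged to mono when ``mixdown`` is set.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / malformed RIFF
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        raise WavFormatError(
            f"unsupported WAV encoding {data.dtype} in {path}; "
            "expected 16/32-bit PCM or IEEE float"
        )
    if samples.ndim == 2:
        samples = samples.mean(axis=1) if mixdown else samples[:, 0]
    return AudioRecording(samples=samples, sample_rate=float(rate),
                          source_path=str(path))


def write_wav(rec: AudioRecording, path: str | Path,
              subtype: str = "FLOAT") -> Path:
    """Write a recording to disk as 32-bit float ('FLOAT') or 16-bit PCM ('PCM_16').

    Float output round-trips float32 samples bit-exactly through
    :func:`read_wav`; PCM_16 quantises with round-half-away and symmetric
    clipping at +/- full scale.
    """
    path = Path(path)
    if subtype == "FLOAT":
        wavfile.write(str(path), int(rec.sample_rate),
                      rec.samples.astype(np.float32))
    elif subtype == "PCM_16":
        q = np.clip(np.round(rec.samples * 32768.0), -32768, 32767)
        wavfile.write(str(path), int(rec.sample_rate), q.astype(np.int16))
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
    return path


def _pattern_to_regex(pattern: str) -> re.Pattern:
    """Translate a ``{site}``/``{datetime}`` template into a regex."""
    if "{site}" not in pattern or "{datetime}" not in pattern:
        raise ValueError("pattern must contain {site} and {datetime} placeholders")
    out = ""
    i = 0
    while i < len(pattern):
        if pattern.startswith("{site}", i):
            out += _SITE_RE
            i += len("{site}")
        elif pattern.startswith("{datetime}", i):
            out += _DATETIME_RE
            i += len("{datetime}")
        else:
            out += re.escape(pattern[i])
            i += 1
    return re.compile("^" + out + "$")


def parse_metadata(filename: str,
                   pattern: str = DEFAULT_FILENAME_PATTERN
                   ) -> tuple[str, datetime]:
    """Extract ``(site_id, timestamp)`` from a recording filename.

    The timestamp is parsed as naive local time from the ``YYYYMMDD_HHMMSS``
    field.  Raises :class:`MetadataParseError` when the name does not match.
    """
    name = Path(filename).name
    m = _pattern_to_regex(pattern).match(name)
    if m is None:
        raise MetadataParseError(
            f"filename {name!r} does not match pattern {pattern!r}"
        )
    ts = datetime.strptime(m.group("datetime"), "%Y%m%d_%H%M%S")
    return m.group("site"), ts


def build_index(root: str | Path,
                pattern: str = DEFAULT_FILENAME_PATTERN,
                read_durations: bool = False) -> RecordingIndex:
    """Index every parseable WAV under ``root`` (recursively).

    Unparseable filenames are collected into a warning, not fatal.  Duplicate
    (site, timestamp) pairs are an error naming both paths.  Durations are
    only read from file headers when ``read_durations`` is set (it touches
    every file).
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectoryError(f"recording root {root} does not exist")
    entries: list[tuple[str, datetime, str, float]] = []
    seen: dict[tuple[str, datetime], str] = {}
    skipped: list[str] = []
    for p in sorted(root.rglob("*.wav")) + sorted(root.rglob("*.WAV")):
        try:
            site, ts = parse_metadata(p.name, pattern)
        except MetadataParseError:
            skipped.append(str(p))
            continue
        key = (site, ts)
        if key in seen:
            raise ValueError(
                f"duplicate (site, timestamp) {key}: {seen[key]} and {p}"
            )
        seen[key] = str(p)
        dur = math.nan
        if read_durations:
            rec = read_wav(p)
            dur = rec.duration
        entries.append((site, ts, str(p), dur))
    if skipped:
        warnings.warn(
            f"{len(skipped)} file(s) did not match the metadata pattern and "
            f"were skipped: {skipped[:5]}{'...' if len(skipped) > 5 else ''}"
        )
    if not entries:
        warnings.warn(f"no parseable WAV recordings found under {root}")
    entries.sort(key=lambda e: (e[0], e[1]))
    return RecordingIndex(entries=entries)


def summarize_index(index: RecordingIndex | int,
                    recording_length_min: float) -> DatasetSummary:
    """Dataset totals: n x length minutes, rounded to whole days.

    Accepts either a :class:`RecordingIndex` or a bare recording count.
    """
    if recording_length_min <= 0:
        raise ValueError("recording_length_min must be positive")
    if isinstance(index, RecordingIndex):
        n = len(index)
        n_sites = len(index.sites)
        ts = [e[1] for e in index.entries]
        date_range = (min(ts), max(ts)) if ts else None
    else:
        n = int(index)
        n_sites = 0
        date_range = None
    total_minutes = n * recording_length_min
    return DatasetSummary(
        n_recordings=n,
        recording_length_min=recording_length_min,
        total_minutes=total_minutes,
        total_days=round(total_minutes / 1440),
        n_sites=n_sites,
        date_range=date_range,
    )


def _recording_stats(rec: AudioRecording) -> dict[str, float]:
    x = rec.samples
    return {
        "rms": float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0,
        "mean_power": float(np.mean(np.square(x))) if len(x) else 0.0,
        "peak": float(np.max(np.abs(x))) if len(x) else 0.0,
    }


def qc_flags(recordings: Sequence[AudioRecording],
             k: float = 3.0,
             clip_level: float = 32767.0 / 32768.0,
             clip_fraction: float = 0.01,
             silence_rms: float = 1e-4) -> QCReport:
    """Flag clipped, silent and statistically outlying recordings.

    ``clipped``: fraction of samples at or above ``clip_level`` in magnitude
    exceeds ``clip_fraction``.  ``silent``: RMS below ``silence_rms``.
    ``stat_outlier``: total power outside median +/- k*IQR across recordings
    of the same site; requires at least 5 recordings per site, otherwise only
    the clipped/silent flags are set.
    """
    flags: dict[str, dict[str, bool]] = {}
    by_site: dict[str, list[tuple[str, float]]] = {}
    for i, rec in enumerate(recordings):
        rid = rec.source_path or f"recording-{i}"
        st = _recording_stats(rec)
        x = rec.samples
        frac_clipped = (float(np.mean(np.abs(x) >= clip_level))
                        if len(x) else 0.0)
        flags[rid] = {
            "clipped": frac_clipped > clip_fraction,
            "silent": st["rms"] < silence_rms,
            "stat_outlier": False,
        }
        by_site.setdefault(rec.site_id, []).append((rid, st["mean_power"]))
    for site, pairs in by_site.items():
        if len(pairs) < 5:
            continue
        vals = np.array([p for _, p in pairs])
        med = np.median(vals)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = med - k * iqr, med + k * iqr
        for rid, v in pairs:
            if v < lo or v > hi:
                flags[rid]["stat_outlier"] = True
    return QCReport(
        flags=flags,
        thresholds={
            "k_iqr": k,
            "clip_level": clip_level,
            "clip_fraction": clip_fraction,
            "silence_rms": silence_rms,
        },
    )


def write_index_csv(index: RecordingIndex, path: str | Path,
                    qc: QCReport | None = None) -> Path:
    """Write the index (optionally with QC flags) as delimited text."""
    import pandas as pd

    df = pd.DataFrame(index.to_rows())
    if qc is not None and len(df):
        for col in ("clipped", "silent", "stat_outlier"):
            df[col] = [
                qc.flags.get(p, {}).get(col, False) for p in df["path"]
            ]
    df.to_csv(path, index=False)
    return Path(path)
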