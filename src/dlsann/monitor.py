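"""Long-run monitoring pipeline: size every recorded series in an experiment.

Intended for slow processes observed through repeated short DLS records —
e.g. a yeast fermentation followed for days with an 8 s series every
30 minutes.  Each series is read, autocorrelated, normalized, and sized by
the trained network (optionally also by the reference fit); summary
statistics (median/quartiles) are computed over user-chosen plateau
intervals of the diameter trajectory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .acr import normalized_acr
from .ann import AnnModel, predict
from .errors import ConfigError, FormatError, RunError
from .physics import OpticalSetup
from .reference import fit_single_exponential
from .simulate import TimeSeries

SERIES_SUFFIXES = (".txt", ".dat", ".csv", ".wav")


@dataclass
class MonitoringRecord:
    """One sized series of a monitoring run."""

    elapsed_time: float  # hours since the first recording
    diameter_ann: float  # m (nan if the series could not be processed)
    diameter_ref: float | None  # m, present when the reference fit was run
    source_file: str
    qc_flags: frozenset = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        return not self.qc_flags


@dataclass
class PlateauSummary:
    """Median and quartiles of the diameter over one time interval."""

    interval: tuple[float, float]  # hours
    median: float  # m
    quartiles: tuple[float, float]  # (q1, q3), m
    n_records: int


# ---------------------------------------------------------------------------
# series file I/O
# ---------------------------------------------------------------------------


def read_series_file(
    path: str | Path, sampling_frequency: float, format: str | None = None
) -> TimeSeries:
    """Read a recorded series from plain text, CSV, or 16-bit mono WAV.

    Text: one sample per line.  CSV: single column, or a column named
    ``intensity``.  WAV: must be mono; integer PCM samples are used as-is
    (no rescaling), matching a 16-bit acquisition system.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"series file does not exist: {path}")
    fmt = format or {".wav": "wav", ".csv": "csv"}.get(path.suffix.lower(), "text")

    if fmt == "wav":
        fs_file, data = wavfile.read(path)
        if data.ndim != 1:
            raise FormatError(f"{path}: WAV must be mono, got {data.shape[1]} channels")
        samples = data.astype(float)
    elif fmt == "csv":
        df = pd.read_csv(path)
        if df.shape[1] == 0 or len(df) == 0:
            raise FormatError(f"{path}: empty CSV")
        col = "intensity" if "intensity" in df.columns else df.columns[0]
        samples = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
    elif fmt == "text":
        try:
            samples = np.loadtxt(path, dtype=float, ndmin=1)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed text series: {exc}") from exc
        if samples.ndim != 1:
            raise FormatError(f"{path}: expected one sample per line")
    else:
        raise FormatError(f"unknown series format {fmt!r}")

    if samples.size < 2:
        raise FormatError(f"{path}: series has fewer than 2 samples")
    return TimeSeries(samples, sampling_frequency, origin="recorded")


def write_series_file(series: TimeSeries, path: str | Path, format: str | None = None) -> None:
    """Write a series as text (one sample per line), CSV, or 16-bit mono WAV."""
    path = Path(path)
    fmt = format or {".wav": "wav", ".csv": "csv"}.get(path.suffix.lower(), "text")
    if fmt == "wav":
        data = np.asarray(np.round(series.samples), dtype=np.int16)
        wavfile.write(path, int(round(series.sampling_frequency)), data)
    elif fmt == "csv":
        pd.DataFrame({"intensity": series.samples}).to_csv(path, index=False)
    else:
        np.savetxt(path, series.samples, fmt="%.17g")


# ---------------------------------------------------------------------------
# run processing
# ---------------------------------------------------------------------------


def _discover(directory: Path, manifest: Path | None):
    """(filename, elapsed_hours | None) pairs in processing order."""
    if manifest is not None:
        rows = []
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                if "filename" not in row:
                    raise ConfigError(f"manifest {manifest} lacks a 'filename' column")
                rows.append(row)
        if not rows:
            raise RunError(f"manifest {manifest} is empty")
        times = None
        if all(r.get("timestamp") for r in rows):
            stamps = pd.to_datetime([r["timestamp"] for r in rows])
            times = (stamps - stamps.min()).total_seconds() / 3600.0
        return [
            (directory / r["filename"], None if times is None else float(times[i]))
            for i, r in enumerate(rows)
        ]
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in SERIES_SUFFIXES
    )
    return [(p, None) for p in files]


def process_run(
    directory: str | Path,
    model: AnnModel,
    setup: OpticalSetup,
    interval_minutes: float = 30.0,
    with_reference: bool = False,
    manifest: str | Path | None = None,
    n_lags: int = 350,
) -> list[MonitoringRecord]:
    """Size every series file in a directory, in manifest or name order.

    Elapsed time is ``index * interval_minutes`` unless the manifest supplies
    timestamps. Per-file failures become qc-flagged records with NaN
    diameters; the run never aborts on a single bad file.
    """
    directory = Path(directory)
    entries = _discover(directory, Path(manifest) if manifest else None)
    if not entries:
        raise RunError(f"no series files found in {directory}")

    records: list[MonitoringRecord] = []
    for i, (path, t_hours) in enumerate(entries):
        elapsed = t_hours if t_hours is not None else i * interval_minutes / 60.0
        flags = set()
        d_ann = float("nan")
        d_ref: float | None = None
        try:
            series = read_series_file(path, setup.sampling_frequency)
            curve = normalized_acr(series, n_lags=n_lags)
        except Exception as exc:
            flags.add("short-series" if "too short" in str(exc) else "degenerate-acr")
            records.append(
                MonitoringRecord(elapsed, d_ann, d_ref, path.name, frozenset(flags))
            )
            continue
        d_ann = predict(model, curve)
        if with_reference:
            fit = fit_single_exponential(curve, setup)
            d_ref = fit.diameter
            if not fit.converged:
                flags.add("boundary-fit")
        records.append(
            MonitoringRecord(elapsed, d_ann, d_ref, path.name, frozenset(flags))
        )
    return records


def records_to_csv(records: Sequence[MonitoringRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "elapsed_hours": [r.elapsed_time for r in records],
            "diameter_ann_nm": [r.diameter_ann * 1e9 for r in records],
            "diameter_ref_nm": [
                r.diameter_ref * 1e9 if r.diameter_ref is not None else np.nan
                for r in records
            ],
            "source_file": [r.source_file for r in records],
            "qc_flags": ["|".join(sorted(r.qc_flags)) for r in records],
        }
    ).to_csv(path, index=False)


def plateau_stats(
    records: Sequence[MonitoringRecord],
    intervals: Sequence[Sequence[float]],
    include_flagged: bool = False,
    use_reference: bool = False,
) -> list[PlateauSummary]:
    """Median and quartiles of the diameter per time interval.

    Intervals are half-open ``[t_start, t_end)`` except the last, which is
    closed, and must not overlap. QC-flagged records are excluded by default.
    """
    iv = [(float(a), float(b)) for a, b in intervals]
    for a, b in iv:
        if not a < b:
            raise ConfigError(f"interval must have t_start < t_end, got {(a, b)}")
    for (a1, b1), (a2, b2) in zip(sorted(iv), sorted(iv)[1:]):
        if b1 > a2:
            raise ConfigError(f"overlapping intervals: {(a1, b1)} and {(a2, b2)}")

    out = []
    last_end = max(b for _, b in iv)
    for a, b in iv:
        ds = [
            d
            for r in records
            if (include_flagged or r.ok)
            and a <= r.elapsed_time < (b + 1e-12 if b == last_end else b)
            for d in [(r.diameter_ref if use_reference else r.diameter_ann)]
            if d is not None and np.isfinite(d)
        ]
        if ds:
            q1, med, q3 = np.percentile(ds, [25, 50, 75])
            out.append(PlateauSummary((a, b), float(med), (float(q1), float(q3)), len(ds)))
        else:
            out.append(PlateauSummary((a, b), float("nan"), (float("nan"), float("nan")), 0))
    return out


def plateau_to_csv(summaries: Sequence[PlateauSummary], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_start_hours": [s.interval[0] for s in summaries],
            "t_end_hours": [s.interval[1] for s in summaries],
            "median_nm": [s.median * 1e9 for s in summaries],
            "q1_nm": [s.quartiles[0] * 1e9 for s in summaries],
            "q3_nm": [s.quartiles[1] * 1e9 for s in summaries],
            "n_records": [s.n_records for s in summaries],
        }
    ).to_csv(path, index=False)
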