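"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* fluorescence trace CSV — columns ``time_s, <channel>, ...`` on a uniform
  time grid (seconds);
* DeepLabCut-dialect pose CSV — three header rows (scorer / bodyparts /
  coords) with an ``x, y, likelihood`` triplet per tracked body part;
* burst-event and phase-segment TSVs;
* cohort (onset-laterality) and photostimulation-trial TSVs;
* a versioned JSON summary.

All text is UTF-8, the decimal separator is ``.``, times are seconds, and
floats are serialized with 9 significant digits so that every writer/reader
pair round-trips bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

#: canonical body-part names of the three tracked midline points:
#: ocellus, middle of the tail, terminal of the tail.
BODYPARTS = ("bodypart1", "bodypart2", "bodypart3")

_FLOAT_FMT = "%.9g"


class FormatError(ValueError):
    """Raised when an on-disk file violates the pipeline's format contract."""


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceTrace:
    """Uniformly sampled multi-channel fluorescence intensity series.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing on a uniform grid
        (relative tolerance 1e-6).
    channels
        Mapping of channel id (e.g. ``"mn2l"``, ``"mn2r"``) to an intensity
        series of the same length as ``times``; raw intensity or
        normalized relative fluorescence (dF/F0) depending on ``normalized``.
    frame_interval
        Grid spacing in seconds.
    normalized
        True once the channels hold dF/F0 rather than raw intensity.
    """

    times: np.ndarray
    channels: dict[str, np.ndarray]
    frame_interval: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-d array with >= 2 samples")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, self.frame_interval, rtol=1e-6,
                           atol=1e-6 * self.frame_interval):
            raise ValueError("times must be uniform within 1e-6 relative tolerance")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, series in self.channels.items():
            if series.shape != self.times.shape:
                raise ValueError(f"channel {name!r} length does not match times")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class MidlineTrack:
    """Per-frame coordinates of the three tracked body parts.

    ``parts`` maps each name in :data:`BODYPARTS` (bodypart1 = ocellus,
    bodypart2 = mid-tail, bodypart3 = tail tip) to an ``(n, 3)`` array of
    ``x, y, likelihood`` rows; likelihoods lie in [0, 1].
    """

    times: np.ndarray
    parts: dict[str, np.ndarray]
    fps: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if tuple(self.parts) != BODYPARTS:
            missing = [p for p in BODYPARTS if p not in self.parts]
            if missing:
                raise ValueError(f"missing body part(s): {', '.join(missing)}")
            self.parts = {p: self.parts[p] for p in BODYPARTS}
        self.parts = {k: np.asarray(v, dtype=float) for k, v in self.parts.items()}
        n = self.times.size
        for name, arr in self.parts.items():
            if arr.shape != (n, 3):
                raise ValueError(f"part {name!r} must be (n_frames, 3)")
            lik = arr[:, 2]
            if np.any((lik < 0) | (lik > 1)):
                raise ValueError(f"part {name!r} has likelihood outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def coords(self, part: str) -> np.ndarray:
        """``(n, 2)`` x, y coordinates of one body part."""
        return self.parts[part][:, :2]

    def likelihood(self, part: str) -> np.ndarray:
        return self.parts[part][:, 2]


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    """Write a trace as ``time_s, <channel>...`` CSV."""
    path = Path(path)
    cols = {"time_s": trace.times, **trace.channels}
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace_csv(
    path: str | Path,
    *,
    time_column: str = "time_s",
    nan_policy: str = "reject",
    max_interp_gap: int = 3,
    normalized: bool = False,
) -> FluorescenceTrace:
    """Read a fluorescence trace CSV and validate its uniform time grid.

    Parameters
    ----------
    nan_policy
        ``"reject"`` (default) raises on any NaN intensity; ``"interpolate"``
        linearly fills NaN runs of at most ``max_interp_gap`` frames and
        rejects longer runs.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a parseable CSV ({exc})") from exc
    if df.empty or len(df) < 2:
        raise FormatError(f"{path}: trace CSV needs >= 2 data rows")
    if time_column not in df.columns:
        raise FormatError(f"{path}: missing time column {time_column!r}")
    chan_cols = [c for c in df.columns if c != time_column]
    if not chan_cols:
        raise FormatError(f"{path}: no channel columns")
    times = df[time_column].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    dt = np.diff(times)
    frame_interval = float(np.median(dt))
    if not np.allclose(dt, frame_interval, rtol=1e-6, atol=1e-6 * frame_interval):
        raise FormatError(f"{path}: non-uniform time grid")
    channels: dict[str, np.ndarray] = {}
    for c in chan_cols:
        series = df[c].to_numpy(dtype=float)
        if np.any(~np.isfinite(series)):
            if nan_policy == "reject":
                raise FormatError(f"{path}: NaN intensity in channel {c!r}")
            elif nan_policy == "interpolate":
                series = _interpolate_short_gaps(series, max_interp_gap, path, c)
            else:
                raise ValueError(f"unknown nan_policy {nan_policy!r}")
        channels[c] = series
    return FluorescenceTrace(times=times, channels=channels,
                             frame_interval=frame_interval, normalized=normalized)


def _interpolate_short_gaps(series: np.ndarray, max_gap: int,
                            path: Path, chan: str) -> np.ndarray:
    bad = ~np.isfinite(series)
    if bad[0] or bad[-1]:
        raise FormatError(f"{path}: channel {chan!r} has NaN at a trace boundary")
    # run-length check before interpolating
    runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
    if runs.size and runs.max() > max_gap:
        raise FormatError(
            f"{path}: channel {chan!r} has a NaN run of {runs.max()} frames "
            f"(> {max_gap} allowed)")
    idx = np.arange(series.size)
    out = series.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], series[~bad])
    return out


# ---------------------------------------------------------------------------
# DeepLabCut-dialect pose CSV
# ---------------------------------------------------------------------------

def write_dlc_csv(track: MidlineTrack, path: str | Path,
                  scorer: str = "synthetic") -> None:
    """Write a track in the DeepLabCut CSV dialect (3 header rows)."""
    path = Path(path)
    columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp in BODYPARTS
         for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"])
    data = np.hstack([track.parts[bp] for bp in BODYPARTS])
    df = pd.DataFrame(data, columns=columns)
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_dlc_csv(path: str | Path, fps: float) -> MidlineTrack:
    """Read a DeepLabCut-dialect CSV into a :class:`MidlineTrack`.

    The dialect requires three header rows (scorer / bodyparts / coords)
    and an ``x, y, likelihood`` triplet per body part; frame times are
    reconstructed from ``fps`` (DeepLabCut exports frame indices only).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, IndexError) as exc:
        raise FormatError(f"{path}: not a DeepLabCut-dialect CSV ({exc})") from exc
    if df.columns.nlevels != 3:
        raise FormatError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    parts: dict[str, np.ndarray] = {}
    for bp in BODYPARTS:
        if bp not in bodyparts:
            raise FormatError(f"{path}: missing body part {bp!r}")
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        for coord in ("x", "y", "likelihood"):
            if coord not in sub.columns:
                raise FormatError(f"{path}: body part {bp!r} lacks {coord!r} column")
        parts[bp] = sub[["x", "y", "likelihood"]].to_numpy(dtype=float)
    n = len(df)
    times = np.arange(n, dtype=float) / fps
    return MidlineTrack(times=times, parts=parts, fps=fps)


# ---------------------------------------------------------------------------
# events / segments / tables TSV
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("channel", "onset_s", "peak_s", "offset_s", "duration_s",
                 "peak_dff", "is_long", "truncated")


def write_events_tsv(trains: Sequence, path: str | Path) -> None:
    """Write burst trains as a TSV with one row per event.

    ``trains`` is a sequence of :class:`~cionacpg.trace_processing.BurstTrain`.
    """
    path = Path(path)
    rows = []
    for train in trains:
        for ev in train.events:
            rows.append({
                "channel": ev.channel,
                "onset_s": _fmt(ev.onset_time),
                "peak_s": _fmt(ev.peak_time),
                "offset_s": _fmt(ev.offset_time),
                "duration_s": _fmt(ev.duration),
                "peak_dff": _fmt(ev.peak_dff),
                "is_long": str(bool(ev.is_long)),
                "truncated": str(bool(ev.truncated)),
            })
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> dict[str, "BurstTrain"]:  # noqa: F821
    """Read an events TSV back into per-channel burst trains."""
    from .trace_processing import BurstEvent, BurstTrain

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    trains: dict[str, BurstTrain] = {}
    for chan, sub in df.groupby("channel", sort=True):
        events = [
            BurstEvent(channel=str(chan),
                       onset_time=float(r.onset_s),
                       peak_time=float(r.peak_s),
                       offset_time=float(r.offset_s),
                       peak_dff=float(r.peak_dff),
                       truncated=bool(r.truncated if isinstance(r.truncated, (bool, np.bool_))
                                      else str(r.truncated) == "True"))
            for r in sub.itertuples()
        ]
        trains[str(chan)] = BurstTrain(channel=str(chan), events=events)
    return trains


SEGMENT_COLUMNS = ("label", "t_start_s", "t_end_s", "mean_interval_s", "cv",
                   "sync_fraction", "long_burst_count")


def write_segments_tsv(segments: Sequence, path: str | Path) -> None:
    """Write phase segments (one row each) as TSV."""
    rows = []
    for seg in segments:
        f = seg.features
        rows.append({
            "label": seg.label,
            "t_start_s": _fmt(seg.t_start),
            "t_end_s": _fmt(seg.t_end),
            "mean_interval_s": _fmt(f.mean_interval_R) if math.isfinite(f.mean_interval_R) else "nan",
            "cv": _fmt(f.cv_R) if math.isfinite(f.cv_R) else "nan",
            "sync_fraction": _fmt(f.sync_fraction) if math.isfinite(f.sync_fraction) else "nan",
            "long_burst_count": int(f.long_burst_count),
        })
    pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS)).to_csv(
        Path(path), sep="\t", index=False)


def write_cohort_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-embryo onset-laterality table (``embryo_id, first_onset``)."""
    table.to_csv(Path(path), sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    if "first_onset" not in df.columns:
        raise FormatError(f"{path}: missing 'first_onset' column")
    return df


def write_trials_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a stimulation-trial table (``stimulated_side, response``)."""
    table.to_csv(Path(path), sep="\t", index=False)


def read_trials_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("stimulated_side", "response"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing {col!r} column")
    return df


# ---------------------------------------------------------------------------
# JSON summary
# ---------------------------------------------------------------------------

def _round_floats(obj):
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return v if not math.isfinite(v) else float(_fmt(v))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_summary_json(summary: Mapping, path: str | Path) -> None:
    """Write the versioned JSON summary (floats at 9 significant digits)."""
    payload = {"schema_version": SCHEMA_VERSION, **_round_floats(dict(summary))}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")


def read_summary_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported schema_version "
                          f"{payload.get('schema_version')!r}")
    return payload


def write_results(report: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Write a full analysis report to ``outdir``.

    ``report`` may hold ``trains`` (burst trains), ``segments``
    (phase segments), ``windows`` (a DataFrame of per-window features),
    ``bouts`` (a DataFrame) and ``summary`` (JSON-serializable mapping).
    Returns the mapping of artifact name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if "trains" in report:
        p = outdir / "events.tsv"
        write_events_tsv(report["trains"], p)
        written["events"] = p
    if "segments" in report:
        p = outdir / "segments.tsv"
        write_segments_tsv(report["segments"], p)
        written["segments"] = p
    if "windows" in report:
        p = outdir / "windows.tsv"
        report["windows"].to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        written["windows"] = p
    if "bouts" in report:
        p = outdir / "bouts.tsv"
        report["bouts"].to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        written["bouts"] = p
    summary = report.get("summary", {})
    p = outdir / "summary.json"
    write_summary_json(summary, p)
    written["summary"] = p
    return written
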