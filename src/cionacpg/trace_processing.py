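"""Normalization, denoised differentiation and Ca2+ burst detection.

The burst definitions follow the derivative convention: the recording is
normalized to dF/F0, differentiated, and Savitzky-Golay filtered; bursts
are found as prominent peaks of this denoised derivative.  A burst's
*onset* is where the derivative last rose from zero before the peak, its
*offset* where the derivative first returns up to zero after the
subsequent negative lobe, its *duration* the offset-onset span, and its
*peak time* the fluorescence maximum between onset and offset.
Inter-burst intervals are peak-to-peak differences; a burst lasting more
than 30 s is flagged long.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .io_formats import FluorescenceTrace
from .synthetic_data import LONG_BURST_THRESHOLD


@dataclass
class BurstEvent:
    """One detected Ca2+ burst on one channel."""

    channel: str
    peak_time: float
    onset_time: float
    offset_time: float
    peak_dff: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_time <= self.peak_time <= self.offset_time):
            raise ValueError("need onset <= peak <= offset")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time

    @property
    def is_long(self) -> bool:
        """Long burst: duration above 30 s."""
        return self.duration > LONG_BURST_THRESHOLD


@dataclass
class BurstTrain:
    """Time-ordered bursts of one channel with derived intervals."""

    channel: str
    events: list[BurstEvent]

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.peak_time)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_time for e in self.events])

    @property
    def intervals(self) -> np.ndarray:
        """Consecutive peak-to-peak differences (empty if < 2 events)."""
        return np.diff(self.peak_times)

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class IntervalSummary:
    """Summary statistics of a train's inter-burst intervals."""

    n_intervals: int
    mean: float
    cv: float
    defined: bool


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_dff(trace: FluorescenceTrace, baseline_method: str = "rolling_percentile",
                window: float = 120.0, percentile: float = 10.0) -> FluorescenceTrace:
    """Normalize a raw trace to relative fluorescence dF/F0 = (F - F0)/F0.

    Parameters
    ----------
    baseline_method
        ``"rolling_percentile"`` (default): F0 is a centered rolling
        percentile, which tracks slow drift while ignoring bursts;
        ``"global_percentile"``: a single percentile of the whole series.
    window
        Rolling window length in seconds.  It must comfortably exceed the
        longest burst so that at least the stated percentile of each
        window is burst-free baseline.
    percentile
        Percentile used as baseline (default 10).
    """
    if trace.normalized:
        raise ValueError("trace is already normalized")
    channels: dict[str, np.ndarray] = {}
    for name, f in trace.channels.items():
        if baseline_method == "rolling_percentile":
            f0 = _rolling_percentile(f, int(round(window / trace.frame_interval)),
                                     percentile)
        elif baseline_method == "global_percentile":
            f0 = np.full_like(f, np.percentile(f, percentile))
        else:
            raise ValueError(f"unknown baseline_method {baseline_method!r}")
        if np.any(f0 <= 0):
            raise ValueError(f"non-positive baseline F0 in channel {name!r}")
        channels[name] = (f - f0) / f0
    return FluorescenceTrace(times=trace.times.copy(), channels=channels,
                             frame_interval=trace.frame_interval, normalized=True)


def _rolling_percentile(x: np.ndarray, win: int, percentile: float) -> np.ndarray:
    win = max(3, min(win, x.size))
    if win % 2 == 0:
        win += 1
    half = win // 2
    padded = np.pad(x, half, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, win)
    return np.percentile(view, percentile, axis=1)


# ---------------------------------------------------------------------------
# denoised derivative
# ---------------------------------------------------------------------------

def denoised_derivative(trace: FluorescenceTrace, sg_window: int = 7,
                        sg_order: int = 3) -> dict[str, np.ndarray]:
    """Savitzky-Golay smoothed first derivative of each dF/F0 channel.

    Implemented with the filter's fused first-derivative kernel
    (``deriv=1``), which on polynomial inputs agrees with
    difference-then-smooth to numerical precision.  Units: dF/F0 per
    second.
    """
    if not trace.normalized:
        raise ValueError("derivative expects a normalized (dF/F0) trace")
    _validate_sg(trace.n_frames, sg_window, sg_order)
    return {name: savgol_filter(x, sg_window, sg_order, deriv=1,
                                delta=trace.frame_interval, mode="interp")
            for name, x in trace.channels.items()}


def difference_then_smooth(trace: FluorescenceTrace, sg_window: int = 7,
                           sg_order: int = 3) -> dict[str, np.ndarray]:
    """Two-step variant (central difference, then SG smoothing).

    Kept as an internal cross-check of :func:`denoised_derivative`.
    """
    if not trace.normalized:
        raise ValueError("derivative expects a normalized (dF/F0) trace")
    _validate_sg(trace.n_frames, sg_window, sg_order)
    out = {}
    for name, x in trace.channels.items():
        d = np.gradient(x, trace.frame_interval)
        out[name] = savgol_filter(d, sg_window, sg_order, mode="interp")
    return out


def _validate_sg(n: int, sg_window: int, sg_order: int) -> None:
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    if sg_window > n:
        raise ValueError("sg_window longer than the series")


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------

def robust_noise_scale(x: np.ndarray) -> float:
    """MAD-based noise scale (consistent with sigma for Gaussian noise)."""
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def detect_bursts(derivative: np.ndarray, trace: FluorescenceTrace,
                  channel: str, prominence_k: float = 4.0,
                  min_separation: float = 2.0) -> BurstTrain:
    """Detect bursts of one channel from its denoised derivative.

    Candidate peaks on the derivative must reach both prominence and
    height ``prominence_k`` times the MAD noise scale of the derivative
    (the height gate suppresses noise peaks whose prominence is inflated
    by sub-zero bases; a genuine burst onset rises from ~0, so its
    height matches its prominence).  Each accepted derivative peak is
    mapped to an event: onset at the last rise of the derivative from
    zero before the peak, offset at the first return up to zero after
    the subsequent negative lobe, with a hysteresis band of 0.1 noise
    scales around zero.  Derivative peaks closer than ``min_separation``
    are merged keeping the larger (earlier onset, later offset).  Events
    whose onset or offset hits the recording boundary are flagged
    truncated.
    """
    d = np.asarray(derivative, dtype=float)
    x = trace.channels[channel]
    if d.shape != x.shape:
        raise ValueError("derivative and trace lengths differ")
    dt = trace.frame_interval
    scale = robust_noise_scale(d)
    ref = float(np.max(d)) if np.any(d > 0) else 0.0
    if ref <= 0:
        return BurstTrain(channel=channel, events=[])
    # relative floors keep the detector meaningful on (near-)noiseless
    # input, where the MAD scale collapses to ~0 and the smoothing
    # filter's tiny ripple sidelobes would otherwise count as peaks
    thr = max(prominence_k * scale, 0.05 * ref)
    eps = max(0.1 * scale, 1e-3 * ref)

    peaks, _ = find_peaks(d, height=thr, prominence=thr)
    if peaks.size == 0:
        return BurstTrain(channel=channel, events=[])
    peaks = _merge_close_peaks(d, peaks, int(round(min_separation / dt)))

    windows: list[list] = []
    for k, p in enumerate(peaks):
        nxt = peaks[k + 1] if k + 1 < peaks.size else d.size
        onset_i, trunc_l = _onset_index(d, p, eps)
        offset_i, trunc_r = _offset_index(d, p, nxt, eps)
        if offset_i <= onset_i:
            continue
        windows.append([onset_i, offset_i, trunc_l or trunc_r, p])
    # Overlapping windows: if no significant decay separates the two
    # derivative peaks, the later peak is part of the same burst (e.g. a
    # noise peak on a long plateau) -> merge, keeping the earlier onset and
    # later offset.  If a decay lobe does lie between them, they are two
    # bursts whose fluorescence overlaps -> split at the derivative minimum.
    merged: list[list] = []
    for w in windows:
        if merged and w[0] <= merged[-1][1]:
            prev = merged[-1]
            between = d[prev[3]:w[3] + 1]
            if between.size == 0 or np.min(between) > -0.5 * thr:
                prev[1] = max(prev[1], w[1])
                prev[2] = prev[2] or w[2]
                prev[3] = w[3]
                continue
            cut = prev[3] + int(np.argmin(between))
            prev[1] = min(prev[1], cut)
            w[0] = max(w[0], cut)
            merged.append(w)
        else:
            merged.append(w)

    # a genuine transient must also rise above the fluorescence noise:
    # require the dF/F gain from the onset sample within a short window
    # after onset (the indicator rise completes within a few rise time
    # constants) to clear rise_k noise scales.  The onset sits on a local
    # trough by construction (a positive derivative lobe follows a dip),
    # which rise_k = 6 absorbs with margin.
    rise_k = 6.0
    rise_gate = rise_k * robust_noise_scale(x)
    look = max(1, int(round(5.0 / dt)))

    events: list[BurstEvent] = []
    for onset_i, offset_i, trunc, _ in merged:
        if offset_i <= onset_i:
            continue
        early = x[onset_i:min(onset_i + look, offset_i) + 1]
        if float(early.max()) - x[onset_i] < rise_gate:
            continue
        seg = x[onset_i:offset_i + 1]
        # peak time = end of the sustained-maximum region.  A saturating
        # burst is flat at its plateau (exactly flat when noiseless, flat
        # to within the noise otherwise), so the raw argmax lands wherever
        # the noise happens to peak; the last sample still within one
        # noise scale of the maximum pins the peak to the plateau end,
        # which is the physical maximum of the underlying transient.
        smax = float(seg.max())
        tie_band = max(robust_noise_scale(x), 1e-12 * max(abs(smax), 1.0))
        top = np.flatnonzero(seg >= smax - tie_band)
        peak_i = onset_i + int(top[-1])
        events.append(BurstEvent(
            channel=channel,
            peak_time=float(trace.times[peak_i]),
            onset_time=float(trace.times[onset_i]),
            offset_time=float(trace.times[offset_i]),
            peak_dff=smax,
            truncated=trunc,
        ))
    return BurstTrain(channel=channel, events=events)


def _merge_close_peaks(d: np.ndarray, peaks: np.ndarray,
                       min_sep_frames: int) -> np.ndarray:
    """Greedily drop the smaller of any pair closer than ``min_sep_frames``."""
    if peaks.size <= 1 or min_sep_frames <= 0:
        return peaks
    order = np.argsort(d[peaks])[::-1]  # largest first
    kept: list[int] = []
    for i in order:
        p = peaks[i]
        if all(abs(p - q) >= min_sep_frames for q in kept):
            kept.append(p)
    return np.sort(np.asarray(kept))


def _onset_index(d: np.ndarray, peak: int, eps: float) -> tuple[int, bool]:
    """Last index before the derivative peak where the derivative is <= eps."""
    below = np.flatnonzero(d[:peak + 1] <= eps)
    if below.size == 0:
        return 0, True
    return int(below[-1]), False


def _offset_index(d: np.ndarray, peak: int, next_peak: int,
                  eps: float) -> tuple[int, bool]:
    """First return of the derivative up to -eps after the negative lobe.

    The burst's negative lobe is anchored at the derivative minimum
    between this peak and the next one (the indicator-decay trough),
    which keeps noise wiggles during a long plateau from being mistaken
    for the decay.
    """
    n = d.size
    at_boundary = next_peak >= n
    if next_peak <= peak + 1:
        return min(peak + 1, n - 1), at_boundary
    lobe = peak + 1 + int(np.argmin(d[peak + 1:next_peak]))
    if d[lobe] > -eps:  # no decay lobe found before the next peak
        return next_peak - 1, at_boundary
    rec = np.flatnonzero(d[lobe:next_peak] >= -eps)
    if rec.size == 0:
        return next_peak - 1, at_boundary
    return lobe + int(rec[0]), False


def compute_intervals(train: BurstTrain) -> tuple[np.ndarray, IntervalSummary]:
    """Peak-to-peak intervals and their summary statistics.

    With fewer than two events the interval list is empty and the summary
    is flagged undefined.
    """
    iv = train.intervals
    if iv.size == 0:
        return iv, IntervalSummary(0, float("nan"), float("nan"), defined=False)
    mean = float(np.mean(iv))
    cv = float(np.std(iv, ddof=1) / mean) if iv.size > 1 and mean > 0 else 0.0
    return iv, IntervalSummary(int(iv.size), mean, cv, defined=True)


def detect_all_channels(trace: FluorescenceTrace, sg_window: int = 7,
                        sg_order: int = 3, prominence_k: float = 4.0,
                        min_separation: float = 2.0,
                        channel_map: dict[str, str] | None = None
                        ) -> dict[str, BurstTrain]:
    """dF/F0-normalized trace -> per-channel burst trains.

    ``channel_map`` renames trace columns to train channel ids (default:
    ``mn2l -> L``, ``mn2r -> R``, otherwise the column name itself).
    """
    derivs = denoised_derivative(trace, sg_window, sg_order)
    channel_map = channel_map or {"mn2l": "L", "mn2r": "R"}
    trains: dict[str, BurstTrain] = {}
    for col, d in derivs.items():
        train = detect_bursts(d, trace, col, prominence_k, min_separation)
        cid = channel_map.get(col, col)
        for ev in train.events:
            ev.channel = cid
        trains[cid] = BurstTrain(channel=cid, events=train.events)
    return trains
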