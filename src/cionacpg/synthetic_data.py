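"""Synthetic two-channel burst oscillators, GCaMP read-out and tail tracks.

The generator emulates the statistical structure of dual-channel Ca2+
recordings from the bilateral MN2 motor-neuron pair during *Ciona*
development: renewal burst trains whose inter-burst intervals move from
sporadic, through a ~40 s constant regime, to synchronized 55 s and 85 s
regimes with occasional long (>30 s) bursts; a double-exponential
calcium-indicator read-out (rise saturating during the burst, first-order
decay at rate ``k_off`` afterwards); additive Gaussian noise; and tail
flick / swim trajectories of three tracked midline points.

Ground-truth event trains are returned alongside every rendered trace so
detection and classification can be scored against them.  All samplers
take explicit seeds; an identical seed yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import BODYPARTS, FluorescenceTrace, MidlineTrack

#: burst duration above which a burst counts as "long" (seconds).
LONG_BURST_THRESHOLD = 30.0

PHASE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII")

#: shortest allowed inter-burst interval (seconds): a refractory floor so
#: consecutive bursts never fuse; negligible for the >= 40 s interval regimes.
MIN_INTERVAL = 5.0


@dataclass(frozen=True)
class PhaseParams:
    """Statistical description of one developmental phase of the oscillator.

    Parameters
    ----------
    label
        Phase identifier, one of ``I`` .. ``VII``.
    mean_interval
        Mean inter-burst interval of the right channel, seconds.
    interval_cv
        Coefficient of variation of intervals (gamma renewal process).
    coupling_prob
        Probability that a right-channel burst spawns a synchronous
        left-channel burst; 0 = independent channels, 1 = full synchrony.
    sync_jitter_sd
        SD (seconds) of the Gaussian timing jitter of coupled left bursts.
    long_burst_prob
        Per-event probability of a long (> 30 s) burst.
    long_burst_duration_range
        ``(lo, hi)`` seconds, uniform draw for long-burst durations; both
        ends must exceed :data:`LONG_BURST_THRESHOLD`.
    short_duration_mean, short_duration_cv
        Gamma parameters of ordinary burst durations, seconds.
    onset_drift
        Optional linear drift of the mean interval (seconds per second of
        recording); 0 disables it.
    """

    label: str
    mean_interval: float
    interval_cv: float
    coupling_prob: float
    sync_jitter_sd: float = 0.5
    long_burst_prob: float = 0.0
    long_burst_duration_range: tuple[float, float] = (31.0, 45.0)
    short_duration_mean: float = 5.0
    short_duration_cv: float = 0.3
    onset_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_interval <= 0:
            raise ValueError("mean_interval must be positive")
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ValueError("coupling_prob must lie in [0, 1]")
        if self.interval_cv < 0:
            raise ValueError("interval_cv must be non-negative")
        lo, hi = self.long_burst_duration_range
        if lo <= LONG_BURST_THRESHOLD or hi < lo:
            raise ValueError("long-burst durations must exceed "
                             f"{LONG_BURST_THRESHOLD} s and be ordered")


@dataclass(frozen=True)
class KernelParams:
    """Calcium-indicator read-out parameters.

    ``k_off`` is the indicator decay rate in 1/s (decay time constant
    ``1/k_off``): 1.1 /s for GCaMP6s, 3.9 /s for GCaMP6f.  ``amplitude``
    values are in dF/F0 units, ``baseline`` in raw intensity units.
    """

    rise_tau: float = 0.5
    k_off: float = 1.1
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.1
    noise_sd: float = 0.05
    baseline: float = 100.0
    frame_interval: float = 0.2

    def __post_init__(self) -> None:
        if self.k_off <= 0:
            raise ValueError("k_off must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.rise_tau <= 0:
            raise ValueError("rise_tau must be positive")

    @property
    def decay_tau(self) -> float:
        return 1.0 / self.k_off


@dataclass
class EventTrain:
    """Ground-truth burst events of one channel.

    ``event_times`` are burst onsets (seconds, strictly increasing);
    ``event_durations`` the burst plateau lengths.  The rendered
    fluorescence peak of an event falls at ``onset + duration`` (the
    kernel rises monotonically until the plateau ends).
    """

    channel: str
    event_times: np.ndarray
    event_durations: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_durations = np.asarray(self.event_durations, dtype=float)
        if self.event_times.shape != self.event_durations.shape:
            raise ValueError("times and durations must have equal length")
        if self.event_times.size:
            if np.any(np.diff(self.event_times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if np.any(self.event_durations <= 0):
                raise ValueError("durations must be positive")

    @property
    def peak_times(self) -> np.ndarray:
        """Ground-truth fluorescence-peak times (plateau ends)."""
        return self.event_times + self.event_durations

    @property
    def n_events(self) -> int:
        return self.event_times.size


# ---------------------------------------------------------------------------
# phase default registry
# ---------------------------------------------------------------------------
# Mean intervals for the regular regimes are the reported values (40 s for
# the convergent II-IV regime, 55 s for V, 85 s for VI); dispersions,
# coupling probabilities and burst-duration parameters are documented
# package defaults chosen to reproduce the qualitative regime descriptions
# (sporadic vs constant, "rarely" vs fully synchronized).

_PHASE_DEFAULTS: dict[str, PhaseParams] = {
    "I": PhaseParams("I", mean_interval=40.0, interval_cv=0.8,
                     coupling_prob=0.0),
    "II": PhaseParams("II", mean_interval=40.0, interval_cv=0.35,
                      coupling_prob=0.0),
    "III": PhaseParams("III", mean_interval=40.0, interval_cv=0.10,
                       coupling_prob=0.0),
    "IV": PhaseParams("IV", mean_interval=40.0, interval_cv=0.10,
                      coupling_prob=0.4),
    "V": PhaseParams("V", mean_interval=55.0, interval_cv=0.10,
                     coupling_prob=1.0, sync_jitter_sd=0.5),
    "VI": PhaseParams("VI", mean_interval=85.0, interval_cv=0.10,
                      coupling_prob=1.0, sync_jitter_sd=0.5,
                      long_burst_prob=0.10),
    "VII": PhaseParams("VII", mean_interval=70.0, interval_cv=0.70,
                       coupling_prob=1.0, sync_jitter_sd=1.0,
                       long_burst_prob=0.10),
}


def phase_defaults(label: str) -> PhaseParams:
    """Return the default :class:`PhaseParams` for one phase label (I..VII)."""
    try:
        return _PHASE_DEFAULTS[label]
    except KeyError:
        raise ValueError(f"unknown phase label {label!r}; "
                         f"expected one of {', '.join(PHASE_LABELS)}") from None


# ---------------------------------------------------------------------------
# event-train sampling
# ---------------------------------------------------------------------------

def _gamma_intervals(rng: np.random.Generator, n: int, mean: float,
                     cv: float) -> np.ndarray:
    """Draw ``n`` renewal intervals: gamma with the stated mean and CV."""
    if cv == 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    scale = mean * cv**2
    draw = rng.gamma(shape, scale, size=n)
    return np.maximum(draw, MIN_INTERVAL)


def _renewal_times(rng: np.random.Generator, span: float, mean: float,
                   cv: float, drift: float) -> np.ndarray:
    """Event onset times of a gamma renewal process over ``[0, span)``."""
    times = []
    t = float(_gamma_intervals(rng, 1, mean, cv)[0])
    while t < span:
        times.append(t)
        local_mean = max(MIN_INTERVAL, mean + drift * t)
        t += float(_gamma_intervals(rng, 1, local_mean, cv)[0])
    return np.asarray(times)


def _sample_durations(rng: np.random.Generator, n: int,
                      params: PhaseParams) -> np.ndarray:
    cv = params.short_duration_cv
    shape = 1.0 / cv**2 if cv > 0 else None
    if shape is None:
        dur = np.full(n, params.short_duration_mean)
    else:
        dur = rng.gamma(shape, params.short_duration_mean * cv**2, size=n)
        dur = np.clip(dur, 0.5, LONG_BURST_THRESHOLD - 1.0)
    if params.long_burst_prob > 0 and n:
        is_long = rng.random(n) < params.long_burst_prob
        lo, hi = params.long_burst_duration_range
        dur[is_long] = rng.uniform(lo, hi, size=int(is_long.sum()))
    return dur


def _clip_durations(times: np.ndarray, durations: np.ndarray,
                    span: float) -> np.ndarray:
    """Keep bursts from overlapping the next one (1 s guard) or the end."""
    if times.size == 0:
        return durations
    gap_next = np.append(np.diff(times), span - times[-1])
    return np.minimum(durations, np.maximum(1.0, gap_next - 1.0))


def sample_event_trains(params: PhaseParams, span: float,
                        rng_seed: int) -> tuple[EventTrain, EventTrain]:
    """Sample coupled left/right ground-truth burst trains over ``[0, span)``.

    The right channel is a gamma renewal process with the requested
    mean/CV.  Each right event spawns a coincident left event (timing
    jittered by ``Normal(0, sync_jitter_sd)`` and sharing the right
    event's duration — a synchronized burst is one episode seen by both
    cells) with probability ``coupling_prob``; right cycles that stay
    uncoupled are filled from an independent left renewal process with
    the same marginal parameters.

    Returns ``(left, right)`` event trains.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    rng = np.random.default_rng(_check_seed(rng_seed))
    r_times = _renewal_times(rng, span, params.mean_interval,
                             params.interval_cv, params.onset_drift)
    r_dur = _clip_durations(r_times, _sample_durations(rng, r_times.size, params),
                            span)

    coupled = rng.random(r_times.size) < params.coupling_prob
    l_coupled_times = r_times[coupled] + rng.normal(
        0.0, params.sync_jitter_sd, size=int(coupled.sum()))
    l_coupled_dur = r_dur[coupled]

    # independent left renewal filling the uncoupled cycles
    l_indep_times = _renewal_times(rng, span, params.mean_interval,
                                   params.interval_cv, params.onset_drift)
    l_indep_dur = _sample_durations(rng, l_indep_times.size, params)
    if r_times.size:
        cycle = np.searchsorted(r_times, l_indep_times, side="right") - 1
        in_uncoupled = np.ones(l_indep_times.size, dtype=bool)
        valid = cycle >= 0
        in_uncoupled[valid] = ~coupled[cycle[valid]]
        # the pre-first-R stretch follows the first cycle's coupling state
        in_uncoupled[~valid] = ~coupled[0] if coupled.size else True
        l_indep_times = l_indep_times[in_uncoupled]
        l_indep_dur = l_indep_dur[in_uncoupled]

    l_times = np.concatenate([l_coupled_times, l_indep_times])
    l_dur = np.concatenate([l_coupled_dur, l_indep_dur])
    order = np.argsort(l_times)
    l_times, l_dur = l_times[order], l_dur[order]
    keep = (l_times > 0) & (l_times < span)
    if l_times.size:  # enforce the refractory floor on the merged train
        sep = np.append(True, np.diff(l_times) >= MIN_INTERVAL)
        keep &= sep
    l_times, l_dur = l_times[keep], l_dur[keep]
    l_dur = _clip_durations(l_times, l_dur, span)

    left = EventTrain("L", l_times, l_dur)
    right = EventTrain("R", r_times, r_dur)
    return left, right


def _check_seed(seed: int) -> int:
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("rng_seed must be a non-negative integer")
    return int(seed)


# ---------------------------------------------------------------------------
# fluorescence rendering
# ---------------------------------------------------------------------------

def burst_kernel(t: np.ndarray, duration: float, kernel: KernelParams) -> np.ndarray:
    """Unit-amplitude burst waveform at times ``t`` after burst onset.

    Saturating rise ``1 - exp(-t/rise_tau)`` while the burst lasts, then
    first-order indicator decay ``exp(-k_off * (t - duration))`` from the
    level reached at the plateau end.  Zero outside the support.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= 0) & (t <= duration)
    out[rising] = 1.0 - np.exp(-t[rising] / kernel.rise_tau)
    peak = 1.0 - np.exp(-duration / kernel.rise_tau)
    decaying = t > duration
    out[decaying] = peak * np.exp(-kernel.k_off * (t[decaying] - duration))
    return out


def render_trace(trains: Sequence[EventTrain], kernel: KernelParams,
                 span: float, rng_seed: int,
                 channel_names: Sequence[str] | None = None) -> FluorescenceTrace:
    """Render ground-truth event trains into a noisy fluorescence trace.

    Each event contributes an amplitude-scaled :func:`burst_kernel`;
    contributions sum; i.i.d. Gaussian noise (``noise_sd``, dF/F0 units)
    is added; the raw intensity is ``baseline * (1 + signal + noise)`` so
    that dF/F0 normalization recovers ``signal + noise``.
    """
    if kernel.frame_interval > span:
        raise ValueError("frame_interval must not exceed span")
    rng = np.random.default_rng(_check_seed(rng_seed))
    n = int(np.floor(span / kernel.frame_interval)) + 1
    times = np.arange(n) * kernel.frame_interval
    if channel_names is None:
        channel_names = ["mn2l" if tr.channel == "L" else "mn2r" for tr in trains]
    support = 10.0 / kernel.k_off  # decay tail rendered to <5e-5 of peak
    channels: dict[str, np.ndarray] = {}
    for train, name in zip(trains, channel_names):
        signal = np.zeros(n)
        if train.n_events:
            amps = _amplitudes(rng, train.n_events, kernel)
            for t0, dur, a in zip(train.event_times, train.event_durations, amps):
                i0 = max(0, int(np.ceil((t0 - times[0]) / kernel.frame_interval)))
                i1 = min(n, int(np.floor((t0 + dur + support) / kernel.frame_interval)) + 1)
                if i1 <= i0:
                    continue
                signal[i0:i1] += a * burst_kernel(times[i0:i1] - t0, dur, kernel)
        noise = (rng.normal(0.0, kernel.noise_sd, size=n)
                 if kernel.noise_sd > 0 else 0.0)
        channels[name] = kernel.baseline * (1.0 + signal + noise)
    return FluorescenceTrace(times=times, channels=channels,
                             frame_interval=kernel.frame_interval,
                             normalized=False)


def _amplitudes(rng: np.random.Generator, n: int,
                kernel: KernelParams) -> np.ndarray:
    if kernel.amplitude_cv == 0:
        return np.full(n, kernel.amplitude_mean)
    shape = 1.0 / kernel.amplitude_cv**2
    return rng.gamma(shape, kernel.amplitude_mean * kernel.amplitude_cv**2, size=n)


def simulate_phase_recording(
    label: str, span: float, rng_seed: int,
    kernel: KernelParams | None = None,
    params: PhaseParams | None = None,
) -> tuple[FluorescenceTrace, EventTrain, EventTrain]:
    """One-call convenience: sample trains for a phase and render them.

    Returns ``(trace, left_train, right_train)``.
    """
    params = params or phase_defaults(label)
    kernel = kernel or KernelParams()
    seed = _check_seed(rng_seed)
    left, right = sample_event_trains(params, span, seed)
    trace = render_trace([left, right], kernel, span, seed + 1)
    return trace, left, right


# ---------------------------------------------------------------------------
# tail trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TailGeometry:
    """Pixel geometry of the synthetic larva used to place the 3 body parts."""

    trunk_length: float = 100.0   # ocellus -> mid-tail, px
    tail_length: float = 120.0    # mid-tail -> tail tip, px
    coord_noise_sd: float = 0.3   # px, tracker-like jitter


def simulate_tail(bout_plan: Sequence[tuple], fps: float, rng_seed: int,
                  span: float | None = None,
                  etf_amplitude: float = 40.0,
                  swim_amplitude: float = 30.0,
                  geometry: TailGeometry | None = None) -> MidlineTrack:
    """Render a tail-movement plan into tracked three-point coordinates.

    ``bout_plan`` rows are ``(type, start_s, duration_s, frequency_hz)``
    with type in ``{"lETF", "rETF", "swim"}`` (frequency ignored for
    ETFs).  ETF bouts are single-signed half-sine bending excursions
    (left positive); swim bouts are sign-alternating sinusoids at the
    stated beat frequency with a short ramp envelope; elsewhere the tail
    is quiescent.  The ocellus sits at the origin, the mid-tail point at
    ``trunk_length`` along +x, and the tail tip is rotated about the
    mid-tail point by the bending angle, so the bending-angle series
    recomputed from the coordinates matches the generating series.
    """
    rng = np.random.default_rng(_check_seed(rng_seed))
    geometry = geometry or TailGeometry()
    plan = sorted(bout_plan, key=lambda b: b[1])
    for (t1, s1, d1, _), (t2, s2, d2, _) in zip(plan, plan[1:]):
        if s2 < s1 + d1:
            raise ValueError("overlapping bouts in plan")
    if span is None:
        span = (plan[-1][1] + plan[-1][2] + 1.0) if plan else 1.0
    n = int(round(span * fps)) + 1
    times = np.arange(n) / fps
    theta = np.zeros(n)  # bending angle, degrees, left positive
    for btype, start, duration, freq in plan:
        if duration <= 0:
            raise ValueError("bout duration must be positive")
        sel = (times >= start) & (times <= start + duration)
        tloc = times[sel] - start
        if btype in ("lETF", "rETF"):
            pulse = etf_amplitude * np.sin(np.pi * tloc / duration)
            theta[sel] = pulse if btype == "lETF" else -pulse
        elif btype == "swim":
            ramp_t = min(0.25, duration / 10.0)
            env = np.minimum(1.0, np.minimum(tloc, duration - tloc) / ramp_t)
            theta[sel] = swim_amplitude * env * np.sin(2 * np.pi * freq * tloc)
        else:
            raise ValueError(f"unknown bout type {btype!r}")

    a = np.zeros((n, 2))                                    # ocellus
    b = np.tile([geometry.trunk_length, 0.0], (n, 1))       # mid-tail
    ang = np.deg2rad(theta)
    c = b + geometry.tail_length * np.column_stack([np.cos(ang), np.sin(ang)])
    parts = {}
    for name, xy in zip(BODYPARTS, (a, b, c)):
        noisy = xy + rng.normal(0.0, geometry.coord_noise_sd, size=xy.shape)
        parts[name] = np.column_stack([noisy, np.ones(n)])
    return MidlineTrack(times=times, parts=parts, fps=fps)


# ---------------------------------------------------------------------------
# cohort / trial tables
# ---------------------------------------------------------------------------

#: observed right-first onset probability (13 of 17 embryos).
DEFAULT_P_RIGHT_FIRST = 13.0 / 17.0


def simulate_cohort(n_embryos: int, p_right_first: float = DEFAULT_P_RIGHT_FIRST,
                    rng_seed: int = 0) -> pd.DataFrame:
    """Per-embryo onset-laterality table (``embryo_id, first_onset``)."""
    if n_embryos <= 0:
        raise ValueError("n_embryos must be positive")
    if not 0.0 <= p_right_first <= 1.0:
        raise ValueError("p_right_first must lie in [0, 1]")
    rng = np.random.default_rng(_check_seed(rng_seed))
    right = rng.random(n_embryos) < p_right_first
    return pd.DataFrame({
        "embryo_id": [f"embryo{i:04d}" for i in range(n_embryos)],
        "first_onset": np.where(right, "R", "L"),
    })
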