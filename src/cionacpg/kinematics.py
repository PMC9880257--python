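"""Tail-movement quantification from three tracked midline points.

Curvature uses the three-point (Menger) form: the reciprocal circumradius
of the triangle through the start, middle and end of the midline,
``4 * Area(ABC) / (|AB| |BC| |CA|)``, signed by the z-component of the
cross product so a leftward bend is positive.  The bending angle at the
mid-tail point is 180 degrees minus the interior angle there, with the
same left-positive sign convention.  Movement epochs are segmented from
the bending-angle (or curvature) series, classified into unilateral
early tail flicks (lETF/rETF) versus left-right alternating swim bouts,
and swim beat frequency is estimated from zero crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import BODYPARTS, MidlineTrack
from .trace_processing import BurstTrain, robust_noise_scale

#: default likelihood below which a tracked frame is excluded.
LIKELIHOOD_MIN = 0.9


@dataclass
class Bout:
    """One movement episode: a unilateral flick or a swim bout."""

    type: str                   # "lETF", "rETF" or "swim"
    t_start: float
    t_end: float
    beat_frequency: float = float("nan")   # Hz, swim bouts only
    peak_abs_bend: float = float("nan")    # degrees (or curvature units)
    n_reversals: int = 0

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("bout must have positive duration")
        if self.type not in ("lETF", "rETF", "swim"):
            raise ValueError(f"unknown bout type {self.type!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def three_point_curvature(A, B, C) -> float | np.ndarray:
    """Signed three-point curvature (1/length units; left bend positive).

    Accepts single points (length-2) or ``(n, 2)`` stacks.  Magnitude is
    the reciprocal circumradius of triangle ABC (0 for collinear
    points); the sign follows the z-component of ``(B-A) x (C-B)``.
    Raises on coincident points.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    single = A.ndim == 1
    A, B, C = np.atleast_2d(A), np.atleast_2d(B), np.atleast_2d(C)
    ab = np.linalg.norm(B - A, axis=1)
    bc = np.linalg.norm(C - B, axis=1)
    ca = np.linalg.norm(A - C, axis=1)
    if np.any(ab == 0) or np.any(bc == 0) or np.any(ca == 0):
        raise ValueError("coincident points have no defined curvature")
    u, v = B - A, C - B
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]   # 2 * signed area
    kappa = 2.0 * cross / (ab * bc * ca)
    return float(kappa[0]) if single else kappa


def bending_angle(track: MidlineTrack,
                  likelihood_min: float = LIKELIHOOD_MIN) -> np.ndarray:
    """Signed tail bending angle (degrees) per frame; straight tail = 0.

    The angle is 180 degrees minus the interior angle at the mid-tail
    point between the segments to the ocellus and to the tail tip,
    signed left-positive.  Frames with any body-part likelihood below
    ``likelihood_min``, or with coincident points, are NaN.
    """
    a = track.coords("bodypart1")
    b = track.coords("bodypart2")
    c = track.coords("bodypart3")
    u, v = b - a, c - b
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = np.einsum("ij,ij->i", u, v)
    theta = np.degrees(np.arctan2(cross, dot))
    bad = np.zeros(track.n_frames, dtype=bool)
    for bp in BODYPARTS:
        bad |= track.likelihood(bp) < likelihood_min
    bad |= (np.linalg.norm(u, axis=1) == 0) | (np.linalg.norm(v, axis=1) == 0)
    theta = theta.astype(float)
    theta[bad] = np.nan
    return theta


def curvature_series(track: MidlineTrack,
                     likelihood_min: float = LIKELIHOOD_MIN) -> np.ndarray:
    """Signed three-point curvature per frame (NaN on flagged frames)."""
    a = track.coords("bodypart1")
    b = track.coords("bodypart2")
    c = track.coords("bodypart3")
    out = three_point_curvature(a, b, c)
    bad = np.zeros(track.n_frames, dtype=bool)
    for bp in BODYPARTS:
        bad |= track.likelihood(bp) < likelihood_min
    out = np.asarray(out, dtype=float)
    out[bad] = np.nan
    return out


# ---------------------------------------------------------------------------
# bout segmentation
# ---------------------------------------------------------------------------

def segment_bouts(signal: np.ndarray, fps: float,
                  threshold: float | None = None,
                  min_duration: float = 0.05,
                  merge_gap: float = 0.3,
                  min_swim_reversals: int = 3,
                  min_swim_rate: float = 3.0) -> list[Bout]:
    """Segment a bending-angle (or curvature) series into movement bouts.

    Movement epochs are runs where ``|signal|`` exceeds ``threshold``
    (default 3x the MAD noise scale of the series) lasting at least
    ``min_duration`` seconds; epochs separated by less than ``merge_gap``
    are merged (an alternating swim dips through zero every half beat).
    An epoch is a swim bout when it contains at least
    ``min_swim_reversals`` sign reversals at a rate of at least
    ``min_swim_rate`` Hz; otherwise it is an ETF whose side is the sign
    of its extreme deflection (left positive -> lETF).
    """
    x = np.asarray(signal, dtype=float)
    finite = np.isfinite(x)
    work = np.where(finite, x, 0.0)
    if threshold is None:
        scale = robust_noise_scale(work[finite]) if finite.any() else 0.0
        threshold = 3.0 * scale if scale > 0 else 1e-9
    active = np.abs(work) > threshold
    runs = _runs(active)
    # discard sub-resolution flickers (single-frame noise spikes) before
    # gap-merging, so sparse noise cannot be bridged into a phantom bout
    min_active = max(1, int(round(0.01 * fps)))
    runs = [(a, b) for a, b in runs if b - a >= min_active]
    runs = _merge_runs(runs, int(round(merge_gap * fps)))
    min_frames = max(1, int(round(min_duration * fps)))
    bouts: list[Bout] = []
    for i0, i1 in runs:
        if i1 - i0 < min_frames:
            continue
        seg = work[i0:i1]
        t0, t1 = i0 / fps, i1 / fps
        n_rev = _count_reversals(seg, deadband=threshold / 2.0)
        duration = t1 - t0
        rate = n_rev / duration if duration > 0 else 0.0
        peak = float(np.max(np.abs(seg)))
        if n_rev >= min_swim_reversals and rate >= min_swim_rate:
            freq = _freq_from_reversals(n_rev, duration)
            bouts.append(Bout("swim", t0, t1, beat_frequency=freq,
                              peak_abs_bend=peak, n_reversals=n_rev))
        else:
            side = "lETF" if seg[np.argmax(np.abs(seg))] > 0 else "rETF"
            bouts.append(Bout(side, t0, t1, peak_abs_bend=peak,
                              n_reversals=n_rev))
    return bouts


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True."""
    if not mask.any():
        return []
    padded = np.r_[0, mask.view(np.int8), 0]
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[::2], edges[1::2]))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for i0, i1 in runs[1:]:
        if i0 - merged[-1][1] <= max_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    return [(a, b) for a, b in merged]


def _count_reversals(seg: np.ndarray, deadband: float) -> int:
    """Sign reversals of ``seg`` ignoring excursions inside the deadband."""
    signs = np.sign(seg[np.abs(seg) > deadband])
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


def _freq_from_reversals(n_reversals: int, duration: float) -> float:
    # one full alternation cycle = two sign reversals
    return (n_reversals / 2.0) / duration


def beat_frequency(bout: Bout, signal: np.ndarray, fps: float,
                   deadband: float | None = None) -> float:
    """Beat frequency (Hz) of a swim bout from zero-crossing count.

    ``signal`` is the full series the bout was segmented from.  Raises
    for non-swim bouts or fewer than 3 reversals.
    """
    if bout.type != "swim":
        raise ValueError("beat frequency is defined for swim bouts only")
    i0, i1 = int(round(bout.t_start * fps)), int(round(bout.t_end * fps))
    seg = np.asarray(signal, dtype=float)[i0:i1]
    seg = seg[np.isfinite(seg)]
    if deadband is None:
        deadband = 0.1 * np.max(np.abs(seg)) if seg.size else 0.0
    n_rev = _count_reversals(seg, deadband)
    if n_rev < 3:
        raise ValueError("insufficient sign reversals for a beat frequency")
    return _freq_from_reversals(n_rev, bout.duration)


# ---------------------------------------------------------------------------
# burst / behaviour co-occurrence
# ---------------------------------------------------------------------------

def cooccurrence(bouts: Sequence[Bout], trains: dict[str, BurstTrain],
                 max_lag: float = 2.0) -> dict[str, dict[str, int]]:
    """Contingency of bout types versus burst channels.

    Each bout is assigned per channel when it overlaps a burst's
    onset-offset window widened by ``max_lag`` seconds; the output maps
    bout type to counts over ``{"L-only", "R-only", "both", "neither"}``.
    """
    table: dict[str, dict[str, int]] = {}
    for bout in bouts:
        hit = {}
        for chan in ("L", "R"):
            train = trains.get(chan)
            hit[chan] = bool(train) and any(
                ev.onset_time - max_lag <= bout.t_end
                and bout.t_start <= ev.offset_time + max_lag
                for ev in train.events)
        if hit["L"] and hit["R"]:
            cat = "both"
        elif hit["L"]:
            cat = "L-only"
        elif hit["R"]:
            cat = "R-only"
        else:
            cat = "neither"
        row = table.setdefault(bout.type, {"L-only": 0, "R-only": 0,
                                           "both": 0, "neither": 0})
        row[cat] += 1
    return table
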