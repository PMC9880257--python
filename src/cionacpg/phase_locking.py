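"""Cycle-anchored circular phase analysis of the bilateral burst rhythm.

Each left-channel burst peak is assigned a phase within the right-channel
cycle that contains it: the right peak starting the cycle is 0 degrees,
the next right peak 360 degrees, and angles are wrapped to the signed
range (-180, 180].  The Rayleigh test of circular uniformity then
summarizes how tightly the left bursts lock to the right rhythm: the
mean resultant length R is 0 for uniform phases and 1 for perfect
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace_processing import BurstTrain


@dataclass
class CircularPhaseResult:
    """Result of the Rayleigh test on cycle-anchored phases.

    ``angles`` are signed degrees in (-180, 180]; ``resultant_R`` the
    mean resultant vector length in [0, 1]; ``mean_angle`` the circular
    mean in degrees (NaN, with ``mean_defined`` False, when R = 0);
    ``rayleigh_p`` the uniformity p-value.
    """

    angles: np.ndarray
    n: int
    mean_angle: float
    resultant_R: float
    rayleigh_p: float
    mean_defined: bool = True

    def summary(self) -> dict:
        return {"n": self.n, "mean_deg": self.mean_angle,
                "R": self.resultant_R, "p": self.rayleigh_p}


def wrap_signed(angles_deg: np.ndarray) -> np.ndarray:
    """Wrap degrees into the signed convention (-180, 180]."""
    a = np.asarray(angles_deg, dtype=float) % 360.0
    return np.where(a > 180.0, a - 360.0, a)


def assign_cycle_phases(train_L: BurstTrain, train_R: BurstTrain,
                        signed: bool = True) -> tuple[np.ndarray, int]:
    """Phase angle of each left peak within its right-channel cycle.

    A left peak at time t with consecutive right peaks t_i <= t < t_{i+1}
    maps to ``360 * (t - t_i) / (t_{i+1} - t_i)`` degrees; a left peak
    exactly at a right peak belongs to the cycle it starts (0 degrees).
    Left peaks before the first or at/after the last right peak are
    discarded.  Returns ``(angles, n_discarded)``; angles signed in
    (-180, 180] by default, raw [0, 360) with ``signed=False``.
    """
    r = train_R.peak_times
    if r.size < 2:
        raise ValueError("need at least 2 right-channel events to define cycles")
    l = train_L.peak_times
    idx = np.searchsorted(r, l, side="right") - 1
    keep = (idx >= 0) & (l < r[-1])
    n_discarded = int((~keep).sum())
    l, idx = l[keep], idx[keep]
    t0, t1 = r[idx], r[idx + 1]
    raw = 360.0 * (l - t0) / (t1 - t0)
    return (wrap_signed(raw) if signed else raw), n_discarded


def rayleigh_test(angles_deg: np.ndarray) -> CircularPhaseResult:
    """Rayleigh test of circular uniformity on angles in degrees.

    R = |sum exp(i theta)| / n; the p-value uses the classical
    small-sample approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` with Rn = nR.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    n = angles_deg.size
    if n == 0:
        raise ValueError("empty angle list")
    z = np.exp(1j * np.deg2rad(angles_deg))
    mean_vec = z.mean()
    R = float(np.abs(mean_vec))
    if R > 1e-12:  # below numerical zero the direction is meaningless
        mean_angle = float(wrap_signed(np.rad2deg(np.angle(mean_vec))))
        mean_defined = True
    else:
        mean_angle, mean_defined = float("nan"), False
    Rn = n * R
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - Rn**2)) - (1.0 + 2.0 * n)))
    return CircularPhaseResult(angles=angles_deg, n=n, mean_angle=mean_angle,
                               resultant_R=R, rayleigh_p=min(p, 1.0),
                               mean_defined=mean_defined)


def rayleigh_p(R: np.ndarray, n: int) -> np.ndarray:
    """Vectorized Rayleigh p-value for resultant lengths ``R`` at size ``n``."""
    Rn = n * np.asarray(R, dtype=float)
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - Rn**2)) - (1.0 + 2.0 * n))
    return np.minimum(p, 1.0)


def circular_histogram(angles_deg: np.ndarray, n_bins: int = 18
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Bin counts over an equal partition of (-180, 180].

    Returns ``(counts, edges)`` with ``len(edges) = n_bins + 1``; the
    counts sum to the number of angles.  Bins are half-open ``(lo, hi]``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    angles = wrap_signed(np.asarray(angles_deg, dtype=float))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # (lo, hi] convention: find the right edge index; angle == edge goes left
    idx = np.searchsorted(edges, angles, side="left") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts, edges
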