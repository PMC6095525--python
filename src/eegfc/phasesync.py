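"""Instantaneous phases and pairwise phase-synchronisation indices.

Phases come from the analytic signal: theta(t) = arg(x(t) + j * H[x](t)),
with H the Hilbert transform; the first/last half second of each segment is
excluded to suppress filter/Hilbert boundary transients.  Two indices are
computed from the relative phase of a channel pair:

* PLV = |<exp(j * phi)>|  — 1 for a constant relative phase, 0 for a
  uniformly distributed one.  Sensitive to zero-lag (volume-conduction-like)
  coupling.
* PLI = |<sign(sin(phi))>| with sign(0) = -1 — blind to relative-phase
  distributions symmetric around 0 or pi, hence robust to zero-lag mixing.

Subject-level matrices average the per-segment index over the selected
segments; diagonals are fixed at 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import (
    ConfigurationError,
    ConnectivityMatrix,
    InsufficientDataError,
    Segment,
    UndefinedPhaseError,
)

__all__ = [
    "PhaseSeries",
    "analytic_phase",
    "relative_phase",
    "relative_phase_signed",
    "plv",
    "pli",
    "connectivity",
]

#: Seconds trimmed from each end of a segment before averaging.
EDGE_SECONDS = 0.5


@dataclass
class PhaseSeries:
    """Wrapped instantaneous phases (channels x samples) with valid bounds."""

    phases: np.ndarray
    valid: tuple[int, int]
    fs: float

    @property
    def valid_phases(self) -> np.ndarray:
        a, b = self.valid
        return self.phases[:, a:b]


def analytic_phase(band_segment: Segment,
                   edge_seconds: float = EDGE_SECONDS) -> PhaseSeries:
    """Instantaneous phase of each channel of a band-limited segment."""
    data = band_segment.data
    amp = np.max(np.abs(data), axis=1)
    dead = np.flatnonzero(amp < 1e-12)
    if dead.size:
        raise UndefinedPhaseError(
            f"channel {band_segment.channel_labels[dead[0]]!r} is all zero; "
            "its instantaneous phase is undefined"
        )
    theta = np.angle(hilbert(data, axis=1))
    E = int(round(edge_seconds * band_segment.fs))
    if 2 * E >= band_segment.n_samples:
        raise InsufficientDataError(
            f"segment of {band_segment.n_samples} samples too short for "
            f"{E}-sample edge exclusion"
        )
    return PhaseSeries(phases=theta, valid=(E, band_segment.n_samples - E),
                       fs=band_segment.fs)


def relative_phase(theta_i: np.ndarray, theta_l: np.ndarray) -> np.ndarray:
    """Relative phase wrapped to [0, 2*pi)."""
    theta_i = np.asarray(theta_i, dtype=float)
    theta_l = np.asarray(theta_l, dtype=float)
    if theta_i.shape != theta_l.shape:
        raise ConfigurationError("phase vectors must have equal length")
    u = np.mod(theta_i - theta_l, 2.0 * np.pi)
    u[u >= 2.0 * np.pi] = 0.0  # float rounding of mod for tiny negatives
    return u


def relative_phase_signed(theta_i: np.ndarray, theta_l: np.ndarray) -> np.ndarray:
    """Signed relative phase wrapped to (-pi, pi] (the PLI convention).

    The unsigned [0, 2*pi) form would bias sign(sin(phi)); the signed wrap
    preserves the lead/lag information PLI is built on.
    """
    d = relative_phase(theta_i, theta_l)
    d = d.copy()
    d[d > np.pi] -= 2.0 * np.pi
    return d


def plv(phi: np.ndarray) -> float:
    """Phase locking value of a relative-phase series."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise InsufficientDataError("empty relative-phase series")
    return float(np.abs(np.mean(np.exp(1j * phi))))


def pli(phi_signed: np.ndarray) -> float:
    """Phase lag index; sign(0) counts as -1."""
    phi_signed = np.asarray(phi_signed, dtype=float)
    if phi_signed.size == 0:
        raise InsufficientDataError("empty relative-phase series")
    s = np.where(np.sin(phi_signed) > 0.0, 1.0, -1.0)
    return float(np.abs(np.mean(s)))


def _segment_matrix(ps: PhaseSeries, index: str) -> np.ndarray:
    theta = ps.valid_phases
    n = theta.shape[0]
    out = np.eye(n)
    for i in range(n):
        for l in range(i + 1, n):
            if index == "PLV":
                val = plv(relative_phase(theta[i], theta[l]))
            else:
                val = pli(relative_phase_signed(theta[i], theta[l]))
            out[i, l] = out[l, i] = val
    return out


def connectivity(band_segments: list[Segment], index: str,
                 edge_seconds: float = EDGE_SECONDS) -> ConnectivityMatrix:
    """Subject-level matrix: mean of the per-segment index over segments."""
    if index not in ("PLV", "PLI"):
        raise ConfigurationError(f"unknown PS index {index!r}")
    if not band_segments:
        raise InsufficientDataError("need at least one segment")
    n = band_segments[0].n_channels
    for seg in band_segments:
        if seg.n_channels != n:
            raise ConfigurationError("inconsistent channel counts across segments")
    acc = np.zeros((n, n))
    for seg in band_segments:
        acc += _segment_matrix(analytic_phase(seg, edge_seconds), index)
    values = acc / len(band_segments)
    np.fill_diagonal(values, 1.0)
    first = band_segments[0]
    return ConnectivityMatrix(
        values=values, index=index, band="", condition=first.condition,
        subject_id=first.subject_id, channel_labels=first.channel_labels,
    )
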