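"""Segmentation, stationarity ranking and zero-phase band-pass filtering.

Recordings are cut into non-overlapping 20 s windows (5120 samples at
256 Hz), each linearly detrended and z-normalised per channel.  Segments are
ranked by the channel-averaged KPSS statistic (lower = more stationary) and
the ``k`` most stationary ones are analysed; a random selection serves as the
baseline.  Band-limiting uses an order-256 Hamming-window FIR applied
forward-backward, so the net phase response is exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import kpss as _kpss

from .core import (
    BandSpec,
    ConfigurationError,
    DegenerateChannelError,
    EegRecording,
    InsufficientDataError,
    Segment,
)

__all__ = [
    "StationarityScore",
    "segment_and_normalize",
    "kpss_average",
    "select_segments",
    "bandpass",
    "design_fir",
]

#: Default FIR filter order (taps = order + 1).
FIR_ORDER = 256


@dataclass(frozen=True)
class StationarityScore:
    """Per-channel KPSS statistics of one segment and their mean."""

    segment_index: int
    ks: tuple[float, ...]

    @property
    def ks_hat(self) -> float:
        return float(np.mean(self.ks))


def segment_and_normalize(recording: EegRecording,
                          seg_seconds: float = 20.0) -> list[Segment]:
    """Cut into floor(T / seg_seconds) windows; detrend + z-normalise each.

    Raises :class:`DegenerateChannelError` naming the channel if a channel
    has (near-)zero variance after detrending.
    """
    L = int(round(seg_seconds * recording.fs))
    if recording.n_samples < L:
        raise InsufficientDataError(
            f"recording has {recording.n_samples} samples, need >= {L}"
        )
    n_segs = recording.n_samples // L
    segments = []
    for g in range(n_segs):
        window = recording.data[:, g * L:(g + 1) * L]
        window = signal.detrend(window, axis=1, type="linear")
        sd = window.std(axis=1)
        bad = np.flatnonzero(sd < 1e-12)
        if bad.size:
            raise DegenerateChannelError(
                f"channel {recording.channel_labels[bad[0]]!r} has zero variance "
                f"in segment {g} of {recording.subject_id}/{recording.condition}"
            )
        window = (window - window.mean(axis=1, keepdims=True)) / sd[:, None]
        segments.append(Segment(
            subject_id=recording.subject_id,
            condition=recording.condition,
            index=g,
            data=window,
            fs=recording.fs,
            channel_labels=recording.channel_labels,
        ))
    return segments


def kpss_average(segment: Segment, variant: str = "level") -> StationarityScore:
    """Channel-averaged KPSS statistic of one segment.

    ``variant="level"`` tests against a constant-mean null, ``"trend"``
    against a deterministic trend.  The Newey-West lag truncation follows the
    textbook rule l = floor(4 * (L/100) ** 0.25).
    """
    regression = {"level": "c", "trend": "ct"}.get(variant)
    if regression is None:
        raise ConfigurationError(f"unknown KPSS variant {variant!r}")
    L = segment.n_samples
    nlags = int(np.floor(4.0 * (L / 100.0) ** 0.25))
    stats = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        for ch in segment.data:
            stat, *_ = _kpss(ch, regression=regression, nlags=nlags)
            stats.append(float(stat))
    return StationarityScore(segment_index=segment.index, ks=tuple(stats))


def select_segments(scores: list[StationarityScore], k: int = 5,
                    mode: str = "stationary",
                    seed: int | None = None) -> list[int]:
    """Indices of the ``k`` analysis segments.

    ``stationary``: the k smallest channel-averaged KPSS statistics, returned
    in ascending order of the statistic (ties broken by segment index).
    ``random``: k indices drawn uniformly without replacement (seeded),
    returned in ascending index order.
    """
    if len(scores) < k:
        raise InsufficientDataError(f"need >= {k} scored segments, have {len(scores)}")
    if mode == "stationary":
        ranked = sorted(scores, key=lambda s: (s.ks_hat, s.segment_index))
        return [s.segment_index for s in ranked[:k]]
    if mode == "random":
        rng = np.random.default_rng(seed)
        chosen = rng.choice([s.segment_index for s in scores], size=k, replace=False)
        return sorted(int(i) for i in chosen)
    raise ConfigurationError(f"unknown selection mode {mode!r}")


def design_fir(band: BandSpec, fs: float, order: int = FIR_ORDER) -> np.ndarray:
    """Hamming-window linear-phase band-pass FIR taps for one band."""
    if not (0.0 < band.lo < band.hi < fs / 2.0):
        raise ConfigurationError(
            f"band [{band.lo}, {band.hi}) outside (0, fs/2) for fs={fs}"
        )
    return signal.firwin(order + 1, [band.lo, band.hi], pass_zero=False,
                         window="hamming", fs=fs)


def bandpass(segment: Segment, band: BandSpec, order: int = FIR_ORDER) -> Segment:
    """Zero-phase band-pass: the FIR is applied forward and backward
    (net order 2 x ``order``, zero phase by construction)."""
    taps = design_fir(band, segment.fs, order)
    padlen = min(3 * order, segment.n_samples - 1)
    data = signal.filtfilt(taps, [1.0], segment.data, axis=1, padlen=padlen)
    return Segment(
        subject_id=segment.subject_id,
        condition=segment.condition,
        index=segment.index,
        data=data,
        fs=segment.fs,
        channel_labels=segment.channel_labels,
    )
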