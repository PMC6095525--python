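"""Shared domain types and errors for the EEG phase-synchronisation pipeline.

The package analyses multichannel EEG-like time series from two groups of
subjects recorded under two conditions (eyes open, ``EO``, and eyes closed,
``EC``).  Everything downstream works on three containers defined here:

* :class:`EegRecording` — one subject/condition, a channels x samples matrix;
* :class:`Segment` — a fixed-length, detrended, z-normalised analysis window;
* :class:`ConnectivityMatrix` — an N x N symmetric matrix of a pairwise
  phase-synchronisation index (PLV or PLI) for one subject, condition and
  frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical scalp electrode order used throughout (10/20 system subset).
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2",
)

CONDITIONS: tuple[str, str] = ("EO", "EC")
GROUPS: tuple[str, str] = ("pos", "neg")

#: Supported pairwise phase-synchronisation indices.
PS_INDICES: tuple[str, str] = ("PLV", "PLI")


class EegfcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EegfcError):
    """A configuration object is internally inconsistent."""


class DegenerateChannelError(EegfcError):
    """A channel has zero variance and cannot be normalised."""


class InsufficientDataError(EegfcError):
    """Not enough samples/segments for the requested operation."""


class UndefinedPhaseError(EegfcError):
    """Instantaneous phase is undefined (e.g. an all-zero channel)."""


class IncompleteProfileError(EegfcError):
    """A connectivity profile is missing one or more matrices."""


class ScaInapplicableError(EegfcError):
    """Synchronisation cluster analysis cannot run (all couplings zero)."""


class UndefinedMeritError(EegfcError):
    """CFS merit requested for an empty feature subset."""


@dataclass(frozen=True)
class BandSpec:
    """A half-open frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 <= lo < hi, got [{self.lo}, {self.hi})"
            )

    @property
    def center(self) -> float:
        """Geometric-mean centre frequency of the band (Hz)."""
        lo = max(self.lo, 1e-6)
        return float(np.sqrt(lo * self.hi))


#: The five classical EEG bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 3.5),
    BandSpec("theta", 3.5, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 48.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str, bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise ConfigurationError(f"unknown band {name!r}")


@dataclass
class EegRecording:
    """One subject/condition: a channels x samples matrix plus metadata."""

    subject_id: str
    condition: str
    group: str
    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("recording data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("recording contains non-finite samples")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}")
        if self.group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Segment:
    """A detrended, z-normalised analysis window of one recording."""

    subject_id: str
    condition: str
    index: int
    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CANONICAL_CHANNELS

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of a pairwise PS index with unit diagonal.

    ``values[i, l]`` is the index between channels ``i`` and ``l`` averaged
    over the analysis segments; the diagonal is 1 by convention and carries
    no information.
    """

    values: np.ndarray
    index: str
    band: str
    condition: str
    subject_id: str
    channel_labels: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ConfigurationError("connectivity values must be square")
        if self.index not in PS_INDICES:
            raise ConfigurationError(f"index must be one of {PS_INDICES}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]
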