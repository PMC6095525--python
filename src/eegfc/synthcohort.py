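"""Synthetic two-group EEG-like cohorts with planted phase coupling.

Each channel carries one noisy phase oscillator per frequency band.  Within a
band the phases evolve as a Kuramoto system discretised at the sampling rate:

    theta_i[t+1] = theta_i[t] + 2*pi*f_b/fs
                   + sum_j K_ij * sin(theta_j[t] - theta_i[t]) / fs
                   + sigma * N(0, 1)

where ``f_b`` is the geometric-mean centre frequency of the band and ``K``
(rad/s) comes from the cohort's coupling plan; the positive group receives an
extra ``dk`` on planned pairs, which is the planted group difference every
downstream stage is asked to recover.  The observed signal of a channel is
the sum of the band oscillators' cosines plus white measurement noise,
optionally passed through an instantaneous (zero-lag) mixing matrix that
mimics volume conduction: mixing produces correlations with zero time lag,
which inflate PLV but not PLI.

The generator is fully deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import detrend

from .core import (
    CANONICAL_CHANNELS,
    CONDITIONS,
    DEFAULT_BANDS,
    BandSpec,
    ConfigurationError,
    EegRecording,
)

__all__ = [
    "CouplingSpec",
    "CohortConfig",
    "generate_subject",
    "generate_cohort",
    "inject_nonstationarity",
    "mixing_matrix",
    "save_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Planted coupling between one channel pair in one band/condition.

    ``k0`` is the base coupling strength (rad/s, both groups) and ``dk`` the
    extra coupling the positive group receives.
    """

    pair: tuple[str, str]
    band: str
    condition: str
    k0: float
    dk: float


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic cohort.

    Defaults mirror the study conditions the pipeline targets: 8 scalp
    channels sampled at 256 Hz, 160 s per condition (8 candidate 20 s
    segments, of which the 5 most stationary are analysed).
    """

    n_pos: int
    n_neg: int
    fs: float = 256.0
    n_channels: int = 8
    duration_s: float = 160.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    coupling_plan: tuple[CouplingSpec, ...] = ()
    mixing_strength: float = 0.0
    nonstationary_fraction: float = 0.0
    nonstationary_magnitude: float = 3.0
    phase_noise_sd: float = 0.4
    measurement_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigurationError("need at least one subject per group")
        hi = max(b.hi for b in self.bands)
        if self.fs <= 2 * hi:
            raise ConfigurationError(
                f"fs={self.fs} must exceed twice the highest band edge ({hi} Hz)"
            )
        if self.duration_s < 7 * 20:
            raise ConfigurationError(
                "duration_s must be >= 140 s so at least 7 candidate 20 s segments exist"
            )
        if not 0.0 <= self.mixing_strength <= 1.0:
            raise ConfigurationError("mixing_strength must lie in [0, 1]")
        if not 0.0 <= self.nonstationary_fraction <= 1.0:
            raise ConfigurationError("nonstationary_fraction must lie in [0, 1]")
        labels = self.channel_labels
        band_names = {b.name for b in self.bands}
        for spec in self.coupling_plan:
            if not np.isfinite(spec.k0) or not np.isfinite(spec.dk):
                raise ConfigurationError(f"non-finite coupling in {spec}")
            if spec.band not in band_names:
                raise ConfigurationError(f"coupling plan references unknown band {spec.band!r}")
            if spec.condition not in CONDITIONS:
                raise ConfigurationError(
                    f"coupling plan references unknown condition {spec.condition!r}"
                )
            for ch in spec.pair:
                if ch not in labels:
                    raise ConfigurationError(
                        f"coupling plan references unknown channel {ch!r}"
                    )

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == len(CANONICAL_CHANNELS):
            return CANONICAL_CHANNELS
        return tuple(f"ch{i:02d}" for i in range(self.n_channels))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def mixing_matrix(n_channels: int, strength: float) -> np.ndarray:
    """Instantaneous mixing matrix ``(1 - m) * I + m * M``.

    ``M`` decays exponentially with inter-electrode index distance — a crude
    but monotone analogue of volume conduction — and is symmetrised to be
    doubly stochastic (Sinkhorn scaling), so rows remain normalised while the
    matrix stays symmetric.
    """
    idx = np.arange(n_channels)
    M = np.exp(-np.abs(idx[:, None] - idx[None, :]).astype(float))
    for _ in range(200):  # symmetric Sinkhorn: converges geometrically
        d = 1.0 / np.sqrt(M.sum(axis=1))
        M = d[:, None] * M * d[None, :]
        if np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
            break
    return (1.0 - strength) * np.eye(n_channels) + strength * M


def _band_coupling(config: CohortConfig, band: BandSpec, group: str,
                   condition: str) -> np.ndarray:
    labels = config.channel_labels
    K = np.zeros((config.n_channels, config.n_channels))
    for spec in config.coupling_plan:
        if spec.band != band.name or spec.condition != condition:
            continue
        i, l = labels.index(spec.pair[0]), labels.index(spec.pair[1])
        k = spec.k0 + (spec.dk if group == "pos" else 0.0)
        K[i, l] += k
        K[l, i] += k
    return K


def _band_phases(config: CohortConfig, K: np.ndarray, center_hz: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Evolve one band's phase oscillators; coupled channels use an Euler
    loop, uncoupled ones a vectorised cumulative sum of the increments."""
    n_ch, n = config.n_channels, config.n_samples
    omega = 2.0 * np.pi * center_hz / config.fs
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
    noise = rng.standard_normal((n_ch, n - 1)) * config.phase_noise_sd
    theta = np.empty((n_ch, n))
    theta[:, 0] = theta0

    coupled = np.flatnonzero(np.any(K != 0.0, axis=1))
    free = np.setdiff1d(np.arange(n_ch), coupled)
    if free.size:
        theta[free, 1:] = theta0[free, None] + np.cumsum(omega + noise[free], axis=1)
    if coupled.size:
        Ksub = K[np.ix_(coupled, coupled)] / config.fs
        th = theta0[coupled].copy()
        sub = theta[coupled]
        for t in range(1, n):
            diff = th[None, :] - th[:, None]  # diff[i, j] = theta_j - theta_i
            th = th + omega + (Ksub * np.sin(diff)).sum(axis=1) + noise[:, t - 1][coupled]
            sub[:, t] = th
        theta[coupled] = sub
    return theta


def generate_subject(config: CohortConfig, group: str, condition: str,
                     seed: int) -> EegRecording:
    """Generate one subject/condition recording (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    n_ch, n = config.n_channels, config.n_samples
    data = np.zeros((n_ch, n))
    for band in config.bands:
        K = _band_coupling(config, band, group, condition)
        data += np.cos(_band_phases(config, K, band.center, rng))
    data += config.measurement_noise_sd * rng.standard_normal((n_ch, n))
    if config.mixing_strength > 0.0:
        data = mixing_matrix(n_ch, config.mixing_strength) @ data

    rec = EegRecording(
        subject_id="",  # filled by callers
        condition=condition,
        group=group,
        data=data,
        fs=config.fs,
        channel_labels=config.channel_labels,
    )
    if config.nonstationary_fraction > 0.0:
        n_segs = int(config.duration_s // 20)
        n_bad = int(round(config.nonstationary_fraction * n_segs))
        bad = rng.choice(n_segs, size=n_bad, replace=False)
        for g in sorted(int(b) for b in bad):
            rec = inject_nonstationarity(rec, g, "trend", config.nonstationary_magnitude)
    return rec


def subject_seed(config_seed: int, subject_index: int, condition: str) -> int:
    """Deterministic per-(subject, condition) seed derived from the cohort seed."""
    ss = np.random.SeedSequence([config_seed, subject_index, CONDITIONS.index(condition)])
    return int(ss.generate_state(1)[0])


def generate_cohort(config: CohortConfig) -> list[EegRecording]:
    """All subjects x both conditions; positive group first."""
    recordings = []
    groups = ["pos"] * config.n_pos + ["neg"] * config.n_neg
    for si, group in enumerate(groups):
        rank = si if group == "pos" else si - config.n_pos
        subject_id = f"{group}{rank + 1:02d}"
        for condition in CONDITIONS:
            rec = generate_subject(config, group, condition,
                                   subject_seed(config.seed, si, condition))
            rec.subject_id = subject_id
            recordings.append(rec)
    return recordings


def inject_nonstationarity(recording: EegRecording, segment_index: int,
                           kind: str, magnitude: float) -> EegRecording:
    """Return a copy with one 20 s window made non-stationary.

    ``trend`` adds a linear ramp of ``magnitude`` times the window's
    detrended per-channel SD (so repeated trends compose additively);
    ``amplitude_ramp`` multiplies by a gain ramp from 1 to 1 + magnitude.
    """
    L = int(round(20 * recording.fs))
    n_segs = recording.n_samples // L
    if not 0 <= segment_index < n_segs:
        raise ConfigurationError(
            f"segment_index {segment_index} out of range (have {n_segs} windows)"
        )
    data = recording.data.copy()
    sl = slice(segment_index * L, (segment_index + 1) * L)
    window = data[:, sl]
    ramp = np.linspace(0.0, 1.0, L)
    if kind == "trend":
        sd = np.std(detrend(window, axis=1), axis=1)
        window = window + magnitude * sd[:, None] * ramp[None, :]
    elif kind == "amplitude_ramp":
        window = window * (1.0 + magnitude * ramp)[None, :]
    else:
        raise ConfigurationError(f"unknown nonstationarity kind {kind!r}")
    data[:, sl] = window
    return EegRecording(
        subject_id=recording.subject_id,
        condition=recording.condition,
        group=recording.group,
        data=data,
        fs=recording.fs,
        channel_labels=recording.channel_labels,
    )


# ---------------------------------------------------------------------------
# Cohort persistence: one .npy per recording + a CSV manifest + YAML config.

def _config_to_dict(config: CohortConfig) -> dict:
    d = {
        "n_pos": config.n_pos, "n_neg": config.n_neg, "fs": config.fs,
        "n_channels": config.n_channels, "duration_s": config.duration_s,
        "mixing_strength": config.mixing_strength,
        "nonstationary_fraction": config.nonstationary_fraction,
        "nonstationary_magnitude": config.nonstationary_magnitude,
        "phase_noise_sd": config.phase_noise_sd,
        "measurement_noise_sd": config.measurement_noise_sd,
        "seed": config.seed,
        "bands": [{"name": b.name, "lo": b.lo, "hi": b.hi} for b in config.bands],
        "coupling_plan": [
            {"pair": list(s.pair), "band": s.band, "condition": s.condition,
             "k0": s.k0, "dk": s.dk}
            for s in config.coupling_plan
        ],
    }
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    bands = tuple(BandSpec(**b) for b in d.pop("bands", [])) or DEFAULT_BANDS
    plan = tuple(
        CouplingSpec(pair=tuple(s["pair"]), band=s["band"], condition=s["condition"],
                     k0=float(s["k0"]), dk=float(s["dk"]))
        for s in d.pop("coupling_plan", [])
    )
    return CohortConfig(bands=bands, coupling_plan=plan, **d)


def load_config(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_cohort(recordings: list[EegRecording], out_dir: str | Path,
                config: CohortConfig | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.condition}.npy"
        np.save(out / fname, rec.data)
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "condition": rec.condition, "file": fname, "fs": rec.fs,
            "channels": ";".join(rec.channel_labels),
        })
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    if config is not None:
        with open(out / "cohort.yaml", "w") as fh:
            yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)
    return manifest


def load_cohort(in_dir: str | Path) -> list[EegRecording]:
    in_dir = Path(in_dir)
    recordings = []
    with open(in_dir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            recordings.append(EegRecording(
                subject_id=row["subject_id"],
                condition=row["condition"],
                group=row["group"],
                data=np.load(in_dir / row["file"]),
                fs=float(row["fs"]),
                channel_labels=tuple(row["channels"].split(";")),
            ))
    return recordings
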