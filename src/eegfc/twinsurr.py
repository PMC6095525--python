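"""Twin surrogates and one-sided significance testing of PS indices.

Twin surrogates resample a delay-embedded trajectory by jumping, with equal
probability, between *twins* — embedded points whose recurrence-matrix
columns are identical — while otherwise following the original succession of
states.  They preserve the individual dynamics of the channel (amplitude
distribution, recurrence structure) but destroy its interdependence with any
other channel, which makes them a null model for phase synchronisation.

A pair's index (PLV or PLI) is *significant* at p < 0.01 when the original
value strictly exceeds the index computed between each of 99 surrogates of
one channel and the untouched partner channel (a one-sided rank test:
P(original is the largest of 100 exchangeable values) = 1/100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .core import (
    ConfigurationError,
    ConnectivityMatrix,
    InsufficientDataError,
    Segment,
)
from .phasesync import pli, plv, relative_phase, relative_phase_signed

__all__ = [
    "EmbeddingParams",
    "SurrogateEnsemble",
    "estimate_embedding",
    "delay_embed",
    "twin_surrogates",
    "significance_test",
    "significance_matrix",
    "threshold_matrix",
]

#: Target recurrence rate used to pick the recurrence threshold delta.
RECURRENCE_RATE = 0.1
#: Kennel false-nearest-neighbour tolerance ratio.
FNN_RTOL = 10.0
#: FNN acceptance threshold (fraction of false neighbours).
FNN_THRESHOLD = 0.01
#: Mutual-information estimation: equal-width bins and maximum lag.
MI_BINS = 16
MI_MAX_LAG = 64
#: Search range for the embedding dimension.
M_MAX = 10


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: dimension ``m`` and delay ``tau`` (samples)."""

    m: int
    tau: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ConfigurationError("need m >= 1 and tau >= 1")


@dataclass
class SurrogateEnsemble:
    """``n_s`` twin-surrogate series of one channel (rows of ``series``)."""

    series: np.ndarray          # n_s x Nv
    params: EmbeddingParams
    delta: float                # recurrence threshold actually used
    n_twins: int                # embedded points that have at least one twin
    seed: int

    @property
    def n_s(self) -> int:
        return self.series.shape[0]


def _lagged_mi(x: np.ndarray, lag: int, bins: int = MI_BINS) -> float:
    a, b = x[:-lag], x[lag:]
    H, _, _ = np.histogram2d(a, b, bins=bins)
    p = H / H.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / np.outer(px, py)[nz])).sum())


def _fnn_fraction(x: np.ndarray, m: int, tau: int, rtol: float = FNN_RTOL) -> float:
    n = len(x) - m * tau
    if n < 10:
        return 1.0
    emb = np.column_stack([x[i * tau:i * tau + n] for i in range(m)])
    tree = cKDTree(emb)
    d, idx = tree.query(emb, k=2)
    d, idx = d[:, 1], idx[:, 1]
    extra = np.abs(x[np.arange(n) + m * tau] - x[idx + m * tau])
    good = d > 0
    if not np.any(good):
        return 0.0
    return float(np.mean(extra[good] / d[good] > rtol))


def estimate_embedding(x: np.ndarray, fs: float) -> EmbeddingParams:
    """Delay from the first strict local minimum of lagged mutual
    information; dimension from the false-nearest-neighbour criterion.

    If the MI curve has no interior minimum up to lag 64 the delay falls
    back to fs/10 (with a warning); if no dimension in 1..10 drops the FNN
    fraction below 1%, the dimension with the smallest fraction is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 500:
        raise InsufficientDataError(f"need >= 500 samples, have {x.size}")
    max_lag = min(MI_MAX_LAG, x.size // 4)
    mi = np.array([_lagged_mi(x, lag) for lag in range(1, max_lag + 1)])
    tau = None
    for k in range(1, len(mi) - 1):
        if mi[k] < mi[k - 1] and mi[k] < mi[k + 1]:
            tau = k + 1  # lags are 1-based
            break
    if tau is None:
        tau = max(1, int(round(fs / 10.0)))
        warnings.warn(
            f"no mutual-information minimum up to lag {max_lag}; "
            f"falling back to tau = fs/10 = {tau}",
            stacklevel=2,
        )
    fractions = []
    for m in range(1, M_MAX + 1):
        frac = _fnn_fraction(x, m, tau)
        fractions.append(frac)
        if frac < FNN_THRESHOLD:
            return EmbeddingParams(m=m, tau=tau)
    m = int(np.argmin(fractions)) + 1
    warnings.warn(
        f"FNN fraction never dropped below {FNN_THRESHOLD:.0%} for m <= {M_MAX}; "
        f"using argmin m = {m} (fraction {min(fractions):.3f})",
        stacklevel=2,
    )
    return EmbeddingParams(m=m, tau=tau)


def delay_embed(x: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Delay-embedded trajectory, shape (Nv, m) with Nv = L - (m-1)*tau."""
    x = np.asarray(x, dtype=float).ravel()
    m, tau = params.m, params.tau
    n = x.size - (m - 1) * tau
    if n < 2:
        raise InsufficientDataError("series too short for this embedding")
    return np.column_stack([x[i * tau:i * tau + n] for i in range(m)])


def _twin_groups(R: np.ndarray, theiler: int) -> list[np.ndarray]:
    """Group embedded points by identical recurrence columns.

    The band |a - b| <= theiler is blanked before comparison so temporally
    adjacent points are not declared twins merely by continuity.
    """
    nv = R.shape[0]
    R = R.copy()
    for off in range(-theiler, theiler + 1):
        np.fill_diagonal(R[max(0, -off):, max(0, off):], False)
    packed = np.packbits(R, axis=0)
    groups: dict[bytes, list[int]] = {}
    for col in range(nv):
        groups.setdefault(packed[:, col].tobytes(), []).append(col)
    return [np.array(g) for g in groups.values()]


def twin_surrogates(x: np.ndarray, params: EmbeddingParams, n_s: int = 99,
                    seed: int = 0,
                    recurrence_rate: float = RECURRENCE_RATE) -> SurrogateEnsemble:
    """Generate ``n_s`` twin surrogates of a single channel.

    The recurrence threshold delta is the ``recurrence_rate`` quantile of the
    off-diagonal max-norm distances between delay vectors.  Each surrogate
    starts at a random embedded point; at every step the walker jumps with
    equal probability to the successor of the current point or of any of its
    twins, restarting at a random point when the trajectory end is reached.
    Surrogate samples are first components of visited delay vectors, so every
    surrogate value occurs in the original series.  With no twins the
    surrogates degenerate to concatenated runs of the original (a warning is
    emitted); the ensemble is still a valid, if weaker, null.
    """
    emb = delay_embed(x, params)
    nv = emb.shape[0]
    dist = squareform(pdist(emb, metric="chebyshev"))
    off = dist[~np.eye(nv, dtype=bool)]
    delta = float(np.quantile(off, recurrence_rate))
    R = dist <= delta
    theiler = params.m * params.tau
    groups = _twin_groups(R, theiler)
    member_of: list[np.ndarray] = [None] * nv  # type: ignore[list-item]
    n_twins = 0
    for g in groups:
        for col in g:
            member_of[col] = g
        if g.size > 1:
            n_twins += g.size
    if n_twins == 0:
        warnings.warn("no twins found; surrogates reduce to shifted copies",
                      stacklevel=2)

    rng = np.random.default_rng(seed)
    first = emb[:, 0]
    series = np.empty((n_s, nv))
    for s in range(n_s):
        idx = int(rng.integers(nv))
        row = series[s]
        for t in range(nv):
            row[t] = first[idx]
            g = member_of[idx]
            jump = int(g[rng.integers(g.size)]) if g.size > 1 else idx
            idx = jump + 1
            if idx >= nv:
                idx = int(rng.integers(nv))
    return SurrogateEnsemble(series=series, params=params, delta=delta,
                             n_twins=n_twins, seed=seed)


def _phase(x: np.ndarray) -> np.ndarray:
    return np.angle(hilbert(x))


def _index_between(xa: np.ndarray, xb: np.ndarray, index: str) -> float:
    ta, tb = _phase(xa), _phase(xb)
    if index == "PLV":
        return plv(relative_phase(ta, tb))
    return pli(relative_phase_signed(ta, tb))


def surrogate_indices(ensemble: SurrogateEnsemble, x_l: np.ndarray,
                      index: str) -> np.ndarray:
    """Index between each surrogate and the untouched partner channel."""
    nv = ensemble.series.shape[1]
    partner = np.asarray(x_l, dtype=float).ravel()[:nv]
    t_l = _phase(partner)
    vals = np.empty(ensemble.n_s)
    for s in range(ensemble.n_s):
        t_s = _phase(ensemble.series[s])
        if index == "PLV":
            vals[s] = plv(relative_phase(t_s, t_l))
        else:
            vals[s] = pli(relative_phase_signed(t_s, t_l))
    return vals


def significance_test(original_index: float, x_i: np.ndarray, x_l: np.ndarray,
                      index: str, params_i: EmbeddingParams, n_s: int = 99,
                      seed: int = 0) -> bool:
    """One-sided rank test: True iff the original index strictly exceeds the
    index of all ``n_s`` surrogate pairings (p < 1/(n_s+1))."""
    if index not in ("PLV", "PLI"):
        raise ConfigurationError(f"unknown PS index {index!r}")
    ens = twin_surrogates(np.asarray(x_i, dtype=float).ravel(), params_i,
                          n_s=n_s, seed=seed)
    surr = surrogate_indices(ens, x_l, index)
    return bool(original_index > surr.max())


def significance_matrix(band_segments: list[Segment], index: str, n_s: int = 99,
                        seed: int = 0,
                        params: dict[int, EmbeddingParams] | None = None,
                        edge_seconds: float = 0.5) -> np.ndarray:
    """Majority-rule significance mask for a set of analysis segments.

    For every channel pair (i, l) with i < l the lower-index channel is
    surrogated (one ensemble per channel per segment, shared across its
    pairs) and the per-segment index is tested against the ensemble.  An
    entry is significant at the subject level iff it is significant in a
    strict majority of segments.  Returns a symmetric boolean matrix with a
    True diagonal.
    """
    if not band_segments:
        raise InsufficientDataError("need at least one segment")
    n = band_segments[0].n_channels
    votes = np.zeros((n, n), dtype=int)
    root = np.random.SeedSequence(seed)
    for seg_no, seg in enumerate(band_segments):
        E = int(round(edge_seconds * seg.fs))
        data = seg.data[:, E:seg.n_samples - E] if 2 * E < seg.n_samples else seg.data
        ensembles = {}
        for i in range(n - 1):
            p = params[i] if params is not None else estimate_embedding(data[i], seg.fs)
            child = np.random.SeedSequence([seed, seg_no, i])
            ensembles[i] = twin_surrogates(data[i], p, n_s=n_s,
                                           seed=int(child.generate_state(1)[0]))
        for i in range(n - 1):
            nv = ensembles[i].series.shape[1]
            for l in range(i + 1, n):
                orig = _index_between(data[i][:nv], data[l][:nv], index)
                surr = surrogate_indices(ensembles[i], data[l], index)
                if orig > surr.max():
                    votes[i, l] += 1
                    votes[l, i] += 1
    sig = votes > len(band_segments) / 2.0
    np.fill_diagonal(sig, True)
    return sig


def threshold_matrix(matrix: ConnectivityMatrix,
                     significance: np.ndarray) -> ConnectivityMatrix:
    """Zero the non-significant off-diagonal entries; diagonal untouched."""
    significance = np.asarray(significance, dtype=bool)
    if significance.shape != matrix.values.shape:
        raise ConfigurationError("significance mask shape mismatch")
    if not np.array_equal(significance, significance.T):
        raise ConfigurationError("significance mask must be symmetric")
    values = np.where(significance, matrix.values, 0.0)
    np.fill_diagonal(values, np.diag(matrix.values))
    return ConnectivityMatrix(
        values=values, index=matrix.index, band=matrix.band,
        condition=matrix.condition, subject_id=matrix.subject_id,
        channel_labels=matrix.channel_labels,
    )
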