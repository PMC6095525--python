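"""Symmetrical uncertainty, FCBF and Scatter Search feature selection.

All three operate on supervised-discretized tables.  Symmetrical uncertainty
SU(X, Y) = 2 * IG(X|Y) / (H(X) + H(Y)) is a normalised information gain in
[0, 1]: 1 when either variable fully determines the other, 0 under
independence.

FCBF (fast correlation-based filter) drops features with SU(X, Y) <= delta,
sorts survivors by class relevance, and removes every feature that has an
*approximate Markov blanket* among the better-ranked ones: X_j blankets X_i
iff SU(X_j, Y) >= SU(X_i, Y) and SU(X_i, X_j) >= SU(X_i, Y).  The retained
features are the predominant ones.

Scatter Search is a population metaheuristic over feature subsets scored by
the CFS merit M_S = k * r_cf / sqrt(k + k*(k-1) * r_ff), with SU as the
correlation measure: it keeps a small reference set of high-quality and
diverse solutions, combines every pair, improves offspring by local search,
and statically re-updates the reference set until it stabilises.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError, EegfcError, UndefinedMeritError
from .dimreduce import FeatureTable

__all__ = [
    "DiscretizedTable",
    "SelectionResult",
    "discretize",
    "mdlp_cut_points",
    "su",
    "fcbf",
    "cfs_merit",
    "scatter_search",
]


@dataclass
class DiscretizedTable:
    """Integer-coded feature table with the bin-edge map that produced it."""

    frame: pd.DataFrame                      # int codes, incl. 'class'
    cut_points: dict[str, np.ndarray]        # feature -> ascending cut values

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c != "class")


def _entropy_counts(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    if counts.size == 0:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _label_entropy(y: np.ndarray) -> float:
    return _entropy_counts(np.bincount(y))


def mdlp_cut_points(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fayyad-Irani recursive entropy cuts with the MDL acceptance test.

    Candidate cuts are boundary midpoints of the sorted values; a cut is
    accepted only when its information gain exceeds
    (log2(n-1) + log2(3**k - 2) - (k*H(S) - k1*H(S1) - k2*H(S2))) / n.
    Features for which no cut is accepted collapse to a single bin.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]

    def recurse(lo: int, hi: int, acc: list[float]) -> None:
        n = hi - lo
        xv, yv = xs[lo:hi], ys[lo:hi]
        if n < 2 or xv[0] == xv[-1]:
            return
        h_s = _label_entropy(yv)
        if h_s == 0.0:
            return
        k = np.unique(yv).size
        best_gain, best_i, best_stats = 0.0, None, None
        # candidate boundaries: positions where the value changes
        change = np.flatnonzero(xv[1:] != xv[:-1]) + 1
        for i in change:
            left, right = yv[:i], yv[i:]
            h1, h2 = _label_entropy(left), _label_entropy(right)
            gain = h_s - (i * h1 + (n - i) * h2) / n
            if gain > best_gain:
                best_gain, best_i = gain, i
                best_stats = (h1, h2, np.unique(left).size, np.unique(right).size)
        if best_i is None:
            return
        h1, h2, k1, k2 = best_stats
        delta = np.log2(3.0 ** k - 2.0) - (k * h_s - k1 * h1 - k2 * h2)
        if best_gain <= (np.log2(n - 1) + delta) / n:
            return
        acc.append(float((xv[best_i - 1] + xv[best_i]) / 2.0))
        recurse(lo, lo + best_i, acc)
        recurse(lo + best_i, hi, acc)

    cuts: list[float] = []
    recurse(0, len(xs), cuts)
    return np.sort(np.array(cuts))


def apply_cut_points(x: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Map values to 0-based bin codes given ascending cut points."""
    if cuts.size == 0:
        return np.zeros(len(x), dtype=int)
    return np.searchsorted(cuts, x, side="left").astype(int)


def discretize(table: FeatureTable | pd.DataFrame, method: str = "mdlp",
               n_bins: int = 4) -> DiscretizedTable:
    """Supervised discretization of every feature column.

    ``mdlp`` (default) uses the MDL-accepted recursive entropy cuts above;
    ``equal_frequency`` is a config alternative with ``n_bins`` quantile
    bins.  The binary class column is passed through untouched.
    """
    frame = table.frame if isinstance(table, FeatureTable) else table
    if "class" not in frame.columns:
        raise ConfigurationError("table needs a 'class' column")
    y = frame["class"].to_numpy()
    if np.unique(y).size > 2:
        raise ConfigurationError("class column must be binary")
    y = y.astype(int)
    out = {}
    cut_points = {}
    for col in frame.columns:
        if col == "class":
            continue
        x = frame[col].to_numpy(dtype=float)
        if method == "mdlp":
            cuts = mdlp_cut_points(x, y)
        elif method == "equal_frequency":
            qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
            cuts = np.unique(qs)
            if np.unique(x).size <= 1:
                cuts = np.array([])
        else:
            raise ConfigurationError(f"unknown discretization method {method!r}")
        cut_points[col] = cuts
        out[col] = apply_cut_points(x, cuts)
    out["class"] = y
    return DiscretizedTable(frame=pd.DataFrame(out, index=frame.index),
                            cut_points=cut_points)


def su(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetrical uncertainty between two discrete vectors.

    Defined as 0 when H(X) + H(Y) = 0 (both variables constant).
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("empty vectors")
    if x.size != y.size:
        raise ConfigurationError("length mismatch")
    xc = np.unique(x, return_inverse=True)[1]
    yc = np.unique(y, return_inverse=True)[1]
    nx, ny = xc.max() + 1, yc.max() + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xc, yc), 1.0)
    hx = _entropy_counts(joint.sum(axis=1))
    hy = _entropy_counts(joint.sum(axis=0))
    if hx + hy == 0.0:
        return 0.0
    # H(X|Y) = sum_j P(y_j) H(X | y_j)
    n = joint.sum()
    h_x_given_y = 0.0
    for j in range(joint.shape[1]):
        col = joint[:, j]
        tot = col.sum()
        if tot > 0:
            h_x_given_y += (tot / n) * _entropy_counts(col)
    ig = hx - h_x_given_y
    return float(2.0 * ig / (hx + hy))


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``selected`` is ordered by descending class-SU; ``removed`` records the
    (feature, blanket) pairs dropped as redundant; ``irrelevant`` the
    features whose class-SU fell at or below the threshold.
    """

    selected: tuple[str, ...]
    su_with_class: dict[str, float]
    removed: tuple[tuple[str, str], ...] = ()
    irrelevant: tuple[str, ...] = ()
    merit: float | None = None


def _class_su(dt: DiscretizedTable) -> dict[str, float]:
    y = dt.frame["class"].to_numpy()
    return {f: su(dt.frame[f].to_numpy(), y) for f in dt.feature_names}


def fcbf(dt: DiscretizedTable, delta: float = 0.0) -> SelectionResult:
    """Fast correlation-based filter with relevance threshold ``delta``.

    An empty selection is a legal result (all features irrelevant).
    """
    su_y = _class_su(dt)
    relevant = [f for f in dt.feature_names if su_y[f] > delta]
    irrelevant = tuple(f for f in dt.feature_names if su_y[f] <= delta)
    # descending class relevance; ties broken lexicographically
    ordered = sorted(relevant, key=lambda f: (-su_y[f], f))
    cols = {f: dt.frame[f].to_numpy() for f in ordered}
    alive = list(ordered)
    removed: list[tuple[str, str]] = []
    pos = 0
    while pos < len(alive):
        xj = alive[pos]
        survivors = alive[:pos + 1]
        for xi in alive[pos + 1:]:
            if su(cols[xi], cols[xj]) >= su_y[xi]:
                removed.append((xi, xj))
            else:
                survivors.append(xi)
        alive = survivors
        pos += 1
    return SelectionResult(selected=tuple(alive), su_with_class=su_y,
                           removed=tuple(removed), irrelevant=irrelevant)


class _SUCache:
    """Memoised pairwise/class SU lookups over one discretized table."""

    def __init__(self, dt: DiscretizedTable):
        self.cols = {f: dt.frame[f].to_numpy() for f in dt.feature_names}
        self.y = dt.frame["class"].to_numpy()
        self._class: dict[str, float] = {}
        self._pair: dict[tuple[str, str], float] = {}

    def class_su(self, f: str) -> float:
        if f not in self._class:
            self._class[f] = su(self.cols[f], self.y)
        return self._class[f]

    def pair_su(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._pair:
            self._pair[key] = su(self.cols[key[0]], self.cols[key[1]])
        return self._pair[key]

    def merit(self, subset: tuple[str, ...]) -> float:
        k = len(subset)
        if k == 0:
            raise UndefinedMeritError("CFS merit of the empty subset is undefined")
        r_cf = np.mean([self.class_su(f) for f in subset])
        if k == 1:
            return float(r_cf)
        pairs = list(itertools.combinations(subset, 2))
        r_ff = np.mean([self.pair_su(a, b) for a, b in pairs])
        return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))


def cfs_merit(subset: tuple[str, ...] | list[str],
              dt: DiscretizedTable) -> float:
    """CFS merit of a feature subset (SU as the correlation measure)."""
    return _SUCache(dt).merit(tuple(subset))


def _hamming(a: frozenset, b: frozenset, universe: tuple[str, ...]) -> int:
    return len(a.symmetric_difference(b))


def _improve(sol: frozenset, cache: _SUCache, features: tuple[str, ...],
             rng: np.random.Generator) -> frozenset:
    """First-improvement bit-flip hill climb on CFS merit (never empties)."""
    current = set(sol)
    merit = cache.merit(tuple(sorted(current)))
    improved = True
    while improved:
        improved = False
        order = rng.permutation(len(features))
        for fi in order:
            f = features[fi]
            trial = set(current)
            if f in trial:
                if len(trial) == 1:
                    continue
                trial.remove(f)
            else:
                trial.add(f)
            m = cache.merit(tuple(sorted(trial)))
            if m > merit + 1e-12:
                current, merit = trial, m
                improved = True
                break
    return frozenset(current)


def _refset_update(pool: list[frozenset], cache: _SUCache,
                   features: tuple[str, ...], n_quality: int,
                   n_diverse: int) -> list[frozenset]:
    uniq = sorted(set(pool), key=lambda s: (-cache.merit(tuple(sorted(s))),
                                            sorted(s)))
    refset = uniq[:n_quality]
    rest = uniq[n_quality:]
    while len(refset) < n_quality + n_diverse and rest:
        best = max(rest, key=lambda s: (min(_hamming(s, r, features) for r in refset),
                                        [f not in s for f in features]))
        refset.append(best)
        rest.remove(best)
    return refset


def scatter_search(dt: DiscretizedTable, seed: int = 0, pop_size: int = 50,
                   ref_quality: int = 5, ref_diverse: int = 5,
                   max_rounds: int = 50) -> SelectionResult:
    """Scatter Search over feature subsets with the CFS merit objective.

    Deterministic given ``seed``.  The candidate pool is restricted to
    features with nonzero class-SU (zero-relevance features only dilute the
    merit).  Combination takes the intersection of two parents and adds each
    symmetric-difference feature with probability 1/2 (repaired to be
    non-empty); improvement is a first-improvement bit-flip hill climb; the
    reference set is statically re-built from quality and max-min-Hamming
    diversity until unchanged or ``max_rounds`` rounds.
    """
    cache = _SUCache(dt)
    features = tuple(sorted(f for f in dt.feature_names if cache.class_su(f) > 0.0))
    su_y = {f: cache.class_su(f) for f in dt.feature_names}
    if not features:
        return SelectionResult(selected=(), su_with_class=su_y,
                               irrelevant=tuple(dt.feature_names))
    rng = np.random.default_rng(seed)
    d = len(features)

    population: list[frozenset] = []
    for _ in range(pop_size):
        size = int(rng.integers(1, d + 1))
        members = rng.choice(d, size=size, replace=False)
        population.append(frozenset(features[i] for i in members))
    population = [_improve(s, cache, features, rng) for s in population]
    refset = _refset_update(population, cache, features, ref_quality, ref_diverse)

    for _ in range(max_rounds):
        children = []
        for a, b in itertools.combinations(refset, 2):
            child = set(a & b)
            for f in a.symmetric_difference(b):
                if rng.random() < 0.5:
                    child.add(f)
            if not child:
                union = sorted(a | b)
                child.add(union[int(rng.integers(len(union)))])
            children.append(_improve(frozenset(child), cache, features, rng))
        new_refset = _refset_update(refset + children, cache, features,
                                    ref_quality, ref_diverse)
        if set(new_refset) == set(refset):
            refset = new_refset
            break
        refset = new_refset

    best = max(refset, key=lambda s: cache.merit(tuple(sorted(s))))
    selected = tuple(sorted(best, key=lambda f: (-su_y[f], f)))
    return SelectionResult(selected=selected, su_with_class=su_y,
                           irrelevant=tuple(f for f in dt.feature_names
                                            if su_y[f] <= 0.0),
                           merit=cache.merit(tuple(sorted(best))))
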