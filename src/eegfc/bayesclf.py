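"""Bayesian-network classifiers: BD scoring, K2 / hill-climbing / look-ahead
hill-climbing structure search, CPT fitting and prediction.

The model is an augmented naive Bayes: the class variable Y has a fixed edge
to every feature node, and structure search only adds, deletes or reverses
feature-feature edges (each feature may gain up to ``max_parents`` feature
parents besides Y).  Structures are scored by the Bayesian Dirichlet
marginal likelihood with a uniform structure prior and equivalent sample
size 1 (BDeu); the score decomposes per node, so searches evaluate only the
nodes a move touches.

Prediction applies the factorisation P(y | x) ~ P(y) * prod_i P(x_i |
parents_i), with add-one (Laplace) smoothed CPTs so unseen parent
configurations fall back to uniform rows.  Exact posterior ties resolve to
the negative (control) class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import lgamma
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError, EegfcError

__all__ = [
    "BayesNetModel",
    "StructureScore",
    "CyclicStructureError",
    "bd_score",
    "k2_search",
    "hc_search",
    "lhc_search",
    "fit_cpts",
    "predict",
]

CLASS_VAR = "class"
#: BDeu equivalent sample size.
ESS = 1.0
#: Default cap on feature parents per node (Y not counted).
MAX_PARENTS = 2


class CyclicStructureError(EegfcError):
    """The proposed edge set contains a directed cycle."""


@dataclass
class StructureScore:
    """Decomposable BD score: total and per-node terms."""

    total: float
    per_node: dict[str, float]


@dataclass
class BayesNetModel:
    """A fitted (or structure-only) Bayesian network classifier.

    ``edges`` holds only feature-feature edges; the Y -> feature edges are
    implicit and always present.  ``cpts[node]`` is an array whose last axis
    is the node's own state and whose leading axes follow ``parents[node]``.
    """

    nodes: tuple[str, ...]                  # class variable first
    edges: tuple[tuple[str, str], ...]      # feature-feature (parent, child)
    class_var: str = CLASS_VAR
    cardinalities: dict[str, int] = field(default_factory=dict)
    parents: dict[str, tuple[str, ...]] = field(default_factory=dict)
    cpts: dict[str, np.ndarray] = field(default_factory=dict)
    cut_points: dict[str, np.ndarray] = field(default_factory=dict)
    score: float | None = None

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n != self.class_var)

    def all_edges(self) -> tuple[tuple[str, str], ...]:
        """Feature-feature edges plus the implicit class edges."""
        return tuple((self.class_var, f) for f in self.features) + self.edges

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "nodes": list(self.nodes),
            "class_var": self.class_var,
            "edges": [list(e) for e in self.all_edges()],
            "cardinalities": self.cardinalities,
            "parents": {k: list(v) for k, v in self.parents.items()},
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
            "cut_points": {k: np.asarray(v).tolist() for k, v in self.cut_points.items()},
            "score": self.score,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_dot(self) -> str:
        lines = ["digraph bnc {"]
        for n in self.nodes:
            shape = "doublecircle" if n == self.class_var else "box"
            lines.append(f'  "{n}" [shape={shape}];')
        for a, b in self.all_edges():
            style = ' [style=dashed]' if a != self.class_var else ""
            lines.append(f'  "{a}" -> "{b}"{style};')
        lines.append("}")
        return "\n".join(lines)


def _check_acyclic(features: tuple[str, ...],
                   edges: set[tuple[str, str]]) -> None:
    adj: dict[str, list[str]] = {f: [] for f in features}
    indeg = {f: 0 for f in features}
    for a, b in edges:
        adj[a].append(b)
        indeg[b] += 1
    queue = [f for f in features if indeg[f] == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for m in adj[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    if seen != len(features):
        raise CyclicStructureError("feature-feature edges contain a cycle")


def _would_cycle(features: tuple[str, ...], edges: set[tuple[str, str]],
                 new_edge: tuple[str, str]) -> bool:
    try:
        _check_acyclic(features, edges | {new_edge})
        return False
    except CyclicStructureError:
        return True


class _ScoreCache:
    """Cached local BD scores over one discretized data frame."""

    def __init__(self, data: pd.DataFrame, class_var: str = CLASS_VAR,
                 ess: float = ESS):
        self.class_var = class_var
        self.ess = ess
        self.codes: dict[str, np.ndarray] = {}
        self.cards: dict[str, int] = {}
        for col in data.columns:
            vals = data[col].to_numpy(dtype=int)
            card = int(vals.max()) + 1 if len(vals) else 1
            self.codes[col] = vals
            self.cards[col] = max(card, 1)
        self._local: dict[tuple[str, tuple[str, ...]], float] = {}

    def local(self, child: str, parents: tuple[str, ...]) -> float:
        """log BD contribution of one node given its parent set."""
        key = (child, tuple(sorted(parents)))
        if key in self._local:
            return self._local[key]
        r = self.cards[child]
        q = 1
        for p in key[1]:
            q *= self.cards[p]
        a_ij = self.ess / q
        a_ijk = self.ess / (q * r)
        child_codes = self.codes[child]
        if key[1]:
            pcfg = np.zeros(len(child_codes), dtype=np.int64)
            mult = 1
            for p in key[1]:
                pcfg += self.codes[p] * mult
                mult *= self.cards[p]
        else:
            pcfg = np.zeros(len(child_codes), dtype=np.int64)
        flat = pcfg * r + child_codes
        counts = np.bincount(flat, minlength=q * r).reshape(q, r)
        n_ij = counts.sum(axis=1)
        score = 0.0
        for j in np.flatnonzero(n_ij):
            score += lgamma(a_ij) - lgamma(a_ij + n_ij[j])
            for k in np.flatnonzero(counts[j]):
                score += lgamma(a_ijk + counts[j, k]) - lgamma(a_ijk)
        self._local[key] = score
        return score


def _feature_parents(features: tuple[str, ...], edges: set[tuple[str, str]],
                     class_var: str) -> dict[str, tuple[str, ...]]:
    parents: dict[str, list[str]] = {f: [class_var] for f in features}
    for a, b in sorted(edges):
        parents[b].append(a)
    return {f: tuple(p) for f, p in parents.items()}


def _structure_total(cache: _ScoreCache, features: tuple[str, ...],
                     edges: set[tuple[str, str]]) -> tuple[float, dict[str, float]]:
    parents = _feature_parents(features, edges, cache.class_var)
    per_node = {cache.class_var: cache.local(cache.class_var, ())}
    for f in features:
        per_node[f] = cache.local(f, parents[f])
    return sum(per_node.values()), per_node


def bd_score(edges, data: pd.DataFrame, class_var: str = CLASS_VAR,
             ess: float = ESS) -> StructureScore:
    """Log BD score of a feature-feature edge set over ``data``.

    ``data`` is an integer-coded frame including the class column; the
    implicit class edges are always part of the structure.  Raises
    :class:`CyclicStructureError` on a cyclic edge set.
    """
    if class_var not in data.columns:
        raise ConfigurationError(f"data lacks class column {class_var!r}")
    features = tuple(c for c in data.columns if c != class_var)
    edge_set = {tuple(e) for e in edges}
    for a, b in edge_set:
        if a not in features or b not in features:
            raise ConfigurationError(f"edge {(a, b)} references a non-feature node")
    _check_acyclic(features, edge_set)
    cache = _ScoreCache(data, class_var, ess)
    total, per_node = _structure_total(cache, features, edge_set)
    return StructureScore(total=total, per_node=per_node)


def _make_model(features: tuple[str, ...], edges: set[tuple[str, str]],
                cache: _ScoreCache, class_var: str) -> BayesNetModel:
    total, _ = _structure_total(cache, features, edges)
    return BayesNetModel(
        nodes=(class_var,) + features,
        edges=tuple(sorted(edges)),
        class_var=class_var,
        cardinalities=dict(cache.cards),
        parents={class_var: (), **_feature_parents(features, edges, class_var)},
        score=total,
    )


def k2_search(data: pd.DataFrame, order: list[str] | None = None,
              max_parents: int = MAX_PARENTS,
              class_var: str = CLASS_VAR) -> BayesNetModel:
    """K2: greedy parent addition along a fixed node ordering.

    The class variable must come first; when ``order`` is omitted, features
    follow in descending SU with the class (ties lexicographic).  For each
    node, the single predecessor whose addition most increases the BD score
    is added until no gain or ``max_parents`` feature parents.
    """
    features = tuple(c for c in data.columns if c != class_var)
    if order is None:
        from .featselect import su as _su
        y = data[class_var].to_numpy()
        rel = {f: _su(data[f].to_numpy(), y) for f in features}
        order = [class_var] + sorted(features, key=lambda f: (-rel[f], f))
    if order[0] != class_var:
        raise ConfigurationError("node ordering must start with the class variable")
    if set(order) != set(data.columns):
        raise ConfigurationError("ordering must cover exactly the data columns")

    cache = _ScoreCache(data, class_var)
    edges: set[tuple[str, str]] = set()
    informative = [f for f in features if cache.cards[f] > 1]
    for pos, node in enumerate(order[1:], start=1):
        parents = [class_var]
        candidates = [p for p in order[1:pos] if p in informative]
        current = cache.local(node, tuple(parents))
        while len(parents) - 1 < max_parents and candidates:
            gains = [(cache.local(node, tuple(parents + [c])), c) for c in candidates]
            best_score, best_c = max(gains, key=lambda t: (t[0], t[1]))
            if best_score <= current:
                break
            parents.append(best_c)
            candidates.remove(best_c)
            current = best_score
            edges.add((best_c, node))
    return _make_model(features, edges, cache, class_var)


_OP_KINDS = ("add", "delete", "reverse")


def _enumerate_ops(features: tuple[str, ...], edges: set[tuple[str, str]],
                   informative: tuple[str, ...], max_parents: int,
                   cache: _ScoreCache):
    """Yield (kind, a, b, delta) for every legal single-edge move, in the
    canonical tie-break order: add < delete < reverse, lexicographic pairs.

    Only informative (multi-state) features take part: a single-state node
    can neither gain nor give information, and its edges never change any
    local score.
    """
    parents = _feature_parents(features, edges, cache.class_var)
    n_feat_parents = {f: len(parents[f]) - 1 for f in features}

    def local(child: str, pset: tuple[str, ...]) -> float:
        return cache.local(child, pset)

    for a in informative:
        for b in informative:
            if a == b:
                continue
            edge = (a, b)
            if edge not in edges:
                if n_feat_parents[b] >= max_parents:
                    continue
                if _would_cycle(features, edges, edge):
                    continue
                old = local(b, parents[b])
                new = local(b, tuple(sorted(parents[b] + (a,))))
                yield ("add", a, b, new - old)
    for a, b in sorted(edges):
        old = cache.local(b, _feature_parents(features, edges, cache.class_var)[b])
        reduced = tuple(p for p in _feature_parents(features, edges, cache.class_var)[b]
                        if p != a)
        yield ("delete", a, b, cache.local(b, reduced) - old)
    for a, b in sorted(edges):
        # reverse: remove a->b, add b->a
        if len(_feature_parents(features, edges, cache.class_var)[a]) - 1 >= max_parents:
            continue
        trial = set(edges)
        trial.remove((a, b))
        if _would_cycle(features, trial, (b, a)):
            continue
        parents_now = _feature_parents(features, edges, cache.class_var)
        trial.add((b, a))
        parents_new = _feature_parents(features, trial, cache.class_var)
        delta = (cache.local(b, parents_new[b]) - cache.local(b, parents_now[b])
                 + cache.local(a, parents_new[a]) - cache.local(a, parents_now[a]))
        yield ("reverse", a, b, delta)


def _apply_op(edges: set[tuple[str, str]], op) -> set[tuple[str, str]]:
    kind, a, b, _ = op
    new = set(edges)
    if kind == "add":
        new.add((a, b))
    elif kind == "delete":
        new.remove((a, b))
    else:
        new.remove((a, b))
        new.add((b, a))
    return new


def _op_sort_key(op):
    kind, a, b, delta = op
    return (-delta, _OP_KINDS.index(kind), a, b)


def hc_search(data: pd.DataFrame, max_parents: int = MAX_PARENTS,
              class_var: str = CLASS_VAR) -> BayesNetModel:
    """Hill climbing from the naive-Bayes structure.

    Repeatedly applies the best strictly-improving single-edge operation
    (add / delete / reverse on feature-feature edges; class edges are
    immutable) until a local optimum.
    """
    features = tuple(c for c in data.columns if c != class_var)
    cache = _ScoreCache(data, class_var)
    informative = tuple(f for f in features if cache.cards[f] > 1)
    edges: set[tuple[str, str]] = set()
    while True:
        ops = sorted(_enumerate_ops(features, edges, informative, max_parents, cache),
                     key=_op_sort_key)
        if not ops or ops[0][3] <= 1e-12:
            break
        edges = _apply_op(edges, ops[0])
    return _make_model(features, edges, cache, class_var)


def lhc_search(data: pd.DataFrame, max_parents: int = MAX_PARENTS,
               beam: int = 5, depth: int = 2,
               class_var: str = CLASS_VAR) -> BayesNetModel:
    """Hill climbing with look-ahead on a limited set of best-scoring moves.

    At every step the ``beam`` best single-edge operations are expanded
    ``depth`` plies; the first move of the best cumulative sequence is
    applied if that sequence improves the score.  ``beam=1, depth=1``
    degenerates to plain hill climbing.  Visited structures are tracked so
    a look-ahead that undoes its own first move cannot cycle forever.
    """
    if beam < 1 or depth < 1:
        raise ConfigurationError("need beam >= 1 and depth >= 1")
    features = tuple(c for c in data.columns if c != class_var)
    cache = _ScoreCache(data, class_var)
    informative = tuple(f for f in features if cache.cards[f] > 1)

    def best_sequence(edges: set[tuple[str, str]], plies: int) -> float:
        """Best cumulative delta achievable in <= ``plies`` beam-limited moves."""
        if plies == 0:
            return 0.0
        ops = sorted(_enumerate_ops(features, edges, informative, max_parents, cache),
                     key=_op_sort_key)[:beam]
        best = 0.0  # stopping early is always allowed
        for op in ops:
            total = op[3] + best_sequence(_apply_op(edges, op), plies - 1)
            best = max(best, total)
        return best

    edges: set[tuple[str, str]] = set()
    visited = {frozenset(edges)}
    best_edges, best_total = set(edges), _structure_total(cache, features, edges)[0]
    while True:
        ops = sorted(_enumerate_ops(features, edges, informative, max_parents, cache),
                     key=_op_sort_key)[:beam]
        scored = [(op[3] + best_sequence(_apply_op(edges, op), depth - 1), op)
                  for op in ops]
        if not scored:
            break
        scored.sort(key=lambda t: (-t[0],) + _op_sort_key(t[1])[1:])
        total, op = scored[0]
        if total <= 1e-12:
            break
        edges = _apply_op(edges, op)
        key = frozenset(edges)
        current = _structure_total(cache, features, edges)[0]
        if current > best_total:
            best_total, best_edges = current, set(edges)
        if key in visited:
            break
        visited.add(key)
    return _make_model(features, best_edges, cache, class_var)


def fit_cpts(model: BayesNetModel, data: pd.DataFrame) -> BayesNetModel:
    """Fill the model's CPTs with add-one smoothed conditional frequencies.

    Rows for parent configurations absent from the data become uniform.
    """
    cards = dict(model.cardinalities)
    for col in model.nodes:
        observed = int(data[col].to_numpy(dtype=int).max()) + 1 if len(data) else 1
        cards[col] = max(cards.get(col, 1), observed, 1)
    cpts: dict[str, np.ndarray] = {}
    for node in model.nodes:
        parents = model.parents.get(node, ())
        shape = tuple(cards[p] for p in parents) + (cards[node],)
        counts = np.ones(shape)  # Laplace add-one
        idx_cols = [data[p].to_numpy(dtype=int) for p in parents]
        child = data[node].to_numpy(dtype=int)
        np.add.at(counts, tuple(idx_cols) + (child,), 1.0)
        cpts[node] = counts / counts.sum(axis=-1, keepdims=True)
    model.cpts = cpts
    model.cardinalities = cards
    return model


def predict(model: BayesNetModel, instance: dict | pd.Series) -> tuple[int, np.ndarray]:
    """MAP class label and posterior for one discretized instance.

    Ties (p(1) == p(0)) resolve to the negative class 0.  Raises
    :class:`ConfigurationError` if a feature is missing from the instance.
    """
    if not model.cpts:
        raise ConfigurationError("model has no CPTs; call fit_cpts first")
    inst = dict(instance)
    for f in model.features:
        if f not in inst:
            raise ConfigurationError(f"instance lacks feature {f!r}")
    n_classes = model.cardinalities[model.class_var]
    logp = np.zeros(n_classes)
    for y in range(n_classes):
        lp = np.log(model.cpts[model.class_var][y])
        assign = {model.class_var: y}
        assign.update({f: min(int(inst[f]), model.cardinalities[f] - 1)
                       for f in model.features})
        for f in model.features:
            idx = tuple(assign[p] for p in model.parents[f]) + (assign[f],)
            lp += np.log(model.cpts[f][idx])
        logp[y] = lp
    posterior = np.exp(logp - logp.max())
    posterior /= posterior.sum()
    label = int(posterior[1] > posterior[0]) if n_classes == 2 else int(np.argmax(posterior))
    return label, posterior
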