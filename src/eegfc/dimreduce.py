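"""Flat connectivity profiles, synchronisation cluster analysis, and the
dataset variants consumed by feature selection and classification.

A subject's *FC profile* concatenates the strictly-upper-triangle entries of
all connectivity matrices in a canonical order: condition-major (EO then
EC), within a condition PLV over the five bands delta..gamma then PLI over
the same bands, within a matrix row-major pairs of the canonical electrode
order.  With 8 electrodes that is 28 features per matrix and 28 x 20 = 560
for the merged profile (280 per PS index).

Synchronisation cluster analysis (SCA) condenses one matrix to a length-N
vector: it fits the single-cluster factor model A_il ~ rho_i * rho_l (i != l)
where rho_i in [0, 1] is the coupling of oscillator i to a common rhythm,
and summarises overall cluster strength as r = lambda_1 / N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BAND_NAMES,
    CONDITIONS,
    PS_INDICES,
    ConfigurationError,
    ConnectivityMatrix,
    IncompleteProfileError,
    ScaInapplicableError,
)

__all__ = [
    "FCProfile",
    "SCAResult",
    "FeatureTable",
    "DATASET_IDS",
    "feature_name",
    "parse_feature_name",
    "vectorize_upper",
    "build_profile",
    "sca",
    "build_tables",
]

#: The seven dataset variants: raw profiles from random (R), stationary (Rt)
#: and surrogate-thresholded stationary (RSt) segments, plus the SCA
#: reductions of R and Rt.
DATASET_IDS: tuple[str, ...] = ("R", "Rt", "RSt", "rho", "r", "rho_t", "r_t")

_NAME_RE = re.compile(
    r"^(?P<index>PLV|PLI)_(?P<condition>EO|EC)_(?P<band>[a-z]+)_"
    r"(?P<a>[A-Za-z0-9]+)-(?P<b>[A-Za-z0-9]+)$"
)


def feature_name(index: str, condition: str, band: str, ch_a: str, ch_b: str) -> str:
    """Canonical name of one pairwise feature, e.g. ``PLV_EO_beta_T3-Fp2``."""
    return f"{index}_{condition}_{band}_{ch_a}-{ch_b}"


def parse_feature_name(name: str) -> tuple[str, str, str, tuple[str, str]]:
    """Inverse of :func:`feature_name` (lossless round-trip)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ConfigurationError(f"not a canonical feature name: {name!r}")
    return (m["index"], m["condition"], m["band"], (m["a"], m["b"]))


@dataclass
class FCProfile:
    """Ordered flat feature vector of one subject."""

    subject_id: str
    group: str
    names: tuple[str, ...]
    values: np.ndarray


@dataclass
class SCAResult:
    """Per-oscillator couplings ``rho`` and overall strength ``r``."""

    rho: np.ndarray
    r: float
    n_iterations: int


def vectorize_upper(matrix: ConnectivityMatrix) -> tuple[tuple[str, ...], np.ndarray]:
    """Strictly-upper-triangle entries in row-major order with canonical
    names; an 8 x 8 matrix yields 28 features."""
    values = matrix.values
    n = values.shape[0]
    if values.shape != (n, n):
        raise ConfigurationError("connectivity matrix must be square")
    names, out = [], []
    labels = matrix.channel_labels
    for i in range(n):
        for l in range(i + 1, n):
            names.append(feature_name(matrix.index, matrix.condition,
                                      matrix.band, labels[i], labels[l]))
            out.append(values[i, l])
    return tuple(names), np.asarray(out)


def build_profile(matrices: list[ConnectivityMatrix],
                  indices: tuple[str, ...] = PS_INDICES,
                  bands: tuple[str, ...] = BAND_NAMES,
                  conditions: tuple[str, ...] = CONDITIONS) -> FCProfile:
    """Concatenate a subject's matrices in the canonical profile order.

    Raises :class:`IncompleteProfileError` naming the first missing
    (index, condition, band) combination.  Input arrival order is
    irrelevant; the output order is always canonical.
    """
    if not matrices:
        raise IncompleteProfileError("no matrices supplied")
    by_key = {}
    for m in matrices:
        by_key[(m.index, m.condition, m.band)] = m
    subject = matrices[0].subject_id
    names: list[str] = []
    values: list[np.ndarray] = []
    for condition in conditions:
        for index in indices:
            for band in bands:
                key = (index, condition, band)
                if key not in by_key:
                    raise IncompleteProfileError(
                        f"missing matrix index={index} condition={condition} "
                        f"band={band} for subject {subject!r}"
                    )
                nm, vals = vectorize_upper(by_key[key])
                names.extend(nm)
                values.append(vals)
    return FCProfile(subject_id=subject, group=getattr(matrices[0], "group", ""),
                     names=tuple(names), values=np.concatenate(values))


def sca(matrix: ConnectivityMatrix | np.ndarray, tol: float = 1e-10,
        max_iter: int = 100) -> SCAResult:
    """Single-cluster factor model of a PS matrix.

    Fits A_il ~ rho_i * rho_l on the off-diagonal by an iterated
    diagonal-corrected leading-eigenpair factorisation: the uninformative
    unit diagonal is first replaced by row-means of the off-diagonal, then
    repeatedly by rho_i**2, with rho = sqrt(lambda_1) * v_1 (sign-fixed
    nonnegative, clipped to [0, 1]) until max |delta rho| < ``tol``.  On an
    exact outer-product matrix the fixed point recovers the generating rho.
    ``r = lambda_1 / N`` so r = 1 iff all rho_i = 1.

    Raises :class:`ScaInapplicableError` when every off-diagonal entry is
    zero (a fully surrogate-thresholded matrix).
    """
    A = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T, atol=1e-12):
        raise ConfigurationError("SCA needs a symmetric square matrix")
    off = A[~np.eye(n, dtype=bool)]
    if np.all(off == 0.0):
        raise ScaInapplicableError(
            "all off-diagonal couplings are zero; the single-cluster model "
            "is undefined for a fully thresholded matrix"
        )
    if off.min() < -1e-12 or off.max() > 1.0 + 1e-12:
        raise ConfigurationError("PS matrix entries must lie in [0, 1]")

    work = A.copy()
    np.fill_diagonal(work, (A.sum(axis=1) - np.diag(A)) / (n - 1))
    rho = np.zeros(n)
    lam = 0.0
    for it in range(1, max_iter + 1):
        eigvals, eigvecs = np.linalg.eigh(work)
        lam, v = eigvals[-1], eigvecs[:, -1]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        new_rho = np.clip(np.sqrt(max(lam, 0.0)) * v, 0.0, 1.0)
        delta = np.max(np.abs(new_rho - rho))
        rho = new_rho
        np.fill_diagonal(work, rho ** 2)
        if delta < tol:
            break
    return SCAResult(rho=rho, r=float(lam / n), n_iterations=it)


@dataclass
class FeatureTable:
    """Subjects x named features plus a binary ``class`` column (1 = pos)."""

    dataset_id: str
    frame: pd.DataFrame

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c != "class")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


MatrixSet = dict[str, list[ConnectivityMatrix]]  # subject_id -> matrices


def _profile_features(mats: list[ConnectivityMatrix], indices: tuple[str, ...],
                      bands: tuple[str, ...]) -> tuple[tuple[str, ...], np.ndarray]:
    p = build_profile(mats, indices=indices, bands=bands)
    return p.names, p.values


def _sca_features(mats: list[ConnectivityMatrix], indices: tuple[str, ...],
                  kind: str, bands: tuple[str, ...]) -> tuple[tuple[str, ...], np.ndarray]:
    by_key = {(m.index, m.condition, m.band): m for m in mats}
    names: list[str] = []
    values: list[float] = []
    for condition in CONDITIONS:
        for index in indices:
            for band in bands:
                key = (index, condition, band)
                if key not in by_key:
                    raise IncompleteProfileError(
                        f"missing matrix index={index} condition={condition} band={band}"
                    )
                res = sca(by_key[key])
                if kind == "rho":
                    labels = by_key[key].channel_labels
                    for ch, val in zip(labels, res.rho):
                        names.append(f"rho_{index}_{condition}_{band}_{ch}")
                        values.append(float(val))
                else:
                    names.append(f"r_{index}_{condition}_{band}")
                    values.append(res.r)
    return tuple(names), np.asarray(values)


def build_tables(subject_matrices: MatrixSet, groups: dict[str, str],
                 variant: str, ps_index: str | tuple[str, ...] = "both",
                 bands: tuple[str, ...] | None = None) -> FeatureTable:
    """Assemble one dataset variant as a feature table.

    ``subject_matrices`` maps each subject to its full matrix set for the
    segment-selection regime the variant implies (random for R/rho/r,
    stationary for Rt/rho_t/r_t, thresholded stationary for RSt) — the
    caller owns that pairing; this function owns naming, ordering and
    feature counts.  ``ps_index`` restricts to one index (Table-style
    per-index datasets, e.g. 280 features for R) or merges both (560).
    ``bands`` defaults to the bands present in the supplied matrices, in
    canonical delta..gamma order.
    """
    if variant not in DATASET_IDS:
        raise ConfigurationError(f"unknown dataset variant {variant!r}")
    if ps_index == "both":
        indices: tuple[str, ...] = PS_INDICES
    elif isinstance(ps_index, str):
        indices = (ps_index,)
    else:
        indices = tuple(ps_index)
    for ix in indices:
        if ix not in PS_INDICES:
            raise ConfigurationError(f"unknown PS index {ix!r}")

    kind = "profile"
    if variant in ("rho", "rho_t"):
        kind = "rho"
    elif variant in ("r", "r_t"):
        kind = "r"

    if bands is None:
        present = {m.band for mats in subject_matrices.values() for m in mats}
        bands = tuple(b for b in BAND_NAMES if b in present)
        bands += tuple(sorted(present - set(bands)))

    rows, idx, names = [], [], None
    for subject in sorted(subject_matrices):
        mats = subject_matrices[subject]
        if kind == "profile":
            nm, vals = _profile_features(mats, indices, bands)
        else:
            nm, vals = _sca_features(mats, indices, kind, bands)
        if names is None:
            names = nm
        elif nm != names:
            raise ConfigurationError("inconsistent feature sets across subjects")
        rows.append(np.append(vals, 1.0 if groups[subject] == "pos" else 0.0))
        idx.append(subject)
    if names is None:
        raise ConfigurationError("empty matrix set")
    frame = pd.DataFrame(rows, index=pd.Index(idx, name="subject_id"),
                         columns=list(names) + ["class"])
    frame["class"] = frame["class"].astype(int)
    if frame.isna().any().any():
        raise ConfigurationError("feature table contains missing values")
    return FeatureTable(dataset_id=variant, frame=frame)
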