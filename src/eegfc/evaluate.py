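"""Leave-one-out evaluation and the dataset x selector x search grid.

``loocv`` holds out one subject per fold; discretization, feature selection
(in nested mode), structure search and CPT fitting all happen on the
training fold only.  In the default *faithful* mode the selector runs once
on the full table before cross-validation — reproducing the original
protocol, at the cost of a selection-leakage optimism that the nested mode
avoids.

``run_grid`` sweeps PS index {PLI, PLV} x dataset variant {r, rho, R, r_t,
rho_t, Rt, RSt} x selector {none, FCBF, SS} x search strategy {K2, HC, LHC}
and emits one tidy row per cell with sensitivity, specificity and accuracy
(positive class = patient group); cells with accuracy >= 0.70 are flagged.
SCA on the surrogate-thresholded variant is emitted as an explicit
``sca-inapplicable`` marker row, since fully thresholded matrices leave the
single-cluster model undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayesclf import fit_cpts, hc_search, k2_search, lhc_search, predict
from .core import (
    CONDITIONS,
    DEFAULT_BANDS,
    BandSpec,
    ConfigurationError,
    ConnectivityMatrix,
    EegRecording,
    ScaInapplicableError,
)
from .dimreduce import DATASET_IDS, FeatureTable, build_tables
from .featselect import (
    DiscretizedTable,
    apply_cut_points,
    discretize,
    fcbf,
    scatter_search,
)
from .phasesync import connectivity
from .preprocess import bandpass, kpss_average, segment_and_normalize, select_segments
from .twinsurr import significance_matrix, threshold_matrix

__all__ = [
    "PipelineConfig",
    "EvalResult",
    "metrics",
    "loocv",
    "compute_connectivity",
    "run_grid",
]

SELECTORS = ("none", "FCBF", "SS")
STRATEGIES = ("K2", "HC", "LHC")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-stage knobs, with the study defaults."""

    seg_seconds: float = 20.0
    k_segments: int = 5
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    edge_seconds: float = 0.5
    fir_order: int = 256
    kpss_variant: str = "level"
    n_surrogates: int = 99
    selector_mode: str = "faithful"     # or "nested"
    discretize_method: str = "mdlp"
    max_parents: int = 2
    beam: int = 5
    depth: int = 2


@dataclass
class EvalResult:
    """One LOOCV run: per-fold predictions plus summary metrics."""

    dataset_id: str
    ps_index: str
    selector: str
    strategy: str
    subjects: tuple[str, ...]
    labels: np.ndarray
    predictions: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    selected_features: tuple[str, ...] = ()

    @property
    def flagged(self) -> bool:
        return bool(self.accuracy >= 0.70)


def metrics(predictions, labels) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with positive class = 1.

    Undefined ratios (no positives, or no negatives, among the true labels)
    are returned as NaN, never silently as 0.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ConfigurationError("predictions and labels must have equal length")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / len(labels) if len(labels) else float("nan")
    return sens, spec, acc


def _run_selector(dt: DiscretizedTable, selector: str, seed: int) -> tuple[str, ...]:
    if selector == "none":
        return dt.feature_names
    if selector == "FCBF":
        return fcbf(dt).selected
    if selector == "SS":
        return scatter_search(dt, seed=seed).selected
    raise ConfigurationError(f"unknown selector {selector!r}")


def _search(strategy: str, frame: pd.DataFrame, config: PipelineConfig):
    if strategy == "K2":
        return k2_search(frame, max_parents=config.max_parents)
    if strategy == "HC":
        return hc_search(frame, max_parents=config.max_parents)
    if strategy == "LHC":
        return lhc_search(frame, max_parents=config.max_parents,
                          beam=config.beam, depth=config.depth)
    raise ConfigurationError(f"unknown search strategy {strategy!r}")


def loocv(table: FeatureTable, selector: str = "none", strategy: str = "K2",
          config: PipelineConfig = PipelineConfig(), seed: int = 0) -> EvalResult:
    """Leave-one-subject-out evaluation of one dataset variant."""
    frame = table.frame
    labels = frame["class"].to_numpy(dtype=int)
    if np.unique(labels).size < 2:
        raise ConfigurationError("cannot cross-validate a single-class table")

    selected_full: tuple[str, ...] | None = None
    if config.selector_mode == "faithful":
        dt_full = discretize(frame, method=config.discretize_method)
        selected_full = _run_selector(dt_full, selector, seed)
    elif config.selector_mode != "nested":
        raise ConfigurationError(f"unknown selector_mode {config.selector_mode!r}")

    predictions = np.empty(len(frame), dtype=int)
    for i in range(len(frame)):
        train = frame.drop(frame.index[i])
        if selected_full is not None:
            features = selected_full
        else:
            features = _run_selector(
                discretize(train, method=config.discretize_method), selector, seed)
        cols = list(features) + ["class"]
        dt_train = discretize(train[cols], method=config.discretize_method)
        model = _search(strategy, dt_train.frame, config)
        model = fit_cpts(model, dt_train.frame)
        model.cut_points = dt_train.cut_points
        instance = {
            f: int(apply_cut_points(
                np.array([frame.iloc[i][f]]), dt_train.cut_points[f])[0])
            for f in features
        }
        predictions[i], _ = predict(model, instance)

    sens, spec, acc = metrics(predictions, labels)
    return EvalResult(
        dataset_id=table.dataset_id, ps_index="", selector=selector,
        strategy=strategy, subjects=tuple(frame.index), labels=labels,
        predictions=predictions, sensitivity=sens, specificity=spec,
        accuracy=acc,
        selected_features=selected_full if selected_full is not None else (),
    )


# ---------------------------------------------------------------------------
# Cohort -> connectivity matrices

def _by_subject(recordings: list[EegRecording]) -> dict[str, dict[str, EegRecording]]:
    out: dict[str, dict[str, EegRecording]] = {}
    for rec in recordings:
        out.setdefault(rec.subject_id, {})[rec.condition] = rec
    return out


def compute_connectivity(recordings: list[EegRecording],
                         config: PipelineConfig = PipelineConfig(),
                         selection_mode: str = "stationary", seed: int = 0,
                         threshold: bool = False,
                         ) -> tuple[dict[str, list[ConnectivityMatrix]], dict[str, str]]:
    """Full preprocessing + connectivity stage for a cohort.

    Returns ``(subject -> 20 matrices, subject -> group)``.  With
    ``threshold=True`` every matrix is surrogate-thresholded (majority rule
    across the analysis segments) — the RSt regime.
    """
    grouped = _by_subject(recordings)
    matrices: dict[str, list[ConnectivityMatrix]] = {}
    groups: dict[str, str] = {}
    for s_no, subject in enumerate(sorted(grouped)):
        mats: list[ConnectivityMatrix] = []
        for condition in CONDITIONS:
            if condition not in grouped[subject]:
                raise ConfigurationError(
                    f"subject {subject!r} lacks condition {condition!r}")
            rec = grouped[subject][condition]
            groups[subject] = rec.group
            segments = segment_and_normalize(rec, config.seg_seconds)
            scores = [kpss_average(s, config.kpss_variant) for s in segments]
            sel_seed = int(np.random.SeedSequence(
                [seed, s_no, CONDITIONS.index(condition)]).generate_state(1)[0])
            chosen = select_segments(scores, k=config.k_segments,
                                     mode=selection_mode, seed=sel_seed)
            analysis = [segments[g] for g in chosen]
            for band in config.bands:
                band_segs = [bandpass(s, band, config.fir_order) for s in analysis]
                for index in ("PLV", "PLI"):
                    m = connectivity(band_segs, index, config.edge_seconds)
                    m.band = band.name
                    if threshold:
                        sig_seed = int(np.random.SeedSequence(
                            [seed, 7919, s_no, CONDITIONS.index(condition),
                             config.bands.index(band),
                             0 if index == "PLV" else 1]).generate_state(1)[0])
                        mask = significance_matrix(
                            band_segs, index, n_s=config.n_surrogates,
                            seed=sig_seed, edge_seconds=config.edge_seconds)
                        m = threshold_matrix(m, mask)
                    mats.append(m)
        matrices[subject] = mats
    return matrices, groups


def run_grid(recordings: list[EegRecording],
             config: PipelineConfig = PipelineConfig(),
             selectors: tuple[str, ...] = ("none",),
             strategies: tuple[str, ...] = STRATEGIES,
             ps_indices: tuple[str, ...] = ("PLI", "PLV"),
             variants: tuple[str, ...] = DATASET_IDS,
             seed: int = 0) -> pd.DataFrame:
    """The full experiment grid as a tidy frame (one row per cell)."""
    need_random = any(v in variants for v in ("R", "rho", "r"))
    need_stationary = any(v in variants for v in ("Rt", "rho_t", "r_t"))
    need_thresh = "RSt" in variants

    random_mats = stationary_mats = thresh_mats = None
    groups: dict[str, str] = {}
    if need_random:
        random_mats, groups = compute_connectivity(
            recordings, config, "random", seed)
    if need_stationary:
        stationary_mats, groups = compute_connectivity(
            recordings, config, "stationary", seed)
    if need_thresh:
        thresh_mats, groups = compute_connectivity(
            recordings, config, "stationary", seed, threshold=True)

    source = {
        "R": random_mats, "rho": random_mats, "r": random_mats,
        "Rt": stationary_mats, "rho_t": stationary_mats, "r_t": stationary_mats,
        "RSt": thresh_mats,
    }

    rows = []
    for ps_index in ps_indices:
        for variant in variants:
            try:
                table = build_tables(source[variant], groups, variant,
                                     ps_index=ps_index)
            except ScaInapplicableError as err:
                rows.append({
                    "ps_index": ps_index, "dataset_id": variant,
                    "selector": "", "strategy": "",
                    "sensitivity": np.nan, "specificity": np.nan,
                    "accuracy": np.nan, "flagged": False, "n_features": 0,
                    "note": f"sca-inapplicable: {err}",
                })
                continue
            for selector in selectors:
                for strategy in strategies:
                    try:
                        res = loocv(table, selector, strategy, config, seed)
                    except Exception as err:  # recorded, not fatal (na cells)
                        rows.append({
                            "ps_index": ps_index, "dataset_id": variant,
                            "selector": selector, "strategy": strategy,
                            "sensitivity": np.nan, "specificity": np.nan,
                            "accuracy": np.nan, "flagged": False,
                            "n_features": table.n_features,
                            "note": f"{type(err).__name__}: {err}",
                        })
                        continue
                    rows.append({
                        "ps_index": ps_index, "dataset_id": variant,
                        "selector": selector, "strategy": strategy,
                        "sensitivity": res.sensitivity,
                        "specificity": res.specificity,
                        "accuracy": res.accuracy, "flagged": res.flagged,
                        "n_features": table.n_features,
                        "note": "",
                    })
        if need_thresh:
            # SCA of the thresholded variant: undefined whenever a subject's
            # matrix is fully zeroed, so it is skipped with an explicit marker.
            for variant in ("rho_St", "r_St"):
                rows.append({
                    "ps_index": ps_index, "dataset_id": variant,
                    "selector": "", "strategy": "",
                    "sensitivity": np.nan, "specificity": np.nan,
                    "accuracy": np.nan, "flagged": False, "n_features": 0,
                    "note": "sca-inapplicable: skipped by design",
                })
    return pd.DataFrame(rows)


def read_edf(path, subject_id: str, condition: str, group: str) -> EegRecording:
    """Optional EDF ingestion (requires the ``mne`` extra)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF input needs the optional dependency mne") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    from .core import CANONICAL_CHANNELS
    present = [ch for ch in CANONICAL_CHANNELS if ch in raw.ch_names]
    if present:
        raw = raw.pick(present)
    return EegRecording(
        subject_id=subject_id, condition=condition, group=group,
        data=raw.get_data(), fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )
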