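"""MDLP discretization, symmetrical uncertainty, FCBF and Scatter Search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eegfc as E
from eegfc.featselect import (
    DiscretizedTable,
    cfs_merit,
    discretize,
    fcbf,
    mdlp_cut_points,
    scatter_search,
    su,
)


def table(frame: pd.DataFrame) -> DiscretizedTable:
    return DiscretizedTable(frame=frame.astype(int), cut_points={})


def random_table(seed, n_features=8, n=30, relevant=4):
    """Random discrete table with a few class-informative features."""
    r = np.random.default_rng(seed)
    y = r.integers(0, 2, n)
    df = pd.DataFrame({f"F{i}": r.integers(0, 3, n) for i in range(n_features)})
    for i in range(min(relevant, n_features)):
        mask = r.random(n) < 0.5
        df.loc[mask, f"F{i}"] = y[mask]
    df["class"] = y
    return table(df)


def fcbf_reference(dt: DiscretizedTable, delta: float = 0.0):
    """Direct transcription of the approximate-Markov-blanket definitions:
    scan features by descending class-SU and keep each one iff no retained
    predecessor blankets it."""
    y = dt.frame["class"].to_numpy()
    su_y = {f: su(dt.frame[f].to_numpy(), y) for f in dt.feature_names}
    ordered = sorted((f for f in dt.feature_names if su_y[f] > delta),
                     key=lambda f: (-su_y[f], f))
    retained = []
    for f in ordered:
        x = dt.frame[f].to_numpy()
        if not any(su(x, dt.frame[g].to_numpy()) >= su_y[f] for g in retained):
            retained.append(f)
    return tuple(retained)


class TestMdlpDiscretize:
    def test_perfect_split_accepted(self):
        cuts = mdlp_cut_points(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert np.allclose(cuts, [2.5])

    def test_single_class_labels_give_single_bin(self):
        cuts = mdlp_cut_points(np.arange(20.0), np.zeros(20, dtype=int))
        assert cuts.size == 0

    def test_constant_feature_gives_single_bin(self):
        cuts = mdlp_cut_points(np.ones(20), np.arange(20) % 2)
        assert cuts.size == 0

    def test_discretize_preserves_class_and_maps_bins(self):
        df = pd.DataFrame({"F0": [1.0, 2, 3, 4] * 5, "class": [0, 0, 1, 1] * 5})
        dt = discretize(df)
        assert np.array_equal(dt.frame["class"], df["class"])
        assert set(dt.frame["F0"]) == {0, 1}
        assert np.array_equal(dt.frame["F0"], (df["F0"] > 2.5).astype(int))

    def test_non_binary_class_rejected(self):
        df = pd.DataFrame({"F0": [1.0, 2, 3], "class": [0, 1, 2]})
        with pytest.raises(E.ConfigurationError):
            discretize(df)


class TestSymmetricalUncertainty:
    def test_identical_balanced_binary_is_one(self):
        x = np.array([0, 0, 1, 1, 0, 1])
        assert su(x, x) == pytest.approx(1.0)

    def test_independent_product_table_is_zero(self):
        # exact product structure: every (x, y) cell equally frequent
        x = np.array([0, 0, 1, 1] * 5)
        y = np.array([0, 1, 0, 1] * 5)
        assert su(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_2x2_counts_3113(self):
        # counts [[3,1],[1,3]]: H(X)=H(Y)=1, H(X|Y)=H(1/4)=0.811278,
        # IG=0.188722, SU = 2*IG/2 = 0.188722
        x = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert su(x, y) == pytest.approx(0.18872187554086717, abs=1e-12)

    def test_constant_pair_defined_as_zero(self):
        assert su(np.zeros(5), np.zeros(5)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(E.ConfigurationError):
            su(np.array([]), np.array([]))

    @given(st.integers(0, 500))
    def test_symmetry_and_range(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 4, 30)
        y = r.integers(0, 3, 30)
        assert su(x, y) == pytest.approx(su(y, x), abs=1e-12)
        assert 0.0 <= su(x, y) <= 1.0


class TestFcbf:
    def toy(self):
        # continuous features through MDLP: the noise column accepts no cut
        # and collapses to one bin (SU = 0)
        r = np.random.default_rng(0)
        y = r.integers(0, 2, 60)
        df = pd.DataFrame({
            "F1": y + 0.01 * r.random(60),
            "F2": y + 0.01 * r.random(60),
            "F3": r.random(60),
            "class": y,
        })
        return discretize(df)

    def test_copy_removed_noise_dropped(self):
        res = fcbf(self.toy())
        assert res.selected == ("F1",)
        assert ("F2", "F1") in res.removed
        assert "F3" in res.irrelevant

    def test_conditionally_independent_relevant_features_all_retained(self):
        # two noisy copies of Y with independent noise: each is class-relevant
        # and their mutual SU (via Y only) is weaker than their class SU, so
        # neither blankets the other
        r = np.random.default_rng(1)
        n = 400
        y = r.integers(0, 2, n)
        f1 = np.where(r.random(n) < 0.8, y, 1 - y)
        f2 = np.where(r.random(n) < 0.8, y, 1 - y)
        res = fcbf(table(pd.DataFrame({"F1": f1, "F2": f2, "class": y})))
        assert set(res.selected) == {"F1", "F2"}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_definition_transcription(self, seed):
        dt = random_table(seed)
        assert fcbf(dt).selected == fcbf_reference(dt)

    def test_empty_selection_is_legal(self):
        r = np.random.default_rng(2)
        df = pd.DataFrame({"F0": np.zeros(20, int), "class": r.integers(0, 2, 20)})
        res = fcbf(table(df))
        assert res.selected == ()


class TestCfsMerit:
    def test_singleton_merit_is_class_su(self):
        dt = random_table(3)
        y = dt.frame["class"].to_numpy()
        for f in dt.feature_names[:3]:
            assert cfs_merit((f,), dt) == pytest.approx(
                su(dt.frame[f].to_numpy(), y))

    def test_pair_of_identical_features_reduces_to_single_su(self):
        # r_ff = 1, r_cf = SU(f, Y):  M = 2 r / sqrt(2 + 2) = r
        r = np.random.default_rng(4)
        y = r.integers(0, 2, 40)
        f = np.where(r.random(40) < 0.8, y, 1 - y)
        df = pd.DataFrame({"F1": f, "F2": f, "class": y})
        dt = table(df)
        assert cfs_merit(("F1", "F2"), dt) == pytest.approx(
            cfs_merit(("F1",), dt), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_duplicating_weakest_member_never_raises_merit(self, seed):
        dt = random_table(seed, n_features=3)
        y = dt.frame["class"].to_numpy()
        su_y = {f: su(dt.frame[f].to_numpy(), y) for f in dt.feature_names}
        for k in (1, 2, 3):
            subset = tuple(dt.feature_names[:k])
            weakest = min(subset, key=lambda f: su_y[f])
            df2 = dt.frame.copy()
            df2.insert(0, "DUP", df2[weakest])
            dt2 = table(df2)
            assert cfs_merit(subset + ("DUP",), dt2) <= cfs_merit(subset, dt2) + 1e-12

    def test_empty_subset_rejected(self):
        with pytest.raises(E.UndefinedMeritError):
            cfs_merit((), random_table(0))


class TestScatterSearch:
    def exhaustive_best_merit(self, dt):
        y = dt.frame["class"].to_numpy()
        feats = [f for f in dt.feature_names
                 if su(dt.frame[f].to_numpy(), y) > 0]
        best = 0.0
        for k in range(1, len(feats) + 1):
            for S in itertools.combinations(feats, k):
                best = max(best, cfs_merit(S, dt))
        return best

    def test_returns_unique_singleton_optimum(self):
        r = np.random.default_rng(5)
        y = r.integers(0, 2, 60)
        df = pd.DataFrame({"F1": y, "F2": r.integers(0, 2, 60),
                           "F3": r.integers(0, 2, 60), "class": y})
        res = scatter_search(table(df), seed=0)
        assert res.selected == ("F1",)
        assert res.merit == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_reaches_exhaustive_optimum_on_toys(self, seed):
        dt = random_table(seed, n_features=7, n=40)
        res = scatter_search(dt, seed=17)
        assert res.merit == pytest.approx(self.exhaustive_best_merit(dt), abs=1e-9)

    def test_seed_deterministic(self):
        dt = random_table(9)
        a = scatter_search(dt, seed=3)
        b = scatter_search(dt, seed=3)
        assert a.selected == b.selected

    def test_merit_at_least_best_singleton(self):
        dt = random_table(11)
        y = dt.frame["class"].to_numpy()
        best_single = max(su(dt.frame[f].to_numpy(), y) for f in dt.feature_names)
        assert scatter_search(dt, seed=1).merit >= best_single - 1e-12

    def test_all_irrelevant_gives_empty_selection(self):
        df = pd.DataFrame({"F0": np.zeros(20, int), "F1": np.zeros(20, int),
                           "class": np.arange(20) % 2})
        res = scatter_search(table(df), seed=0)
        assert res.selected == ()
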