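"""Nested PERMANOVA: pseudo-F, type III SS, omega^2, permutations, dispersion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from spatiomic.distances import bray_curtis
from spatiomic.permanova import (
    DesignSpec,
    Term,
    beta_dispersion,
    mle_design,
    omega_squared,
    one_factor_design,
    permanova,
)
from spatiomic.simulate import SimulationConfig, simulate_community, simulate_design

from conftest import grid_metadata, random_table


def _euclid_dm(x: np.ndarray, ids):
    return DistanceMatrix(squareform(pdist(np.atleast_2d(x.T).T)), ids=ids)


def _one_factor_meta(labels):
    meta = grid_metadata(len(labels))
    meta["group"] = labels
    return meta


class TestPseudoF:
    def test_equals_classical_anova_f(self, rng):
        for _ in range(5):
            groups = ["a"] * 5 + ["b"] * 4 + ["c"] * 6
            x = rng.normal(size=len(groups)) + np.repeat(rng.normal(size=3, scale=2), [5, 4, 6])
            meta = _one_factor_meta(groups)
            dm = _euclid_dm(x[:, None], list(meta.index))
            tab = permanova(dm, meta, one_factor_design("group"), n_perm=0)
            f_classic = stats.f_oneway(x[:5], x[5:9], x[9:]).statistic
            assert tab.loc["group", "pseudo_F"] == pytest.approx(f_classic, rel=1e-8)
            assert tab.loc["group", "df"] == 2

    def test_matches_skbio_one_factor(self, rng):
        table = random_table(rng, n_samples=12, n_taxa=10, depth=300)
        dm = bray_curtis(table)
        labels = ["a"] * 6 + ["b"] * 6
        meta = _one_factor_meta(labels)
        ours = permanova(dm, meta, one_factor_design("group"), n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        assert ours.loc["group", "pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-8)

    def test_gower_identity_total_ss(self, rng):
        x = rng.normal(size=(9, 3))
        dm = _euclid_dm(x, [f"s{i}" for i in range(9)])
        meta = _one_factor_meta(["a"] * 4 + ["b"] * 5)
        tab = permanova(dm, meta, one_factor_design("group"), n_perm=0)
        expect = np.sum((x - x.mean(axis=0)) ** 2)
        assert tab.loc["Total", "SS"] == pytest.approx(expect, rel=1e-8)

    def test_balanced_ss_additivity(self, rng):
        # crossed 2-factor balanced design: marginal SS are orthogonal
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(np.repeat(["b1", "b2"], 3), 2)
        meta = grid_metadata(12)
        meta["fa"], meta["fb"] = a, b
        x = rng.normal(size=(12, 4))
        dm = _euclid_dm(x, list(meta.index))
        design = DesignSpec(
            terms=[Term("A", ["fa"]), Term("B", ["fb"]), Term("AB", ["fa", "fb"])]
        )
        tab = permanova(dm, meta, design, n_perm=0)
        parts = tab.loc[["A", "B", "AB", "Residual"], "SS"].sum()
        assert parts == pytest.approx(tab.loc["Total", "SS"], rel=1e-8)
        assert tab.loc[["A", "B", "AB", "Residual"], "df"].sum() == 11

    def test_aliased_design_rejected(self, rng):
        meta = _one_factor_meta(["a"] * 4 + ["b"] * 4)
        meta["copy"] = meta["group"]
        x = rng.normal(size=8)
        dm = _euclid_dm(x[:, None], list(meta.index))
        design = DesignSpec(terms=[Term("g", ["group"]), Term("g2", ["copy"])])
        with pytest.raises(ValueError, match="aliased|singular"):
            permanova(dm, meta, design, n_perm=0)


class TestPermutations:
    def test_exact_enumeration_matches_brute_force(self, rng):
        # one factor, n = 6: full enumeration of all 720 relabelings
        labels = np.array(["a"] * 3 + ["b"] * 3)
        x = rng.normal(size=6)
        x[3:] += 1.5
        meta = _one_factor_meta(list(labels))
        dm = _euclid_dm(x[:, None], list(meta.index))
        tab = permanova(dm, meta, one_factor_design("group"), enumerate_all=True, n_perm=0)

        def f_of(perm):
            xp = x[list(perm)]
            g1, g2 = xp[labels == "a"], xp[labels == "b"]
            return stats.f_oneway(g1, g2).statistic

        f_obs = f_of(range(6))
        fs = np.array([f_of(p) for p in itertools.permutations(range(6))])
        p_exact = np.mean(fs >= f_obs - 1e-12)
        assert tab.loc["group", "p_perm"] == pytest.approx(p_exact, abs=1e-12)

    def test_p_value_convention(self, rng):
        # Monte-Carlo p = (b + 1) / (n_perm + 1) is never 0
        meta = _one_factor_meta(["a"] * 4 + ["b"] * 4)
        x = rng.normal(size=8)
        x[4:] += 10
        dm = _euclid_dm(x[:, None], list(meta.index))
        tab = permanova(dm, meta, one_factor_design("group"), n_perm=99, seed=1)
        assert tab.loc["group", "p_perm"] >= 1 / 100

    def test_deterministic_given_seed(self, rng):
        table = random_table(rng, n_samples=10, n_taxa=8, depth=300)
        dm = bray_curtis(table)
        meta = _one_factor_meta(["a"] * 5 + ["b"] * 5)
        t1 = permanova(dm, meta, one_factor_design("group"), n_perm=49, seed=3)
        t2 = permanova(dm, meta, one_factor_design("group"), n_perm=49, seed=3)
        pd.testing.assert_frame_equal(t1, t2)


class TestNestedDesign:
    def test_mle_df_column(self):
        cfg = SimulationConfig(design="mle", n_taxa=60, seed=0)
        meta = simulate_design(cfg)
        soil = meta[meta["niche"] == "soil"]
        table, _ = simulate_community(cfg, soil)
        tab = permanova(bray_curtis(table), meta, mle_design(), n_perm=0)
        assert tab.loc["Site", "df"] == 4
        assert tab.loc["N add", "df"] == 1
        assert tab.loc["Site*N add", "df"] == 4
        assert tab.loc["Plot(Site*N)", "df"] == 28
        assert tab["df"].iloc[:-1].sum() == tab.loc["Total", "df"]

    def test_r2_in_unit_interval_and_omega_below_r2(self):
        cfg = SimulationConfig(design="mle", n_taxa=60, seed=1, site_sigma=0.5)
        meta = simulate_design(cfg)
        table, _ = simulate_community(cfg, meta[meta["niche"] == "soil"])
        tab = permanova(bray_curtis(table), meta, mle_design(), n_perm=0)
        terms = tab.index[:-2]
        assert ((tab.loc[terms, "R2"] >= 0) & (tab.loc[terms, "R2"] <= 1)).all()
        assert (tab.loc[terms, "omega2"] <= tab.loc[terms, "R2"] + 1e-12).all()


class TestOmegaSquared:
    def test_hand_value(self):
        assert omega_squared(10, 2, 1, 20) == pytest.approx(8 / 21, rel=1e-12)

    def test_null_expectation_zero(self):
        assert omega_squared(3 * 1.7, 3, 1.7, 50) == pytest.approx(0.0, abs=1e-12)

    def test_negative_reported_as_computed(self):
        assert omega_squared(1.0, 4, 1.0, 10) < 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            omega_squared(1, 0, 1, 10)
        with pytest.raises(ValueError):
            omega_squared(1, 1, 1, -5)

    def test_never_exceeds_r2_randomized(self, rng):
        for _ in range(300):
            n = int(rng.integers(6, 14))
            k = int(rng.integers(2, 4))
            labels = rng.integers(0, k, n)
            if len(np.unique(labels)) < 2 or np.bincount(labels, minlength=k).min() == 0:
                continue
            x = rng.normal(size=(n, 2)) + labels[:, None] * rng.normal()
            meta = grid_metadata(n)
            meta["group"] = [f"g{v}" for v in labels]
            dm = _euclid_dm(x, list(meta.index))
            tab = permanova(dm, meta, one_factor_design("group"), n_perm=0)
            assert tab.loc["group", "omega2"] <= tab.loc["group", "R2"] + 1e-12


class TestBetaDispersion:
    def test_one_dimensional_median_oracle(self):
        # odd group sizes: the 1-D spatial median is the unique sample median
        vals = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 14.0, 20.0, 21.0])
        meta = grid_metadata(len(vals))
        groups = pd.Series(["a"] * 5 + ["b"] * 3 + ["c"] * 3, index=meta.index)
        dm = DistanceMatrix(np.abs(vals[:, None] - vals[None, :]), ids=list(meta.index))
        res = beta_dispersion(dm, groups, n_perm=0)
        for g in ("a", "b", "c"):
            member_vals = vals[(groups == g).to_numpy()]
            expect = np.abs(member_vals - np.median(member_vals))
            got = np.sort(res.distances[groups == g].to_numpy())
            np.testing.assert_allclose(got, np.sort(expect), atol=1e-6)

    def test_mirror_image_groups_equal_dispersion(self, rng):
        pts = rng.normal(size=(6, 2))
        pts -= pts.mean(axis=0)
        both = np.vstack([pts + 10, -pts - 10])
        ids = [f"s{i}" for i in range(12)]
        dm = DistanceMatrix(squareform(pdist(both)), ids=ids)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=ids)
        res = beta_dispersion(dm, groups, n_perm=199, seed=0)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"], rel=1e-6)
        assert res.p_perm > 0.5

    def test_scaled_group_detected(self, rng):
        pts = rng.normal(size=(10, 2))
        both = np.vstack([pts, 3.0 * rng.normal(size=(10, 2)) + 50])
        ids = [f"s{i}" for i in range(20)]
        dm = DistanceMatrix(squareform(pdist(both)), ids=ids)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=ids)
        res = beta_dispersion(dm, groups, n_perm=999, seed=0)
        assert res.group_means["b"] > res.group_means["a"]
        assert res.p_perm < 0.05

    def test_singleton_group_excluded(self, rng):
        vals = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0, 99.0])
        ids = [f"s{i}" for i in range(7)]
        dm = DistanceMatrix(np.abs(vals[:, None] - vals[None, :]), ids=ids)
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"], index=ids)
        with pytest.warns(UserWarning, match="excluded"):
            res = beta_dispersion(dm, groups, n_perm=0)
        assert res.excluded == ["c"]
        assert len(res.distances) == 6
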