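"""Core-community ranking/selection, neutral model, differential abundance."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spatiomic.community import OtuTable
from spatiomic.core import (
    CoreResult,
    SloanNeutralModel,
    bc_contribution_curve,
    differential_family_abundance,
    fit_neutral,
    group_guilds,
    occupancy_abundance,
    rank_taxa,
    select_core,
    threshold_scan,
)

from conftest import grid_metadata, random_table


def _meta_with_groups(table, groups):
    meta = grid_metadata(table.n_samples)
    meta.index = table.sample_ids
    meta["site"] = groups
    return meta


class TestOccupancyAbundance:
    def test_simple_fractions(self):
        t = OtuTable(
            ["a", "b", "c", "d"],
            ["t1", "t2"],
            np.array([[1, 5], [1, 0], [1, 3], [0, 2]]),
        )
        meta = _meta_with_groups(t, ["g1", "g1", "g2", "g2"])
        stats = occupancy_abundance(t, meta, group_by="site")
        assert stats.loc["t1", "occupancy"] == 0.75
        assert stats.loc["t2", "occupancy"] == 0.75
        # t1 full in g1 only; t2 full in g2 only
        assert stats.loc["t1", "replicate_consistency"] == 0.5
        assert stats.loc["t2", "replicate_consistency"] == 0.5

    def test_brute_force_oracle(self, rng):
        t = random_table(rng, n_samples=8, n_taxa=10, depth=50)
        groups = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 2
        meta = _meta_with_groups(t, groups)
        stats = occupancy_abundance(t, meta, group_by="site")
        rel = t.counts / t.counts.sum(axis=1, keepdims=True)
        for j, taxon in enumerate(t.taxon_ids):
            present = t.counts[:, j] > 0
            assert stats.loc[taxon, "occupancy"] == pytest.approx(present.mean())
            assert stats.loc[taxon, "mean_rel_abund"] == pytest.approx(rel[:, j].mean())
            g_occ = [present[:3].mean(), present[3:6].mean(), present[6:].mean()]
            assert stats.loc[taxon, "mean_group_occupancy"] == pytest.approx(np.mean(g_occ))
            cons = np.mean([present[:3].all(), present[3:6].all(), present[6:].all()])
            assert stats.loc[taxon, "replicate_consistency"] == pytest.approx(cons)


class TestRanking:
    def test_ubiquitous_taxon_first(self, rng):
        t = random_table(rng, n_samples=6, n_taxa=5, depth=40)
        counts = t.counts.copy()
        counts[:, 2] = 100  # everywhere, abundant
        counts[::2, 0] = 0
        t2 = OtuTable(t.sample_ids, t.taxon_ids, counts)
        meta = _meta_with_groups(t2, ["g1"] * 3 + ["g2"] * 3)
        ranked = rank_taxa(occupancy_abundance(t2, meta, group_by="site"))
        assert ranked.index[0] == "t2"

    def test_tie_broken_by_abundance_then_id(self):
        t = OtuTable(
            ["a", "b"],
            ["tB", "tA", "tC"],
            np.array([[10, 10, 80], [10, 10, 80]]),
        )
        meta = _meta_with_groups(t, ["g1", "g1"])
        ranked = rank_taxa(occupancy_abundance(t, meta, group_by="site"))
        assert list(ranked.index) == ["tC", "tA", "tB"]

    def test_permutation_invariance_of_ranking(self, rng):
        t = random_table(rng, n_samples=6, n_taxa=8, depth=60)
        meta = _meta_with_groups(t, ["g1"] * 3 + ["g2"] * 3)
        base = list(rank_taxa(occupancy_abundance(t, meta, group_by="site")).index)
        perm = rng.permutation(t.n_taxa)
        t2 = OtuTable(t.sample_ids, [t.taxon_ids[k] for k in perm], t.counts[:, perm])
        shuffled = list(rank_taxa(occupancy_abundance(t2, meta, group_by="site")).index)
        assert shuffled == base


def _brute_force_curve(table, ranking):
    """Independent reimplementation: mean partial BC over all pairs/prefixes."""
    x = table.counts.astype(float)
    n = table.n_samples
    idx = {t: k for k, t in enumerate(table.taxon_ids)}
    out = []
    for i in range(1, len(ranking) + 1):
        prefix = [idx[t] for t in ranking[:i]]
        vals = []
        for a, b in itertools.combinations(range(n), 2):
            num = sum(abs(x[a, c] - x[b, c]) for c in prefix)
            den = x[a].sum() + x[b].sum()
            vals.append(num / den)
        out.append(np.mean(vals))
    out = np.array(out)
    return out / out[-1]


class TestContributionCurve:
    def test_exhaustive_oracle_small_table(self, rng):
        t = random_table(rng, n_samples=4, n_taxa=5, depth=30)
        meta = _meta_with_groups(t, ["g1", "g1", "g2", "g2"])
        ranking = list(rank_taxa(occupancy_abundance(t, meta, group_by="site")).index)
        curve = bc_contribution_curve(t, ranking)
        np.testing.assert_allclose(
            curve.bc_contribution, _brute_force_curve(t, ranking), atol=1e-12
        )

    def test_monotone_and_terminal_one(self, rng):
        for _ in range(5):
            t = random_table(rng, n_samples=5, n_taxa=9, depth=40)
            curve = bc_contribution_curve(t, list(t.taxon_ids))
            assert np.all(np.diff(curve.bc_contribution) >= -1e-12)
            assert curve.bc_contribution[-1] == pytest.approx(1.0, abs=1e-9)

    def test_absent_taxon_does_not_change_curve(self, rng):
        t = random_table(rng, n_samples=4, n_taxa=5, depth=40)
        counts = np.hstack([t.counts, np.zeros((4, 1), dtype=int)])
        t2 = OtuTable(t.sample_ids, t.taxon_ids + ["ghost"], counts)
        c1 = bc_contribution_curve(t, list(t.taxon_ids)).bc_contribution
        c2 = bc_contribution_curve(t2, list(t.taxon_ids) + ["ghost"]).bc_contribution
        np.testing.assert_allclose(c2[:-1], c1, atol=1e-12)
        assert c2[-1] == c2[-2]


def _brute_force_core(curve_vals, threshold):
    """Literal application of the 'last >= threshold relative step' rule."""
    last = None
    for i in range(1, len(curve_vals)):
        prev = curve_vals[i - 1]
        if prev > 0 and (curve_vals[i] - prev) / prev >= threshold:
            last = i + 1  # prefix size
    return last if last is not None else 1


class TestSelectCore:
    def test_reference_curve(self):
        t = OtuTable(
            ["a", "b"], ["t1", "t2", "t3", "t4"],
            np.array([[10, 10, 10, 10], [20, 5, 10, 10]]),
        )
        curve = CoreResult(["t1", "t2", "t3", "t4"], np.array([0.40, 0.60, 0.62, 0.624]))
        res = select_core(curve, t)
        assert res.threshold_index == 2
        assert res.core_taxa == ["t1", "t2"]
        assert res.richness_share == pytest.approx(0.5)

    def test_single_taxon_community(self):
        t = OtuTable(["a", "b"], ["t1"], np.array([[5], [9]]))
        curve = bc_contribution_curve(t, ["t1"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = select_core(curve, t)
        assert res.core_taxa == ["t1"]
        assert res.read_share == 1.0

    def test_matches_brute_force_on_small_tables(self, rng):
        for _ in range(25):
            n_taxa = int(rng.integers(2, 13))
            t = random_table(rng, n_samples=4, n_taxa=n_taxa, depth=60)
            curve = bc_contribution_curve(t, list(t.taxon_ids))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = select_core(curve, t)
            assert res.threshold_index == _brute_force_core(curve.bc_contribution, 0.05)

    def test_raising_threshold_never_enlarges_core(self, rng):
        t = random_table(rng, n_samples=5, n_taxa=10, depth=60)
        curve = bc_contribution_curve(t, list(t.taxon_ids))
        sizes = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for thr in (0.01, 0.05, 0.10, 0.25):
                sizes.append(len(select_core(curve, t, threshold=thr).core_taxa))
        assert sizes == sorted(sizes, reverse=True)


class TestNeutralModel:
    def test_predicted_occupancy_monotone_in_abundance(self):
        model = SloanNeutralModel(N=10_000)
        model.m_ = 0.1
        p = np.logspace(-6, -1, 60)
        occ = model.predict_occupancy(p)
        assert np.all(np.diff(occ) >= -1e-12)
        assert model.predict_occupancy(np.array([0.5]))[0] > 0.999

    def test_perfect_agreement_gives_r2_one(self, rng):
        truth = SloanNeutralModel(N=10_000)
        truth.m_ = 0.07
        p = np.sort(rng.uniform(1e-5, 1e-2, 80))
        occ = truth.predict_occupancy(p)
        fit = SloanNeutralModel(N=10_000).fit(p, occ, n_samples=100)
        assert fit.m_ == pytest.approx(0.07, rel=1e-3)
        assert fit.r2_ == pytest.approx(1.0, abs=1e-9)
        assert not fit.failed_

    def test_classification_partitions_taxa(self, rng):
        p = np.sort(rng.uniform(1e-5, 1e-2, 50))
        truth = SloanNeutralModel(N=10_000)
        truth.m_ = 0.1
        occ = np.clip(truth.predict_occupancy(p) + rng.normal(0, 0.1, 50), 0, 1)
        fit = SloanNeutralModel(N=10_000).fit(p, occ, n_samples=30)
        assert set(fit.table_["neutral_class"]) <= {"above", "neutral", "below"}
        assert len(fit.table_) == 50

    def test_recovery_order_of_magnitude(self, rng):
        # reads drawn binomially from Sloan fractions; the detection-limit
        # approximation biases m upward, so only coarse agreement holds
        N, T, S, m = 10_000, 300, 60, 0.1
        base = rng.lognormal(0, 1.5, T)
        p = base / base.sum()
        rel = rng.beta(np.maximum(N * m * p, 1e-9), np.maximum(N * m * (1 - p), 1e-9), size=(S, T))
        cnt = rng.binomial(N, rel)
        stats_df = pd.DataFrame(
            {"mean_rel_abund": (cnt / N).mean(axis=0), "occupancy": (cnt > 0).mean(axis=0)},
            index=[f"t{i}" for i in range(T)],
        )
        fit = fit_neutral(stats_df, N=N, n_samples=S)
        assert 0.05 < fit.m_ < 0.2
        assert fit.r2_ > 0.9

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            SloanNeutralModel().fit(np.array([1e-3] * 5), np.array([0.5] * 5), 10)

    def test_threshold_scan_shape(self, rng):
        t = random_table(rng, n_samples=8, n_taxa=15, depth=100)
        meta = _meta_with_groups(t, ["g1"] * 4 + ["g2"] * 4)
        stats_df = occupancy_abundance(t, meta, group_by="site")
        ranked = rank_taxa(stats_df)
        curve = bc_contribution_curve(t, list(ranked.index))
        scan = threshold_scan(t, curve, stats_df, thresholds=[0.02, 0.05, 0.1], N=100)
        assert list(scan["threshold"]) == [0.02, 0.05, 0.1]
        assert (scan["core_richness"].diff().dropna() <= 0).all()


class TestDifferentialAbundance:
    def _tables(self):
        # family F1 ~4x more abundant in roots; F2 identical in both
        root = OtuTable(
            [f"r{i}" for i in range(4)], ["t1", "t2"],
            np.array([[40, 60], [40, 60], [39, 61], [41, 59]]),
        )
        soil = OtuTable(
            [f"s{i}" for i in range(4)], ["t1", "t2"],
            np.array([[10, 90], [10, 90], [9, 91], [11, 89]]),
        )
        ann = pd.DataFrame({"family": ["F1", "F2"]}, index=pd.Index(["t1", "t2"], name="taxon_id"))
        return root, soil, ann

    def test_log2_ratio_of_medians(self):
        root, soil, ann = self._tables()
        out = differential_family_abundance(root, soil, ann)
        assert out.loc["F1", "log2_ratio"] == pytest.approx(2.0, abs=1e-9)
        assert out.loc["F1", "p_value"] < 0.05

    def test_identical_distributions(self):
        t = OtuTable(["a", "b", "c"], ["t1", "t2"], np.array([[30, 70], [30, 70], [30, 70]]))
        ann = pd.DataFrame({"family": ["F1", "F2"]}, index=pd.Index(["t1", "t2"], name="taxon_id"))
        out = differential_family_abundance(t, t, ann)
        assert out.loc["F1", "log2_ratio"] == 0.0
        assert out.loc["F1", "p_value"] == pytest.approx(1.0)

    def test_wilcoxon_matches_exact_enumeration(self, rng):
        # independent oracle: enumerate all group assignments of the pooled
        # values and compare the exact two-sided p
        x = rng.normal(size=5)
        y = rng.normal(size=4) + 0.8
        u_obs = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        pooled = np.concatenate([x, y])
        n = len(x)
        stats_all = []

        def u_stat(xi, yi):
            return sum((a > b) + 0.5 * (a == b) for a in xi for b in yi)

        for combo in itertools.combinations(range(9), n):
            mask = np.zeros(9, bool)
            mask[list(combo)] = True
            stats_all.append(u_stat(pooled[mask], pooled[~mask]))
        stats_all = np.array(stats_all)
        u0 = u_stat(x, y)
        mean_u = len(x) * len(y) / 2
        p_exact = np.mean(np.abs(stats_all - mean_u) >= abs(u0 - mean_u) - 1e-12)
        assert u_obs == pytest.approx(p_exact, abs=1e-9)

    def test_zero_median_uses_pseudocount(self):
        root = OtuTable(["r0", "r1", "r2"], ["t1", "t2"],
                        np.array([[50, 50], [60, 40], [55, 45]]))
        soil = OtuTable(["s0", "s1", "s2"], ["t1", "t2"],
                        np.array([[0, 100], [0, 100], [1, 99]]))
        ann = pd.DataFrame({"family": ["F1", "F2"]}, index=pd.Index(["t1", "t2"], name="taxon_id"))
        out = differential_family_abundance(root, soil, ann, pseudo_n=100)
        assert bool(out.loc["F1", "pseudo_count_used"])
        assert np.isfinite(out.loc["F1", "log2_ratio"])


class TestGuilds:
    def _map(self):
        return pd.DataFrame(
            {
                "guild_label": ["Arbuscular Mycorrhizal", "Plant Pathogen",
                                "Wood Saprotroph-Plant Pathogen"],
                "guild_group": ["symbiotroph", "pathogen", "multiple pathogen-saprotroph"],
            }
        )

    def test_mapped_and_confidence_filter(self):
        ann = pd.DataFrame(
            {
                "guild_label": ["Arbuscular Mycorrhizal", "Plant Pathogen", "Plant Pathogen", ""],
                "guild_confidence": ["Highly Probable", "Probable", "Possible", ""],
            },
            index=pd.Index(["t1", "t2", "t3", "t4"], name="taxon_id"),
        )
        out = group_guilds(ann, self._map())
        assert out.loc["t1", "guild_group"] == "symbiotroph"
        assert out.loc["t2", "guild_group"] == "pathogen"
        assert out.loc["t3", "guild_group"] == "unknown"  # below Probable
        assert out.loc["t4", "guild_group"] == "unknown"

    def test_unmapped_multi_guild_kept_verbatim(self):
        ann = pd.DataFrame(
            {
                "guild_label": ["Endophyte-Epiphyte"],
                "guild_confidence": ["Probable"],
            },
            index=pd.Index(["t1"], name="taxon_id"),
        )
        with pytest.warns(UserWarning, match="unmapped"):
            out = group_guilds(ann, self._map())
        assert out.loc["t1", "guild_group"] == "Endophyte-Epiphyte"
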