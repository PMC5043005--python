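import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from cultx import (
    GeneSetCollection,
    assign_motifs,
    build_profiles,
    fuzzy_cmeans,
    overrepresentation,
    select_cluster_count,
    split_rescued,
)
from _util import make_deg_table


def _profiles_from_centers(centers, n_per, noise, seed=0):
    """Gaussian blobs around given center profiles, z-scaled per row."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for ci, center in enumerate(centers):
        for _ in range(n_per):
            rows.append(np.asarray(center, dtype=float) + rng.normal(0, noise, len(center)))
            labels.append(ci)
    raw = pd.DataFrame(rows, index=[f"g{i:04d}" for i in range(len(rows))])
    scaled = raw.sub(raw.mean(axis=1), axis=0).div(raw.std(axis=1, ddof=1), axis=0)
    return scaled, np.array(labels)


class TestBuildProfiles:
    def test_constant_deregulation_excluded(self):
        tables = [
            make_deg_table(["flat", "varied"], [2.0, 2.0 * d], day=d) for d in (1, 2, 3)
        ]
        profiles = build_profiles(tables)
        assert "flat" not in profiles.index
        assert "varied" in profiles.index
        assert profiles.attrs["n_excluded"] == 1

    def test_proportional_profiles_scale_identically(self):
        tables = [
            make_deg_table(["a", "b"], [1.0 * d, 3.0 * d], day=d) for d in (1, 2, 4)
        ]
        profiles = build_profiles(tables, gene_filter="all")
        assert np.allclose(profiles.loc["a"], profiles.loc["b"])

    def test_matches_brute_force_zscale_oracle(self):
        rng = np.random.default_rng(0)
        fcs = rng.normal(0, 2, (5, 3))
        tables = [
            make_deg_table([f"g{i}" for i in range(5)], fcs[:, j], day=d)
            for j, d in enumerate((1, 2, 3))
        ]
        profiles = build_profiles(tables, gene_filter="all")
        for i in range(5):
            row = fcs[i]
            oracle = (row - row.mean()) / row.std(ddof=1)
            assert np.allclose(profiles.loc[f"g{i}"], oracle)

    def test_deg_filter_drops_never_called_genes(self):
        tables = [make_deg_table(["deg", "null"], [fc, 0.1][0:2], day=d) for d, fc in ((1, 2.0), (2, 1.5))]
        tables = [
            make_deg_table(["deg", "null"], [2.0 if d == 1 else 1.5, 0.1], day=d) for d in (1, 2)
        ]
        profiles = build_profiles(tables, gene_filter="any-contrast-DEG")
        assert list(profiles.index) == ["deg"]

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError, match="2 timepoints"):
            build_profiles([make_deg_table(["g"], [2.0], day=1)])


class TestFuzzyCMeans:
    def test_recovers_two_separated_motifs(self):
        profiles, truth = _profiles_from_centers(
            [[2, 1, 0, -1, -2], [-2, -1, 0, 1, 2]], n_per=40, noise=0.3, seed=1
        )
        fit = fuzzy_cmeans(profiles, c=2, seed=0, n_restarts=5)
        hard = fit.hard_label.to_numpy()
        assert adjusted_rand_score(truth, hard) >= 0.95

    def test_hard_clustering_limit_small_m(self):
        profiles, _ = _profiles_from_centers(
            [[2, 0, -2, 0], [-2, 0, 2, 0]], n_per=25, noise=0.2, seed=2
        )
        fit = fuzzy_cmeans(profiles, c=2, m=1.01, seed=0)
        assert (fit.membership.max(axis=1) >= 0.99).all()

    def test_duplicated_gene_identical_membership(self):
        profiles, _ = _profiles_from_centers([[1, 0, -1], [-1, 0, 1]], n_per=10, noise=0.3, seed=3)
        profiles.loc["dup"] = profiles.iloc[0]
        fit = fuzzy_cmeans(profiles, c=2, seed=0)
        assert np.allclose(fit.membership.loc["dup"], fit.membership.iloc[0])

    def test_membership_rows_sum_to_one(self):
        profiles, _ = _profiles_from_centers([[1, -1, 0], [0, 1, -1]], n_per=15, noise=0.5, seed=4)
        fit = fuzzy_cmeans(profiles, c=3, seed=0)
        assert np.allclose(fit.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_trace_non_increasing(self):
        profiles, _ = _profiles_from_centers([[1, -1, 0], [0, 1, -1]], n_per=20, noise=0.6, seed=5)
        fit = fuzzy_cmeans(profiles, c=2, seed=0, n_restarts=3)
        trace = np.array(fit.objective_trace)
        assert (np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1)).all()

    def test_centers_within_profile_bounds(self):
        profiles, _ = _profiles_from_centers([[2, -2, 0], [0, 2, -2]], n_per=20, noise=0.4, seed=6)
        fit = fuzzy_cmeans(profiles, c=2, seed=0)
        lo = profiles.min(axis=0).to_numpy()
        hi = profiles.max(axis=0).to_numpy()
        assert (fit.centers >= lo - 1e-9).all() and (fit.centers <= hi + 1e-9).all()

    def test_deterministic_given_seed(self):
        profiles, _ = _profiles_from_centers([[1, 0, -1], [-1, 0, 1]], n_per=10, noise=0.5, seed=7)
        a = fuzzy_cmeans(profiles, c=2, seed=42)
        b = fuzzy_cmeans(profiles, c=2, seed=42)
        pd.testing.assert_frame_equal(a.membership, b.membership)

    def test_invalid_args(self):
        profiles, _ = _profiles_from_centers([[1, 0, -1]], n_per=5, noise=0.2)
        with pytest.raises(ValueError):
            fuzzy_cmeans(profiles, c=1)
        with pytest.raises(ValueError):
            fuzzy_cmeans(profiles, c=2, m=1.0)
        with pytest.raises(ValueError):
            fuzzy_cmeans(profiles.iloc[:1], c=2)

    def test_nonconvergence_warns(self):
        profiles, _ = _profiles_from_centers([[1, 0, -1], [-1, 0, 1]], n_per=10, noise=0.8, seed=8)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fuzzy_cmeans(profiles, c=2, seed=0, max_iter=2, n_restarts=1)


class TestSelectClusterCount:
    def test_three_planted_motifs_chosen(self):
        profiles, _ = _profiles_from_centers(
            [[3, 0, -3, 0, 3], [-3, 0, 3, 0, -3], [0, 3, 0, -3, 0]],
            n_per=30,
            noise=0.3,
            seed=9,
        )
        chosen, table = select_cluster_count(profiles, range(2, 6), seed=0, n_restarts=3)
        assert chosen == 3
        assert set(table["c"]) == {2, 3, 4, 5}

    def test_singleton_range_trivially_chosen(self):
        profiles, _ = _profiles_from_centers([[1, 0, -1], [-1, 0, 1]], n_per=10, noise=0.4, seed=10)
        chosen, table = select_cluster_count(profiles, [4], seed=0, n_restarts=2)
        assert chosen == 4 and len(table) == 1

    def test_single_cluster_data_degrades_with_c(self):
        # on structure-free data the partition coefficient (crispness)
        # decays monotonically with c on average
        pc = {c: [] for c in (2, 3, 4, 6)}
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            raw = pd.DataFrame(rng.normal(0, 1, (60, 5)))
            profiles = raw.sub(raw.mean(axis=1), axis=0).div(raw.std(axis=1, ddof=1), axis=0)
            profiles.index = [f"g{i}" for i in range(60)]
            _, table = select_cluster_count(profiles, [2, 3, 4, 6], seed=seed, n_restarts=2)
            for c in pc:
                pc[c].append(float(table.loc[table["c"] == c, "partition_coefficient"].iloc[0]))
        means = [np.mean(pc[c]) for c in (2, 3, 4, 6)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_cluster_count(pd.DataFrame([[1.0, -1.0]]), [])


class TestOverrepresentation:
    def test_full_set_query_matches_point_mass_oracle(self):
        universe = [f"u{i}" for i in range(40)]
        target = universe[:8]
        other = universe[20:30]
        coll = GeneSetCollection({"target": target, "other": other}, universe)
        result = overrepresentation(target, coll).set_index("set")
        # oracle: exact hypergeometric point mass when the query IS the set
        n, big_n, big_k = 8, 40, 8
        point = math.comb(big_k, n) * math.comb(big_n - big_k, 0) / math.comb(big_n, n)
        assert result.loc["target", "p_raw"] == pytest.approx(point, abs=1e-12)
        assert result.loc["target", "p_raw"] == result["p_raw"].min()

    def test_zero_overlap_huge_universe(self):
        universe = [f"u{i}" for i in range(10000)]
        coll = GeneSetCollection({"s": universe[:20]}, universe)
        result = overrepresentation(universe[-10:], coll)
        assert result["p_raw"].iloc[0] > 0.97

    def test_hypergeom_equals_fisher_exact(self):
        # oracle equivalence over random 2x2 tables
        rng = np.random.default_rng(11)
        universe = [f"u{i}" for i in range(200)]
        for _ in range(50):
            set_size = int(rng.integers(5, 80))
            query_size = int(rng.integers(5, 80))
            members = list(rng.choice(universe, set_size, replace=False))
            query = list(rng.choice(universe, query_size, replace=False))
            coll = GeneSetCollection({"s": members}, universe)
            p = overrepresentation(query, coll)["p_raw"].iloc[0]
            k = len(set(members) & set(query))
            table = [
                [k, query_size - k],
                [set_size - k, 200 - set_size - query_size + k],
            ]
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert abs(p - p_fisher) < 1e-10

    def test_random_query_p_roughly_uniform(self):
        # a correct discrete tail p gives *exactly* uniform randomized
        # p-values p - U*pmf(k); KS on those detects any miscalibration
        rng = np.random.default_rng(12)
        universe = [f"u{i}" for i in range(1000)]
        members = set(universe[:100])
        coll = GeneSetCollection({"s": list(members)}, universe)
        ps = []
        for _ in range(200):
            query = list(rng.choice(universe, 150, replace=False))
            p = overrepresentation(query, coll)["p_raw"].iloc[0]
            k = len(members & set(query))
            p_rand = p - rng.uniform() * stats.hypergeom.pmf(k, 1000, 100, 150)
            ps.append(p_rand)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_odds_ratio_zero_cell_correction(self):
        universe = [f"u{i}" for i in range(30)]
        coll = GeneSetCollection({"s": universe[:10]}, universe)
        result = overrepresentation(universe[:10], coll)  # zero cells appear
        assert np.isfinite(result["odds_ratio"].iloc[0])

    def test_query_outside_universe_rejected(self):
        coll = GeneSetCollection({"s": ["a"]}, ["a", "b"])
        with pytest.raises(ValueError, match="outside the universe"):
            overrepresentation(["z"], coll)

    def test_empty_query_rejected(self):
        coll = GeneSetCollection({"s": ["a"]}, ["a"])
        with pytest.raises(ValueError):
            overrepresentation([], coll)

    def test_collection_validates_membership(self):
        with pytest.raises(ValueError, match="outside the universe"):
            GeneSetCollection({"s": ["zzz"]}, ["a"])
        coll = GeneSetCollection.restricted({"s": ["a", "zzz"]}, ["a", "b"])
        assert coll.sets["s"] == ["a"]


class TestAssignMotifs:
    def _clustering_stub(self, clusters):
        profiles, _ = _profiles_from_centers([[1, 0, -1], [-1, 0, 1]], n_per=10, noise=0.3)
        return fuzzy_cmeans(profiles, c=clusters, seed=0)

    def test_planted_inflammation_cluster_labelled(self):
        fit = self._clustering_stub(2)
        enr = pd.DataFrame(
            {"set": ["inflammation_set"], "p_adj": [1e-6], "odds_ratio": [30.0]}
        )
        labels = assign_motifs(fit, {0: enr}, {"inflammation": ["inflammation_set"]})
        assert labels[0] == "inflammation"

    def test_no_significant_rule_leaves_unlabelled(self):
        fit = self._clustering_stub(2)
        enr = pd.DataFrame({"set": ["s"], "p_adj": [0.9], "odds_ratio": [1.0]})
        labels = assign_motifs(fit, {0: enr, 1: enr}, {"m": ["s"]})
        assert labels == {0: None, 1: None}

    def test_empty_rule_map_all_unlabelled(self):
        fit = self._clustering_stub(2)
        enr = pd.DataFrame({"set": ["s"], "p_adj": [1e-9], "odds_ratio": [50.0]})
        labels = assign_motifs(fit, {0: enr}, {})
        assert all(v is None for v in labels.values())

    def test_tie_broken_by_odds_ratio(self):
        fit = self._clustering_stub(2)
        enr = pd.DataFrame(
            {"set": ["s1", "s2"], "p_adj": [1e-4, 1e-4], "odds_ratio": [5.0, 50.0]}
        )
        labels = assign_motifs(fit, {0: enr}, {"weak": ["s1"], "strong": ["s2"]})
        assert labels[0] == "strong"


class TestSplitRescued:
    def test_attenuated_genes_split_off(self):
        raw = pd.DataFrame(
            {
                "M_C_d1": [-2.0, -2.0],
                "M_C_d3": [-2.5, -2.5],
                "S_d1": [-0.4, -1.9],
                "S_d3": [-0.5, -2.4],
            },
            index=["rescued_gene", "stuck_gene"],
        )
        rescued, unrescued = split_rescued(raw, ["rescued_gene", "stuck_gene"])
        assert rescued == ["rescued_gene"]
        assert unrescued == ["stuck_gene"]

    def test_missing_condition_rejected(self):
        raw = pd.DataFrame({"M_C_d1": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            split_rescued(raw, ["g"])
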