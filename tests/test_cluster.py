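"""Hierarchical clustering, multiscale-bootstrap AU/BP support, accuracy, PCA."""

import numpy as np
import pandas as pd
import pytest

from rumengwas import (
    DataError,
    cluster_accuracy,
    hcluster,
    multiscale_bootstrap,
    nested_group_clustering,
    pca_scores,
    top_split_edges,
)
from rumengwas.cluster import scale_rng

from conftest import make_abundance


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def naive_average_linkage(X):
    """O(n^3) agglomeration oracle on correlation distance.

    Returns (merge heights sorted, set of frozenset leaf clusters).
    """
    n = X.shape[0]
    d = 1.0 - np.corrcoef(X)
    clusters = {i: [i] for i in range(n)}
    heights = []
    merged_sets = set()
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merged_sets.add(frozenset(clusters[next_id]))
        heights.append(dist)
        next_id += 1
    return sorted(heights), merged_sets


def cluster_sets(X):
    """Leaf sets of every internal node of the naive-oracle dendrogram."""
    return naive_average_linkage(X)[1]


class TestHcluster:
    def test_duplicate_animals_merge_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(size=(5, 12))
        X[3] = X[1]
        d = hcluster(make_abundance(X))
        assert d.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = d.edges.iloc[0]
        assert set(first["members"]) == {"s1", "s3"}

    def test_two_blob_top_split(self):
        rng = np.random.default_rng(1)
        base_a, base_b = rng.lognormal(2, 1, 10), rng.lognormal(2, 1, 10)
        X = np.vstack([[base_a * rng.uniform(0.9, 1.1, 10) for _ in range(3)],
                       [base_b * rng.uniform(0.9, 1.1, 10) for _ in range(3)]])
        d = hcluster(make_abundance(X))
        tops = top_split_edges(d)
        sets = [set(m) for m in tops["members"]]
        assert {"s0", "s1", "s2"} in sets or {"s3", "s4", "s5"} in sets

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(size=(6, 10))
        d = hcluster(make_abundance(X))
        oracle_heights, oracle_sets = naive_average_linkage(X)
        np.testing.assert_allclose(sorted(d.linkage[:, 2]), oracle_heights, atol=1e-10)
        ours = {frozenset(int(s[1:]) for s in mem) for mem in d.edges["members"]}
        assert ours == oracle_sets

    def test_flat_profile_errors_with_animal_name(self):
        X = np.ones((4, 6))
        X[0] = np.arange(6) + 1.0
        X[1] = (np.arange(6) + 1.0)[::-1]
        with pytest.raises(DataError, match="s2"):
            hcluster(make_abundance(X))

    def test_too_few_samples_or_features(self):
        with pytest.raises(DataError):
            hcluster(make_abundance(np.random.default_rng(0).lognormal(size=(2, 5))))
        with pytest.raises(DataError):
            hcluster(make_abundance(np.random.default_rng(0).lognormal(size=(5, 1))))


class TestMultiscaleBootstrap:
    def test_bp_at_scale_one_matches_resample_count_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(size=(5, 6))
        m = make_abundance(X)
        d = multiscale_bootstrap(m, scales=(0.8, 1.0, 1.2), b_per_scale=200, seed=17)
        # independent oracle: replay the scale-1 stream, recluster with the
        # naive agglomerator, count exact leaf-set matches
        p = X.shape[1]
        counts = {mask: 0 for mask in d.edges.index}
        oracle_rng = scale_rng(17, 1.0)
        for _ in range(200):
            idx = oracle_rng.integers(0, p, size=p)
            for fs in cluster_sets(X[:, idx]):
                mask = sum(1 << i for i in fs)
                if mask in counts:
                    counts[mask] += 1
        for mask, row in d.edges.iterrows():
            assert row["bp_by_scale"][1.0] == pytest.approx(counts[mask] / 200, abs=1e-12)

    def test_bp_scale_one_independent_of_grid(self):
        rng = np.random.default_rng(4)
        m = make_abundance(rng.lognormal(size=(6, 15)))
        wide = multiscale_bootstrap(m, scales=(0.5, 1.0, 1.4), b_per_scale=150, seed=5)
        narrow = multiscale_bootstrap(m, scales=(1.0, 1.2), b_per_scale=150, seed=5)
        for mask in wide.edges.index:
            assert wide.edges.loc[mask, "bp_by_scale"][1.0] == \
                narrow.edges.loc[mask, "bp_by_scale"][1.0]

    def test_identical_animal_pair_has_full_support(self):
        # enough features that resamples cannot degenerate into exact-tie clades
        rng = np.random.default_rng(5)
        X = rng.lognormal(size=(6, 30))
        X[4] = X[2]
        d = multiscale_bootstrap(make_abundance(X), scales=(0.6, 1.0, 1.3),
                                 b_per_scale=120, seed=9)
        pair_mask = (1 << 2) | (1 << 4)
        edge = d.edges.loc[pair_mask]
        assert all(bp == 1.0 for bp in edge["bp_by_scale"].values())
        assert edge["au"] == 1.0

    def test_never_observed_edge_gets_zero_au(self):
        # force an original edge that bootstrap replicates essentially never
        # reproduce by using few, noisy features
        rng = np.random.default_rng(6)
        m = make_abundance(rng.lognormal(size=(8, 4)))
        d = multiscale_bootstrap(m, scales=(0.75, 1.0), b_per_scale=120, seed=2)
        never = d.edges[d.edges["flag"] == "never observed"]
        for _, row in never.iterrows():
            assert row["au"] == 0.0

    def test_bit_reproducible(self):
        rng = np.random.default_rng(7)
        m = make_abundance(rng.lognormal(size=(6, 12)))
        d1 = multiscale_bootstrap(m, scales=(0.7, 1.0, 1.2), b_per_scale=150, seed=21)
        d2 = multiscale_bootstrap(m, scales=(0.7, 1.0, 1.2), b_per_scale=150, seed=21)
        pd.testing.assert_frame_equal(d1.edges, d2.edges)

    def test_au_values_within_unit_interval(self):
        rng = np.random.default_rng(8)
        m = make_abundance(rng.lognormal(size=(7, 20)))
        d = multiscale_bootstrap(m, scales=(0.5, 0.8, 1.0, 1.2), b_per_scale=150, seed=1)
        assert ((d.edges["au"] >= 0) & (d.edges["au"] <= 1)).all()
        for bp in d.edges["bp_by_scale"]:
            assert all(0 <= v <= 1 for v in bp.values())

    def test_validates_inputs(self):
        m = make_abundance(np.random.default_rng(0).lognormal(size=(5, 8)))
        with pytest.raises(DataError):
            multiscale_bootstrap(m, scales=(1.0,), b_per_scale=200)
        with pytest.raises(DataError):
            multiscale_bootstrap(m, scales=(0.5, 1.0), b_per_scale=10)

    def test_newick_serialization_contains_support(self):
        rng = np.random.default_rng(9)
        m = make_abundance(rng.lognormal(size=(5, 10)))
        d = multiscale_bootstrap(m, scales=(0.8, 1.0), b_per_scale=120, seed=3)
        nwk = d.to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")")
        assert "au=" in nwk and "bp=" in nwk
        for sid in m.sample_ids:
            assert sid in nwk


class TestClusterAccuracy:
    @staticmethod
    def two_blob_matrix(n_per=15, seed=0, noise=0.05):
        rng = np.random.default_rng(seed)
        a, b = rng.lognormal(2, 1, 30), rng.lognormal(2, 1, 30)
        rows = [a * rng.uniform(1 - noise, 1 + noise, 30) for _ in range(n_per)]
        rows += [b * rng.uniform(1 - noise, 1 + noise, 30) for _ in range(n_per)]
        return make_abundance(np.array(rows))

    def test_perfect_split(self):
        m = self.two_blob_matrix()
        truth = pd.Series(["HIGH"] * 15 + ["LOW"] * 15,
                          index=[f"s{i}" for i in range(30)])
        rep = cluster_accuracy(hcluster(m), truth, k=2)
        assert rep.accuracy == 1.0

    def test_one_misplaced_animal(self):
        m = self.two_blob_matrix()
        labels = ["HIGH"] * 15 + ["LOW"] * 15
        labels[0] = "LOW"  # truth disagrees with structure for one animal
        truth = pd.Series(labels, index=[f"s{i}" for i in range(30)])
        rep = cluster_accuracy(hcluster(m), truth, k=2)
        assert rep.accuracy == pytest.approx(29 / 30)

    def test_random_labels_match_monte_carlo_baseline(self):
        m = self.two_blob_matrix(seed=3)
        d = hcluster(m)
        rng = np.random.default_rng(10)
        accs = []
        for _ in range(60):
            labels = rng.permutation(["HIGH"] * 15 + ["LOW"] * 15)
            truth = pd.Series(labels, index=[f"s{i}" for i in range(30)])
            accs.append(cluster_accuracy(d, truth, k=2).accuracy)
        # oracle: best-of-two-assignments accuracy for a fixed 15/15 cut under
        # random labels, by direct Monte Carlo on the confusion counts
        sizes = np.bincount(cluster_accuracy(
            d, pd.Series(["HIGH"] * 15 + ["LOW"] * 15,
                         index=[f"s{i}" for i in range(30)]), k=2).predicted)[1:]
        mc = []
        for _ in range(4000):
            perm = rng.permutation(30) < 15  # which animals are HIGH
            in_first = perm[:sizes[0]].sum()
            match1 = in_first + (sizes[1] - (15 - in_first))          # c1=HIGH, c2=LOW
            match2 = (sizes[0] - in_first) + (15 - in_first)          # c1=LOW, c2=HIGH
            mc.append(max(match1, match2) / 30)
        assert np.mean(accs) == pytest.approx(np.mean(mc), abs=0.03)

    def test_k_larger_than_leaves_errors(self):
        m = self.two_blob_matrix()
        truth = pd.Series(["HIGH"] * 30, index=[f"s{i}" for i in range(30)])
        with pytest.raises(DataError):
            cluster_accuracy(hcluster(m), truth, k=31)


class TestPcaScores:
    def test_two_blob_pc1_separates(self):
        m = TestClusterAccuracy.two_blob_matrix(seed=5)
        scores = pca_scores(m)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:15] > 0).all() != (pc1[15:] > 0).all()  # one side each

    def test_matches_eigendecomposition_oracle(self):
        X = np.array([[1.0, 2.0, 3.0],
                      [2.0, 3.0, 8.0],
                      [0.5, 1.0, 2.0],
                      [4.0, 5.0, 6.0]])
        scores = pca_scores(make_abundance(X)).to_numpy()
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1]
        oracle = Xc @ V[:, order[:2]]
        for j in range(2):
            assert (np.allclose(scores[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(scores[:, j], -oracle[:, j], atol=1e-8))

    def test_scores_centered(self):
        m = TestClusterAccuracy.two_blob_matrix(seed=6)
        scores = pca_scores(m).to_numpy()
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-8)


class TestNestedClustering:
    def test_strong_intake_signal_recovered_within_fe_groups(self, strong_dmi_setup):
        out = strong_dmi_setup
        for grp in ("HIGH", "LOW"):
            assert out[grp] is not None
            assert out[grp]["report"].accuracy >= 0.9
            labels = set(out[grp]["composite_labels"].values())
            assert labels <= {f"{grp[0]}-Hdmi", f"{grp[0]}-Ldmi"}

    def test_small_outer_group_skipped(self):
        from rumengwas import SimulationConfig, simulate_cohorts, derive_fe, assign_groups
        from rumengwas import cpm_normalize
        cfg = SimulationConfig(n_contigs=300, n_informative=10, n_informative_dmi=10,
                               library_size_range=(30_000, 60_000), rng_seed=0)
        (ref_m, ref_p), _, _ = simulate_cohorts(cfg)
        ref_p = derive_fe(ref_p)
        ref_p = assign_groups(ref_p, "fe", 2)  # outer groups of size 2
        cpm = cpm_normalize(ref_m)
        assoc = pd.DataFrame({"significant": [True] * 3},
                             index=pd.Index(cpm.feature_ids[:3], name="feature_id"))
        out = nested_group_clustering(cpm, ref_p, "dmi", assoc,
                                      scales=(0.8, 1.0), b_per_scale=100)
        assert out["HIGH"] is None and out["LOW"] is None


@pytest.fixture(scope="module")
def strong_dmi_setup():
    from rumengwas import (SimulationConfig, simulate_cohorts, derive_fe, assign_groups,
                           cpm_normalize, group_labels, metagwas, prevalence_filter)
    cfg = SimulationConfig(n_contigs=500, n_informative=10, n_informative_dmi=40,
                           dmi_effect_size=4.0, dmi_noise_sd=0.25, dispersion=0.15,
                           library_size_range=(60_000, 120_000), rng_seed=12)
    (ref_m, ref_p), _, _ = simulate_cohorts(cfg)
    ref_p = derive_fe(ref_p)
    ref_p = assign_groups(ref_p, "fe", 15)
    filt, _ = prevalence_filter(ref_m, 7)
    cpm = cpm_normalize(filt)
    # inner association: metaGWAS on DMI groups over all animals
    dmi_groups = assign_groups(ref_p, "dmi", 15)
    assoc = metagwas(cpm, group_labels(dmi_groups, cpm.sample_ids), alpha=0.05)
    return nested_group_clustering(cpm, ref_p, "dmi", assoc,
                                   scales=(0.8, 1.0, 1.2), b_per_scale=150, seed=4)
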