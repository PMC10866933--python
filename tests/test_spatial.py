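"""Tests of the neighborhood statistics: kNN, phenotype distance profiles,
the mean-distance matrix, PDR (against an exhaustive rank oracle and its
invariances), Welch's ANOVA, and interaction zones."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imcspatial import spatial, synthetic
from conftest import make_config


def cells(xy, roi="r1", cond="c", labels=None):
    t = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(xy) + 1),
            "roi_id": roi,
            "condition": cond,
            "x_um": [p[0] for p in xy],
            "y_um": [p[1] for p in xy],
            "area_um2": 50.0,
            "marker_1": 1.0,
        }
    )
    if labels is not None:
        t["true_phenotype"] = labels
    return t


def brute_force_knn(xy, k):
    """All-pairs sort oracle with (distance, lower index) tie-break."""
    n = len(xy)
    out_i, out_d = [], []
    for i in range(n):
        cand = sorted(
            (float(np.hypot(*(np.asarray(xy[i]) - np.asarray(xy[j])))), j)
            for j in range(n)
            if j != i
        )
        out_i.append([j for _, j in cand[:k]])
        out_d.append([d for d, _ in cand[:k]])
    return out_i, out_d


def pdr_rank_oracle(D):
    """Independent enumeration: sort-based fractional ranks, affine scale,
    geometric mean of the two ordered ranks."""
    entries = [
        (i, j, D.iloc[i, j])
        for i in range(len(D))
        for j in range(len(D))
        if i != j and not np.isnan(D.iloc[i, j])
    ]
    vals = [v for _, _, v in entries]
    ranks = []
    for v in vals:
        below = sum(1 for u in vals if u < v)
        ties = sum(1 for u in vals if u == v)
        ranks.append(below + (ties + 1) / 2.0)  # average-tie rank (1-based)
    lo, hi = min(ranks), max(ranks)
    scaled = [0.5 if hi == lo else (r - lo) / (hi - lo) for r in ranks]
    rmat = np.full((len(D), len(D)), np.nan)
    for (i, j, _), s in zip(entries, scaled):
        rmat[i, j] = s
    out = np.sqrt(rmat * rmat.T)
    return pd.DataFrame(out, index=D.index, columns=D.columns)


class TestKnn:
    def test_pythagorean_pair(self):
        t = cells([(0, 0), (3, 4)])
        ns = spatial.knn(t, k=50)
        assert ns.indices[0, 0] == 1 and ns.indices[1, 0] == 0
        assert ns.distances[0, 0] == pytest.approx(5.0)
        assert np.all(ns.indices[:, 1:] == -1)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 120))
            k = int(rng.integers(1, 60))
            xy = rng.uniform(0, 300, size=(n, 2))
            t = cells(list(map(tuple, xy)))
            ns = spatial.knn(t, k=k)
            oi, od = brute_force_knn(xy, k)
            kk = min(k, n - 1)
            for i in range(n):
                np.testing.assert_array_equal(ns.indices[i, :kk], oi[i][:kk])
                np.testing.assert_allclose(ns.distances[i, :kk], od[i][:kk], rtol=1e-9)

    def test_rois_are_independent(self, rng):
        xy = rng.uniform(0, 100, size=(30, 2))
        t1 = cells(list(map(tuple, xy[:15])), roi="a")
        t2 = cells(list(map(tuple, xy[15:])), roi="b")
        t = pd.concat([t1, t2], ignore_index=True)
        ns = spatial.knn(t, k=10)
        assert ns.indices[:15][ns.indices[:15] >= 0].max() < 15
        assert ns.indices[15:][ns.indices[15:] >= 0].min() >= 15

    def test_single_cell_roi_flagged(self):
        t = pd.concat(
            [cells([(0, 0)], roi="solo"), cells([(0, 0), (1, 1)], roi="pair")],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="single cell"):
            ns = spatial.knn(t, k=5)
        assert ns.n_neighbors()[0] == 0

    def test_k_truncates_to_roi_size(self):
        t = cells([(0, 0), (1, 0), (2, 0)])
        ns = spatial.knn(t, k=50)
        assert set(ns.n_neighbors()) == {2}


class TestProfiles:
    def test_single_phenotype_neighborhood(self):
        t = cells([(0, 0), (1, 0), (2, 0)], labels=["A", "B", "B"])
        ns = spatial.knn(t, k=2)
        prof = spatial.phenotype_profiles(ns, t.true_phenotype.to_numpy(object))
        assert prof.loc[0, "B"] == pytest.approx(1.5)  # distances 1 and 2
        assert np.isnan(prof.loc[0, "A"])

    def test_two_group_mean(self):
        # neighbors of cell 0: X at 3 and 4, Y at 10
        t = cells([(0, 0), (3, 0), (4, 0), (10, 0)], labels=["Z", "X", "X", "Y"])
        ns = spatial.knn(t, k=3)
        prof = spatial.phenotype_profiles(ns, t.true_phenotype.to_numpy(object))
        assert prof.loc[0, "X"] == pytest.approx(3.5)
        assert prof.loc[0, "Y"] == pytest.approx(10.0)

    def test_matches_per_cell_loop_oracle(self, rng):
        n = 80
        xy = rng.uniform(0, 200, size=(n, 2))
        labels = rng.choice(["A", "B", "C"], n)
        t = cells(list(map(tuple, xy)), labels=labels)
        k = 12
        ns = spatial.knn(t, k=k)
        prof = spatial.phenotype_profiles(ns, labels)
        oi, od = brute_force_knn(xy, k)
        for i in range(n):
            for p in "ABC":
                ds = [d for d, j in zip(od[i], oi[i]) if labels[j] == p]
                if ds:
                    assert prof.loc[i, p] == pytest.approx(np.mean(ds), abs=1e-9)
                else:
                    assert np.isnan(prof.loc[i, p])

    def test_unlabeled_neighbor_rejected(self):
        t = cells([(0, 0), (1, 0)], labels=["A", None])
        ns = spatial.knn(t, k=1)
        with pytest.raises(ValueError, match="unlabeled"):
            spatial.phenotype_profiles(ns, t.true_phenotype.to_numpy(object))


class TestMeanDistanceMatrix:
    def _profiles(self, t, k=50):
        labels = t.true_phenotype.to_numpy(object)
        ns = spatial.knn(t, k=k)
        return spatial.phenotype_profiles(ns, labels), labels

    def test_symmetric_pair(self):
        t = cells([(0, 0), (7, 0)], labels=["A", "B"])
        prof, labels = self._profiles(t)
        D, N = spatial.mean_distance_matrix(prof, labels, t.roi_id.to_numpy(object))
        assert D.loc["A", "B"] == pytest.approx(7.0)
        assert D.loc["B", "A"] == pytest.approx(7.0)
        assert N.loc["A", "B"] == 1

    def test_distance_scale_homogeneity(self, rng):
        xy = rng.uniform(0, 100, size=(40, 2))
        labels = rng.choice(["A", "B"], 40)
        t1 = cells(list(map(tuple, xy)), labels=labels)
        t2 = cells(list(map(tuple, xy * 2.0)), labels=labels)
        D1, _ = spatial.mean_distance_matrix(
            self._profiles(t1, k=10)[0], labels, t1.roi_id.to_numpy(object))
        D2, _ = spatial.mean_distance_matrix(
            self._profiles(t2, k=10)[0], labels, t2.roi_id.to_numpy(object))
        np.testing.assert_allclose(D2.to_numpy(), 2.0 * D1.to_numpy(), rtol=1e-9)

    def test_attracted_pair_closer_than_inert(self):
        """With A->B attraction and an inert phenotype C at equal density,
        D[A][B] < D[A][C] in expectation (20 seeds)."""
        wins = 0
        for seed in range(20):
            cfg = make_config(
                n_phenotypes=3, cells_per_roi=300.0, roi_size=400.0,
                rois={"c": 1}, proportions=[0.2, 0.4, 0.4],
                attraction=("P0", "P1", 20.0, 0.7), seed=seed,
            )
            t, _ = synthetic.generate_roi(cfg, "c", 1, seed=seed)
            prof, labels = self._profiles(t)
            D, _ = spatial.mean_distance_matrix(prof, labels, t.roi_id.to_numpy(object))
            wins += D.loc["P0", "P1"] < D.loc["P0", "P2"]
        assert wins >= 18

    def test_empty_roi_selection(self):
        t = cells([(0, 0), (1, 0)], labels=["A", "B"])
        prof, labels = self._profiles(t)
        with pytest.raises(ValueError, match="empty ROI"):
            spatial.mean_distance_matrix(prof, labels, t.roi_id.to_numpy(object),
                                         rois=["nope"])


class TestPdr:
    def test_three_phenotype_fixture_matches_oracle(self):
        D = pd.DataFrame(
            [[np.nan, 12.0, 30.0], [14.0, np.nan, 22.0], [28.0, 20.0, np.nan]],
            index=list("ABC"), columns=list("ABC"),
        )
        P = spatial.pdr(D)
        ref = pdr_rank_oracle(D)
        np.testing.assert_allclose(P.to_numpy(), ref.to_numpy(), atol=1e-12)
        # extremes: closest ordered pair has rank 0, furthest rank 1
        assert P.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_range_diagonal(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 7))
            D = pd.DataFrame(rng.uniform(5, 50, (n, n)),
                             index=range(n), columns=range(n))
            P = spatial.pdr(D)
            M = P.to_numpy()
            np.testing.assert_allclose(M, M.T, atol=1e-15)
            off = M[~np.eye(n, dtype=bool)]
            assert np.nanmin(off) >= 0.0 and np.nanmax(off) <= 1.0
            assert np.isnan(np.diag(M)).all()

    def test_total_tie_gives_common_value(self):
        D = pd.DataFrame(np.full((3, 3), 9.0), index=list("ABC"), columns=list("ABC"))
        P = spatial.pdr(D)
        off = P.to_numpy()[~np.eye(3, dtype=bool)]
        assert len(set(off)) == 1

    def test_rank_invariance_under_monotone_transform(self, rng):
        D = pd.DataFrame(rng.uniform(1, 40, (5, 5)), index=range(5), columns=range(5))
        P1 = spatial.pdr(D)
        P2 = spatial.pdr(np.exp(D / 10.0))
        np.testing.assert_allclose(P1.to_numpy(), P2.to_numpy(), atol=1e-12)

    def test_invariance_under_coordinate_rescaling(self, rng):
        xy = rng.uniform(0, 300, size=(120, 2))
        labels = rng.choice(["A", "B", "C"], 120)
        out = []
        for s in (1.0, 3.7):
            t = cells(list(map(tuple, xy * s)), labels=labels)
            ns = spatial.knn(t, k=20)
            prof = spatial.phenotype_profiles(ns, labels)
            D, _ = spatial.mean_distance_matrix(prof, labels, t.roi_id.to_numpy(object))
            out.append(spatial.pdr(D).to_numpy())
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_missing_entries_propagate(self):
        D = pd.DataFrame(
            [[np.nan, 10.0, np.nan], [12.0, np.nan, 20.0], [np.nan, 18.0, np.nan]],
            index=list("ABC"), columns=list("ABC"),
        )
        P = spatial.pdr(D)
        assert np.isnan(P.loc["A", "C"]) and np.isnan(P.loc["C", "A"])
        assert not np.isnan(P.loc["A", "B"])

    def test_too_few_entries_rejected(self):
        D = pd.DataFrame([[np.nan, 3.0], [np.nan, np.nan]], index=list("AB"),
                         columns=list("AB"))
        with pytest.raises(ValueError, match="2 defined"):
            spatial.pdr(D)


class TestFeatureMap:
    def _pdr(self, rng, n=5):
        a = rng.uniform(0, 1, (n, n))
        M = (a + a.T) / 2
        np.fill_diagonal(M, np.nan)
        return pd.DataFrame(M, index=[f"P{i}" for i in range(n)],
                            columns=[f"P{i}" for i in range(n)])

    def test_duplicate_rows_land_close(self, rng):
        """Identical PDR rows embed no farther apart than any other pair;
        checked through the pluggable-embedder contract with a
        distance-preserving linear embedding (UMAP's stochastic layout does
        not guarantee metric faithfulness at a handful of nodes)."""
        from sklearn.decomposition import PCA

        P = self._pdr(rng, 5)
        P.iloc[1] = P.iloc[0]
        P.iloc[:, 1] = P.iloc[:, 0]
        P.iloc[1, 1] = np.nan
        P.iloc[0, 1] = P.iloc[1, 0] = 0.0
        freq = {p: 0.2 for p in P.index}
        nodes, _ = spatial.pdr_feature_map(
            P, freq, seed=0,
            embedder=lambda m: PCA(n_components=2, random_state=0).fit_transform(m),
        )
        xy = nodes[["x", "y"]].to_numpy()
        d01 = np.hypot(*(xy[0] - xy[1]))
        others = [
            np.hypot(*(xy[i] - xy[j]))
            for i in range(5) for j in range(i + 1, 5) if (i, j) != (0, 1)
        ]
        assert d01 <= min(others) + 1e-9

    def test_default_umap_embedding_is_deterministic(self, rng):
        P = self._pdr(rng, 6)
        freq = {p: 1 / 6 for p in P.index}
        n1, _ = spatial.pdr_feature_map(P, freq, seed=3)
        n2, _ = spatial.pdr_feature_map(P, freq, seed=3)
        assert np.isfinite(n1[["x", "y"]].to_numpy()).all()
        pd.testing.assert_frame_equal(n1, n2)

    def test_node_size_ordering_matches_abundance(self, rng):
        P = self._pdr(rng, 4)
        freq = {"P0": 0.4, "P1": 0.3, "P2": 0.2, "P3": 0.1}
        nodes, _ = spatial.pdr_feature_map(P, freq, seed=0)
        assert list(nodes.sort_values("size", ascending=False).index) == \
            ["P0", "P1", "P2", "P3"]

    def test_edge_weights_are_one_minus_pdr(self, rng):
        P = self._pdr(rng, 4)
        nodes, edges = spatial.pdr_feature_map(P, {p: 0.25 for p in P.index}, seed=0)
        for e in edges.itertuples(index=False):
            assert e.weight == pytest.approx(1.0 - P.loc[e.phenotype_a, e.phenotype_b])

    def test_two_phenotype_fallback(self, rng):
        P = pd.DataFrame([[np.nan, 0.3], [0.3, np.nan]], index=["A", "B"],
                         columns=["A", "B"])
        with pytest.warns(UserWarning, match="circular"):
            nodes, _ = spatial.pdr_feature_map(P, {"A": 0.5, "B": 0.5}, seed=0)
        assert len(nodes) == 2


class TestWelchAnova:
    def test_textbook_fixture_matches_independent_oracles(self):
        groups = [np.array([10.0, 12, 14]), np.array([20.0, 22, 24]),
                  np.array([30.0, 32, 34])]
        F, df1, df2, p = spatial.welch_anova(groups)
        # independent oracle 1: scipy's unequal-variance one-way ANOVA
        res = stats.f_oneway(*groups, equal_var=False)
        assert F == pytest.approx(res.statistic, abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-10)
        # independent oracle 2: pingouin, which also reports the df
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat([0, 1, 2], 3)}
        )
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        assert F == pytest.approx(float(ref["F"].iloc[0]), abs=1e-10)
        assert df1 == pytest.approx(float(ref["ddof1"].iloc[0]), abs=1e-10)
        assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-10)

    def test_equal_groups_null_identity(self):
        g = [np.array([5.0, 5.0]), np.array([5.0, 5.0]), np.array([5.0, 5.0])]
        F, _, _, p = spatial.welch_anova(g)
        assert F == 0.0 and p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 values"):
            spatial.welch_anova([np.array([1.0]), np.array([2.0, 3.0])])


class TestNeighborDistanceSummary:
    def test_attracted_phenotype_has_lowest_group_mean(self):
        wins = 0
        for seed in range(20):
            cfg = make_config(
                n_phenotypes=4, cells_per_roi=400.0, roi_size=500.0,
                rois={"c": 4}, proportions=[0.1, 0.3, 0.3, 0.3],
                attraction=("P0", "P1", 20.0, 0.7), seed=seed,
            )
            t, _ = synthetic.generate_cohort(cfg)
            labels = t.true_phenotype.to_numpy(object)
            ns = spatial.knn(t, k=50)
            prof = spatial.phenotype_profiles(ns, labels)
            per_roi, _ = spatial.neighbor_distance_summary(
                prof, labels, t.roi_id.to_numpy(object), "P0"
            )
            means = per_roi.mean(axis=0)
            wins += means.idxmin() == "P1"
        assert wins >= 18

    def test_welch_significant_for_planted_attraction(self):
        cfg = make_config(
            n_phenotypes=4, cells_per_roi=600.0, roi_size=500.0,
            rois={"c": 6}, proportions=[0.1, 0.3, 0.3, 0.3],
            attraction=("P0", "P1", 15.0, 0.9), seed=5,
        )
        t, _ = synthetic.generate_cohort(cfg)
        labels = t.true_phenotype.to_numpy(object)
        ns = spatial.knn(t, k=50)
        prof = spatial.phenotype_profiles(ns, labels)
        _, anova = spatial.neighbor_distance_summary(
            prof, labels, t.roi_id.to_numpy(object), "P0"
        )
        assert anova["p"].iloc[0] < 0.01

    def test_requires_two_rois(self):
        t = cells([(0, 0), (1, 0), (2, 2)], labels=["A", "B", "B"])
        ns = spatial.knn(t, k=2)
        prof = spatial.phenotype_profiles(ns, t.true_phenotype.to_numpy(object))
        with pytest.raises(ValueError, match="2 ROIs"):
            spatial.neighbor_distance_summary(
                prof, t.true_phenotype.to_numpy(object),
                t.roi_id.to_numpy(object), "A",
            )


class TestInteractionZones:
    def test_coincident_with_all_references_is_white(self):
        t = cells([(5, 5), (5, 5), (5, 5), (5, 5)], labels=["R", "G", "B", "other"])
        rgb = spatial.interaction_zones(t, t.true_phenotype.to_numpy(object),
                                        ("R", "G", "B"), tau=25.0)
        np.testing.assert_allclose(rgb.iloc[3].to_numpy(), [1.0, 1.0, 1.0])

    def test_far_cell_fades_to_black(self):
        t = cells([(0, 0), (0, 0), (0, 0), (5000, 5000)],
                  labels=["R", "G", "B", "other"])
        rgb = spatial.interaction_zones(t, t.true_phenotype.to_numpy(object),
                                        ("R", "G", "B"), tau=25.0)
        assert rgb.iloc[3].max() < 1e-8

    def test_reference_cell_own_channel_is_one(self):
        t = cells([(0, 0), (40, 0), (0, 40)], labels=["R", "G", "B"])
        rgb = spatial.interaction_zones(t, t.true_phenotype.to_numpy(object),
                                        ("R", "G", "B"), tau=25.0)
        assert rgb.iloc[0]["R"] == 1.0
        assert rgb.iloc[1]["G"] == 1.0

    def test_toy_layout_matches_kernel_oracle(self):
        tau = 25.0
        pts = [(0, 0), (30, 0), (0, 40), (10, 10), (50, 50), (25, 20)]
        labels = ["R", "G", "B", "x", "y", "z"]
        t = cells(pts, labels=labels)
        rgb = spatial.interaction_zones(t, np.array(labels, object),
                                        ("R", "G", "B"), tau=tau)
        refs = {c: np.array(p) for c, p in zip("RGB", pts[:3])}
        for i, p in enumerate(pts):
            for c, ch in enumerate("RGB"):
                d = np.hypot(*(np.array(p) - refs[ch]))
                assert rgb.iloc[i, c] == pytest.approx(np.exp(-d / tau), abs=1e-12)

    def test_absent_reference_zeroes_channel(self):
        t = cells([(0, 0), (1, 1)], labels=["R", "G"])
        with pytest.warns(UserWarning, match="absent"):
            rgb = spatial.interaction_zones(t, t.true_phenotype.to_numpy(object),
                                            ("R", "G", "B"), tau=25.0)
        assert np.all(rgb["B"] == 0.0)


class TestNullBehavior:
    def test_distance_matrix_dispersion_shrinks_with_cohort_size(self):
        """Under the CSR null (equal-density phenotypes), the mean-distance
        matrix concentrates as the cohort grows. PDR itself is rank-based
        and scale-free, so the concentration is visible in D, not in the
        ranks."""
        def d_dispersion(cells_per_roi, n_rois, seed):
            cfg = make_config(n_phenotypes=5, cells_per_roi=cells_per_roi,
                              rois={"c": n_rois}, seed=seed)
            t, _ = synthetic.generate_cohort(cfg)
            labels = t.true_phenotype.to_numpy(object)
            ns = spatial.knn(t, k=50)
            prof = spatial.phenotype_profiles(ns, labels)
            D, _ = spatial.mean_distance_matrix(prof, labels,
                                                t.roi_id.to_numpy(object))
            M = D.to_numpy()
            return np.nanstd(M[~np.eye(len(M), dtype=bool)])

        small = np.mean([d_dispersion(300, 2, s) for s in range(4)])
        large = np.mean([d_dispersion(1200, 6, s) for s in range(4)])
        assert large < small / 2
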