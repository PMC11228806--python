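"""HVG selection, elbow k-means, PC signatures, TME inheritance, markers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from geomxeco.cluster import (PCAResult, assign_tme_clusters, choose_k_elbow,
                              cluster_markers, extract_pc_signatures,
                              kmeans_cluster, orient_pca_by_score, run_pca,
                              select_hvg)
from geomxeco.preprocess import ExpressionMatrix


def em_from_array(arr, genes=None, segs=None, state="log2q3"):
    genes = genes or [f"g{i:03d}" for i in range(arr.shape[0])]
    segs = segs or [f"s{j:03d}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=segs), state)


def blob_matrix(k, per_blob=12, n_genes=40, sep=8.0, sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(k, n_genes))
    cols, labels = [], []
    for b in range(k):
        cols.append(centers[b] + rng.normal(0, sd, size=(per_blob, n_genes)))
        labels += [b] * per_blob
    return em_from_array(np.vstack(cols).T), np.array(labels)


class TestSelectHvg:
    def test_constant_matrix_breaks_ties_alphabetically(self):
        em = em_from_array(np.ones((20, 5)))
        assert select_hvg(em, 10) == sorted(em.genes)[:10]

    def test_single_variable_gene_wins(self):
        arr = np.ones((10, 4))
        arr[3] = [0, 5, 0, 5]
        em = em_from_array(arr)
        assert select_hvg(em, 1) == ["g003"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        em = em_from_array(rng.normal(size=(50, 12)))
        var = em.values.var(axis=1, ddof=1)
        expected = list(var.sort_values(ascending=False).index[:20])
        assert set(select_hvg(em, 20)) == set(expected)

    def test_invalid_n(self):
        em = em_from_array(np.ones((5, 3)))
        with pytest.raises(ValueError):
            select_hvg(em, 0)
        with pytest.raises(ValueError):
            select_hvg(em, 6)


class TestElbow:
    @pytest.mark.parametrize("k_true", [3, 5])
    def test_planted_blobs_recovered(self, k_true):
        em, _ = blob_matrix(k_true, seed=k_true)
        k_star, wss = choose_k_elbow(em, 10, seed=1)
        assert k_star == k_true
        ks = sorted(wss)
        assert all(wss[a] >= wss[b] - 1e-6 for a, b in zip(ks, ks[1:]))

    def test_identical_points_give_k1(self):
        em = em_from_array(np.ones((10, 20)))
        k_star, wss = choose_k_elbow(em, 10, seed=0)
        assert k_star == 1 and wss[1] == pytest.approx(0.0)

    def test_too_few_segments(self):
        em = em_from_array(np.ones((10, 5)))
        with pytest.raises(ValueError):
            choose_k_elbow(em, 10, seed=0)


class TestKmeans:
    def test_k1_wss_is_total_sum_of_squares(self):
        rng = np.random.default_rng(0)
        em = em_from_array(rng.normal(size=(8, 15)))
        a = kmeans_cluster(em, 1, seed=0)
        X = em.values.T.to_numpy()
        assert a.wss == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-9)

    def test_planted_blobs_perfect_ari_and_determinism(self):
        em, labels = blob_matrix(3, seed=11)
        a1 = kmeans_cluster(em, 3, seed=5)
        a2 = kmeans_cluster(em, 3, seed=5)
        assert adjusted_rand_score(labels, a1.labels) == 1.0
        assert (a1.labels == a2.labels).all()

    def test_orienting_score_orders_labels(self):
        em, labels = blob_matrix(3, seed=2)
        score = pd.Series(labels * 10.0, index=em.segments)
        a = kmeans_cluster(em, 3, seed=0, orient_by=score)
        means = score.groupby(a.labels).mean()
        assert list(means.sort_values().index) == [1, 2, 3]

    def test_more_attempts_never_worse(self):
        em, _ = blob_matrix(4, per_blob=8, sd=4.0, seed=9)
        many = kmeans_cluster(em, 4, seed=3, attempts=200)
        one = kmeans_cluster(em, 4, seed=3, attempts=1)
        assert many.wss <= one.wss + 1e-9

    def test_k_exceeding_segments(self):
        em = em_from_array(np.ones((5, 4)))
        with pytest.raises(ValueError):
            kmeans_cluster(em, 5, seed=0)


class TestPCA:
    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(4)
        em = em_from_array(rng.normal(size=(20, 10)))
        pca = run_pca(em)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T \
            + pca.mean.to_numpy()
        assert np.allclose(recon, em.values.T.to_numpy(), atol=1e-6)

    def test_loadings_orthonormal_and_evr_sorted(self):
        rng = np.random.default_rng(8)
        em = em_from_array(rng.normal(size=(15, 12)))
        pca = run_pca(em)
        L = pca.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        assert (np.diff(pca.explained_variance_fraction) <= 1e-12).all()

    def test_orientation_rule_fixes_sign(self):
        rng = np.random.default_rng(8)
        em = em_from_array(rng.normal(size=(15, 12)))
        pca = run_pca(em)
        for comp in pca.loadings.columns:
            col = pca.loadings[comp]
            assert col[col.abs().idxmax()] > 0


def pca_from_loadings(loadings: pd.DataFrame) -> PCAResult:
    n = loadings.shape[1]
    scores = pd.DataFrame(np.zeros((3, n)), columns=loadings.columns)
    return PCAResult(loadings=loadings, scores=scores,
                     explained_variance_fraction=np.linspace(0.5, 0.1, n),
                     mean=pd.Series(0.0, index=loadings.index))


class TestExtractSignatures:
    def test_identity_loadings(self):
        load = pd.DataFrame(np.eye(2), index=["gA", "gB"], columns=["PC1", "PC2"])
        sigs = extract_pc_signatures(pca_from_loadings(load), ["gA", "gB"])
        assert list(sigs.sig_cluster1.index) == ["gA"]
        assert list(sigs.sig_cluster2.index) == ["gB"]
        assert len(sigs.sig_cluster3) == 0

    def test_pc2_sign_flip_swaps_sig2_sig3(self):
        rng = np.random.default_rng(1)
        load = pd.DataFrame(np.linalg.qr(rng.normal(size=(30, 2)))[0],
                            index=[f"g{i}" for i in range(30)],
                            columns=["PC1", "PC2"])
        sigs = extract_pc_signatures(pca_from_loadings(load), list(load.index))
        flipped = load.copy()
        flipped["PC2"] *= -1
        sigs_f = extract_pc_signatures(pca_from_loadings(flipped), list(load.index))
        assert list(sigs_f.sig_cluster2.index) == list(sigs.sig_cluster3.index)
        assert list(sigs_f.sig_cluster3.index) == list(sigs.sig_cluster2.index)

    def test_signatures_disjoint_and_within_universe(self):
        rng = np.random.default_rng(2)
        load = pd.DataFrame(np.linalg.qr(rng.normal(size=(40, 3)))[0][:, :2],
                            index=[f"g{i}" for i in range(40)],
                            columns=["PC1", "PC2"])
        sigs = extract_pc_signatures(pca_from_loadings(load), list(load.index))
        s1, s2, s3 = (set(sigs.sig_cluster1.index), set(sigs.sig_cluster2.index),
                      set(sigs.sig_cluster3.index))
        assert not (s1 & s2) and not (s1 & s3) and not (s2 & s3)
        assert (s1 | s2 | s3) <= set(load.index)

    def test_degenerate_pca_raises(self):
        load = pd.DataFrame(np.zeros((5, 2)), index=[f"g{i}" for i in range(5)],
                            columns=["PC1", "PC2"])
        with pytest.raises(ValueError, match="degenerate"):
            extract_pc_signatures(pca_from_loadings(load), list(load.index))

    def test_planted_programs_recovered(self, config, preprocessed, tumor_segments,
                                        ne_profiles, dataset):
        # >= 80% of each planted phenotype program lands in the matching
        # PC-contribution signature once components are oriented by NE score
        from geomxeco.scoring import ne_score

        _, _, truth = dataset
        em = preprocessed["log2q3"].subset_segments(tumor_segments)
        hvg = select_hvg(em, 500)
        ne, nonne = ne_profiles
        pca = orient_pca_by_score(run_pca(em, genes=hvg), ne_score(em, ne, nonne))
        sigs = extract_pc_signatures(pca, hvg)
        for sig, pheno in [(sigs.sig_cluster1, "nonNE"),
                           (sigs.sig_cluster2, "hybrid"),
                           (sigs.sig_cluster3, "NE")]:
            planted = set(truth.signature_genes[pheno])
            assert len(planted & set(sig.index)) / len(planted) >= 0.8


class TestAssignTme:
    def test_paired_design_inherits_labels(self, preprocessed, tumor_segments,
                                           dataset):
        _, _, truth = dataset
        ann = preprocessed["ann"]
        labels = pd.Series(1, index=tumor_segments)
        for seg in tumor_segments:
            labels[seg] = {"nonNE": 1, "hybrid": 2, "NE": 3}[
                truth.segment_phenotypes[seg]]
        tme = assign_tme_clusters(labels, ann)
        assert len(tme) == 30
        for seg, lab in tme.items():
            expected = {"nonNE": 1, "hybrid": 2, "NE": 3}[
                truth.segment_phenotypes[seg]]
            assert lab == expected

    def test_unpaired_tme_flagged(self):
        ann = pd.DataFrame({
            "compartment": ["tumor", "TME", "TME"],
            "patient_id": ["P1"] * 3, "region_id": ["R1", "R1", "R2"],
            "area": [1e5] * 3, "nuclei": [100] * 3, "saturation": [0.9] * 3,
        }, index=["t1", "m1", "m2"])
        labels = pd.Series({"t1": 2})
        tme = assign_tme_clusters(labels, ann)
        assert tme["m1"] == 2 and pd.isna(tme["m2"])


class TestClusterMarkers:
    @staticmethod
    def q3_em(arr, **kw):
        return em_from_array(arr, state="q3", **kw)

    def test_identical_distributions_no_markers(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(2, 0.1, size=20)
        arr = np.tile(base[:, None], (1, 12))
        em = self.q3_em(arr)
        labels = pd.Series([1] * 6 + [2] * 6, index=em.segments)
        table = cluster_markers(em, labels)
        assert not table["is_marker"].any()

    def test_fourfold_shift_detected(self):
        rng = np.random.default_rng(1)
        arr = rng.lognormal(2, 0.05, size=(10, 30))
        arr[0, :10] *= 4.0
        em = self.q3_em(arr)
        labels = pd.Series([1] * 10 + [2] * 20, index=em.segments)
        table = cluster_markers(em, labels)
        row = table[(table["gene"] == "g000") & (table["cluster"] == 1)].iloc[0]
        assert row["is_marker"]
        assert row["log2fc"] == pytest.approx(2.0, abs=0.3)

    def test_wilcoxon_matches_exact_permutation_oracle(self):
        # exact two-sided rank-sum p by full enumeration at n = 4 vs 4
        from itertools import combinations

        x = np.array([1.3, 2.1, 5.0, 6.2])
        y = np.array([0.4, 0.9, 1.7, 3.3])
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:4].sum()
        n = len(pooled)
        sums = [ranks[list(c)].sum() for c in combinations(range(n), 4)]
        mu = np.mean(sums)
        p_exact = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-12 for s in sums])
        p_mw = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="exact").pvalue
        assert p_mw == pytest.approx(p_exact, abs=1e-12)

    def test_zero_median_flagged(self):
        arr = np.zeros((3, 8))
        arr[0, :4] = 9.0
        em = self.q3_em(arr)
        labels = pd.Series([1] * 4 + [2] * 4, index=em.segments)
        table = cluster_markers(em, labels)
        row = table[(table["gene"] == "g000") & (table["cluster"] == 1)].iloc[0]
        assert row["pseudocount_applied"]
        assert row["log2fc"] == pytest.approx(np.log2(10))

    def test_requires_two_segments_per_cluster(self):
        em = self.q3_em(np.ones((4, 5)))
        labels = pd.Series([1, 2, 2, 2, 2], index=em.segments)
        with pytest.raises(ValueError):
            cluster_markers(em, labels)
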