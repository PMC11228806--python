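"""ssGSEA engine, NE score, purity model, indices, preranked GSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from geomxeco.scoring import (GeneSetCollection, fit_purity_model, h_score,
                              ne_score, pairwise_signature_correlation,
                              predict_purity, preranked_gsea,
                              rank_by_signed_logp, shannon_index, ssgsea)


def ssgsea_reference(values: pd.DataFrame, gene_set: set, alpha: float) -> dict:
    """Direct double-loop ssGSEA for one set (independent oracle)."""
    out = {}
    for seg in values.columns:
        df = pd.DataFrame({"x": values[seg], "g": values.index}).sort_values(
            ["x", "g"], ascending=[False, True], kind="mergesort")
        in_set = df["g"].isin(gene_set).to_numpy()
        n = len(df)
        weights = np.arange(n, 0, -1, dtype=float) ** alpha
        w_in_total = weights[in_set].sum()
        n_out = (~in_set).sum()
        es, cum_in, cum_out = 0.0, 0.0, 0
        for i in range(n):
            if in_set[i]:
                cum_in += weights[i]
            else:
                cum_out += 1
            es += cum_in / w_in_total - (cum_out / n_out if n_out else 0.0)
        out[seg] = es
    return out


class TestSsgsea:
    def test_singleton_top_gene_walk(self):
        # 4 genes, set = {top gene}: stepwise differences 1 + 2/3 + 1/3 + 0
        em = pd.DataFrame({"s": [10.0, 5.0, 2.0, 1.0]}, index=list("ABCD"))
        with pytest.warns(UserWarning, match="single gene"):
            sm = ssgsea(em, GeneSetCollection({"top": ["A"]}), normalize=False)
        assert sm.values.loc["top", "s"] == pytest.approx(2.0, abs=1e-12)

    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(1, 1, 30)
        em = pd.DataFrame({"s1": col, "s2": col},
                          index=[f"g{i}" for i in range(30)])
        sm = ssgsea(em, GeneSetCollection({"a": ["g0", "g5", "g7"]}))
        assert sm.values["s1"].equals(sm.values["s2"])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        em = pd.DataFrame(rng.lognormal(1, 1, (80, 10)),
                          index=[f"g{i:03d}" for i in range(80)],
                          columns=[f"s{j}" for j in range(10)])
        sets = {f"set{k}": list(rng.choice(em.index, size=12, replace=False))
                for k in range(5)}
        sm = ssgsea(em, GeneSetCollection(sets), alpha=0.25, normalize=False)
        for name, genes in sets.items():
            ref = ssgsea_reference(em, set(genes), 0.25)
            for seg in em.columns:
                assert sm.values.loc[name, seg] == pytest.approx(ref[seg], abs=1e-10)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        em = pd.DataFrame(rng.lognormal(0, 1, (40, 6)),
                          index=[f"g{i}" for i in range(40)])
        sets = GeneSetCollection({"a": ["g1", "g4", "g9", "g20"]})
        s1 = ssgsea(em, sets, normalize=False)
        s2 = ssgsea(np.exp(em / 3.0) + 5.0, sets, normalize=False)
        assert np.allclose(s1.values, s2.values)

    def test_zero_overlap_gives_nan(self):
        em = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=list("ABC"))
        with pytest.warns(UserWarning, match="no overlap"):
            sm = ssgsea(em, GeneSetCollection({"x": ["Z1", "Z2"]}))
        assert np.isnan(sm.values.loc["x", "s"])

    def test_normalization_divides_by_global_span(self):
        rng = np.random.default_rng(3)
        em = pd.DataFrame(rng.lognormal(0, 1, (30, 4)),
                          index=[f"g{i}" for i in range(30)])
        sets = GeneSetCollection({"a": ["g1", "g2", "g3"],
                                  "b": ["g10", "g11", "g12", "g13"]})
        raw = ssgsea(em, sets, normalize=False).values
        norm = ssgsea(em, sets, normalize=True).values
        span = raw.to_numpy().max() - raw.to_numpy().min()
        assert np.allclose(norm, raw / span)


class TestNeScore:
    def test_perfect_match_scores_one(self):
        genes = [f"g{i}" for i in range(10)]
        prof = pd.Series(np.linspace(1, 5, 10), index=genes)
        em = pd.DataFrame({"s": prof})
        assert ne_score(em, prof, -prof)["s"] == pytest.approx(1.0)

    def test_antisymmetric_under_profile_swap(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(12)]
        ne = pd.Series(rng.normal(size=12), index=genes)
        nonne = pd.Series(rng.normal(size=12), index=genes)
        em = pd.DataFrame(rng.normal(size=(12, 5)), index=genes)
        assert np.allclose(ne_score(em, ne, nonne), -ne_score(em, nonne, ne))

    def test_orthogonal_segment_scores_zero(self):
        genes = [f"g{i}" for i in range(4)]
        ne = pd.Series([1.0, 1, -1, -1], index=genes)
        nonne = pd.Series([1.0, -1, 1, -1], index=genes)
        em = pd.DataFrame({"s": [1.0, -1, -1, 1]}, index=genes)
        assert ne_score(em, ne, nonne)["s"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_phenotypes_ordered(self, preprocessed, tumor_segments,
                                        ne_profiles, dataset):
        _, _, truth = dataset
        em = preprocessed["log2q3"].subset_segments(tumor_segments)
        ne, nonne = ne_profiles
        scores = ne_score(em, ne, nonne)
        pheno = pd.Series(truth.segment_phenotypes)[tumor_segments]
        means = scores.groupby(pheno).mean()
        assert means["NE"] > means["hybrid"] > means["nonNE"]

    def test_needs_three_shared_genes(self):
        prof = pd.Series([1.0, 2.0], index=["a", "b"])
        em = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            ne_score(em, prof, prof)


class TestPurityModel:
    def test_noiseless_recovery_exact(self):
        rng = np.random.default_rng(0)
        s, i = rng.uniform(0, 0.4, 50), rng.uniform(0, 0.4, 50)
        purity = 0.95 - 0.7 * s - 0.5 * i
        model = fit_purity_model(pd.DataFrame(
            {"stromal": s, "immune": i, "purity": purity}))
        assert model.intercept == pytest.approx(0.95, abs=1e-8)
        assert model.beta_stromal == pytest.approx(-0.7, abs=1e-8)
        assert model.beta_immune == pytest.approx(-0.5, abs=1e-8)
        assert model.training_r2 == pytest.approx(1.0)

    def test_noisy_recovery_small_bias(self):
        rng = np.random.default_rng(1)
        biases = []
        for _ in range(100):
            s, i = rng.uniform(0, 0.4, 100), rng.uniform(0, 0.4, 100)
            purity = np.clip(0.9 - 0.6 * s - 0.5 * i
                             + rng.normal(0, 0.05, 100), 0, 1)
            m = fit_purity_model(pd.DataFrame(
                {"stromal": s, "immune": i, "purity": purity}))
            biases.append(m.beta_stromal - (-0.6))
        assert abs(np.mean(biases)) < 0.02

    def test_predictions_clamped_and_flagged(self):
        model = fit_purity_model(pd.DataFrame(
            {"stromal": [0.0, 0.1, 0.2, 0.3], "immune": [0.0, 0.2, 0.1, 0.3],
             "purity": [1.0, 0.7, 0.7, 0.4]}))
        scores = pd.DataFrame({"stromal": [-1.0], "immune": [-1.0]}, index=["s"])
        pred, flags = predict_purity(model, scores)
        assert pred["s"] == 1.0 and flags["s"]

    def test_collinear_predictors_rejected(self):
        s = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="collinear"):
            fit_purity_model(pd.DataFrame(
                {"stromal": s, "immune": 2 * s, "purity": 1 - s * 0.5}))


class TestShannon:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_uniform_is_maximal_ln_n(self, n):
        assert shannon_index(np.full(n, 1 / n)) == pytest.approx(np.log(n))

    def test_examples(self):
        assert shannon_index([1.0, 0, 0]) == 0.0
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=2e-4)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_uniform_entropy(self, raw):
        p = np.array(raw) / np.sum(raw)
        assert shannon_index(p) <= np.log(len(p)) + 1e-9

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([-0.1, 1.1])


class TestHScore:
    def test_examples(self):
        assert h_score(0, 0, 100) == 300.0
        assert h_score(0, 0, 0) == 0.0
        assert h_score(50, 30, 20) == 170.0

    def test_sum_above_100_rejected(self):
        with pytest.raises(ValueError):
            h_score(60, 30, 20)

    @given(st.tuples(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100))
           .filter(lambda t: sum(t) <= 100))
    @settings(max_examples=100, deadline=None)
    def test_weighted_sum_formula(self, t):
        w, m, s = t
        assert h_score(w, m, s) == pytest.approx(w + 2 * m + 3 * s)
        assert 0 <= h_score(w, m, s) <= 300


class TestPrerankedGsea:
    @staticmethod
    def monotone_ranking(n=40):
        return pd.Series(np.linspace(2, -2, n), index=[f"g{i:02d}" for i in range(n)])

    def test_es_matches_cumulative_sum_oracle(self):
        ranked = self.monotone_ranking()
        genes = ["g00", "g03", "g10"]
        res = preranked_gsea(ranked, GeneSetCollection({"s": genes}),
                             n_perm=100, seed=0)
        metric = ranked.to_numpy()
        mask = np.isin(ranked.index.to_numpy(), genes)
        w = np.abs(metric) * mask
        running = np.cumsum(w) / w.sum() - np.cumsum(~mask) / (~mask).sum()
        expected = running[np.argmax(np.abs(running))]
        assert res.loc["s", "es"] == pytest.approx(expected, abs=1e-12)

    def test_top_k_set_is_maximal_among_same_size(self):
        from itertools import combinations

        ranked = pd.Series(np.linspace(3, -3, 12),
                           index=[f"g{i:02d}" for i in range(12)])

        def es_of(genes):
            res = preranked_gsea(ranked, GeneSetCollection(
                {"s": list(genes)}), n_perm=100, seed=0)
            return res.loc["s", "es"]

        top = es_of(["g00", "g01"])
        assert top > 0
        for combo in combinations(ranked.index, 2):
            assert es_of(combo) <= top + 1e-12

    def test_random_set_null_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(60)]
        pvals = []
        for b in range(60):
            ranked = pd.Series(rng.normal(size=60), index=genes)
            gset = list(rng.choice(genes, size=10, replace=False))
            res = preranked_gsea(ranked, GeneSetCollection({"s": gset}),
                                 n_perm=200, seed=b)
            pvals.append(res.loc["s", "p"])
        from scipy import stats as sps
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_non_overlapping_set_skipped(self):
        ranked = self.monotone_ranking()
        res = preranked_gsea(ranked, GeneSetCollection(
            {"a": ["g00", "g01"], "b": ["ZZ1", "ZZ2"]}), n_perm=100, seed=0)
        assert res.attrs["skipped"] == ["b"]
        assert list(res.index) == ["a"]


class TestRankBySignedLogp:
    def test_signed_log10(self):
        table = pd.DataFrame({"gene": ["up", "down"], "p": [0.01, 0.01],
                              "log2fc": [1.5, -1.5]})
        ranked = rank_by_signed_logp(table)
        assert ranked["up"] == pytest.approx(2.0)
        assert ranked["down"] == pytest.approx(-2.0)
        assert list(ranked.index) == ["up", "down"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"gene": [f"g{i}" for i in range(20)],
                              "p": rng.uniform(0.001, 1, 20),
                              "log2fc": rng.normal(size=20)})
        r1 = rank_by_signed_logp(table)
        r2 = rank_by_signed_logp(table.sample(frac=1, random_state=1))
        assert r1.equals(r2)

    def test_zero_p_floored_with_warning(self):
        table = pd.DataFrame({"gene": ["a", "b"], "p": [0.0, 0.5],
                              "log2fc": [2.0, 1.0]})
        with pytest.warns(UserWarning, match="floored"):
            ranked = rank_by_signed_logp(table)
        assert np.isfinite(ranked["a"]) and ranked["a"] > 100


class TestPairwiseCorrelation:
    def test_duplicate_and_negated_rows(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=10)
        scores = pd.DataFrame([base, base, -base], index=["a", "a2", "neg"])
        corr, order, excluded = pairwise_signature_correlation(scores)
        assert corr.loc["a", "a2"] == pytest.approx(1.0)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)
        assert excluded == []
        assert set(order) == {"a", "a2", "neg"}

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(rng.normal(size=(5, 20)),
                              index=[f"r{i}" for i in range(5)])
        corr, _, _ = pairwise_signature_correlation(scores)
        assert np.allclose(corr, np.corrcoef(scores.to_numpy()), atol=1e-12)

    def test_constant_row_excluded(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(rng.normal(size=(3, 8)), index=["a", "b", "c"])
        scores.loc["c"] = 5.0
        corr, order, excluded = pairwise_signature_correlation(scores)
        assert excluded == ["c"] and "c" not in corr.index
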