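"""Composition statistics: CLR, PCA, NB/rank regressions, PERMANOVA,
correlations, Fisher tests, and Lasso feature selection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

from esoatlas.composition import (
    CompositionTable,
    activity_correlation,
    clr_transform,
    composition_pca,
    composition_table,
    condition_proportion_fisher,
    fisher_tests,
    lasso_fraction_predictor,
    nb_abundance,
    permanova,
    proportion_correlation_clusters,
    quantile_normalize,
    quantile_rank_regression,
)
from esoatlas.synthetic import simulate_composition


def _comp(n_samples=20, seed=0, **kw):
    counts, samples, _ = simulate_composition(n_samples=n_samples, seed=seed, **kw)
    return CompositionTable(counts, samples)


# ---------------------------------------------------------------------------
# CLR + PCA
# ---------------------------------------------------------------------------

class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        counts = pd.DataFrame([[7, 7, 7]], index=["s"], columns=list("abc"))
        np.testing.assert_allclose(clr_transform(counts).to_numpy(), 0.0, atol=1e-12)

    def test_hand_evaluated_example(self):
        counts = pd.DataFrame([[10, 20, 40]], index=["s"], columns=list("abc"))
        gm = (10 * 20 * 40) ** (1 / 3)
        expected = [np.log(c / gm) for c in (10, 20, 40)]
        np.testing.assert_allclose(
            clr_transform(counts).to_numpy().ravel(), expected, atol=1e-12
        )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        hst.lists(
            hst.lists(hst.integers(0, 500), min_size=4, max_size=4),
            min_size=2, max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    def test_rows_sum_to_zero_and_scale_invariance(self, rows):
        counts = pd.DataFrame(rows, columns=list("abcd"))
        clr = clr_transform(counts)
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)
        scaled = clr_transform(counts * 3)
        # scaling a sample's counts only rescales the imputed zeros;
        # nonzero rows are exactly invariant
        nonzero = (counts > 0).all(axis=1)
        if nonzero.any():
            np.testing.assert_allclose(
                clr[nonzero].to_numpy(), scaled[nonzero].to_numpy(), atol=1e-9
            )

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame([[0, 0, 0]], columns=list("abc"))
        with pytest.raises(ValueError, match="all-zero"):
            clr_transform(counts)


class TestCompositionPCA:
    def test_separating_cell_type_dominates_pc1(self):
        # two duplicated sample groups differing only in cell type "b"
        lo = [50, 10, 40]
        hi = [50, 60, 40]
        counts = pd.DataFrame(
            [lo] * 4 + [hi] * 4, columns=list("abc"),
            index=[f"s{i}" for i in range(8)],
        )
        res = composition_pca(clr_transform(counts))
        pc1 = res.scores["PC1"]
        assert (pc1.iloc[:4] < pc1.iloc[4:].min()).all() or (
            pc1.iloc[:4] > pc1.iloc[4:].max()
        ).all()
        assert res.loadings["PC1"].abs().idxmax() == "b"

    def test_identical_samples_give_zero_scores(self):
        counts = pd.DataFrame([[5, 5, 5]] * 4, columns=list("abc"))
        res = composition_pca(clr_transform(counts))
        np.testing.assert_allclose(res.scores.to_numpy(), 0.0, atol=1e-9)

    def test_explained_variance_is_a_simplex(self):
        comp = _comp(n_samples=15, seed=3)
        res = composition_pca(clr_transform(comp))
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)


# ---------------------------------------------------------------------------
# NB + rank regressions
# ---------------------------------------------------------------------------

class TestNBAbundance:
    def test_constant_covariate_dropped_with_warning(self):
        comp = _comp(n_samples=16, seed=5)
        comp.samples["steroid"] = False  # constant
        with pytest.warns(UserWarning, match="constant"):
            res = nb_abundance(comp)
        assert len(res) == comp.counts.shape[1]

    def test_all_zero_cell_type_excluded(self):
        comp = _comp(n_samples=16, seed=5)
        comp.counts["ct00"] = 0
        with pytest.warns(UserWarning, match="zero counts"):
            res = nb_abundance(comp)
        assert "ct00" not in res.index

    def test_planted_enrichment_detected(self):
        comp = _comp(
            n_samples=30, seed=8, effects={("ct05", "active"): np.log(2.0)}
        )
        res = nb_abundance(comp)
        assert res.loc["ct05", "fdr"] < 0.05
        assert res.loc["ct05", "beta"] > 0

    def test_bh_fdr_matches_direct_step_up(self):
        comp = _comp(n_samples=24, seed=2)
        res = nb_abundance(comp)
        p = res["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        direct = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            direct[order[rank]] = running
        np.testing.assert_allclose(res["fdr"].to_numpy(), direct, atol=1e-12)


class TestQuantileRank:
    def test_quantile_normalized_columns_share_sorted_values(self):
        # continuous values: tie-free, so the sorted multisets match exactly
        rng = np.random.default_rng(1)
        props = pd.DataFrame(rng.uniform(size=(12, 5)), columns=list("abcde"))
        qn = quantile_normalize(props)
        ref = np.sort(qn.to_numpy()[:, 0])
        for j in range(1, qn.shape[1]):
            np.testing.assert_allclose(np.sort(qn.to_numpy()[:, j]), ref, atol=1e-12)

    def test_planted_enrichment_detected(self):
        comp = _comp(
            n_samples=30, seed=8, effects={("ct05", "active"): np.log(2.0)}
        )
        res = quantile_rank_regression(comp)
        assert res.loc["ct05", "fdr"] < 0.05


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class TestPermanova:
    def test_deterministic_given_seed(self):
        comp = _comp(n_samples=14, seed=6)
        a = permanova(comp, n_perm=199, seed=3)
        b = permanova(comp, n_perm=199, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_scikit_bio_single_factor_pseudo_f(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        comp = _comp(n_samples=16, seed=7)
        mine = permanova(comp, terms=("condition",), n_perm=99, seed=0)
        Y = quantile_normalize(comp.proportions).to_numpy()
        dm = DistanceMatrix(
            squareform(pdist(Y)), ids=[str(i) for i in range(len(Y))]
        )
        sk = sk_permanova(dm, comp.samples["condition"].to_numpy(), permutations=99)
        assert mine.loc["condition", "pseudo_F"] == pytest.approx(
            sk["test statistic"], rel=1e-10
        )

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_vegan_adonis2_sequential_partition(self, tmp_path):
        comp = _comp(n_samples=18, seed=42, n_cell_types=6)
        mine = permanova(comp, terms=("condition", "chemistry"), n_perm=99, seed=1)
        Y = quantile_normalize(comp.proportions)
        np.savetxt(tmp_path / "Y.csv", Y.to_numpy(), delimiter=",")
        comp.samples[["condition", "chemistry"]].to_csv(
            tmp_path / "meta.csv", index=False
        )
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            'Y <- as.matrix(read.csv("Y.csv", header=FALSE))\n'
            'meta <- read.csv("meta.csv")\n'
            'res <- adonis2(Y ~ condition + chemistry, data=meta,'
            ' method="euclidean", by="terms", permutations=99)\n'
            'write.csv(data.frame(term=rownames(res), ss=res$SumOfSqs, f=res$F),'
            ' "out.csv", row.names=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True
        )
        vg = pd.read_csv(tmp_path / "out.csv").set_index("term")
        for term in ("condition", "chemistry"):
            assert mine.loc[term, "ss"] == pytest.approx(vg.loc[term, "ss"], rel=1e-8)
            assert mine.loc[term, "pseudo_F"] == pytest.approx(
                vg.loc[term, "f"], rel=1e-8
            )

    def test_separated_groups_reach_minimum_p(self):
        rng = np.random.default_rng(0)
        counts = np.vstack(
            [rng.multinomial(1000, [0.8, 0.1, 0.1], size=8),
             rng.multinomial(1000, [0.1, 0.1, 0.8], size=8)]
        )
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(16)],
             "condition": ["healthy"] * 8 + ["active"] * 8}
        ).set_index("sample_id", drop=False)
        comp = CompositionTable(
            pd.DataFrame(counts, index=samples.index, columns=list("abc")), samples
        )
        res = permanova(comp, n_perm=199, seed=0)
        assert res.loc["condition", "p"] == pytest.approx(1 / 200)

    def test_single_level_term_dropped(self):
        comp = _comp(n_samples=12, seed=3)
        comp.samples["region"] = "distal"
        with pytest.warns(UserWarning, match="single level"):
            res = permanova(comp, terms=("condition", "region"), n_perm=99, seed=0)
        assert list(res.index) == ["condition"]


# ---------------------------------------------------------------------------
# activity correlation, clustering, Fisher, Lasso
# ---------------------------------------------------------------------------

class TestActivityCorrelation:
    def test_perfect_monotone_association(self):
        comp = _comp(n_samples=10, seed=4)
        activity = pd.Series(
            comp.counts["ct00"].to_numpy(), index=comp.counts.index, dtype=float
        )
        res = activity_correlation(comp, activity)
        assert res.loc["ct00", "rho"] == pytest.approx(1.0)
        assert res.loc["ct00", "p"] == 0.0

    def test_t_statistic_matches_closed_form(self):
        comp = _comp(n_samples=14, seed=9)
        activity = pd.Series(
            np.arange(14, dtype=float), index=comp.counts.index
        )
        res = activity_correlation(comp, activity)
        for ct in res.index:
            rho = res.loc[ct, "rho"]
            if abs(rho) == 1:
                continue
            t_expected = rho * np.sqrt((14 - 2) / (1 - rho ** 2))
            p_expected = 2 * st.t.sf(abs(t_expected), df=12)
            assert res.loc[ct, "t"] == pytest.approx(t_expected, rel=1e-12)
            assert res.loc[ct, "p"] == pytest.approx(p_expected, rel=1e-12)

    def test_constant_activity_rejected(self):
        comp = _comp(n_samples=8, seed=4)
        activity = pd.Series(1.0, index=comp.counts.index)
        with pytest.raises(ValueError, match="constant"):
            activity_correlation(comp, activity)


class TestProportionClusters:
    def test_duplicated_type_merges_first_at_zero_height(self):
        rng = np.random.default_rng(1)
        a = rng.integers(50, 150, size=8)
        counts = pd.DataFrame(
            {"a": a, "a2": a, "b": rng.integers(50, 150, size=8),
             "c": rng.integers(50, 150, size=8)},
            index=[f"s{i}" for i in range(8)],
        )
        samples = pd.DataFrame(
            {"sample_id": counts.index, "condition": "healthy"}
        ).set_index("sample_id", drop=False)
        res = proportion_correlation_clusters(CompositionTable(counts, samples))
        assert res.correlation.loc["a", "a2"] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(res.correlation), 1.0, atol=1e-12)
        first = res.linkage[0]
        merged = {res.correlation.columns[int(first[0])],
                  res.correlation.columns[int(first[1])]}
        assert merged == {"a", "a2"}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_closure_complement_is_anticorrelated(self):
        rng = np.random.default_rng(2)
        a = rng.integers(100, 900, size=10)
        counts = pd.DataFrame(
            {"a": a, "b": 1000 - a, "c": rng.integers(95, 105, size=10)},
            index=[f"s{i}" for i in range(10)],
        )
        samples = pd.DataFrame(
            {"sample_id": counts.index, "condition": "healthy"}
        ).set_index("sample_id", drop=False)
        res = proportion_correlation_clusters(CompositionTable(counts, samples))
        assert res.correlation.loc["a", "b"] < -0.95


class TestFisher:
    def test_balanced_table_not_associated(self):
        _, p, flag = condition_proportion_fisher([[10, 10], [10, 10]])
        assert p == pytest.approx(1.0) and not flag

    def test_diagonal_table_matches_hypergeometric_enumeration(self):
        _, p, _ = condition_proportion_fisher([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_empty_margin_flagged(self):
        _, p, flag = condition_proportion_fisher([[0, 0], [3, 4]])
        assert p == 1.0 and flag

    def test_vectorized_bh(self):
        out = fisher_tests(
            {"x": np.array([[5, 0], [0, 5]]), "y": np.array([[3, 3], [3, 3]])}
        )
        assert out.loc["x", "fdr"] <= 2 * out.loc["x", "p"]
        assert out.loc["y", "fdr"] == pytest.approx(1.0)


class TestLasso:
    def test_identity_signal_selected_with_near_zero_cv_error(self):
        rng = np.random.default_rng(3)
        F = pd.DataFrame(
            rng.normal(size=(20, 6)), columns=[f"f{i}" for i in range(6)]
        )
        target = pd.Series(F["f2"].to_numpy(), index=F.index)
        fit = lasso_fraction_predictor(target, F)
        assert "f2" in fit.coefficients.index
        assert fit.coefficients.abs().idxmax() == "f2"
        resid = fit.loocv_predictions.to_numpy() - target.to_numpy()
        assert np.mean(resid ** 2) < 0.01 * target.var()
        assert fit.slope_p < 1e-6

    def test_collinear_features_not_both_selected_at_strong_penalty(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=24)
        F = pd.DataFrame(
            {"dup1": x, "dup2": x, "noise": rng.normal(size=24)}
        )
        target = pd.Series(x + 0.05 * rng.normal(size=24))
        amax = np.abs(
            ((F - F.mean()) / F.std(ddof=0)).to_numpy().T
            @ (target - target.mean()).to_numpy()
        ).max() / len(target)
        fit = lasso_fraction_predictor(
            target, F, alphas=np.array([amax * 0.5])
        )
        assert (fit.coefficients.index.isin(["dup1", "dup2"])).sum() <= 1

    def test_all_zero_target_rejected(self):
        F = pd.DataFrame(np.eye(6))
        with pytest.raises(ValueError, match="all-zero"):
            lasso_fraction_predictor(pd.Series(np.zeros(6)), F)


def test_composition_table_from_cell_metadata(small_atlas):
    data, samples, _ = small_atlas
    comp = composition_table(data.obs, samples)
    assert comp.counts.sum().sum() == data.n_obs
    assert (comp.totals > 0).all()
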