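import numpy as np
import pandas as pd
import pytest

from subloc import synth
from subloc.clip import ClipPeakTable
from subloc.code import LocalizationCode, prepare_design


def small_features(genes):
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "mrna_length": rng.integers(500, 8000, len(genes)),
        "mean_cds_exon_length": rng.uniform(50, 400, len(genes)),
    }, index=genes)


class TestPrepareDesign:
    def test_sqrt_then_standardize(self):
        genes = pd.Index([f"g{i}" for i in range(4)], name="gene_id")
        counts = pd.DataFrame({r: [0, 0, 0, 0] for r in
                               ("HuR", "PUM2", "HNRNPC", "TIA1/L1",
                                "LARP4B", "METAP2")}, index=genes)
        counts["TIS11B"] = [0, 1, 4, 9]
        with pytest.warns(UserWarning):  # the all-zero columns are dropped
            design = prepare_design(ClipPeakTable(counts),
                                    small_features(genes), "rbp_only",
                                    genes=genes)
        col = design.X["TIS11B"]
        # sqrt gives {0,1,2,3}; mean 1.5, population SD sqrt(1.25)
        expect = (np.array([0, 1, 2, 3]) - 1.5) / np.sqrt(1.25)
        np.testing.assert_allclose(col, expect, atol=1e-12)
        assert abs(col.mean()) < 1e-8 and abs(col.std(ddof=0) - 1) < 1e-8

    def test_zero_variance_column_dropped(self):
        genes = pd.Index(["g0", "g1", "g2"], name="gene_id")
        counts = pd.DataFrame({r: [1, 2, 3] for r in
                               ("TIS11B", "HuR", "PUM2", "HNRNPC",
                                "TIA1/L1", "LARP4B")}, index=genes)
        counts["METAP2"] = [2, 2, 2]
        with pytest.warns(UserWarning, match="METAP2"):
            design = prepare_design(ClipPeakTable(counts),
                                    small_features(genes), "rbp_only",
                                    genes=genes)
        assert "METAP2" in design.dropped
        assert "METAP2" not in design.covariates

    def test_missing_genes_imputed_as_zero(self):
        genes = pd.Index([f"g{i}" for i in range(6)], name="gene_id")
        counts = pd.DataFrame(
            {r: [3, 1, 4, 1] for r in
             ("TIS11B", "HuR", "PUM2", "HNRNPC", "TIA1/L1", "LARP4B",
              "METAP2")}, index=genes[:4])  # g4, g5 absent from CLIP table
        design = prepare_design(ClipPeakTable(counts), small_features(genes),
                                "rbp_only", genes=genes)
        raw_sqrt = np.sqrt([3, 1, 4, 1, 0, 0])
        st = design.transform_state.loc["TIS11B"]
        np.testing.assert_allclose(design.X["TIS11B"],
                                   (raw_sqrt - st["mean"]) / st["sd"])

    def test_transform_state_reusable_on_new_genes(self):
        peaks, features, labels, design, _ = synth.simulate_code_dataset(
            n_genes=300, seed=2)
        raw = peaks.counts.join(
            features[["mrna_length", "mean_cds_exon_length"]]).iloc[:10]
        again = design.apply_to(raw)
        np.testing.assert_allclose(again, design.X.iloc[:10], atol=1e-10)


@pytest.fixture(scope="module")
def fitted():
    peaks, features, labels, design, coef = synth.simulate_code_dataset(
        n_genes=5000, seed=17)
    res = LocalizationCode(design, labels).fit()
    return res, coef, design


class TestFit:
    def test_parameter_recovery_within_three_se(self, fitted):
        res, coef, _ = fitted
        z = (res.params - coef) / res.bse
        assert (np.abs(z.to_numpy()) < 3).mean() >= 0.95

    def test_agrees_with_independent_sklearn_fit(self, fitted):
        sklearn = pytest.importorskip("sklearn.linear_model")
        res, _, design = fitted
        clf = sklearn.LogisticRegression(C=1e6, max_iter=2000,
                                         solver="lbfgs")
        y = res.model.labels.to_numpy()
        clf.fit(design.X.to_numpy(), y)
        # re-express sklearn's symmetric coefficients relative to 'unbiased'
        classes = list(clf.classes_)
        base = classes.index("unbiased")
        for cls in res.params.index:
            i = classes.index(cls)
            delta = clf.coef_[i] - clf.coef_[base]
            mine = res.params.loc[cls, design.covariates].to_numpy()
            np.testing.assert_allclose(mine, delta, atol=0.02)

    def test_null_covariates_give_nominal_t_rate(self):
        rng = np.random.default_rng(21)
        peaks, features, labels, design, _ = synth.simulate_code_dataset(
            n_genes=4000, seed=3)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
        res = LocalizationCode(design, shuffled).fit()
        t = res.tvalues.drop(columns="intercept").to_numpy().ravel()
        frac = (np.abs(t) > 1.96).mean()
        assert frac < 0.15  # ~5% expected; generous binomial slack at 27 df

    def test_probabilities_sum_to_one_and_base_is_reference(self, fitted):
        res, _, _ = fitted
        proba = res.predict_proba()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert proba.columns[0] == "unbiased"

    def test_thin_class_raises(self):
        peaks, features, labels, design, _ = synth.simulate_code_dataset(
            n_genes=300, seed=4)
        few = int(labels.value_counts().min())
        with pytest.raises(ValueError, match="genes"):
            LocalizationCode(design, labels, min_per_class=few + 1)


class TestPropensity:
    def test_gene_at_covariate_mean_gets_intercept(self, fitted):
        res, _, design = fitted
        zero = pd.DataFrame(0.0, index=["mean_gene"],
                            columns=design.covariates)
        prop = res.propensity("TG_plus", zero)
        assert prop.iloc[0] == pytest.approx(
            res.params.at["TG_plus", "intercept"])

    def test_monotone_in_positive_coefficient(self, fitted):
        res, _, design = fitted
        cov = "TIS11B"
        assert res.params.at["TG_plus", cov] > 0
        grid = pd.DataFrame(0.0, index=range(5), columns=design.covariates)
        grid[cov] = np.linspace(-2, 2, 5)
        prop = res.propensity("TG_plus", grid)
        assert (np.diff(prop) > 0).all()

    def test_additive_strata_are_ordered(self, fitted):
        # the combinatorial claim: binding and architecture act additively,
        # so (no RBP, short exons) < single-positive strata < both-positive
        res, _, design = fitted
        X = design.X
        bound = X["TIS11B"] > 0.5
        long_exons = X["mean_cds_exon_length"] > 0.5
        prop = res.propensity("TG_plus")
        strata = [prop[~bound & ~long_exons].median(),
                  prop[bound ^ long_exons].median(),
                  prop[bound & long_exons].median()]
        assert strata[0] < strata[1] < strata[2]

    def test_unknown_class_or_missing_columns_raise(self, fitted):
        res, _, design = fitted
        with pytest.raises(ValueError, match="unknown class"):
            res.propensity("nuclear")
        with pytest.raises(ValueError, match="missing covariate"):
            res.propensity("TG_plus", pd.DataFrame({"TIS11B": [0.0]}))

    def test_top_covariates_ranked_by_t(self, fitted):
        res, _, _ = fitted
        top = res.top_covariates(k=3)
        assert len(top) == 3
        t = res.tvalues.drop(columns="intercept").abs().max(axis=0)
        assert set(top) <= set(t.index)
        assert t[top[0]] == t.drop(
            index=[c for c in ("mrna_length", "mean_cds_exon_length")
                   if c in t.index]).max()
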