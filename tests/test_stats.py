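"""Outlier rule, GEE estimation, Wald tests, LSD comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dgquant.stats as dgstats


class TestIqrRule:
    def test_tight_set_clean(self):
        assert not dgstats.iqr_outliers([1, 2, 3, 4, 5]).any()

    def test_hand_quartiles_flag_extreme(self):
        # Q1=2, Q3=4, upper fence 4 + 2.2*2 = 8.4
        flags = dgstats.iqr_outliers([1, 2, 3, 4, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_identical_values_never_flagged(self):
        assert not dgstats.iqr_outliers([5.0] * 6).any()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(values=st.lists(st.integers(-1000, 1000), min_size=4,
                           max_size=30),
           a=st.integers(1, 40), b=st.integers(-100, 100))
    def test_affine_invariance(self, values, a, b):
        # integer lattice keeps the transform exact in float arithmetic
        x = np.asarray(values, dtype=float)
        base = dgstats.iqr_outliers(x)
        mapped = dgstats.iqr_outliers((a / 4.0) * x + b / 2.0)
        assert (base == mapped).all()

    def test_screen_keeps_audit_trail(self):
        df = pd.DataFrame({
            "value": [1, 2, 3, 4, 100, 1, 2, 3, 4, 5],
            "cell": ["a"] * 5 + ["b"] * 5})
        clean, audit = dgstats.outlier_screen(df, "value", ["cell"])
        assert len(clean) == 9
        assert len(audit) == 1
        assert audit["value"].iloc[0] == 100


def _clustered_data(rng, n_clusters=200, beta=(1.0, 2.0), alpha=0.5,
                    sizes=(2, 3, 4)):
    rows = []
    for cid in range(n_clusters):
        n = int(rng.choice(sizes))
        shared = rng.normal(scale=np.sqrt(alpha))
        x = rng.normal(size=n)
        eps = rng.normal(scale=np.sqrt(1 - alpha), size=n)
        y = beta[0] + beta[1] * x + shared + eps
        for xi, yi in zip(x, y):
            rows.append({"y": yi, "x": xi, "cid": cid})
    return pd.DataFrame(rows)


class TestGee:
    def test_independence_equals_ols(self):
        rng = np.random.default_rng(0)
        df = _clustered_data(rng, n_clusters=40)
        fit = dgstats.gee_fit(df, "y ~ x", groups="cid",
                              cov_struct="independence")
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert np.abs(fit.params.to_numpy() - ols).max() < 1e-8

    def test_singleton_clusters_degenerate_to_ols(self):
        rng = np.random.default_rng(1)
        df = _clustered_data(rng, n_clusters=60, sizes=(1,))
        fit = dgstats.gee_fit(df, "y ~ x", groups="cid")
        assert fit.alpha == 0.0
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert np.abs(fit.params.to_numpy() - ols).max() < 1e-8

    def test_matches_reference_implementation(self):
        import statsmodels.api as sm
        from statsmodels.genmod.cov_struct import Exchangeable

        rng = np.random.default_rng(2)
        df = _clustered_data(rng, n_clusters=80)
        fit = dgstats.gee_fit(df, "y ~ x", groups="cid")
        ref = sm.GEE.from_formula("y ~ x", groups="cid", data=df,
                                  cov_struct=Exchangeable()).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params.to_numpy(),
                           atol=1e-6)
        assert fit.alpha == pytest.approx(float(ref.cov_struct.dep_params),
                                          abs=1e-6)
        assert np.allclose(np.sqrt(np.diag(fit.robust_cov)),
                           ref.bse.to_numpy(), atol=1e-6)

    def test_simulation_recovery(self):
        """Known beta and alpha recovered over replicated cohorts."""
        alphas, covered = [], 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            df = _clustered_data(rng, n_clusters=200)
            fit = dgstats.gee_fit(df, "y ~ x", groups="cid")
            alphas.append(fit.alpha)
            se = np.sqrt(fit.robust_cov.loc["x", "x"])
            covered += abs(fit.params["x"] - 2.0) < 3 * se
        assert abs(np.mean(alphas) - 0.5) < 0.05
        assert covered / n_rep > 0.95

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [1.0, 1, 2, 2],
                           "x2": [2.0, 2, 4, 4], "cid": [0, 0, 1, 1]})
        with pytest.raises(dgstats.AliasingError):
            dgstats.gee_fit(df, "y ~ x + x2", groups="cid")


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(3)
    df = _clustered_data(rng, n_clusters=50)
    return dgstats.gee_fit(df, "y ~ x", groups="cid")


class TestWald:
    def test_zero_coefficient_gives_unit_p(self, fit):
        mod = fit.params.copy()
        mod["x"] = 0.0
        zero_fit = dgstats.GeeFit(
            params=mod, robust_cov=fit.robust_cov,
            naive_cov=fit.naive_cov, alpha=fit.alpha, scale=fit.scale,
            cov_struct=fit.cov_struct, n_clusters=fit.n_clusters,
            n_obs=fit.n_obs, n_iter=fit.n_iter, converged=True,
            wald_table=fit.wald_table, design_info=fit.design_info)
        chi2, df_, p = dgstats.wald_test(zero_fit, [[0.0, 1.0]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_zero_row_contrast_rejected(self, fit):
        with pytest.raises(dgstats.ContrastError):
            dgstats.wald_test(fit, [[0.0, 0.0]])

    def test_reparameterization_invariance(self, fit):
        L1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        M = np.array([[2.0, 1.0], [1.0, 1.0]])  # invertible
        chi1, df1, _ = dgstats.wald_test(fit, L1)
        chi2, df2, _ = dgstats.wald_test(fit, M @ L1)
        assert df1 == df2
        assert chi1 == pytest.approx(chi2, rel=1e-9)


@pytest.fixture(scope="module")
def factorial_fit():
    rng = np.random.default_rng(4)
    rows = []
    means = {("E", "dorsal"): 2.0, ("E", "ventral"): 1.0,
             ("C", "dorsal"): 1.5, ("C", "ventral"): 1.5}
    for cid in range(40):
        t = "E" if cid % 2 else "C"
        for region in ("dorsal", "ventral"):
            rows.append({"value": means[(t, region)] + rng.normal(0, .3),
                         "treatment": t, "region": region, "cid": cid})
    df = pd.DataFrame(rows)
    gfit = dgstats.gee_fit(df, "value ~ treatment * region", groups="cid")
    cells = pd.DataFrame([(t, r) for t in ("E", "C")
                          for r in ("dorsal", "ventral")],
                         columns=["treatment", "region"])
    return gfit, cells


class TestLsdPosthoc:
    def test_four_cells_give_six_pairs(self, factorial_fit):
        fit, cells = factorial_fit
        table = dgstats.lsd_posthoc(fit, cells)
        assert len(table) == 6

    def test_identical_cells_give_unit_p(self, factorial_fit):
        fit, cells = factorial_fit
        doubled = pd.concat([cells.iloc[:1]] * 2, ignore_index=True)
        table = dgstats.lsd_posthoc(fit, doubled)
        assert table["p"].iloc[0] == pytest.approx(1.0)
        assert table["diff"].iloc[0] == pytest.approx(0.0)


class TestCovariateR2:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"region": ["v"] * 10,
                           "d": np.arange(10.0),
                           "y": 3.0 + 2.0 * np.arange(10.0)})
        assert dgstats.covariate_r2(df, "y", "d")["v"] == pytest.approx(1.0)

    def test_independent_covariate(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"region": ["v"] * 500,
                           "d": rng.normal(size=500),
                           "y": rng.normal(size=500)})
        assert dgstats.covariate_r2(df, "y", "d")["v"] < 0.05

    def test_small_groups_omitted(self):
        df = pd.DataFrame({"region": ["v", "v", "d"],
                           "d": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        assert dgstats.covariate_r2(df, "y", "d") == {}
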