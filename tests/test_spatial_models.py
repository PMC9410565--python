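import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from spatialtme import fit_all_pathways, lag_model_fit, morans_i, spca
from spatialtme.graph import NeighborGraph
from spatialtme.scoring import ScoreTable
from spatialtme.simulate import simulate_sar_field
from spatialtme.spatial_models import pvalue_matrix, row_weight_eigenvalues

from conftest import full_grid


def random_table(graph, n_features, seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(graph.n_nodes, n_features))
    return ScoreTable(
        pd.DataFrame(vals, index=graph.nodes, columns=[f"f{k}" for k in range(n_features)])
    )


def sar_response(graph, rho, X, beta, sigma, rng):
    n = graph.n_nodes
    W = graph.W_row.toarray()
    eps = rng.normal(0, sigma, n)
    return np.linalg.solve(np.eye(n) - rho * W, X @ beta + eps)


class TestSPCA:
    def test_eigenvalue_identity(self):
        """lambda_k = var(score_k) * I(score_k) with row weights, every k."""
        g = full_grid(15, 15)
        res = spca(random_table(g, 5, seed=0), g)
        ident = res.variance_part * res.moran_part
        assert np.allclose(res.eigenvalues, ident, atol=1e-8)

    def test_eigenvalues_sorted_descending(self):
        g = full_grid(10, 10)
        res = spca(random_table(g, 4, seed=1), g)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_loadings_unit_norm(self):
        g = full_grid(10, 10)
        res = spca(random_table(g, 4, seed=2), g)
        assert np.allclose(np.linalg.norm(res.loadings.to_numpy(), axis=0), 1.0)

    def test_zero_variance_feature_dropped(self, caplog):
        g = full_grid(8, 8)
        table = random_table(g, 3, seed=3)
        table.values["flat"] = 1.0
        with caplog.at_level("WARNING"):
            res = spca(ScoreTable(table.values), g)
        assert res.dropped_features == ["flat"]
        assert "flat" not in res.loadings.index

    def test_fewer_than_two_features_fatal(self):
        g = full_grid(8, 8)
        table = random_table(g, 1, seed=4)
        with pytest.raises(ValueError, match="fewer than 2"):
            spca(table, g)

    def test_misaligned_spots_fatal(self):
        g = full_grid(4, 4)
        table = random_table(g, 3, seed=5)
        table.values.index = [f"other{i}" for i in range(16)]
        with pytest.raises(ValueError, match="not aligned"):
            spca(ScoreTable(table.values), g)

    def test_planted_sar_feature_dominates_first_component(self):
        g = full_grid(15, 15)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(g.n_nodes, 5))
            vals[:, 2] = simulate_sar_field(g, 0.9, 1.0, seed=1000 + seed)
            table = ScoreTable(
                pd.DataFrame(vals, index=g.nodes, columns=list("abcde"))
            )
            res = spca(table, g)
            hits += res.loadings["sPC1"].abs().idxmax() == "c"
        assert hits >= 18

    def test_identity_weights_reduce_to_ordinary_pca(self):
        """With each node its own sole neighbor, sPCA eigenvalues are the
        ordinary PCA variances."""

        class SelfNeighborGraph(NeighborGraph):
            @property
            def W_row(self):
                from scipy.sparse import identity

                return identity(self.n_nodes, format="csr")

        base = full_grid(9, 9)
        g = SelfNeighborGraph(
            nodes=base.nodes, coords=base.coords, edges=base.edges
        )
        table = random_table(g, 4, seed=6)
        res = spca(table, g, scale=False)
        X = table.values.to_numpy() - table.values.to_numpy().mean(axis=0)
        pca_vars = np.sort(np.linalg.eigvalsh(X.T @ X / g.n_nodes))[::-1]
        assert np.allclose(res.eigenvalues, pca_vars, atol=1e-10)


class TestLagModel:
    def test_loglik_at_rho_zero_equals_ols(self):
        """Concentrated likelihood at rho = 0 is exactly the OLS value."""
        g = full_grid(10, 10)
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(100), rng.normal(size=(100, 2))])
        y = X @ np.array([1.0, 0.5, -0.5]) + rng.normal(size=100)
        fit = lag_model_fit(y, X, g)
        ols = sm.OLS(y, X).fit()
        assert fit.loglik_rho0 == pytest.approx(ols.llf, abs=1e-9)
        assert fit.loglik >= fit.loglik_rho0 - 1e-12

    def test_rho_zero_data_reduces_to_ols(self):
        g = full_grid(20, 20)
        rng = np.random.default_rng(1)
        for rep in range(5):
            X = np.column_stack([np.ones(400), rng.normal(size=(400, 2))])
            y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=400)
            fit = lag_model_fit(y, X, g)
            ols = sm.OLS(y, X).fit()
            assert abs(fit.rho) <= 0.1
            assert np.all(np.abs(fit.beta.to_numpy() - ols.params) <= 3 * ols.bse)

    def test_grid_search_oracle_agreement(self):
        """rho-hat agrees with a dense 1e-4 grid search of the concentrated
        likelihood on random instances."""
        g = full_grid(10, 10)
        n = g.n_nodes
        lam = row_weight_eigenvalues(g)
        W = g.W_row.toarray()
        rng = np.random.default_rng(7)
        for rep in range(10):
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            rho_true = rng.uniform(-0.3, 0.8)
            y = sar_response(g, rho_true, X, np.array([1.0, 1.0, -2.0]), 1.0, rng)
            fit = lag_model_fit(y, X, g)

            grid = np.arange(1 / lam.min() + 1e-4, 1.0 - 1e-4, 1e-4)
            Wy = W @ y
            best, best_ll = None, -np.inf
            for r in grid:
                ay = y - r * Wy
                beta = np.linalg.lstsq(X, ay, rcond=None)[0]
                resid = ay - X @ beta
                s2 = resid @ resid / n
                ll = -(n / 2) * (np.log(2 * np.pi * s2) + 1) + np.log1p(-r * lam).sum()
                if ll > best_ll:
                    best, best_ll = r, ll
            assert abs(fit.rho - best) < 1e-3

    def test_constant_response_fatal(self):
        g = full_grid(5, 5)
        X = np.column_stack([np.ones(25), np.arange(25.0)])
        with pytest.raises(ValueError, match="zero variance"):
            lag_model_fit(np.ones(25), X, g)

    def test_collinear_design_fatal_names_columns(self):
        g = full_grid(6, 6)
        rng = np.random.default_rng(2)
        a = rng.normal(size=36)
        X = np.column_stack([np.ones(36), a, 2 * a])
        y = rng.normal(size=36)
        with pytest.raises(ValueError, match="collinear"):
            lag_model_fit(y, X, g, feature_names=["intercept", "a", "twice_a"])

    def test_fragmented_graph_refused(self):
        from spatialtme.graph import grid_graph_from_coords

        # two far-apart 3x3 islands: largest component = 50% of nodes
        coords = [(x, y) for x in range(3) for y in range(3)]
        coords += [(x + 50, y) for x in range(3) for y in range(3)]
        g = grid_graph_from_coords(np.array(coords), [f"s{i}" for i in range(18)], "queen")
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(18), rng.normal(size=18)])
        with pytest.raises(ValueError, match="component"):
            lag_model_fit(rng.normal(size=18), X, g)

    def test_standard_errors_cover_truth_roughly(self):
        g = full_grid(20, 20)
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(400), rng.normal(size=(400, 2))])
        beta = np.array([1.0, 2.0, -1.0])
        y = sar_response(g, 0.5, X, beta, 1.0, rng)
        fit = lag_model_fit(y, X, g)
        assert np.all(np.isfinite(fit.se.to_numpy()))
        z_rho = (fit.rho - 0.5) / fit.se["rho"]
        assert abs(z_rho) < 4


class TestFitAllPathways:
    def test_bookkeeping_rows(self, small_sample):
        g = full_grid(8, 8)
        rng = np.random.default_rng(4)
        ct = ScoreTable(
            pd.DataFrame(
                rng.normal(size=(64, 4)), index=g.nodes, columns=list("wxyz")
            )
        )
        pw = ScoreTable(
            pd.DataFrame(
                rng.normal(size=(64, 3)), index=g.nodes, columns=["p1", "p2", "p3"]
            )
        )
        fits, long = fit_all_pathways(pw, ct, g)
        assert len(fits) == 3
        # rho + intercept + 4 cell types per pathway
        assert len(long) == 3 * (4 + 2)
        mat = pvalue_matrix(long)
        assert mat.shape == (3, 4)
        assert long["p_bh"].notna().sum() == 12

    def test_failed_fit_recorded_not_fatal(self):
        g = full_grid(8, 8)
        rng = np.random.default_rng(5)
        ct = ScoreTable(
            pd.DataFrame(rng.normal(size=(64, 2)), index=g.nodes, columns=["a", "b"])
        )
        pw = ScoreTable(
            pd.DataFrame(
                {"fine": rng.normal(size=64), "flat": np.zeros(64)}, index=g.nodes
            )
        )
        fits, long = fit_all_pathways(pw, ct, g)
        assert set(fits) == {"fine"}
        assert (long.loc[long["pathway"] == "flat", "term"] == "ERROR").any()

    def test_planted_tumor_effect_detected(self, small_sample):
        """A pathway built as 2 x tumor score + SAR noise yields a small
        tumor-coefficient p-value in most replicates."""
        from spatialtme import cell_type_scores

        s = small_sample
        ct = cell_type_scores(s.dataset, s.markers)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            noise = simulate_sar_field(s.graph, 0.4, 1.0, seed=500 + rep)
            tumor = ct.values["tumor"]
            y = 2.0 * (tumor - tumor.mean()) / tumor.std() + noise
            pw = ScoreTable(pd.DataFrame({"synthetic": y}, index=ct.barcodes))
            _, long = fit_all_pathways(pw, ct, s.graph)
            p = long.loc[long["term"] == "tumor", "p"].iloc[0]
            hits += p < 0.01
        assert hits >= 9
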