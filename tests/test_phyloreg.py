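"""Phylogenetic GLS, model selection, bisector lines, ANCOVA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import callometry as cm
from callometry.errors import (
    DegenerateInputError,
    InsufficientDataError,
    NumericalError,
    ParameterError,
    TreeError,
)
from callometry.phyloreg import (
    CANDIDATE_KINDS,
    Phylogeny,
    TraitTable,
    bisector_slope,
    fit_candidates,
    normalize_name,
)
from callometry.synth import simulate_clade, yule_tree

NEWICK6 = "(((a:1,b:1):1,(c:1,d:1):1):1,(e:2,f:2):1);"


class TestPhylogeny:
    def test_mrca_matrix_of_known_tree(self):
        tree = Phylogeny.from_newick(NEWICK6)
        order = tree.tip_names
        V = tree.mrca_depth
        i = {name: k for k, name in enumerate(order)}
        assert V[i["a"], i["a"]] == pytest.approx(3.0)
        assert V[i["a"], i["b"]] == pytest.approx(2.0)
        assert V[i["a"], i["c"]] == pytest.approx(1.0)
        assert V[i["a"], i["e"]] == pytest.approx(0.0)
        assert V[i["e"], i["f"]] == pytest.approx(1.0)
        assert tree.is_ultrametric()
        assert tree.height == pytest.approx(3.0)

    def test_name_normalization(self):
        assert normalize_name("  Panthera Leo ") == "panthera_leo"
        tree = Phylogeny.from_newick("('Genus sp':1,'Other sp':1);")
        assert set(tree.tip_names) == {"genus_sp", "other_sp"}

    def test_subset_reorders(self):
        tree = Phylogeny.from_newick(NEWICK6)
        sub = tree.subset(["f", "a", "c"])
        assert sub.tip_names == ["f", "a", "c"]
        assert sub.mrca_depth[0, 0] == pytest.approx(3.0)
        assert sub.mrca_depth[1, 2] == pytest.approx(1.0)  # a-c

    def test_subset_missing_species(self):
        tree = Phylogeny.from_newick(NEWICK6)
        with pytest.raises(TreeError, match="missing"):
            tree.subset(["a", "zebra"])

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError):
            Phylogeny.from_newick("((a:1,a:1):1,b:2);")

    def test_negative_branch_rejected(self):
        with pytest.raises(TreeError):
            Phylogeny.from_newick("((a:1,b:-0.5):1,c:2);")


class TestPhyloCovariance:
    def setup_method(self):
        self.tree = Phylogeny.from_newick(NEWICK6)

    def test_np_is_identity(self):
        V = cm.phylo_covariance(self.tree, cm.CorrelationModel("NP"))
        assert np.array_equal(V, np.eye(6))

    def test_bm_is_mrca_depth(self):
        V = cm.phylo_covariance(self.tree, cm.CorrelationModel("BM"))
        assert np.array_equal(V, self.tree.mrca_depth)

    def test_lambda_endpoints(self):
        V1 = cm.phylo_covariance(
            self.tree, cm.CorrelationModel("BM_lambda", 1.0))
        V0 = cm.phylo_covariance(
            self.tree, cm.CorrelationModel("BM_lambda", 0.0))
        assert np.allclose(V1, self.tree.mrca_depth)
        assert np.allclose(V0, np.diag(self.tree.tip_depths))

    def test_rho_one_recovers_bm(self):
        V = cm.phylo_covariance(self.tree, cm.CorrelationModel("BM_rho", 1.0))
        assert np.allclose(V, self.tree.mrca_depth)

    def test_rho_bends_monotonically(self):
        v_lo = cm.phylo_covariance(
            self.tree, cm.CorrelationModel("BM_rho", 0.2))
        v_hi = cm.phylo_covariance(
            self.tree, cm.CorrelationModel("BM_rho", 3.0))
        off = ~np.eye(6, dtype=bool)
        mask = self.tree.mrca_depth > 0
        assert np.all(v_lo[off & mask] >= v_hi[off & mask])

    def test_ou_unit_diagonal_and_decay(self):
        V = cm.phylo_covariance(self.tree, cm.CorrelationModel("OU", 0.7))
        assert np.allclose(np.diag(V), 1.0)
        # correlation decays with patristic distance
        i = {n: k for k, n in enumerate(self.tree.tip_names)}
        assert V[i["a"], i["b"]] > V[i["a"], i["c"]] > V[i["a"], i["e"]]
        assert V[i["a"], i["b"]] == pytest.approx(math.exp(-0.7 * 2.0))

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            cm.phylo_covariance(
                self.tree, cm.CorrelationModel("BM_lambda", 1.5))
        with pytest.raises(ParameterError):
            cm.phylo_covariance(self.tree, cm.CorrelationModel("BM_rho", 0.0))
        with pytest.raises(ParameterError):
            cm.phylo_covariance(self.tree, cm.CorrelationModel("OU", -1.0))


def brute_force_gls(X, y, V):
    """Textbook normal equations, dense inverses."""
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    n, p = X.shape
    r = y - X @ beta
    sigma2 = float(r @ Vi @ r) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ Vi @ X)
    return beta, np.sqrt(np.diag(cov))


class TestGlsFit:
    def test_matches_brute_force_normal_equations(self, balanced_tree_tables):
        tree, table = balanced_tree_tables
        for kind, theta in [("BM", None), ("BM_lambda", 0.6),
                            ("OU", 0.4), ("BM_rho", 2.0)]:
            model = cm.CorrelationModel(kind, theta)
            fit = cm.gls_fit(table, tree, model)
            V = cm.phylo_covariance(tree.subset(table.species), model)
            X = np.column_stack([np.ones(table.n), table.x])
            beta, ses = brute_force_gls(X, table.y, V)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope_se == pytest.approx(ses[1], abs=1e-10)
            assert fit.intercept_se == pytest.approx(ses[0], abs=1e-10)

    def test_np_equals_ols(self, balanced_tree_tables):
        _, table = balanced_tree_tables
        gls = cm.gls_fit(table, None, cm.CorrelationModel("NP"))
        slope, intercept = np.polyfit(table.x, table.y, 1)
        assert gls.slope == pytest.approx(slope, abs=1e-10)
        assert gls.intercept == pytest.approx(intercept, abs=1e-10)

    def test_lambda_one_equals_bm(self, balanced_tree_tables):
        tree, table = balanced_tree_tables
        bm = cm.gls_fit(table, tree, cm.CorrelationModel("BM"))
        lam1 = cm.gls_fit(table, tree, cm.CorrelationModel("BM_lambda", 1.0))
        assert lam1.slope == pytest.approx(bm.slope, abs=1e-12)
        assert lam1.loglik == pytest.approx(bm.loglik, abs=1e-10)

    def test_lambda_zero_equals_np_slope(self, balanced_tree_tables):
        # the tree is ultrametric, so lambda = 0 gives a scaled identity
        tree, table = balanced_tree_tables
        np_fit = cm.gls_fit(table, None, cm.CorrelationModel("NP"))
        lam0 = cm.gls_fit(table, tree, cm.CorrelationModel("BM_lambda", 0.0))
        assert lam0.slope == pytest.approx(np_fit.slope, abs=1e-10)

    def test_x_on_y_reexpression(self, balanced_tree_tables):
        _, table = balanced_tree_tables
        fit = cm.gls_fit(table, None, cm.CorrelationModel("NP"),
                         direction="x_on_y_expressed")
        b_raw, a_raw = np.polyfit(table.y, table.x, 1)
        assert fit.slope == pytest.approx(1.0 / b_raw, abs=1e-10)
        assert fit.intercept == pytest.approx(-a_raw / b_raw, abs=1e-10)
        assert fit.direction == "x_on_y_expressed"

    def test_reml_invariant_to_response_shift(self, balanced_tree_tables):
        # REML likelihoods are comparable across fixed-effect shifts
        tree, table = balanced_tree_tables
        shifted = TraitTable(table.species, table.x, table.y + 10.0)
        f1 = cm.gls_fit(table, tree, cm.CorrelationModel("BM"))
        f2 = cm.gls_fit(shifted, tree, cm.CorrelationModel("BM"))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-10)

    def test_estimates_lambda_near_truth(self):
        tree, newick = yule_tree(80, seed=5, return_newick=True)
        table = simulate_clade(cm.CladeSimSpec(
            n_tips=80, slope=-1.2, intercept=5.0, sigma=0.3,
            lambda_true=0.85, seed=5))[1]
        fit = cm.gls_fit(table, tree, cm.CorrelationModel("BM_lambda"))
        assert fit.model.estimated
        assert 0.6 <= fit.model.theta <= 1.0

    def test_too_few_species(self):
        table = TraitTable(["a", "b", "c"], np.arange(3.0), np.arange(3.0))
        with pytest.raises(InsufficientDataError):
            cm.gls_fit(table, None, cm.CorrelationModel("NP"))

    def test_bm_without_tree_rejected(self, balanced_tree_tables):
        _, table = balanced_tree_tables
        with pytest.raises(TreeError):
            cm.gls_fit(table, None, cm.CorrelationModel("BM"))


class TestOlsFit:
    def test_r2_is_squared_correlation(self, balanced_tree_tables):
        _, table = balanced_tree_tables
        fit = cm.ols_fit(table)
        assert fit.r2 == pytest.approx(
            np.corrcoef(table.x, table.y)[0, 1] ** 2)
        assert fit.k == 3

    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        table = TraitTable(list("abcd"), x, 2.0 - 0.5 * x)
        fit = cm.ols_fit(table)
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_variance_predictor(self):
        table = TraitTable(list("abcd"), np.ones(4), np.arange(4.0))
        with pytest.raises(DegenerateInputError):
            cm.ols_fit(table)


class TestModelSelection:
    def test_aicc_formula(self, balanced_tree_tables):
        tree, table = balanced_tree_tables
        fit = cm.gls_fit(table, tree, cm.CorrelationModel("BM"))
        n, k = table.n, fit.k
        expected = -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert cm.aicc(fit, n) == pytest.approx(expected)

    def test_aicc_undefined_for_tiny_n(self, balanced_tree_tables):
        tree, table = balanced_tree_tables
        fit = cm.gls_fit(table, tree, cm.CorrelationModel("BM_lambda", 0.5))
        with pytest.raises(InsufficientDataError):
            cm.aicc(fit, fit.k + 1)

    def test_selects_generating_family_on_lambda_sims(self):
        tree, _ = yule_tree(60, seed=2, return_newick=True)
        table = simulate_clade(cm.CladeSimSpec(
            n_tips=60, slope=-1.2, intercept=5.0, sigma=0.3,
            lambda_true=0.9, seed=2))[1]
        fits = fit_candidates(table, tree)
        comp = cm.select_model(fits, table.n)
        assert set(comp.aicc) == set(CANDIDATE_KINDS)
        # strong intermediate signal: NP should never win
        assert comp.best_kind != "NP"

    def test_empty_fits_rejected(self):
        with pytest.raises(InsufficientDataError):
            cm.select_model({}, 10)


class TestBisector:
    def test_reference_slopes(self):
        assert bisector_slope(-0.679, -2.267) == pytest.approx(
            -1.1997, abs=5e-4)
        assert bisector_slope(-1.004, -2.265) == pytest.approx(
            -1.4632, abs=5e-4)

    def test_identical_slopes_fixed_point(self):
        assert bisector_slope(-1.3, -1.3) == pytest.approx(-1.3, abs=1e-12)

    @given(b1=st.floats(-5.0, -0.1), b2=st.floats(-5.0, -0.1))
    @settings(max_examples=100, deadline=None)
    def test_angle_bisection_property(self, b1, b2):
        b3 = bisector_slope(b1, b2)
        tol = 1e-9 * (1 + abs(b3))
        assert min(b1, b2) - tol <= b3 <= max(b1, b2) + tol
        # the bisector halves the angle between the two lines
        assert math.atan(b3) == pytest.approx(
            (math.atan(b1) + math.atan(b2)) / 2, abs=1e-9)

    def test_opposite_signs_rejected(self):
        with pytest.raises(NumericalError):
            bisector_slope(1.0, -1.0)

    def test_line_through_centroid(self, balanced_tree_tables):
        _, table = balanced_tree_tables
        yx = cm.ols_fit(table, "y_on_x")
        xy = cm.ols_fit(table, "x_on_y_expressed")
        line = cm.bisector(yx, xy)
        xbar, ybar = np.mean(table.x), np.mean(table.y)
        assert line.slope * xbar + line.intercept == pytest.approx(
            ybar, abs=1e-10)


class TestAncova:
    def test_parallel_groups_small_f(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 20)
        g = ["A"] * 10 + ["B"] * 10
        y = 1.0 - 2.0 * x + np.where(np.array(g) == "B", 0.5, 0.0)
        y = y + 0.01 * rng.standard_normal(20)
        table = TraitTable([f"s{i}" for i in range(20)], x, y, group=g)
        F, (df1, df2), p = cm.ancova_slopes(table)
        assert (df1, df2) == (1, 16)
        assert p > 0.05

    def test_diverging_slopes_detected(self):
        x = np.concatenate([np.linspace(0, 1, 10)] * 2)
        g = ["A"] * 10 + ["B"] * 10
        y = np.concatenate([2.0 * x[:10], -2.0 * x[:10]])
        y = y + 0.01 * np.random.default_rng(1).standard_normal(20)
        table = TraitTable([f"s{i}" for i in range(20)], x, y, group=g)
        F, (df1, df2), p = cm.ancova_slopes(table)
        assert p < 1e-6
        assert F > 100

    def test_f_matches_manual_computation(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 16)
        g = ["A", "B"] * 8
        y = 1.0 - x + rng.standard_normal(16) * 0.3
        table = TraitTable([f"s{i}" for i in range(16)], x, y, group=g)
        F, dfs, p = cm.ancova_slopes(table)
        gi = np.array([1.0 if v == "B" else 0.0 for v in g])
        Xf = np.column_stack([np.ones(16), x, gi, x * gi])
        rf = y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]
        Xr = Xf[:, :3]
        rr = y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]
        expected = (rr @ rr - rf @ rf) / (rf @ rf / 12)
        assert F == pytest.approx(expected, abs=1e-10)

    def test_group_requirements(self):
        table = TraitTable(list("abcd"), np.arange(4.0), np.arange(4.0))
        with pytest.raises(DegenerateInputError):
            cm.ancova_slopes(table)
        table3 = TraitTable(
            [f"s{i}" for i in range(9)], np.arange(9.0), np.arange(9.0),
            group=["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        with pytest.raises(DegenerateInputError):
            cm.ancova_slopes(table3)


class TestShapiro:
    def test_normal_sample_passes(self):
        vals = np.random.default_rng(0).standard_normal(50)
        w, p = cm.shapiro_wilk(vals)
        assert 0.9 < w <= 1.0
        assert p > 0.05

    def test_heavy_skew_fails(self):
        vals = np.random.default_rng(0).lognormal(0, 1.5, 80)
        _, p = cm.shapiro_wilk(vals)
        assert p < 1e-4

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            cm.shapiro_wilk([1.0, 1.0, 1.0, 1.0])
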