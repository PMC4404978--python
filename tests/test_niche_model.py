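"""Distribution-model stack: NIPALS, subset selection, AUC, thresholds,
assessment gates, and the ensemble fallback."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cwrgap.geodata import GridSpec, Raster, VariableStack
from cwrgap.niche_model import (
    ModelError,
    assess,
    auc,
    build_distribution,
    compare_methods,
    draw_background,
    fit_presence_background,
    nipals_pca,
    roc_threshold,
    select_subset,
    variance_inflation_factors,
)


class TestNipals:
    def test_matches_eigendecomposition_on_complete_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 5)) @ rng.normal(size=(5, 5))
        res = nipals_pca(X, n_components=3)
        # independent oracle: eigenvectors of the correlation matrix
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        eigval, eigvec = np.linalg.eigh(np.corrcoef(Z, rowvar=False))
        order = np.argsort(eigval)[::-1]
        expected = np.abs(eigvec[:, order[:3]])
        np.testing.assert_allclose(np.abs(res.loadings), expected, atol=1e-6)

    def test_two_identical_columns_load_symmetrically(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=80)
        X = np.column_stack([t, t])
        res = nipals_pca(X, n_components=1)
        np.testing.assert_allclose(np.abs(res.loadings[:, 0]),
                                   [1 / np.sqrt(2)] * 2, atol=1e-8)

    def test_missing_data_scores_track_complete_scores(self):
        rng = np.random.default_rng(5)
        t1, t2 = rng.normal(size=(2, 120))
        p1, p2 = rng.normal(size=(2, 6))
        X = np.outer(t1, p1) + np.outer(t2, p2) + 0.05 * rng.normal(size=(120, 6))
        complete = nipals_pca(X, n_components=2)
        Xm = X.copy()
        mask = rng.uniform(size=X.shape) < 0.10
        Xm[mask] = np.nan
        masked = nipals_pca(Xm, n_components=2)
        assert all(masked.converged)
        r = abs(np.corrcoef(complete.scores[:, 0], masked.scores[:, 0])[0, 1])
        assert r > 0.99

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.random.default_rng(0).normal(size=30),
                             np.full(30, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            res = nipals_pca(X, n_components=1)
        assert res.loadings.shape[0] == 1


class TestSelectSubset:
    def test_strong_loaders_kept_with_low_vif(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=400)
        strong = [t * 0.9 + rng.normal(size=400) * np.sqrt(1 - 0.81)
                  for _ in range(4)]
        noise = [rng.normal(size=400) for _ in range(3)]
        X = np.column_stack(strong + noise)
        names = [f"s{i}" for i in range(4)] + [f"n{i}" for i in range(3)]
        method = select_subset(X, names)
        assert set(method.variables) == {"s0", "s1", "s2", "s3"}
        Z = (X[:, :4] - X[:, :4].mean(0)) / X[:, :4].std(0, ddof=1)
        assert variance_inflation_factors(Z).max() < 10

    def test_near_duplicate_candidate_pruned_by_vif(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=500)
        a = t + 0.01 * rng.normal(size=500)  # r ~ 0.9999 with t
        b = rng.normal(size=500)
        X = np.column_stack([t, a, b])
        method = select_subset(X, ["t", "a", "b"], min_candidates=2)
        # t and a both clear the loading rule but VIF > 10 drops one of them
        assert not {"t", "a"} <= set(method.variables)

    def test_vif_formula_hand_check(self):
        # two columns correlated at r: VIF = 1/(1 - r^2)
        rng = np.random.default_rng(8)
        t = rng.normal(size=2000)
        u = 0.999 * t + np.sqrt(1 - 0.999**2) * rng.normal(size=2000)
        vifs = variance_inflation_factors(np.column_stack([t, u]))
        r2 = np.corrcoef(t, u)[0, 1] ** 2
        np.testing.assert_allclose(vifs, 1 / (1 - r2), rtol=1e-6)
        assert vifs.max() > 10

    def test_weak_loadings_fall_back_to_top_three(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 6))  # independent noise: all loadings small
        method = select_subset(X, [f"v{i}" for i in range(6)])
        assert len(method.variables) == 3

    def test_too_few_rows_direct_to_ensemble(self):
        with pytest.raises(ModelError, match="ensemble"):
            select_subset(np.zeros((2, 4)), list("abcd"))


class TestRocThreshold:
    def test_perfect_separation_returns_lowest_presence_score(self):
        thr = roc_threshold([0.9] * 5, [0.1] * 7)
        assert thr == 0.9

    def test_matches_brute_force_on_random_scores(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pres = rng.uniform(size=15)
            bg = rng.uniform(size=40)
            cand = np.unique(np.concatenate([pres, bg]))
            best, best_thr = np.inf, None
            for c in cand:  # brute-force oracle, high-threshold tie-break
                sens = (pres >= c).mean()
                spec = (bg < c).mean()
                d = np.hypot(1 - sens, 1 - spec)
                if d < best - 1e-12 or (abs(d - best) <= 1e-12 and c > best_thr):
                    best, best_thr = d, c
            assert roc_threshold(pres, bg) == pytest.approx(best_thr)

    def test_single_presence_above_background(self):
        thr = roc_threshold([0.95], np.linspace(0, 0.9, 10))
        assert ((np.array([0.95]) >= thr).mean() == 1.0
                and (np.linspace(0, 0.9, 10) < thr).mean() == 1.0)

    def test_identical_scores_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            assert roc_threshold([0.4, 0.4], [0.4]) == 0.4


class TestAuc:
    def test_pair_counting_examples(self):
        # exhaustive pair counting: wins / (n_pos * n_neg)
        assert auc([0.9, 0.8], [0.7, 0.1]) == 1.0
        assert auc([0.8, 0.1], [0.9, 0.2]) == 0.25  # one winning pair of four
        assert auc([0.8, 0.2], [0.9, 0.1]) == 0.5  # two of four

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 30), st.integers(2, 30), st.integers(0, 10_000))
    def test_equals_normalized_mann_whitney(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.5, 1, n_pos).round(1)  # rounding forces ties
        neg = rng.normal(0, 1, n_neg).round(1)
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auc(pos, neg) == pytest.approx(u / (n_pos * n_neg))


class TestCompareMethods:
    def test_identical_groups_give_zero(self):
        assert compare_methods({"a": [1, 1, 1], "b": [1, 1, 1]}) == (0.0, 1.0)

    def test_hand_ranked_example(self):
        h, p = compare_methods(
            {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        )
        assert h == pytest.approx(7.2, abs=1e-9)
        assert p == pytest.approx(float(stats.chi2.sf(7.2, 2)))

    def test_permutation_null_matches_chi_square(self):
        rng = np.random.default_rng(12)
        pooled = rng.normal(size=18)
        hs = []
        for _ in range(400):
            perm = rng.permutation(pooled)
            h, _ = compare_methods(
                {"a": perm[:6], "b": perm[6:12], "c": perm[12:]}
            )
            hs.append(h)
        # chi-square(df=2) has mean 2 and P(H > 5.99) = 0.05
        assert np.mean(hs) == pytest.approx(2.0, abs=0.4)
        assert np.mean(np.array(hs) > 5.99) == pytest.approx(0.05, abs=0.04)


def _noise_stack(seed, n_rows=30, n_cols=40, n_vars=5):
    rng = np.random.default_rng(seed)
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, x_min=-70, y_max=0,
                    resolution=0.5)
    names, layers, roles = [], {}, {}
    for i in range(n_vars):
        names.append(f"v{i}")
        layers[f"v{i}"] = Raster(spec, rng.normal(size=(n_rows, n_cols)),
                                 nodata=-9999.0)
        roles[f"v{i}"] = "bioclim"
    return VariableStack(names, layers, roles)


class TestFitAndAssess:
    def test_suitability_monotone_in_informative_variable(self):
        rng = np.random.default_rng(13)
        spec = GridSpec(n_rows=30, n_cols=40, x_min=-70, y_max=0, resolution=0.5)
        grad = np.linspace(0, 1, 40)[None, :] * np.ones((30, 1))
        grad = grad + 0.01 * rng.normal(size=grad.shape)
        stack = VariableStack(
            ["info", "junk"],
            {"info": Raster(spec, grad, nodata=-9999.0),
             "junk": Raster(spec, rng.normal(size=(30, 40)), nodata=-9999.0)},
            {"info": "bioclim", "junk": "bioclim"},
        )
        # presences in the top quintile of the informative variable
        rows, cols = np.where(grad > np.quantile(grad, 0.8))
        take = rng.choice(rows.size, 100, replace=False)
        pts = np.array([spec.cell_center(int(r), int(c))
                        for r, c in zip(rows[take], cols[take])])
        bg = draw_background(np.ones((30, 40), bool), spec, 800, seed=1)
        from cwrgap.niche_model import VariableMethod

        model = fit_presence_background(
            pts, stack, VariableMethod("full27", ("info", "junk")), bg, seed=1
        )
        rho, _ = stats.spearmanr(grad.ravel(), model.mean.values.ravel())
        assert rho > 0.9

    def test_perfect_and_degenerate_assessment_cases(self):
        # replicates identical => ASD15 = 0; separable scores => ATAUC 1
        assert auc([0.9, 0.8, 0.7], [0.3, 0.2, 0.1]) == 1.0

    def test_pure_noise_fails_gates(self):
        fails, ataucs = 0, []
        n_runs = 10
        for seed in range(n_runs):
            stack = _noise_stack(seed)
            rng = np.random.default_rng(100 + seed)
            rows = rng.integers(0, 30, 60)
            cols = rng.integers(0, 40, 60)
            pts = np.unique(
                np.array([stack.spec.cell_center(int(r), int(c))
                          for r, c in zip(rows, cols)]), axis=0)
            bg = draw_background(np.ones((30, 40), bool), stack.spec, 600,
                                 seed=seed)
            from cwrgap.niche_model import VariableMethod

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_presence_background(
                    pts, stack, VariableMethod("full27", tuple(stack.names)),
                    bg, seed=seed)
                model = assess(model, bg)
            ataucs.append(model.assessment["ATAUC"])
            fails += not model.passes_gates
        assert fails >= 0.9 * n_runs
        assert np.mean(ataucs) == pytest.approx(0.5, abs=0.1)

    def test_too_few_points_rejected(self):
        stack = _noise_stack(0)
        bg = draw_background(np.ones((30, 40), bool), stack.spec, 100, seed=0)
        from cwrgap.niche_model import VariableMethod

        with pytest.raises(ModelError, match="minimum"):
            fit_presence_background(
                np.array([[-69, -1.0], [-68, -2.0]]), stack,
                VariableMethod("full27", tuple(stack.names)), bg)


class TestBuildDistribution:
    def test_rich_species_uses_subset_method(self, recovery_distribution):
        assert recovery_distribution.provenance == "subset"

    def test_support_confined_to_native_land(
        self, recovery_distribution, world, recovery_species
    ):
        from cwrgap.synthetic import native_mask

        nat = native_mask(world, recovery_species)
        assert not (recovery_distribution.support & ~nat).any()

    def test_sparse_species_gets_ensemble(self, recovery_points, world,
                                          background, recovery_species):
        from cwrgap.synthetic import native_mask

        nat = native_mask(world, recovery_species)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = build_distribution(
                "sparse", recovery_points[:8], world.stack, nat, background,
                seed=2)
        assert dist.provenance == "ensemble"
        # intersection semantics: support contained in every component model
        assert set(dist.components) == {"bioclim19", "full27", "subset"}
        for sup in dist.components.values():
            assert not (dist.support & ~sup).any()

    def test_unmodelable_species_rejected(self, world, background,
                                          recovery_points, recovery_species):
        from cwrgap.synthetic import native_mask

        nat = native_mask(world, recovery_species)
        with pytest.raises(ModelError, match="unmodelable"):
            build_distribution("tiny", recovery_points[:3], world.stack, nat,
                               background)

    def test_subset_selector_recovers_informative_niche_variables(
        self, recovery_points, world, recovery_species
    ):
        X = np.empty((recovery_points.shape[0], len(world.stack.names)))
        for j, name in enumerate(world.stack.names):
            X[:, j] = world.stack.layers[name].sample(
                recovery_points[:, 0], recovery_points[:, 1])
        method = select_subset(X, list(world.stack.names))
        true_vars = set(recovery_species.niche_center)
        recovered = true_vars & set(method.variables)
        assert len(recovered) >= len(true_vars) / 2

    def test_range_recovery_jaccard(self, recovery_distribution,
                                    recovery_sample, world, recovery_species):
        from cwrgap.synthetic import native_mask

        nat = native_mask(world, recovery_species)
        truth = (recovery_sample.truth.values >= 0.5) & nat
        model = recovery_distribution.support
        jac = (truth & model).sum() / (truth | model).sum()
        assert jac >= 0.5
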