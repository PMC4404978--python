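"""Overlap indices, PCA with Bartlett's test, clustering, niche summaries."""

import numpy as np
import pandas as pd
import pytest

from cwrgap.geodata import GridSpec, Raster, VariableStack
from cwrgap.niche_compare import (
    CompareError,
    crop_baseline,
    geographic_overlap,
    hcpc_clusters,
    niche_summary,
    pca_with_bartlett,
    schoener_d,
    warren_i,
)


def _binary(spec, cells):
    v = np.zeros(spec.shape, np.uint8)
    for r, c in cells:
        v[r, c] = 1
    return Raster(spec, v, nodata=255)


def _surface(values, nodata=-9999.0):
    values = np.atleast_2d(np.asarray(values, float))
    spec = GridSpec(n_rows=values.shape[0], n_cols=values.shape[1],
                    x_min=0, y_max=values.shape[0] * 0.5, resolution=0.5)
    return Raster(spec, values, nodata=nodata)


class TestGeographicOverlap:
    def test_identical_ranges(self):
        spec = GridSpec(n_rows=4, n_cols=4, x_min=0, y_max=2, resolution=0.5)
        a = _binary(spec, [(0, 0), (1, 1), (2, 2)])
        assert geographic_overlap(a, a) == 1.0

    def test_disjoint_ranges(self):
        spec = GridSpec(n_rows=4, n_cols=4, x_min=0, y_max=2, resolution=0.5)
        a = _binary(spec, [(0, 0)])
        b = _binary(spec, [(3, 3)])
        assert geographic_overlap(a, b) == 0.0

    def test_enumeration_oracle(self):
        # |A| = 3, |B| = 4, shared 2 -> 2 / 5
        spec = GridSpec(n_rows=4, n_cols=4, x_min=0, y_max=2, resolution=0.5)
        a = _binary(spec, [(0, 0), (1, 1), (2, 2)])
        b = _binary(spec, [(1, 1), (2, 2), (3, 3), (0, 3)])
        assert geographic_overlap(a, b) == pytest.approx(0.4)

    def test_shift_beyond_extent_gives_zero(self):
        spec = GridSpec(n_rows=4, n_cols=8, x_min=0, y_max=2, resolution=0.5)
        a = _binary(spec, [(1, 0), (1, 1)])
        b = _binary(spec, [(1, 6), (1, 7)])
        assert geographic_overlap(a, b) == 0.0

    def test_both_empty_errors(self):
        spec = GridSpec(n_rows=2, n_cols=2, x_min=0, y_max=1, resolution=0.5)
        with pytest.raises(CompareError):
            geographic_overlap(_binary(spec, []), _binary(spec, []))


class TestNicheIndices:
    def test_equal_surfaces_score_one(self):
        p = _surface([[0.2, 0.3, 0.5]])
        assert schoener_d(p, p) == pytest.approx(1.0)
        assert warren_i(p, p) == pytest.approx(1.0)

    def test_disjoint_supports_score_zero(self):
        a = _surface([[1.0, 0.0]])
        b = _surface([[0.0, 1.0]])
        assert schoener_d(a, b) == pytest.approx(0.0)
        assert warren_i(a, b) == pytest.approx(0.0)

    def test_two_cell_hand_computation(self):
        # pA = (1, 0), pB = (0.5, 0.5):
        # D = 1 - (|0.5| + |0.5|)/2 = 0.5
        # I = 1 - ((1 - sqrt(.5))^2 + (sqrt(.5))^2)/2 = sqrt(.5) ~ 0.7071
        a = _surface([[1.0, 0.0]])
        b = _surface([[0.5, 0.5]])
        assert schoener_d(a, b) == pytest.approx(0.5)
        assert warren_i(a, b) == pytest.approx(0.70710678, abs=1e-6)

    def test_d_never_exceeds_i_on_random_surfaces(self):
        rng = np.random.default_rng(40)
        for _ in range(1000):
            a = _surface(rng.uniform(size=(4, 5)))
            b = _surface(rng.uniform(size=(4, 5)))
            d = schoener_d(a, b)
            i = warren_i(a, b)
            assert 0 <= d <= i <= 1 + 1e-12

    def test_d_decreases_as_niches_separate(self):
        # two Gaussian responses to one gradient, growing center offsets
        x = np.linspace(0, 10, 200)[None, :]
        prev = None
        for offset in (0.0, 1.0, 2.0, 4.0, 6.0):
            a = _surface(np.exp(-0.5 * (x - 3.0) ** 2))
            b = _surface(np.exp(-0.5 * (x - 3.0 - offset) ** 2))
            d = schoener_d(a, b)
            if prev is not None:
                assert d < prev + 1e-12
            prev = d

    def test_all_zero_surface_errors(self):
        with pytest.raises(CompareError):
            schoener_d(_surface([[0.0, 0.0]]), _surface([[1.0, 0.0]]))


class TestPcaBartlett:
    def test_independent_noise_fails_to_reject_sphericity(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(2000, 5))
        rep = pca_with_bartlett(X)
        assert rep.bartlett_p > 0.05
        assert rep.bartlett_df == 10

    def test_correlated_data_rejects_sphericity(self):
        rng = np.random.default_rng(42)
        t = rng.normal(size=(300, 1))
        X = np.hstack([t + 0.3 * rng.normal(size=(300, 3)),
                       rng.normal(size=(300, 2))])
        rep = pca_with_bartlett(X)
        assert rep.bartlett_p < 1e-6

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(43)
        X = rng.normal(size=(100, 6)) @ rng.normal(size=(6, 6))
        rep = pca_with_bartlett(X)
        assert rep.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_duplicated_variable_pair_loads_equally(self):
        rng = np.random.default_rng(44)
        t = rng.normal(size=200)
        X = np.column_stack([t, t + 1e-6 * rng.normal(size=200),
                             rng.normal(size=200)])
        rep = pca_with_bartlett(X, names=["a", "a_copy", "b"])
        lead = rep.variable_correlations[:, 0]
        assert abs(lead[0]) == pytest.approx(abs(lead[1]), abs=1e-3)

    def test_exactly_singular_correlation_warns(self):
        rng = np.random.default_rng(47)
        t = rng.normal(size=200)
        X = np.column_stack([t, t, rng.normal(size=200)])
        with pytest.warns(UserWarning, match="singular"):
            rep = pca_with_bartlett(X)
        assert np.isfinite(rep.bartlett_chi2)

    def test_requires_more_rows_than_columns(self):
        with pytest.raises(CompareError, match="n > p"):
            pca_with_bartlett(np.zeros((4, 6)))


class TestHcpc:
    def _blobs(self, sep=6.0, n=60, seed=45):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 2))
        b = rng.normal(sep, 1, size=(n, 2))
        scores = np.vstack([a, b])
        # describing variable tracks the blob; a constant rides along
        variables = np.column_stack([
            np.concatenate([np.full(n, 10.0), np.full(n, 20.0)])
            + rng.normal(0, 0.5, 2 * n),
            np.full(2 * n, 7.0),
        ])
        species = np.array(["north"] * n + ["south"] * n)
        return scores, variables, species

    def test_well_separated_blobs_recovered(self):
        scores, variables, species = self._blobs()
        res = hcpc_clusters(scores, variables, ["driver", "flat"], species)
        assert res.n_clusters == 2
        # every point of each species lands in a single cluster
        for taxon in ("north", "south"):
            primary, secondary = res.species_labels[taxon]
            assert secondary is None
            assert res.species_proportions.loc[taxon].max() == 1.0

    def test_constant_variable_never_describes_a_cluster(self):
        scores, variables, species = self._blobs()
        res = hcpc_clusters(scores, variables, ["driver", "flat"], species,
                            n_clusters=2)
        for desc in res.describing_variables.values():
            assert all(name != "flat" for name, _ in desc)

    def test_driver_variable_describes_with_direction(self):
        scores, variables, species = self._blobs()
        res = hcpc_clusters(scores, variables, ["driver", "flat"], species,
                            n_clusters=2)
        directions = {
            d for desc in res.describing_variables.values()
            for name, d in desc if name == "driver"
        }
        assert directions == {"+", "-"}

    def test_membership_proportions_sum_to_one(self):
        rng = np.random.default_rng(46)
        scores = rng.normal(size=(80, 3))
        variables = rng.normal(size=(80, 4))
        species = rng.choice(["a", "b", "c"], size=80)
        res = hcpc_clusters(scores, variables, list("wxyz"), species,
                            n_clusters=3)
        sums = res.species_proportions.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_split_species_gets_secondary_label(self):
        scores, variables, species = self._blobs()
        species = np.array(
            ["mixed"] * 30 + ["north"] * 30 + ["mixed"] * 30 + ["south"] * 30
        )
        res = hcpc_clusters(scores, variables, ["driver", "flat"], species,
                            n_clusters=2)
        primary, secondary = res.species_labels["mixed"]
        assert secondary is not None and secondary != primary

    def test_too_few_rows_rejected(self):
        with pytest.raises(CompareError):
            hcpc_clusters(np.zeros((3, 2)), np.zeros((3, 2)), ["a", "b"],
                          np.array(["x", "x", "y"]), n_clusters=5)


class TestNicheSummaries:
    def _stack(self):
        spec = GridSpec(n_rows=2, n_cols=2, x_min=0, y_max=1, resolution=0.5)
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        return VariableStack(
            ["v"], {"v": Raster(spec, vals, nodata=-9999.0)}, {"v": "bioclim"}
        ), spec

    def test_single_point_summary_is_degenerate(self):
        stack, spec = self._stack()
        pts = np.array([spec.cell_center(1, 0)])
        summary = niche_summary(pts, stack, "solo")
        row = summary.table.loc["v"]
        assert set(row.round(12)) == {3.0}

    def test_quartile_ordering_invariant(self, world, recovery_points):
        summary = niche_summary(recovery_points, world.stack, "recovery")
        t = summary.table
        assert (t["min"] <= t["q25"]).all()
        assert (t["q25"] <= t["median"]).all()
        assert (t["median"] <= t["q75"]).all()
        assert (t["q75"] <= t["max"]).all()
        assert (t["p5"] <= t["p95"]).all()

    def test_point_mass_harvested_area(self):
        stack, spec = self._stack()
        w = np.zeros((2, 2))
        w[0, 1] = 5.0
        baseline = crop_baseline(Raster(spec, w, nodata=-9999.0), stack,
                                 n=50, seed=1)
        assert set(baseline.table.loc["v"].round(12)) == {2.0}

    def test_weighted_draw_frequencies_match_multinomial_oracle(self):
        spec = GridSpec(n_rows=2, n_cols=2, x_min=0, y_max=1, resolution=0.5)
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        stack = VariableStack(
            ["v"], {"v": Raster(spec, vals, nodata=-9999.0)}, {"v": "bioclim"}
        )
        weights = Raster(spec, np.ones((2, 2)), nodata=-9999.0)
        baseline = crop_baseline(weights, stack, n=100_000, seed=7)
        # uniform over cells {1,2,3,4}: median 2.5, quartiles at 2 and 3-ish
        assert baseline.table.loc["v", "median"] == pytest.approx(2.5, abs=0.5)
        draws = crop_baseline(weights, stack, n=100_000, seed=7).table
        assert draws.loc["v", "min"] == 1.0 and draws.loc["v", "max"] == 4.0

    def test_zero_harvested_area_errors(self):
        stack, spec = self._stack()
        with pytest.raises(CompareError, match="zero"):
            crop_baseline(Raster(spec, np.zeros((2, 2)), nodata=-9999.0),
                          stack, n=10)
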