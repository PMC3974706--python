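"""Centres of gravity, leave-one-out CIs, separation and Moran's I."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seascape.errors import DegenerateSpatialError, InsufficientDataError
from seascape.spatial import (
    DegenerateYearWarning,
    above_median_filter,
    centre_of_gravity,
    cog_separation,
    jackknife_cog,
    moran_i,
    moran_weights,
)


def ymap(lats, lons, **values):
    df = pd.DataFrame({"lat": lats, "lon": lons})
    for k, v in values.items():
        df[k] = v
    return df


def moran_brute_force(values, w):
    """Independent O(n^2) double-sum implementation of Moran's I."""
    n = len(values)
    xbar = sum(values) / n
    num = s0 = den = 0.0
    for i in range(n):
        den += (values[i] - xbar) ** 2
        for j in range(n):
            num += w[i][j] * (values[i] - xbar) * (values[j] - xbar)
            s0 += w[i][j]
    return (n / s0) * num / den


class TestAboveMedianFilter:
    def test_even_count(self):
        m = ymap([55, 55.5, 56, 56.5], [15] * 4, density=[1, 2, 3, 4])
        out = above_median_filter(m, "density")
        assert sorted(out["density"]) == [3, 4]

    def test_odd_count_strict_at_median_element(self):
        m = ymap([55, 55.5, 56], [15] * 3, density=[1, 2, 3])
        out = above_median_filter(m, "density")
        assert list(out["density"]) == [3]

    def test_all_equal_is_degenerate(self):
        m = ymap([55, 55.5, 56, 56.5], [15] * 4, density=[5, 5, 5, 5])
        with pytest.warns(DegenerateYearWarning):
            out = above_median_filter(m, "density")
        assert out.empty


class TestCentreOfGravity:
    def test_equal_weights_midpoint(self):
        m = ymap([55.0, 57.0], [15.0, 17.0], density=[2.0, 2.0])
        assert centre_of_gravity(m, "density") == pytest.approx((56.0, 16.0))

    def test_all_weight_on_one_cell(self):
        m = ymap([55.0, 57.0], [15.0, 17.0], density=[0.0, 3.0])
        assert centre_of_gravity(m, "density") == (57.0, 17.0)

    def test_hand_checked_weighted_mean(self):
        m = ymap([55.0, 57.0], [15.0, 15.0], density=[1.0, 3.0])
        lat, _ = centre_of_gravity(m, "density")
        assert lat == pytest.approx(56.5, abs=1e-12)

    def test_all_zero_weights_undefined(self):
        m = ymap([55.0, 57.0], [15.0, 17.0], density=[0.0, 0.0])
        with pytest.raises(DegenerateSpatialError):
            centre_of_gravity(m, "density")

    @given(
        dlat=st.floats(-5, 5, allow_nan=False),
        dlon=st.floats(-5, 5, allow_nan=False),
        scale=st.floats(0.01, 100.0, allow_nan=False),
    )
    def test_translation_equivariant_and_weight_scale_invariant(self, dlat, dlon, scale):
        rng = np.random.default_rng(0)
        m = ymap(rng.uniform(54, 60, 12), rng.uniform(14, 22, 12),
                 density=rng.uniform(0.1, 5.0, 12))
        lat0, lon0 = centre_of_gravity(m, "density")
        shifted = m.assign(lat=m["lat"] + dlat, lon=m["lon"] + dlon,
                           density=m["density"] * scale)
        lat1, lon1 = centre_of_gravity(shifted, "density")
        assert lat1 == pytest.approx(lat0 + dlat, abs=1e-9)
        assert lon1 == pytest.approx(lon0 + dlon, abs=1e-9)

    def test_cog_inside_bounding_box_of_above_median_subset(self):
        rng = np.random.default_rng(4)
        m = ymap(rng.uniform(54, 60, 30), rng.uniform(14, 22, 30),
                 density=rng.lognormal(0, 1, 30))
        sub = above_median_filter(m, "density")
        lat, lon = centre_of_gravity(sub, "density")
        assert sub["lat"].min() <= lat <= sub["lat"].max()
        assert sub["lon"].min() <= lon <= sub["lon"].max()


class TestJackknifeCog:
    def test_enumerated_three_cell_example(self):
        """Equal weights at lat 55, 56, 57: deleting each in turn gives
        leave-one-out latitudes {56.5, 56.0, 55.5}, median 56.0."""
        m = ymap([55.0, 56.0, 57.0], [15.0, 16.0, 17.0],
                 density=[1.0, 1.0, 1.0], year=[2000] * 3)
        est = jackknife_cog(m, "density", min_cells=3, above_median=False)
        assert est.lat == 56.0
        assert (est.lat_lo, est.lat_hi) == (
            pytest.approx(55.525), pytest.approx(56.475))
        assert est.n_used == 3

    def test_point_estimate_within_ci_on_synthetic_year(self):
        rng = np.random.default_rng(1)
        m = ymap(rng.uniform(54, 60, 40), rng.uniform(14, 22, 40),
                 density=rng.lognormal(0, 1, 40), year=[2001] * 40)
        est = jackknife_cog(m, "density", min_cells=10)
        assert est.lat_lo <= est.lat <= est.lat_hi
        assert est.lon_lo <= est.lon <= est.lon_hi
        assert est.n_used < 40  # above-median filtering really happened

    def test_identical_coordinates_zero_width_ci(self):
        m = ymap([56.0] * 5, [16.0] * 5, density=[1, 2, 3, 4, 5], year=[2000] * 5)
        est = jackknife_cog(m, "density", min_cells=1)
        assert est.lat_lo == est.lat == est.lat_hi == 56.0

    def test_symmetric_equal_weight_map_returns_symmetry_centre(self):
        lats = [55.0, 55.0, 57.0, 57.0, 54.0, 58.0]
        lons = [15.0, 17.0, 15.0, 17.0, 16.0, 16.0]
        m = ymap(lats, lons, density=[1.0] * 6, year=[2000] * 6)
        est = jackknife_cog(m, "density", min_cells=3, above_median=False)
        assert est.lat == pytest.approx(56.0, abs=1e-12)
        assert est.lon == pytest.approx(16.0, abs=1e-12)

    def test_too_few_cells_excluded(self):
        m = ymap([55.0, 56.0, 57.0, 58.0], [15.0] * 4,
                 density=[1.0, 2.0, 3.0, 4.0], year=[2000] * 4)
        assert jackknife_cog(m, "density", min_cells=10) is None


class TestCogSeparation:
    def cogs(self, years, lats, lons):
        return pd.DataFrame({"year": years, "lat": lats, "lon": lons})

    def test_identical_series_all_zero(self):
        a = self.cogs([2000, 2001], [56.0, 56.5], [16.0, 17.0])
        out = cog_separation(a, a.copy())
        assert (out[["dlat", "dlon", "distance"]] == 0).all().all()

    def test_signed_and_absolute(self):
        a = self.cogs([2000], [56.0], [16.0])
        b = self.cogs([2000], [55.0], [18.0])
        out = cog_separation(a, b)
        assert out.loc[0, "dlat"] == 1.0 and out.loc[0, "dlon"] == -2.0
        assert out.loc[0, "abs_dlat"] == 1.0 and out.loc[0, "abs_dlon"] == 2.0
        assert out.loc[0, "distance"] == pytest.approx(np.sqrt(5.0))

    def test_disjoint_years_empty(self):
        a = self.cogs([2000], [56.0], [16.0])
        b = self.cogs([2001], [55.0], [18.0])
        assert cog_separation(a, b).empty


class TestMoranWeights:
    def test_two_points_farthest_pair_weight_zero(self):
        w = moran_weights([(0.0, 0.0), (3.0, 4.0)])
        assert w[0, 1] == w[1, 0] == 0.0
        assert w[0, 0] == w[1, 1] == 0.0

    def test_three_collinear_equidistant(self):
        w = moran_weights([(0, 0), (1, 0), (2, 0)])
        assert w[0, 1] == w[1, 2] == pytest.approx(0.5)
        assert w[0, 2] == 0.0

    def test_matches_double_loop_recomputation(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 10, size=(10, 2))
        w = moran_weights(pts)
        d = np.array([[np.hypot(*(p - q)) for q in pts] for p in pts])
        expected = 1 - d / d.max()
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(w, expected, atol=1e-12)
        assert np.all((w >= 0) & (w <= 1))
        np.testing.assert_allclose(w, w.T, atol=0)

    def test_coincident_points_error(self):
        with pytest.raises(DegenerateSpatialError):
            moran_weights([(1.0, 1.0), (1.0, 1.0)])

    def test_great_circle_metric_available(self):
        w_deg = moran_weights([(54, 14), (56, 14), (58, 14)])
        w_km = moran_weights([(54, 14), (56, 14), (58, 14)],
                             metric="great_circle_km")
        # equidistant in latitude: same relative structure under either metric
        np.testing.assert_allclose(w_km, w_deg, atol=1e-6)


class TestMoranI:
    def test_hand_derived_instance(self):
        w = moran_weights([(0, 0), (1, 0), (2, 0)])
        res = moran_i([1.0, 0.0, 1.0], w)
        assert res.I == pytest.approx(-1.0, abs=1e-12)
        assert res.expected_null == pytest.approx(-0.5)

    def test_smooth_gradient_is_clustered(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        values = (xs + ys).ravel()  # smooth monotone surface
        w = moran_weights(coords)
        res = moran_i(values, w)
        assert res.I > 0
        assert res.I == pytest.approx(
            moran_brute_force(values.tolist(), w.tolist()), abs=1e-12)

    @given(seed=st.integers(0, 1000))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        coords = rng.uniform(0, 5, size=(n, 2))
        values = rng.normal(size=n)
        w = moran_weights(coords)
        res = moran_i(values, w)
        assert res.I == pytest.approx(
            moran_brute_force(values.tolist(), w.tolist()), abs=1e-12)

    @given(a=st.floats(-5, 5, allow_nan=False).filter(lambda v: abs(v) > 1e-3),
           c=st.floats(-10, 10, allow_nan=False))
    def test_affine_invariance(self, a, c):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 5, size=(8, 2))
        values = rng.normal(size=8)
        w = moran_weights(coords)
        i0 = moran_i(values, w).I
        i1 = moran_i(a * values + c, w).I
        assert i1 == pytest.approx(i0, rel=1e-9, abs=1e-9)

    def test_degenerate_inputs(self):
        w = moran_weights([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(DegenerateSpatialError):
            moran_i([2.0, 2.0, 2.0], w)  # constant seascape
        with pytest.raises(InsufficientDataError):
            moran_i([1.0, 2.0], np.zeros((2, 2)))
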