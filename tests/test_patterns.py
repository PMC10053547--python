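"""Ripley's K, circumference projection, MAD test and heat maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scabra import synthetic as syn
from scabra.patterns import (
    PointPattern,
    circular_k,
    density_heatmap,
    mad_test,
    mad_test_angles,
    project_to_circumference,
    ripley_k_disk,
)
from scabra.windows import Disk


def brute_force_k_uncorrected(pts, r_grid, area):
    """Independent oracle: count ordered pairs within r, one pair at a time."""
    n = len(pts)
    k = np.zeros(len(r_grid))
    for ri, r in enumerate(r_grid):
        count = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.hypot(*(pts[i] - pts[j])) <= r:
                    count += 1
        k[ri] = area / (n * (n - 1)) * count
    return k


def circle_fraction_inside(center, radius, disk, n_angles=20000):
    """Numerical fraction of a circle lying inside a disk window."""
    th = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    pts = center + radius * np.column_stack((np.cos(th), np.sin(th)))
    return disk.contains(pts).mean()


class TestRipleyKDisk:
    def test_two_interior_points_hand_value(self, tank):
        """Both correction circles fully interior: K jumps to the disk area."""
        pat = PointPattern([(0.0, 0.0), (3.0, 0.0)], Disk((0, 0), 10.0))
        est = ripley_k_disk(pat, r_grid=np.array([1.0, 3.0, 5.0]))
        assert est.k_values[0] == 0.0
        assert est.k_values[1] == pytest.approx(np.pi * 100.0)
        assert est.k_values[2] == pytest.approx(np.pi * 100.0)

    def test_k_is_zero_at_tiny_r(self, tank, rng):
        pat = PointPattern(tank.sample_uniform(30, rng), tank)
        est = ripley_k_disk(pat, r_grid=np.array([1e-9, 10.0]))
        assert est.k_values[0] == 0.0

    def test_matches_brute_force_pair_counting(self, tank, rng):
        """Exact oracle equivalence for small uncorrected patterns."""
        for n in (3, 5, 8):
            pts = tank.sample_uniform(n, rng)
            pat = PointPattern(pts, tank)
            r_grid = np.linspace(1.0, 30.0, 12)
            est = ripley_k_disk(pat, r_grid=r_grid, correction="none")
            oracle = brute_force_k_uncorrected(pts, r_grid, tank.area)
            np.testing.assert_allclose(est.k_values, oracle, rtol=1e-12)

    def test_csr_unbiasedness_at_r10(self, tank):
        """Mean K(10) over replicates approximates the CSR value pi*100."""
        seeds = np.random.SeedSequence(42).spawn(500)
        vals = []
        for s in seeds:
            pat = syn.gen_csr_pattern(50, tank, s)
            est = ripley_k_disk(pat, r_grid=np.array([10.0]))
            vals.append(est.k_values[0])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - np.pi * 100.0) < 3 * se

    def test_monotone_and_rotation_invariant(self, tank, rng):
        pts = tank.sample_uniform(25, rng)
        pat = PointPattern(pts, tank)
        est = ripley_k_disk(pat)
        assert (np.diff(est.k_values) >= -1e-12).all()
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        est2 = ripley_k_disk(PointPattern(pts @ rot.T, tank), est.r_grid)
        np.testing.assert_allclose(est.k_values, est2.k_values, rtol=1e-9)

    def test_correction_weights_against_geometric_oracle(self, tank, rng):
        """e_ij >= 1, equality exactly when the circle is fully interior."""
        from scabra.patterns import _disk_correction_weights

        pts = tank.sample_uniform(12, rng)
        rho = np.hypot(pts[:, 0], pts[:, 1])
        for i in range(len(pts)):
            for j in range(len(pts)):
                if i == j:
                    continue
                d = np.hypot(*(pts[i] - pts[j]))
                w = _disk_correction_weights(
                    np.array([d]), np.array([rho[i]]), tank.radius
                )[0]
                frac = circle_fraction_inside(pts[i], d, tank)
                assert w >= 1.0 - 1e-12
                assert w == pytest.approx(1.0 / frac, rel=5e-3)

    def test_needs_two_points_and_increasing_grid(self, tank):
        with pytest.raises(ValueError, match="at least 2"):
            ripley_k_disk(PointPattern([(0.0, 0.0)], tank))
        pat = PointPattern([(0.0, 0.0), (1.0, 1.0)], tank)
        with pytest.raises(ValueError, match="increasing"):
            ripley_k_disk(pat, r_grid=np.array([5.0, 2.0]))


class TestCircumferenceProjection:
    def test_axis_conventions(self, tank):
        pat = PointPattern([(30.0, 0.0), (0.0, 30.0), (15.0, 0.0)], tank)
        ang = project_to_circumference(pat)
        assert ang[0] == pytest.approx(0.0)
        assert ang[1] == pytest.approx(np.pi / 2)
        assert ang[2] == pytest.approx(0.0)  # radius does not matter

    def test_center_point_named_in_error(self, tank):
        pat = PointPattern([(1.0, 1.0), (0.0, 0.0)], tank)
        with pytest.raises(ValueError, match="point 1"):
            project_to_circumference(pat)

    def test_reflection_negates_angles(self, tank, rng):
        pts = tank.sample_uniform(20, rng)
        ang = project_to_circumference(PointPattern(pts, tank))
        refl = pts * np.array([1.0, -1.0])
        ang_r = project_to_circumference(PointPattern(refl, tank))
        np.testing.assert_allclose(
            np.mod(ang + ang_r, 2 * np.pi), 0.0, atol=1e-9
        )

    def test_count_preserved(self, tank, rng):
        pts = tank.sample_uniform(17, rng)
        assert len(project_to_circumference(PointPattern(pts, tank))) == 17


class TestCircularK:
    def test_antipodal_pair(self):
        L = 2 * np.pi * 30.0
        s = np.array([L / 4, L / 2])
        est = circular_k(np.array([0.0, np.pi]), L, s)
        assert est.k_values[0] == 0.0
        assert est.k_values[1] == pytest.approx(L)

    def test_identical_angles_saturate(self):
        L = 100.0
        est = circular_k(np.array([1.0, 1.0, 1.0]), L, np.array([0.5, 10.0]))
        np.testing.assert_allclose(est.k_values, L)

    def test_uniform_mean_matches_closed_form(self):
        """Under uniform angles E[K(s)] = 2s on the circle."""
        L = 2 * np.pi * 30.0
        s_grid = np.linspace(L / 50, L / 4, 10)
        rng = np.random.default_rng(3)
        curves = np.array(
            [
                circular_k(rng.random(25) * 2 * np.pi, L, s_grid).k_values
                for _ in range(500)
            ]
        )
        se = curves.std(axis=0, ddof=1) / np.sqrt(len(curves))
        assert (np.abs(curves.mean(axis=0) - 2 * s_grid) < 4 * se + 1e-9).all()

    def test_rotation_invariance_through_projection(self, tank, rng):
        pts = tank.sample_uniform(15, rng)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        L = 2 * np.pi * tank.radius
        s = np.linspace(1.0, L / 4, 20)
        k1 = circular_k(project_to_circumference(PointPattern(pts, tank)), L, s)
        k2 = circular_k(project_to_circumference(PointPattern(pts @ rot.T, tank)), L, s)
        np.testing.assert_allclose(k1.k_values, k2.k_values, atol=1e-9)


class TestMadTest:
    def test_nsim_floor(self, tank, rng):
        pat = PointPattern(tank.sample_uniform(10, rng), tank)
        with pytest.raises(ValueError, match="19"):
            mad_test(pat, n_sim=10)

    def test_p_value_rank_formula_and_range(self, tank, rng):
        pat = PointPattern(tank.sample_uniform(20, rng), tank)
        res = mad_test(pat, n_sim=39, seed=8)
        expect = (1 + np.count_nonzero(res.null_stats >= res.observed_stat)) / 40
        assert res.p_value == pytest.approx(expect)
        assert 0 < res.p_value <= 1

    def test_null_p_uniform_on_grid(self, tank):
        """Under CSR with n_sim=19 the p-value is uniform on {1/20,...,1}."""
        from scipy import stats

        seeds = np.random.SeedSequence(9).spawn(300)
        pvals = []
        for s in seeds:
            a, b = s.spawn(2)
            pat = syn.gen_csr_pattern(15, tank, a)
            pvals.append(mad_test(pat, n_sim=19, seed=b).p_value)
        counts = np.bincount((np.array(pvals) * 20).round().astype(int), minlength=21)[1:]
        assert stats.chisquare(counts).pvalue > 0.001

    def test_clustered_pattern_rejected(self, tank):
        pat = syn.gen_clustered_tank(40, seed=77)
        res = mad_test(pat, n_sim=199, seed=78)
        assert res.p_value <= 0.05

    def test_theoretical_reference_also_rejects_clusters(self, tank):
        pat = syn.gen_clustered_tank(40, seed=79)
        res = mad_test(pat, n_sim=99, seed=80, reference="theoretical")
        assert res.reference == "theoretical"
        assert res.p_value <= 0.05

    def test_angular_variant_detects_arc_clumping(self, tank):
        rng = np.random.default_rng(5)
        angles = rng.normal(1.0, 0.1, size=30) % (2 * np.pi)
        res = mad_test_angles(angles, 2 * np.pi * 30.0, n_sim=199, seed=6)
        assert res.p_value <= 0.05


class TestDensityHeatmap:
    def test_mass_normalised_to_n(self, tank, rng):
        pat = PointPattern(tank.sample_uniform(40, rng), tank)
        hm = density_heatmap(pat, bandwidth=5.0, grid_resolution=80)
        mass = np.nansum(hm.density) * hm.cell_area
        assert mass == pytest.approx(40.0, rel=1e-6)

    def test_single_point_peak_location(self, tank):
        pat = PointPattern([(10.0, -5.0), (10.2, -5.1)], tank)
        hm = density_heatmap(pat, bandwidth=2.0, grid_resolution=120)
        iy, ix = np.unravel_index(np.nanargmax(hm.density), hm.density.shape)
        assert hm.x_centers[ix] == pytest.approx(10.0, abs=1.0)
        assert hm.y_centers[iy] == pytest.approx(-5.0, abs=1.0)

    def test_tight_cluster_exceeds_reported_density_scale(self, tank):
        """One 40-animal clump peaks above 0.04 ind/cm^2 at 5 cm bandwidth."""
        pat = syn.gen_clustered_tank(40, seed=4, n_clusters=1, spread=2.0)
        hm = density_heatmap(pat, bandwidth=5.0, grid_resolution=100)
        assert np.nanmax(hm.density) > 0.04

    def test_bad_bandwidth_rejected(self, tank, rng):
        pat = PointPattern(tank.sample_uniform(5, rng), tank)
        with pytest.raises(ValueError, match="bandwidth"):
            density_heatmap(pat, bandwidth=0.0)

    def test_rendered_image_written(self, tank, rng, tmp_path):
        from scabra.viz import plot_heatmap

        pat = PointPattern(tank.sample_uniform(10, rng), tank)
        hm = density_heatmap(pat, bandwidth=5.0, grid_resolution=40)
        out = tmp_path / "tank.png"
        plot_heatmap(hm, out, pattern=pat)
        assert out.stat().st_size > 0


@given(st.integers(0, 2**31 - 1))
@settings(derandomize=True, max_examples=25, deadline=None)
def test_pattern_points_always_inside_window(seed):
    tank = Disk((0.0, 0.0), 30.0)
    pat = syn.gen_csr_pattern(30, tank, seed)
    assert tank.contains(pat.points).all()
    clustered = syn.gen_clustered_tank(20, seed)
    assert tank.contains(clustered.points).all()
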