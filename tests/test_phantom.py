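"""Digital phantom: defect fields, rasterisation, degradation, cohorts."""

import numpy as np
import pytest
from scipy.integrate import quad

import perfvec as pv
from perfvec.errors import (
    DegenerateWeightsError,
    EmptyTableError,
    FieldOfViewError,
    ParameterError,
)
from perfvec.phantom import (
    AcquisitionSpec,
    DefectSpec,
    _area_centroid_arc,
    _extent_window,
    add_poisson_noise,
    apply_gaussian_blur,
    defect_area_fraction,
    ideal_surface_weights,
    render_volume,
    simulate_study,
)
from perfvec.sampling import sample_weights
from perfvec.surface import meridian_arc_table

FWHM_TO_SIGMA = 2 * np.sqrt(2 * np.log(2))


class TestIdealWeights:
    def test_no_defect_all_ones(self, default_grid):
        w = ideal_surface_weights(default_grid, None)
        np.testing.assert_array_equal(w, np.ones(len(default_grid)))

    def test_full_defect_zeroes_everything(self, default_grid):
        defect = DefectSpec("anterior", alpha_deg=360.0, extent_mm=1e4, severity=1.0)
        w = ideal_surface_weights(default_grid, defect)
        np.testing.assert_array_equal(w, 0.0)
        with pytest.raises(DegenerateWeightsError):
            pv.compute_perfusion_vector(default_grid, w)

    def test_sector_membership(self, default_grid):
        defect = DefectSpec("anterior", alpha_deg=90.0, severity=0.5)
        w = ideal_surface_weights(default_grid, defect)
        theta = default_grid.theta_deg
        arc = default_grid.arc_from_apex_mm
        s_lo, s_hi = _extent_window(
            defect,
            meridian_arc_table(default_grid.shape)[1][-1],
            _area_centroid_arc(default_grid.shape),
        )
        # stay one full cell width inside/outside the border
        margin = float(default_grid.darc_mm.max())
        mid_band = (arc > s_lo + margin) & (arc < s_hi - margin)
        at_anterior = np.abs(theta - 270.0) < 10.0
        at_inferior = np.abs(theta - 90.0) < 10.0
        assert np.all(w[mid_band & at_anterior] == 0.5)
        assert np.all(w[mid_band & at_inferior] == 1.0)

    def test_invalid_defects_rejected(self):
        with pytest.raises(ParameterError):
            DefectSpec(alpha_deg=0.0)
        with pytest.raises(ParameterError):
            DefectSpec(severity=1.5)
        with pytest.raises(ParameterError):
            DefectSpec(location="nowhere")
        with pytest.raises(ParameterError):
            DefectSpec(location="custom")

    def test_area_fraction_matches_analytic_sector(self, default_grid):
        """Defect area fraction = (alpha/360) x meridional coverage fraction."""
        shape = default_grid.shape
        defect = DefectSpec("anterior", alpha_deg=70.0, extent_mm=60.0)
        got = defect_area_fraction(default_grid, defect)
        phi_tab, s_tab = meridian_arc_table(shape)
        s_lo, s_hi = _extent_window(defect, s_tab[-1], _area_centroid_arc(shape))
        a, c = shape.mid_short_radius, shape.mid_long_radius

        def density(phi):
            return np.sin(phi) * np.sqrt((a * np.cos(phi)) ** 2 + (c * np.sin(phi)) ** 2)

        phi_lo = np.interp(s_lo, s_tab, phi_tab)
        phi_hi = np.interp(s_hi, s_tab, phi_tab)
        band, _ = quad(density, phi_lo, phi_hi)
        total, _ = quad(density, 0, shape.phi_base)
        want = (70.0 / 360.0) * band / total
        assert got == pytest.approx(want, rel=0.02)


class TestRender:
    def test_membership_matches_brute_force(self, solved_shape, noiseless_acq):
        vol = render_volume(solved_shape, None, noiseless_acq)
        xs, ys, zs = vol.voxel_centers_mm()
        a, c = solved_shape.mid_short_radius, solved_shape.mid_long_radius
        t2 = solved_shape.wall_thickness / 2
        count = 0
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                r2 = x * x + y * y
                q_epi = r2 / (a + t2) ** 2 + zs**2 / (c + t2) ** 2
                q_endo = r2 / (a - t2) ** 2 + zs**2 / (c - t2) ** 2
                count += int(
                    np.sum((q_epi <= 1) & (q_endo >= 1) & (zs >= solved_shape.base_plane_z))
                )
        assert int(np.count_nonzero(vol.values)) == count

    def test_full_severity_defect_zero_inside(self, solved_shape, noiseless_acq):
        defect = DefectSpec("lateral", alpha_deg=60.0, severity=1.0)
        vol = render_volume(solved_shape, defect, noiseless_acq)
        vol0 = render_volume(solved_shape, None, noiseless_acq)
        inside = vol0.values != vol.values
        assert inside.any()
        assert np.all(vol.values[inside] == 0.0)

    def test_total_uptake_converges(self, solved_shape):
        v1 = render_volume(solved_shape, None, AcquisitionSpec(voxel_size=4.8, noise=False))
        v2 = render_volume(solved_shape, None, AcquisitionSpec(voxel_size=2.4, noise=False))
        s1 = v1.values.sum() * 4.8**3
        s2 = v2.values.sum() * 2.4**3
        assert abs(s1 - s2) / s1 < 0.02

    def test_field_of_view_error(self, solved_shape):
        with pytest.raises(FieldOfViewError):
            render_volume(solved_shape, None, AcquisitionSpec(matrix=(8, 8, 8)))


class TestBlur:
    def test_zero_fwhm_is_identity(self, blurred_normal_volume):
        out = apply_gaussian_blur(blurred_normal_volume, 0.0)
        np.testing.assert_array_equal(out.values, blurred_normal_volume.values)

    def test_point_source_matches_sampled_gaussian(self):
        vol = pv.VoxelVolume(np.zeros((41, 41, 41)), (4.8, 4.8, 4.8))
        vol.values[20, 20, 20] = 1.0
        out = apply_gaussian_blur(vol, 7.0)
        sigma = 7.0 / FWHM_TO_SIGMA / 4.8
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-(x**2) / (2 * sigma**2))
        k /= k.sum()
        got = out.values[20 - radius : 20 + radius + 1, 20, 20]
        want = k * k[radius] * k[radius]
        assert np.max(np.abs(got - want) / want) < 1e-6

    def test_mass_conserved(self, solved_shape, noiseless_acq):
        vol = render_volume(solved_shape, None, noiseless_acq)
        out = apply_gaussian_blur(vol, 7.0)
        assert 0.999 <= out.values.sum() / vol.values.sum() <= 1.001

    def test_negative_fwhm_rejected(self, blurred_normal_volume):
        with pytest.raises(ParameterError):
            apply_gaussian_blur(blurred_normal_volume, -1.0)


class TestPoissonNoise:
    def test_zero_volume_stays_zero(self):
        vol = pv.VoxelVolume(np.zeros((5, 5, 5)), (1, 1, 1))
        out = add_poisson_noise(vol, 100.0, 0)
        np.testing.assert_array_equal(out.values, 0)

    def test_deterministic_for_fixed_seed(self, blurred_normal_volume):
        a = add_poisson_noise(blurred_normal_volume, 500.0, 42)
        b = add_poisson_noise(blurred_normal_volume, 500.0, 42)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.issubdtype(a.values.dtype, np.integer)

    def test_moments(self):
        vol = pv.VoxelVolume(np.ones((50, 50, 40)), (1, 1, 1))
        out = add_poisson_noise(vol, 1e4, 7)
        mean = out.values.mean()
        assert abs(mean - 1e4) / 1e4 < 0.01
        assert 0.97 <= out.values.var() / mean <= 1.03

    def test_bad_scale_rejected(self, blurred_normal_volume):
        with pytest.raises(ParameterError):
            add_poisson_noise(blurred_normal_volume, 0.0, 0)


class TestSimulateStudy:
    def test_normal_phantom_weights_nearly_uniform(self, default_grid,
                                                   blurred_normal_volume):
        w = sample_weights(blurred_normal_volume, default_grid)
        arc = default_grid.arc_from_apex_mm
        mid = (arc > 15) & (arc < arc.max() - 15)
        assert w[mid].std() / w[mid].mean() < 0.05

    def test_larger_defect_larger_component(self, solved_shape):
        acq = AcquisitionSpec(noise=False)
        py = {}
        for alpha in (10.0, 70.0):
            vol, grid = simulate_study(
                solved_shape, DefectSpec("anterior", alpha_deg=alpha), acq
            )
            w = sample_weights(vol, grid)
            py[alpha] = pv.compute_perfusion_vector(grid, w).vector[1]
        assert abs(py[70.0]) > abs(py[10.0])

    def test_seeded_run_is_byte_identical(self, solved_shape):
        acq = AcquisitionSpec(seed=9)
        v1, _ = simulate_study(solved_shape, DefectSpec("inferior"), acq)
        v2, _ = simulate_study(solved_shape, DefectSpec("inferior"), acq)
        assert v1.values.tobytes() == v2.values.tobytes()

    def test_vector_stable_under_voxel_halving(self, solved_shape, default_grid):
        """Discretisation stability: halving voxel size moves P by < 0.2 mm."""
        defect = DefectSpec("anterior", alpha_deg=50.0)
        ps = {}
        for size in (4.8, 2.4):
            acq = AcquisitionSpec(voxel_size=size, noise=False)
            vol = apply_gaussian_blur(render_volume(solved_shape, defect, acq), 7.0)
            w = sample_weights(vol, default_grid)
            ps[size] = pv.compute_perfusion_vector(default_grid, w).p
        assert np.linalg.norm(ps[4.8] - ps[2.4]) < 0.2

    def test_noise_floor_below_moderate_defect(self, solved_shape, default_grid,
                                               blurred_normal_volume):
        """Normal-phantom |P| under noise never reaches a 30-degree defect's |P|."""
        acq = AcquisitionSpec(noise=False)
        vol = apply_gaussian_blur(
            render_volume(solved_shape, DefectSpec("anterior", alpha_deg=30.0), acq),
            acq.blur_fwhm,
        )
        defect_mag = pv.compute_perfusion_vector(
            default_grid, sample_weights(vol, default_grid)
        ).magnitude
        mags = []
        for seed in range(100):
            noisy = add_poisson_noise(blurred_normal_volume, 500.0, seed)
            mags.append(
                pv.compute_perfusion_vector(
                    default_grid, sample_weights(noisy, default_grid)
                ).magnitude
            )
        assert np.median(mags) < defect_mag
        assert max(mags) < defect_mag  # zero distribution overlap


class TestCohort:
    def test_normals_only(self):
        spec = pv.CohortSpec(n_normal=3, n_per_defect_group=0, master_seed=5)
        table = pv.generate_cohort(spec)
        assert len(table) == 3
        assert set(table["group"]) == {"normal"}

    def test_empty_spec_rejected(self):
        with pytest.raises(EmptyTableError):
            pv.generate_cohort(pv.CohortSpec(n_normal=0, n_per_defect_group=0))

    def test_reproducible_from_master_seed(self, tmp_path):
        from perfvec.io import write_cohort_csv

        spec = pv.CohortSpec(
            n_normal=2, n_per_defect_group=1, locations=("anterior",), master_seed=11
        )
        paths = []
        for name in ("a.csv", "b.csv"):
            table = pv.generate_cohort(spec)
            p = tmp_path / name
            write_cohort_csv(table, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
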