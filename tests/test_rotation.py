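"""Registration, azimuthal decomposition, SVD grouping, director extraction, arrows."""

import dataclasses

import numpy as np
import pytest
import scipy.linalg as sla

import vsfgmap as v
from vsfgmap.preprocess import OpticalGeometry
from vsfgmap.rotation import (
    Aligned4D,
    RegistrationError,
    align_rotation_series,
    arrow_map,
    azimuthal_decompose,
    extract_director,
    svd_decompose,
)
from vsfgmap.spectra import lorentzian
from vsfgmap.synth import GridSpec, texture_scene

from conftest import circular_rmse_deg, interior_mask, run_to_director

GRID = GridSpec(nx=64, ny=64, pixel_size_um=0.5)
PHI6 = np.arange(6) * 60.0


def _aligned_from(data, angles, wavenumber, pixel=0.5):
    nphi, ny, nx, nw = data.shape
    return Aligned4D(
        data=data,
        angles_deg=np.asarray(angles, float),
        wavenumber=np.asarray(wavenumber, float),
        mask=np.ones((ny, nx), bool),
        rot_centre_px=((ny - 1) / 2, (nx - 1) / 2),
        shifts_px=np.zeros((nphi, 2)),
        registration_corr=np.ones(nphi),
        pixel_size_um=pixel,
    )


class TestAlign:
    def test_duplicate_zero_angle_frames_identity(self, model, geometry):
        scene = texture_scene("radial-cw", seed=0, grid=GRID, radius_um=8.0)
        series = v.synthesize_chi2_series(
            scene, model, OpticalGeometry(rotation_angles_deg=(0.0, 120.0, 240.0))
        )
        dup = v.RotationSeries(
            data=np.repeat(series.data[:1], 3, axis=0),
            angles_deg=np.zeros(3),
            wavenumber=series.wavenumber,
            pixel_size_um=series.pixel_size_um,
            rot_centre_px=series.rot_centre_px,
        )
        al = align_rotation_series(dup, search_radius_px=0.0)
        assert np.array_equal(al.data[1], dup.data[0])
        assert al.mask.all()

    def test_centre_recovery_within_one_pixel(self, model):
        # off-centre rotation axis, estimated from the data alone
        scene = texture_scene("spiral-cw-plus-virtual", seed=5)
        scene = dataclasses.replace(scene, rot_centre_um=(1.5, -2.0))
        series = v.synthesize_chi2_series(scene, model, OpticalGeometry())
        guess = ((scene.grid.ny - 1) / 2, (scene.grid.nx - 1) / 2)  # image centre
        al = align_rotation_series(series, centre_guess=guess, search_radius_px=6.0)
        true_centre = series.rot_centre_px
        assert abs(al.rot_centre_px[0] - true_centre[0]) < 1.0
        assert abs(al.rot_centre_px[1] - true_centre[1]) < 1.0
        # registration fidelity is judged on a rotation-invariant signal: the
        # in-plane response is physically modulated by the rotation, so only
        # an out-of-plane-only scene has magnitude images that can agree
        bands = tuple(dataclasses.replace(b, a_ip=0.0) for b in model.bands)
        model_op = v.SpectralModel(bands=bands)
        series_op = v.synthesize_chi2_series(scene, model_op, OpticalGeometry())
        al_op = align_rotation_series(series_op, centre_guess=al.rot_centre_px,
                                      search_radius_px=0.0)
        ref = np.abs(al_op.data[0]).sum(-1)
        for i in range(1, al_op.n_rotations):
            m = np.abs(al_op.data[i]).sum(-1)
            rms = np.sqrt(np.mean((m - ref)[al_op.mask] ** 2))
            assert rms < 0.02 * ref.max()

    def test_mask_shrinks_as_angles_accumulate(self, model):
        # intersection property: adding frames can only remove mask pixels
        scene = texture_scene("radial-acw", seed=1, grid=GRID, radius_um=8.0)
        series = v.synthesize_chi2_series(scene, model, OpticalGeometry())
        areas = []
        for k in (3, 4, 6):
            sub = v.RotationSeries(series.data[:k], series.angles_deg[:k],
                                   series.wavenumber, pixel_size_um=0.5,
                                   rot_centre_px=series.rot_centre_px)
            al = align_rotation_series(sub, centre_guess=series.rot_centre_px,
                                       search_radius_px=0.0)
            areas.append(al.mask.sum())
        assert areas[0] >= areas[1] >= areas[2]

    def test_low_correlation_raises_naming_angle(self, model):
        scene = texture_scene("radial-cw", seed=2, grid=GRID, radius_um=8.0)
        series = v.synthesize_chi2_series(scene, model, OpticalGeometry())
        rng = np.random.default_rng(0)
        bad = series.data.copy()
        bad[3] = rng.normal(size=bad[3].shape) + 1j * rng.normal(size=bad[3].shape)
        series2 = v.RotationSeries(bad, series.angles_deg, series.wavenumber,
                                   pixel_size_um=0.5, rot_centre_px=series.rot_centre_px)
        with pytest.raises(RegistrationError, match="180"):
            align_rotation_series(series2, centre_guess=series.rot_centre_px,
                                  search_radius_px=0.0)


class TestAzimuthalDecompose:
    def test_constant_series_all_in_f0(self):
        w = np.linspace(2700, 3100, 8)
        const = np.full((6, 8, 8, 8), 2.0 - 1.0j)
        comp = azimuthal_decompose(_aligned_from(const, PHI6, w))
        np.testing.assert_allclose(comp.F0, 2.0 - 1.0j, atol=1e-12)
        np.testing.assert_allclose(comp.F1, 0.0, atol=1e-12)
        np.testing.assert_allclose(comp.confidence, 1.0)

    def test_cosine_against_least_squares_oracle(self):
        # S(phi) = B cos(d + phi): |F1| = B/2, arg F1 = d, matching a per-pixel
        # least-squares sinusoid fit
        rng = np.random.default_rng(3)
        ny = nx = 16
        B = rng.uniform(0.5, 2.0, (ny, nx))
        d = rng.uniform(0, 2 * np.pi, (ny, nx))
        phi = np.deg2rad(PHI6)
        S = (B[None] * np.cos(d[None] + phi[:, None, None]))[..., None].astype(complex)
        comp = azimuthal_decompose(_aligned_from(S, PHI6, np.array([2875.0])))
        # oracle: per-pixel lstsq on [1, cos, sin]
        A = np.stack([np.ones_like(phi), np.cos(phi), np.sin(phi)], axis=1)
        coef, *_ = np.linalg.lstsq(A, S[..., 0].reshape(6, -1).real, rcond=None)
        Bc, Bs = coef[1].reshape(ny, nx), coef[2].reshape(ny, nx)
        # B cos(d+phi) = Bc cos(phi) + Bs sin(phi) with Bc = B cos d, Bs = -B sin d
        F1_oracle = 0.5 * (Bc - 1j * Bs)  # = (B/2)(cos d + i sin d)
        np.testing.assert_allclose(comp.F1[..., 0], F1_oracle, atol=1e-10)
        np.testing.assert_allclose(np.abs(comp.F1[..., 0]), B / 2, atol=1e-10)

    def test_two_fold_signal_orthogonal_at_six_angles(self):
        phi = np.deg2rad(PHI6)
        S = np.cos(2 * phi)[:, None, None, None] * np.ones((1, 4, 4, 2))
        comp = azimuthal_decompose(_aligned_from(S.astype(complex), PHI6, np.array([2875.0, 2885.0])))
        np.testing.assert_allclose(comp.F1, 0.0, atol=1e-12)
        np.testing.assert_allclose(comp.F0, 0.0, atol=1e-12)

    def test_f0_invariant_when_dropping_one_angle(self):
        # harmonic model is exact, so the non-uniform lstsq path reproduces F0
        rng = np.random.default_rng(1)
        F0 = rng.normal(size=(5, 5, 3)) + 1j * rng.normal(size=(5, 5, 3))
        F1 = rng.normal(size=(5, 5, 3)) + 1j * rng.normal(size=(5, 5, 3))
        phi = np.deg2rad(PHI6)
        S = F0[None] + 2 * np.real(F1[None] * np.exp(1j * phi)[:, None, None, None])
        S = S.astype(complex)
        full = azimuthal_decompose(_aligned_from(S, PHI6, np.arange(3.0)))
        dropped = azimuthal_decompose(_aligned_from(S[1:], PHI6[1:], np.arange(3.0)))
        assert not dropped.uniform_angles
        np.testing.assert_allclose(dropped.F0, full.F0, atol=1e-9)

    def test_inversion_symmetric_scene_cancels_inplane(self, model, geometry):
        # counter-directional packing: equal populations at theta and theta+180
        # within each pixel leave no 1-fold signal
        w = np.array([2875.0])
        phi = PHI6
        theta = np.deg2rad(40.0)
        d1 = np.cos(theta + np.deg2rad(phi))
        d2 = np.cos(theta + np.pi + np.deg2rad(phi))
        S = 0.5 * (d1 + d2)[:, None, None, None] * np.ones((1, 4, 4, 1))
        comp = azimuthal_decompose(_aligned_from(S.astype(complex), phi, w))
        np.testing.assert_allclose(comp.F1, 0.0, atol=1e-12)


class TestSVD:
    def test_rank_two_for_two_chromophores(self, model, geometry):
        scene = texture_scene("spiral-cw-plus-virtual", seed=3)
        *_, aligned, _, _ = _run_aligned(scene, model, geometry)
        res = svd_decompose(aligned)
        s = res.singular_values
        assert np.sum(s > 1e-8 * s[0]) == 2

    def test_subspace_matches_ground_truth_profiles(self, model, geometry):
        scene = texture_scene("spiral-acw-minus-real", seed=4)
        *_, aligned, _, _ = _run_aligned(scene, model, geometry)
        res = svd_decompose(aligned, n_components=2)
        w = res.wavenumber
        t_op = sum(b.a_op * lorentzian(w, b.omega0, b.gamma) for b in model.bands)
        # effective in-plane profile carries the dipole-offset signs
        t_ip = sum(
            b.a_ip * np.cos(np.deg2rad(b.dipole_offset_deg))
            * lorentzian(w, b.omega0, b.gamma)
            for b in model.bands
        )
        A = np.stack([t_op, t_ip]).T
        B = res.spectra.T
        ang = sla.subspace_angles(np.vstack([A.real, A.imag]), np.vstack([B.real, B.imag]))
        assert np.cos(ang).min() > 0.999

    def test_scaling_homogeneity(self, model, geometry):
        scene = texture_scene("radial-cw", seed=5, grid=GRID, radius_um=8.0)
        *_, aligned, _, _ = _run_aligned(scene, model, geometry)
        r1 = svd_decompose(aligned, n_components=2)
        doubled = dataclasses.replace(aligned, data=2.0 * aligned.data)
        r2 = svd_decompose(doubled, n_components=2)
        np.testing.assert_allclose(r2.singular_values, 2 * r1.singular_values, rtol=1e-9)
        np.testing.assert_allclose(np.abs(r2.spectra), np.abs(r1.spectra), atol=1e-9)

    def test_component_sign_fixed_positive_ch3_ss(self, model, geometry):
        scene = texture_scene("spiral-cw-plus-virtual", seed=6)
        *_, aligned, _, _ = _run_aligned(scene, model, geometry)
        res = svd_decompose(aligned, n_components=2)
        j = np.argmin(np.abs(res.wavenumber - 2875.0))
        assert all(res.spectra[i, j].imag > 0 for i in range(2))

    def test_too_many_components_rejected(self, model, geometry):
        scene = texture_scene("radial-acw", seed=0, grid=GRID, radius_um=8.0)
        *_, aligned, _, _ = _run_aligned(scene, model, geometry)
        with pytest.raises(ValueError, match="components"):
            svd_decompose(aligned, n_components=10 ** 6)


def _run_aligned(scene, model, geometry):
    series = v.synthesize_chi2_series(scene, model, geometry)
    aligned = align_rotation_series(series, centre_guess=series.rot_centre_px,
                                    search_radius_px=0.0)
    return series, aligned, None, None


class TestExtractDirector:
    def test_uniform_scene_circular_mean_recovery(self, model, geometry):
        from vsfgmap.synth import DomainSpec, SyntheticScene, TextureModel

        theta0 = 137.0
        tex = TextureModel(family="linear", beta_deg=theta0)
        scene = SyntheticScene(grid=GRID, domains=(DomainSpec((0.0, 0.0), 10.0, tex),))
        *_, _, comp, director = run_to_director(scene, model, geometry)
        truth = scene.director_field()
        m = interior_mask(truth, director)
        z = np.exp(1j * np.deg2rad(director.theta_deg[m]))
        mean_dir = np.rad2deg(np.angle(z.mean())) % 360.0
        assert abs(mean_dir - theta0) < 0.1

    def test_dipole_opposite_convention_self_consistent(self, model, geometry):
        # generated with CH3 dipole at theta+180: the extracted direction is
        # theta itself, not theta+180
        scene = texture_scene("parallel-cw", seed=0, grid=GRID, radius_um=8.0)
        *_, comp, director = run_to_director(scene, model, geometry)
        truth = scene.director_field()
        m = interior_mask(truth, director)
        assert circular_rmse_deg(director.theta_deg, truth.theta_deg, m) < 0.1

    def test_band_mode_agrees_with_template_mode(self, model, geometry):
        scene = texture_scene("spiral-cw-plus-virtual", seed=1)
        series, aligned, comp, director = run_to_director(scene, model, geometry)
        band = extract_director(comp, model, mode="band")
        truth = scene.director_field()
        m = interior_mask(truth, director) & interior_mask(truth, band)
        assert circular_rmse_deg(band.theta_deg, director.theta_deg, m) < 0.2

    def test_low_magnitude_pixels_masked_not_guessed(self, model, geometry):
        scene = texture_scene("radial-cw", seed=2, grid=GRID, radius_um=8.0)
        *_, comp, director = run_to_director(scene, model, geometry)
        # the disordered background (s = 0) has no in-plane signal; evaluate
        # away from the optical edge response at the boundary
        from scipy.ndimage import binary_dilation

        outside = ~binary_dilation(scene.director_field().mask, iterations=3)
        assert not director.mask[outside & comp.mask].any()

    def test_rigid_rotation_equivariance(self, model, geometry):
        # rotating the whole scene by Delta shifts every director angle by Delta
        from vsfgmap.synth import DomainSpec, SyntheticScene, TextureModel

        delta = 60.0
        # virtual boojum centre: the director varies smoothly inside the domain
        tex = TextureModel(family="boojum", centre_um=(12.0, 4.0), k=1,
                           beta_deg=200.0, q_deg_per_um=2.0)
        base = SyntheticScene(grid=GRID, domains=(DomainSpec((1.0, 0.5), 8.0, tex),))
        a = np.deg2rad(delta)
        rot = lambda p: (p[0] * np.cos(a) - p[1] * np.sin(a),
                         p[0] * np.sin(a) + p[1] * np.cos(a))
        # rigid rotation of a k=1 boojum: psi itself picks up delta, so beta
        # is unchanged and the directors still shift by delta
        tex_r = TextureModel(family="boojum", centre_um=rot(tex.centre_um), k=1,
                             beta_deg=tex.beta_deg, q_deg_per_um=2.0)
        rotated = SyntheticScene(grid=GRID,
                                 domains=(DomainSpec(rot((1.0, 0.5)), 8.0, tex_r),))
        *_, d1 = run_to_director(base, model, geometry)
        *_, d2 = run_to_director(rotated, model, geometry)
        t1 = base.director_field()
        t2 = rotated.director_field()
        m1 = interior_mask(t1, d1)
        m2 = interior_mask(t2, d2)
        assert circular_rmse_deg(d1.theta_deg, t1.theta_deg, m1) < 0.1
        assert circular_rmse_deg(d2.theta_deg, t2.theta_deg, m2) < 0.1
        # and the recovered distributions differ by exactly Delta (circular means)
        z1 = np.exp(1j * np.deg2rad(t1.theta_deg[m1])).mean()
        z2 = np.exp(1j * np.deg2rad(t2.theta_deg[m2])).mean()
        shift = (np.rad2deg(np.angle(z2 / z1))) % 360.0
        assert min(shift, 360 - shift) == pytest.approx(delta, abs=1.0)


class TestArrowMap:
    def _uniform_field(self, theta0=75.0):
        from vsfgmap.rotation import DirectorField

        th = np.full((12, 12), theta0)
        return DirectorField(theta_deg=th, magnitude=np.ones_like(th),
                             confidence=np.ones_like(th),
                             mask=np.ones_like(th, bool), pixel_size_um=0.5)

    def test_uniform_field_uniform_arrows(self):
        arrows = arrow_map(self._uniform_field(), block=6)
        assert len(arrows) == 4
        np.testing.assert_allclose(arrows["theta_deg"], 75.0, atol=1e-10)

    def test_opposite_directions_cancel_and_omit(self):
        from vsfgmap.rotation import DirectorField

        th = np.zeros((6, 6))
        th[:, 3:] = 180.0
        f = DirectorField(theta_deg=th, magnitude=np.ones_like(th),
                          confidence=np.ones_like(th), mask=np.ones_like(th, bool),
                          pixel_size_um=0.5)
        arrows = arrow_map(f, block=6)
        assert len(arrows) == 0

    def test_matches_brute_force_vector_sum(self, model, geometry):
        scene = texture_scene("spiral-acw-minus-real", seed=0)
        *_, director = run_to_director(scene, model, geometry)
        arrows = arrow_map(director, block=6)
        assert len(arrows) > 0
        z = director.magnitude * np.exp(1j * np.deg2rad(director.theta_deg))
        nx = director.theta_deg.shape[1]
        ny = director.theta_deg.shape[0]
        for _, row in arrows.head(10).iterrows():
            ix = int(round(row.x_um / 0.5 + (nx - 1) / 2 - 2.5))
            iy = int(round(row.y_um / 0.5 + (ny - 1) / 2 - 2.5))
            zb = z[iy:iy + 6, ix:ix + 6][director.mask[iy:iy + 6, ix:ix + 6]]
            assert row.theta_deg == pytest.approx(
                np.rad2deg(np.angle(zb.sum())) % 360.0, abs=1e-10
            )

    def test_block_must_be_positive(self):
        with pytest.raises(ValueError):
            arrow_map(self._uniform_field(), block=0)
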