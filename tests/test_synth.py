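"""Forward model: domain layout, textures, chi2 series, interferograms, noise, mirror."""

import numpy as np
import pytest

import vsfgmap as v
from vsfgmap.preprocess import OpticalGeometry
from vsfgmap.spectra import lorentzian
from vsfgmap.synth import (
    DomainSpec,
    GridSpec,
    PlacementError,
    PulseSpec,
    SyntheticScene,
    TextureModel,
    add_detection_noise,
    make_domain_layout,
    make_texture_field,
    mirror_scene,
    synthesize_chi2_series,
    synthesize_interferograms,
    synthesize_reference,
    texture_scene,
)

GRID = GridSpec(nx=64, ny=64, pixel_size_um=0.5)


class TestDomainLayout:
    def test_empty_request_gives_background_only(self):
        labels, centres = make_domain_layout(GRID, 0)
        assert labels.max() == 0 and centres == []

    def test_single_disc_area_matches_analytic(self):
        labels, _ = make_domain_layout(GRID, 1, radius_um=5.0, seed=1)
        area = (labels == 1).sum() * GRID.pixel_size_um ** 2
        assert area == pytest.approx(np.pi * 25.0, rel=0.03)

    def test_default_radius_gives_ten_micron_diameters(self):
        # the generator default emulates LC domains of ca. 10 um diameter
        labels, _ = make_domain_layout(GRID, 2, seed=0)
        for lab in (1, 2):
            area = (labels == lab).sum() * GRID.pixel_size_um ** 2
            diameter = 2 * np.sqrt(area / np.pi)
            assert diameter == pytest.approx(10.0, rel=0.05)

    def test_non_overlap_and_gap(self):
        labels, centres = make_domain_layout(GRID, 3, radius_um=4.0, min_gap_um=2.0, seed=3)
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.hypot(centres[i][0] - centres[j][0], centres[i][1] - centres[j][1])
                assert d >= 2 * 4.0 + 2.0 - 1e-9

    def test_determinism_per_seed(self):
        a, ca = make_domain_layout(GRID, 3, seed=7)
        b, cb = make_domain_layout(GRID, 3, seed=7)
        assert np.array_equal(a, b) and ca == cb

    def test_impossible_placement_raises_with_parameters(self):
        with pytest.raises(PlacementError, match="radius"):
            make_domain_layout(GRID, 1, radius_um=50.0)
        with pytest.raises(PlacementError, match="tries"):
            make_domain_layout(GRID, 20, radius_um=6.0, min_gap_um=2.0, max_tries=200)


class TestTextureField:
    def test_uniform_linear_field(self):
        mask = np.ones((GRID.ny, GRID.nx), bool)
        f = make_texture_field(TextureModel(family="linear", beta_deg=40.0), GRID, mask)
        assert np.all(f.theta_deg[f.mask] == pytest.approx(40.0))

    def test_tangential_boojum_gives_concentric_circles(self):
        # k=1, q=0, beta=90: at (1, 0) um the director is 90 deg (tangential)
        tex = TextureModel(family="boojum", centre_um=(0.0, 0.0), k=1, beta_deg=90.0)
        X = np.array([[1.0]])
        Y = np.array([[0.0]])
        assert tex.theta_deg(X, Y)[0, 0] == pytest.approx(90.0)
        # and at (0, 1) um (psi = 90) it is 180: everywhere perpendicular to r
        assert tex.theta_deg(np.array([[0.0]]), np.array([[1.0]]))[0, 0] == pytest.approx(180.0)

    def test_boojum_centre_pixel_masked(self):
        mask = np.ones((GRID.ny, GRID.nx), bool)
        tex = TextureModel(family="boojum",
                           centre_um=(0.25, 0.25), k=1, beta_deg=0.0)  # exact pixel centre
        f = make_texture_field(tex, GRID, mask)
        row, col = GRID.um_to_px((0.25, 0.25))
        assert not f.mask[int(row), int(col)]
        assert f.mask.sum() == mask.sum() - 1

    def test_spiral_iso_angle_pixels_lie_on_archimedean_curve(self):
        # brute force: pixels with theta ~= level must satisfy psi = theta - beta - q r
        beta, q = 20.0, 3.0
        tex = TextureModel(family="boojum", centre_um=(0.0, 0.0), k=1,
                           beta_deg=beta, q_deg_per_um=q)
        mask = np.ones((GRID.ny, GRID.nx), bool)
        f = make_texture_field(tex, GRID, mask)
        X, Y = GRID.coords_um()
        r = np.hypot(X, Y)
        psi = np.rad2deg(np.arctan2(Y, X))
        level = 140.0
        sel = f.mask & (np.abs((f.theta_deg - level + 180) % 360 - 180) < 1.5) & (r > 1)
        assert sel.sum() > 20
        resid = (psi[sel] - (level - beta - q * r[sel]) + 180) % 360 - 180
        assert np.max(np.abs(resid)) < 1.5 + 1e-9  # bounded by the iso-angle tolerance

    def test_wrap_to_360(self):
        tex = TextureModel(family="linear", beta_deg=350.0, g_deg_per_um=(30.0, 0.0))
        mask = np.ones((GRID.ny, GRID.nx), bool)
        f = make_texture_field(tex, GRID, mask)
        assert np.all((f.theta_deg >= 0) & (f.theta_deg < 360))


class TestChi2Series:
    def test_out_of_plane_only_scene_is_rotation_invariant(self, geometry):
        import dataclasses

        model = v.default_band_table()
        bands = tuple(dataclasses.replace(b, a_ip=0.0) for b in model.bands)
        model0 = v.SpectralModel(bands=bands, chi_nr=model.chi_nr)
        scene = texture_scene("radial-acw", seed=0, grid=GRID, radius_um=8.0)
        # rotation-symmetric geometry: use a centred domain so the maps coincide
        scene = SyntheticScene(
            grid=GRID,
            domains=(DomainSpec((0.0, 0.0), 8.0, scene.domains[0].texture),),
        )
        series = synthesize_chi2_series(scene, model0, geometry)
        for i in range(1, series.n_rotations):
            var = np.abs(series.data[i] - series.data[0])
            # compare away from the disc edge (the lab-frame lattice rotates)
            X, Y = GRID.coords_um()
            interior = np.hypot(X, Y) < 7.0
            assert var[interior].max() < 1e-12

    def test_cosine_antisymmetry_under_180_rotation(self, model):
        import dataclasses

        scene = texture_scene("spiral-cw-plus-virtual", seed=1, grid=GRID, radius_um=8.0)
        # pin the rotation axis to an exact pixel centre so that pixel sees
        # the same sample point at every rotation
        scene = dataclasses.replace(scene, rot_centre_um=(0.25, 0.25))
        geom = OpticalGeometry(rotation_angles_deg=(0.0, 180.0, 90.0, 270.0))
        series = synthesize_chi2_series(scene, model, geom)
        # at the rotation centre pixel (invariant point) the out-of-plane part
        # is even and the in-plane part flips sign between phi and phi + 180
        row, col = map(int, map(round, series.rot_centre_px))
        s0, s180 = series.data[0, row, col], series.data[1, row, col]
        even = 0.5 * (s0 + s180)
        odd = 0.5 * (s0 - s180)
        m = scene.maps(0.0)
        f_ip, f_op = geom.f_ip, geom.f_op
        # reconstruct from the closed form
        import vsfgmap.spectra as sp

        rho, s, th = m["rho"][row, col], m["s"][row, col], m["theta_deg"][row, col]
        op = sum(b.a_op * rho * f_op * lorentzian(series.wavenumber, b.omega0, b.gamma)
                 for b in model.bands)
        np.testing.assert_allclose(even, op + model.chi_nr, atol=1e-9)
        ip = sum(
            b.a_ip * rho * s * f_ip
            * np.cos(np.deg2rad(th + b.dipole_offset_deg + 0.0))
            * lorentzian(series.wavenumber, b.omega0, b.gamma)
            for b in model.bands
        )
        np.testing.assert_allclose(odd, ip, atol=1e-9)

    def test_scalar_oracle_single_pixel_single_band(self):
        # independent scalar evaluation of the closed-form forward model
        band = v.LorentzianBand("CH3 SS", 2875.0, 6.0, a_op=1.0, a_ip=0.5,
                                assignment="CH3", dipole_offset_deg=180.0)
        model = v.SpectralModel(bands=(band,), chi_nr=0.07 + 0.0j)
        theta = 25.0
        tex = TextureModel(family="linear", beta_deg=theta)
        scene = SyntheticScene(
            grid=GRID, domains=(DomainSpec((0.0, 0.0), 10.0, tex, rho=0.9, s=0.7),),
            rho_background=0.2,
        )
        geom = OpticalGeometry(rotation_angles_deg=(0.0, 60.0, 120.0, 180.0, 240.0, 300.0))
        series = synthesize_chi2_series(scene, model, geom)
        row, col = map(int, map(round, series.rot_centre_px))
        w = series.wavenumber
        f_ip, f_op = geom.f_ip, geom.f_op
        for j, phi in enumerate(geom.rotation_angles_deg):
            expected = model.chi_nr + lorentzian(w, 2875.0, 6.0) * 0.9 * (
                f_op * 1.0
                + f_ip * 0.7 * 0.5 * np.cos(np.deg2rad(theta + 180.0 + phi))
            )
            np.testing.assert_allclose(series.data[j, row, col], expected, atol=1e-12)

    def test_empty_band_table_rejected(self, geometry):
        scene = texture_scene("radial-cw", seed=0, grid=GRID, radius_um=8.0)
        with pytest.raises(ValueError, match="empty"):
            synthesize_chi2_series(scene, v.SpectralModel(bands=()), geometry)


class TestInterferograms:
    def test_zero_chi_gives_zero_traces(self):
        pulse = PulseSpec()
        w = pulse.wavenumber_grid()
        series = v.RotationSeries(np.zeros((1, 2, 2, w.size), complex),
                                  np.array([0.0]), w)
        stack = synthesize_interferograms(series, pulse)[0]
        assert np.all(stack.data == 0)

    def test_linearity_in_chi(self, model):
        pulse = PulseSpec()
        w = pulse.wavenumber_grid()
        chi = v.evaluate_model(model, w, "op")
        s1 = v.RotationSeries(np.broadcast_to(chi, (1, 2, 2, w.size)).copy(),
                              np.array([0.0]), w)
        s2 = v.RotationSeries(2 * s1.data, np.array([0.0]), w)
        t1 = synthesize_interferograms(s1, pulse)[0]
        t2 = synthesize_interferograms(s2, pulse)[0]
        np.testing.assert_allclose(t2.data, 2 * t1.data, rtol=1e-12, atol=1e-14)

    def test_envelope_gap_recorded_as_warning(self, model):
        pulse = PulseSpec(ir_fwhm_cm1=60.0)  # far too narrow for the roi
        w = PulseSpec().wavenumber_grid()
        series = v.RotationSeries(np.ones((1, 2, 2, w.size), complex),
                                  np.array([0.0]), w)
        with pytest.warns(UserWarning, match="envelope"):
            stacks = synthesize_interferograms(series, pulse)
        assert "envelope_warning" in stacks[0].meta


class TestReference:
    def test_grid_coarsening_factor(self):
        pulse = PulseSpec()
        ref = synthesize_reference(pulse.reduced(600.0), sample_pulse=pulse)
        # FFT axis arithmetic: 600 fs span vs 3300 fs -> 5.5x coarser omega grid
        from vsfgmap.preprocess import fft_wavenumber_axis

        dref = fft_wavenumber_axis(ref.delay_fs.size, 2.0)[1]
        dsam = fft_wavenumber_axis(pulse.delay_fs.size, 2.0)[1]
        assert dref / dsam == pytest.approx(3300.0 / 600.0, rel=0.01)

    def test_flat_magnitude_zero_phase_inside_envelope(self):
        pulse = PulseSpec()
        ref = synthesize_reference(pulse.reduced(600.0), sample_pulse=pulse)
        spec = v.interferogram_to_spectrum(ref, roi=(2700.0, 3100.0))
        env = pulse.envelope(spec.wavenumber)
        np.testing.assert_allclose(np.abs(spec.data[0, 0]), env, rtol=1e-9)
        np.testing.assert_allclose(np.angle(spec.data[0, 0]), 0.0, atol=1e-9)

    def test_deterministic_without_noise(self):
        pulse = PulseSpec()
        a = synthesize_reference(pulse.reduced(600.0))
        b = synthesize_reference(pulse.reduced(600.0))
        assert np.array_equal(a.data, b.data)

    def test_range_must_be_inside_sample_scan(self):
        pulse = PulseSpec()
        with pytest.raises(ValueError, match="inside"):
            synthesize_reference(PulseSpec(delay_start_fs=-400.0, delay_stop_fs=300.0),
                                 sample_pulse=pulse)


class TestNoise:
    def test_sigma_zero_is_identity(self, model, geometry):
        scene = texture_scene("radial-cw", seed=0, grid=GRID, radius_um=8.0)
        series = synthesize_chi2_series(scene, model, geometry)
        out = add_detection_noise(series, 0.0, seed=5)
        assert np.array_equal(out.data, series.data)

    def test_same_seed_reproduces(self):
        w = np.linspace(2700, 3100, 16)
        series = v.RotationSeries(np.zeros((2, 4, 4, 16), complex),
                                  np.array([0.0, 180.0]), w)
        a = add_detection_noise(series, 0.3, seed=9)
        b = add_detection_noise(series, 0.3, seed=9)
        assert np.array_equal(a.data, b.data)
        c = add_detection_noise(series, 0.3, seed=10)
        assert not np.array_equal(a.data, c.data)

    def test_empirical_sd_matches_sigma(self):
        t = np.arange(0.0, 200.0, 2.0)
        stack = v.InterferogramStack(np.zeros((50, 20, t.size)), t)
        noisy = add_detection_noise(stack, 0.7, seed=0)
        assert noisy.data.std() == pytest.approx(0.7, rel=0.02)  # 1e5 samples

    def test_negative_sigma_rejected(self):
        t = np.arange(0.0, 10.0, 2.0)
        with pytest.raises(ValueError):
            add_detection_noise(v.InterferogramStack(np.zeros((2, 2, t.size)), t), -1.0)


class TestMirror:
    def test_involution_on_scene(self):
        scene = texture_scene("spiral-acw-minus-real", seed=4)
        assert mirror_scene(mirror_scene(scene)) == scene

    def test_theta_mapping(self):
        scene = texture_scene("parallel-cw", seed=0, grid=GRID)
        f = scene.director_field()
        fm = mirror_scene(f)
        # theta = 90 maps to 270, mask rows flip
        sel = f.mask & (np.abs(f.theta_deg - 90.0) < 1e-9)
        if sel.any():
            rows, cols = np.where(sel)
            np.testing.assert_allclose(fm.theta_deg[f.theta_deg.shape[0] - 1 - rows, cols],
                                       270.0)
        assert np.array_equal(fm.mask, f.mask[::-1, :])

    def test_handedness_metadata_flips(self):
        scene = texture_scene("spiral-cw-plus-virtual", seed=0)
        assert scene.handedness == "CW"
        assert mirror_scene(scene).handedness == "ACW"

    def test_mirroring_scene_and_stacks_commute(self, model):
        # synthesize(mirror(scene)) at phi=0 equals the pixel-mirrored,
        # dipole-reflected synthesis of the original scene
        geom = OpticalGeometry(rotation_angles_deg=(0.0, 120.0, 240.0))
        scene = texture_scene("spiral-cw-plus-virtual", seed=2, grid=GRID, radius_um=8.0)
        sm = mirror_scene(scene)
        a = synthesize_chi2_series(sm, model, geom).data[0]
        m = scene.maps(0.0)
        # direct forward evaluation of the mirrored maps
        from vsfgmap.spectra import band_profiles

        profiles = band_profiles(model, PulseSpec().wavenumber_grid())
        rho = m["rho"][::-1, :]
        s = m["s"][::-1, :]
        th = np.mod(-m["theta_deg"][::-1, :], 360.0)
        f_ip, f_op = geom.f_ip, geom.f_op
        coefs = np.stack([
            b.a_op * rho * f_op
            + b.a_ip * f_ip * rho * s * np.cos(np.deg2rad(th + b.dipole_offset_deg))
            for b in model.bands
        ])
        b_direct = np.tensordot(coefs, profiles, axes=(0, 0)) + model.chi_nr
        valid = m["valid"][::-1, :]
        np.testing.assert_allclose(a[valid], b_direct[valid], atol=1e-10)
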