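"""Shared fixtures: band models, geometry, and the scene-to-director harness."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

import vsfgmap as v
from vsfgmap.preprocess import OpticalGeometry
from vsfgmap.spectra import integrate_band_magnitude


@pytest.fixture(scope="session")
def model():
    """Default band table with the non-resonant offset removed (baselined)."""
    return v.default_band_table().with_chi_nr(0)


@pytest.fixture(scope="session")
def model_nr():
    """Default band table including the non-resonant offset."""
    return v.default_band_table()


@pytest.fixture(scope="session")
def geometry():
    return OpticalGeometry()


def run_to_director(scene, model, geometry, snr=None, noise_seed=0, mode="azimuthal",
                    trust_centre=True):
    """Forward model -> alignment -> decomposition -> director field.

    The rotation centre is taken from the scene metadata (the calibrated
    rotation axis) unless ``trust_centre`` is False, in which case the
    harmonic-leakage search estimates it.
    """
    series = v.synthesize_chi2_series(scene, model, geometry)
    if snr is not None:
        sigma = v.synth.inplane_peak_amplitude(scene, model, geometry, series.wavenumber) / snr
        series = v.add_detection_noise(series, sigma, seed=noise_seed)
    aligned = v.align_rotation_series(
        series,
        centre_guess=series.rot_centre_px if trust_centre else None,
        search_radius_px=0.0 if trust_centre else 4.0,
    )
    components = v.azimuthal_decompose(aligned)
    if mode == "svd":
        decomp = v.svd_decompose(aligned, n_components=2)
    else:
        decomp = components
    director = v.extract_director(decomp, model)
    return series, aligned, components, director


def circular_rmse_deg(theta_a_deg, theta_b_deg, mask):
    """Wrap-safe root-mean-square angular deviation in degrees."""
    d = np.deg2rad(theta_a_deg - theta_b_deg)
    return float(np.rad2deg(np.sqrt(np.mean(2.0 * (1.0 - np.cos(d[mask]))))))


def interior_mask(truth_field, director, erode_px=2):
    """Domain-interior evaluation mask: boundary pixels mix LC and LE signal."""
    m = truth_field.mask & director.mask
    return binary_erosion(m, iterations=erode_px)


def segment_from_components(components, model, pixel_size_um):
    """Standard segmentation input: out-of-plane CH3 band-integrated magnitude."""
    windows = {"CH3": model.assignment_windows()["CH3"]}
    f0 = integrate_band_magnitude(components.F0, components.wavenumber, windows)["CH3"]
    return v.segment_domains(f0 * components.mask, pixel_size_um, within=components.mask)


#: expected {class, curvature, spiral sign, boojum} labels per scene preset
EXPECTED_LABELS = {
    "parallel-cw": ("parallel", "CW", "n/a", "n/a"),
    "parallel-acw": ("parallel", "ACW", "n/a", "n/a"),
    "radial-cw": ("radial", "CW", "n/a", "real"),
    "radial-acw": ("radial", "ACW", "n/a", "real"),
    "spiral-cw-plus-virtual": ("spiral", "CW", "+", "virtual"),
    "spiral-acw-minus-real": ("spiral", "ACW", "-", "real"),
}


def labels_of(fit):
    return (fit.texture_class, fit.curvature, fit.spiral_sign, fit.boojum)
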