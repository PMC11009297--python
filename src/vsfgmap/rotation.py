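"""Rotation-series analysis: registration, azimuthal decomposition, SVD, director extraction.

The central inference of phase-resolved vSFG microscopy with sample rotation:
out-of-plane responses are invariant under rotating the sample about the
surface normal, while in-plane responses are modulated as cos(d + phi) with
``d`` the sample-frame azimuth of the transition dipole.  Registering the
rotation series into the sample frame and Fourier transforming over the
azimuth therefore separates the two: the 0-fold component carries the
out-of-plane spectrum, the 1-fold component the in-plane spectrum, and the
*phase* of the 1-fold component encodes the absolute in-plane molecular
direction per pixel.

Angle conventions: degrees, counter-clockwise positive, x rightward and y
upward; sample rotation phi counter-clockwise.  Azimuthal Fourier
normalisation is F_n = (1/N) sum_j S(phi_j) e^{-i n phi_j}, so a cosine
modulation B cos(d + phi) appears as |F1| = B/2 with arg F1 = d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .preprocess import SpectralStack
from .spectra import SpectralModel, lorentzian

__all__ = [
    "RotationSeries",
    "Aligned4D",
    "AzimuthalComponents",
    "DirectorField",
    "SVDResult",
    "RegistrationError",
    "align_rotation_series",
    "azimuthal_decompose",
    "svd_decompose",
    "extract_director",
    "arrow_map",
]


@dataclass
class RotationSeries:
    """Lab-frame complex spectral images recorded at several sample rotations.

    ``data`` has shape (n_rotations, ny, nx, n_omega).  ``rot_centre_px`` is
    the (row, col) pixel position of the rotation axis, if known; the
    registration step can refine or search for it.
    """

    data: np.ndarray
    angles_deg: np.ndarray
    wavenumber: np.ndarray
    pixel_size_um: float = 1.0
    rot_centre_px: tuple[float, float] | None = None
    frame: str = "lab"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_rotations, ny, nx, n_omega)")
        if self.data.shape[0] != self.angles_deg.size:
            raise ValueError("one rotation angle per frame required")
        if self.data.shape[-1] != self.wavenumber.size:
            raise ValueError("last axis must match the wavenumber axis")

    @property
    def n_rotations(self) -> int:
        return int(self.data.shape[0])

    def stacks(self) -> list[SpectralStack]:
        return [
            SpectralStack(self.data[i], self.wavenumber, frame=self.frame,
                          rotation_deg=float(self.angles_deg[i]))
            for i in range(self.n_rotations)
        ]


@dataclass
class Aligned4D:
    """Back-rotated rotation series on a common sample-frame pixel lattice."""

    data: np.ndarray  # (n_rotations, ny, nx, n_omega), complex
    angles_deg: np.ndarray
    wavenumber: np.ndarray
    mask: np.ndarray  # (ny, nx) bool: True where every rotation contributes
    rot_centre_px: tuple[float, float]
    shifts_px: np.ndarray  # (n_rotations, 2) residual translations applied
    registration_corr: np.ndarray  # per-angle correlation with the reference frame
    pixel_size_um: float = 1.0

    @property
    def n_rotations(self) -> int:
        return int(self.data.shape[0])


@dataclass
class AzimuthalComponents:
    """0-fold and (+/-)1-fold azimuthal Fourier components per pixel.

    Convention tag ``1/N e^{-i n phi}``: F1 of B cos(d + phi) has magnitude
    B/2 and phase d.  ``confidence`` is 1 minus the fraction of azimuthal
    power outside harmonics {0, +1, -1} (noise and higher-fold content).
    """

    F0: np.ndarray  # (ny, nx, n_omega)
    F1: np.ndarray
    Fm1: np.ndarray
    mask: np.ndarray
    confidence: np.ndarray  # (ny, nx)
    wavenumber: np.ndarray
    pixel_size_um: float = 1.0
    convention: str = "1/N e^{-i n phi}"
    uniform_angles: bool = True
    #: per-pixel azimuthal residual power (mean over phi and omega of
    #: |S - harmonic model|^2); for pure detection noise this estimates the
    #: per-sample complex noise power and feeds magnitude bias corrections
    noise_power: np.ndarray | None = None


@dataclass
class DirectorField:
    """Per-pixel absolute in-plane molecular direction.

    ``theta_deg`` is the full 360-degree direction (phase-resolved detection
    removes the 180-degree ambiguity of intensity methods), wrapped to
    [0, 360).  ``magnitude`` is twice the 1-fold amplitude, i.e. the in-plane
    response amplitude; pixels with magnitude below the noise floor are
    masked rather than assigned a direction.
    """

    theta_deg: np.ndarray
    magnitude: np.ndarray
    confidence: np.ndarray
    mask: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.theta_deg = np.mod(np.asarray(self.theta_deg, dtype=float), 360.0)

    def coords_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre sample coordinates (x to the right, y upward), centred."""
        ny, nx = self.theta_deg.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_size_um
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_size_um
        return np.meshgrid(x, y)

    def mirrored(self) -> "DirectorField":
        """Reflection about the x-axis: y -> -y and theta -> 360 - theta."""
        return DirectorField(
            theta_deg=np.mod(-self.theta_deg[::-1, :], 360.0),
            magnitude=self.magnitude[::-1, :].copy(),
            confidence=self.confidence[::-1, :].copy(),
            mask=self.mask[::-1, :].copy(),
            pixel_size_um=self.pixel_size_um,
        )


@dataclass
class SVDResult:
    """Spectral SVD of the aligned 4D dataset (via real time-domain traces).

    Component spectra are unit-normalised on the roi grid with the sign fixed
    so that Im at the CH3 SS (2875 cm^-1) is positive; singular values are
    non-increasing.  ``loadings`` are the corresponding left singular vectors
    reshaped to (component, rotation, ny, nx), scaled by the singular value.
    """

    spectra: np.ndarray  # (n_retained, n_omega) complex, unit norm
    loadings: np.ndarray  # (n_retained, n_rotations, ny, nx) real
    singular_values: np.ndarray  # all singular values, non-increasing
    n_retained: int
    wavenumber: np.ndarray
    angles_deg: np.ndarray
    mask: np.ndarray
    pixel_size_um: float = 1.0


class RegistrationError(RuntimeError):
    pass


def _rotate_complex(image: np.ndarray, angle_deg: float, centre_px: tuple[float, float],
                    order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``image`` on a grid rotated by +angle about ``centre_px``.

    Returns the resampled cube (same shape) and a validity mask that is True
    where the source coordinates fell inside the original footprint.  With
    the (x right, y up = increasing row) convention, back-rotating a lab
    frame acquired at sample rotation phi means sampling it at coordinates
    rotated by +phi.
    """
    ny, nx = image.shape[:2]
    cy, cx = centre_px
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    a = np.deg2rad(angle_deg)
    dx, dy = cols - cx, rows - cy
    # rotate the sampling point by +angle in (x, y): x' = x cos - y sin, y' = x sin + y cos
    src_x = cx + dx * np.cos(a) - dy * np.sin(a)
    src_y = cy + dx * np.sin(a) + dy * np.cos(a)
    coords = np.stack([src_y.ravel(), src_x.ravel()])
    valid = (
        (src_x >= 0) & (src_x <= nx - 1) & (src_y >= 0) & (src_y <= ny - 1)
    )
    if image.ndim == 2:
        planes = [image]
    else:
        planes = [image[..., k] for k in range(image.shape[-1])]
    out_planes = []
    for p in planes:
        if np.iscomplexobj(p):
            re = ndimage.map_coordinates(p.real, coords, order=order, mode="nearest")
            im = ndimage.map_coordinates(p.imag, coords, order=order, mode="nearest")
            out_planes.append((re + 1j * im).reshape(ny, nx))
        else:
            out_planes.append(ndimage.map_coordinates(p, coords, order=order,
                                                      mode="nearest").reshape(ny, nx))
    out = out_planes[0] if image.ndim == 2 else np.stack(out_planes, axis=-1)
    return out, valid


def _magnitude_image(frame: np.ndarray) -> np.ndarray:
    """Band-integrated magnitude image of one (ny, nx, n_omega) frame."""
    return np.abs(frame).sum(axis=-1)


def _masked_corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av, bv = a[mask], b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av ** 2).sum() * (bv ** 2).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def _harmonic_residual(frames: list[np.ndarray], angles: np.ndarray,
                       centre: tuple[float, float]) -> float:
    """Fraction of azimuthal power outside harmonics {0, +1, -1}.

    Physically, a perfectly registered rotation series carries only the
    0-fold (out-of-plane) and 1-fold (in-plane) azimuthal components per
    pixel; a mis-placed rotation centre mixes neighbouring pixels and leaks
    power into higher azimuthal frequencies.  Minimising this leak is a
    sharp, model-based criterion for the rotation centre.
    """
    phi = np.deg2rad(angles - angles[0])
    rot = []
    mask = np.ones(frames[0].shape, dtype=bool)
    for i, f in enumerate(frames):
        if abs(angles[i] - angles[0]) % 360.0 < 1e-12:
            r, valid = f, np.ones(f.shape, dtype=bool)
        else:
            r, valid = _rotate_complex(f, angles[i] - angles[0], centre)
        rot.append(r)
        mask &= valid
    if mask.sum() < 16:
        return np.inf
    S = np.stack(rot)  # (nphi, ny, nx)
    n = len(frames)
    F0 = S.mean(axis=0)
    e = np.exp(-1j * phi)[:, None, None]
    F1 = (S * e).mean(axis=0)
    Fm1 = (S * np.conj(e)).mean(axis=0)
    recon = F0[None] + F1[None] * np.conj(e) + Fm1[None] * e
    num = (np.abs(S - recon) ** 2).mean(axis=0)[mask].sum()
    den = (np.abs(S) ** 2).mean(axis=0)[mask].sum()
    return float(num / den) if den > 0 else np.inf


def estimate_rotation_centre(
    series: RotationSeries,
    centre_guess: tuple[float, float],
    search_radius_px: float = 4.0,
) -> tuple[float, float]:
    """Coarse-to-fine search for the rotation centre.

    Minimises the azimuthal harmonic leakage (power outside the 0- and
    1-fold components) of the back-rotated, band-integrated complex images,
    with a Nelder-Mead sub-pixel refinement from the best grid point.
    """
    from scipy.optimize import minimize

    frames = [series.data[i].sum(axis=-1) for i in range(series.n_rotations)]
    best = tuple(map(float, centre_guess))
    if search_radius_px <= 0:
        return best
    step = max(search_radius_px / 2.0, 0.5)
    while True:
        cy0, cx0 = best
        cands = [
            (cy0 + dy, cx0 + dx)
            for dy in (-2 * step, -step, 0, step, 2 * step)
            for dx in (-2 * step, -step, 0, step, 2 * step)
        ]
        scores = [_harmonic_residual(frames, series.angles_deg, c) for c in cands]
        best = cands[int(np.argmin(scores))]
        if step <= 0.5:
            break
        step /= 2.0
    res = minimize(
        lambda p: _harmonic_residual(frames, series.angles_deg, (p[0], p[1])),
        np.array(best, dtype=float), method="Nelder-Mead",
        options={"xatol": 0.005, "fatol": 1e-12, "maxiter": 200},
    )
    if res.fun <= _harmonic_residual(frames, series.angles_deg, best):
        best = (float(res.x[0]), float(res.x[1]))
    return (float(best[0]), float(best[1]))


def align_rotation_series(
    series: RotationSeries,
    centre_guess: tuple[float, float] | None = None,
    search_radius_px: float = 4.0,
    refine_shifts: bool = True,
    min_correlation: float = 0.3,
) -> Aligned4D:
    """Back-rotate every frame into the sample frame of the first rotation.

    Each lab-frame image is rotated by -phi about the rotation centre using
    bilinear interpolation; a residual translation per angle is refined by
    phase cross-correlation of the band-integrated magnitude images.  Pixels
    outside any frame's rotated footprint are excluded from the common mask
    rather than zero-filled (zeros would bias the 0-fold component).
    """
    from skimage.registration import phase_cross_correlation

    ny, nx = series.data.shape[1:3]
    if centre_guess is None:
        centre_guess = series.rot_centre_px or ((ny - 1) / 2.0, (nx - 1) / 2.0)
    centre = estimate_rotation_centre(series, centre_guess, search_radius_px)

    ref_angle = series.angles_deg[0]
    aligned = np.empty_like(series.data)
    mask = np.ones((ny, nx), dtype=bool)
    shifts = np.zeros((series.n_rotations, 2))
    corrs = np.ones(series.n_rotations)
    ref_mag = None
    for i in range(series.n_rotations):
        rel = series.angles_deg[i] - ref_angle
        if abs(rel) % 360.0 < 1e-12:
            frame, valid = series.data[i].copy(), np.ones((ny, nx), dtype=bool)
        else:
            frame, valid = _rotate_complex(series.data[i], rel, centre)
        mag = _magnitude_image(frame)
        if i == 0:
            ref_mag = mag
        elif refine_shifts:
            win = mask & valid
            a = np.where(win, ref_mag - ref_mag[win].mean(), 0.0)
            b = np.where(win, mag - mag[win].mean(), 0.0)
            shift, *_ = phase_cross_correlation(a, b, upsample_factor=50, normalization=None)
            if np.any(np.abs(shift) > 2.0):
                shift = np.zeros(2)  # implausible for a rotation stage; leave to the QC corr
            if np.any(np.abs(shift) > 0.05):
                shifted = np.stack(
                    [
                        ndimage.shift(frame[..., k].real, shift, order=1, cval=0.0)
                        + 1j * ndimage.shift(frame[..., k].imag, shift, order=1, cval=0.0)
                        for k in range(frame.shape[-1])
                    ],
                    axis=-1,
                )
                valid_s = ndimage.shift(valid.astype(float), shift, order=0, cval=0.0) > 0.5
                mag_s = _magnitude_image(shifted)
                # keep the shift only if it removes a meaningful part of the
                # decorrelation; marginal gains are interpolation artefacts
                c_old = _masked_corr(ref_mag, mag, mask & valid)
                c_new = _masked_corr(ref_mag, mag_s, mask & valid_s)
                if (1.0 - c_new) < 0.9 * (1.0 - c_old):
                    frame, valid, mag = shifted, valid_s, mag_s
                else:
                    shift = np.zeros(2)
            shifts[i] = shift
        if i > 0:
            corrs[i] = _masked_corr(ref_mag, mag, mask & valid)
        aligned[i] = frame
        mask &= valid
    low = np.where(corrs < min_correlation)[0]
    if low.size:
        bad = ", ".join(f"{series.angles_deg[j]:.0f} deg (r={corrs[j]:.2f})" for j in low)
        raise RegistrationError(f"registration correlation below {min_correlation}: {bad}")
    return Aligned4D(
        data=aligned,
        angles_deg=series.angles_deg.copy(),
        wavenumber=series.wavenumber.copy(),
        mask=mask,
        rot_centre_px=centre,
        shifts_px=shifts,
        registration_corr=corrs,
        pixel_size_um=series.pixel_size_um,
    )


def _angles_uniform(angles_deg: np.ndarray) -> bool:
    ang = np.sort(np.mod(angles_deg, 360.0))
    n = ang.size
    step = 360.0 / n
    return bool(np.allclose(np.diff(np.concatenate([ang, [ang[0] + 360.0]])), step, atol=1e-9))


def azimuthal_decompose(aligned: Aligned4D) -> AzimuthalComponents:
    """Azimuthal Fourier components F_n = (1/N) sum_j S(phi_j) e^{-i n phi_j}.

    For uniformly distributed angles this is the DFT over the rotation axis;
    otherwise a per-pixel least-squares fit of the harmonic model
    S(phi) = F0 + F1 e^{i phi} + F_{-1} e^{-i phi} is used and flagged.
    Under the forward model F0 is the out-of-plane spectrum and
    F1 = (a_ip s rho f_ip / 2) L(omega) e^{i d} per band.
    """
    phi = np.deg2rad(aligned.angles_deg)
    S = aligned.data  # (nphi, ny, nx, nw)
    n = phi.size
    uniform = _angles_uniform(aligned.angles_deg)
    if uniform:
        e0 = np.ones(n)
        em = np.exp(-1j * phi)
        F0 = np.tensordot(e0, S, axes=(0, 0)) / n
        F1 = np.tensordot(em, S, axes=(0, 0)) / n
        Fm1 = np.tensordot(np.conj(em), S, axes=(0, 0)) / n
    else:
        A = np.stack([np.ones(n), np.exp(1j * phi), np.exp(-1j * phi)], axis=1)
        nphi, ny, nx, nw = S.shape
        coef, *_ = np.linalg.lstsq(A, S.reshape(nphi, ny * nx * nw), rcond=None)
        F0 = coef[0].reshape(ny, nx, nw)
        F1 = coef[1].reshape(ny, nx, nw)
        Fm1 = coef[2].reshape(ny, nx, nw)
    # residual azimuthal power outside {0, +1, -1}
    model = (
        F0[None, ...]
        + F1[None, ...] * np.exp(1j * phi)[:, None, None, None]
        + Fm1[None, ...] * np.exp(-1j * phi)[:, None, None, None]
    )
    resid_power = np.mean(np.abs(S - model) ** 2, axis=(0, 3))
    total_power = np.mean(np.abs(S) ** 2, axis=(0, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        confidence = np.where(total_power > 0, 1.0 - resid_power / total_power, 0.0)
    return AzimuthalComponents(
        F0=F0, F1=F1, Fm1=Fm1,
        mask=aligned.mask.copy(),
        confidence=np.clip(confidence, 0.0, 1.0),
        wavenumber=aligned.wavenumber.copy(),
        pixel_size_um=aligned.pixel_size_um,
        uniform_angles=uniform,
        noise_power=resid_power,
    )


def svd_decompose(
    aligned: Aligned4D,
    roi: tuple[float, float] | None = None,
    n_components: int | None = None,
    rel_threshold: float = 0.05,
    ch3_ss_cm1: float = 2875.0,
) -> SVDResult:
    """SVD grouping of related spectral contributions via real time traces.

    The spectra are truncated to ``roi``, inverse Fourier transformed with
    Hermitian completion to real time-domain traces, and the matrix
    (pixels x rotations) by (time) is decomposed.  Retained right singular
    vectors are transformed back to the frequency domain; each component's
    sign is fixed so its Im part at the CH3 SS is positive.  ``n_components``
    defaults to the number of singular values above ``rel_threshold`` of the
    largest (two for an ideal two-chromophore monolayer).
    """
    w = aligned.wavenumber
    if roi is not None:
        sel = (w >= roi[0]) & (w <= roi[1])
        if not np.any(sel):
            raise ValueError(f"roi {roi} outside the wavenumber axis")
    else:
        sel = np.ones(w.shape, dtype=bool)
    w = w[sel]
    cube = aligned.data[..., sel]  # (nphi, ny, nx, K)
    cube = cube * aligned.mask[None, :, :, None]  # off-mask pixels carry no weight
    nphi, ny, nx, K = cube.shape
    m = 1
    while m < 2 * (K + 2):
        m *= 2
    if m < nphi:  # degenerate guard; never hit in practice
        raise ValueError("fewer time points than rotations")
    spec_full = np.zeros(cube.shape[:-1] + (m // 2 + 1,), dtype=complex)
    spec_full[..., 1:K + 1] = cube  # keep bin 0 empty so completion is exact
    traces = np.fft.irfft(spec_full, n=m, axis=-1)  # real, (nphi, ny, nx, m)
    X = np.moveaxis(traces, 0, 2).reshape(ny * nx * nphi, m)
    if m < 2:
        raise ValueError("fewer time points than requested components")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if n_components is None:
        n_components = max(int(np.sum(s > rel_threshold * s[0])), 1)
        n_components = min(n_components, s.size)
    elif n_components > s.size:
        raise ValueError(
            f"requested {n_components} components but only {s.size} time points available"
        )
    spectra = []
    loadings = []
    for i in range(n_components):
        comp = np.fft.rfft(Vt[i], n=m)[1:K + 1]
        norm = np.linalg.norm(comp)
        if norm == 0:
            norm = 1.0
        comp = comp / norm
        load = (s[i] * norm) * U[:, i].reshape(ny, nx, nphi)
        j_ss = int(np.argmin(np.abs(w - ch3_ss_cm1)))
        if comp[j_ss].imag < 0:
            comp, load = -comp, -load
        spectra.append(comp)
        loadings.append(np.moveaxis(load, 2, 0))  # (nphi, ny, nx)
    return SVDResult(
        spectra=np.stack(spectra),
        loadings=np.stack(loadings),
        singular_values=s.copy(),
        n_retained=n_components,
        wavenumber=w,
        angles_deg=aligned.angles_deg.copy(),
        mask=aligned.mask.copy(),
        pixel_size_um=aligned.pixel_size_um,
    )


def _inplane_template(model: SpectralModel, omega: np.ndarray) -> np.ndarray:
    """Complex in-plane spectral template sum_m a_ip,m L_m(w) e^{i off_m}.

    The per-band dipole offsets implement the molecular-direction convention:
    the CH3 SS in-plane dipole points exactly opposite the defined molecular
    axis, so projecting the 1-fold spectrum onto this template returns the
    molecular direction itself (no residual 180-degree correction).
    """
    t = np.zeros(omega.shape, dtype=complex)
    for b in model.bands:
        t += b.a_ip * lorentzian(omega, b.omega0, b.gamma) * np.exp(1j * np.deg2rad(b.dipole_offset_deg))
    return t


def _outofplane_template(model: SpectralModel, omega: np.ndarray) -> np.ndarray:
    t = np.zeros(omega.shape, dtype=complex)
    for b in model.bands:
        t += b.a_op * lorentzian(omega, b.omega0, b.gamma)
    return t


def _f1_from_svd(result: SVDResult) -> tuple[np.ndarray, np.ndarray]:
    """Rank-truncated reconstruction -> azimuthal F1(omega) and residual power.

    Raw SVD components can mix the physical in-plane/out-of-plane spectra
    (the right singular vectors orthogonalise them), so the 1-fold analysis
    runs on the denoised reconstruction, where the mixing cancels exactly.
    """
    phi = np.deg2rad(result.angles_deg)
    n = phi.size
    recon = np.einsum("cw,cpyx->pyxw", result.spectra, result.loadings)
    em = np.exp(-1j * phi)
    F1 = np.tensordot(em, recon, axes=(0, 0)) / n
    F0 = np.tensordot(np.ones(n), recon, axes=(0, 0)) / n
    Fm1 = np.tensordot(np.conj(em), recon, axes=(0, 0)) / n
    model = (
        F0[None] + F1[None] * np.exp(1j * phi)[:, None, None, None]
        + Fm1[None] * np.exp(-1j * phi)[:, None, None, None]
    )
    resid = np.mean(np.abs(recon - model) ** 2, axis=(0, 3))
    total = np.mean(np.abs(recon) ** 2, axis=(0, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = np.where(total > 0, 1.0 - resid / total, 0.0)
    return F1, np.clip(conf, 0.0, 1.0)


def extract_director(
    components: "AzimuthalComponents | SVDResult",
    model: SpectralModel,
    mode: str = "auto",
    min_magnitude_rel: float = 0.1,
) -> DirectorField:
    """Absolute in-plane director map from the 1-fold azimuthal component.

    The complex 1-fold spectrum F1(omega) of each pixel is projected onto the
    in-plane band template (all in-plane bands with their signed amplitudes
    and dipole-offset phases, ``mode='template'``) or onto the CH3 SS band
    alone (``mode='band'``, the cross-check mode).  The projection phase is
    the molecular direction theta; the magnitude is twice the 1-fold
    amplitude, i.e. the full in-plane response amplitude.  Pixels whose
    magnitude falls below ``min_magnitude_rel`` of the in-mask 99th
    percentile are masked, not guessed.
    """
    if isinstance(components, SVDResult):
        F1, confidence = _f1_from_svd(components)
        omega = components.wavenumber
        mask = components.mask
        px = components.pixel_size_um
    else:
        F1 = components.F1
        confidence = components.confidence
        omega = components.wavenumber
        mask = components.mask
        px = components.pixel_size_um

    if mode == "auto":
        mode = "template"
    if mode == "template":
        t = _inplane_template(model, omega)
        denom = np.vdot(t, t).real
        if denom == 0:
            raise ValueError("in-plane template is identically zero; no in-plane amplitudes set")
        A = np.tensordot(F1, np.conj(t), axes=(2, 0)) / denom
    elif mode == "band":
        # per-band unmixing: solve F1(w) = sum_m c_m a_m L_m(w) e^{i off_m}
        # and keep the CH3 SS coefficient; plain projection onto one band
        # would be phase-biased by the complex overlap of neighbouring
        # Lorentzians
        names = [b.name for b in model.bands]
        if "CH3 SS" not in names:
            raise ValueError("CH3 SS band not found in the model")
        cols = [
            b.a_ip * lorentzian(omega, b.omega0, b.gamma)
            * np.exp(1j * np.deg2rad(b.dipole_offset_deg))
            for b in model.bands
            if b.a_ip != 0
        ]
        active = [b.name for b in model.bands if b.a_ip != 0]
        if "CH3 SS" not in active:
            raise ValueError("CH3 SS band has zero in-plane amplitude")
        M = np.stack(cols, axis=1)  # (nw, nbands_active)
        sol, *_ = np.linalg.lstsq(M, F1.reshape(-1, omega.size).T, rcond=None)
        A = sol[active.index("CH3 SS")].reshape(F1.shape[:2])
    else:
        raise ValueError("mode must be 'auto', 'template' or 'band'")
    theta = np.rad2deg(np.angle(A))
    magnitude = 2.0 * np.abs(A)
    inm = magnitude[mask]
    floor = min_magnitude_rel * (np.percentile(inm, 99) if inm.size else 0.0)
    good = mask & (magnitude >= floor)
    return DirectorField(
        theta_deg=np.where(good, theta, 0.0),
        magnitude=magnitude,
        confidence=confidence,
        mask=good,
        pixel_size_um=px,
    )


def arrow_map(field: DirectorField, block: int = 6, min_resultant: float = 0.3):
    """Block-averaged phase arrows (the 6x6-pixel averaging of the maps).

    Each block's arrow is the magnitude-weighted circular mean direction;
    blocks whose resultant length (|sum m e^{i theta}| / sum m) falls below
    ``min_resultant`` — e.g. equal-magnitude opposite directions cancelling —
    are omitted.  Returns a DataFrame with columns x_um, y_um, theta_deg,
    magnitude.
    """
    import pandas as pd

    if block < 1:
        raise ValueError("block must be >= 1")
    ny, nx = field.theta_deg.shape
    z = field.magnitude * np.exp(1j * np.deg2rad(field.theta_deg))
    rows = []
    for iy in range(0, ny - block + 1, block):
        for ix in range(0, nx - block + 1, block):
            m = field.mask[iy:iy + block, ix:ix + block]
            if not np.any(m):
                continue
            zb = z[iy:iy + block, ix:ix + block][m]
            wsum = field.magnitude[iy:iy + block, ix:ix + block][m].sum()
            if wsum <= 0:
                continue
            resultant = np.abs(zb.sum()) / wsum
            if resultant < min_resultant:
                continue
            cx = (ix + (block - 1) / 2.0 - (nx - 1) / 2.0) * field.pixel_size_um
            cy = (iy + (block - 1) / 2.0 - (ny - 1) / 2.0) * field.pixel_size_um
            rows.append(
                {
                    "x_um": cx,
                    "y_um": cy,
                    "theta_deg": float(np.mod(np.rad2deg(np.angle(zb.sum())), 360.0)),
                    "magnitude": float(np.abs(zb.sum()) / m.sum()),
                }
            )
    return pd.DataFrame(rows, columns=["x_um", "y_um", "theta_deg", "magnitude"])
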