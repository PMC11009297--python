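"""Physics-based forward model and ground-truth scene generator.

Builds scenes of condensed (LC) lipid domains — circular islands of roughly
10 um diameter carrying curved, co-directional in-plane director textures —
and synthesizes everything the analysis pipeline consumes: lab-frame complex
chi2 image stacks over a rotation series, heterodyne interferograms with a
local oscillator, and the reduced-resolution quartz reference.

Textures are parametrised as
    boojum family:  theta(r, psi) = k * psi + beta + q * r
    linear family:  theta(x, y)   = beta + g . (x, y)
with psi the azimuth about the texture centre, winding number k in {0, +-1},
offset beta (deg), pitch q (deg/um) and gradient g (deg/um).  k=1, q=0 gives
radial contours (concentric circles of lipids), k=1, q!=0 gives spirals with
the sign of q setting the (+)/(-) spiralling direction, and the linear family
gives parallel contours.

Per pixel p, band m and sample rotation phi the emitted susceptibility is

    chi(w; p, phi) = chi_NR
      + sum_m L_m(w) * rho(p) * [ f_op a_op,m + f_ip s(p) a_ip,m cos(d_m(p) + phi) ]

with L_m the complex Lorentzian, rho the relative molecular density, s the
in-plane orientational order, f_ip/f_op the P-field projections, and d_m the
sample-frame azimuth of band m's in-plane transition dipole (theta + 180 deg
for the CH3 bands, whose SS dipole points exactly opposite the defined
molecular direction).  Images are emitted in the lab frame, i.e. rotated by
+phi about the rotation centre, so the pipeline must back-rotate.

Coordinates: x rightward, y upward, degrees counter-clockwise from +x,
0-based pixels with centres on integer indices, sample coordinates centred
on the grid.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .preprocess import (
    C_CM_PER_FS,
    InterferogramStack,
    OpticalGeometry,
    SpectralStack,
    fft_wavenumber_axis,
)
from .rotation import DirectorField, RotationSeries
from .spectra import SpectralModel, band_profiles, default_band_table

__all__ = [
    "GridSpec",
    "TextureModel",
    "DomainSpec",
    "SyntheticScene",
    "PulseSpec",
    "PlacementError",
    "make_domain_layout",
    "make_texture_field",
    "synthesize_chi2_series",
    "synthesize_interferograms",
    "synthesize_reference",
    "add_detection_noise",
    "mirror_scene",
    "inplane_peak_amplitude",
    "texture_scene",
    "demo_scene",
    "TEXTURE_KINDS",
]


@dataclass(frozen=True)
class GridSpec:
    """Image lattice: pixel counts and physical pixel size."""

    nx: int = 128
    ny: int = 128
    pixel_size_um: float = 0.5
    origin: str = "center"  # sample (0,0) at the grid centre

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError("grid must be at least 16x16 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.origin != "center":
            raise ValueError("only the centred origin convention is supported")

    def coords_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of pixel-centre sample coordinates in um."""
        x = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pixel_size_um
        y = (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.pixel_size_um
        return np.meshgrid(x, y)

    def um_to_px(self, xy_um: tuple[float, float]) -> tuple[float, float]:
        """Sample coordinates (x, y) in um -> pixel (row, col)."""
        x, y = xy_um
        return (
            y / self.pixel_size_um + (self.ny - 1) / 2.0,
            x / self.pixel_size_um + (self.nx - 1) / 2.0,
        )


@dataclass(frozen=True)
class TextureModel:
    """Parametric in-plane director texture of one domain."""

    family: str  # "boojum" | "linear"
    centre_um: tuple[float, float] = (0.0, 0.0)  # boojum centre (sample coords)
    k: int = 1  # winding number, {0, +-1}
    beta_deg: float = 0.0  # angular offset / base angle
    q_deg_per_um: float = 0.0  # spiral pitch (boojum family)
    g_deg_per_um: tuple[float, float] = (0.0, 0.0)  # gradient (linear family)

    def __post_init__(self) -> None:
        if self.family not in ("boojum", "linear"):
            raise ValueError(f"unknown texture family {self.family!r}")
        if self.k not in (-1, 0, 1):
            raise ValueError("winding number k must be in {0, +1, -1}")

    def theta_deg(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Director angle at sample coordinates, wrapped to [0, 360).

        At the exact boojum centre the azimuth is undefined; the returned
        value there is NaN and callers must mask it.
        """
        if self.family == "linear":
            gx, gy = self.g_deg_per_um
            th = self.beta_deg + gx * x_um + gy * y_um
            return np.mod(th, 360.0)
        cx, cy = self.centre_um
        dx, dy = x_um - cx, y_um - cy
        r = np.hypot(dx, dy)
        psi = np.rad2deg(np.arctan2(dy, dx))
        th = self.k * psi + self.beta_deg + self.q_deg_per_um * r
        th = np.mod(th, 360.0)
        return np.where(r > 0, th, np.nan)

    def mirrored(self) -> "TextureModel":
        """Reflect about the x-axis (theta -> -theta, y -> -y)."""
        cx, cy = self.centre_um
        gx, gy = self.g_deg_per_um
        return replace(
            self,
            centre_um=(cx, -cy),
            k=self.k,  # theta' = k psi' - beta - q r keeps the winding number
            beta_deg=-self.beta_deg,
            q_deg_per_um=-self.q_deg_per_um,
            g_deg_per_um=(-gx, gy),
        )


@dataclass(frozen=True)
class DomainSpec:
    """One circular LC domain: geometry, texture and composition."""

    centre_um: tuple[float, float]
    radius_um: float
    texture: TextureModel
    rho: float = 1.0  # relative molecular density inside
    s: float = 0.8  # in-plane orientational order inside, in [0, 1]

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be > 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("order parameter s must be in [0, 1]")


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth scene: grid, domains with textures, density and order maps.

    The surrounding liquid-expanded phase carries density ``rho_background``
    (it contributes out-of-plane signal: phase separation is incomplete) but
    no in-plane order (s = 0).  ``handedness`` is metadata recording the
    packing-curvature sense the scene was built with; mirroring flips it.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    domains: tuple[DomainSpec, ...] = ()
    rho_background: float = 0.35
    rot_centre_um: tuple[float, float] = (0.0, 0.0)
    #: width (um) of the Gaussian optical edge response at the domain
    #: boundary (PSF-blurred disc, sigma = edge_softness_um / 2).  The
    #: default matches a PSF sigma of one 0.5-um pixel, i.e. an edge the
    #: pixel lattice can actually sample; ground-truth labels stay hard.
    edge_softness_um: float = 1.0
    handedness: str = "CW"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho_background < 0:
            raise ValueError("rho_background must be >= 0")
        if self.edge_softness_um < 0:
            raise ValueError("edge_softness_um must be >= 0")

    # -- map evaluation ------------------------------------------------
    def _sample_coords(self, phi_deg: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample-frame coordinates seen by each lab pixel at rotation phi."""
        X, Y = self.grid.coords_um()
        if phi_deg % 360.0 == 0.0:
            return X, Y
        a = np.deg2rad(-phi_deg)  # lab -> sample is the inverse rotation
        cx, cy = self.rot_centre_um
        dx, dy = X - cx, Y - cy
        xs = cx + dx * np.cos(a) - dy * np.sin(a)
        ys = cy + dx * np.sin(a) + dy * np.cos(a)
        return xs, ys

    def maps(self, phi_deg: float = 0.0) -> dict[str, np.ndarray]:
        """Evaluate labels, rho, s and theta analytically at rotation phi.

        Returned maps live on the lab-frame pixel lattice; ``theta_deg`` is
        the sample-frame director (the +phi lab rotation of the dipole is
        applied by the spectral forward model, not here).
        """
        xs, ys = self._sample_coords(phi_deg)
        labels = np.zeros(xs.shape, dtype=int)
        rho = np.full(xs.shape, self.rho_background, dtype=float)
        s = np.zeros(xs.shape, dtype=float)
        theta = np.zeros(xs.shape, dtype=float)
        valid = np.ones(xs.shape, dtype=bool)
        h = self.edge_softness_um
        for i, d in enumerate(self.domains, start=1):
            dist = np.hypot(xs - d.centre_um[0], ys - d.centre_um[1])
            labels[dist <= d.radius_um] = i
            if h > 0:  # Gaussian (erf) optical edge response across the boundary
                from scipy.special import erfc

                w = 0.5 * erfc((dist - d.radius_um) / (h / 2.0 * np.sqrt(2.0)))
            else:
                w = (dist <= d.radius_um).astype(float)
            sel = w > 1e-6
            th = d.texture.theta_deg(xs, ys)
            bad = sel & ~np.isfinite(th)
            good = sel & np.isfinite(th)
            rho[good] += (d.rho - self.rho_background) * w[good]
            s[good] += d.s * w[good]
            theta[good] = th[good]
            valid &= ~bad
        return {"labels": labels, "rho": rho, "s": s, "theta_deg": theta, "valid": valid}

    def director_field(self, phi_deg: float = 0.0) -> DirectorField:
        """Ground-truth director field (unit magnitude inside domains)."""
        m = self.maps(phi_deg)
        mask = (m["labels"] > 0) & m["valid"]
        return DirectorField(
            theta_deg=np.where(mask, m["theta_deg"], 0.0),
            magnitude=mask.astype(float),
            confidence=mask.astype(float),
            mask=mask,
            pixel_size_um=self.grid.pixel_size_um,
        )

    def label_image(self) -> np.ndarray:
        return self.maps(0.0)["labels"]

    def coverage(self) -> float:
        lab = self.label_image()
        return float((lab > 0).mean())


@dataclass(frozen=True)
class PulseSpec:
    """IR pulse envelope, delay scan and local oscillator of the instrument.

    The delay axis defaults to the acquisition protocol: 2 fs steps from
    -300 fs to 3000 fs, giving ~10 cm^-1 spectral resolution; the quartz
    reference uses the reduced -300..300 fs span.
    """

    ir_centre_cm1: float = 2900.0
    ir_fwhm_cm1: float = 400.0
    delay_start_fs: float = -300.0
    delay_stop_fs: float = 3000.0
    delay_step_fs: float = 2.0
    lo_amplitude: float = 1.0
    lo_phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.delay_step_fs <= 0:
            raise ValueError("delay_step_fs must be > 0")
        if self.delay_stop_fs <= self.delay_start_fs:
            raise ValueError("delay range is empty")
        if self.ir_fwhm_cm1 <= 0:
            raise ValueError("ir_fwhm_cm1 must be > 0")

    @property
    def delay_fs(self) -> np.ndarray:
        n = int(round((self.delay_stop_fs - self.delay_start_fs) / self.delay_step_fs)) + 1
        return self.delay_start_fs + self.delay_step_fs * np.arange(n)

    @property
    def lo(self) -> complex:
        return self.lo_amplitude * np.exp(1j * np.deg2rad(self.lo_phase_deg))

    def envelope(self, omega_cm1: np.ndarray) -> np.ndarray:
        """Gaussian IR amplitude envelope, unit peak, FWHM in cm^-1."""
        w = np.asarray(omega_cm1, dtype=float)
        return np.exp(-4.0 * np.log(2.0) * ((w - self.ir_centre_cm1) / self.ir_fwhm_cm1) ** 2)

    def wavenumber_grid(self, roi: tuple[float, float] = (2700.0, 3100.0)) -> np.ndarray:
        """FFT-conjugate wavenumber samples of the delay axis inside ``roi``.

        Synthesizing chi2 on this grid makes the interferogram round trip
        (synthesis -> FFT) exact up to floating point.
        """
        omega = fft_wavenumber_axis(self.delay_fs.size, self.delay_step_fs)
        sel = (omega >= roi[0]) & (omega <= roi[1])
        if not np.any(sel):
            raise ValueError(f"roi {roi} contains no conjugate-grid samples")
        return omega[sel]

    def reduced(self, span_fs: float = 600.0) -> "PulseSpec":
        """Reference scan: same pulse, symmetric reduced delay range."""
        return replace(self, delay_start_fs=-span_fs / 2.0, delay_stop_fs=span_fs / 2.0)


# ---------------------------------------------------------------------------
# scene construction


def make_domain_layout(
    grid: GridSpec,
    n_domains: int,
    radius_um: float = 5.0,
    min_gap_um: float = 2.0,
    seed: int = 0,
    max_tries: int = 5000,
    field_radius_um: float | None = None,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Place non-overlapping circular domains; returns (labels, centres).

    Discs of ``radius_um`` (default 5 um: domain diameters of ca. 10 um) are
    placed uniformly at random with pairwise edge gaps of at least
    ``min_gap_um`` and a margin to the field edge.  With ``field_radius_um``
    the discs are confined to a central circle — the surface region common
    to all sample rotations.  Placement is deterministic per seed; an
    impossible request raises :class:`PlacementError` naming the parameters.
    """
    half_x = (grid.nx - 1) / 2.0 * grid.pixel_size_um
    half_y = (grid.ny - 1) / 2.0 * grid.pixel_size_um
    margin = radius_um + grid.pixel_size_um
    if n_domains > 0 and (margin > half_x or margin > half_y):
        raise PlacementError(
            f"radius {radius_um} um does not fit a {2*half_x:.1f} x {2*half_y:.1f} um field"
        )
    if field_radius_um is not None and n_domains > 0 and margin > field_radius_um:
        raise PlacementError(
            f"radius {radius_um} um does not fit a field circle of {field_radius_um} um"
        )
    rng = np.random.default_rng(seed)
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < n_domains:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_domains} discs of radius {radius_um} um with "
                f"min gap {min_gap_um} um in {2*half_x:.1f} x {2*half_y:.1f} um "
                f"after {max_tries} tries (placed {len(centres)})"
            )
        tries += 1
        cx = rng.uniform(-half_x + margin, half_x - margin)
        cy = rng.uniform(-half_y + margin, half_y - margin)
        if field_radius_um is not None and np.hypot(cx, cy) > field_radius_um - margin:
            continue
        if all(np.hypot(cx - ox, cy - oy) >= 2 * radius_um + min_gap_um for ox, oy in centres):
            centres.append((float(cx), float(cy)))
    X, Y = grid.coords_um()
    labels = np.zeros((grid.ny, grid.nx), dtype=int)
    for i, (cx, cy) in enumerate(centres, start=1):
        labels[np.hypot(X - cx, Y - cy) <= radius_um] = i
    return labels, centres


def make_texture_field(texture: TextureModel, grid: GridSpec, mask: np.ndarray) -> DirectorField:
    """Rasterize a texture on a grid: theta per pixel inside ``mask``.

    The exact boojum-centre pixel (undefined azimuth) is masked out.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.ny, grid.nx):
        raise ValueError("mask shape must match the grid")
    X, Y = grid.coords_um()
    th = texture.theta_deg(X, Y)
    good = mask & np.isfinite(th)
    return DirectorField(
        theta_deg=np.where(good, th, 0.0),
        magnitude=good.astype(float),
        confidence=good.astype(float),
        mask=good,
        pixel_size_um=grid.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# spectral synthesis


def synthesize_chi2_series(
    scene: SyntheticScene,
    model: SpectralModel | None = None,
    geometry: OpticalGeometry | None = None,
    wavenumber: np.ndarray | None = None,
) -> RotationSeries:
    """Emit the lab-frame complex chi2 rotation series of a scene.

    ``wavenumber`` defaults to the FFT-conjugate grid of the default delay
    scan inside 2700-3100 cm^-1, so the interferogram stage can round-trip
    exactly.  See the module docstring for the per-pixel forward model.
    """
    model = model if model is not None else default_band_table()
    geometry = geometry if geometry is not None else OpticalGeometry()
    if len(model.bands) == 0:
        raise ValueError("band table is empty")
    if wavenumber is None:
        wavenumber = PulseSpec().wavenumber_grid()
    wavenumber = np.asarray(wavenumber, dtype=float)
    profiles = band_profiles(model, wavenumber)  # (nbands, nw)
    a_op = model.amplitudes("op")
    a_ip = model.amplitudes("ip")
    offsets = np.array([b.dipole_offset_deg for b in model.bands])
    f_ip, f_op = geometry.f_ip, geometry.f_op
    angles = np.asarray(geometry.rotation_angles_deg, dtype=float)
    ny, nx = scene.grid.ny, scene.grid.nx
    out = np.empty((angles.size, ny, nx, wavenumber.size), dtype=complex)
    for j, phi in enumerate(angles):
        m = scene.maps(phi)
        rho, s, theta = m["rho"], m["s"], m["theta_deg"]
        op_coef = rho * f_op  # shared by all bands up to a_op
        coefs = np.empty((len(model.bands), ny, nx))
        for i in range(len(model.bands)):
            d = theta + offsets[i]
            coefs[i] = a_op[i] * op_coef + a_ip[i] * f_ip * rho * s * np.cos(
                np.deg2rad(d + phi)
            )
        out[j] = np.tensordot(coefs, profiles, axes=(0, 0)) + model.chi_nr
        out[j][~m["valid"]] = model.chi_nr  # undefined-texture pixels carry no resonance
    return RotationSeries(
        data=out,
        angles_deg=angles,
        wavenumber=wavenumber,
        pixel_size_um=scene.grid.pixel_size_um,
        rot_centre_px=scene.grid.um_to_px(scene.rot_centre_um),
        frame="lab",
        meta={"scene_seed": scene.seed, "f_ip": f_ip, "f_op": f_op},
    )


def inplane_peak_amplitude(
    scene: SyntheticScene,
    model: SpectralModel | None = None,
    geometry: OpticalGeometry | None = None,
    wavenumber: np.ndarray | None = None,
) -> float:
    """Peak in-plane spectral amplitude of the scene (noise-level reference).

    The maximum over the roi of |sum_m a_ip,m L_m(w)| times the largest
    rho*s in the scene and f_ip: the amplitude of the in-plane response at
    perfect dipole alignment.  Detection noise for an "amplitude SNR" of x
    is sigma = inplane_peak_amplitude / x per real/imaginary sample.
    """
    model = model if model is not None else default_band_table()
    geometry = geometry if geometry is not None else OpticalGeometry()
    if wavenumber is None:
        wavenumber = PulseSpec().wavenumber_grid()
    profiles = band_profiles(model, wavenumber)
    spec_ip = model.amplitudes("ip") @ profiles
    top = max((d.rho * d.s for d in scene.domains), default=0.0)
    return float(top * geometry.f_ip * np.max(np.abs(spec_ip)))


# ---------------------------------------------------------------------------
# interferogram synthesis


def synthesize_interferograms(
    series: RotationSeries,
    pulse: PulseSpec | None = None,
    band_range_cm1: tuple[float, float] | None = None,
) -> list[InterferogramStack]:
    """Heterodyne time-domain traces of every rotation frame.

    Per pixel the real trace is the heterodyne cross-term

        I(t) = Re[ sum_w chi(w) G(w) LO* e^{-i 2 pi c w t} ]

    with G the Gaussian IR envelope (homodyne |chi|^2 terms are removed by
    the balanced detection and are not modelled).  If the series' wavenumber
    grid matches the FFT-conjugate grid of the delay axis, the preprocessing
    FFT recovers chi * G * LO* exactly.
    """
    pulse = pulse if pulse is not None else PulseSpec()
    t = pulse.delay_fs
    w = series.wavenumber
    env = pulse.envelope(w)
    meta_warn = None
    check = band_range_cm1 if band_range_cm1 is not None else (w[0], w[-1])
    edge = pulse.envelope(np.asarray(check))
    if np.min(edge) < 0.05:
        meta_warn = (
            f"IR envelope (centre {pulse.ir_centre_cm1}, FWHM {pulse.ir_fwhm_cm1} cm^-1) "
            f"drops below 5% inside the band range {check}"
        )
        warnings.warn(meta_warn)
    lo_conj = np.conj(pulse.lo)
    nu = w * C_CM_PER_FS  # cycles/fs
    kernel = np.exp(-2j * np.pi * np.outer(nu, t))  # (nw, nt)
    stacks = []
    for i in range(series.n_rotations):
        c = series.data[i] * env * lo_conj  # (ny, nx, nw)
        trace = np.real(c.reshape(-1, w.size) @ kernel).reshape(c.shape[:2] + (t.size,))
        meta: dict[str, Any] = {"pulse": pulse, **series.meta}
        if meta_warn:
            meta["envelope_warning"] = meta_warn
        stacks.append(
            InterferogramStack(
                data=trace,
                delay_fs=t.copy(),
                rotation_deg=float(series.angles_deg[i]),
                meta=meta,
            )
        )
    return stacks


def synthesize_reference(
    pulse_reduced: PulseSpec,
    chi_quartz: float = 1.0,
    shape: tuple[int, int] = (4, 4),
    sample_pulse: PulseSpec | None = None,
) -> InterferogramStack:
    """Quartz reference: spatially uniform, spectrally flat real chi.

    Recorded at reduced frequency resolution (shorter delay span); the
    reduced range must lie strictly inside the sample scan range when a
    ``sample_pulse`` is given for validation.
    """
    if sample_pulse is not None:
        if not (
            pulse_reduced.delay_start_fs >= sample_pulse.delay_start_fs
            and pulse_reduced.delay_stop_fs <= sample_pulse.delay_stop_fs
            and (pulse_reduced.delay_stop_fs - pulse_reduced.delay_start_fs)
            < (sample_pulse.delay_stop_fs - sample_pulse.delay_start_fs)
        ):
            raise ValueError("reference delay range must lie strictly inside the sample range")
    t = pulse_reduced.delay_fs
    omega = fft_wavenumber_axis(t.size, pulse_reduced.delay_step_fs)
    c = chi_quartz * pulse_reduced.envelope(omega) * np.conj(pulse_reduced.lo)
    nu = omega * C_CM_PER_FS
    kernel = np.exp(-2j * np.pi * np.outer(nu, t))
    trace = np.real(c @ kernel)
    data = np.broadcast_to(trace, shape + (t.size,)).copy()
    return InterferogramStack(
        data=data, delay_fs=t.copy(), rotation_deg=0.0,
        meta={"reference": True, "chi_quartz": chi_quartz, "pulse": pulse_reduced},
    )


def add_detection_noise(stack, sigma: float, seed: int = 0):
    """Add Gaussian detection noise; identity for sigma = 0, seeded.

    Real stacks get N(0, sigma) per sample; complex stacks get independent
    N(0, sigma) on the real and imaginary parts.  Accepts
    InterferogramStack, SpectralStack or RotationSeries and returns the
    same type.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)

    def noisy(arr: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return arr.copy()
        if np.iscomplexobj(arr):
            return arr + rng.normal(0, sigma, arr.shape) + 1j * rng.normal(0, sigma, arr.shape)
        return arr + rng.normal(0, sigma, arr.shape)

    if isinstance(stack, InterferogramStack):
        return InterferogramStack(noisy(stack.data), stack.delay_fs.copy(),
                                  stack.rotation_deg, dict(stack.meta))
    if isinstance(stack, SpectralStack):
        return stack.copy_with(noisy(stack.data))
    if isinstance(stack, RotationSeries):
        return RotationSeries(
            data=noisy(stack.data),
            angles_deg=stack.angles_deg.copy(),
            wavenumber=stack.wavenumber.copy(),
            pixel_size_um=stack.pixel_size_um,
            rot_centre_px=stack.rot_centre_px,
            frame=stack.frame,
            meta=dict(stack.meta),
        )
    raise TypeError(f"unsupported stack type {type(stack).__name__}")


def mirror_scene(obj):
    """Reflect a scene (or director field) about the x-axis.

    Geometry maps y -> -y and directions theta -> (360 - theta) mod 360;
    texture handedness metadata is flipped.  mirror(mirror(x)) == x.
    """
    if isinstance(obj, DirectorField):
        return obj.mirrored()
    if isinstance(obj, SyntheticScene):
        domains = tuple(
            replace(d, centre_um=(d.centre_um[0], -d.centre_um[1]), texture=d.texture.mirrored())
            for d in obj.domains
        )
        flip = {"CW": "ACW", "ACW": "CW"}
        return replace(
            obj,
            domains=domains,
            rot_centre_um=(obj.rot_centre_um[0], -obj.rot_centre_um[1]),
            handedness=flip.get(obj.handedness, obj.handedness),
        )
    raise TypeError(f"cannot mirror object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# scene presets

#: Texture classes used throughout testing.  The spiral presets reproduce the
#: two experimentally observed configurations: a CW (+)-spiral whose boojum
#: centre falls outside the domain (virtual), and its enantiomeric mirror, an
#: ACW (-)-spiral enclosing its centre (real).
TEXTURE_KINDS = (
    "parallel-cw",
    "parallel-acw",
    "radial-cw",
    "radial-acw",
    "spiral-cw-plus-virtual",
    "spiral-acw-minus-real",
)


def texture_scene(
    kind: str,
    seed: int = 0,
    grid: GridSpec | None = None,
    radius_um: float = 10.0,
    rho: float = 1.0,
    s: float = 0.8,
) -> SyntheticScene:
    """Single-domain scene of a given texture class, jittered per seed.

    Parameter jitters are kept small enough that the class labels (contour
    class, packing curvature, spiral sign, real/virtual boojum) are
    unambiguous ground truth for every seed.
    """
    if kind not in TEXTURE_KINDS:
        raise ValueError(f"kind must be one of {TEXTURE_KINDS}")
    grid = grid if grid is not None else GridSpec(nx=96, ny=96, pixel_size_um=0.5)
    rng = np.random.default_rng(seed)
    # domain centre jitter, keeping the disc inside the field
    half = min((grid.nx - 1), (grid.ny - 1)) / 2.0 * grid.pixel_size_um
    jit = max(half - radius_um - 2.0, 0.0)
    cx, cy = rng.uniform(-jit, jit, size=2) * 0.5

    if kind.startswith("parallel"):
        beta = rng.uniform(0, 360)
        gmag = rng.uniform(1.5, 2.5)  # deg/um along the director
        sign = +1.0 if kind.endswith("acw") else -1.0
        g = (
            sign * gmag * np.cos(np.deg2rad(beta)),
            sign * gmag * np.sin(np.deg2rad(beta)),
        )
        tex = TextureModel(family="linear", beta_deg=beta, g_deg_per_um=g)
        hand = "ACW" if sign > 0 else "CW"
    elif kind.startswith("radial"):
        acw = kind.endswith("acw")
        beta = (90.0 if acw else 270.0) + rng.uniform(-25, 25)
        tex = TextureModel(family="boojum", centre_um=(cx, cy), k=1, beta_deg=beta,
                           q_deg_per_um=0.0)
        hand = "ACW" if acw else "CW"
    elif kind == "spiral-cw-plus-virtual":
        # centre outside the domain: r in [D-R, D+R] with D = 1.5 R;
        # beta + q r stays in the third quadrant so the curvature is CW throughout
        q = rng.uniform(2.5, 3.5)
        D = 1.5 * radius_um
        ang = rng.uniform(0, 360)
        bx = cx + D * np.cos(np.deg2rad(ang))
        by = cy + D * np.sin(np.deg2rad(ang))
        beta = 215.0 + rng.uniform(-10, 10) - q * D  # centre of the domain near sin<0, cos<0
        tex = TextureModel(family="boojum", centre_um=(bx, by), k=1, beta_deg=beta,
                           q_deg_per_um=q)
        hand = "CW"
    else:  # spiral-acw-minus-real
        q = -rng.uniform(2.5, 3.5)
        off = rng.uniform(0.0, 0.25 * radius_um)
        ang = rng.uniform(0, 360)
        bx = cx + off * np.cos(np.deg2rad(ang))
        by = cy + off * np.sin(np.deg2rad(ang))
        beta = 145.0 + rng.uniform(-10, 10) - q * 0.5 * radius_um
        tex = TextureModel(family="boojum", centre_um=(bx, by), k=1, beta_deg=beta,
                           q_deg_per_um=q)
        hand = "ACW"
    dom = DomainSpec(centre_um=(cx, cy), radius_um=radius_um, texture=tex, rho=rho, s=s)
    return SyntheticScene(grid=grid, domains=(dom,), handedness=hand, seed=seed)


def demo_scene(
    seed: int = 0,
    grid: GridSpec | None = None,
    n_domains: int = 5,
    radius_um: float = 5.0,
    rho: float = 1.0,
    s: float = 0.8,
    kind: str = "spiral-cw-plus-virtual",
) -> SyntheticScene:
    """Multi-domain scene: randomly placed ~10 um LC domains, one texture class.

    Every domain carries an independently jittered texture of the same
    class, mimicking a monolayer of one enantiomeric mixture.
    """
    grid = grid if grid is not None else GridSpec()
    field_radius = min((grid.nx - 1), (grid.ny - 1)) / 2.0 * grid.pixel_size_um
    labels, centres = make_domain_layout(grid, n_domains, radius_um=radius_um,
                                         min_gap_um=2.0, seed=seed,
                                         field_radius_um=field_radius)
    rng = np.random.default_rng(seed + 1)
    domains = []
    for (cx, cy) in centres:
        single = texture_scene(kind, seed=int(rng.integers(0, 2**31 - 1)),
                               radius_um=radius_um, rho=rho, s=s)
        tex = single.domains[0].texture
        # translate the texture so it sits relative to this domain's centre
        dcx, dcy = single.domains[0].centre_um
        if tex.family == "boojum":
            bx, by = tex.centre_um
            tex = replace(tex, centre_um=(cx + (bx - dcx), cy + (by - dcy)))
        domains.append(DomainSpec(centre_um=(cx, cy), radius_um=radius_um, texture=tex,
                                  rho=rho, s=s))
    hand = texture_scene(kind, seed=0).handedness
    return SyntheticScene(grid=grid, domains=tuple(domains), handedness=hand, seed=seed)
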