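"""Raw-data treatment: interferogram FFT, quartz referencing, baseline removal.

The microscope records, per camera pixel, a real heterodyne interferogram
over the IR-visible delay.  A Fourier transform over the delay axis converts
the stack into complex spectral images; dividing by a spectrally flat z-cut
quartz reference removes the instrument envelope and absolute phase; dark
counts and the linear non-resonant baseline are then subtracted using anchor
windows outside the resonant region.

Conventions
-----------
* wavenumbers in cm^-1, delays in fs; ``C_CM_PER_FS`` converts between them.
* The transform that recovers the complex spectrum uses the e^{+i 2 pi nu t}
  kernel (the analytic, positive-frequency part of the real trace), phase
  referenced to t = 0, and is normalised by 2/N so that an on-grid cross-term
  Re[chi * G * LO^* e^{-i 2 pi nu t}] returns exactly chi * G * LO^*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: speed of light in cm/fs: converts wavenumber (cm^-1) to cycles/fs
C_CM_PER_FS = 2.99792458e-5

__all__ = [
    "C_CM_PER_FS",
    "OpticalGeometry",
    "InterferogramStack",
    "SpectralStack",
    "field_fractions",
    "interferogram_to_spectrum",
    "normalize_reference",
    "correct_dark_baseline",
]


def field_fractions(incidence_deg: float) -> tuple[float, float]:
    """In-plane / out-of-plane fractions of a P-polarised driving field.

    For incidence angle theta from the surface normal the in-plane (surface)
    projection of the P field is E_P cos(theta) and the out-of-plane
    projection E_P sin(theta), giving fractions

        f_ip = cos(theta) / (cos(theta) + sin(theta))
        f_op = sin(theta) / (cos(theta) + sin(theta))

    At the instrument's 36 degrees this is (0.579, 0.421).
    """
    if not 0.0 <= incidence_deg <= 90.0:
        raise ValueError(f"incidence angle must be in [0, 90] deg, got {incidence_deg}")
    th = np.deg2rad(incidence_deg)
    denom = np.cos(th) + np.sin(th)
    return float(np.cos(th) / denom), float(np.sin(th) / denom)


@dataclass(frozen=True)
class OpticalGeometry:
    """Beam geometry and the rotation protocol of an acquisition."""

    incidence_deg: float = 36.0
    polarization: str = "PPP"
    rotation_angles_deg: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
    ir_centre_cm1: float = 2900.0
    ir_fwhm_cm1: float = 400.0

    def __post_init__(self) -> None:
        if not 0.0 < self.incidence_deg < 90.0:
            raise ValueError("incidence_deg must be in (0, 90)")
        ang = np.sort(np.mod(np.asarray(self.rotation_angles_deg, dtype=float), 360.0))
        if len(ang) < 3 or len(set(ang.tolist())) < 3:
            raise ValueError("need at least 3 distinct rotation angles")
        step = 360.0 / len(ang)
        if not np.allclose(np.diff(np.concatenate([ang, [ang[0] + 360.0]])), step, atol=1e-6):
            raise ValueError("rotation angles must uniformly cover 360 degrees")

    @property
    def f_ip(self) -> float:
        return field_fractions(self.incidence_deg)[0]

    @property
    def f_op(self) -> float:
        return field_fractions(self.incidence_deg)[1]


@dataclass
class InterferogramStack:
    """Real interferometric image cube (ny, nx, ndelay) at one sample rotation."""

    data: np.ndarray
    delay_fs: np.ndarray
    rotation_deg: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.delay_fs = np.asarray(self.delay_fs, dtype=float)
        if self.data.ndim != 3 or self.data.shape[-1] != self.delay_fs.size:
            raise ValueError("data must be (ny, nx, ndelay) matching delay axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("interferogram data must be finite")
        d = np.diff(self.delay_fs)
        if d.size and not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("delay axis must be uniform")

    @property
    def delay_step_fs(self) -> float:
        return float(self.delay_fs[1] - self.delay_fs[0])


@dataclass
class SpectralStack:
    """Complex spectral image cube (ny, nx, nomega).

    ``frame`` records whether the image is in the laboratory frame (as
    acquired, sample rotated by ``rotation_deg``) or already back-rotated to
    the sample frame.  ``flags`` tracks the treatment state:
    raw -> referenced -> baseline-corrected.
    """

    data: np.ndarray
    wavenumber: np.ndarray
    frame: str = "lab"
    rotation_deg: float = 0.0
    flags: dict[str, bool] = field(default_factory=lambda: {"referenced": False, "baselined": False})
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        if self.data.ndim != 3 or self.data.shape[-1] != self.wavenumber.size:
            raise ValueError("data must be (ny, nx, nomega) matching wavenumber axis")
        if self.wavenumber.size > 1 and not np.all(np.diff(self.wavenumber) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.frame not in ("lab", "sample"):
            raise ValueError("frame must be 'lab' or 'sample'")

    def copy_with(self, data: np.ndarray, **kw: Any) -> "SpectralStack":
        out = SpectralStack(
            data=data,
            wavenumber=kw.pop("wavenumber", self.wavenumber).copy(),
            frame=kw.pop("frame", self.frame),
            rotation_deg=kw.pop("rotation_deg", self.rotation_deg),
            flags=dict(self.flags),
            meta=dict(self.meta),
        )
        out.flags.update(kw.pop("flags", {}))
        out.meta.update(kw.pop("meta", {}))
        if kw:
            raise TypeError(f"unknown fields: {sorted(kw)}")
        return out


def fft_wavenumber_axis(n_delay: int, delay_step_fs: float) -> np.ndarray:
    """Conjugate (rfft) wavenumber grid of a uniform delay axis, in cm^-1."""
    freq_per_fs = np.fft.rfftfreq(n_delay, d=delay_step_fs)
    return freq_per_fs / C_CM_PER_FS


def interferogram_to_spectrum(
    stack: InterferogramStack,
    roi: tuple[float, float] = (2700.0, 3100.0),
) -> SpectralStack:
    """Per-pixel FFT of the delay axis, truncated to the wavenumber ``roi``.

    The delay origin is phase-referenced to t = 0 (the acquisition starts at
    negative delay), so resonance phases are independent of the scan start.
    Spectral resolution is 1/(c * span): about 10 cm^-1 for a 3.3 ps scan.
    """
    n = stack.data.shape[-1]
    dt = stack.delay_step_fs
    omega = fft_wavenumber_axis(n, dt)
    # analytic part: (2/N) sum_n y_n e^{+i 2 pi j n / N}, then reference to t=0
    spec = 2.0 * np.fft.ifft(stack.data, axis=-1)[..., : omega.size]
    t0 = stack.delay_fs[0]
    nu = omega * C_CM_PER_FS  # cycles/fs
    spec = spec * np.exp(2j * np.pi * nu * t0)
    sel = (omega >= roi[0]) & (omega <= roi[1])
    if not np.any(sel):
        raise ValueError(f"roi {roi} contains no spectral samples (resolution {omega[1]:.2f} cm^-1)")
    return SpectralStack(
        data=spec[..., sel],
        wavenumber=omega[sel],
        frame="lab",
        rotation_deg=stack.rotation_deg,
        meta={**stack.meta, "delay_span_fs": float(stack.delay_fs[-1] - stack.delay_fs[0])},
    )


def normalize_reference(
    sample: SpectralStack,
    reference: SpectralStack,
    min_magnitude: float = 1e-6,
) -> SpectralStack:
    """Divide by a (spatially averaged) quartz reference spectrum.

    The reference is recorded at reduced frequency resolution, so its
    magnitude and unwrapped phase are interpolated separately onto the
    sample grid before the complex division; polar interpolation avoids the
    amplitude dips that linear interpolation of Re/Im would create between
    coarse samples.  A quartz-like sample ends up with zero phase.
    """
    ref = reference.data.mean(axis=(0, 1))  # quartz is spatially uniform
    w_ref = reference.wavenumber
    w = sample.wavenumber
    if w[0] < w_ref[0] - 1e-9 or w[-1] > w_ref[-1] + 1e-9:
        raise ValueError("reference grid does not cover the sample roi")
    mag = np.abs(ref)
    low = mag < min_magnitude
    if np.any(low):
        bad = w_ref[np.argmax(low)]
        raise ValueError(f"reference magnitude below {min_magnitude} at {bad:.1f} cm^-1")
    phase = np.unwrap(np.angle(ref))
    mag_i = np.interp(w, w_ref, mag)
    phase_i = np.interp(w, w_ref, phase)
    ref_i = mag_i * np.exp(1j * phase_i)
    out = sample.copy_with(sample.data / ref_i, flags={"referenced": True})
    out.meta["reference_resolution_cm1"] = float(w_ref[1] - w_ref[0]) if w_ref.size > 1 else 0.0
    return out


def correct_dark_baseline(
    stack: SpectralStack,
    anchors: tuple[tuple[float, float], ...] = ((0.0, 2800.0), (3050.0, 1e9)),
    band_windows: list[tuple[float, float]] | None = None,
) -> SpectralStack:
    """Remove dark counts and the linear non-resonant baseline per pixel.

    A complex linear fit (offset + slope, fitted separately for Re and Im as
    one complex polynomial) over the anchor windows is subtracted across the
    whole roi.  Anchors default to below 2800 and above 3050 cm^-1, outside
    the resonant C-H region; passing the band table's windows lets the
    routine verify the anchors are disjoint from every resonance.
    """
    w = stack.wavenumber
    sel = np.zeros(w.shape, dtype=bool)
    for (a0, a1) in anchors:
        sel |= (w >= a0) & (w <= a1)
    if band_windows is not None:
        for (b0, b1) in band_windows:
            for (a0, a1) in anchors:
                if max(a0, b0) < min(a1, b1):
                    raise ValueError(
                        f"anchor window [{a0}, {a1}] overlaps band window [{b0}, {b1}]"
                    )
    if sel.sum() < 2:
        raise ValueError("anchor windows select fewer than 2 spectral points")
    x = w[sel]
    # centred design matrix for numerical conditioning
    x0 = x.mean()
    A = np.stack([np.ones_like(x), x - x0], axis=1)
    y = stack.data[..., sel]
    ny, nx, _ = stack.data.shape
    coef, *_ = np.linalg.lstsq(A, y.reshape(ny * nx, -1).T, rcond=None)
    baseline = (np.stack([np.ones_like(w), w - x0], axis=1) @ coef).T.reshape(ny, nx, w.size)
    return stack.copy_with(stack.data - baseline, flags={"baselined": True})
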