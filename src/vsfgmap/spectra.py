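"""Complex Lorentzian spectral model for phase-resolved vSFG.

In heterodyne-detected SFG, the measured quantity is the complex second-order
susceptibility chi2(w).  Each vibrational resonance contributes a Lorentzian

    chi2(w) = chi_NR + sum_m  A_m / (w_m - w - i*Gamma_m)

with real signed amplitude ``A_m``, centre ``w_m`` and half-width ``Gamma_m``
(all in cm^-1).  The denominator sign is chosen so that a positive amplitude
gives a positive-going peak in Im chi2 at resonance (the absorptive line
shapes shown by the CH3 symmetric stretch), because both sign conventions
circulate in the SFG literature.

Every band carries two amplitudes: ``a_op`` for the out-of-plane (surface
normal) response and ``a_ip`` for the in-plane response; they are combined
with the projection factors of the driving field by the forward model in
:mod:`vsfgmap.synth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LorentzianBand",
    "SpectralModel",
    "BandFitResult",
    "default_band_table",
    "evaluate_model",
    "lorentzian",
    "fit_bands",
    "integrate_band_magnitude",
]


@dataclass(frozen=True)
class LorentzianBand:
    """One vibrational resonance of the C-H stretch manifold."""

    name: str
    omega0: float  # centre, cm^-1
    gamma: float  # half-width at half maximum, cm^-1
    a_op: float  # signed out-of-plane amplitude
    a_ip: float  # signed in-plane amplitude
    assignment: str = "unassigned"  # "CH3" | "CH2" | "unassigned"
    #: sample-frame offset (deg) of the band's in-plane transition dipole
    #: relative to the defined molecular direction.  The CH3 SS dipole points
    #: exactly opposite the molecular axis, hence 180 for the CH3 bands.
    dipole_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"band {self.name!r}: gamma must be > 0, got {self.gamma}")
        if self.assignment not in ("CH3", "CH2", "unassigned"):
            raise ValueError(f"band {self.name!r}: unknown assignment {self.assignment!r}")


@dataclass(frozen=True)
class SpectralModel:
    """A band table plus a non-resonant complex offset."""

    bands: tuple[LorentzianBand, ...]
    chi_nr: complex = 0.0 + 0.0j

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        freqs = [b.omega0 for b in self.bands]
        if list(freqs) != sorted(freqs):
            object.__setattr__(self, "bands", tuple(sorted(self.bands, key=lambda b: b.omega0)))

    def band(self, name: str) -> LorentzianBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def with_chi_nr(self, chi_nr: complex) -> "SpectralModel":
        return replace(self, chi_nr=chi_nr)

    def amplitudes(self, component: str) -> np.ndarray:
        if component == "op":
            return np.array([b.a_op for b in self.bands])
        if component == "ip":
            return np.array([b.a_ip for b in self.bands])
        raise ValueError("component must be 'op' or 'ip'")

    def assignment_windows(self, halfwidths: float = 2.0) -> dict[str, list[tuple[float, float]]]:
        """Frequency windows per assignment, ``halfwidths`` * gamma wide on each side.

        The default +-2 gamma keeps the CH2 and CH3 windows disjoint for the
        canonical table (neighbouring bands are 30 cm^-1 apart).
        """
        out: dict[str, list[tuple[float, float]]] = {}
        for b in self.bands:
            if b.assignment == "unassigned":
                continue
            out.setdefault(b.assignment, []).append(
                (b.omega0 - halfwidths * b.gamma, b.omega0 + halfwidths * b.gamma)
            )
        return out


def lorentzian(omega: np.ndarray, omega0: float, gamma: float) -> np.ndarray:
    """Unit-amplitude complex line shape 1/(w0 - w - i*Gamma).

    On resonance the value is i/Gamma: purely imaginary and positive, so a
    positive amplitude produces a positive Im chi2 peak.
    """
    omega = np.asarray(omega, dtype=float)
    return 1.0 / (omega0 - omega - 1j * gamma)


def default_band_table() -> SpectralModel:
    """Canonical CH2/CH3 band table of a DPPC monolayer in the C-H stretch region.

    Centres follow the standard literature assignments: CH2 SS 2845, CH3 SS
    2875, CH2 FR 2905, CH3 FR 2935 and CH3 AS 2965 cm^-1.  Symmetric
    stretches and Fermi resonances are positive, antisymmetric stretches
    negative, which is the sign pattern of upright alkyl tails with the
    terminal methyl groups pointing away from the surface.  Two weak
    unassigned bands (headgroup CH / additional CH2 contributions) are
    included for the deconvolution but excluded from CH2/CH3 magnitude maps.

    Amplitudes are effective band-level parameters (arbitrary units): the
    CH3 bands dominate out-of-plane, the CH2 bands dominate in-plane.
    Half-widths default to 6 cm^-1.
    """
    g = 6.0
    bands = (
        LorentzianBand("CH2 SS", 2845.0, g, a_op=0.25, a_ip=1.00, assignment="CH2",
                       dipole_offset_deg=0.0),
        LorentzianBand("CH3 SS", 2875.0, g, a_op=2.00, a_ip=0.80, assignment="CH3",
                       dipole_offset_deg=180.0),
        LorentzianBand("CH2 FR", 2905.0, g, a_op=0.15, a_ip=0.60, assignment="CH2",
                       dipole_offset_deg=0.0),
        LorentzianBand("unassigned 1", 2822.0, g, a_op=0.10, a_ip=0.10),
        LorentzianBand("CH3 FR", 2935.0, g, a_op=1.20, a_ip=0.50, assignment="CH3",
                       dipole_offset_deg=180.0),
        LorentzianBand("unassigned 2", 2915.0, g, a_op=0.08, a_ip=0.08),
        LorentzianBand("CH3 AS", 2965.0, g, a_op=-1.00, a_ip=-0.40, assignment="CH3",
                       dipole_offset_deg=180.0),
    )
    return SpectralModel(bands=bands, chi_nr=0.05 + 0.0j)


def evaluate_model(
    model: SpectralModel,
    omega: np.ndarray,
    component: str = "op",
    amplitudes: Sequence[float] | None = None,
) -> np.ndarray:
    """Evaluate chi2(w) = chi_NR + sum_m A_m/(w_m - w - i Gamma_m).

    ``component`` selects each band's out-of-plane or in-plane amplitude;
    ``amplitudes`` overrides them with an explicit vector.
    """
    omega = np.asarray(omega, dtype=float)
    if amplitudes is None:
        amps = model.amplitudes(component)
    else:
        amps = np.asarray(amplitudes, dtype=float)
        if amps.shape != (len(model.bands),):
            raise ValueError("amplitudes must have one entry per band")
    chi = np.full(omega.shape, complex(model.chi_nr), dtype=complex)
    for a, b in zip(amps, model.bands):
        chi += a * lorentzian(omega, b.omega0, b.gamma)
    return chi


def band_profiles(model: SpectralModel, omega: np.ndarray) -> np.ndarray:
    """Matrix of unit Lorentzian line shapes, one row per band, on ``omega``."""
    return np.stack([lorentzian(omega, b.omega0, b.gamma) for b in model.bands])


@dataclass
class BandFitResult:
    """Outcome of a bounded nonlinear least-squares band deconvolution."""

    model: SpectralModel
    component: str
    residual_norm: float
    stderr: dict[str, dict[str, float]]  # per band: amplitude/omega0/gamma standard errors
    n_starts: int
    success: bool

    def summary(self) -> str:
        lines = [
            f"Lorentzian band fit ({self.component}); residual norm {self.residual_norm:.3e}; "
            f"{self.n_starts} start(s)",
            f"{'band':<14}{'omega0':>10}{'gamma':>8}{'amp':>10}{'se(amp)':>10}",
        ]
        for b in self.model.bands:
            a = b.a_op if self.component == "op" else b.a_ip
            se = self.stderr.get(b.name, {}).get("amplitude", float("nan"))
            lines.append(f"{b.name:<14}{b.omega0:>10.2f}{b.gamma:>8.2f}{a:>10.3f}{se:>10.3f}")
        lines.append(f"chi_NR = {self.model.chi_nr.real:+.4f}{self.model.chi_nr.imag:+.4f}j")
        return "\n".join(lines)


class FitConvergenceError(RuntimeError):
    def __init__(self, residual_norm: float, last_params: np.ndarray):
        super().__init__(f"band fit failed to converge; residual norm {residual_norm:.3e}")
        self.residual_norm = residual_norm
        self.last_params = last_params


def _pack(model: SpectralModel, component: str) -> np.ndarray:
    amps = model.amplitudes(component)
    p = [model.chi_nr.real, model.chi_nr.imag]
    for a, b in zip(amps, model.bands):
        p += [a, b.omega0, b.gamma]
    return np.array(p)


def _unpack(p: np.ndarray, template: SpectralModel, component: str) -> SpectralModel:
    chi_nr = complex(p[0], p[1])
    bands = []
    for i, b in enumerate(template.bands):
        a, w0, g = p[2 + 3 * i: 5 + 3 * i]
        kw = {"omega0": float(w0), "gamma": float(g)}
        kw["a_op" if component == "op" else "a_ip"] = float(a)
        bands.append(replace(b, **kw))
    return SpectralModel(bands=tuple(bands), chi_nr=chi_nr)


def fit_bands(
    spectrum: np.ndarray,
    omega: np.ndarray,
    init: SpectralModel,
    component: str = "op",
    freq_bounds_cm1: float = 8.0,
    gamma_bounds: tuple[float, float] = (2.0, 15.0),
    unassigned_freq_bounds: tuple[float, float] = (2800.0, 2940.0),
    unassigned_halfwidth_cm1: float = 12.0,
    n_restarts: int = 3,
    seed: int = 0,
) -> BandFitResult:
    """Bounded least-squares deconvolution of a complex spectrum into bands.

    Re and Im parts are fitted jointly.  Frequencies are bounded within
    ``freq_bounds_cm1`` of the initial estimates (the literature values).
    Unassigned bands live in the ``unassigned_freq_bounds`` region but are
    additionally confined to ``unassigned_halfwidth_cm1`` of their initial
    centres: with fully free centres an unassigned band can migrate onto a
    named resonance and silently take over its amplitude, which destroys
    the CH2/CH3 attribution the deconvolution exists for.  On failure the
    fit is restarted from jittered initial parameters; the best residual
    wins.
    """
    omega = np.asarray(omega, dtype=float)
    spectrum = np.asarray(spectrum, dtype=complex)
    if spectrum.shape != omega.shape:
        raise ValueError("spectrum and omega must have matching shapes")

    p0 = _pack(init, component)
    lo = np.full_like(p0, -np.inf)
    hi = np.full_like(p0, np.inf)
    for i, b in enumerate(init.bands):
        j = 2 + 3 * i
        if b.assignment == "unassigned":
            lo[j + 1] = max(unassigned_freq_bounds[0], b.omega0 - unassigned_halfwidth_cm1)
            hi[j + 1] = min(unassigned_freq_bounds[1], b.omega0 + unassigned_halfwidth_cm1)
        else:
            lo[j + 1], hi[j + 1] = b.omega0 - freq_bounds_cm1, b.omega0 + freq_bounds_cm1
        lo[j + 2], hi[j + 2] = gamma_bounds
    p0 = np.clip(p0, lo, hi)

    def residuals(p: np.ndarray) -> np.ndarray:
        m = _unpack(p, init, component)
        chi = evaluate_model(m, omega, component=component)
        d = chi - spectrum
        return np.concatenate([d.real, d.imag])

    rng = np.random.default_rng(seed)
    best = None
    n_used = 0
    scale = max(np.max(np.abs(spectrum)), 1e-12)
    for attempt in range(1 + n_restarts):
        start = p0.copy()
        if attempt > 0:  # jitter amplitudes and frequencies, keep within bounds
            for i in range(len(init.bands)):
                j = 2 + 3 * i
                start[j] *= rng.uniform(0.5, 1.5)
                start[j + 1] += rng.uniform(-2.0, 2.0)
            start = np.clip(start, lo, hi)
        n_used += 1
        sol = least_squares(residuals, start, bounds=(lo, hi), method="trf", x_scale="jac")
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < (1e-8 * scale) ** 2 * omega.size:
            break
    assert best is not None
    rnorm = float(np.sqrt(2 * best.cost))
    if not best.success and rnorm > 0.5 * scale * np.sqrt(omega.size):
        raise FitConvergenceError(rnorm, best.x)

    # covariance diagnostics from the Jacobian at the solution
    stderr: dict[str, dict[str, float]] = {}
    try:
        J = best.jac
        dof = max(J.shape[0] - J.shape[1], 1)
        s2 = 2 * best.cost / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        for i, b in enumerate(init.bands):
            j = 2 + 3 * i
            stderr[b.name] = {
                "amplitude": float(se[j]),
                "omega0": float(se[j + 1]),
                "gamma": float(se[j + 2]),
            }
    except np.linalg.LinAlgError:
        pass

    return BandFitResult(
        model=_unpack(best.x, init, component),
        component=component,
        residual_norm=rnorm,
        stderr=stderr,
        n_starts=n_used,
        success=bool(best.success),
    )


def integrate_band_magnitude(
    data: np.ndarray,
    omega: np.ndarray,
    windows: dict[str, list[tuple[float, float]]],
    mode: str = "abs",
) -> dict[str, np.ndarray]:
    """Band-integrated magnitude images per assignment.

    ``data`` has the frequency axis last (e.g. (ny, nx, nw)).  For each
    assignment the values inside its frequency windows are summed, either as
    magnitudes (``mode='abs'``) or as signed imaginary parts (``mode='imag'``).
    Windows of different assignments must not overlap.
    """
    omega = np.asarray(omega, dtype=float)
    keys = list(windows)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            for (a0, a1) in windows[ka]:
                for (b0, b1) in windows[kb]:
                    if max(a0, b0) < min(a1, b1):
                        raise ValueError(
                            f"windows of {ka!r} and {kb!r} overlap in [{max(a0,b0)}, {min(a1,b1)}]"
                        )
    out: dict[str, np.ndarray] = {}
    for key, wins in windows.items():
        sel = np.zeros(omega.shape, dtype=bool)
        for (w0, w1) in wins:
            sel |= (omega >= w0) & (omega <= w1)
        vals = np.abs(data[..., sel]) if mode == "abs" else np.imag(data[..., sel])
        out[key] = vals.sum(axis=-1)
    return out
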