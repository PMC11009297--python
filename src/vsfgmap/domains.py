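"""Mesoscale domain analysis: segmentation, composition, contours, texture classes.

Condensed (LC) domains are segmented from the out-of-plane CH3 magnitude
image; per-domain spectra, relative molecular density and orientational
order are extracted from the 0-fold and 1-fold azimuthal components; and
each domain's director texture is fitted with the parametric boojum /
linear families and classified into the contour-line classes

    parallel  - straight iso-direction contours (linear texture)
    radial    - rays from a centre (boojum, zero pitch: concentric lipids)
    spiral    - Archimedean contours (boojum, non-zero pitch), signed '+'
                when the contours wind clockwise moving outward

together with the packing curvature (CW / ACW, the turning sense of the
molecular direction along the director) and, for boojum textures, whether
the symmetry centre lies inside the domain (real boojum) or outside
(virtual boojum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import filters, measure

from .preprocess import SpectralStack
from .rotation import AzimuthalComponents, DirectorField
from .spectra import SpectralModel, integrate_band_magnitude

__all__ = [
    "DomainSet",
    "TextureFit",
    "DomainComposition",
    "ContourSet",
    "segment_domains",
    "mean_spectra",
    "estimate_density_order",
    "compare_compositions",
    "phase_contours",
    "fit_and_classify_texture",
]


@dataclass
class DomainSet:
    """Labelled LC domains with per-domain geometry records."""

    labels: np.ndarray  # int image, background 0, labels 1..n
    pixel_size_um: float
    records: pd.DataFrame  # label, area_um2, centroid_x_um, centroid_y_um
    polygons: dict[int, list[np.ndarray]] = field(default_factory=dict)

    @property
    def n_domains(self) -> int:
        return int(self.records.shape[0])

    def mask(self, label: int | None = None) -> np.ndarray:
        if label is None:
            return self.labels > 0
        return self.labels == label

    def coverage(self, within: np.ndarray | None = None) -> float:
        """LC area fraction, optionally within a validity mask."""
        if within is None:
            return float((self.labels > 0).mean())
        within = np.asarray(within, dtype=bool)
        if within.sum() == 0:
            return 0.0
        return float((self.labels > 0)[within].mean())


def segment_domains(
    op_ch3_magnitude: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 3.0,
    threshold: float | None = None,
    within: np.ndarray | None = None,
) -> DomainSet:
    """Threshold + connected components on the out-of-plane CH3 magnitude.

    Otsu's threshold by default; components smaller than ``min_area_um2``
    are dropped and labels relabelled contiguously.  An all-background image
    yields an empty DomainSet, not an error.
    """
    img = np.asarray(op_ch3_magnitude, dtype=float)
    if np.any(img < 0):
        raise ValueError("magnitude image must be non-negative")
    valid = np.ones(img.shape, dtype=bool) if within is None else np.asarray(within, dtype=bool)
    vals = img[valid]
    if threshold is None:
        if vals.size == 0 or np.allclose(vals, vals.flat[0] if vals.size else 0.0):
            threshold = np.inf  # featureless image: nothing to segment
        else:
            threshold = float(filters.threshold_otsu(vals))
    fg = (img > threshold) & valid
    lab, n = ndimage.label(fg)
    px_area = pixel_size_um ** 2
    rows = []
    polygons: dict[int, list[np.ndarray]] = {}
    ny, nx = img.shape
    new_label = 0
    out = np.zeros_like(lab)
    for i in range(1, n + 1):
        m = lab == i
        area = m.sum() * px_area
        if area < min_area_um2:
            continue
        new_label += 1
        out[m] = new_label
        cy, cx = ndimage.center_of_mass(m)
        rows.append(
            {
                "label": new_label,
                "area_um2": float(area),
                "centroid_x_um": (cx - (nx - 1) / 2.0) * pixel_size_um,
                "centroid_y_um": (cy - (ny - 1) / 2.0) * pixel_size_um,
            }
        )
        contours = measure.find_contours(m.astype(float), 0.5)
        polys = []
        for c in contours:
            xy = np.column_stack(
                [
                    (c[:, 1] - (nx - 1) / 2.0) * pixel_size_um,
                    (c[:, 0] - (ny - 1) / 2.0) * pixel_size_um,
                ]
            )
            polys.append(xy)
        polygons[new_label] = polys
    records = pd.DataFrame(rows, columns=["label", "area_um2", "centroid_x_um", "centroid_y_um"])
    return DomainSet(labels=out, pixel_size_um=pixel_size_um, records=records, polygons=polygons)


def mean_spectra(
    stack: SpectralStack,
    domains: DomainSet,
    within: np.ndarray | None = None,
) -> dict[str, Any]:
    """Complex mean spectra inside the domains, outside, and over the image.

    The total is algebraically the coverage-weighted combination of inside
    and outside.  Empty regions are flagged with a None spectrum.
    """
    if stack.data.shape[:2] != domains.labels.shape:
        raise ValueError("stack and domain labels are not co-registered")
    valid = np.ones(domains.labels.shape, bool) if within is None else np.asarray(within, bool)
    inside = (domains.labels > 0) & valid
    outside = (domains.labels == 0) & valid
    out: dict[str, Any] = {"wavenumber": stack.wavenumber.copy()}
    out["inside"] = stack.data[inside].mean(axis=0) if inside.any() else None
    out["outside"] = stack.data[outside].mean(axis=0) if outside.any() else None
    out["total"] = stack.data[valid].mean(axis=0) if valid.any() else None
    out["coverage"] = domains.coverage(within=valid)
    return out


@dataclass
class DomainComposition:
    """Coverage, relative density and relative order of the LC domains.

    ``rho_rel`` is proportional to the molecular density (the out-of-plane
    CH3 response per molecule is assumed orientation-invariant between
    samples); ``s_rel`` is proportional to the in-plane orientational order
    (the ratio of in-plane to out-of-plane CH3 magnitude cancels density).
    Both are relative scales: only ratios between samples are meaningful.
    """

    coverage: float
    rho_rel: np.ndarray  # per domain
    s_rel: np.ndarray  # per domain (NaN where the 0-fold signal was too weak)
    rho_out: float
    labels: np.ndarray

    @property
    def rho_rel_mean(self) -> float:
        return float(np.mean(self.rho_rel)) if self.rho_rel.size else float("nan")

    @property
    def s_rel_mean(self) -> float:
        good = self.s_rel[np.isfinite(self.s_rel)]
        return float(np.mean(good)) if good.size else float("nan")

    @property
    def dppc_excess(self) -> float:
        return (self.rho_rel_mean - self.rho_out) / self.rho_out if self.rho_out > 0 else float("nan")


def estimate_density_order(
    components: AzimuthalComponents,
    domains: DomainSet,
    model: SpectralModel,
    min_f0_rel: float = 0.1,
    interior_erode_px: int = 3,
) -> DomainComposition:
    """Relative density and order from the 0-fold / 1-fold CH3 magnitudes.

    rho_rel per domain is the mean CH3-band-integrated |F0|; s_rel is the
    mean of 2|F1| / |F0| over the same CH3 windows (the factor 2 undoes the
    1/N azimuthal-transform convention, making the numerator the full
    in-plane amplitude).  Averages run over the domain interior (the
    segmented mask eroded by ``interior_erode_px``): boundary pixels carry
    the optical edge response, which suppresses the in-plane/out-of-plane
    ratio and would bias the order estimate low.  Domains whose 0-fold
    magnitude falls below ``min_f0_rel`` of the in-domain median are
    excluded from s_rel.
    """
    windows = {"CH3": model.assignment_windows()["CH3"]}
    f0 = integrate_band_magnitude(components.F0, components.wavenumber, windows)["CH3"]
    sel = np.zeros(components.wavenumber.shape, dtype=bool)
    for (w0, w1) in windows["CH3"]:
        sel |= (components.wavenumber >= w0) & (components.wavenumber <= w1)
    f1_sq = np.abs(components.F1[..., sel]) ** 2
    if components.noise_power is not None:
        # Rician debias: with N uniform angles the 1-fold estimate carries
        # complex noise power (residual power)/3, which inflates |F1| and
        # compresses order contrasts between samples
        f1_sq = np.clip(f1_sq - components.noise_power[..., None] / 3.0, 0.0, None)
    f1 = np.sqrt(f1_sq).sum(axis=-1)
    valid = components.mask
    inside_all = (domains.labels > 0) & valid
    floor = min_f0_rel * np.median(f0[inside_all]) if inside_all.any() else 0.0
    rho, s = [], []
    for lab in domains.records["label"]:
        m = (domains.labels == int(lab)) & valid
        if interior_erode_px > 0:
            interior = ndimage.binary_erosion(m, iterations=interior_erode_px)
            if interior.sum() >= 9:
                m = interior
        if not m.any():
            rho.append(np.nan)
            s.append(np.nan)
            continue
        rho.append(float(f0[m].mean()))
        ok = m & (f0 > floor)
        if ok.any():
            # median: robust to the suppressed-|F1| tail at a boojum core,
            # where the director turns within a pixel; unbiased for the
            # symmetric noise scatter of a homogeneous domain
            s.append(float(np.median(2.0 * f1[ok] / f0[ok])))
        else:
            s.append(np.nan)
    outside = (domains.labels == 0) & valid
    if interior_erode_px > 0:
        far = ndimage.binary_erosion(outside, iterations=interior_erode_px)
        if far.sum() >= 9:
            outside = far
    rho_out = float(f0[outside].mean()) if outside.any() else float("nan")
    return DomainComposition(
        coverage=domains.coverage(within=valid),
        rho_rel=np.asarray(rho),
        s_rel=np.asarray(s),
        rho_out=rho_out,
        labels=domains.labels.copy(),
    )


def compare_compositions(a: DomainComposition, b: DomainComposition) -> dict[str, float]:
    """Percent differences of b relative to a (positive: b greater)."""
    return {
        "density_pct": 100.0 * (b.rho_rel_mean / a.rho_rel_mean - 1.0),
        "order_pct": 100.0 * (b.s_rel_mean / a.s_rel_mean - 1.0),
        "coverage_a": a.coverage,
        "coverage_b": b.coverage,
        "dppc_excess_a": a.dppc_excess,
        "dppc_excess_b": b.dppc_excess,
    }


@dataclass
class ContourSet:
    """Iso-direction contour polylines per level (sample coordinates, um)."""

    levels_deg: tuple[float, ...]
    contours: dict[float, list[np.ndarray]]
    degenerate: bool = False


def phase_contours(
    field: DirectorField,
    levels_deg: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0),
    mask: np.ndarray | None = None,
    min_spread_deg: float = 2.0,
) -> ContourSet:
    """Wrap-aware iso-theta contour lines of a director field.

    For each level L the zero crossings of sin(theta - L) are traced and
    restricted to the half where cos(theta - L) > 0 (the other half belongs
    to level L + 180).  A field whose circular spread is below
    ``min_spread_deg`` has no meaningful contours and is flagged degenerate.
    """
    m = field.mask if mask is None else (np.asarray(mask, bool) & field.mask)
    th = np.deg2rad(field.theta_deg)
    z = np.exp(1j * th)
    if m.sum() == 0:
        return ContourSet(tuple(levels_deg), {L: [] for L in levels_deg}, degenerate=True)
    resultant = np.abs(z[m].mean())
    spread = np.rad2deg(np.sqrt(max(-2.0 * np.log(max(resultant, 1e-300)), 0.0)))
    if spread < min_spread_deg:
        return ContourSet(tuple(levels_deg), {L: [] for L in levels_deg}, degenerate=True)
    ny, nx = th.shape
    px = field.pixel_size_um
    out: dict[float, list[np.ndarray]] = {}
    for L in levels_deg:
        rot = z * np.exp(-1j * np.deg2rad(L))
        f = np.imag(rot)  # sin(theta - L)
        g = np.real(rot)  # cos(theta - L)
        try:
            raw = measure.find_contours(f, 0.0, mask=m)
        except TypeError:  # older scikit-image without mask kw
            f2 = np.where(m, f, np.nan)
            raw = measure.find_contours(f2, 0.0)
        polylines: list[np.ndarray] = []
        for c in raw:
            gv = ndimage.map_coordinates(g, c.T, order=1, mode="nearest")
            keep = gv > 0.0
            # split into contiguous runs of the correct half
            idx = np.where(keep)[0]
            if idx.size == 0:
                continue
            breaks = np.where(np.diff(idx) > 1)[0]
            for seg in np.split(idx, breaks + 1):
                if seg.size < 2:
                    continue
                cc = c[seg]
                xy = np.column_stack(
                    [(cc[:, 1] - (nx - 1) / 2.0) * px, (cc[:, 0] - (ny - 1) / 2.0) * px]
                )
                polylines.append(xy)
        out[L] = polylines
    return ContourSet(tuple(levels_deg), out, degenerate=False)


@dataclass
class TextureFit:
    """Fitted parametric texture and its classification labels."""

    family: str  # winning family: "boojum" | "linear"
    centre_um: tuple[float, float] | None  # boojum centre (None for linear)
    k: int
    beta_deg: float
    q_deg_per_um: float
    g_deg_per_um: tuple[float, float]
    rms_deg: float  # circular residual of the winning family
    rms_linear_deg: float
    rms_boojum_deg: float
    texture_class: str  # "parallel" | "radial" | "spiral" | "unclassified"
    curvature: str  # "CW" | "ACW" | "n/a"
    curvature_rate_deg_per_um: float
    spiral_sign: str  # "+" | "-" | "n/a"
    boojum: str  # "real" | "virtual" | "n/a"
    n_pixels: int

    def summary(self) -> str:
        lines = [
            f"texture class: {self.texture_class}  curvature: {self.curvature}"
            f"  spiral sign: {self.spiral_sign}  boojum: {self.boojum}",
            f"family {self.family}; circular RMS {self.rms_deg:.2f} deg "
            f"(linear {self.rms_linear_deg:.2f}, boojum {self.rms_boojum_deg:.2f}); "
            f"{self.n_pixels} px",
        ]
        if self.family == "boojum" and self.centre_um is not None:
            lines.append(
                f"centre ({self.centre_um[0]:+.2f}, {self.centre_um[1]:+.2f}) um, "
                f"beta {self.beta_deg:.1f} deg, pitch q {self.q_deg_per_um:+.2f} deg/um"
            )
        else:
            gx, gy = self.g_deg_per_um
            lines.append(f"beta {self.beta_deg:.1f} deg, gradient ({gx:+.2f}, {gy:+.2f}) deg/um")
        return "\n".join(lines)


def _circ_rms_deg(score: float, wsum: float) -> float:
    """Circular RMS (deg) from the resultant |sum w e^{i residual}|.

    mean(1 - cos(res)) = 1 - score/wsum; for small residuals this equals
    var/2, so rms = sqrt(2 (1 - R)) in radians.
    """
    R = min(max(score / wsum, 0.0), 1.0)
    return float(np.rad2deg(np.sqrt(2.0 * (1.0 - R))))


def _fit_linear(theta_rad, w, x, y, g_max=6.0, g_step=0.5):
    """Best-fit affine texture by maximising |sum w e^{i(theta - g.r)}|."""
    gs = np.arange(-g_max, g_max + g_step / 2, g_step) * np.pi / 180.0  # rad/um
    zw = w * np.exp(1j * theta_rad)

    def score_of(gx, gy):
        return np.abs(np.sum(zw * np.exp(-1j * (gx * x + gy * y))))

    # coarse separable-ish grid
    best, best_g = -1.0, (0.0, 0.0)
    phase_x = np.exp(-1j * np.outer(gs, x))  # (ng, npx)
    for gy in gs:
        zy = zw * np.exp(-1j * gy * y)
        sc = np.abs(phase_x @ zy)
        i = int(np.argmax(sc))
        if sc[i] > best:
            best, best_g = float(sc[i]), (float(gs[i]), float(gy))

    res = optimize.minimize(
        lambda p: -score_of(p[0], p[1]), np.array(best_g), method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-10},
    )
    gx, gy = res.x
    sc = score_of(gx, gy)
    beta = np.angle(np.sum(zw * np.exp(-1j * (gx * x + gy * y))))
    return {
        "beta_deg": float(np.rad2deg(beta) % 360.0),
        "g_deg_per_um": (float(np.rad2deg(gx)), float(np.rad2deg(gy))),
        "rms_deg": _circ_rms_deg(float(sc), float(w.sum())),
    }


def _boojum_score(zw, x, y, cx, cy, qs_rad):
    """Scores over a pitch grid for one candidate centre (k = 1)."""
    dx, dy = x - cx, y - cy
    r = np.hypot(dx, dy)
    psi = np.arctan2(dy, dx)
    z = zw * np.exp(-1j * psi)
    return np.abs(np.exp(-1j * np.outer(qs_rad, r)) @ z), r, psi


def _fit_boojum(theta_rad, w, x, y, extent, q_max=8.0, q_step=0.5, centre_step_um=3.0,
                max_coarse_px=400):
    """Best-fit boojum texture: grid over centres (virtual centres allowed) + refine.

    The coarse centre/pitch grid runs on a deterministic pixel subsample for
    speed; the Nelder-Mead refinement uses every pixel.
    """
    zw = w * np.exp(1j * theta_rad)
    if x.size > max_coarse_px:
        idx = np.linspace(0, x.size - 1, max_coarse_px).astype(int)
        zw_c, x_c, y_c = zw[idx], x[idx], y[idx]
    else:
        zw_c, x_c, y_c = zw, x, y
    qs = np.arange(-q_max, q_max + q_step / 2, q_step) * np.pi / 180.0
    (x0, x1), (y0, y1) = extent
    cxs = np.arange(x0, x1 + centre_step_um / 2, centre_step_um)
    cys = np.arange(y0, y1 + centre_step_um / 2, centre_step_um)
    best = (-1.0, 0.0, 0.0, 0.0)  # score, cx, cy, q
    for cy in cys:
        for cx in cxs:
            sc, _, _ = _boojum_score(zw_c, x_c, y_c, cx, cy, qs)
            i = int(np.argmax(sc))
            if sc[i] > best[0]:
                best = (float(sc[i]), float(cx), float(cy), float(qs[i]))

    def neg_score(p):
        sc, _, _ = _boojum_score(zw, x, y, p[0], p[1], np.array([p[2]]))
        return -float(sc[0])

    res = optimize.minimize(
        neg_score, np.array(best[1:]), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 600},
    )
    cx, cy, q = res.x
    sc, r, psi = _boojum_score(zw, x, y, cx, cy, np.array([q]))
    beta = np.angle(np.sum(zw * np.exp(-1j * (psi + q * r))))
    return {
        "centre_um": (float(cx), float(cy)),
        "beta_deg": float(np.rad2deg(beta) % 360.0),
        "q_deg_per_um": float(np.rad2deg(q)),
        "rms_deg": _circ_rms_deg(float(sc[0]), float(w.sum())),
    }


def curvature_rate(field: DirectorField, mask: np.ndarray) -> float:
    """Magnitude-weighted mean of grad(theta) . (cos theta, sin theta), deg/um.

    The directional derivative of the direction along the director: positive
    means the packing turns anti-clockwise as one moves along the molecular
    direction (ACW curvature), negative clockwise (CW).  Wrap-safe central
    differences; pixels lacking two valid neighbours are skipped.
    """
    th = np.deg2rad(field.theta_deg)
    z = np.exp(1j * th)
    px = field.pixel_size_um
    m = np.asarray(mask, bool) & field.mask
    # wrap-safe central differences of theta
    dthx = np.full(th.shape, np.nan)
    dthy = np.full(th.shape, np.nan)
    dthx[:, 1:-1] = np.angle(z[:, 2:] * np.conj(z[:, :-2])) / (2 * px)
    dthy[1:-1, :] = np.angle(z[2:, :] * np.conj(z[:-2, :])) / (2 * px)
    okx = np.zeros_like(m)
    okx[:, 1:-1] = m[:, 2:] & m[:, :-2]
    oky = np.zeros_like(m)
    oky[1:-1, :] = m[2:, :] & m[:-2, :]
    ok = m & okx & oky
    if not ok.any():
        return float("nan")
    rate = dthx * np.cos(th) + dthy * np.sin(th)  # rad/um
    wgt = field.magnitude[ok]
    return float(np.rad2deg(np.average(rate[ok], weights=wgt)))


def fit_and_classify_texture(
    field: DirectorField,
    mask: np.ndarray,
    q_tol_deg_per_um: float = 0.5,
    parsimony_margin: float = 0.10,
    min_linear_rms_deg: float = 0.5,
    reject_rms_deg: float = 25.0,
    curvature_tol_deg_per_um: float = 0.1,
    centre_extent_factor: float = 1.5,
) -> TextureFit:
    """Fit boojum and linear textures to a domain's director field and classify.

    Both families are fitted by circular least squares (the 1 - cos loss,
    bounded and wrap-safe); the boojum centre is searched on a grid
    extending ``centre_extent_factor`` domain diameters beyond the mask so
    virtual centres outside the domain are found.  The linear family wins
    ties unless the boojum residual is at least ``parsimony_margin`` lower
    (preventing spurious spiral calls on flat fields).  Classification:

    * class: parallel (linear), radial (boojum, |q| < tol), spiral (else);
      residual above ``reject_rms_deg`` -> "unclassified", never a guess.
    * curvature: sign of the magnitude-weighted mean directional derivative
      of theta along the director (negative -> CW).
    * spiral sign: '+' iff the iso-direction contours wind clockwise moving
      outward from the fitted centre, which for theta = psi + beta + q r
      means q > 0 (contours follow psi = const - q r).
    * boojum: real iff the fitted centre lies inside the domain mask.
    """
    m = np.asarray(mask, bool) & field.mask
    n_px = int(m.sum())
    if n_px < 50:
        raise ValueError(f"need at least 50 valid pixels to fit a texture, got {n_px}")
    X, Y = field.coords_um()
    x, y = X[m], Y[m]
    w = field.magnitude[m]
    th = np.deg2rad(field.theta_deg[m])

    lin = _fit_linear(th, w, x, y)
    area_um2 = n_px * field.pixel_size_um ** 2
    diameter = 2.0 * np.sqrt(area_um2 / np.pi)
    ext = centre_extent_factor * diameter
    extent = ((x.min() - ext, x.max() + ext), (y.min() - ext, y.max() + ext))
    boo = _fit_boojum(th, w, x, y, extent)

    # parsimony: the boojum family wins only on a clear relative margin AND
    # when the linear fit is genuinely inadequate — a flat field fits both
    # families to ~zero residual and must stay "parallel"
    boojum_wins = (
        boo["rms_deg"] < (1.0 - parsimony_margin) * lin["rms_deg"]
        and lin["rms_deg"] > min_linear_rms_deg
    )
    rate = curvature_rate(field, m)
    if abs(rate) < curvature_tol_deg_per_um or not np.isfinite(rate):
        curvature = "n/a"
    else:
        curvature = "ACW" if rate > 0 else "CW"

    if boojum_wins:
        family = "boojum"
        rms = boo["rms_deg"]
        q = boo["q_deg_per_um"]
        cx, cy = boo["centre_um"]
        texture_class = "radial" if abs(q) < q_tol_deg_per_um else "spiral"
        spiral_sign = ("+" if q > 0 else "-") if texture_class == "spiral" else "n/a"
        # real boojum: fitted centre falls on an in-domain pixel
        ny, nx = field.theta_deg.shape
        row = cy / field.pixel_size_um + (ny - 1) / 2.0
        col = cx / field.pixel_size_um + (nx - 1) / 2.0
        ir, ic = int(round(row)), int(round(col))
        inside = 0 <= ir < ny and 0 <= ic < nx and bool(mask[ir, ic])
        boojum = "real" if inside else "virtual"
        centre = (cx, cy)
        beta = boo["beta_deg"]
        g = (0.0, 0.0)
        k = 1
    else:
        family = "linear"
        rms = lin["rms_deg"]
        q = 0.0
        texture_class = "parallel"
        spiral_sign = "n/a"
        boojum = "n/a"
        centre = None
        beta = lin["beta_deg"]
        g = lin["g_deg_per_um"]
        k = 0

    if rms > reject_rms_deg:
        texture_class = "unclassified"
        spiral_sign = "n/a"
        boojum = "n/a"

    return TextureFit(
        family=family,
        centre_um=centre,
        k=k,
        beta_deg=beta,
        q_deg_per_um=q,
        g_deg_per_um=g,
        rms_deg=rms,
        rms_linear_deg=lin["rms_deg"],
        rms_boojum_deg=boo["rms_deg"],
        texture_class=texture_class,
        curvature=curvature,
        curvature_rate_deg_per_um=rate,
        spiral_sign=spiral_sign,
        boojum=boojum,
        n_pixels=n_px,
    )
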