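# Methods

## Signal model

Per pixel p, vibrational band m and sample rotation φ, the emitted complex
susceptibility is

    χ(ω; p, φ) = χ_NR + Σ_m L_m(ω) · ρ(p) · [ f_op a_op,m
                 + f_ip s(p) a_ip,m cos(d_m(p) + φ) ]

with

* L_m(ω) = 1/(ω_m − ω − iΓ_m) — the complex Lorentzian of the resonant SFG
  response. The denominator sign is chosen so a positive amplitude gives a
  positive Im χ peak on resonance (both conventions circulate in the
  literature; this one matches the observed positive CH₃ SS line shape).
* ρ(p) ≥ 0 — relative molecular density; s(p) ∈ [0, 1] — in-plane
  orientational order.
* f_ip = cos θ_i/(cos θ_i + sin θ_i), f_op = sin θ_i/(cos θ_i + sin θ_i) —
  the in-plane/out-of-plane fractions of the P-polarised driving field at
  incidence angle θ_i (0.579 / 0.421 at the instrument's 36°).
* d_m(p) — the sample-frame azimuth of band m's in-plane transition dipole.
  The CH₃ SS dipole points exactly opposite the defined molecular direction
  θ, so the CH₃ bands carry a 180° dipole offset and the CH₂ bands 0°
  (per-band `dipole_offset_deg`, a generator parameter: only the CH₃ SS
  relation is anchored by the molecular geometry; the CH₂ default is a
  convention).

Images are emitted in the laboratory frame (the scene rotated by +φ about
the rotation axis); the analysis must back-rotate. Heterodyne detection is
reduced to the cross-term Re[χ(ω)G(ω)LO* e^{−i2πcωt}] — balanced imaging
removes the homodyne |χ|² term, and the cross-term is the analysed
quantity.

Conventions throughout: x rightward, y upward, angles in degrees
counter-clockwise from +x, sample rotation φ counter-clockwise, 0-based
pixels with centres on integer indices, sample origin at the grid centre.
Wavenumbers in cm⁻¹, delays in fs, lengths in µm.

## Band table

Canonical CH-stretch assignments of a DPPC monolayer: CH₂ SS 2845, CH₃ SS
2875, CH₂ FR 2905, CH₃ FR 2935, CH₃ AS 2965 cm⁻¹; symmetric stretches and
Fermi resonances positive, antisymmetric stretches negative (upright alkyl
tails); CH₃ dominates out-of-plane, CH₂ in-plane. Two weak unassigned
bands (2822 and 2915 cm⁻¹ defaults) participate in fits but are excluded
from CH₂/CH₃ magnitude maps. Half-widths Γ = 6 cm⁻¹ and all amplitudes are
effective band-level conventions, not measured constants. 2815 cm⁻¹ is
deliberately off-resonance.

## Synthetic scenes

A scene is a set of non-overlapping circular LC domains (default radius
5 µm — diameters of ca. 10 µm — on a 128×128, 0.5 µm/px grid) in a
disordered background that carries density (ρ_bg = 0.35, phase separation
is incomplete) but no in-plane order (s = 0). Domain boundaries carry a
Gaussian optical edge response (erf profile, σ = 0.5 µm, one pixel): a
hard disc aliases under rotational resampling at this pixel size,
whereas a PSF-blurred edge is what a widefield image of a sharp boundary
actually looks like. Ground-truth label masks remain hard discs.

Director textures:

* boojum family θ(r, ψ) = k·ψ + β + q·r with winding k ∈ {0, ±1}, offset β
  (deg) and pitch q (deg/µm): q = 0 gives radial contours (concentric
  lipids), q ≠ 0 Archimedean spirals; the exact centre pixel (undefined
  azimuth) is masked.
* linear family θ = β + g·(x, y): parallel contours.

Mirroring (reflection about the x-axis) maps θ → −θ, β → −β, q → −q,
g → (−g_x, g_y) and flips handedness metadata; mirror∘mirror is the
identity.

Scene presets (`texture_scene`) produce the six tested configurations —
parallel CW/ACW, radial CW/ACW, and the two experimentally relevant
spirals: CW (+) with a virtual centre (1.5 domain radii outside) and its
enantiomer ACW (−) enclosing a real centre. Jitter ranges are chosen so
the class labels remain unambiguous ground truth for every seed (e.g. the
virtual spiral keeps β + q·r in the third quadrant across the domain, so
the curvature is CW everywhere).

Detection noise is Gaussian per real/imaginary sample, seeded. "Amplitude
SNR x" means σ = (peak in-plane spectral amplitude at perfect dipole
alignment)/x. When two samples are compared, one σ — set by the baseline
sample — applies to both: the noise level belongs to the instrument, not
the sample; per-sample σ would impose different Rician biases on the two
samples and distort their contrast.

## Interferograms and pretreatment

Delay axis −300…3000 fs in 2 fs steps (spectral resolution ≈ 10 cm⁻¹);
quartz reference at −300…300 fs (≈ 5.5× coarser grid). χ is synthesized on
the FFT-conjugate wavenumber grid of the delay axis, making the round trip
(synthesis → per-pixel FFT with the (2/N)·e^{+i2πνt} kernel, phase
referenced to t = 0) exact to floating point; the quartz normalization
(magnitude and unwrapped phase interpolated separately onto the sample
grid — polar interpolation avoids amplitude dips between coarse samples)
recovers χ to <1%. Dark counts and the linear non-resonant baseline are
removed by one per-pixel complex linear fit over anchor windows (<2800 and
>3050 cm⁻¹ by default); the fit's intercept subsumes a separate dark-count
estimate. The correction is idempotent; Lorentzian tails reaching into the
anchors are absorbed into the line like any other slowly varying
background.

## Registration

Each lab frame is back-rotated by −φ about the rotation centre (bilinear
interpolation; out-of-footprint pixels are excluded from the common mask
rather than zero-filled, which would bias the 0-fold component). Residual
per-angle translations are refined by windowed phase cross-correlation and
kept only when they remove ≥10% of the decorrelation — marginal "gains"
are interpolation artefacts.

The rotation centre is treated as a calibrated instrument constant when
available (it is, on a motorized rotation stage). When it must be
estimated from the data, a coarse-to-fine grid search with Nelder–Mead
refinement minimizes the azimuthal harmonic leakage (power outside the 0-
and 1-fold components) of back-rotated band-integrated complex images,
reaching ≈0.05–0.3 px. A fundamental limitation applies: a centre error δ
is exactly equivalent to per-angle translations (R(φ)−I)δ, which alias
*into* the 1-fold component at first order — so any residual-power
criterion senses δ only at second order, and a centre error of 1 px maps
to roughly 2° of director error. High-accuracy director work therefore
assumes a calibrated axis.

## Azimuthal decomposition and SVD

F_n = (1/N) Σ_j S(φ_j) e^{−inφ_j} for n ∈ {0, ±1}; with this normalization
|F1| is half the cosine amplitude (magnitudes quoted as in-plane
amplitudes use 2|F1|). Uniform angle sets use the DFT; non-uniform sets
fall back to per-pixel least squares on the three-harmonic model, flagged
via `uniform_angles`. Per-pixel confidence = 1 − (power outside
{0, ±1})/(total); the same residual power estimates the per-sample noise
power for magnitude debiasing.

The SVD groups related spectral contributions: the roi spectra are
Hermitian-completed and inverse-FFT'd to real time traces, the
(pixels·rotations) × time matrix is decomposed, and retained right
singular vectors are transformed back to the frequency domain
(unit-normalized, sign fixed so Im at the CH₃ SS is positive). An ideal
two-chromophore monolayer yields exactly two significant singular values,
and the retained spectra span the true in-plane/out-of-plane spectral
subspace. Note the raw component spectra are in general *mixtures* of the
two physical profiles (singular vectors orthogonalize non-orthogonal
spectra); the director extraction therefore operates on the rank-truncated
reconstruction, where the mixing cancels identically, rather than on
single-component loadings.

## Director extraction

The per-pixel 1-fold spectrum F1(ω) (from the azimuthal DFT, or from the
SVD reconstruction for denoising) is projected onto the in-plane band
template Σ_m a_ip,m L_m(ω) e^{i·off_m}. Because the CH₃ dipole offsets are
built into the template, the projection phase *is* the molecular direction
θ — the "dipole exactly opposite" convention is applied once, here.
Magnitude = 2|projection| (the in-plane response amplitude ρ·s·f_ip);
pixels below 10% of the in-mask 99th-percentile magnitude are masked, not
guessed. The cross-check mode (`mode="band"`) solves the per-band linear
system and keeps the CH₃ SS coefficient — naive projection onto a single
Lorentzian would be phase-biased by the complex overlap of neighbouring
bands (≈17° with this band table). Phase arrows average 6×6-pixel blocks
(magnitude-weighted circular mean; blocks with resultant length <0.3
omitted).

Verified recovery: circular RMSE of θ inside domain interiors <0.01°
noiseless and ≈1.3° at amplitude SNR 10 (6 rotations). "Interior" excludes
2 px at the boundary, where LC and LE signal mix under any finite optical
resolution.

## Segmentation, composition, classification

Domains are segmented from the out-of-plane CH₃ band-integrated magnitude
(Otsu threshold, connected components, 3 µm² minimum area). Inside /
outside / total mean spectra obey the coverage-weighted recombination
identity.

Composition (the density/order estimator; a reimplementation defined by
its exact invertibility under the forward model, not a transcription):

* ρ_rel per domain = mean CH₃-integrated |F0| over the domain interior
  (segmented mask eroded 3 px, excluding the edge response). The
  out-of-plane response per molecule is assumed orientation-invariant
  between samples.
* s_rel per domain = median over interior pixels of 2|F1|/|F0| (CH₃
  windows). The median is robust to the suppressed-|F1| tail at a real
  boojum core, where the director turns within a pixel. |F1|² is debiased
  by (azimuthal residual power)/3 — the Rician correction for the 1-fold
  estimate from N = 6 angles — before the square root.
* Only ratios between samples are meaningful; contrasts are reported as
  percent differences. Injected 21%/22% density/order contrasts are
  recovered within ±1 point at SNR 20.

Texture classification fits both families by circular least squares
(1 − cos loss — bounded and wrap-safe), with the boojum centre searched on
a grid extending 1.5 domain diameters beyond the mask (virtual centres)
and refined by Nelder–Mead; the coarse grid runs on a ≤400-pixel
subsample, the refinement on all pixels. The linear family wins unless the
boojum residual is ≥10% lower *and* the linear residual exceeds 0.5° — a
flat field fits both families to ~zero residual and must stay "parallel".
Labels:

* class: parallel / radial (|q| < 0.5°/µm) / spiral; residual >25° RMS →
  "unclassified", never a guess.
* curvature: sign of the magnitude-weighted mean of ∇θ·(cos θ, sin θ)
  (wrap-safe central differences); negative → CW; |mean| < 0.1°/µm → n/a.
* spiral sign: '+' iff the iso-direction contours wind clockwise moving
  outward from the fitted centre; for θ = ψ + β + q·r the contours follow
  ψ = const − q·r, so '+' ⇔ q > 0. (Whether the printed (+)/(−) refers to
  contour or director winding is not pinned down by the source figures;
  the contour-winding definition is adopted and documented.)
* boojum: real iff the fitted centre lands on an in-domain pixel.

Classification is 100% correct over the seeded scene battery at SNR 10,
and mirror-equivariant: classifying a mirrored scene (or field) preserves
the class and flips CW↔ACW and +↔−.

Iso-direction contour lines are traced wrap-aware as zero crossings of
sin(θ − level) restricted to cos(θ − level) > 0; fields with circular
spread below 2° are flagged degenerate rather than contoured.

## Numerical and design notes

* All randomness flows from explicit integer seeds; identical seeds give
  bit-identical scenes and runs; the pipeline manifest records a config
  hash, stage timings and QC (registration correlations, masked fractions,
  fit residuals).
* Band deconvolution is bounded nonlinear least squares on (Re, Im)
  jointly: named bands within ±8 cm⁻¹ of their literature centres,
  unassigned bands within the 2800–2940 cm⁻¹ region *and* ±12 cm⁻¹ of
  their initial estimates — fully free unassigned centres can migrate onto
  a named resonance and silently absorb its amplitude, destroying the
  CH₂/CH₃ attribution. Γ ∈ [2, 15] cm⁻¹; three jittered restarts on
  failure, best residual wins, seeded. At SNR 20 (50 runs) the CH₃ SS
  centre is recovered to <1 cm⁻¹ in every run and the amplitude to 2.7%
  mean error; individual runs can reach ~11% through the Γ–amplitude
  trade-off, which is weakly identified at this noise level.
* Test problem sizes (96–128 px grids, 6 rotations, 20–60 seeded scenes,
  50-fit Monte Carlo) were chosen as the smallest at which the estimators'
  asymptotics are visible.

## What the synthetic data do and do not show

The generator emulates the geometry (domain size, textures, rotation
series), spectroscopy (band positions, signs, non-resonant offset,
envelope, quartz referencing) and detection (cross-term heterodyne, dark
offset, Gaussian noise, finite resolution at the domain edge) of the
experiment. It does not model hyperpolarizability tensors, Fresnel
factors, collection optics, camera nonlinearity, sample drift,
heterogeneous Γ, or within-domain disorder beyond the scalar order map —
so passing tests demonstrate the *analysis* is correct and well-scaled,
not that real data meet its assumptions. The sinusoidal in-plane /
constant out-of-plane rotation response is itself the modelling statement
the analysis relies on; higher azimuthal orders are surfaced only through
the confidence metric.
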