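# Methods

## Encoding model

The simulator implements a 2D projection FFL scanner.  In the gantry frame
(x′, y′, z′) the selection field is the trace-free tensor field
(Gx·x′, 0, −Gz·z′): it vanishes on the line x′ = 0, z′ = 0 and, because a
static field must be divergence free, the z gradient carries the sign
opposite the x′ gradient (quoted strengths are magnitudes).  The gantry
rotation R(θ) maps gantry to patient coordinates,
(x, y, z) = R(θ)(x′, y′, z′), with

    R(θ) = [[cos θ,  sin θ, 0],
            [−sin θ, cos θ, 0],
            [0,      0,     1]].

A homogeneous shift field along x′ (rotating with the gantry) translates
the FFL: the shifted in-plane field is Gx·x′ + H_s, so amplitude
H_s = −Gx·p places the line at x′ = p.  The drive field
H_d·sin(2πf₀t)·ẑ is fixed in the patient frame.  All fields are expressed
as B = μ₀H in tesla so that quoted values (25 mT drive, 1.5 T/m gradient)
appear literally and no μ₀ bookkeeping leaks into downstream modules.

Acquisition is strictly discrete: the FFL is static while each record of
`periods_per_point` drive periods is digitized, then stepped; one
projection per gantry angle, angles uniform on [0°, 180°).  There is no
continuous sweep, gridding, or velocity compensation.

## Tracer model

The tracer magnetization is the quasi-static Langevin law

    M(B) = c · s_sat · L(β‖B‖) · B/‖B‖,    L(x) = coth x − 1/x,

with concentration c in kg Fe/m³, specific saturation moment s_sat in
A·m²/kg Fe, and field scale β in 1/T.  Because fields already carry μ₀,
the single-particle relation is β = m_p/(k_B·T) with
m_p = (π/6)d³·M_s,bulk the particle moment.  The default tracer is an
ideal monodisperse 25 nm magnetite sphere at 300 K:
m_p ≈ 3.93·10⁻¹⁸ A·m², β ≈ 948 1/T (knee ≈ 1 mT), and
s_sat = M_s,bulk/(ρ·w_Fe) ≈ 128 A·m²/kg Fe using ρ = 5170 kg/m³ and an Fe
mass fraction of 0.724.  Commercial single-core tracers have broader,
weaker M(H) transitions than this ideal sphere and their fitted parameters
are generally proprietary; consequences are discussed under Limitations.
`fit_mh_curve` recovers (s_sat, β) from sampled M(H) data by nonlinear
least squares; at least three distinct fields spanning the knee are
required for the two parameters to be separable.

L(x) uses the series x/3 − x³/45 below |x| = 10⁻⁴ (series and closed form
agree there to 10⁻¹⁰).  The tracer environment temperature (300 K) is
deliberately independent of the 273 K used for Johnson noise.

## Signal chain

The receive sensitivity B₁/I is the coil field per unit current
(reciprocity).  For point masses m_Fe at positions r_s the coil flux is
Φ(t) = Σ_s (B₁(r_s)/I) · m_s(t) with m_s the Langevin moment of the
source, and the received voltage is the time derivative of Φ, evaluated
spectrally on the periodic steady-state record (exact for band-limited
signals; a central-difference oracle converges to it at second order).
Note the flux form carries no extra μ₀: B₁ in tesla per ampere times a
moment in A·m² is already a flux in webers.

Receiver noise is i.i.d. white Gaussian per digitized sample, with std set
to the Johnson noise of the dominant resistance over the digitization
bandwidth (9.77 nV for the head coil, 4.46 nV for the rodent coil, both at
273 K over 100 kHz).

Harmonic detection normalizes the DFT so a sinusoid of amplitude A at
k·f₀ gives |c_k| = A; records must span an integer period count (the comb
bins otherwise do not exist).  The projection value is the **real part of
the phase-referenced coefficient sum**: reference phases are computed once
per protocol from a unit source at the FFL center, and each measured
coefficient is rotated by them before taking the real part.  This keeps
the sinogram exactly linear in concentration and the detected noise
zero-mean Gaussian with std σ·√(2N_h/N) (N samples, N_h harmonics),
reduced by √n_averages for frame-averaged acquisitions; a magnitude
convention would instead Rician-bias the noise floor.  With a symmetric
drive the noiseless response contains only odd harmonics (the in-plane
field is static, so the z magnetization is odd under a half-period shift).

## Coil models

Windings are ordered straight segments with signed current multipliers;
fields use the exact finite-segment Biot–Savart closed form with a 1 μm
guard distance around conductors.  Circular loops default to 64-segment
polygons (inscribed-polygon bias +0.08%; +1.3% at 16 segments).  Solenoids
place their turns at the centers of N equal axial cells (pitch l/N), the
geometry of a physical single-layer winding; this reproduces the budget
table's center-field entries to ≤1.2% where the endpoint-inclusive
alternative deviates by up to 3%.  The racetrack (stadium) gradient pair
is two opposed flat filament loops — two straight sides joined by
semicircular ends — carrying turns×current ampere-turns each.

## Reconstruction and SNR

The forward operator column for pixel p is the noiseless sinogram of a
unit mass at that pixel center.  With ideal fields, uniform receive, and
sources in the slice plane, the projection value depends only on the
signed x′ offset u between source and FFL, so columns factor through a 1D
kernel K(u).  The fast path samples K exactly on a dense grid (32768
points over the needed range) and interpolates with a cubic spline; this
matches brute-force per-pixel simulation to better than 10⁻⁶ relative and
is validated against it in the tests.

Images solve min ‖Ax − b‖² + λ‖x‖² by conjugate gradients on the normal
equations; the default ridge λ = 10⁻⁶·tr(AᵀA)/n_pixels stabilizes the
deconvolution (the default grid matches the shift sampling: 35×35 over
the scan FOV).  Analytic SNR maps propagate the per-measurement noise std
through the rows of R = (AᵀA + λI)⁻¹Aᵀ: std_p = σ_meas·‖row_p R‖,
SNR_p = |x̂_p|/std_p.  The Monte-Carlo path draws measurement-level noise
(exact, since the comb filter is linear in the record) and uses the
empirical per-pixel std; at 500 realizations its estimator carries ~3%
sampling error, so agreement with the analytic map is asserted in
aggregate at 500 and per-pixel at 4000 realizations.

Projection peaks are fitted with both Gaussian and Lorentzian shapes; the
lower-residual shape supplies the reported FWHM.  Kernel width scales
inversely with gradient strength (verified at 1.5 vs 7 T/m).

## Scanner presets

* **human**: 53 projections × 35 points, 20 cm FOV, Gx = Gz = 1.5 T/m,
  25 mT @ 10 kHz drive, 16 periods per point at 200 ksps, 3rd-harmonic
  detection, head solenoid receive (uniform-sensitivity descriptor pinned
  to the coil's Biot–Savart center value, 92.6 μT/A), 9.77 nV noise, 200
  averages.  2.968 s per image, 593.6 s per averaged run.
* **rodent**: same schedule over a 4 cm FOV with 7 T/m, 50 mT @ 10 kHz,
  the small solenoid (444.6 μT/A) and 4.46 nV noise.

The uniform-receive descriptor is exact for sources at the isocenter and
keeps the shift-invariant fast path available; full Biot–Savart receive
profiles can be selected per protocol at brute-force cost.

## Phantoms

Phantoms are point masses in the slice plane; voxel phantoms expose voxel
centers as point masses, valid while the voxel pitch stays below the
projection kernel width.  The dose arithmetic ties them to physiology: a
400 mg Fe dose in 5 L of blood with 5% cortical blood volume puts ~108 ng
Fe in a 3 mm voxel, of which a ~20% activation-driven blood-volume change
modulates ~22 ng — the `point_22ng` preset.  The brain stand-in is a 2D
annular "cortical ribbon" (outer radius 9 cm, thickness 1.2 cm — invented
geometry) at 4 ng Fe/mm³ over an interior disc at 0.8 ng Fe/mm³ (the 5%
vs 1% blood-volume tissue concentrations); it emulates the gray/white
contrast of a segmented axial slice, not anatomy.

## Safety screening

Drive amplitude is checked against peripheral-nerve-stimulation limits
log-log interpolated between the published torso anchors (9.9 mT at
4.5 kHz, 7.6 mT at 25 kHz), constant outside, times a head-coil factor
(literature range 2–3, default 3).  The shift field is screened against
retinal magneto-phosphene thresholds both in amplitude (~40 mT) and slew
(~5 T/s), with the slew computed as a full linear sweep of G·FOV per
projection interval — the human preset lands at 5.35 T/s, flagged as at
threshold.  Gantry-rotation exposure uses the numerically maximized
|dB/dt| of the rotating ideal gradient at a given radius, which for that
field equals 2π·f_rot·G·r (0.94 T/s at 1.5 T/m, 10 cm, 1 Hz — below
threshold).  Values within 20% of a limit are flagged `near_threshold`.

## Limitations

* **Absolute signal levels depend on the tracer fit.**  The ideal 25 nm
  sphere saturates at ~1 mT, far below both drive amplitudes, which has
  two systematic consequences: doubling the drive gains almost no
  additional harmonic signal, and the projection kernel is broadened by
  the drive (FWHM ≈ 15 mm at 1.5 T/m, 3.3 mm at 7 T/m) rather than by the
  Langevin transition.  Real single-core tracers with broader M(H)
  transitions yield narrower, drive-sensitive kernels.  Reported absolute
  SNRs — and especially max-SNR *ratios* between scanner presets — are
  therefore regularization- and tracer-dependent: with the default ridge
  the rodent/human ratio for the 22 ng source computes to ≈ 4.7, while
  the measurement-domain matched-filter bound gives ≈ 16; design
  estimates based on relative detection sensitivity (~10×) times the
  drive factor (~2×) land near 19–20.  The package reports what its
  defaults compute.
* **Filament coils.**  Windings are zero-thickness filaments.  For the
  opposed stadium pair at its nominal dimensions (150 × 30 cm, 30 cm
  plane separation, 360 turns, 140 A) the isocenter gradient computes to
  0.90 T/m; distributed winding bundles (larger effective spacing) reduce
  this — the same pair at ~36 cm effective separation gives 0.7 T/m.
  Finite-element, permanent-magnet, and iron-yoke modeling are out of
  scope.
* No relaxation or hysteresis (Néel/Brownian dynamics), no particle size
  distribution, no tuned-circuit/transformer/preamplifier chain (a tuned
  circuit scales signal and coil noise together), no eddy currents, no
  drive feedthrough, no interior/truncated-projection reconstruction.
* The synthetic phantoms are deliberately simple: passing tests
  demonstrate correct linear-systems behavior of the pipeline (linearity,
  shift invariance, noise propagation, resolution scaling), not
  anatomical realism or in-vivo signal levels.
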