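# Methods

This note documents the models implemented in `derheo`, their assumptions,
the tunable parameters, the numerical choices, and what the synthetic-data
tests do and do not demonstrate about real measurements.

## 1. Coupled-oscillator model and de-embedding

Each microcantilever is a driven, damped harmonic oscillator (spring k,
dashpot c, effective mass m*), and the sandwiched cell couples the two
through a complex, frequency-dependent stiffness k_c*(f).  In the harmonic
regime the equations of motion reduce per frequency to a 2×2 complex linear
system; with the cantilever-alone receptances g_j(f) = 1/(k_j + 2πif·c_j −
(2πf)²m_j) the master-driven steady state is

    x_m − x_s = g_m F_m / (1 + k_c(g_m + g_s))
    x_m = g_m F_m (1 + k_c g_s) / (1 + k_c(g_m + g_s))
    x_s = k_c g_m g_s F_m / (1 + k_c(g_m + g_s)).

Substituting the three measured configurations into

    g_c(f) = χ_MS / (χ_MM·χ_SS − (F_m/F_s)·χ_MS²) · F_m

recovers k_c*(f) exactly — *provided* the force convention is consistent.
For F_m = F_s this is unconditional.  For F_m ≠ F_s the literal formula does
not invert the two-oscillator model; the package's default `normalized`
convention first rescales the slave-driven channel onto the master force
(χ_SS → χ_SS·F_m/F_s, i.e. the per-unit-force response re-driven at F_m),
after which the inversion is again exact.  The `verbatim` variant applies the
formula as written; both are exposed, the discrepancy is a documented
property, and the test suite pins the exactness of the normalized route and
the failure of the verbatim route under force asymmetry.

Samples where |χ_MM·χ_SS − (F_m/F_s)χ_MS²| falls below a floor (default
1e−6 × the band median of |χ_MM·χ_SS|) are flagged as ill-conditioned; the
extraction aborts if more than 20% of the band is flagged.

**Assumptions.** Linear response (the assay's amplitude-linearity is a
physical prerequisite, not checked by the algebra); one effective coupling
point per cantilever; cantilever and cell inertia entirely absorbed in the
lumped parameters.  Fluid-inertia effects, relevant only far above the band
(~400 kHz), are out of scope.

## 2. Calibration

The electronics chain delays the signal, adding a linear phase background
b₁f + b₂.  It is estimated on a cell-free sweep by least squares with a
resonance model plus linear term, then subtracted from every sweep read
through the same chain (MM uses the master chain's fit; MS and SS the
slave's).  Two resonance models are available:

* `sho`: φ(f) = atan2(f·f_cant/Q, f_cant² − f²) + b₁f + b₂, the
  single-oscillator form, fitted by Levenberg–Marquardt over the full band
  (parameters f_cant, Q, b₁, b₂; analytic branch chosen so the resonance
  phase rises 0 → π).
* `beam`: the structural phase of the multi-mode beam surrogate (§3) at the
  actual laser positions; only (b₁, b₂) remain, a linear least-squares
  problem.

The choice matters.  With f_cant ≈ 10 kHz and a band extending to ≈ 4 f_cant,
the second beam mode contributes percent-level, frequency-dependent phase
that the single-oscillator form cannot represent; the fit then aliases it
into (b₁, b₂) and biases the extracted g_c by ~20%.  The pipeline therefore
defaults to the calibration model that matches the structural model used for
the laser-position correction (`beam` when beam corrections are enabled);
`sho` remains available and appropriate when the band stays near a single
resonance.  This mirrors the experimental practice of deriving position
corrections from a full structural (FEM) model rather than from the lumped
form.

The effective actuation force defaults to a constant F₀ extracted from the
amplitude resonance fit, A(f) = (F₀/m*)/(4π²)·[(f_cant²−f²)² +
(f_cant·f/Q)²]^(−1/2), fitted in the centre region of the resonance (default
window f_peak/2 … 2·f_peak), with m* = k/(2πf_cant)².  Because the published
frequency dependence of the photothermal drive is not available, the force
model is pluggable: `constant`, `thermal_lowpass` (first-order low-pass with
cut-off f_th), or `tabulated`.  The spring constant in the metadata is
interpreted at the readout point so that calibration amplitudes and beam
statics agree.

## 3. Beam surrogate and laser-position correction

A clamped–free Euler–Bernoulli beam in modal superposition stands in for the
distributed cantilever:

    R(z_f, z_r, f) = Σ_n φ_n(z_f)φ_n(z_r) / (m_b·4π²·(f_n² − f² + i f_n f/Q_n))

with the standard clamped-free mode shapes (λ₁ ≈ 1.8751, λ₂ ≈ 4.6941, …),
f_n = f₁(λ_n/λ₁)², uniform modal damping Q_n = Q, and the mass scale m_b
fixed so the static receptance at the reference point reproduces the
calibrated spring constant (this pins the truncation error to zero at DC).
Mode shapes are evaluated in a cancellation-free exponential form so high
modes stay accurate.  The correction C(f) = R(z_red,z_red,f)/R(z_blue,z_red,f)
shifts the actuation point; a convergence guard recomputes it with two extra
modes and warns above 0.1% drift.

A useful exact property (proved by the receptance algebra and pinned by
tests): when the cell couples the beams *at the readout point*, applying the
free-beam correction to the coupled measurement reproduces the on-point
coupled measurement exactly — every channel is proportional to the drive-to-
contact receptance, which is the only factor the correction touches.  The
residual pipeline error therefore comes from model mismatch (truncation,
calibration), not from the correction algebra itself.

**Defaults and their rationale.**  n_modes = 6 for corrections (documented
accuracy envelope; the convergence warning fires when the band stresses it);
rectangular geometry (the real triangular cantilevers would need tabulated
mode shapes, for which a hook exists); laser spots treated as points at the
spot centres.

## 4. Validation harness (the headline numbers)

`pipeline.run_validation` forward-simulates the three configurations with a
12-mode beam "reality" (converged to <0.1% on the band), actuation at 0.1 L,
readout at 0.9 L, cell contact at the readout spot, per-chain injected phase
backgrounds (b₁, b₂) = (5e−5 rad/Hz, 0.3 rad) and (3e−5, −0.2), and a known
k_c*(f) = G·E*(f) anchored at the experimental stiffness scale of 3 mN/m.
The pipeline then re-estimates everything from generated cell-free sweeps
and corrects with its own 6-mode model — the same kind of structural
mismatch a real extraction faces.  Five qualitatively different cortical
rheologies are used (double power-law, structural damping, Maxwell,
polynomial, oscillating polynomial; the latter two are simulation-only
shapes that probe the extraction independently of fit-model structure).

Measured this way the worst-case deviation of extracted from generating
g_c(f) over 1–38 kHz is ≈0.85% for all five rheologies.  The deviation is
rheology-independent because the cell stiffness is ~1% of the cantilever
stiffness, so extraction errors act as a common multiplicative calibration
factor on k_c*.  A lumped-generator variant (`run_lumped_validation`,
colocated lasers, single-oscillator calibration) isolates the algebra from
beam mismatch and recovers k_c* to <0.1% noiselessly.

Error propagation worth knowing: a frequency-structured calibration error of
~0.8% in g_c biases the *small* double power-law amplitude B (= 0.05 A) by
~7% while leaving A at ~0.2% — the global fit shunts spectral-shape error
into the minor component.  Recovery statements about B are therefore made on
Monte-Carlo means, not single noisy realizations.

## 5. Solid-shell–liquid-core geometry

The compressed cell is a truncated sphere: plate separation H = 2R − Δ,
bulged free-surface radius R′ from exact volume conservation (linear in R′²,
so closed-form), contact radius a = √(R′² − H²/4).  A uniform-tension
membrane with internal pressure takes exactly this constant-mean-curvature
shape, so the geometry is the equilibrium membrane solution, not an
approximation.  The cortex resists areal stretch with 2-D modulus
K_A = E·h_cort/(1 − ν) (ν = 0.5 by default, config-exposed), optional
resting tension T₀ (default 0: with prestress the force acquires a
modulus-independent part and the linear g_c ↔ E* map would not exist);
tension T = T₀ + K_A·ΔA/A₀, Laplace pressure P = 2T/R′, plate force
F = T·dA/dΔ by virtual work at fixed volume, and stiffness k_cell = dF/dΔ by
central difference with step Δ/100 (a Δ/200 Richardson check is available).
Two evaluation routes — meridional quadrature over ~200 nodes
(`membrane_shell`, authoritative) and the fully algebraic closed form
(`plate_contact_surrogate`) — agree to numerical precision and cross-check
each other.

The geometry factor G = k_cell(Δ; E = 1 Pa, h_cort) is exactly linear in E
and in h_cort (thin shell), and is applied per frequency via the elastic–
viscoelastic correspondence principle: E*(f) = g_c(f)/G.  This assumes the
quasi-static shape is maintained across the band (shape inertia negligible
well below ~400 kHz).  G is *model-dependent*: a Hertzian sphere–plate
alternative (provided for comparison) has a much larger conversion factor
and therefore yields much smaller moduli for the same g_c — absolute moduli
magnitudes carry the geometry model's assumptions, while ratios, exponents
and crossing frequencies do not.  Because the membrane-stretching stiffness
of an unprestressed shell is small, the package's G makes the simulated
"3 mN/m cell" correspond to a large Pa-scale E; all validation quantities
are deliberately relative for this reason.

Thickness sensitivity: since moduli ∝ 1/h_cort exactly, varying h_cort by up
to ±36% around 200 nm (the reported cortex-thickness variability) changes
the extracted moduli by (1/0.64 − 1/1.36)/2 ≈ 41% relative to the nominal
value.  The reported measure is this half-range over nominal, i.e. the ±
variation induced by the thickness uncertainty; it is frequency-independent
by linearity.

## 6. Rheological models and fitting

Registered models (f₀ = 1 kHz unless overridden):

| model | E*(f) | parameters |
|---|---|---|
| single_pl | A(if/f₀)^α | A, α |
| double_pl | A(if/f₀)^α + B(if/f₀)^β | A, B, α, β |
| structural_damping | A(f/f₀)^α(1 + i·tan(πα/2)) + iμf/f₀ | A, α, μ |
| maxwell | E·(if/f_r)/(1 + if/f_r) | E, f_r |
| polynomial / oscillating_polynomial | complex polynomial in f/f₀ (± sinusoidal ripple) | coefficients (simulation only) |

Principal branch i^x = e^(iπx/2) throughout; the real/imaginary split with
cos/sin prefactors is verified against the complex evaluation by property
test.  The structural-damping and Maxwell forms are standard choices made
here (the originals being unavailable) and are config-overridable.

Fitting stacks Re and Im residuals into one unweighted least-squares problem
(TRF with bounds A, B, μ, E ≥ 0; α, β ∈ [0,1]; a relative-weighting option
exists but is off by default, matching the "unrestricted global fit"
convention).  The double power-law's label-exchange symmetry is resolved by
ordering α ≤ β after the fit.  Fit quality is reported through
ℓ1* = Σ|Re(y−ŷ)| + |Im(y−ŷ)| and ℓ2* = (Σ Re(y−ŷ)² + Im(y−ŷ)²)^0.5, and
ℓ2*² coincides with the minimised objective.  Standard errors come from the
Gauss–Newton covariance.

**Model selection.**  The single power-law is nested in both the double
power-law and the structural-damping form, so the raw ℓ2* minimum cannot
identify a nested generating model (the richer model always fits noise
slightly better).  Selection therefore uses a parsimony rule: among models
whose ℓ2* is within 1% of the minimum, the fewest-parameter model wins.  The
1% tolerance is the expected noise-fitting gain of ~2 extra parameters among
2N ≈ 372 residuals (≈0.3%), with margin; genuine model mismatch exceeds it
by an order of magnitude at 2% noise.

**Crossing frequency.**  E″ = E′ is solved by bisection (1 Hz tolerance)
after a coarse log-spaced sign scan on a 0.1–400 kHz bracket; crossings
above the measured band are extrapolations of the fitted model and are
labelled as such by the caller.  α = 0.5 single power-laws are degenerate
(E′ ≡ E″) and reported as such; multiple roots return the lowest with a
multiplicity flag.

## 7. Morphometrics and population statistics

STED line profiles across the cortex are fitted with the area-normalised
Gaussian I(s) = I₀ + I₁·exp(−4 ln2 (s−s₀)²/w²)/(w√(π/4ln2)), whose width
parameter w *is* the FWHM; I₀ absorbs constant background.  Per-cell
thickness is the mean w over that cell's profiles (10 in the reference
protocol); the population mean ± SD is taken over cells.  Cell radii from
imaging use two orthogonal centre lines, each fitted as two independent
cortex peaks; the radius is the mean diameter halved.

Size–stiffness correlation uses the Pearson coefficient with
t = c·√((n−2)/(1−c²)) against H₀: c = 0 (two-sided, n−2 df).  For moduli
sampled over frequency the default test aggregates (frequency-averaged
log-moduli); the per-frequency table is emitted alongside, with an optional
Benjamini–Hochberg adjustment (off by default, matching the convention of
reporting raw p-values).  Laplace-law reference curves E_P ∝ 1/R and
E_T ∝ 1/R² are anchored at a chosen (R₀, E₀).

## 8. What the synthetic data does and does not show

The generator emulates: the three-configuration sweep structure on the
1–38 kHz, 200 Hz grid; resonance-crossing cantilever dynamics (k = 0.35 N/m,
f_cant = 10 kHz, Q = 3); off-point actuation/readout via the beam surrogate;
per-chain electronics phase backgrounds; multiplicative log-normal amplitude
noise and additive Gaussian phase noise; cell-stiffness scales at the
experimental 3 mN/m; and populations with radius 7–11 µm, cortical thickness
194 ± 27 nm, and double power-law parameters around (1 kPa, 50 Pa, 0.1, 0.9)
with 20% scale scatter.

It does **not** emulate: triangular cantilever geometry (rectangular modes
stand in; absolute agreement with a triangular FEM cannot be asserted, only
internal consistency); hydrodynamic squeeze-film coupling through the medium
(the residual ≈4% no-cell coupling can at most be approximated by an
additive χ_MS offset, off by default); drive-force frequency dependence;
drift, 1/f noise, or cell-state changes during a sweep.  Passing round-trip
tests therefore validates the *analysis chain*, not the instrument physics.

Statistical power caveat: with realistic 20% biological scale scatter and
n = 10 cells, the 1/R and 1/R² Laplace scenarios are only marginally
distinguishable (~80% of seeded replicates) — consistent with the
observation that no size scaling is detectable in comparable data.  The
scenario-discrimination property test therefore runs at 10% scatter, where
the effect is resolvable; the generator exposes `scale_sigma` so both
regimes are reproducible.

## 9. Problem sizes and determinism

All validation and test computations are desk-scale by construction: 186
frequency points per sweep, ≤12 beam modes, ~200 meridional nodes, 20-seed
Monte-Carlo loops, and a 10,000-replicate type-I-error simulation; the whole
suite runs in well under a minute on one core.  Every stochastic element
takes a NumPy `default_rng` seed; fixed seeds give bit-identical sweeps.
The time-domain ODE cross-check integrates the equations of motion for 16
amplitude-decay times (transient burn-in) plus six measurement cycles and
demodulates at the drive frequency.

## 10. Known limitations

* The absolute geometry factor (hence absolute Pa values) depends on the
  unprestressed membrane-shell idealisation; bending, prestress and
  poroelasticity are not modelled (a prestress option exists for the force
  curve but is incompatible with the linear modulus conversion).
* The single-oscillator calibration biases extractions on bands that reach
  well past f_cant; use the beam-consistent calibration there (§2).
* The verbatim force-asymmetric de-embedding formula is not an exact inverse
  of the two-oscillator model; the normalized convention is.
* Crossing frequencies above the measured band are model extrapolations.
* Fits assume independent, identically scaled noise on Re and Im parts;
  no error-in-variables treatment.
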