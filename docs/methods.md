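# Methods

## Scope and model

`magnetodose` does force and dose bookkeeping for magnetomechanical
stimulation experiments: superparamagnetic particles internalized by
cells or injected into tissue, actuated by a static gradient magnetic
field, delivered on an intermittent schedule. Everything is reduced to a
1-D axial ("scalar co-linear") picture: the particle moment is taken to
be aligned with the local field, so the tensor force (m·∇)B collapses to
F = m·dB/dz. This matches how such experiments are reported — a single
axial gradient value per field generator — and avoids pretending to 3-D
field maps nobody measured. Off-axis fields, pole-tip finite-element
modeling and hysteresis are out of scope (the particles are
superparamagnetic: negligible remanence and coercivity).

Units are SI internally (kg, m, s, T, A·m²); the public API accepts and
emits the units of laboratory practice (nm, pg, μg, pN, μN, T/m, emu/g ≡
A·m²/kg), with conversions at the boundary only.

## Particle composition

Per-particle iron mass: m_Fe = (π/6)·d³·φ·ρ·w_Fe with core diameter d,
magnetite packing fraction φ, magnetite density ρ = 5.18 g/cm³, and
w_Fe = 3·55.845/231.533 ≈ 0.7236 from Fe₃O₄ stoichiometry. Defaults
describe a 56.60 nm core. The packing fraction default φ = 0.62 is a
*calibrated* constant: vendor-style composition assays for such
superparticles are rarely published, and 0.62 is what makes the default
geometry consistent with a measured per-particle iron mass of
2.21×10⁻⁴ pg; it is an ordinary parameter and can be overridden in any
config. The organic shell (polydopamine/ligand) is treated as
magnetically and elementally inert. A single effective core diameter is
used — no size-distribution modeling; the hydrodynamic (DLS) diameter is
metadata only.

Particle counts are real numbers (never rounded to integers): at the
10³–10¹⁰ scale integrality is meaningless and rounding would break the
count × per-particle-mass = total-mass identity that the tests enforce to
machine precision.

## Moment and force

Two moment modes:

* **calibrated** (default): the per-particle moment is backed out of a
  measured per-particle force at a known gradient, m = F/∇B. The bundled
  calibration holds two points — 1.59×10⁻⁵ pN at 3.25 T/m and
  1.27×10⁻⁴ pN at 16.0 T/m — and selects the point nearest in gradient.
  Two points are kept rather than one because the magnetization is
  field-dependent: the two settings imply different moments (4.89 vs
  7.94 ×10⁻¹⁸ A·m²), and collapsing them onto one Langevin curve would
  require the local flux density B at each sample, which is not
  characterized.
* **model**: M(B) = M_s·L(μB/k_BT) with L(x) = coth(x) − 1/x, crystallite
  moment μ = M_bulk·(π/6)d_c³ (d_c = 5.80 nm crystallites, M_bulk =
  480 kA/m, bulk magnetite — an assumption, stated as such), M_s =
  30 emu/g, T = 300 K by default (the magnetometry condition; 310 K for
  physiological scenarios). This mode requires the caller to supply the
  local field B. L(x) is evaluated by series below |x| = 10⁻⁴ to avoid
  cancellation; it is odd, monotone, and bounded by min(1, x/3).

Forces are bilinear products m·∇B; ensemble force is count × per-particle
force. Formatting switches pN → μN above 10⁶ pN.

## Field generators

*Electromagnet*: gradient vs coil current is fitted by ordinary least
squares through the calibration points (≥2 required, strictly increasing
currents) and hard-overridden to 0 at zero current; extrapolation beyond
the calibrated range warns. A least-squares line rather than
interpolation keeps the evaluator smooth and robust to a noisy added
point; typical published calibrations (e.g. 1.25/2.25/3.25 T/m at
1/2/3 A) are exactly co-linear, so the fit reproduces them exactly.

*Ring array*: the on-axis field of an axially magnetized annulus is the
difference of two closed-form solid-cylinder expressions
B(z) = (B_r/2)[u₁/√(u₁²+R²) − u₂/√(u₂²+R²)] (outer minus inner radius),
superposed over the stack with polarity signs; the gradient is the
analytic derivative of the same expression, finite at the magnet faces.
Tests pin this to a central-finite-difference check (10⁻⁴ relative) and
to a point-dipole far-field oracle of equal total moment (5% at
|z| ≫ R_outer). `study_ring_array()` builds the qualitative four-annulus
geometry (70 mm ID / 150 mm OD / 15 mm thick, two co-oriented pairs
opposed across a 15 mm gap); with an assumed N48-grade remanence of
1.40 T it yields a central gradient of ~20 T/m — order-of-magnitude
agreement with the ~16 T/m such devices are reported to produce. The
exact polarity arrangement of fielded devices is not published, so the
factory is validated qualitatively (antisymmetric B, maximal central
gradient), never against a specific printed gradient.

## Clearance and dose

Tissue iron series are fitted as m(t) = m₀e^(−kt) by OLS on (t, ln m):
with four time points a weighted nonlinear fit would be
over-engineering, and the log-linear estimator is closed-form and
reproducible. decay_rate = −slope; half-life = ln2/k (infinite for k ≤ 0);
r² is reported from the log-domain residuals. Non-positive masses are
rejected with the offending time point named.

The force timecourse divides each measured mass by the per-particle iron
mass and multiplies by the per-particle force. Between measurement days
the *fitted* exponential, not a raw-point interpolation, carries the
force, with t = 0 at injection; the cumulative mechanical dose is then
∫F(t)dt over the ON intervals of the schedule, by adaptive quadrature
(per-interval, summed — hence exactly additive over schedule
partitions), reported in pN·s. Under the bundled 14-day conditions this
dose evaluates to ≈3.3×10⁴ μN·s. No compartmental pharmacokinetics, no
uptake-mechanism or spatial-diffusion modeling.

## Schedules

Two protocol shapes: cyclic ON/OFF within one session (defaults 15/15 min
over 12 h → 24 ON intervals, duty cycle 0.5) and clock-anchored daily
sessions (defaults 3 × 15 min at 6:00/12:00/18:00 for 14 days → 42
intervals, 630 min ON). Clock times are naive local times on a day grid —
no timezone or DST handling, since the anchors are nominal. A trailing
partial ON cycle is truncated, not dropped (with the default parameters
the case never triggers: 720/30 divides evenly). Schedules are
deterministic, sorted, non-overlapping, and round-trip exactly through
CSV.

## Bioassay metrics

All scalar formulas, no image analysis (angles, diameters and footprints
arrive as measured tables):

* SFI = −38.3·(EPL−NPL)/NPL + 109.5·(ETS−NTS)/NTS + 13.3·(EIT−NIT)/NIT
  − 8.8 (Bain coefficients). Identity limbs score −8.8; the score is
  invariant under common rescaling of all six lengths.
* Viability% = 100·(A_sample − A_drug)/(A_control − A_blank). The drug
  control removes nanomaterial absorbance; the corrected form is
  invariant under a common shift of all four absorbances (the shift
  cancels in both differences) — the test suite guards against the naive
  A_sample/A_control implementation instead. Values outside [0, 100] are
  reported as-is; negative values warn.
* Orientation index Oi = cos θ after folding any input angle to the
  acute angle in [0, π/2] (axes are direction-free; folding is
  idempotent).
* G-ratio = axon diameter / fiber diameter ∈ (0, 1].
* Calcium metrics: F₀ = mean intensity before stimulation onset (default
  onset 50 s in a 650 s window); ΔF/F₀ = (F_stim − F₀)/F₀ × 100 with
  F_stim the post-onset mean — the averaging window is configurable
  because reporting conventions vary (instantaneous vs averaged);
  F_max/F₀ = post-onset max / F₀. ΔF/F₀ is reported ×100 because group
  values in this literature sit two orders above unit ratios, while
  F_max/F₀ stays a plain ratio (~1–2).
* MNCV = distance / (proximal latency − distal latency), mm/ms ≡ m/s.
* F/G-actin = plain ratio.

Batch aggregation reports median [Q1–Q3], the convention for these
non-normally distributed morphometrics.

## Synthetic data

Generators produce every input the chain consumes, with defaults at the
study conditions: per-cell uptake normal(2.05, 0.64) pg truncated at zero
(clipping, not redraw — simpler stream accounting; the induced mean bias
is < 1% at mean/sd ≈ 3.2 and is asserted in the tests); clearance series
m₀e^(−kt)·e^ε with lognormal noise (matching the log-linear fit model);
footprint records constructed by inverting the SFI through a single
severity parameter s (EPL = NPL(1+s), ETS = NTS(1−s), EIT = NIT(1−s), so
SFI = −161.1·s − 8.8, exactly invertible for targets in (−169.9, 152.3)
with positive lengths; nominal normal-limb lengths 40/20/12 mm);
orientation angles von Mises about alignment, folded to [0, π/2]
(concentration 0 reduces to uniform); calcium traces baseline + smooth
rise–plateau–decay transient (rise τ 15 s, decay τ 400 s) + additive
Gaussian noise; fiber pairs with lognormal fiber diameters (median 6 μm)
and G-ratios normal about the target.

Each generator draws from its own substream of one global seed (fixed
`SeedSequence` spawn keys), so outputs are byte-reproducible and adding a
generator never perturbs existing streams.

What the generators do *not* emulate: real per-animal correlation
structure, assay drift, photobleaching, heteroscedastic ICP-AES error,
or any biological treatment effect. Passing round-trip and recovery tests
therefore demonstrates that the estimators are correct and unbiased under
their own noise model — not that the noise model captures real
laboratory variability.

## Numerical choices

* Langevin series switch at |x| = 10⁻⁴; relative error of the two-term
  series there is ~10⁻¹⁶.
* Quadrature: `scipy.integrate.quad` per ON interval (limit 200);
  verified against a 2×10⁴-point trapezoid oracle at 10⁻⁶ relative.
* Clearance fit uses `numpy.polyfit` degree 1 (closed-form normal
  equations would be identical; polyfit's scaling is numerically safer).
* Test problem sizes: 10⁴ draws for mean-recovery checks, 200 replicates
  × 8 time points for clearance recovery, 10³ fibers for median
  G-ratio — large enough for the stated tolerances (1–5%), small enough
  that the whole suite runs in seconds.
* Counts and forces are compared at 1% relative tolerance in tests,
  matching 3-significant-figure reporting; chain values that inherit an
  upstream rounding (day-3 count, day-14 force) get 2–4%.

## Known limitations

* The 1-D co-linear force model cannot represent torque or off-axis
  force components; near a pole tip the true field is strongly 3-D.
* Calibrated-moment mode interpolates nothing between its calibration
  gradients: it selects the nearest point. With calibrations at two very
  different field strengths this is honest (magnetization differs), but
  a dense calibration would warrant a proper M(B) fit.
* The log-linear clearance fit weights late (small-mass) points more
  than a nonlinear least-squares fit would; with few time points and
  multiplicative error this is the right default, but heteroscedastic
  absolute error would argue for weighting.
* The ring-array factory is a plausible reconstruction of a
  four-annulus gradient device, not a validated model of any specific
  instrument.
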