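# Methods

## The device and the model

A skin-strain-actuated microfluidic pump converts cyclic skin strain into a
unidirectional liquid displacement without valves or moving parts.  An
elastomeric actuator chamber dilates under strain and drives flow through a
pair of *asymmetric pumping channels* (APCs): one with a high aspect ratio
(AR = h/w > 1) and one with a low aspect ratio (AR < 1).  When a strain ε
is applied orthogonally to the channel axes, the cross-sections deform as

    w' = w (1 + ε),    h' = h (1 − ν ε),    AR' = γ AR,
    γ = (1 − ν ε) / (1 + ε)

with ν the elastomer Poisson ratio (0.5 by default, incompressible).  The
asymmetry in strain-induced deformation (ASID) changes the two hydraulic
resistances oppositely relative to each other, so the suction (strained)
and discharge (relaxed) half-cycles split the actuator stroke unequally —
a strain-powered flow rectifier.

## Hydraulic resistance

Rectangular-duct resistance in the single-term lubrication form, written
with `a = min(w, h)`, `b = max(w, h)` so one expression covers both
orientations:

    R = 12 μ L / [(1 − 0.63 a/b) · a³ b]

`hydraulic_resistance` evaluates this exactly for any (possibly deformed)
cross-section; `approx_deformed_resistance` provides the first-order
small-strain expansions

    R'_LAR ≈ R_LAR · (1 − 0.63 AR)/(1 − 0.63 γ AR) · 1/(1 − ε/2)     (AR ≤ 1)
    R'_HAR ≈ R_HAR · (1 − 0.63/AR)/(1 − 0.63/(γ AR)) · 1/(1 + 5ε/2)  (AR > 1)

which agree with the exact route to second order in ε (verified by a
quadratic-shrink test on AR ∈ {1/3, 1/2, 2, 3}).  A validity flag warns
beyond |ε| = 0.15.  AR exactly 1 routes through the low-AR branch; both
branches give the identical value there.

Two numerical caveats found while validating, both documented in tests:

* The popular statement "low-AR resistance rises under tension" holds only
  for AR below roughly 0.4 at ν = 0.5; between ~0.43 and 1 the width gain
  outweighs the height loss and R' < R.  What actually drives pumping is
  that R'/R decreases *monotonically* with AR, so the strained divider
  always shifts toward the high-AR branch; that monotonicity is the tested
  invariant.
* The first-order HAR expansion is invalid just above AR = 1 (its ratio
  limit disagrees with the exact model there), producing a spurious ridge
  near the diagonal in approximate-model sweeps.  Analyses that probe the
  neighbourhood of AR = 1 should use the exact model; the package default
  for single-configuration PE is `model="exact"`.

## Quasi-static pumping efficiency

The equivalent-circuit model treats the two branches as parallel resistors
fed by a cyclic flow source.  The flow divider places the *cross*
resistance in the numerator (the lower-resistance branch carries the larger
flow): `Q_a = R_b/(R_a + R_b) · Q_total`.  Per cycle, a stroke volume
`V_total` is drawn through the strained resistances and returned through
the rest resistances; the pumping efficiency is the difference of the
high-AR branch's divider fractions between the two phases,

    PE = R'_LAR/(R'_LAR + R'_HAR) − R_LAR/(R_LAR + R_HAR)

PE is independent of `V_total`, zero exactly when the two ARs are equal
(any areas), and positive — transport from the high-AR branch toward the
low-AR branch — for every asymmetric pair.  Sign conventions: the scalar
`pumping_efficiency` is HAR-referenced (invariant under relabelling the
sides); the side-resolved `CycleResult.net` carries the geometry (positive
on the LAR side, negative on the HAR side, summing to zero); `pe_sweep`
uses the heat-map convention of positive for right-to-left transport, which
makes the grid antisymmetric under transposition for equal areas.

Observation channels — identical meniscus-readout channels downstream of
each branch — are held at their rest resistance on both phases (they lie
outside the strained footprint).  Being equal on both sides they only
dilute the divider asymmetry, strictly reducing |PE|.

`pe_sweep` defaults to the first-order model on a 101×101 log grid over
[0.1, 10] (the symmetric decade range samples the AR = 1 diagonal and the
antisymmetric corners exactly); at ε = 0.1 with equal areas the grid
maximum of |PE| is 0.063, i.e. 0.06 at two decimals, attained at the
antisymmetric corner.  The antisymmetric AR 3 / (1/3) pair at ε = 0.1
gives |PE| = 0.0535 (exact) or 0.0488 (first-order), both 0.05 at two
decimals.

Scaling one side's width and height by 1.5 (area ×2.25) lowers that side's
resistance ~5×; the attainable |PE| drops and the argmax leaves the fully
antisymmetric corner — with the exact model the high-AR member of the
argmax pair moves from AR 10 to AR ≈ 3.3.  Because of the first-order
artifact near AR = 1 noted above, the scaled-area comparison is made with
the exact model.

## Transient lumped network

The actuator is a compliant chamber: capacity `V₀(1 + βε)` with compliance
`C`, so with gauge pressure `P` and branch flows `Q_i = P/R_i`,

    C dP/dt = −V₀ β dε/dt − P (1/R_L + 1/R_R)
    dx_i/dt = Q_i / A_obs,i

where `x_i` is the liquid-filled length of branch *i*'s observation channel
and `R_i(ε, x_i)` the pumping-channel resistance at the current strain plus
the observation channel's per-length resistance times `x_i`.  Capillary
pressure and the air column beyond the menisci are neglected; outlets are
at atmospheric pressure.

Numerics: the strain waveform is a piecewise-linear trapezoid, integrated
segment by segment with a fixed-step classical RK4 (step ≤ τ/100, τ =
C·R_parallel at rest) — deterministic by construction, and the dynamics are
not stiff.  Zero-duration ramps are ideal steps applied as an impulsive
pressure jump `ΔP = −V₀βΔε/C`, mirroring the quasi-static theory's
instantaneous-load assumption.  Cumulative branch volumes are integrated
with the same RK4 stages as the pressure, making the volume balance
`ΣV_i + C·P + V₀βε = 0` exact to rounding (observed ~1e-15 relative; the
contract is 1e-6).  A meniscus leaving its observation channel raises
`DynamicRangeExceededError` — the device's dynamic range is exhausted and
the lumped model no longer applies.

Default parameters (the device the tests exercise): pumping channels
200×600 and 600×200 μm, 5 mm long; observation channels 500×500 μm, 10 mm;
viscosity 28 mPa·s.  The actuator's `V₀ = 1 μL`, `β = 2`, `C = 9.03e-3
μL/Pa` are free parameters chosen so τ ≈ 2 s for this channel pair and the
stroke is 0.1 μL at 5% strain — a time constant of a couple of seconds
means stabilization within ~15 s, the regime the benchtop protocol
(1 s ramps, 15 s holds) operates in.

Validated limits: an ideal step with 20τ holds reproduces the quasi-static
PE to ~1e-6 relative (1% contract); back-to-back cycling without
stabilization time degrades the mean per-cycle PE monotonically (single
stabilized cycle > 10 back-to-back > 20 back-to-back).  Over hundreds of
actuations the continuous design (no observation channel) repeats the same
cycle exactly, so its cumulative series is linear (R² > 0.999); the
observation-channel design accumulates a meniscus imbalance that perturbs
the per-cycle increment, curving the series and lowering its linear-fit R².
In this purely resistive model the drift *raises* the increment slightly
(the strained resistance sum is smaller than the rest sum, so a symmetric
series imbalance increases the divider difference); a measured decrease
would implicate effects outside the model, e.g. capillary pressure.  The
R² ordering — continuous ≥ non-continuous — holds either way and is the
tested property.  The long-run acceptance check uses 200 actuations of an
ideal-step cycle with 8 s holds (4τ, residual flow < 2%), keeping the
simulation at ~160k RK4 steps.

## Resultant strain on the sensor

DIC post-processing gives principal Lagrangian strain magnitudes M1, M2
and orthogonal unit directions û1, û2 per surface point.  The scalar the
pump responds to is the resultant strain along the sensor axis ŝ (the line
orthogonal to the reservoirs):

    ε_R = M1 (û1·ŝ) + M2 (û2·ŝ)

summed with *signed* projections by default — compressive resultants are
physical and appear as negative pumping — with a rectified
(absolute-projection) variant behind a flag.  The device-level predictor
⟨ε_R⟩ is the unweighted mean over grid points inside the closed footprint
(circle or polygon; boundary points count as inside).  Both quantities are
rotation-invariant (≤1e-9 in tests) and ⟨ε_R⟩ is bounded by the maximum
pointwise |M1| + |M2| inside the footprint.  Field files are point-list
CSVs carrying the first principal angle; û2 is its perpendicular, so
orthogonality is exact by construction.

## Measurement reductions

* **PE slope** — OLS of V_net/V_total against actuation count, HAR-side
  records sign-flipped before pooling (the two sides displace equal and
  opposite volumes).  Constant-y series return slope 0 with R² defined as 0
  by convention; error-bar weighting is not used (unweighted OLS).
* **Pumping rate** — OLS slope of cumulative per-set displacement across
  sets, divided by repetitions per set; a single set falls back to
  displacement/reps.
* **Correlation** — Pearson product-moment r of rates vs ⟨ε_R⟩ with the
  simple-regression identity R² = r².
* **Box summaries** — median, quartiles by linear interpolation between
  order statistics (the convention is stated because several exist),
  whiskers at the sample min and max.

OLS and r go through `scipy.stats.linregress`/`pearsonr`; definition-level
brute-force recomputations back them in tests to 1e-12.

## Synthetic inputs

The generators emulate the two measured inputs at the scales the wrist
experiments operate at (rates of order 0.01 μL per actuation): meniscus
series as an exactly linear trend (slope PE_true·V_total, default 0.02 and
0.1 μL) with i.i.d. Gaussian read-off noise (default σ = 0.002 μL, 10
actuations) mirrored across sides, and strain fields as a Gaussian
magnitude bump (default peaks 0.08/0.03, width 8 mm on a 40 mm grid) with
constant principal directions.  They are deterministic under a fixed seed
and round-trip bit-identically through the CSV readers.  They do not
emulate non-uniform load profiles, set-to-set drift, or correlated noise —
recovery tests therefore validate the estimators, not skin biomechanics,
and passing them says nothing about subject-specific published rates
(which depend on unrecorded biomechanics and are deliberately not targets).
A 500-seed campaign recovers the true PE within two Monte-Carlo standard
errors of the mean.

## Known limitations

* Quasi-static and transient models are purely resistive/compliant: no
  capillary pressure (hook present in the pressure balance), no channel
  compliance, no air-column resistance, uniform orthogonal load only.
* The first-order resistance forms degrade near AR = 1⁺ and beyond
  |ε| ≈ 0.15 (flagged).
* Meniscus tracking assumes equal observation cross-sections along their
  length and neglects contact-angle hysteresis.
* The actuator parameters β and C are not identifiable from published
  device dimensions; they are user inputs with defaults pinned only by the
  ~2 s time constant.
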