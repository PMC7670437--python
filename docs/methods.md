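# Methods

This note records the model choices, numerical settings and known
limitations of the package in one place.

## Scope and data flow

The pipeline runs COSMO file → sigma profile → activity coefficients →
equilibria (solubility, log K_OW, cocrystal diagrams), with error
statistics on top. Quantum-chemistry COSMO calculations are out of scope:
the `cosmo_io` module reads/writes their text output, and the `synthetic`
module generates physically well-formed stand-ins (spherical cavities,
charge-neutral segment tables, controlled donor/acceptor structure) so the
whole pipeline is exercisable and testable without external data. The toys
exercise the mathematics — normalization, conservation, fixed points,
consistency — not chemistry; agreement of the suite on toys says nothing
about predictive accuracy for real drugs, which requires real COSMO files
and experimental solubilities.

## COSMO files

Two text layouts are supported, auto-detected by sentinel strings: the
package's DMol3-style layout (lengths in Å) and a VT-database-style layout
whose sections are annotated `(au)` and parsed in atomic units
(bohr → Å conversion, factor 0.529177, applied at parse time only).
Validation enforces: positive segment areas; header cavity area within 2%
of the segment-table sum; every segment referencing an existing atom;
stored charge/area consistent with the stored charge density (1e-6
relative); and net charge |Σq| ≤ 0.01 e.

Hydrogen-bonding classes are assigned per atom and inherited by its
segments: O and O-bonded H are hydroxyl (OH); N, F and their hydrogens are
"other" (OT); everything else is non-hydrogen-bonding (NHB). Covalent
bonding is inferred from interatomic distances below 1.25× the sum of
covalent radii (Cordero values); hydroxyl takes precedence for a hydrogen
within bonding distance of both O and N/F. This detection rule is a
package choice — atom-class assignment schemes in the literature state the
classes but not the bond-detection procedure.

## Sigma profiles

* Averaging radius r_ave = 0.81764 Å (the VT-database value), configurable.
  The averaged segment itself is included in both sums (d_mm = 0).
* Grid: 51 points, σ ∈ [−0.025, 0.025] e/Å², step 0.001. Binning is
  standard linear interpolation: weight w = (σ − σ_left)/0.001 goes to the
  *right* grid point and 1 − w to the left. The opposite orientation
  (w to the left) would bias the profile's mean charge density; a unit test
  pins the mean-preserving choice.
* Segments beyond ±0.025 after averaging are clamped to the edge bin with
  a warning; areas are conserved exactly through averaging and binning.
* Three-part split: the hydroxyl/other parts receive, bin-wise,
  A^cls/(A^OH+A^OT) · p(σ) · (1 − exp(−σ²/σ_o²)) with σ_o = 0.007 e/Å²;
  the NHB part is the remainder, so the parts sum to the unsplit profile
  by construction and both HB parts vanish at σ = 0.
* Mixture profiles weight component profiles by x_i·A_i with A_i the total
  molecular area (constant weights); a bin-wise area weight would
  double-count p_i(σ).

## Activity models

All models expose `ln_gamma(x, T)` and support exact infinite dilution:
compositions may contain zeros, and the combinatorial term is evaluated in
ratio form (φ_i/x_i = r_i/Σx_j r_j), never by extrapolation.

**COSMO-SAC (2002).** Universal constants (VT-database set): a_eff = 7.50 Å²,
α′ = 16466.72 kcal·Å⁴/(mol·e²), c_hb = 85580.0 kcal·Å⁴/(mol·e²),
σ_hb = 0.0084 e/Å², q₀ = 79.53 Å², r₀ = 66.69 Å³, z = 10,
R = 1.987·10⁻³ kcal/(mol·K). These are configuration, not ground truth:
published COSMO-SAC studies cite them from parameterization papers and
different sigma-profile generation settings imply slightly different
optimal constants.

**COSMO-SAC (2010).** A_ES = 6525.69, B_ES = 1.4859·10⁸ (kcal·Å⁴·K²/(mol·e²)),
c_OH-OH = 4013.78, c_OT-OT = 932.31, c_OH-OT = 3016.43, σ_o = 0.007. The
hydrogen-bond term enters with sign `hb_sign = −1` by default: the
attractive (negative) form is the physical one and the one used by the
model's parameterization; the repulsive literal `+` form is available via
`hb_sign=+1` for comparison. Geometry constants (r₀, q₀, a_eff, z) are
shared with the 2002 set. The 153-segment (3 parts × 51 bins) fixed point
couples all parts.

**Segment fixed point.** Γ is iterated with damping 0.5 (the undamped map
two-cycles for hydrogen-bonding profiles); convergence is declared when
the undamped residual max|Γ′−Γ|/Γ < 1e-8 (configurable), with a hard cap
of 1000 iterations and an error carrying the residual on failure. The
solve is deterministic and seedless.

**Hansen Flory–Huggins.** χ_ij = V_i/RT·[(Δδ_d)² + 0.25(Δδ_p)² +
0.25(Δδ_h)²] with δ² in MPa = J/cm³, V in cm³/mol, R = 8.314 J/(mol·K);
χ_ij is asymmetric (it carries V_i). The multicomponent activity
expression in circulation,

ln γ_i = ln(φ_i/x_i) + 1 − φ_i/x_i + 2V_i Σ_j χ_ij φ_j² − V_i Σ_j Σ_k φ_j φ_k χ_jk,

is dimensionally ambiguous (χ already contains a molar volume) and, in its
literal φ_j² form, violates the Gibbs–Duhem relation at any asymmetric
composition (an analytic check on an equal-volume binary gives a residual
proportional to 2x₁−1). Three conventions are therefore shipped:

* `per-volume` (default): χ is divided by V_i before entering the
  V_i-weighted sums (χ′ = Hansen distance/RT, symmetric) — the
  dimensionally consistent reading of the literal structure;
* `as-printed`: the literal expression with the V_i-bearing χ;
* `regular`: ln γ_i^res = V_i(δ_i − δ̄)²_H/RT with δ̄ the volume-fraction
  average — the Hansen regular-solution form, the only variant that is
  Gibbs–Duhem-exact. Thermodynamic-consistency checks use this variant;
  the other two are retained for fidelity to the published structure.

`calibration.calibrate_chi_convention()` evaluates all three against the
published Flory–Huggins octanol/water log K_OW values computed entirely
from the embedded Hansen table at 298.15 K (the source tabulation states
no temperature; ambient standard is assumed). No convention reproduces any
published value to ±0.05 — the published set lies entirely at or below
log₁₀(0.151) ≈ −0.82, which would require γ^W,∞ < γ^O,∞ even for strongly
hydrophobic solutes, and no reading of the stated equations produces that.
The routine therefore reports the per-compound discrepancy for every
convention instead of absorbing it, and the default remains `per-volume`.

**Group contributions.** δ_d = ΣF_d/ΣV, δ_p = √(ΣF_p²)/ΣV,
δ_h = √(ΣE_h)/ΣV, δ_t² = δ_d² + δ_p² + δ_h², implemented exactly as the
source prints them; note the δ_h rule differs from the common van Krevelen
form √(ΣE_h/ΣV). Group values (F_d, F_p, E_h, V) are user input.

## Embedded Hansen table

42 substances (13 solvents, 29 drugs) with δ_d/δ_p/δ_h/δ_t, the
group-contribution molar volume used by Flory–Huggins, and the COSMO
cavity molar volume. The transcription resolves run-together digit strings
by maximizing the δ_t = √(δ_d²+δ_p²+δ_h²) consistency; three rows
(Salicylic acid, Carvedilol, Pentoxifylline) admit more than one
consistent reading and carry an `ambiguous` flag — they are excluded from
consistency checks and should not be treated as ground truth. The δ_t
consistency tolerance is printed-precision aware: 0.05 plus half an ULP of
the tabulated δ_t (values printed to fewer decimals legitimately deviate
more, e.g. a δ_t printed as "20" versus components giving 19.935).

## Equilibria

* The ΔC_p term of the saturation equation is implemented but defaults to
  0 (the common neglect); it vanishes identically at T = T_m.
* Gas constant: scipy's CODATA value (8.31446 J/(mol·K)).
* Mixed solvents: the user supplies solute-free solvent fractions; the
  solver rescales them by (1 − x) each iteration.
* The solubility fixed point x = exp(ideal − ln γ(x)) uses damping 0.5,
  tolerance 1e-8 on the ln-x residual, 500 iterations; if the substitution
  oscillates (strongly composition-dependent γ), the solver falls back to
  bracketed Brent root finding on the saturation residual, which changes
  sign on (0, 1) whenever T < T_m. Above T_m the result is clamped to
  x = 1 with a warning.
* log K_OW: the water-rich phase contains neither octanol nor solute (true
  infinite dilution); the octanol-rich phase is 27.5 mol% water; the
  total-concentration ratio C_o,W/C_o,O defaults to 0.151.
* Invariant points are found by 1-D bisection (Brent) of the
  activity-product residual along each pure-solid solubility line,
  parameterized by the solute-free coformer loading u; the scan bracket is
  log-spaced at the low end because strongly non-ideal systems cross the
  solubility product at very small loadings. The A-rich point is returned
  first. The cocrystal line solves (x_Aγ_A)^a(x_Bγ_B)^b = K_CC for x_B on
  an x_A grid between the invariant points with a damped inner fixed point
  (tolerance 1e-8), warm-started from the previous grid point; endpoints
  are the invariant points themselves. All solvers are deterministic.
* K_CC is determined from a single saturated composition
  (`kcc_from_point`); fitting to multiple points is out of scope. A larger
  K_CC (a more soluble cocrystal) narrows the span between the invariant
  points.
* Mass-fraction diagrams require user-supplied molar masses; the source
  tables do not include them.

## Synthetic data

Toy molecules place equal-area segments on a Fibonacci sphere whose total
area is the requested cavity area (default 150 Å², 60 segments — the scale
of a small organic molecule), in a seed-dependent rigid orientation.
Charge patterns: `neutral-apolar` draws σ ~ U(−0.004, 0.004) so every
averaged |σ| stays below the hydrogen-bond cutoff 0.0084 e/Å² (HB energies
exactly zero); `donor-acceptor-pair` puts opposite polar caps at
±0.012 e/Å² (beyond the cutoff, activating HB terms) on an O/H atom pair;
`uniform` is for degenerate-input tests. The background charges are
shifted so the net charge is exactly zero without touching the patches.

Synthetic solubility studies use multiplicative log-normal noise
x_obs = x_true·exp(ε), ε ~ N(0, sd²), the natural error model for
positive, orders-of-magnitude-spanning solubilities; at sd = 0.1 the
expected relative deviation E|e^ε − 1| ≈ 8%. Defaults (20 temperatures over
280–340 K, sd = 0.05) represent a careful single-lab campaign. ΔH_m
recovery regresses ln x on (1/T_m − 1/T)/R through the origin; the
standard error comes from the residual variance, and the generating value
is recovered within 2 SE at the default noise level.

## Statistics

AAD% = 100·mean|Δ/Ω_exp| (undefined for zero experimental values; the
offending index is reported), RMSE = √(mean Δ²). The goodness-of-fit
measures are the "fit" conventions with the experimental series as
reference: NRMSE = 1 − ‖e‖/‖Ω_exp − mean‖ and NMSE = 1 − ‖e‖²/‖...‖²,
where 1 is perfect and negative values mean worse than the mean predictor
— the only conventions consistent with negative reported NMSE values in
the literature this package accompanies. NMSE = 1 − (1 − NRMSE)² holds
identically and is asserted to prevent convention drift.

## Problem sizes and determinism

The test suite and the acceptance script run on 51-bin (2002) and 153-bin
(2010) fixed points, toy binaries/ternaries, a 20-point recovery study and
a 50-point noise study; everything completes in well under a minute on one
CPU. Every stochastic quantity derives from an explicit integer seed; all
solvers are deterministic.

## Known limitations

* Toy COSMO surfaces are not chemistry: no conformers, no realistic charge
  correlation, spherical cavities only.
* The VT-layout parser handles the package's own annotated format and
  best-effort variants; exotic third-party COSMO dialects may need the
  explicit `dialect` argument or preprocessing.
* The published Flory–Huggins log K_OW set is not reproducible from the
  stated equations and tabulated inputs (see calibration above); the
  package reports its own computed values.
* Later COSMO-SAC revisions (dispersion terms, decay-factor averaging,
  equation-of-state coupling) are intentionally out of scope.
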