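# Methods

## Physical model

A titration consists of n identical injections of volume V_inj of a
peptide solution at syringe concentration c_inj into a cell of volume
V_cell. Concentration bookkeeping is additive: injection n takes the cell
from c_(n−1) to c_(n−1) + Δc₀ with Δc₀ = c_inj·V_inj/V_cell, treating the
cell volume as constant. An overflow-displacement variant (each injection
also displaces a fraction V_inj/V_cell of the current contents) is
available via `cell_concentration_series(..., displacement=True)` but is
not the default, because the additive model reproduces the instrument's
own reported concentrations. The optional 2 μL lead-in (null) injection is
excluded from both analysis and bookkeeping.

The injected material is partly aggregated (fraction f_agg = 1 − c_s/c_inj,
with c_s the monomer solubility). Below c_s the aggregates dissolve. The
monomer production is modelled with the sigmoidal test function

    c_mon(t) = c_mon(0) + (1 − f_agg)·Δc(t) + f_agg·Δc(t)·(1 − e^(−kt))^α ,

where Δc(t) = Δc₀(1 − e^(−k_inj t)) is the smoothed injection ramp. The
exponential ramp replaces the ideal piecewise-linear ramp (which is kept
in the API for reference) to avoid a discontinuous first derivative;
k_inj = 1/15 s⁻¹ mimics a 30 s injection. The dissolution differential
power is A·d/dt of the third term:

    ΔP_dis(t) = A f_agg Δc₀ [ k_inj e^(−k_inj t)(1−e^(−kt))^α
                 + (1−e^(−k_inj t)) α k e^(−kt)(1−e^(−kt))^(α−1) ] ,

which integrates in closed form to ΔH_dis = A·f_agg·Δc₀. For α > 1 the
power vanishes at t = 0 and has a single delayed extremum — the lag
phase. Dilution heats are modelled empirically: a half-sine
B·sin(ωt − δ) on its half-period support (windowed to zero outside so the
signal is integrable), plus, above c_s, an endothermic Lorentzian
C/[1 + w(t − δ_L)²].

Sign convention: ΔP is baseline-subtracted and exothermic events are
negative, so A < 0 reproduces the observed dissolution minima.

Units are s, μJ/s, mM and μL throughout. Molar enthalpies come out of the
identity μJ/(mM·μL) = kJ/mol; the default normalisation is per mole of
*dissolved aggregate* (dissolved_fraction·f_agg·Δc₀·V_cell), with a
per-mole-of-injected-peptide alternative exposed alongside, since the two
differ by the factor f_agg and either convention is defensible.

## Synthetic data generator

The generator emulates the two reference experiments: 27 × 10 μL
injections of a 30 mM solution into a 1.46 mL cell initially at 0 mM
(experiment A) or 4.4 mM (experiment B), 30 s injections, 1 h spacing, 1 s
sampling. Ground-truth kinetics per injection are derived from the cell
concentration before the injection: k from the reversible rate law
k⁻¹(c) = k₀⁻¹·c_s/(c_s − c) with defaults k₀⁻¹ = 30 s and c_s = 5 mM, and
the lag exponent interpolated linearly from α = 10 at infinite dilution to
1 at c_s. The interpolation law is a declared modelling choice — the decay
of the lag with concentration is qualitative in the experiments the
generator emulates. The amplitude A corresponds to a molar dissolution
enthalpy of −1.4 kJ/mol (A = −1.4·V_cell μJ/mM). Dilution heats default to
−30 μJ (half-sine, completing within ~2 injection times) and +15 μJ
(Lorentzian, above c_s); they are an order of magnitude smaller than the
dissolution heat, as in the experiments. An injection that straddles c_s
dissolves only the fraction clip((c_s − c_before)/Δc₀, 0, 1) of its
aggregate, scaling A accordingly.

Instrument imperfections are additive: a drift polynomial of degree ≤ 3 in
absolute time plus i.i.d. Gaussian noise (default SD 0, typical
instrument-scale value ~0.01 μJ/s). Each injection's components extend
from its onset to the end of the trace, so unfinished dissolution tails
carry into later windows exactly as in a real series. Simulations are
deterministic for a fixed seed; seeds only change the noise realisation.

What the generator does **not** emulate: the calorimeter's feedback
response (peaks are the empirical shapes themselves, not convolutions),
temperature dependence, heat-of-dilution physics (empirical amplitudes
only) and any concentration error sources other than the bookkeeping
model. Passing recovery tests therefore demonstrates correctness of the
decomposition machinery under the stated signal model, not robustness to
instrument physics outside it.

## Preprocessing

Peak boundaries are detected per injection slot as the first and last time
|dΔP/dt| of a moving-average-smoothed copy (default window 5 samples;
wider, e.g. 51, is appropriate when noise is large relative to the 2×10⁻³
μJ s⁻¹ per s threshold) exceeds the threshold. Two robustness devices:
the effective threshold is floored at 5× the robust (MAD) noise level of
the smoothed derivative, so detection cannot degenerate into whole-window
"peaks" on noisy data; and the search stops a few samples short of each
slot's end, because smoothing smears the next injection's onset step
backwards across the boundary.

Baseline correction is two-regime: one global third-degree polynomial
subtracted outside all peaks, and a first-degree polynomial (straight
line) across each peak interval. Two choices here deviate from the naive
procedure, both because slow dissolution tails are still measurably above
baseline at the detected peak end (the signal there is ≈ threshold/k):

* the in-peak line joins the *fitted baseline polynomial* evaluated at the
  peak bounds rather than the raw signal values (`peak_endpoint="signal"`
  restores the literal variant). Raw endpoints sit on the tail and would
  remove ~1% of the dissolution area;
* the polynomial's fit support excludes a right-hand margin of one
  peak-width after every peak and, when the schedule is known, the first
  2/3 of every injection slot. Near c_s the dissolution is slow enough
  that it never crosses the detection threshold at all, and without the
  slot-based exclusion its quasi-constant signal bends the global cubic.

Baseline correction is idempotent, leaves zero traces untouched, and
recovers a pure cubic drift to machine precision.

## Decomposition fitting

Each injection window is fitted independently (no parameters shared across
windows) as half-sine + (above c_s) Lorentzian + (below c_s) dissolution.
The dilution shape constants (ω, δ; w, δ_L) are calibrated on a few
windows with all shape parameters free and then frozen for the series,
with only the amplitudes B, C varying per injection — mirroring the
original analysis protocol. Because the small half-sine is weakly
identified on windows dominated by dissolution, the calibration takes the
median constants over up to five windows per shape family.

The per-window fit is Levenberg–Marquardt least squares (lmfit) over
(A, k⁻¹, α, B[, C]) with α bounded to [1, 20], k⁻¹ to [1 s, 10×spacing],
k_inj fixed at 1/15 s⁻¹ and a multi-start over α ∈ {1.5, 3, 10} with
best-RSS selection. k⁻¹ is initialised from the (smoothed) location of the
delayed power minimum. A window failing from every start is reported with
`converged=False` and absent parameters.

Because near-solubility dissolution is, on a single pass, statistically
indistinguishable from baseline drift, `fit_series` re-estimates the
baseline on the trace minus the fitted per-injection models and refits
(default 3 passes). The separation converges geometrically; three passes
bring noiseless round-trip errors of all well-constrained injections below
10⁻³ relative.

Dissolution enthalpies use the closed form A·f_agg·Δc₀; dilution
enthalpies are trapezoidal quadratures of the fitted shapes over the
window. The assembled series flags injections with fitted k⁻¹ > spacing/3
as unreliable: their dissolution is not complete before the next
injection, so the window cannot constrain the tail.

Problem sizes used by the test suite: the full 27-injection series at 1 h
spacing and 1 s sampling for noiseless round-trips, and a 6-injection,
600 s-spacing series for the 20-seed noise ensemble — chosen so the whole
suite runs on a laptop in well under a minute while every injection that
the criteria assess keeps ≥ 20 dissolution e-folds inside its window.
Round-trip accuracy is asserted for injections with
3·k_inj⁻¹ ≤ k⁻¹ ≤ spacing/10: below that range the dissolution is not
separable from the injection ramp, above it the unfinished tail carries
into the next window.

## Secondary analyses

* Reversible rate law: k⁻¹(c) = k₀⁻¹·c_s/(c_s − c). This is the unique
  simple form with the two required limits (k₀⁻¹ at infinite dilution,
  divergence at c_s) for a process whose net rate is detachment minus
  attachment; `fit_rate_model` estimates (k₀⁻¹, c_s) by least squares with
  c_s constrained above the largest data concentration.
* Diffusion-limited reference: a sphere at infinite dilution shrinks as
  R(t) = √(R₀² − 2·D·v·c_s·t) and vanishes at t = R₀²/(2·D·v·c_s). v is a
  molar volume in cm³/mol (derivable as M/ρ = 829/1.5 ≈ 550); v·c_s is the
  dimensionless volume fraction, and all conversions are SI. With
  D = 2×10⁻¹⁰ m²/s, R₀ = 100 nm and c_s = 5 mM this gives ≈ 9 ms. Note
  that with c_s = 2 mM instead (the pH-derived solubility) the same
  formula gives ≈ 23 ms; the package never hard-codes c_s, because the
  different experimental routes to it (light scattering 5 mM, calorimetry
  ~8 mM, pH 2 mM) disagree for reasons that remain open.
* pH model: pH = −log₁₀[(c − c_s)·f] above c_s (concentrations in mol/L,
  base-10 logarithm — the standard convention), solvent pH below.
  `fit_ph_deprotonation` fits (c_s, f) on points clearly on the acid
  branch (pH < pH_solvent − 0.2), with f constrained to (0, 1]. No
  activity corrections are applied.

## Known limitations

* The fitted α is poorly determined when most of the lag phase hides under
  the dilution peak (high concentrations, α → 1); k⁻¹ and ΔH are much
  more robust.
* Injections within ~Δc₀ of c_s mix partial dissolution with a diverging
  timescale; their parameters are reported but flagged unreliable.
* The derivative-threshold/baseline procedure assumes the drift is
  globally polynomial of degree ≤ 3; faster instrument wander would alias
  into the slow components.
* No Bayesian uncertainty quantification: standard errors come from the
  least-squares covariance only.
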