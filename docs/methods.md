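# Methods

## The coupled binding model

One membrane-protein entity A (a trimeric channel treated as a single
binding unit) binds one soluble partner G (also trimeric, 1:1
trimer-to-trimer) and up to `n_max` lipids L. All concentrations are molar
in trimer units; display conversion to µM/nM happens only at I/O. Species
weights relative to apo A follow from mass action,

    w(AL_n)  = [L]^n ∏_{j≤n} K_A,ALj
    w(AGL_n) = K_A,ALnG [G] [L]^n ∏_{j≤n} K_A,ALj ,

and mole fractions are weights over the binding polynomial. The model is
parameterised by `{K_A,AG, K_A,ALn, K_A,ALnG}`; the lipid-binding constants
of the complex, `K_A,AGLn`, are not free parameters — they are fixed by
thermodynamic cycle closure `K_A,AGLn = K_A,ALn · K_A,ALnG / K_A,AL(n-1)G`,
which the test suite asserts as an algebraic identity on every fitted set.

The background nucleotide (ADP) required for complex formation is held at a
fixed concentration in the experiments being modelled and is not an explicit
species: all constants are apparent constants at that background. The
nucleotide-titration scenario treats each nominal level as its own apparent
`K_D,AG`.

Weights are evaluated in log space (log-sum-exp normalisation) so that
`n·log(K·L)` products cannot overflow; an error is raised only on NaN.

## Free-concentration solution

The mass-balance system in (free G, free L) is solved by damped fixed-point
iteration `g ← G_tot − bound_G(g, l)`, `l ← L_tot − bound_L(g, l)` with
damping 0.5 (halved whenever the residual grows), residual-based convergence
at 1e-12 relative, and an iteration cap of 2000. If the iteration stalls the
solver falls back to nested bounded root finding (Brent's method on free L
with an inner solve on free G), which is guaranteed to converge because both
residuals are monotone in their own variable — binding polynomials are
monotone in the free concentrations, which also gives uniqueness of the
root. The cap is deliberately modest: the fallback is exact, so a long
fixed-point tail buys nothing.

Two evaluation modes exist for calculated fractions. `self_consistent`
solves the full system and is used for simulation-side truth and
predictions. `measured_fractions` takes free [G] and [L] from the *observed*
fractions via the mass balances and evaluates the model fractions at those
free concentrations — the literal form of the published analysis — and is
the default during fitting. Both agree at the optimum on noise-free data
(tested). A negative implied free concentration is never clamped silently;
it raises, because it means the observed fractions contradict the stated
totals.

## Global titration fit

The pseudo-χ² objective sums squared deviations of all `F_ALn` and `F_AGLn`
over every titration point, unweighted. Constants are optimised as log₁₀
values bounded to [0, 12] (positivity plus search conditioning). The search
uses a derivative-free Nelder–Mead simplex from 16 seeded uniform starts in
log₁₀K ∈ [2, 8] plus one data-derived heuristic start (lipid-free point →
K_A,AG estimate); the best simplex solution is then polished by bounded
trust-region least squares, which reliably takes the noiseless round-trip
error below 1e-10 in log₁₀K where the simplex alone can stall near 1e-5.
Each replicate is fitted independently; constants are aggregated as mean ±
s.e.m. on the log₁₀ scale (geometric-mean constants), matching how replicate
uncertainty is reported in this field. Identifiability is checked up front:
every lipid count up to `n_max` must be observed in at least one point, else
the unconstrained parameters are named in the error.

Non-specific +1 nucleotide adduct satellites are folded into their parent
species before fraction conversion; rows claiming ≥ 2 non-specific adducts
are outside the modelled ionisation behaviour and are dropped with a
warning.

## Coupling factors and classification

Default convention (`lipid_event`): `α_i = K_A,AGLi / K_A,ALi`, equal by
cycle closure to `K_A,ALiG / K_A,AL(i-1)G`, defined for every event i ≥ 1.
A `verbatim` convention `α_i = K_A,AGLi / K_A,AGL(i-1)` is also provided;
its denominator does not exist at i = 1, so it is restricted to i ≥ 2 and
requesting i = 1 is an explicit error. The per-event convention is the
default because it is defined for the first lipid and is invariant to a
common rescaling of all constants (tested).

Classification per event: neutral if `|α − 1| ≤ 0.05` (practical
equivalence) or if the `z·s.e.m.` interval (z = 1) overlaps 1; otherwise
positive (α > 1) or negative (α < 1). The equivalence margin exists because
the s.e.m. of three replicates is itself a noisy, small-sample estimate: a
genuinely neutral system lands more than one estimated s.e.m. away from 1
roughly 40% of the time (Student-t with 2 degrees of freedom), so a bare
error-bar-overlap rule would over-call tiny deviations whenever the fit is
precise. A 5% change in a ratio of association constants is below what these
titrations resolve as a real allosteric effect, and the margin is far below
the smallest effect the synthetic panels construct (|α − 1| ≥ 0.2). The
coupling trend is an ordinary least-squares slope of α against event index.

## Van't Hoff thermodynamics

The nonlinear van't Hoff model with constant ΔC_p is fitted on ln K_A (not
K_A, avoiding an unstated heteroscedasticity choice). The model is linear in
the transformed parameters a = (ΔH_T0 − T0·ΔC_p)/R, b = ΔC_p/R, c = ln K0,
so the fit is solved exactly by linear least squares — same model, no
iterative optimiser to tune. T0 defaults to 298 K (configurable);
R = 8.31446 J mol⁻¹ K⁻¹. At least 4 distinct temperatures are required for
the 3-parameter fit. ΔG(T0) = −R·T0·ln K0 and ΔS(T0) = (ΔH − ΔG)/T0 are
derived properties, so the thermodynamic identities hold by construction;
r² is computed on ln K_A, with the convention that a zero-variance target
with zero residuals is a perfect fit. Per-replicate fitting then mean ±
s.e.m.; K0 is averaged on the log scale. The ΔC_p = 0 limit reproduces the
linear van't Hoff line exactly (tested as model nesting).

## SPR kinetics

Langmuir 1:1 sensorgrams use the closed form (association
`R = Req(1 − e^{−(kon·C+koff)t})` with `Req = Rmax·C/(C+KD)`; dissociation
exponential from the response at the injection end). The closed form is
cross-checked in the tests against numerical integration of
`dR/dt = kon·C·(Rmax − R) − koff·R`. Fitting is global nonlinear least
squares over (log₁₀kon, log₁₀koff, Rmax) shared across concentrations, with
a koff initial guess from the log-linear dissociation tail and a small kon
multi-start. Mass-transport limitation, drift, and bulk refractive-index
jumps are not modelled; traces are assumed reference- and buffer-subtracted.
A single-concentration series triggers an identifiability warning (kon and
Rmax trade off).

## Synthetic data: what it emulates and what it does not

Generators write the same CSV/YAML/JSON formats the analysis consumes.
Defaults encode the study conditions: both proteins at 2 µM, a 12-point
lipid titration (0–150 µM, roughly log-spaced so all three lipid-binding
events are populated), three replicates, lipid-free `K_D,AG = 1.12 µM`,
lipid constants of order 1–2 × 10⁵ M⁻¹, 5% lognormal intensity noise, and a
5% +1-adduct satellite fraction. Intensity noise is multiplicative lognormal
per species with a median-1 multiplier (`exp(σZ)`), matching the error
character of MS peak intensities and preserving expected fractions to first
order; Dirichlet composition resampling is available as an alternative.
Thermodynamic truth for the temperature series is ΔH(298 K) = −80 kJ mol⁻¹,
ΔC_p = −4 kJ mol⁻¹ K⁻¹ (enthalpy-driven binding with strongly negative heat
capacity, the regime the analysis targets) over 284–302 K; SPR truth is
kon = 5.49 × 10⁴ M⁻¹ s⁻¹, koff = 3.14 × 10⁻² s⁻¹.

The preconfigured scenarios build panels with one synthetic lipid per
allostery class (coupling factors per event: positive 1.4/1.8/2.2, neutral
exactly 1, negative 0.78/0.72/0.66; a stereochemistry panel reaching
α₃ = 5.28 and 1.71) and a nucleotide titration whose apparent K_D falls
monotonically from 3.8 µM to 77.68 nM with an ~80 nM asymptote.

Not emulated: raw m/z spectra, charge-state envelopes, deconvolution
artifacts beyond the +1 adduct satellite, detector saturation, and any
species-dependent ionisation-efficiency bias. Passing round-trip tests
therefore demonstrates the correctness of the estimation pipeline given
faithfully deconvolved intensities, not robustness to deconvolution error.

## Numerical choices and limitations

- Fractions are validated to sum to 1 within 1e-10 and mass balance to 1e-8
  relative; titration points accept a 1e-6 sum tolerance (experimental
  rounding).
- Problem sizes in tests and the acceptance script (12-point titrations,
  ≤ 3 lipids, 3–4 replicates, 100–200 random solver draws) are the study's
  own scale; fits complete in seconds each.
- The χ² surface is only explored from 17 starts; pathological parameter
  sets far outside log₁₀K ∈ [0, 12] are out of scope by construction.
- Replicate uncertainty is refit-based (mean ± s.e.m. across replicates),
  not curvature-based; single replicates report NaN s.e.m. and are
  classified with the error bar treated as zero.
- The sequential-binding helper assumes strictly ordered stepwise sites and
  ignores statistical-factor corrections; it is meant for occupancy
  predictions from published stepwise K_D values.
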