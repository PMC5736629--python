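# lipallo

Quantifying how individual lipid-binding events allosterically modulate the
interaction between an integral membrane protein and a soluble regulatory
protein, from native mass spectrometry titration data.

## The problem

Native MS resolves individual ligand-binding stoichiometries of intact
protein complexes. For the *E. coli* ammonia channel AmtB (a trimer, treated
as one binding entity A) and its regulator GlnK (a trimer, G), a deconvoluted
spectrum at one lipid titration point yields intensities for every species
`AL_n` (channel with n lipids) and `AGL_n` (channel–regulator complex with n
lipids). Converting those intensities to mole fractions and fitting a coupled
equilibrium model across the titration gives every association constant in
the scheme — and therefore a direct, per-binding-event measure of whether a
lipid strengthens or weakens the protein–protein interaction.

`lipallo` is aimed at native-MS practitioners who have species-abundance
tables (e.g. UniDec output) for a titration and want binding constants,
coupling factors, and binding thermodynamics out the other end.

## The model

Species equilibria (association constants, M⁻¹):

- `K_A,ALnG = [AL_nG] / ([AL_n][G])` — G binding to A carrying n lipids
  (`K_A,AG` for n = 0),
- `K_A,ALn = [AL_n] / ([AL_(n-1)][L])` — the n-th lipid binding to A,
- `K_A,AGLn = [AGL_n] / ([AGL_(n-1)][L])` — the n-th lipid binding to AG,

linked by thermodynamic cycle closure
`K_A,AGLn · K_A,AL(n-1)G = K_A,ALn · K_A,ALnG`. Mole fractions follow from
the binding polynomial, e.g.
`F_ALn = [L]ⁿ ∏ⱼ K_A,ALj / Σ(all species weights)`, with free [G] and [L]
fixed by mass balance. The model is fitted globally over a titration by
minimising the pseudo-χ²

```
χ² = Σ_points Σ_n (F_ALn^exp − F_ALn^calc)² + (F_AGLn^exp − F_AGLn^calc)²
```

over log₁₀-parameterised constants (multi-start simplex + least-squares
polish), one fit per replicate, reported as mean ± s.e.m.

The coupling factor for the i-th lipid-binding event,
`α_i = K_A,AGLi / K_A,ALi = K_A,ALiG / K_A,AL(i-1)G`, measures the fold
change in partner affinity caused by that lipid: α > 1 positive allosteric
modulation, α ≈ 1 neutral, α < 1 negative.

Also included: nonlinear van't Hoff analysis
`ln K_A(T) = (ΔH_T0 − T0·ΔC_p)/R · (1/T0 − 1/T) + ΔC_p/R · ln(T/T0) + ln K0`
with the linear fit for comparison and derived ΔG/ΔS; Langmuir 1:1 SPR
kinetics (`KD = koff/kon`) for orthogonal validation; sequential
nucleotide-binding occupancy predictions; and a synthetic-data module that
generates every input format from known ground truth.

## Worked example

```python
from lipallo import fit_binding_model
from lipallo.allostery import coupling_factors_from_fit
from lipallo.synthetic import NoiseSpec, default_study_params, generate_titration

truth = default_study_params()   # K_D,AG = 1.12 uM, positive coupling
bundle = generate_titration(truth, noise=NoiseSpec(sigma=0.05, seed=42), replicates=3)
fit = fit_binding_model(bundle.series, n_max=3, seed=7)
cfs = coupling_factors_from_fit(fit)
print(f"K_D,AG = {1e6 / fit.params_hat.k_ag:.2f} uM  (truth 1.12 uM)")
for i, (a, s, c) in enumerate(zip(cfs.alpha, cfs.alpha_sem, cfs.classification), 1):
    print(f"alpha_{i} = {a:.2f} +/- {s:.2f}  ({c})")
```

prints

```
K_D,AG = 1.11 uM  (truth 1.12 uM)
alpha_1 = 1.38 +/- 0.04  (positive)
alpha_2 = 1.80 +/- 0.03  (positive)
alpha_3 = 2.20 +/- 0.04  (positive)
```

The fitted lipid-free dissociation constant reproduces the generating truth,
and each lipid-binding event is recovered as increasingly positive allosteric
modulation (the generating coupling factors were 1.4, 1.8, 2.2).

The same pipeline is available from the shell:

```
lipallo simulate-titration --out sim --seed 7
lipallo fit-titration sim/synthetic_manifest.yaml --out fit --seed 7
lipallo coupling fit/synthetic_fit.json --out coupling
```

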