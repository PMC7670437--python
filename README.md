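# cosmopharm-sle

Solid–liquid equilibria for pharmaceutical compounds from predictive and
semi-predictive activity-coefficient models: COSMO-SAC (2002), COSMO-SAC
(2010) and a Hansen-parameter Flory–Huggins model, with downstream
solubility, octanol/water partition-coefficient and cocrystal
phase-diagram calculations.

## Who this is for

Formulation and crystallization scientists (and thermodynamics-minded
developers) who want to estimate how much of a drug dissolves in a solvent
or solvent blend, how it partitions between octanol and water, and where a
drug/coformer cocrystal is stable in a ternary diagram — starting from
either quantum-chemistry COSMO files or tabulated Hansen solubility
parameters, without fitting to experimental data.

## The models

**Sigma profiles.** A COSMO file lists the molecular cavity's surface
segments with positions, areas A_n and screening-charge densities σ*_n.
The raw charges are spatially averaged,

σ_m = Σ_n σ*_n w_n(m) / Σ_n w_n(m),  w_n(m) = (r_ave² r_n²)/(r_ave² + r_n²) · exp(−d_mn²/(r_ave² + r_n²)),

with r_n = (A_n/π)^½, then histogrammed onto 51 bins on σ ∈ [−0.025, 0.025]
e/Å² to give the sigma profile p(σ) — the molecular fingerprint of
COSMO-SAC. The 2010 revision splits p(σ) into hydroxyl (OH), other
hydrogen-bonding (N, F and their hydrogens; OT) and non-hydrogen-bonding
parts via the factor 1 − exp(−σ²/σ_o²).

**Activity coefficients.** ln γ_i = ln γ_i^C + ln γ_i^R: a
Staverman–Guggenheim combinatorial term from normalized volume r_i = V_i/r₀
and area q_i = A_i/q₀, and a residual term

ln γ_i^R = n_i Σ_σ p_i(σ) [ln Γ_S(σ) − ln Γ_i(σ)],

where the segment activity coefficients Γ solve the self-consistent
fixed point ln Γ(σ_m) = −ln Σ_n p(σ_n) Γ(σ_n) exp(−ΔW(σ_m,σ_n)/RT). The
2002 exchange energy is ΔW = (α′/2)(σ_m+σ_n)² + c_hb·max(0, σ_acc−σ_hb)·
min(0, σ_don+σ_hb); the 2010 one is (A_ES + B_ES/T²)(σ_m+σ_n)² minus a
pair-class-specific hydrogen-bond term c_hb(t,s)·(σ_m−σ_n)². The
Flory–Huggins model builds its interaction parameter from Hansen
parameters, χ_ij = V_i/RT [(δ_d,i−δ_d,j)² + 0.25(δ_p,i−δ_p,j)² +
0.25(δ_h,i−δ_h,j)²] (three χ conventions are provided; see
`docs/methods.md`).

**Equilibria.** Saturation follows
ln x = ΔH_m/R (1/T_m − 1/T) − ΔC_p/R (1 − T_m/T − ln(T/T_m)) − ln γ;
log K_OW = log₁₀(C_o,W γ^W,∞ / (C_o,O γ^O,∞)) with the octanol-rich phase
at 27.5 mol% water and C_o,W/C_o,O = 0.151; cocrystal stability is governed
by the solubility product K_CC = (x_A γ_A)^a (x_B γ_B)^b, and invariant
points are the intersections of the pure-solid solubility lines with the
cocrystal line.

Because quantum-chemistry inputs cannot be regenerated here, the
`synthetic` module provides toy COSMO molecules with controlled charge
structure and noisy synthetic solubility studies; a 42-substance Hansen
parameter/molar-volume table is embedded.

## Worked example

```bash
$ cosmopharm synth molecule --pattern donor-acceptor-pair --hb-fraction 0.3 --seed 1 --out drug.cosmo
wrote drug.cosmo
$ cosmopharm parse drug.cosmo
molecule      : toy-donor-acceptor-pair-1
area (A^2)    : 150.0000
volume (A^3)  : 172.7471
segments      : 60
net charge (e): +0.000000
```

The cavity has 150 Å² of surface split over 60 segments and is exactly
charge-neutral, as a conductor-screened molecule must be. Activity
coefficients of a binary mixture of two toys (an apolar one and the
hydrogen-bonding one above):

```python
>>> from cosmopharm import *
>>> a = Component.from_molecule(make_toy_molecule(ToyMoleculeSpec(seed=1)))
>>> b = Component.from_molecule(make_toy_molecule(
...     ToyMoleculeSpec(charge_pattern="donor-acceptor-pair", hb_fraction=0.3, seed=2)))
>>> CosmoSac2002([a, b]).ln_gamma([0.5, 0.5], 298.15)
array([0.67227 , 0.419588])
```

Both γ > 1 (0.672 and 0.420 in ln units): mixing an apolar surface with a
donor/acceptor surface is unfavourable, so each component escapes the
mixture more readily than from its own pure liquid. Solubility of
ibuprofen in ethanol from the Hansen/Flory–Huggins route (fusion data
ΔH_m = 25.5 kJ/mol, T_m = 347.6 K):

```python
>>> model = FloryHuggins([hansen_lookup("Ibuprofen"), hansen_lookup("Ethanol")],
...                      convention="regular")
>>> solve_solubility(model, FusionProperties(dHm=25500.0, Tm=347.6), 298.15)
0.001196...
```

The ideal (van 't Hoff) solubility is x = 0.2315; the Hansen mismatch
(χ = 5.82) suppresses it to x ≈ 1.2·10⁻³.

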