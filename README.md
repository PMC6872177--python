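# erythropy

Tools for asking how a drug simultaneously changes **stochastic gene
expression** and **differentiation kinetics** in erythroid progenitor
cultures (T2EC-style experiments: cells self-renew in one medium, are
induced to differentiate in another, and are followed by live-cell counts,
differentiated-cell percentages, and single-cell RT-qPCR panels).

The package implements two linked analyses:

**1. Compartmental kinetics with AICc model selection.** Cell populations
follow a linear three-compartment model — self-renewing S, committed C,
differentiated B:

    dS/dt = (ρ_S − δ_SC) S
    dC/dt = ρ_C C + δ_SC S − δ_CB C
    dB/dt = ρ_B B + δ_CB C

solved in closed form. Observations (total live cells; percent
differentiated) carry multiplicative Gaussian noise, y ~ N(f, b·f), and
parameters are estimated by bounded multistart truncated-Newton
minimization of −2 log L. Under a treatment, each of the six estimable
parameters (ρ_S, ρ_C, δ_CB, ρ_B, b₁, b₂; δ_SC is tied to ρ_S by an
S-clearance constraint) is either re-estimated or tied to its control
value, giving 2⁶ = 64 nested variants. Variants are ranked by
AICc = −2 log L + 2kn/(n−k−1), converted to Akaike weights, and the 95%
cumulative-weight set is selected — the selected models' parameters,
relative to control, say *which rates the drug changed*.

**2. Histogram Shannon entropy of single-cell expression.** Per gene,
cell-to-cell variability is E = −Σ p_k log₂ p_k over a histogram with
N = Nc/2 equal-width bins (Nc cells, fixed across compared groups; bin
ranges pooled per gene over the compared conditions). Drug effects are
summarized by relative entropy RE = E_treated/E_control with quartile
classification, paired Wilcoxon shift tests, and Pearson correlations
between drugs and against relative mean expression — separating changes in
*variability* from changes in *mean*.

A seeded synthetic-data module generates kinetics datasets from the error
model and paired control/treated expression matrices (lognormal, with
orthogonal mean- and dispersion-multiplier effects), so every stage is
testable and calibratable without external data.

## Worked example

```python
import erythropy as e

# -- kinetics: which rates did a differentiation-slowing drug change? --
control_theta, treated_theta = e.make_treatment_scenario("noise_down")
control = e.simulate_kinetics(e.KineticsDesign(true_params=control_theta, seed=1))
treated = e.simulate_kinetics(e.KineticsDesign(true_params=treated_theta, seed=2))

sel = e.TreatmentModelSelection(n_restarts_control=20, n_restarts=4, seed=0)
sel.fit(control, treated)
top = sel.result_.scored[0]
print(f"top variant: {top.variant.label()}  (weight {top.weight:.3f})")
print(f"models selected at 95%: {len(sel.result_.selected)} of 64")
print(sel.relative_parameters_.head(3).round(3).to_string(index=False))
```

prints

```
top variant: rho_C+delta_CB+b2  (weight 0.358)
models selected at 95%: 8 of 64
 rho_S  rho_C  delta_CB  rho_B    b1    b2                 variant  weight
   1.0  0.601     0.534  1.000 1.000 1.848       rho_C+delta_CB+b2   0.358
   1.0  0.599     0.534  1.000 1.109 1.849    rho_C+delta_CB+b1+b2   0.167
   1.0  0.685     0.549  0.883 1.000 1.810 rho_C+delta_CB+rho_B+b2   0.153
```

The "drug" in this scenario multiplied ρ_C by 0.6 and δ_CB by 0.5; the
top-weight model frees exactly those rates and estimates them at 0.60 and
0.53 of control — the selection recovers both *which* parameters changed
and *by how much*.

```python
# -- entropy: a drug that halves expression dispersion, mean untouched --
c, t = e.simulate_expression(e.ExpressionDesign(dispersion_effect=0.5, seed=3))
cmp_ = e.EntropyComparison(seed=0).fit(c, t)
print(f"median RE = {cmp_.relative_.table['RE'].median():.3f}, "
      f"median relative mean = {cmp_.relative_means_.median():.3f}")
print(f"Wilcoxon entropy-shift p = {cmp_.shift_p_:.2e}")
```

prints

```
median RE = 0.835, median relative mean = 0.997
Wilcoxon entropy-shift p = 8.28e-17
```

— a strongly significant drop in per-gene entropy (median RE 0.84) with
the mean expression level unchanged (relative mean 1.00): variability and
mean decouple, which is the pattern this analysis is designed to detect.

A `erythropy` command-line interface wraps the same stages
(`simulate-kinetics`, `simulate-expression`, `fit`, `select`, `entropy`,
`correlate`, `report`); every subcommand logs its seed and writes plain-CSV
outputs plus a YAML run manifest.

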