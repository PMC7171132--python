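# reservecalc

Quantification of **metabolic and translational reserve capacities** in
microbial cells from steady-state chemostat multi-omics.

When *Saccharomyces cerevisiae* grows in nitrogen-limited chemostats at a
fixed dilution rate, total cellular protein falls to ~50% and total mRNA to
~25% of carbon-limited levels — yet growth continues unchanged. The excess
expression under carbon limitation is *reserve capacity*: enzymes and
translational machinery held beyond immediate demand so the cell can
respond quickly when the environment improves. `reservecalc` implements
the full analysis chain that turns raw platform signals into quantified
reserves, together with a synthetic-data generator that emulates the
chemostat study design with known ground truth, so every stage is testable
without access to the original deposited datasets.

## What it computes

**Absolute quantification** (`reservecalc.absquant`) — log₁₀–log₁₀
standard-curve regression on spike-in calibrators (transcript standards,
UPS2-style protein standards), inversion with extrapolation flagging,
rescaling to measured total RNA/protein content, reference-anchored
conversion of TMT-style relative ratios, and a zero-intercept
synthetic-peptide mini-calibration with linearity QC.

**Molar allocation** (`reservecalc.allocation`) — the molar fraction of the
transcriptome/proteome pool dedicated to each gene set
(% mol mol⁻¹), sliding-window Fisher enrichment over ranked abundance with
Benjamini–Hochberg FDR, cross-condition log₂ fold comparison, log–log
allocation regression (slope > 1 ⇒ translational amplification), and
isozyme differential-allocation / switching analysis.

**Enzyme-constrained FBA** (`reservecalc.ecfba`) — a GECKO-convention
ec-model: each enzyme draws from a shared pool (mass bound *P*_met,
g gDW⁻¹) through a usage pseudo-flux, with *v*ⱼ ≤ *k*_cat · *e* coupling.
Analyses: biomass-composition rescaling, condition constraining, the
minimum enzyme demand LP whose ratio to the measured pool is the
**saturation coefficient σ** (reserve = 1 − σ), flux variability analysis,
random-objective sampling with histogram-mode optimal solutions, and
superpathway usage/reserve tables (usage = Σ simulated demand / Σ measured
abundance).

**Translation efficiency** (`reservecalc.translation`) — the steady-state
protein balance gives *k*_sP = protein · (μ + *k*_deg) / mRNA
(protein mRNA⁻¹ h⁻¹). Genes are grouped by the nitrogen-reduction step at
which *k*_sP first rises >2-fold; the activation fold converts to a
reserve fraction as 1 − 1/fold (5.6-fold ⇒ 82% reserve).

**Ribosome stoichiometry** (`reservecalc.ribosome`) — RP : rRNA ratios,
data-driven core vs sub-stoichiometric classification (deterministic 1-D
2-means on log₁₀ abundance), exact-integer ribosome composition diversity
D(n) = C(n_sub, n − n_core), buildable-ribosome capacity curves, and
selective RP upregulation calls including paralog-specific responses.

**Synthetic data** (`reservecalc.synthetic`) — chemostat-like paired omics
with constant per-process allocation, configurable global protein/mRNA
reductions, lognormal abundance and measurement noise, known k_sP
activation groups, spike-in standards, toy fermentation/respiration
ec-models with known minimal enzyme demand, and bimodal RP profiles. With
`noise_cv = 0` every downstream stage recovers the stored truth exactly.

## Worked example

```python
from reservecalc import synthetic as sy, ecfba as ec, translation as tr

# toy fermentation/respiration network, constrained by a measured pool
model = ec.constrain(sy.generate_toy_model("branched-fermentation"), P_met=2.0)
p_min, sol = ec.minimize_enzyme_pool(model)
sat = ec.saturation_sigma(p_min, 2.0)
print(f"P_min = {p_min:.3f} g/gDW, sigma = {sat.sigma:.3f}, reserve = {sat.reserve:.1%}")

# glucose-fermentation benchmark: flux 2.4 -> 6.0 mmol/gDW/h, enzymes halved
bench = ec.pathway_usage_fold(flux_ref=2.4, enzyme_ref=1.0,
                              flux_alt=6.0, enzyme_alt=0.5)
print(f"flux fold = {bench.flux_fold:.1f}, usage fold = {bench.usage_fold:.1f}, "
      f"C-limited usage = {bench.reference_usage:.0%}")

print(f"reserve at 5.6-fold activation = {tr.reserve_from_fold(5.6):.0%}")
```

prints

```
P_min = 0.667 g/gDW, sigma = 0.333, reserve = 66.7%
flux fold = 2.5, usage fold = 5.0, C-limited usage = 20%
reserve at 5.6-fold activation = 82%
```

The toy network needs only a third of the supplied 2 g/gDW enzyme pool to
meet its ATP demand (two thirds reserve). The benchmark shows the
fermentation superpathway running at 20% of capacity under carbon
limitation: the flux rises 2.5-fold while pathway enzymes halve, a
fivefold usage increase to saturation. A gene whose translation efficiency
can rise 5.6-fold was keeping 82% of its translational capacity in
reserve.

A command-line interface mirrors the library
(`reservecalc synth|calib|alloc|ecfba|ksp|rp ...`); run
`reservecalc --help` for the command tree.

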