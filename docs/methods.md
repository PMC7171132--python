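# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of `reservecalc`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design emulated by the generator

The synthetic dataset mimics steady-state chemostat cultures at a fixed
dilution rate μ = 0.2 h⁻¹ across four conditions ordered from
carbon-limited (reference) to increasingly nitrogen-limited (media C/N
ratios ~3.5, 30, 50, 115), in biological duplicates. Built-in ground
truth:

- **Total content.** Total protein declines geometrically to
  `protein_reduction` (default 0.5) and total mRNA to `mrna_reduction`
  (default 0.25) of the reference. Defaults are the plateau reductions the
  chemostat design is meant to reach.
- **Constant allocation.** The molar fraction of each omic layer assigned
  to each biological process is constant across conditions (configurable
  per-condition for constructed comparisons, e.g. the 97-of-99 scenario).
  The default profile assigns 45% to metabolism, 12% to translation, and
  smaller fractions to five further functional categories; the remainder
  is carried by an explicit unassigned pool so that allocation over a
  partition sums to exactly 100%.
- **Abundance distributions.** Per-gene base abundances are lognormal with
  log₁₀ SD 1.0 (mRNA) and 1.5 (protein), so the proteome spans a larger
  dynamic range than the transcriptome — the amplification that the
  log–log allocation regression detects as slope > 1.
- **Measurement noise.** Multiplicative lognormal noise with unit mean and
  CV `noise_cv` (default 0.2) per gene × condition × replicate. At
  `noise_cv = 0` the data equal the stored truth exactly.
- **Translation-efficiency groups.** Every gene carries an activation
  group: group *g* (of 4) first exceeds a 2-fold k_sP increase at
  nitrogen-reduction step *g*; the last group never does.
- **Turnover.** Degradation rates k_deg are lognormal around a median of
  0.04 h⁻¹ (log-SD 0.5), standing in for mined turnover measurements.

### Exact allocation closure

Keeping (i) per-process allocation exactly constant, (ii) total protein
and mRNA on their configured trajectories, and (iii) per-gene k_sP folds
that cross 2-fold at assigned steps, simultaneously and exactly, requires
care: the three constraints couple through the process protein-mass
balance. The generator solves, per process and condition, for one fold
*F* > 2 shared by activated genes and one fold *u* < 2 shared by
not-yet-activated genes from

    F·s + u·(1 − s) = T(c),   T(c) = r_protein(c) / r_mRNA(c),

where *s* is the activated protein-mass share. *u* is targeted at the
value implied by `activated_fold` (default 2.5) and clipped into
[0.2, 1.8] so activation stays separated from the 2-fold decision line;
*F* then closes the balance exactly. The heaviest gene of each process is
assigned to the never-activated group — mirroring the highly abundant
translation-machinery proteins, which do not modulate k_sP — and the
remaining genes are greedily mass-balanced, which bounds any activating
group's mass share at 1/2 and keeps the solve feasible. Configurations in
which mRNA is reduced less than protein leave the supported regime and
raise an error rather than silently distorting groups.

A consequence of balancing *mass* rather than gene counts is that the
never-activated group holds few, heavy genes; the *count* of genes per
group is therefore not controlled, and the generator makes no claim about
the fraction of genes (as opposed to protein mass) crossing 2-fold.

### What the generator does not emulate

Simulation starts at gene-level summary signals: no reads, spectra or
reporter-ion signals, no peptide-to-protein inference, no batch effects,
no count-based (Poisson/NB) noise for lowly expressed transcripts, no
correlation between noise across genes, and no growth-rate variation.
Passing recovery tests therefore demonstrates correctness of the
computational chain under the stated noise model, not robustness to every
artifact of real LC-MS or RNA-seq data.

## Calibration chain

Standard-curve regressions run in log₁₀–log₁₀ space (signals span orders
of magnitude; fit diagnostics — adjusted R², regression p — come from the
OLS fit and are stored with the curve). Inversion maps zero signals to
zero abundance rather than imputing, so molar sums are never inflated;
signals outside the standards' range are converted but flagged as
extrapolated, since quantifying the full transcriptome from ~31 standards
necessarily extrapolates. Total-content scaling is a per-condition
multiplicative rescale (optionally mass-weighted) and preserves all
within-condition ratios to machine precision. The peptide
mini-calibration uses a zero-intercept fit of S/N versus known amount;
linearity QC requires the sample signal within the standards' range and
uncentered R² ≥ 0.95 (configurable). `cells_per_gDW` for copies-per-cell
conversion and the rRNA fraction of total RNA (default 0.8) and rRNA mass
per ribosome (default 1700 g mmol⁻¹, ≈1.7 MDa) are explicit, configurable
assumptions.

## Enrichment statistics

Both enrichment paths (sliding windows of ranked abundance; activation
groups) use two-sided Fisher's exact tests on 2×2 tables and
Benjamini–Hochberg FDR across all tests of an analysis jointly (the
joint scope is configurable). The window slides by a default step of 1
gene for maximal resolution; larger steps are available for speed and are
what the null-calibration tests use. Over- vs under-representation is
reported as a direction alongside the two-sided p. The test suite checks
every produced p-value against an exact-rational hypergeometric
enumeration (1e-10) and calibrates the family-wise false-positive rate of
both paths under 500 null permutations.

## Enzyme-constrained FBA

Variables are reaction fluxes plus one usage pseudo-flux per enzyme
(mmol gDW⁻¹); constraints are S·v = 0, bounds, vⱼ ≤ k_cat·e for every
catalyzed (irreversible) reaction — promiscuous enzymes share one usage
variable — and Σ MW·e ≤ P_met when a pool bound is set. LPs are solved by
HiGHS through a narrow interface; any solver meeting a 1e-9 feasibility
tolerance is acceptable.

- **Biomass rescaling** sets the protein and RNA pseudo-coefficients to
  measured contents and lets the carbohydrate coefficient absorb the
  difference so component masses total 1 g gDW⁻¹. Growth-associated
  maintenance is a configured constant and never recalculated.
- **Condition constraining** fixes the biomass/demand flux to the growth
  rate exactly but clamps measured exchange fluxes to ±5% (relative,
  configurable) rather than hard equalities — exact equalities are brittle
  against measurement noise.
- **σ** is minimum demand / measured pool; reserve = 1 − σ.
- **Random sampling**: each sample maximizes and minimizes one weighted
  flux sum ("pair"); weights are uniform(0, 1] over a random half of the
  reactions. Whether the pair shares one weight vector (default) or draws
  two is a flag, since either reading is defensible. Per-reaction modes
  use Freedman–Diaconis histogram binning inside the FVA interval, ties
  broken toward the bin containing the sample median; degenerate (point)
  intervals return the point. All sampling is seeded and bit-reproducible.
- **Pathway usage** excludes pathways with fewer than 5 matched enzymes or
  zero simulated demand (logged), mirroring the superpathway filter.

The toy models are deliberately tiny (≤ 6 reactions) so that every LP
result can be verified against exhaustive basic-feasible-solution
enumeration; they are not reduced yeast models, and the package makes no
attempt to reproduce genome-scale results (29% total enzyme reserve,
7/23 superpathways) that require the full ec-model and the deposited
omics. Metabolite-concentration/thermodynamic constraints are out of
scope by design.

## Translation efficiency

k_sP = protein·(μ + k_deg)/mRNA from the steady-state balance
(synthesis = dilution + degradation). When turnover data is missing,
k_deg = 0 is used and logged — k_sP is then an apparent, dilution-only
efficiency. Group assignment uses first-crossing semantics by default
("first step at which the fold exceeds 2"), with a sustained-crossing
variant behind a flag; groups are summarized by medians. Reserve
conversion 1 − 1/fold is monotone and bounded in [0, 1).

## Ribosome stoichiometry

Core vs sub-stoichiometric classification is a data-driven 1-D 2-means on
log₁₀ abundance with deterministic initialization at the two extreme
values (scale-invariant; a single population yields all-core plus a
warning) rather than a fixed 10× cut, since the separation is described
qualitatively. Diversity D(n) = C(n_sub, n − n_core) uses exact integer
arithmetic; values near 10⁶ must not round. With n_core = 54 and
n_sub = 22 the curve peaks at n = 65 with C(22, 11) = 705,432
compositions — slightly under 10⁶; a larger published peak would require
counting paralog choices or a different construction, so the binomial
model is stated explicitly and kept swappable rather than silently
reconciled. The capacity model
N(n) = min(ribosomes-from-rRNA, ⌊Σ sub-stoichiometric copies/(n − n_core)⌋)
for n > n_core (the rRNA-derived count below) is likewise an explicit,
documented choice. Upregulation calls flag subunits whose maximum log₂
change versus the reference exceeds 1; paralog-specific calls require
exactly one of two paralogs to cross while the sibling does not. Shared
peptides are counted once in paralog-summed abundances and toward each
paralog when paralogs are reported separately.

## Problem sizes and tolerances

Unit and property tests run on 200–3000-gene synthetic datasets,
500-replicate null calibrations, and 20-seed recovery sweeps; the
acceptance script uses the default 3000-gene configuration with content
reductions averaged over 10 generated datasets, because molar totals of a
heavy-tailed (log₁₀ SD 1.5) proteome are dominated by the few most
abundant genes and a single dataset's total carries ~5–10% sampling
error. Exact-recovery assertions use 1e-9 relative tolerance; LP-oracle
comparisons 1e-8; Fisher-oracle comparisons 1e-10. All randomness flows
through seeded NumPy generators; spawned seeds stay below 2³¹.

## Known limitations

- The ec-FBA engine targets small, irreversible-catalysis models; it does
  not split reversible catalyzed reactions automatically.
- 1-D 2-means assumes two abundance populations; strongly trimodal RP
  profiles would need a different classifier.
- The sliding-window null calibration assumes exchangeable genes; strong
  abundance-dependent annotation structure (which real GO terms have) is
  exactly what the test is designed to detect, not a violation.
- Copies-per-cell outputs inherit the configured `cells_per_gDW` constant;
  no attempt is made to estimate it from data.
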