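# Methods

`orthoarray` implements the inference chain for comparing LPS-induced
transcriptional responses across humans, chimpanzees and rhesus macaques
measured on a multi-species microarray with orthologous probes. This note
documents the models, the conventions that make them identifiable, the
synthetic-data generator, and the numerical choices, in enough detail to
reproduce or audit every stage.

## Study design and data model

Each gene is measured by 3–7 probes; each probe is derived from one
species' sequence (its *origin*). Every individual contributes one
non-stimulated (NS) and one LPS-stimulated sample at 4, 12 and 24 hours;
the reference design is 3 species × 6 individuals × 3 time points × 2
classes = 108 arrays. Intensities are normalized log2 values; upstream
background correction and normalization are assumed done.

Gene-level filters: genes enter the models only with ≥3 orthologous probes
(`filter_genes_by_probe_support`); the enrichment background is the set of
genes whose stratum-mean intensity exceeds 7.5 in at least one
(species, time, class) stratum (`flag_expressed_genes`). Missing cells are
tolerated; genes whose per-stratum missingness exceeds 20% can be screened
out (`genes_with_excess_missingness`) so the near-balanced likelihood
computations stay trustworthy.

## Species-difference model

Within one (treatment, time) stratum, for probe r of individual i from
species s:

    y_{s,r,i} = mu_s + pi_r + kappa_{s,r} + gamma_{s,i} + eps,
    gamma ~ N(0, sigma_ind^2),  eps ~ N(0, sigma^2)

`pi_r` is the probe effect, `kappa_{s,r}` the attenuation of hybridization
when sample species s differs from probe r's origin (identically zero on
matched pairs), and `gamma` a per-individual random intercept. The null
model replaces the per-species means by one common mean. Both are fit by
maximum likelihood (not REML, because likelihoods are compared across
fixed-effect structures) and compared by a likelihood-ratio test against
chi-square with two degrees of freedom, with Benjamini–Hochberg FDR across
genes.

### Identifiability conventions

Raw indicators over-parameterize the mean. We impose:

* `sum_r pi_r = 0` within each gene;
* `kappa = 0` on matched (species == origin) pairs;
* the per-species means of `kappa` over mismatched probes are **equal
  across species**.

The first two alone still leave a two-dimensional gauge freedom (a shift of
`mu_s` can be traded against probe and attenuation effects); the third pins
it down exactly, making the alternative model full rank — in fact saturated
on the species × probe cell means — and the null model two parameters
smaller, so the LRT df is 2 as required. Each species must have at least
one perfect-match probe with data; otherwise the fit aborts naming the
species.

A consequence worth stating plainly: with probe-specific attenuation, a
gene whose *average* attenuation genuinely differs by sample species is
mathematically indistinguishable from a gene with species-different
expression. The species test is therefore calibrated when attenuation is
homogeneous across a gene's probes (any shared attenuation level is
absorbed harmlessly), and gene-to-gene scatter in per-species mean
attenuation will read as species signal. This is a property of the design,
not of the implementation; the calibration checks below generate data under
the model's own assumption (fixed attenuation level, no per-probe scatter).

### Fitting algorithm

Iterated least squares: alternate (a) generalized-least-squares updates of
the fixed effects given the variance components — the grouped covariance
`sigma^2 I + sigma_ind^2 J` is inverted analytically per individual — and
(b) exact closed-form ML updates of `(sigma_ind^2, sigma^2)` given the
fixed effects when groups are balanced, or an EM step when they are not.
Iteration stops when the log-likelihood moves < 1e-8 (max 200 iterations);
variances are floored at 1e-8 so zero-noise fixtures remain well posed;
the LRT is clamped at 0 (tolerance 1e-4, larger discrepancies raise).
Constraints are handled by re-parameterizing in the constraint null space,
so the solved systems are always full rank.

### Small-sample (Bartlett) factor

With p_alt mean parameters and N observations, the raw ML ratio is
inflated by a factor ≈ N/(N − p_alt); at 20 individuals/species the null
rejection rate at 0.05 runs near 6% and p-values visibly depart from
uniform. Both LRTs therefore carry a first-order Bartlett factor by
default: the species statistic is scaled by (N − p_alt)/N, and the paired
treatment statistic uses (m − 1)·log(RSS0/RSS1) for m pairs. The reference
distributions (chi-square, df 2 and 1) are unchanged, and `bartlett=False`
recovers the raw ratio. Measured effect under null simulations: species
test 5.0–5.9% rejection with Kolmogorov–Smirnov uniformity p in 0.5–0.97
(raw: 5.9–6.8%, KS p down to 0.01); treatment test at the study's own
six pairs, 6.1% instead of 8.8%.

## Treatment model

The paired design is handled in two stages per time point.

**Stage one** adds to the species model a treatment effect `delta` and a
treatment-by-species interaction `tau_s` (sum-to-zero over species), with
the random individual intercept shared across the individual's two
classes. Its only downstream role is to supply `pi_hat` and `kappa_hat`
for the corrected expression

    y*_{s,i,t} = mean_r ( y_{s,r,i,t} - pi_hat_r - kappa_hat_{s,r} ),

which removes probe composition and cross-species hybridization artifacts
while leaving species, individual and treatment signal untouched. In any
complete balanced design the within-individual (LPS − NS) contrast of y*
is algebraically identical to the same contrast of raw probe means, so
correction noise cannot contaminate the treatment tests.

**Stage two** tests, per gene / species / time point, whether treatment
shifted y*. The individual effect shared across the two classes is
eliminated exactly by within-individual differencing; with paired
differences d_i, the effect size is `delta_hat = mean(d)` (log2 scale) and
the statistic is the Bartlett-scaled likelihood ratio above, referred to
chi-square df 1. Genes with fewer than 3 complete pairs are reported
untested. FDR is computed separately per (species, time point), matching
how the classification cutoffs are applied. An equivalent view of the
differencing: per-individual effects treated as fixed and profiled out —
this keeps `delta_hat` exactly the mean paired difference and makes the
test invariant to per-individual shifts, while avoiding the severe
anticonservatism (≈19% at 0.05, n=20) of the naive 2m-observation ML ratio
whose per-individual parameter count grows with the sample.

## Response classification

Primary call in a species at a time point: FDR below the species' primary
cutoff AND |delta_hat| at or above the species' effect floor. Defaults:
human and rhesus 0.001 / 0.3, chimpanzee 0.1 / 0.1 (chimpanzee effect
sizes run lower overall). Conditional on a primary call in some species at
a time point, other species are rescued into a secondary call when their
nominal p < 0.05 at the same time point. Rescue never chains off secondary
calls, no direction agreement is required, and rescue is confined to the
triggering time point (treatment tests are per time point by
construction). Per-species response = union of calls over time points
(rescue-then-union); genes partition into the seven species-combination
Venn cells (HCR … R-only) plus none.

The convergence screen selects genes differentially expressed between
species before treatment (species-LRT FDR < 0.05 in the NS stratum) whose
post-treatment species-LRT p exceeds 0.05 — expression converged to
practically the same level after stimulation.

## Enrichment and contingency analyses

Term enrichment: upper-tail hypergeometric probability of the observed
overlap between a target set and each term, over the expressed-gene
background, BH-adjusted across terms. The target must be a subset of the
background (a universe mismatch raises rather than silently mis-counting).

Category conservation: responding genes are binned by how many species
shared the call (3/2/1) and cross-tabulated against the universal /
bacterial / viral TLR-response categories; homogeneity is tested by
Pearson chi-square on the 3×3 table without continuity correction (a flag
enables Yates). Genes with multiple category labels are resolved by the
priority universal > viral > bacterial, with a warning.

Marker over-representation (disease-associated, HIV-1-interacting genes):
2×2 Pearson chi-square of marker membership against species-specific
responder status over the expressed background, df 1, no continuity
correction by default.

## Co-expression modules

For one species, gene-gene Pearson correlations are computed across all
(individual, time, class) corrected-expression cells (≥4 required;
constant genes are flagged degenerate with correlations set to 0). Module
detection follows the modulated-modularity idea: the |r| similarity is
sharpened as |r|^beta, a seeded modularity-maximizing Leiden partition is
computed for each beta on the grid {1..6}, and the beta with the highest
modularity wins; the chosen beta, modularity and method name are recorded
in the ModuleSet metadata. A module's average connectivity is the mean
absolute pairwise correlation among its genes, and only modules above the
0.5 cutoff are counted as reported modules. The chance expectation is
estimated by independently permuting every gene's values across samples —
breaking gene-gene correlation, preserving marginals — and re-running
detection (default 100 permutations, seed-controlled; sd uses the n−1
denominator).

## Synthetic-data generator

`simulate_dataset` draws data from exactly the additive structure the
models assume: per-gene baseline (N(8, 1) log2 by default), optional
per-species shifts, probe effects N(0, 0.5) **centered within each gene**
so gene-level species means are well defined, attenuation N(−0.5, 0.25) on
mismatched pairs only, per-individual intercepts N(0, 0.2), i.i.d. noise
N(0, 0.3), treatment effects injected per (species, time) according to
responder classes, optional shared latent factors that plant co-expression
modules, and category / disease / HIV-interaction labels with configurable
rates and per-class rate multipliers. Probe origins cycle the species
within each gene's probe set so every sample species keeps a perfect-match
probe, as the physical array guarantees. All draws flow from one seeded
generator; identical seeds give bit-identical output.

The magnitudes are chosen for statistical realism and test power — the
study itself reports no variance components — so passing tests demonstrate
correctness of the machinery under the model's assumptions, not fidelity
to any particular array. Features of real data the generator does not
emulate: probe-sequence-specific hybridization physics, scanner or batch
effects, normalization artifacts, heavy-tailed noise, and per-probe
attenuation scatter whose species means differ per gene (see the
identifiability caveat above).

## Problem sizes used by the checks

The statistical acceptance checks (and `scripts/acceptance.py`) use: 5,000
null genes at 20 individuals/species for treatment-test calibration and
2,000 for species-LRT uniformity; 500 genes at 6 individuals for
effect-size recovery (delta = 1.0, sigma = 0.25) and 120 genes at 20
individuals for attenuation recovery; a 1,000-gene planted classification
(100 shared responders, 100 human-only, delta = 1.5 at 4 h, 800 nulls); 50
genes with two planted 10-gene blocks (rho = 0.95) and 100 permutations
for the module null; and 200 replicates of a 2,000-gene truth-level draw
for marker-enrichment power. These sizes give Monte-Carlo error comfortably
inside each check's tolerance.

## Known limitations

* Attenuation–species confounding (above) is intrinsic to the design; the
  species test should be read as "species difference OR species-patterned
  attenuation" for genes where probe-level attenuation varies a lot.
* The chi-square references remain asymptotic even with the Bartlett
  factor; at 6 individuals the treatment test still rejects ~6% at nominal
  5%.
* The two-cutoff classification inherits the arbitrariness of its
  thresholds; cutoffs are config, not constants.
* Module detection is one realization of modularity clustering on a
  sharpened similarity; other clusterers can be compared via the recorded
  metadata but are not bundled.
* No multiple-time-point longitudinal modeling; each time point is
  analyzed separately by design.
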