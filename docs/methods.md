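# Methods

This note records the models, defaults and design choices behind
`tephraseq`, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The decontamination cascade

### Prevalence test

For each ASV we form the 2×2 table of presence (count ≥ `min_count`,
default 1) versus absence in true samples and negative controls. The
two-sided p-value comes from the chi-square statistic Σ(O−E)²/E without
continuity correction, replaced by Fisher's exact test whenever any expected
cell is below 5 (the standard small-sample rule; with only a handful of
controls this is the branch that almost always fires). An ASV is removed
only when p < 0.5 **and** the control prevalence fraction exceeds the
true-sample fraction — without the one-sided direction requirement, an ASV
strongly enriched in true samples would be flagged. ASVs absent from every
control are retained untested. The 0.5 score threshold follows the
prevalence-method convention for low-biomass studies; it is a
classification score cut, not a significance level.

### Taxonomy screen

Chloroplast is matched at the order rank, mitochondria at the family rank,
eukaryotes and unassigned lineages at the kingdom rank, and the genus
blocklist case-insensitively. All missing-name spellings ("NA", "",
"unclassified", "Unknown") are canonicalized to a single `UNASSIGNED`
sentinel at read time so these rules are deterministic. The shipped
blocklist is a small illustrative set of ubiquitous reagent genera
(Cutibacterium, Ralstonia, …); real surveys should substitute their own
curated list via `--blocklist`.

### Overlap classifier

Rules are evaluated in priority order R1 → R3 → R2, so an ASV present in
all four groups is removed by R1: the subaerial deposit acts as a natural
negative control for marine taxa, and any overlap with it outranks the
seawater-inflow exemption. The classifier is a pure function of the
presence pattern — invariant to how counts are distributed within a group
and to feature order (both properties are tested). `venn_census` reports
the 15-region occupancy table for audit. The default group map assigns
drill cores shallower than 58 m below surface (the tidal-flux zone at the
top of the submarine deposit) to SUB_A and deeper cores to SUB_M; the
boundary, and the entire map, can be overridden per sample.

Removal deletes the feature's entire row from the remaining samples rather
than zeroing it per sample, and the drilling-fluid and negative-control
samples are dropped from the cleaned dataset before downstream analysis.

## The synthetic survey generator

The generator emulates the post-denoising state of a contaminated
low-biomass drilling survey; it is the test bed for the cascade, not a
read-level simulator (no FASTQ, chimera or PCR-bias models).

**Pools.** 300 features by default: 40 endemic subaerial, 110 endemic
submarine, 30 seawater, 90 drilling-fluid-only, 30 reagent. The
contaminant side is deliberately dominated by the drilling-fluid-only pool:
when fluid sterilization fails, the stored fluid develops a bloom community
that need not resemble the open sea, while the genuinely shared
sea/fluid overlap stays modest. Reagent richness matches typical
extraction-kit profiles.

**Abundances.** Each feature has a fixed lognormal base abundance
(meanlog 0, sdlog 1.5 — a heavy-tailed rank-abundance curve typical of
amplicon data) that does not vary between samples; only niche weighting and
mixing vary, which separates habitat signal from sampling noise.

**Thermal niches.** Endemic features carry a Gaussian niche
w = exp(−(T−T_opt)²/2σ²) with per-feature optima ~ Uniform(10, 125) °C and
σ = 25 °C. The optimum range spans the borehole's observed temperature
span; σ = 25 °C makes neighbouring depth categories overlap in composition
while the gradient end-members clearly differ, which is what drives the
depth/temperature correlation that envfit and PERMANOVA detect.

**Sample design.** 17 drill cores with the borehole's published
depth/temperature profile (2 subaerial DC_1, 3 intertidal DC_2, 7 DC_3 at
the thermal maximum, 5 DC_4 below the inflow zone), 18 borehole fluids,
2 fumaroles, 4 seawater, 8 drilling fluid, 2 negative controls — 51 samples.
Borehole fluids draw on the submarine endemic pool (they sample the same
subsurface aquifer) and fumaroles on the subaerial pool (surface expression
of the tuff cone); the generator's contract only fixes the drill-core,
fluid, seawater and control compositions, so these two choices are
conventions, not constraints.

**Mixing.** Drill core j at temperature T has expected composition
(1−c_j)·endemic(T) + c_j·fluid, with c_j ~ Beta(2, 6) (mean 0.25). The
carryover level of the real survey is not quantifiable from read fractions
alone, so the Beta(2, 6) default is a modelling choice producing visibly
contaminated but not swamped cores. DC_4 cores additionally receive
seawater mass at inflow fraction 0.10, emulating the natural infiltration
that justifies the R3 retention rule. Counts are multinomial with library
sizes ~ LogNormal(ln 30000, 0.3). 5% of reagent features carry blocklisted
genera and 2% of all features carry order Chloroplast, so the taxonomy
screen has planted targets.

**What passing tests do and do not show.** The generator plants clean pool
separations: reagent taxa never appear in true samples, endemic taxa never
in fluid or sea. Real data blur these boundaries (cross-contamination
between wells, genuinely shared taxa), so recovery scores on synthetic data
are an upper bound on real-world performance; the cascade's rule logic, not
its field accuracy, is what the tests certify. Scoring treats
drilling-fluid-only and reagent features as the positive class; seawater
features stripped from cores by R1 count against precision even though
their removal is the intended behaviour, making the reported F1
conservative.

## Community statistics

* **Rarefaction** subsamples each column without replacement (multivariate
  hypergeometric) to a common depth, by default the minimum column sum; the
  pipeline uses the minimum *positive* column sum, since cleaning can empty
  a habitat's samples entirely. Samples below depth are dropped with a
  warning. The closed-form expectation
  E[S] = Σ_i [1 − C(N−n_i, d)/C(N, d)] is implemented for validation.
* **Shannon** uses the natural log (the phyloseq convention).
* **ANOVA/Tukey** follow the textbook fixed-effects formulas; Tukey-Kramer
  standard errors handle unbalanced groups, with p from the
  studentized-range distribution (k groups, N−k df). Cross-checked against
  scipy's implementations in the tests.
* **NMDS** minimizes Kruskal stress-1 by SMACOF iterations with disparities
  from an isotonic regression (primary/averaging tie handling) of the
  configuration distances on the rank order of the input dissimilarities.
  Restart 1 starts from classical (Torgerson) scaling, the remaining 19
  restarts from seeded Gaussian configurations; within a restart the
  reported stress trace is non-increasing by construction (iteration stops
  on any uptick, keeping the matching configuration). Coordinates are
  centered and scaled to unit RMS distance — stress-1 is invariant to both.
  Tolerance 1e-7 on the stress decrement, max 300 iterations.
* **PERMANOVA** uses SS_total = (1/N)Σ_{j<k} d²_jk and group-wise
  SS_within; p = (1 + #{F_perm ≥ F_obs})/(1 + m) over free label
  permutations (no strata). An exhaustive mode enumerates distinct label
  arrangements for small designs and is used as its own oracle in tests.
  The all-zero distance matrix is reported as F = 0, p = 1.
* **envfit** regresses the centered variable on the ordination axes;
  r² = 1 − SS_res/SS_tot, direction = unit coefficient vector, p by
  permuting the variable. Samples with missing values are dropped per
  variable with a logged warning (the reader keeps such samples; each
  downstream consumer owns its exclusion rule).

## Differential abundance

A deliberately simplified negative-binomial Wald test: median-of-ratios
size factors computed over positive counts (zero-heavy amplicon tables
would otherwise lose the reference), rescaled to geometric mean 1;
method-of-moments dispersion α = max(α_min, (V−μ)/μ²) from the pooled
within-group variance of normalized counts; lfc = log2((μ_B+½)/(μ_A+½))
with the pseudo-count stabilizing zero-mean groups; delta-method standard
error and a two-sided normal p-value; Benjamini-Hochberg adjustment with
significance at adjusted p < 0.01. There is no dispersion shrinkage, GLM
iteration or LFC shrinkage, so feature lists will differ from shrinkage
estimators — the calibration contract (type-I error near nominal, unbiased
recovery of planted fold changes) is what the tests assert. The pipeline's
default two-group comparison is drill cores versus borehole fluids, the two
habitats that share the submarine endemic pool.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → cascade → rarefy + α/β statistics →
differential abundance, writing TSV/JSON outputs and a manifest with
per-stage seeds, feature/sample counts, per-rule removal tallies and SHA-256
hashes of every output. A single global seed derives per-stage seeds by
fixed offsets; no stage touches global RNG state, so a rerun with the same
config byte-reproduces every output. On any stage error, partial outputs
are renamed with a `.partial` suffix.

## Problem sizes in the validation suite

The permutation-test calibration uses 500 null simulations of 20 samples at
199 permutations; the differential-abundance calibration uses 2,000 null
features at n = 20 per group; rarefaction expectation uses 1,000 seeds; the
prevalence oracle enumerates every 2×2 presence table with both group sizes
≤ 12. These sizes give Monte-Carlo error comfortably inside the asserted
bands while keeping the whole suite fast.

## Known limitations

* The prevalence stage implements only the prevalence flavour of
  control-based contaminant identification; frequency (DNA-concentration)
  scoring and batch-aware designs are out of scope.
* The overlap classifier needs all four groups sampled; surveys without a
  subaerial (or otherwise contamination-free) stratum cannot use R1.
* Bray-Curtis/NMDS/PERMANOVA are taxonomy-blind; no phylogeny-aware
  distances (UniFrac) are provided.
* The taxonomic bin aggregation sometimes used to summarize significant
  ASVs is intentionally not part of the tested surface.
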