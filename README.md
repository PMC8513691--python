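# tephraseq

Contamination-aware 16S rRNA amplicon community analysis for low-biomass
subsurface drill-core surveys.

When a borehole is drilled with (nominally sterilized) seawater as the
circulation fluid, marine microbial DNA is carried into every core, and in a
low-biomass habitat that carryover can rival or exceed the endemic signal.
`tephraseq` implements the full computational strategy for separating
endemic subsurface taxa from that contamination and analysing what remains:

1. **Prevalence test** — each ASV's presence/absence is compared between
   true samples and negative extraction controls in a 2×2 table (chi-square
   without continuity correction, Fisher's exact test when expected cells
   are < 5); an ASV more prevalent in controls with p below the 0.5 score
   threshold is removed as a reagent contaminant.
2. **Taxonomy screen** — chloroplast (order), mitochondria (family),
   eukaryote / unassigned kingdom, and a user-editable blocklist of known
   contaminant genera.
3. **Overlap classifier** — each ASV's presence pattern across four sample
   groups (subaerial drill cores SUB_A, submarine drill cores SUB_M,
   drilling fluid DF, seawater SW) is mapped to a rule, in priority order:
   * `R1_subaerial_marine` (remove): SUB_A ∧ (DF ∨ SW). The subaerial
     deposit sits above coastal sea level and should contain no marine taxa.
   * `R3_inflow_retained` (retain): SUB_M ∧ DF ∧ SW. Seawater naturally
     infiltrates the deep submarine deposit, so the triple overlap is kept.
   * `R2_drillfluid_only` (remove): SUB_M ∧ DF. Carried downhole by fluid.
   * `endemic_candidate` (retain) otherwise.

Downstream of the cascade the package provides rarefaction, observed/Shannon
α-diversity with one-way ANOVA and Tukey HSD, Bray-Curtis dissimilarities,
NMDS ordination (Kruskal stress-1, isotonic regression, multiple restarts),
PERMANOVA (pseudo-F = (SS_among/(g−1))/(SS_within/(N−g)), free label
permutations) with pairwise comparisons and Benjamini-Hochberg adjustment,
envfit-style environmental vector fitting, and a simplified two-group
negative-binomial Wald differential-abundance test (median-of-ratios size
factors, method-of-moments dispersion).

A first-class synthetic-community generator produces ASV tables with the
survey's statistical structure — endemic pools on a depth/temperature
gradient, drilling-fluid carryover with per-core mixing fractions
c_j ~ Beta(2, 6), seawater inflow into the deepest cores, reagent taxa in
controls — together with ground-truth origin labels, so the whole cascade
can be scored (precision/recall/F1, Bray-Curtis composition error) against
a known answer.

## Worked example

```python
from tephraseq import (SimulationConfig, simulate_dataset, run_cascade,
                       apply_calls, evaluate_calls, composition_error)
from tephraseq.synthetic_community import DEFAULT_BLOCKLIST
from tephraseq.tables_io import SampleType

dataset, truth = simulate_dataset(SimulationConfig(seed=42))
calls, patterns = run_cascade(dataset, blocklist_genera=DEFAULT_BLOCKLIST)
cleaned, report = apply_calls(dataset, calls)

m = evaluate_calls(calls, truth)
cores = dataset.samples_of_type(SampleType.DRILL_CORE)
before = composition_error(dataset.table.select_samples(cores), truth)
after = composition_error(cleaned.table, truth)
print(f"precision={m.precision:.3f} recall={m.recall:.3f} f1={m.f1:.3f}")
print(f"composition error: {before:.3f} -> {after:.3f}")
```

prints

```
precision=0.769 recall=1.000 f1=0.870
composition error: 0.306 -> 0.050
```

i.e. on the default 300-feature, 51-sample survey the cascade removes every
planted drilling-fluid and reagent contaminant (recall 1.0); the removals
that count against precision are dominated by seawater-origin taxa that the
overlap rules legitimately strip from the cores. Cleaning reduces the mean
Bray-Curtis distance between each core's observed composition and its true
endemic profile from 0.31 to 0.05.

The same stages are exposed on the command line:

```bash
tephraseq simulate --seed 42 --out sim/
tephraseq decontam --table sim/table.tsv --metadata sim/metadata.tsv \
    --taxonomy sim/taxonomy.tsv --out dec/
tephraseq stats --table dec/cleaned_table.tsv --metadata sim/metadata.tsv \
    --perms 999 --seed 1 --out stats/
tephraseq run --config run.yaml      # full pipeline with manifest
```

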