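# microtriage

Contaminant triage, relative microbial load, and diversity analysis for
**low-biomass 16S amplicon studies** — the setting where a tissue
biopsy (e.g. brain tissue sampled around an intracortical
microelectrode implant) yields so little microbial DNA that host
genomic DNA and reagent microbiota (the "kitome") dominate the
sequencing library, and naïve community analysis would mostly describe
the contamination.

The package is written for microbiome bioinformaticians and
neuro-engineering labs analysing ASV/OTU count tables from such
designs: tissue samples, high-biomass reference samples (feces), and
no-template sequencing blanks processed in batches.

## The model

Each sample is assumed to receive a constant absolute contaminant
template mass *C* while its microbial template mass *B_s* varies; with
library depth *N_s ∝ B_s + C*, the expected contaminant read fraction
is *C/(B_s + C)* — so contaminant relative abundance falls with read
count, and the per-sample ratio

&nbsp;&nbsp;&nbsp;&nbsp;*r_s = (16S amplicon reads) / (contaminant reads)*, with *E[r_s] ≈ B_s / C*,

is a relative microbial-load proxy. On top of this model the package
provides:

- **Triage** — exclusive partition of features into host gDNA (genome
  hit, or no 16S hit with classifier confidence < 10%), technical
  contaminants (one-sided Fisher enrichment in blanks, and a
  fixed-slope F test of log₁₀ abundance vs log₁₀ depth — slope −1 vs 0
  — per sequencing batch and sample source at *p* < 0.1), and
  amplicons.
- **Load** — per-sample ratios, Kruskal-Wallis + two-sided Dunn tests
  with Benjamini-Hochberg adjustment, Spearman/LOESS depth diagnostics.
- **Origin accounting** — genus-level observed-set bookkeeping
  (total / unique / invading / non-invasive), and an exclusive
  partition of implanted-tissue taxa into background-shared,
  distinct-gut and distinct-unknown, with category abundances over
  repeated rarefactions and Tukey HSD contrasts.
- **Diversity** — repeated rarefaction (multivariate hypergeometric),
  Shannon *H = −Σ pᵢ ln pᵢ* and observed features with two-way ANOVA
  (status × treatment, type II), unweighted UniFrac (own
  implementation, validated against a per-branch oracle and
  scikit-bio), PCoA, and PERMANOVA (Anderson's pseudo-F, seeded
  permutations) per replicate with BH adjustment across replicates.
- **Biomarkers** — a LEfSe-style screen: per-rank Kruskal-Wallis filter
  plus a bootstrap LDA effect size on the counts-per-million scale,
  reporting taxa with log₁₀ score > 4.5.
- **Synthetic studies** — a generator that plants the model above
  (constant contamination, lognormal per-group biomass,
  depth ∝ template, group-structured taxon pools, no-template blanks)
  with full ground truth for recovery testing.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import microtriage as mt

table, metadata, annotations, tree, truth = mt.simulate_study(
    mt.SimulationConfig(seed=1))
tri = mt.triage_features(table, metadata, annotations)
print(tri.summary())

profiles = mt.load_profiles(table, tri)
ctrl = profiles.join(metadata)
for status in ("unimplanted", "acute", "chronic"):
    sel = (ctrl["implant_status"] == status) & (ctrl["treatment"] == "control")
    print(status, round(ctrl.loc[sel, "ratio"].median(), 3))
```

prints

```
{'HOST_GDNA': 60, 'TECHNICAL_CONTAMINANT': 36, 'AMPLICON': 214}
unimplanted 0.057
acute 2.4
chronic 0.168
```

All 60 planted host-gDNA features are triaged as host, all 30 planted
kitome features (plus a few borderline amplicons) as technical, and
the group-median read ratios recover the planted load ordering: a
transient rise of microbial signal in acutely implanted tissue
(ratio ≈ 2.4, amplicons outnumber contaminants) that subsides toward
background level (≈ 0.06–0.17, contaminant-dominated) by the chronic
time point.

The `examples/` directory contains one narrative script per
capability (simulation, triage, load, origin accounting, diversity,
biomarkers); each prints the numbers it computes and a line on what
they mean. A thin CLI mirrors the pipeline:

```sh
microtriage --seed 7 --outdir out run-all   # simulate + all stages
microtriage --outdir out report             # aggregate stage summaries
```

Stage outputs are TSV tables plus one JSON summary per stage; reruns
with the same seed are byte-identical.

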