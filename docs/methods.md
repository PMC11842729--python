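# Methods

## The problem and the model

16S amplicon sequencing of very-low-biomass tissue (the motivating case
is brain biopsies taken around intracortical microelectrode implants,
with feces and no-template blanks as companions) is dominated by two
contamination sources: host genomic DNA that co-amplifies with 16S
primers, and reagent/laboratory microbial DNA (the "kitome").  The
package is built around one structural assumption:

*Every sample processed in parallel under the same protocol receives
approximately the same absolute mass `C` of contaminant template, while
the microbial template mass `B_s` varies from sample to sample.*

Two consequences drive the whole pipeline.  First, with sequencing
depth roughly proportional to total template `B_s + C`, the expected
contaminant fraction of a library is `C / (B_s + C)` — contaminant
relative abundance is inversely related to read count, which is the
signature the frequency test detects.  Second, the per-sample ratio of
amplicon-class to contaminant-class reads has expectation `B_s / C`, so
the ratio is a *relative* microbial-load proxy that can be compared
between groups without spike-in controls.

## Triage cascade

Features are partitioned exclusively, in fixed precedence:

1. **Host gDNA** — the feature hit a host genome, or has no 16S
   reference hit *and* classifier confidence < 0.10.  Both flags arrive
   as annotations; an optional exact k-mer screen
   (`kmer_host_screen`, default k = 31) can produce the genome-hit flag
   when nucleotide sequences are available.
2. **Technical contaminant** — among the remaining features, within
   each (sequencing batch × sample source) stratum: a one-sided exact
   Fisher test for enrichment of presence in that batch's no-template
   blanks, and — in fecal strata only, where biomass spans a wide
   range — a frequency test comparing two fixed-slope regressions of
   log10 relative abundance on log10 depth (slope −1 = constant
   contaminant mass vs slope 0 = constant proportion) by the F ratio of
   their residual sums of squares with (n−1, n−1) degrees of freedom.
   A feature is called technical if any applicable stratum test gives
   p < 0.10, or if it is observed only in blanks.  Brain strata use the
   prevalence test alone because brain libraries are contaminant-
   dominated and give the frequency test little dynamic range.
3. **Amplicon** — everything else; the substrate of all downstream
   analysis.

Numerical choices: presence means count ≥ 1; the frequency test needs
≥ 4 present samples (the fixed-slope fits are degenerate below that);
only present samples enter the log fit, so no pseudocount is needed;
stratum results combine by "any test significant".  Read depth is the
concentration proxy throughout — the pipeline assumes no DNA
quantification data.  A one-sided Spearman variant of the frequency
test is available (`TriageConfig(frequency_method="spearman")`) for
sensitivity analysis.

## Load quantification

`load_profiles` sums reads by triage class per sample; `ratio =
amplicon/contaminant`, +∞ (flagged) when contaminant reads are zero and
undefined for empty samples.  Group comparison is Kruskal-Wallis
(tie-corrected) followed by two-sided Dunn z-tests on mean ranks using
the tie-corrected pooled-rank variance, Benjamini-Hochberg adjusted
within one family per call; infinite ratios participate through their
ranks.  The headline per-group summary is the **median** ratio.
Diagnostics use two-sided Spearman correlations (exact permutation
p-values for n ≤ 9, t approximation otherwise) and a local-linear LOESS
smooth with tricube weights, span 0.75, no robustness iterations;
pointwise bands are normal-approximation standard errors of the local
weighted least-squares fit with a globally estimated residual scale.

## Origin accounting

Counts are collapsed to a taxonomic rank (default genus; features
lacking the rank map to `unclassified_<lowest assigned rank>`).  Set
membership ("observed") is count ≥ 1 anywhere in the group on the
*unrarefied* amplicon table; abundance quantification uses rarefied
tables.  For an implanted group `G`: `invading = G \ background`,
`non_invasive = G ∩ background` (so invading + non-invasive = total),
`unique = G` minus the union of the other three displayed sets.  The
origin partition is exclusive with background membership taking
precedence: background-shared ⊃ distinct-gut ⊃ distinct-unknown.
Category abundances are averaged over rarefaction replicates; group
contrasts use two-sided Tukey HSD on replicate-level values.  Treating
each replicate as an observation inflates the effective sample size
(replicates of one sample are not independent), which is why Tukey
intervals are very tight; outputs record the replicate count so readers
can judge this.

## Diversity

Rarefaction is multivariate-hypergeometric subsampling without
replacement to a common depth (default: the minimum library depth of
the analysed table), repeated `n_reps` times from seeded child
generators.  Alpha metrics are the Shannon index (natural log; `base=2`
available) and observed features, compared by crossed two-way
fixed-effects ANOVA (implant status × treatment) with type-II sums of
squares — robust to the mild imbalance of the cohort sizes — plus Tukey
HSD on design cells.  A constant response is reported as p = 1 by
convention; an empty design cell drops the interaction with a warning.

Unweighted UniFrac midpoint-roots the tree (the input tree is
unrooted), then computes, over branches leading to any observed taxon,
the fraction of branch length unique to one of the two samples, by a
single post-order presence propagation vectorised over branches.  If
the midpoint falls exactly on a labelled node that taxon subtends no
branch and contributes no length.  PCoA is Gower double-centering of
−D²/2 with a symmetric eigendecomposition; negative eigenvalues are
reported but excluded from coordinates, and proportions explained are
relative to the sum of positive eigenvalues.  PERMANOVA uses Anderson's
pseudo-F computed directly from the distance matrix with seeded label
permutations and the (1 + exceedances)/(1 + permutations) convention,
so p can never be zero.  `beta_ensemble` runs UniFrac → PERMANOVA per
rarefaction replicate, BH-adjusts across replicates, and reports both
the largest adjusted and the smallest unadjusted p (the two reporting
conventions used for robust and null results respectively).

## Biomarker screen

The LEfSe-style screen agglomerates at each rank phylum…genus, scales
samples to counts-per-million, filters taxa by Kruskal-Wallis across
classes (α = 0.05, one-against-all), and estimates an effect size over
30 seeded bootstrap rounds using 2/3 of each class's samples: a
one-dimensional linear discriminant on the taxon's CPM values, its axis
rescaled by the raw between-class mean difference so the projected
class-mean gap is on the CPM scale (for a single taxon the rescaled gap
equals the raw gap, computed directly).  The score is log10 of the
bootstrap-mean gap; hits need score > 4.5.  The canonical subclass
(within-class Wilcoxon) stage is omitted — the targeted designs define
no subclasses — making this a one-level simplification.

## Synthetic study generator

The generator emulates the statistical structure above with planted
ground truth.  Feature pools: host gDNA (60), kitome (30), background
brain taxa (40), gut-shared invaders (60), unknown-origin invaders
(40), fecal-only taxa (80).  Group sizes follow the modelled study:
5/5 unimplanted, 6/5 acute, 7/6 chronic control/antibiotic brains,
38 baseline and 55 antibiotic fecal samples, and 5 blanks spread over
4 batches (batch 1 unimplanted brains + a third of feces, batch 2 all
implanted brains, batches 3/4 the remaining feces).

Per sample: `B_s` is lognormal around its group median with σ = 0.5;
the group medians are expressed in units of the contaminant mass
(C = 1) and set to the published per-group median read ratios
(unimplanted 0.04, acute 2.10, chronic control 0.12, chronic antibiotic
0.23, baseline fecal 3.72, antibiotic fecal 0.76), so the generator
plants exactly the relative-load ordering the ratio statistic should
recover.  Depth is `30000 · (B_s + C)/mean(B + C)` with lognormal noise
(σ = 0.3), which lands per-group depth ranges in the regime reported
for such studies (unimplanted brains ≈ 7–17 k reads, acute brains
several-fold deeper).  Reads are a single multinomial draw over the
per-sample mass vector, so column sums equal the drawn depths exactly.

Pool eligibility: unimplanted brains draw from background only; acute
brains add both invader pools at mass fractions 0.19 (gut) and 0.28
(unknown) of amplicon mass; chronic brains scale invader mass by 0.2
and antibiotic treatment by a further 0.5 (values chosen once to
reproduce the qualitative orderings — rise and fall of invasion,
reduction under antibiotics — as no generative magnitudes exist to
copy); fecal samples mix gut invaders (0.30) with fecal-only taxa;
blanks contain only contaminants (B = 0).  Contaminant composition
(Dirichlet, α = 0.5) is drawn once globally — the kitome is shared by
construction.  Amplicon compositions are drawn once per (brain group,
pool), which is what PERMANOVA must detect; the two *fecal* treatment
groups share one draw per pool, because a treatment effect on gut
composition is not part of the planted signal and a per-treatment draw
would couple composition to depth within fecal strata, mimicking the
contaminant signature and corrupting the frequency test's planted
truth.  A configurable fraction (0.3) of host features carries no
genome hit and instead exercises the low-confidence rule
(confidence < 0.10, no 16S hit).

What the generator does *not* emulate: nucleotide sequences, PCR and
chimera artifacts, batch effects beyond the batch label, taxonomic
misassignment, compositional correlation between the brain invader
pools and the fecal community beyond shared feature identity, and any
treatment effect on fecal composition.  Passing recovery tests
therefore demonstrate correctness of the inference chain *under the
constant-contamination model*, not performance on real data, where
contaminant mass varies between samples and batches.

## Determinism and scale

Every stochastic operation takes an explicit integer seed; ensembles
spawn per-replicate child seeds from `numpy.random.SeedSequence`.  The
pipeline derives per-stage seeds from the master seed by fixed offsets
and logs one structured line per stage.  Library functions default to
the full-scale convention (500 rarefactions, 10 000 permutations); the
bundled pipeline configuration runs the same chain at the package's
desk-scale default (50 rarefactions, 999 permutations), which leaves
every qualitative conclusion of the synthetic study unchanged, and both
knobs are plain config fields.  All pipeline outputs use fixed float
formatting and sorted JSON keys, so a rerun with the same seed is
byte-identical.

## Known limitations

- The frequency test conditions on presence; features observed with
  systematically low counts can mimic the 1/depth signature, a known
  caveat of prevalence/frequency contaminant screens.
- The ratio is only a *relative* load proxy; absolute quantification
  needs spike-ins, which are out of scope.
- Tukey HSD on rarefaction replicates pseudo-replicates samples (see
  above).
- The origin partition attributes any taxon absent from background and
  feces to "unknown origin"; with shallow background sampling this
  overstates novelty.
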