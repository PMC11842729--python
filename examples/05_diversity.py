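"""Repeated-rarefaction alpha and beta diversity on brain samples.

Shannon/observed-feature metrics per rarefaction replicate with two-way
ANOVA (implant status x treatment), then unweighted UniFrac + PCoA +
PERMANOVA per replicate with BH adjustment across replicates.
"""

import microtriage as mt

table, metadata, annotations, tree, truth = mt.simulate_study(
    mt.SimulationConfig(seed=1))
tri = mt.triage_features(table, metadata, annotations)
amplicon = table.select_features(tri.features_in_class(mt.AMPLICON))
brains = list(metadata.index[metadata["source"] == "brain"])
brain = amplicon.select_samples(brains)

alpha = mt.alpha_ensemble(brain, metadata, n_reps=50, seed=5)
print(f"rarefaction depth: {alpha['depth']} reads, 50 replicates")
means = alpha["per_sample"].join(metadata[["implant_status", "treatment"]])
print(means.groupby(["implant_status", "treatment"], observed=True)
      .mean().round(2).to_string())
print("\nShannon two-way ANOVA (type II):")
print(alpha["anova"]["shannon"].round(4).to_string())

for treatment in ("control", "antibiotic"):
    cohort = list(metadata.index[(metadata["source"] == "brain")
                                 & (metadata["treatment"] == treatment)])
    beta = mt.beta_ensemble(amplicon.select_samples(cohort), tree, metadata,
                            n_reps=20, n_permutations=999, seed=6)
    print(f"\n{treatment} cohort PERMANOVA by implantation status over "
          f"{beta['n_reps']} rarefactions: largest BH-adjusted p = "
          f"{beta['max_adjusted_p']:.4f}, smallest raw p = {beta['min_raw_p']:.4f}")
    pc = beta["first_replicate"]["pcoa"]
    print(f"  first-replicate PCoA: PC1 explains "
          f"{pc.proportion_explained[0]:.0%} of positive-eigenvalue variance")
print("\nsmall adjusted p in every replicate = the planted compositional "
      "shift between unimplanted and implanted brains is robust to rarefaction.")
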