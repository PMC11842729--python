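"""Relative microbial load via the 16S:contaminant read ratio.

Under constant per-sample contamination the ratio of amplicon reads to
contaminant reads is proportional to microbial biomass, so group medians
can be compared (Kruskal-Wallis + Dunn/BH).
"""

from scipy import stats

import microtriage as mt

table, metadata, annotations, tree, truth = mt.simulate_study(
    mt.SimulationConfig(seed=1))
tri = mt.triage_features(table, metadata, annotations)
profiles = mt.load_profiles(table, tri)


def group_label(row):
    if row["source"] == "fecal":
        return f"fecal_{row['treatment']}"
    return f"{row['implant_status']}_{row['treatment']}"


groups = metadata.apply(group_label, axis=1)
nonblank = metadata.index[metadata["source"] != "blank"]
res = mt.compare_ratios(profiles.loc[nonblank], metadata.assign(group=groups), "group")

print("median 16S:contaminant ratio per group:")
for g, m in sorted(res.extra["group_medians"].items()):
    print(f"  {g:24s} {m:8.3f}")
print(f"\nKruskal-Wallis H = {res.statistic:.1f}, p = {res.p_value:.3g}")
sig = res.pairwise[res.pairwise["p_adjusted"] < 0.05]
print(f"{len(sig)}/{len(res.pairwise)} Dunn pairwise contrasts significant after BH")

rho = stats.spearmanr(profiles.loc[nonblank, "ratio"],
                      truth.biomass[nonblank]).statistic
print(f"\nSpearman(ratio, planted biomass) = {rho:.3f} — the ratio tracks "
      "the latent microbial load almost perfectly under the model.")
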