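"""Synthetic low-biomass 16S study generator.

The generator emulates the statistical structure that the triage and
load analyses assume: every sample receives a *constant* absolute mass
``C`` of contaminant template (split between host-gDNA-like and
kitome-like features), while microbial biomass ``B_s`` varies
sample-to-sample (lognormal around a per-group median).  Sequencing
depth is proportional to total template mass ``B_s + C``, so the
relative abundance of contaminants is inversely related to read count —
the property the frequency test exploits — and the expected
amplicon:contaminant read ratio equals ``B_s / C``.

Feature pools carry ground-truth roles: HOST (host gDNA), TECH (kitome),
BACKGROUND (taxa of unimplanted brains), GUT_INVADER (shared between
implanted brains and feces), UNKNOWN_INVADER (implanted brains only) and
FECAL_ONLY.  Unimplanted brains draw from BACKGROUND alone; acutely
implanted brains add both invader pools; chronically implanted brains
add them at reduced mass; antibiotic treatment scales invader mass
further; fecal samples mix GUT_INVADER and FECAL_ONLY; no-template
blanks contain contaminants only.  One Dirichlet draw per (group, pool)
creates the between-group compositional signal; per-sample multinomial
sampling provides within-group variation.

Default group sizes, batch structure and biomass medians follow the
mouse intracortical-microelectrode study design this package models:
5/5 unimplanted, 6/5 acute, 7/6 chronic control/antibiotic brains,
38 baseline and 55 antibiotic-treated fecal samples, five no-template
blanks over four sequencing batches, and per-group biomass medians equal
to the published per-group median 16S:contaminant read ratios (in units
of the contaminant mass C = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import dendropy
import numpy as np
import pandas as pd

from .containers import FeatureTable, validate_annotations, validate_metadata

ROLES = ("HOST", "TECH", "BACKGROUND", "GUT_INVADER", "UNKNOWN_INVADER", "FECAL_ONLY")

#: brain/fecal group cells: (source, implant_status, treatment, sample-id tag)
GROUP_CELLS = (
    ("brain", "unimplanted", "control", "UC"),
    ("brain", "unimplanted", "antibiotic", "UA"),
    ("brain", "acute", "control", "AC"),
    ("brain", "acute", "antibiotic", "AA"),
    ("brain", "chronic", "control", "CC"),
    ("brain", "chronic", "antibiotic", "CA"),
    ("fecal", "not_applicable", "control", "FC"),
    ("fecal", "not_applicable", "antibiotic", "FA"),
)


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Masses are in arbitrary units of the constant per-sample contaminant
    mass (``contaminant_mass = 1``), so a group biomass median of 2.10
    plants a median amplicon:contaminant read ratio of 2.10.
    """

    # samples per (source x status x treatment) cell, keyed by tag
    n_samples: dict = field(
        default_factory=lambda: {
            "UC": 5, "UA": 5, "AC": 6, "AA": 5, "CC": 7, "CA": 6, "FC": 38, "FA": 55,
        }
    )
    n_blanks: int = 5
    # feature pool sizes
    n_host: int = 60
    n_tech: int = 30
    n_background: int = 40
    n_gut_invader: int = 60
    n_unknown_invader: int = 40
    n_fecal_only: int = 80
    # biomass medians per group tag (units of contaminant mass)
    biomass_median: dict = field(
        default_factory=lambda: {
            "UC": 0.04, "UA": 0.04, "AC": 2.10, "AA": 2.10,
            "CC": 0.12, "CA": 0.23, "FC": 3.72, "FA": 0.76,
        }
    )
    biomass_sigma: float = 0.5  # lognormal sigma (natural-log scale)
    contaminant_mass: float = 1.0
    host_mass_fraction: float = 0.5  # host share of the contaminant mass
    depth_scale: int = 30000  # expected depth of an average-template sample
    depth_sigma: float = 0.3
    dirichlet_alpha: float = 0.5
    # invader mass fractions of acute-control amplicon mass
    invader_gut_frac: float = 0.19
    invader_unknown_frac: float = 0.28
    chronic_invader_scale: float = 0.2
    antibiotic_invader_scale: float = 0.5
    fecal_gut_frac: float = 0.30  # gut-invader share of fecal amplicon mass
    host_lowconf_frac: float = 0.3  # HOST features flagged by confidence, not host_hit
    shared_pool_proportions: bool = False  # disable the between-group signal
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        pools = [self.n_host, self.n_tech, self.n_background,
                 self.n_gut_invader, self.n_unknown_invader, self.n_fecal_only]
        if any(n < 0 for n in pools):
            raise ConfigError("pool sizes must be >= 0")
        if self.contaminant_mass < 0:
            raise ConfigError("contaminant_mass must be >= 0")
        if self.dirichlet_alpha <= 0 or self.biomass_sigma < 0:
            raise ConfigError("dirichlet_alpha must be > 0 and sigmas >= 0")
        for tag, n in self.n_samples.items():
            if n == 0 and self.biomass_median.get(tag, 0) > 0:
                raise ConfigError(f"group {tag} has 0 samples but a nonzero biomass median")
            if n > 0 and self.biomass_median.get(tag, 0) <= 0:
                raise ConfigError(f"group {tag} needs a positive biomass median")
        return self


@dataclass
class SyntheticTruth:
    """Planted ground truth enabling recovery tests."""

    biomass: pd.Series  # latent microbial mass B_s per sample (blanks: 0)
    roles: pd.Series  # feature -> role enum value
    config: SimulationConfig


def simulate_tree(n_features: int, seed: int, labels=None) -> dendropy.Tree:
    """Random bifurcating tree over *n_features* leaves with Exp(1) branch
    lengths; deterministic given *seed*."""
    if n_features < 2:
        raise ConfigError("need at least 2 features for a tree")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"F{i:04d}" for i in range(n_features)]
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.exponential(1.0, size=2)
        merged = f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# taxonomy themes per pool: (phylum, class, order, family, genus-stem)

_POOL_THEMES = {
    "HOST": None,  # host gDNA: classifier stops at domain
    "TECH": ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales",
             "Burkholderiaceae", "Kitome"),
    "BACKGROUND": ("Bacteroidota", "Bacteroidia", "Bacteroidales",
                   "Muribaculaceae", "Background"),
    "GUT_INVADER": ("Firmicutes", "Clostridia", "Lachnospirales",
                    "Lachnospiraceae", "Gut"),
    "UNKNOWN_INVADER": ("Actinobacteriota", "Actinobacteria", "Micrococcales",
                        "Micrococcaceae", "Unknown"),
    "FECAL_ONLY": ("Firmicutes", "Bacilli", "Lactobacillales",
                   "Lactobacillaceae", "Fecal"),
}


def _make_lineages(role: str, ids: list[str]) -> list[str]:
    theme = _POOL_THEMES[role]
    if theme is None:
        return ["d__Bacteria"] * len(ids)
    p, c, o, f, stem = theme
    n_genera = max(1, round(0.8 * len(ids)))
    out = []
    for i in range(len(ids)):
        base = f"d__Bacteria; p__{p}; c__{c}; o__{o}; f__{f}"
        if i % 10 == 9:
            out.append(base)  # genus unassigned: exercises the placeholder rule
        else:
            out.append(f"{base}; g__{stem}{i % n_genera:03d}")
    return out


def _group_pool_weights(config: SimulationConfig) -> dict:
    """Amplicon mass fraction per pool for each group tag."""
    g0, u0 = config.invader_gut_frac, config.invader_unknown_frac
    weights = {}
    for source, status, treatment, tag in GROUP_CELLS:
        if source == "fecal":
            weights[tag] = {"GUT_INVADER": config.fecal_gut_frac,
                           "FECAL_ONLY": 1.0 - config.fecal_gut_frac}
            continue
        if status == "unimplanted":
            weights[tag] = {"BACKGROUND": 1.0}
            continue
        g, u = g0, u0
        if status == "chronic":
            g *= config.chronic_invader_scale
            u *= config.chronic_invader_scale
        if treatment == "antibiotic":
            g *= config.antibiotic_invader_scale
            u *= config.antibiotic_invader_scale
        bg = 1.0 - g0 - u0  # background mass is unaffected by treatment
        total = bg + g + u
        weights[tag] = {"BACKGROUND": bg / total, "GUT_INVADER": g / total,
                        "UNKNOWN_INVADER": u / total}
    return weights


def _batches(config: SimulationConfig, tags: dict) -> dict:
    """Batch label per sample id, mirroring the four-batch study design:
    batch1 = unimplanted brains (+ their fecal), batch2 = implanted brains,
    batches 3/4 = fecal of the implanted cohorts."""
    batch = {}
    for tag, ids in tags.items():
        if tag in ("UC", "UA"):
            for s in ids:
                batch[s] = "batch1"
        elif tag in ("AC", "AA", "CC", "CA"):
            for s in ids:
                batch[s] = "batch2"
        else:  # fecal: thirds across batches 1, 3, 4
            thirds = np.array_split(np.asarray(ids, dtype=object), 3)
            for b, part in zip(("batch1", "batch3", "batch4"), thirds):
                for s in part:
                    batch[s] = b
    return batch


def simulate_study(config: SimulationConfig | None = None):
    """Generate a full synthetic study.

    Returns ``(table, metadata, annotations, tree, truth)``; column sums of
    *table* equal the drawn per-sample depths exactly.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed)

    # ---- features ----
    pool_sizes = {
        "HOST": config.n_host, "TECH": config.n_tech,
        "BACKGROUND": config.n_background, "GUT_INVADER": config.n_gut_invader,
        "UNKNOWN_INVADER": config.n_unknown_invader, "FECAL_ONLY": config.n_fecal_only,
    }
    prefix = {"HOST": "H", "TECH": "T", "BACKGROUND": "B",
              "GUT_INVADER": "G", "UNKNOWN_INVADER": "U", "FECAL_ONLY": "F"}
    feature_ids, roles, lineages = [], [], []
    for role in ROLES:
        ids = [f"{prefix[role]}{i:04d}" for i in range(pool_sizes[role])]
        feature_ids += ids
        roles += [role] * len(ids)
        lineages += _make_lineages(role, ids)
    roles = pd.Series(roles, index=feature_ids, name="role")
    pool_idx = {role: np.flatnonzero(roles.to_numpy() == role) for role in ROLES}

    # ---- annotations ----
    n_feat = len(feature_ids)
    host_hit = np.zeros(n_feat, dtype=bool)
    has_16s = np.zeros(n_feat, dtype=bool)
    confidence = np.zeros(n_feat)
    for role in ROLES:
        idx = pool_idx[role]
        if role == "HOST":
            lowconf = rng.random(idx.size) < config.host_lowconf_frac
            host_hit[idx[~lowconf]] = True
            confidence[idx[~lowconf]] = rng.uniform(0.0, 0.5, (~lowconf).sum())
            confidence[idx[lowconf]] = rng.uniform(0.0, 0.0999, lowconf.sum())
        else:
            has_16s[idx] = True
            confidence[idx] = rng.uniform(0.7, 1.0, idx.size)
    annotations = pd.DataFrame(
        {"taxon": lineages, "confidence": confidence,
         "host_hit": host_hit, "has_16s_hit": has_16s},
        index=pd.Index(feature_ids, name="feature_id"),
    )

    # ---- tree over all features ----
    tree = simulate_tree(n_feat, int(rng.integers(2**31)), labels=feature_ids)

    # ---- samples, metadata, latent biomass ----
    sample_ids, meta_rows, tags = [], [], {}
    biomass = {}
    subj = 0
    for source, status, treatment, tag in GROUP_CELLS:
        n = config.n_samples.get(tag, 0)
        ids = [f"{tag}{i + 1:02d}" for i in range(n)]
        tags[tag] = ids
        for s in ids:
            subj += 1
            meta_rows.append((s, source, status, treatment, f"S{subj:03d}"))
            biomass[s] = config.biomass_median[tag] * float(
                np.exp(config.biomass_sigma * rng.standard_normal())
            )
        sample_ids += ids
    blank_ids = [f"BL{i + 1:02d}" for i in range(config.n_blanks)]
    for s in blank_ids:
        meta_rows.append((s, "blank", "not_applicable", "not_applicable", "NTC"))
        biomass[s] = 0.0
    sample_ids += blank_ids
    batch = _batches(config, tags)
    for i, s in enumerate(blank_ids):  # at least one blank per batch, extras wrap
        batch[s] = f"batch{(i % 4) + 1}"
    metadata = pd.DataFrame(
        [(src, st, tr, batch[s], su) for (s, src, st, tr, su) in meta_rows],
        index=pd.Index([r[0] for r in meta_rows], name="#SampleID"),
        columns=["source", "implant_status", "treatment", "batch", "subject_id"],
    )
    biomass = pd.Series(biomass, name="biomass").loc[sample_ids]

    # ---- compositional proportions ----
    alpha = config.dirichlet_alpha
    # contaminant composition is global: the 'kitome' is shared by construction
    contam_props = {
        role: rng.dirichlet(np.full(pool_sizes[role], alpha))
        for role in ("HOST", "TECH") if pool_sizes[role] > 0
    }
    pool_weights = _group_pool_weights(config)
    # Amplicon compositions are drawn once per (group, pool): the brain
    # groups differ compositionally (the signal beta diversity must
    # detect).  The two fecal treatment groups share one draw — the gut
    # composition itself is not a planted treatment effect, only its
    # biomass is — so fecal depth differences stay uncoupled from
    # composition (treatment-by-depth confounding would otherwise mimic
    # the contaminant signature).
    group_props: dict = {}
    draws: dict = {}
    for source, _, _, tag in GROUP_CELLS:
        group_props[tag] = {}
        for pool in pool_weights[tag]:
            if pool_sizes[pool] == 0:
                continue
            if config.shared_pool_proportions:
                key = pool
            elif source == "fecal":
                key = ("fecal", pool)
            else:
                key = (tag, pool)
            if key not in draws:
                draws[key] = rng.dirichlet(np.full(pool_sizes[pool], alpha))
            group_props[tag][pool] = draws[key]

    # ---- per-sample mass vectors, depths, multinomial reads ----
    c_mass = config.contaminant_mass
    tag_of = {s: tag for tag, ids in tags.items() for s in ids}
    mass = np.zeros((n_feat, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        if c_mass > 0:
            if "HOST" in contam_props:
                mass[pool_idx["HOST"], j] = (
                    c_mass * config.host_mass_fraction * contam_props["HOST"]
                )
            if "TECH" in contam_props:
                mass[pool_idx["TECH"], j] = (
                    c_mass * (1 - config.host_mass_fraction) * contam_props["TECH"]
                )
        if s in tag_of:
            tag = tag_of[s]
            for pool, w in pool_weights[tag].items():
                if pool in group_props[tag]:
                    mass[pool_idx[pool], j] += biomass[s] * w * group_props[tag][pool]

    template = biomass.to_numpy() + c_mass
    mean_template = float(template.mean())
    depths = np.maximum(
        1,
        np.round(
            config.depth_scale * template / mean_template
            * np.exp(config.depth_sigma * rng.standard_normal(len(sample_ids)))
        ).astype(np.int64),
    )
    counts = np.zeros((n_feat, len(sample_ids)), dtype=np.int64)
    for j in range(len(sample_ids)):
        total_mass = mass[:, j].sum()
        if total_mass <= 0:
            continue
        counts[:, j] = rng.multinomial(depths[j], mass[:, j] / total_mass)

    table = FeatureTable(counts, feature_ids, sample_ids)
    validate_metadata(metadata, table)
    validate_annotations(annotations, table)
    truth = SyntheticTruth(biomass=biomass, roles=roles, config=config)
    return table, metadata, annotations, tree, truth


def config_from_dict(overrides: dict) -> SimulationConfig:
    """Build a config from a plain dict (e.g. parsed YAML), merging dict
    fields with the defaults."""
    base = SimulationConfig()
    known = set(asdict(base))
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    merged = dict(overrides)
    for key in ("n_samples", "biomass_median"):
        if key in merged:
            merged[key] = {**getattr(base, key), **merged[key]}
    return replace(base, **merged).validate()
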