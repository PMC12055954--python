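"""Synthetic longitudinal oral-microbiome study generator.

Emulates the study design — 22 subjects sampled at three oral sites
(saliva SA, tongue TO, subgingival plaque SU) at three times (t0, t1,
t2), with an 11/11 control/juice arm split — on a Dirichlet-multinomial
count model with known ground truth:

* site-distinct base compositions built block-wise so that the pairwise
  Bray-Curtis distances between them equal the centroid-dissimilarity
  anchors (SA-TO 0.22 < SA-SU 0.42 < TO-SU 0.53);
* persistent per-subject multiplicative random effects (the
  repeated-measures signal the within-subject tests exploit);
* taxa with time effects (fold change at t1 that persists at t2) and
  taxa with time x arm interactions (fold change at t1 in the juice arm
  only);
* three contaminant clusters whose counts ride on a shared per-sample
  log-normal load, inducing the mutual Spearman correlations the
  network filter detects;
* uneven log-normal library depths.

Depths default to a desk scale of ~5,000 reads per sample; the
``paper_scale`` preset raises the mean to 55,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata, TaxonomyMap

#: (block name, taxa count, total mass, sites carrying the block)
#: Base Bray-Curtis separations are 0.05 (SA-TO), 0.32 (SA-SU) and 0.37
#: (TO-SU) — deliberately smaller than the centroid-dissimilarity targets
#: (22/42/53%) because within-site sampling noise inflates estimated
#: centroid distances; these masses are calibrated so the measured
#: centroid dissimilarities land on the targets at default settings.
_BLOCKS = (
    ("core", 40, 0.63, ("SA", "TO", "SU")),
    ("sa_to", 20, 0.32, ("SA", "TO")),
    ("sa_su", 10, 0.05, ("SA", "SU")),
    ("to", 15, 0.05, ("TO",)),
    ("su", 25, 0.32, ("SU",)),
)

_CONTAM_CLUSTERS = (
    ("Ralstonia solanacearum", "Ralstonia"),
    ("Exiguobacterium aurantiacum", "Exiguobacterium"),
    ("Alkalibacterium pelagium", "Alkalibacterium"),
)


@dataclass
class SimulationConfig:
    seed: int
    n_subjects: int = 22
    n_juice: int = 11
    sites: tuple[str, ...] = ("SA", "TO", "SU")
    times: tuple[str, ...] = ("t0", "t1", "t2")
    depth_mean: float = 5000.0
    depth_sigma: float = 0.3           # log-scale sd of library sizes
    depth_min: int = 1000
    dm_concentration: float = 300.0    # Dirichlet-multinomial overdispersion
    subject_sigma: float = 0.6         # log-sd of persistent subject effects
    n_time_taxa: int = 10              # per site, fold applied at t1 and t2
    time_fold: float = 3.0
    n_interaction_taxa: int = 6        # per site, fold at t1 in juice arm only
    interaction_fold: float = 3.0
    n_contaminant_clusters: int = 3
    contaminant_cluster_size: int = 6  # species per cluster, incl. the seed
    contaminant_share: float = 0.08    # expected contaminant read fraction
    contaminant_load_sigma: float = 1.0  # log-sd of the shared per-sample load

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.time_fold <= 0 or self.interaction_fold <= 0:
            raise ValueError("fold changes must be positive")
        if self.n_juice > self.n_subjects:
            raise ValueError("more juice subjects than subjects")
        if self.n_contaminant_clusters > len(_CONTAM_CLUSTERS):
            raise ValueError("at most 3 contaminant clusters are defined")


def null_config(seed: int, **overrides) -> SimulationConfig:
    """All effects off: no time/interaction signal, no contaminants, no
    subject random effects.  Samples are fully exchangeable — the
    configuration for null-calibration experiments."""
    if "n_subjects" in overrides and "n_juice" not in overrides:
        overrides["n_juice"] = overrides["n_subjects"] // 2
    cfg = SimulationConfig(seed=seed, subject_sigma=0.0, n_time_taxa=0,
                           n_interaction_taxa=0, contaminant_cluster_size=0)
    return replace(cfg, **overrides)


def paper_scale(seed: int, **overrides) -> SimulationConfig:
    """Library depths at the sequenced study's scale (~55,000 reads)."""
    return replace(SimulationConfig(seed=seed), depth_mean=55000.0,
                   depth_min=15000, **overrides)


@dataclass
class GroundTruth:
    contaminant_species: set[str]
    time_taxa: dict[str, dict[str, int]]          # site -> species -> ±1
    interaction_taxa: dict[str, dict[str, int]]   # site -> species -> ±1
    site_targets: dict[tuple[str, str], float] = field(default_factory=dict)

    def all_signal_taxa(self) -> set[str]:
        out: set[str] = set()
        for d in (*self.time_taxa.values(), *self.interaction_taxa.values()):
            out |= set(d)
        return out


def _base_compositions(rng: np.random.Generator):
    """Species list, per-site base composition vectors, per-species genus."""
    species: list[str] = []
    genus: dict[str, str] = {}
    masses: dict[str, np.ndarray] = {}
    site_mass: dict[str, list[tuple[int, float]]] = {"SA": [], "TO": [], "SU": []}
    for block, count, mass, sites in _BLOCKS:
        # geometric rank-abundance within the block
        w = 0.93 ** np.arange(count)
        w = w / w.sum() * mass
        for i in range(count):
            name = f"{block.capitalize()}bacter species {i + 1:02d}"
            idx = len(species)
            species.append(name)
            genus[name] = f"{block.capitalize()}bacter g{i // 2 + 1:02d}"
            for s in sites:
                site_mass[s].append((idx, w[i]))
    base = {}
    for s, pairs in site_mass.items():
        v = np.zeros(len(species))
        for idx, m in pairs:
            v[idx] = m
        base[s] = v / v.sum()
    return species, base, genus


def _pick_signal(rng: np.random.Generator, base: dict[str, np.ndarray],
                 species: list[str], n_time: int, n_inter: int):
    time_taxa: dict[str, dict[str, int]] = {}
    inter_taxa: dict[str, dict[str, int]] = {}
    for site, vec in base.items():
        # candidates: reasonably abundant in the site so folds are visible
        order = np.argsort(vec)[::-1]
        candidates = [i for i in order if vec[i] > 0][: 3 * (n_time + n_inter)]
        chosen = rng.choice(len(candidates), size=min(n_time + n_inter, len(candidates)),
                            replace=False)
        picks = [candidates[c] for c in chosen]
        time_taxa[site] = {species[i]: (1 if k % 2 == 0 else -1)
                           for k, i in enumerate(picks[:n_time])}
        inter_taxa[site] = {species[i]: (1 if k % 2 == 0 else -1)
                            for k, i in enumerate(picks[n_time:n_time + n_inter])}
    return time_taxa, inter_taxa


def generate(config: SimulationConfig):
    """Simulate the study.

    Returns ``(counts, metadata, taxonomy, truth)`` with a variant-level
    count table (most species carry one sequence variant, the ten most
    abundant carry two, and a handful of rare variants lack a species
    call and pool into "others" at species level).
    """
    rng = np.random.default_rng(config.seed)
    species, base, genus_of = _base_compositions(rng)
    n_sp = len(species)

    time_taxa, inter_taxa = _pick_signal(
        rng, {s: base[s] for s in config.sites if s in base},
        species, config.n_time_taxa, config.n_interaction_taxa)

    # contaminant species, disjoint from the biological pool
    contam_species: list[str] = []
    contam_cluster: list[list[str]] = []
    contam_w: list[np.ndarray] = []
    if config.contaminant_cluster_size > 0 and config.contaminant_share > 0:
        for c in range(config.n_contaminant_clusters):
            seed_name, genus_name = _CONTAM_CLUSTERS[c]
            members = [seed_name] + [f"{genus_name} contaminans sp{k + 1:02d}"
                                     for k in range(config.contaminant_cluster_size - 1)]
            for m in members:
                genus_of[m] = genus_name
            contam_cluster.append(members)
            contam_species.extend(members)
            w = 0.9 ** np.arange(len(members))
            contam_w.append(w / w.sum())

    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    arm_of = {s: ("juice" if i >= config.n_subjects - config.n_juice else "control")
              for i, s in enumerate(subjects)}

    # persistent subject x site x species multiplicative effects
    subj_eff = {}
    for subj in subjects:
        for site in config.sites:
            if config.subject_sigma > 0:
                subj_eff[(subj, site)] = np.exp(
                    rng.normal(0.0, config.subject_sigma, n_sp))
            else:
                subj_eff[(subj, site)] = np.ones(n_sp)

    mu_log = np.log(config.depth_mean) - config.depth_sigma ** 2 / 2
    load_mean = np.exp(config.contaminant_load_sigma ** 2 / 2)

    all_names = species + contam_species
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for subj in subjects:
        for site in config.sites:
            for time in config.times:
                sid = f"{subj}_{site}_{time}"
                w = base[site] * subj_eff[(subj, site)]
                if time in ("t1", "t2"):
                    for sp, direction in time_taxa.get(site, {}).items():
                        w[species.index(sp)] *= config.time_fold ** direction
                if time == "t1" and arm_of[subj] == "juice":
                    for sp, direction in inter_taxa.get(site, {}).items():
                        w[species.index(sp)] *= config.interaction_fold ** direction
                support = w > 0
                p = np.zeros(n_sp)
                alpha = config.dm_concentration * w[support] / w[support].sum()
                p[support] = rng.dirichlet(alpha)
                depth = max(config.depth_min,
                            int(rng.lognormal(mu_log, config.depth_sigma)))
                counts = np.zeros(len(all_names), dtype=np.int64)
                counts[:n_sp] = rng.multinomial(depth, p)
                if contam_species:
                    offset = n_sp
                    for members, w_c in zip(contam_cluster, contam_w):
                        load = rng.lognormal(0.0, config.contaminant_load_sigma)
                        lam = (load / load_mean) * w_c * \
                            config.contaminant_share * depth / len(contam_cluster)
                        counts[offset: offset + len(members)] = rng.poisson(lam)
                        offset += len(members)
                columns[sid] = counts
                meta_rows.append({"sample_id": sid, "subject_id": subj,
                                  "site": site, "time": time, "arm": arm_of[subj]})

    species_table = pd.DataFrame(columns, index=all_names)

    # expand to sequence variants: the 10 most abundant species carry two
    # variants; 5 rare biological species lack a species-level call
    totals = species_table.sum(axis=1)
    split = list(totals.loc[species].sort_values(ascending=False).index[:10])
    rare_unassigned = set(totals.loc[species].sort_values().index[:5]) - \
        set().union(*[set(d) for d in time_taxa.values()],
                    *[set(d) for d in inter_taxa.values()]) if species else set()
    var_rows, var_ids, genus_map, species_map = [], [], {}, {}
    counter = 0
    for name in all_names:
        row = species_table.loc[name].to_numpy()
        parts = [row]
        if name in split:
            first = rng.binomial(row, 0.6)
            parts = [first, row - first]
        for part in parts:
            counter += 1
            vid = f"ASV_{counter:04d}"
            var_ids.append(vid)
            var_rows.append(part)
            genus_map[vid] = genus_of[name]
            if name not in rare_unassigned:
                species_map[vid] = name
    counts = CountTable(pd.DataFrame(np.vstack(var_rows), index=var_ids,
                                     columns=species_table.columns), level="variant")
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    taxonomy = TaxonomyMap(genus=genus_map, species=species_map)
    truth = GroundTruth(
        contaminant_species=set(contam_species),
        time_taxa=time_taxa, interaction_taxa=inter_taxa,
        site_targets={("SA", "TO"): 22.0, ("SA", "SU"): 42.0, ("TO", "SU"): 53.0},
    )
    return counts, metadata, taxonomy, truth


# ---------------------------------------------------------------------------
# Ground-truth round-trip

def export_truth(truth: GroundTruth, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"species": sorted(truth.contaminant_species)}).to_csv(
        directory / "contaminants.tsv", sep="\t", index=False)
    rows = []
    for kind, table in (("time", truth.time_taxa), ("interaction", truth.interaction_taxa)):
        for site, taxa in table.items():
            for sp, direction in taxa.items():
                rows.append({"site": site, "taxon": sp, "kind": kind,
                             "direction": direction})
    pd.DataFrame(rows, columns=["site", "taxon", "kind", "direction"]).to_csv(
        directory / "signal_taxa.tsv", sep="\t", index=False)
    pd.DataFrame([{"site_a": a, "site_b": b, "dissimilarity_pct": v}
                  for (a, b), v in truth.site_targets.items()]).to_csv(
        directory / "site_targets.tsv", sep="\t", index=False)


def read_truth(directory: str | Path) -> GroundTruth:
    directory = Path(directory)
    contam = set(pd.read_csv(directory / "contaminants.tsv", sep="\t")["species"])
    sig = pd.read_csv(directory / "signal_taxa.tsv", sep="\t")
    time_taxa: dict[str, dict[str, int]] = {}
    inter_taxa: dict[str, dict[str, int]] = {}
    for _, row in sig.iterrows():
        target = time_taxa if row["kind"] == "time" else inter_taxa
        target.setdefault(row["site"], {})[row["taxon"]] = int(row["direction"])
    targets = {}
    tf = directory / "site_targets.tsv"
    if tf.exists():
        for _, row in pd.read_csv(tf, sep="\t").iterrows():
            targets[(row["site_a"], row["site_b"])] = float(row["dissimilarity_pct"])
    return GroundTruth(contaminant_species=contam, time_taxa=time_taxa,
                       interaction_taxa=inter_taxa, site_targets=targets)
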