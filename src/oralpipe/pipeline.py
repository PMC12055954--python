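"""End-to-end orchestration: decontamination -> aggregation -> diversity
-> community structure -> Friedman screening -> juice-effect
classification, with a run report.

Per-site analyses are independent runs sharing one decontaminated
variant table: the contaminant screen is computed once on subgingival
samples and the removal applied study-wide, after which each site is
analysed separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import alpha, contamination, differential, juice, structure
from .tables import (CountTable, SampleMetadata, TaxonomyMap, aggregate,
                     read_count_table, read_metadata, read_taxonomy,
                     to_relative, write_count_table)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts_path: str | Path | None = None
    metadata_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    rho_threshold: float = 0.7
    min_edges: int = 3
    prevalence: float = 0.10
    rarefaction_depth: int | None = None  # None = smallest library
    permutations: int = 9999
    alpha_level: float = 0.05
    q_primary: float = 0.05
    q_secondary: float = 0.10
    seed: int = 0
    sites: tuple[str, ...] = ("SA", "TO", "SU")
    level: str = "species"        # level for structure analyses
    screen_level: str = "genus"   # level for Friedman / juice screens
    contaminant_seeds: tuple[str, ...] = contamination.DEFAULT_SEEDS
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if not 0 < self.rho_threshold < 1:
            raise ValueError("rho threshold must be in (0, 1)")
        if self.permutations < 99:
            raise ValueError("use at least 99 permutations")


@dataclass
class RunResult:
    report: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def load_inputs(config: RunConfig) -> tuple[CountTable, SampleMetadata, TaxonomyMap]:
    if not (config.counts_path and config.metadata_path and config.taxonomy_path):
        raise ValueError("counts, metadata and taxonomy paths are all required")
    counts = read_count_table(config.counts_path)
    metadata = read_metadata(config.metadata_path)
    taxonomy = read_taxonomy(config.taxonomy_path)
    return counts, metadata, taxonomy


def run_all(counts: CountTable, metadata: SampleMetadata, taxonomy: TaxonomyMap,
            config: RunConfig) -> RunResult:
    metadata = metadata.align_to(counts)  # fails fast on mismatch
    result = RunResult()
    report = result.report
    report["n_samples"] = len(counts.sample_ids)
    report["reads_pre"] = int(counts.library_sizes().sum())

    # --- stage 1: contaminant screen on SU, removal study-wide
    species_counts = aggregate(counts, taxonomy, "species")
    species_rel = to_relative(species_counts)
    su = metadata.samples_for(site="SU")
    contam_report = contamination.screen(
        species_rel, su, seeds=list(config.contaminant_seeds),
        threshold=config.rho_threshold, min_prevalence=config.prevalence)
    clean_counts, contam_report = contamination.apply_removal(
        counts, contam_report, taxonomy)
    report["removed_species"] = sorted(contam_report.removed_species)
    report["reads_removed"] = contam_report.removed_read_count
    report["reads_post"] = int(clean_counts.library_sizes().sum())
    assert report["reads_pre"] - report["reads_removed"] == report["reads_post"]

    species_clean = aggregate(clean_counts, taxonomy, "species")
    level_clean = species_clean if config.level == "species" else \
        aggregate(clean_counts, taxonomy, config.level)
    screen_clean = aggregate(clean_counts, taxonomy, config.screen_level)

    # --- stage 2: rarefaction + alpha diversity (per-site comparison)
    rarefied = alpha.rarefy(species_clean, config.rarefaction_depth,
                            seed=config.seed)
    div = alpha.diversity_table(rarefied)
    div["site"] = metadata.data.loc[div.index, "site"]
    result.tables["diversity"] = div
    groups = {s: div.loc[div["site"] == s, "shannon"].to_numpy()
              for s in config.sites}
    aov = alpha.anova_holm_sidak(groups)
    aov["pairwise"] = {f"{a}-{b}": v for (a, b), v in aov["pairwise"].items()}
    report["diversity_anova"] = aov
    report["rarefaction_depth"] = int(rarefied.library_sizes().iloc[0])

    # --- stage 3: community structure
    rel = to_relative(level_clean)
    dmat = structure.bray_curtis(rel)
    site_groups = {s: metadata.samples_for(site=s) for s in config.sites}
    result.tables["centroid_dissimilarity"] = structure.centroid_dissimilarity(
        dmat, site_groups)
    report["dispersion_sites"] = structure.dispersion(
        dmat, site_groups, permutations=min(config.permutations, 999),
        seed=config.seed)
    per_site: dict[str, dict] = {}
    for site in config.sites:
        ids = site_groups[site]
        sub = dmat.subset(ids)
        sub_meta = SampleMetadata(metadata.data.loc[ids].copy())
        res = structure.permanova(sub, sub_meta, factors=["time", "arm"],
                                  permutations=config.permutations,
                                  seed=config.seed)
        per_site[site] = {
            "permanova": {name: {"pseudo_F": t.pseudo_f, "p": t.p, "df": t.df}
                          for name, t in res.terms.items()},
            "pairwise_time": {
                f"{a}-{b}": v for (a, b), v in structure.pairwise_permanova(
                    sub, sub_meta, "time", permutations=config.permutations,
                    seed=config.seed).items()},
        }
    report["structure"] = per_site

    # --- stage 4: Friedman / Dunn screening per site
    screen_rel = to_relative(screen_clean)
    screen_frames = []
    report["friedman"] = {}
    for site in config.sites:
        res = differential.screen(screen_rel, metadata, site,
                                  min_prevalence=config.prevalence,
                                  q_primary=config.q_primary,
                                  q_secondary=config.q_secondary,
                                  alpha=config.alpha_level)
        frame = differential.results_table(res)
        screen_frames.append(frame)
        n_primary = sum(r.tier == "primary" for r in res)
        report["friedman"][site] = {
            "n_tested": len(res), "n_primary": n_primary,
            "n_secondary": sum(r.tier == "secondary" for r in res),
            "pct_primary": round(100 * n_primary / len(res), 1) if res else 0.0,
        }
    result.tables["friedman"] = pd.concat(screen_frames, ignore_index=True) \
        if screen_frames else pd.DataFrame()

    # --- stage 5: juice-effect classification per site
    juice_frames = []
    report["juice_effect"] = {}
    for site in config.sites:
        res = juice.screen(screen_rel, metadata, site,
                           min_prevalence=config.prevalence)
        juice_frames.append(juice.results_table(res))
        report["juice_effect"][site] = {
            "n_tested": len(res),
            "n_effect": sum(r.verdict == "effect" for r in res),
            "n_probable": sum(r.verdict.startswith("probable") for r in res),
            "n_excluded": sum(r.verdict == "excluded_baseline" for r in res),
        }
    result.tables["juice_effect"] = pd.concat(juice_frames, ignore_index=True) \
        if juice_frames else pd.DataFrame()

    if config.out_dir is not None:
        _write_outputs(result, clean_counts, config)
    return result


def _write_outputs(result: RunResult, clean_counts: CountTable,
                   config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(clean_counts, out / "counts_decontaminated.tsv")
    for name, frame in result.tables.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t")
    import json

    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
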