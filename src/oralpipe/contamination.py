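"""Contaminant identification via a seed-anchored Spearman network.

Kit and paper-point contaminants (e.g. *Ralstonia*, *Exiguobacterium*,
*Alkalibacterium*) co-vary across samples because they enter with a
shared per-sample load rather than with the biology.  Species whose
abundances correlate strongly (Spearman rho > 0.7) therefore form tight
clusters around known contaminant seeds; cluster members with at least
three strong correlations are removed study-wide.

The screen is computed on subgingival (SU) samples, where the biomass is
lowest and contamination most visible; removal is applied to all sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tables import CountTable, RelativeAbundanceTable, TaxonomyMap, prevalence_filter

log = logging.getLogger(__name__)

RHO_THRESHOLD = 0.7
MIN_EDGES = 3

#: species anchoring the contaminant clusters
DEFAULT_SEEDS = (
    "Ralstonia solanacearum",
    "Exiguobacterium aurantiacum",
    "Alkalibacterium pelagium",
    "Alkalibacterium thalassium",
)


@dataclass
class CorrelationNetwork:
    graph: nx.Graph            # nodes: species ids; edge attr "rho"
    threshold: float = RHO_THRESHOLD

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class ContaminantReport:
    clusters: list[set[str]]
    removed_species: set[str]
    removed_read_count: int = 0
    sensitivity: float | None = None   # filled when ground truth is known
    specificity: float | None = None
    edge_counts: dict[str, int] = field(default_factory=dict)


def spearman_matrix(abund: RelativeAbundanceTable, samples: list[str] | None = None,
                    min_prevalence: float = 0.10) -> pd.DataFrame:
    """Pairwise Spearman rho between species over a sample subset.

    Taxa are pre-filtered to strict prevalence > ``min_prevalence`` within
    the subset.  Constant taxa have undefined correlations, recorded as
    NaN (never an edge).  Ties receive average ranks.
    """
    sub = abund if samples is None else abund.subset_samples(samples)
    if sub.data.shape[1] < 4:
        raise ValueError("need at least 4 samples for the correlation screen")
    keep = prevalence_filter(sub, min_prevalence, strict=True)
    data = sub.data.loc[keep]
    # rank transform (average ties) then Pearson: robust to constant taxa,
    # which yield NaN rows rather than collapsing the whole matrix
    ranks = data.rank(axis=1, method="average")
    rho = ranks.T.corr(method="pearson").to_numpy()
    const = data.nunique(axis=1).to_numpy() == 1
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=data.index, columns=data.index)


def build_network(rho: pd.DataFrame, threshold: float = RHO_THRESHOLD) -> CorrelationNetwork:
    """Graph with an edge wherever rho strictly exceeds the threshold."""
    if not np.allclose(rho.to_numpy(), rho.to_numpy().T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(rho.index)
    arr = rho.to_numpy()
    idx = rho.index.to_list()
    iu, ju = np.triu_indices(len(idx), k=1)
    for i, j in zip(iu, ju):
        r = arr[i, j]
        if np.isfinite(r) and r > threshold:
            g.add_edge(idx[i], idx[j], rho=float(r))
    return CorrelationNetwork(graph=g, threshold=threshold)


def find_clusters(net: CorrelationNetwork, seeds: list[str]) -> list[set[str]]:
    """Connected components of the network containing at least one seed."""
    present = [s for s in seeds if s in net.graph]
    for s in set(seeds) - set(present):
        log.warning("seed %r absent from network; skipped", s)
    clusters: list[set[str]] = []
    for comp in nx.connected_components(net.graph):
        if any(s in comp for s in present):
            clusters.append(set(comp))
    return clusters


def flag_removals(net: CorrelationNetwork, clusters: list[set[str]],
                  seeds: list[str] | None = None,
                  intra_cluster: bool = True) -> ContaminantReport:
    """Species to remove: seed-cluster members with >= 3 strong edges.

    With ``intra_cluster=True`` (default) only edges to other members of
    the same cluster qualify; the alternative counts all edges.  Seeds
    themselves are always removed.
    """
    seeds = list(seeds or DEFAULT_SEEDS)
    removed: set[str] = set()
    edge_counts: dict[str, int] = {}
    for cluster in clusters:
        for sp in cluster:
            if intra_cluster:
                deg = sum(1 for nb in net.graph.neighbors(sp) if nb in cluster)
            else:
                deg = net.graph.degree(sp)
            edge_counts[sp] = deg
            if deg >= MIN_EDGES or sp in seeds:
                removed.add(sp)
    return ContaminantReport(clusters=clusters, removed_species=removed,
                             edge_counts=edge_counts)


def apply_removal(table: CountTable, report: ContaminantReport,
                  tax: TaxonomyMap | None = None) -> tuple[CountTable, ContaminantReport]:
    """Drop all variants of removed species from every sample.

    For a variant-level table a taxonomy map translates species to
    variants; species/genus tables are filtered directly by label.
    """
    if table.level == "variant":
        if tax is None:
            raise ValueError("variant-level removal needs a taxonomy map")
        drop = [vid for vid in table.taxon_ids
                if tax.species.get(vid) in report.removed_species]
    else:
        drop = [t for t in table.taxon_ids if t in report.removed_species]
    removed_reads = int(table.data.loc[drop].to_numpy().sum()) if drop else 0
    report.removed_read_count = removed_reads
    return table.drop_taxa(drop), report


def screen(abund: RelativeAbundanceTable, su_samples: list[str],
           seeds: list[str] | None = None, threshold: float = RHO_THRESHOLD,
           min_prevalence: float = 0.10, intra_cluster: bool = True) -> ContaminantReport:
    """Full contaminant screen on a species-level abundance table."""
    seeds = list(seeds or DEFAULT_SEEDS)
    rho = spearman_matrix(abund, su_samples, min_prevalence=min_prevalence)
    net = build_network(rho, threshold=threshold)
    clusters = find_clusters(net, seeds)
    return flag_removals(net, clusters, seeds=seeds, intra_cluster=intra_cluster)


def score_against_truth(report: ContaminantReport, true_contaminants: set[str],
                        all_species: set[str]) -> ContaminantReport:
    """Fill sensitivity/specificity of the flagging given ground truth."""
    flagged = report.removed_species
    tp = len(flagged & true_contaminants)
    fp = len(flagged - true_contaminants)
    negatives = all_species - true_contaminants
    report.sensitivity = tp / len(true_contaminants) if true_contaminants else None
    report.specificity = (len(negatives) - fp) / len(negatives) if negatives else None
    return report


def export_edge_list(net: CorrelationNetwork, path: str | Path) -> None:
    rows = [{"source": u, "target": v, "rho": d["rho"]}
            for u, v, d in net.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "rho"]).to_csv(
        path, sep="\t", index=False)
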