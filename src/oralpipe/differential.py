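"""Per-site Friedman screening of taxa over time.

For every taxon present in at least 10% of a site's samples, abundances
of the complete subjects are compared over t0/t1/t2 with the Friedman
test, p-values are Benjamini-Hochberg adjusted across taxa, and taxa
with q < 0.1 receive Dunn's within-block post-hoc per time pair.

Two-tier selection: a taxon is "primary" when q < 0.05; "secondary"
when the raw Friedman p < 0.05, 0.05 <= q < 0.1 and at least one Dunn
pair is significant at 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import RelativeAbundanceTable, SampleMetadata, TIMES, prevalence_filter

log = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    taxon: str
    site: str
    statistic: float
    p: float
    q: float = np.nan
    dunn: dict[tuple[str, str], dict] = field(default_factory=dict)  # pair -> {"z":, "p":}
    tier: str = "none"  # primary | secondary | none
    mean_abundance: dict[str, float] = field(default_factory=dict)  # time -> mean %
    n_subjects: int = 0


def friedman(values: pd.DataFrame) -> tuple[float, float, int] | None:
    """Friedman chi-square (tie-corrected) on a subject x time matrix.

    Subjects with any missing time point are dropped (complete-case);
    returns ``None`` when fewer than two complete subjects remain.
    """
    if values.shape[1] != 3:
        raise ValueError("expected exactly 3 time levels")
    complete = values.dropna(axis=0)
    dropped = len(values) - len(complete)
    if dropped:
        log.info("dropped %d incomplete subjects", dropped)
    n = len(complete)
    if n < 2:
        log.warning("fewer than 2 complete subjects; test skipped")
        return None
    cols = [complete.iloc[:, j].to_numpy() for j in range(3)]
    if all(np.ptp(complete.iloc[i].to_numpy()) == 0 for i in range(n)):
        return 0.0, 1.0, n  # every subject constant: all ties
    stat, p = stats.friedmanchisquare(*cols)
    return float(stat), float(p), n


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def dunn_posthoc(values: pd.DataFrame) -> dict[tuple[str, str], dict]:
    """Dunn's post-hoc in its within-block (Friedman) form.

    z = (Rbar_i - Rbar_j) / sqrt(k(k+1) / (6 n)) from within-subject
    average ranks; two-sided normal p, unadjusted.
    """
    complete = values.dropna(axis=0)
    n, k = complete.shape
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    ranks = complete.rank(axis=1, method="average")
    rbar = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    out: dict[tuple[str, str], dict] = {}
    cols = list(values.columns)
    for i in range(k):
        for j in range(i + 1, k):
            z = float((rbar.iloc[i] - rbar.iloc[j]) / se)
            out[(cols[i], cols[j])] = {"z": z, "p": float(2 * stats.norm.sf(abs(z)))}
    return out


def assign_tier(p: float, q: float, any_pair_significant: bool,
                q_primary: float = 0.05, q_secondary: float = 0.10,
                alpha: float = 0.05) -> str:
    """Two-tier selection rule from the omnibus p, BH q and Dunn pairs."""
    if q < q_primary:
        return "primary"
    if p < alpha and q_primary <= q < q_secondary and any_pair_significant:
        return "secondary"
    return "none"


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def subject_by_time(abund: RelativeAbundanceTable, metadata: SampleMetadata,
                    taxon: str, site: str) -> pd.DataFrame:
    """Pivot one taxon's site abundances to a subject x time matrix."""
    meta = metadata.data
    ids = [s for s in abund.sample_ids if meta.loc[s, "site"] == site]
    rows = meta.loc[ids]
    vals = abund.data.loc[taxon, ids]
    frame = pd.DataFrame({"subject": rows["subject_id"], "time": rows["time"],
                          "value": vals.to_numpy()})
    return frame.pivot(index="subject", columns="time", values="value").reindex(
        columns=list(TIMES))


def screen(abund: RelativeAbundanceTable, metadata: SampleMetadata, site: str,
           min_prevalence: float = 0.10, q_primary: float = 0.05,
           q_secondary: float = 0.10, alpha: float = 0.05) -> list[DifferentialResult]:
    """Friedman/BH/Dunn screen of all sufficiently prevalent taxa at a site."""
    meta = metadata.data
    site_ids = [s for s in abund.sample_ids if meta.loc[s, "site"] == site]
    if not site_ids:
        raise ValueError(f"no samples for site {site!r}")
    site_abund = abund.subset_samples(site_ids)
    taxa = prevalence_filter(site_abund, min_prevalence, strict=False)

    results: list[DifferentialResult] = []
    for taxon in taxa:
        mat = subject_by_time(site_abund, metadata, taxon, site)
        fr = friedman(mat)
        if fr is None:
            continue
        stat, p, n = fr
        means = {t: float(np.nanmean(mat[t])) for t in TIMES}
        results.append(DifferentialResult(taxon=taxon, site=site, statistic=stat,
                                          p=p, mean_abundance=means, n_subjects=n))
    if not results:
        return results
    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
        if r.q < q_secondary:
            mat = subject_by_time(site_abund, metadata, r.taxon, site)
            r.dunn = dunn_posthoc(mat)
        r.tier = assign_tier(r.p, r.q,
                             any(v["p"] < alpha for v in r.dunn.values()),
                             q_primary, q_secondary, alpha)
    return results


def results_table(results: list[DifferentialResult]) -> pd.DataFrame:
    """Supplementary-style output table."""
    rows = []
    for r in results:
        row = {"taxon": r.taxon, "site": r.site, "n_subjects": r.n_subjects,
               **{f"mean_{t}": r.mean_abundance.get(t, np.nan) for t in TIMES},
               "friedman_stat": r.statistic, "p": r.p, "q": r.q, "tier": r.tier}
        for (a, b), v in r.dunn.items():
            row[f"dunn_{a}_{b}_p"] = v["p"]
            row[f"dunn_{a}_{b}_stars"] = significance_stars(v["p"])
        rows.append(row)
    return pd.DataFrame(rows)
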