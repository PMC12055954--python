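"""Rarefaction and alpha-diversity indices.

Samples are subsampled without replacement to a common depth (the
smallest library size by default) before computing species richness ST,
Shannon diversity H (natural log) and Pielou's evenness J = H / ln ST.
Group differences are assessed by ordinary one-way ANOVA with
Holm-Šidák-adjusted all-pairs comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CountTable


@dataclass
class DiversityIndices:
    richness: int
    shannon: float
    evenness: float | None  # undefined for richness <= 1


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Subsample each sample without replacement to a fixed depth.

    ``depth=None`` uses the smallest library size.  Draws are
    multivariate hypergeometric, reproducible for a given seed.
    """
    sizes = table.library_sizes()
    if depth is None:
        depth = int(sizes.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    too_small = sizes[sizes < depth]
    if len(too_small):
        raise ValueError(
            f"depth {depth} exceeds library size of samples: {too_small.index.tolist()}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.data.to_numpy())
    for k, col in enumerate(table.data.columns):
        counts = table.data[col].to_numpy()
        out[:, k] = rng.multivariate_hypergeometric(counts, depth)
    return CountTable(pd.DataFrame(out, index=table.data.index,
                                   columns=table.data.columns), level=table.level)


def indices(sample_counts: np.ndarray | pd.Series) -> DiversityIndices:
    """Richness, Shannon H (nats) and Pielou's J for one sample."""
    counts = np.asarray(sample_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = counts[counts > 0] / total
    st = int(p.size)
    h = float(-(p * np.log(p)).sum())
    j = h / np.log(st) if st >= 2 else None
    return DiversityIndices(richness=st, shannon=h, evenness=j)


def diversity_table(table: CountTable) -> pd.DataFrame:
    """Per-sample indices as a tidy table."""
    rows = {}
    for sid in table.sample_ids:
        d = indices(table.data[sid])
        rows[sid] = {"richness": d.richness, "shannon": d.shannon,
                     "evenness": np.nan if d.evenness is None else d.evenness}
    return pd.DataFrame(rows).T.rename_axis("sample_id")


def anova_holm_sidak(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with Holm-Šidák all-pairs comparisons.

    Pairwise t statistics use the pooled within-group variance from the
    ANOVA (residual df), then step-down Šidák adjustment.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    f_stat, p_val = stats.f_oneway(*arrays)

    n_tot = sum(a.size for a in arrays)
    df_res = n_tot - len(arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_res

    pairs, raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t = (a.mean() - b.mean()) / se
            p = 2 * stats.t.sf(abs(t), df_res)
            pairs.append((names[i], names[j]))
            raw.append(p)
    adj = multipletests(raw, method="holm-sidak")[1] if raw else []
    return {
        "F": float(f_stat),
        "p": float(p_val),
        "pairwise": {pair: {"p_raw": float(r), "p_adj": float(a)}
                     for pair, r, a in zip(pairs, raw, adj)},
    }
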