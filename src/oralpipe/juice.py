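"""Juice-effect decision procedure.

For each taxon, square-root-transformed t0/t1 relative abundances enter
a two-way mixed repeated-measures ANOVA (time within-subject, arm
between-subject) followed by four Šidák-corrected pairwise comparisons:
t0 vs t1 within each arm and control vs juice at each time.

Verdicts:

* ``excluded_baseline`` — arms already differ at t0 (p < 0.05); the
  taxon is not further analysed.
* ``effect`` — significant time x arm interaction (p < 0.05).
* ``probable_direct`` — the juice arm changed from t0 to t1 (p < 0.05)
  while the control arm shows no difference (p > 0.1), or the arms
  differ at t1 but not at t0 with the juice arm driving the change.
* ``probable_prevented`` — the control arm changed while the juice arm
  shows no difference (a change prevented by juice), or the t1
  between-arm route with the control arm driving the change.
* ``none`` — anything else, including the ambiguous band
  0.05 <= p <= 0.1 in the "other" group (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import RelativeAbundanceTable, SampleMetadata, prevalence_filter

log = logging.getLogger(__name__)

SIDAK_FAMILY = 4
COMPARISONS = ("control_t0_t1", "juice_t0_t1", "between_t0", "between_t1")


@dataclass
class EffectClassification:
    taxon: str
    site: str
    interaction_p: float
    pairwise_p: dict[str, float] = field(default_factory=dict)  # Šidák-adjusted
    verdict: str = "none"
    anova: dict = field(default_factory=dict)


def sqrt_transform(values: np.ndarray | pd.DataFrame):
    """Element-wise square root (variance stabilisation of skewed percents)."""
    arr = np.asarray(values, dtype=float) if not isinstance(values, pd.DataFrame) else values
    if (np.asarray(arr) < 0).any():
        raise ValueError("negative abundance")
    return np.sqrt(arr) if not isinstance(values, pd.DataFrame) else values.pow(0.5)


def sidak_adjust(p: float, m: int = SIDAK_FAMILY) -> float:
    """Šidák-adjusted p = 1 - (1 - p)^m for a family of m comparisons."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return float(1.0 - (1.0 - p) ** m)


def mixed_rm_anova(values: pd.DataFrame, arm: pd.Series) -> dict:
    """Two-way mixed ANOVA: time (within, t0/t1) x arm (between).

    ``values`` is subject x {t0, t1}; ``arm`` maps subject -> arm label.
    Subjects missing a cell are dropped.  Returns F and p per term.
    """
    complete = values.dropna(axis=0)
    dropped = set(values.index) - set(complete.index)
    if dropped:
        log.info("dropped incomplete subjects: %s", sorted(dropped))
    arm = arm.loc[complete.index]
    if arm.value_counts().min() < 2 or arm.nunique() < 2:
        raise ValueError("need at least 2 subjects per arm")
    if np.ptp(complete.to_numpy()) == 0:
        raise ValueError("no variance anywhere in the data")
    idx_name = complete.index.name or "index"
    long = complete.reset_index().melt(id_vars=idx_name, var_name="time",
                                       value_name="value")
    long = long.rename(columns={idx_name: "subject"})
    long["arm"] = long["subject"].map(arm)
    import pingouin as pg

    aov = pg.mixed_anova(data=long, dv="value", within="time",
                         subject="subject", between="arm")
    out = {}
    for _, row in aov.iterrows():
        key = {"arm": "arm", "time": "time", "Interaction": "interaction"}[row["Source"]]
        out[key] = {"F": float(row["F"]), "p": float(row["p_unc"])}
    return out


def _safe_p(stat_p: float) -> float:
    return 1.0 if np.isnan(stat_p) else float(stat_p)


def pairwise_comparisons(values: pd.DataFrame, arm: pd.Series,
                         family: int = SIDAK_FAMILY) -> dict[str, float]:
    """The four pairwise tests, Šidák-adjusted.

    Within-arm t0 vs t1 use paired t; between-arm tests at each time use
    two-sample t.  All on the (already transformed) values.
    """
    complete = values.dropna(axis=0)
    arm = arm.loc[complete.index]
    arms = sorted(arm.unique())
    raw: dict[str, float] = {}
    for a in arms:
        sub = complete[arm == a]
        raw[f"{a}_t0_t1"] = _safe_p(stats.ttest_rel(sub["t0"], sub["t1"]).pvalue)
    for t in ("t0", "t1"):
        g0 = complete.loc[arm == arms[0], t]
        g1 = complete.loc[arm == arms[1], t]
        raw[f"between_{t}"] = _safe_p(stats.ttest_ind(g0, g1).pvalue)
    return {k: sidak_adjust(p, family) for k, p in raw.items()}


def classify(taxon: str, site: str, anova: dict, pairwise: dict[str, float],
             values: pd.DataFrame | None = None,
             arm: pd.Series | None = None) -> EffectClassification:
    """Apply the effect/probable/none decision rules to one taxon."""
    res = EffectClassification(taxon=taxon, site=site,
                               interaction_p=anova["interaction"]["p"],
                               pairwise_p=dict(pairwise), anova=anova)
    p_base = pairwise["between_t0"]
    p_t1 = pairwise["between_t1"]
    p_ctrl = pairwise["control_t0_t1"]
    p_juice = pairwise["juice_t0_t1"]

    if p_base < 0.05:
        res.verdict = "excluded_baseline"
        return res
    if res.interaction_p < 0.05:
        res.verdict = "effect"
        return res
    if p_juice < 0.05 and p_ctrl > 0.1:
        res.verdict = "probable_direct"
        return res
    if p_ctrl < 0.05 and p_juice > 0.1:
        res.verdict = "probable_prevented"
        return res
    if p_t1 < 0.05 and p_base > 0.1:
        # arms differ only after the intervention; attribute to whichever
        # arm moved more between t0 and t1
        direct = True
        if values is not None and arm is not None:
            complete = values.dropna(axis=0)
            a = arm.loc[complete.index]
            d_j = (complete.loc[a == "juice", "t1"] - complete.loc[a == "juice", "t0"]).mean()
            d_c = (complete.loc[a == "control", "t1"] - complete.loc[a == "control", "t0"]).mean()
            direct = abs(d_j) >= abs(d_c)
        res.verdict = "probable_direct" if direct else "probable_prevented"
        return res
    return res


def subject_matrix(abund: RelativeAbundanceTable, metadata: SampleMetadata,
                   taxon: str, site: str) -> tuple[pd.DataFrame, pd.Series]:
    """Subject x {t0, t1} abundances at a site, plus per-subject arm."""
    meta = metadata.data
    ids = [s for s in abund.sample_ids
           if meta.loc[s, "site"] == site and meta.loc[s, "time"] in ("t0", "t1")]
    rows = meta.loc[ids]
    frame = pd.DataFrame({"subject": rows["subject_id"], "time": rows["time"],
                          "value": abund.data.loc[taxon, ids].to_numpy()})
    mat = frame.pivot(index="subject", columns="time", values="value")
    arm = rows.drop_duplicates("subject_id").set_index("subject_id")["arm"]
    return mat.reindex(columns=["t0", "t1"]), arm.loc[mat.index]


def screen(abund: RelativeAbundanceTable, metadata: SampleMetadata, site: str,
           min_prevalence: float = 0.10,
           family: int = SIDAK_FAMILY) -> list[EffectClassification]:
    """Run the full juice-effect procedure for every prevalent taxon."""
    meta = metadata.data
    site_ids = [s for s in abund.sample_ids if meta.loc[s, "site"] == site]
    site_abund = abund.subset_samples(site_ids)
    taxa = prevalence_filter(site_abund, min_prevalence, strict=False)
    out: list[EffectClassification] = []
    for taxon in taxa:
        mat, arm = subject_matrix(abund, metadata, taxon, site)
        sq = mat.pow(0.5)
        try:
            aov = mixed_rm_anova(sq, arm)
        except ValueError as exc:
            log.warning("taxon %r skipped: %s", taxon, exc)
            continue
        pw = pairwise_comparisons(sq, arm, family=family)
        out.append(classify(taxon, site, aov, pw, values=sq, arm=arm))
    return out


def results_table(results: list[EffectClassification]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({"taxon": r.taxon, "site": r.site,
                     "interaction_p": r.interaction_p,
                     **{f"p_{k}": v for k, v in r.pairwise_p.items()},
                     "verdict": r.verdict})
    return pd.DataFrame(rows)
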