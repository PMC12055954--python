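"""Community structure: Bray-Curtis resemblance, nMDS ordination,
two-factor PERMANOVA with Type III (partial) sums of squares, pairwise
tests, centroid dissimilarities and multivariate dispersion.

The PERMANOVA uses the McArdle-Anderson trace formulation: with the
Gower-centred inner-product matrix ``G`` of the (squared) dissimilarities
and hat matrices built from sum-coded design matrices, the partial sum
of squares of a term is ``tr((H_full - H_without_term) G)`` and the
pseudo-F is judged against a permutation null obtained by permuting
sample labels (rows and columns of ``G`` jointly).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .tables import RelativeAbundanceTable, SampleMetadata

log = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 9999


@dataclass
class ResemblanceMatrix:
    data: pd.DataFrame  # square, symmetric, zero diagonal

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: list[str]) -> "ResemblanceMatrix":
        return ResemblanceMatrix(self.data.loc[sample_ids, sample_ids].copy())


@dataclass
class TermResult:
    ss: float
    df: int
    pseudo_f: float
    p: float


@dataclass
class PermanovaResult:
    terms: dict[str, TermResult]
    ss_residual: float
    df_residual: int
    ss_total: float
    permutations: int
    pairwise: dict = field(default_factory=dict)  # (factor, lvl_a, lvl_b) -> {"t":, "p":}


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x 2
    stress: float
    restarts: int


# ---------------------------------------------------------------------------
# Resemblance

def bray_curtis(abund: RelativeAbundanceTable) -> ResemblanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between percent-standardized samples."""
    x = abund.data.to_numpy().T  # samples as rows
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample in abundance table")
    d = squareform(pdist(x, metric="braycurtis"))
    return ResemblanceMatrix(pd.DataFrame(d, index=abund.sample_ids,
                                          columns=abund.sample_ids))


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -(1/2) J D^2 J."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


# ---------------------------------------------------------------------------
# Design matrices (sum coding -> Type III partial SS)

def _sum_code(labels: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError(f"factor has a single level: {levels}")
    cols = []
    for lv in levels[:-1]:
        col = np.where(labels == lv, 1.0, np.where(labels == levels[-1], -1.0, 0.0))
        cols.append(col)
    return np.column_stack(cols)


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _term_matrices(meta: pd.DataFrame, factors: list[str], interaction: bool):
    """Per-term projector differences M_t = H_full - H_minus_t and dfs."""
    n = len(meta)
    blocks: dict[str, np.ndarray] = {}
    for f in factors:
        blocks[f] = _sum_code(meta[f])
    if interaction and len(factors) == 2:
        a, b = factors
        inter = np.einsum("ni,nj->nij", blocks[a], blocks[b]).reshape(n, -1)
        blocks[f"{a}:{b}"] = inter
    ones = np.ones((n, 1))
    x_full = np.hstack([ones] + list(blocks.values()))
    h_full = _hat(x_full)
    rank_full = np.linalg.matrix_rank(x_full)
    terms = {}
    for name in blocks:
        others = [v for k, v in blocks.items() if k != name]
        x_red = np.hstack([ones] + others)
        h_red = _hat(x_red)
        df = rank_full - np.linalg.matrix_rank(x_red)
        terms[name] = (h_full - h_red, df)
    m_res = np.eye(n) - h_full
    df_res = n - rank_full
    return terms, m_res, df_res


# ---------------------------------------------------------------------------
# Permutation schemes

def _permutation_iter(meta: pd.DataFrame, scheme: str, permutations: int,
                      rng: np.random.Generator, exhaustive: bool):
    n = len(meta)
    if exhaustive:
        return itertools.permutations(range(n)), None
    if scheme == "free":
        return (rng.permutation(n) for _ in range(permutations)), permutations
    if scheme == "within_subject":
        groups = [np.flatnonzero((meta["subject_id"] == s).to_numpy())
                  for s in pd.unique(meta["subject_id"])]

        def gen():
            for _ in range(permutations):
                perm = np.arange(n)
                for idx in groups:
                    perm[idx] = rng.permutation(idx)
                yield perm
        return gen(), permutations
    if scheme == "between_subject":
        subjects = list(pd.unique(meta["subject_id"]))
        blocks = [np.flatnonzero((meta["subject_id"] == s).to_numpy())
                  for s in subjects]
        sizes = {len(b) for b in blocks}
        if len(sizes) != 1:
            raise ValueError("between-subject permutation needs balanced blocks")

        def gen():
            for _ in range(permutations):
                order = rng.permutation(len(blocks))
                perm = np.arange(n)
                for orig, new in zip(blocks, (blocks[k] for k in order)):
                    perm[orig] = new
                yield perm
        return gen(), permutations
    raise ValueError(f"unknown permutation scheme {scheme!r}")


# ---------------------------------------------------------------------------
# PERMANOVA

def permanova(d: ResemblanceMatrix, metadata: SampleMetadata,
              factors: list[str] = ("time", "arm"), interaction: bool = True,
              permutations: int = DEFAULT_PERMUTATIONS, seed: int = 0,
              scheme: str = "free", exhaustive: bool = False) -> PermanovaResult:
    """Two-factor (or one-factor) PERMANOVA with Type III partial SS.

    ``scheme`` selects the label-permutation null: "free" (unrestricted),
    "within_subject" (repeated-measures restriction for time effects) or
    "between_subject" (whole-subject exchange for the arm factor).
    ``exhaustive=True`` enumerates every permutation (small n only).
    """
    meta = metadata.data.loc[d.sample_ids]
    factors = [f for f in factors]
    for f in list(factors):
        if meta[f].nunique() < 2:
            log.warning("factor %r has one level; dropped", f)
            factors.remove(f)
    if not factors:
        raise ValueError("no testable factors")
    if len(factors) < 2:
        interaction = False
    dist = d.data.to_numpy()
    g = gower_center(dist)
    n = g.shape[0]
    terms, m_res, df_res = _term_matrices(meta, factors, interaction)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ss_total = float(np.trace(g))
    ss_res = float((m_res * g).sum())
    obs = {}
    for name, (m_t, df_t) in terms.items():
        ss_t = float((m_t * g).sum())
        f_t = (ss_t / df_t) / (ss_res / df_res)
        obs[name] = (ss_t, df_t, f_t)

    rng = np.random.default_rng(seed)
    perms, _ = _permutation_iter(meta, scheme, permutations, rng, exhaustive)
    exceed = {name: 0 for name in terms}
    count = 0
    for perm in perms:
        idx = np.asarray(perm)
        gp = g[np.ix_(idx, idx)]
        ss_res_p = (m_res * gp).sum()
        for name, (m_t, df_t) in terms.items():
            f_star = ((m_t * gp).sum() / df_t) / (ss_res_p / df_res)
            if f_star >= obs[name][2] - 1e-12:
                exceed[name] += 1
        count += 1

    results = {}
    for name, (ss_t, df_t, f_t) in obs.items():
        if exhaustive:
            p = exceed[name] / count
        else:
            p = (1 + exceed[name]) / (count + 1)
        results[name] = TermResult(ss=ss_t, df=df_t, pseudo_f=f_t, p=float(p))
    return PermanovaResult(terms=results, ss_residual=ss_res, df_residual=df_res,
                           ss_total=ss_total, permutations=count)


def pairwise_permanova(d: ResemblanceMatrix, metadata: SampleMetadata,
                       factor: str, pairs: list[tuple[str, str]] | None = None,
                       permutations: int = DEFAULT_PERMUTATIONS, seed: int = 0,
                       scheme: str = "free") -> dict[tuple[str, str], dict]:
    """Two-level PERMANOVA per pair of factor levels; t = sqrt(pseudo-F)."""
    meta = metadata.data.loc[d.sample_ids]
    levels = sorted(pd.unique(meta[factor]))
    if pairs is None:
        pairs = list(itertools.combinations(levels, 2))
    out: dict[tuple[str, str], dict] = {}
    for a, b in pairs:
        ids = list(meta.index[meta[factor].isin([a, b])])
        counts = meta.loc[ids, factor].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            log.warning("pair (%s, %s) degenerate; skipped", a, b)
            continue
        sub_meta = SampleMetadata(metadata.data.loc[ids].copy())
        res = permanova(d.subset(ids), sub_meta, factors=[factor],
                        interaction=False, permutations=permutations,
                        seed=seed, scheme=scheme)
        term = res.terms[factor]
        out[(a, b)] = {"t": float(np.sqrt(term.pseudo_f)), "p": term.p,
                       "pseudo_f": term.pseudo_f}
    return out


# ---------------------------------------------------------------------------
# Centroids and dispersion (principal-coordinate space, negative
# eigenvalues kept through the Gower matrix / signed axes)

def centroid_dissimilarity(d: ResemblanceMatrix, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Percent dissimilarity between group centroids.

    Centroid distances are computed directly from the Gower-centred
    matrix, which is equivalent to embedding with real and imaginary
    principal-coordinate axes and so matches centroids computed from
    the full (possibly non-Euclidean) Bray-Curtis matrix.
    """
    ids = d.sample_ids
    pos = {s: k for k, s in enumerate(ids)}
    g = gower_center(d.data.to_numpy())
    names = list(groups)
    out = pd.DataFrame(0.0, index=names, columns=names)
    idx = {name: np.array([pos[s] for s in groups[name]]) for name in names}
    for a, b in itertools.combinations(names, 2):
        ia, ib = idx[a], idx[b]
        sq = (g[np.ix_(ia, ia)].mean() + g[np.ix_(ib, ib)].mean()
              - 2 * g[np.ix_(ia, ib)].mean())
        dist = float(np.sqrt(max(sq, 0.0))) * 100.0
        out.loc[a, b] = out.loc[b, a] = dist
    return out


def _signed_coordinates(d: np.ndarray, tol: float = 1e-10):
    g = gower_center(d)
    w, v = np.linalg.eigh((g + g.T) / 2)
    scale = max(abs(w).max(), 1.0)
    pos = w > tol * scale
    neg = w < -tol * scale
    xp = v[:, pos] * np.sqrt(w[pos])
    xn = v[:, neg] * np.sqrt(-w[neg])
    return xp, xn


def dispersion(d: ResemblanceMatrix, groups: dict[str, list[str]],
               permutations: int = 999, seed: int = 0) -> dict:
    """PERMDISP-style homogeneity of multivariate dispersion.

    Per-group mean distance to the group centroid in signed
    principal-coordinate space; the homogeneity p-value permutes group
    labels and recomputes the one-way F on the distances.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ids = d.sample_ids
    pos_of = {s: k for k, s in enumerate(ids)}
    dist = d.data.to_numpy()
    xp, xn = _signed_coordinates(dist)

    labels = np.empty(len(ids), dtype=object)
    for name, members in groups.items():
        if len(members) == 1:
            log.warning("group %r is a singleton; dispersion 0", name)
        for s in members:
            labels[pos_of[s]] = name
    mask = labels != None  # noqa: E711 - samples outside any group excluded
    xp, xn, labels = xp[mask], xn[mask], labels[mask]

    def group_distances(lab):
        z = np.empty(len(lab))
        for name in np.unique(lab):
            sel = lab == name
            cp = xp[sel].mean(axis=0)
            cn = xn[sel].mean(axis=0) if xn.size else None
            sq = ((xp[sel] - cp) ** 2).sum(axis=1)
            if xn.size:
                sq = sq - ((xn[sel] - cn) ** 2).sum(axis=1)
            z[sel] = np.sqrt(np.clip(sq, 0.0, None))
        return z

    def anova_f(z, lab):
        grand = z.mean()
        ss_b = ss_w = 0.0
        k = 0
        for name in np.unique(lab):
            sel = lab == name
            k += 1
            ss_b += sel.sum() * (z[sel].mean() - grand) ** 2
            ss_w += ((z[sel] - z[sel].mean()) ** 2).sum()
        df1, df2 = k - 1, len(z) - k
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df1) / (ss_w / df2)

    z_obs = group_distances(labels)
    f_obs = anova_f(z_obs, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        lab_p = labels[rng.permutation(len(labels))]
        z_p = group_distances(lab_p)
        if anova_f(z_p, lab_p) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (permutations + 1)
    means = {name: float(z_obs[labels == name].mean()) for name in groups}
    return {"mean_distance": means, "F": float(f_obs), "p": float(p)}


# ---------------------------------------------------------------------------
# Ordination

def nmds(d: ResemblanceMatrix, restarts: int = 50, seed: int = 0,
         n_components: int = 2) -> OrdinationResult:
    """Non-metric MDS (Kruskal stress-1) keeping the best of random restarts."""
    if len(d.sample_ids) < 4:
        raise ValueError("need at least 4 samples for nMDS")
    model = MDS(n_components=n_components, metric=False, n_init=restarts,
                dissimilarity="precomputed", random_state=seed,
                normalized_stress=True)
    coords = model.fit_transform(d.data.to_numpy())
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.sample_ids,
                                 columns=[f"MDS{i + 1}" for i in range(n_components)]),
        stress=float(model.stress_), restarts=restarts)
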