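"""Community structure: Bray-Curtis, PERMANOVA against exhaustive
enumeration and an independent group-SS oracle, centroid dissimilarity,
dispersion, and nMDS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oralpipe import structure
from oralpipe.structure import (ResemblanceMatrix, bray_curtis,
                                centroid_dissimilarity, dispersion,
                                gower_center, nmds, pairwise_permanova,
                                permanova)
from oralpipe.tables import RelativeAbundanceTable, SampleMetadata


def _rel(mat, samples):
    df = pd.DataFrame(mat, columns=samples, dtype=float)
    return RelativeAbundanceTable(df.div(df.sum(axis=0), axis=1) * 100)


def _meta(samples, arms, subjects=None, times=None):
    return SampleMetadata(pd.DataFrame({
        "subject_id": subjects or [f"P{i}" for i in range(len(samples))],
        "site": "SA",
        "time": times or "t0",
        "arm": arms,
    }, index=samples))


def oracle_oneway(dist: np.ndarray, labels: np.ndarray):
    """Anderson's direct group-SS formulation, independent of the
    hat-matrix trace route."""
    n = len(labels)
    d2 = dist ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
    k = len(np.unique(labels))
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestBrayCurtis:
    def test_identical_zero(self):
        rel = _rel([[50, 50], [50, 50]], ["a", "b"])
        assert bray_curtis(rel).data.loc["a", "b"] == 0.0

    def test_disjoint_one(self):
        rel = _rel([[100, 0], [0, 100]], ["a", "b"])
        assert bray_curtis(rel).data.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_formula(self):
        rel = _rel([[50, 25], [50, 25], [0, 50]], ["x", "y"])
        assert bray_curtis(rel).data.loc["x", "y"] == pytest.approx(0.5)

    def test_symmetric_bounded(self, rng):
        rel = _rel(rng.random((6, 8)) + 0.01, [f"s{i}" for i in range(8)])
        d = bray_curtis(rel).data.to_numpy()
        assert np.allclose(d, d.T) and (d >= 0).all() and (d <= 1).all()


class TestPermanova:
    def _random_case(self, seed, n_per=3):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(2 * n_per)]
        rel = _rel(rng.random((10, 2 * n_per)) + 0.05, samples)
        arms = ["control"] * n_per + ["juice"] * n_per
        return bray_curtis(rel), _meta(samples, arms), np.array(arms)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_equals_bruteforce_oracle(self, seed):
        d, meta, labels = self._random_case(seed)
        res = permanova(d, meta, factors=["arm"], interaction=False,
                        exhaustive=True)
        f_oracle = oracle_oneway(d.data.to_numpy(), labels)
        assert res.terms["arm"].pseudo_f == pytest.approx(f_oracle)
        # exact p: proportion of the 720 relabellings with F* >= F
        dist = d.data.to_numpy()
        f_stars = []
        for perm in itertools.permutations(range(6)):
            f_stars.append(oracle_oneway(dist[np.ix_(perm, perm)], labels))
        p_exact = np.mean(np.array(f_stars) >= f_oracle - 1e-12)
        assert res.terms["arm"].p == pytest.approx(p_exact)

    def test_montecarlo_converges_to_exact(self):
        d, meta, labels = self._random_case(5)
        exact = permanova(d, meta, factors=["arm"], interaction=False,
                          exhaustive=True).terms["arm"].p
        mc = permanova(d, meta, factors=["arm"], interaction=False,
                       permutations=4999, seed=0).terms["arm"].p
        assert abs(mc - exact) < 0.03

    def test_skbio_oneway_crosscheck(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d, meta, labels = self._random_case(7, n_per=4)
        res = permanova(d, meta, factors=["arm"], interaction=False,
                        permutations=99, seed=0)
        dm = skbio_stats.DistanceMatrix(d.data.to_numpy(), ids=d.sample_ids)
        ref = skbio_stats.permanova(dm, grouping=list(labels), permutations=99)
        assert res.terms["arm"].pseudo_f == pytest.approx(ref["test statistic"])

    def test_balanced_type3_decomposition_closes(self, rng):
        # 2x3 balanced crossed design, 4 replicates per cell
        samples, arms, times, subjects = [], [], [], []
        k = 0
        for arm in ("control", "juice"):
            for t in ("t0", "t1", "t2"):
                for r in range(4):
                    samples.append(f"s{k}")
                    arms.append(arm)
                    times.append(t)
                    subjects.append(f"P{k}")
                    k += 1
        rel = _rel(rng.random((12, len(samples))) + 0.05, samples)
        d = bray_curtis(rel)
        meta = _meta(samples, arms, subjects=subjects, times=times)
        res = permanova(d, meta, factors=["time", "arm"], permutations=99, seed=0)
        total = sum(t.ss for t in res.terms.values()) + res.ss_residual
        assert total == pytest.approx(res.ss_total, abs=1e-8)

    def test_pairwise_t_is_sqrt_f(self):
        d, meta, labels = self._random_case(3, n_per=4)
        res = permanova(d, meta, factors=["arm"], interaction=False,
                        permutations=99, seed=0)
        pw = pairwise_permanova(d, meta, "arm", permutations=99, seed=0)
        t = pw[("control", "juice")]["t"]
        assert t ** 2 == pytest.approx(res.terms["arm"].pseudo_f)

    def test_separated_clouds_detected(self, rng):
        samples = [f"s{i}" for i in range(12)]
        base = rng.random((10, 12)) + 0.05
        base[:3, 6:] *= 6.0  # planted shift for the second group
        rel = _rel(base, samples)
        meta = _meta(samples, ["control"] * 6 + ["juice"] * 6)
        pw = pairwise_permanova(bray_curtis(rel), meta, "arm",
                                permutations=999, seed=0)
        assert pw[("control", "juice")]["p"] <= 0.05

    def test_single_level_factor_dropped(self):
        d, meta, _ = self._random_case(0)
        with pytest.raises(ValueError):
            permanova(d, _meta(d.sample_ids, ["control"] * 6),
                      factors=["arm"], interaction=False, permutations=99)


class TestCentroids:
    def test_identical_groups_zero(self):
        rel = _rel([[50, 50, 50, 50], [50, 50, 50, 50]], list("abcd"))
        d = bray_curtis(rel)
        cd = centroid_dissimilarity(d, {"g1": ["a", "b"], "g2": ["c", "d"]})
        assert cd.loc["g1", "g2"] == pytest.approx(0.0, abs=1e-9)

    def test_singletons_reduce_to_pairwise(self, rng):
        rel = _rel(rng.random((8, 4)) + 0.05, list("abcd"))
        d = bray_curtis(rel)
        cd = centroid_dissimilarity(d, {"g1": ["a"], "g2": ["b"]})
        assert cd.loc["g1", "g2"] == pytest.approx(100 * d.data.loc["a", "b"])

    def test_gower_identity(self, rng):
        """||x_i - x_j||^2 in Gower space reproduces d^2."""
        rel = _rel(rng.random((6, 5)) + 0.05, list("abcde"))
        d = bray_curtis(rel).data.to_numpy()
        g = gower_center(d)
        for i, j in itertools.combinations(range(5), 2):
            assert g[i, i] + g[j, j] - 2 * g[i, j] == pytest.approx(d[i, j] ** 2)


class TestDispersion:
    def test_nonnegative_and_scaling_monotone(self, rng):
        x = rng.normal(0, 1, (8, 4))
        tight = np.vstack([x, x * 0.3 + 5])
        samples = [f"s{i}" for i in range(16)]
        df = pd.DataFrame(np.abs(tight).T + 0.05, columns=samples)
        rel = RelativeAbundanceTable(df.div(df.sum(axis=0), axis=1) * 100)
        d = bray_curtis(rel)
        groups = {"wide": samples[:8], "tight": samples[8:]}
        res = dispersion(d, groups, permutations=99, seed=0)
        assert all(v >= 0 for v in res["mean_distance"].values())
        assert res["mean_distance"]["wide"] > res["mean_distance"]["tight"]

    def test_requires_two_groups(self, rng):
        rel = _rel(rng.random((5, 4)) + 0.05, list("abcd"))
        with pytest.raises(ValueError):
            dispersion(bray_curtis(rel), {"g": list("abcd")})


class TestNmds:
    def test_collinear_embeds_with_low_stress(self):
        # 4 points on a line with additive distances
        coords = np.array([0.0, 1.0, 2.0, 3.0])
        d = np.abs(coords[:, None] - coords[None, :]) / 3.0
        dm = ResemblanceMatrix(pd.DataFrame(d, index=list("abcd"),
                                            columns=list("abcd")))
        res = nmds(dm, restarts=8, seed=0)
        assert res.stress < 0.05

    def test_duplicate_samples_coincide(self, rng):
        mat = rng.random((6, 5)) + 0.05
        mat[:, 4] = mat[:, 3]  # duplicate pair
        rel = _rel(mat, list("abcde"))
        res = nmds(bray_curtis(rel), restarts=8, seed=0)
        xy = res.coordinates.to_numpy()
        dup = np.linalg.norm(xy[4] - xy[3])
        spread = max(np.linalg.norm(xy[i] - xy[j])
                     for i, j in itertools.combinations(range(5), 2))
        assert dup < 0.1 * spread

    def test_best_of_restarts_not_worse(self, rng):
        rel = _rel(rng.random((8, 7)) + 0.05, [f"s{i}" for i in range(7)])
        d = bray_curtis(rel)
        single = nmds(d, restarts=1, seed=0).stress
        best = nmds(d, restarts=10, seed=0).stress
        assert best <= single + 1e-12
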