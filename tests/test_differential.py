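"""Friedman screening: statistic against a hand-coded rank oracle,
BH adjustment, Dunn's within-block post-hoc (normal approximation vs a
within-subject permutation oracle), and the two-tier selection rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oralpipe import differential
from oralpipe.differential import (assign_tier, bh_adjust, dunn_posthoc,
                                   friedman, screen)
from oralpipe.tables import RelativeAbundanceTable, SampleMetadata


def oracle_friedman_stat(values: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square computed directly from ranks."""
    n, k = values.shape
    ranks = np.array([stats.rankdata(row) for row in values])
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (rj ** 2).sum() - 3 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts ** 3 - counts).sum()
    c = 1 - ties / (n * k * (k ** 2 - 1))
    return stat / c


def oracle_dunn_z(values: np.ndarray, i: int, j: int) -> float:
    n, k = values.shape
    ranks = np.array([stats.rankdata(row) for row in values])
    rbar = ranks.mean(axis=0)
    return (rbar[i] - rbar[j]) / np.sqrt(k * (k + 1) / (6.0 * n))


def _frame(arr):
    return pd.DataFrame(np.asarray(arr, dtype=float),
                        columns=["t0", "t1", "t2"])


class TestFriedman:
    def test_perfect_concordance_statistic(self):
        # every subject ordered t0 < t1 < t2: statistic = 2n = 20
        vals = _frame([[1, 2, 3]] * 10) + np.arange(10)[:, None]
        stat, p, n = friedman(vals)
        assert stat == pytest.approx(20.0)
        assert p < 0.01 and n == 10

    def test_constant_subjects_zero_statistic(self):
        stat, p, _ = friedman(_frame([[5, 5, 5]] * 6))
        assert stat == 0.0 and p == 1.0

    def test_incomplete_subjects_dropped(self):
        vals = _frame([[1, 2, 3], [2, 3, 4], [np.nan, 1, 2]])
        assert friedman(vals)[2] == 2

    def test_fewer_than_two_complete_skips(self):
        vals = _frame([[1, 2, 3], [np.nan, 1, 2]])
        assert friedman(vals) is None

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_statistic_matches_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((4, 3)) * 10
        stat, _, _ = friedman(_frame(vals))
        assert stat == pytest.approx(oracle_friedman_stat(vals))

    def test_null_distribution_by_enumeration(self):
        """At n=4 the within-subject permutation null from full
        enumeration (6^4 orderings) matches the statistic's exact
        exceedance probability computed from the implementation."""
        rng = np.random.default_rng(11)
        vals = rng.random((4, 3)) * 10
        stat_obs, _, _ = friedman(_frame(vals))
        perms = list(itertools.permutations(range(3)))
        exceed = total = 0
        for combo in itertools.product(range(6), repeat=4):
            permuted = np.array([vals[r][list(perms[c])]
                                 for r, c in enumerate(combo)])
            s = oracle_friedman_stat(permuted)
            total += 1
            if s >= stat_obs - 1e-12:
                exceed += 1
        p_exact = exceed / total
        # the chi-square p is an approximation of this exact tail
        _, p_chi2, _ = friedman(_frame(vals))
        assert abs(p_chi2 - p_exact) < 0.12


class TestBH:
    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_q_at_least_p_and_order_preserved(self, rng):
        p = np.sort(rng.random(20))
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (np.diff(q) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDunn:
    def test_identical_profiles_zero(self):
        z = dunn_posthoc(_frame([[1, 2, 3], [2, 3, 4]] * 3))
        # identical ordering in all subjects: t0 vs t1 z is nonzero, but
        # equal rank profiles across a pair means symmetric z values
        vals = _frame([[5, 5, 5]] * 4)
        z0 = dunn_posthoc(vals)
        for v in z0.values():
            assert v["z"] == pytest.approx(0.0)

    def test_antisymmetry(self, rng):
        vals = _frame(rng.random((6, 3)))
        res = dunn_posthoc(vals)
        rev = dunn_posthoc(vals[["t1", "t0", "t2"]].rename(
            columns={"t1": "t0", "t0": "t1"}))
        assert res[("t0", "t1")]["z"] == pytest.approx(-rev[("t0", "t1")]["z"])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_z_matches_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((4, 3)) * 10
        res = dunn_posthoc(_frame(vals))
        assert res[("t0", "t1")]["z"] == pytest.approx(oracle_dunn_z(vals, 0, 1))
        assert res[("t0", "t2")]["z"] == pytest.approx(oracle_dunn_z(vals, 0, 2))

    def test_normal_approx_close_to_permutation(self):
        """Two-sided normal p vs a within-subject permutation null at n=6."""
        rng = np.random.default_rng(5)
        # a shift large enough to put z in the decision-relevant tail,
        # where the approximation must hold
        vals = rng.random((6, 3)) + np.array([0.0, 0.6, 0.1])
        res = dunn_posthoc(_frame(vals))
        z_obs = abs(res[("t0", "t1")]["z"])
        perms = list(itertools.permutations(range(3)))
        count = 0
        reps = 3000
        for _ in range(reps):
            permuted = np.array([row[list(perms[rng.integers(6)])]
                                 for row in vals])
            z = abs(oracle_dunn_z(permuted, 0, 1))
            if z >= z_obs - 1e-12:
                count += 1
        p_perm = count / reps
        assert abs(res[("t0", "t1")]["p"] - p_perm) < 0.05


class TestTierRule:
    @pytest.mark.parametrize("p,q,pair,expected", [
        (0.001, 0.04, False, "primary"),
        (0.03, 0.07, True, "secondary"),
        (0.03, 0.07, False, "none"),
        (0.2, 0.5, True, "none"),
        (0.03, 0.12, True, "none"),
    ])
    def test_rules(self, p, q, pair, expected):
        assert assign_tier(p, q, pair) == expected


class TestScreen:
    def test_recovers_planted_time_effects(self, default_sim, species_rel):
        _, meta, _, truth = default_sim
        rel, _ = species_rel
        hits = planted = 0
        for site in ("SU", "SA", "TO"):
            res = screen(rel, meta, site)
            primary = {r.taxon for r in res if r.tier == "primary"}
            planted += len(truth.time_taxa[site])
            hits += len(primary & set(truth.time_taxa[site]))
        assert hits / planted >= 0.7

    def test_output_table_columns(self, default_sim, species_rel):
        _, meta, _, _ = default_sim
        rel, _ = species_rel
        res = screen(rel, meta, "TO")
        frame = differential.results_table(res)
        for col in ("taxon", "mean_t0", "p", "q", "tier"):
            assert col in frame.columns
        assert (frame["q"] >= frame["p"] - 1e-12).all()
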