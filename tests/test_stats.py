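"""Statistics tests: exact rank-sum behaviour, group GE comparison,
severity classing, and the GE–FMA Pearson correlation."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from tvconn.containers import CohortRecord, EfficiencySeries
from tvconn.stats import (classify_severity, compare_ge, correlate_ge_fma,
                          edgewise_ranksum, ranksum)


def exact_ranksum_p(x, y):
    """Exhaustive two-sided rank-sum p: enumerate all rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    m = len(x)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    mu = m * len(y) / 2
    count = 0
    for idx in combinations(range(len(pooled)), m):
        u = ranks[list(idx)].sum() - m * (m + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / comb(len(pooled), m)


class TestRanksum:
    def test_separated_triplets_exact_p(self):
        _, p = ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("m,n", [(2, 2), (3, 3), (3, 4), (4, 4)])
    def test_matches_exhaustive_enumeration(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        for _ in range(10):
            x = rng.standard_normal(m)
            y = rng.standard_normal(n) + rng.uniform(-1, 1)
            _, p = ranksum(x, y)
            assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_identical_constant_samples_give_p_one(self):
        stat, p = ranksum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0


class TestEdgewiseRanksum:
    @staticmethod
    def _mats(rng, n_subj, n=3, shift=0.0, edge=None):
        mats = []
        for _ in range(n_subj):
            m = rng.uniform(0, 1, (n, n))
            np.fill_diagonal(m, 0)
            if edge is not None:
                m[edge] += shift
            mats.append(m)
        return mats

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        g = self._mats(rng, 4)
        ec = edgewise_ranksum(g, [m.copy() for m in g])
        assert np.all(ec.sign == 0)
        assert not ec.significant.any()

    def test_planted_group_difference_detected(self):
        # one edge shifted by ~3 SD in group A, 9 vs 7 subjects
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = self._mats(rng, 9, shift=0.9, edge=(1, 0))
            b = self._mats(rng, 7)
            ec = edgewise_ranksum(a, b, alpha=0.05)
            hits += bool(ec.significant[1, 0] and ec.sign[1, 0] == 1)
        assert hits >= 45

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            edgewise_ranksum(self._mats(rng, 1), self._mats(rng, 4))

    def test_bh_correction_never_adds_discoveries(self):
        rng = np.random.default_rng(2)
        a = self._mats(rng, 5, shift=0.5, edge=(0, 2))
        b = self._mats(rng, 5)
        raw = edgewise_ranksum(a, b, correct=False)
        adj = edgewise_ranksum(a, b, correct=True)
        assert adj.significant.sum() <= raw.significant.sum()


def series(vals, subject, condition="left"):
    vals = np.asarray(vals, dtype=float)
    return EfficiencySeries(times=np.arange(vals.size, dtype=float), ge=vals,
                            subject=subject, condition=condition)


class TestCompareGe:
    def test_identical_groups(self):
        a = [series([0.4] * 5, f"A{i}") for i in range(3)]
        b = [series([0.4] * 5, f"B{i}") for i in range(3)]
        _, p, direction = compare_ge(a, b, window=(0, 4))
        assert p == 1.0 and direction == 0

    def test_swapping_groups_flips_direction(self):
        rng = np.random.default_rng(3)
        a = [series(0.6 + 0.01 * rng.standard_normal(5), f"A{i}") for i in range(4)]
        b = [series(0.4 + 0.01 * rng.standard_normal(5), f"B{i}") for i in range(4)]
        s1, p1, d1 = compare_ge(a, b, window=(0, 4))
        s2, p2, d2 = compare_ge(b, a, window=(0, 4))
        assert d1 == 1 and d2 == -1
        assert p1 == pytest.approx(p2)

    def test_planted_gap_power(self):
        # HC-like vs RS-like: group-level GE gap ~2 SD, 9 vs 5 subjects
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            hc = [series(0.64 + 0.02 * rng.standard_normal(10), f"H{i}")
                  for i in range(9)]
            rs = [series(0.60 + 0.02 * rng.standard_normal(10), f"R{i}")
                  for i in range(5)]
            _, p, d = compare_ge(hc, rs, window=(0, 9))
            hits += bool(p < 0.05 and d == 1)
        assert hits >= 40

    def test_conditions_collapse_to_one_value_per_subject(self):
        a = [series([0.5] * 4, "A1", "left"), series([0.7] * 4, "A1", "right"),
             series([0.6] * 4, "A2", "left")]
        b = [series([0.1] * 4, "B1"), series([0.2] * 4, "B2")]
        stat, _, _ = compare_ge(a, b, window=(0, 3))
        # 2 subjects vs 2 subjects, all A above all B: U = 4
        assert stat == 4.0


class TestSeverity:
    @pytest.mark.parametrize("fma,expected", [
        (15, "severe"), (35, "moderate"), (55, "mild"),
        (0, "severe"), (20, "moderate"), (40, "mild"), (60, "mild"),
    ])
    def test_class_boundaries(self, fma, expected):
        assert classify_severity(fma) == expected

    @pytest.mark.parametrize("fma", [-1, 61])
    def test_out_of_range_rejected(self, fma):
        with pytest.raises(ValueError):
            classify_severity(fma)


class TestCorrelateGeFma:
    @staticmethod
    def _records(fmas, ges):
        recs = []
        for i, (f, g) in enumerate(zip(fmas, ges)):
            r = CohortRecord(subject=f"P{i}", group="LS", fma=float(f))
            r.ge_series = [series([g] * 4, f"P{i}")]
            recs.append(r)
        return recs

    def test_exact_linear_relationship(self):
        fmas = [10, 20, 30, 40, 50]
        recs = self._records(fmas, [0.1 + 0.01 * f for f in fmas])
        r, _ = correlate_ge_fma(recs, window=(0, 3))
        assert r == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # x=(1,2,3), y=(6,4,5): covariance -0.5, SDs 1 and 1 -> r = -0.5
        # (y rescaled into the efficiency range; Pearson r is scale-free)
        recs = self._records([1, 2, 3], [0.6, 0.4, 0.5])
        r, _ = correlate_ge_fma(recs, window=(0, 3))
        assert r == pytest.approx(-0.5)

    def test_zero_variance_rejected(self):
        recs = self._records([10, 20, 30], [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="zero variance"):
            correlate_ge_fma(recs, window=(0, 3))

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(4)
        fmas = rng.uniform(5, 55, 8)
        ges = rng.uniform(0.2, 0.8, 8)
        r1, _ = correlate_ge_fma(self._records(fmas, ges), window=(0, 3))
        r2, _ = correlate_ge_fma(self._records(fmas, 0.05 + 0.5 * ges), window=(0, 3))
        r3, _ = correlate_ge_fma(self._records(fmas, -ges + 1.0), window=(0, 3))
        assert r2 == pytest.approx(r1)
        assert r3 == pytest.approx(-r1)

    def test_healthy_controls_excluded(self):
        recs = self._records([10, 30, 50], [0.3, 0.4, 0.5])
        hc = CohortRecord(subject="H1", group="HC")
        r, _ = correlate_ge_fma(recs + [hc], window=(0, 3))
        assert r == pytest.approx(1.0)
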