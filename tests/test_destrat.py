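import itertools

import numpy as np
import pytest
from scipy import stats

from todrhythm.datatypes import ExpressionMatrix, SubjectRecord, ValidationError
from todrhythm.destrat import (
    bic_select,
    de_stratum,
    overlap_fisher,
    split_day_night,
    storey_pi0,
    storey_q,
    variance_explained,
)
from todrhythm.rhythm import bh_fdr


def _subjects(zts, diagnoses=None):
    out = []
    for i, z in enumerate(zts):
        d = (diagnoses[i] if diagnoses else "control")
        out.append(SubjectRecord(f"s{i}", d, zt=float(z)))
    return out


class TestSplitDayNight:
    def test_label_rule(self):
        day, night = split_day_night(_subjects([3, 13, -2, 11]))
        assert [s.zt for s in day] == [3, 11]
        assert [s.zt for s in night] == [13, -2]

    def test_missing_zt_named(self):
        subs = _subjects([3.0])
        subs.append(SubjectRecord("missing", "control", zt=5.0))
        subs[1].zt = None
        with pytest.raises(ValidationError, match="missing"):
            split_day_night(subs)

    def test_agrees_with_day_night_label(self):
        from todrhythm.zeitgeber import day_night_label
        zts = np.linspace(-6, 17.9, 50)
        day, night = split_day_night(_subjects(zts))
        for s in day:
            assert day_night_label(s.zt) == "day"
        for s in night:
            assert day_night_label(s.zt) == "night"


class TestBICSelect:
    def _pool(self, rng, n):
        return {name: rng.normal(size=n) for name in ("age", "ph", "pmi", "rin")}

    def test_matches_independent_enumeration(self, rng):
        # independent oracle: re-enumerate all <=2-subsets with statsmodels-free OLS
        n = 40
        for _ in range(10):
            diag = rng.integers(0, 2, size=n).astype(float)
            pool = self._pool(rng, n)
            y = rng.normal(size=n) + 0.5 * diag + 0.8 * pool["age"]
            got = bic_select(y, diag, pool, max_k=2)

            best = (np.inf, None)
            names = sorted(pool)
            for k in range(3):
                for S in itertools.combinations(names, k):
                    X = np.column_stack([np.ones(n), diag] + [pool[c] for c in S])
                    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                    rss = ((y - X @ beta) ** 2).sum()
                    bic = n * np.log(rss / n) + X.shape[1] * np.log(n)
                    if bic < best[0]:
                        best = (bic, S)
            assert got["covariates"] == best[1]
            assert got["bic"] == pytest.approx(best[0])

    def test_noise_covariates_rarely_selected(self):
        chosen_null = 0
        n_genes = 100
        rng = np.random.default_rng(77)
        n = 60
        diag = np.repeat([0.0, 1.0], 30)
        pool = self._pool(rng, n)
        for _ in range(n_genes):
            y = rng.normal(size=n)
            if bic_select(y, diag, pool, max_k=2)["covariates"] == ():
                chosen_null += 1
        assert chosen_null >= 0.7 * n_genes

    def test_strong_confounder_selected(self):
        rng = np.random.default_rng(78)
        n = 60
        diag = np.repeat([0.0, 1.0], 30)
        pool = self._pool(rng, n)
        hits = 0
        n_genes = 100
        for _ in range(n_genes):
            y = rng.normal(size=n) + 2.0 * pool["ph"]
            if "ph" in bic_select(y, diag, pool, max_k=2)["covariates"]:
                hits += 1
        assert hits >= 0.95 * n_genes


class TestVarianceExplained:
    def test_pure_diagnosis_signal(self):
        diag = np.repeat([0.0, 1.0], 10)
        out = variance_explained(diag.copy(), diag, {})
        assert out["diagnosis"] == pytest.approx(1.0)

    def test_null_fractions_small(self, rng):
        diag = np.repeat([0.0, 1.0], 30)
        covs = {"age": rng.normal(size=60)}
        for _ in range(20):
            out = variance_explained(rng.normal(size=60), diag, covs)
            assert all(v < 0.1 for v in out.values())

    def test_fractions_bounded(self, rng):
        diag = (rng.random(30) < 0.5).astype(float)
        for _ in range(20):
            covs = {"a": rng.normal(size=30), "b": rng.normal(size=30)}
            out = variance_explained(rng.normal(size=30), diag, covs)
            assert all(v >= 0 for v in out.values())
            assert sum(out.values()) <= 1 + 1e-10

    def test_zero_variance_input(self):
        out = variance_explained(np.full(20, 2.0), np.repeat([0.0, 1.0], 10), {})
        assert out["diagnosis"] == 0.0


class TestStorey:
    def test_pi0_near_one_under_uniform(self, rng):
        p = rng.uniform(size=2000)
        assert 0.9 <= storey_pi0(p) <= 1.0

    def test_strong_signal_small_q(self, rng):
        p = rng.uniform(1e-8, 1e-6, size=100)
        assert np.all(storey_q(p) <= 1e-4)

    def test_q_below_bh_when_pi0_small(self, rng):
        p = np.concatenate([rng.uniform(1e-6, 1e-3, size=500),
                            rng.uniform(size=100)])
        pi0 = storey_pi0(p)
        assert pi0 < 1
        np.testing.assert_array_less(storey_q(p), bh_fdr(p) + 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            storey_q([0.0, 0.5])

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        q = storey_q(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _de_cohort(rng, n_per_group=12, n_genes=30, effect=0.0, noise_sd=1.0):
    subs = []
    for i in range(2 * n_per_group):
        d = "case" if i >= n_per_group else "control"
        subs.append(SubjectRecord(
            f"s{i}", d, zt=float(rng.uniform(0, 12)),
            age=float(rng.uniform(30, 60)), sex="M" if i % 2 else "F",
            pmi=float(rng.uniform(5, 30)), rin=float(rng.uniform(6, 9)),
            ph=float(rng.uniform(6.2, 7.0)), medication_flag=bool(i % 3 == 0)))
    diag = np.array([1.0 if s.diagnosis == "case" else 0.0 for s in subs])
    values = rng.normal(5, noise_sd, size=(n_genes, len(subs)))
    values[0] += effect * diag
    expr = ExpressionMatrix(values=values,
                            gene_ids=[f"g{i}" for i in range(n_genes)],
                            subject_ids=[s.subject_id for s in subs],
                            scale_tag="log2cpm")
    return expr, subs


class TestDEStratum:
    def test_deterministic(self, rng):
        expr, subs = _de_cohort(rng)
        a = de_stratum(expr, subs, n_perm=100, seed=5)
        b = de_stratum(expr, subs, n_perm=100, seed=5)
        np.testing.assert_array_equal(a.corrected_p, b.corrected_p)
        np.testing.assert_array_equal(a.storey_q, b.storey_q)

    def test_true_effect_detected(self):
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(200 + rep)
            expr, subs = _de_cohort(rng, n_per_group=16, n_genes=30, effect=1.0,
                                    noise_sd=0.5)
            res = de_stratum(expr, subs, n_perm=200, seed=rep)
            hits += res.corrected_p[0] < 0.05
        assert hits >= 0.9 * n_rep

    def test_corrected_p_uniform_under_null(self):
        rng = np.random.default_rng(42)
        expr, subs = _de_cohort(rng, n_per_group=15, n_genes=200, effect=0.0)
        res = de_stratum(expr, subs, n_perm=200, seed=0)
        assert stats.kstest(res.corrected_p, "uniform").pvalue > 0.01

    def test_small_group_rejected(self, rng):
        expr, subs = _de_cohort(rng, n_per_group=12)
        only_ctrl = [s for s in subs if s.diagnosis == "control"] + \
            [s for s in subs if s.diagnosis == "case"][:2]
        with pytest.raises(ValidationError):
            de_stratum(expr.subset_subjects([s.subject_id for s in only_ctrl]),
                       only_ctrl, n_perm=100)

    def test_max_covariates_respected(self, rng):
        expr, subs = _de_cohort(rng)
        res = de_stratum(expr, subs, n_perm=100, seed=1, max_k=2)
        assert all(len(c) <= 2 for c in res.selected_covariates)


class TestOverlapFisher:
    def test_perfect_association(self):
        universe = {f"g{i}" for i in range(40)}
        half = {f"g{i}" for i in range(20)}
        odds, p = overlap_fisher(half, half, universe)
        assert np.isinf(odds) and p < 1e-9

    def test_independence_table(self):
        universe = {f"g{i}" for i in range(40)}
        day = {f"g{i}" for i in range(20)}
        night = {f"g{i}" for i in range(10, 30)}
        odds, p = overlap_fisher(day, night, universe)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        # table {{3,1},{1,3}}: enumerate all tables with the same margins
        universe = {f"g{i}" for i in range(8)}
        day = {"g0", "g1", "g2", "g3"}
        night = {"g0", "g1", "g2", "g4"}
        _, p = overlap_fisher(day, night, universe)
        import math
        probs = []
        for a in range(0, 5):
            b, c = 4 - a, 4 - a
            d = a  # margins force d = a given 4/4/8
            if b < 0 or d < 0:
                continue
            probs.append((a, math.comb(4, a) * math.comb(4, b) / math.comb(8, 4)))
        p_obs = dict(probs)[3]
        expect = sum(pr for _, pr in probs if pr <= p_obs + 1e-12)
        assert p == pytest.approx(expect)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            overlap_fisher(set(), set(), set())
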