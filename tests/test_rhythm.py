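import numpy as np
import pytest

from conftest import sinusoid
from todrhythm.datatypes import OMEGA, ExpressionMatrix, NullDistribution, ValidationError
from todrhythm.rhythm import (
    bh_fdr,
    build_null,
    circular_hour_diff,
    compare_params,
    delta_r2_test,
    empirical_p,
    fit_sinusoid,
    fit_sinusoid_matrix,
    rhythmicity_analysis,
)


def _expr(values):
    g, s = np.asarray(values).shape
    return ExpressionMatrix(values=np.asarray(values, float),
                            gene_ids=[f"g{i}" for i in range(g)],
                            subject_ids=[f"s{j}" for j in range(s)],
                            scale_tag="log2cpm")


class TestFitSinusoid:
    def test_exact_noiseless_recovery(self):
        t = np.linspace(0, 23, 24)
        f = fit_sinusoid(t, sinusoid(t, 2.0, 0.0, 5.0))
        assert f.amplitude == pytest.approx(2.0, abs=1e-6)
        assert min(f.phase, 2 * np.pi - f.phase) == pytest.approx(0.0, abs=1e-6)
        assert f.offset == pytest.approx(5.0, abs=1e-6)
        assert f.r2 == pytest.approx(1.0, abs=1e-6)
        assert f.peak_hour == pytest.approx(6.0, abs=1e-6)

    def test_constant_expression_flat_fit(self):
        t = np.linspace(-6, 17, 24)
        f = fit_sinusoid(t, np.full(24, 3.0))
        assert f.amplitude == pytest.approx(0.0, abs=1e-9)
        assert f.offset == pytest.approx(3.0)
        assert f.r2 == 0.0

    def test_peak_hour_formula(self):
        t = np.linspace(0, 23, 24)
        assert fit_sinusoid(t, sinusoid(t, 1, 0.0, 0)).peak_hour == \
            pytest.approx(6.0, abs=1e-9)
        assert fit_sinusoid(t, sinusoid(t, 1, np.pi / 2, 0)).peak_hour == \
            pytest.approx(0.0, abs=1e-9)

    def test_lm_engine_agrees_with_linear(self, rng):
        # f fixed makes the problem linear in disguise; engines must agree
        for _ in range(20):
            t = rng.uniform(-6, 18, size=30)
            y = sinusoid(t, rng.uniform(0.2, 3), rng.uniform(0, 2 * np.pi),
                         rng.uniform(2, 10)) + rng.normal(0, 1, size=30)
            lin = fit_sinusoid(t, y, engine="linear")
            lm = fit_sinusoid(t, y, engine="lm")
            assert lm.rss_model == pytest.approx(lin.rss_model, abs=1e-6)

    def test_grid_search_oracle(self, rng):
        # dense grid over phase with per-phase linear solve for (A, b)
        t = rng.uniform(-6, 18, size=40)
        y = sinusoid(t, 1.0, 1.3, 6.0) + rng.normal(0, 1, size=40)
        fit = fit_sinusoid(t, y)
        best = (np.inf, None)
        for p in np.linspace(0, 2 * np.pi, 40000, endpoint=False):
            X = np.column_stack([np.sin(OMEGA * t + p), np.ones_like(t)])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ coef) ** 2).sum())
            if rss < best[0]:
                best = (rss, (abs(coef[0]), p if coef[0] >= 0 else (p + np.pi) % (2 * np.pi), coef[1]))
        rss_grid, (A_g, p_g, b_g) = best
        assert fit.rss_model <= rss_grid + 1e-9
        assert fit.amplitude == pytest.approx(A_g, abs=1e-3)
        assert fit.offset == pytest.approx(b_g, abs=1e-3)

    def test_r2_affine_invariant(self, rng):
        t = rng.uniform(-6, 18, size=30)
        y = sinusoid(t, 1.5, 0.4, 5.0) + rng.normal(0, 0.7, size=30)
        r2 = fit_sinusoid(t, y).r2
        assert fit_sinusoid(t, 3.2 * y - 7.0).r2 == pytest.approx(r2, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_sinusoid([0, 1, 2, 3, 4], [1, 2, 3, 4, 5])

    def test_degenerate_zt_rejected(self):
        with pytest.raises(ValidationError):
            fit_sinusoid(np.full(10, 2.0), np.arange(10.0))


class TestNullAndP:
    def test_null_size_contract(self, noise_matrix, uniform_zt):
        null = build_null(noise_matrix, uniform_zt, n_shuffles=10, seed=1)
        assert null.values.size == 10 * noise_matrix.n_genes
        assert null.per_shuffle.shape == (10, noise_matrix.n_genes)

    def test_null_deterministic(self, noise_matrix, uniform_zt):
        a = build_null(noise_matrix, uniform_zt, 5, seed=42)
        b = build_null(noise_matrix, uniform_zt, 5, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empirical_p_counting(self):
        null = NullDistribution(values=np.linspace(0, 0.5, 999),
                                per_shuffle=np.zeros((1, 999)),
                                n_shuffles=1, seed=0)
        assert empirical_p(0.9, null)[0] == pytest.approx(1 / 1000)
        assert empirical_p(0.0, null)[0] == pytest.approx(1.0)

    def test_empirical_p_hand_null(self):
        null = NullDistribution(values=np.array([0.1, 0.2, 0.3, 0.4]),
                                per_shuffle=np.zeros((1, 4)),
                                n_shuffles=1, seed=0)
        # (1 + #{null >= 0.25}) / (1 + 4) = 3/5
        assert empirical_p(0.25, null)[0] == pytest.approx(0.6)

    def test_pvalues_uniform_under_null(self, rng):
        zt = rng.uniform(-6, 18, size=40)
        Y = rng.normal(0, 1, size=(400, 40))
        expr = _expr(Y)
        res = rhythmicity_analysis(expr, zt, n_shuffles=100, seed=0)
        from scipy.stats import kstest
        assert kstest(res.empirical_p, "uniform").pvalue > 0.01


class TestBH:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_q_dominates_p(self, rng):
        p = rng.uniform(0.001, 1, size=50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)


class TestDeltaR2:
    def test_identical_cohorts_all_unchanged(self, rng):
        zt = rng.uniform(-6, 18, size=30)
        Y = rng.normal(0, 1, size=(40, 30))
        expr = _expr(Y)
        a = rhythmicity_analysis(expr, zt, 50, seed=1, cohort="case")
        b = rhythmicity_analysis(expr, zt, 50, seed=1, cohort="control")
        res = delta_r2_test(a, b, alpha=0.05)
        np.testing.assert_allclose(res.delta_r2, 0.0, atol=1e-12)
        assert set(res.classification) == {"unchanged"}

    def test_case_only_rhythm_called_gain(self, rng):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(100 + rep)
            zt_case = r.uniform(-6, 18, size=46)
            zt_ctrl = r.uniform(-6, 18, size=46)
            Yc = np.vstack([sinusoid(zt_case, 1.5, 0.7, 5) + r.normal(0, 1, 46),
                            r.normal(5, 1, size=(20, 46))])
            Yt = r.normal(5, 1, size=(21, 46))
            a = rhythmicity_analysis(_expr(Yc), zt_case, 100, seed=rep)
            b = rhythmicity_analysis(_expr(Yt), zt_ctrl, 100, seed=rep + 999)
            res = delta_r2_test(a, b, alpha=0.05)
            hits += res.classification[0] == "gain"
        assert hits >= 0.9 * n_rep

    def test_null_gene_rarely_called(self, rng):
        calls = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(500 + rep)
            zt = r.uniform(-6, 18, size=46)
            a = rhythmicity_analysis(_expr(r.normal(5, 1, (20, 46))), zt, 100, seed=rep)
            b = rhythmicity_analysis(_expr(r.normal(5, 1, (20, 46))), zt, 100, seed=rep + 1)
            res = delta_r2_test(a, b, alpha=0.05)
            calls += res.classification[0] != "unchanged"
        assert calls <= 0.1 * n_rep + 1

    def test_mismatched_universe_rejected(self, rng):
        zt = rng.uniform(-6, 18, size=30)
        a = rhythmicity_analysis(_expr(rng.normal(size=(5, 30))), zt, 5, seed=0)
        b = rhythmicity_analysis(_expr(rng.normal(size=(6, 30))), zt, 5, seed=0)
        with pytest.raises(ValidationError):
            delta_r2_test(a, b)


class TestCompareParams:
    def test_wrap_rule(self):
        assert circular_hour_diff(1.0, 23.0) == pytest.approx(2.0)
        assert circular_hour_diff(23.0, 1.0) == pytest.approx(-2.0)
        assert circular_hour_diff(0.0, 12.0) == pytest.approx(12.0)

    def test_identical_cohorts_zero_differences(self, rng):
        zt = rng.uniform(-6, 18, size=30)
        Y = sinusoid(zt, 2.0, 0.5, 5.0) + rng.normal(0, 0.3, size=(3, 30))
        ec, et = _expr(Y), _expr(Y)
        a = rhythmicity_analysis(ec, zt, 50, seed=3)
        b = rhythmicity_analysis(et, zt, 50, seed=4)
        out = compare_params(ec.gene_ids, ec, zt, et, zt, a, b,
                             n_perms=20, seed=0)
        np.testing.assert_allclose(out["amplitude_diff"], 0, atol=1e-12)
        np.testing.assert_allclose(out["phase_diff"], 0, atol=1e-12)

    def test_amplitude_difference_power(self):
        detected = 0
        n_rep = 25
        for rep in range(n_rep):
            r = np.random.default_rng(900 + rep)
            zt_c = r.uniform(-6, 18, 46)
            zt_t = r.uniform(-6, 18, 46)
            Yc = (sinusoid(zt_c, 2.0, 0.5, 5) + r.normal(0, 0.5, 46))[None, :]
            Yt = (sinusoid(zt_t, 1.0, 0.5, 5) + r.normal(0, 0.5, 46))[None, :]
            ec, et = _expr(Yc), _expr(Yt)
            a = rhythmicity_analysis(ec, zt_c, 100, seed=rep)
            b = rhythmicity_analysis(et, zt_t, 100, seed=rep + 1)
            out = compare_params(["g0"], ec, zt_c, et, zt_t, a, b,
                                 alpha=0.05, n_perms=100, seed=rep)
            if out["gene_ids"] and out["p_amplitude"][0] < 0.05:
                detected += 1
        assert detected >= 0.8 * n_rep

    def test_nonrhythmic_gene_excluded(self, rng):
        zt = rng.uniform(-6, 18, size=30)
        Y = rng.normal(5, 1, size=(2, 30))
        e = _expr(Y)
        a = rhythmicity_analysis(e, zt, 50, seed=0)
        b = rhythmicity_analysis(e, zt, 50, seed=1)
        out = compare_params(e.gene_ids, e, zt, e, zt, a, b, alpha=1e-6,
                             n_perms=10, seed=0)
        assert out["gene_ids"] == [] and set(out["excluded"]) == {"g0", "g1"}
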