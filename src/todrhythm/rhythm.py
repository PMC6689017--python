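"""Per-gene sinusoidal rhythmicity analysis on the zeitgeber time scale.

Each gene's expression y is regressed on time of death t with the fixed
24-h sinusoid

    y = A sin(f t + p) + b,   f = pi/12 rad/h,

and rhythmicity is scored by R^2 = 1 - RSS_m / RSS_0 against the
intercept-only model. Because f is fixed, the fit is linear in disguise:
y = c1 sin(ft) + c2 cos(ft) + b with A = sqrt(c1^2 + c2^2),
p = atan2(c2, c1). The exact least-squares solution of that
reparameterisation is the default engine; a Levenberg-Marquardt
multi-start path on the (A, p, b) parameterisation is available via
``engine="lm"`` and must agree to within 1e-6 in RSS.

Significance comes from an empirical null: the zeitgeber times are
shuffled (one permutation per shuffle, shared by all genes, preserving
gene-gene correlation), every gene is refit, and the resulting R^2 values
are pooled across genes and shuffles. Gain/loss of rhythmicity between
two cohorts is tested with the difference statistic dR2 = R2_case -
R2_ctrl against a paired null built from the two cohorts' shuffles.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    OMEGA,
    DeltaR2Result,
    ExpressionMatrix,
    NullDistribution,
    RhythmicityResult,
    RunConfig,
    SinusoidFit,
    ValidationError,
)

logger = logging.getLogger(__name__)

MIN_SUBJECTS = 6


def _design(zt: np.ndarray) -> np.ndarray:
    wt = OMEGA * zt
    return np.column_stack([np.sin(wt), np.cos(wt), np.ones_like(zt)])


def fit_sinusoid_matrix(zt: np.ndarray, Y: np.ndarray):
    """Exact least-squares sinusoid fits for all rows of a genes x subjects block.

    Returns (amplitude, phase, offset, rss_m, rss_0, r2) arrays. ``phase``
    is canonicalised into [0, 2*pi) with amplitude >= 0.
    """
    zt = np.asarray(zt, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if zt.size < MIN_SUBJECTS:
        raise ValidationError(f"need >= {MIN_SUBJECTS} subjects, got {zt.size}")
    if np.ptp(zt) == 0:
        raise ValidationError("zeitgeber times are all identical")
    if np.ptp(zt) < 4.0:
        logger.warning("zeitgeber span < 4 h; rhythm R^2 is unreliable")
    X = _design(zt)
    coef, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ coef
    rss_m = (resid**2).sum(axis=0)
    rss_0 = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    c1, c2, b = coef
    amplitude = np.hypot(c1, c2)
    phase = np.mod(np.arctan2(c2, c1), 2 * np.pi)
    phase = np.where(phase >= 2 * np.pi, 0.0, phase)  # float mod can hit 2*pi
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(rss_0 > 0, 1.0 - rss_m / rss_0, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    return amplitude, phase, b, rss_m, rss_0, r2


def fit_sinusoid(zt: Sequence[float], expr: Sequence[float],
                 engine: str = "linear") -> SinusoidFit:
    """Fit y = A sin(ft + p) + b to one gene; see module docstring for engines."""
    zt = np.asarray(zt, dtype=float)
    y = np.asarray(expr, dtype=float)
    if engine == "linear":
        A, p, b, rss_m, rss_0, _ = fit_sinusoid_matrix(zt, y[None, :])
        return SinusoidFit(float(A[0]), float(p[0]), float(b[0]),
                           float(rss_m[0]), float(rss_0[0]))
    if engine != "lm":
        raise ValidationError(f"unknown engine {engine!r}")
    if zt.size < MIN_SUBJECTS:
        raise ValidationError(f"need >= {MIN_SUBJECTS} subjects, got {zt.size}")
    rss_0 = float(((y - y.mean()) ** 2).sum())
    best = None
    a0 = max(float(y.std(ddof=0)) * np.sqrt(2.0), 1e-6)
    for p0 in np.arange(8) * (np.pi / 4):  # 8 phase multi-starts
        sol = least_squares(
            lambda th: th[0] * np.sin(OMEGA * zt + th[1]) + th[2] - y,
            x0=[a0, p0, float(y.mean())], method="lm", xtol=1e-12, ftol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    A, p, b = best.x
    if A < 0:  # canonicalise: A >= 0, p in [0, 2*pi)
        A, p = -A, p + np.pi
    p = float(np.mod(p, 2 * np.pi))
    if p >= 2 * np.pi:
        p = 0.0
    rss_m = float(2.0 * best.cost)
    return SinusoidFit(float(abs(A)), p, float(b), rss_m, rss_0)


def build_null(expr: ExpressionMatrix, zt: np.ndarray, n_shuffles: int,
               seed: int) -> NullDistribution:
    """Pooled null R^2 from TOD-shuffled refits.

    One zt permutation per shuffle, applied to every gene, so the null
    preserves the gene-gene correlation structure; all R^2 values are
    pooled over genes and shuffles.
    """
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    zt = np.asarray(zt, dtype=float)
    rng = np.random.default_rng(seed)
    per_shuffle = np.empty((n_shuffles, expr.n_genes))
    for k in range(n_shuffles):
        perm = rng.permutation(zt.size)
        *_, r2 = fit_sinusoid_matrix(zt[perm], expr.values)
        per_shuffle[k] = r2
    return NullDistribution(values=per_shuffle.ravel(),
                            per_shuffle=per_shuffle,
                            n_shuffles=n_shuffles, seed=seed)


def empirical_p(r2_obs, null: NullDistribution) -> np.ndarray:
    """Add-one empirical p: (1 + #{null >= obs}) / (1 + |null|)."""
    if null.values.size == 0:
        raise ValidationError("empty null distribution")
    sorted_null = np.sort(null.values)
    obs = np.atleast_1d(np.asarray(r2_obs, dtype=float))
    n_ge = sorted_null.size - np.searchsorted(sorted_null, obs, side="left")
    return (1.0 + n_ge) / (1.0 + sorted_null.size)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


def rhythmicity_analysis(expr: ExpressionMatrix, zt: np.ndarray,
                         n_shuffles: int = 1000, seed: int = 0,
                         cohort: str = "") -> RhythmicityResult:
    """Fit every gene, build the pooled shuffled null, and score rhythmicity."""
    zt = np.asarray(zt, dtype=float)
    A, p, b, rss_m, rss_0, r2 = fit_sinusoid_matrix(zt, expr.values)
    fits = [SinusoidFit(float(A[g]), float(p[g]), float(b[g]),
                        float(rss_m[g]), float(rss_0[g]))
            for g in range(expr.n_genes)]
    null = build_null(expr, zt, n_shuffles, seed)
    pvals = empirical_p(r2, null)
    return RhythmicityResult(
        gene_ids=list(expr.gene_ids), fits=fits, empirical_p=pvals,
        bh_fdr=bh_fdr(pvals), cohort=cohort, null=null,
    )


def delta_r2_test(result_case: RhythmicityResult, result_ctrl: RhythmicityResult,
                  alpha: float = 0.05) -> DeltaR2Result:
    """Gain/loss-of-rhythmicity calls from the paired shuffled null.

    dR2 = R2_case - R2_ctrl per gene. The null pairs shuffle k of the case
    cohort with shuffle k of the control cohort per gene and pools the
    differences; p is two-sided by add-one counting of |null| >= |observed|.
    A gene is a *loss* when it is rhythmic in controls (empirical p <
    alpha), dR2 < 0 and the dR2 test is significant; a *gain* when rhythmic
    in cases with a significant positive dR2.
    """
    if result_case.gene_ids != result_ctrl.gene_ids:
        raise ValidationError("gene universes differ between cohorts")
    if result_case.null is None or result_ctrl.null is None:
        raise ValidationError("both results must carry their null distributions")
    n_sh = min(result_case.null.n_shuffles, result_ctrl.null.n_shuffles)
    null_delta = (result_case.null.per_shuffle[:n_sh]
                  - result_ctrl.null.per_shuffle[:n_sh]).ravel()
    delta = result_case.r2 - result_ctrl.r2
    sorted_abs = np.sort(np.abs(null_delta))
    n_ge = sorted_abs.size - np.searchsorted(sorted_abs, np.abs(delta), side="left")
    p_delta = (1.0 + n_ge) / (1.0 + sorted_abs.size)
    classification = []
    for g in range(len(delta)):
        sig = p_delta[g] < alpha
        if sig and delta[g] > 0 and result_case.empirical_p[g] < alpha:
            classification.append("gain")
        elif sig and delta[g] < 0 and result_ctrl.empirical_p[g] < alpha:
            classification.append("loss")
        else:
            classification.append("unchanged")
    return DeltaR2Result(gene_ids=list(result_case.gene_ids), delta_r2=delta,
                         p_delta=p_delta, classification=classification)


def circular_hour_diff(peak_a, peak_b) -> np.ndarray:
    """Circular difference of peak hours, in (-12, 12]."""
    d = np.mod(np.asarray(peak_a, dtype=float) - np.asarray(peak_b, dtype=float), 24.0)
    return np.where(d > 12.0, d - 24.0, d)


def compare_params(gene_ids: Sequence[str],
                   expr_case: ExpressionMatrix, zt_case: np.ndarray,
                   expr_ctrl: ExpressionMatrix, zt_ctrl: np.ndarray,
                   result_case: RhythmicityResult, result_ctrl: RhythmicityResult,
                   alpha: float = 0.05, n_perms: int = 1000, seed: int = 0):
    """Phase/amplitude/base differences for genes rhythmic in BOTH cohorts.

    Genes not rhythmic (empirical p < alpha) in both cohorts are excluded
    (reported in the ``excluded`` list). Permutation p-values come from
    refitting both groups under diagnosis-label shuffles.

    Returns a dict with per-gene observed differences and permutation p's.
    """
    idx_by_id = {g: i for i, g in enumerate(result_case.gene_ids)}
    kept, excluded = [], []
    for g in gene_ids:
        i = idx_by_id[g]
        if result_case.empirical_p[i] < alpha and result_ctrl.empirical_p[i] < alpha:
            kept.append(g)
        else:
            excluded.append(g)
    if not kept:
        return {"gene_ids": [], "excluded": excluded}
    gi_case = [expr_case.gene_ids.index(g) for g in kept]
    gi_ctrl = [expr_ctrl.gene_ids.index(g) for g in kept]
    Yc = expr_case.values[gi_case]
    Yt = expr_ctrl.values[gi_ctrl]
    zt_case = np.asarray(zt_case, dtype=float)
    zt_ctrl = np.asarray(zt_ctrl, dtype=float)

    def diffs(Ya, za, Yb, zb):
        Aa, pa, ba, *_ = fit_sinusoid_matrix(za, Ya)
        Ab, pb, bb, *_ = fit_sinusoid_matrix(zb, Yb)
        peak_a = np.mod((np.pi / 2 - pa) / OMEGA, 24.0)
        peak_b = np.mod((np.pi / 2 - pb) / OMEGA, 24.0)
        return (Aa - Ab, ba - bb, circular_hour_diff(peak_a, peak_b))

    amp_obs, base_obs, phase_obs = diffs(Yc, zt_case, Yt, zt_ctrl)

    Y = np.hstack([Yc, Yt])
    zt = np.concatenate([zt_case, zt_ctrl])
    n_case = zt_case.size
    rng = np.random.default_rng(seed)
    counts = {k: np.zeros(len(kept)) for k in ("amp", "base", "phase")}
    for _ in range(n_perms):
        perm = rng.permutation(zt.size)
        ia, ib = perm[:n_case], perm[n_case:]
        amp_d, base_d, phase_d = diffs(Y[:, ia], zt[ia], Y[:, ib], zt[ib])
        counts["amp"] += np.abs(amp_d) >= np.abs(amp_obs)
        counts["base"] += np.abs(base_d) >= np.abs(base_obs)
        counts["phase"] += np.abs(phase_d) >= np.abs(phase_obs)
    pvals = {k: (1.0 + c) / (1.0 + n_perms) for k, c in counts.items()}
    return {
        "gene_ids": kept,
        "excluded": excluded,
        "amplitude_diff": amp_obs,
        "base_diff": base_obs,
        "phase_diff": phase_obs,
        "p_amplitude": pvals["amp"],
        "p_base": pvals["base"],
        "p_phase": pvals["phase"],
    }
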