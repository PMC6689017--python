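"""Day/night-stratified differential expression with per-gene model selection.

The matched cohort is split by death time into a day stratum (ZT 0-12) and
a night stratum (ZT 12-24). Within a stratum, each gene gets its own linear
model: the diagnosis term is always included and at most ``max_k``
covariates (from a configurable pool: PMI, RIN, sex, medication, age, pH)
are chosen by exhaustive BIC minimisation. Because per-gene model selection
biases the parametric diagnosis p-value, an empirical corrected p is
obtained by re-running the full procedure (selection + fit, by default) on
diagnosis-label permutations; multiple testing is handled with Storey
q-values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SubjectRecord, ValidationError
from .rhythm import bh_fdr
from .zeitgeber import day_night_label

logger = logging.getLogger(__name__)

DEFAULT_COVARIATE_POOL = ("pmi", "rin", "sex", "medication_flag", "age", "ph")


@dataclass
class DEResult:
    """Per-gene stratified differential-expression statistics."""

    gene_ids: list[str]
    effect_size: np.ndarray  # diagnosis coefficient, log2 scale (case - control)
    selected_covariates: list[tuple[str, ...]]
    raw_p: np.ndarray  # parametric p from the selected model
    corrected_p: np.ndarray  # permutation-corrected empirical p
    storey_q: np.ndarray
    variance_explained: list[dict[str, float]]
    stratum: str = ""


def split_day_night(subjects: Sequence[SubjectRecord]):
    """Partition subjects into (day, night) by their ZT label."""
    missing = [s.subject_id for s in subjects if s.zt is None]
    if missing:
        raise ValidationError(f"subjects lacking zt: {missing}")
    day = [s for s in subjects if day_night_label(s.zt) == "day"]
    night = [s for s in subjects if day_night_label(s.zt) == "night"]
    return day, night


def _covariate_matrix(subjects: Sequence[SubjectRecord],
                      pool: Sequence[str]) -> dict[str, np.ndarray]:
    """Numeric covariate columns; covariates with any missing value are dropped."""
    out = {}
    for name in pool:
        vals = []
        ok = True
        for s in subjects:
            v = getattr(s, name)
            if v is None:
                ok = False
                break
            if name == "sex":
                v = 1.0 if str(v).upper().startswith("M") else 0.0
            vals.append(float(v))
        if ok:
            col = np.array(vals)
            if np.ptp(col) == 0:
                logger.warning("covariate %s is constant in stratum; dropped", name)
                continue
            out[name] = col
        else:
            logger.warning("covariate %s has missing values; dropped from pool", name)
    return out


def _candidate_subsets(names: Sequence[str], max_k: int):
    """All covariate subsets of size <= max_k, ordered by size then name."""
    names = sorted(names)
    subsets: list[tuple[str, ...]] = []
    for k in range(0, max_k + 1):
        subsets.extend(itertools.combinations(names, k))
    return subsets


def _fit_all_subsets(Y: np.ndarray, diagnosis: np.ndarray,
                     covs: dict[str, np.ndarray],
                     subsets: Sequence[tuple[str, ...]]):
    """BIC, diagnosis coefficient and parametric p for every subset x gene.

    ``Y`` is genes x subjects. Returns (bic, beta, pval) each of shape
    (n_subsets, n_genes); rank-deficient designs get +inf BIC.
    """
    n = diagnosis.size
    G = Y.shape[0]
    bic = np.full((len(subsets), G), np.inf)
    beta = np.zeros((len(subsets), G))
    pval = np.ones((len(subsets), G))
    Yt = Y.T
    for si, S in enumerate(subsets):
        X = np.column_stack([np.ones(n), diagnosis] + [covs[c] for c in S])
        k = X.shape[1]
        if np.linalg.matrix_rank(X) < k:
            logger.warning("rank-deficient design for covariates %s; skipped", S)
            continue
        coef, _, _, _ = np.linalg.lstsq(X, Yt, rcond=None)
        resid = Yt - X @ coef
        rss = np.maximum((resid**2).sum(axis=0), 1e-300)
        bic[si] = n * np.log(rss / n) + k * np.log(n)
        beta[si] = coef[1]
        if n > k:
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(rss / (n - k) * xtx_inv[1, 1])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, coef[1] / se, 0.0)
            pval[si] = 2.0 * stats.t.sf(np.abs(t), df=n - k)
    return bic, beta, pval


def bic_select(y: np.ndarray, diagnosis: np.ndarray,
               covariate_pool: dict[str, np.ndarray],
               max_k: int = 2):
    """Minimum-BIC model for one gene.

    Exhaustive over all covariate subsets of size <= max_k with diagnosis
    always included; BIC = n ln(RSS/n) + k ln(n) with k counting intercept,
    diagnosis and covariates. Ties go to fewer covariates, then
    lexicographic order (guaranteed by subset enumeration order and strict
    improvement).
    """
    subsets = _candidate_subsets(covariate_pool.keys(), max_k)
    bic, beta, pval = _fit_all_subsets(np.atleast_2d(np.asarray(y, float)),
                                       np.asarray(diagnosis, float),
                                       covariate_pool, subsets)
    si = int(np.argmin(bic[:, 0]))  # argmin returns the first minimum
    return {
        "covariates": subsets[si],
        "bic": float(bic[si, 0]),
        "effect": float(beta[si, 0]),
        "p": float(pval[si, 0]),
    }


def variance_explained(y: np.ndarray, diagnosis: np.ndarray,
                       covariates: dict[str, np.ndarray]) -> dict[str, float]:
    """Sequential (type-I) variance fractions, diagnosis entered last.

    Each term's incremental sum of squares over the preceding model is
    divided by the total sum of squares of y.
    """
    y = np.asarray(y, float)
    n = y.size
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        return {name: 0.0 for name in list(covariates) + ["diagnosis"]}
    X = np.ones((n, 1))
    rss_prev = tss
    out = {}
    terms = [(name, covariates[name]) for name in covariates]
    terms.append(("diagnosis", np.asarray(diagnosis, float)))
    for name, col in terms:
        X = np.column_stack([X, col])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ coef) ** 2).sum())
        out[name] = max(0.0, (rss_prev - rss) / tss)
        rss_prev = rss
    return out


def storey_pi0(pvals: np.ndarray,
               lambda_grid: Optional[np.ndarray] = None,
               seed: int = 0) -> float:
    """Estimate the null proportion pi0 from a p-value histogram.

    Uses a cubic smoother of pi0(lambda) evaluated at the largest lambda;
    for fewer than 50 p-values falls back to Storey's bootstrap lambda
    choice. The estimate is clamped into (0, 1].
    """
    p = np.asarray(pvals, float)
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lam = np.asarray(lambda_grid, float)
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if m >= 50:
        coefs = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coefs, lam.max()))
    else:
        rng = np.random.default_rng(seed)
        min_pi0 = pi0_lam.min()
        mse = np.zeros(lam.size)
        for _ in range(100):
            pb = rng.choice(p, size=m, replace=True)
            pi0_b = np.array([(pb > l).sum() / (m * (1.0 - l)) for l in lam])
            mse += (pi0_b - min_pi0) ** 2
        pi0 = float(pi0_lam[np.argmin(mse)])
    return min(max(pi0, 1.0 / m), 1.0)


def storey_q(pvals, lambda_grid: Optional[np.ndarray] = None,
             seed: int = 0) -> np.ndarray:
    """Storey q-values: pi0-scaled BH step-up with monotonicity."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    pi0 = storey_pi0(p, lambda_grid, seed=seed)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def de_stratum(expr: ExpressionMatrix, subjects: Sequence[SubjectRecord],
               covariate_pool: Sequence[str] = DEFAULT_COVARIATE_POOL,
               n_perm: int = 1000, seed: int = 0, max_k: int = 2,
               reselect: bool = True, stratum: str = "") -> DEResult:
    """Differential expression for one death-time stratum.

    For every gene: BIC covariate selection, diagnosis-effect fit, and a
    corrected empirical p from ``n_perm`` diagnosis-label permutations
    (re-running selection inside each permutation when ``reselect``,
    the conservative default). Storey q-values are computed over the
    corrected p's.
    """
    ids = [s.subject_id for s in subjects]
    sub = expr.subset_subjects(ids)
    groups = {s.diagnosis for s in subjects}
    for g in ("control", "case"):
        if sum(1 for s in subjects if s.diagnosis == g) < 3:
            raise ValidationError(f"stratum has fewer than 3 {g} subjects")
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: permutation p resolution is coarse", n_perm)
    diagnosis = np.array([1.0 if s.diagnosis == "case" else 0.0 for s in subjects])
    covs = _covariate_matrix(subjects, covariate_pool)
    # a covariate with no variation inside one diagnosis group is a relabelled
    # subset indicator of the other group: not estimable separately from the
    # diagnosis effect, and it breaks label-permutation exchangeability
    for name in list(covs):
        col = covs[name]
        if np.ptp(col[diagnosis == 1]) == 0 or np.ptp(col[diagnosis == 0]) == 0:
            logger.warning("covariate %s constant within a diagnosis group; "
                           "dropped (confounded with diagnosis)", name)
            del covs[name]
    subsets = _candidate_subsets(covs.keys(), max_k)
    Y = sub.values

    bic, beta, pval = _fit_all_subsets(Y, diagnosis, covs, subsets)
    sel = np.argmin(bic, axis=0)
    gidx = np.arange(Y.shape[0])
    obs_p = pval[sel, gidx]
    obs_beta = beta[sel, gidx]
    selected = [subsets[s] for s in sel]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(Y.shape[0])
    for _ in range(n_perm):
        dperm = diagnosis[rng.permutation(diagnosis.size)]
        if reselect:
            bic_p, _, pval_p = _fit_all_subsets(Y, dperm, covs, subsets)
            perm_p = pval_p[np.argmin(bic_p, axis=0), gidx]
        else:
            _, _, pval_p = _fit_all_subsets(Y, dperm, covs, subsets)
            perm_p = pval_p[sel, gidx]
        exceed += perm_p <= obs_p
    corrected = (1.0 + exceed) / (1.0 + n_perm)
    qvals = storey_q(corrected, seed=seed)

    varfrac = [
        variance_explained(Y[g], diagnosis, {c: covs[c] for c in selected[g]})
        for g in range(Y.shape[0])
    ]
    return DEResult(
        gene_ids=list(sub.gene_ids), effect_size=obs_beta,
        selected_covariates=selected, raw_p=obs_p, corrected_p=corrected,
        storey_q=qvals, variance_explained=varfrac, stratum=stratum,
    )


def overlap_fisher(set_day: set[str], set_night: set[str],
                   universe: set[str]):
    """Two-sided Fisher exact test of day/night DE-list overlap.

    Returns (odds_ratio, p); the odds ratio is the sample OR with the
    infinity convention for zero cells.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    if not (set_day <= universe and set_night <= universe):
        raise ValidationError("sets must be subsets of the universe")
    a = len(set_day & set_night)
    b = len(set_day - set_night)
    c = len(set_night - set_day)
    d = len(universe - set_day - set_night)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def de_table(result: DEResult) -> pd.DataFrame:
    rows = []
    for i, g in enumerate(result.gene_ids):
        rows.append({
            "gene_id": g,
            "effect_log2": result.effect_size[i],
            "fold_change": 2.0 ** result.effect_size[i],
            "covariates": ",".join(result.selected_covariates[i]) or ".",
            "raw_p": result.raw_p[i],
            "corrected_p": result.corrected_p[i],
            "storey_q": result.storey_q[i],
        })
    return pd.DataFrame(rows)
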