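"""Gene filtering, log2 CPM transform, batch adjustment, cohort matching.

Filtering keeps a gene when its counts-per-million exceed a threshold in at
least a given fraction of subjects, the gene is not on the Y chromosome, and
it carries an identifier. Site (brain-bank) effects are removed with a
parametric empirical-Bayes location-scale adjustment: per-gene per-site mean
and variance effects are estimated on standardized data, shrunk toward
across-gene priors, and removed, with the per-gene grand mean preserved.
Case/control cohorts are matched one-to-one by minimum-cost assignment
(exact match on sex and collection site; standardized distances on age,
circular time-of-death, PMI and pH; 0/1 race distance).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import (
    ExpressionMatrix,
    FilterReport,
    SubjectRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


def filter_genes(expr: ExpressionMatrix, cpm_threshold: float = 1.0,
                 cpm_fraction: float = 0.5,
                 pseudocount: float = 0.5) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply the CPM / Y-chromosome / annotation filter and log2-transform.

    Retains gene g iff cpm_gs > ``cpm_threshold`` (strict) in at least
    ``cpm_fraction`` of subjects, chromosome != "Y", and the gene has an
    identifier (non-empty symbol when symbols are provided). Returns the
    retained genes as log2(cpm + pseudocount) plus a :class:`FilterReport`.
    """
    if expr.scale_tag != "counts":
        raise ValidationError("filter_genes expects a counts-scale matrix")
    lib = expr.values.sum(axis=0)
    zero = np.flatnonzero(lib <= 0)
    if zero.size:
        raise ValidationError(
            f"zero library size for subjects {[expr.subject_ids[i] for i in zero]}"
        )
    cpm = expr.values / lib * 1e6
    pass_cpm = (cpm > cpm_threshold).mean(axis=1) >= cpm_fraction

    chrom = expr.gene_chromosome or ["" for _ in expr.gene_ids]
    is_y = np.array([str(c).strip().upper() == "Y" for c in chrom])
    if expr.gene_symbols is not None:
        unannot = np.array(
            [s is None or str(s).strip() in ("", "NA") for s in expr.gene_symbols]
        )
    else:
        unannot = np.zeros(expr.n_genes, dtype=bool)

    n_after_cpm = int(pass_cpm.sum())
    y_dropped = int((pass_cpm & is_y).sum())
    unannot_dropped = int((pass_cpm & ~is_y & unannot).sum())
    keep = pass_cpm & ~is_y & ~unannot
    report = FilterReport(
        n_input_genes=expr.n_genes,
        n_after_cpm=n_after_cpm,
        n_y_dropped=y_dropped,
        n_unannotated_dropped=unannot_dropped,
        n_retained=int(keep.sum()),
    )
    log2cpm = np.log2(cpm + pseudocount)
    out = expr.subset_genes(keep, scale_tag="log2cpm", values=log2cpm)
    return out, report


def batch_adjust(expr: ExpressionMatrix, site_labels: Sequence[str],
                 method: str = "eb") -> ExpressionMatrix:
    """Remove per-site location/scale effects from a log2 CPM matrix.

    ``method="eb"`` is the parametric empirical-Bayes adjustment;
    ``"center"`` does per-site gene mean-centering only; ``"none"`` is the
    identity. A single site is always the identity. Per-gene grand means
    are preserved exactly.
    """
    if expr.scale_tag != "log2cpm":
        raise ValidationError("batch_adjust expects a log2cpm-scale matrix")
    site_labels = [str(s) for s in site_labels]
    if len(site_labels) != expr.n_subjects:
        raise ValidationError("site label count does not match subjects")
    sites = sorted(set(site_labels))
    if method == "none" or len(sites) == 1:
        return expr
    groups = {s: np.array([i for i, l in enumerate(site_labels) if l == s])
              for s in sites}
    for s, idx in groups.items():
        if idx.size < 2:
            raise ValidationError(f"site {s!r} has fewer than 2 subjects")
    Y = expr.values.astype(float).copy()
    grand = Y.mean(axis=1, keepdims=True)
    if method == "center":
        adj = Y.copy()
        for idx in groups.values():
            adj[:, idx] -= adj[:, idx].mean(axis=1, keepdims=True)
        adj += grand
    elif method == "eb":
        adj = _eb_adjust(Y, [groups[s] for s in sites])
        # enforce exact grand-mean preservation (shrinkage perturbs it slightly)
        adj += grand - adj.mean(axis=1, keepdims=True)
    else:
        raise ValidationError(f"unknown batch method {method!r}")
    return ExpressionMatrix(
        values=adj,
        gene_ids=list(expr.gene_ids),
        subject_ids=list(expr.subject_ids),
        scale_tag="log2cpm",
        gene_symbols=list(expr.gene_symbols) if expr.gene_symbols else None,
        gene_chromosome=list(expr.gene_chromosome) if expr.gene_chromosome else None,
    )


def _eb_adjust(Y: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Parametric EB location-scale batch adjustment of a genes x subjects matrix."""
    n_total = Y.shape[1]
    batch_means = np.stack([Y[:, idx].mean(axis=1) for idx in groups], axis=1)
    weights = np.array([idx.size / n_total for idx in groups])
    grand = batch_means @ weights  # design-weighted grand mean per gene
    resid = Y.copy()
    for b, idx in enumerate(groups):
        resid[:, idx] -= batch_means[:, [b]]
    var_pooled = (resid**2).mean(axis=1)
    sd = np.sqrt(np.maximum(var_pooled, _VAR_FLOOR))
    Z = (Y - grand[:, None]) / sd[:, None]

    adj = np.empty_like(Z)
    for b, idx in enumerate(groups):
        Zb = Z[:, idx]
        n_b = idx.size
        gamma_hat = Zb.mean(axis=1)
        delta_hat = np.maximum(Zb.var(axis=1, ddof=1), _VAR_FLOOR)
        gamma_star, delta_star = _eb_shrink(Zb, gamma_hat, delta_hat, n_b)
        adj[:, idx] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
    out = adj * sd[:, None] + grand[:, None]
    # genes with no within-site variance: location adjustment only
    flat = var_pooled < _VAR_FLOOR
    if flat.any():
        loc = Y[flat].copy()
        for b, idx in enumerate(groups):
            loc[:, idx] -= batch_means[flat][:, [b]]
        out[flat] = loc + grand[flat, None]
    return out


def _eb_shrink(Zb: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
               n_b: int, conv: float = 1e-4, max_iter: int = 200):
    """Shrink per-gene batch effects toward across-gene parametric priors."""
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1) if delta_hat.size > 1 else 0.0
    if tau2 <= 0 or s2 <= 0:
        return gamma_hat, delta_hat  # degenerate priors: no shrinkage
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau2 * gamma_hat + d_old * gamma_bar) / (n_b * tau2 + d_old)
        sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, np.maximum(d_old, _VAR_FLOOR)


def _circular_zt_diff(a: float, b: float) -> float:
    d = abs(a - b) % 24.0
    return min(d, 24.0 - d)


def match_cohort(cases: Sequence[SubjectRecord],
                 controls: Sequence[SubjectRecord],
                 covariates: Sequence[str] = ("age", "zt", "pmi", "ph"),
                 ) -> list[SubjectRecord]:
    """Select |cases| controls best matched to the cases.

    Exact match is required on sex and site; within each (sex, site)
    stratum an optimal assignment minimises the summed distance over the
    standardized continuous covariates (zt circularly) plus a 0/1 race
    mismatch penalty. Raises when a stratum has fewer eligible controls
    than cases.
    """
    if len(controls) < len(cases):
        raise ValidationError("fewer controls than cases")
    pooled = list(cases) + list(controls)
    scales = {}
    for cov in covariates:
        vals = np.array([getattr(r, cov) for r in pooled
                         if getattr(r, cov) is not None], dtype=float)
        scales[cov] = float(vals.std(ddof=0)) if vals.size > 1 else 1.0
        if scales[cov] <= 0:
            scales[cov] = 1.0

    def strat(r: SubjectRecord):
        return (r.sex, r.site)

    strata_cases: dict[tuple, list[SubjectRecord]] = {}
    for c in cases:
        strata_cases.setdefault(strat(c), []).append(c)
    strata_ctrls: dict[tuple, list[SubjectRecord]] = {}
    for c in controls:
        strata_ctrls.setdefault(strat(c), []).append(c)

    infeasible = [k for k, v in strata_cases.items()
                  if len(strata_ctrls.get(k, [])) < len(v)]
    if infeasible:
        raise ValidationError(
            f"no feasible exact-match assignment; short strata (sex, site): {infeasible}"
        )

    selected: list[SubjectRecord] = []
    for key, cs in strata_cases.items():
        pool = strata_ctrls[key]
        cost = np.zeros((len(cs), len(pool)))
        for i, a in enumerate(cs):
            for j, b in enumerate(pool):
                d = 0.0
                for cov in covariates:
                    va, vb = getattr(a, cov), getattr(b, cov)
                    if va is None or vb is None:
                        continue
                    diff = _circular_zt_diff(va, vb) if cov == "zt" else abs(va - vb)
                    d += (diff / scales[cov]) ** 2
                if a.race is not None and b.race is not None and a.race != b.race:
                    d += 1.0
                cost[i, j] = d
        rows, cols = linear_sum_assignment(cost)
        selected.extend(pool[j] for j in cols)
    return selected
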