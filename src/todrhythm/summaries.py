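"""Gene-set diurnal profiles, phase concordance, clustering, heatmap tables.

The Z-set score condenses a gene set (e.g. mitochondrial-function genes)
into one per-subject value: each gene is Z-scored across subjects and the
set genes are averaged per subject; fitting the sinusoid to that profile
shows whether the set as a whole cycles. Phase concordance compares peak
hours between two analyses with the asymmetric circular rule
|difference| <= 5 h or >= 20 h counted as concordant (taken literally on
the raw 0-24 difference). Heatmap export orders rhythmic genes by peak
hour and subjects by time of death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datatypes import ExpressionMatrix, SinusoidFit, ValidationError
from .rhythm import fit_sinusoid

logger = logging.getLogger(__name__)


@dataclass
class GeneSetProfile:
    subject_ids: list[str]
    score: np.ndarray  # per-subject mean of gene-wise Z-scores
    fit: Optional[SinusoidFit]
    genes_used: list[str]
    genes_missing: list[str]


def _zscore_rows(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


def zscore_geneset(expr: ExpressionMatrix, gene_set: Sequence[str],
                   zt: Optional[np.ndarray] = None,
                   ddof: int = 0) -> GeneSetProfile:
    """Per-subject mean of gene-wise Z-scores over a gene set.

    Set members are matched against gene symbols when available, else gene
    IDs; absent genes are reported, an empty intersection is an error. When
    ``zt`` is given the sinusoid is fitted to the profile.
    """
    index: dict[str, int] = {}
    for i, k in enumerate(expr.gene_ids):
        index.setdefault(str(k), i)
    if expr.gene_symbols is not None:  # symbols resolve too (set files use them)
        for i, k in enumerate(expr.gene_symbols):
            index.setdefault(str(k), i)
    present = [g for g in gene_set if g in index]
    missing = [g for g in gene_set if g not in index]
    if not present:
        raise ValidationError("no gene-set members found in the matrix")
    if missing:
        logger.info("gene set: %d of %d members absent from matrix",
                    len(missing), len(gene_set))
    Z = _zscore_rows(expr.values[[index[g] for g in present]], ddof=ddof)
    score = Z.mean(axis=0)
    fit = fit_sinusoid(zt, score) if zt is not None else None
    return GeneSetProfile(subject_ids=list(expr.subject_ids), score=score,
                          fit=fit, genes_used=present, genes_missing=missing)


def phase_concordance(peaks_a: Sequence[float], peaks_b: Sequence[float]) -> float:
    """Proportion of gene pairs with raw peak difference <= 5 h or >= 20 h."""
    a = np.asarray(peaks_a, float)
    b = np.asarray(peaks_b, float)
    if a.size == 0 or a.size != b.size:
        raise ValidationError("peak lists must be equal-length and nonempty")
    d = np.abs(a - b)
    return float(((d <= 5.0) | (d >= 20.0)).mean())


def kmeans_rhythm_clusters(z_matrix: np.ndarray, k: int = 2,
                           seed: int = 0, n_init: int = 20):
    """k-means over Z-scored rhythmic-gene rows (k-means++, 20 restarts).

    Returns (labels, inertia).
    """
    z_matrix = np.asarray(z_matrix, float)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > z_matrix.shape[0]:
        raise ValidationError("k exceeds the number of genes")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed).fit(z_matrix)
    return km.labels_, float(km.inertia_)


def heatmap_table(fits: Sequence[SinusoidFit], gene_ids: Sequence[str],
                  empirical_p: Sequence[float], expr: ExpressionMatrix,
                  zt: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Z-scored matrix of rhythmic genes, peak-hour rows x death-time columns.

    Rows are the genes with empirical p < alpha sorted by peak hour;
    columns are subjects sorted by zt. ``expr`` may belong to a different
    cohort than the one the fits came from (cross-cohort heatmaps), as
    long as it contains the same gene IDs.
    """
    empirical_p = np.asarray(empirical_p, float)
    keep = [i for i in range(len(gene_ids)) if empirical_p[i] < alpha]
    if not keep:
        logger.warning("no rhythmic genes at p < %g; empty heatmap", alpha)
        return pd.DataFrame()
    keep.sort(key=lambda i: fits[i].peak_hour)
    zt = np.asarray(zt, float)
    col_order = np.argsort(zt, kind="stable")
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = [pos[gene_ids[i]] for i in keep]
    Z = _zscore_rows(expr.values[rows])[:, col_order]
    return pd.DataFrame(
        Z,
        index=pd.Index([gene_ids[i] for i in keep], name="gene_id"),
        columns=[expr.subject_ids[j] for j in col_order],
    )
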