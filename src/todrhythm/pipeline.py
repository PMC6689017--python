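"""End-to-end orchestration of the time-of-death rhythmicity analysis.

Stage order: simulate|ingest -> zeitgeber annotation -> preprocessing ->
cohort matching -> per-cohort rhythmicity -> gain/loss (delta R^2) ->
RRHO -> day/night differential expression -> summary tables. Every stage
reads and writes plain TSV so any stage can be replaced by an external
tool; a manifest records the config hash, seed and a digest per output
file, and a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import destrat, io, preprocess, rhythm, rrho, summaries
from .datatypes import ExpressionMatrix, RunConfig, SubjectRecord, ValidationError
from .synthetic import CohortSpec, generate_cohort
from .zeitgeber import annotate_zt, day_night_label

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages.append({
            "stage": stage,
            "outputs": {str(p): _digest(p) for p in outputs},
        })

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "stages": self.stages, "warnings": self.warnings},
            indent=2) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _rhythm_table(res) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": res.gene_ids,
        "amplitude": [f.amplitude for f in res.fits],
        "phase": [f.phase for f in res.fits],
        "offset": [f.offset for f in res.fits],
        "r2": res.r2,
        "peak_hour": res.peak_hour,
        "empirical_p": res.empirical_p,
        "bh_fdr": res.bh_fdr,
    })


def run_pipeline(config: RunConfig, out_dir, *,
                 cohort_spec: Optional[CohortSpec] = None,
                 expression_path=None, metadata_path=None,
                 n_de_perm: Optional[int] = None) -> RunManifest:
    """Run every stage under one config; returns the manifest.

    Either ``cohort_spec`` (simulate) or both ``expression_path`` and
    ``metadata_path`` (ingest; expression must be log2 CPM for this entry
    point, or counts to be filtered first) must be provided. Validation
    happens before any stage output is written.
    """
    if cohort_spec is None and (expression_path is None or metadata_path is None):
        raise ValidationError(
            "run_pipeline needs a cohort_spec or expression+metadata paths")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.rng_seed)

    # --- stage: simulate / ingest ------------------------------------------
    if cohort_spec is not None:
        spec = cohort_spec
        expr, records, truth = generate_cohort(spec)
        io.write_expression(expr, out / "expression.tsv", config)
        io.write_metadata(records, out / "metadata.tsv", config)
        io.write_table(pd.DataFrame({
            "gene_id": truth.gene_ids,
            "rhythm_class": truth.rhythm_class,
            "de_class": truth.de_class,
            "amplitude_ctrl": truth.amplitude_ctrl,
            "amplitude_case": truth.amplitude_case,
            "de_effect": truth.de_effect,
        }), out / "truth.tsv", config)
        manifest.record("simulate", [out / "expression.tsv", out / "metadata.tsv",
                                     out / "truth.tsv"])
    else:
        expr = io.read_expression(expression_path, scale_tag="log2cpm")
        records = io.read_metadata(metadata_path)
        io.check_id_agreement(expr, records)
        manifest.record("ingest", [])

    # --- stage: zeitgeber ---------------------------------------------------
    records = annotate_zt(records)
    io.write_metadata(
        records, out / "metadata_zt.tsv", config,
        extra_columns={"day_night": [day_night_label(r.zt) for r in records]})
    manifest.record("zt", [out / "metadata_zt.tsv"])

    # --- stage: preprocess --------------------------------------------------
    if expr.scale_tag == "counts":
        expr, report = preprocess.filter_genes(
            expr, config.cpm_threshold, config.cpm_fraction,
            config.cpm_pseudocount)
        io.write_table(pd.DataFrame([report.__dict__]),
                       out / "filter_report.tsv", config)
    by_id = {r.subject_id: r for r in records}
    site_labels = [by_id[s].site or "site0" for s in expr.subject_ids]
    expr = preprocess.batch_adjust(expr, site_labels, method="eb")
    io.write_expression(expr, out / "expression_adjusted.tsv", config)
    manifest.record("preprocess", [out / "expression_adjusted.tsv"])

    # --- stage: match -------------------------------------------------------
    cases = [r for r in records if r.diagnosis == "case"]
    controls = [r for r in records if r.diagnosis == "control"]
    if len(controls) > len(cases):
        matched_ctrl = preprocess.match_cohort(cases, controls)
    else:
        matched_ctrl = controls
    (out / "matched_controls.txt").write_text(
        "\n".join(r.subject_id for r in matched_ctrl) + "\n")
    manifest.record("match", [out / "matched_controls.txt"])

    # --- stage: rhythm per cohort ------------------------------------------
    def cohort_zt(rs):
        return np.array([r.zt for r in rs])

    expr_case = expr.subset_subjects([r.subject_id for r in cases])
    expr_ctrl = expr.subset_subjects([r.subject_id for r in matched_ctrl])
    res_case = rhythm.rhythmicity_analysis(
        expr_case, cohort_zt(cases), config.n_shuffles,
        config.stage_seed("rhythm_case"), cohort="case")
    res_ctrl = rhythm.rhythmicity_analysis(
        expr_ctrl, cohort_zt(matched_ctrl), config.n_shuffles,
        config.stage_seed("rhythm_ctrl"), cohort="control")
    for tag, res in (("case", res_case), ("ctrl", res_ctrl)):
        io.write_table(_rhythm_table(res), out / f"rhythm_{tag}.tsv", config)
    manifest.record("rhythm", [out / "rhythm_case.tsv", out / "rhythm_ctrl.tsv"])

    # --- stage: delta R^2 ---------------------------------------------------
    delta = rhythm.delta_r2_test(res_case, res_ctrl, config.rhythm_alpha)
    io.write_table(pd.DataFrame({
        "gene_id": delta.gene_ids, "delta_r2": delta.delta_r2,
        "p_delta": delta.p_delta, "classification": delta.classification,
    }), out / "delta_r2.tsv", config,
        comment="two-sided add-one p; null pairs shuffle k case vs ctrl")
    manifest.record("drhythm", [out / "delta_r2.tsv"])

    # --- stage: rrho --------------------------------------------------------
    p_case = dict(zip(res_case.gene_ids, res_case.empirical_p))
    p_ctrl = dict(zip(res_ctrl.gene_ids, res_ctrl.empirical_p))
    rmap = rrho.rrho_map(rrho.rank_genes(p_case), rrho.rank_genes(p_ctrl),
                         step=config.rrho_step)
    io.write_table(pd.DataFrame(rmap.matrix), out / "rrho_case_vs_ctrl.tsv",
                   config, comment=f"step={rmap.step} N={rmap.n_universe} "
                   "no across-map multiplicity correction (display statistic)")
    manifest.record("rrho", [out / "rrho_case_vs_ctrl.tsv"])

    # --- stage: day/night DE ------------------------------------------------
    matched_all = matched_ctrl + cases
    day, night = destrat.split_day_night(matched_all)
    n_perm = n_de_perm if n_de_perm is not None else config.n_label_perms
    de_outputs = []
    for name, stratum in (("day", day), ("night", night)):
        ok = all(sum(1 for s in stratum if s.diagnosis == g) >= 3
                 for g in ("control", "case"))
        if not ok:
            logger.warning("stratum %s too small; DE skipped", name)
            manifest.warnings.append(f"de_{name}_skipped")
            continue
        res = destrat.de_stratum(
            expr, stratum, n_perm=n_perm, max_k=config.max_covariates,
            seed=config.stage_seed(f"de_{name}"), stratum=name)
        io.write_table(destrat.de_table(res), out / f"de_{name}.tsv", config)
        de_outputs.append(out / f"de_{name}.tsv")
    manifest.record("de", de_outputs)

    # --- stage: summaries ---------------------------------------------------
    heat = summaries.heatmap_table(
        res_ctrl.fits, res_ctrl.gene_ids, res_ctrl.empirical_p,
        expr_ctrl, cohort_zt(matched_ctrl), config.rhythm_alpha)
    heat.to_csv(out / "heatmap_ctrl.tsv", sep="\t", float_format="%.10g")
    summary_outputs = [out / "heatmap_ctrl.tsv"]
    if len(heat) >= 2:
        labels, inertia = summaries.kmeans_rhythm_clusters(
            heat.values, k=2, seed=config.stage_seed("kmeans"))
        io.write_table(pd.DataFrame({"gene_id": heat.index, "cluster": labels}),
                       out / "clusters_ctrl.tsv", config,
                       comment=f"k=2 inertia={inertia:.6g}")
        summary_outputs.append(out / "clusters_ctrl.tsv")
    manifest.record("summaries", summary_outputs)

    manifest.write(out / "manifest.json")
    return manifest
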