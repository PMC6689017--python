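"""Readers and writers for the tab-separated interchange formats.

Expression: TSV with genes in rows, first column the gene ID, header row of
subject IDs. The reserved header names ``symbol`` and ``chromosome`` mark
annotation columns and are stripped from the numeric block. Metadata: TSV,
one subject per row. Missing values are written as ``NA``; an NA inside the
numeric expression block is an error (downstream assumes complete matrices).
Output TSVs carry a ``#`` comment line recording config hash and seed.
"""

from __future__ import annotations

import io as _io
from dataclasses import fields as dc_fields
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    RESERVED_ANNOTATION_COLUMNS,
    ExpressionMatrix,
    RunConfig,
    SubjectRecord,
    ValidationError,
)

PathLike = Union[str, Path]

_META_REQUIRED = ("subject_id", "diagnosis")
_META_FLOATS = ("zt", "tz_offset_hours", "latitude", "longitude", "elevation",
                "age", "pmi", "rin", "ph")
_META_BOOLS = ("dst_flag", "medication_flag")
_DEATH_FIELDS = ("death_local", "tz_offset_hours", "dst_flag",
                 "latitude", "longitude", "elevation")


def read_expression(path: PathLike, scale_tag: str) -> ExpressionMatrix:
    """Read a gene x subject expression TSV.

    Raises :class:`ValidationError` with the offending row/column for
    non-numeric cells and with the duplicate list for repeated IDs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected gene-ID column plus subjects")
    gene_col = df.columns[0]
    gene_ids = df[gene_col].tolist()
    ann = {}
    for col in RESERVED_ANNOTATION_COLUMNS:
        if col in df.columns[1:]:
            ann[col] = df[col].tolist()
    subject_cols = [c for c in df.columns[1:] if c not in RESERVED_ANNOTATION_COLUMNS]
    block = df[subject_cols]
    values = np.empty((len(gene_ids), len(subject_cols)), dtype=float)
    for j, col in enumerate(subject_cols):
        converted = pd.to_numeric(block[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.values)[0])
            raise ValidationError(
                f"{path}: non-numeric cell at gene {gene_ids[i]!r}, "
                f"subject column {col!r}: {block[col].iloc[i]!r}"
            )
        values[:, j] = converted.values
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        subject_ids=subject_cols,
        scale_tag=scale_tag,
        gene_symbols=ann.get("symbol"),
        gene_chromosome=ann.get("chromosome"),
    )


def write_expression(expr: ExpressionMatrix, path: PathLike,
                     config: Optional[RunConfig] = None,
                     float_format: str = "%.10g") -> None:
    cols: dict[str, object] = {"gene_id": expr.gene_ids}
    if expr.gene_symbols is not None:
        cols["symbol"] = expr.gene_symbols
    if expr.gene_chromosome is not None:
        cols["chromosome"] = expr.gene_chromosome
    df = pd.DataFrame(cols)
    for j, sid in enumerate(expr.subject_ids):
        df[sid] = expr.values[:, j]
    _write_tsv(df, path, config, float_format=float_format)


def read_metadata(path: PathLike) -> list[SubjectRecord]:
    """Read a subject metadata TSV into validated records.

    Each row must carry either a precomputed ``zt`` or the full death
    time/place field set (death_local, tz_offset_hours, dst_flag, latitude,
    longitude, elevation); optional covariates left blank or ``NA`` are
    recorded as missing, never zero-filled.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(_row_to_record(row))
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"{path}: duplicate subject IDs {dupes}")
    return records


def _na(val) -> bool:
    return val is None or (isinstance(val, float) and np.isnan(val)) or \
        (isinstance(val, str) and val.strip() in ("", "NA"))


def _row_to_record(row: pd.Series) -> SubjectRecord:
    kw: dict = {"subject_id": str(row["subject_id"]),
                "diagnosis": str(row["diagnosis"])}
    for col in _META_FLOATS:
        if col in row.index and not _na(row[col]):
            kw[col] = float(row[col])
    for col in _META_BOOLS:
        if col in row.index and not _na(row[col]):
            kw[col] = str(row[col]).strip().lower() in ("1", "true", "t", "yes")
    for col in ("sex", "race", "site"):
        if col in row.index and not _na(row[col]):
            kw[col] = str(row[col]).strip()
    if "death_local" in row.index and not _na(row["death_local"]):
        kw["death_local"] = datetime.fromisoformat(str(row["death_local"]).strip())
    return SubjectRecord(**kw)


def write_metadata(records: Sequence[SubjectRecord], path: PathLike,
                   config: Optional[RunConfig] = None,
                   extra_columns: Optional[dict[str, Sequence]] = None) -> None:
    rows = []
    for r in records:
        d = {}
        for f in dc_fields(SubjectRecord):
            v = getattr(r, f.name)
            if v is None:
                d[f.name] = "NA"
            elif isinstance(v, datetime):
                d[f.name] = v.isoformat(sep=" ")
            elif isinstance(v, bool):
                d[f.name] = "true" if v else "false"
            else:
                d[f.name] = v
        rows.append(d)
    df = pd.DataFrame(rows)
    if extra_columns:
        for name, vals in extra_columns.items():
            df[name] = list(vals)
    _write_tsv(df, path, config)


def read_gene_set(path: PathLike) -> list[str]:
    """One gene symbol per line; blank lines and # comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_config(path: PathLike) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    if "day_window" in raw:
        raw["day_window"] = tuple(raw["day_window"])
    return RunConfig(**raw)


def write_config(config: RunConfig, path: PathLike) -> None:
    d = {f.name: getattr(config, f.name) for f in dc_fields(RunConfig)}
    d["day_window"] = list(d["day_window"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def check_id_agreement(expr: ExpressionMatrix,
                       records: Sequence[SubjectRecord]) -> None:
    """Subjects are reconciled by ID, never position; any mismatch is fatal."""
    e = set(expr.subject_ids)
    m = {r.subject_id for r in records}
    if e != m:
        only_e = sorted(e - m)
        only_m = sorted(m - e)
        raise ValidationError(
            f"subject ID mismatch: only in expression {only_e}; "
            f"only in metadata {only_m}"
        )


def _write_tsv(df: pd.DataFrame, path: PathLike,
               config: Optional[RunConfig] = None,
               float_format: str = "%.10g") -> None:
    buf = _io.StringIO()
    if config is not None:
        buf.write(f"# config_hash={config.config_hash()} seed={config.rng_seed}\n")
    df.to_csv(buf, sep="\t", index=False, float_format=float_format)
    Path(path).write_text(buf.getvalue())


def write_table(df: pd.DataFrame, path: PathLike,
                config: Optional[RunConfig] = None,
                comment: Optional[str] = None) -> None:
    """Generic provenance-stamped TSV writer for stage outputs."""
    buf = _io.StringIO()
    if config is not None:
        buf.write(f"# config_hash={config.config_hash()} seed={config.rng_seed}\n")
    if comment:
        buf.write(f"# {comment}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    Path(path).write_text(buf.getvalue())
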