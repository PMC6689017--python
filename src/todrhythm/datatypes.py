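"""Core domain types shared across the pipeline.

The pipeline operates on a gene x subject expression matrix (raw counts or
log2 CPM), per-subject death metadata (from which zeitgeber time is derived),
and a run configuration carrying every tunable threshold and the master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

RESERVED_ANNOTATION_COLUMNS = ("symbol", "chromosome")

#: fixed angular frequency of the diurnal sinusoid, rad/h (24 h period)
OMEGA = np.pi / 12.0


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates its contract."""


@dataclass
class ExpressionMatrix:
    """Gene x subject expression values with gene annotations.

    ``scale_tag`` is ``"counts"`` (nonnegative raw counts) or ``"log2cpm"``.
    Gene identity is the gene ID; symbols/chromosomes are annotation only.
    """

    values: np.ndarray
    gene_ids: list[str]
    subject_ids: list[str]
    scale_tag: str
    gene_symbols: Optional[list[str]] = None
    gene_chromosome: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.subject_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.subject_ids)} subjects"
            )
        for name, ids in (("gene", self.gene_ids), ("subject", self.subject_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} IDs: {sorted(dupes)}")
        if self.scale_tag not in ("counts", "log2cpm"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite (no NA)")
        if self.scale_tag == "counts" and np.any(self.values < 0):
            raise ValidationError("counts-scale values must be nonnegative")
        for attr in ("gene_symbols", "gene_chromosome"):
            ann = getattr(self, attr)
            if ann is not None and len(ann) != len(self.gene_ids):
                raise ValidationError(f"{attr} length does not match gene count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subject_index(self, subject_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise ValidationError(f"subjects absent from matrix: {missing}")
        return np.array([pos[s] for s in subject_ids], dtype=int)

    def subset_subjects(self, subject_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.subject_index(subject_ids)
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            subject_ids=[self.subject_ids[i] for i in idx],
            scale_tag=self.scale_tag,
            gene_symbols=list(self.gene_symbols) if self.gene_symbols else None,
            gene_chromosome=list(self.gene_chromosome) if self.gene_chromosome else None,
        )

    def subset_genes(self, keep: np.ndarray, scale_tag: Optional[str] = None,
                     values: Optional[np.ndarray] = None) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        vals = self.values if values is None else values
        return ExpressionMatrix(
            values=vals[keep],
            gene_ids=[self.gene_ids[i] for i in keep],
            subject_ids=list(self.subject_ids),
            scale_tag=scale_tag or self.scale_tag,
            gene_symbols=[self.gene_symbols[i] for i in keep] if self.gene_symbols else None,
            gene_chromosome=[self.gene_chromosome[i] for i in keep] if self.gene_chromosome else None,
        )


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        (dup if x in seen else seen).add(x)
    return dup


@dataclass
class SubjectRecord:
    """Per-subject metadata: diagnosis, death time/place, covariates.

    ``zt`` is zeitgeber time in hours on [-6, 18): hours since the most
    recent sunrise at the death place (negative values count down to the
    next sunrise). It may be supplied precomputed or derived from
    ``death_local`` + timezone + coordinates by the zeitgeber module.
    """

    subject_id: str
    diagnosis: str  # "control" or "case"
    zt: Optional[float] = None
    death_local: Optional[datetime] = None
    tz_offset_hours: Optional[float] = None
    dst_flag: Optional[bool] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    elevation: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    race: Optional[str] = None
    pmi: Optional[float] = None
    rin: Optional[float] = None
    ph: Optional[float] = None
    site: Optional[str] = None
    medication_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.diagnosis not in ("control", "case"):
            raise ValidationError(
                f"{self.subject_id}: diagnosis must be control/case, got {self.diagnosis!r}"
            )
        if self.zt is not None and not (-6.0 <= self.zt < 18.0):
            raise ValidationError(
                f"{self.subject_id}: zt {self.zt} outside [-6, 18)"
            )
        if self.zt is None and not self.has_death_place:
            raise ValidationError(
                f"{self.subject_id}: needs zt or full death time/place fields"
            )
        if self.latitude is not None and abs(self.latitude) > 90:
            raise ValidationError(f"{self.subject_id}: |latitude| > 90")
        for attr in ("pmi", "age"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValidationError(f"{self.subject_id}: {attr} < 0")

    @property
    def has_death_place(self) -> bool:
        return all(
            getattr(self, a) is not None
            for a in ("death_local", "tz_offset_hours", "dst_flag",
                      "latitude", "longitude", "elevation")
        )


@dataclass
class RunConfig:
    """All tunable thresholds plus the master seed.

    Stage seeds are derived deterministically from ``rng_seed`` by stage
    name (see :meth:`stage_seed`) so any stage can be rerun in isolation.
    """

    n_shuffles: int = 1000
    rng_seed: int = 0
    rhythm_alpha: float = 0.05
    strict_alpha: float = 0.01
    cpm_threshold: float = 1.0
    cpm_fraction: float = 0.5
    cpm_pseudocount: float = 0.5
    max_covariates: int = 2
    n_label_perms: int = 1000
    rrho_step: Optional[int] = None  # None -> max(1, N // 100)
    day_window: tuple[float, float] = (0.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValidationError("n_shuffles must be >= 1")
        for a in ("rhythm_alpha", "strict_alpha", "cpm_fraction"):
            v = getattr(self, a)
            if not (0 < v <= 1):
                raise ValidationError(f"{a} must lie in (0, 1]")
        if self.max_covariates < 0:
            raise ValidationError("max_covariates must be >= 0")

    def stage_seed(self, stage: str) -> int:
        """Deterministic child seed for a named pipeline stage (< 2**31)."""
        h = hashlib.sha256(f"{self.rng_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        items = [(f.name, getattr(self, f.name)) for f in fields(self)]
        return hashlib.sha256(repr(items).encode()).hexdigest()[:12]


@dataclass
class SinusoidFit:
    """One gene's fitted sinusoid y = A sin(f t + p) + b with f = pi/12."""

    amplitude: float
    phase: float  # radians, [0, 2*pi)
    offset: float
    rss_model: float
    rss_null: float

    @property
    def r2(self) -> float:
        if self.rss_null <= 0:
            return 0.0
        return max(0.0, 1.0 - self.rss_model / self.rss_null)

    @property
    def peak_hour(self) -> float:
        """ZT hour at which the fitted curve is maximal, in [0, 24)."""
        return float(((np.pi / 2 - self.phase) / OMEGA) % 24.0)

    def predict(self, zt: np.ndarray) -> np.ndarray:
        zt = np.asarray(zt, dtype=float)
        return self.amplitude * np.sin(OMEGA * zt + self.phase) + self.offset


@dataclass
class NullDistribution:
    """Pooled null R^2 samples from TOD-shuffled refits (all genes pooled)."""

    values: np.ndarray  # flat, pooled over genes and shuffles
    per_shuffle: np.ndarray  # (n_shuffles, n_genes) — kept for delta-R2 pairing
    n_shuffles: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("null R^2 values must lie in [0, 1]")


@dataclass
class RhythmicityResult:
    """Per-gene rhythmicity statistics for one cohort."""

    gene_ids: list[str]
    fits: list[SinusoidFit]
    empirical_p: np.ndarray
    bh_fdr: np.ndarray
    cohort: str = ""
    null: Optional[NullDistribution] = None

    @property
    def r2(self) -> np.ndarray:
        return np.array([f.r2 for f in self.fits])

    @property
    def peak_hour(self) -> np.ndarray:
        return np.array([f.peak_hour for f in self.fits])


@dataclass
class DeltaR2Result:
    """Gain/loss-of-rhythmicity calls from the paired shuffled-null test."""

    gene_ids: list[str]
    delta_r2: np.ndarray  # r2_case - r2_ctrl
    p_delta: np.ndarray
    classification: list[str]  # gain / loss / unchanged


@dataclass
class FilterReport:
    n_input_genes: int
    n_after_cpm: int
    n_y_dropped: int
    n_unannotated_dropped: int
    n_retained: int


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters for a synthetic cohort."""

    gene_ids: list[str]
    amplitude_ctrl: np.ndarray
    amplitude_case: np.ndarray
    phase_ctrl: np.ndarray
    phase_case: np.ndarray
    offset: np.ndarray
    noise_sd: np.ndarray
    rhythm_class: list[str]  # none / shared / gain / loss
    de_class: list[str]  # none / night_only / day_and_night
    de_effect: np.ndarray
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    batch_shift: Optional[np.ndarray] = None  # (n_genes, n_sites)
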