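"""Synthetic cohort generator: the ground truth for every downstream test.

Emulates the statistical structure of a postmortem brain RNA-seq cohort
sampled at a single time point per subject (the time of death): log2-CPM-
like values for ~10^3-10^4 genes over ~10^2 subjects; a fraction of genes
sinusoidal on a 24-h period with group-specific amplitude/phase (shared,
gain-in-case, loss-in-case classes); genes differentially expressed only
among night-death subjects; two-site batch shifts; and realistic subject
covariates. Death times follow a bimodal mixture (morning / late-evening
clustering) by default; uniform sampling is used for calibration.

Expression of gene g in subject s:

    y_gs = b_g + batch_g(site_s) + A_g(group_s) sin(f zt_s + p_g(group_s))
           + delta_g 1[case_s and DE window] + Normal(0, sigma_g)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Optional

import numpy as np

from .datatypes import (
    OMEGA,
    ExpressionMatrix,
    SubjectRecord,
    SyntheticTruth,
    ValidationError,
)
from .zeitgeber import SolarQuery, day_night_label, sunrise_utc

SITES = ("Pitt", "MSSM")


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic cohort."""

    n_ctrl: int = 46
    n_case: int = 46
    n_genes: int = 2000
    f_shared: float = 0.05
    f_gain: float = 0.05
    f_loss: float = 0.05
    f_de_night: float = 0.02
    f_de_both: float = 0.01
    amplitude: float = 1.5  # log2 units, rhythmic genes
    noise_sd: float = 1.0  # Gaussian noise on the log2 scale
    noise_df: Optional[float] = None  # Student-t noise when set (stress test)
    de_effect: float = 1.0  # |log2 fold change| for DE genes
    tod_mode: str = "bimodal"  # bimodal / uniform
    n_night_ctrl: Optional[int] = None  # exact night-death counts, else sampled
    n_night_case: Optional[int] = None
    n_sites: int = 2
    site_shift_sd: float = 0.3  # per gene-site batch shift, log2 units
    offset_range: tuple[float, float] = (2.0, 10.0)
    coherent_set_size: int = 0  # case-only rhythmic genes sharing one peak
    coherent_set_peak: float = 3.5  # ZT hours
    coherent_set_amp: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.f_shared, self.f_gain, self.f_loss,
              self.f_de_night, self.f_de_both)
        if any(f < 0 for f in fr) or sum(fr) > 1:
            raise ValidationError("class fractions must be >= 0 and sum <= 1")
        if self.tod_mode not in ("bimodal", "uniform"):
            raise ValidationError(f"unknown tod_mode {self.tod_mode!r}")


def _wrap_zt(zt: np.ndarray) -> np.ndarray:
    return ((zt + 6.0) % 24.0) - 6.0


def _sample_zt(rng: np.random.Generator, n: int, mode: str,
               n_night: Optional[int]) -> np.ndarray:
    """Death times on the ZT scale; optionally with an exact night count."""
    if n_night is not None:
        if n_night > n:
            raise ValidationError("n_night exceeds group size")
        day = rng.uniform(0.0, 12.0, size=n - n_night)
        night = _wrap_zt(rng.uniform(12.0, 24.0, size=n_night))
        zt = np.concatenate([day, night])
        return zt[rng.permutation(n)]
    if mode == "uniform":
        return rng.uniform(-6.0, 18.0, size=n)
    # bimodal: wrapped-normal mixture, morning and late-evening death peaks
    comp = rng.random(n) < 0.6
    zt = np.where(comp, rng.normal(2.0, 2.5, size=n),
                  rng.normal(15.0, 2.5, size=n))
    return _wrap_zt(zt)


def _phase_for_peak(peak_hour: float) -> float:
    return float(np.mod(np.pi / 2 - OMEGA * peak_hour, 2 * np.pi))


def generate_cohort(spec: CohortSpec):
    """Simulate (expression, subject records, ground truth) for one cohort.

    Deterministic given ``spec.seed``. Gene classes are assigned in blocks
    (shared, gain, loss, night-only DE, day+night DE, coherent set, null)
    so truth counts equal ``round(fraction * n_genes)`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_sub = spec.n_ctrl + spec.n_case
    G = spec.n_genes

    # --- subjects -----------------------------------------------------------
    diagnosis = ["control"] * spec.n_ctrl + ["case"] * spec.n_case
    zt = np.concatenate([
        _sample_zt(rng, spec.n_ctrl, spec.tod_mode, spec.n_night_ctrl),
        _sample_zt(rng, spec.n_case, spec.tod_mode, spec.n_night_case),
    ])
    # equal site proportions within each group, as in the matched design
    sites = []
    for n_grp in (spec.n_ctrl, spec.n_case):
        lab = [SITES[i % spec.n_sites] for i in range(n_grp)]
        sites.extend(np.array(lab)[rng.permutation(n_grp)])
    site_index = {s: i for i, s in enumerate(SITES[: spec.n_sites])}
    records = []
    for i in range(n_sub):
        is_case = diagnosis[i] == "case"
        records.append(SubjectRecord(
            subject_id=f"S{i:04d}",
            diagnosis=diagnosis[i],
            zt=float(zt[i]),
            age=float(np.clip(rng.normal(50, 10), 18, 65)),
            sex="M" if rng.random() < 0.6 else "F",
            race="W" if rng.random() < 0.8 else "B",
            pmi=float(rng.uniform(5, 30)),
            rin=float(np.clip(rng.normal(7.5, 0.8), 5, 10)),
            ph=float(np.clip(rng.normal(6.7, 0.25), 6.0, 7.4)),
            site=sites[i],
            medication_flag=bool(rng.random() < 0.8) if is_case else False,
        ))

    # --- gene classes -------------------------------------------------------
    n_shared = round(spec.f_shared * G)
    n_gain = round(spec.f_gain * G)
    n_loss = round(spec.f_loss * G)
    n_de_night = round(spec.f_de_night * G)
    n_de_both = round(spec.f_de_both * G)
    n_set = spec.coherent_set_size
    if n_shared + n_gain + n_loss + n_de_night + n_de_both + n_set > G:
        raise ValidationError("gene class counts exceed n_genes")

    rhythm_class = ["none"] * G
    de_class = ["none"] * G
    pos = 0
    for cls, n in (("shared", n_shared), ("gain", n_gain), ("loss", n_loss)):
        for g in range(pos, pos + n):
            rhythm_class[g] = cls
        pos += n
    for cls, n in (("night_only", n_de_night), ("day_and_night", n_de_both)):
        for g in range(pos, pos + n):
            de_class[g] = cls
        pos += n
    set_genes = list(range(pos, pos + n_set))
    for g in set_genes:
        rhythm_class[g] = "gain"

    offset = rng.uniform(*spec.offset_range, size=G)
    noise_sd = np.full(G, spec.noise_sd)
    phase = rng.uniform(0, 2 * np.pi, size=G)
    amp_ctrl = np.zeros(G)
    amp_case = np.zeros(G)
    phase_ctrl = phase.copy()
    phase_case = phase.copy()
    for g in range(G):
        if rhythm_class[g] == "shared":
            amp_ctrl[g] = amp_case[g] = spec.amplitude
        elif rhythm_class[g] == "gain":
            amp_case[g] = spec.amplitude
        elif rhythm_class[g] == "loss":
            amp_ctrl[g] = spec.amplitude
    for g in set_genes:
        amp_case[g] = spec.coherent_set_amp
        phase_case[g] = _phase_for_peak(spec.coherent_set_peak)
    de_effect = np.zeros(G)
    for g in range(G):
        if de_class[g] != "none":
            de_effect[g] = spec.de_effect * rng.choice([-1.0, 1.0])

    batch = rng.normal(0.0, spec.site_shift_sd, size=(G, spec.n_sites)) \
        if spec.n_sites > 1 else np.zeros((G, 1))

    # --- assemble the matrix ------------------------------------------------
    is_case = np.array([d == "case" for d in diagnosis])
    night = np.array([day_night_label(z) == "night" for z in zt])
    site_col = np.array([site_index[s] for s in sites])
    amp = np.where(is_case[None, :], amp_case[:, None], amp_ctrl[:, None])
    ph_m = np.where(is_case[None, :], phase_case[:, None], phase_ctrl[:, None])
    signal = amp * np.sin(OMEGA * zt[None, :] + ph_m)
    de_window = np.zeros((G, n_sub))
    for g in range(G):
        if de_class[g] == "night_only":
            de_window[g] = is_case & night
        elif de_class[g] == "day_and_night":
            de_window[g] = is_case
    if spec.noise_df is not None:
        noise = rng.standard_t(spec.noise_df, size=(G, n_sub)) * noise_sd[:, None]
    else:
        noise = rng.normal(0.0, 1.0, size=(G, n_sub)) * noise_sd[:, None]
    values = (offset[:, None] + batch[:, site_col] + signal
              + de_effect[:, None] * de_window + noise)

    gene_ids = [f"G{g:05d}" for g in range(G)]
    expr = ExpressionMatrix(
        values=values, gene_ids=gene_ids, subject_ids=[r.subject_id for r in records],
        scale_tag="log2cpm", gene_symbols=[f"SYM{g:05d}" for g in range(G)],
        gene_chromosome=[str(1 + g % 22) for g in range(G)],
    )
    truth = SyntheticTruth(
        gene_ids=gene_ids, amplitude_ctrl=amp_ctrl, amplitude_case=amp_case,
        phase_ctrl=phase_ctrl, phase_case=phase_case, offset=offset,
        noise_sd=noise_sd, rhythm_class=rhythm_class, de_class=de_class,
        de_effect=de_effect,
        gene_sets={"mito": [gene_ids[g] for g in set_genes]} if set_genes else {},
        batch_shift=batch,
    )
    return expr, records, truth


def generate_death_records(n: int, geography: Optional[dict] = None,
                           date_range: tuple[date, date] = (date(2015, 1, 1),
                                                            date(2016, 12, 31)),
                           seed: int = 0):
    """Death metadata rows exercising the full solar ZT derivation.

    Each record targets a uniform ZT: the local death time is constructed
    from the actual sunrise at the sampled mid-latitude site and date, so
    rederiving ZT through the zeitgeber module recovers the target within
    sunrise-interval drift. Returns (records, target_zt).
    """
    geography = geography or {"lat": (25.0, 50.0), "lon": (-125.0, -70.0),
                              "elevation": (0.0, 1500.0)}
    lat_lo, lat_hi = geography["lat"]
    if max(abs(lat_lo), abs(lat_hi)) > 55:
        raise ValidationError("polar latitudes are not supported (|lat| <= 55)")
    rng = np.random.default_rng(seed)
    d0, d1 = date_range
    n_days = (d1 - d0).days
    records, targets = [], []
    for i in range(n):
        lat = rng.uniform(lat_lo, lat_hi)
        lon = rng.uniform(*geography["lon"])
        elev = rng.uniform(*geography["elevation"])
        civil = d0 + timedelta(days=int(rng.integers(0, n_days + 1)))
        target = rng.uniform(-6.0, 18.0)
        sr = sunrise_utc(SolarQuery(civil, lat, lon, elev))
        death_utc = sr + timedelta(hours=target)
        tz_offset = round(lon / 15.0)
        local = (death_utc + timedelta(hours=tz_offset)).replace(tzinfo=None)
        records.append(SubjectRecord(
            subject_id=f"D{i:04d}",
            diagnosis="control",
            death_local=local,
            tz_offset_hours=float(tz_offset),
            dst_flag=False,
            latitude=float(lat),
            longitude=float(lon),
            elevation=float(elev),
        ))
        targets.append(target)
    return records, np.array(targets)
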