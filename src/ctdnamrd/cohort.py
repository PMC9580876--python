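"""Synthetic patient-cohort generator.

Emulates a stage II-III colorectal-cancer surveillance study: 112
patients (23.2% stage II), ~24% recurrences with log-normal times to
radiological recurrence (median 12.2 months), ~36 months follow-up for
the rest, and per-patient blood draws — preoperative, an early
postoperative window draw (<=60 days after surgery, before adjuvant
chemotherapy), and 3-monthly surveillance draws after end of definitive
treatment.  Each draw yields paired aliquots of the same 8 mL of
plasma, so the single-target and multitarget assays downstream see the
same cfDNA and true ctDNA concentrations.

Tumour dynamics are deliberately minimal: a patient-specific
preoperative ctDNA level, a postoperative residual level (zero for
cured patients), and exponential regrowth with a patient-specific
doubling time for recurrence patients.  ctDNA-positive non-recurrence
patients are modelled as cleared at adjuvant start.  cfDNA
concentrations are log-normal, calibrated so the extracted genome
equivalents per 8 mL draw have a median near 13,000 GE, with
preoperative draws running higher — high enough to engage the
multitarget assay's 20,000 GE input cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import math

import numpy as np

__all__ = [
    "CohortConfig",
    "PatientProfile",
    "CohortSample",
    "simulate_cohort",
    "tumor_trajectory",
    "draw_sample",
]


def _lognormal(rng: np.random.Generator, median: float,
               sigma_log: float) -> float:
    if median <= 0:
        return 0.0
    return float(median * math.exp(sigma_log * rng.standard_normal()))


@dataclass
class CohortConfig:
    """Generator defaults: the study conditions being emulated."""

    n_patients: int = 112
    stage2_fraction: float = 0.232
    recurrence_fraction: float = 0.24
    recurrence_time_median_months: float = 12.2
    recurrence_time_sigma_log: float = 0.25
    followup_mean_months: float = 35.8
    followup_sd_months: float = 0.7
    adjuvant_fraction: float = 0.705
    adjuvant_start_months: float = 2.0
    adjuvant_duration_months: float = 4.0
    # Draw availability (not every patient contributed every sub-analysis).
    preop_draw_prob: float = 0.82
    postop_draw_prob: float = 0.50
    serial_draw_prob: float = 0.58
    preop_draw_time_months: float = -0.25
    postop_draw_time_months: float = 1.0
    surveillance_interval_months: float = 3.0
    max_serial_draws: int = 3
    # Concentrations (GE per mL plasma, log-normal medians / log-SDs).
    cfdna_median_ge_per_ml: float = 1650.0
    cfdna_sigma_log: float = 0.6
    preop_cfdna_factor: float = 1.6
    preop_ctdna_median_ge_per_ml: float = 1.0
    preop_ctdna_sigma_log: float = 2.0
    residual_median_ge_per_ml: float = 0.08
    residual_sigma_log: float = 2.0
    nonrecurrence_residual_fraction: float = 0.06
    doubling_time_median_months: float = 1.5
    doubling_time_sigma_log: float = 0.3
    biological_noise_sigma_log: float = 0.3
    plasma_ml: float = 8.0

    def __post_init__(self) -> None:
        for name in ("stage2_fraction", "recurrence_fraction",
                     "adjuvant_fraction", "preop_draw_prob",
                     "postop_draw_prob", "serial_draw_prob",
                     "nonrecurrence_residual_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("recurrence_time_median_months", "followup_mean_months",
                     "surveillance_interval_months", "plasma_ml",
                     "doubling_time_median_months",
                     "cfdna_median_ge_per_ml"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PatientProfile:
    patient_id: str
    stage: str  # "II" or "III"
    recurrence: bool
    recurrence_time_months: Optional[float]
    followup_months: float
    adjuvant_treated: bool
    preop_ctdna_ge_per_ml: float
    postop_residual_ge_per_ml: float
    doubling_time_months: float
    cleared_at_months: Optional[float] = None  # adjuvant clearance
    has_preop_draw: bool = True
    has_postop_draw: bool = True
    has_serial_draws: bool = True

    def __post_init__(self) -> None:
        if self.stage not in ("II", "III"):
            raise ValueError("stage must be 'II' or 'III'")
        if self.recurrence and self.recurrence_time_months is None:
            raise ValueError("recurrence requires a recurrence time")
        if not self.doubling_time_months > 0:
            raise ValueError("doubling time must be > 0")


@dataclass
class CohortSample:
    """One timed blood draw; both assay aliquots share its concentrations."""

    sample_id: str
    patient_id: str
    time_months: float  # negative = preoperative
    timing_class: str   # preop | postop_window | surveillance
    cfdna_ge_per_ml: float
    true_ctdna_ge_per_ml: float
    plasma_ml: float = 8.0

    def __post_init__(self) -> None:
        if self.timing_class not in ("preop", "postop_window", "surveillance"):
            raise ValueError(f"unknown timing class {self.timing_class!r}")
        if self.cfdna_ge_per_ml < 0 or self.true_ctdna_ge_per_ml < 0:
            raise ValueError("concentrations must be >= 0")


def tumor_trajectory(patient: PatientProfile, t_months: float) -> float:
    """True ctDNA concentration (GE/mL) at time ``t_months`` from surgery.

    Preoperative times return the preoperative level; after surgery the
    residual level doubles every ``doubling_time_months`` (recurrence
    patients), is zero for cured patients, and drops to zero at adjuvant
    clearance for patients whose residual disease adjuvant therapy
    eliminated.
    """
    if t_months < 0:
        return patient.preop_ctdna_ge_per_ml
    if patient.postop_residual_ge_per_ml <= 0:
        return 0.0
    if (patient.cleared_at_months is not None
            and t_months >= patient.cleared_at_months):
        return 0.0
    return (patient.postop_residual_ge_per_ml
            * 2.0 ** (t_months / patient.doubling_time_months))


def _simulate_patient(pid: str, cfg: CohortConfig,
                      rng: np.random.Generator) -> PatientProfile:
    stage = "II" if rng.random() < cfg.stage2_fraction else "III"
    recurrence = bool(rng.random() < cfg.recurrence_fraction)
    adjuvant = bool(rng.random() < cfg.adjuvant_fraction)
    recurrence_time = None
    cleared_at = None
    followup = float(rng.normal(cfg.followup_mean_months,
                                cfg.followup_sd_months))
    if recurrence:
        recurrence_time = _lognormal(rng, cfg.recurrence_time_median_months,
                                     cfg.recurrence_time_sigma_log)
        residual = _lognormal(rng, cfg.residual_median_ge_per_ml,
                              cfg.residual_sigma_log)
        followup = max(followup, recurrence_time + 1.0)
    elif (adjuvant and rng.random() < cfg.nonrecurrence_residual_fraction):
        # Residual disease eliminated by adjuvant treatment.
        residual = _lognormal(rng, cfg.residual_median_ge_per_ml,
                              cfg.residual_sigma_log)
        cleared_at = cfg.adjuvant_start_months
    else:
        residual = 0.0
    return PatientProfile(
        patient_id=pid,
        stage=stage,
        recurrence=recurrence,
        recurrence_time_months=recurrence_time,
        followup_months=followup,
        adjuvant_treated=adjuvant,
        preop_ctdna_ge_per_ml=_lognormal(rng, cfg.preop_ctdna_median_ge_per_ml,
                                         cfg.preop_ctdna_sigma_log),
        postop_residual_ge_per_ml=residual,
        doubling_time_months=_lognormal(rng, cfg.doubling_time_median_months,
                                        cfg.doubling_time_sigma_log),
        cleared_at_months=cleared_at,
        has_preop_draw=bool(rng.random() < cfg.preop_draw_prob),
        has_postop_draw=bool(rng.random() < cfg.postop_draw_prob),
        has_serial_draws=bool(rng.random() < cfg.serial_draw_prob),
    )


def draw_sample(patient: PatientProfile, t_months: float,
                config: CohortConfig, rng: np.random.Generator,
                sample_id: str = "") -> CohortSample:
    """Realise one blood draw with log-normal biological noise.

    The draw's cfDNA and true ctDNA concentrations are shared by the
    paired single-target and multitarget aliquots downstream.
    """
    cfdna_median = config.cfdna_median_ge_per_ml
    if t_months < 0:
        cfdna_median *= config.preop_cfdna_factor
    cfdna = _lognormal(rng, cfdna_median, config.cfdna_sigma_log)
    base = tumor_trajectory(patient, t_months)
    ctdna = (base * math.exp(config.biological_noise_sigma_log
                             * rng.standard_normal())
             if base > 0 else 0.0)
    if t_months < 0:
        timing = "preop"
    elif (t_months <= min(2.0, config.adjuvant_start_months)
          if patient.adjuvant_treated else t_months <= 2.0):
        timing = "postop_window"
    else:
        timing = "surveillance"
    return CohortSample(
        sample_id=sample_id or f"{patient.patient_id}_t{t_months:+.2f}",
        patient_id=patient.patient_id,
        time_months=t_months,
        timing_class=timing,
        cfdna_ge_per_ml=cfdna,
        true_ctdna_ge_per_ml=ctdna,
        plasma_ml=config.plasma_ml,
    )


def _draw_schedule(patient: PatientProfile, cfg: CohortConfig) -> list[float]:
    times: list[float] = []
    if patient.has_preop_draw:
        times.append(cfg.preop_draw_time_months)
    if patient.has_postop_draw:
        times.append(cfg.postop_draw_time_months)
    if patient.has_serial_draws:
        # Surveillance starts after end of definitive therapy.
        start = (cfg.adjuvant_start_months + cfg.adjuvant_duration_months
                 if patient.adjuvant_treated
                 else cfg.surveillance_interval_months)
        end = (patient.recurrence_time_months if patient.recurrence
               else patient.followup_months)
        t = start
        n_drawn = 0
        while t < end and n_drawn < cfg.max_serial_draws:
            times.append(t)
            n_drawn += 1
            t += cfg.surveillance_interval_months
    return times


def simulate_cohort(config: CohortConfig, seed
                    ) -> tuple[list[PatientProfile], list[CohortSample]]:
    """Generate a full synthetic cohort (patients plus timed draws).

    A fixed seed reproduces the cohort exactly.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    patients: list[PatientProfile] = []
    samples: list[CohortSample] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        patient = _simulate_patient(pid, config, rng)
        patients.append(patient)
        for j, t in enumerate(_draw_schedule(patient, config)):
            samples.append(draw_sample(patient, t, config, rng,
                                       sample_id=f"{pid}_S{j:02d}"))
    return patients, samples
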