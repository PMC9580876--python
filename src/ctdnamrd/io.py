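"""Run configuration and CSV interchange.

All pipeline constants live in :class:`RunConfig` (loadable from YAML or
JSON, unknown keys rejected) and CSV is the interchange format for the
plate-export-style well tables, blank panels, multitarget molecule
tables and cohort manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .calling import CtdnaCall, NoiseProfile
from .cohort import CohortConfig, CohortSample, PatientProfile
from .ddpcr import DdpcrReaction
from .mt import MtSampleResult

__all__ = [
    "RunConfig",
    "read_reaction_table",
    "read_noise_profile_table",
    "read_mt_table",
    "write_calls_table",
    "read_calls_table",
    "patients_to_frame",
    "samples_to_frame",
]

log = logging.getLogger("ctdnamrd")


@dataclass
class RunConfig:
    """Every tunable constant of the pipeline, with protocol defaults."""

    # Shared plasma / DNA accounting
    plasma_ml: float = 8.0
    pg_per_ge: float = 3.3
    # ST ddPCR protocol volumes (µL).  The eluate is 60 µL of which
    # 54 µL are intended for ctDNA analysis (4 µL go to quantification;
    # the bookkeeping discrepancy is the protocol's own and both values
    # are exposed rather than reconciled).
    eluate_ul: float = 60.0
    analysis_ul: float = 54.0
    step1_ul: float = 18.0
    step2_ul: float = 36.0
    #: Fraction of samples analysed with the DNA-sparing two-step
    #: strategy (18 µL first, remainder only if negative); the study
    #: applied it to a subset (105/373), the rest got the full volume.
    two_step_fraction: float = 105 / 373
    eluate_ul_per_well: float = 9.0
    reaction_volume_ul: float = 20.0
    prepared_volume_ul: float = 22.0
    droplet_volume_nl: float = 0.834
    min_droplets: int = 8000
    threshold_sd_k: float = 3.0
    # ST noise / calling
    n_assays: int = 8
    fp_rate_per_ge: float = 1e-5
    n_blanks: int = 94
    blank_ge_median: float = 10000.0
    blank_ge_sigma_log: float = 0.5
    caller_alpha: float = 0.05
    lob_quantile: float = 0.95
    # MT panel
    n_targets: int = 16
    mt_cap_ge: float = 20000.0
    mt_background_rate_per_ge: float = 3e-6
    mt_detectability: float = 1.0
    per_target_alpha: float = 1e-3
    mt_min_targets: int = 2
    # Survival model
    cox_penalizer: float = 0.1
    # Cohort generator
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = _from_mapping(CohortConfig, self.cohort, "cohort")
        if not 0 < self.caller_alpha < 1:
            raise ValueError("caller_alpha must lie in (0, 1)")
        if not 0 < self.lob_quantile < 1:
            raise ValueError("lob_quantile must lie in (0, 1)")
        if not 0 < self.per_target_alpha < 1:
            raise ValueError("per_target_alpha must lie in (0, 1)")
        for name in ("plasma_ml", "eluate_ul", "step1_ul", "step2_ul",
                     "eluate_ul_per_well", "reaction_volume_ul",
                     "prepared_volume_ul", "droplet_volume_nl", "mt_cap_ge"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_blanks < 2:
            raise ValueError("n_blanks must be >= 2")
        if self.step1_ul + self.step2_ul > self.eluate_ul:
            raise ValueError("two-step volumes exceed the eluate")

    # -- (de)serialisation ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_mapping(cls, data, "run config")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _from_mapping(cls, data: dict, what: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**data)


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = ("sample_id", "assay_id", "role",
                     "n_droplets", "k_mutant", "k_wildtype")
_NOISE_COLUMNS = ("assay_id", "blank_id", "ge_screened", "fp_count")
_MT_COLUMNS = ("sample_id", "target_index", "mutant_molecules",
               "input_ge", "plasma_ml")
_CALL_COLUMNS = ("sample_id", "method", "positive", "level_ge_per_ml")


def _require_columns(df: pd.DataFrame, columns: Sequence[str],
                     path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")


def _int_column(df: pd.DataFrame, name: str, path: Path) -> pd.Series:
    col = pd.to_numeric(df[name], errors="coerce")
    if col.isna().any():
        row = int(df.index[col.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path} line {row}: non-numeric {name!r}")
    if not np.allclose(col, col.round()):
        row = int(df.index[~np.isclose(col, col.round())][0]) + 2
        raise ValueError(f"{path} line {row}: non-integer {name!r}")
    return col.astype(int)


def read_reaction_table(path: Union[str, Path]) -> list[DdpcrReaction]:
    """Read a QuantaSoft-style well-count CSV into validated reactions."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _REACTION_COLUMNS, path)
    for name in ("n_droplets", "k_mutant", "k_wildtype"):
        df[name] = _int_column(df, name, path)
    reactions = []
    for idx, row in df.iterrows():
        try:
            reactions.append(DdpcrReaction(
                assay_id=str(row["assay_id"]),
                n_droplets=int(row["n_droplets"]),
                k_mutant=int(row["k_mutant"]),
                k_wildtype=int(row["k_wildtype"]),
                role=str(row["role"]),
                sample_id=str(row["sample_id"]),
            ))
        except ValueError as exc:
            raise ValueError(f"{path} line {int(idx) + 2}: {exc}") from exc
    return reactions


def read_noise_profile_table(path: Union[str, Path]
                             ) -> dict[str, NoiseProfile]:
    """Read a blank-panel CSV into per-assay noise profiles."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _NOISE_COLUMNS, path)
    df["fp_count"] = _int_column(df, "fp_count", path)
    profiles = {}
    for assay_id, group in df.groupby("assay_id", sort=True):
        profiles[str(assay_id)] = NoiseProfile(
            assay_id=str(assay_id),
            blanks=tuple((float(ge), int(fp)) for ge, fp in
                         zip(group["ge_screened"], group["fp_count"])),
        )
    return profiles


def read_mt_table(path: Union[str, Path]) -> list[MtSampleResult]:
    """Read a per-target multitarget molecule-count CSV.

    Detection flags are not read back; they are recomputed by the
    caller from the molecule counts and the configured background.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _MT_COLUMNS, path)
    df["mutant_molecules"] = _int_column(df, "mutant_molecules", path)
    df["target_index"] = _int_column(df, "target_index", path)
    results = []
    for sample_id, group in df.groupby("sample_id", sort=True):
        group = group.sort_values("target_index")
        expected = np.arange(1, len(group) + 1)
        if not np.array_equal(group["target_index"].to_numpy(), expected):
            raise ValueError(
                f"{path}: sample {sample_id!r} target indices must run 1..n")
        results.append(MtSampleResult(
            sample_id=str(sample_id),
            input_ge=float(group["input_ge"].iloc[0]),
            per_target_mutant_molecules=group["mutant_molecules"].to_numpy(),
            per_target_detected=np.zeros(len(group), dtype=bool),
            plasma_ml=float(group["plasma_ml"].iloc[0]),
        ))
    return results


def write_calls_table(calls: Sequence[CtdnaCall],
                      path: Union[str, Path]) -> None:
    rows = []
    for call in calls:
        row = {
            "sample_id": call.sample_id,
            "method": call.method,
            "positive": call.positive,
            "level_ge_per_ml": call.level_ge_per_ml,
        }
        if call.votes:
            for caller, vote in call.votes.items():
                row[f"vote_{caller}"] = vote
        if call.p_values:
            for caller, p in call.p_values.items():
                row[f"p_{caller}"] = p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calls_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _CALL_COLUMNS, path)
    return df


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

def patients_to_frame(patients: Sequence[PatientProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": p.patient_id,
        "stage": p.stage,
        "recurrence": p.recurrence,
        "recurrence_time_months": p.recurrence_time_months,
        "followup_months": p.followup_months,
        "adjuvant_treated": p.adjuvant_treated,
        "preop_ctdna_ge_per_ml": p.preop_ctdna_ge_per_ml,
        "postop_residual_ge_per_ml": p.postop_residual_ge_per_ml,
        "doubling_time_months": p.doubling_time_months,
    } for p in patients])


def samples_to_frame(samples: Sequence[CohortSample]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": s.sample_id,
        "patient_id": s.patient_id,
        "time_months": s.time_months,
        "timing_class": s.timing_class,
        "cfdna_ge_per_ml": s.cfdna_ge_per_ml,
        "true_ctdna_ge_per_ml": s.true_ctdna_ge_per_ml,
        "plasma_ml": s.plasma_ml,
    } for s in samples])
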