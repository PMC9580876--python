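"""Multitarget (16-plex mPCR-NGS) ctDNA measurement model.

A tumour-informed multiplex panel tracks 16 patient-specific clonal
mutations in cfDNA from 8 mL plasma.  Library input is capped (66 ng of
cfDNA, ~20,000 genome equivalents), so in high-cfDNA samples only a
fraction of the extracted molecules can contribute.  Each target
samples its own mutant fragments independently — the source of the
multitarget strategy's resilience to sampling stochasticity.  The model
works at molecule level: per-target mutant molecule counts are Poisson
draws from the ctDNA concentration scaled by the input fraction and a
per-target recovery (sequencing reads are collapsed to the molecules
that generated them).

Calling: a target is detected when its molecule count clears a Poisson
confidence test against the per-target background; the sample is
positive when at least 2 of the 16 targets are detected.  The reported
level is the mean over all 16 targets of molecules per mL plasma,
including targets with zero molecules — which deliberately shrinks
level estimates in the sub-molecule regime where a single-target assay
can only ever report one-fragment quanta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .calling import CtdnaCall

__all__ = [
    "N_TARGETS",
    "MT_INPUT_CAP_GE",
    "MtPanel",
    "MtSampleResult",
    "simulate_mt_sample",
    "detect_target",
    "call_mt",
    "mt_level",
    "analytic_blank_positivity",
]

N_TARGETS = 16
MT_INPUT_CAP_GE = 20000.0


def _per_target(value: Union[float, Sequence[float]],
                n_targets: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), n_targets).copy()
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    return arr


@dataclass
class MtPanel:
    """Patient-specific 16-target panel parameters.

    ``background_rate_per_ge`` is the per-target false mutant-molecule
    rate per GE of input; ``detectability`` the fraction of tumour
    molecules at a target that survive library conversion and clear
    read-level filtering.
    """

    patient_id: str
    n_targets: int = N_TARGETS
    background_rate_per_ge: Union[float, Sequence[float]] = 3e-6
    detectability: Union[float, Sequence[float]] = 1.0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("panel needs >= 1 target")
        self.background_rate_per_ge = _per_target(
            self.background_rate_per_ge, self.n_targets, "background rate")
        det = _per_target(self.detectability, self.n_targets, "detectability")
        if np.any(det <= 0) or np.any(det > 1):
            raise ValueError("detectability must lie in (0, 1]")
        self.detectability = det


@dataclass
class MtSampleResult:
    """Per-target molecule counts and detection flags for one sample."""

    sample_id: str
    input_ge: float
    per_target_mutant_molecules: np.ndarray
    per_target_detected: np.ndarray
    plasma_ml: float = 8.0

    def __post_init__(self) -> None:
        self.per_target_mutant_molecules = np.asarray(
            self.per_target_mutant_molecules, dtype=int)
        self.per_target_detected = np.asarray(self.per_target_detected,
                                              dtype=bool)
        if (self.per_target_mutant_molecules.shape
                != self.per_target_detected.shape):
            raise ValueError("molecule and detection arrays must align")
        if np.any(self.per_target_mutant_molecules < 0):
            raise ValueError("molecule counts must be >= 0")
        if not self.plasma_ml > 0:
            raise ValueError("plasma_ml must be > 0")
        if self.input_ge < 0:
            raise ValueError("input_ge must be >= 0")

    @property
    def n_targets(self) -> int:
        return int(self.per_target_mutant_molecules.size)

    @property
    def n_detected(self) -> int:
        return int(self.per_target_detected.sum())


def detect_target(molecules: int, background_mean: float,
                  per_target_alpha: float = 1e-3) -> bool:
    """Per-target confidence test: Poisson tail against the background.

    Detected iff P(X >= molecules | Poisson(background_mean)) falls
    below ``per_target_alpha``.  Zero molecules never detect; with zero
    background a single molecule does.
    """
    if molecules < 0 or background_mean < 0:
        raise ValueError("molecules and background_mean must be >= 0")
    if molecules == 0:
        return False
    if background_mean == 0.0:
        return True
    p = float(stats.poisson.sf(molecules - 1, background_mean))
    return p < per_target_alpha


def simulate_mt_sample(ctdna_ge_per_ml: float,
                       cfdna_ge_per_ml: float,
                       panel: MtPanel,
                       seed=None,
                       plasma_ml: float = 8.0,
                       cap_ge: float = MT_INPUT_CAP_GE,
                       per_target_alpha: float = 1e-3,
                       sample_id: str = "") -> MtSampleResult:
    """Simulate one multitarget measurement.

    Extracted GE is ``cfdna_ge_per_ml * plasma_ml``; library input is
    capped at ``cap_ge``, so only ``input/extracted`` of the plasma's
    tumour molecules can enter each target's amplicon.  Per-target
    tumour molecules are Poisson with mean
    ``ctdna * plasma * input_fraction * detectability`` and background
    molecules add at ``background_rate * input_ge`` per target.
    """
    if ctdna_ge_per_ml < 0 or cfdna_ge_per_ml < 0:
        raise ValueError("concentrations must be >= 0")
    if not plasma_ml > 0:
        raise ValueError("plasma_ml must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    extracted = cfdna_ge_per_ml * plasma_ml
    input_ge = min(extracted, cap_ge)
    input_fraction = 1.0 if extracted == 0 else input_ge / extracted
    tumour_mean = (ctdna_ge_per_ml * plasma_ml * input_fraction
                   * panel.detectability)
    bg_mean = panel.background_rate_per_ge * input_ge
    molecules = rng.poisson(tumour_mean) + rng.poisson(bg_mean)
    detected = np.array([
        detect_target(int(m), float(b), per_target_alpha)
        for m, b in zip(molecules, bg_mean)
    ])
    return MtSampleResult(
        sample_id=sample_id,
        input_ge=input_ge,
        per_target_mutant_molecules=molecules,
        per_target_detected=detected,
        plasma_ml=plasma_ml,
    )


def mt_level(result: MtSampleResult) -> float:
    """Mean tumour molecules per mL plasma over all targets (zeros included)."""
    if not result.plasma_ml > 0:
        raise ValueError("plasma_ml must be > 0")
    per_target_per_ml = result.per_target_mutant_molecules / result.plasma_ml
    return float(per_target_per_ml.mean())


def call_mt(result: MtSampleResult, min_targets: int = 2,
            n_targets: int = N_TARGETS) -> CtdnaCall:
    """Sample-level MT call: positive iff >= ``min_targets`` detected."""
    if result.n_targets != n_targets:
        raise ValueError(
            f"expected a {n_targets}-target panel, got {result.n_targets}")
    return CtdnaCall(
        sample_id=result.sample_id,
        method="MT",
        positive=result.n_detected >= min_targets,
        level_ge_per_ml=mt_level(result),
    )


def analytic_blank_positivity(p_target: float,
                              n_targets: int = N_TARGETS) -> float:
    """Closed-form blank positivity of the >=2-of-n rule.

    With independent per-target false-detection probability ``p``, the
    sample-level false-positive rate is 1 - (1-p)^n - n p (1-p)^(n-1).
    """
    if not 0 <= p_target <= 1:
        raise ValueError("p_target must lie in [0, 1]")
    q = 1.0 - p_target
    return 1.0 - q ** n_targets - n_targets * p_target * q ** (n_targets - 1)
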