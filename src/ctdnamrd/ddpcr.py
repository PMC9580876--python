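"""Droplet digital PCR partition model.

A ddPCR reaction partitions a ~20 µL PCR mix into ~17,000 droplets of
~0.834 nL each.  Template molecules distribute across droplets
approximately independently, so the number of copies per droplet is
Poisson distributed and the target concentration can be recovered from
the fraction of droplets that light up:

    lambda = -ln(1 - k/n),   copies/µL = lambda / v_droplet

where ``k`` is the number of positive droplets, ``n`` the total droplet
count and ``v_droplet`` the droplet volume.  This module provides the
domain types for assays, single wells and merged (sample-level) results,
the threshold/classification/QC steps applied to raw droplet
amplitudes, the Poisson concentration math, and a seeded well simulator
used by the cohort generator and by the test-suite oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DROPLET_VOLUME_NL",
    "MEAN_DROPLETS_PER_WELL",
    "SD_DROPLETS_PER_WELL",
    "MIN_DROPLETS_PER_WELL",
    "PG_PER_HAPLOID_GE",
    "AmplitudeCluster",
    "DdpcrAssay",
    "DdpcrReaction",
    "MergedSample",
    "PartitionEstimate",
    "QcVerdict",
    "set_amplitude_threshold",
    "classify_droplets",
    "lambda_from_counts",
    "concentration_from_lambda",
    "partition_estimate",
    "qc_reaction",
    "merge_reactions",
    "mutant_per_ml",
    "simulate_reaction",
]

# Protocol constants (Bio-Rad QX200-style workflow).
DROPLET_VOLUME_NL: float = 0.834
MEAN_DROPLETS_PER_WELL: float = 16948.0
SD_DROPLETS_PER_WELL: float = 1852.0
MIN_DROPLETS_PER_WELL: int = 8000
#: Mass of one haploid genome equivalent; 66 ng of cfDNA is ~20,000 GE.
PG_PER_HAPLOID_GE: float = 3.3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplitudeCluster:
    """Gaussian fluorescence-amplitude cluster (arbitrary units)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("amplitude cluster SD must be > 0")


@dataclass(frozen=True)
class DdpcrAssay:
    """One mutation-specific ddPCR assay.

    ``threshold_sd_k`` is the assay-specific number of standard
    deviations below the positive-control positive-cluster mean at which
    the positivity threshold is placed.  ``fp_rate_per_ge`` is the
    simulator's ground-truth chemistry noise: expected false-positive
    mutant events per wild-type genome equivalent screened.
    """

    assay_id: str
    target_label: str
    threshold_sd_k: float = 3.0
    empty_cluster: AmplitudeCluster = AmplitudeCluster(1000.0, 120.0)
    wildtype_cluster: AmplitudeCluster = AmplitudeCluster(3000.0, 200.0)
    mutant_cluster: AmplitudeCluster = AmplitudeCluster(10000.0, 500.0)
    fp_rate_per_ge: float = 1e-5

    def __post_init__(self) -> None:
        if not self.threshold_sd_k > 0:
            raise ValueError("threshold_sd_k must be > 0")
        if self.fp_rate_per_ge < 0:
            raise ValueError("fp_rate_per_ge must be >= 0")
        if not (self.empty_cluster.mean < self.wildtype_cluster.mean
                and self.empty_cluster.mean < self.mutant_cluster.mean):
            raise ValueError("empty cluster must sit below positive clusters")


#: Allowed well roles.
_ROLES = ("sample", "NTC", "positive_control", "negative_control")


@dataclass
class DdpcrReaction:
    """Droplet counts (and optionally per-droplet amplitudes) for one well."""

    assay_id: str
    n_droplets: int
    k_mutant: int
    k_wildtype: int
    role: str = "sample"
    amplitudes: Optional[np.ndarray] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")
        if not 0 <= self.k_mutant <= self.n_droplets:
            raise ValueError("k_mutant must satisfy 0 <= k <= n_droplets")
        if not 0 <= self.k_wildtype <= self.n_droplets:
            raise ValueError("k_wildtype must satisfy 0 <= k <= n_droplets")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.size != self.n_droplets:
                raise ValueError("amplitude count must equal n_droplets")


@dataclass
class MergedSample:
    """Sample-level totals over all QC-passing wells of one assay."""

    sample_id: str
    assay_id: str
    n_droplets_total: int
    k_mutant_total: int
    k_wildtype_total: int
    ge_screened: float
    plasma_ml: float = 8.0
    fraction_eluate_analyzed: float = 1.0

    def __post_init__(self) -> None:
        if not self.plasma_ml > 0:
            raise ValueError("plasma_ml must be > 0")
        if not 0 < self.fraction_eluate_analyzed <= 1:
            raise ValueError("fraction_eluate_analyzed must be in (0, 1]")
        if self.ge_screened < 0:
            raise ValueError("ge_screened must be >= 0")


@dataclass(frozen=True)
class PartitionEstimate:
    """Poisson partition estimate for one channel of one well or sample."""

    lambda_per_droplet: float
    copies_per_ul: float
    copies_total: float


@dataclass(frozen=True)
class QcVerdict:
    """Per-rule QC flags for one well; the verdict is their conjunction."""

    ntc_clean: bool
    positive_control_ok: bool
    droplet_count_ok: bool
    amplitudes_ok: bool

    @property
    def passed(self) -> bool:
        return (self.ntc_clean and self.positive_control_ok
                and self.droplet_count_ok and self.amplitudes_ok)


# ---------------------------------------------------------------------------
# Thresholding and classification
# ---------------------------------------------------------------------------

def set_amplitude_threshold(positive_control: DdpcrReaction,
                            k_sd: float) -> float:
    """Place the positivity threshold from a positive-control well.

    The positive cluster is identified from the control's own amplitude
    structure (droplets above the midpoint of the amplitude range) and
    the threshold is set ``k_sd`` standard deviations below that
    cluster's mean amplitude.
    """
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    amps = positive_control.amplitudes
    if amps is None or amps.size == 0:
        raise ValueError("uninformative positive control: no amplitudes")
    lo, hi = float(np.min(amps)), float(np.max(amps))
    midpoint = 0.5 * (lo + hi)
    positive = amps[amps > midpoint]
    negative = amps[amps <= midpoint]
    if positive.size == 0 or negative.size == 0:
        raise ValueError("uninformative positive control: no positive cluster")
    # A usable control is bimodal: the cloud above the range midpoint must
    # stand well clear of the cloud below it.
    separation = float(np.mean(positive) - np.mean(negative))
    spread = math.hypot(float(np.std(positive)), float(np.std(negative)))
    if spread > 0 and separation < 3.0 * spread:
        raise ValueError("uninformative positive control: no positive cluster")
    mean = float(np.mean(positive))
    sd = float(np.std(positive, ddof=0))
    return mean - k_sd * sd


def classify_droplets(amplitudes: Sequence[float],
                      threshold: float) -> tuple[int, int]:
    """Count droplets at/above vs below an amplitude threshold."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size == 0:
        return (0, 0)
    k_above = int(np.count_nonzero(amps >= threshold))
    return k_above, int(amps.size - k_above)


# ---------------------------------------------------------------------------
# Poisson partition math
# ---------------------------------------------------------------------------

def lambda_from_counts(k: int, n: int) -> float:
    """Mean copies per droplet from positive-droplet counts."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if k == n:
        raise ValueError("saturated well: k == n gives unbounded lambda")
    if k == 0:
        return 0.0
    return -math.log1p(-k / n)


def concentration_from_lambda(lam: float,
                              droplet_volume_nl: float = DROPLET_VOLUME_NL
                              ) -> float:
    """Copies per µL from mean copies per droplet (volume in nL)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not droplet_volume_nl > 0:
        raise ValueError("droplet volume must be > 0")
    return lam / droplet_volume_nl * 1000.0  # copies/nL -> copies/µL


def partition_estimate(k: int, n: int,
                       droplet_volume_nl: float = DROPLET_VOLUME_NL
                       ) -> PartitionEstimate:
    """Full partition estimate (per droplet, per µL, and total copies)."""
    lam = lambda_from_counts(k, n)
    return PartitionEstimate(
        lambda_per_droplet=lam,
        copies_per_ul=concentration_from_lambda(lam, droplet_volume_nl),
        copies_total=lam * n,
    )


# ---------------------------------------------------------------------------
# QC and merging
# ---------------------------------------------------------------------------

def qc_reaction(reaction: DdpcrReaction,
                ntc: DdpcrReaction,
                pos_ctrl: DdpcrReaction,
                amplitude_bounds: Optional[tuple[float, float]] = None,
                min_droplets: int = MIN_DROPLETS_PER_WELL) -> QcVerdict:
    """Apply the four well-level QC rules.

    Pass requires: no mutant signal in the no-template control, signal in
    the positive control, at least ``min_droplets`` droplets in the well,
    and (when both bounds and amplitudes are available) all droplet
    amplitudes inside the expected interval.
    """
    if not (reaction.assay_id == ntc.assay_id == pos_ctrl.assay_id):
        raise ValueError("QC controls must come from the same assay")
    amplitudes_ok = True
    if amplitude_bounds is not None and reaction.amplitudes is not None:
        lo, hi = amplitude_bounds
        amplitudes_ok = bool(np.all((reaction.amplitudes >= lo)
                                    & (reaction.amplitudes <= hi)))
    return QcVerdict(
        ntc_clean=ntc.k_mutant == 0,
        positive_control_ok=pos_ctrl.k_mutant > 0,
        droplet_count_ok=reaction.n_droplets >= min_droplets,
        amplitudes_ok=amplitudes_ok,
    )


def merge_reactions(reactions: Sequence[DdpcrReaction],
                    sample_id: str,
                    plasma_ml: float = 8.0,
                    fraction_eluate_analyzed: float = 1.0) -> MergedSample:
    """Merge QC-passing wells of one sample/assay into sample-level totals.

    ``ge_screened`` (wild-type genome equivalents actually analysed) is
    recovered from the pooled wild-type channel by partition math: one
    haploid GE carries one copy of the wild-type locus, so the total
    wild-type copies in the analysed droplets equal the GE screened.
    """
    if len(reactions) == 0:
        raise ValueError("cannot merge an empty reaction list")
    assay_ids = {r.assay_id for r in reactions}
    if len(assay_ids) > 1:
        raise ValueError(f"cannot merge mixed assays: {sorted(assay_ids)}")
    n_total = sum(r.n_droplets for r in reactions)
    k_mut = sum(r.k_mutant for r in reactions)
    k_wt = sum(r.k_wildtype for r in reactions)
    if k_wt >= n_total:
        raise ValueError("saturated wild-type channel after merging")
    lam_wt = lambda_from_counts(k_wt, n_total)
    return MergedSample(
        sample_id=sample_id,
        assay_id=assay_ids.pop(),
        n_droplets_total=n_total,
        k_mutant_total=k_mut,
        k_wildtype_total=k_wt,
        ge_screened=lam_wt * n_total,
        plasma_ml=plasma_ml,
        fraction_eluate_analyzed=fraction_eluate_analyzed,
    )


def mutant_per_ml(corrected_copies: float,
                  plasma_ml: float = 8.0,
                  fraction_eluate_analyzed: float = 1.0) -> float:
    """Mutant genome equivalents per mL plasma.

    Divides the (error-corrected) mutant copy count by the plasma volume
    the analysed DNA represents.  Over-subtracted counts clamp at zero.
    """
    if not plasma_ml > 0:
        raise ValueError("plasma_ml must be > 0")
    if not 0 < fraction_eluate_analyzed <= 1:
        raise ValueError("fraction_eluate_analyzed must be in (0, 1]")
    return max(0.0, corrected_copies) / (plasma_ml * fraction_eluate_analyzed)


# ---------------------------------------------------------------------------
# Well simulator
# ---------------------------------------------------------------------------

def _occupied(rng: np.random.Generator, n_molecules: int,
              n_droplets: int) -> np.ndarray:
    """Droplet indices receiving >=1 molecule under uniform assignment."""
    if n_molecules == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(rng.integers(0, n_droplets, size=n_molecules))


def simulate_reaction(mutant_copies_per_ul: float,
                      wt_copies_per_ul: float,
                      assay: DdpcrAssay,
                      seed=None,
                      reaction_volume_ul: float = 20.0,
                      n_droplets: Optional[int] = None,
                      role: str = "sample",
                      sample_id: str = "",
                      with_amplitudes: bool = False) -> DdpcrReaction:
    """Simulate one ddPCR well.

    Molecule totals are Poisson draws from concentration x dropletised
    volume; molecules are assigned to droplets uniformly (multinomial
    occupancy); false-positive mutant events arise at the assay's
    ``fp_rate_per_ge`` per wild-type GE screened.  ``seed`` may be an int
    or a ``numpy.random.Generator``; the same seed reproduces the well
    exactly.
    """
    if mutant_copies_per_ul < 0 or wt_copies_per_ul < 0:
        raise ValueError("concentrations must be >= 0")
    if not reaction_volume_ul > 0:
        raise ValueError("reaction volume must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if n_droplets is None:
        n_droplets = int(round(rng.normal(MEAN_DROPLETS_PER_WELL,
                                          SD_DROPLETS_PER_WELL)))
        n_droplets = max(n_droplets, 1000)
    m_mut = int(rng.poisson(mutant_copies_per_ul * reaction_volume_ul))
    m_wt = int(rng.poisson(wt_copies_per_ul * reaction_volume_ul))
    wt_idx = _occupied(rng, m_wt, n_droplets)
    mut_idx = _occupied(rng, m_mut, n_droplets)
    # Chemistry noise: false mutant-channel events per wild-type GE.
    n_fp = int(rng.poisson(assay.fp_rate_per_ge * m_wt))
    if n_fp:
        fp_idx = rng.integers(0, n_droplets, size=n_fp)
        mut_idx = np.unique(np.concatenate([mut_idx, fp_idx]))
    amplitudes = None
    if with_amplitudes:
        # Mutant-channel view: mutant-positive droplets fluoresce high,
        # everything else sits in the empty cloud.
        amplitudes = rng.normal(assay.empty_cluster.mean,
                                assay.empty_cluster.sd, size=n_droplets)
        if mut_idx.size:
            amplitudes[mut_idx] = rng.normal(assay.mutant_cluster.mean,
                                             assay.mutant_cluster.sd,
                                             size=mut_idx.size)
    return DdpcrReaction(
        assay_id=assay.assay_id,
        n_droplets=n_droplets,
        k_mutant=int(mut_idx.size),
        k_wildtype=int(wt_idx.size),
        role=role,
        amplitudes=amplitudes,
        sample_id=sample_id,
    )
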