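"""Blank-derived noise profiles and consensus ddPCR ctDNA calling.

Positive droplets appear in mutation assays even on tumour-free DNA
(polymerase errors, deamination).  Each assay therefore carries a noise
profile: false-positive counts measured on a panel of blank
(buffy-coat) DNA samples at a range of DNA inputs.  Four callers
compare a plasma sample against that profile:

* ``poisson`` — pooled blank rate, Poisson tail test;
* ``dynamic_lob`` — empirical limit of blank scaled to the sample's
  DNA input;
* ``castle`` — negative-binomial noise regression with DNA input as
  exposure, plus an error-corrected mutant-copy estimate;
* ``alpaca`` — beta-binomial test on the mutant droplet fraction with
  moments matched to the blank fractions.

A sample is called positive when at least three of the four agree; on a
2-2 split the castle call decides, and the reported ctDNA level is
always the castle error-corrected molecule count per mL plasma.  The
caller internals stand in for the published algorithms of the same
names: they keep each method's documented character (error-model vs
limit-of-blank vs Poisson) and the shared interface, not the original
code paths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .ddpcr import MergedSample, mutant_per_ml

__all__ = [
    "CALLERS",
    "NoiseProfile",
    "CallerResult",
    "CtdnaCall",
    "build_noise_profile",
    "call_poisson",
    "call_dynamic_lob",
    "call_castle",
    "call_alpaca",
    "consensus_call",
    "call_sample",
    "two_step_call",
]

CALLERS = ("CASTLE", "Poisson", "ALPACA", "DynamicLOB")

#: Blank panel size used throughout (94 fractionated buffy-coat samples).
DEFAULT_N_BLANKS = 94


@dataclass(frozen=True)
class NoiseProfile:
    """Per-assay blank panel: (GE screened, false-positive count) pairs."""

    assay_id: str
    blanks: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if len(self.blanks) < 2:
            raise ValueError("profile underdetermined: need >= 2 blanks")
        for ge, fp in self.blanks:
            if not ge > 0:
                raise ValueError("blank ge_screened must be > 0")
            if fp < 0:
                raise ValueError("blank fp_count must be >= 0")

    @property
    def n_blanks(self) -> int:
        return len(self.blanks)

    @property
    def ge(self) -> np.ndarray:
        return np.array([b[0] for b in self.blanks], dtype=float)

    @property
    def fp(self) -> np.ndarray:
        return np.array([b[1] for b in self.blanks], dtype=float)

    @property
    def pooled_rate(self) -> float:
        """Pooled false-positive rate per GE screened."""
        return float(self.fp.sum() / self.ge.sum())


@dataclass(frozen=True)
class CallerResult:
    caller: str
    positive: bool
    p_value: Optional[float]
    expected_noise_copies: float
    corrected_copies: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")
        if self.corrected_copies is not None and self.corrected_copies < 0:
            raise ValueError("corrected_copies must be >= 0")


@dataclass
class CtdnaCall:
    """Unified sample-level call shared by the ST and MT routes."""

    sample_id: str
    method: str  # "ST" or "MT"
    positive: bool
    level_ge_per_ml: float
    votes: Optional[dict[str, bool]] = None
    p_values: Optional[dict[str, Optional[float]]] = None

    def __post_init__(self) -> None:
        if self.method not in ("ST", "MT"):
            raise ValueError("method must be 'ST' or 'MT'")
        if self.level_ge_per_ml < 0:
            raise ValueError("level must be >= 0")


def build_noise_profile(blank_samples: Sequence[MergedSample]) -> NoiseProfile:
    """Assemble a noise profile from blank-panel merged samples, verbatim."""
    if len(blank_samples) < 2:
        raise ValueError("profile underdetermined: need >= 2 blanks")
    assay_ids = {b.assay_id for b in blank_samples}
    if len(assay_ids) > 1:
        raise ValueError("blanks from mixed assays")
    return NoiseProfile(
        assay_id=assay_ids.pop(),
        blanks=tuple((float(b.ge_screened), int(b.k_mutant_total))
                     for b in blank_samples),
    )


# ---------------------------------------------------------------------------
# Individual callers
# ---------------------------------------------------------------------------

def _poisson_tail(k: int, mu: float) -> float:
    """P(X >= k) for X ~ Poisson(mu); 1 when k == 0."""
    if k <= 0:
        return 1.0
    if mu == 0.0:
        return 0.0
    return float(stats.poisson.sf(k - 1, mu))


def call_poisson(sample: MergedSample, profile: NoiseProfile,
                 alpha: float = 0.05) -> CallerResult:
    """Poisson tail test against the pooled blank false-positive rate."""
    if not sample.ge_screened > 0:
        raise ValueError("sample has no DNA screened")
    mu = profile.pooled_rate * sample.ge_screened
    p = _poisson_tail(sample.k_mutant_total, mu)
    return CallerResult("Poisson", positive=p < alpha, p_value=p,
                        expected_noise_copies=mu)


def call_dynamic_lob(sample: MergedSample, profile: NoiseProfile,
                     quantile: float = 0.95) -> CallerResult:
    """Limit-of-blank caller with the LOB rescaled to the sample's input.

    Each blank count is scaled by the ratio of the sample's GE screened
    to the blank's, the LOB is the empirical ``quantile`` of the scaled
    counts, and the sample is positive only if its mutant count strictly
    exceeds the LOB (an exactly-LOB count stays negative).
    """
    if not sample.ge_screened > 0:
        raise ValueError("sample has no DNA screened")
    scaled = profile.fp * (sample.ge_screened / profile.ge)
    lob = float(np.quantile(scaled, quantile, method="higher"))
    return CallerResult("DynamicLOB",
                        positive=sample.k_mutant_total > lob,
                        p_value=None,
                        expected_noise_copies=lob)


# castle/alpaca fit caching: profiles are frozen/hashable and each cohort
# reuses a handful of them across hundreds of samples, so the per-profile
# model fit is memoised.
_castle_cache: dict[NoiseProfile, tuple[float, float, str]] = {}
_alpaca_cache: dict[NoiseProfile, tuple[float, float, float, str]] = {}


def _fit_castle(profile: NoiseProfile) -> tuple[float, float, str]:
    """Fit the noise model behind the castle caller.

    Returns ``(rate_per_ge, nb_alpha, note)``: a negative-binomial
    regression of blank counts on a constant with log(GE) exposure.
    When the dispersion is unidentifiable (e.g. all-zero or equidispersed
    blanks) the model degrades to Poisson (``nb_alpha == 0``).
    """
    if profile in _castle_cache:
        return _castle_cache[profile]
    rate, nb_alpha, note = profile.pooled_rate, 0.0, ""
    if profile.fp.sum() > 0:
        try:
            import statsmodels.api as sm
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.NegativeBinomial(
                    profile.fp, np.ones((profile.n_blanks, 1)),
                    offset=np.log(profile.ge))
                res = model.fit(disp=0, maxiter=200)
            fitted_rate = float(np.exp(res.params[0]))
            fitted_alpha = float(res.params[1])
            if (np.isfinite(fitted_rate) and np.isfinite(fitted_alpha)
                    and fitted_rate > 0):
                rate = fitted_rate
                nb_alpha = max(0.0, fitted_alpha)
            else:
                note = "castle fit degenerate; Poisson fallback"
        except Exception:
            note = "castle fit failed; Poisson fallback"
    _castle_cache[profile] = (rate, nb_alpha, note)
    return rate, nb_alpha, note


def call_castle(sample: MergedSample, profile: NoiseProfile,
                alpha: float = 0.05) -> CallerResult:
    """Negative-binomial noise-regression caller with error correction.

    The expected noise count scales with the sample's GE screened; the
    tail probability uses the fitted dispersion, and the error-corrected
    mutant copy number is ``max(0, k - expected_noise)``.
    """
    if not sample.ge_screened > 0:
        raise ValueError("sample has no DNA screened")
    rate, nb_alpha, note = _fit_castle(profile)
    mu = rate * sample.ge_screened
    k = sample.k_mutant_total
    if k == 0:
        p = 1.0
    elif mu == 0.0:
        p = 0.0
    elif nb_alpha > 1e-8:
        r = 1.0 / nb_alpha
        p = float(stats.nbinom.sf(k - 1, r, r / (r + mu)))
    else:
        p = _poisson_tail(k, mu)
    return CallerResult("CASTLE", positive=p < alpha, p_value=p,
                        expected_noise_copies=mu,
                        corrected_copies=max(0.0, k - mu), note=note)


def _fit_alpaca(profile: NoiseProfile) -> tuple[float, float, float, str]:
    """Method-of-moments beta parameters for blank mutant fractions.

    Returns ``(mean_fraction, a, b, note)``; ``a == b == 0`` marks the
    binomial degenerate case (blank fractions with no excess variance).
    """
    if profile in _alpaca_cache:
        return _alpaca_cache[profile]
    fractions = profile.fp / profile.ge
    m = float(fractions.mean())
    v = float(fractions.var(ddof=1))
    a = b = 0.0
    note = ""
    if m <= 0:
        note = "all-zero blanks; binomial reduction"
    elif v <= 0 or v >= m * (1 - m):
        note = "blank fractions under/over beta bounds; binomial reduction"
    else:
        common = m * (1 - m) / v - 1.0
        a, b = m * common, (1 - m) * common
        if not (a > 0 and b > 0):
            a = b = 0.0
            note = "degenerate moments; binomial reduction"
    _alpaca_cache[profile] = (m, a, b, note)
    return m, a, b, note


def call_alpaca(sample: MergedSample, profile: NoiseProfile,
                alpha: float = 0.05) -> CallerResult:
    """Beta-binomial caller on the mutant droplet fraction."""
    n_total = sample.k_mutant_total + sample.k_wildtype_total
    k = sample.k_mutant_total
    if n_total == 0:
        return CallerResult("ALPACA", positive=False, p_value=1.0,
                            expected_noise_copies=0.0,
                            note="no positive droplets in either channel")
    m, a, b, note = _fit_alpaca(profile)
    if k == 0:
        p = 1.0
    elif a > 0 and b > 0:
        p = float(stats.betabinom.sf(k - 1, n_total, a, b))
    elif m <= 0:
        p = 0.0  # zero-noise binomial limit
    else:
        p = float(stats.binom.sf(k - 1, n_total, m))
    return CallerResult("ALPACA", positive=p < alpha, p_value=p,
                        expected_noise_copies=m * n_total, note=note)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_call(results: Sequence[CallerResult],
                   sample: MergedSample) -> CtdnaCall:
    """Combine the four caller votes into the sample-level ST call.

    >=3/4 agreement decides; a 2-2 split defers to the castle call.  The
    reported level is always the castle error-corrected molecule count
    converted to GE per mL plasma.
    """
    by_name = {r.caller: r for r in results}
    missing = [c for c in CALLERS if c not in by_name]
    if missing or len(results) != 4:
        raise ValueError(f"need exactly one result per caller; missing {missing}")
    castle = by_name["CASTLE"]
    n_pos = sum(r.positive for r in by_name.values())
    positive = castle.positive if n_pos == 2 else n_pos >= 3
    corrected = castle.corrected_copies or 0.0
    level = mutant_per_ml(corrected, sample.plasma_ml,
                          sample.fraction_eluate_analyzed)
    return CtdnaCall(
        sample_id=sample.sample_id,
        method="ST",
        positive=positive,
        level_ge_per_ml=level,
        votes={c: by_name[c].positive for c in CALLERS},
        p_values={c: by_name[c].p_value for c in CALLERS},
    )


def call_sample(sample: MergedSample, profile: NoiseProfile,
                alpha: float = 0.05,
                lob_quantile: float = 0.95) -> CtdnaCall:
    """Run all four callers on a merged sample and take the consensus."""
    results = [
        call_castle(sample, profile, alpha),
        call_poisson(sample, profile, alpha),
        call_alpaca(sample, profile, alpha),
        call_dynamic_lob(sample, profile, lob_quantile),
    ]
    return consensus_call(results, sample)


def two_step_call(step1: MergedSample,
                  full_builder: Callable[[], MergedSample],
                  profile: NoiseProfile,
                  alpha: float = 0.05,
                  lob_quantile: float = 0.95) -> CtdnaCall:
    """DNA-sparing two-step eluate strategy.

    A first slice of the eluate is analysed; samples testing positive
    are not analysed further, while negatives have the remaining eluate
    analysed and all wells merged (``full_builder`` supplies the merged
    full-eluate sample).  The returned call's underlying sample carries
    the eluate fraction actually consumed.
    """
    first = call_sample(step1, profile, alpha, lob_quantile)
    if first.positive:
        return first
    return call_sample(full_builder(), profile, alpha, lob_quantile)
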