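"""Concordance, specificity, lead-time and survival statistics.

The head-to-head comparison of two binary ctDNA assays reduces to a
small set of canonical statistics: Cohen's kappa and raw agreement on
the paired 2x2 call table, Wilson score intervals for detection
fractions, Fisher's exact test for unpaired binary splits, Wilcoxon
rank-sum / signed-rank tests for level and fraction comparisons, a
log-log linear regression (with Pearson's r) of the two level
estimates, sample- and patient-level specificity on non-recurrence
serial draws, lead times from first ctDNA detection to radiological
recurrence, and a Cox proportional-hazards model with ctDNA status as
a time-dependent covariate (start-stop episodes, Efron ties).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConcordanceTable",
    "SerialRecord",
    "LeadTimeResult",
    "cohens_kappa",
    "agreement_fraction",
    "wilson_interval",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "pearson_loglog",
    "sample_specificity",
    "patient_specificity",
    "lead_times",
    "cox_time_dependent",
    "DAYS_PER_MONTH",
]

#: Mean Gregorian month length, used for day/month conversions.
DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class ConcordanceTable:
    """Paired 2x2 call table for two methods on the same samples."""

    n_both_pos: int
    n_mt_only: int
    n_st_only: int
    n_both_neg: int

    def __post_init__(self) -> None:
        if min(self.n_both_pos, self.n_mt_only,
               self.n_st_only, self.n_both_neg) < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def total(self) -> int:
        return (self.n_both_pos + self.n_mt_only
                + self.n_st_only + self.n_both_neg)

    @classmethod
    def from_calls(cls, st_positive: Sequence[bool],
                   mt_positive: Sequence[bool]) -> "ConcordanceTable":
        st = np.asarray(st_positive, dtype=bool)
        mt = np.asarray(mt_positive, dtype=bool)
        if st.shape != mt.shape:
            raise ValueError("call vectors must align")
        return cls(
            n_both_pos=int(np.sum(st & mt)),
            n_mt_only=int(np.sum(~st & mt)),
            n_st_only=int(np.sum(st & ~mt)),
            n_both_neg=int(np.sum(~st & ~mt)),
        )


@dataclass(frozen=True)
class SerialRecord:
    """Post-definitive-treatment serial calls for one patient."""

    patient_id: str
    times_months: tuple[float, ...]
    st_positive: tuple[bool, ...]
    mt_positive: tuple[bool, ...]
    recurrence_time_months: Optional[float]
    followup_months: float

    def __post_init__(self) -> None:
        if not (len(self.times_months) == len(self.st_positive)
                == len(self.mt_positive)):
            raise ValueError("serial vectors must align")
        if any(b >= a for a, b in zip(self.times_months[1:],
                                      self.times_months)):
            raise ValueError("times must be strictly increasing")

    def flags(self, method: str) -> tuple[bool, ...]:
        if method == "ST":
            return self.st_positive
        if method == "MT":
            return self.mt_positive
        raise ValueError("method must be 'ST' or 'MT'")

    def first_positive_time(self, method: str) -> Optional[float]:
        for t, flag in zip(self.times_months, self.flags(method)):
            if flag:
                return t
        return None


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def cohens_kappa(table: ConcordanceTable) -> float:
    """Chance-corrected agreement on the paired 2x2 table."""
    n = table.total
    if n == 0:
        raise ValueError("empty table")
    a, b, c, d = (table.n_both_pos, table.n_mt_only,
                  table.n_st_only, table.n_both_neg)
    po = (a + d) / n
    pe = ((a + c) * (a + b) + (b + d) * (c + d)) / n ** 2
    if pe == 1.0:
        raise ValueError("degenerate margins: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def agreement_fraction(table: ConcordanceTable) -> float:
    """Raw fraction of samples on which both methods agree."""
    if table.total == 0:
        raise ValueError("empty table")
    return (table.n_both_pos + table.n_both_neg) / table.total


def wilson_interval(k: int, n: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    # boundary cases are exact: the score interval is one-sided there
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return float(lo), float(hi)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p (sum of point probabilities <= observed)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a nonnegative 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def wilcoxon_rank_sum(x: Sequence[float],
                      y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null for small tie-free samples, normal approximation with
    midranks and tie correction otherwise.  Returns (U statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    if math.isnan(p):  # fully tied data: no evidence either way
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]
                         ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; if every difference is zero the test
    carries no information and (0, 1) is returned with a warning.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("need a nonempty sequence of pairs")
    d = arr[:, 0] - arr[:, 1]
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def pearson_loglog(st_levels: Sequence[float], mt_levels: Sequence[float]
                   ) -> tuple[float, float, float]:
    """Least-squares fit of log10(MT level) on log10(ST level).

    Only defined for both-positive samples: any nonpositive level is a
    filter violation.  Returns (slope, intercept, Pearson r).
    """
    x = np.asarray(st_levels, dtype=float)
    y = np.asarray(mt_levels, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 aligned level pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("both-positive filter violated: nonpositive level")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        raise ValueError("degenerate levels: zero variance on log scale")
    res = sps.linregress(lx, ly)
    return float(res.slope), float(res.intercept), float(res.rvalue)


# ---------------------------------------------------------------------------
# Specificity on serial samples
# ---------------------------------------------------------------------------

def _check_nonrecurrence(records: Sequence[SerialRecord]) -> None:
    if any(r.recurrence_time_months is not None for r in records):
        raise ValueError("specificity is defined on non-recurrence patients")


def sample_specificity(records: Sequence[SerialRecord], method: str) -> float:
    """1 - (positive serial samples / total serial samples)."""
    _check_nonrecurrence(records)
    total = sum(len(r.times_months) for r in records)
    if total == 0:
        raise ValueError("no serial samples")
    positives = sum(sum(r.flags(method)) for r in records)
    return 1.0 - positives / total


def patient_specificity(records: Sequence[SerialRecord], method: str) -> float:
    """Fraction of patients with no positive serial sample at all."""
    _check_nonrecurrence(records)
    if len(records) == 0:
        raise ValueError("no patients")
    clean = sum(1 for r in records if not any(r.flags(method)))
    return clean / len(records)


# ---------------------------------------------------------------------------
# Lead times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeadTimeResult:
    patient_ids: tuple[str, ...]
    st_lead_months: tuple[float, ...]
    mt_lead_months: tuple[float, ...]
    excluded_patient_ids: tuple[str, ...]

    @property
    def median_st(self) -> float:
        return float(np.median(self.st_lead_months))

    @property
    def median_mt(self) -> float:
        return float(np.median(self.mt_lead_months))

    @property
    def p_st_vs_zero(self) -> float:
        return wilcoxon_signed_rank([(l, 0.0) for l in self.st_lead_months])[1]

    @property
    def p_mt_vs_zero(self) -> float:
        return wilcoxon_signed_rank([(l, 0.0) for l in self.mt_lead_months])[1]

    @property
    def p_paired(self) -> float:
        """Paired test on first-detection times (ST vs MT)."""
        return wilcoxon_signed_rank(list(zip(self.st_lead_months,
                                             self.mt_lead_months)))[1]


def lead_times(records: Sequence[SerialRecord]) -> LeadTimeResult:
    """Lead from first ctDNA detection to radiological recurrence.

    Restricted to recurrence patients detected by both methods; patients
    lacking a positive sample for either method are excluded and
    reported.  Lead = recurrence time - first positive sample time.
    """
    ids, st_leads, mt_leads, excluded = [], [], [], []
    for rec in records:
        if rec.recurrence_time_months is None:
            continue
        t_st = rec.first_positive_time("ST")
        t_mt = rec.first_positive_time("MT")
        if t_st is None or t_mt is None:
            excluded.append(rec.patient_id)
            continue
        ids.append(rec.patient_id)
        st_leads.append(rec.recurrence_time_months - t_st)
        mt_leads.append(rec.recurrence_time_months - t_mt)
    if not ids:
        raise ValueError("no recurrence patients detected by both methods")
    return LeadTimeResult(tuple(ids), tuple(st_leads), tuple(mt_leads),
                          tuple(excluded))


# ---------------------------------------------------------------------------
# Time-dependent Cox regression
# ---------------------------------------------------------------------------

def serial_records_to_episodes(records: Sequence[SerialRecord],
                               method: str) -> pd.DataFrame:
    """Start-stop episode table with ctDNA switching 0 -> 1 at detection."""
    rows = []
    for rec in records:
        end = (rec.recurrence_time_months
               if rec.recurrence_time_months is not None
               else rec.followup_months)
        event = rec.recurrence_time_months is not None
        if end <= 0:
            raise ValueError(f"nonpositive follow-up for {rec.patient_id}")
        t1 = rec.first_positive_time(method)
        if t1 is not None and 0 < t1 < end:
            rows.append((rec.patient_id, 0.0, t1, 0, False))
            rows.append((rec.patient_id, t1, end, 1, event))
        elif t1 is not None and t1 <= 0:
            rows.append((rec.patient_id, 0.0, end, 1, event))
        else:
            rows.append((rec.patient_id, 0.0, end, 0, event))
    return pd.DataFrame(rows, columns=["patient_id", "start", "stop",
                                       "ctdna", "event"])


def cox_time_dependent(records: Sequence[SerialRecord], method: str,
                       penalizer: float = 0.0
                       ) -> tuple[float, tuple[float, float], float]:
    """Cox model with ctDNA status as a time-dependent covariate.

    Episodes are split at first detection; the partial likelihood is
    maximised with Efron tie handling (lifelines).  Returns the hazard
    ratio, its Wald 95% CI and the Wald p-value.
    """
    episodes = serial_records_to_episodes(records, method)
    if episodes["event"].sum() == 0:
        raise ValueError("no events: hazard ratio inestimable")
    at_event = episodes.loc[episodes["event"], "ctdna"]
    if episodes["ctdna"].nunique() < 2:
        raise ValueError("inestimable: ctDNA covariate never varies")
    from lifelines import CoxTimeVaryingFitter

    ctv = CoxTimeVaryingFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(episodes, id_col="patient_id", event_col="event",
                start_col="start", stop_col="stop")
    coef = float(ctv.params_["ctdna"])
    se = float(ctv.standard_errors_["ctdna"])
    lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    p = float(ctv.summary.loc["ctdna", "p"])

    def _exp(x: float) -> float:  # guard monotone-likelihood blowups
        return math.exp(min(x, 700.0))

    return _exp(coef), (_exp(lo), _exp(hi)), p
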