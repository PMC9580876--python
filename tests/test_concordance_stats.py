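"""Concordance, proportion, rank and survival statistics vs oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from scipy.stats import hypergeom

from ctdnamrd.stats import (
    ConcordanceTable, SerialRecord, agreement_fraction, cohens_kappa,
    cox_time_dependent, fisher_exact, lead_times, patient_specificity,
    pearson_loglog, sample_specificity, serial_records_to_episodes,
    wilcoxon_rank_sum, wilcoxon_signed_rank, wilson_interval,
)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(ConcordanceTable(50, 0, 0, 50)) == 1.0

    def test_independence(self):
        assert cohens_kappa(ConcordanceTable(50, 50, 50, 50)) == 0.0

    def test_published_table(self):
        table = ConcordanceTable(134, 27, 11, 207)
        assert cohens_kappa(table) == pytest.approx(0.79, abs=0.005)

    def test_against_sklearn(self):
        # Independent implementation on expanded label vectors.
        from sklearn.metrics import cohen_kappa_score
        a, b, c, d = 17, 5, 9, 41
        st_labels = [1] * a + [0] * b + [1] * c + [0] * d
        mt_labels = [1] * a + [1] * b + [0] * c + [0] * d
        assert cohens_kappa(ConcordanceTable(a, b, c, d)) == pytest.approx(
            cohen_kappa_score(st_labels, mt_labels), abs=1e-12)

    def test_transpose_symmetry(self):
        # Swapping which method is "rows" flips b and c only.
        table = ConcordanceTable(30, 12, 4, 80)
        flipped = ConcordanceTable(30, 4, 12, 80)
        assert cohens_kappa(table) == pytest.approx(cohens_kappa(flipped))

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(ConcordanceTable(10, 0, 0, 0))


class TestAgreement:
    def test_published_fraction(self):
        table = ConcordanceTable(134, 27, 11, 207)
        assert agreement_fraction(table) == pytest.approx(341 / 379)

    @pytest.mark.parametrize("table, expected", [
        (ConcordanceTable(5, 0, 0, 7), 1.0),
        (ConcordanceTable(0, 3, 4, 0), 0.0),
    ])
    def test_edges(self, table, expected):
        assert agreement_fraction(table) == expected


class TestWilson:
    def test_boundaries(self):
        assert wilson_interval(0, 50)[0] == 0.0
        assert wilson_interval(50, 50)[1] == 1.0

    def test_closed_form_oracle(self):
        # Direct evaluation of the Wilson score formula.
        k, n, z = 3, 124, 1.959963984540054
        p = k / n
        den = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / den
        hw = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / den
        lo, hi = wilson_interval(k, n)
        assert lo == pytest.approx(centre - hw, abs=1e-6)
        assert hi == pytest.approx(centre + hw, abs=1e-6)

    def test_contains_point_estimate(self):
        lo, hi = wilson_interval(11, 22)
        assert lo < 0.5 < hi

    def test_width_shrinks_with_n(self):
        widths = [np.diff(wilson_interval(k, n))[0]
                  for k, n in ((5, 20), (25, 100), (125, 500))]
        assert widths[0] > widths[1] > widths[2]


def fisher_enumeration(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    ks = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {k: hypergeom.pmf(k, n, r1, c1) for k in ks}
    obs = pmf[a]
    return sum(p for p in pmf.values() if p <= obs * (1 + 1e-7))


class TestFisher:
    def test_published_discordant_split(self):
        # Preop/postop split of discordant samples.
        assert fisher_exact([[1, 10], [17, 10]]) == pytest.approx(
            0.0036, abs=1e-4)

    def test_proportional_rows(self):
        assert fisher_exact([[2, 4], [3, 6]]) == 1.0

    def test_empty_margin(self):
        assert fisher_exact([[0, 0], [3, 6]]) == 1.0

    def test_matches_enumeration_on_all_small_tables(self):
        # Criterion oracle: every 2x2 table with total <= 8.
        for total in range(1, 9):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        t = [[a, b], [c, d]]
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            continue
                        assert fisher_exact(t) == pytest.approx(
                            fisher_enumeration(t), abs=1e-12), t

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_invariant_under_row_and_column_swaps(self, cells):
        a, b, c, d = cells
        p = fisher_exact([[a, b], [c, d]])
        assert fisher_exact([[c, d], [a, b]]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact([[b, a], [d, c]]) == pytest.approx(p, abs=1e-12)


def rank_sum_enumeration(x, y):
    """Exact two-sided Mann-Whitney p over all label assignments."""
    pooled = sorted(x) + sorted(y)
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestRankSum:
    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_fully_separated_small_samples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_matches_enumeration_on_small_tie_free_samples(self):
        rng = np.random.default_rng(2)
        for n in (2, 3, 4):
            for m in (2, 3, 4):
                if n + m > 8:
                    continue
                data = rng.permutation(np.arange(1.0, n + m + 1))
                x, y = data[:n], data[n:]
                _, p = wilcoxon_rank_sum(x, y)
                assert p == pytest.approx(rank_sum_enumeration(list(x),
                                                               list(y)),
                                          abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        x, y = [0.5, 1.2, 3.0], [2.0, 4.0, 9.0, 0.1]
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSignedRank:
    def test_all_positive_differences_exact(self):
        # n = 5, every difference positive: one-sided 1/32, two-sided 1/16.
        pairs = [(i + 1.0, float(i)) for i in range(5)]
        _, p = wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(2 / 32)

    def test_antisymmetry(self):
        pairs = [(1.0, 3.0), (5.0, 2.0), (0.5, 0.1), (2.0, 2.5)]
        flipped = [(b, a) for a, b in pairs]
        assert wilcoxon_signed_rank(pairs)[1] == pytest.approx(
            wilcoxon_signed_rank(flipped)[1])

    def test_all_zero_differences_warns_p_one(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])
        assert p == 1.0


class TestLogLogRegression:
    def test_exact_power_law(self):
        x = np.array([0.1, 1.0, 3.0, 10.0])
        slope, intercept, r = pearson_loglog(x, x ** 1.7)
        assert slope == pytest.approx(1.7)
        assert r == pytest.approx(1.0)

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError, match="both-positive"):
            pearson_loglog([1.0, 0.0], [1.0, 2.0])

    def test_constant_levels_flagged_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_loglog([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_noisy_identity_highly_correlated(self, rng):
        x = np.exp(rng.normal(0, 1.2, 134))
        y = x * np.exp(rng.normal(0, 0.1, 134))
        _, _, r = pearson_loglog(x, y)
        assert r > 0.95


def make_record(pid, times, st_flags, mt_flags, recurrence=None,
                followup=36.0):
    return SerialRecord(patient_id=pid, times_months=tuple(times),
                        st_positive=tuple(st_flags),
                        mt_positive=tuple(mt_flags),
                        recurrence_time_months=recurrence,
                        followup_months=followup)


class TestSpecificity:
    def records(self, n_patients, positive_patients, draws=3):
        recs = []
        for i in range(n_patients):
            flags = [False] * draws
            if i < positive_patients:
                flags[1] = True
            recs.append(make_record(f"P{i}", [3 * (j + 1) for j in
                                              range(draws)], flags, flags))
        return recs

    def test_published_sample_specificities(self):
        # 3 positives over 124 samples -> 97.6%; 1 over 124 -> 99.2%
        recs = self.records(31, 3, draws=4)
        assert sample_specificity(recs, "ST") == pytest.approx(121 / 124)
        recs = self.records(31, 1, draws=4)
        assert sample_specificity(recs, "MT") == pytest.approx(123 / 124)

    def test_published_patient_specificities(self):
        recs = self.records(49, 3)
        assert patient_specificity(recs, "ST") == pytest.approx(46 / 49)
        recs = self.records(49, 1)
        assert patient_specificity(recs, "MT") == pytest.approx(48 / 49)

    def test_no_positives_is_one(self):
        recs = self.records(10, 0)
        assert sample_specificity(recs, "ST") == 1.0
        assert patient_specificity(recs, "ST") == 1.0

    def test_recurrence_patients_rejected(self):
        rec = make_record("P0", [3.0], [False], [False], recurrence=12.0)
        with pytest.raises(ValueError):
            sample_specificity([rec], "ST")

    def test_patient_at_most_sample_specificity(self, rng):
        # Each patient contributes >= 1 sample, so one positive sample
        # taints a whole patient: patient-level can never exceed
        # sample-level specificity.
        for trial in range(20):
            recs = []
            for i in range(rng.integers(3, 12)):
                k = int(rng.integers(1, 5))
                flags = list(rng.random(k) < 0.2)
                recs.append(make_record(f"P{i}", [3.0 * (j + 1)
                                                  for j in range(k)],
                                        flags, flags))
            assert (patient_specificity(recs, "ST")
                    <= sample_specificity(recs, "ST") + 1e-12)


class TestLeadTimes:
    def test_detection_at_recurrence_gives_zero_lead(self):
        rec = make_record("P1", [6.0, 12.0], [False, True], [False, True],
                          recurrence=12.0)
        lt = lead_times([rec])
        assert lt.st_lead_months == (0.0,)

    def test_identical_detection_times_paired_p_one(self):
        recs = [make_record(f"P{i}", [3.0, 6.0], [False, True],
                            [False, True], recurrence=10.0 + i)
                for i in range(5)]
        lt = lead_times(recs)
        with pytest.warns(UserWarning):
            assert lt.p_paired == 1.0

    def test_median(self):
        recs = [make_record(f"P{i}", [t], [True], [True],
                            recurrence=t + lead)
                for i, (t, lead) in enumerate([(3.0, 2.0), (6.0, 4.0),
                                               (9.0, 6.0)])]
        lt = lead_times(recs)
        assert lt.median_st == 4.0

    def test_undetected_patients_excluded(self):
        recs = [make_record("P1", [6.0], [True], [True], recurrence=12.0),
                make_record("P2", [6.0], [False], [True], recurrence=12.0)]
        lt = lead_times(recs)
        assert lt.excluded_patient_ids == ("P2",)
        assert lt.patient_ids == ("P1",)


class TestCoxTimeDependent:
    def test_episode_splitting(self):
        rec = make_record("P1", [3.0, 6.0], [False, True], [False, True],
                          recurrence=10.0)
        df = serial_records_to_episodes([rec], "ST")
        assert list(df.start) == [0.0, 6.0]
        assert list(df.stop) == [6.0, 10.0]
        assert list(df.ctdna) == [0, 1]
        assert list(df.event) == [False, True]

    def test_toy_data_matches_partial_likelihood_grid_search(self):
        # Three subjects; the written Efron/Breslow partial likelihood has
        # its maximum at beta = ln(sqrt(2)) (closed form via dPL/dbeta = 0),
        # confirmed by a grid search, and the fit must agree to 1e-4.
        recs = [
            make_record("A", [1.0], [True], [True], recurrence=3.0),
            make_record("B", [2.5], [False], [False], recurrence=2.0,
                        followup=2.0),
            make_record("C", [3.5], [False], [False], followup=4.0),
        ]
        grid = np.linspace(-2, 2, 40001)

        def log_pl(b):
            # event at t=2 (cov 0; risk set covs {1,0,0}) and t=3 (cov 1;
            # risk set covs {1,0})
            return (0 - np.log(np.exp(b) + 2)) + (b - np.log(np.exp(b) + 1))

        beta_grid = grid[np.argmax(log_pl(grid))]
        assert beta_grid == pytest.approx(math.log(math.sqrt(2)), abs=1e-4)
        hr, (lo, hi), p = cox_time_dependent(recs, "ST")
        assert math.log(hr) == pytest.approx(beta_grid, abs=1e-4)
        assert lo < hr < hi

    def test_no_events_rejected(self):
        recs = [make_record("A", [1.0], [True], [True], followup=5.0)]
        with pytest.raises(ValueError, match="no events"):
            cox_time_dependent(recs, "ST")

    def test_constant_covariate_rejected(self):
        recs = [make_record("A", [1.0], [False], [False], recurrence=3.0),
                make_record("B", [1.0], [False], [False], followup=5.0)]
        with pytest.raises(ValueError, match="inestimable"):
            cox_time_dependent(recs, "ST")

    def test_null_simulation_centred_at_zero(self):
        # True hazard ratio 1: the mean estimated log-HR over replicates
        # must sit within 3 SE of zero.
        rng = np.random.default_rng(31)
        betas = []
        for _ in range(200):
            recs = []
            for i in range(60):
                event_t = float(rng.exponential(20.0))
                cens = float(rng.uniform(5, 30))
                t = min(event_t, cens)
                switch = float(rng.uniform(1, 25))
                times, flags = [], []
                for draw in np.arange(1.0, t, 3.0):
                    times.append(float(draw))
                    flags.append(bool(draw >= switch))
                if not times:
                    times, flags = [t * 0.5], [False]
                recs.append(make_record(
                    f"P{i}", times, flags, flags,
                    recurrence=t if event_t < cens else None,
                    followup=t))
            try:
                hr, _, _ = cox_time_dependent(recs, "ST")
                betas.append(math.log(hr))
            except ValueError:
                continue
        betas = np.array(betas)
        assert len(betas) > 150
        se = betas.std(ddof=1) / math.sqrt(len(betas))
        assert abs(betas.mean()) < 3 * se
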