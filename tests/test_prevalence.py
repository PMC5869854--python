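"""Grouped prevalence, epoch binning, and trend fitting."""

import datetime

import numpy as np
import pytest

from robmine import (
    EpochSpec,
    EvaluationError,
    GroupingError,
    assign_epoch,
    assign_epochs,
    clopper_pearson,
    fit_trend,
    group_prevalence,
)
from robmine.prevalence import PrevalenceEstimate, add_months

from conftest import doc

D = datetime.date


class TestMonthArithmetic:
    @pytest.mark.parametrize(
        "start, months, expected",
        [
            (D(2016, 10, 4), -6, D(2016, 4, 4)),
            (D(2016, 10, 31), -6, D(2016, 4, 30)),   # day clamped
            (D(2016, 1, 31), 1, D(2016, 2, 29)),     # leap-year clamp
            (D(2016, 12, 15), 1, D(2017, 1, 15)),    # year rollover
        ],
    )
    def test_calendar_shift_with_day_clamp(self, start, months, expected):
        assert add_months(start, months) == expected


class TestFixedWidthEpochs:
    SPEC = EpochSpec(mode="fixed_width", width_months=6, anchor_date=D(2016, 10, 4))

    @pytest.mark.parametrize(
        "date, epoch",
        [
            (D(2016, 9, 1), 0),
            (D(2016, 10, 4), 0),
            (D(2016, 4, 5), 0),   # first day inside epoch 0
            (D(2016, 4, 4), 1),   # boundary day belongs to the older epoch
            (D(2016, 3, 1), 1),
            (D(2015, 1, 1), 3),
        ],
    )
    def test_interval_arithmetic(self, date, epoch):
        assert assign_epoch(date, self.SPEC) == epoch

    def test_date_after_anchor_fatal(self):
        with pytest.raises(GroupingError, match="after the anchor"):
            assign_epoch(D(2016, 10, 5), self.SPEC)

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        dates = [D(2014, 10, 5) + datetime.timedelta(days=int(d))
                 for d in rng.integers(0, 730, size=80)]
        idx, labels = assign_epochs(dates, self.SPEC)
        assert len(idx) == len(dates)
        assert set(idx) <= set(labels)
        # indices run oldest -> newest
        oldest = min(range(len(dates)), key=lambda i: dates[i])
        newest = max(range(len(dates)), key=lambda i: dates[i])
        assert idx[oldest] == 0 and idx[newest] == max(idx)


class TestQuantileEpochs:
    def test_equal_split_with_distinct_dates(self):
        dates = [D(2015, 1, 1) + datetime.timedelta(days=30 * i) for i in range(8)]
        idx, labels = assign_epochs(dates, EpochSpec(mode="quantile", n_bins=4))
        sizes = [idx.count(b) for b in sorted(set(idx))]
        assert sizes == [2, 2, 2, 2]

    def test_ties_stay_in_one_bin(self):
        # 6 copies of one date straddle the quartile boundaries
        dates = ([D(2015, 1, 1)] * 2 + [D(2015, 6, 1)] * 6 + [D(2016, 1, 1)] * 4)
        idx, _ = assign_epochs(dates, EpochSpec(mode="quantile", n_bins=4))
        by_date = {}
        for d, b in zip(dates, idx):
            by_date.setdefault(d, set()).add(b)
        assert all(len(bins) == 1 for bins in by_date.values())
        assert len(idx) == len(dates)

    def test_brute_force_tie_rule(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            dates = sorted(D(2015, 1, 1) + datetime.timedelta(days=int(d))
                           for d in rng.integers(0, 60, size=n))
            idx, _ = assign_epochs(dates, EpochSpec(mode="quantile", n_bins=4))
            # oracle: rank-based bin of the first occurrence of each date
            first_rank = {}
            for rank, d in enumerate(dates):
                first_rank.setdefault(d, rank)
            prelim = {d: r * 4 // n for d, r in first_rank.items()}
            remap = {b: j for j, b in enumerate(sorted(set(prelim.values())))}
            expected = [remap[prelim[d]] for d in dates]
            assert idx == expected


class TestGroupPrevalence:
    def _docs(self, spec):
        """spec: list of (journal, n_docs, n_positive)."""
        docs, flags, i = [], {}, 0
        for journal, n, k in spec:
            for j in range(n):
                d = doc("", doc_id=f"d{i:03d}", journal=journal,
                        date=(D(2015, 1, 1) + datetime.timedelta(days=i)).isoformat())
                docs.append(d)
                flags[d.doc_id] = j < k
                i += 1
        return docs, flags

    def test_small_journals_pooled_into_other(self):
        docs, flags = self._docs([("A", 10, 6), ("B", 3, 1)])
        ests = group_prevalence(flags, docs, "blinding", group_by="journal")
        assert [(e.group_label, e.k, e.n) for e in ests] == [("A", 6, 10), ("other", 1, 3)]

    def test_ranked_descending_ties_broken_by_label(self):
        docs, flags = self._docs([("B", 6, 3), ("A", 6, 3), ("C", 6, 5)])
        ests = group_prevalence(flags, docs, "blinding", group_by="journal")
        assert [e.group_label for e in ests] == ["C", "A", "B"]

    def test_boundary_all_positive_ci_high_is_one(self):
        docs, flags = self._docs([("A", 7, 7)])
        (est,) = group_prevalence(flags, docs, "blinding", group_by="all")
        assert est.proportion == 1.0 and est.ci.high == 1.0

    def test_counts_conserved_across_journal_groups(self):
        rng = np.random.default_rng(23)
        spec = [(f"J{j}", int(rng.integers(1, 12)), 0) for j in range(8)]
        spec = [(j, n, int(rng.integers(0, n + 1))) for j, n, _ in spec]
        docs, flags = self._docs(spec)
        ests = group_prevalence(flags, docs, "blinding", group_by="journal")
        assert sum(e.k for e in ests) == sum(flags.values())
        assert sum(e.n for e in ests) == len(docs)

    def test_matches_brute_force_per_group_tally(self):
        rng = np.random.default_rng(31)
        docs, flags = self._docs([(f"J{j}", 6, 0) for j in range(5)])
        flags = {d: bool(rng.integers(2)) for d in flags}
        ests = group_prevalence(flags, docs, "blinding", group_by="journal")
        for e in ests:
            if e.group_label == "other":
                continue
            members = [d for d in docs if d.journal == e.group_label]
            assert e.n == len(members)
            assert e.k == sum(flags[d.doc_id] for d in members)


def _est(props, n=100):
    return [PrevalenceEstimate(group_label=f"e{i}", item="blinding",
                               k=round(p * n), n=n, proportion=p,
                               ci=clopper_pearson(round(p * n), n))
            for i, p in enumerate(props)]


class TestFitTrend:
    def test_constant_series_has_zero_slope(self):
        fit = fit_trend(_est([0.5, 0.5, 0.5, 0.5]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        fit = fit_trend(_est([0.1, 0.2, 0.3, 0.4]))
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_longhand(self):
        rng = np.random.default_rng(77)
        y = rng.uniform(0.1, 0.9, size=6)
        fit = fit_trend(_est(list(y)))
        x = np.arange(6.0)
        props = np.array([e.proportion for e in _est(list(y))])
        xm, ym = x.mean(), props.mean()
        slope = np.sum((x - xm) * (props - ym)) / np.sum((x - xm) ** 2)
        intercept = ym - slope * xm
        resid = props - (intercept + slope * x)
        ss_res, ss_tot = np.sum(resid ** 2), np.sum((props - ym) ** 2)
        se = np.sqrt(ss_res / 4 / np.sum((x - xm) ** 2))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
        assert fit.slope_se == pytest.approx(se, abs=1e-10)

    def test_known_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(123)
        beta = 0.04
        props = np.clip(0.3 + beta * np.arange(8) + rng.normal(0, 0.02, 8), 0, 1)
        fit = fit_trend(_est(list(props)))
        assert abs(fit.slope - beta) <= 2 * fit.slope_se

    def test_fewer_than_three_epochs_fatal(self):
        with pytest.raises(EvaluationError, match=">= 3"):
            fit_trend(_est([0.1, 0.2]))

    def test_weighted_fit_matches_unweighted_on_equal_sizes(self):
        series = _est([0.2, 0.35, 0.4, 0.55, 0.6])
        fit_u = fit_trend(series)
        fit_w = fit_trend(series, weighted=True)
        assert fit_w.slope == pytest.approx(fit_u.slope, abs=1e-10)
        assert fit_w.p_value == pytest.approx(fit_u.p_value, abs=1e-8)
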