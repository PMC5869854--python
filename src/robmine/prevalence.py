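"""Reporting-prevalence summaries and time trends.

Prevalence of reported randomization, blinding and sample size calculation is
summarized for a whole corpus, by journal (journals below a minimum size are
pooled into an "other" row, mirroring review practice of plotting only
journals with five or more relevant manuscripts), or by time epoch.  Epochs
are either fixed calendar-width bins counted backwards from an anchor date
(default six months, the resolution used for plotting) or date quantiles
(default quartiles, the grouping used for regression).  Every group estimate
carries a Clopper-Pearson exact interval.

The trend fit is ordinary least squares of epoch proportion on epoch index,
oldest epoch first, so a positive slope means reporting is improving.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Mapping, Sequence

from scipy import stats

from .corpus import Document
from .evaluate import EvaluationError, ExactCI, clopper_pearson


class GroupingError(ValueError):
    """Invalid grouping request (bad dates, too few epochs, ...)."""


@dataclasses.dataclass(frozen=True)
class PrevalenceEstimate:
    group_label: str
    item: str
    k: int
    n: int
    proportion: float
    ci: ExactCI


@dataclasses.dataclass(frozen=True)
class EpochSpec:
    """How to bin record dates.

    ``fixed_width``: epochs of ``width_months`` calendar months counted
    backwards from ``anchor_date`` (epoch 0 is the most recent; a boundary
    moves by whole months with the day-of-month clamped, so an anchor of
    Oct-31 six months back is Apr-30).  ``quantile``: ``n_bins`` groups of
    as-equal-as-possible size in date order, identical dates never split.
    """

    mode: str = "fixed_width"
    width_months: int = 6
    n_bins: int = 4
    anchor_date: datetime.date | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_width", "quantile"):
            raise GroupingError(f"unknown epoch mode {self.mode!r}")
        if self.width_months < 1:
            raise GroupingError("width_months must be >= 1")
        if self.n_bins < 2:
            raise GroupingError("n_bins must be >= 2")


@dataclasses.dataclass(frozen=True)
class TrendFit:
    item: str
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    p_value: float
    n_epochs: int
    weighted: bool = False


def add_months(date: datetime.date, months: int) -> datetime.date:
    """Shift by calendar months, clamping the day-of-month."""
    y, m = divmod(date.year * 12 + (date.month - 1) + months, 12)
    m += 1
    # clamp day to the target month's length
    if m == 12:
        last = 31
    else:
        last = (datetime.date(y, m + 1, 1) - datetime.timedelta(days=1)).day
    return datetime.date(y, m, min(date.day, last))


def assign_epoch(record_date: datetime.date, spec: EpochSpec) -> int:
    """Fixed-width epoch index for one date: 0 is the most recent bin.

    Epoch ``e`` contains dates in ``(anchor - (e+1)*width, anchor - e*width]``.
    """
    if spec.mode != "fixed_width":
        raise GroupingError("assign_epoch is defined for fixed_width mode; "
                            "use assign_epochs for quantile binning")
    if spec.anchor_date is None:
        raise GroupingError("fixed_width epochs require an anchor_date")
    if record_date > spec.anchor_date:
        raise GroupingError(
            f"date {record_date} is after the anchor {spec.anchor_date}; "
            "fixed-width epochs count backwards from the anchor"
        )
    e = 0
    while record_date <= add_months(spec.anchor_date, -(e + 1) * spec.width_months):
        e += 1
    return e


def epoch_label(e: int, spec: EpochSpec) -> str:
    lo = add_months(spec.anchor_date, -(e + 1) * spec.width_months)
    hi = add_months(spec.anchor_date, -e * spec.width_months)
    return f"{lo + datetime.timedelta(days=1)}/{hi}"


def assign_epochs(
    dates: Sequence[datetime.date], spec: EpochSpec
) -> tuple[list[int], dict[int, str]]:
    """Epoch index per date plus index -> label map; a partition of the input.

    Quantile mode targets ``n_bins`` equal-sized groups in date order; all
    copies of an identical date stay in the bin of its first occurrence, so
    realized bin sizes can differ.  Indices are ordered oldest -> newest in
    both modes (ready for trend fitting).
    """
    if any(d is None for d in dates):
        raise GroupingError("every document needs a record_date for epoch grouping")
    n = len(dates)
    if spec.mode == "fixed_width":
        anchor = spec.anchor_date or max(dates)
        eff = EpochSpec(mode="fixed_width", width_months=spec.width_months,
                        n_bins=spec.n_bins, anchor_date=anchor)
        raw = [assign_epoch(d, eff) for d in dates]
        e_max = max(raw)
        idx = [e_max - e for e in raw]  # reverse: oldest epoch -> index 0
        labels = {e_max - e: epoch_label(e, eff) for e in set(raw)}
        return idx, labels
    # quantile mode
    if n < spec.n_bins:
        raise GroupingError(f"cannot form {spec.n_bins} date quantiles from {n} documents")
    order = sorted(range(n), key=lambda i: (dates[i], i))
    prelim = [0] * n
    for rank, i in enumerate(order):
        prelim[i] = rank * spec.n_bins // n
    # ties on identical dates stay in the first occurrence's bin
    first_bin: dict[datetime.date, int] = {}
    for i in order:
        first_bin.setdefault(dates[i], prelim[i])
    idx = [first_bin[dates[i]] for i in range(n)]
    labels = {}
    for b in sorted(set(idx)):
        in_bin = [dates[i] for i in range(n) if idx[i] == b]
        labels[b] = f"Q{b + 1}: {min(in_bin)}/{max(in_bin)}"
    # re-densify indices in case a tiny bin was emptied by tie merging
    remap = {b: j for j, b in enumerate(sorted(set(idx)))}
    idx = [remap[b] for b in idx]
    labels = {remap[b]: lab for b, lab in labels.items()}
    return idx, labels


def group_prevalence(
    positives: Mapping[str, bool],
    documents: Sequence[Document],
    item: str,
    group_by: str = "all",
    epoch_spec: EpochSpec | None = None,
    min_group_size: int | None = None,
    level: float = 0.95,
    corpus_label: str = "all",
) -> list[PrevalenceEstimate]:
    """Prevalence (k/n with exact CI) per group.

    ``positives`` maps doc_id -> bool (detector calls or gold labels) for one
    item.  ``group_by`` is ``all``, ``journal`` or ``epoch``.  Journal groups
    smaller than ``min_group_size`` (default 5) are pooled into an ``other``
    row; ranked groups are ordered by proportion descending, ties broken by
    label.  Epoch groups are ordered oldest first.
    """
    docs = [d for d in documents if d.doc_id in positives]
    if not docs:
        raise GroupingError("no documents overlap the supplied calls/labels")

    def estimate(label: str, members: Sequence[Document]) -> PrevalenceEstimate:
        k = sum(bool(positives[d.doc_id]) for d in members)
        n = len(members)
        return PrevalenceEstimate(group_label=label, item=item, k=k, n=n,
                                  proportion=k / n, ci=clopper_pearson(k, n, level))

    if group_by == "all":
        return [estimate(corpus_label, docs)]

    if group_by == "journal":
        if min_group_size is None:
            min_group_size = 5
        if min_group_size < 1:
            raise GroupingError("min_group_size must be >= 1")
        by_journal: dict[str, list[Document]] = {}
        for d in docs:
            by_journal.setdefault(d.journal or "(unknown)", []).append(d)
        ranked = [estimate(j, ms) for j, ms in by_journal.items() if len(ms) >= min_group_size]
        ranked.sort(key=lambda p: (-p.proportion, p.group_label))
        pooled = [d for j, ms in by_journal.items() if len(ms) < min_group_size for d in ms]
        if pooled:
            ranked.append(estimate("other", pooled))
        return ranked

    if group_by == "epoch":
        spec = epoch_spec or EpochSpec()
        try:
            idx, labels = assign_epochs([d.record_date for d in docs], spec)
        except GroupingError:
            raise
        out = []
        for b in sorted(labels):
            members = [docs[i] for i in range(len(docs)) if idx[i] == b]
            if members:
                out.append(estimate(labels[b], members))
        return out

    raise GroupingError(f"unknown group_by {group_by!r}")


def fit_trend(
    estimates: Sequence[PrevalenceEstimate],
    weighted: bool = False,
) -> TrendFit:
    """OLS of epoch proportion on epoch index (oldest epoch = index 0).

    ``weighted=True`` weights each epoch by its document count (WLS), a
    sensitivity analysis for unequal bins.  Requires at least three epochs;
    the p value is the two-sided t test of zero slope on ``n_epochs - 2``
    degrees of freedom.
    """
    if len(estimates) < 3:
        raise EvaluationError(
            f"trend fitting needs >= 3 epochs, got {len(estimates)}"
        )
    x = list(range(len(estimates)))
    y = [e.proportion for e in estimates]
    item = estimates[0].item
    if not weighted:
        res = stats.linregress(x, y)
        r2 = float(res.rvalue) ** 2
        if len(set(y)) == 1:  # constant series: zero slope, no explained variance
            r2 = 0.0
        return TrendFit(item=item, slope=float(res.slope), intercept=float(res.intercept),
                        r_squared=r2, slope_se=float(res.stderr),
                        p_value=float(res.pvalue), n_epochs=len(estimates))
    import statsmodels.api as sm

    X = sm.add_constant(list(map(float, x)))
    fit = sm.WLS(y, X, weights=[e.n for e in estimates]).fit()
    return TrendFit(item=item, slope=float(fit.params[1]), intercept=float(fit.params[0]),
                    r_squared=float(fit.rsquared), slope_se=float(fit.bse[1]),
                    p_value=float(fit.pvalues[1]), n_epochs=len(estimates), weighted=True)


PREVALENCE_COLUMNS = ("group_label", "item", "k", "n", "proportion", "ci_low", "ci_high")
TREND_COLUMNS = ("item", "slope", "intercept", "r_squared", "slope_se", "p_value",
                 "n_epochs", "weighted")


def prevalence_report_rows(estimates: Sequence[PrevalenceEstimate]) -> list[dict]:
    return [{
        "group_label": e.group_label, "item": e.item, "k": e.k, "n": e.n,
        "proportion": round(e.proportion, 4),
        "ci_low": round(e.ci.low, 4), "ci_high": round(e.ci.high, 4),
    } for e in estimates]


def trend_report_rows(fits: Sequence[TrendFit]) -> list[dict]:
    return [{
        "item": f.item, "slope": round(f.slope, 6), "intercept": round(f.intercept, 6),
        "r_squared": round(f.r_squared, 6), "slope_se": round(f.slope_se, 6),
        "p_value": round(f.p_value, 6), "n_epochs": f.n_epochs, "weighted": f.weighted,
    } for f in fits]
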