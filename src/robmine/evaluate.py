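"""Diagnostic-accuracy evaluation against a manual gold standard.

Sensitivity is the proportion of gold-positive documents the tool calls
positive, specificity the proportion of gold-negatives called negative, and
accuracy the proportion of all documents labelled correctly.  Each proportion
carries a Clopper-Pearson exact binomial confidence interval.  A metric with
a zero denominator (no gold positives, say) is flagged undefined rather than
silently coerced to 0 or 1.

``reconstruct_counts`` inverts published summary rows: given a corpus size,
gold prevalence, sensitivity and specificity it recovers the implied
confusion matrix (round-to-nearest on expected counts), implied accuracy
``p*Se + (1-p)*Sp`` and implied tool call rate ``p*Se + (1-p)*(1-Sp)``.
Because published inputs are themselves rounded, implied metrics are exact
only to about one percentage point.
"""

from __future__ import annotations

import dataclasses
import math

from scipy import stats

from .corpus import GoldAnnotation


class EvaluationError(ValueError):
    """Invalid evaluation input (empty intersection, bad counts, ...)."""


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise EvaluationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class ExactCI:
    """Clopper-Pearson exact binomial confidence interval for k/n."""

    k: int
    n: int
    level: float
    low: float
    high: float

    @property
    def estimate(self) -> float:
        return self.k / self.n


@dataclasses.dataclass(frozen=True)
class Proportion:
    """A proportion with its exact CI, or an undefined-flagged placeholder."""

    value: float | None
    ci: ExactCI | None
    defined: bool
    note: str = ""


@dataclasses.dataclass(frozen=True)
class PerformanceMetrics:
    item: str
    cm: ConfusionMatrix
    sensitivity: Proportion
    specificity: Proportion
    accuracy: Proportion
    prevalence_tool: float
    prevalence_gold: float
    n_excluded: int = 0  # calls without a gold annotation, left out of the matrix


def clopper_pearson(k: int, n: int, level: float = 0.95) -> ExactCI:
    """Exact binomial CI by inverting binomial tails (Beta quantiles).

    ``low = BetaInv(alpha/2; k, n-k+1)`` for ``k > 0`` else 0;
    ``high = BetaInv(1-alpha/2; k+1, n-k)`` for ``k < n`` else 1.
    """
    if not (isinstance(k, int) and isinstance(n, int)):
        raise EvaluationError(f"k and n must be integers, got k={k!r}, n={n!r}")
    if n < 1 or not 0 <= k <= n:
        raise EvaluationError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise EvaluationError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return ExactCI(k=k, n=n, level=level, low=low, high=high)


def _proportion(k: int, n: int, level: float, what: str) -> Proportion:
    if n == 0:
        return Proportion(value=None, ci=None, defined=False,
                          note=f"{what} undefined: denominator 0")
    return Proportion(value=k / n, ci=clopper_pearson(k, n, level), defined=True)


def confusion(
    calls,
    gold: list[GoldAnnotation] | dict[str, bool],
    item: str,
) -> tuple[ConfusionMatrix, int]:
    """Tally the confusion matrix for one item over call/gold intersection.

    ``calls`` is an iterable of detector calls (``RobCall`` or any object with
    ``doc_id``, ``item``, ``call``).  Returns the matrix and the number of
    calls for ``item`` that had no gold annotation (excluded, but counted).
    """
    if isinstance(gold, dict):
        gold_map = dict(gold)
    else:
        gold_map = {g.doc_id: g[item] for g in gold}
    call_map: dict[str, bool] = {}
    for c in calls:
        if c.item != item:
            continue
        call_map[c.doc_id] = bool(c.call)
    missing_calls = [doc_id for doc_id in gold_map if doc_id not in call_map]
    if missing_calls:
        raise EvaluationError(
            f"no {item} call for gold-annotated document(s): {sorted(missing_calls)[:5]}"
        )
    shared = [d for d in call_map if d in gold_map]
    if not shared:
        raise EvaluationError(f"no documents shared between calls and gold for {item}")
    tp = fp = tn = fn = 0
    for doc_id in shared:
        called, truth = call_map[doc_id], gold_map[doc_id]
        if truth and called:
            tp += 1
        elif truth and not called:
            fn += 1
        elif not truth and called:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn), len(call_map) - len(shared)


def metrics(
    cm: ConfusionMatrix,
    level: float = 0.95,
    item: str = "",
    n_excluded: int = 0,
) -> PerformanceMetrics:
    """Sensitivity, specificity and accuracy with exact CIs from a matrix."""
    n = cm.n
    if n == 0:
        raise EvaluationError("cannot compute metrics on an empty confusion matrix")
    return PerformanceMetrics(
        item=item,
        cm=cm,
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn, level, "sensitivity"),
        specificity=_proportion(cm.tn, cm.tn + cm.fp, level, "specificity"),
        accuracy=_proportion(cm.tp + cm.tn, n, level, "accuracy"),
        prevalence_tool=(cm.tp + cm.fp) / n,
        prevalence_gold=(cm.tp + cm.fn) / n,
        n_excluded=n_excluded,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class ReconstructedRow:
    cm: ConfusionMatrix
    implied_accuracy: float   # prev*Se + (1-prev)*Sp
    implied_call_rate: float  # prev*Se + (1-prev)*(1-Sp)


def reconstruct_counts(
    n: int,
    prevalence_gold: float,
    sensitivity: float,
    specificity: float,
) -> ReconstructedRow:
    """Recover the confusion matrix implied by a published summary row."""
    if n < 1:
        raise EvaluationError(f"n must be >= 1, got {n}")
    for name, v in (("prevalence_gold", prevalence_gold),
                    ("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise EvaluationError(f"{name} must be in [0, 1], got {v}")
    n_pos = _round_half_up(n * prevalence_gold)
    tp = _round_half_up(n * prevalence_gold * sensitivity)
    fn = n_pos - tp
    tn = _round_half_up(n * (1.0 - prevalence_gold) * specificity)
    fp = n - tp - fn - tn
    if min(tp, fn, tn, fp) < 0:
        raise EvaluationError(
            f"inconsistent summary row: implied counts tp={tp} fn={fn} tn={tn} fp={fp} "
            f"from n={n}, prev={prevalence_gold}, Se={sensitivity}, Sp={specificity}"
        )
    return ReconstructedRow(
        cm=ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn),
        implied_accuracy=prevalence_gold * sensitivity
        + (1.0 - prevalence_gold) * specificity,
        implied_call_rate=prevalence_gold * sensitivity
        + (1.0 - prevalence_gold) * (1.0 - specificity),
    )


def metrics_report_rows(per_item: dict[str, PerformanceMetrics]) -> list[dict]:
    """Flatten metrics to report rows (percentages rounded half-up)."""
    rows = []
    for item, m in per_item.items():
        def fmt(p: Proportion):
            if not p.defined:
                return ("NA", "NA", "NA")
            return (round(p.value, 4), round(p.ci.low, 4), round(p.ci.high, 4))

        se, se_lo, se_hi = fmt(m.sensitivity)
        sp, sp_lo, sp_hi = fmt(m.specificity)
        ac, ac_lo, ac_hi = fmt(m.accuracy)
        rows.append({
            "item": item,
            "n": m.cm.n,
            "tp": m.cm.tp, "fp": m.cm.fp, "tn": m.cm.tn, "fn": m.cm.fn,
            "prevalence_tool": round(m.prevalence_tool, 4),
            "prevalence_gold": round(m.prevalence_gold, 4),
            "sensitivity": se, "sensitivity_ci_low": se_lo, "sensitivity_ci_high": se_hi,
            "specificity": sp, "specificity_ci_low": sp_lo, "specificity_ci_high": sp_hi,
            "accuracy": ac, "accuracy_ci_low": ac_lo, "accuracy_ci_high": ac_hi,
            "n_excluded": m.n_excluded,
        })
    return rows


METRICS_REPORT_COLUMNS = (
    "item", "n", "tp", "fp", "tn", "fn",
    "prevalence_tool", "prevalence_gold",
    "sensitivity", "sensitivity_ci_low", "sensitivity_ci_high",
    "specificity", "specificity_ci_low", "specificity_ci_high",
    "accuracy", "accuracy_ci_low", "accuracy_ci_high",
    "n_excluded",
)
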