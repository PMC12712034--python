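"""Diagnostic accuracy metrics with exact and score confidence intervals.

Accuracy, sensitivity and specificity carry exact Clopper-Pearson binomial
intervals; PPV and NPV carry Wilson score (Newcombe efficient-score)
intervals, the convention of the reader trial this package evaluates.
Averaged (fractional) confusion counts are allowed: point estimates are
computed directly from the means, while interval successes/trials are
rounded to the nearest integer first, since binomial intervals need counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

from .aggregation import ConfusionCounts

CIMethod = Literal["clopper_pearson", "wilson_score"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 digit -> 0.1), as tables print it."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float = 0.95
    method: CIMethod = "clopper_pearson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")

    def contains(self, p: float) -> bool:
        return self.lower <= p <= self.upper


def _check_counts(successes: int, trials: int) -> None:
    if trials < 1 or not (0 <= successes <= trials):
        raise ValueError(f"need 0 <= successes <= trials, trials >= 1; got {successes}/{trials}")


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> ConfidenceInterval:
    """Exact binomial interval from beta quantiles.

    Lower bound is exactly 0 at successes=0 and upper exactly 1 at
    successes=trials.
    """
    _check_counts(successes, trials)
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == trials else float(hi)
    return ConfidenceInterval(lo, hi, level=level, method="clopper_pearson")


def _wilson_cc(k: int, n: int, level: float) -> tuple[float, float]:
    """Continuity-corrected Wilson bounds (Newcombe's closed form)."""
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - level) / 2))
    p = k / n
    denom = 2 * (n + z * z)
    lo = (
        0.0
        if k == 0
        else (2 * n * p + z * z - 1 - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1)))
        / denom
    )
    hi = (
        1.0
        if k == n
        else (2 * n * p + z * z + 1 + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1)))
        / denom
    )
    return max(0.0, lo), min(1.0, hi)


def wilson_score(
    successes: int, trials: int, level: float = 0.95, continuity: bool = False
) -> ConfidenceInterval:
    """Wilson score interval (score-test inversion), optionally
    continuity-corrected.  Contained in [0, 1] by construction."""
    _check_counts(successes, trials)
    if continuity:
        lo, hi = _wilson_cc(successes, trials, level)
    else:
        lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    lo = max(0.0, float(lo))
    hi = min(1.0, float(hi))
    if successes == 0:
        lo = 0.0
    if successes == trials:
        hi = 1.0
    return ConfidenceInterval(lo, hi, level=level, method="wilson_score")


@dataclass(frozen=True)
class MetricValue:
    """A proportion with its numerator/denominator and interval.

    ``value is None`` flags an undefined metric (zero denominator); no
    exception is raised for those.
    """

    value: Optional[float]
    numerator: float
    denominator: float
    ci: Optional[ConfidenceInterval] = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def pct(self, ndigits: int = 1) -> Optional[float]:
        return None if self.value is None else round_half_up(100.0 * self.value, ndigits)


@dataclass(frozen=True)
class MetricSet:
    accuracy: MetricValue
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue

    def as_dict(self) -> dict[str, MetricValue]:
        return {
            "ppv": self.ppv,
            "npv": self.npv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def _nearest_int(x: float) -> int:
    return int(math.floor(x + 0.5))


def _metric(num: float, den: float, method: CIMethod, ci_level: float) -> MetricValue:
    if den <= 0:
        return MetricValue(value=None, numerator=num, denominator=den, ci=None)
    value = num / den
    k, n = _nearest_int(num), _nearest_int(den)
    k = min(max(k, 0), n)
    ci: Optional[ConfidenceInterval] = None
    if n >= 1:
        if method == "clopper_pearson":
            ci = clopper_pearson(k, n, level=ci_level)
        else:
            ci = wilson_score(k, n, level=ci_level)
    return MetricValue(value=value, numerator=num, denominator=den, ci=ci)


def metrics_from_counts(c: ConfusionCounts, ci_level: float = 0.95) -> MetricSet:
    """Accuracy/sensitivity/specificity (Clopper-Pearson) and PPV/NPV
    (Wilson score) from a confusion quadruple."""
    return MetricSet(
        accuracy=_metric(c.tp + c.tn, c.total, "clopper_pearson", ci_level),
        sensitivity=_metric(c.tp, c.tp + c.fn, "clopper_pearson", ci_level),
        specificity=_metric(c.tn, c.tn + c.fp, "clopper_pearson", ci_level),
        ppv=_metric(c.tp, c.tp + c.fp, "wilson_score", ci_level),
        npv=_metric(c.tn, c.tn + c.fn, "wilson_score", ci_level),
    )


_COUNT_ROWS = [("tp", "True positive"), ("fp", "False positive"), ("tn", "True negative"), ("fn", "False negative")]
_METRIC_ROWS = [("ppv", "PPV"), ("npv", "NPV"), ("sensitivity", "Sensitivity"), ("specificity", "Specificity"), ("accuracy", "Accuracy")]


def render_metric_table(
    counts: Mapping[str, ConfusionCounts],
    ci_level: float = 0.95,
    baseline: str = "avg_radiologist",
    assisted: str = "avg_radiologist_ai",
    standalone: str = "ai",
    ndigits: int = 1,
):
    """Counts + metrics for the three reading conditions with delta columns.

    Columns: baseline, assisted, delta (assisted - baseline), standalone,
    delta vs baseline, delta vs assisted.  Deltas are computed on unrounded
    values and rounded for display afterwards.  All sources must share a
    level.
    """
    import pandas as pd

    order = [baseline, assisted, standalone]
    missing = [k for k in order if k not in counts]
    if missing:
        raise ValueError(f"missing sources in counts: {missing}")
    levels = {counts[k].level for k in order}
    if len(levels) > 1:
        raise ValueError(f"sources are at different levels: {sorted(levels)}")
    metric_sets = {k: metrics_from_counts(counts[k], ci_level) for k in order}

    cols = [
        baseline,
        assisted,
        "delta_assisted",
        standalone,
        "delta_ai_vs_baseline",
        "delta_ai_vs_assisted",
    ]
    rows = {}
    for key, label in _COUNT_ROWS:
        b = counts[baseline].as_dict()[key]
        a = counts[assisted].as_dict()[key]
        s = counts[standalone].as_dict()[key]
        rows[label] = [
            round_half_up(b, ndigits),
            round_half_up(a, ndigits),
            round_half_up(a - b, ndigits),
            round_half_up(s, ndigits),
            round_half_up(s - b, ndigits),
            round_half_up(s - a, ndigits),
        ]
    for key, label in _METRIC_ROWS:
        vals = [metric_sets[k].as_dict()[key].value for k in order]
        b, a, s = vals

        def pct(x):
            return None if x is None else round_half_up(100 * x, ndigits)

        def dpct(x, y):
            return None if x is None or y is None else round_half_up(100 * (x - y), ndigits)

        rows[label] = [pct(b), pct(a), dpct(a, b), pct(s), dpct(s, b), dpct(s, a)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def metric_table_json(
    counts: Mapping[str, ConfusionCounts], ci_level: float = 0.95
) -> dict:
    """Raw (unrounded) counts, metrics and intervals keyed by source."""
    out: dict = {}
    for label, c in counts.items():
        ms = metrics_from_counts(c, ci_level)
        out[label] = {
            "level": c.level,
            "counts": c.as_dict(),
            "metrics": {
                name: {
                    "value": mv.value,
                    "numerator": mv.numerator,
                    "denominator": mv.denominator,
                    "ci": None
                    if mv.ci is None
                    else {"lower": mv.ci.lower, "upper": mv.ci.upper, "method": mv.ci.method, "level": mv.ci.level},
                }
                for name, mv in ms.as_dict().items()
            },
        }
    return out
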