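"""Diagnostic-accuracy measures with confidence intervals, and ranking.

Point estimates are kept as exact :class:`~fractions.Fraction` values until
rendering. Rendering follows the source tables' two-stage convention: the
percent is first rounded to one decimal (half away from zero) and the METRIC
form is then rounded again to an integer — so 31.47 renders as "32", not "31".
Intervals are Wald by default; Wilson and Clopper–Pearson are available via
``ci_method``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction
from typing import Mapping, Sequence

from scipy import stats as sps

__all__ = [
    "ConfusionTable",
    "MetricsRow",
    "PercentKind",
    "confusion_table",
    "diagnostic_metrics",
    "wald_ci",
    "wilson_ci",
    "clopper_pearson_ci",
    "rank_algorithms",
    "render_percent",
    "format_metric",
]

MEASURES = ("sensitivity", "specificity", "ppv", "npv")


class PercentKind(str, enum.Enum):
    METRIC = "METRIC"        # integer percent
    PREVALENCE = "PREVALENCE"  # one decimal place


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsRow:
    """One algorithm's accuracy measures. Undefined measures (zero
    denominator) are None, never 0 or 1."""

    algorithm_id: str
    sensitivity: Fraction | None
    specificity: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None
    pre_test_prev: Fraction | None
    post_test_prev: Fraction | None
    ci: dict[str, tuple[float, float] | None] = field(default_factory=dict)

    def as_dict(self) -> dict:
        def num(x):
            return None if x is None else float(x)

        return {
            "algorithm_id": self.algorithm_id,
            "sensitivity": num(self.sensitivity),
            "specificity": num(self.specificity),
            "ppv": num(self.ppv),
            "npv": num(self.npv),
            "pre_test_prev": num(self.pre_test_prev),
            "post_test_prev": num(self.post_test_prev),
            "ci": {k: (list(v) if v else None) for k, v in self.ci.items()},
        }

    def rendered(self, measure: str) -> str:
        """Table-style cell, e.g. ``"90 (83-97)"``; ``"NA"`` if undefined."""
        return format_metric(getattr(self, measure), self.ci.get(measure))


def confusion_table(
    predictions: Mapping[str, bool], labels: Mapping[str, bool]
) -> ConfusionTable:
    """Cross-tabulate classifier output against the binary reference."""
    missing = set(labels) ^ set(predictions)
    if missing:
        raise KeyError(
            f"prediction/label key mismatch for ids: {sorted(missing)[:10]}"
        )
    tp = fp = fn = tn = 0
    for pid, predicted in predictions.items():
        actual = labels[pid]
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Fraction | None:
    return None if den == 0 else Fraction(num, den)


def _z(level: float) -> float:
    return float(sps.norm.ppf(0.5 + level / 2.0))


def wald_ci(
    p_hat: float | Fraction, denom: int, level: float = 0.95
) -> tuple[float, float] | None:
    """Normal-approximation interval, clipped to [0, 1]."""
    if denom < 1:
        return None
    p = float(p_hat)
    half = _z(level) * math.sqrt(p * (1.0 - p) / denom)
    return (max(0.0, p - half), min(1.0, p + half))


def wilson_ci(
    p_hat: float | Fraction, denom: int, level: float = 0.95
) -> tuple[float, float] | None:
    if denom < 1:
        return None
    p = float(p_hat)
    z2 = _z(level) ** 2
    centre = (p + z2 / (2 * denom)) / (1 + z2 / denom)
    half = (
        _z(level)
        / (1 + z2 / denom)
        * math.sqrt(p * (1 - p) / denom + z2 / (4 * denom**2))
    )
    return (max(0.0, centre - half), min(1.0, centre + half))


def clopper_pearson_ci(
    count: int, denom: int, level: float = 0.95
) -> tuple[float, float] | None:
    if denom < 1:
        return None
    alpha = 1.0 - level
    lo = 0.0 if count == 0 else float(sps.beta.ppf(alpha / 2, count, denom - count + 1))
    hi = 1.0 if count == denom else float(
        sps.beta.ppf(1 - alpha / 2, count + 1, denom - count)
    )
    return (lo, hi)


_CI_FUNCS = {"wald": wald_ci, "wilson": wilson_ci}


def diagnostic_metrics(
    ct: ConfusionTable,
    algorithm_id: str = "",
    ci_method: str = "wald",
    level: float = 0.95,
) -> MetricsRow:
    """Sensitivity, specificity, PPV, NPV and prevalences from one table."""
    n = ct.total
    pieces = {
        "sensitivity": (ct.tp, ct.tp + ct.fn),
        "specificity": (ct.tn, ct.fp + ct.tn),
        "ppv": (ct.tp, ct.tp + ct.fp),
        "npv": (ct.tn, ct.fn + ct.tn),
        "pre_test_prev": (ct.tp + ct.fn, n),
        "post_test_prev": (ct.tp + ct.fp, n),
    }
    points = {k: _ratio(num, den) for k, (num, den) in pieces.items()}
    ci: dict[str, tuple[float, float] | None] = {}
    for measure in MEASURES:
        num, den = pieces[measure]
        if den == 0:
            ci[measure] = None
        elif ci_method == "clopper_pearson":
            ci[measure] = clopper_pearson_ci(num, den, level)
        else:
            try:
                fn = _CI_FUNCS[ci_method]
            except KeyError:
                raise ValueError(f"unknown ci_method {ci_method!r}") from None
            ci[measure] = fn(Fraction(num, den), den, level)
    return MetricsRow(algorithm_id=algorithm_id, ci=ci, **points)


def render_percent(
    p: float | Fraction | None, kind: PercentKind = PercentKind.METRIC
) -> str:
    """Render a proportion as a percent string.

    PREVALENCE keeps one decimal ("4.1"); METRIC re-rounds that one-decimal
    value to an integer ("90"), matching tables that were first formatted at
    one decimal and then rounded again.
    """
    if p is None:
        return "NA"
    kind = PercentKind(kind)
    with localcontext() as ctx:
        ctx.prec = 50
        if isinstance(p, Fraction):
            pct = Decimal(p.numerator) * 100 / Decimal(p.denominator)
        else:
            pct = Decimal(repr(float(p))) * 100
        one_dp = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        if kind is PercentKind.PREVALENCE:
            return str(one_dp)
        return str(one_dp.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def format_metric(
    p: Fraction | float | None, ci: tuple[float, float] | None = None
) -> str:
    """``"90 (83-97)"`` style cell."""
    if p is None:
        return "NA"
    cell = render_percent(p, PercentKind.METRIC)
    if ci is not None:
        lo, hi = ci
        cell += f" ({render_percent(lo)}-{render_percent(hi)})"
    return cell


def rank_algorithms(
    rows: Sequence[MetricsRow], min_sensitivity: float | None = None
) -> list[MetricsRow]:
    """Stable sort by (PPV desc, sensitivity desc, specificity desc), after an
    optional minimum-sensitivity filter; ties keep input order. Undefined
    measures sort below any defined value."""

    def key(row: MetricsRow):
        def val(x):
            return float(x) if x is not None else -1.0

        return (-val(row.ppv), -val(row.sensitivity), -val(row.specificity))

    kept = [
        r
        for r in rows
        if min_sensitivity is None
        or (r.sensitivity is not None and float(r.sensitivity) >= min_sensitivity)
    ]
    return sorted(kept, key=key)
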