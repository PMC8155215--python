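"""Direction-of-change statistics per event type.

Among the events called differentially spliced, is the direction of change
(delta PSI > 0, i.e. higher inclusion in the test condition) balanced? For
each event type we test the observed proportion of positive delta PSI values
against a fair 0.5 with the one-sample Pearson chi-squared proportion test
with continuity correction, and report the matching Wilson score interval.

The correction term is capped at |observed - expected|, so an observation
exactly at the null gives chi2 = 0, p = 1; the capped term is reused inside
the interval. This reproduces R's ``prop.test(k, n, p = 0.5, correct = TRUE)``
to full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .errors import InputValidationError
from .events import EventType
from .model import DifferentialResult

__all__ = [
    "DirectionSummary",
    "direction_counts",
    "proportion_test",
    "proportion_ci",
    "summarize_directions",
    "summary_frame",
]


@dataclass(frozen=True)
class DirectionSummary:
    """Positive/total counts and the proportion test for one event type.

    Test fields are NaN when no significant event of the type exists
    (n_total = 0); the row is still reported.
    """

    event_type: EventType
    n_positive: int
    n_total: int
    proportion: float
    chi2: float
    p_value: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


def direction_counts(
    results: Iterable[DifferentialResult], event_type: EventType
) -> tuple[int, int]:
    """(positive, total) counts over *significant* results of one type."""
    n_pos = 0
    n_tot = 0
    for r in results:
        if r.event_type is event_type and r.significant:
            n_tot += 1
            if r.delta_psi > 0:
                n_pos += 1
    return n_pos, n_tot


def proportion_test(n_positive: int, n_total: int, null_p: float = 0.5) -> tuple[float, float]:
    """Chi-squared statistic and two-sided p of the corrected proportion test.

    chi2 = (|k - n p0| - c)^2 / (n p0 (1 - p0)) with c = min(0.5, |k - n p0|);
    p from the chi-squared distribution with 1 df.
    """
    if n_total < 1:
        raise InputValidationError("proportion test undefined for n_total = 0")
    if not 0 <= n_positive <= n_total:
        raise InputValidationError(f"need 0 <= n_positive <= n_total, got {n_positive}/{n_total}")
    if not 0 < null_p < 1:
        raise InputValidationError(f"null proportion must be in (0, 1), got {null_p}")
    dev = abs(n_positive - n_total * null_p)
    correction = min(0.5, dev)
    chi2 = (dev - correction) ** 2 / (n_total * null_p * (1.0 - null_p))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p_value


def proportion_ci(
    n_positive: int,
    n_total: int,
    conf_level: float = 0.95,
    null_p: float = 0.5,
) -> tuple[float, float]:
    """Wilson score interval with the same capped continuity correction.

    The correction shifts the point estimate by c/n towards each limit
    before the Wilson inversion (c = min(0.5, |k - n p0|), as in the test);
    the interval is clipped to [0, 1].
    """
    if n_total < 1:
        raise InputValidationError("confidence interval undefined for n_total = 0")
    if not 0 < conf_level < 1:
        raise InputValidationError(f"conf_level must be in (0, 1), got {conf_level}")
    p_hat = n_positive / n_total
    z = stats.norm.ppf((1.0 + conf_level) / 2.0)
    correction = min(0.5, abs(n_positive - n_total * null_p))
    z22n = z * z / (2.0 * n_total)

    p_c = p_hat + correction / n_total
    if p_c >= 1.0:
        upper = 1.0
    else:
        upper = (p_c + z22n + z * math.sqrt(p_c * (1.0 - p_c) / n_total + z22n / (2.0 * n_total))) / (
            1.0 + 2.0 * z22n
        )
    p_c = p_hat - correction / n_total
    if p_c <= 0.0:
        lower = 0.0
    else:
        lower = (p_c + z22n - z * math.sqrt(p_c * (1.0 - p_c) / n_total + z22n / (2.0 * n_total))) / (
            1.0 + 2.0 * z22n
        )
    return max(0.0, lower), min(1.0, upper)


def summarize_directions(
    results: Sequence[DifferentialResult], conf_level: float = 0.95
) -> list[DirectionSummary]:
    """One :class:`DirectionSummary` per event type present among the results.

    Types present in the input but with zero significant events are reported
    with NaN test fields rather than dropped.
    """
    types_present = []
    for r in results:
        if r.event_type not in types_present:
            types_present.append(r.event_type)
    summaries = []
    for event_type in sorted(types_present, key=lambda t: t.value):
        n_pos, n_tot = direction_counts(results, event_type)
        if n_tot == 0:
            summaries.append(
                DirectionSummary(event_type, 0, 0, math.nan, math.nan, math.nan,
                                 math.nan, math.nan, conf_level)
            )
            continue
        chi2, p_value = proportion_test(n_pos, n_tot)
        ci_low, ci_high = proportion_ci(n_pos, n_tot, conf_level)
        summaries.append(
            DirectionSummary(
                event_type=event_type,
                n_positive=n_pos,
                n_total=n_tot,
                proportion=n_pos / n_tot,
                chi2=chi2,
                p_value=p_value,
                ci_low=ci_low,
                ci_high=ci_high,
                conf_level=conf_level,
            )
        )
    return summaries


def summary_frame(summaries: Sequence[DirectionSummary]):
    """Direction summaries as a DataFrame with percentages rendered to 2 dp."""
    import pandas as pd

    from .tables import round_half_up

    return pd.DataFrame(
        {
            "event_type": [str(s.event_type) for s in summaries],
            "n_positive": [s.n_positive for s in summaries],
            "n_total": [s.n_total for s in summaries],
            "proportion_pct": [
                round_half_up(100 * s.proportion, 2) if s.n_total else math.nan
                for s in summaries
            ],
            "chi2": [s.chi2 for s in summaries],
            "p_value": [s.p_value for s in summaries],
            "ci_low_pct": [
                round_half_up(100 * s.ci_low, 2) if s.n_total else math.nan for s in summaries
            ],
            "ci_high_pct": [
                round_half_up(100 * s.ci_high, 2) if s.n_total else math.nan for s in summaries
            ],
            "conf_level": [s.conf_level for s in summaries],
        }
    )
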