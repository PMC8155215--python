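"""Readers and writers for the tab-separated table formats.

Inclusion table dialect
-----------------------
Fixed leading columns ``EVENT``, ``GENE``, ``TYPE``; then, per sample, a pair
``<sample>.PSI`` (percentage with 2 decimals, or NA for zero-coverage) and
``<sample>.Q`` (quality string ``SCORE@inc,exc`` with SCORE one of
N/VLOW/LOW/OK/SOK and integer junction counts). The PSI column is redundant
with the counts and is cross-checked on read.

A lenient mode maps the common external variants of the quality string —
multi-field score prefixes (``OK,OK,SOK@...``), extra numeric fields after
the counts, and fractional mapability-corrected counts (rounded half to even
with a warning) — onto (score, inc, exc), and rejects what it cannot map.

All writers produce deterministic output: rows sorted by event id,
percentages rounded half-up to 2 decimals, probabilities to 4 decimals.
"""

from __future__ import annotations

import logging
import math
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, ParseError
from .events import (
    CoverageScore,
    EventType,
    JunctionCounts,
    SampleObservation,
    SpliceEvent,
    StudyDesign,
    empirical_psi,
)
from .model import DifferentialResult
from .proportions import DirectionSummary, summary_frame

logger = logging.getLogger(__name__)

__all__ = [
    "read_inclusion_table",
    "write_inclusion_table",
    "read_design",
    "read_results",
    "write_results",
    "write_direction_summary",
    "write_truth_table",
    "round_half_up",
]

_LEAD_COLUMNS = ["EVENT", "GENE", "TYPE"]
# printed-percent tolerance for the PSI/count cross-check (2-decimal rounding)
_PSI_PCT_TOL = 0.005 + 1e-9


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at ``decimals`` places (report rendering rule)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _parse_count(token: str, *, lenient: bool, row: int, column: str) -> int:
    token = token.strip()
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"junction count {token!r} is not numeric", row=row, column=column)
    if value < 0:
        raise ParseError(f"junction count {token!r} is negative", row=row, column=column)
    if value != int(value):
        if not lenient:
            raise ParseError(
                f"junction count {token!r} is fractional (use lenient=True to round)",
                row=row, column=column,
            )
        rounded = int(Decimal(repr(value)).quantize(Decimal(1), rounding=ROUND_HALF_EVEN))
        logger.warning(
            "fractional junction count %s rounded half-to-even to %d (row %d, %s)",
            token, rounded, row, column,
        )
        return rounded
    return int(value)


def _parse_quality(q: str, *, lenient: bool, row: int, column: str
                   ) -> tuple[CoverageScore, JunctionCounts]:
    if not isinstance(q, str) or "@" not in q:
        raise ParseError(f"quality string {q!r} lacks 'SCORE@inc,exc' form",
                         row=row, column=column)
    score_part, _, count_part = q.partition("@")
    score_tokens = [t for t in score_part.split(",") if t.strip()]
    if not lenient and len(score_tokens) != 1:
        raise ParseError(f"quality string {q!r} has a multi-field score prefix",
                         row=row, column=column)
    score = None
    for token in score_tokens:
        try:
            score = CoverageScore.from_string(token)
            break
        except Exception:
            continue
    if score is None:
        raise ParseError(f"no recognisable coverage score in {score_part!r}",
                         row=row, column=column)
    count_tokens = [t for t in count_part.split(",") if t.strip()]
    if (not lenient and len(count_tokens) != 2) or len(count_tokens) < 2:
        raise ParseError(f"expected two junction counts in {count_part!r}",
                         row=row, column=column)
    inc = _parse_count(count_tokens[0], lenient=lenient, row=row, column=column)
    exc = _parse_count(count_tokens[1], lenient=lenient, row=row, column=column)
    return score, JunctionCounts(inc=inc, exc=exc)


def read_inclusion_table(path, lenient: bool = False) -> list[SpliceEvent]:
    """Parse an inclusion table into :class:`SpliceEvent` objects.

    Raises :class:`ParseError` (naming row and column) on unknown event types,
    malformed quality strings, duplicate event ids, or a PSI column that
    disagrees with its junction counts beyond rounding tolerance.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:3]) != _LEAD_COLUMNS:
        raise ParseError(
            f"header must start with {_LEAD_COLUMNS}, got {list(frame.columns[:3])}"
        )
    sample_ids = []
    rest = list(frame.columns[3:])
    for i in range(0, len(rest), 2):
        pair = rest[i : i + 2]
        if len(pair) != 2 or not pair[0].endswith(".PSI") or not pair[1].endswith(".Q") \
                or pair[0][:-4] != pair[1][:-2]:
            raise ParseError(f"sample columns must come in '<s>.PSI','<s>.Q' pairs, got {pair}")
        sample_ids.append(pair[0][:-4])
    if not sample_ids:
        raise ParseError("inclusion table has no sample columns")

    events: list[SpliceEvent] = []
    seen: set[str] = set()
    for idx, record in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        row = dict(zip(frame.columns, record))
        event_id = row["EVENT"]
        if event_id in seen:
            raise ParseError(f"duplicate EVENT id {event_id!r}", row=idx, column="EVENT")
        seen.add(event_id)
        try:
            event_type = EventType.from_string(row["TYPE"])
        except Exception as exc:
            raise ParseError(str(exc), row=idx, column="TYPE") from None
        samples = {}
        for sample_id in sample_ids:
            q_col = f"{sample_id}.Q"
            psi_col = f"{sample_id}.PSI"
            score, counts = _parse_quality(row[q_col], lenient=lenient, row=idx, column=q_col)
            psi_cell = row[psi_col]
            emp = empirical_psi(counts)
            if psi_cell is None or (isinstance(psi_cell, float) and math.isnan(psi_cell)) \
                    or str(psi_cell).strip().upper() == "NA":
                if emp is not None:
                    raise ParseError(
                        f"PSI is NA but counts {counts.inc},{counts.exc} are non-zero",
                        row=idx, column=psi_col,
                    )
            else:
                try:
                    psi_pct = float(psi_cell)
                except ValueError:
                    raise ParseError(f"PSI cell {psi_cell!r} is not numeric",
                                     row=idx, column=psi_col)
                if emp is None:
                    raise ParseError(
                        f"PSI {psi_pct} given but counts are zero", row=idx, column=psi_col
                    )
                if abs(psi_pct - 100.0 * emp) > _PSI_PCT_TOL:
                    raise ParseError(
                        f"PSI {psi_pct} disagrees with counts "
                        f"{counts.inc},{counts.exc} ({100 * emp:.4f})",
                        row=idx, column=psi_col,
                    )
            samples[sample_id] = SampleObservation(counts=counts, coverage=score)
        events.append(
            SpliceEvent(event_id=event_id, gene_id=row["GENE"], event_type=event_type,
                        samples=samples)
        )
    return events


def write_inclusion_table(events: Sequence[SpliceEvent], path) -> None:
    """Write events in the inclusion-table dialect (rows sorted by event id)."""
    events = sorted(events, key=lambda e: e.event_id)
    sample_ids = events[0].sample_ids if events else []
    columns = _LEAD_COLUMNS + [c for s in sample_ids for c in (f"{s}.PSI", f"{s}.Q")]
    rows = []
    for event in events:
        if event.sample_ids != sample_ids:
            raise ConfigError("all events must share the same sample set, in the same order")
        row = [event.event_id, event.gene_id, str(event.event_type)]
        for sample_id in sample_ids:
            obs = event.samples[sample_id]
            psi = obs.psi
            row.append("NA" if psi is None else f"{round_half_up(100 * psi, 2):.2f}")
            row.append(f"{obs.coverage}@{obs.counts.inc},{obs.counts.exc}")
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_design(path, reference_condition: str | None = None) -> StudyDesign:
    """Parse a two-column (sample, condition) TSV into a :class:`StudyDesign`.

    When no reference is given, the condition of the first data row is taken
    as reference (logged as a warning).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ConfigError("design table needs two columns: sample, condition")
    if frame.empty:
        raise ConfigError("design table has no rows")
    samples = frame.iloc[:, 0]
    conditions = frame.iloc[:, 1]
    if samples.duplicated().any():
        dupes = sorted(samples[samples.duplicated()].unique())
        raise ConfigError(f"duplicate sample ids in design: {dupes}")
    if reference_condition is None:
        reference_condition = conditions.iloc[0]
        logger.warning(
            "no reference condition given; using %r (first row of the design)",
            reference_condition,
        )
    return StudyDesign(assignment=dict(zip(samples, conditions)),
                       reference=reference_condition)


_RESULT_COLUMNS = [
    "event_id", "event_type", "psi_control_pct", "psi_knockdown_pct", "delta_psi_pct",
    "prob_positive", "prob_differential", "significant",
]


def write_results(results: Sequence[DifferentialResult], path) -> None:
    """Per-event results as TSV; percentages 2 dp, probabilities 4 dp, by event id."""
    rows = []
    for r in sorted(results, key=lambda r: r.event_id):
        rows.append([
            r.event_id,
            str(r.event_type),
            f"{round_half_up(100 * r.psi_control, 2):.2f}",
            f"{round_half_up(100 * r.psi_knockdown, 2):.2f}",
            f"{round_half_up(100 * r.delta_psi, 2):.2f}",
            f"{round_half_up(r.prob_positive, 4):.4f}",
            f"{round_half_up(r.prob_differential, 4):.4f}",
            str(bool(r.significant)),
        ])
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results(path) -> list[DifferentialResult]:
    """Read a results TSV back into :class:`DifferentialResult` objects.

    PSIs come back at the table's 2-decimal percent resolution.
    """
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != _RESULT_COLUMNS:
        raise ParseError(f"unexpected results header: {list(frame.columns)}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            DifferentialResult(
                event_id=str(row.event_id),
                event_type=EventType.from_string(row.event_type),
                psi_control=row.psi_control_pct / 100.0,
                psi_knockdown=row.psi_knockdown_pct / 100.0,
                delta_psi=row.delta_psi_pct / 100.0,
                prob_positive=row.prob_positive,
                prob_differential=row.prob_differential,
                significant=bool(row.significant),
            )
        )
    return out


def write_direction_summary(summaries: Sequence[DirectionSummary], path) -> None:
    """Direction summaries as TSV (event_type ... conf_level)."""
    summary_frame(summaries).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_truth_table(truth: Iterable, path) -> None:
    """Simulation ground truth as TSV."""
    rows = [
        [t.event_id, str(t.event_type), f"{t.true_psi_control:.6f}",
         f"{t.true_psi_knockdown:.6f}", f"{t.true_delta:.6f}", str(bool(t.is_effect))]
        for t in sorted(truth, key=lambda t: t.event_id)
    ]
    pd.DataFrame(
        rows,
        columns=["event_id", "event_type", "true_psi_control", "true_psi_knockdown",
                 "true_delta", "is_effect"],
    ).to_csv(path, sep="\t", index=False)
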