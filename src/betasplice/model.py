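"""Beta-resampling differential splicing: the engine and the model object.

For each event and sample, ``n_emit`` pseudo-PSI values are drawn from
Beta(inc + 1, exc + 1); the scatter of the draws encodes the read-coverage
uncertainty of that sample's PSI. Draws are pooled per condition, the pooled
median is the condition-level PSI, and

    delta_psi = psi(test) - psi(reference).

Significance of delta_psi is the fraction of randomly ordered elementwise
differences (test - reference) of the pooled vectors that are strictly
positive — a Monte-Carlo estimate of P(PSI_test > PSI_ref). An event is called
differentially spliced when max(p, 1 - p) exceeds ``prob_threshold`` (default
0.8) AND |delta_psi| exceeds ``dpsi_threshold`` (default 0.05, the "5%" rule);
both inequalities strict.

Calling is direction-symmetric: events with negative delta_psi are judged on
1 - p against the same threshold, since changes are reported in both
directions.

Reproducibility: one master seed; each event gets an independent RNG
substream keyed by a stable hash of its event id, so results do not depend on
event order and adding or removing events leaves the others untouched.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, InputValidationError
from .events import (
    CoverageScore,
    EventType,
    JunctionCounts,
    SpliceEvent,
    StudyDesign,
    beta_params,
    coverage_pass,
)

__all__ = [
    "CallThresholds",
    "BetaEmission",
    "DifferentialResult",
    "emit_psi",
    "pooled_condition_values",
    "condition_psi",
    "prob_positive",
    "differential_event",
    "run_differential",
    "BetaSpliceModel",
    "BetaSpliceResults",
]


@dataclass(frozen=True)
class CallThresholds:
    """Calling criteria: probability cut, |delta PSI| cut, emissions per sample."""

    prob_threshold: float = 0.8
    dpsi_threshold: float = 0.05
    n_emit: int = 500

    def __post_init__(self) -> None:
        if not 0.5 <= self.prob_threshold < 1:
            raise InputValidationError(
                f"prob_threshold must be in [0.5, 1), got {self.prob_threshold}"
            )
        if not 0 < self.dpsi_threshold < 1:
            raise InputValidationError(
                f"dpsi_threshold must be in (0, 1), got {self.dpsi_threshold}"
            )
        if int(self.n_emit) != self.n_emit or self.n_emit < 1:
            raise InputValidationError(f"n_emit must be a positive integer, got {self.n_emit}")


@dataclass(frozen=True)
class BetaEmission:
    """The beta-distributed PSI pseudo-samples for one sample of one event."""

    sample_id: str
    alpha: int
    beta: int
    values: np.ndarray

    @property
    def n_emit(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DifferentialResult:
    """Per-event differential-splicing result.

    ``prob_positive`` estimates P(PSI_test > PSI_ref); ``prob_differential``
    is max(p, 1-p), the direction-symmetric evidence for any change.
    """

    event_id: str
    event_type: EventType
    psi_control: float
    psi_knockdown: float
    delta_psi: float
    prob_positive: float
    prob_differential: float
    significant: bool


def emit_psi(counts: JunctionCounts, n_emit: int, rng: np.random.Generator,
             sample_id: str = "") -> BetaEmission:
    """Draw ``n_emit`` values from Beta(inc + 1, exc + 1)."""
    if int(n_emit) != n_emit or n_emit < 1:
        raise InputValidationError(f"n_emit must be a positive integer, got {n_emit}")
    a, b = beta_params(counts)
    values = rng.beta(a, b, size=int(n_emit))
    return BetaEmission(sample_id=sample_id, alpha=a, beta=b, values=values)


def pooled_condition_values(
    event: SpliceEvent,
    design: StudyDesign,
    thresholds: CallThresholds,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-condition concatenation of each replicate's beta emissions.

    Samples are visited in sorted order so the draw sequence is deterministic
    given the RNG state, independent of dict ordering.
    """
    pooled: dict[str, list[np.ndarray]] = {c: [] for c in design.conditions}
    for sample_id in sorted(event.samples):
        condition = design.condition_of(sample_id)
        emission = emit_psi(event.samples[sample_id].counts, thresholds.n_emit, rng,
                            sample_id=sample_id)
        pooled[condition].append(emission.values)
    for condition, chunks in pooled.items():
        if not chunks:
            raise ConfigError(
                f"event {event.event_id!r} has no samples in condition {condition!r}"
            )
    return {c: np.concatenate(chunks) for c, chunks in pooled.items()}


def condition_psi(pooled: Sequence[float] | np.ndarray) -> float:
    """Condition-level PSI: the median of the pooled emitted values."""
    pooled = np.asarray(pooled, dtype=float)
    if pooled.size == 0:
        raise InputValidationError("cannot take the median of an empty value sequence")
    return float(np.median(pooled))


def prob_positive(
    pooled_kd: np.ndarray,
    pooled_ctrl: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Fraction of randomly ordered differences (test - reference) that are > 0.

    Both pooled vectors are shuffled independently; with unequal replicate
    counts the longer vector is truncated (after shuffling, i.e. subsampled
    without replacement) to the shorter length so the differences stay
    elementwise. Ties at exactly zero count as not positive.
    """
    kd = np.asarray(pooled_kd, dtype=float)
    ctrl = np.asarray(pooled_ctrl, dtype=float)
    if kd.size == 0 or ctrl.size == 0:
        raise InputValidationError("pooled emission vectors must be non-empty")
    kd = rng.permutation(kd)
    ctrl = rng.permutation(ctrl)
    n = min(kd.size, ctrl.size)
    diffs = kd[:n] - ctrl[:n]
    return float(np.count_nonzero(diffs > 0) / n)


def _event_rng(master_seed: int, event_id: str) -> np.random.Generator:
    # stable across runs and platforms: substream keyed by sha256 of the id
    digest = hashlib.sha256(event_id.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % (2**32), *words]))


def differential_event(
    event: SpliceEvent,
    design: StudyDesign,
    thresholds: CallThresholds,
    rng: np.random.Generator,
) -> DifferentialResult:
    """Full per-event computation: condition PSIs, delta PSI, probability, call."""
    pooled = pooled_condition_values(event, design, thresholds, rng)
    ref, test = design.conditions
    psi_ctrl = condition_psi(pooled[ref])
    psi_kd = condition_psi(pooled[test])
    delta = psi_kd - psi_ctrl
    p_pos = prob_positive(pooled[test], pooled[ref], rng)
    p_diff = max(p_pos, 1.0 - p_pos)
    significant = (p_diff > thresholds.prob_threshold) and (abs(delta) > thresholds.dpsi_threshold)
    return DifferentialResult(
        event_id=event.event_id,
        event_type=event.event_type,
        psi_control=psi_ctrl,
        psi_knockdown=psi_kd,
        delta_psi=delta,
        prob_positive=p_pos,
        prob_differential=p_diff,
        significant=significant,
    )


def run_differential(
    events: Iterable[SpliceEvent],
    design: StudyDesign,
    thresholds: CallThresholds | None = None,
    master_seed: int = 0,
) -> list[DifferentialResult]:
    """Differential results for a collection of (pre-filtered) events.

    Each event draws from its own seed-derived substream, so the output is
    invariant to the order events arrive in.
    """
    thresholds = thresholds or CallThresholds()
    seen: set[str] = set()
    results = []
    for event in events:
        if event.event_id in seen:
            raise InputValidationError(f"duplicate event_id {event.event_id!r}")
        seen.add(event.event_id)
        rng = _event_rng(master_seed, event.event_id)
        results.append(differential_event(event, design, thresholds, rng))
    results.sort(key=lambda r: r.event_id)
    return results


class BetaSpliceModel:
    """Differential-splicing model over a set of events and a two-condition design.

    Parameters
    ----------
    events
        Splice events with per-sample junction counts and coverage scores.
    design
        Two-condition study design; differences are test minus reference.
    thresholds
        Calling criteria (probability > 0.8, |delta PSI| > 0.05, 500 emissions
        per sample by default).
    min_coverage
        Events with any sample scoring below this are excluded before any
        emission (default VLOW).

    Examples
    --------
    >>> model = BetaSpliceModel.from_tables("inclusion.tsv", "design.tsv",
    ...                                     reference_condition="control")
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        events: Sequence[SpliceEvent],
        design: StudyDesign,
        thresholds: CallThresholds | None = None,
        min_coverage: CoverageScore = CoverageScore.VLOW,
    ):
        self.events = list(events)
        self.design = design
        self.thresholds = thresholds or CallThresholds()
        self.min_coverage = min_coverage
        for event in self.events:
            for sample_id in event.samples:
                design.condition_of(sample_id)  # raises ConfigError if missing

    @classmethod
    def from_tables(
        cls,
        inclusion_path,
        design_path,
        reference_condition: str | None = None,
        **kwargs,
    ) -> "BetaSpliceModel":
        """Build the model from an inclusion table and a design table on disk."""
        from .tables import read_design, read_inclusion_table

        events = read_inclusion_table(inclusion_path)
        design = read_design(design_path, reference_condition=reference_condition)
        return cls(events, design, **kwargs)

    def fit(self, seed: int = 0) -> "BetaSpliceResults":
        """Run the resampling analysis; deterministic given ``seed``."""
        kept = [e for e in self.events if coverage_pass(e, self.min_coverage)]
        results = run_differential(kept, self.design, self.thresholds, master_seed=seed)
        return BetaSpliceResults(
            model=self,
            results=results,
            n_input=len(self.events),
            n_filtered=len(self.events) - len(kept),
            seed=seed,
        )


@dataclass
class BetaSpliceResults:
    """Fitted results: one :class:`DifferentialResult` per retained event."""

    model: BetaSpliceModel
    results: list[DifferentialResult]
    n_input: int
    n_filtered: int
    seed: int
    _frame: "object" = field(default=None, repr=False, compare=False)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.results)

    def results_frame(self):
        """Per-event results as a pandas DataFrame (PSI as fractions)."""
        import pandas as pd

        if self._frame is None:
            self._frame = pd.DataFrame(
                {
                    "event_id": [r.event_id for r in self.results],
                    "event_type": [str(r.event_type) for r in self.results],
                    "psi_control": [r.psi_control for r in self.results],
                    "psi_knockdown": [r.psi_knockdown for r in self.results],
                    "delta_psi": [r.delta_psi for r in self.results],
                    "prob_positive": [r.prob_positive for r in self.results],
                    "prob_differential": [r.prob_differential for r in self.results],
                    "significant": [r.significant for r in self.results],
                }
            )
        return self._frame

    def direction_summary(self, conf_level: float = 0.95):
        """Per-event-type direction-of-change summaries (see proportions)."""
        from .proportions import summarize_directions

        return summarize_directions(self.results, conf_level=conf_level)

    def summary(self, conf_level: float = 0.95) -> str:
        """Human-readable run summary, statsmodels style."""
        from .proportions import summary_frame

        ref, test = self.model.design.conditions
        th = self.model.thresholds
        lines = [
            "Beta-resampling differential splicing",
            "=" * 54,
            f"conditions:        {test} vs {ref} (reference)",
            f"events read:       {self.n_input}",
            f"events filtered:   {self.n_filtered} (coverage < {self.model.min_coverage})",
            f"events tested:     {len(self.results)}",
            f"events called:     {self.n_significant} "
            f"(P > {th.prob_threshold:g}, |dPSI| > {th.dpsi_threshold * 100:g}%)",
            f"emissions/sample:  {th.n_emit}",
            f"seed:              {self.seed}",
            "",
            "Direction of change among called events (positive = higher PSI in test):",
        ]
        frame = summary_frame(self.direction_summary(conf_level))
        lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """|delta PSI| vs differential probability scatter; called events marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        th = self.model.thresholds
        frame = self.results_frame()
        called = frame["significant"]
        ax.scatter(frame.loc[~called, "delta_psi"] * 100,
                   frame.loc[~called, "prob_differential"], s=8, c="0.6", label="not called")
        ax.scatter(frame.loc[called, "delta_psi"] * 100,
                   frame.loc[called, "prob_differential"], s=10, c="crimson", label="called")
        ax.axhline(th.prob_threshold, ls="--", lw=0.8, c="k")
        for x in (-th.dpsi_threshold * 100, th.dpsi_threshold * 100):
            ax.axvline(x, ls="--", lw=0.8, c="k")
        ax.set_xlabel("delta PSI (%)")
        ax.set_ylabel("P(differential)")
        ax.legend(frameon=False)
        return ax
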