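"""Domain types for alternative-splicing events quantified from junction reads.

An AS event (skipped exon, retained intron, or alternative 5'/3' splice site)
is observed, per sample, as a pair of junction read counts: reads supporting
inclusion of the alternative sequence (``inc``) and reads supporting its
exclusion (``exc``). The percent-spliced-in (PSI) is ``inc / (inc + exc)``.
Read-coverage uncertainty of a PSI is modelled with the conjugate
Beta(inc + 1, exc + 1) posterior of a binomial inclusion model under a uniform
prior; the +1 pseudo-counts keep both shape parameters strictly positive even
for zero-count samples.

PSI is held internally as a fraction in [0, 1] everywhere; only table writers
render it as a percentage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigError, InputValidationError

__all__ = [
    "CoverageScore",
    "EventType",
    "JunctionCounts",
    "SampleObservation",
    "SpliceEvent",
    "StudyDesign",
    "beta_params",
    "beta_mean",
    "empirical_psi",
    "coverage_pass",
]


class CoverageScore(enum.IntEnum):
    """Ordinal per-sample read-coverage quality label, N < VLOW < LOW < OK < SOK.

    The analysis keeps an event only if every sample scores at least VLOW.
    Unknown score strings are rejected, never coerced.
    """

    N = 0
    VLOW = 1
    LOW = 2
    OK = 3
    SOK = 4

    @classmethod
    def from_string(cls, label: str) -> "CoverageScore":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise InputValidationError(
                f"unknown coverage score {label!r}; expected one of "
                f"{', '.join(m.name for m in cls)}"
            ) from None

    def __str__(self) -> str:  # table rendering
        return self.name


class EventType(str, enum.Enum):
    """The four splicing-decision categories."""

    ES = "ES"  # exon skipping
    IR = "IR"  # intron retention
    ALT5 = "Alt5"  # alternative 5' splice site
    ALT3 = "Alt3"  # alternative 3' splice site

    @classmethod
    def from_string(cls, label: str) -> "EventType":
        for member in cls:
            if member.value.lower() == label.strip().lower():
                return member
        raise InputValidationError(
            f"unknown event type {label!r}; expected one of "
            f"{', '.join(m.value for m in cls)}"
        )

    def __str__(self) -> str:
        return self.value


def _check_count(value: int, name: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int,)):
        # numpy integers pass via int() upstream; be strict here
        try:
            as_int = int(value)
        except (TypeError, ValueError):
            raise InputValidationError(f"{name} must be an integer, got {value!r}") from None
        if as_int != value:
            raise InputValidationError(f"{name} must be an integer, got {value!r}")
        value = as_int
    if value < 0:
        raise InputValidationError(f"{name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class JunctionCounts:
    """Junction reads supporting inclusion (inc) and exclusion (exc)."""

    inc: int
    exc: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "inc", _check_count(self.inc, "inc"))
        object.__setattr__(self, "exc", _check_count(self.exc, "exc"))

    @property
    def total(self) -> int:
        return self.inc + self.exc


def beta_params(counts: JunctionCounts) -> tuple[int, int]:
    """Shape parameters (alpha, beta) = (inc + 1, exc + 1) of the PSI posterior."""
    return counts.inc + 1, counts.exc + 1


def beta_mean(counts: JunctionCounts) -> float:
    """Posterior mean (inc+1)/(inc+exc+2), a shrunk approximation of the PSI."""
    a, b = beta_params(counts)
    return a / (a + b)


def empirical_psi(counts: JunctionCounts) -> float | None:
    """Raw PSI inc/(inc+exc); None when the event has no junction reads.

    The undefined marker is deliberate: 0 and 0.5 are meaningful PSI values
    and must not stand in for "no information".
    """
    if counts.total == 0:
        return None
    return counts.inc / counts.total


@dataclass(frozen=True)
class SampleObservation:
    """One sample's view of one event: counts plus coverage quality."""

    counts: JunctionCounts
    coverage: CoverageScore

    @property
    def psi(self) -> float | None:
        return empirical_psi(self.counts)


@dataclass(frozen=True)
class SpliceEvent:
    """One AS event with per-sample junction counts and coverage scores."""

    event_id: str
    gene_id: str
    event_type: EventType
    samples: Mapping[str, SampleObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.event_type, EventType):
            object.__setattr__(self, "event_type", EventType.from_string(str(self.event_type)))
        object.__setattr__(self, "samples", dict(self.samples))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)


def coverage_pass(event: SpliceEvent, min_score: CoverageScore = CoverageScore.VLOW) -> bool:
    """True iff every sample of the event scores at least ``min_score``."""
    if not event.samples:
        raise InputValidationError(f"event {event.event_id!r} has no samples")
    return all(obs.coverage >= min_score for obs in event.samples.values())


@dataclass(frozen=True)
class StudyDesign:
    """Two-condition design: sample -> condition, with a designated reference.

    ``reference`` is the control condition; the single remaining condition is
    the test (knockdown) condition. Differences are always test minus
    reference.
    """

    assignment: Mapping[str, str]
    reference: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        conditions = set(self.assignment.values())
        if len(conditions) != 2:
            raise ConfigError(
                f"design must have exactly two conditions, got {sorted(conditions)!r}"
            )
        if self.reference not in conditions:
            raise ConfigError(
                f"reference condition {self.reference!r} not among {sorted(conditions)!r}"
            )

    @property
    def conditions(self) -> tuple[str, str]:
        """(reference, test) condition labels."""
        return self.reference, self.test

    @property
    def test(self) -> str:
        (other,) = {c for c in self.assignment.values() if c != self.reference}
        return other

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == condition]

    def condition_of(self, sample_id: str) -> str:
        try:
            return self.assignment[sample_id]
        except KeyError:
            raise ConfigError(f"sample {sample_id!r} is not in the study design") from None
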