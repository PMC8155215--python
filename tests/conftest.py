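import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py importable

from betasplice.events import (
    CoverageScore,
    EventType,
    JunctionCounts,
    SampleObservation,
    SpliceEvent,
    StudyDesign,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design_3v3():
    assignment = {f"ctrl_{i}": "control" for i in range(1, 4)}
    assignment.update({f"kd_{i}": "knockdown" for i in range(1, 4)})
    return StudyDesign(assignment=assignment, reference="control")


def make_event(event_id="EV1", event_type=EventType.IR, counts_by_sample=None,
               coverage=CoverageScore.OK, gene_id="GeneA"):
    counts_by_sample = counts_by_sample or {"s1": (10, 10)}
    samples = {
        sid: SampleObservation(counts=JunctionCounts(inc=i, exc=e), coverage=coverage)
        for sid, (i, e) in counts_by_sample.items()
    }
    return SpliceEvent(event_id=event_id, gene_id=gene_id, event_type=event_type,
                       samples=samples)


@pytest.fixture
def single_rep_design():
    return StudyDesign(assignment={"c1": "control", "k1": "knockdown"}, reference="control")
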