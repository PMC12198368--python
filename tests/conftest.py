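from __future__ import annotations

import numpy as np
import pytest

from mitopunct import (
    AlignedRead,
    AnalysisParams,
    ReadSet,
    mouse_like_annotation,
    toy_annotation,
)


@pytest.fixture(scope="session")
def toy_ann():
    return toy_annotation()


@pytest.fixture(scope="session")
def mouse_ann():
    return mouse_like_annotation()


@pytest.fixture
def params():
    return AnalysisParams()


def make_read(start, end, strand="+", read_id="r", sample="s"):
    return AlignedRead(read_id, start, end, strand, sample)


@pytest.fixture
def random_toy_reads(toy_ann):
    """1,000 random reads over the toy genome (mixed strands, seeded)."""
    rng = np.random.default_rng(2024)
    reads = []
    for i in range(1000):
        a, b = sorted(rng.integers(0, toy_ann.genome_length, size=2))
        if a == b:
            b += 1
        strand = "+" if rng.random() < 0.8 else "-"
        reads.append(AlignedRead(f"rand{i}", int(a), int(b), strand, "rand"))
    return ReadSet("rand", tuple(reads))
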