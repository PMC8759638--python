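"""Shared fixtures: small genomes, default config, fragment factories."""

from __future__ import annotations

import numpy as np
import pytest

from minidomain import AnalysisConfig, Fragment, GenomeTable


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def small_genome() -> GenomeTable:
    return GenomeTable({"chr2L": 100_000})


def uniform_short_fragments(
    rng: np.random.Generator,
    n: int,
    chrom: str = "chr2L",
    chrom_len: int = 100_000,
    length: int = 80,
) -> list[Fragment]:
    """n short fragments with uniform midpoints (fixed length for simplicity)."""
    mids = rng.integers(length // 2, chrom_len - length // 2, size=n)
    return [Fragment(chrom, int(m) - length // 2, int(m) - length // 2 + length)
            for m in mids]


def clustered_short_fragments(
    rng: np.random.Generator,
    n: int,
    center: int,
    sd: float,
    chrom: str = "chr2L",
    length: int = 80,
) -> list[Fragment]:
    """n short fragments with ~Normal(center, sd) midpoints."""
    mids = np.rint(rng.normal(center, sd, size=n)).astype(int)
    return [Fragment(chrom, int(m) - length // 2, int(m) - length // 2 + length)
            for m in mids]
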