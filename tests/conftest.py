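"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oristress.core import GenomicTrack
from oristress.synthetic import GenomeConfig, build_genome

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_track(values, bin_size=1000, chrom="chrI", label="") -> GenomicTrack:
    """One-chromosome track from a plain array."""
    return GenomicTrack(bin_size, {chrom: np.asarray(values, dtype=float)}, label=label)


@pytest.fixture(scope="session")
def default_genome():
    """The default study genome: 1 Mb, 40 jittered origins, flanking genes."""
    return build_genome(GenomeConfig())


@pytest.fixture(scope="session")
def small_genome():
    """A 200-kb genome (8 origins) for fast simulation tests."""
    return build_genome(GenomeConfig(chromosomes=(("chrI", 200_000),), seed=3))
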