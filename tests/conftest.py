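import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prdm9scan import GenomeAssembly, Interval, RegionSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    """Three small chromosomes, no sequence: a playground for interval ops."""
    return GenomeAssembly(chroms=[("chr1", 1000), ("chr2", 800), ("chr3", 500)])


@pytest.fixture
def seq_assembly() -> GenomeAssembly:
    """One 15-bp chromosome carrying the headline variant at position 0."""
    return GenomeAssembly(
        chroms=[("chr1", 15)], sequence={"chr1": "CCACCATCACCACAA"}
    )


def random_regions(
    rng: np.random.Generator,
    assembly: GenomeAssembly,
    n: int,
    max_len: int = 50,
    label: str = "rand",
) -> RegionSet:
    """n random intervals on the assembly (shared helper for oracle tests)."""
    intervals = []
    for _ in range(n):
        chrom, length = assembly.chroms[int(rng.integers(len(assembly.chroms)))]
        L = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, length - L + 1))
        intervals.append(Interval(chrom, start, start + L))
    return RegionSet(label=label, intervals=intervals, assembly=assembly)
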