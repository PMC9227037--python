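import numpy as np
import pytest

from triplextad.core import GenomeAssembly, IntervalSet


@pytest.fixture
def tiny_assembly():
    return GenomeAssembly((("chr1", 100_000), ("chr2", 50_000)))


@pytest.fixture
def mb_assembly():
    return GenomeAssembly((("chr1", 1_000_000),))


def random_interval_set(rng, assembly, n, max_len=500):
    """Random valid intervals on an assembly (may overlap)."""
    chroms, starts, ends = [], [], []
    names = assembly.names
    for _ in range(n):
        c = names[int(rng.integers(0, len(names)))]
        L = assembly.length_of(c)
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, L - length + 1))
        chroms.append(c)
        starts.append(start)
        ends.append(start + length)
    return IntervalSet(chroms, starts, ends)


def bitmap_of(iset, assembly):
    """Per-base boolean occupancy map, the brute-force oracle."""
    maps = {c: np.zeros(l, dtype=bool) for c, l in assembly.chromosomes}
    for i in range(len(iset)):
        maps[iset.chroms[i]][iset.starts[i]:iset.ends[i]] = True
    return maps
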