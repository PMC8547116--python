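import numpy as np
import pytest

from landgen import GenotypeMatrix, PopulationMap


def genotypes_from_lists(pop_calls: dict[str, list[list[tuple[int, int]]]],
                         locus_names: list[str] | None = None):
    """Build (GenotypeMatrix, PopulationMap) from per-population call lists.

    ``pop_calls[pop]`` is a list of individuals, each a list of (a1, a2)
    calls, one per locus.
    """
    ids, rows, assignment = [], [], {}
    for p, inds in pop_calls.items():
        for i, calls in enumerate(inds):
            ind = f"{p}_{i + 1}"
            ids.append(ind)
            assignment[ind] = p
            rows.append(calls)
    n_loci = len(rows[0])
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    g = GenotypeMatrix(ids, locus_names, np.array(rows, dtype=np.int64))
    pops = list(pop_calls)
    coords = {p: (float(-51 + i), float(-30 - i)) for i, p in enumerate(pops)}
    m = PopulationMap(pops, assignment, coords)
    return g, m


@pytest.fixture
def two_pop_toy():
    """pop1: AA, AA; pop2: AB, BB at one locus (alleles 100 and 102)."""
    return genotypes_from_lists({
        "p1": [[(100, 100)], [(100, 100)]],
        "p2": [[(100, 102)], [(102, 102)]],
    })
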