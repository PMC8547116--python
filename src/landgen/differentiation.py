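"""Pairwise population differentiation: Weir & Cockerham's theta (FST).

The estimator partitions allelic variance into components a (among
populations), b (among individuals within populations) and c (within
individuals), per allele per locus, with the unequal-sample-size weights of
the original method-of-moments derivation. The multilocus estimate is the
ratio of sums, theta = sum(a) / sum(a + b + c), never the mean of per-locus
ratios. Negative estimates are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, PairwiseMatrix, PopulationMap, ValidationError


def _locus_components(calls_by_pop: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed (a, b, c) over alleles for one locus across r populations.

    ``calls_by_pop[i]`` is the (n_i, 2) array of non-missing calls in
    population i. Returns NaNs when fewer than two populations have >= 2
    genotyped individuals.
    """
    pops = [c for c in calls_by_pop if len(c) >= 2]
    r = len(pops)
    if r < 2:
        return (np.nan, np.nan, np.nan)
    ns = np.array([len(c) for c in pops], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([c.ravel() for c in pops]))
    sa = sb = sc = 0.0
    for a in alleles:
        p_i = np.array([ (c == a).sum() / (2 * len(c)) for c in pops])
        h_i = np.array(
            [((c[:, 0] != c[:, 1]) & ((c == a).any(axis=1))).mean() for c in pops]
        )
        pbar = (ns * p_i).sum() / (r * nbar)
        s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h_i).sum() / (r * nbar)
        sa += (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        sb += (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        sc += hbar / 2
    return (sa, sb, sc)


@dataclass
class FstMatrix:
    """Multilocus pairwise theta plus the per-locus variance components."""

    matrix: PairwiseMatrix
    components: pd.DataFrame  # columns: pop_1, pop_2, locus, a, b, c

    @property
    def labels(self) -> list[str]:
        return self.matrix.labels

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


def pairwise_fst(g: GenotypeMatrix, m: PopulationMap) -> FstMatrix:
    """Weir-Cockerham theta for every population pair.

    Pairs where no locus has >= 2 genotyped individuals in both populations
    are NaN. Missing data reduce the per-locus sample counts.
    """
    idx = m.indices(g)
    pops = m.population_ids
    k = len(pops)
    # pre-extract non-missing calls per (pop, locus)
    calls: dict[tuple[str, int], np.ndarray] = {}
    for p in pops:
        sub = g.calls[idx[p]]
        for j in range(g.n_loci):
            c = sub[:, j, :]
            calls[(p, j)] = c[c[:, 0] != MISSING]

    values = np.zeros((k, k))
    comp_rows = []
    for i in range(k):
        for j2 in range(i + 1, k):
            p1, p2 = pops[i], pops[j2]
            sa = sbc = 0.0
            any_locus = False
            for l in range(g.n_loci):
                a, b, c = _locus_components([calls[(p1, l)], calls[(p2, l)]])
                comp_rows.append((p1, p2, g.locus_names[l], a, b, c))
                if np.isnan(a):
                    continue
                any_locus = True
                sa += a
                sbc += a + b + c
            theta = sa / sbc if any_locus and sbc != 0 else np.nan
            values[i, j2] = values[j2, i] = theta
    matrix = PairwiseMatrix(list(pops), values, symmetric=True)
    components = pd.DataFrame(
        comp_rows, columns=["pop_1", "pop_2", "locus", "a", "b", "c"]
    )
    return FstMatrix(matrix, components)


def linearize_fst(f: FstMatrix | PairwiseMatrix) -> PairwiseMatrix:
    """Rousset's linearization theta / (1 - theta); monotone for theta < 1."""
    matrix = f.matrix if isinstance(f, FstMatrix) else f
    v = matrix.values
    ones = np.argwhere(np.isclose(v, 1.0) & ~np.eye(len(matrix.labels), dtype=bool))
    if len(ones):
        i, j = ones[0]
        raise ValidationError(
            f"theta = 1 between {matrix.labels[i]!r} and {matrix.labels[j]!r}: "
            "linearized distance is infinite"
        )
    out = v / (1.0 - v)
    np.fill_diagonal(out, 0.0)
    return PairwiseMatrix(list(matrix.labels), out, symmetric=True)
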