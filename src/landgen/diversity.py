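"""Per-population genetic diversity statistics and within-population tests.

Implements the classical microsatellite summary toolkit: allele frequencies,
observed and Nei-unbiased expected heterozygosity, hypergeometric rarefied
allelic richness, private alleles, the Garza-Williamson M ratio, the
Weir-Cockerham within-population inbreeding coefficient f (FIS) with
bootstrap-over-loci confidence limits, Hardy-Weinberg exact tests
(full Levene enumeration for biallelic loci, Guo-Thompson Markov chain
otherwise) and a G-statistic permutation test of linkage disequilibrium.

Statistics are computed over non-missing gene copies only; sample sizes vary
per (population, locus) accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import MISSING, GenotypeMatrix, PopulationMap, ValidationError


# ---------------------------------------------------------------------------
# Counts and frequencies
# ---------------------------------------------------------------------------

def allele_counts(
    g: GenotypeMatrix, m: PopulationMap
) -> dict[str, dict[str, dict[int, int]]]:
    """Non-missing allele-copy counts per population per locus.

    Returns ``counts[pop][locus] = {allele_size: n_copies}`` (empty dict when
    every call is missing).
    """
    idx = m.indices(g)
    out: dict[str, dict[str, dict[int, int]]] = {}
    for p, rows in idx.items():
        out[p] = {}
        for j, loc in enumerate(g.locus_names):
            alleles = g.calls[np.ix_(rows, [j])][:, 0, :].ravel()
            alleles = alleles[alleles != MISSING]
            sizes, counts = np.unique(alleles, return_counts=True)
            out[p][loc] = {int(a): int(c) for a, c in zip(sizes, counts)}
    return out


def allele_frequencies(g: GenotypeMatrix, m: PopulationMap) -> pd.DataFrame:
    """Long-form allele frequency table.

    Columns: population, locus, allele, count, frequency. A
    (population, locus) with no data contributes a single row with
    ``allele = NaN`` and ``defined = False``.
    """
    rows = []
    for p, loci in allele_counts(g, m).items():
        for loc, counts in loci.items():
            total = sum(counts.values())
            if total == 0:
                rows.append((p, loc, np.nan, 0, np.nan, False))
                continue
            for a, c in sorted(counts.items()):
                rows.append((p, loc, a, c, c / total, True))
    return pd.DataFrame(
        rows, columns=["population", "locus", "allele", "count", "frequency", "defined"]
    )


def _per_locus_frame(values: dict[str, dict[str, float]], m: PopulationMap,
                     loci: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {loc: [values[p].get(loc, np.nan) for p in m.population_ids] for loc in loci},
        index=list(m.population_ids),
    )


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def observed_heterozygosity(g: GenotypeMatrix, m: PopulationMap) -> pd.DataFrame:
    """Ho per population x locus: fraction of non-missing calls with two
    distinct alleles. Row means (over defined loci) in column ``mean``."""
    idx = m.indices(g)
    out: dict[str, dict[str, float]] = {}
    for p, rows in idx.items():
        out[p] = {}
        for j, loc in enumerate(g.locus_names):
            calls = g.calls[rows, j, :]
            ok = calls[:, 0] != MISSING
            if not ok.any():
                continue
            out[p][loc] = float((calls[ok, 0] != calls[ok, 1]).mean())
    df = _per_locus_frame(out, m, g.locus_names)
    df["mean"] = df.mean(axis=1, skipna=True)
    return df


def expected_heterozygosity(g: GenotypeMatrix, m: PopulationMap) -> pd.DataFrame:
    """Nei's unbiased He: ``n/(n-1) * (1 - sum p_a^2)`` with n = gene copies.

    Undefined (NaN) where fewer than 2 gene copies are observed.
    """
    counts = allele_counts(g, m)
    out: dict[str, dict[str, float]] = {}
    for p, loci in counts.items():
        out[p] = {}
        for loc, cnt in loci.items():
            n = sum(cnt.values())
            if n < 2:
                continue
            freqs = np.array(list(cnt.values()), dtype=float) / n
            he = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
            out[p][loc] = float(np.clip(he, 0.0, 1.0))
    df = _per_locus_frame(out, m, g.locus_names)
    df["mean"] = df.mean(axis=1, skipna=True)
    return df


# ---------------------------------------------------------------------------
# Allelic richness, private alleles, Garza-Williamson
# ---------------------------------------------------------------------------

def _rarefied_richness(counts: Mapping[int, int], g_genes: int) -> float:
    n = sum(counts.values())
    # AR = sum over alleles of P(allele present in a subsample of g_genes)
    total = 0.0
    for c in counts.values():
        total += 1.0 - math.comb(n - c, g_genes) / math.comb(n, g_genes)
    return total


def default_rarefaction_size(g: GenotypeMatrix, m: PopulationMap) -> int:
    """Smallest non-zero gene-copy count over (population, locus) cells."""
    counts = allele_counts(g, m)
    sizes = [
        sum(cnt.values())
        for loci in counts.values()
        for cnt in loci.values()
        if sum(cnt.values()) > 0
    ]
    if not sizes:
        raise ValidationError("no genotyped cells: cannot choose rarefaction size")
    return min(sizes)


def rarefied_allelic_richness(
    g: GenotypeMatrix, m: PopulationMap, g_genes: int | None = None
) -> pd.DataFrame:
    """Expected allele count in a hypergeometric subsample of ``g_genes``
    gene copies, per population x locus; cells with fewer copies are NaN and
    excluded from the row mean."""
    if g_genes is None:
        g_genes = default_rarefaction_size(g, m)
    if g_genes < 1:
        raise ValidationError("rarefaction size must be >= 1")
    counts = allele_counts(g, m)
    out: dict[str, dict[str, float]] = {}
    for p, loci in counts.items():
        out[p] = {}
        for loc, cnt in loci.items():
            n = sum(cnt.values())
            if n < g_genes or n == 0:
                continue
            out[p][loc] = _rarefied_richness(cnt, g_genes)
    df = _per_locus_frame(out, m, g.locus_names)
    df["mean"] = df.mean(axis=1, skipna=True)
    df.attrs["rarefaction_size"] = g_genes
    return df


def private_alleles(g: GenotypeMatrix, m: PopulationMap) -> pd.Series:
    """Count of alleles observed in exactly one population, per population."""
    counts = allele_counts(g, m)
    seen: dict[tuple[str, int], set[str]] = {}
    for p, loci in counts.items():
        for loc, cnt in loci.items():
            for a in cnt:
                seen.setdefault((loc, a), set()).add(p)
    out = {p: 0 for p in m.population_ids}
    for (_, _), pops in seen.items():
        if len(pops) == 1:
            out[next(iter(pops))] += 1
    return pd.Series(out, name="private_alleles")


def garza_williamson(
    g: GenotypeMatrix,
    m: PopulationMap,
    repeat_units: Mapping[str, int] | int = 2,
) -> pd.DataFrame:
    """Garza-Williamson M = k / (r + 1) per population x locus.

    ``k`` is the number of distinct alleles and ``r`` the allele-size range in
    repeat units. Allele sizes must be integer multiples of the locus repeat
    unit apart; M is in (0, 1], with 1 for a contiguous allele ladder.
    """
    if isinstance(repeat_units, int):
        repeat_units = {loc: repeat_units for loc in g.locus_names}
    counts = allele_counts(g, m)
    out: dict[str, dict[str, float]] = {}
    for p, loci in counts.items():
        out[p] = {}
        for loc, cnt in loci.items():
            if not cnt:
                continue
            unit = repeat_units[loc]
            sizes = np.array(sorted(cnt))
            if ((sizes - sizes[0]) % unit != 0).any():
                raise ValidationError(
                    f"locus {loc!r}: allele sizes not on a {unit}-bp ladder"
                )
            r = int((sizes[-1] - sizes[0]) // unit)
            out[p][loc] = len(sizes) / (r + 1)
    df = _per_locus_frame(out, m, g.locus_names)
    df["mean"] = df.mean(axis=1, skipna=True)
    return df


# ---------------------------------------------------------------------------
# Weir-Cockerham FIS with bootstrap over loci
# ---------------------------------------------------------------------------

def _fis_components(g: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """Per-locus summed Weir-Cockerham (b, c) components for one population.

    Returns shape (n_loci, 2): [sum_b, sum_c] over alleles; NaN rows where the
    locus has < 2 genotyped individuals.
    """
    out = np.full((g.n_loci, 2), np.nan)
    for j in range(g.n_loci):
        calls = g.calls[rows, j, :]
        ok = calls[:, 0] != MISSING
        calls = calls[ok]
        n = len(calls)
        if n < 2:
            continue
        alleles, inverse = np.unique(calls.ravel(), return_inverse=True)
        inv = inverse.reshape(-1, 2)
        het = inv[:, 0] != inv[:, 1]
        sb = sc = 0.0
        for a_idx in range(len(alleles)):
            p = float((inv == a_idx).sum()) / (2 * n)
            h = float((het & ((inv == a_idx).any(axis=1))).sum()) / n
            sb += n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            sc += h / 2.0
        out[j] = (sb, sc)
    return out


@dataclass
class FisResult:
    population: str
    fis: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int


def fis_bootstrap(
    g: GenotypeMatrix,
    m: PopulationMap,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Weir-Cockerham f (FIS) per population with bootstrap-over-loci CIs.

    f = 1 - sum(c) / sum(b + c) with (b, c) variance components summed over
    alleles and loci. The confidence interval is the 2.5/97.5 percentile of f
    recomputed on loci resampled with replacement; the two-sided p-value is
    the bootstrap tail probability of f crossing zero (add-one rule).
    With a single informative locus the CI and p-value are NaN.
    """
    idx = m.indices(g)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51F]))
    rows_out = []
    for p in m.population_ids:
        comp = _fis_components(g, idx[p])
        valid = ~np.isnan(comp[:, 0])
        comp_v = comp[valid]
        denom = comp_v.sum(axis=0)[0] + comp_v.sum(axis=0)[1]
        if len(comp_v) == 0 or denom == 0:
            rows_out.append((p, np.nan, np.nan, np.nan, np.nan, n_boot, seed))
            continue
        fis = 1.0 - comp_v[:, 1].sum() / denom
        if len(comp_v) < 2:
            rows_out.append((p, fis, np.nan, np.nan, np.nan, n_boot, seed))
            continue
        draws = rng.integers(0, len(comp_v), size=(n_boot, len(comp_v)))
        boot_b = comp_v[draws, 0].sum(axis=1)
        boot_c = comp_v[draws, 1].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot_f = 1.0 - boot_c / (boot_b + boot_c)
        boot_f = boot_f[np.isfinite(boot_f)]
        lo, hi = np.percentile(boot_f, [2.5, 97.5])
        nb = len(boot_f)
        p_low = (1 + np.sum(boot_f <= 0)) / (1 + nb)
        p_high = (1 + np.sum(boot_f >= 0)) / (1 + nb)
        pval = min(1.0, 2.0 * min(p_low, p_high))
        rows_out.append((p, fis, lo, hi, pval, n_boot, seed))
    return pd.DataFrame(
        rows_out,
        columns=["population", "fis", "ci_low", "ci_high", "p_value", "n_boot", "seed"],
    ).set_index("population")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact tests
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, log_const: float) -> float:
    """Log conditional probability of a genotype-count table given allele
    counts (Levene's distribution). ``table`` is lower-triangular (i >= j)."""
    het = np.tril(table, -1).sum()
    log_num = het * math.log(2.0) - gammaln(table[np.tril_indices_from(table)] + 1).sum()
    return float(log_const + log_num)


def _levene_log_const(allele_counts_: np.ndarray, n: int) -> float:
    # log [ n! * prod(m_a!) / (2n)! ]
    return float(
        gammaln(n + 1) + gammaln(allele_counts_ + 1).sum() - gammaln(2 * n + 1)
    )


def hwe_enumerate_biallelic(n_het_obs: int, n_a: int, n_b: int) -> float:
    """Exact Levene p-value for a biallelic locus (probability test).

    Enumerates every heterozygote count compatible with the allele counts and
    sums the probabilities of tables no more probable than the observed one.
    """
    n = (n_a + n_b) // 2
    h_min = n_a % 2
    probs = {}
    for h in range(h_min, min(n_a, n_b) + 1, 2):
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        if naa < 0 or nbb < 0 or naa + nbb + h != n:
            continue
        logp = (
            gammaln(n + 1) - gammaln(naa + 1) - gammaln(h + 1) - gammaln(nbb + 1)
            + h * math.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
        )
        probs[h] = math.exp(logp)
    p_obs = probs[n_het_obs]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def _hwe_mc(table: np.ndarray, n_steps: int, rng: np.random.Generator) -> float:
    """Markov-chain exact test of Hardy-Weinberg (probability-based rejection).

    The chain state is the assignment of the 2n allele copies to the 2n
    gamete positions of the n diploid genotypes; a step swaps the contents of
    two uniformly chosen positions and is always accepted, so the chain is
    uniform over assignments and the induced genotype tables follow Levene's
    conditional distribution exactly. The p-value is the fraction of visited
    states whose table probability does not exceed the observed table's.
    """
    k = table.shape[0]
    alleles: list[int] = []
    for i in range(k):
        for j in range(i + 1):
            alleles.extend([i, j] * int(table[i, j]))
    pos = np.array(alleles, dtype=np.int64)  # position 2t, 2t+1 = genotype t
    n = len(pos) // 2
    counts = table.astype(np.int64).copy()
    het = int(np.tril(counts, -1).sum())

    log_fact = gammaln(np.arange(2 * n + 2) + 1.0)
    log2 = math.log(2.0)
    obs_logp = het * log2 - log_fact[counts[np.tril_indices(k)]].sum()
    cur_logp = obs_logp
    hits = 0
    pick = rng.integers(0, 2 * n, size=(n_steps, 2))
    for s in range(n_steps):
        p1, p2 = pick[s]
        s1, s2 = p1 >> 1, p2 >> 1
        a1, a2 = pos[p1], pos[p2]
        if s1 != s2 and a1 != a2:
            o1a, o1b = pos[2 * s1], pos[2 * s1 + 1]
            o2a, o2b = pos[2 * s2], pos[2 * s2 + 1]
            pos[p1], pos[p2] = a2, a1
            n1a, n1b = pos[2 * s1], pos[2 * s1 + 1]
            n2a, n2b = pos[2 * s2], pos[2 * s2 + 1]
            delta = 0.0
            dhet = 0
            for ga, gb, sign in (
                (o1a, o1b, -1), (o2a, o2b, -1), (n1a, n1b, +1), (n2a, n2b, +1),
            ):
                if ga < gb:
                    ga, gb = gb, ga
                c = counts[ga, gb]
                if sign < 0:
                    delta += log_fact[c] - log_fact[c - 1]
                    counts[ga, gb] = c - 1
                else:
                    delta -= log_fact[c + 1] - log_fact[c]
                    counts[ga, gb] = c + 1
                if ga != gb:
                    dhet += sign
            cur_logp += delta + dhet * log2
            het += dhet
        hits += cur_logp <= obs_logp + 1e-12
    return (1 + hits) / (1 + n_steps)


@dataclass
class HWETestResult:
    population: str
    locus: str
    p_value: float
    method: str
    n_steps: int
    seed: int


def hwe_exact_test(
    g: GenotypeMatrix,
    m: PopulationMap,
    n_steps: int = 1_000_000,
    seed: int = 0,
    enumeration_max_n: int = 50,
) -> pd.DataFrame:
    """Hardy-Weinberg exact test per (population, locus).

    Biallelic loci with <= ``enumeration_max_n`` individuals use full Levene
    enumeration; everything else the Guo-Thompson Markov chain with
    ``n_steps`` steps. Monomorphic or under-sampled cells are skipped and
    flagged with method ``"skipped"``.
    """
    idx = m.indices(g)
    results = []
    for p in m.population_ids:
        for j, loc in enumerate(g.locus_names):
            calls = g.calls[idx[p], j, :]
            calls = calls[calls[:, 0] != MISSING]
            n = len(calls)
            alleles, inverse = np.unique(calls.ravel(), return_inverse=True)
            k = len(alleles)
            if n < 2 or k < 2:
                results.append((p, loc, np.nan, "skipped", 0, seed))
                continue
            inv = np.sort(inverse.reshape(-1, 2), axis=1)[:, ::-1]  # a >= b
            table = np.zeros((k, k), dtype=np.int64)
            np.add.at(table, (inv[:, 0], inv[:, 1]), 1)
            if k == 2 and n <= enumeration_max_n:
                n_het = int(table[1, 0])
                m_counts = np.array(
                    [2 * table[0, 0] + n_het, 2 * table[1, 1] + n_het]
                )
                pval = hwe_enumerate_biallelic(n_het, int(m_counts[0]), int(m_counts[1]))
                results.append((p, loc, pval, "enumeration", 0, seed))
            else:
                pi = m.population_ids.index(p)
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, 0xA0, pi * g.n_loci + j])
                )
                pval = _hwe_mc(table, n_steps, rng)
                results.append((p, loc, pval, "markov_chain", n_steps, seed))
    return pd.DataFrame(
        results, columns=["population", "locus", "p_value", "method", "n_steps", "seed"]
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium permutation test
# ---------------------------------------------------------------------------

def _g_statistic(codes_a: np.ndarray, codes_b: np.ndarray, ka: int, kb: int) -> float:
    table = np.zeros((ka, kb))
    np.add.at(table, (codes_a, codes_b), 1.0)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return 2.0 * float(terms.sum())


def ld_permutation_test(
    g: GenotypeMatrix,
    m: PopulationMap,
    n_perm: int = 1000,
    seed: int = 0,
    min_n: int = 5,
) -> pd.DataFrame:
    """G-test of two-locus genotypic association, permutation null.

    For each population and locus pair, the statistic is the log-likelihood
    ratio G of the joint genotype contingency table; the null distribution is
    built by permuting one locus's genotypes across individuals within the
    population. Add-one p-values. Pairs with fewer than ``min_n`` jointly
    genotyped individuals are skipped.
    """
    idx = m.indices(g)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1D]))
    rows = []
    for p in m.population_ids:
        sub = g.calls[idx[p]]
        for j1 in range(g.n_loci):
            for j2 in range(j1 + 1, g.n_loci):
                ok = (sub[:, j1, 0] != MISSING) & (sub[:, j2, 0] != MISSING)
                n = int(ok.sum())
                loc1, loc2 = g.locus_names[j1], g.locus_names[j2]
                if n < min_n:
                    rows.append((p, loc1, loc2, np.nan, np.nan, 0, seed, "skipped"))
                    continue
                ga = np.sort(sub[ok, j1, :], axis=1)
                gb = np.sort(sub[ok, j2, :], axis=1)
                _, codes_a = np.unique(ga, axis=0, return_inverse=True)
                _, codes_b = np.unique(gb, axis=0, return_inverse=True)
                ka, kb = codes_a.max() + 1, codes_b.max() + 1
                if ka < 2 or kb < 2:
                    rows.append((p, loc1, loc2, np.nan, np.nan, 0, seed, "skipped"))
                    continue
                g_obs = _g_statistic(codes_a, codes_b, ka, kb)
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(n)
                    if _g_statistic(codes_a, codes_b[perm], ka, kb) >= g_obs - 1e-12:
                        hits += 1
                pval = (1 + hits) / (1 + n_perm)
                rows.append((p, loc1, loc2, g_obs, pval, n_perm, seed, "ok"))
    return pd.DataFrame(
        rows,
        columns=["population", "locus_1", "locus_2", "g_statistic", "p_value",
                 "n_perm", "seed", "status"],
    )


# ---------------------------------------------------------------------------
# Combined diversity table
# ---------------------------------------------------------------------------

def diversity_table(
    g: GenotypeMatrix,
    m: PopulationMap,
    repeat_units: Mapping[str, int] | int = 2,
    rarefaction_size: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population summary: mean Ho, mean He, rarefied allelic richness,
    private alleles, mean Garza-Williamson M, and FIS with CI and p-value."""
    ho = observed_heterozygosity(g, m)["mean"]
    he = expected_heterozygosity(g, m)["mean"]
    ar = rarefied_allelic_richness(g, m, rarefaction_size)["mean"]
    pa = private_alleles(g, m)
    gw = garza_williamson(g, m, repeat_units)["mean"]
    fis = fis_bootstrap(g, m, n_boot=n_boot, seed=seed)
    out = pd.DataFrame(
        {
            "mean_ho": ho,
            "mean_he": he,
            "allelic_richness": ar,
            "private_alleles": pa,
            "garza_williamson": gw,
            "fis": fis["fis"],
            "fis_ci_low": fis["ci_low"],
            "fis_ci_high": fis["ci_high"],
            "fis_p_value": fis["p_value"],
        }
    )
    out.index.name = "population"
    return out
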