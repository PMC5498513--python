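"""Monte-Carlo exact tests: Hardy-Weinberg and linkage disequilibrium.

The HWE test is the Monte-Carlo version of the exact probability test:
allele copies are shuffled and re-paired holding allele counts fixed,
and the p-value is the proportion of genotype tables whose conditional
probability (Levene's formula) is at most that of the observed table.

The LD test is a probability (G) test on the genotype x genotype
contingency table of two loci, with a Monte-Carlo null formed by
permuting one locus's genotypes among individuals within a population;
population tests are combined across populations by Fisher's method,
mirroring the Genepop workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
from scipy import stats as sps

from .io import MISSING, GenotypeMatrix

#: Returned where a test does not apply (monomorphic locus, etc.).
NOT_APPLICABLE = np.nan

_LOG2 = log(2.0)


def _genotype_log_prob(pair_codes: np.ndarray, n_alleles: int) -> float:
    """Log conditional probability of a genotype table given allele counts.

    Levene (1949): P = n! * prod_a(c_a!) * 2^h / ((2n)! * prod_{i<=j} f_ij!)
    with n individuals, allele copy counts c_a, h heterozygotes and
    genotype counts f_ij.  ``pair_codes`` encodes each individual's
    sorted genotype as i * n_alleles + j.
    """
    n = pair_codes.shape[0]
    codes, f = np.unique(pair_codes, return_counts=True)
    i = codes // n_alleles
    j = codes % n_alleles
    h = int(f[i != j].sum())
    alleles = np.concatenate([i, j])
    c = np.bincount(alleles, weights=np.concatenate([f, f]), minlength=n_alleles)
    # homozygote copies are counted twice by the concatenation above —
    # correct: each genotype contributes both its alleles, so c is right.
    lp = lgamma(n + 1) + sum(lgamma(ci + 1) for ci in c) + h * _LOG2
    lp -= lgamma(2 * n + 1) + sum(lgamma(fi + 1) for fi in f)
    return lp


def _pair_codes(alleles: np.ndarray, index: dict[int, int], n_alleles: int) -> np.ndarray:
    a = np.vectorize(index.__getitem__, otypes=[np.int64])(alleles)
    lo = np.minimum(a[:, 0], a[:, 1])
    hi = np.maximum(a[:, 0], a[:, 1])
    return lo * n_alleles + hi


def hwe_exact_test(
    g: GenotypeMatrix,
    site: str,
    locus: str | int,
    mc_reps: int = 999,
    seed: int | None = None,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test at one (site, locus).

    Returns the estimated exact p-value, or ``NOT_APPLICABLE`` (NaN)
    when fewer than two alleles segregate there.
    """
    j = locus if isinstance(locus, int) else [l.name for l in g.loci].index(locus)
    rows = g.population_indices(site)
    calls = g.calls[rows, j, :]
    calls = calls[calls[:, 0] != MISSING]
    sizes = np.unique(calls.ravel())
    if sizes.size < 2:
        return NOT_APPLICABLE
    index = {int(s): k for k, s in enumerate(sizes)}
    na = sizes.size
    observed = _genotype_log_prob(_pair_codes(calls, index, na), na)

    rng = np.random.default_rng(seed)
    copies = np.vectorize(index.__getitem__, otypes=[np.int64])(calls.ravel())
    n = calls.shape[0]
    hits = 0
    for _ in range(mc_reps):
        perm = rng.permutation(copies).reshape(n, 2)
        lo = np.minimum(perm[:, 0], perm[:, 1])
        hi = np.maximum(perm[:, 0], perm[:, 1])
        lp = _genotype_log_prob(lo * na + hi, na)
        if lp <= observed + 1e-12:
            hits += 1
    return (1 + hits) / (mc_reps + 1)


def hwe_exact_enumeration_2alleles(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-allele HWE p-value by full enumeration over heterozygote counts.

    Independent closed-form check for the Monte-Carlo test: with allele
    counts fixed, the table is determined by the heterozygote count,
    which must share the parity of the rarer-allele copy number.
    """
    n = n_aa + n_ab + n_bb
    ca = 2 * n_aa + n_ab
    cb = 2 * n_bb + n_ab
    rare = min(ca, cb)

    def logp(h: int) -> float:
        aa = (ca - h) // 2
        bb = (cb - h) // 2
        return (
            lgamma(n + 1) + lgamma(ca + 1) + lgamma(cb + 1) + h * _LOG2
            - lgamma(2 * n + 1) - lgamma(aa + 1) - lgamma(h + 1) - lgamma(bb + 1)
        )

    obs = logp(n_ab)
    total = 0.0
    tail = 0.0
    for h in range(rare % 2, rare + 1, 2):
        p = np.exp(logp(h))
        total += p
        if logp(h) <= obs + 1e-12:
            tail += p
    return tail / total


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass
class LdResult:
    """Pairwise-locus LD probability test, per population and pooled."""

    locus_a: str
    locus_b: str
    per_population: dict[str, float]
    pooled: float


def _g_statistic(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    total = table.sum()
    if total == 0 or min(table.shape) < 2:
        return 0.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / exp[mask])))


def _ld_one_population(
    ga: np.ndarray, gb: np.ndarray, mc_reps: int, rng: np.random.Generator
) -> float:
    """G-test p-value for genotype association between two loci."""
    scored = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
    ga, gb = ga[scored], gb[scored]
    if ga.shape[0] < 2:
        return NOT_APPLICABLE

    def codes(calls: np.ndarray) -> np.ndarray:
        lo = np.minimum(calls[:, 0], calls[:, 1])
        hi = np.maximum(calls[:, 0], calls[:, 1])
        _, inv = np.unique(lo * 100000 + hi, return_inverse=True)
        return inv

    ca, cb = codes(ga), codes(gb)
    if ca.max() == 0 or cb.max() == 0:  # a locus monomorphic here
        return NOT_APPLICABLE
    na, nb = ca.max() + 1, cb.max() + 1
    obs_table = np.zeros((na, nb))
    np.add.at(obs_table, (ca, cb), 1)
    g_obs = _g_statistic(obs_table)
    hits = 0
    for _ in range(mc_reps):
        perm = rng.permutation(cb)
        table = np.zeros((na, nb))
        np.add.at(table, (ca, perm), 1)
        if _g_statistic(table) >= g_obs - 1e-12:
            hits += 1
    return (1 + hits) / (mc_reps + 1)


def ld_probability_test(
    g: GenotypeMatrix,
    locus_a: str | int,
    locus_b: str | int,
    scope: str = "pooled",
    mc_reps: int = 499,
    seed: int | None = None,
) -> LdResult:
    """LD probability test between two loci.

    ``scope='site'`` reports only per-population p-values; ``'pooled'``
    additionally combines them with Fisher's method.  Populations where
    either locus is monomorphic are reported as NaN and excluded from
    the pooled combination.
    """
    names = [l.name for l in g.loci]
    ja = locus_a if isinstance(locus_a, int) else names.index(locus_a)
    jb = locus_b if isinstance(locus_b, int) else names.index(locus_b)
    if ja == jb:
        raise ValueError("need two distinct loci")
    rng = np.random.default_rng(seed)
    per = {}
    for pop in g.population_names:
        rows = g.population_indices(pop)
        per[pop] = _ld_one_population(
            g.calls[rows, ja, :], g.calls[rows, jb, :], mc_reps, rng
        )
    pooled = NOT_APPLICABLE
    if scope == "pooled":
        ps = [p for p in per.values() if not np.isnan(p)]
        if ps:
            x2 = -2.0 * float(np.sum(np.log(ps)))
            pooled = float(sps.chi2.sf(x2, 2 * len(ps)))
    return LdResult(names[ja], names[jb], per, pooled)


def bonferroni(pvalues: list[float]) -> list[float]:
    """Bonferroni-adjusted p-values (NaN entries pass through)."""
    m = sum(1 for p in pvalues if not np.isnan(p))
    return [min(1.0, p * m) if not np.isnan(p) else p for p in pvalues]
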