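"""Hierarchical AMOVA, pairwise FST and Mantel / partial Mantel tests.

AMOVA here is the Excoffier sums-of-squares decomposition on
allele-identity (infinite-allele) distances between gene copies, with
three strata: among regions, among populations within regions, and
within populations.  Because the distance between two copies is 0/1,
every sum of squared distances reduces to allele counts, so the whole
analysis — permutations included — runs on count vectors.  Pairwise
FST is the corresponding two-level estimator (the GenAlEx "Phi-PT"
style statistic); an RST variant on squared size differences is
available for comparison.  Permutation tests resample whole diploid
individuals (both gene copies move together).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, SiteTable


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with labels and a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < -1e-12:
                raise ValueError("entries must be nonnegative")
        self.values = v

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(frame.index), frame.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def align(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Count-based sums of squares
# ---------------------------------------------------------------------------


def _locus_layout(g: GenotypeMatrix, locus: int, distance: str = "iam"):
    """Per-individual allele codes and copy counts for one locus.

    Returns (codes, sq_sizes): codes is (n_ind, 2) with -1 for missing;
    for 'rst' distance sq_sizes maps code -> allele size in repeat units.
    """
    calls = g.calls[:, locus, :]
    scored = calls[:, 0] != MISSING
    sizes = np.unique(calls[scored].ravel())
    code = np.full_like(calls, -1)
    if sizes.size:
        lut = {int(s): k for k, s in enumerate(sizes)}
        for c in (0, 1):
            code[scored, c] = [lut[int(v)] for v in calls[scored, c]]
    repeat_sizes = sizes / g.loci[locus].motif_length if distance == "rst" else None
    return code, sizes.size, repeat_sizes


@dataclass
class AmovaResult:
    """Three-level AMOVA: variance components, percentages, Phi statistics."""

    components: dict[str, float]  # among_region, among_pop_within_region, within_pop
    percents: dict[str, float]
    phi_rt: float
    phi_pr: float
    phi_pt: float
    p_values: dict[str, float] = field(default_factory=dict)
    df: dict[str, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        strata = ["among_region", "among_pop_within_region", "within_pop"]
        phi = {"among_region": self.phi_rt,
               "among_pop_within_region": self.phi_pr,
               "within_pop": self.phi_pt}
        return pd.DataFrame(
            {
                "df": [self.df.get(s, np.nan) for s in strata],
                "variance": [self.components[s] for s in strata],
                "percent": [self.percents[s] for s in strata],
                "phi": [phi[s] for s in strata],
                "p": [self.p_values.get(s, np.nan) for s in strata],
            },
            index=strata,
        )


def _three_level_components(counts_pl, pop_region, n_regions):
    """Variance components from per-(pop, locus) allele-count vectors.

    counts_pl: list over loci of (P, A_l) count arrays.
    pop_region: array of region index per population.
    Returns (sigma_a, sigma_b, sigma_c) summed over loci, plus df.
    """
    P = len(pop_region)
    G = n_regions
    sig = np.zeros(3)
    df = None
    for counts in counts_pl:
        n_p = counts.sum(axis=1).astype(float)
        N = n_p.sum()
        if N < 2:
            continue
        reg_counts = np.zeros((G, counts.shape[1]))
        np.add.at(reg_counts, pop_region, counts)
        n_g = reg_counts.sum(axis=1)
        tot_counts = counts.sum(axis=0)

        def ssd(c, n):
            if n < 2:
                return 0.0
            return (n * (n - 1) / 2 - float(np.sum(c * (c - 1) / 2))) / n

        ss_tot = ssd(tot_counts, N)
        ss_wp = sum(ssd(counts[p], n_p[p]) for p in range(P))
        ss_wr = sum(ssd(reg_counts[g], n_g[g]) for g in range(G))
        ss_ap = ss_wr - ss_wp
        ss_ar = ss_tot - ss_wr

        df_a, df_b, df_c = G - 1, P - G, int(N) - P
        sum_np2_by_region = np.zeros(G)
        np.add.at(sum_np2_by_region, pop_region, n_p**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            s_g = float(np.sum(np.where(n_g > 0, sum_np2_by_region / n_g, 0.0)))
        n1 = (N - s_g) / df_b if df_b > 0 else np.nan
        n2 = (s_g - float(np.sum(n_p**2)) / N) / df_a if df_a > 0 else np.nan
        n3 = (N - float(np.sum(n_g**2)) / N) / df_a if df_a > 0 else np.nan

        ms_c = ss_wp / df_c if df_c > 0 else 0.0
        sc = ms_c
        sb = ((ss_ap / df_b) - sc) / n1 if df_b > 0 and n1 > 0 else 0.0
        sa = 0.0
        if df_a > 0 and n3 > 0:
            sa = ((ss_ar / df_a) - sc - n2 * sb) / n3
        sig += (sa, sb, sc)
        df = {"among_region": df_a, "among_pop_within_region": df_b,
              "within_pop": df_c}
    return sig, df


def _counts_for_assignment(code_l, pops, n_pops, n_alleles):
    """(P, A) allele-count array for one locus under a pop assignment."""
    flat_pop = np.repeat(pops, 2)
    flat_code = code_l.ravel()
    ok = flat_code >= 0
    return np.bincount(
        flat_pop[ok] * n_alleles + flat_code[ok], minlength=n_pops * n_alleles
    ).reshape(n_pops, n_alleles)


def amova(
    g: GenotypeMatrix,
    regions: SiteTable | dict[str, str],
    permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Three-level AMOVA (regions / populations / gene copies).

    Variance components are summed over loci; Phi statistics are ratios
    of the summed components.  Permutation p-values: whole individuals
    permuted among populations within regions (for Phi-PR), and whole
    populations permuted among regions (for Phi-RT); Phi-PT tested by
    permuting individuals among populations without restriction.
    """
    region_of = regions.region_of() if isinstance(regions, SiteTable) else dict(regions)
    pop_names = g.population_names
    missing = [p for p in pop_names if p not in region_of]
    if missing:
        raise ValueError(f"populations without region assignment: {missing}")
    region_names = sorted({region_of[p] for p in pop_names})
    if len(region_names) < 2:
        raise ValueError("AMOVA requires >= 2 regions")
    pop_index = {p: i for i, p in enumerate(pop_names)}
    reg_index = {r: i for i, r in enumerate(region_names)}
    pops = np.array([pop_index[p] for p in g.populations])
    pop_region = np.array([reg_index[region_of[p]] for p in pop_names])
    singles = [r for r in region_names
               if np.sum(pop_region == reg_index[r]) == 1]
    if singles:
        warnings.warn(
            f"regions with a single population {singles}: their populations "
            "contribute no among-population-within-region information"
        )

    layouts = [_locus_layout(g, j) for j in range(g.n_loci)]

    def components(pop_assign, preg):
        counts_pl = [
            _counts_for_assignment(code, pop_assign, len(pop_names), na)
            for code, na, _ in layouts
            if na > 0
        ]
        return _three_level_components(counts_pl, preg, len(region_names))

    sig, df = _three_level_components(
        [
            _counts_for_assignment(code, pops, len(pop_names), na)
            for code, na, _ in layouts if na > 0
        ],
        pop_region,
        len(region_names),
    )
    sa, sb, sc = sig
    total = sa + sb + sc
    if total <= 0:
        warnings.warn("no molecular variance: Phi statistics undefined, set to 0")
        phi_rt = phi_pr = phi_pt = 0.0
        percents = dict(among_region=0.0, among_pop_within_region=0.0,
                        within_pop=100.0)
    else:
        phi_rt = sa / total
        phi_pr = sb / (sb + sc) if (sb + sc) > 0 else 0.0
        phi_pt = (sa + sb) / total
        percents = dict(
            among_region=100 * sa / total,
            among_pop_within_region=100 * sb / total,
            within_pop=100 * sc / total,
        )

    p_values: dict[str, float] = {}
    if permutations > 0 and total > 0:
        rng = np.random.default_rng(seed)
        hits_pt = hits_pr = hits_rt = 0
        region_of_ind = pop_region[pops]
        for _ in range(permutations):
            # Phi-PT: individuals among populations, unrestricted
            perm = rng.permutation(pops)
            (a, b, c), _ = components(perm, pop_region)
            t = a + b + c
            if t > 0 and (a + b) / t >= phi_pt - 1e-12:
                hits_pt += 1
            # Phi-PR: individuals among populations within their region
            perm2 = pops.copy()
            for r in range(len(region_names)):
                m = region_of_ind == r
                perm2[m] = rng.permutation(pops[m])
            (a, b, c), _ = components(perm2, pop_region)
            if (b + c) > 0 and b / (b + c) >= phi_pr - 1e-12:
                hits_pr += 1
            # Phi-RT: whole populations among regions
            preg = rng.permutation(pop_region)
            (a, b, c), _ = components(pops, preg)
            t = a + b + c
            if t > 0 and a / t >= phi_rt - 1e-12:
                hits_rt += 1
        p_values = {
            "among_region": (1 + hits_rt) / (permutations + 1),
            "among_pop_within_region": (1 + hits_pr) / (permutations + 1),
            "within_pop": (1 + hits_pt) / (permutations + 1),
        }

    return AmovaResult(
        components=dict(among_region=sa, among_pop_within_region=sb, within_pop=sc),
        percents=percents,
        phi_rt=phi_rt,
        phi_pr=phi_pr,
        phi_pt=phi_pt,
        p_values=p_values,
        df=df or {},
    )


# ---------------------------------------------------------------------------
# Pairwise FST
# ---------------------------------------------------------------------------


def _pair_fst(counts_a_l, counts_b_l) -> float:
    """Two-level AMOVA FST from per-locus allele counts of two groups."""
    sa_sum = sw_sum = 0.0
    for ca, cb in zip(counts_a_l, counts_b_l):
        na, nb = float(ca.sum()), float(cb.sum())
        N = na + nb
        if na < 1 or nb < 1 or N < 3:
            continue

        def ssd(c, n):
            if n < 2:
                return 0.0
            return (n * (n - 1) / 2 - float(np.sum(c * (c - 1) / 2))) / n

        ss_tot = ssd(ca + cb, N)
        ss_w = ssd(ca, na) + ssd(cb, nb)
        df_a, df_w = 1, int(N) - 2
        if df_w <= 0:
            continue
        ms_w = ss_w / df_w
        n0 = (N - (na**2 + nb**2) / N) / df_a
        sa = ((ss_tot - ss_w) / df_a - ms_w) / n0
        sa_sum += sa
        sw_sum += ms_w
    tot = sa_sum + sw_sum
    return sa_sum / tot if tot > 0 else 0.0


def pairwise_fst(
    g: GenotypeMatrix, distance: str = "iam"
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Pairwise FST between every pair of populations.

    Returns a clamped (negative -> 0) :class:`DistanceMatrix` plus a
    long-format side frame holding the raw (possibly negative)
    estimates.  ``distance='iam'`` is the allele-identity estimator;
    ``'rst'`` uses squared size differences in repeat units.
    """
    pops = g.population_names
    if len(pops) < 2:
        raise ValueError("pairwise FST requires >= 2 populations")
    if distance not in ("iam", "rst"):
        raise ValueError("distance must be 'iam' or 'rst'")
    pop_idx = {p: i for i, p in enumerate(pops)}
    pvec = np.array([pop_idx[p] for p in g.populations])
    per_pop_counts: list[list[np.ndarray]] = []
    repeat_sizes = []
    for j in range(g.n_loci):
        code, na, rsz = _locus_layout(g, j, distance)
        counts = _counts_for_assignment(code, pvec, len(pops), max(na, 1))
        per_pop_counts.append([counts[i] for i in range(len(pops))])
        repeat_sizes.append(rsz)

    n = len(pops)
    raw = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            if distance == "iam":
                f = _pair_fst(
                    [per_pop_counts[l][i] for l in range(g.n_loci)],
                    [per_pop_counts[l][k] for l in range(g.n_loci)],
                )
            else:
                f = _pair_rst(
                    [per_pop_counts[l][i] for l in range(g.n_loci)],
                    [per_pop_counts[l][k] for l in range(g.n_loci)],
                    repeat_sizes,
                )
            raw[i, k] = raw[k, i] = f
    clamped = np.clip(raw, 0.0, None)
    np.fill_diagonal(clamped, 0.0)
    records = [
        {"pop_a": pops[i], "pop_b": pops[k], "fst_raw": raw[i, k]}
        for i in range(n)
        for k in range(i + 1, n)
    ]
    return DistanceMatrix(pops, clamped), pd.DataFrame(records)


def _pair_rst(counts_a_l, counts_b_l, repeat_sizes) -> float:
    """Two-level RST analogue on squared repeat-count differences."""
    sa_sum = sw_sum = 0.0
    for ca, cb, x in zip(counts_a_l, counts_b_l, repeat_sizes):
        if x is None:
            continue
        na, nb = float(ca.sum()), float(cb.sum())
        N = na + nb
        if na < 2 or nb < 2:
            continue

        def ssd(c, n):
            s1 = float(np.sum(c * x))
            s2 = float(np.sum(c * x**2))
            return (n * s2 - s1**2) / n

        ss_tot = ssd(ca + cb, N)
        ss_w = ssd(ca, na) + ssd(cb, nb)
        df_w = int(N) - 2
        ms_w = ss_w / df_w
        n0 = N - (na**2 + nb**2) / N
        sa = ((ss_tot - ss_w) - ms_w) / n0
        sa_sum += sa
        sw_sum += ms_w
    tot = sa_sum + sw_sum
    return sa_sum / tot if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _as_matrix(m) -> DistanceMatrix:
    if isinstance(m, DistanceMatrix):
        return m
    if isinstance(m, pd.DataFrame):
        return DistanceMatrix.from_frame(m)
    raise TypeError("expected DistanceMatrix or square DataFrame")


def mantel(
    a, b, permutations: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Mantel test: Pearson r between two distance matrices.

    The p-value is one-sided (greater), from joint row/column
    permutations of ``b`` — the direction isolation-by-distance
    predicts.  Matrices are aligned on labels; needs >= 4 labels.
    """
    a, b = _as_matrix(a), _as_matrix(b)
    b = b.align(a.labels)
    n = len(a.labels)
    if n < 4:
        raise ValueError("Mantel test needs >= 4 labels")
    x = _upper(a.values)
    y = _upper(b.values)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance distance matrix: r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    if permutations <= 0:
        return r_obs, np.nan
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    hits = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        yp = _upper(b.values[np.ix_(p, p)])
        r = float(np.mean(xc * (yp - yp.mean()) / yp.std()))
        if r >= r_obs - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (permutations + 1)


def partial_mantel(
    a, b, c, permutations: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Partial Mantel test of a ~ b controlling c (residual permutation).

    Computes the partial correlation of the upper triangles of ``a``
    and ``b`` given ``c``; significance by permuting the residual
    matrix of ``a`` on ``c`` (Legendre's method), one-sided greater.
    """
    a, b, c = _as_matrix(a), _as_matrix(b), _as_matrix(c)
    b, c = b.align(a.labels), c.align(a.labels)
    n = len(a.labels)
    if n < 4:
        raise ValueError("partial Mantel test needs >= 4 labels")
    x, y, z = _upper(a.values), _upper(b.values), _upper(c.values)
    for v, name in ((x, "a"), (y, "b"), (z, "c")):
        if np.std(v) == 0:
            raise ValueError(f"zero-variance matrix {name!r}")
    ryz = float(np.corrcoef(y, z)[0, 1])
    if abs(ryz) > 1 - 1e-10:
        # c explains b entirely (self-control limit): nothing of b is
        # left to correlate with, so the partial correlation vanishes
        warnings.warn("control matrix explains b entirely; partial r is 0")
        return 0.0, 1.0

    def residual_matrix(m_vals, ctrl_vals):
        iu = np.triu_indices(n, k=1)
        mv, cv = m_vals[iu], ctrl_vals[iu]
        beta = np.polyfit(cv, mv, 1)
        res = np.zeros((n, n))
        res[iu] = mv - (beta[0] * cv + beta[1])
        return res + res.T

    res_a = residual_matrix(a.values, c.values)
    res_b = residual_matrix(b.values, c.values)
    xa, xb = _upper(res_a), _upper(res_b)
    r_obs = float(np.corrcoef(xa, xb)[0, 1])
    if permutations <= 0:
        return r_obs, np.nan
    rng = np.random.default_rng(seed)
    xbc = (xb - xb.mean()) / xb.std()
    hits = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        xp = _upper(res_a[np.ix_(p, p)])
        r = float(np.mean(xbc * (xp - xp.mean()) / xp.std()))
        if r >= r_obs - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (permutations + 1)


def cluster_membership_matrix(labels: dict[str, str]) -> DistanceMatrix:
    """Binary different-cluster matrix (1 = different cluster) for partial Mantel."""
    names = list(labels)
    vals = np.array(
        [[0.0 if labels[i] == labels[j] else 1.0 for j in names] for i in names]
    )
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(names, vals)
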