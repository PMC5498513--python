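"""Per-site diversity statistics and latitude regressions.

Implements the GenAlEx-flavoured descriptive panel for codominant
microsatellite data: mean alleles per locus (na), rare-allele count
(AR), Shannon information index (I), observed and expected
heterozygosity (Ho, He), the inbreeding coefficient
FIS = (He - Ho) / He with a locus-resampling bootstrap CI, and OLS
regressions of any diversity column on latitude.

He is plain Nei gene diversity 1 - sum(p^2); the small-sample unbiased
version (2n/(2n-1) correction) is available behind ``unbiased=True``.
Missing calls are excluded locus-wise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MISSING, GenotypeMatrix, SiteTable

logger = logging.getLogger(__name__)

#: Sentinel returned where FIS is undefined (He = 0).
FIS_UNDEFINED = np.nan


@dataclass
class DiversityRow:
    """One site's diversity panel (one row of a Table-1-style table)."""

    site: str
    n: int
    na: float
    ar: int
    shannon_i: float
    ho: float
    he: float
    fis: float
    fis_ci: tuple[float, float]

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        lo, hi = d.pop("fis_ci")
        d["fis_lo"], d["fis_hi"] = lo, hi
        return d


def fis(ho: float, he: float) -> float:
    """Inbreeding coefficient (He - Ho) / He; NaN where He = 0."""
    if he == 0:
        return FIS_UNDEFINED
    return (he - ho) / he


def _per_locus_stats(
    g: GenotypeMatrix, rows: np.ndarray, unbiased: bool = False
) -> pd.DataFrame:
    """Ho, He, Shannon I, distinct-allele count per locus for given rows.

    Loci with no scored call in these rows get NaN and are dropped from
    site means by the caller.
    """
    recs = []
    for j, locus in enumerate(g.loci):
        calls = g.calls[rows, j, :]
        scored = calls[:, 0] != MISSING
        gsub = calls[scored]
        if gsub.shape[0] == 0:
            recs.append((locus.name, np.nan, np.nan, np.nan, np.nan))
            continue
        copies = gsub.ravel()
        _, counts = np.unique(copies, return_counts=True)
        p = counts / counts.sum()
        he = 1.0 - float(np.sum(p**2))
        if unbiased:
            n2 = counts.sum()
            he *= n2 / (n2 - 1) if n2 > 1 else 1.0
        shannon = float(-np.sum(p * np.log(p)))
        ho = float(np.mean(gsub[:, 0] != gsub[:, 1]))
        recs.append((locus.name, ho, he, shannon, float(len(counts))))
    return pd.DataFrame(recs, columns=["locus", "ho", "he", "shannon", "na"])


def _rare_alleles(g: GenotypeMatrix, rows: np.ndarray, threshold: float) -> int:
    """Alleles present at the site whose pooled (all-site) frequency < threshold."""
    rare = 0
    for j in range(g.n_loci):
        pooled = g.calls[:, j, :].ravel()
        pooled = pooled[pooled != MISSING]
        sizes, counts = np.unique(pooled, return_counts=True)
        freq = dict(zip(sizes.tolist(), (counts / counts.sum()).tolist()))
        here = g.calls[rows, j, :].ravel()
        here = np.unique(here[here != MISSING])
        rare += int(sum(freq[a] < threshold for a in here.tolist()))
    return rare


def diversity_table(
    g: GenotypeMatrix,
    rare_threshold: float = 0.05,
    bootstrap_reps: int = 999,
    ci_level: float = 0.95,
    seed: int | None = 0,
    unbiased: bool = False,
) -> list[DiversityRow]:
    """Per-site diversity panel.

    na, I, Ho and He are means over loci scored at the site; AR counts
    alleles present at the site whose pooled frequency across all sites
    is below ``rare_threshold``.  FIS is computed from the site's mean
    Ho/He, with a percentile CI from ``bootstrap_reps`` locus resamples
    (skipped when ``bootstrap_reps`` is 0).
    """
    rng = np.random.default_rng(seed)
    out = []
    for site in g.population_names:
        rows = g.population_indices(site)
        per = _per_locus_stats(g, rows, unbiased=unbiased)
        dropped = per["ho"].isna()
        if dropped.any():
            logger.warning(
                "site %s: dropping all-missing loci %s from means",
                site,
                per.loc[dropped, "locus"].tolist(),
            )
        per = per.dropna()
        ho, he = float(per["ho"].mean()), float(per["he"].mean())
        ci = (np.nan, np.nan)
        if bootstrap_reps > 0 and len(per) >= 2:
            ci = fis_bootstrap_ci(
                g, site, reps=bootstrap_reps, level=ci_level,
                seed=int(rng.integers(2**31)), unbiased=unbiased,
            )
        elif len(per) == 1:
            warnings.warn(
                f"site {site}: single scored locus, degenerate zero-width CI"
            )
            ci = (fis(ho, he), fis(ho, he))
        out.append(
            DiversityRow(
                site=site,
                n=len(rows),
                na=float(per["na"].mean()),
                ar=_rare_alleles(g, rows, rare_threshold),
                shannon_i=float(per["shannon"].mean()),
                ho=ho,
                he=he,
                fis=fis(ho, he),
                fis_ci=ci,
            )
        )
    return out


def diversity_frame(rows: list[DiversityRow]) -> pd.DataFrame:
    """Table-1-shaped DataFrame (site, n, na, ar, I, Ho, He, FIS, CI)."""
    return pd.DataFrame([r.as_dict() for r in rows])


def fis_bootstrap_ci(
    g: GenotypeMatrix,
    site: str,
    reps: int = 999,
    level: float = 0.95,
    seed: int | None = None,
    unbiased: bool = False,
) -> tuple[float, float]:
    """Percentile bootstrap CI for multilocus FIS, resampling loci.

    Each replicate resamples loci with replacement, recomputes the
    site's mean Ho/He over the resampled loci, and takes
    FIS = (He - Ho)/He.  Replicates with He = 0 are undefined and
    discarded; an error is raised if every replicate is undefined.
    """
    if g.n_loci < 2:
        raise ValueError("bootstrap CI requires >= 2 loci")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    per = _per_locus_stats(g, g.population_indices(site), unbiased=unbiased).dropna()
    ho = per["ho"].to_numpy()
    he = per["he"].to_numpy()
    idx = rng.integers(0, len(per), size=(reps, len(per)))
    he_m = he[idx].mean(axis=1)
    ho_m = ho[idx].mean(axis=1)
    ok = he_m > 0
    if not ok.any():
        raise ValueError(f"site {site}: FIS undefined in every bootstrap replicate")
    f = (he_m[ok] - ho_m[ok]) / he_m[ok]
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(f, alpha)), float(np.quantile(f, 1 - alpha)))


def latitude_regression(
    rows: list[DiversityRow],
    sites: SiteTable,
    response: str = "na",
    exclude: set[str] | frozenset[str] = frozenset(),
) -> tuple[float, float, tuple[int, int], float]:
    """OLS of a diversity column on decimal latitude.

    Returns ``(slope, F, (1, n - 2), p)``.  ``response`` is any numeric
    :class:`DiversityRow` field (na, ar, shannon_i, ho, he, fis).
    Sites in ``exclude`` (e.g. a small-sample locality) are dropped first.
    """
    lat = sites.latitudes()
    pairs = [
        (lat[r.site], getattr(r, response))
        for r in rows
        if r.site not in exclude
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 sites after exclusion")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    n = len(x)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0, 0.0, (1, n - 2), 1.0
    res = sps.linregress(x, y)
    # F for the single regressor equals t^2; cap a numerically perfect fit
    with np.errstate(divide="ignore"):
        f = np.inf if res.stderr == 0 else (res.slope / res.stderr) ** 2
    p = 0.0 if np.isinf(f) else float(sps.f.sf(f, 1, n - 2))
    return float(res.slope), float(f), (1, n - 2), p
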