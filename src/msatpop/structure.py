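"""Model-based Bayesian clustering of multilocus genotypes.

A Gibbs sampler for the admixture model: each allele copy has a latent
cluster of origin Z, each individual an admixture vector Q ~
Dirichlet(alpha), and each cluster allele frequencies P.  Under the
correlated-frequency (F) model, P[k, l] ~ Dirichlet(p_anc[l] *
(1 - F_k) / F_k) around ancestral frequencies with per-cluster drift
F_k; the independent model uses a flat Dirichlet(lambda).  alpha, F_k
and the ancestral frequencies move by Metropolis steps.

The model log-probability reported for choosing K is the
harmonic-style estimator ln P(D) ~ mean(L) - var(L)/2 over
post-burn-in log-likelihood samples, and K is selected by the
rate-of-change rule on successive ln P(D) means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix


@dataclass
class StructureResults:
    """Posterior summaries of one MCMC run at a fixed K."""

    k: int
    q_matrix: pd.DataFrame  # individuals x K admixture proportions
    ln_p_d: float
    alpha_trace: np.ndarray
    loglik_trace: np.ndarray
    seed: int | None
    populations: list[str]

    def __post_init__(self):
        rows = self.q_matrix.to_numpy().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("q rows must sum to 1")
        if not np.isfinite(self.ln_p_d):
            raise ValueError("ln P(D) must be finite")

    def summary(self) -> str:
        lines = [
            f"admixture model, K = {self.k}",
            f"ln P(D) = {self.ln_p_d:.2f}",
            f"mean alpha = {self.alpha_trace.mean():.3f}",
            "mean cluster membership by population:",
        ]
        mean_q = self.q_matrix.groupby(self.populations).mean()
        lines.append(mean_q.round(3).to_string())
        return "\n".join(lines)


class StructureModel:
    """Admixture-model clustering bound to a genotype matrix.

    Parameters
    ----------
    g : GenotypeMatrix
    k : int
        Number of clusters (>= 1, at most the number of individuals).
    frequency_model : {'correlated', 'independent'}
    lambda_ : float
        Dirichlet parameter of the ancestral (or independent) frequency
        prior.
    alpha_prior : (low, high)
        Uniform prior for the admixture concentration alpha.
    alpha_proposal_sd, f_proposal_sd : float
        Metropolis step sizes; mixing depends on them.
    """

    def __init__(
        self,
        g: GenotypeMatrix,
        k: int,
        frequency_model: str = "correlated",
        lambda_: float = 1.0,
        alpha_prior: tuple[float, float] = (0.0, 10.0),
        f_prior: tuple[float, float] = (0.001, 0.5),
        alpha_proposal_sd: float = 0.025,
        f_proposal_sd: float = 0.05,
    ):
        if k < 1:
            raise ValueError("K must be >= 1")
        if k > g.n_individuals:
            raise ValueError("K exceeds the number of individuals")
        if frequency_model not in ("correlated", "independent"):
            raise ValueError(f"unknown frequency model {frequency_model!r}")
        self.g = g
        self.k = k
        self.frequency_model = frequency_model
        self.lambda_ = lambda_
        self.alpha_prior = alpha_prior
        self.f_prior = f_prior
        self.alpha_sd = alpha_proposal_sd
        self.f_sd = f_proposal_sd
        self._prepare()

    def _prepare(self):
        g = self.g
        n, L = g.n_individuals, g.n_loci
        self.n_alleles = np.zeros(L, dtype=np.int64)
        codes = np.full((n, L, 2), -1, dtype=np.int64)
        for j in range(L):
            col = g.calls[:, j, :]
            sizes = np.unique(col[col != MISSING])
            lut = {int(s): a for a, s in enumerate(sizes)}
            self.n_alleles[j] = len(sizes)
            for c in (0, 1):
                m = col[:, c] != MISSING
                codes[m, j, c] = [lut[int(v)] for v in col[m, c]]
        self.amax = int(self.n_alleles.max())
        ii, ll, cc = np.nonzero(codes >= 0)
        self._ii, self._ll = ii, ll
        self._aa = codes[ii, ll, cc]
        self._m = len(ii)
        # valid-allele mask (L, Amax)
        self.valid = np.arange(self.amax)[None, :] < self.n_alleles[:, None]
        # empirical frequencies for initialization
        emp = np.zeros((L, self.amax))
        np.add.at(emp, (self._ll, self._aa), 1.0)
        emp += np.where(self.valid, self.lambda_, 0.0)
        self._empirical = emp / emp.sum(axis=1, keepdims=True)

    # -- conditional samplers ---------------------------------------------

    def _log_dirichlet(self, x, a):
        """Row-wise log Dirichlet density over valid alleles."""
        a = np.where(self.valid, a, 0.0)
        lx = np.where(self.valid, np.log(np.clip(x, 1e-300, None)), 0.0)
        return (
            gammaln(a.sum(axis=-1))
            - np.where(self.valid, gammaln(np.clip(a, 1e-300, None)), 0.0).sum(axis=-1)
            + ((a - 1) * lx * self.valid).sum(axis=-1)
        )

    def _sample_dirichlet(self, shape_arr, rng):
        """Dirichlet rows via gamma draws; invalid alleles stay zero."""
        gam = rng.gamma(np.where(self.valid, np.clip(shape_arr, 1e-6, None), 1.0))
        gam = np.where(self.valid, gam, 0.0)
        tot = gam.sum(axis=-1, keepdims=True)
        return gam / np.clip(tot, 1e-300, None)

    def fit(
        self,
        n_iter: int = 50000,
        burn_in: int = 5000,
        seed: int | None = None,
        thin: int = 1,
    ) -> StructureResults:
        """Run the Gibbs sampler and summarize the posterior.

        ``n_iter`` is the total chain length including ``burn_in``;
        the posterior mean Q and the ln P(D) estimate use every
        ``thin``-th post-burn-in sample.
        """
        if not n_iter > burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        rng = np.random.default_rng(seed)
        n, L, K = self.g.n_individuals, self.g.n_loci, self.k
        ii, ll, aa = self._ii, self._ll, self._aa

        p_anc = self._empirical.copy()
        f_k = np.full(K, 0.1)
        alpha = 1.0
        q = np.full((n, K), 1.0 / K)
        p = np.stack([
            self._sample_dirichlet(self.lambda_ + 20 * self._empirical, rng)
            for _ in range(K)
        ])

        q_sum = np.zeros((n, K))
        logliks = []
        alphas = []
        n_kept = 0

        for it in range(n_iter):
            # Z | P, Q   (flat over scored allele copies)
            pv = p[:, ll, aa]                       # (K, M)
            w = pv * q.T[:, ii]
            tot = w.sum(axis=0)
            w /= np.clip(tot, 1e-300, None)
            u = rng.random(self._m)
            z = (w.cumsum(axis=0) < u).sum(axis=0)
            z = np.minimum(z, K - 1)

            # allele counts per (k, l, a) and per (i, k)
            counts = np.zeros((K, L, self.amax))
            np.add.at(counts, (z, ll, aa), 1.0)
            cnt_ik = np.zeros((n, K))
            np.add.at(cnt_ik, (ii, z), 1.0)

            # P | Z
            if self.frequency_model == "correlated":
                prior = p_anc[None] * ((1 - f_k) / f_k)[:, None, None]
            else:
                prior = np.full((K, L, self.amax), self.lambda_)
            p = np.stack([
                self._sample_dirichlet(prior[k] + counts[k], rng) for k in range(K)
            ])

            # Q | Z
            gam = rng.gamma(alpha + cnt_ik)
            q = gam / np.clip(gam.sum(axis=1, keepdims=True), 1e-300, None)

            # alpha | Q  (Metropolis, uniform prior)
            if K > 1:
                prop = alpha + rng.normal(0.0, self.alpha_sd)
                if self.alpha_prior[0] < prop < self.alpha_prior[1]:
                    slq = np.log(np.clip(q, 1e-300, None)).sum()
                    def alpha_loglik(a):
                        return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1) * slq
                    if np.log(rng.random()) < alpha_loglik(prop) - alpha_loglik(alpha):
                        alpha = prop

            # F_k | P, p_anc  (Metropolis)
            if self.frequency_model == "correlated":
                for k in range(K):
                    prop = f_k[k] + rng.normal(0.0, self.f_sd)
                    if not self.f_prior[0] < prop < self.f_prior[1]:
                        continue
                    cur = self._log_dirichlet(p[k], p_anc * ((1 - f_k[k]) / f_k[k])).sum()
                    new = self._log_dirichlet(p[k], p_anc * ((1 - prop) / prop)).sum()
                    if np.log(rng.random()) < new - cur:
                        f_k[k] = prop

                # ancestral frequencies | P, F  (Metropolis, Dirichlet proposal)
                conc = 50.0
                prop_anc = self._sample_dirichlet(conc * p_anc + 0.5, rng)
                cur_ll = np.zeros(L)
                new_ll = np.zeros(L)
                for k in range(K):
                    ck = (1 - f_k[k]) / f_k[k]
                    cur_ll += self._log_dirichlet(p[k], p_anc * ck)
                    new_ll += self._log_dirichlet(p[k], prop_anc * ck)
                # flat Dirichlet(lambda=1) prior cancels; asymmetric proposal correction
                fwd = self._log_dirichlet(prop_anc, conc * p_anc + 0.5)
                rev = self._log_dirichlet(p_anc, conc * prop_anc + 0.5)
                accept = np.log(rng.random(L)) < (new_ll - cur_ll + rev - fwd)
                p_anc[accept] = prop_anc[accept]

            if it >= burn_in and (it - burn_in) % thin == 0:
                pv = p[:, ll, aa]
                mix = (pv * q.T[:, ii]).sum(axis=0)
                logliks.append(float(np.log(np.clip(mix, 1e-300, None)).sum()))
                alphas.append(alpha)
                q_sum += q
                n_kept += 1

        logliks_arr = np.array(logliks)
        alpha_arr = np.array(alphas)
        if K > 1 and np.std(alpha_arr) == 0:
            warnings.warn("alpha trace has zero variance: chain may not be mixing")
        ln_p_d = float(np.mean(logliks_arr) - 0.5 * np.var(logliks_arr))
        q_mean = q_sum / n_kept
        q_mean /= q_mean.sum(axis=1, keepdims=True)
        return StructureResults(
            k=K,
            q_matrix=pd.DataFrame(
                q_mean,
                index=self.g.individuals,
                columns=[f"cluster_{c + 1}" for c in range(K)],
            ),
            ln_p_d=ln_p_d,
            alpha_trace=alpha_arr,
            loglik_trace=logliks_arr,
            seed=seed,
            populations=list(self.g.populations),
        )


def run_structure(
    g: GenotypeMatrix,
    k: int,
    burn_in: int = 5000,
    length: int = 50000,
    seed: int | None = None,
    **model_options,
) -> StructureResults:
    """One clustering run (model construction + MCMC) at a fixed K."""
    return StructureModel(g, k, **model_options).fit(
        n_iter=length, burn_in=burn_in, seed=seed
    )


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------


@dataclass
class KSelection:
    """Mean ln P(D) per K, the successive-increase curve, and chosen K."""

    table: pd.DataFrame  # index K; mean, sd, n_runs
    delta: pd.Series  # increase of mean ln P(D) at each K
    chosen_k: int
    rule: str
    threshold_frac: float = 0.1

    def summary(self) -> str:
        out = [self.table.round(2).to_string(), ""]
        out.append("increase in mean ln P(D):")
        out.append(self.delta.round(2).to_string())
        out.append(f"chosen K = {self.chosen_k} ({self.rule})")
        return "\n".join(out)


def select_k(runs: list[StructureResults], threshold_frac: float = 0.1) -> KSelection:
    """Choose K by the rate of change of mean ln P(D).

    The chosen K is one below the first K whose increase in mean
    ln P(D) falls under ``threshold_frac`` of the largest increase; if
    the increase never collapses the largest K is returned with a
    plateau warning, and if ln P(D) never rises K = 1 is chosen.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.k, []).append(r.ln_p_d)
    if len(by_k) < 2:
        raise ValueError("K selection needs >= 2 distinct K values")
    ks = sorted(by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must form a contiguous range")
    table = pd.DataFrame(
        {
            "mean_ln_p_d": [float(np.mean(by_k[k])) for k in ks],
            "sd_ln_p_d": [float(np.std(by_k[k], ddof=1)) if len(by_k[k]) > 1 else 0.0
                           for k in ks],
            "n_runs": [len(by_k[k]) for k in ks],
        },
        index=pd.Index(ks, name="K"),
    )
    means = table["mean_ln_p_d"]
    delta = means.diff().dropna()
    dmax = delta.max()
    if dmax <= 0:
        return KSelection(table, delta, ks[0], "no increase in ln P(D)", threshold_frac)
    for k in delta.index:
        if delta[k] < threshold_frac * dmax:
            return KSelection(
                table, delta, k - 1,
                f"increase at K={k} fell below {threshold_frac:.0%} of the largest",
                threshold_frac,
            )
    warnings.warn("ln P(D) keeps increasing: plateau never reached")
    return KSelection(table, delta, ks[-1], "no plateau; largest K", threshold_frac)


# ---------------------------------------------------------------------------
# Membership reporting and label alignment
# ---------------------------------------------------------------------------


def membership_report(
    run: StructureResults, threshold: float = 0.80
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign individuals to clusters at a q threshold.

    An individual is assigned to its max-q cluster iff that proportion
    is at least ``threshold`` (in (0.5, 1]); otherwise it is reported
    as 'admixed'.  Also returns the per-site mean q vectors (the
    pie-chart fractions).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    q = run.q_matrix
    best = q.to_numpy().argmax(axis=1)
    maxq = q.to_numpy().max(axis=1)
    assignment = [
        q.columns[b] if m >= threshold else "admixed" for b, m in zip(best, maxq)
    ]
    individuals = pd.DataFrame(
        {
            "individual": q.index,
            "site": run.populations,
            "assignment": assignment,
            "max_q": maxq,
        }
    )
    site_means = q.groupby(run.populations).mean()
    site_means.index.name = "site"
    return individuals, site_means


def align_clusters(reference: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Permute ``other``'s cluster columns to best match ``reference``.

    Greedy maximum q-correlation matching, for label switching across
    replicate runs before averaging or majority assignment.
    """
    if reference.shape != other.shape:
        raise ValueError("q matrices must have identical shape")
    k = reference.shape[1]
    corr = np.corrcoef(reference.to_numpy().T, other.to_numpy().T)[:k, k:]
    corr = np.nan_to_num(corr, nan=-1.0)
    perm = [-1] * k
    used_ref, used_oth = set(), set()
    for _ in range(k):
        best = None
        for a in range(k):
            if a in used_ref:
                continue
            for b in range(k):
                if b in used_oth:
                    continue
                if best is None or corr[a, b] > corr[best]:
                    best = (a, b)
        a, b = best
        perm[a] = b
        used_ref.add(a)
        used_oth.add(b)
    out = other.iloc[:, perm]
    out.columns = reference.columns
    return out
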