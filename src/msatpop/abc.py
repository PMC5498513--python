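"""Approximate Bayesian computation for demographic model choice.

The workflow mirrors the DIYABC design: draw parameters from uniform
priors (rejection-sampling any structural constraints), simulate a
dataset per draw under each candidate scenario, reduce each dataset to
a fixed-order summary-statistic vector computed separately per locus
group (dinucleotide vs trinucleotide), then

* choose among scenarios by multinomial logistic regression of the
  scenario indicator on the statistics within the retained nearest
  fraction of simulations, evaluated at the observed point, with a
  bootstrap CI; and
* estimate parameters of the chosen scenario by Beaumont-style
  local-linear regression adjustment of the retained draws,
  Epanechnikov-weighted by distance, reporting posterior medians and
  central 90% intervals.

Summary statistics per locus group: for every population the mean
number of alleles, mean gene diversity and mean allele-size variance
(repeat units); for every population pair the two-level AMOVA FST and
the (delta-mu)^2 distance (squared difference of mean repeat counts,
averaged over loci).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .coalescent import DemographicScenario, MutationModel, simulate_dataset
from .differentiation import _pair_fst
from .io import MISSING, GenotypeMatrix, SiteTable


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parameter:
    """Uniform prior for one scalar parameter (linear or log10 scale)."""

    name: str
    low: float
    high: float
    scale: str = "linear"  # or "log10"

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "log10" and self.low <= 0:
            raise ValueError(f"{self.name}: log10 scale needs positive bounds")

    def draw(self, rng: np.random.Generator, size=None):
        if self.scale == "log10":
            return 10 ** rng.uniform(np.log10(self.low), np.log10(self.high), size)
        return rng.uniform(self.low, self.high, size)


@dataclass
class PriorSpec:
    """Parameter list plus '<' constraints between named parameters."""

    parameters: list[Parameter]
    constraints: list[tuple[str, str]] = field(default_factory=list)  # (smaller, larger)

    def __post_init__(self):
        names = {p.name for p in self.parameters}
        for a, b in self.constraints:
            if a not in names or b not in names:
                raise ValueError(f"constraint ({a} < {b}) names unknown parameter")
        if not self._feasible():
            raise ValueError("constraints define an empty prior region")

    def _feasible(self) -> bool:
        by = {p.name: p for p in self.parameters}
        return all(by[a].low < by[b].high for a, b in self.constraints)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def draw(self, rng: np.random.Generator, max_tries: int = 10000) -> dict[str, float]:
        """One draw respecting constraints, by rejection."""
        for _ in range(max_tries):
            d = {p.name: float(p.draw(rng)) for p in self.parameters}
            if all(d[a] < d[b] for a, b in self.constraints):
                return d
        raise RuntimeError("prior rejection sampling failed; constraints too tight")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def _group_key(motif_length: int) -> str:
    return {2: "di", 3: "tri"}.get(motif_length, f"m{motif_length}")


def stat_names(groups: list[str], populations: list[str]) -> list[str]:
    """Declared ordering of the summary-statistic vector."""
    names = []
    for grp in groups:
        for pop in populations:
            names += [f"{grp}|{pop}|na", f"{grp}|{pop}|he", f"{grp}|{pop}|var"]
    for grp in groups:
        for a, b in itertools.combinations(populations, 2):
            names += [f"{grp}|{a}-{b}|fst", f"{grp}|{a}-{b}|dmu2"]
    return names


def summarize(g: GenotypeMatrix) -> pd.Series:
    """Summary-statistic vector of a dataset, per locus group.

    Monomorphic groups yield zero diversity/FST entries rather than
    NaN so vector length depends only on (groups, populations).
    """
    pops = g.population_names
    groups: list[str] = []
    group_loci: dict[str, list[int]] = {}
    for j, locus in enumerate(g.loci):
        k = _group_key(locus.motif_length)
        if k not in group_loci:
            groups.append(k)
            group_loci[k] = []
        group_loci[k].append(j)

    pop_rows = {p: g.population_indices(p) for p in pops}
    # per (locus, pop): allele count vector and repeat-count moments
    counts: dict[tuple[int, str], np.ndarray] = {}
    moments: dict[tuple[int, str], tuple[float, float, float]] = {}
    for j, locus in enumerate(g.loci):
        col = g.calls[:, j, :]
        pooled = np.unique(col[col != MISSING])
        lut = {int(s): k for k, s in enumerate(pooled)}
        for p in pops:
            sub = col[pop_rows[p]].ravel()
            sub = sub[sub != MISSING]
            c = np.zeros(max(len(pooled), 1), dtype=np.int64)
            for v in sub:
                c[lut[int(v)]] += 1
            counts[(j, p)] = c
            reps = sub / locus.motif_length
            n = len(reps)
            var = float(np.var(reps, ddof=1)) if n > 1 else 0.0
            mean = float(np.mean(reps)) if n else 0.0
            moments[(j, p)] = (n, mean, var)

    values = []
    for grp in groups:
        loci = group_loci[grp]
        for p in pops:
            na = he = vr = 0.0
            for j in loci:
                c = counts[(j, p)]
                tot = c.sum()
                na += float(np.count_nonzero(c))
                if tot > 0:
                    pfreq = c / tot
                    he += 1.0 - float(np.sum(pfreq**2))
                vr += moments[(j, p)][2]
            values += [na / len(loci), he / len(loci), vr / len(loci)]
    for grp in groups:
        loci = group_loci[grp]
        for a, b in itertools.combinations(pops, 2):
            # negative finite-sample estimates truncate to 0, matching
            # the distance-matrix semantics of the pairwise statistic
            fst = max(
                _pair_fst(
                    [counts[(j, a)] for j in loci],
                    [counts[(j, b)] for j in loci],
                ),
                0.0,
            )
            dmu2 = float(
                np.mean(
                    [(moments[(j, a)][1] - moments[(j, b)][1]) ** 2 for j in loci]
                )
            )
            values += [fst, dmu2]
    return pd.Series(values, index=stat_names(groups, pops), dtype=float)


def collapse_to_regions(g: GenotypeMatrix, sites: SiteTable) -> GenotypeMatrix:
    """Relabel individuals by the region of their site, in region order."""
    region_of = sites.region_of()
    order = {r: i for i, r in enumerate(SiteTable.REGIONS)}
    regions = [region_of[p] for p in g.populations]
    idx = sorted(range(len(regions)), key=lambda i: order[regions[i]])
    return GenotypeMatrix(
        [g.individuals[i] for i in idx],
        [regions[i] for i in idx],
        g.loci,
        g.calls[idx],
        validate=False,
    )


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Sampling layout the simulations must match: diploid counts per
    population and the motif length of each locus."""

    sample_sizes: dict[str, int]
    motif_lengths: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 2, 3)

    def mutation_models(self, params: dict[str, float]) -> list[MutationModel]:
        return [
            MutationModel(
                mu=params["mu_di"] if m == 2 else params["mu_tri"],
                gsm_p=params.get("gsm_p", 0.0),
                motif_length=m,
            )
            for m in self.motif_lengths
        ]


@dataclass
class ScenarioSpec:
    """One candidate scenario: a name, a prior, and a builder mapping a
    parameter draw plus sample sizes to a :class:`DemographicScenario`."""

    name: str
    prior: PriorSpec
    builder: "callable"


def _mutation_parameters() -> list[Parameter]:
    return [
        Parameter("mu_di", 1e-5, 1e-3, "log10"),
        Parameter("mu_tri", 1e-5, 1e-3, "log10"),
        Parameter("gsm_p", 0.1, 0.3, "linear"),
    ]


def _ne_parameters() -> list[Parameter]:
    return [
        Parameter("ne_n", 100, 50000, "log10"),
        Parameter("ne_c", 100, 50000, "log10"),
        Parameter("ne_s", 100, 50000, "log10"),
        Parameter("ne_anc", 100, 50000, "log10"),
    ]


def default_scenarios() -> list[ScenarioSpec]:
    """The three candidate histories with their default priors."""
    from .coalescent import (
        scenario_admixture,
        scenario_divergence,
        scenario_stepping_stone,
    )

    div_prior = PriorSpec(
        _ne_parameters()
        + [
            Parameter("t_split_cs", 160, 20000, "log10"),
            Parameter("t_split_n", 2000, 200000, "log10"),
        ]
        + _mutation_parameters(),
        constraints=[("t_split_cs", "t_split_n")],
    )
    step_prior = PriorSpec(
        _ne_parameters()
        + [
            Parameter("t_found_n", 160, 20000, "log10"),
            Parameter("t_found_c", 2000, 200000, "log10"),
            Parameter("nb", 10, 1000, "log10"),
            Parameter("db", 10, 150, "linear"),
        ]
        + _mutation_parameters(),
        constraints=[("t_found_n", "t_found_c"), ("db", "t_found_n")],
    )
    adm_prior = PriorSpec(
        _ne_parameters()
        + [
            Parameter("t_adm", 160, 20000, "log10"),
            Parameter("t_div", 2000, 200000, "log10"),
            Parameter("r", 0.05, 0.95, "linear"),
        ]
        + _mutation_parameters(),
        constraints=[("t_adm", "t_div")],
    )

    def build_div(p, sizes):
        return scenario_divergence(
            p["t_split_cs"], p["t_split_n"], p["ne_n"], p["ne_c"], p["ne_s"],
            p["ne_anc"], sizes,
        )

    def build_step(p, sizes):
        return scenario_stepping_stone(
            p["t_found_n"], p["t_found_c"], p["ne_n"], p["ne_c"], p["ne_s"],
            p["ne_anc"], min(p["nb"], p["ne_n"]), p["db"], sizes,
        )

    def build_adm(p, sizes):
        return scenario_admixture(
            p["t_adm"], p["t_div"], p["r"], p["ne_n"], p["ne_c"], p["ne_s"],
            p["ne_anc"], sizes,
        )

    return [
        ScenarioSpec("divergence", div_prior, build_div),
        ScenarioSpec("stepping_stone", step_prior, build_step),
        ScenarioSpec("admixture", adm_prior, build_adm),
    ]


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary statistics) rows."""

    table: pd.DataFrame
    stat_columns: list[str]
    param_columns: dict[str, list[str]]  # per scenario
    priors: dict[str, PriorSpec]
    seed: int | None = None

    @property
    def scenarios(self) -> list[str]:
        return list(self.param_columns)

    def stats(self) -> np.ndarray:
        return self.table[self.stat_columns].to_numpy(dtype=float)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# msatpop reference table; seed={self.seed}\n")
            fh.write(f"# stat_columns={','.join(self.stat_columns)}\n")
            for s, cols in self.param_columns.items():
                fh.write(f"# params[{s}]={','.join(cols)}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        stat_cols: list[str] = []
        param_cols: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                body = line[1:].strip()
                if body.startswith("stat_columns="):
                    stat_cols = body.split("=", 1)[1].split(",")
                elif body.startswith("params["):
                    name = body[len("params["):].split("]", 1)[0]
                    param_cols[name] = body.split("=", 1)[1].split(",")
                pos = fh.tell()
            table = pd.read_csv(fh, sep="\t")
        return cls(table, stat_cols, param_cols, priors={})


def build_reference_table(
    scenarios: list[ScenarioSpec],
    design: SampleDesign,
    n_per_scenario: int,
    seed: int,
    row_offset: int = 0,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario.

    Row seeds derive from ``(seed, scenario index, row index)``, so
    tables are reproducible and can be built in resumable chunks via
    ``row_offset`` and concatenated.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    pops = list(design.sample_sizes)
    records = []
    stat_cols: list[str] | None = None
    for si, spec in enumerate(scenarios):
        for ri in range(row_offset, row_offset + n_per_scenario):
            ss = np.random.SeedSequence(seed, spawn_key=(si, ri))
            rng = np.random.default_rng(ss)
            params = spec.prior.draw(rng)
            scen = spec.builder(params, dict(design.sample_sizes))
            g = simulate_dataset(
                scen, design.mutation_models(params),
                seed=int(rng.integers(2**31)),
            )
            stats = summarize(g)
            if stat_cols is None:
                stat_cols = list(stats.index)
            rec = {"scenario": spec.name}
            rec.update(params)
            rec.update(stats.to_dict())
            records.append(rec)
    table = pd.DataFrame(records)
    return ReferenceTable(
        table=table,
        stat_columns=stat_cols or [],
        param_columns={s.name: s.prior.names for s in scenarios},
        priors={s.name: s.prior for s in scenarios},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Model: statsmodels-style fit
# ---------------------------------------------------------------------------


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum /= ws.sum()
    return np.interp(q, cum, xs)


@dataclass
class AbcResults:
    """Posterior scenario probabilities and parameter posteriors."""

    scenario_probabilities: pd.DataFrame  # index scenario; prob, lo95, hi95
    best_scenario: str
    parameters: pd.DataFrame  # index parameter; median, lo90, hi90
    diagnostics: dict

    def summary(self) -> str:
        lines = ["ABC model choice", "-" * 52]
        for s, row in self.scenario_probabilities.iterrows():
            star = " *" if s == self.best_scenario else ""
            lines.append(
                f"{s:>18}  P = {row['prob']:.3f}  "
                f"95% CI [{row['lo95']:.3f}, {row['hi95']:.3f}]{star}"
            )
        lines.append("")
        lines.append(f"parameter posteriors ({self.best_scenario})")
        lines.append("-" * 52)
        for p, row in self.parameters.iterrows():
            lines.append(
                f"{p:>12}  median = {row['median']:.4g}  "
                f"90% CI [{row['lo90']:.4g}, {row['hi90']:.4g}]"
            )
        d = self.diagnostics
        lines.append("")
        lines.append(
            f"retained {d['retained']} of {d['n_rows']} simulations "
            f"(distance <= {d['threshold']:.3g})"
        )
        return "\n".join(lines)


class AbcModel:
    """ABC estimator bound to a reference table and an observed dataset.

    Parameters
    ----------
    reference : ReferenceTable
    observed : pandas.Series or GenotypeMatrix
        Observed summary statistics (or a dataset to summarize), in the
        reference table's statistic ordering.
    """

    def __init__(self, reference: ReferenceTable, observed):
        if isinstance(observed, GenotypeMatrix):
            observed = summarize(observed)
        self.reference = reference
        self.observed = observed.reindex(reference.stat_columns)
        if self.observed.isna().any():
            bad = list(self.observed.index[self.observed.isna()])
            raise ValueError(f"observed statistics missing entries: {bad}")
        stats = reference.stats()
        self._mean = stats.mean(axis=0)
        self._sd = stats.std(axis=0)
        self._keep = self._sd > 0
        self._z = (stats[:, self._keep] - self._mean[self._keep]) / self._sd[self._keep]
        self._z_obs = (
            self.observed.to_numpy()[self._keep] - self._mean[self._keep]
        ) / self._sd[self._keep]
        self._dist = np.sqrt(np.sum((self._z - self._z_obs) ** 2, axis=1))

    # -- scenario choice ---------------------------------------------------

    def _retained(self, retain_frac: float) -> np.ndarray:
        n = len(self._dist)
        k = max(int(np.ceil(retain_frac * n)), 2)
        return np.argsort(self._dist, kind="stable")[:k]

    def _epanechnikov(self, idx: np.ndarray) -> np.ndarray:
        d = self._dist[idx]
        dmax = d.max()
        if dmax == 0:
            return np.ones_like(d)
        w = 1.0 - (d / (dmax * (1 + 1e-9))) ** 2
        return np.clip(w, 1e-12, None)

    def _fit_logistic(self, idx: np.ndarray, rng) -> np.ndarray | None:
        labels = self.reference.table["scenario"].to_numpy()[idx]
        present = sorted(set(labels))
        if len(present) < 2:
            return None
        clf = LogisticRegression(C=1e4, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(self._z[idx], labels, sample_weight=self._epanechnikov(idx))
        probs = dict(zip(clf.classes_, clf.predict_proba(self._z_obs[None, :])[0]))
        return np.array([probs.get(s, 0.0) for s in self.reference.scenarios])

    def fit(
        self,
        retain_frac: float = 0.01,
        n_bootstrap: int = 100,
        seed: int | None = None,
        estimate_scenario: str | None = None,
    ) -> AbcResults:
        """Scenario choice plus parameter posteriors.

        ``estimate_scenario`` overrides which scenario's parameters are
        estimated (default: the highest-probability one).
        """
        if not 0 < retain_frac <= 1:
            raise ValueError("retain_frac must be in (0, 1]")
        rng = np.random.default_rng(seed)
        scen_names = self.reference.scenarios
        idx = self._retained(retain_frac)
        probs = self._fit_logistic(idx, rng)
        if probs is None:
            warnings.warn(
                "retained set lacks a scenario: falling back to weighted rejection"
            )
            labels = self.reference.table["scenario"].to_numpy()[idx]
            w = self._epanechnikov(idx)
            probs = np.array(
                [w[labels == s].sum() for s in scen_names]
            )
        probs = probs / probs.sum()

        boot = np.empty((n_bootstrap, len(scen_names)))
        for b in range(n_bootstrap):
            take = idx[rng.integers(0, len(idx), size=len(idx))]
            pb = self._fit_logistic(take, rng)
            if pb is None:
                labels = self.reference.table["scenario"].to_numpy()[take]
                w = self._epanechnikov(take)
                pb = np.array([w[labels == s].sum() for s in scen_names])
            boot[b] = pb / pb.sum()
        lo = np.quantile(boot, 0.025, axis=0)
        hi = np.quantile(boot, 0.975, axis=0)
        prob_frame = pd.DataFrame(
            {"prob": probs, "lo95": np.minimum(lo, probs), "hi95": np.maximum(hi, probs)},
            index=scen_names,
        )
        best = prob_frame["prob"].idxmax()
        target = estimate_scenario or best
        params = self.estimate_parameters(target, retain_frac)
        return AbcResults(
            scenario_probabilities=prob_frame,
            best_scenario=best,
            parameters=params,
            diagnostics={
                "retained": len(idx),
                "n_rows": len(self._dist),
                "threshold": float(self._dist[idx].max()),
                "retain_frac": retain_frac,
            },
        )

    # -- parameter estimation ---------------------------------------------

    def estimate_parameters(
        self, scenario: str, retain_frac: float = 0.01
    ) -> pd.DataFrame:
        """Local-linear posterior for one scenario's parameters.

        Retains the nearest fraction of that scenario's rows, adjusts
        each retained draw by the weighted-least-squares fit of the
        parameter on (stats - observed) (log10 scale where the prior is
        log-uniform), and reports weighted median and central 90%
        interval, clipped to the prior support.
        """
        tbl = self.reference.table
        mask = (tbl["scenario"] == scenario).to_numpy()
        if not mask.any():
            raise ValueError(f"scenario {scenario!r} not in reference table")
        rows = np.flatnonzero(mask)
        d = self._dist[rows]
        # floor the retained count so the local regression stays
        # overdetermined relative to the statistic dimension
        k = max(
            int(np.ceil(retain_frac * len(rows))),
            min(len(rows), 4 * (self._z.shape[1] + 1)),
        )
        sel = rows[np.argsort(d, kind="stable")[:k]]
        w = self._epanechnikov(sel)
        X = self._z[sel] - self._z_obs
        prior = self.reference.priors.get(scenario)
        out = {}
        for pname in self.reference.param_columns[scenario]:
            y = tbl[pname].to_numpy(dtype=float)[sel]
            pdef = None
            if prior is not None:
                pdef = next(p for p in prior.parameters if p.name == pname)
            logscale = pdef is not None and pdef.scale == "log10"
            yt = np.log10(y) if logscale else y
            Xd = np.column_stack([np.ones(len(sel)), X])
            WX = Xd * w[:, None]
            xtx = WX.T @ Xd
            # light ridge on the slope block guards near-collinear stats
            ridge = 1e-3 * np.trace(xtx) / xtx.shape[0] * np.eye(xtx.shape[0])
            ridge[0, 0] = 0.0
            try:
                beta = np.linalg.solve(xtx + ridge, WX.T @ yt)
                adjusted = yt - X @ beta[1:]
            except np.linalg.LinAlgError:
                warnings.warn(f"{pname}: singular local regression; rejection posterior")
                adjusted = yt
            qs = _weighted_quantile(adjusted, w, [0.05, 0.5, 0.95])
            lo90, med, hi90 = (10**qs if logscale else qs)
            if pdef is not None:
                lo90 = float(np.clip(lo90, pdef.low, pdef.high))
                med = float(np.clip(med, pdef.low, pdef.high))
                hi90 = float(np.clip(hi90, pdef.low, pdef.high))
            out[pname] = {"median": med, "lo90": lo90, "hi90": hi90}
        return pd.DataFrame(out).T[["median", "lo90", "hi90"]]


def generations_to_kya(t: float, generation_time: float = 5.0) -> float:
    """Generations to thousand years ago: t * generation_time / 1000."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return t * generation_time / 1000.0
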