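"""Structured coalescent simulation of microsatellite genotypes.

Backward-in-time Kingman coalescent over named populations with a
time-ordered event list (merges, admixture splits, size changes,
bottlenecks), followed by stepwise mutation (SMM or generalized
stepwise, GSM) dropped on the genealogy.  Within a population of
diploid effective size Ne each lineage pair coalesces at rate 1/(2Ne)
per generation; there is no migration between events.

Time is measured in generations, increasing into the past.  Trees are
returned as parent/time arrays; allele sizes are in base pairs,
congruent with the locus motif.  The three study scenarios — ancient
north/south-type divergence, northward stepping-stone colonization
with a founder bottleneck, and a glacial-admixture origin of the
central population — are provided as scenario builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, Locus


class ScenarioError(ValueError):
    """Invalid demographic scenario (ordering, stranded lineages, ...)."""


# ---------------------------------------------------------------------------
# Demographic scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Merge:
    """Backward in time at ``t``, all lineages of ``source`` move into ``sink``."""

    t: float
    source: str
    sink: str


@dataclass(frozen=True)
class Admixture:
    """Backward at ``t``, each lineage of ``pop`` joins ``parent_a`` with
    probability ``prop_a``, else ``parent_b``; ``pop`` becomes inactive."""

    t: float
    pop: str
    parent_a: str
    parent_b: str
    prop_a: float


@dataclass(frozen=True)
class SizeChange:
    """At ``t`` (pastward), ``pop``'s diploid effective size becomes ``ne``."""

    t: float
    pop: str
    ne: float


@dataclass(frozen=True)
class Bottleneck:
    """Reduced size ``nb`` on ``pop`` during [t_start, t_start + duration].

    ``t_start`` is the backward-time onset, i.e. the bottleneck occupies
    the stretch of the branch just pastward of t_start (for a founder
    event at time T, use t_start = T - duration so the squeeze sits
    immediately after founding in forward time).
    """

    t_start: float
    duration: float
    pop: str
    nb: float


Event = Merge | Admixture | SizeChange | Bottleneck


@dataclass
class DemographicScenario:
    """Named populations with sizes, samples, and a backward event list."""

    populations: list[str]
    ne: dict[str, float]
    sample_sizes: dict[str, int]  # diploid individuals per sampled population
    events: list[Event] = field(default_factory=list)
    name: str = "scenario"

    def __post_init__(self):
        self._validate()

    def _validate(self):
        times = [self._event_time(e) for e in self.events]
        if any(t <= 0 for t in times):
            raise ScenarioError("event times must be strictly positive")
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ScenarioError("events must be listed in nondecreasing time order")
        for e in self.events:
            if isinstance(e, Admixture) and not (0.0 < e.prop_a < 1.0):
                raise ScenarioError(f"admixture proportion must be in (0,1), got {e.prop_a}")
            if isinstance(e, Bottleneck):
                if e.duration < 0:
                    raise ScenarioError("bottleneck duration must be >= 0")
                if e.nb > self.ne[e.pop]:
                    raise ScenarioError("bottleneck size Nb must not exceed Ne")
        # reachability: all sampled populations must funnel to one root
        active = {p for p, n in self.sample_sizes.items() if n > 0}
        for e in self.events:
            if isinstance(e, Merge):
                if e.source in active:
                    active.discard(e.source)
                    active.add(e.sink)
            elif isinstance(e, Admixture):
                if e.pop in active:
                    active.discard(e.pop)
                    active.update((e.parent_a, e.parent_b))
        if len(active) > 1:
            raise ScenarioError(
                f"lineages stranded in {sorted(active)}: no common root reachable"
            )

    @staticmethod
    def _event_time(e: Event) -> float:
        return e.t_start if isinstance(e, Bottleneck) else e.t

    def flattened_events(self) -> list[tuple[float, Event]]:
        """Events with bottlenecks expanded into paired size changes."""
        out: list[tuple[float, Event]] = []
        for e in self.events:
            if isinstance(e, Bottleneck):
                out.append((e.t_start, SizeChange(e.t_start, e.pop, e.nb)))
                out.append(
                    (e.t_start + e.duration,
                     SizeChange(e.t_start + e.duration, e.pop, self.ne[e.pop]))
                )
            else:
                out.append((self._event_time(e), e))
        out.sort(key=lambda te: te[0])
        return out


def scenario_divergence(
    t_split_cs: float,
    t_split_n: float,
    ne_n: float,
    ne_c: float,
    ne_s: float,
    ne_anc: float,
    sample_sizes: dict[str, int],
) -> DemographicScenario:
    """Ancient divergence of the north, later split of center and south.

    Backward: center and south merge at ``t_split_cs``; the result
    merges with north at ``t_split_n`` into an ancestral population of
    size ``ne_anc``.
    """
    if not t_split_cs < t_split_n:
        raise ScenarioError("requires t_split_cs < t_split_n")
    return DemographicScenario(
        populations=["north", "center", "south"],
        ne={"north": ne_n, "center": ne_c, "south": ne_s},
        sample_sizes=sample_sizes,
        events=[
            Merge(t_split_cs, "center", "south"),
            Merge(t_split_n, "north", "south"),
            SizeChange(t_split_n, "south", ne_anc),
        ],
        name="divergence",
    )


def scenario_stepping_stone(
    t_found_n: float,
    t_found_c: float,
    ne_n: float,
    ne_c: float,
    ne_s: float,
    ne_anc: float,
    nb: float,
    db: float,
    sample_sizes: dict[str, int],
    bottleneck_center: bool = False,
) -> DemographicScenario:
    """Sequential northward colonization with founder bottlenecks.

    Backward: north merges into center at ``t_found_n`` with a
    bottleneck (Nb, db) on the north branch immediately after founding;
    center then merges into south at ``t_found_c``.  With
    ``bottleneck_center`` the center branch gets a matching bottleneck.
    """
    if not t_found_n < t_found_c:
        raise ScenarioError("requires t_found_n < t_found_c")
    if db >= t_found_n:
        raise ScenarioError("bottleneck duration must be < t_found_n")
    if bottleneck_center and db >= t_found_c:
        raise ScenarioError("bottleneck duration must be < t_found_c")
    events: list[Event] = [Bottleneck(t_found_n - db, db, "north", nb)] if db > 0 else []
    if bottleneck_center and db > 0:
        events.append(Bottleneck(t_found_c - db, db, "center", nb))
    events.append(Merge(t_found_n, "north", "center"))
    events.append(Merge(t_found_c, "center", "south"))
    events.append(SizeChange(t_found_c, "south", ne_anc))
    events.sort(key=DemographicScenario._event_time)
    return DemographicScenario(
        populations=["north", "center", "south"],
        ne={"north": ne_n, "center": ne_c, "south": ne_s},
        sample_sizes=sample_sizes,
        events=events,
        name="stepping_stone",
    )


def scenario_admixture(
    t_adm: float,
    t_div: float,
    r: float,
    ne_n: float,
    ne_c: float,
    ne_s: float,
    ne_anc: float,
    sample_sizes: dict[str, int],
) -> DemographicScenario:
    """Central population founded by admixture of north and south.

    Backward: center's lineages at ``t_adm`` join north with
    probability ``r`` else south; north and south merge at ``t_div``
    into an ancestral population of size ``ne_anc``.
    """
    if not t_adm < t_div:
        raise ScenarioError("requires t_adm < t_div")
    if not 0.0 < r < 1.0:
        raise ScenarioError(f"admixture rate r must be in (0,1), got {r}")
    return DemographicScenario(
        populations=["north", "center", "south"],
        ne={"north": ne_n, "center": ne_c, "south": ne_s},
        sample_sizes=sample_sizes,
        events=[
            Admixture(t_adm, "center", "north", "south", r),
            Merge(t_div, "north", "south"),
            SizeChange(t_div, "south", ne_anc),
        ],
        name="admixture",
    )


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------


@dataclass
class Genealogy:
    """Rooted coalescent tree: parent pointers and node times (generations).

    Nodes 0..n_samples-1 are leaves at time 0, ordered population by
    population in scenario order; internal nodes are numbered in
    coalescence order, so ids increase with time.  The root's parent
    is -1.
    """

    parent: np.ndarray
    time: np.ndarray
    n_samples: int
    leaf_population: np.ndarray  # population index per leaf

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def total_length(self) -> float:
        child = np.arange(len(self.parent) - 1)
        return float(np.sum(self.time[self.parent[child]] - self.time[child]))


def _simulate_one_tree(
    scenario: DemographicScenario, rng: np.random.Generator
) -> Genealogy:
    pops = scenario.populations
    pop_idx = {p: i for i, p in enumerate(pops)}
    samples = [scenario.sample_sizes.get(p, 0) * 2 for p in pops]
    n_samples = sum(samples)
    if n_samples < 2:
        raise ScenarioError("need at least 2 sampled gene copies")

    n_nodes = 2 * n_samples - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    leaf_population = np.repeat(np.arange(len(pops)), samples)

    active: dict[int, list[int]] = {}
    nid = 0
    for i, k in enumerate(samples):
        active[i] = list(range(nid, nid + k))
        nid += k
    next_node = n_samples

    ne = {pop_idx[p]: float(scenario.ne[p]) for p in pops}
    schedule = scenario.flattened_events() + [(np.inf, None)]

    t = 0.0
    for t_ev, event in schedule:
        # coalesce within each population until t_ev
        for p, lineages in active.items():
            k = len(lineages)
            if k < 2:
                continue
            tp = t
            size = ne[p]
            while k >= 2:
                rate = k * (k - 1) / (4.0 * size)
                tp += rng.exponential(1.0 / rate)
                if tp >= t_ev:
                    break
                i = rng.integers(k)
                j = rng.integers(k - 1)
                if j >= i:
                    j += 1
                a, b = lineages[i], lineages[j]
                node = next_node
                next_node += 1
                parent[a] = parent[b] = node
                time[node] = tp
                # swap-remove the two children, append the new node
                hi, lo = max(i, j), min(i, j)
                lineages[hi] = lineages[-1]
                lineages.pop()
                lineages[lo] = lineages[-1]
                lineages.pop()
                lineages.append(node)
                k -= 1
        if event is None:
            break
        t = t_ev
        if isinstance(event, SizeChange):
            ne[pop_idx[event.pop]] = float(event.ne)
        elif isinstance(event, Merge):
            src, snk = pop_idx[event.source], pop_idx[event.sink]
            active.setdefault(snk, []).extend(active.pop(src, []))
        elif isinstance(event, Admixture):
            src = pop_idx[event.pop]
            pa, pb = pop_idx[event.parent_a], pop_idx[event.parent_b]
            lineages = active.pop(src, [])
            to_a = rng.random(len(lineages)) < event.prop_a
            active.setdefault(pa, []).extend(
                l for l, m in zip(lineages, to_a) if m
            )
            active.setdefault(pb, []).extend(
                l for l, m in zip(lineages, to_a) if not m
            )

    remaining = [ls for ls in active.values() if ls]
    if sum(len(ls) for ls in remaining) != 1:
        raise ScenarioError("simulation ended with more than one lineage")
    return Genealogy(parent, time, n_samples, leaf_population)


def simulate_genealogy(
    scenario: DemographicScenario, locus_count: int, seed: int | None = None
) -> list[Genealogy]:
    """Independent coalescent genealogies, one per locus."""
    rng = np.random.default_rng(seed)
    return [_simulate_one_tree(scenario, rng) for _ in range(locus_count)]


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationModel:
    """Stepwise microsatellite mutation.

    ``mu`` is the per-locus per-generation mutation rate.  Each
    mutation changes the repeat count by +-k where k = 1 under the
    strict stepwise model (SMM) and k ~ Geometric(1 - gsm_p) under the
    generalized model (GSM, step k with probability gsm_p^(k-1) *
    (1 - gsm_p)); the sign is a fair coin.  SMM is exactly gsm_p = 0.
    """

    mu: float
    gsm_p: float = 0.0
    motif_length: int = 2

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if not 0.0 <= self.gsm_p < 1.0:
            raise ValueError("gsm_p must be in [0, 1)")

    @property
    def model(self) -> str:
        return "SMM" if self.gsm_p == 0.0 else "GSM"


_FLOOR_REPEATS = 2  # reflection floor: allele keeps at least two repeat units


def mutate_tree(
    tree: Genealogy,
    model: MutationModel,
    ancestral_repeats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Leaf repeat counts after dropping stepwise mutations on a genealogy."""
    n_nodes = len(tree.parent)
    child = np.arange(n_nodes - 1)  # root excluded
    lengths = tree.time[tree.parent[child]] - tree.time[child]
    muts = rng.poisson(model.mu * lengths)
    net = np.zeros(n_nodes, dtype=np.int64)
    total = int(muts.sum())
    if total:
        owner = np.repeat(child, muts)
        if model.gsm_p == 0.0:
            steps = np.ones(total, dtype=np.int64)
        else:
            steps = rng.geometric(1.0 - model.gsm_p, size=total)
        signs = rng.integers(0, 2, size=total) * 2 - 1
        np.add.at(net, owner, steps * signs)

    value = np.empty(n_nodes, dtype=np.int64)
    value[n_nodes - 1] = ancestral_repeats
    parent = tree.parent
    for node in range(n_nodes - 2, -1, -1):
        value[node] = value[parent[node]] + net[node]
    leaves = value[: tree.n_samples]
    # reflect at the floor so alleles stay physical
    low = leaves < _FLOOR_REPEATS
    while low.any():
        leaves[low] = 2 * _FLOOR_REPEATS - leaves[low]
        low = leaves < _FLOOR_REPEATS
    return leaves


def drop_mutations(
    trees: list[Genealogy],
    models: MutationModel | list[MutationModel],
    scenario: DemographicScenario,
    ancestral_size: int = 150,
    seed: int | None = None,
    locus_names: list[str] | None = None,
    validate: bool = True,
) -> GenotypeMatrix:
    """Mutate genealogies and assemble a diploid :class:`GenotypeMatrix`.

    ``ancestral_size`` is the root allele size in bp and must be
    congruent with each locus motif.  Gene copies are paired into
    diploids within each population; copies are exchangeable, so
    consecutive pairing is a uniform random pairing.
    """
    if isinstance(models, MutationModel):
        models = [models] * len(trees)
    if len(models) != len(trees):
        raise ValueError("one mutation model per tree required")
    rng = np.random.default_rng(seed)
    pops = scenario.populations
    sampled = [(p, scenario.sample_sizes.get(p, 0)) for p in pops]
    n_ind = sum(n for _, n in sampled)
    calls = np.empty((n_ind, len(trees), 2), dtype=np.int64)
    for j, (tree, model) in enumerate(zip(trees, models)):
        if ancestral_size % model.motif_length != 0:
            raise ValueError(
                f"ancestral size {ancestral_size} not a multiple of motif "
                f"{model.motif_length}"
            )
        repeats = mutate_tree(tree, model, ancestral_size // model.motif_length, rng)
        sizes = repeats * model.motif_length
        calls[:, j, :] = sizes.reshape(n_ind, 2)
    individuals = [
        f"{p}_{i + 1:03d}" for p, n in sampled for i in range(n)
    ]
    populations = [p for p, n in sampled for _ in range(n)]
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(len(trees))]
    loci = [Locus(nm, m.motif_length) for nm, m in zip(locus_names, models)]
    return GenotypeMatrix(individuals, populations, loci, calls, validate=validate)


def simulate_dataset(
    scenario: DemographicScenario,
    models: list[MutationModel],
    seed: int | None = None,
    locus_names: list[str] | None = None,
    validate: bool = False,
) -> GenotypeMatrix:
    """Simulate one multilocus dataset: genealogies plus mutations."""
    rng = np.random.default_rng(seed)
    trees = [_simulate_one_tree(scenario, rng) for _ in models]
    return drop_mutations(
        trees,
        models,
        scenario,
        seed=rng.integers(2**31),
        locus_names=locus_names,
        validate=validate,
    )
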