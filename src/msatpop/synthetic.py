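"""Study-shaped synthetic datasets.

The genotype data behind the original nine-site survey were never
deposited, so every pipeline stage is exercised on synthetic data that
emulates the study design: 9 coastal sites in three latitudinal
regions (north / center / south), 124 diploid individuals, 8
microsatellite loci (7 dinucleotide, 1 trinucleotide), generated under
the glacial-admixture history with its posterior-median parameters
(admixture of the central population 6,330 generations ago, r = 0.64
from the north; north/south divergence 27,800 generations ago;
Ne = 12,800 / 21,200 / 4,360 north / center / south).

The three regional populations of the demographic model are sampled
and then partitioned into sites, so within-region substructure arises
from sampling noise only — a deliberate fidelity limit.  The mean
mutation rate (3e-5 per locus per generation) is set so that expected
within-region heterozygosity and among-region differentiation match
the study's reported levels (He ~ 0.4-0.6, FST ~ 0.36) under the
posterior-median sizes: a one-off calibration, documented in the
methods note, after which the value is frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import MutationModel, scenario_admixture, simulate_dataset
from .io import GenotypeMatrix, Locus, SiteTable, dms_to_decimal

#: Printed per-site summary of the original survey (coordinates as
#: degree/minute South-West, diversity columns as published).  These are
#: published numbers usable as inputs; they are not reproducible from
#: raw data, which was never released.
TABLE1 = pd.DataFrame(
    [
        ("FrayJorge", 30, 39, 71, 40, "north", 15, 4.71, 1.04, 0.37, 0.52, 0.28),
        ("Talinay", 30, 27, 71, 37, "north", 15, 4.14, 0.93, 0.36, 0.48, 0.25),
        ("SantaInes", 32, 8, 71, 30, "center", 15, 4.86, 1.25, 0.43, 0.64, 0.33),
        ("Cachagua", 33, 36, 71, 25, "center", 15, 3.14, 0.92, 0.33, 0.53, 0.38),
        ("Mirasol", 33, 20, 71, 40, "center", 7, 2.43, 0.66, 0.32, 0.40, 0.20),
        ("QdaCordova", 33, 36, 71, 39, "center", 12, 4.00, 0.97, 0.37, 0.53, 0.30),
        ("Tanume", 34, 9, 71, 59, "south", 15, 3.14, 0.75, 0.54, 0.43, -0.26),
        ("Cahuil", 34, 35, 72, 0, "south", 15, 2.57, 0.63, 0.35, 0.38, 0.08),
        ("LoValdivia", 34, 41, 72, 0, "south", 15, 3.00, 0.70, 0.29, 0.40, 0.28),
    ],
    columns=[
        "site", "lat_deg", "lat_min", "lon_deg", "lon_min", "region",
        "n", "na", "shannon_i", "ho", "he", "fis",
    ],
)

#: 'Cachagua' and 'Zapallar' name the same central site in different
#: places of the source survey; both resolve to the canonical label.
SITE_ALIASES = {"Zapallar": "Cachagua"}

#: Posterior-median parameters of the admixture scenario used as the
#: study emulator.  The ancestral size was not reported; 10,000 sits
#: mid-range among the three reported sizes.
STUDY_PARAMETERS = {
    "t_adm": 6330.0,
    "t_div": 27800.0,
    "r": 0.64,
    "ne_n": 12800.0,
    "ne_c": 21200.0,
    "ne_s": 4360.0,
    "ne_anc": 10000.0,
    "mu_di": 3e-5,
    "mu_tri": 3e-5,
    "gsm_p": 0.2,
}

#: Locus panel: 7 dinucleotide loci and 1 trinucleotide locus.
STUDY_LOCI = [
    Locus("P3", 2), Locus("P4", 2), Locus("P5", 2), Locus("P6", 2),
    Locus("P9", 2), Locus("P11", 2), Locus("P15", 2), Locus("P17", 3),
]


def study_site_table() -> SiteTable:
    """The nine study sites with decimal coordinates and region labels."""
    lat = [dms_to_decimal(d, m) for d, m in zip(TABLE1["lat_deg"], TABLE1["lat_min"])]
    lon = [dms_to_decimal(d, m) for d, m in zip(TABLE1["lon_deg"], TABLE1["lon_min"])]
    return SiteTable(
        pd.DataFrame(
            {"site": TABLE1["site"], "lat": lat, "lon": lon,
             "region": TABLE1["region"]}
        )
    )


@dataclass
class StudyDesign:
    """Sampling design of the survey: sites, sizes, loci, parameters."""

    sites: SiteTable = field(default_factory=study_site_table)
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: dict(zip(TABLE1["site"], TABLE1["n"]))
    )
    loci: list[Locus] = field(default_factory=lambda: list(STUDY_LOCI))
    parameters: dict[str, float] = field(default_factory=lambda: dict(STUDY_PARAMETERS))

    def __post_init__(self):
        if sum(self.sample_sizes.values()) != 124:
            raise ValueError("study design samples must total 124 individuals")
        regions = set(self.sites.frame["region"])
        if regions != {"north", "center", "south"}:
            raise ValueError("study design needs the three latitudinal regions")

    def region_samples(self) -> dict[str, int]:
        region_of = self.sites.region_of()
        out = {"north": 0, "center": 0, "south": 0}
        for site, n in self.sample_sizes.items():
            out[region_of[site]] += n
        return out


def make_study_fixture(
    design: StudyDesign | None = None,
    seed: int = 0,
    scale: float = 1.0,
) -> tuple[GenotypeMatrix, SiteTable]:
    """Simulate one study-shaped dataset.

    ``scale`` co-scales all times and effective sizes while scaling the
    mutation rate inversely, preserving theta = 4*Ne*mu and relative
    event times t/Ne, so smaller values trade a shorter runtime for
    extra coalescent noise.  Sites within a region are subsamples of
    that region's simulated population.
    """
    if design is None:
        design = StudyDesign()
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    p = design.parameters
    scen = scenario_admixture(
        t_adm=p["t_adm"] * scale,
        t_div=p["t_div"] * scale,
        r=p["r"],
        ne_n=p["ne_n"] * scale,
        ne_c=p["ne_c"] * scale,
        ne_s=p["ne_s"] * scale,
        ne_anc=p["ne_anc"] * scale,
        sample_sizes=design.region_samples(),
    )
    models = [
        MutationModel(
            mu=(p["mu_di"] if l.motif_length == 2 else p["mu_tri"]) / scale,
            gsm_p=p["gsm_p"],
            motif_length=l.motif_length,
        )
        for l in design.loci
    ]
    g = simulate_dataset(
        scen, models, seed=seed, locus_names=[l.name for l in design.loci]
    )
    # partition each region's individuals into its sites, site order as listed
    region_of = design.sites.region_of()
    new_ids: list[str] = []
    new_pops: list[str] = []
    order: list[int] = []
    cursor = {r: 0 for r in ("north", "center", "south")}
    offsets = {}
    start = 0
    for region, n in [(r, scen.sample_sizes[r]) for r in scen.populations]:
        offsets[region] = start
        start += n
    for site in design.sites.sites:
        region = region_of[site]
        n = design.sample_sizes[site]
        lo = offsets[region] + cursor[region]
        order.extend(range(lo, lo + n))
        cursor[region] += n
        new_ids.extend(f"{site}_{i + 1:02d}" for i in range(n))
        new_pops.extend([site] * n)
    g = GenotypeMatrix(new_ids, new_pops, g.loci, g.calls[order], validate=False)
    return g, design.sites


def fixture_manifest(design: StudyDesign, seed: int, scale: float) -> dict:
    """Machine-readable record of how a fixture was generated."""
    from . import __version__

    return {
        "generator": "msatpop.synthetic.make_study_fixture",
        "version": __version__,
        "seed": int(seed),
        "scale": float(scale),
        "parameters": {k: float(v) for k, v in design.parameters.items()},
        "sample_sizes": {k: int(v) for k, v in design.sample_sizes.items()},
    }


def make_null_fixture(
    n_pops: int,
    n_per_pop: int,
    n_loci: int,
    theta: float,
    seed: int = 0,
    motif_length: int = 2,
) -> GenotypeMatrix:
    """Exchangeable null data: one panmictic population, arbitrary labels.

    A single population of constant size is simulated and its
    individuals partitioned into ``n_pops`` labelled groups; any
    apparent differentiation, linkage or inbreeding is sampling noise,
    making this the calibration null for FST, Mantel, HWE and LD tests.
    ``theta`` is the population-scaled mutation rate 4*Ne*mu.
    """
    if min(n_pops, n_per_pop, n_loci) < 1:
        raise ValueError("all counts must be >= 1")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    from .coalescent import DemographicScenario

    ne = 1000.0
    mu = max(theta, 1e-9) / (4 * ne)
    scen = DemographicScenario(
        populations=["panmictic"],
        ne={"panmictic": ne},
        sample_sizes={"panmictic": n_pops * n_per_pop},
        events=[],
        name="null",
    )
    models = [MutationModel(mu=mu, motif_length=motif_length) for _ in range(n_loci)]
    g = simulate_dataset(scen, models, seed=seed)
    pops = [f"pop_{i // n_per_pop + 1}" for i in range(n_pops * n_per_pop)]
    ids = [f"pop_{i // n_per_pop + 1}_{i % n_per_pop + 1:02d}"
           for i in range(n_pops * n_per_pop)]
    return GenotypeMatrix(ids, pops, g.loci, g.calls, validate=False)
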