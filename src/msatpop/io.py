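"""Genotype and site-metadata I/O.

Microsatellite genotypes are exchanged as GenePop v4 text and held in
memory as a :class:`GenotypeMatrix`: an individuals x loci array of
unordered diploid allele-size pairs (base pairs), plus per-individual
population labels and per-locus repeat-motif lengths.  Site metadata
(coordinates in degree/minute notation, region labels) travels in a
delimited table and is held as a :class:`SiteTable`.

Conventions
-----------
* Allele sizes are true fragment sizes in bp.  GenePop 3-digit coding is
  canonical; 2-digit files are read by adding a base offset (default 100)
  so sizes stay in a realistic range and motif congruence stays checkable.
* A call is missing as a unit: both alleles are coded 0 (or 000).
  Half-missing calls are rejected.
* Coordinates are stored as positive decimal degrees South / West; all
  distances are great-circle on a sphere of radius 6371 km.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

MISSING = -1


class GenePopParseError(ValueError):
    """Raised for malformed GenePop input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and its repeat-unit length."""

    name: str
    motif_length: int = 2

    def __post_init__(self):
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")

    @property
    def group(self) -> str:
        """Locus group by motif: 'dinucleotide', 'trinucleotide' or 'other'."""
        return {2: "dinucleotide", 3: "trinucleotide"}.get(self.motif_length, "other")


@dataclass
class GenotypeMatrix:
    """Diploid microsatellite calls for a set of individuals.

    Parameters
    ----------
    individuals : list of str
        Individual identifiers, one per row.
    populations : list of str
        Population (site) label per individual.
    loci : list of Locus
    calls : ndarray, shape (n_individuals, n_loci, 2), int
        Allele sizes in bp; both entries ``MISSING`` (-1) for a missing
        call.  Pairs are unordered; the stored order is not meaningful.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[Locus]
    calls: np.ndarray
    validate: bool = True

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if len(self.populations) != n:
            raise ValueError("one population label required per individual")
        if self.validate:
            self._check()

    def _check(self):
        a, b = self.calls[..., 0], self.calls[..., 1]
        half = (a == MISSING) != (b == MISSING)
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call at individual {self.individuals[i]!r}, "
                f"locus {self.loci[j].name!r}: calls are missing as a unit"
            )
        scored = a != MISSING
        if ((a <= 0) & scored).any() or ((b <= 0) & scored).any():
            raise ValueError("allele sizes must be positive integers")
        for j, locus in enumerate(self.loci):
            col = scored[:, j]
            if col.any():
                bad = (a[col, j] - b[col, j]) % locus.motif_length != 0
                if bad.any():
                    i = np.flatnonzero(col)[np.flatnonzero(bad)[0]]
                    raise ValueError(
                        f"alleles {a[i, j]}/{b[i, j]} at locus {locus.name!r} "
                        f"not congruent modulo motif length {locus.motif_length}"
                    )
            else:
                raise ValueError(
                    f"locus {locus.name!r} has no scored call in any individual"
                )

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_names(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, name: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations, dtype=object) == name)
        if idx.size == 0:
            raise KeyError(f"population {name!r} not present")
        return idx

    def subset(self, populations: list[str] | None = None) -> "GenotypeMatrix":
        """Rows restricted to the given populations (order preserved)."""
        if populations is None:
            return self
        keep = [i for i, p in enumerate(self.populations) if p in set(populations)]
        return GenotypeMatrix(
            [self.individuals[i] for i in keep],
            [self.populations[i] for i in keep],
            self.loci,
            self.calls[keep],
            validate=False,
        )

    def allele_counts(self, pop: str, locus_index: int) -> dict[int, int]:
        """Counts of allele sizes among scored gene copies at one locus."""
        rows = self.population_indices(pop)
        g = self.calls[rows, locus_index, :].ravel()
        g = g[g != MISSING]
        sizes, counts = np.unique(g, return_counts=True)
        return dict(zip(sizes.tolist(), counts.tolist()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if (
            self.individuals != other.individuals
            or self.populations != other.populations
            or self.loci != other.loci
        ):
            return False
        a = np.sort(self.calls, axis=2)
        b = np.sort(other.calls, axis=2)
        return bool(np.array_equal(a, b))


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _block_label(ids: list[str], index: int) -> str:
    """Population label for one POP block.

    Uses the last-individual naming convention: the shared prefix of the
    block's identifiers with trailing separators and digits stripped.  If
    that leaves nothing, the block is numbered ``pop_<index>``.
    """
    import os

    prefix = os.path.commonprefix(ids) if ids else ""
    label = re.sub(r"[\s_\-.]*\d*$", "", prefix)
    return label if label else f"pop_{index}"


def read_genepop(
    path,
    motif_lengths: list[int] | None = None,
    two_digit_offset: int = 100,
) -> GenotypeMatrix:
    """Parse a GenePop v4 file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str or Path
    motif_lengths : list of int, optional
        Repeat-unit length per locus, in file order.  Defaults to 1 for
        every locus (congruence checking disabled) since GenePop files do
        not carry motif information.
    two_digit_offset : int
        Added to every allele code in 2-digit files so stored sizes are
        true bp (default 100).

    Allele code 0 (or 000) marks a missing allele; a call must be missing
    as a unit.  Population labels follow the last-individual naming
    convention when it yields one, else blocks are numbered in file order.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenePopParseError("empty file", 1)

    # locus names: either one per line, or one comma-separated line
    locus_names: list[str] = []
    body_start = None
    for ln, line in enumerate(lines[1:], start=2):
        if _POP_RE.match(line):
            body_start = ln
            break
        for name in line.split(","):
            name = name.strip()
            if name:
                locus_names.append(name)
    if body_start is None:
        raise GenePopParseError("no POP line found", len(lines))
    if not locus_names:
        raise GenePopParseError("no locus names before first POP", 2)

    if motif_lengths is None:
        motif_lengths = [1] * len(locus_names)
    if len(motif_lengths) != len(locus_names):
        raise GenePopParseError(
            f"{len(motif_lengths)} motif lengths for {len(locus_names)} loci"
        )
    loci = [Locus(n, m) for n, m in zip(locus_names, motif_lengths)]

    blocks: list[list[tuple[str, list[str], int]]] = [[]]
    for ln, line in enumerate(lines[body_start:], start=body_start + 1):
        if _POP_RE.match(line):
            blocks.append([])
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenePopParseError("genotype row lacks ',' separator", ln)
        ident, _, rest = line.partition(",")
        tokens = rest.split()
        blocks[-1].append((ident.strip(), tokens, ln))

    labels = [
        _block_label([ident for ident, _, _ in block], bi)
        for bi, block in enumerate(blocks, start=1)
    ]
    if len(set(labels)) != len(labels):
        # naming convention ambiguous across blocks: number them instead
        labels = [f"pop_{bi}" for bi in range(1, len(blocks) + 1)]

    digit_width: int | None = None
    individuals: list[str] = []
    populations: list[str] = []
    rows: list[np.ndarray] = []
    for label, block in zip(labels, blocks):
        for ident, tokens, ln in block:
            if len(tokens) != len(loci):
                raise GenePopParseError(
                    f"{len(tokens)} genotypes for {len(loci)} loci", ln
                )
            call_row = np.empty((len(loci), 2), dtype=np.int64)
            for j, tok in enumerate(tokens):
                if not tok.isdigit() or len(tok) not in (4, 6):
                    raise GenePopParseError(
                        f"genotype token {tok!r} is not 4 or 6 digits", ln
                    )
                w = len(tok) // 2
                if digit_width is None:
                    digit_width = w
                elif w != digit_width:
                    raise GenePopParseError(
                        f"mixed allele digit widths ({digit_width} then {w})", ln
                    )
                a, b = int(tok[:w]), int(tok[w:])
                if (a == 0) != (b == 0):
                    raise GenePopParseError(
                        f"half-missing genotype {tok!r}", ln
                    )
                if a == 0:
                    call_row[j] = (MISSING, MISSING)
                else:
                    off = two_digit_offset if w == 2 else 0
                    call_row[j] = (a + off, b + off)
            individuals.append(ident)
            populations.append(label)
            rows.append(call_row)

    if not individuals:
        raise GenePopParseError("file contains no individuals", len(lines))
    calls = np.stack(rows)
    return GenotypeMatrix(individuals, populations, loci, calls)


def write_genepop(g: GenotypeMatrix, path, title: str | None = None) -> None:
    """Write ``g`` as GenePop v4 text with 3-digit allele coding.

    Individuals are grouped into POP blocks by population, in order of
    first appearance; output is bit-stable for identical inputs.
    ``read_genepop`` inverts it exactly when identifiers follow the
    ``<population>_<number>`` convention.
    """
    if (g.calls >= 1000).any():
        raise ValueError("allele size >= 1000 not representable in 3-digit coding")
    lines = [title if title is not None else "msatpop genotypes"]
    lines.extend(locus.name for locus in g.loci)
    for pop in g.population_names:
        lines.append("POP")
        for i in g.population_indices(pop):
            cells = []
            for j in range(g.n_loci):
                a, b = g.calls[i, j]
                if a == MISSING:
                    cells.append("000000")
                else:
                    cells.append(f"{a:03d}{b:03d}")
            lines.append(f"{g.individuals[i]} ,  " + " ".join(cells))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site metadata
# ---------------------------------------------------------------------------


@dataclass
class SiteTable:
    """Study sites: name, position (decimal degrees S/W) and region label."""

    frame: pd.DataFrame = field(repr=False)

    REGIONS = ("north", "center", "south")

    def __post_init__(self):
        required = {"site", "lat", "lon", "region"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"site table missing columns {sorted(missing)}")
        if self.frame["site"].duplicated().any():
            raise ValueError("site names must be unique")
        bad = ~self.frame["region"].isin(self.REGIONS)
        if bad.any():
            raise ValueError(
                f"unknown region labels: {sorted(self.frame.loc[bad, 'region'])}"
            )
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sites(self) -> list[str]:
        return self.frame["site"].tolist()

    def region_of(self) -> dict[str, str]:
        return dict(zip(self.frame["site"], self.frame["region"]))

    def latitudes(self) -> pd.Series:
        return self.frame.set_index("site")["lat"]

    def great_circle_km(self) -> pd.DataFrame:
        """Pairwise great-circle distances (km) between sites.

        Latitudes are degrees South and longitudes degrees West, both
        stored positive; the haversine below is sign-symmetric so the
        hemisphere convention does not matter.
        """
        lat = np.radians(self.frame["lat"].to_numpy())
        lon = np.radians(self.frame["lon"].to_numpy())
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=self.sites, columns=self.sites)


def dms_to_decimal(degrees: float, minutes: float) -> float:
    """Degree/minute pair to decimal degrees (deg + min/60)."""
    if not 0 <= minutes < 60:
        raise ValueError(f"minutes must be in [0, 60), got {minutes}")
    return degrees + minutes / 60.0


def read_site_table(path, lat_range: tuple[float, float] = (25.0, 38.0)) -> SiteTable:
    """Read delimited site metadata with degree/minute coordinates.

    Expects columns ``site, lat_deg, lat_min, lon_deg, lon_min, region``
    (comma- or tab-separated, header required).  Latitude/longitude are
    degrees South / West and converted to positive decimal degrees.
    Tables already in decimal degrees (``lat``/``lon`` columns, as
    written by :func:`write_site_table`) are accepted as-is.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if {"site", "lat", "lon", "region"} <= set(df.columns):
        lat = df["lat"].tolist()
        lon = df["lon"].tolist()
    else:
        required = {"site", "lat_deg", "lat_min", "lon_deg", "lon_min", "region"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"site table missing columns {sorted(missing)}")
        lat = [dms_to_decimal(d, m) for d, m in zip(df["lat_deg"], df["lat_min"])]
        lon = [dms_to_decimal(d, m) for d, m in zip(df["lon_deg"], df["lon_min"])]
    out = pd.DataFrame(
        {"site": df["site"], "lat": lat, "lon": lon, "region": df["region"]}
    )
    lo, hi = lat_range
    bad = (out["lat"] < lo) | (out["lat"] > hi)
    if bad.any():
        raise ValueError(
            f"latitudes outside [{lo}, {hi}]: {out.loc[bad, 'site'].tolist()}"
        )
    return SiteTable(out)


def write_site_table(table: SiteTable, path) -> None:
    """Write a site table back to CSV (decimal-degree columns)."""
    table.frame.to_csv(path, index=False)
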