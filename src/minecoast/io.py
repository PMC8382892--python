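"""Reading, writing and validation of the genotype and population-map formats.

The internal data model is deliberately small: a diploid dosage matrix with
per-site scaffold/position metadata (:class:`GenotypeMatrix`) and a mapping
from individuals to populations, habitats, regions and coordinates
(:class:`PopulationMap`).  Dosages count ALT alleles (0/1/2); missing
genotypes are stored as :data:`MISSING` and are always excluded site-wise
from allele counts downstream, never imputed.

Only biallelic SNPs are retained when reading VCF: multiallelic records and
indels are skipped (and counted).  Positions are 1-based as in VCF; all
window arithmetic elsewhere in the package uses half-open ``[start, end)``
bp intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype.
MISSING: int = -1

HABITATS = ("mine", "coast")


class DataValidationError(ValueError):
    """Input data violates an invariant of the data model."""


class VcfParseError(ValueError):
    """A VCF file could not be parsed."""


@dataclass
class GenotypeMatrix:
    """Diploid ALT-allele dosages for ``n_individuals x n_sites``.

    Attributes
    ----------
    dosages
        int8 array, values in {0, 1, 2, MISSING}.
    site_scaffold
        Scaffold identifier per site (object array of str).
    site_pos
        1-based bp position per site (int64).
    sample_ids
        Unique individual labels, one per matrix row.
    """

    dosages: np.ndarray
    site_scaffold: np.ndarray
    site_pos: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise DataValidationError("dosages must be a 2-D matrix")
        self.site_scaffold = np.asarray(self.site_scaffold, dtype=object)
        self.site_pos = np.asarray(self.site_pos, dtype=np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]

    # -- shape helpers -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> "GenotypeMatrix":
        """Check all invariants; return self for chaining."""
        n_ind, n_sites = self.dosages.shape
        if len(self.sample_ids) != n_ind:
            raise DataValidationError(
                f"{len(self.sample_ids)} sample ids for {n_ind} matrix rows"
            )
        if len(set(self.sample_ids)) != n_ind:
            raise DataValidationError("duplicate sample ids")
        if len(self.site_scaffold) != n_sites or len(self.site_pos) != n_sites:
            raise DataValidationError("site metadata length mismatch")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise DataValidationError("dosages outside {0,1,2,missing}")
        if n_sites and self.site_pos.min() < 1:
            raise DataValidationError("positions must be 1-based (>= 1)")
        keys = list(zip(self.site_scaffold, self.site_pos))
        if sorted(set(keys)) != keys:
            raise DataValidationError(
                "sites must be sorted by (scaffold, position) and unique"
            )
        return self

    def sort_sites(self) -> "GenotypeMatrix":
        """Return a copy with sites sorted by (scaffold, position)."""
        order = np.lexsort((self.site_pos, self.site_scaffold.astype(str)))
        return GenotypeMatrix(
            self.dosages[:, order],
            self.site_scaffold[order],
            self.site_pos[order],
            list(self.sample_ids),
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Sub-matrix restricted to the given site index (order preserved)."""
        return GenotypeMatrix(
            self.dosages[:, index],
            self.site_scaffold[index],
            self.site_pos[index],
            list(self.sample_ids),
        )

    def filter_missing(self, max_missing: float = 0.2) -> "GenotypeMatrix":
        """Drop sites whose missing-genotype fraction exceeds ``max_missing``."""
        frac = (self.dosages == MISSING).mean(axis=0)
        return self.take_sites(np.nonzero(frac <= max_missing)[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.dosages.shape == other.dosages.shape
            and np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.site_scaffold, other.site_scaffold)
            and np.array_equal(self.site_pos, other.site_pos)
        )


@dataclass
class PopulationMap:
    """Individual -> population assignment plus per-population metadata."""

    individual_population: dict[str, str]
    population_habitat: dict[str, str]
    population_region: dict[str, str]
    population_coords: dict[str, tuple[float, float]]

    def validate(self, gm: GenotypeMatrix | None = None) -> "PopulationMap":
        pops = set(self.individual_population.values())
        for pop in pops:
            if pop not in self.population_habitat:
                raise DataValidationError(f"population {pop!r} has no habitat")
            if self.population_habitat[pop] not in HABITATS:
                raise DataValidationError(
                    f"habitat {self.population_habitat[pop]!r} for {pop!r} "
                    f"is not one of {HABITATS}"
                )
            if pop in self.population_coords:
                lat, lon = self.population_coords[pop]
                if not (abs(lat) <= 90 and abs(lon) <= 180):
                    raise DataValidationError(f"coordinates out of range for {pop!r}")
        if gm is not None:
            unmapped = [s for s in gm.sample_ids if s not in self.individual_population]
            if unmapped:
                raise DataValidationError(
                    f"{len(unmapped)} individuals lack a population "
                    f"(first: {unmapped[0]!r})"
                )
        return self

    # -- convenience ---------------------------------------------------
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.individual_population.values():
            seen.setdefault(pop, None)
        return list(seen)

    def individuals_of(self, pop: str) -> list[str]:
        return [i for i, p in self.individual_population.items() if p == pop]

    def habitat_populations(self, habitat: str) -> list[str]:
        return [p for p in self.populations() if self.population_habitat.get(p) == habitat]

    def mine_coast_pairs(self) -> list[tuple[str, str, str]]:
        """(region, mine_pop, coast_pop) for every region with one of each."""
        pairs = []
        regions: dict[str, dict[str, str]] = {}
        for pop in self.populations():
            reg = self.population_region.get(pop)
            hab = self.population_habitat.get(pop)
            if reg is not None and hab is not None:
                regions.setdefault(reg, {})[hab] = pop
        for reg, byhab in regions.items():
            if "mine" in byhab and "coast" in byhab:
                pairs.append((reg, byhab["mine"], byhab["coast"]))
        return pairs


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_vcf(path: str | Path, max_missing: float | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (a summary count is
    logged).  Missing genotypes become :data:`MISSING`; when
    ``max_missing`` is given, sites with a higher missing fraction are
    dropped (the upstream pipeline this mirrors kept sites with <20%
    missing data, i.e. ``max_missing=0.2``).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _precheck_vcf(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions
        raise VcfParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise DataValidationError(f"duplicate sample ID(s) in {path}: {dup}")

    cols: list[np.ndarray] = []
    scaffolds: list[str] = []
    positions: list[int] = []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        cols.append(col)
        scaffolds.append(var.CHROM)
        positions.append(var.POS)
    if n_skipped:
        logger.info("%s: skipped %d multiallelic/non-SNP records", path, n_skipped)

    if cols:
        dosages = np.stack(cols, axis=1)
    else:
        dosages = np.empty((len(samples), 0), dtype=np.int8)
    gm = GenotypeMatrix(
        dosages, np.array(scaffolds, dtype=object), np.array(positions), samples
    ).sort_sites()
    keys = list(zip(gm.site_scaffold, gm.site_pos))
    if len(set(keys)) != len(keys):
        raise DataValidationError(f"duplicate (scaffold, position) records in {path}")
    gm.validate()
    if max_missing is not None:
        gm = gm.filter_missing(max_missing)
    return gm


def _precheck_vcf(path: Path) -> None:
    """Cheap structural check so malformed files fail with a line number."""
    with open(path, "rt") as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise VcfParseError(f"{path}: line 1: missing ##fileformat header")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                return
            raise VcfParseError(f"{path}: line {lineno}: expected #CHROM header line")
    raise VcfParseError(f"{path}: missing #CHROM header line")


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (v4.2) such that read_vcf round-trips.

    The data model does not carry REF/ALT alleles, so constant A/T
    placeholder alleles are written; dosages encode as 0/0, 0/1, 1/1, ./..
    """
    gm.validate()
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaf in dict.fromkeys(gm.site_scaffold):
            fh.write(f"##contig=<ID={scaf}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:7] + ["INFO", "FORMAT"] + gm.sample_ids) + "\n")
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STRING[int(d)] for d in gm.dosages[:, j])
            row = (
                f"{gm.site_scaffold[j]}\t{gm.site_pos[j]}\t.\tA\tT\t.\t.\t.\tGT"
            )
            if gm.n_individuals:
                row += "\t" + gts
            fh.write(row + "\n")


# ----------------------------------------------------------------------
# Population map / coordinates
# ----------------------------------------------------------------------

def read_popmap(path: str | Path, pops_path: str | Path | None = None) -> PopulationMap:
    """Read a population map from TSV.

    Two layouts are accepted:

    * one file with columns ``individual, population, habitat, region,
      lat, lon`` (per-individual rows; population metadata repeated), or
    * ``path`` with ``individual, population`` plus ``pops_path`` with
      ``population, habitat, region, lat, lon``.

    Habitat tokens are case-folded to ``mine``/``coast``.
    """
    ind_df = pd.read_csv(path, sep="\t", dtype=str)
    ind_df.columns = [c.strip().lower() for c in ind_df.columns]
    for col in ("individual", "population"):
        if col not in ind_df.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")

    if pops_path is not None:
        pop_df = pd.read_csv(pops_path, sep="\t", dtype=str)
        pop_df.columns = [c.strip().lower() for c in pop_df.columns]
        if "population" not in pop_df.columns:
            raise DataValidationError(f"{pops_path}: missing column 'population'")
    else:
        meta_cols = [c for c in ("population", "habitat", "region", "lat", "lon")
                     if c in ind_df.columns]
        pop_df = ind_df[meta_cols].drop_duplicates()

    dup = ind_df.groupby("individual")["population"].nunique()
    conflicted = dup[dup > 1]
    if len(conflicted):
        raise DataValidationError(
            f"individual(s) mapped to multiple populations: "
            f"{list(conflicted.index[:3])}"
        )
    ind_to_pop = dict(
        zip(ind_df["individual"].str.strip(), ind_df["population"].str.strip())
    )

    habitat: dict[str, str] = {}
    region: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    if "population" in pop_df.columns:
        if pop_df["population"].duplicated().any():
            raise DataValidationError("conflicting duplicate population metadata rows")
        for _, row in pop_df.iterrows():
            pop = row["population"].strip()
            if "habitat" in pop_df.columns and pd.notna(row.get("habitat")):
                tok = str(row["habitat"]).strip().casefold()
                if tok not in HABITATS:
                    raise DataValidationError(f"unknown habitat token {row['habitat']!r}")
                habitat[pop] = tok
            if "region" in pop_df.columns and pd.notna(row.get("region")):
                region[pop] = str(row["region"]).strip()
            if (
                "lat" in pop_df.columns
                and "lon" in pop_df.columns
                and pd.notna(row.get("lat"))
                and pd.notna(row.get("lon"))
            ):
                coords[pop] = (float(row["lat"]), float(row["lon"]))
    pm = PopulationMap(ind_to_pop, habitat, region, coords)
    return pm.validate()


def write_popmap(pm: PopulationMap, path: str | Path) -> None:
    """Write a single-file population map TSV (inverse of read_popmap)."""
    rows = []
    for ind, pop in pm.individual_population.items():
        lat, lon = pm.population_coords.get(pop, (np.nan, np.nan))
        rows.append(
            {
                "individual": ind,
                "population": pop,
                "habitat": pm.population_habitat.get(pop, ""),
                "region": pm.population_region.get(pop, ""),
                "lat": lat,
                "lon": lon,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
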