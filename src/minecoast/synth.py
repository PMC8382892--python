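"""Synthetic genotype datasets with known population structure.

Generates the statistical structure the analysis pipeline assumes —
hierarchical differentiation (coast-coast < mine-coast < mine-mine FST),
reduced diversity in mine populations, planted high-FST outliers shared
across chosen mine-coast comparisons, and optional admixture between
populations — so that every downstream stage is testable against a known
truth without any external data.

Allele frequencies follow a hierarchical Balding-Nichols model: an
ancestral frequency ``p ~ Uniform(0.05, 0.95)`` drifts to a regional
frequency with intensity ``F_region`` (a Beta draw with mean p and
variance ``F * p * (1 - p)``), then to a population frequency with
intensity ``F_habitat``; mine populations take one extra drift step with
intensity ``1 - mine_diversity_factor``, which depresses their expected
heterozygosity by exactly that factor.  Genotypes are then binomial
Hardy-Weinberg draws within populations.

Default drift intensities are calibrated so the expected pair-class
Weir-Cockerham FST is ~0.25 for coast-coast, ~0.45 for mine-mine and
~0.34 for local mine-coast pairs (the hierarchical model cannot push the
within-region mine-coast value all the way to the mine-mine level while
keeping cross-region coastal differentiation lower).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GenotypeMatrix, PopulationMap, write_popmap, write_vcf

REGIONS = ("WWA", "SWA", "ENG", "IRE")

#: Approximate sampling-site geography: region anchor (lat, lon) for the
#: mine, and the local mine-coast separation in km (coast displaced north).
_REGION_GEOGRAPHY = {
    "WWA": ((52.35, -3.85), 16.1),
    "SWA": ((51.63, -3.93), 14.8),
    "ENG": ((51.25, -2.65), 25.6),
    "IRE": ((52.02, -9.55), 26.8),
}
_KM_PER_DEG_LAT = 111.195  # spherical earth, radius 6371.0088 km


@dataclass(frozen=True)
class PlantedOutliers:
    """Outlier signal planted into chosen mine-coast comparisons.

    ``comparisons`` are region ids; at each selected SNP the mine
    frequency is pulled toward the allele opposite the coastal frequency
    with weight ``effect`` and, when ``divergent`` (the default, modelling
    divergent selection between the habitats), the coastal frequency is
    pulled toward the other allele with the same weight.  SNPs are either
    ``n_snps`` drawn at random or all SNPs on the named scaffolds.
    """

    comparisons: tuple[str, ...]
    effect: float = 0.95
    n_snps: int = 50
    scaffolds: tuple[str, ...] | None = None
    divergent: bool = True


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic dataset generator."""

    n_per_pop: int = 27
    n_snps: int = 20_000
    n_scaffolds: int = 2_000
    F_region: float = 0.01
    F_habitat: float = 0.242
    mine_diversity_factor: float = 0.733
    planted_outliers: tuple[PlantedOutliers, ...] = ()
    admixture_edges: tuple[tuple[str, str, float], ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("F_region", "F_habitat"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 < self.mine_diversity_factor <= 1.0:
            raise ValueError("mine_diversity_factor must be in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    planted_snps: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    planted_scaffolds: dict[str, list[str]] = field(default_factory=dict)
    admixture_edges: list[tuple[str, str, float]] = field(default_factory=list)
    target_fst: dict[str, float] = field(default_factory=dict)
    expected_pi: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_snps": {
                    k: [[s, int(p)] for s, p in v] for k, v in self.planted_snps.items()
                },
                "planted_scaffolds": self.planted_scaffolds,
                "admixture_edges": [list(e) for e in self.admixture_edges],
                "target_fst": self.target_fst,
                "expected_pi": self.expected_pi,
            },
            indent=1,
        )


def population_names() -> list[str]:
    return [f"{r}-{h}" for r in REGIONS for h in ("M", "C")]


def _bn_step(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: Beta with mean p, variance f*p*(1-p)."""
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))


def default_population_map(cfg: GeneratorConfig) -> PopulationMap:
    """Population map matching the generator's 4 mine-coast region pairs."""
    ind_to_pop: dict[str, str] = {}
    habitat: dict[str, str] = {}
    region: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    for reg in REGIONS:
        (lat, lon), sep_km = _REGION_GEOGRAPHY[reg]
        for hab_code, hab in (("M", "mine"), ("C", "coast")):
            pop = f"{reg}-{hab_code}"
            habitat[pop] = hab
            region[pop] = reg
            coords[pop] = (lat, lon) if hab == "mine" else (lat + sep_km / _KM_PER_DEG_LAT, lon)
            for i in range(cfg.n_per_pop):
                ind_to_pop[f"{pop}_{i + 1:02d}"] = pop
    return PopulationMap(ind_to_pop, habitat, region, coords).validate()


def _scaffold_layout(cfg: GeneratorConfig, rng: np.random.Generator):
    """Assign SNPs to scaffolds (log-normal lengths, uniform positions)."""
    lengths = np.maximum(
        rng.lognormal(mean=np.log(4000.0), sigma=0.8, size=cfg.n_scaffolds), 500.0
    ).astype(np.int64)
    names = np.array([f"scaffold_{i + 1:05d}" for i in range(cfg.n_scaffolds)], dtype=object)
    probs = lengths / lengths.sum()
    scaffold_idx = rng.choice(cfg.n_scaffolds, size=cfg.n_snps, p=probs)
    positions = np.empty(cfg.n_snps, dtype=np.int64)
    used: set[tuple[int, int]] = set()
    for j in range(cfg.n_snps):
        s = int(scaffold_idx[j])
        pos = int(rng.integers(1, lengths[s] + 1))
        while (s, pos) in used:
            pos = int(rng.integers(1, lengths[s] + 1))
        used.add((s, pos))
        positions[j] = pos
    order = np.lexsort((positions, names[scaffold_idx].astype(str)))
    return names[scaffold_idx][order], positions[order]


def gen_frequencies(
    cfg: GeneratorConfig,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, SyntheticTruth]:
    """Per-population allele frequencies plus the planted truth.

    Returns ``(freqs, site_scaffold, site_pos, truth)``.  Planting and
    admixture are applied after the hierarchical drift draws: planted
    SNPs pull the mine frequency toward the allele opposite the local
    coastal frequency, and each admixture edge (donor, recipient, f)
    replaces the recipient's frequencies with the f-mixture.
    """
    rng = np.random.default_rng(cfg.seed)
    scaffolds, positions = _scaffold_layout(cfg, rng)
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    f_extra = 1.0 - cfg.mine_diversity_factor

    freqs: dict[str, np.ndarray] = {}
    for reg in REGIONS:
        p_region = _bn_step(p_anc, cfg.F_region, rng)
        for hab_code in ("M", "C"):
            p_pop = _bn_step(p_region, cfg.F_habitat, rng)
            if hab_code == "M":
                p_pop = _bn_step(p_pop, f_extra, rng)
            freqs[f"{reg}-{hab_code}"] = p_pop

    truth = SyntheticTruth(
        admixture_edges=list(cfg.admixture_edges),
        target_fst=_expected_class_fst(cfg),
        expected_pi=_expected_pi(cfg),
    )

    for plant in cfg.planted_outliers:
        if plant.scaffolds is not None:
            snp_idx = np.nonzero(np.isin(scaffolds.astype(str), plant.scaffolds))[0]
        else:
            snp_idx = rng.choice(cfg.n_snps, size=plant.n_snps, replace=False)
        key = "&".join(plant.comparisons)
        truth.planted_snps[key] = [
            (str(scaffolds[j]), int(positions[j])) for j in np.sort(snp_idx)
        ]
        truth.planted_scaffolds[key] = sorted({str(scaffolds[j]) for j in snp_idx})
        for reg in plant.comparisons:
            coast = freqs[f"{reg}-C"]
            target = np.where(coast[snp_idx] < 0.5, 1.0, 0.0)
            mine = freqs[f"{reg}-M"]
            mine[snp_idx] = np.clip(
                (1.0 - plant.effect) * mine[snp_idx] + plant.effect * target, 0.0, 1.0
            )
            if plant.divergent:
                coast[snp_idx] = np.clip(
                    (1.0 - plant.effect) * coast[snp_idx]
                    + plant.effect * (1.0 - target),
                    0.0,
                    1.0,
                )

    for donor, recipient, f in cfg.admixture_edges:
        freqs[recipient] = (1.0 - f) * freqs[recipient] + f * freqs[donor]

    return freqs, scaffolds, positions, truth


def _expected_class_fst(cfg: GeneratorConfig) -> dict[str, float]:
    """Approximate expected pair-class W&C FST implied by the drift model."""
    f_r, f_h = cfg.F_region, cfg.F_habitat
    f_x = 1.0 - cfg.mine_diversity_factor
    f_coast = 1.0 - (1.0 - f_r) * (1.0 - f_h)
    f_mine = 1.0 - (1.0 - f_r) * (1.0 - f_h) * (1.0 - f_x)
    return {
        "coast-coast": f_coast,
        "mine-mine": f_mine,
        # same-region pair: shared regional drift f_r is common to both
        "mine-coast": ((f_coast + f_mine) / 2.0 - f_r) / (1.0 - f_r),
    }


def _expected_pi(cfg: GeneratorConfig) -> dict[str, float]:
    # ancestral p ~ U(0.05, 0.95): E[p(1-p)] = 1/4 - (1/12) * 0.9^2 - 0 ...
    lo, hi = 0.05, 0.95
    e_p2 = (hi**3 - lo**3) / (3.0 * (hi - lo))
    e_p1p = 0.5 - e_p2
    f_coast = 1.0 - (1.0 - cfg.F_region) * (1.0 - cfg.F_habitat)
    f_mine = 1.0 - (1.0 - f_coast) * cfg.mine_diversity_factor
    out = {}
    for reg in REGIONS:
        out[f"{reg}-C"] = 2.0 * e_p1p * (1.0 - f_coast)
        out[f"{reg}-M"] = 2.0 * e_p1p * (1.0 - f_mine)
    return out


def gen_genotypes(
    freqs: dict[str, np.ndarray],
    cfg: GeneratorConfig,
    scaffolds: np.ndarray,
    positions: np.ndarray,
) -> GenotypeMatrix:
    """Binomial(2, p) Hardy-Weinberg genotypes for every population."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    pm = default_population_map(cfg)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    for pop in population_names():
        p = np.clip(freqs[pop], 0.0, 1.0)
        dos = rng.binomial(2, p[None, :].repeat(cfg.n_per_pop, axis=0)).astype(np.int8)
        if cfg.missing_rate > 0:
            mask = rng.random(dos.shape) < cfg.missing_rate
            dos[mask] = -1
        rows.append(dos)
        sample_ids.extend(pm.individuals_of(pop))
    gm = GenotypeMatrix(
        np.concatenate(rows, axis=0), scaffolds, positions, sample_ids
    )
    return gm.validate()


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SyntheticTruth]:
    """One-call generator: frequencies, genotypes, map and truth."""
    freqs, scaffolds, positions, truth = gen_frequencies(cfg)
    gm = gen_genotypes(freqs, cfg, scaffolds, positions)
    return gm, default_population_map(cfg), truth


def write_dataset(
    cfg: GeneratorConfig, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Emit VCF + popmap TSV + truth JSON; returns the three paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, pm, truth = generate_dataset(cfg)
    vcf = outdir / "synthetic.vcf"
    popmap = outdir / "popmap.tsv"
    truth_path = outdir / "truth.json"
    write_vcf(gm, vcf)
    write_popmap(pm, popmap)
    truth_path.write_text(truth.to_json())
    return vcf, popmap, truth_path
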