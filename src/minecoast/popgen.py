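"""Core population-genetic estimators.

Implements the Weir & Cockerham (1984) two-allele FST variance components,
per-variant-site nucleotide diversity, windowed Tajima's D, genotypic LD
r-squared pruning, great-circle distance, and the two small-sample t-tests
consumed by the downstream contrast analyses.

Conventions
-----------
* Missing genotypes are excluded site-wise from allele counts.
* The multilocus FST is the ratio of summed among-population components to
  summed total components (ratio of sums, not mean of per-site ratios).
* Per-site FST values are not clamped; small negatives are a property of
  the estimator and are retained in downstream percentile ranking.
* Tajima's D windows are non-overlapping half-open 20 kb bins anchored at
  position 1 on each scaffold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MISSING, GenotypeMatrix, PopulationMap

EARTH_RADIUS_KM = 6371.0088


class InsufficientDataError(ValueError):
    """A statistic cannot be computed from the data provided."""


# ----------------------------------------------------------------------
# Allele-count helpers
# ----------------------------------------------------------------------

def _pop_rows(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> np.ndarray:
    if pop not in pm.populations():
        raise KeyError(f"population {pop!r} not in population map")
    members = set(pm.individuals_of(pop))
    rows = np.array([i for i, s in enumerate(gm.sample_ids) if s in members])
    if rows.size == 0:
        raise InsufficientDataError(f"no genotyped individuals for {pop!r}")
    return rows


def site_allele_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_genotyped, ALT frequency, observed het frequency).

    ``dosages``: (individuals x sites) with MISSING sentinel.  Sites with
    no genotyped individual get frequency/het 0 and n 0.
    """
    ok = dosages != MISSING
    n = ok.sum(axis=0)
    alt = np.where(ok, dosages, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), 0.0)
        het = np.where(n > 0, ((dosages == 1) & ok).sum(axis=0) / np.maximum(n, 1), 0.0)
    return n, p, het


# ----------------------------------------------------------------------
# Weir & Cockerham FST
# ----------------------------------------------------------------------

@dataclass
class FstResult:
    """Weir-Cockerham FST between one pair of populations."""

    pair: tuple[str, str]
    multilocus_fst: float
    per_site_fst: np.ndarray  # NaN where undefined
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    defined: np.ndarray  # bool per site
    n_sites_used: int


def wc_fst_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site W&C (1984) variance components for two populations.

    Arguments are per-site sample sizes (diploid individuals), ALT allele
    frequencies and observed heterozygote frequencies.  Returns
    ``(a, b, c, defined)`` where ``defined`` flags sites with >= 2
    genotyped individuals in each population that are polymorphic across
    the pair.  The among-population component ``a``, the among-individual
    component ``b`` and the within-individual component ``c`` follow the
    two-allele, r=2 formulation.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    polymorphic = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    defined = (n1 >= 2) & (n2 >= 2) & polymorphic
    a = np.where(defined, a, np.nan)
    b = np.where(defined, b, np.nan)
    c = np.where(defined, c, np.nan)
    return a, b, c, defined


def wc_fst(gm: GenotypeMatrix, pm: PopulationMap, pop_a: str, pop_b: str) -> FstResult:
    """Weir-Cockerham FST between ``pop_a`` and ``pop_b``.

    Sites monomorphic across the pair, or with fewer than two genotyped
    individuals in either population, are flagged undefined and excluded
    from both the numerator and denominator of the multilocus ratio.
    """
    rows_a = _pop_rows(gm, pm, pop_a)
    rows_b = _pop_rows(gm, pm, pop_b)
    n1, p1, h1 = site_allele_stats(gm.dosages[rows_a])
    n2, p2, h2 = site_allele_stats(gm.dosages[rows_b])
    a, b, c, defined = wc_fst_components(n1, p1, h1, n2, p2, h2)
    if not defined.any():
        raise InsufficientDataError(
            f"no usable polymorphic sites for pair ({pop_a!r}, {pop_b!r})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = a / (a + b + c)
    multilocus = float(np.nansum(a) / np.nansum(a + b + c))
    return FstResult(
        pair=(pop_a, pop_b),
        multilocus_fst=multilocus,
        per_site_fst=per_site,
        a=a,
        b=b,
        c=c,
        defined=defined,
        n_sites_used=int(defined.sum()),
    )


def multilocus_fst_from_dosages(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Multilocus W&C FST straight from two dosage matrices.

    Convenience path used by the simulator (same estimator as
    :func:`wc_fst`, skipping GenotypeMatrix packaging).  Returns NaN when
    no site is usable.
    """
    n1, p1, h1 = site_allele_stats(dos_a)
    n2, p2, h2 = site_allele_stats(dos_b)
    a, b, c, defined = wc_fst_components(n1, p1, h1, n2, p2, h2)
    if not defined.any():
        return float("nan")
    return float(np.nansum(a) / np.nansum(a + b + c))


# ----------------------------------------------------------------------
# Diversity
# ----------------------------------------------------------------------

@dataclass
class DiversityResult:
    """Per-population diversity summaries."""

    population: str
    pi_per_variant_site: float | None = None
    n_sites: int = 0
    #: list of (scaffold, window_start, D, S); D is NaN where undefined
    tajima_d_windows: list[tuple[str, int, float, int]] = field(default_factory=list)
    mean_d: float | None = None


def nucleotide_diversity(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> DiversityResult:
    """Mean pairwise difference per variant site within ``pop``.

    Per site, the unbiased estimator ``(n/(n-1)) * 2 p (1-p)`` with ``n``
    the number of allele copies genotyped in the population.  Averaged
    over the sites of the SNP panel (sites variant across the whole
    matrix); sites monomorphic within the population contribute zero, as
    in the per-variant-site averaging of standard RAD pipelines.
    """
    rows = _pop_rows(gm, pm, pop)
    n_all, p_all, _ = site_allele_stats(gm.dosages)
    variant = (p_all > 0) & (p_all < 1)
    if not variant.any():
        raise InsufficientDataError("matrix contains no variant sites")
    n, p, _ = site_allele_stats(gm.dosages[rows])
    usable = variant & (n >= 2)
    if not usable.any():
        raise InsufficientDataError(f"no usable sites for population {pop!r}")
    alleles = 2.0 * n[usable]
    pi_site = alleles / (alleles - 1.0) * 2.0 * p[usable] * (1.0 - p[usable])
    return DiversityResult(
        population=pop,
        pi_per_variant_site=float(pi_site.mean()),
        n_sites=int(usable.sum()),
    )


def _tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) for sample size n allele copies."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop: str,
    window_bp: int = 20_000,
) -> DiversityResult:
    """Tajima's D in non-overlapping ``window_bp`` windows for one population.

    Windows are half-open ``[start, start+window_bp)`` bins anchored at
    position 1 on each scaffold.  Within the population, sites with any
    missing genotype are skipped so that the constants use a fixed sample
    size of ``2 * n_individuals`` allele copies.  D is NaN (undefined)
    when the window has no segregating site, fewer than 4 allele copies,
    or a non-positive variance estimate.
    """
    rows = _pop_rows(gm, pm, pop)
    dos = gm.dosages[rows]
    n_alleles = 2 * len(rows)

    windows: list[tuple[str, int, float, int]] = []
    complete = (dos != MISSING).all(axis=0)
    alt = dos.sum(axis=0)

    # group sites by (scaffold, window index)
    win_idx = (gm.site_pos - 1) // window_bp
    order = range(gm.n_sites)
    groups: dict[tuple[str, int], list[int]] = {}
    for j in order:
        groups.setdefault((str(gm.site_scaffold[j]), int(win_idx[j])), []).append(j)

    if n_alleles >= 4:
        a1, e1, e2 = _tajima_constants(n_alleles)
    for (scaf, w), sites in sorted(groups.items()):
        start = int(w * window_bp + 1)
        js = [j for j in sites if complete[j]]
        k = alt[np.array(js, dtype=int)] if js else np.array([], dtype=int)
        seg = (k > 0) & (k < n_alleles)
        s = int(seg.sum())
        d = float("nan")
        if n_alleles >= 4 and s >= 1:
            kk = k[seg].astype(float)
            pi_sum = float(np.sum(2.0 * kk * (n_alleles - kk) / (n_alleles * (n_alleles - 1.0))))
            var = e1 * s + e2 * s * (s - 1.0)
            if var > 0:
                d = (pi_sum - s / a1) / math.sqrt(var)
        windows.append((scaf, start, d, s))
    defined = [d for *_x, d, _s in windows if not math.isnan(d)]
    return DiversityResult(
        population=pop,
        tajima_d_windows=windows,
        mean_d=float(np.mean(defined)) if defined else None,
    )


def cross_population_mean_d(results: list[DiversityResult]) -> dict[str, float]:
    """Mean windowed D per population over windows defined in every population.

    Raises if no window is defined in all populations.
    """
    keyed = []
    for res in results:
        keyed.append(
            {(s, w): d for (s, w, d, _n) in res.tajima_d_windows if not math.isnan(d)}
        )
    common = set(keyed[0])
    for kd in keyed[1:]:
        common &= set(kd)
    if not common:
        raise InsufficientDataError("no window has defined D in every population")
    return {
        res.population: float(np.mean([kd[k] for k in sorted(common)]))
        for res, kd in zip(results, keyed)
    }


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------

def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over individuals genotyped at both sites; 0.0 when either
    vector is constant or fewer than two complete pairs exist.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def minor_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-site MAF over all genotyped individuals."""
    _, p, _ = site_allele_stats(dosages)
    return np.minimum(p, 1.0 - p)


def ld_prune(
    gm: GenotypeMatrix,
    r2_threshold: float = 0.1,
    maf_threshold: float = 0.05,
    window_sites: int = 50,
) -> GenotypeMatrix:
    """MAF filter then greedy LD pruning in genome order.

    Sites with MAF < ``maf_threshold`` are removed first.  The remaining
    sites are scanned in (scaffold, position) order; a site is dropped
    when its genotypic r-squared with any retained site among the
    preceding ``window_sites`` retained sites on the same scaffold
    exceeds ``r2_threshold`` (the later site of the pair is removed).
    """
    maf = minor_allele_frequency(gm.dosages)
    candidates = np.nonzero(maf >= maf_threshold)[0]
    kept: list[int] = []
    kept_scaffold: list[str] = []
    for j in candidates:
        scaf = str(gm.site_scaffold[j])
        drop = False
        for prev, prev_scaf in zip(kept[-window_sites:], kept_scaffold[-window_sites:]):
            if prev_scaf != scaf:
                continue
            if genotype_r2(gm.dosages[:, prev], gm.dosages[:, j]) > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(int(j))
            kept_scaffold.append(scaf)
    return gm.take_sites(np.array(kept, dtype=int))


# ----------------------------------------------------------------------
# Geography
# ----------------------------------------------------------------------

def haversine_km(coord_a: tuple[float, float], coord_b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) decimal-degree points."""
    for lat, lon in (coord_a, coord_b):
        if not (abs(lat) <= 90 and abs(lon) <= 180):
            raise ValueError(f"coordinate out of range: ({lat}, {lon})")
    lat1, lon1 = np.radians(coord_a)
    lat2, lon2 = np.radians(coord_b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


# ----------------------------------------------------------------------
# t-tests
# ----------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t(x, y) -> TTestResult:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("need >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0, degenerate=True)
        t = math.inf if x.mean() > y.mean() else -math.inf
        return TTestResult(t=t, df=float(len(x) + len(y) - 2), p=0.0, degenerate=True)
    sx, sy = vx / len(x), vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def paired_t(x, y) -> TTestResult:
    """Paired t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise InsufficientDataError("need >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    df = float(len(d) - 1)
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        t = math.inf if d.mean() > 0 else -math.inf
        return TTestResult(t=t, df=df, p=0.0, degenerate=True)
    t = d.mean() / (sd / math.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))
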