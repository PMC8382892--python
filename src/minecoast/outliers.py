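"""FST outlier calling and exact multi-set intersection tests.

For each mine-coast comparison, SNPs with per-site Weir-Cockerham FST at
or above the 95th percentile of defined values are outlier loci, and any
scaffold carrying at least one outlier SNP is an outlier scaffold.
Overlap of outlier sets across comparisons is summarized in inclusive
(plain intersection) and exclusive (upset-style, partitioning the union)
modes, and the significance of each inclusive intersection is assessed
with the exact distribution of the intersection size of independent,
uniformly drawn fixed-size subsets of a common universe — the multi-set
generalization of Fisher's exact test, computed by iterated
hypergeometric compounding.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .io import GenotypeMatrix, PopulationMap
from .popgen import wc_fst

logger = logging.getLogger(__name__)

Site = tuple[str, int]


@dataclass
class OutlierSet:
    """Outlier SNPs/scaffolds for one mine-coast comparison."""

    comparison: str
    outlier_snps: set[Site]
    outlier_scaffolds: set[str]
    threshold_value: float
    n_snps_tested: int
    tested_snps: set[Site] = field(default_factory=set)


@dataclass
class IntersectionTest:
    """Observed inclusive intersection with its exact null expectation."""

    comparisons: tuple[str, ...]
    observed: int
    background: int
    set_sizes: tuple[int, ...]
    expected: float
    p_value: float
    log10_p: float = 0.0  # exact even when p_value underflows
    mode: str = "inclusive"
    valid: bool = True


def call_outliers(
    per_site_fst: np.ndarray,
    scaffolds: np.ndarray,
    positions: np.ndarray,
    comparison: str = "",
    percentile: float = 95.0,
) -> OutlierSet:
    """Designate the top ``100 - percentile`` % of defined FST values as outliers.

    The threshold is the linear-interpolation percentile of defined
    (non-NaN) per-site values; SNPs with FST >= threshold are outliers,
    ties included.  Raises when fewer than 20 defined values exist (the
    percentile is too unstable to rank).
    """
    fst = np.asarray(per_site_fst, dtype=float)
    defined = ~np.isnan(fst)
    n_def = int(defined.sum())
    if n_def < 20:
        raise ValueError(f"only {n_def} defined FST values; need >= 20")
    threshold = float(np.percentile(fst[defined], percentile))
    is_out = defined & (fst >= threshold)
    if is_out.sum() == n_def:
        logger.warning(
            "%s: all %d defined sites tie at the %gth percentile threshold",
            comparison, n_def, percentile,
        )
    snps = {
        (str(scaffolds[j]), int(positions[j])) for j in np.nonzero(is_out)[0]
    }
    tested = {
        (str(scaffolds[j]), int(positions[j])) for j in np.nonzero(defined)[0]
    }
    return OutlierSet(
        comparison=comparison,
        outlier_snps=snps,
        outlier_scaffolds={s for s, _ in snps},
        threshold_value=threshold,
        n_snps_tested=n_def,
        tested_snps=tested,
    )


def intersections(sets: dict[str, set], mode: str = "inclusive") -> dict[tuple[str, ...], int]:
    """Intersection counts for every subset of >= 1 sets.

    ``inclusive``: plain ``|intersection|`` of the subset's sets.
    ``exclusive``: upset-style counts — elements in exactly that subset
    and no other set; exclusive counts partition the union.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    if mode not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    names = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    if mode == "inclusive":
        for k in range(1, len(names) + 1):
            for combo in itertools.combinations(names, k):
                inter = set.intersection(*(sets[n] for n in combo))
                out[combo] = len(inter)
        return out
    membership: dict[object, frozenset[str]] = {}
    for name in names:
        for el in sets[name]:
            membership[el] = membership.get(el, frozenset()) | {name}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            out[combo] = sum(1 for m in membership.values() if m == frozenset(combo))
    return out


def _log_multiset_distribution(n: int, sizes: list[int]) -> np.ndarray:
    """Log-pmf of |intersection| of m uniform fixed-size subsets of [N].

    Iterated hypergeometric compounding in log space: conditional on the
    running intersection having size s, intersecting with the next set of
    size n_j is hypergeometric(N, s, n_j).
    """
    from scipy.special import logsumexp

    if not sizes:
        raise ValueError("need at least one set size")
    for sz in sizes:
        if not 0 <= sz <= n:
            raise ValueError(f"set size {sz} outside [0, {n}]")
    logpmf = np.full(sizes[0] + 1, -np.inf)
    logpmf[sizes[0]] = 0.0  # |intersection of one set| == its size
    for n_j in sizes[1:]:
        support = np.nonzero(np.isfinite(logpmf))[0]
        new_max = min(int(support.max()), n_j)
        t = np.arange(new_max + 1)
        # transition matrix: rows = previous size s, cols = new size t
        trans = np.stack([hypergeom.logpmf(t, n, int(s), n_j) for s in support])
        logpmf = logsumexp(trans + logpmf[support][:, None], axis=0)
    return logpmf


def multiset_intersection_distribution(n_background: int, sizes: list[int]) -> np.ndarray:
    """Exact pmf of the intersection size, truncated to [0, min(sizes)]."""
    logpmf = _log_multiset_distribution(int(n_background), [int(s) for s in sizes])
    kmax = min(sizes)
    out = np.zeros(kmax + 1)
    upto = min(kmax + 1, len(logpmf))
    out[:upto] = np.exp(logpmf[:upto])
    return out


def multiset_exact_p(n_background: int, sizes: list[int], k: int) -> IntersectionTest:
    """Exact upper-tail P(X >= k) for a multi-set intersection of size k.

    Computed in log space; ``log10_p`` stays exact when the linear
    ``p_value`` underflows (overlaps of strongly enriched sets can be
    more extreme than 1e-300).
    """
    from scipy.special import logsumexp

    sizes = [int(s) for s in sizes]
    expected = n_background * float(np.prod([s / n_background for s in sizes]))
    valid = 0 <= k <= min(sizes) if sizes else False
    if not valid:
        return IntersectionTest(
            comparisons=(), observed=k, background=n_background,
            set_sizes=tuple(sizes), expected=expected, p_value=0.0,
            log10_p=-math.inf, valid=False,
        )
    logpmf = _log_multiset_distribution(int(n_background), sizes)
    log_p = float(logsumexp(logpmf[k:])) if k < len(logpmf) else -math.inf
    log_p = min(log_p, 0.0)
    return IntersectionTest(
        comparisons=(), observed=k, background=n_background,
        set_sizes=tuple(sizes), expected=expected,
        p_value=float(np.exp(log_p)),
        log10_p=log_p / math.log(10.0),
    )


# ----------------------------------------------------------------------
# Whole-scan driver
# ----------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Per-pair outlier sets plus intersection tests at SNP and scaffold level."""

    outlier_sets: dict[str, OutlierSet]
    snp_tests: dict[tuple[str, ...], IntersectionTest]
    scaffold_tests: dict[tuple[str, ...], IntersectionTest]
    snp_counts_exclusive: dict[tuple[str, ...], int]
    scaffold_counts_exclusive: dict[tuple[str, ...], int]


def scan_all_pairs(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pairs: list[tuple[str, str, str]] | None = None,
    percentile: float = 95.0,
) -> OverlapReport:
    """FST outlier scan over mine-coast pairs with overlap significance.

    ``pairs`` is a list of (comparison_id, mine_pop, coast_pop); when
    omitted, the region-matched mine-coast pairs of the population map
    are used.  The exact-test background is the number of SNPs (or
    scaffolds bearing >= 1 tested SNP) tested in every compared set, and
    outlier sets are restricted to that common universe so the fixed-size
    sampling model applies.
    """
    if pairs is None:
        pairs = pm.mine_coast_pairs()
        pairs = [(region, mine, coast) for region, mine, coast in pairs]
    if len(pairs) < 2:
        raise ValueError("need >= 2 mine-coast comparisons")
    for _, mine, coast in pairs:
        for pop in (mine, coast):
            if pop not in pm.populations():
                raise KeyError(f"population {pop!r} not in population map")

    outlier_sets: dict[str, OutlierSet] = {}
    for comp, mine, coast in pairs:
        res = wc_fst(gm, pm, mine, coast)
        outlier_sets[comp] = call_outliers(
            res.per_site_fst, gm.site_scaffold, gm.site_pos,
            comparison=comp, percentile=percentile,
        )

    snp_tests = _level_tests({c: o.outlier_snps for c, o in outlier_sets.items()},
                             {c: o.tested_snps for c, o in outlier_sets.items()})
    scaffold_tests = _level_tests(
        {c: o.outlier_scaffolds for c, o in outlier_sets.items()},
        {c: {s for s, _ in o.tested_snps} for c, o in outlier_sets.items()},
    )
    return OverlapReport(
        outlier_sets=outlier_sets,
        snp_tests=snp_tests,
        scaffold_tests=scaffold_tests,
        snp_counts_exclusive=intersections(
            {c: o.outlier_snps for c, o in outlier_sets.items()}, mode="exclusive"
        ),
        scaffold_counts_exclusive=intersections(
            {c: o.outlier_scaffolds for c, o in outlier_sets.items()}, mode="exclusive"
        ),
    )


def _level_tests(
    outlier: dict[str, set], tested: dict[str, set]
) -> dict[tuple[str, ...], IntersectionTest]:
    names = sorted(outlier)
    tests: dict[tuple[str, ...], IntersectionTest] = {}
    for k in range(2, len(names) + 1):
        for combo in itertools.combinations(names, k):
            universe = set.intersection(*(tested[n] for n in combo))
            n_bg = len(universe)
            sets = [outlier[n] & universe for n in combo]
            observed = len(set.intersection(*sets))
            test = multiset_exact_p(n_bg, [len(s) for s in sets], observed)
            test.comparisons = combo
            tests[combo] = test
    return tests


def report_records(report: OverlapReport, level: str = "scaffold") -> list[dict]:
    """Flatten an overlap report to TSV/JSON-ready records."""
    tests = report.scaffold_tests if level == "scaffold" else report.snp_tests
    excl = (
        report.scaffold_counts_exclusive
        if level == "scaffold"
        else report.snp_counts_exclusive
    )
    rows = []
    for combo, test in sorted(tests.items(), key=lambda kv: (len(kv[0]), kv[0])):
        rows.append(
            {
                "level": level,
                "comparisons": "&".join(combo),
                "degree": len(combo),
                "observed_inclusive": test.observed,
                "exclusive_count": excl.get(combo, 0),
                "expected": test.expected,
                "background": test.background,
                "set_sizes": ",".join(map(str, test.set_sizes)),
                "p_value": test.p_value,
                "log10_p": test.log10_p,
            }
        )
    return rows
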