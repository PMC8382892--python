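"""f4 quartet statistics with block-jackknife z-scores.

For four populations arranged as ``((A, B), (C, D))`` the f4 statistic is
the mean over sites of ``(pA - pB) * (pC - pD)``.  Under a strictly
tree-like history matching the tested arrangement, allele-frequency
differences across the two cherries are uncorrelated and f4 is zero in
expectation; a significant deviation indicates drift shared across the
tree (e.g. admixture).  Standard errors come from a delete-one
block jackknife over contiguous SNP blocks, and significance is judged
against a Dunn-Bonferroni-corrected normal quantile.

Quartets are classified by mine/coast composition:

====  =========================================================
Type  Composition of the tested tree
====  =========================================================
1     four coastal populations
2     four mine populations
3     three coastal + one mine
4     three mine + one coastal
5     two + two, same-habitat populations sister to each other
6     two + two, each cherry mixing one mine and one coastal
====  =========================================================
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import GenotypeMatrix, PopulationMap
from .popgen import site_allele_stats

Quartet = tuple[tuple[str, str], tuple[str, str]]


@dataclass
class QuartetTest:
    """One f4 test of a four-population arrangement."""

    quartet: Quartet
    type: int
    f4: float
    jackknife_se: float
    z: float
    n_blocks: int
    n_sites: int
    tested_topology: bool = True
    significant: bool | None = None


def f4_statistic(
    freqs: dict[str, np.ndarray], a: str, b: str, c: str, d: str
) -> tuple[float, np.ndarray]:
    """f4 = mean over usable sites of (pA - pB)(pC - pD).

    ``freqs`` maps population -> per-site allele frequency with NaN where
    a population has no genotyped individual; such sites are excluded.
    Returns the statistic and the per-site products it averages.
    """
    cols = [np.asarray(freqs[p], dtype=float) for p in (a, b, c, d)]
    ok = ~np.any([np.isnan(col) for col in cols], axis=0)
    if not ok.any():
        raise ValueError("no site is genotyped in all four populations")
    pa, pb, pc, pd = (col[ok] for col in cols)
    prod = (pa - pb) * (pc - pd)
    return float(prod.mean()), prod


def block_jackknife_z(
    per_site_products: np.ndarray, block_size_snps: int = 500
) -> tuple[float, float]:
    """Delete-one-block jackknife SE and z for a mean of per-site values.

    Sites must be in genome order; blocks are contiguous runs of
    ``block_size_snps`` SNPs (the last block may be shorter) and the
    variance uses the weighted delete-one jackknife, which reduces to the
    classic formula for equal blocks.  Raises with fewer than two blocks.
    When all leave-one-out estimates coincide the SE is zero and z is
    reported as signed infinity (or NaN for a zero mean).
    """
    x = np.asarray(per_site_products, dtype=float)
    n = len(x)
    g = math.ceil(n / block_size_snps)
    if g < 2:
        raise ValueError(
            f"need >= 2 blocks ({n} sites / block size {block_size_snps})"
        )
    total = x.sum()
    theta = total / n
    edges = [(i * block_size_snps, min((i + 1) * block_size_snps, n)) for i in range(g)]
    m = np.array([hi - lo for lo, hi in edges], dtype=float)
    block_sums = np.array([x[lo:hi].sum() for lo, hi in edges])
    theta_del = (total - block_sums) / (n - m)

    # weighted delete-one jackknife (Busing et al. 1999)
    h = n / m
    theta_j = g * theta - float(np.sum((1.0 - m / n) * theta_del))
    var = float(
        np.mean((h * theta - (h - 1.0) * theta_del - theta_j) ** 2 / (h - 1.0))
    )
    se = math.sqrt(max(var, 0.0))
    if se <= 1e-12 * max(1.0, abs(theta)):  # numerically zero
        se = 0.0
    if se == 0.0:
        z = math.nan if theta == 0 else math.copysign(math.inf, theta)
    else:
        z = theta / se
    return se, z


def classify_quartet(quartet: Quartet, habitats: dict[str, str]) -> int:
    """Mine/coast composition type (1-6) of an arranged quartet."""
    (a, b), (c, d) = quartet
    try:
        labels = [habitats[p] for p in (a, b, c, d)]
    except KeyError as exc:
        raise ValueError(f"population {exc.args[0]!r} has no habitat label") from exc
    n_mine = sum(lab == "mine" for lab in labels)
    if n_mine == 0:
        return 1
    if n_mine == 4:
        return 2
    if n_mine == 1:
        return 3
    if n_mine == 3:
        return 4
    # two of each: sister arrangement decides
    same_habitat_sisters = labels[0] == labels[1]  # implies labels[2] == labels[3]
    return 5 if same_habitat_sisters else 6


def bonferroni_z(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Two-sided Dunn-Bonferroni z threshold for a family of ``n_tests``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(sps.norm.isf(alpha / (2.0 * n_tests)))


# ----------------------------------------------------------------------
# Topology handling
# ----------------------------------------------------------------------

def _topological_distances(newick: str, taxa: list[str]) -> dict[tuple[str, str], float]:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise ValueError(f"population(s) missing from topology: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    dist: dict[tuple[str, str], float] = {}
    namespace = {t.label: t for t in tree.taxon_namespace}
    for a, b in itertools.combinations(taxa, 2):
        d = pdm.path_edge_count(namespace[a], namespace[b])
        dist[(a, b)] = dist[(b, a)] = float(d)
    return dist


def _consistent_arrangement(
    four: tuple[str, str, str, str], dist: dict[tuple[str, str], float]
) -> Quartet:
    """Arrangement ((A,B),(C,D)) minimizing within-cherry path length.

    Four-point condition on the reference topology: of the three pairings,
    the one whose within-pair distance sum is smallest is the tree-
    consistent arrangement.
    """
    a, b, c, d = four
    pairings: list[Quartet] = [
        ((a, b), (c, d)),
        ((a, c), (b, d)),
        ((a, d), (b, c)),
    ]
    scores = [dist[p1] + dist[p2] for p1, p2 in pairings]
    return pairings[int(np.argmin(scores))]


def run_all_quartets(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    topology: str,
    block_size_snps: int = 500,
    alpha: float = 0.05,
) -> list[QuartetTest]:
    """f4 tests for every 4-subset of populations, all three arrangements.

    ``topology`` is a Newick string over the population labels (the
    reference tree is supplied, never inferred).  For each 4-subset the
    arrangement consistent with the topology is flagged
    ``tested_topology``; all three arrangements contribute to the
    Dunn-Bonferroni family (3 * C(n, 4) tests).
    """
    pops = sorted(pm.populations())
    dist = _topological_distances(topology, pops)
    freqs: dict[str, np.ndarray] = {}
    for pop in pops:
        members = set(pm.individuals_of(pop))
        rows = np.array([i for i, s in enumerate(gm.sample_ids) if s in members])
        n, p, _ = site_allele_stats(gm.dosages[rows])
        freqs[pop] = np.where(n > 0, p, np.nan)

    arrangements: list[tuple[Quartet, bool]] = []
    for four in itertools.combinations(pops, 4):
        tested = _consistent_arrangement(four, dist)
        a, b, c, d = four
        for quartet in (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))):
            is_tested = {frozenset(quartet[0]), frozenset(quartet[1])} == {
                frozenset(tested[0]),
                frozenset(tested[1]),
            }
            arrangements.append((quartet, is_tested))

    threshold = bonferroni_z(alpha, len(arrangements))
    out: list[QuartetTest] = []
    for quartet, is_tested in arrangements:
        (a, b), (c, d) = quartet
        f4, prod = f4_statistic(freqs, a, b, c, d)
        se, z = block_jackknife_z(prod, block_size_snps)
        out.append(
            QuartetTest(
                quartet=quartet,
                type=classify_quartet(quartet, pm.population_habitat),
                f4=f4,
                jackknife_se=se,
                z=z,
                n_blocks=math.ceil(len(prod) / block_size_snps),
                n_sites=len(prod),
                tested_topology=is_tested,
                significant=bool(abs(z) > threshold) if not math.isnan(z) else None,
            )
        )
    return out


def quartet_records(tests: list[QuartetTest]) -> list[dict]:
    """Flatten quartet tests to TSV-ready records."""
    return [
        {
            "pop_a": t.quartet[0][0],
            "pop_b": t.quartet[0][1],
            "pop_c": t.quartet[1][0],
            "pop_d": t.quartet[1][1],
            "type": t.type,
            "f4": t.f4,
            "se": t.jackknife_se,
            "z": t.z,
            "n_sites": t.n_sites,
            "n_blocks": t.n_blocks,
            "tested_topology": t.tested_topology,
            "significant": t.significant,
        }
        for t in tests
    ]
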