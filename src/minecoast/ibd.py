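"""Isolation-by-distance regressions and the mine/coast scenario contrast.

The discriminating statistic of the whole analysis: within each habitat
class, pairwise FST is regressed on pairwise distance (chain steps for
simulated demes, haversine km for observed populations).  Under multiple
independent colonizations of the mine habitat, IBD among mine populations
is steeper than among coastal populations; under a single origin the mine
IBD relationship collapses and the contrast reverses.  The contrast is a
paired two-sided t-test of the per-replicate difference in IBD strength
(slope), and likewise for intercepts.

Measuring IBD strength in the simulated, strongly drifted regime
----------------------------------------------------------------
Mine demes descend from coastal demes through a severe bottleneck, so on
the raw FST scale their pairwise differentiation is a *compression* of
the source pattern toward 1 (``F_m = 1 - (1 - F_b)(1 - F_c)``): raw-scale
slopes among mines are always shallower, however strong the inherited
geographic signal.  The standard linearization ``FST / (1 - FST)``
(Rousset 1997) removes exactly this compression — on that scale the mine
slope is the coastal slope *divided* by ``1 - F_b``, i.e. steeper, with a
higher intercept, whenever mines inherit their sources' differentiation,
and flat when all mines share one source.  Because simulated FST can
saturate at 1 (zero within-habitat diversity at the handful of
segregating sites), odds values are capped (default FST <= 0.99) and the
per-replicate slope uses the bounded-influence Theil-Sen median-of-
pairwise-slopes estimator rather than OLS.  Observed data (tens of
thousands of SNPs, moderate FST) are analysed with plain OLS on raw FST.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GenotypeMatrix, PopulationMap
from .popgen import TTestResult, haversine_km, paired_t, wc_fst
from .wfsim import CHAIN_POSITION, ReplicateSummary

#: FST cap before the odds transform (saturated pairs carry no resolution).
FST_ODDS_CAP = 0.99


@dataclass
class IbdFit:
    """Fit of (possibly linearized) pairwise FST on pairwise distance."""

    pair_class: str
    slope: float
    intercept: float
    r2: float
    n_pairs: int
    distance_metric: str  # "chain_steps", "neg_log10_migration" or "km"
    transform: str = "linear"  # "linear" or "rousset"
    estimator: str = "ols"  # "ols" or "theil_sen"


@dataclass
class ScenarioContrast:
    """Paired mine-vs-coast IBD comparison across simulation replicates."""

    scenario: str
    mine_slopes: np.ndarray
    coast_slopes: np.ndarray
    mine_intercepts: np.ndarray
    coast_intercepts: np.ndarray
    slope_test: TTestResult = field(default=None)  # type: ignore[assignment]
    intercept_test: TTestResult = field(default=None)  # type: ignore[assignment]


def _theil_sen(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i, j in itertools.combinations(range(len(x)), 2)
        if x[i] != x[j]
    ]
    slope = float(np.median(slopes))
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def ibd_regression(
    fst_values,
    distances,
    pair_class: str,
    distance_metric: str = "chain_steps",
    transform: str = "linear",
    estimator: str = "ols",
    odds_cap: float = FST_ODDS_CAP,
) -> IbdFit:
    """Regression of pairwise FST on pairwise distance.

    ``transform="linear"`` regresses raw FST; ``"rousset"`` regresses
    ``FST/(1-FST)`` with FST capped at ``odds_cap``.  ``estimator`` is
    ordinary least squares or the Theil-Sen median slope.  NaN FST values
    (pairs with no usable site) are dropped.  Raises when fewer than three
    pairs remain or all distances are identical (no slope is estimable).
    """
    y = np.asarray(fst_values, dtype=float)
    x = np.asarray(distances, dtype=float)
    if len(x) != len(y):
        raise ValueError("one distance per FST value required")
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 pairs for an IBD fit, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("all distances identical; slope undefined")
    if transform == "rousset":
        y = np.minimum(y, odds_cap)
        y = y / (1.0 - y)
    elif transform != "linear":
        raise ValueError(f"unknown transform {transform!r}")

    if estimator == "theil_sen":
        slope, intercept = _theil_sen(x, y)
        ss_res = float(np.sum((y - slope * x - intercept) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    elif estimator == "ols":
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return IbdFit(
        pair_class=pair_class,
        slope=slope,
        intercept=intercept,
        r2=r2,
        n_pairs=int(len(x)),
        distance_metric=distance_metric,
        transform=transform,
        estimator=estimator,
    )


def _replicate_fits(
    summary: ReplicateSummary,
    metric: str = "chain_steps",
    transform: str = "rousset",
    estimator: str = "theil_sen",
) -> dict[str, IbdFit]:
    """Mine-mine and coast-coast IBD fits for one simulated replicate."""
    fits = {}
    for cls in ("mine-mine", "coast-coast"):
        pairs = summary.pairs_of_class(cls)
        if not pairs:
            raise ValueError(f"replicate missing pair class {cls!r}")
        dist = []
        vals = []
        for (a, b), v in sorted(pairs.items()):
            if metric == "chain_steps":
                dist.append(abs(CHAIN_POSITION[a] - CHAIN_POSITION[b]))
            elif metric == "neg_log10_migration":
                from .wfsim import SimulationConfig, effective_migration

                dist.append(-np.log10(effective_migration(SimulationConfig(), a, b)))
            else:
                raise ValueError(f"unknown simulated distance metric {metric!r}")
            vals.append(v)
        fits[cls] = ibd_regression(
            vals, dist, cls, distance_metric=metric,
            transform=transform, estimator=estimator,
        )
    return fits


def scenario_contrast(
    replicates: list[ReplicateSummary],
    distance_metric: str = "chain_steps",
    transform: str = "rousset",
    estimator: str = "theil_sen",
) -> ScenarioContrast:
    """Paired t-tests of mine vs. coast IBD slopes and intercepts.

    Each replicate contributes one mine-mine and one coast-coast fit; a
    replicate missing either class raises.  Defaults implement the
    linearized, bounded-influence IBD strength described in the module
    docstring; ``transform="linear", estimator="ols"`` gives plain OLS on
    raw FST.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates for a paired contrast")
    ms, cs, mi, ci = [], [], [], []
    for rep in replicates:
        fits = _replicate_fits(rep, distance_metric, transform, estimator)
        ms.append(fits["mine-mine"].slope)
        cs.append(fits["coast-coast"].slope)
        mi.append(fits["mine-mine"].intercept)
        ci.append(fits["coast-coast"].intercept)
    contrast = ScenarioContrast(
        scenario=replicates[0].scenario,
        mine_slopes=np.array(ms),
        coast_slopes=np.array(cs),
        mine_intercepts=np.array(mi),
        coast_intercepts=np.array(ci),
    )
    contrast.slope_test = paired_t(contrast.mine_slopes, contrast.coast_slopes)
    contrast.intercept_test = paired_t(contrast.mine_intercepts, contrast.coast_intercepts)
    return contrast


def observed_ibd(gm: GenotypeMatrix, pm: PopulationMap) -> dict[str, IbdFit]:
    """IBD fits from observed genotypes: one per pair class.

    Pairwise W&C FST for every population pair and haversine distances
    between population coordinates; classes are mine-mine, coast-coast
    and mine-coast.  Raw FST is regressed on km by OLS, matching how
    field data of this kind are usually summarized.
    """
    pops = pm.populations()
    by_class: dict[str, tuple[list, list]] = {
        "mine-mine": ([], []),
        "coast-coast": ([], []),
        "mine-coast": ([], []),
    }
    for a, b in itertools.combinations(sorted(pops), 2):
        for pop in (a, b):
            if pop not in pm.population_coords:
                raise ValueError(f"population {pop!r} has no coordinates")
        hab = tuple(sorted((pm.population_habitat[a], pm.population_habitat[b])))
        if hab == ("mine", "mine"):
            cls = "mine-mine"
        elif hab == ("coast", "coast"):
            cls = "coast-coast"
        else:
            cls = "mine-coast"
        fst = wc_fst(gm, pm, a, b).multilocus_fst
        km = haversine_km(pm.population_coords[a], pm.population_coords[b])
        by_class[cls][0].append(fst)
        by_class[cls][1].append(km)
    fits = {}
    for cls, (vals, dist) in by_class.items():
        if vals:
            fits[cls] = ibd_regression(vals, dist, cls, distance_metric="km")
    return fits
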