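"""Forward-in-time diploid Wright-Fisher colonization simulator.

Simulates a stepping-stone chain of four coastal demes (p1..p4) founded
from a large ancestral population, followed — ten thousand generations
later — by colonization of four mine demes (m1..m4) under one of two
scenarios:

* ``multiple_origin``: each mine ``mk`` is founded from its geographically
  matched coastal deme ``pk`` (independent, parallel colonizations);
* ``single_origin``: all four mines are founded from one coastal deme,
  drawn uniformly at random per replicate.

Individuals are diploid and hermaphroditic (selfing allowed); generations
are non-overlapping.  Each haplotype is a set of derived-allele positions
under infinite sites on ``[1, L]`` (collisions with currently tracked
positions are redrawn).  Migration is backward: each offspring first
chooses its parental deme with probability equal to the migration rate for
each neighbouring deme (remainder local), then draws two parents uniformly
with replacement from that deme.  Each transmitted gamete receives
``Poisson(rec * (L - 1))`` crossovers at uniform breakpoints and
``Poisson(mu * L)`` new mutations.

All demographic parameters can be rescaled by an integer factor ``Q``:
sizes and durations are divided by Q and per-generation rates multiplied
by Q, preserving 4*N*mu, 4*N*rec, N*m and t/N exactly.

At the sampling generation, pairwise Weir-Cockerham FST is computed for
every deme pair with the same estimator used for empirical data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .popgen import multilocus_fst_from_dosages

ScenarioKind = Literal["multiple_origin", "single_origin"]

COASTAL_DEMES = ("p1", "p2", "p3", "p4")
MINE_DEMES = ("m1", "m2", "m3", "m4")

#: Position of each deme along the coastal chain; mines inherit the
#: position of their geographically matched coastal deme.
CHAIN_POSITION = {**{f"p{i}": i for i in range(1, 5)}, **{f"m{i}": i for i in range(1, 5)}}


@dataclass(frozen=True)
class SimulationConfig:
    """Demographic parameterization of the colonization scenarios.

    Defaults are the unscaled study values; ``rescale_Q`` > 1 yields a
    desk-scale model with identical composite parameters.
    """

    L: int = 50_000                 # chromosome length, bp
    mu: float = 7.5e-9              # mutation rate / bp / generation
    rec: float = 4.0e-9             # recombination rate / bp / generation
    N_anc: int = 10_000             # ancestral population size
    burn_in: int = 100_000          # generations before colonization
    coastal_founders: int = 500
    coastal_size: int = 1_000
    growth_delay: int = 10          # generations from founding to full size
    colonization_interval: int = 20  # generations between coastal foundings
    m12: float = 1e-5               # p1 <-> p2 migration
    m23: float = 1e-4
    m34: float = 1e-4
    mine_founders: int = 100
    mine_coast_gap: int = 10_000    # generations between coastal and mine founding
    m_mine_coast: float = 2e-4
    post_mine_generations: int = 100
    extra_end_generations: int = 0  # optional extra offset before sampling
    n_replicates: int = 100
    rescale_Q: int = 1
    seed: int | None = None
    sample_size: int | None = None  # per-deme subsample for FST (None = all)

    def __post_init__(self) -> None:
        for name in ("mu", "rec", "m12", "m23", "m34", "m_mine_coast"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        for name in (
            "L", "N_anc", "burn_in", "coastal_founders", "coastal_size",
            "growth_delay", "colonization_interval", "mine_founders",
            "mine_coast_gap", "post_mine_generations", "rescale_Q",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def scaled(self) -> "SimulationConfig":
        """Apply the rescaling factor; the result has ``rescale_Q == 1``."""
        q = self.rescale_Q
        if q == 1:
            return self

        def div(name: str) -> int:
            v = getattr(self, name)
            if v % q:
                raise ValueError(f"{name}={v} not divisible by rescale_Q={q}")
            return v // q

        return replace(
            self,
            mu=self.mu * q,
            rec=self.rec * q,
            m12=self.m12 * q,
            m23=self.m23 * q,
            m34=self.m34 * q,
            m_mine_coast=self.m_mine_coast * q,
            N_anc=div("N_anc"),
            burn_in=div("burn_in"),
            coastal_founders=div("coastal_founders"),
            coastal_size=div("coastal_size"),
            growth_delay=div("growth_delay"),
            colonization_interval=div("colonization_interval"),
            mine_founders=div("mine_founders"),
            mine_coast_gap=div("mine_coast_gap"),
            post_mine_generations=div("post_mine_generations"),
            extra_end_generations=self.extra_end_generations // q,
            rescale_Q=1,
        )


# ----------------------------------------------------------------------
# Events
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Found:
    generation: int
    deme: str
    source: str
    n: int


@dataclass(frozen=True)
class Resize:
    generation: int
    deme: str
    n: int


@dataclass(frozen=True)
class SetMigration:
    generation: int
    deme_a: str
    deme_b: str
    rate: float


@dataclass(frozen=True)
class Remove:
    generation: int
    deme: str


@dataclass(frozen=True)
class SampleAndStop:
    generation: int


Event = Found | Resize | SetMigration | Remove | SampleAndStop


@dataclass
class EventSchedule:
    """Demographic events in generation order."""

    events: list[Event]

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.generation)
        founded = {"anc"}
        for ev in self.events:
            if isinstance(ev, Found):
                if ev.source not in founded:
                    raise ValueError(
                        f"deme {ev.deme!r} founded from unknown source {ev.source!r}"
                    )
                founded.add(ev.deme)
            elif isinstance(ev, (Resize, Remove)) and ev.deme not in founded:
                raise ValueError(f"event references unfounded deme {ev.deme!r}")
            elif isinstance(ev, SetMigration):
                for d in (ev.deme_a, ev.deme_b):
                    if d not in founded:
                        raise ValueError(f"migration references unfounded deme {d!r}")

    @property
    def stop_generation(self) -> int:
        stops = [e.generation for e in self.events if isinstance(e, SampleAndStop)]
        if len(stops) != 1:
            raise ValueError("schedule must contain exactly one SampleAndStop")
        return stops[0]

    def at(self, generation: int) -> list[Event]:
        return [e for e in self.events if e.generation == generation]


def build_scenario(
    cfg: SimulationConfig,
    kind: ScenarioKind,
    founder_choice: int | None = None,
) -> EventSchedule:
    """Construct the event schedule for one colonization scenario.

    ``founder_choice`` (0..3) names the coastal deme founding all mines in
    the single-origin scenario; it is required there and ignored for
    multiple origins.
    """
    if kind not in ("multiple_origin", "single_origin"):
        raise ValueError(f"unknown scenario kind {kind!r}")
    eff = cfg.scaled()
    b, ci, gd = eff.burn_in, eff.colonization_interval, eff.growth_delay
    ev: list[Event] = []
    # coastal chain: p1/p2 from the ancestral deme, then p2 -> p3 -> p4
    ev += [
        Found(b, "p1", "anc", eff.coastal_founders),
        Found(b, "p2", "anc", eff.coastal_founders),
        Remove(b, "anc"),
        SetMigration(b + 1, "p1", "p2", eff.m12),
        Found(b + ci, "p3", "p2", eff.coastal_founders),
        SetMigration(b + ci + 1, "p2", "p3", eff.m23),
        Found(b + 2 * ci, "p4", "p3", eff.coastal_founders),
        SetMigration(b + 2 * ci + 1, "p3", "p4", eff.m34),
    ]
    for k, fg in enumerate((b, b, b + ci, b + 2 * ci), start=1):
        ev.append(Resize(fg + gd, f"p{k}", eff.coastal_size))
    # mines, ten thousand (unscaled) generations after the coastal chain
    mg = b + 2 * ci + eff.mine_coast_gap
    if kind == "multiple_origin":
        sources = list(COASTAL_DEMES)
    else:
        if founder_choice is None or not 0 <= founder_choice < 4:
            raise ValueError("single_origin requires founder_choice in 0..3")
        sources = [COASTAL_DEMES[founder_choice]] * 4
    for k, src in enumerate(sources, start=1):
        ev.append(Found(mg, f"m{k}", src, eff.mine_founders))
        # each mine exchanges migrants with its geographically matched coastal deme
        ev.append(SetMigration(mg + 1, f"m{k}", f"p{k}", eff.m_mine_coast))
    ev.append(SampleAndStop(mg + eff.post_mine_generations + eff.extra_end_generations))
    return EventSchedule(ev)


# ----------------------------------------------------------------------
# Replicate summaries
# ----------------------------------------------------------------------

def pair_class(deme_a: str, deme_b: str) -> str:
    ha = "mine" if deme_a.startswith("m") else "coast"
    hb = "mine" if deme_b.startswith("m") else "coast"
    if ha == hb == "mine":
        return "mine-mine"
    if ha == hb == "coast":
        return "coast-coast"
    return "mine-coast"


@dataclass
class ReplicateSummary:
    """Pairwise FST output of one simulation replicate."""

    scenario: ScenarioKind
    seed: int
    founder_choice: int | None
    fst: dict[tuple[str, str], float]
    n_segregating: int = 0
    genotypes: dict[str, np.ndarray] | None = None

    def pairs_of_class(self, cls: str) -> dict[tuple[str, str], float]:
        return {k: v for k, v in self.fst.items() if pair_class(*k) == cls}


# ----------------------------------------------------------------------
# Simulation engine
# ----------------------------------------------------------------------

class _State:
    """Haplotype matrix with a dynamic register of segregating positions."""

    def __init__(self, n_max_haplotypes: int, capacity: int = 256):
        self.H = np.zeros((n_max_haplotypes, capacity), dtype=np.uint8)
        self.Hn = np.zeros_like(self.H)
        self.positions = np.zeros(capacity, dtype=np.int64)
        self.n_cols = 0
        self.occupied: set[int] = set()

    def grow(self, needed: int) -> None:
        cap = self.H.shape[1]
        while cap < needed:
            cap *= 2
        if cap != self.H.shape[1]:
            for name in ("H", "Hn"):
                old = getattr(self, name)
                new = np.zeros((old.shape[0], cap), dtype=np.uint8)
                new[:, : self.n_cols] = old[:, : self.n_cols]
                setattr(self, name, new)
            pos = np.zeros(cap, dtype=np.int64)
            pos[: self.n_cols] = self.positions[: self.n_cols]
            self.positions = pos


def _reproduce(
    state: _State,
    parent_blocks: dict[str, tuple[int, int]],
    child_plan: list[tuple[str, int, list[tuple[str, float]]]],
    rng: np.random.Generator,
    mu: float,
    rec: float,
    L: int,
    prune: bool = True,
) -> dict[str, tuple[int, int]]:
    """Produce one offspring generation.

    ``parent_blocks``: deme -> (start_haplotype_row, n_individuals) in
    ``state.H``.  ``child_plan``: (deme, n_children, [(parental_deme,
    prob), ...]) with probabilities summing to 1.  Returns the child block
    layout (rows of ``state.Hn``, which is swapped into ``state.H``).

    Each gamete's base haplotype is a uniform draw over the parental
    deme's haplotype rows — with uniform parent choice, a uniform starting
    haplotype, and selfing allowed, this is distributionally identical to
    drawing the parent first.  Recombinant gametes then alternate between
    that row and its within-individual partner (``row ^ 1``; deme blocks
    always start at even rows).
    """
    S = state.n_cols
    child_blocks: dict[str, tuple[int, int]] = {}
    row = 0
    for deme, n_children, _ in child_plan:
        child_blocks[deme] = (row, n_children)
        row += 2 * n_children
    g_haps = row

    hap_rows = np.empty(g_haps, dtype=np.intp)
    for (deme, n_children, sources), (start, _) in zip(child_plan, child_blocks.values()):
        seg = slice(start, start + 2 * n_children)
        if len(sources) == 1:
            s0, npar = parent_blocks[sources[0][0]]
            hap_rows[seg] = s0 + rng.integers(0, 2 * npar, size=2 * n_children)
        else:
            cum = np.cumsum([p for _, p in sources])
            cum[-1] = 1.0
            choice = np.searchsorted(cum, rng.random(n_children), side="right")
            per_gamete = np.repeat(choice, 2)  # both gametes share the child's deme
            starts = np.array([parent_blocks[name][0] for name, _ in sources])
            sizes = np.array([parent_blocks[name][1] for name, _ in sources])
            hap_rows[seg] = starts[per_gamete] + np.floor(
                rng.random(2 * n_children) * 2 * sizes[per_gamete]
            ).astype(np.intp)

    Hn = state.Hn
    Hn[:g_haps, :S] = state.H[hap_rows, :S]

    # crossovers: rare, fixed up per recombinant gamete
    n_cross = rng.poisson(rec * (L - 1), size=g_haps)
    for g in np.nonzero(n_cross)[0]:
        bps = np.sort(rng.uniform(1.0, float(L), size=n_cross[g]))
        lane = np.searchsorted(bps, state.positions[:S]) & 1
        partner = state.H[hap_rows[g] ^ 1, :S]
        mask = lane == 1
        Hn[g, :S][mask] = partner[mask]

    # new mutations, infinite sites with redraw on collision
    n_mut = rng.poisson(mu * L * g_haps)
    if n_mut:
        state.grow(S + n_mut)
        Hn = state.Hn
        targets = rng.integers(0, g_haps, size=n_mut)
        draws = rng.integers(1, L + 1, size=n_mut)
        occupied = state.occupied
        for i in range(n_mut):
            pos = int(draws[i])
            while pos in occupied:
                pos = int(rng.integers(1, L + 1))
            occupied.add(pos)
            state.positions[S + i] = pos
        Hn[:g_haps, S : S + n_mut] = 0
        Hn[targets, S + np.arange(n_mut)] = 1
        S += n_mut

    # drop columns lost or fixed across all active haplotypes
    if prune and S:
        counts = Hn[:g_haps, :S].sum(axis=0, dtype=np.int64)
        keep = (counts > 0) & (counts < g_haps)
        if not keep.all():
            dead = state.positions[:S][~keep]
            state.occupied.difference_update(int(p) for p in dead)
            k = int(keep.sum())
            Hn[:g_haps, :k] = Hn[:g_haps, :S][:, keep]
            state.positions[:k] = state.positions[:S][keep]
            S = k
    state.n_cols = S
    state.H, state.Hn = state.Hn, state.H
    return child_blocks


def run_replicate(
    schedule: EventSchedule,
    cfg: SimulationConfig,
    rng_seed: int | np.random.SeedSequence,
    scenario: ScenarioKind = "multiple_origin",
    founder_choice: int | None = None,
    return_genotypes: bool = False,
) -> ReplicateSummary:
    """Run one replicate of a schedule and summarize pairwise FST.

    The schedule is interpreted in already-rescaled units (as produced by
    :func:`build_scenario` from ``cfg``); only ``cfg``'s rescaled rates
    and chromosome length are consulted here.
    """
    eff = cfg.scaled()
    rng = np.random.default_rng(rng_seed)
    stop = schedule.stop_generation

    max_inds = _max_concurrent_individuals(schedule, eff)
    state = _State(2 * max_inds)
    blocks: dict[str, tuple[int, int]] = {"anc": (0, eff.N_anc)}
    migration: dict[frozenset[str], float] = {}
    pending_resize: dict[str, int] = {}

    events_by_gen: dict[int, list[Event]] = {}
    for ev in schedule.events:
        events_by_gen.setdefault(ev.generation, []).append(ev)

    for gen in range(1, stop + 1):
        founds: dict[str, tuple[str, int]] = {}
        removed: set[str] = set()
        for ev in events_by_gen.get(gen, ()):
            if isinstance(ev, Found):
                if ev.n > blocks[ev.source][1]:
                    raise ValueError(
                        f"cannot found {ev.deme!r} with {ev.n} individuals from "
                        f"{ev.source!r} of size {blocks[ev.source][1]}"
                    )
                founds[ev.deme] = (ev.source, ev.n)
            elif isinstance(ev, Remove):
                removed.add(ev.deme)
            elif isinstance(ev, Resize):
                pending_resize[ev.deme] = ev.n
            elif isinstance(ev, SetMigration):
                migration[frozenset((ev.deme_a, ev.deme_b))] = ev.rate

        plan: list[tuple[str, int, list[tuple[str, float]]]] = []
        for deme, (start, size) in blocks.items():
            if deme in removed:
                continue
            size = pending_resize.pop(deme, size)
            sources: list[tuple[str, float]] = []
            away = 0.0
            for pair, rate in migration.items():
                if deme in pair:
                    other = next(d for d in pair if d != deme)
                    if other in blocks and other not in removed:
                        sources.append((other, rate))
                        away += rate
            sources.insert(0, (deme, 1.0 - away))
            plan.append((deme, size, sources))
        for deme, (src, n) in founds.items():
            plan.append((deme, n, [(src, 1.0)]))

        blocks = _reproduce(
            state, blocks, plan, rng, eff.mu, eff.rec, eff.L,
            prune=(gen % 8 == 0 or gen == stop),
        )

    return _summarize(state, blocks, scenario, rng_seed, founder_choice,
                      eff, rng, return_genotypes)


def _max_concurrent_individuals(schedule: EventSchedule, eff: SimulationConfig) -> int:
    sizes = {"anc": eff.N_anc}
    peak = eff.N_anc
    for ev in schedule.events:
        if isinstance(ev, Found):
            sizes[ev.deme] = ev.n
        elif isinstance(ev, Resize):
            sizes[ev.deme] = ev.n
        elif isinstance(ev, Remove):
            sizes.pop(ev.deme, None)
        peak = max(peak, sum(sizes.values()))
    return peak


def _summarize(
    state: _State,
    blocks: dict[str, tuple[int, int]],
    scenario: ScenarioKind,
    rng_seed,
    founder_choice: int | None,
    eff: SimulationConfig,
    rng: np.random.Generator,
    return_genotypes: bool,
) -> ReplicateSummary:
    dosages: dict[str, np.ndarray] = {}
    S = state.n_cols
    for deme, (start, n_ind) in blocks.items():
        rows = state.H[start : start + 2 * n_ind, :S]
        dos = (rows[0::2].astype(np.int8) + rows[1::2]).astype(np.int8)
        if eff.sample_size is not None and eff.sample_size < n_ind:
            pick = rng.choice(n_ind, size=eff.sample_size, replace=False)
            dos = dos[np.sort(pick)]
        dosages[deme] = dos
    fst: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(sorted(dosages), 2):
        fst[(a, b)] = multilocus_fst_from_dosages(dosages[a], dosages[b])
    seed_int = rng_seed if isinstance(rng_seed, (int, np.integer)) else -1
    return ReplicateSummary(
        scenario=scenario,
        seed=int(seed_int),
        founder_choice=founder_choice,
        fst=fst,
        n_segregating=S,
        genotypes=dosages if return_genotypes else None,
    )


def run_experiment(
    cfg: SimulationConfig,
    kind: ScenarioKind,
    progress: bool = False,
) -> list[ReplicateSummary]:
    """Run ``cfg.n_replicates`` independent replicates of one scenario.

    Per-replicate seeds are derived reproducibly from ``cfg.seed``; for
    the single-origin scenario the founding coastal deme is drawn
    uniformly at random per replicate.
    """
    if cfg.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if cfg.seed is None:
        raise ValueError("cfg.seed must be set for a reproducible experiment")
    root = np.random.SeedSequence(cfg.seed)
    out: list[ReplicateSummary] = []
    for i, child in enumerate(root.spawn(cfg.n_replicates)):
        rep_rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        founder = None
        if kind == "single_origin":
            founder = int(rep_rng.integers(0, 4))
        schedule = build_scenario(cfg, kind, founder_choice=founder)
        summary = run_replicate(
            schedule, cfg, np.random.SeedSequence(rep_seed),
            scenario=kind, founder_choice=founder,
        )
        summary.seed = rep_seed
        out.append(summary)
        if progress:
            print(f"  replicate {i + 1}/{cfg.n_replicates} done", flush=True)
    return out


def summaries_to_records(summaries: list[ReplicateSummary]) -> list[dict]:
    """Flatten replicate summaries to TSV-ready records."""
    records = []
    for idx, s in enumerate(summaries):
        for (a, b), v in sorted(s.fst.items()):
            records.append(
                {
                    "replicate": idx,
                    "scenario": s.scenario,
                    "seed": s.seed,
                    "founder_choice": -1 if s.founder_choice is None else s.founder_choice,
                    "deme_a": a,
                    "deme_b": b,
                    "class": pair_class(a, b),
                    "fst": v,
                }
            )
    return records


def effective_migration(cfg: SimulationConfig, deme_a: str, deme_b: str) -> float:
    """Product of per-generation migration rates along the chain path."""
    eff = cfg.scaled()
    chain_rates = {("p1", "p2"): eff.m12, ("p2", "p3"): eff.m23, ("p3", "p4"): eff.m34}

    def pos(d: str) -> int:
        return CHAIN_POSITION[d]

    rate = 1.0
    for d in (deme_a, deme_b):
        if d.startswith("m"):
            rate *= eff.m_mine_coast
    lo, hi = sorted((pos(deme_a), pos(deme_b)))
    for i in range(lo, hi):
        rate *= chain_rates[(f"p{i}", f"p{i + 1}")]
    if rate == 1.0 and deme_a != deme_b:
        raise ValueError(f"no migration path between {deme_a!r} and {deme_b!r}")
    return rate
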