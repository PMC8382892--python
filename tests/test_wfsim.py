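import math

import numpy as np
import pytest

from minecoast.wfsim import (
    EventSchedule,
    Found,
    Remove,
    SampleAndStop,
    SetMigration,
    SimulationConfig,
    build_scenario,
    run_experiment,
    run_replicate,
)


def tiny_cfg(**kw):
    base = dict(
        N_anc=60, burn_in=40, coastal_founders=30, coastal_size=40,
        growth_delay=4, colonization_interval=8, mine_founders=8,
        mine_coast_gap=40, post_mine_generations=8, n_replicates=2,
        mu=2e-6,  # enough variation to segregate at this tiny scale
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_rescaling_preserves_composite_parameters(self):
        cfg = SimulationConfig(rescale_Q=10)
        eff = cfg.scaled()
        assert eff.N_anc == 1_000 and eff.burn_in == 10_000
        assert eff.coastal_founders == 50 and eff.mine_founders == 10
        assert eff.mu == pytest.approx(7.5e-8)
        # theta = 4 N mu per site unchanged
        assert 4 * eff.N_anc * eff.mu == pytest.approx(4 * cfg.N_anc * cfg.mu)
        assert eff.N_anc * eff.m23 == pytest.approx(cfg.N_anc * cfg.m23 / 1.0)
        assert eff.burn_in / eff.N_anc == pytest.approx(cfg.burn_in / cfg.N_anc)

    def test_indivisible_rescale_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SimulationConfig(rescale_Q=3).scaled()

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(m12=1.5)


class TestBuildScenario:
    def test_default_timeline_matches_study_design(self):
        sched = build_scenario(SimulationConfig(), "multiple_origin")
        founds = {e.deme: e for e in sched.events if isinstance(e, Found)}
        assert founds["p1"].generation == 100_000
        assert founds["p3"].generation == 100_020
        assert founds["p4"].generation == 100_040
        for k in range(1, 5):
            assert founds[f"m{k}"].generation == 110_040
            assert founds[f"m{k}"].source == f"p{k}"
            assert founds[f"m{k}"].n == 100
        assert sched.stop_generation == 110_140

    def test_single_origin_uses_one_founder(self):
        sched = build_scenario(SimulationConfig(), "single_origin", founder_choice=2)
        founds = {e.deme: e for e in sched.events if isinstance(e, Found)}
        assert all(founds[f"m{k}"].source == "p3" for k in range(1, 5))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            build_scenario(SimulationConfig(), "no_origin")

    def test_single_origin_requires_founder(self):
        with pytest.raises(ValueError, match="founder_choice"):
            build_scenario(SimulationConfig(), "single_origin")

    def test_schedule_rejects_unfounded_references(self):
        with pytest.raises(ValueError, match="unfounded|unknown source"):
            EventSchedule([Found(5, "p2", "p1", 10), SampleAndStop(10)])


class TestRunReplicate:
    def test_zero_mutation_rate_gives_no_segregating_sites(self):
        cfg = tiny_cfg(mu=0.0)
        sched = build_scenario(cfg, "multiple_origin")
        rep = run_replicate(sched, cfg, 1)
        assert rep.n_segregating == 0

    def test_replicate_reports_all_28_pairs(self):
        cfg = tiny_cfg()
        rep = run_replicate(build_scenario(cfg, "multiple_origin"), cfg, 3)
        assert len(rep.fst) == 28
        assert len(rep.pairs_of_class("mine-mine")) == 6
        assert len(rep.pairs_of_class("coast-coast")) == 6
        assert len(rep.pairs_of_class("mine-coast")) == 16

    def test_overlarge_founding_rejected(self):
        cfg = tiny_cfg(mine_founders=500)
        sched = build_scenario(cfg, "multiple_origin")
        with pytest.raises(ValueError, match="found"):
            run_replicate(sched, cfg, 1)

    def test_neutral_diversity_matches_4Nmu(self):
        # single panmictic deme at mutation-drift equilibrium
        N, gens, mu, L = 100, 1_200, 3.0e-7, 50_000
        cfg = SimulationConfig(N_anc=N, burn_in=gens, mu=mu, L=L)
        sched = EventSchedule([SampleAndStop(gens)])
        pis = []
        for seed in range(25):
            rep = run_replicate(sched, cfg, 500 + seed, return_genotypes=True)
            dos = rep.genotypes["anc"]
            n = 2 * dos.shape[0]
            k = dos.sum(axis=0)
            pis.append(np.sum(2.0 * k * (n - k) / (n * (n - 1))) / L)
        pis = np.array(pis)
        se = pis.std(ddof=1) / math.sqrt(len(pis))
        assert abs(pis.mean() - 4 * N * mu) < 3 * se

    def test_two_deme_split_fst_matches_drift_expectation(self):
        # split t = N/2 generations ago, no migration: E[FST] = 1 - exp(-t/2N)
        N, t, mu = 100, 50, 3.0e-7
        cfg = SimulationConfig(N_anc=N, burn_in=1_000, mu=mu)
        sched = EventSchedule(
            [
                Found(1_000, "p1", "anc", N),
                Found(1_000, "p2", "anc", N),
                Remove(1_000, "anc"),
                SampleAndStop(1_000 + t),
            ]
        )
        vals = []
        for seed in range(30):
            rep = run_replicate(sched, cfg, 9_000 + seed)
            vals.append(rep.fst[("p1", "p2")])
        vals = np.array(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        expected = 1.0 - math.exp(-t / (2.0 * N))
        assert abs(vals.mean() - expected) < 3 * se

    def test_migration_edge_constrains_differentiation(self):
        # strong migration between p1 and p2 keeps FST near zero
        N, t = 60, 120
        cfg = SimulationConfig(N_anc=N, burn_in=200, mu=3.0e-7)
        sched = EventSchedule(
            [
                Found(200, "p1", "anc", N),
                Found(200, "p2", "anc", N),
                Remove(200, "anc"),
                SetMigration(201, "p1", "p2", 0.2),
                SampleAndStop(200 + t),
            ]
        )
        vals = [run_replicate(sched, cfg, 100 + s).fst[("p1", "p2")] for s in range(10)]
        assert np.nanmean(vals) < 0.05


class TestRunExperiment:
    def test_same_seed_is_bit_identical(self):
        cfg = tiny_cfg(seed=99)
        a = run_experiment(cfg, "multiple_origin")
        b = run_experiment(cfg, "multiple_origin")
        assert len(a) == len(b) == 2
        for ra, rb in zip(a, b):
            assert sorted(ra.fst) == sorted(rb.fst)
            np.testing.assert_array_equal(  # NaN-aware bitwise identity
                np.array([ra.fst[k] for k in sorted(ra.fst)]),
                np.array([rb.fst[k] for k in sorted(rb.fst)]),
            )

    def test_single_origin_founder_uniform(self):
        cfg = tiny_cfg(
            N_anc=20, burn_in=8, coastal_founders=10, coastal_size=12,
            growth_delay=2, colonization_interval=2, mine_founders=4,
            mine_coast_gap=4, post_mine_generations=2,
            n_replicates=200, seed=5, mu=0.0,
        )
        reps = run_experiment(cfg, "single_origin")
        counts = np.bincount([r.founder_choice for r in reps], minlength=4)
        se = math.sqrt(200 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 50) < 3.5 * se)

    def test_rescaling_invariance_of_diversity(self):
        # the same base model rescaled by different factors gives the same
        # equilibrium diversity (4 N mu per site is preserved)
        means = {}
        for q in (4, 8):
            cfg = SimulationConfig(
                N_anc=800, burn_in=8_000, mu=7.5e-9, L=50_000, rescale_Q=q,
                coastal_founders=400, coastal_size=800, growth_delay=8,
                colonization_interval=16, mine_founders=80, mine_coast_gap=8_000,
                post_mine_generations=80,
            ).scaled()
            sched = EventSchedule([SampleAndStop(cfg.burn_in)])
            pis = []
            for seed in range(12):
                rep = run_replicate(sched, cfg, 40 + seed, return_genotypes=True)
                dos = rep.genotypes["anc"]
                n = 2 * dos.shape[0]
                k = dos.sum(axis=0)
                pis.append(np.sum(2.0 * k * (n - k) / (n * (n - 1))) / cfg.L)
            means[q] = (np.mean(pis), np.std(pis, ddof=1) / math.sqrt(len(pis)))
        diff = abs(means[4][0] - means[8][0])
        pooled = math.hypot(means[4][1], means[8][1])
        assert diff < 3 * pooled
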