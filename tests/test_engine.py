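"""Event-kernel mechanics: scheduling, stalling, queueing, repair,
removal fates, burn-in, conservation and exclusion invariants."""

import math

import numpy as np
import pytest

import uvpol
from uvpol.engine import MOVING, STALLED, Simulation, removal_waiting_time
from uvpol.params import GeneSpec, SimParams


def tiny_params(**over):
    base = dict(
        genes=[GeneSpec("g", 100_000, 1.0)],
        pool_size=10,
        initiation_rate_per_free_pol=0.0,
        elongation_speed=33.33,
        footprint=40.0,
        lesion_density=0.0,
        moving_removal_hazard=0.0,
        stalled_removal_hazard=0.0,
        snapshot_times=[100.0],
    )
    base.update(over)
    return SimParams(**base)


class TestInitState:
    def test_everything_starts_free(self):
        sim = uvpol.init_state(uvpol.default_params("single_100kb", pool_size=500), 1)
        assert sim.free_pool == 500
        assert sim.engaged_count() == 0
        assert sim.degraded_count == 0
        assert sim.clock == 0.0

    def test_same_seed_same_state(self):
        p = uvpol.default_params("single_100kb")
        a, b = uvpol.init_state(p, 42), uvpol.init_state(p, 42)
        a.advance_until(500.0), b.advance_until(500.0)
        sa, sb = a.snapshot(), b.snapshot()
        assert sa.free_pool == sb.free_pool
        assert np.allclose(sa.genes["gene_100kb"]["positions"],
                           sb.genes["gene_100kb"]["positions"])

    def test_zero_pool_never_initiates(self):
        sim = uvpol.init_state(uvpol.default_params("single_100kb", pool_size=0), 1)
        sim.advance_until(10_000.0)
        assert sim.engaged_count() == 0 and sum(sim.init_assigned.values()) == 0


class TestAdvancePositions:
    def test_moving_polymerase_translocates(self):
        sim = Simulation(tiny_params(elongation_speed=20.0), 0)
        pol = sim.place_polymerase(0, 1000.0)
        sim.advance_positions(10.0)
        assert pol.position(sim.clock) == pytest.approx(1200.0)

    def test_stalled_polymerase_fixed(self):
        sim = Simulation(tiny_params(), 0)
        sim.inject_lesion(0, 1000.0, 1e9)
        pol = sim.place_polymerase(0, 1000.0 - 40)
        sim.advance_until(5.0)  # let it reach and stall at the lesion
        assert pol.status == STALLED
        x = pol.position(sim.clock)
        sim.advance_positions(10.0)
        assert pol.position(sim.clock) == x

    def test_dt_zero_is_identity(self):
        sim = Simulation(tiny_params(), 0)
        pol = sim.place_polymerase(0, 500.0)
        sim.advance_positions(0.0)
        assert pol.position(sim.clock) == 500.0

    def test_cannot_step_over_pending_event(self):
        sim = Simulation(tiny_params(elongation_speed=100.0), 0)
        sim.place_polymerase(0, 99_990.0)  # completion due in 0.1 s
        with pytest.raises(uvpol.StateError):
            sim.advance_positions(10.0)


class TestNextArrival:
    def test_lesion_target(self):
        sim = Simulation(tiny_params(elongation_speed=33.33), 0)
        sim.inject_lesion(0, 11_000.0, 1e9)
        pol = sim.place_polymerase(0, 10_000.0)
        t, target, cause = sim.next_arrival(pol)
        assert target == 11_000.0 and cause[0] == "lesion"
        assert t == pytest.approx(1000.0 / 33.33)

    def test_stalled_neighbor_beats_far_lesion(self):
        sim = Simulation(tiny_params(), 0)
        sim.inject_lesion(0, 11_000.0, 1e9)
        blocker = sim.place_polymerase(0, 11_000.0 - 40)
        sim.advance_until(2.0)  # blocker reaches lesion and stalls
        assert blocker.status == STALLED and blocker.pos0 == 11_000.0
        sim.inject_lesion(0, 20_000.0, 1e9)
        pol = sim.place_polymerase(0, 10_000.0)
        _, target, cause = sim.next_arrival(pol)
        assert target == pytest.approx(10_960.0)
        assert cause == ("queue", blocker.pol_id)

    def test_gene_end_completion(self):
        sim = Simulation(tiny_params(elongation_speed=33.33), 0)
        pol = sim.place_polymerase(0, 99_000.0)
        t, target, cause = sim.next_arrival(pol)
        assert cause[0] == "end" and target == 100_000.0
        assert t == pytest.approx(1000.0 / 33.33)


class TestHandleEvent:
    def test_stall_zeroes_speed(self):
        sim = Simulation(tiny_params(), 0)
        sim.inject_lesion(0, 500.0, 1e9)
        pol = sim.place_polymerase(0, 400.0)
        sim.advance_until(10.0)
        assert pol.status == STALLED and pol.speed == 0.0
        assert pol.pos0 == pytest.approx(500.0)

    def test_repair_resumes_blocked_polymerase(self):
        sim = Simulation(tiny_params(), 0)
        sim.inject_lesion(0, 500.0, 100.0)
        pol = sim.place_polymerase(0, 400.0)
        sim.advance_until(50.0)
        assert pol.status == STALLED
        sim.advance_until(101.0)
        assert pol.status == MOVING
        assert pol.position(sim.clock) > 500.0

    def test_mid_queue_removal_advances_upstream_by_footprint(self):
        """Removing the middle of a three-polymerase queue lets the tail
        advance exactly one footprint before re-stalling (cross-checked by
        hand against the obstacle-chasing dynamics)."""
        sim = Simulation(tiny_params(), 0)
        sim.inject_lesion(0, 1000.0, 1e9)
        pols = [sim.place_polymerase(0, 1000.0 - 120 + 40 * i) for i in range(3)]
        sim.advance_until(10.0)  # queue compacts: 1000, 960, 920
        head, mid, tail = pols[2], pols[1], pols[0]
        assert [round(p.pos0) for p in (head, mid, tail)] == [1000, 960, 920]
        sim.force_remove(mid.pol_id)
        sim.advance_until(sim.clock + 5.0)
        assert tail.status == STALLED
        assert tail.pos0 == pytest.approx(960.0)  # advanced by >= footprint
        sim.check_invariants()

    def test_completion_counts_mrna_and_recycles(self):
        sim = Simulation(tiny_params(completion_recycle_prob=1.0), 0)
        free0 = sim.free_pool
        sim.place_polymerase(0, 99_990.0)
        sim.advance_until(10.0)
        assert sim.mrna_counts["g"] == 1
        assert sim.free_pool == free0


class TestRemovalSampling:
    def test_zero_hazard_never_fires(self):
        rng = np.random.default_rng(0)
        assert removal_waiting_time(rng, 0.0) == math.inf

    def test_exponential_mean(self):
        rng = np.random.default_rng(1)
        lam = 1.0 / 1800.0
        draws = np.array([removal_waiting_time(rng, lam) for _ in range(10_000)])
        se = 1800.0 / math.sqrt(10_000)
        assert abs(draws.mean() - 1800.0) < 3 * se

    def test_stalled_hazard_dominates(self):
        """Higher hazard gives stochastically smaller waiting times."""
        rng = np.random.default_rng(2)
        lam_m, lam_s = 1 / 3600.0, 1 / 600.0
        moving = np.array([removal_waiting_time(rng, lam_m) for _ in range(10_000)])
        stalled = np.array([removal_waiting_time(rng, lam_s) for _ in range(10_000)])
        assert np.mean(stalled < moving) > 0.5
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(stalled, q) < np.quantile(moving, q)


class TestRemovalFate:
    def _removal_fates(self, prob, n, seed=0):
        sim = Simulation(tiny_params(pool_size=n + 1, removal_recycle_prob=prob), seed)
        fates = []
        for _ in range(n):
            pol = sim.place_polymerase(0, 50_000.0)
            fates.append(sim.force_remove(pol.pol_id))
        return fates

    def test_always_recycle(self):
        assert set(self._removal_fates(1.0, 200)) == {"recycled"}

    def test_always_degrade(self):
        assert set(self._removal_fates(0.0, 200)) == {"degraded"}

    def test_binomial_split(self):
        fates = self._removal_fates(0.5, 10_000)
        frac = fates.count("recycled") / len(fates)
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 10_000)


class TestBurnIn:
    def test_zero_initiation_converges_immediately(self):
        p = uvpol.default_params("single_100kb", initiation_rate_per_free_pol=0.0)
        sim = Simulation(p, 0)
        sim.burn_in()
        assert sim.engaged_count() == 0
        sim.check_invariants()

    def test_flux_balance_and_uniform_occupancy(self):
        """At steady state the post-TSS occupancy per 1-kb bin is flat:
        density = initiation flux / speed per unit length."""
        p = uvpol.default_params("single_100kb")
        sim = Simulation(p, 3)
        sim.burn_in()
        sim.check_invariants()
        snap = sim.snapshot()
        pos = snap.genes["gene_100kb"]["positions"]
        hist, _ = np.histogram(pos, bins=20, range=(0, 100_000))
        mean = hist.mean()
        assert mean > 3
        assert hist.std() < 0.55 * mean  # Poisson-like scatter, no trend
        lin = np.polyfit(np.arange(20), hist, 1)[0]
        assert abs(lin) < 0.35 * mean / 20 * 10  # no systematic slope

    def test_burn_in_failure_raises(self):
        # with near-certain premature termination (and full recycling) the
        # initiation and completion fluxes can never balance
        p = tiny_params(initiation_rate_per_free_pol=0.005, pool_size=100,
                        moving_removal_hazard=1.0 / 100.0,
                        removal_recycle_prob=1.0, burn_in_time=100.0)
        sim = Simulation(p, 0)
        with pytest.raises(uvpol.ConvergenceError):
            sim.burn_in()


class TestApplyDamage:
    def test_zero_density_no_lesions(self):
        p = uvpol.default_params("single_100kb", lesion_density=0.0)
        sim = Simulation(p, 1)
        sim.burn_in()
        before = sim.snapshot()
        sim.apply_damage()
        assert len(sim.lesions) == 0
        after = sim.snapshot()
        assert np.allclose(before.genes["gene_100kb"]["positions"],
                           after.genes["gene_100kb"]["positions"])

    def test_poisson_lesion_count(self):
        p = uvpol.default_params("single_100kb", pool_size=0,
                                 initiation_rate_per_free_pol=0.0, burn_in_time=0.0)
        counts = []
        for seed in range(1000):
            sim = Simulation(p, seed)
            sim.apply_damage()
            counts.append(len(sim.lesions))
        mean = np.mean(counts)
        se = math.sqrt(4.0 / 1000)  # Poisson var = mean = L*rho = 4
        assert abs(mean - 4.0) < 3 * se

    def test_repair_times_median_is_halflife(self):
        p = uvpol.default_params("single_100kb", pool_size=0,
                                 initiation_rate_per_free_pol=0.0, burn_in_time=0.0,
                                 lesion_density=10 / 100_000.0)
        times = []
        for seed in range(1000):
            sim = Simulation(p, seed)
            sim.apply_damage()
            times.extend(l.repair_time for l in sim.lesions.values())
        med = np.median(times)
        # exponential: median = mean*ln2 = halflife; SE of the median via
        # asymptotics ~ 1/(2 f(m) sqrt(n))
        n = len(times)
        se = p.lesion_halflife / math.log(2) / math.sqrt(n)
        assert abs(med - p.lesion_halflife) < 3 * se

    def test_double_damage_rejected(self):
        p = uvpol.default_params("single_100kb")
        sim = Simulation(p, 1)
        sim.apply_damage()
        with pytest.raises(uvpol.StateError):
            sim.apply_damage()


class TestRunContract:
    def test_deterministic_trajectories(self):
        p = uvpol.default_params("single_100kb",
                                 snapshot_times=[600.0, 1800.0], burn_in_time=6000.0)
        a, b = uvpol.run(p, 9), uvpol.run(p, 9)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert sa.free_pool == sb.free_pool
            assert sa.degraded_count == sb.degraded_count
            assert np.allclose(sa.genes["gene_100kb"]["positions"],
                               sb.genes["gene_100kb"]["positions"])

    def test_onset_snapshot_is_burn_in_state_plus_lesions(self):
        p = uvpol.default_params("single_100kb", snapshot_times=[600.0])
        traj = uvpol.run(p, 5)
        s0 = traj.snapshots[0]
        assert s0.time == 0.0
        assert s0.degraded_count == 0
        assert all(v == 0 for v in s0.mrna_counts.values())
        assert sum(len(v) for v in s0.lesions.values()) >= 0

    def test_conservation_in_every_snapshot(self):
        p = uvpol.default_params("single_100kb", snapshot_times=[600.0, 1800.0])
        traj = uvpol.run(p, 6)
        for s in traj.snapshots:
            assert s.free_pool + s.engaged + s.degraded_count == p.pool_size

    def test_no_loss_regime_balances_fluxes(self):
        """Without lesions or removal and with full recycling, nothing
        degrades and the completion rate over a >= 10-transit steady-state
        window matches the initiation rate within 5%."""
        p = uvpol.default_params(
            "single_100kb", lesion_density=0.0, moving_removal_hazard=0.0,
            stalled_removal_hazard=0.0, completion_recycle_prob=1.0)
        sim = Simulation(p, 7)
        sim.burn_in()
        placed0 = sum(sim.init_placed.values())
        completed0 = sum(sim.completions_total().values())
        sim.advance_until(sim.clock + 30_000.0)  # 10 transit times
        placed = sum(sim.init_placed.values()) - placed0
        completed = sum(sim.completions_total().values()) - completed0
        assert sim.degraded_count == 0
        assert placed > 500
        assert abs(placed - completed) / placed < 0.05

    def test_validated_small_run_holds_invariants_each_event(self):
        p = uvpol.default_params("single_100kb", pool_size=50,
                                 snapshot_times=[600.0, 1800.0], burn_in_time=4000.0)
        uvpol.run(p, 8, validate=True)  # raises on any violation
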