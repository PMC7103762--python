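"""Fixed-step brute-force simulator used as an independent oracle.

Implements the same physical model as the event-driven kernel - finite
pool, mass-action initiation gated on a free TSS footprint, constant-speed
elongation with head-to-tail exclusion, stalling at unrepaired lesions,
status-dependent exponential removal with recycle/degrade fates - but by
naive time stepping at dt = 0.01 s, applying each hazard as the per-step
probability 1 - exp(-hazard*dt).  Deliberately shares no code with the
kernel.

Removal is drawn as a geometric step count (redrawn on every status
change), the discrete-time equivalent of redrawing an exponential clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class TinyConditions:
    """The small single-gene instance both simulators are run on."""

    length: float = 2000.0
    pool_size: int = 5
    k_init: float = 0.02  # 1/s per free polymerase
    speed: float = 40.0  # nt/s
    footprint: float = 40.0
    lesion_position: float = 1200.0
    lesion_mean_life: float = 90.0  # s (exponential)
    moving_hazard: float = 0.002  # 1/s
    stalled_hazard: float = 0.01  # 1/s
    recycle_prob: float = 0.5
    completion_recycle_prob: float = 1.0
    horizon: float = 120.0  # s


def brute_force_run(c: TinyConditions, seed: int, dt: float = 0.01) -> dict:
    """One realization; returns final positions, degraded count, mRNA count
    and free pool."""
    rng = np.random.default_rng(seed)
    n_steps = int(round(c.horizon / dt))
    p_move = -math.expm1(-c.moving_hazard * dt)
    p_stall = -math.expm1(-c.stalled_hazard * dt)

    def removal_steps(stalled: bool) -> float:
        p = p_stall if stalled else p_move
        return float(rng.geometric(p)) if p > 0 else math.inf

    repair_time = rng.exponential(c.lesion_mean_life)
    pos: list[float] = []  # ascending
    stalled: list[bool] = []
    counters: list[float] = []
    free = c.pool_size
    degraded = 0
    mrna = 0
    step_adv = c.speed * dt
    for step in range(n_steps):
        t = step * dt
        lesion_active = t < repair_time
        # advance downstream-to-upstream with capping
        n = len(pos)
        for i in range(n - 1, -1, -1):
            cap = c.length
            if lesion_active and pos[i] < c.lesion_position + 1e-9:
                cap = min(cap, c.lesion_position)
            if i < len(pos) - 1:
                cap = min(cap, pos[i + 1] - c.footprint)
            new = min(pos[i] + step_adv, cap)
            now_stalled = new < pos[i] + step_adv - 1e-12 and new < c.length - 1e-9
            if now_stalled != stalled[i]:
                stalled[i] = now_stalled
                counters[i] = removal_steps(now_stalled)
            pos[i] = new
        # completions
        while pos and pos[-1] >= c.length - 1e-9:
            pos.pop(); stalled.pop(); counters.pop()
            mrna += 1
            if rng.random() < c.completion_recycle_prob:
                free += 1
            else:
                degraded += 1
        # removals
        i = 0
        while i < len(pos):
            counters[i] -= 1
            if counters[i] <= 0:
                pos.pop(i); stalled.pop(i); counters.pop(i)
                if rng.random() < c.recycle_prob:
                    free += 1
                else:
                    degraded += 1
            else:
                i += 1
        # initiation
        if free > 0:
            p_init = -math.expm1(-c.k_init * free * dt)
            if rng.random() < p_init:
                if not pos or pos[0] >= c.footprint:
                    pos.insert(0, 0.0)
                    stalled.insert(0, False)
                    counters.insert(0, removal_steps(False))
                    free -= 1
    return {"positions": np.array(pos), "degraded": degraded, "mrna": mrna,
            "free": free}


def event_driven_run(c: TinyConditions, seed: int) -> dict:
    """The same instance on the event-driven kernel (no burn-in; the lesion
    is injected at t=0 with a repair time drawn from the run's own rng)."""
    from uvpol.engine import Simulation
    from uvpol.params import GeneSpec, SimParams

    params = SimParams(
        genes=[GeneSpec("tiny", int(c.length), 1.0)],
        pool_size=c.pool_size,
        initiation_rate_per_free_pol=c.k_init,
        elongation_speed=c.speed,
        footprint=c.footprint,
        lesion_density=0.0,
        moving_removal_hazard=c.moving_hazard,
        stalled_removal_hazard=c.stalled_hazard,
        removal_recycle_prob=c.recycle_prob,
        completion_recycle_prob=c.completion_recycle_prob,
        snapshot_times=[c.horizon],
    )
    sim = Simulation(params, seed)
    repair = float(sim.rng.exponential(c.lesion_mean_life))
    sim.inject_lesion(0, c.lesion_position, repair)
    sim.advance_until(c.horizon)
    snap = sim.snapshot()
    return {"positions": snap.genes["tiny"]["positions"],
            "degraded": sim.degraded_count,
            "mrna": sim.mrna_counts["tiny"],
            "free": sim.free_pool}
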