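"""Continuous-time, discrete-event kernel for RNAPII transcription.

The system state is a small ensemble of genes, each carrying an ordered list
of engaged polymerases and a list of unrepaired lesions, plus a shared free
pool.  Between events every moving polymerase translocates at the common
elongation speed; events (initiation, arrival at an obstacle or the gene
end, lesion repair, stochastic removal, pause expiry) apply abrupt updates
and schedule fresh future events.  Stale events are invalidated by a
per-polymerase revision counter and discarded when popped.

Because all moving polymerases share one speed, a mover can only be caught
by an obstacle that is *stationary*: a lesion, a stalled neighbour's
footprint boundary, the optional pause site, or the gene end.  A polymerase
queued behind a stalled neighbour resumes the instant its blocker resumes
or is removed (wake cascade), re-stalling immediately if an obstacle
remains - the piecewise-linear trajectories this produces are exactly those
of the obstacle-chasing formulation.

Removal clocks are exponential and memoryless: they are redrawn at every
status change with the hazard of the new status, which is equivalent to a
hazard that switches instantaneously with status.
"""

from __future__ import annotations

import heapq
from bisect import bisect_right, insort
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ConvergenceError, StateError
from .params import GeneSpec, SimParams, validate_params

EPS = 1e-6  # nt; tolerance for position comparisons

# Polymerase status
FREE, MOVING, STALLED, DEGRADED = "free", "moving", "stalled", "degraded"

# Event kinds, with the fixed tie-break priority at equal times:
# repair < pause-end < completion < stall < removal < initiation < snapshot.
K_REPAIR, K_PAUSE_END, K_ARRIVAL, K_REMOVAL, K_INIT = "repair", "pause_end", "arrival", "removal", "initiation"
_PRIORITY = {K_REPAIR: 0, K_PAUSE_END: 1, K_REMOVAL: 4, K_INIT: 5}
_ARRIVAL_PRIORITY = {"end": 2, "lesion": 3, "queue": 3, "pause": 3}


def removal_waiting_time(rng: np.random.Generator, hazard: float) -> float:
    """Exponential waiting time to removal; +inf when the hazard is zero."""
    if hazard <= 0.0:
        return float("inf")
    return float(rng.exponential(1.0 / hazard))


@dataclass(slots=True)
class Polymerase:
    """An engaged or free polymerase.  ``pos0``/``t0`` anchor the lazy
    position: position(t) = pos0 + speed * (t - t0) while moving."""

    pol_id: int
    status: str = FREE
    gene: int = -1
    pos0: float = 0.0
    t0: float = 0.0
    speed: float = 0.0
    idx: int = -1  # index in the gene's occupant list
    stall_reason: str | None = None  # "lesion" | "queue" | "pause"
    cause_id: int = -1  # lesion id or blocker polymerase id
    pending_cause: tuple = ()  # cause of the currently scheduled arrival
    pending_target: float = 0.0  # target position of that arrival
    rev: int = 0
    paused_done: bool = False

    def position(self, clock: float) -> float:
        if self.status == MOVING:
            return self.pos0 + self.speed * (clock - self.t0)
        return self.pos0


@dataclass(slots=True)
class Lesion:
    """A transcription-blocking lesion with a repair time fixed at creation."""

    lesion_id: int
    gene: int
    position: float
    repair_time: float
    blocker: int = -1  # pol_id stalled exactly at the lesion, if any


@dataclass
class _GeneRuntime:
    spec: GeneSpec
    occupants: list = field(default_factory=list)  # pol_ids by ascending position
    lesion_pos: list = field(default_factory=list)  # sorted positions
    lesion_ids: list = field(default_factory=list)  # parallel to lesion_pos


@dataclass
class Snapshot:
    """State record at one instant (time relative to damage onset)."""

    time: float
    free_pool: int
    degraded_count: int
    mrna_counts: dict  # gene_id -> completed transcripts since damage onset
    genes: dict  # gene_id -> dict(positions, statuses, reasons, cause_ids, pol_ids)
    lesions: dict  # gene_id -> list of (lesion_id, position)

    @property
    def engaged(self) -> int:
        return sum(len(g["positions"]) for g in self.genes.values())


@dataclass
class Trajectory:
    """Output of one simulation run."""

    params: SimParams
    seed: int
    damage_time: float  # absolute clock time of damage onset
    snapshots: list  # of Snapshot, times relative to damage onset
    init_assigned: dict  # gene_id -> initiation events assigned (incl. gated drops)
    init_placed: dict  # gene_id -> successful initiations
    completions: dict  # gene_id -> lifetime completed transcripts
    n_events: int = 0  # handled events over the whole run
    event_log: list | None = None

    def snapshot_at(self, t_rel: float) -> Snapshot:
        for s in self.snapshots:
            if abs(s.time - t_rel) < 1e-9:
                return s
        raise KeyError(f"no snapshot at t={t_rel}")


class Simulation:
    """One realization of the stochastic kernel.

    Usual lifecycle: ``burn_in()`` (reach pre-damage steady state),
    ``apply_damage()`` (Poisson lesion placement, defines relative time 0),
    then ``advance_until`` / ``snapshot`` as needed; :func:`run` wraps this.
    """

    def __init__(self, params: SimParams, seed: int, record_events: bool = False,
                 validate: bool = False):
        self.p = validate_params(params)
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.clock = 0.0
        self.genes = [_GeneRuntime(spec=g) for g in self.p.genes]
        self._weights = np.array([g.initiation_weight for g in self.p.genes])
        self._cum_weights = np.cumsum(self._weights)
        self.pols: dict[int, Polymerase] = {}
        self.lesions: dict[int, Lesion] = {}
        self.free_pool = int(self.p.pool_size)
        self.degraded_count = 0
        self.mrna_counts = {g.gene_id: 0 for g in self.p.genes}
        self._mrna_at_damage: dict | None = None
        self.damage_time: float | None = None
        self.init_assigned = {g.gene_id: 0 for g in self.p.genes}
        self.init_placed = {g.gene_id: 0 for g in self.p.genes}
        self.init_dropped = 0
        self._heap: list = []
        self._seq = 0
        self.n_events = 0
        self._next_pol_id = 0
        self._next_lesion_id = 0
        self._init_rev = 0
        self._validate = validate
        self.event_log: list | None = [] if record_events else None
        self._schedule_init()

    # ------------------------------------------------------------ helpers

    def _log(self, kind, **info):
        if self.event_log is not None:
            self.event_log.append({"time": self.clock, "kind": kind, **info})

    def _push(self, time, kind, a=0, b=0):
        self._seq += 1
        prio = _PRIORITY[kind] if kind != K_ARRIVAL else _ARRIVAL_PRIORITY[self.pols[a].pending_cause[0]]
        heapq.heappush(self._heap, (time, prio, self._seq, kind, a, b))

    def _pos(self, pol: Polymerase) -> float:
        return pol.position(self.clock)

    def engaged_count(self) -> int:
        return sum(len(g.occupants) for g in self.genes)

    @property
    def initiation_rate(self) -> float:
        return self.p.initiation_rate_per_free_pol * self.free_pool

    # ------------------------------------------------- event scheduling

    def _schedule_init(self):
        """(Re)schedule the single pending initiation event.  Called after
        every free-pool change; memorylessness makes the redraw exact for a
        piecewise-constant mass-action rate."""
        self._init_rev += 1
        rate = self.initiation_rate
        if rate > 0.0:
            t = self.clock + self.rng.exponential(1.0 / rate)
            self._push(t, K_INIT, self._init_rev)

    def next_arrival(self, pol: Polymerase):
        """Earliest deterministic obstacle for a moving polymerase: pause
        site, nearest unrepaired lesion strictly ahead, a stalled downstream
        neighbour's footprint boundary, or the gene end (completion).

        Returns (time, target_position, cause) where cause is one of
        ("end", -1), ("lesion", lesion_id), ("queue", blocker_pol_id),
        ("pause", -1).  Ties prefer the queue boundary (exclusion binds
        before a co-located lesion)."""
        g = self.genes[pol.gene]
        x = self._pos(pol)
        target, cause = float(g.spec.length), ("end", -1)
        if (self.p.pause_site_offset is not None and not pol.paused_done
                and x < self.p.pause_site_offset - EPS
                and self.p.pause_site_offset < target):
            target, cause = self.p.pause_site_offset, ("pause", -1)
        i = bisect_right(g.lesion_pos, x + EPS)
        if i < len(g.lesion_pos) and g.lesion_pos[i] < target:
            target, cause = g.lesion_pos[i], ("lesion", g.lesion_ids[i])
        j = pol.idx + 1
        if j < len(g.occupants):
            nb = self.pols[g.occupants[j]]
            if nb.status == STALLED:
                tn = nb.pos0 - self.p.footprint
                if tn <= target + EPS:
                    target, cause = tn, ("queue", nb.pol_id)
        dt = max(0.0, target - x) / pol.speed
        return self.clock + dt, target, cause

    # Alias: the next stall/completion event for a moving polymerase.
    schedule_next_stall = next_arrival

    def _schedule_arrival(self, pol: Polymerase):
        t, target, cause = self.next_arrival(pol)
        pol.pending_cause = cause
        pol.pending_target = target
        self._push(t, K_ARRIVAL, pol.pol_id, pol.rev)

    def sample_removal_times(self, pol: Polymerase) -> float:
        """Draw (and schedule) a fresh removal time for ``pol`` with the
        hazard of its current status; returns the absolute event time
        (+inf, unscheduled, when the hazard is zero)."""
        if pol.status == MOVING or pol.stall_reason == "pause":
            hazard = self.p.moving_removal_hazard
        else:
            hazard = self.p.effective_stalled_hazard
        t = self.clock + removal_waiting_time(self.rng, hazard)
        if np.isfinite(t):
            self._push(t, K_REMOVAL, pol.pol_id, pol.rev)
        return t

    _schedule_removal = sample_removal_times

    def _refresh(self, pol: Polymerase):
        """Invalidate all events referencing ``pol`` and schedule fresh ones."""
        pol.rev += 1
        if pol.status == MOVING:
            self._schedule_arrival(pol)
        self._schedule_removal(pol)

    # -------------------------------------------------- state mutation

    def _insert_occupant(self, g: _GeneRuntime, pol: Polymerase, index: int):
        g.occupants.insert(index, pol.pol_id)
        pol.idx = index
        for pid in g.occupants[index + 1:]:
            self.pols[pid].idx += 1

    def _remove_occupant(self, g: _GeneRuntime, pol: Polymerase):
        del g.occupants[pol.idx]
        for pid in g.occupants[pol.idx:]:
            self.pols[pid].idx -= 1
        pol.idx = -1

    def _resume(self, pol: Polymerase):
        pol.status = MOVING
        pol.speed = self.p.elongation_speed
        pol.pos0 = pol.pos0  # position unchanged
        pol.t0 = self.clock
        pol.stall_reason = None
        pol.cause_id = -1
        self._refresh(pol)

    def _wake_chain(self, pol: Polymerase):
        """Resume the contiguous queue stalled behind ``pol`` (which has just
        resumed or been removed), then refresh any mover behind the chain
        whose pending arrival referenced a resumed polymerase."""
        g = self.genes[pol.gene] if pol.gene >= 0 else None
        if g is None:
            return
        i = pol.idx - 1 if pol.idx >= 0 else None
        prev_id = pol.pol_id
        while i is not None and i >= 0:
            q = self.pols[g.occupants[i]]
            if q.status == STALLED and q.stall_reason == "queue" and q.cause_id == prev_id:
                self._resume(q)
                prev_id = q.pol_id
                i -= 1
            else:
                if q.status == MOVING and q.pending_cause and q.pending_cause[1] == prev_id:
                    self._refresh(q)
                break

    def _notify_upstream(self, g: _GeneRuntime, index: int):
        """After the occupant at ``index`` stalls, the mover just behind it
        must re-target to the new footprint boundary."""
        if index > 0:
            q = self.pols[g.occupants[index - 1]]
            if q.status == MOVING:
                self._refresh(q)

    def resolve_removal_fate(self, pol: Polymerase) -> str:
        """Removed polymerases recycle to the free pool with probability
        ``removal_recycle_prob`` (1 in the K1268R regime) or are degraded."""
        if self.rng.random() < self.p.effective_recycle_prob:
            pol.status = FREE
            self.free_pool += 1
            self._schedule_init()
            return "recycled"
        pol.status = DEGRADED
        self.degraded_count += 1
        return "degraded"

    def force_remove(self, pol_id: int) -> str:
        """Remove an engaged polymerase immediately (as a removal event
        would).  Exposed for tests and queue microsurgery."""
        return self._do_removal(self.pols[pol_id])

    def _do_removal(self, pol: Polymerase) -> str:
        g = self.genes[pol.gene]
        pol.pos0 = self._pos(pol)
        if pol.stall_reason == "lesion" and pol.cause_id in self.lesions:
            self.lesions[pol.cause_id].blocker = -1
        upstream = self.pols[g.occupants[pol.idx - 1]] if pol.idx > 0 else None
        self._remove_occupant(g, pol)
        pol.rev += 1  # invalidate any events still referencing this pol
        fate = self.resolve_removal_fate(pol)
        pol.gene = -1
        if upstream is not None:
            if upstream.status == MOVING:
                self._refresh(upstream)
            elif (upstream.status == STALLED and upstream.stall_reason == "queue"
                  and upstream.cause_id == pol.pol_id):
                self._resume(upstream)
                self._wake_chain(upstream)
        self._log("removal", pol_id=pol.pol_id, gene=g.spec.gene_id,
                  position=pol.pos0, fate=fate)
        return fate

    # ------------------------------------------------------ damage

    def inject_lesion(self, gene_index: int, position: float, repair_time: float) -> Lesion:
        """Place a single lesion deterministically (testing/low-level API).
        ``repair_time`` is absolute clock time."""
        g = self.genes[gene_index]
        if not (0.0 < position < g.spec.length):
            raise ConfigError("lesion position must lie strictly inside the gene")
        if repair_time < self.clock:
            raise ConfigError("repair_time precedes the current clock")
        lid = self._next_lesion_id
        self._next_lesion_id += 1
        les = Lesion(lid, gene_index, float(position), float(repair_time))
        self.lesions[lid] = les
        k = bisect_right(g.lesion_pos, les.position)
        g.lesion_pos.insert(k, les.position)
        g.lesion_ids.insert(k, lid)
        self._push(repair_time, K_REPAIR, lid)
        # Movers on this gene must consider the new obstacle (redrawing the
        # removal clock alongside is exact by memorylessness).
        for pid in list(g.occupants):
            pol = self.pols[pid]
            if pol.status == MOVING:
                self._refresh(pol)
        return les

    def place_polymerase(self, gene_index: int, position: float) -> Polymerase:
        """Place a moving polymerase at an arbitrary position (testing/
        low-level API); it acquires arrival and removal events immediately."""
        g = self.genes[gene_index]
        if not (0.0 <= position <= g.spec.length):
            raise ConfigError("position outside the gene")
        if self.free_pool <= 0:
            raise StateError("no free polymerase to place")
        pol = Polymerase(self._next_pol_id, status=MOVING, gene=gene_index,
                         pos0=float(position), t0=self.clock,
                         speed=self.p.elongation_speed)
        self._next_pol_id += 1
        self.pols[pol.pol_id] = pol
        index = bisect_right([self.pols[pid].position(self.clock) for pid in g.occupants],
                             position)
        self._insert_occupant(g, pol, index)
        self.free_pool -= 1
        self._schedule_arrival(pol)
        self._schedule_removal(pol)
        return pol

    def apply_damage(self):
        """Introduce UV damage: per gene, Poisson(length * lesion_density)
        lesions at uniform positions, each with an exponential lifetime of
        mean lesion_halflife / ln 2.  Defines relative time 0.  Moving
        polymerases are retargeted against the new obstacle set."""
        if self.damage_time is not None:
            raise StateError("damage already applied to this run")
        self.damage_time = self.clock
        self._mrna_at_damage = dict(self.mrna_counts)
        mean_life = self.p.lesion_halflife / np.log(2.0)
        for gi, g in enumerate(self.genes):
            n = self.rng.poisson(g.spec.length * self.p.lesion_density)
            for _ in range(int(n)):
                pos = 0.0
                while pos <= 0.0:
                    pos = self.rng.uniform(0.0, g.spec.length)
                life = self.rng.exponential(mean_life) if mean_life > 0 else 0.0
                self.inject_lesion(gi, pos, self.clock + life)
        self._log("damage_onset", n_lesions=len(self.lesions))

    # ------------------------------------------------------ event loop

    def advance_positions(self, dt: float):
        """Materialize all positions ``dt`` seconds ahead and advance the
        clock.  ``dt`` must not carry any polymerase past its next scheduled
        arrival."""
        if dt < 0:
            raise StateError("dt must be non-negative")
        if self._heap and self.clock + dt > self._heap[0][0] + 1e-9:
            raise StateError("dt would step over the next pending event")
        self.clock += dt
        for g in self.genes:
            for pid in g.occupants:
                pol = self.pols[pid]
                if pol.status == MOVING:
                    pol.pos0 += pol.speed * (self.clock - pol.t0)
                    pol.t0 = self.clock

    def step(self, t_max: float | None = None) -> str | None:
        """Pop and handle the next valid event; returns its kind, or None
        when the queue holds no valid event (at or before ``t_max``, when
        given - the event is then left pending)."""
        while self._heap:
            item = heapq.heappop(self._heap)
            time, _prio, _seq, kind, a, b = item
            if kind == K_INIT:
                if a != self._init_rev:
                    continue
            elif kind in (K_ARRIVAL, K_REMOVAL, K_PAUSE_END):
                pol = self.pols.get(a)
                if pol is None or pol.rev != b:
                    continue  # superseded by invalidation
            elif kind == K_REPAIR:
                if a not in self.lesions:
                    continue
            if t_max is not None and time > t_max:
                heapq.heappush(self._heap, item)
                return None
            self.clock = max(self.clock, time)
            self._handle(kind, a, b)
            self.n_events += 1
            if self._validate:
                self.check_invariants()
            return kind
        return None

    def handle_event(self, kind: str, a: int, b: int = 0):
        """Apply one event to the state (the earliest pending one is what
        :meth:`step` passes here)."""
        self._handle(kind, a, b)

    def _handle(self, kind, a, b):
        if kind == K_INIT:
            self._handle_init()
        elif kind == K_ARRIVAL:
            self._handle_arrival(self.pols[a])
        elif kind == K_REMOVAL:
            self._do_removal(self.pols[a])
        elif kind == K_REPAIR:
            self._handle_repair(self.lesions[a])
        elif kind == K_PAUSE_END:
            pol = self.pols[a]
            self._resume(pol)
            self._wake_chain(pol)
            self._log("pause_end", pol_id=pol.pol_id)
        else:  # pragma: no cover
            raise StateError(f"unknown event kind {kind!r}")

    def _handle_init(self):
        gi = int(np.searchsorted(self._cum_weights, self.rng.random(), side="right"))
        gi = min(gi, len(self.genes) - 1)
        g = self.genes[gi]
        self.init_assigned[g.spec.gene_id] += 1
        blocked = (g.occupants and
                   self.pols[g.occupants[0]].position(self.clock) < self.p.footprint)
        if blocked or self.free_pool <= 0:
            self.init_dropped += 1
        else:
            pol = Polymerase(self._next_pol_id, status=MOVING, gene=gi,
                             pos0=0.0, t0=self.clock, speed=self.p.elongation_speed)
            self._next_pol_id += 1
            self.pols[pol.pol_id] = pol
            self._insert_occupant(g, pol, 0)
            self.free_pool -= 1
            self.init_placed[g.spec.gene_id] += 1
            self._schedule_arrival(pol)
            self._schedule_removal(pol)
            self._log("initiation", pol_id=pol.pol_id, gene=g.spec.gene_id)
        self._schedule_init()

    def _handle_arrival(self, pol: Polymerase):
        g = self.genes[pol.gene]
        target = pol.pending_target
        cause = pol.pending_cause
        pol.pos0 = target
        pol.t0 = self.clock
        if cause[0] == "end":
            self._complete(pol)
            return
        pol.status = STALLED
        pol.speed = 0.0
        pol.stall_reason = cause[0]
        pol.cause_id = cause[1]
        if cause[0] == "lesion":
            self.lesions[cause[1]].blocker = pol.pol_id
        if cause[0] == "pause":
            pol.paused_done = True
        self._refresh(pol)
        if cause[0] == "pause":
            dwell = self.rng.exponential(self.p.pause_mean_dwell)
            self._push(self.clock + dwell, K_PAUSE_END, pol.pol_id, pol.rev)
        self._notify_upstream(g, pol.idx)
        self._log("stall", pol_id=pol.pol_id, gene=g.spec.gene_id,
                  position=pol.pos0, reason=cause[0])

    def _complete(self, pol: Polymerase):
        g = self.genes[pol.gene]
        self._remove_occupant(g, pol)
        pol.rev += 1
        pol.gene = -1
        self.mrna_counts[g.spec.gene_id] += 1
        if self.rng.random() < self.p.completion_recycle_prob:
            pol.status = FREE
            self.free_pool += 1
            self._schedule_init()
        else:
            pol.status = DEGRADED
            self.degraded_count += 1
        self._log("completion", pol_id=pol.pol_id, gene=g.spec.gene_id)

    def _handle_repair(self, les: Lesion):
        g = self.genes[les.gene]
        k = g.lesion_ids.index(les.lesion_id)
        del g.lesion_pos[k]
        del g.lesion_ids[k]
        del self.lesions[les.lesion_id]
        if les.blocker >= 0:
            blk = self.pols[les.blocker]
            self._resume(blk)
            self._wake_chain(blk)
        # Any mover that was heading for this lesion must re-target.
        for pid in list(g.occupants):
            pol = self.pols[pid]
            if (pol.status == MOVING and pol.pending_cause
                    and pol.pending_cause == ("lesion", les.lesion_id)):
                self._refresh(pol)
        self._log("repair", lesion_id=les.lesion_id, gene=g.spec.gene_id,
                  position=les.position)

    # ------------------------------------------------------ driving

    def advance_until(self, t_end: float):
        """Handle every event with time <= t_end, then set the clock to
        t_end (positions stay lazily consistent)."""
        while self.step(t_max=t_end) is not None:
            pass
        self.clock = max(self.clock, t_end)

    def burn_in(self):
        """Advance without damage for the burn-in period, then in windows of
        one longest-gene transit time until initiation and completion counts
        over a window agree within 5%.  Hard cap: 20x transit time."""
        if self.damage_time is not None:
            raise StateError("burn_in must precede damage")
        self.advance_until(self.p.effective_burn_in)
        if self.initiation_rate <= 0.0 and self.engaged_count() == 0:
            return
        window = max(self.p.max_transit_time, 1.0)
        cap = 20.0 * max(self.p.max_transit_time, self.p.effective_burn_in, 1.0)
        while True:
            i0 = sum(self.init_placed.values())
            c0 = sum(self.completions_total().values())
            self.advance_until(self.clock + window)
            di = sum(self.init_placed.values()) - i0
            dc = sum(self.completions_total().values()) - c0
            if abs(di - dc) <= 0.05 * max(di, dc, 1):
                return
            if self.clock > cap:
                raise ConvergenceError(
                    f"burn-in flux balance not reached by t={self.clock:.0f}s "
                    f"(initiations {di} vs completions {dc} per window)")

    def completions_total(self) -> dict:
        return dict(self.mrna_counts)

    # ------------------------------------------------------ observation

    def snapshot(self, time_rel: float | None = None) -> Snapshot:
        t_rel = (self.clock - self.damage_time) if self.damage_time is not None else self.clock
        if time_rel is not None:
            t_rel = time_rel
        base = self._mrna_at_damage or {g.gene_id: 0 for g in self.p.genes}
        genes = {}
        lesions = {}
        for g in self.genes:
            pols = [self.pols[pid] for pid in g.occupants]
            genes[g.spec.gene_id] = {
                "pol_ids": np.array([p.pol_id for p in pols], dtype=int),
                "positions": np.array([self._pos(p) for p in pols]),
                "statuses": [p.status for p in pols],
                "reasons": [p.stall_reason for p in pols],
                "cause_ids": np.array([p.cause_id for p in pols], dtype=int),
            }
            lesions[g.spec.gene_id] = [
                (lid, pos) for pos, lid in zip(g.lesion_pos, g.lesion_ids)
            ]
        return Snapshot(
            time=t_rel,
            free_pool=self.free_pool,
            degraded_count=self.degraded_count,
            mrna_counts={k: self.mrna_counts[k] - base.get(k, 0) for k in self.mrna_counts},
            genes=genes,
            lesions=lesions,
        )

    def check_invariants(self):
        """Conservation, exclusion, ordering, and stall-consistency checks."""
        engaged = self.engaged_count()
        total = self.free_pool + engaged + self.degraded_count
        if total != self.p.pool_size:
            raise StateError(
                f"conservation violated: free {self.free_pool} + engaged {engaged}"
                f" + degraded {self.degraded_count} != pool {self.p.pool_size}")
        for g in self.genes:
            prev = None
            for pid in g.occupants:
                pol = self.pols[pid]
                x = self._pos(pol)
                if not (-EPS <= x <= g.spec.length + EPS):
                    raise StateError(f"polymerase {pid} outside gene at {x}")
                if prev is not None and x - prev < self.p.footprint - 1e-6:
                    raise StateError(
                        f"exclusion violated on {g.spec.gene_id}: gap {x - prev:.3f}")
                prev = x
                if pol.status == STALLED and pol.stall_reason == "lesion":
                    if pol.cause_id not in self.lesions:
                        raise StateError(f"polymerase {pid} stalled at repaired lesion")


# --------------------------------------------------------------- top level


def init_state(params: SimParams, seed: int, **kw) -> Simulation:
    """Fresh simulation: clock 0, all polymerases free, no lesions, the
    first initiation event scheduled, rng seeded from ``seed``."""
    return Simulation(params, seed, **kw)


def run(params: SimParams, seed: int, record_events: bool = False,
        validate: bool = False) -> Trajectory:
    """Full protocol: init -> burn-in -> damage onset -> snapshots at the
    requested times (relative to onset).  Deterministic in (params, seed)."""
    sim = Simulation(params, seed, record_events=record_events, validate=validate)
    sim.burn_in()
    sim.apply_damage()
    snaps = [sim.snapshot(0.0)]
    for t_rel in params.snapshot_times:
        if t_rel == 0.0:
            continue
        sim.advance_until(sim.damage_time + t_rel)
        snaps.append(sim.snapshot(t_rel))
    sim.check_invariants()
    return Trajectory(
        params=params,
        seed=seed,
        damage_time=sim.damage_time,
        snapshots=snaps,
        init_assigned=dict(sim.init_assigned),
        init_placed=dict(sim.init_placed),
        completions=sim.completions_total(),
        n_events=sim.n_events,
        event_log=sim.event_log,
    )
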