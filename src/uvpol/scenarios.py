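"""Preset experiments, replicate orchestration, and hazard calibration.

Regimes map the two biological toggles onto the kernel's fate parameters:

* ``WT``             - degradation on (recycle < 1), dissociation on.
* ``K1268R``         - non-degradable polymerase: every removed polymerase
                       recycles to the free pool (dissociation still on).
* ``no_dissociation``- halted polymerases are never removed: the pile-up
                       thought experiment.
* ``undamaged``      - lesion density zero; everything else as WT.

A scenario's density map is the mean binned occupancy over ``n_replicates``
independent runs (default 100) with per-replicate seeds ``seed + i``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("uvpol.scenarios")

from . import engine
from .errors import CalibrationError, ConfigError, UvpolError
from .params import SimParams, default_params, validate_params
from .summaries import DensityMap, density_profile, fit_half_life, surviving_pool_series

REGIMES = ("WT", "K1268R", "no_dissociation", "undamaged")


@dataclass
class Scenario:
    """A named, fully parameterized in silico experiment."""

    name: str
    params: SimParams
    regime: str = "WT"
    n_replicates: int = 100

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}", field="regime")
        apply_regime(self.params, self.regime)
        validate_params(self.params)


def apply_regime(params: SimParams, regime: str) -> SimParams:
    """Set the toggle fields for a regime; the toggles are the only fields a
    regime touches."""
    if regime == "WT":
        params.degradation_enabled = True
        params.dissociation_enabled = True
    elif regime == "K1268R":
        params.degradation_enabled = False
        params.dissociation_enabled = True
    elif regime == "no_dissociation":
        params.degradation_enabled = False
        params.dissociation_enabled = False
    elif regime == "undamaged":
        params.degradation_enabled = True
        params.dissociation_enabled = True
        params.lesion_density = 0.0
    else:
        raise ConfigError(f"unknown regime {regime!r}", field="regime")
    return params


_PRESETS = {
    "single-gene-wt": ("single_100kb", "WT"),
    "single-gene-k1268r": ("single_100kb", "K1268R"),
    "single-gene-pileup": ("single_100kb", "no_dissociation"),
    "single-gene-undamaged": ("single_100kb", "undamaged"),
    "three-gene-wt": ("three_gene", "WT"),
    "three-gene-k1268r": ("three_gene", "K1268R"),
    "three-gene-undamaged": ("three_gene", "undamaged"),
}


def scenario_names() -> list:
    return sorted(_PRESETS)


def make_scenario(name: str, n_replicates: int | None = None, **overrides) -> Scenario:
    """Build a preset scenario; ``overrides`` are SimParams fields."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown scenario preset {name!r} "
                          f"(known: {', '.join(scenario_names())})", field="preset")
    ensemble, regime = _PRESETS[name]
    params = default_params(ensemble, **overrides)
    return Scenario(name=name, params=params, regime=regime,
                    n_replicates=n_replicates if n_replicates is not None
                    else params.n_replicates)


@dataclass
class ReplicateEnsemble:
    """Replicate-averaged density plus per-replicate scalar series."""

    scenario: Scenario
    seed: int
    density: DensityMap
    pool: pd.DataFrame  # replicate, time, free_pool, degraded_count, engaged
    mrna: pd.DataFrame  # replicate, time, gene_id, count
    trajectories: list = field(default_factory=list)  # kept only on request


def run_replicates(scenario: Scenario, seed: int | None = None,
                   keep_trajectories: bool = False) -> ReplicateEnsemble:
    """Run ``n_replicates`` independent realizations (seeds seed+i) and
    average binned occupancy per gene per snapshot time."""
    base_seed = scenario.params.seed if seed is None else int(seed)
    p = scenario.params
    gene_lengths = {g.gene_id: g.length for g in p.genes}
    all_snaps = []
    pool_rows = []
    mrna_rows = []
    trajectories = []
    for i in range(scenario.n_replicates):
        try:
            traj = engine.run(p, base_seed + i)
        except UvpolError as exc:
            log.error("replicate %d (seed %d) failed: %s", i, base_seed + i, exc)
            raise UvpolError(f"replicate {i} (seed {base_seed + i}) failed: {exc}") from exc
        final = traj.snapshots[-1]
        log.info("replicate %d: seed %d, %d events, conservation ok "
                 "(free %d + engaged %d + degraded %d = %d)",
                 i, base_seed + i, traj.n_events,
                 final.free_pool, final.engaged, final.degraded_count,
                 p.pool_size)
        all_snaps.extend(traj.snapshots)
        for s in traj.snapshots:
            pool_rows.append((i, s.time, s.free_pool, s.degraded_count, s.engaged))
            for gid, n in s.mrna_counts.items():
                mrna_rows.append((i, s.time, gid, n))
        if keep_trajectories:
            trajectories.append(traj)
    dmap = density_profile(all_snaps, gene_lengths, p.bin_size,
                           n_replicates=scenario.n_replicates)
    pool = pd.DataFrame(pool_rows, columns=["replicate", "time", "free_pool",
                                            "degraded_count", "engaged"])
    mrna = pd.DataFrame(mrna_rows, columns=["replicate", "time", "gene_id", "count"])
    return ReplicateEnsemble(scenario=scenario, seed=base_seed, density=dmap,
                             pool=pool, mrna=mrna, trajectories=trajectories)


def predicted_mrna_counts(scenario: Scenario, horizon: float,
                          seed: int | None = None) -> pd.DataFrame:
    """Completed transcripts per gene within [damage onset, horizon], as
    mean +/- sd over replicates."""
    if horizon > max(scenario.params.snapshot_times):
        raise ConfigError("horizon exceeds the largest snapshot time", field="horizon")
    if horizon not in scenario.params.snapshot_times and horizon != 0.0:
        params = dataclasses.replace(
            scenario.params,
            snapshot_times=sorted(set(scenario.params.snapshot_times) | {horizon}))
        scenario = dataclasses.replace(scenario, params=params)
    ens = run_replicates(scenario, seed=seed)
    at_h = ens.mrna[np.isclose(ens.mrna["time"], horizon)]
    out = (at_h.groupby("gene_id")["count"]
           .agg(["mean", "std", "count"])
           .rename(columns={"count": "n_replicates"})
           .reset_index())
    return out


def initiation_fractions(scenario: Scenario, min_events: int = 10_000,
                         seed: int | None = None) -> pd.DataFrame:
    """Long-run fraction of initiation events assigned to each gene.

    Counts the weight-multinomial gene assignments (including the rare
    attempts dropped because the TSS footprint was occupied), which is what
    the class weights describe; successful placements are reported too.
    """
    base_seed = scenario.params.seed if seed is None else int(seed)
    sim = engine.Simulation(scenario.params, base_seed)
    chunk = max(scenario.params.max_transit_time, 1000.0)
    hard_cap = 10_000 * chunk
    while sum(sim.init_assigned.values()) < min_events:
        sim.advance_until(sim.clock + chunk)
        if sim.clock > hard_cap:
            raise UvpolError("initiation too rare to collect the requested events")
    total_a = sum(sim.init_assigned.values())
    total_p = max(sum(sim.init_placed.values()), 1)
    rows = [(g.gene_id, g.class_label, g.initiation_weight,
             sim.init_assigned[g.gene_id], sim.init_assigned[g.gene_id] / total_a,
             sim.init_placed[g.gene_id], sim.init_placed[g.gene_id] / total_p)
            for g in scenario.params.genes]
    return pd.DataFrame(rows, columns=["gene_id", "class_label", "weight",
                                       "assigned", "assigned_fraction",
                                       "placed", "placed_fraction"])


@dataclass
class CalibrationResult:
    """Outcome of the degradation-hazard bisection."""

    stalled_removal_hazard: float
    achieved_half_life: float  # seconds, from the final high-replicate fit
    target_half_life: float
    iterations: list  # (hazard, fitted half-life, replicates used)
    n_replicates_final: int
    verification: "ReplicateEnsemble | None" = None


def _calib_params(params: SimParams, hazard: float, horizon: float,
                  step: float) -> SimParams:
    return dataclasses.replace(
        params,
        stalled_removal_hazard=hazard,
        snapshot_times=list(np.arange(step, horizon + step / 2, step)))


def _fitted_half_life(params: SimParams, hazard: float, n_reps: int, seed: int,
                      horizon: float, step: float,
                      keep_trajectories: bool = False):
    p = _calib_params(params, hazard, horizon, step)
    scen = Scenario(name="calib", params=p, regime="WT", n_replicates=n_reps)
    ens = run_replicates(scen, seed=seed, keep_trajectories=keep_trajectories)
    series = surviving_pool_series(ens.pool, p.pool_size)
    series = series[series["surviving"] > 0]
    hl = fit_half_life(series["time"], series["surviving"]).half_life
    return (hl, ens) if keep_trajectories else hl


def calibrate_degradation(scenario: Scenario, target_halflife: float,
                          tol: float = 0.1, bracket=(1e-5, 1e-2),
                          n_reps_iter: int = 20, n_reps_final: int = 100,
                          max_iter: int = 10, seed: int | None = None,
                          horizon: float = 4 * 3600.0,
                          sample_step: float = 900.0,
                          keep_verification: bool = False) -> CalibrationResult:
    """Bisection over the stalled-removal hazard so the exponential
    half-life fitted to the mean surviving polymerase count over
    [0, horizon] post-damage matches ``target_halflife`` within ``tol``
    (relative).

    The fitted half-life decreases monotonically in the hazard, so
    log-space bisection applies, but each evaluation is a Monte-Carlo
    estimate: iterates use ``n_reps_iter`` replicates while the bracket is
    wide and three times as many once it has narrowed, and the final
    hazard is polished by a local log-log regression over all iterates
    near the target (the response is smooth and shallow there, so the
    regression centres the answer better than the last noisy midpoint).
    The returned half-life comes from a fresh ``n_reps_final``-replicate
    verification.
    """
    if scenario.regime != "WT":
        raise ConfigError("calibration requires the WT regime", field="regime")
    if target_halflife <= 0:
        raise ConfigError("target half-life must be positive", field="target_halflife")
    if tol <= 0:
        raise ConfigError("tolerance must be positive", field="tol")
    base_seed = scenario.params.seed if seed is None else int(seed)
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ConfigError("bracket must satisfy 0 < lo < hi", field="bracket")
    iters = []

    def measure(h, s, n):
        hl = _fitted_half_life(scenario.params, h, n, s, horizon, sample_step)
        iters.append((h, hl, n))
        return hl

    hl_lo = measure(lo, base_seed, n_reps_iter)
    hl_hi = measure(hi, base_seed + 1000, n_reps_iter)
    if not (hl_hi <= target_halflife <= hl_lo):
        raise CalibrationError(
            f"target {target_halflife:.0f}s outside achievable range "
            f"[{hl_hi:.0f}s at hazard {hi:g}, {hl_lo:.0f}s at hazard {lo:g}]",
            bracket=(lo, hi, hl_lo, hl_hi))
    llo, lhi = np.log(lo), np.log(hi)
    for k in range(max_iter):
        mid = 0.5 * (llo + lhi)
        n = n_reps_iter if (lhi - llo) > np.log(4.0) else 3 * n_reps_iter
        hl = measure(float(np.exp(mid)), base_seed + 2000 + 97 * k, n)
        if hl > target_halflife:
            llo = mid  # decay too slow -> raise hazard
        else:
            lhi = mid
    # regression polish: weighted log-log fit over iterates near the target
    log_t = np.log(target_halflife)
    pts = [(np.log(h), np.log(hl), n) for h, hl, n in iters
           if np.isfinite(hl) and abs(np.log(hl) - log_t) < np.log(2.0)]
    hazard = float(np.exp(0.5 * (llo + lhi)))
    slope = -0.25  # typical local sensitivity d(log hl)/d(log hazard)
    if len(pts) >= 3:
        x, y, w = (np.array(v, dtype=float) for v in zip(*pts))
        fit_slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        if fit_slope < -1e-3:
            slope = float(np.clip(fit_slope, -1.0, -0.05))
            hazard = float(np.clip(np.exp((log_t - intercept) / fit_slope), lo, hi))
    # Secant polish at full replication: the low-replicate iterates are
    # heavy-tailed, so the final centring is done against the
    # n_reps_final-replicate estimate itself (SD a few percent), updating
    # the local log-log slope from successive high-precision measurements.
    achieved, ens = _fitted_half_life(scenario.params, hazard, n_reps_final,
                                      base_seed + 9000, horizon, sample_step,
                                      keep_trajectories=True)
    iters.append((hazard, achieved, n_reps_final))
    history = [(np.log(hazard), np.log(achieved))]
    for extra in range(5):
        if abs(achieved - target_halflife) <= 0.5 * tol * target_halflife:
            break
        slope_loc = slope
        if len(history) >= 2:
            (x1, y1), (x2, y2) = history[-2], history[-1]
            if abs(x2 - x1) > 1e-6:
                slope_loc = (y2 - y1) / (x2 - x1)
        slope_loc = float(np.clip(slope_loc, -0.8, -0.15))
        hazard = float(np.clip(
            np.exp(history[-1][0] + (log_t - history[-1][1]) / slope_loc),
            lo, hi))
        achieved, ens = _fitted_half_life(
            scenario.params, hazard, n_reps_final,
            base_seed + 9000 + 137 * (extra + 1), horizon, sample_step,
            keep_trajectories=True)
        iters.append((hazard, achieved, n_reps_final))
        history.append((np.log(hazard), np.log(achieved)))
    return CalibrationResult(stalled_removal_hazard=hazard,
                             achieved_half_life=achieved,
                             target_half_life=target_halflife,
                             iterations=iters,
                             n_replicates_final=n_reps_final,
                             verification=ens if keep_verification else None)
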