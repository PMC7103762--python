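import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uvpol
from uvpol.scenarios import Scenario

settings.register_profile(
    "uvpol",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("uvpol")

SNAP_GRID = [float(t) for t in range(900, 14401, 900)]  # every 15 min over 0-4 h


@pytest.fixture(scope="session")
def calibration_result():
    """Stalled-removal hazard calibrated so the WT surviving pool decays
    with ~1.5 h half-life over 0-4 h post-damage."""
    scen = uvpol.make_scenario("single-gene-wt")
    return uvpol.calibrate_degradation(scen, target_halflife=1.5 * 3600.0,
                                       tol=0.1, seed=101)


@pytest.fixture(scope="session")
def wt_ensemble(calibration_result):
    """100 replicates of the damaged 100-kb gene, WT regime, calibrated
    degradation hazard, sampled every 15 min."""
    scen = uvpol.make_scenario(
        "single-gene-wt",
        stalled_removal_hazard=calibration_result.stalled_removal_hazard,
        snapshot_times=SNAP_GRID)
    return uvpol.run_replicates(scen, seed=2024, keep_trajectories=True)


@pytest.fixture(scope="session")
def k1268r_ensemble():
    """100 replicates of the damaged 100-kb gene with non-degradable
    polymerase (every removal recycles)."""
    scen = uvpol.make_scenario("single-gene-k1268r",
                               snapshot_times=[2700.0, 10800.0])
    return uvpol.run_replicates(scen, seed=3024, keep_trajectories=True)


@pytest.fixture(scope="session")
def pileup_ensemble():
    """100 replicates with dissociation disabled: polymerases pile up
    head-to-tail at lesions."""
    scen = uvpol.make_scenario("single-gene-pileup",
                               snapshot_times=[2700.0, 10800.0])
    return uvpol.run_replicates(scen, seed=4024, keep_trajectories=True)


def _three_gene(preset, seed):
    scen = uvpol.make_scenario(preset, snapshot_times=[14400.0])
    return uvpol.run_replicates(scen, seed=seed)


@pytest.fixture(scope="session")
def three_gene_k1268r():
    return _three_gene("three-gene-k1268r", 5024)


@pytest.fixture(scope="session")
def three_gene_wt():
    return _three_gene("three-gene-wt", 6024)


@pytest.fixture(scope="session")
def three_gene_undamaged():
    return _three_gene("three-gene-undamaged", 7024)


def replicate_profiles(ensemble, time, bin_size=1000):
    """Per-replicate binned occupancy of the first gene at one snapshot."""
    gid = ensemble.scenario.params.genes[0].gene_id
    length = ensemble.scenario.params.genes[0].length
    nb = int(np.ceil(length / bin_size))
    out = []
    for traj in ensemble.trajectories:
        snap = traj.snapshot_at(time)
        pos = snap.genes[gid]["positions"]
        hist, _ = np.histogram(pos, bins=nb, range=(0, nb * bin_size))
        out.append(hist)
    return np.asarray(out, dtype=float)
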