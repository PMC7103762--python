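"""Summary statistics over simulated trajectories and coverage tracks.

These operations turn raw occupancy into the quantities the simulation is
interrogated with: replicate-averaged density maps, length-stratified
metagene profiles, exponential half-life fits of the surviving polymerase
pool, shutdown ratios, queue statistics at lesions, and an L1 profile
distance with a replicate-bootstrap null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, UvpolError
from .params import classify_gene_length


@dataclass
class DensityMap:
    """Replicate-averaged binned polymerase occupancy.

    ``values[gene_id]`` is an (n_times, n_bins) array of mean polymerases
    per bin per run; bins are half-open [k*bin, (k+1)*bin) from the TSS.
    """

    gene_ids: list
    gene_lengths: dict
    bin_size: int
    times: list
    values: dict
    n_replicates: int = 1

    def n_bins(self, gene_id: str) -> int:
        return math.ceil(self.gene_lengths[gene_id] / self.bin_size)

    def time_index(self, t: float) -> int:
        for i, ti in enumerate(self.times):
            if abs(ti - t) < 1e-9:
                return i
        raise KeyError(f"time {t} not in density map (have {self.times})")

    def profile(self, gene_id: str, t: float) -> np.ndarray:
        return self.values[gene_id][self.time_index(t)]

    def total(self, gene_id: str, t: float) -> float:
        return float(self.profile(gene_id, t).sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid in self.gene_ids:
            for ti, t in enumerate(self.times):
                vals = self.values[gid][ti]
                for b, v in enumerate(vals):
                    rows.append((gid, t, b * self.bin_size, float(v)))
        return pd.DataFrame(rows, columns=["gene_id", "time", "bin_start", "value"])


def density_profile(snapshots, gene_lengths: dict, bin_size: int,
                    n_replicates: int = 1) -> DensityMap:
    """Bin engaged-polymerase positions from snapshots into a DensityMap.

    ``snapshots``: iterable of Snapshot (possibly pooled across replicates);
    every engaged polymerase is counted once in bin floor(position/bin_size).
    Values are divided by ``n_replicates`` to give per-run means.
    """
    if bin_size <= 0:
        raise ConfigError("bin_size must be positive", field="bin_size")
    snapshots = list(snapshots)
    times = sorted({s.time for s in snapshots})
    gene_ids = list(gene_lengths)
    values = {
        gid: np.zeros((len(times), math.ceil(gene_lengths[gid] / bin_size)))
        for gid in gene_ids
    }
    t_index = {t: i for i, t in enumerate(times)}
    for s in snapshots:
        ti = t_index[s.time]
        for gid, rec in s.genes.items():
            pos = np.asarray(rec["positions"], dtype=float)
            if pos.size == 0:
                continue
            nb = values[gid].shape[1]
            idx = np.minimum((pos // bin_size).astype(int), nb - 1)
            np.add.at(values[gid][ti], idx, 1.0)
    for gid in gene_ids:
        values[gid] /= max(n_replicates, 1)
    return DensityMap(gene_ids=gene_ids, gene_lengths=dict(gene_lengths),
                      bin_size=int(bin_size), times=times, values=values,
                      n_replicates=n_replicates)


def _relative_profile(values: np.ndarray, n_points: int) -> np.ndarray:
    """Rescale a binned gene-body signal onto n_points relative positions
    between TSS and TTS (linear interpolation of bin centres)."""
    values = np.asarray(values, dtype=float)
    if values.size == 1:
        return np.full(n_points, values[0])
    src = (np.arange(values.size) + 0.5) / values.size
    dst = (np.arange(n_points) + 0.5) / n_points
    return np.interp(dst, src, values)


def metagene_profile(tracks, stratify: bool = False, n_points: int = 100) -> dict:
    """Average per-gene signal on a common relative TSS->TTS axis.

    ``tracks``: iterable of objects with ``gene_id``, a per-bin signal
    (``counts`` or ``values``) and a gene length (``gene_length``).
    Multiple tracks for one gene are averaged first, so the metagene is
    invariant to duplicating a gene (per-gene, then across-gene means).
    With ``stratify`` the result is keyed by length class (short/medium/
    long); empty classes are simply absent.  Without it the key is "all".
    """
    per_gene: dict = {}
    lengths: dict = {}
    for tr in tracks:
        sig = np.asarray(getattr(tr, "counts", getattr(tr, "values", None)), dtype=float)
        gid = tr.gene_id
        lengths[gid] = getattr(tr, "gene_length", None) or len(sig) * tr.bin_size
        per_gene.setdefault(gid, []).append(_relative_profile(sig, n_points))
    if not per_gene:
        raise ConfigError("no tracks supplied")
    gene_means = {gid: np.mean(profs, axis=0) for gid, profs in sorted(per_gene.items())}
    if not stratify:
        return {"all": np.mean(list(gene_means.values()), axis=0)}
    out: dict = {}
    for gid, prof in gene_means.items():
        cls = classify_gene_length(lengths[gid])
        out.setdefault(cls, []).append(prof)
    return {cls: np.mean(profs, axis=0) for cls, profs in out.items()}


def tss_profile(tracks, window: float = 100_000.0) -> dict:
    """TSS-anchored absolute-scale mean profile: per-class mean signal over
    the first ``window`` nt downstream of the TSS, on the tracks' bin grid
    (genes shorter than the window contribute only the bins they have).
    Companion to :func:`metagene_profile` for read-coverage-style plots
    anchored at the start site rather than rescaled to the gene body."""
    per_class: dict = {}
    bin_size = None
    for tr in tracks:
        sig = np.asarray(getattr(tr, "counts", getattr(tr, "values", None)), dtype=float)
        if bin_size is None:
            bin_size = tr.bin_size
        elif tr.bin_size != bin_size:
            raise ConfigError("tracks must share bin_size for a TSS profile")
        length = getattr(tr, "gene_length", None) or len(sig) * tr.bin_size
        cls = classify_gene_length(length)
        nb = int(math.ceil(window / bin_size))
        per_class.setdefault(cls, []).append(sig[:nb])
    if not per_class:
        raise ConfigError("no tracks supplied")
    out = {}
    for cls, sigs in per_class.items():
        nb = max(len(s) for s in sigs)
        acc = np.zeros(nb)
        cnt = np.zeros(nb)
        for s in sigs:
            acc[:len(s)] += s
            cnt[:len(s)] += 1
        out[cls] = acc / np.maximum(cnt, 1)
    return out


@dataclass
class HalfLifeFit:
    """Result of a log-linear exponential-decay fit."""

    half_life: float  # seconds; +inf when no decay is resolvable
    slope: float
    stderr: float
    intercept: float
    r_squared: float

    @property
    def half_life_hours(self) -> float:
        return self.half_life / 3600.0


def fit_half_life(times, counts) -> HalfLifeFit:
    """Least-squares fit of log(count) against time.

    half-life = ln 2 / |slope|; reported as +inf when the slope is
    non-negative within one standard error (no resolvable decay).
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times.size < 3:
        raise ConfigError("need at least 3 points to fit a half-life")
    if np.any(np.diff(times) <= 0):
        raise ConfigError("times must be strictly increasing")
    if np.any(counts <= 0):
        raise ConfigError("counts must be positive (log-linear fit)")
    res = stats.linregress(times, np.log(counts))
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    if res.slope + stderr >= 0.0:
        hl = float("inf")
    else:
        hl = math.log(2.0) / abs(res.slope)
    return HalfLifeFit(half_life=hl, slope=float(res.slope), stderr=stderr,
                       intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2))


def shutdown_ratio(dmap: DensityMap, t_early: float, t_late: float) -> dict:
    """Per-gene ratio of total gene-body signal late/early.  1.0 means the
    activity profile mass is unchanged; NaN flags an undefined ratio
    (zero early signal)."""
    out = {}
    for gid in dmap.gene_ids:
        early = dmap.total(gid, t_early)
        late = dmap.total(gid, t_late)
        out[gid] = float("nan") if early == 0.0 else late / early
    return out


@dataclass
class QueueStats:
    """Per-lesion queue lengths in one snapshot."""

    per_lesion: pd.DataFrame  # gene_id, lesion_id, position, queue_len
    mean: float
    max: int


def queue_statistics(snapshot) -> QueueStats:
    """Count, for each unrepaired lesion, the stalled polymerases whose
    stall-cause chain terminates at it (the lesion-adjacent polymerase plus
    everything queued head-to-tail behind it)."""
    rows = []
    for gid, rec in snapshot.genes.items():
        pol_ids = list(rec["pol_ids"])
        reasons = rec["reasons"]
        causes = list(rec["cause_ids"])
        # chase each stalled pol's chain to a lesion (or nothing)
        by_id = {pid: k for k, pid in enumerate(pol_ids)}
        terminal = {}
        for k, pid in enumerate(pol_ids):
            chain = k
            seen = 0
            while reasons[chain] == "queue" and causes[chain] in by_id and seen <= len(pol_ids):
                chain = by_id[causes[chain]]
                seen += 1
            if reasons[chain] == "lesion":
                terminal[pid] = causes[chain]
        counts: dict = {}
        for pid, lid in terminal.items():
            counts[lid] = counts.get(lid, 0) + 1
        for lid, pos in snapshot.lesions.get(gid, []):
            rows.append((gid, lid, pos, counts.get(lid, 0)))
    df = pd.DataFrame(rows, columns=["gene_id", "lesion_id", "position", "queue_len"])
    if len(df):
        return QueueStats(per_lesion=df, mean=float(df["queue_len"].mean()),
                          max=int(df["queue_len"].max()))
    return QueueStats(per_lesion=df, mean=0.0, max=0)


@dataclass
class ProfileStat:
    """Normalized L1 distance between two profiles with a bootstrap null
    band derived from replicate resampling of the first profile."""

    statistic: float  # in [0, 2]
    null_band: tuple  # (lo, hi) percentile interval of the null
    n_boot: int

    @property
    def within_null(self) -> bool:
        return self.null_band[0] <= self.statistic <= self.null_band[1]


def _l1(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise UvpolError("zero-mass profile in L1 distance")
    return float(np.abs(a / sa - b / sb).sum())


def profile_distance(profile_a, profile_b, replicates_a=None, n_boot: int = 1000,
                     alpha: float = 0.01, seed: int = 0) -> ProfileStat:
    """L1 distance of unit-mass-normalized profiles (0 identical, 2 for
    disjoint support).  When per-replicate profiles of condition A are
    supplied, a null distribution of the distance between two bootstrap
    means of A quantifies replicate noise; a statistic inside the
    (alpha-level upper) null band is indistinguishable from stationarity.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("profiles must share binning")
    stat = _l1(a, b)
    band = (0.0, float("inf"))
    if replicates_a is not None:
        reps = np.asarray(replicates_a, dtype=float)
        rng = np.random.default_rng(seed)
        n = reps.shape[0]
        null = np.empty(n_boot)
        for i in range(n_boot):
            m1 = reps[rng.integers(0, n, n)].mean(axis=0)
            m2 = reps[rng.integers(0, n, n)].mean(axis=0)
            null[i] = _l1(m1, m2)
        band = (0.0, float(np.quantile(null, 1.0 - alpha)))
    return ProfileStat(statistic=stat, null_band=band, n_boot=n_boot)


def surviving_pool_series(pool_frame: pd.DataFrame, pool_size: int) -> pd.DataFrame:
    """Mean surviving polymerase count (pool_size - degraded, i.e. free +
    engaged: the whole-extract readout) per snapshot time across replicates."""
    g = pool_frame.groupby("time", as_index=False)["degraded_count"].mean()
    g["surviving"] = pool_size - g["degraded_count"]
    return g[["time", "surviving"]]
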