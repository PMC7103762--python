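"""File formats: bedGraph coverage, tidy TSV exports, run manifests.

bedGraph is 4-column (chrom, start, end, value) with 0-based half-open
intervals and chrom = gene_id.  Numeric output uses 6 significant digits so
repeated runs with the same (config, seed) are byte-identical.  TSV exports
carry a single '#' header comment with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BedgraphParseError, ConfigError
from .params import SimParams
from .synth import CoverageTrack

__version__ = "0.1.0"


def _fmt(x) -> str:
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.6g}"


def config_hash(params: SimParams) -> str:
    """Deterministic hash of the canonicalized configuration."""
    payload = json.dumps(params.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- bedGraph


def write_bedgraph(tracks, path, sidecar: bool = True) -> Path:
    """Write coverage tracks as sorted 4-column bedGraph; the per-sample
    spike-in scale factors go to a JSON sidecar (<path>.scales.json)."""
    path = Path(path)
    lines = []
    scales = {}
    for tr in sorted(tracks, key=lambda t: (t.gene_id, t.sample_label)):
        scales[tr.gene_id] = tr.spike_scale
        for i, v in enumerate(tr.counts):
            start = i * tr.bin_size
            end = min((i + 1) * tr.bin_size, tr.gene_length or (i + 1) * tr.bin_size)
            lines.append(f"{tr.gene_id}\t{start}\t{end}\t{_fmt(v)}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    if sidecar:
        Path(str(path) + ".scales.json").write_text(
            json.dumps(scales, indent=2, sort_keys=True) + "\n")
    return path


def read_bedgraph(path, spike_scales: dict | None = None) -> list:
    """Parse a bedGraph file into one CoverageTrack per chrom (gene).

    Intervals per chrom must be sorted, non-overlapping and of uniform
    width (the last may be shorter); gaps become zero bins.  Scale factors
    come from ``spike_scales`` or the JSON sidecar when present.
    """
    path = Path(path)
    if spike_scales is None:
        side = Path(str(path) + ".scales.json")
        spike_scales = json.loads(side.read_text()) if side.exists() else {}
    per_gene: dict = {}
    last_end: dict = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise BedgraphParseError(f"expected 4 columns, got {len(parts)}", line_no=ln)
        chrom, s, e, v = parts
        try:
            start, end, value = int(s), int(e), float(v)
        except ValueError as exc:
            raise BedgraphParseError(str(exc), line_no=ln) from exc
        if start < 0 or end <= start:
            raise BedgraphParseError(f"bad interval [{start}, {end})", line_no=ln)
        if value < 0:
            raise BedgraphParseError("negative coverage value", line_no=ln)
        if chrom in last_end and start < last_end[chrom]:
            raise BedgraphParseError(
                f"interval overlaps or is out of order on {chrom}", line_no=ln)
        last_end[chrom] = end
        per_gene.setdefault(chrom, []).append((start, end, value))
    tracks = []
    for gid in sorted(per_gene):
        ivals = per_gene[gid]
        widths = [e - s for s, e, _ in ivals[:-1]]
        bin_size = widths[0] if widths else (ivals[0][1] - ivals[0][0])
        if any(w != bin_size for w in widths):
            raise BedgraphParseError(f"non-uniform bin width on {gid}")
        length = ivals[-1][1]
        counts = np.zeros(int(np.ceil(length / bin_size)))
        for s, e, v in ivals:
            counts[s // bin_size] = v
        arr = counts.astype(int) if np.allclose(counts, np.round(counts)) else counts
        tracks.append(CoverageTrack(
            gene_id=gid, bin_size=bin_size, counts=arr,
            spike_scale=float(spike_scales.get(gid, 1.0)),
            sample_label=gid, gene_length=length))
    return tracks


# ------------------------------------------------------------------- TSV


def _header(params: SimParams, seed: int) -> str:
    return f"# uvpol v{__version__} config_hash={config_hash(params)} seed={seed}\n"


def write_density_tsv(dmap, params: SimParams, seed: int, path) -> Path:
    """Tidy density map: gene_id, time, bin_start, value."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(params, seed))
        fh.write("gene_id\ttime\tbin_start\tvalue\n")
        for gid in dmap.gene_ids:
            for ti, t in enumerate(dmap.times):
                for b, v in enumerate(dmap.values[gid][ti]):
                    fh.write(f"{gid}\t{_fmt(t)}\t{b * dmap.bin_size}\t{_fmt(v)}\n")
    return path


def write_scalars_tsv(pool_frame, mrna_frame, params: SimParams, seed: int, path) -> Path:
    """Per-replicate scalar series: pool, degraded, engaged and per-gene
    mRNA counts in long format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(params, seed))
        fh.write("replicate\ttime\tfree_pool\tdegraded_count\tengaged\tgene_id\tmrna\n")
        mrna_idx = {(r, t, g): c for r, t, g, c in
                    mrna_frame[["replicate", "time", "gene_id", "count"]].itertuples(index=False)}
        for row in pool_frame.itertuples(index=False):
            for g in params.genes:
                c = mrna_idx.get((row.replicate, row.time, g.gene_id), 0)
                fh.write(f"{row.replicate}\t{_fmt(row.time)}\t{row.free_pool}\t"
                         f"{row.degraded_count}\t{row.engaged}\t{g.gene_id}\t{c}\n")
    return path


def write_snapshot_tsv(trajectory, path) -> Path:
    """One row per engaged polymerase: time, gene_id, position."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(trajectory.params, trajectory.seed))
        fh.write("time\tgene_id\tposition\tstatus\n")
        for s in trajectory.snapshots:
            for gid, rec in s.genes.items():
                for pos, st in zip(rec["positions"], rec["statuses"]):
                    fh.write(f"{_fmt(s.time)}\t{gid}\t{_fmt(pos)}\t{st}\n")
    return path


def write_metagene_tsv(profiles: dict, params: SimParams, seed: int, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(params, seed))
        fh.write("class_label\trel_position\tvalue\n")
        for cls in sorted(profiles):
            vals = profiles[cls]
            for i, v in enumerate(vals):
                fh.write(f"{cls}\t{_fmt((i + 0.5) / len(vals))}\t{_fmt(v)}\n")
    return path


# -------------------------------------------------------------- manifest


@dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    config_hash: str
    seed: int
    tool_version: str = __version__
    start_time: str = ""
    end_time: str = ""
    outputs: list = field(default_factory=list)
    error: str | None = None

    def write(self, path) -> Path:
        path = Path(path)
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "tool_version": self.tool_version,
            "start_time": self.start_time,
            "end_time": self.end_time,
            "outputs": sorted(str(o) for o in self.outputs),
            "error": self.error,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def new_manifest(params: SimParams, seed: int) -> RunManifest:
    return RunManifest(config_hash=config_hash(params), seed=seed,
                       start_time=_time.strftime("%Y-%m-%dT%H:%M:%S"))
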