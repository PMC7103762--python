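"""Synthetic nascent-RNA coverage: TT-seq-like tracks from density maps.

A CoverageTrack emulates binned, spike-in-scaled sequencing coverage of one
gene: per-bin counts are Poisson around depth x density x spike_scale, and
the per-sample spike-in scale factor is carried as known truth (an
estimator from a simulated spike-in track is provided to mirror the
size-factor idea).  The noise model is Poisson only; overdispersion is a
documented extension hook.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .params import GeneSpec, SHORT_MAX, LONG_MIN, classify_gene_length
from .summaries import DensityMap


@dataclass
class CoverageTrack:
    """Binned signal for one gene in one sample, with its library-size
    (spike-in) scale factor."""

    gene_id: str
    bin_size: int
    counts: np.ndarray
    spike_scale: float
    sample_label: str = ""
    gene_length: int | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.spike_scale is not None and self.spike_scale <= 0:
            raise ConfigError("spike_scale must be positive", field="spike_scale")
        if self.gene_length is None:
            self.gene_length = len(self.counts) * self.bin_size


def simulate_coverage(dmap: DensityMap, depth: float, spike_scale: float,
                      seed: int, time: float | None = None,
                      sample_label: str = "sample") -> list:
    """Draw Poisson read counts over a density map.

    ``depth`` is the expected reads per unit density per bin; one track is
    produced per gene (for ``time``, or every snapshot time when None).
    """
    if depth < 0:
        raise ConfigError("depth must be >= 0", field="depth")
    if spike_scale <= 0:
        raise ConfigError("spike_scale must be positive", field="spike_scale")
    rng = np.random.default_rng(seed)
    times = [time] if time is not None else dmap.times
    tracks = []
    for t in times:
        for gid in dmap.gene_ids:
            lam = depth * dmap.profile(gid, t) * spike_scale
            counts = rng.poisson(lam)
            tracks.append(CoverageTrack(
                gene_id=gid, bin_size=dmap.bin_size, counts=counts,
                spike_scale=spike_scale,
                sample_label=f"{sample_label}_t{t:g}",
                gene_length=dmap.gene_lengths[gid]))
    return tracks


def spike_in_normalize(tracks) -> list:
    """Divide each track's counts by its spike-in scale factor so tracks
    from the same underlying density agree in expectation across samples."""
    out = []
    for tr in tracks:
        if tr.spike_scale is None:
            raise ConfigError("track is missing its spike_scale", field="spike_scale")
        if tr.spike_scale <= 0:
            raise ConfigError("spike_scale must be positive", field="spike_scale")
        out.append(replace(tr, counts=tr.counts / tr.spike_scale, spike_scale=1.0))
    return out


def estimate_spike_scale(spike_counts, reference_counts) -> float:
    """Ratio-of-totals size factor from a simulated spike-in track relative
    to a reference sample (mirrors library-size estimation without a full
    differential-expression model)."""
    s, r = float(np.sum(spike_counts)), float(np.sum(reference_counts))
    if r <= 0:
        raise ConfigError("reference spike-in track has zero total")
    return s / r


_CLASS_BOUNDS = {
    "short": (1_000.0, float(SHORT_MAX)),
    "medium": (float(SHORT_MAX), float(LONG_MIN)),
    "long": (float(LONG_MIN), 1_000_000.0),
}


def random_gene_ensemble(n_genes: int, class_proportions=(0.1, 0.2, 0.7),
                         seed: int = 0) -> list:
    """Random gene ensemble with multinomial class labels and log-uniform
    lengths within each class interval (long capped at 1 Mb).

    ``class_proportions`` is (long, medium, short), matching the genomic
    representation weighting; initiation weights are split evenly inside a
    class so each class receives its proportion in aggregate.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1", field="n_genes")
    props = np.asarray(class_proportions, dtype=float)
    if props.shape != (3,) or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ConfigError("class_proportions must be 3 non-negative fractions summing to 1")
    rng = np.random.default_rng(seed)
    classes = ["long", "medium", "short"]
    labels = [classes[i] for i in rng.choice(3, size=n_genes, p=props)]
    counts = {c: labels.count(c) for c in classes}
    present = [c for c in classes if counts[c] > 0]
    mass = sum(props[classes.index(c)] for c in present)
    genes = []
    for i, cls in enumerate(labels):
        lo, hi = _CLASS_BOUNDS[cls]
        length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        length = min(max(length, int(lo)), int(hi) - 1 if cls != "long" else int(hi))
        weight = props[classes.index(cls)] / mass / counts[cls]
        genes.append(GeneSpec(gene_id=f"{cls}_{i}", length=length,
                              initiation_weight=float(weight)))
    # guard: construction must agree with the classifier
    for g in genes:
        assert classify_gene_length(g.length) == g.class_label
    return genes
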