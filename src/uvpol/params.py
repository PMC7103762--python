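"""Domain types and parameter handling for the RNAPII/UV simulator.

The simulator works in base units of nucleotides (positions, lengths) and
seconds (times, rates).  Configuration files may use unit-suffixed strings
("100kb", "45min", "1.5h"); they are converted on load and serialized back
in base units, so a written config reloads to an identical parameter set.

Gene-length classes follow the genomic stratification used for metagene
analysis: short < 30 kb, medium 30-100 kb (lower-inclusive), long >= 100 kb.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigError

# Gene-length class boundaries in nucleotides (lower-inclusive upper bins).
SHORT_MAX = 30_000
LONG_MIN = 100_000

_LENGTH_UNITS = {"nt": 1.0, "bp": 1.0, "kb": 1_000.0, "mb": 1_000_000.0}
_TIME_UNITS = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3_600.0, "hr": 3_600.0}

_QTY_RE = re.compile(r"^\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*([a-zA-Z]*)\s*$")


def _parse_quantity(value, units: dict, kind: str) -> float:
    """Parse a number or unit-suffixed string into base units."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        m = _QTY_RE.match(value)
        if not m:
            raise ConfigError(f"cannot parse {kind} quantity {value!r}")
        num, unit = float(m.group(1)), m.group(2).lower()
        if unit == "":
            return num
        if unit not in units:
            raise ConfigError(f"unknown {kind} unit {m.group(2)!r} in {value!r}")
        return num * units[unit]
    raise ConfigError(f"cannot parse {kind} quantity {value!r}")


def parse_length(value) -> float:
    """Parse a length in nt; accepts "40", 40, "5kb", "0.1Mb"."""
    return _parse_quantity(value, _LENGTH_UNITS, "length")


def parse_time(value) -> float:
    """Parse a time in seconds; accepts "45min", "1.5h", 2700."""
    return _parse_quantity(value, _TIME_UNITS, "time")


def classify_gene_length(length) -> str:
    """Assign a gene-length class: short (<30 kb), medium (30-100 kb),
    long (>=100 kb).  Boundaries are lower-inclusive."""
    length = parse_length(length)
    if length <= 0:
        raise ConfigError("gene length must be positive", field="length")
    if length < SHORT_MAX:
        return "short"
    if length < LONG_MIN:
        return "medium"
    return "long"


@dataclass(frozen=True)
class GeneSpec:
    """A model gene: a linear template of ``length`` nt transcribed from
    position 0 (TSS) to ``length`` (TTS), receiving the fraction
    ``initiation_weight`` of initiation attempts."""

    gene_id: str
    length: int
    initiation_weight: float
    class_label: str = ""

    def __post_init__(self):
        if self.class_label == "":
            object.__setattr__(self, "class_label", classify_gene_length(self.length))

    def validate(self) -> "GeneSpec":
        if self.length <= 0:
            raise ConfigError("gene length must be positive", field=f"genes[{self.gene_id}].length")
        if not (0.0 <= self.initiation_weight <= 1.0):
            raise ConfigError(
                "initiation weight must lie in [0, 1]",
                field=f"genes[{self.gene_id}].initiation_weight",
            )
        expected = classify_gene_length(self.length)
        if self.class_label != expected:
            raise ConfigError(
                f"class_label {self.class_label!r} inconsistent with length "
                f"{self.length} nt (expected {expected!r})",
                field=f"genes[{self.gene_id}].class_label",
            )
        return self


@dataclass
class SimParams:
    """Full tunable parameter set of the simulator.

    Defaults that the source data do not pin down numerically are package
    defaults chosen for a 20 J/m^2-equivalent UV dose on a scaled-down
    polymerase pool; see docs/methods.md for the rationale behind each.
    All of them are config-overridable.
    """

    genes: list[GeneSpec] = field(default_factory=list)
    pool_size: int = 500
    initiation_rate_per_free_pol: float = 5e-4  # 1/s per free polymerase
    elongation_speed: float = 33.3  # nt/s (~2 kb/min)
    pause_site_offset: float | None = None  # nt from TSS; None disables pausing
    pause_mean_dwell: float | None = None  # s
    footprint: float = 40.0  # nt head-to-tail exclusion
    lesion_density: float = 1.0 / 25_000.0  # lesions per nt of template strand
    lesion_halflife: float = 12 * 3600.0  # s; TC-NER removal half-life
    moving_removal_hazard: float = 0.0  # 1/s while translocating
    stalled_removal_hazard: float = 1.0 / 1800.0  # 1/s while halted (lesion or queue)
    removal_recycle_prob: float = 0.5  # recycle vs degrade on removal
    completion_recycle_prob: float = 1.0  # recycle vs degrade on completion
    degradation_enabled: bool = True
    dissociation_enabled: bool = True
    burn_in_time: float | None = None  # s; None -> 5x longest gene transit time
    snapshot_times: list[float] = field(default_factory=lambda: [2700.0, 10800.0, 14400.0])
    n_replicates: int = 100
    bin_size: int = 1000  # nt
    seed: int = 0

    # --- effective values implementing the two biological toggles -------

    @property
    def effective_recycle_prob(self) -> float:
        """degradation_enabled=False (K1268R regime) means every removed
        polymerase returns to the free pool."""
        return 1.0 if not self.degradation_enabled else self.removal_recycle_prob

    @property
    def effective_stalled_hazard(self) -> float:
        """dissociation_enabled=False (pile-up regime) means halted
        polymerases are never removed from the template."""
        return 0.0 if not self.dissociation_enabled else self.stalled_removal_hazard

    @property
    def max_transit_time(self) -> float:
        if not self.genes:
            return 0.0
        return max(g.length for g in self.genes) / self.elongation_speed

    @property
    def effective_burn_in(self) -> float:
        return self.burn_in_time if self.burn_in_time is not None else 5.0 * self.max_transit_time

    # --- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes"] = [dataclasses.asdict(g) for g in self.genes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        genes = [
            g if isinstance(g, GeneSpec) else GeneSpec(
                gene_id=str(g["gene_id"]),
                length=int(round(parse_length(g["length"]))),
                initiation_weight=float(g["initiation_weight"]),
                class_label=g.get("class_label", ""),
            )
            for g in d.pop("genes", [])
        ]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("pause_site_offset", "footprint", "bin_size"):
            if d.get(key) is not None:
                d[key] = parse_length(d[key])
        for key in ("lesion_halflife", "burn_in_time", "pause_mean_dwell"):
            if d.get(key) is not None:
                d[key] = parse_time(d[key])
        if "snapshot_times" in d:
            d["snapshot_times"] = [parse_time(t) for t in d["snapshot_times"]]
        if "bin_size" in d:
            d["bin_size"] = int(round(d["bin_size"]))
        return cls(genes=genes, **d)

    def save(self, path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=True))
        else:
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "SimParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(payload)


def make_preset_ensemble(preset_name: str) -> list[GeneSpec]:
    """Gene ensembles for the two canonical experiments.

    ``single_100kb``: one 100-kb gene taking all initiation events.
    ``three_gene``: 100 kb / 63 kb / 5 kb genes competing for the shared
    polymerase pool with initiation weights 0.1 / 0.2 / 0.7 (the genomic
    representation of long / medium / short genes).
    """
    if preset_name == "single_100kb":
        return [GeneSpec("gene_100kb", 100_000, 1.0)]
    if preset_name == "three_gene":
        return [
            GeneSpec("long_100kb", 100_000, 0.1),
            GeneSpec("medium_63kb", 63_000, 0.2),
            GeneSpec("short_5kb", 5_000, 0.7),
        ]
    raise ConfigError(f"unknown gene ensemble preset {preset_name!r}", field="preset")


def validate_params(params: SimParams) -> SimParams:
    """Check every SimParams invariant; returns the (possibly weight-
    renormalized) params or raises :class:`ConfigError` naming the field."""
    p = params
    if not p.genes:
        raise ConfigError("at least one gene is required", field="genes")
    ids = [g.gene_id for g in p.genes]
    if len(set(ids)) != len(ids):
        raise ConfigError("gene_id values must be unique", field="genes")
    for g in p.genes:
        g.validate()

    wsum = sum(g.initiation_weight for g in p.genes)
    if abs(wsum - 1.0) > 1e-6:
        raise ConfigError(
            f"initiation weights sum to {wsum:.9g}, expected 1",
            field="genes.initiation_weight",
        )
    if abs(wsum - 1.0) > 1e-12:
        p.genes = [
            dataclasses.replace(g, initiation_weight=g.initiation_weight / wsum)
            for g in p.genes
        ]

    def _nonneg(name):
        v = getattr(p, name)
        if v is None:
            return
        if not math.isfinite(v) or v < 0:
            raise ConfigError("must be a finite non-negative number", field=name)

    for name in (
        "initiation_rate_per_free_pol",
        "elongation_speed",
        "lesion_density",
        "lesion_halflife",
        "moving_removal_hazard",
        "stalled_removal_hazard",
        "pause_mean_dwell",
        "burn_in_time",
    ):
        _nonneg(name)
    if p.elongation_speed <= 0:
        raise ConfigError("must be positive", field="elongation_speed")
    for name in ("removal_recycle_prob", "completion_recycle_prob"):
        v = getattr(p, name)
        if not (0.0 <= v <= 1.0):
            raise ConfigError(f"probability {v} outside [0, 1]", field=name)
    if p.pool_size < 0 or int(p.pool_size) != p.pool_size:
        raise ConfigError("must be a non-negative integer", field="pool_size")
    if p.footprint < 0:
        raise ConfigError("must be non-negative", field="footprint")
    if p.footprint >= min(g.length for g in p.genes):
        raise ConfigError("footprint must be smaller than the shortest gene", field="footprint")
    if (p.pause_site_offset is None) != (p.pause_mean_dwell is None):
        raise ConfigError(
            "pause_site_offset and pause_mean_dwell must be set together",
            field="pause_site_offset",
        )
    if p.pause_site_offset is not None and not (0 < p.pause_site_offset < min(g.length for g in p.genes)):
        raise ConfigError("pause site must lie inside every gene", field="pause_site_offset")
    times = list(p.snapshot_times)
    if any(t < 0 for t in times):
        raise ConfigError("snapshot times must be >= 0", field="snapshot_times")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ConfigError("snapshot times must be strictly increasing", field="snapshot_times")
    if p.n_replicates < 1:
        raise ConfigError("must be >= 1", field="n_replicates")
    if p.bin_size <= 0:
        raise ConfigError("must be positive", field="bin_size")
    return p


def default_params(preset_name: str = "single_100kb", **overrides) -> SimParams:
    """Convenience constructor: preset ensemble + default parameters."""
    p = SimParams(genes=make_preset_ensemble(preset_name), **overrides)
    return validate_params(p)
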