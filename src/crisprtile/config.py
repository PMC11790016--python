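"""Run configuration: a single YAML document drives simulate → count →
analyze → annotate → overlap with one seed.

Unknown keys are rejected and numeric parameters are validated against the
ranges the downstream operations require, before any stage runs.  The
canonical JSON serialization of a config is hashed and stamped into every
output file for provenance.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import SchemaError, ValidationError
from .sim import BIN_LABELS, PlantedElement

DEFAULT_COMPARISONS = ("low_vs_high", "center_vs_high")


def _strict(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) in {where}: {', '.join(sorted(map(str, unknown)))}")


@dataclass
class GeneScreenConfig:
    """One screened gene: its name and the planted ground-truth elements."""

    name: str
    elements: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict, default_chrom: str) -> "GeneScreenConfig":
        _strict(d, {"name", "elements"}, "genes[]")
        elements = []
        for e in d.get("elements", []):
            _strict(e, {"chrom", "start", "end", "effect"}, "elements[]")
            elements.append(
                PlantedElement(
                    chrom=e.get("chrom", default_chrom),
                    start=int(e["start"]),
                    end=int(e["end"]),
                    effect=float(e["effect"]),
                )
            )
        return cls(name=str(d["name"]), elements=elements)


@dataclass
class SimulateConfig:
    region_start: int
    region_end: int
    n_tiling: int
    n_nontargeting: int
    n_nonexpressed: int
    n_cells: int
    depth_per_bin: int
    genes: list
    chrom: str = "chr3"
    expr_cv: float = 0.3
    control_cv: float = 0.1
    jitter: Optional[int] = None
    write_fastq: bool = False

    def __post_init__(self):
        if self.region_end <= self.region_start:
            raise ValidationError("simulate: region_end must exceed region_start")
        if self.n_tiling < 1:
            raise ValidationError("simulate: n_tiling must be >= 1")
        if self.n_cells < 1 or self.depth_per_bin < 1:
            raise ValidationError("simulate: n_cells and depth_per_bin must be >= 1")
        if self.expr_cv < 0 or self.control_cv < 0:
            raise ValidationError("simulate: coefficients of variation must be >= 0")
        if not self.genes:
            raise ValidationError("simulate: at least one gene screen is required")
        for g in self.genes:
            for el in g.elements:
                if not (self.region_start <= el.start and el.end <= self.region_end):
                    raise ValidationError(
                        f"simulate: element [{el.start}, {el.end}) outside the screen region"
                    )

    @property
    def region(self) -> tuple[int, int]:
        return (self.region_start, self.region_end)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulateConfig":
        allowed = {
            "region_start", "region_end", "n_tiling", "n_nontargeting",
            "n_nonexpressed", "n_cells", "depth_per_bin", "genes", "chrom",
            "expr_cv", "control_cv", "jitter", "write_fastq",
        }
        _strict(d, allowed, "simulate")
        chrom = str(d.get("chrom", "chr3"))
        genes = [GeneScreenConfig.from_dict(g, chrom) for g in d.get("genes", [])]
        kwargs = {k: v for k, v in d.items() if k not in ("genes", "chrom")}
        return cls(chrom=chrom, genes=genes, **kwargs)


@dataclass
class AnalysisConfig:
    window: int = 2000
    step: int = 500
    min_guides: int = 5
    alpha: float = 0.05
    pseudocount: float = 0.5
    B: int = 10000
    comparisons: tuple = DEFAULT_COMPARISONS
    require_direction: Optional[int] = 1
    statistic: str = "mean"

    def __post_init__(self):
        if not (self.window >= self.step >= 1):
            raise ValidationError("analysis: require window >= step >= 1")
        if not (0 < self.alpha <= 1):
            raise ValidationError("analysis: alpha must lie in (0, 1]")
        if self.pseudocount < 0:
            raise ValidationError("analysis: pseudocount must be >= 0")
        if self.B < 1:
            raise ValidationError("analysis: B must be >= 1")
        if self.min_guides < 1:
            raise ValidationError("analysis: min_guides must be >= 1")
        self.comparisons = tuple(self.comparisons)
        for comp in self.comparisons:
            a, _, b = comp.partition("_vs_")
            if a not in BIN_LABELS or b not in BIN_LABELS:
                raise ValidationError(f"analysis: unknown comparison {comp!r}")
        if self.require_direction not in (None, 1, -1):
            raise ValidationError("analysis: require_direction must be 1, -1 or null")
        if self.statistic not in ("mean", "rank_sum"):
            raise ValidationError("analysis: statistic must be 'mean' or 'rank_sum'")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        allowed = {
            "window", "step", "min_guides", "alpha", "pseudocount", "B",
            "comparisons", "require_direction", "statistic",
        }
        _strict(d, allowed, "analysis")
        return cls(**d)


@dataclass
class AnnotateConfig:
    peaks: Optional[str] = None
    tss: Optional[str] = None
    promoter_window: int = 1000

    def __post_init__(self):
        if self.promoter_window < 0:
            raise ValidationError("annotate: promoter_window must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotateConfig":
        _strict(d, {"peaks", "tss", "promoter_window"}, "annotate")
        return cls(**d)


@dataclass
class RunConfig:
    """Full pipeline configuration (simulate, analyze, annotate stages)."""

    seed: int
    simulate: SimulateConfig
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _strict(d, {"seed", "simulate", "analysis", "annotate"}, "config")
        if "simulate" not in d:
            raise SchemaError("config: a 'simulate' section is required")
        return cls(
            seed=int(d.get("seed", 0)),
            simulate=SimulateConfig.from_dict(d["simulate"]),
            analysis=AnalysisConfig.from_dict(d.get("analysis", {})),
            annotate=AnnotateConfig.from_dict(d.get("annotate", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(doc)
        # resolve annotation paths relative to the config file
        for attr in ("peaks", "tss"):
            value = getattr(cfg.annotate, attr)
            if value is not None:
                p = Path(value)
                if not p.is_absolute():
                    p = path.parent / p
                setattr(cfg.annotate, attr, str(p))
        return cfg

    def canonical_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
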