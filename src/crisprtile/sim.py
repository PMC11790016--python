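"""Synthetic CRISPRi tiling screens with planted ground truth.

The generator emulates the experimental design of a FACS-bin tiling screen:
a guide library densely tiling a contiguous locus plus nontargeting and
nonexpressed-promoter control guides; a cell population in which every cell
carries a single integrated guide (low-MOI transduction followed by
selection); an in situ expression readout expressed as the ratio of target-
gene to control-gene fluorescence; percentile sorting gates (low 0–15%,
center 35–65%, high 85–100% of the ranked ratio); and per-bin amplicon
sequencing modeled as a multinomial draw over the cell tallies.

Planted regulatory elements define the ground truth: a cell whose guide
midpoint falls inside an element has its target expression multiplied by
(1 − effect).  Positive effects are repressive (the expected on-target
CRISPRi consequence of silencing a true regulatory element); negative
effects model paradoxical activation.
"""
from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyBinError, GenerationError, ValidationError
from .quant import (
    AUDIT_COLUMNS,
    KEY_LENGTH,
    SCAFFOLD_ANCHOR,
    SPACER_LENGTH,
    CountTable,
    spacer_key,
)

CATEGORIES = ("tiling", "nontargeting", "nonexpressed_promoter")
BIN_LABELS = ("low", "center", "high")

#: Genomic footprint recorded for a tiling guide's target interval, bp.
GUIDE_TARGET_SPAN = 20

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GuideRecord:
    """One library entry.

    Tiling guides carry a 0-based half-open genomic target interval inside the
    screened region; control guides (nontargeting, nonexpressed-promoter)
    carry no coordinates.  The 15 nt of the spacer proximal to the scaffold
    serve as the matching key during quantification.
    """

    guide_id: str
    spacer: str
    chrom: Optional[str]
    start: Optional[int]
    end: Optional[int]
    strand: str
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown guide category: {self.category!r}")

    @property
    def key(self) -> str:
        return spacer_key(self.spacer)

    @property
    def midpoint(self) -> Optional[int]:
        if self.start is None or self.end is None:
            return None
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PlantedElement:
    """A ground-truth regulatory element: half-open interval plus signed effect.

    ``effect`` is a fraction in [-1, 1]; expression of cells whose guide
    midpoint lies inside is multiplied by ``1 - effect``, so positive values
    repress and negative values activate.
    """

    chrom: str
    start: int
    end: int
    effect: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError("element interval must satisfy start < end")
        if abs(self.effect) > 1:
            raise ValidationError("|effect| must not exceed 1")

    def contains(self, chrom: Optional[str], pos: Optional[int]) -> bool:
        return chrom == self.chrom and pos is not None and self.start <= pos < self.end


@dataclass(frozen=True)
class SortGates:
    """Percentile gates on the ranked expression ratio.

    Each gate is a fraction interval of the ranked population; defaults are
    low 0–15%, center 35–65%, high 85–100%.
    """

    low: tuple[float, float] = (0.0, 0.15)
    center: tuple[float, float] = (0.35, 0.65)
    high: tuple[float, float] = (0.85, 1.0)

    def __post_init__(self):
        gates = [self.low, self.center, self.high]
        for a, b in gates:
            if not (0.0 <= a < b <= 1.0):
                raise ValidationError("each gate must satisfy 0 <= lo < hi <= 1")
        if not (self.low[1] <= self.center[0] and self.center[1] <= self.high[0]):
            raise ValidationError("gates must be ordered low < center < high without overlap")

    @property
    def labeled(self) -> list[tuple[str, tuple[float, float]]]:
        return list(zip(BIN_LABELS, (self.low, self.center, self.high)))

    def bin_sizes(self, n: int) -> dict[str, int]:
        """Number of cells each gate captures out of ``n`` (floor boundaries)."""
        return {
            label: math.floor(b * n) - math.floor(a * n)
            for label, (a, b) in self.labeled
        }


@dataclass
class CellPopulation:
    """Cells carrying single guides with their expression ratio readout.

    ``r`` is target fluorescence over control-gene fluorescence per cell;
    ``guide_index`` indexes into ``guide_ids``.
    """

    guide_ids: tuple
    guide_index: np.ndarray
    r: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.r.shape[0]


def _random_spacers(n: int, rng: np.random.Generator, max_rounds: int = 50) -> list[str]:
    """Random 20-nt spacers with pairwise-distinct 15-mer matching keys."""
    spacers: list[str] = []
    seen: set[str] = set()
    rounds = 0
    while len(spacers) < n:
        rounds += 1
        if rounds > max_rounds:
            raise GenerationError(
                f"could not generate {n} spacers with unique {KEY_LENGTH}-mer keys "
                f"within {max_rounds} rounds"
            )
        draw = rng.integers(0, 4, size=(n - len(spacers), SPACER_LENGTH))
        for row in draw:
            sp = "".join(_BASES[row])
            k = sp[-KEY_LENGTH:]
            if k not in seen:
                seen.add(k)
                spacers.append(sp)
    return spacers


def build_library(
    region: tuple[int, int],
    n_tiling: int,
    n_nontargeting: int = 0,
    n_nonexpressed: int = 0,
    seed=None,
    *,
    chrom: str = "chr3",
    jitter: Optional[int] = None,
) -> list[GuideRecord]:
    """Build a synthetic guide library tiling ``region`` on ``chrom``.

    Tiling guides are evenly spaced with uniform positional jitter (default a
    quarter of the spacing; pass ``jitter=0`` for an exact grid).  Spacers are
    random with unique matching keys; the library composition is exactly the
    requested category counts.
    """
    start, end = region
    length = end - start
    if n_tiling < 1:
        raise ValidationError("n_tiling must be >= 1")
    if length < n_tiling:
        raise ValidationError("region shorter than the number of tiling guides")
    if n_nontargeting < 0 or n_nonexpressed < 0:
        raise ValidationError("control guide counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_total = n_tiling + n_nontargeting + n_nonexpressed
    spacers = _random_spacers(n_total, rng)

    spacing = length / n_tiling
    jit = int(spacing // 4) if jitter is None else int(jitter)
    if jit < 0:
        raise ValidationError("jitter must be non-negative")
    span = min(GUIDE_TARGET_SPAN, length)
    base = start + np.floor(np.arange(n_tiling) * spacing).astype(np.int64)
    offsets = rng.integers(-jit, jit + 1, size=n_tiling) if jit > 0 else np.zeros(n_tiling, dtype=np.int64)
    starts = np.clip(base + offsets, start, end - span)

    library: list[GuideRecord] = []
    it = iter(spacers)
    for i in range(n_tiling):
        s = int(starts[i])
        library.append(
            GuideRecord(f"TILE_{i:06d}", next(it), chrom, s, s + span, "+", "tiling")
        )
    for i in range(n_nontargeting):
        library.append(
            GuideRecord(f"NT_{i:05d}", next(it), None, None, None, ".", "nontargeting")
        )
    for i in range(n_nonexpressed):
        library.append(
            GuideRecord(
                f"NEP_{i:05d}", next(it), None, None, None, ".", "nonexpressed_promoter"
            )
        )
    return library


def _lognormal_unit_mean(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal draws with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_cells(
    library: Sequence[GuideRecord],
    elements: Sequence[PlantedElement],
    n_cells: int,
    expr_cv: float = 0.3,
    seed=None,
    *,
    control_cv: float = 0.1,
) -> CellPopulation:
    """Draw a cell population: one guide per cell, ratio readout per cell.

    Each cell draws one guide uniformly from the library.  Baseline target
    expression is log-normal with mean 1 and coefficient of variation
    ``expr_cv``; a cell whose guide midpoint lies inside a planted element has
    expression multiplied by ``1 - effect`` (multiplicatively across
    overlapping elements).  The control-gene normalization contributes
    independent multiplicative log-normal noise with CV ``control_cv``.
    """
    if not library:
        raise ValidationError("library is empty")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if expr_cv < 0 or control_cv < 0:
        raise ValidationError("coefficients of variation must be non-negative")
    rng = np.random.default_rng(seed)

    multiplier = np.ones(len(library))
    for j, g in enumerate(library):
        for el in elements:
            if el.contains(g.chrom, g.midpoint):
                multiplier[j] *= 1.0 - el.effect

    idx = rng.integers(0, len(library), size=n_cells)
    base = _lognormal_unit_mean(expr_cv, n_cells, rng)
    noise = _lognormal_unit_mean(control_cv, n_cells, rng)
    r = base * multiplier[idx] * noise
    return CellPopulation(
        guide_ids=tuple(g.guide_id for g in library),
        guide_index=idx,
        r=r,
    )


def sort_cells(pop: CellPopulation, gates: Optional[SortGates] = None) -> pd.DataFrame:
    """Tally cells per guide per sorting bin.

    Cells are ranked ascending by ``r`` with ties broken by stable cell index;
    gate (a, b) captures ranked positions [floor(a·n), floor(b·n)).  The
    result is a guides × bins integer DataFrame covering every library guide.
    """
    if pop.n_cells == 0:
        raise ValidationError("population is empty")
    gates = gates or SortGates()
    n = pop.n_cells
    order = np.argsort(pop.r, kind="stable")
    n_guides = len(pop.guide_ids)
    cols = {}
    for label, (a, b) in gates.labeled:
        lo, hi = math.floor(a * n), math.floor(b * n)
        picked = pop.guide_index[order[lo:hi]]
        cols[label] = np.bincount(picked, minlength=n_guides)
    return pd.DataFrame(cols, index=pd.Index(pop.guide_ids, name="guide_id"), dtype=np.int64)


def sequence_bins(
    tallies: pd.DataFrame,
    depth_per_bin: int,
    seed=None,
    *,
    library: Optional[Sequence[GuideRecord]] = None,
    fastq_dir=None,
    sample_prefix: str = "screen",
    read_length: int = 75,
    gzip_fastq: bool = True,
    overdispersion: Optional[float] = None,
) -> CountTable:
    """Sequence each sorted bin to a fixed depth.

    Counts per bin are multinomial with probabilities proportional to the cell
    tallies (optionally Dirichlet-multinomial with concentration
    ``overdispersion × p`` for extra-multinomial noise).  When ``fastq_dir``
    is given, per-bin FASTQ files are also written: each read is a random
    0–10 nt prefix, the 20 nt spacer, the scaffold anchor, and random filler
    to ``read_length``, with constant Sanger quality 'I'.
    """
    if depth_per_bin < 1:
        raise ValidationError("depth_per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    samples = {}
    for label in tallies.columns:
        tally = tallies[label].to_numpy(dtype=float)
        total = tally.sum()
        if total == 0:
            raise EmptyBinError(f"bin {label!r} received no cells")
        p = tally / total
        if overdispersion is not None:
            alpha = np.where(p > 0, p * overdispersion, 0.0)
            p = np.zeros_like(p)
            nz = alpha > 0
            p[nz] = rng.dirichlet(alpha[nz])
        samples[f"{sample_prefix}_{label}"] = rng.multinomial(depth_per_bin, p)
    raw = pd.DataFrame(samples, index=tallies.index, dtype=np.int64)
    depth = raw.sum(axis=0)
    audit = pd.DataFrame(
        {
            "total_reads": depth,
            "anchored": depth,
            "matched": depth,
            "ambiguous": 0,
            "unmatched": 0,
        },
        columns=list(AUDIT_COLUMNS),
    ).rename_axis("sample")

    fastq_paths = None
    if fastq_dir is not None:
        if library is None:
            raise ValidationError("library is required to emit FASTQ reads")
        fastq_paths = _write_fastqs(
            raw, library, Path(fastq_dir), rng, read_length, gzip_fastq
        )
    return CountTable(raw=raw, audit=audit, fastq_paths=fastq_paths)


def _write_fastqs(raw, library, outdir, rng, read_length, gzip_fastq):
    outdir.mkdir(parents=True, exist_ok=True)
    spacer_of = {g.guide_id: g.spacer for g in library}
    paths = {}
    for sample in raw.columns:
        counts = raw[sample]
        n_reads = int(counts.sum())
        spacers = np.repeat(
            [spacer_of[g] for g in counts.index], counts.to_numpy()
        )
        order = rng.permutation(n_reads)
        prefix_len = rng.integers(0, 11, size=n_reads)
        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        path = outdir / f"{sample}{suffix}"
        # mtime=0 keeps gzip output byte-identical across runs
        handle = (
            gzip.GzipFile(path, "wb", mtime=0)
            if gzip_fastq
            else open(path, "wb")
        )
        with handle:
            for i, cell in enumerate(order):
                sp = spacers[cell]
                k = int(prefix_len[i])
                core_len = k + len(sp) + len(SCAFFOLD_ANCHOR)
                fill = max(0, read_length - core_len)
                bases = rng.integers(0, 4, size=k + fill)
                pre = "".join(_BASES[bases[:k]])
                post = "".join(_BASES[bases[k:]])
                seq = f"{pre}{sp}{SCAFFOLD_ANCHOR}{post}"
                rec = f"@{sample}.{i}\n{seq}\n+\n{'I' * len(seq)}\n"
                handle.write(rec.encode())
        paths[sample] = path
    return paths


def write_truth(elements: Sequence[PlantedElement], path) -> None:
    """Write planted elements as BED6 with the signed effect in the score column."""
    with open(path, "w") as fh:
        for i, el in enumerate(elements):
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\tel{i + 1}\t{el.effect!r}\t.\n")


def read_truth(path) -> list[PlantedElement]:
    """Read a truth BED written by :func:`write_truth`."""
    elements = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            elements.append(
                PlantedElement(fields[0], int(fields[1]), int(fields[2]), float(fields[4]))
            )
    return elements
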