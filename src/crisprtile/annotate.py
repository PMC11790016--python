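"""Feature annotation and cross-gene domain overlap.

Interval conventions are uniformly 0-based half-open.  TSS proximity uses the
item midpoint against a symmetric ±window around each TSS (1,000 bp default);
peak overlap is non-empty half-open intersection; the distance from a point
to a peak is the distance to the nearest covered base (0 inside).  Domain
overlap between the two screened genes is summarized as Venn counts at a
chosen stringency tier.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError

FEATURE_KINDS = ("tss", "exon", "atac_peak", "variant")


@dataclass
class FeatureSet:
    """Named genomic intervals of one kind, sorted per chromosome."""

    df: pd.DataFrame  # columns: chrom, start, end, name
    kind: str

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind: {self.kind!r}")
        required = {"chrom", "start", "end", "name"}
        if not required.issubset(self.df.columns):
            raise ValidationError(f"feature table needs columns {sorted(required)}")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValidationError("features must satisfy start < end")
        self.df = (
            self.df.sort_values(["chrom", "start", "end"], kind="stable")
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, records, kind: str) -> "FeatureSet":
        """Build from an iterable of (chrom, start, end[, name]) tuples."""
        rows = []
        for i, rec in enumerate(records):
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            name = rec[3] if len(rec) > 3 else f"{kind}_{i + 1}"
            rows.append((chrom, start, end, name))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        return cls(df=df, kind=kind)

    @classmethod
    def variants_from_positions(cls, positions) -> "FeatureSet":
        """Represent point variants as 1-bp half-open intervals."""
        recs = [(c, p, p + 1, n) for c, p, *rest in positions for n in [rest[0] if rest else f"var_{p}"]]
        return cls.from_records(recs, "variant")

    def on(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def __len__(self) -> int:
        return len(self.df)


def _as_intervals(items) -> list[tuple]:
    """Normalize items to (chrom, start, end) tuples.

    Accepts DomainCall-like objects, Window-like objects, tuples, or a
    DataFrame with chrom/start/end columns.
    """
    if isinstance(items, pd.DataFrame):
        return list(zip(items["chrom"], items["start"], items["end"]))
    out = []
    for it in items:
        if isinstance(it, (tuple, list)):
            out.append((it[0], int(it[1]), int(it[2])))
        else:
            out.append((it.chrom, int(it.start), int(it.end)))
    return out


def annotate_tss(
    items,
    tss: FeatureSet,
    promoter_window: int = 1000,
    upstream_only: bool = False,
) -> pd.DataFrame:
    """Label items promoter-proximal when their midpoint lies within
    ±``promoter_window`` bp of a TSS.

    The TSS position is the feature start.  With ``upstream_only`` the window
    is one-sided on the upstream flank of a stranded TSS (requires a
    ``strand`` column in the feature table).  Returns one row per item with
    the nearest TSS name, signed-distance magnitude, and the proximity flag.
    """
    if len(tss) == 0:
        raise ValidationError("TSS feature set is empty")
    ivals = _as_intervals(items)
    rows = []
    for chrom, start, end in ivals:
        mid = (start + end) // 2
        feats = tss.on(chrom)
        if feats.empty:
            rows.append((None, np.nan, False))
            continue
        pos = feats["start"].to_numpy()
        dist = np.abs(pos - mid)
        j = int(np.argmin(dist))
        d = int(dist[j])
        if upstream_only:
            strand = feats.iloc[j].get("strand", "+")
            delta = pos[j] - mid  # positive when item is left of the TSS
            upstream = delta >= 0 if strand == "+" else delta <= 0
            proximal = upstream and d <= promoter_window
        else:
            proximal = d <= promoter_window
        rows.append((feats.iloc[j]["name"], d, bool(proximal)))
    return pd.DataFrame(rows, columns=["nearest_tss", "tss_distance", "promoter_proximal"])


def overlap_peaks(items, peaks: FeatureSet) -> np.ndarray:
    """Boolean per item: non-empty half-open intersection with any peak."""
    ivals = _as_intervals(items)
    out = np.zeros(len(ivals), dtype=bool)
    for i, (chrom, start, end) in enumerate(ivals):
        feats = peaks.on(chrom)
        if feats.empty:
            continue
        out[i] = bool(
            ((feats["start"].to_numpy() < end) & (feats["end"].to_numpy() > start)).any()
        )
    return out


def nearest_peak_distance(positions, peaks: FeatureSet) -> np.ndarray:
    """Distance in bp from each point to the nearest peak (0 inside a peak).

    Distance is measured to the nearest covered base of the nearest peak.
    Positions on a chromosome with no peaks get NaN with a warning.
    """
    pts = [(p[0], int(p[1])) for p in positions]
    out = np.empty(len(pts), dtype=float)
    for i, (chrom, pos) in enumerate(pts):
        feats = peaks.on(chrom)
        if feats.empty:
            warnings.warn(f"no peaks on {chrom}; distance undefined", stacklevel=2)
            out[i] = np.nan
            continue
        starts = feats["start"].to_numpy()
        ends = feats["end"].to_numpy()
        d = np.maximum.reduce([starts - pos, pos - (ends - 1), np.zeros_like(starts)])
        out[i] = float(d.min())
    return out


def domain_overlap(calls_a, calls_b, tier: Optional[str] = None):
    """Venn summary of candidate domains between two genes.

    A domain is *shared* when it genomically intersects at least one domain
    called for the other gene; shared groups of mutually intersecting domains
    are counted once (connected components of the cross-intersection graph),
    so ``shared <= min(|A|, |B|)``.  Returns ``(counts, shared_intervals)``
    where counts is ``{"only_a", "shared", "only_b"}`` and shared_intervals
    are the merged pairwise intersections (symmetric under argument swap).
    """
    if tier is not None:
        calls_a = [c for c in calls_a if c.flags.get(tier)]
        calls_b = [c for c in calls_b if c.flags.get(tier)]
    a = _as_intervals(calls_a)
    b = _as_intervals(calls_b)

    # union-find over A ∪ B linked by cross-gene intersections
    parent = list(range(len(a) + len(b)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    pieces = []
    a_hit = [False] * len(a)
    b_hit = [False] * len(b)
    for i, (ca, sa, ea) in enumerate(a):
        for j, (cb, sb, eb) in enumerate(b):
            if ca == cb and sa < eb and sb < ea:
                union(i, len(a) + j)
                a_hit[i] = True
                b_hit[j] = True
                pieces.append((ca, max(sa, sb), min(ea, eb)))

    shared_roots = {find(i) for i in range(len(a)) if a_hit[i]}
    counts = {
        "only_a": sum(1 for h in a_hit if not h),
        "shared": len(shared_roots),
        "only_b": sum(1 for h in b_hit if not h),
    }
    return counts, merge_intervals(pieces)


def merge_intervals(intervals) -> list[tuple]:
    """Merge overlapping or abutting (chrom, start, end) intervals."""
    merged: list[list] = []
    for chrom, start, end in sorted(_as_intervals(intervals)):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(m) for m in merged]


def expression_correlation(x, y) -> dict:
    """Squared Pearson correlation of paired per-tissue expression values.

    Returns ``{"R2": ..., "p": ...}`` with the two-sided p-value of the
    correlation test.  Requires at least 3 finite pairs and non-zero variance
    in both genes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the genes")
    r, p = stats.pearsonr(x, y)
    return {"R2": float(r * r), "p": float(p)}
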