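"""Sliding-window differential guide abundance and domain calling.

Guides are aggregated into fixed-width sliding windows (default 2,000 bp,
step 500 bp) by target midpoint.  For a pairwise bin comparison the window
statistic T is the mean member-guide log2 fold change; its significance is an
empirical two-sided p-value against a size-matched null built by resampling
nontargeting-guide log2 fold changes.  Windows passing a permissive nominal
threshold are merged into candidate cis-regulatory domains with stringency
tier flags: nominal, on-target direction (enrichment in the lower-expression
bin, the expected CRISPRi consequence), and accessible-chromatin overlap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

#: The two pairwise bin comparisons: each lower-expression bin versus high.
DEFAULT_COMPARISONS = ("low_vs_high", "center_vs_high")


@dataclass
class ComparisonResult:
    """Statistics of one window under one bin comparison."""

    T: float
    p: float = float("nan")
    q: float = float("nan")

    @property
    def direction(self) -> int:
        return int(np.sign(self.T))


@dataclass
class Window:
    """One sliding window: genomic span, member tiling guides, statistics."""

    chrom: str
    start: int
    end: int
    guide_ids: tuple
    stats: dict = field(default_factory=dict)

    @property
    def n_guides(self) -> int:
        return len(self.guide_ids)


@dataclass
class DomainCall:
    """A maximal run of merged significant windows for one gene/comparison."""

    gene: Optional[str]
    comparison: str
    chrom: str
    start: int
    end: int
    min_p: float
    direction: int
    n_windows: int
    flags: dict


def assign_windows(
    library,
    region: tuple[int, int],
    window: int = 2000,
    step: int = 500,
    min_guides: int = 5,
) -> list[Window]:
    """Lay windows of width ``window`` every ``step`` bp across ``region``.

    A tiling guide belongs to every window containing its target midpoint;
    control guides are never members.  Windows with fewer than ``min_guides``
    members are dropped.
    """
    start, end = region
    if end <= start:
        raise ValidationError("region is empty")
    if not (window >= step >= 1):
        raise ValidationError("require window >= step >= 1")
    tiling = [g for g in library if g.category == "tiling" and g.midpoint is not None]
    if tiling:
        chrom = tiling[0].chrom
    else:
        chrom = "."
    mids = np.array([g.midpoint for g in tiling], dtype=np.int64)
    ids = np.array([g.guide_id for g in tiling], dtype=object)
    order = np.argsort(mids, kind="stable")
    mids, ids = mids[order], ids[order]

    out: list[Window] = []
    w_start = start
    while w_start + window <= end:
        lo = np.searchsorted(mids, w_start, side="left")
        hi = np.searchsorted(mids, w_start + window, side="left")
        members = tuple(sorted(ids[lo:hi]))
        if len(members) >= min_guides:
            out.append(Window(chrom, w_start, w_start + window, members))
        w_start += step
    return out


def guide_log2fc(table, sample_a: str, sample_b: str) -> pd.Series:
    """Per-guide log2 fold change of normalized abundance, a over b.

    Positive values mean enrichment in ``sample_a``.
    """
    if table.normalized is None:
        raise ValidationError("count table has no normalized abundances; normalize first")
    for s in (sample_a, sample_b):
        if s not in table.normalized.columns:
            raise KeyError(f"unknown sample label: {s!r}")
    a = table.normalized[sample_a]
    b = table.normalized[sample_b]
    return np.log2(a / b).rename(f"log2fc[{sample_a}/{sample_b}]")


def window_test(
    windows: Sequence[Window],
    guide_fc: pd.Series,
    null_guide_ids: Sequence[str],
    comparison: str = "low_vs_high",
    B: int = 10000,
    seed=None,
    statistic: str = "mean",
) -> list[Window]:
    """Fill T and empirical p for each window under one comparison.

    T is the mean member log2FC (``statistic="rank_sum"`` uses the mean rank
    of member guides within the pooled member+null values instead).  The null
    is built per window by resampling ``n_guides`` values, with replacement,
    from the nontargeting guides' log2FCs and recomputing the statistic B
    times; ``p = (1 + #{|T_b| >= |T|}) / (B + 1)`` so p is never 0.
    Deterministic for a fixed seed and invariant to library ordering.
    """
    null_ids = sorted(set(null_guide_ids))
    if not null_ids:
        raise ValidationError("empty nontargeting null pool")
    if len(null_ids) < 20:
        warnings.warn(
            f"null pool has only {len(null_ids)} guides; empirical p-values may be coarse",
            stacklevel=2,
        )
    if B < 1:
        raise ValidationError("B must be >= 1")
    if statistic not in ("mean", "rank_sum"):
        raise ValidationError(f"unknown statistic: {statistic!r}")
    null_vals = guide_fc.loc[null_ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    for w in sorted(windows, key=lambda w: (w.chrom, w.start, w.end)):
        member_vals = guide_fc.loc[list(w.guide_ids)].to_numpy(dtype=float)
        n = member_vals.shape[0]
        draw = null_vals[rng.integers(0, null_vals.shape[0], size=(B, n))]
        if statistic == "mean":
            T = float(member_vals.mean())
            null_T = draw.mean(axis=1)
        else:
            T = _rank_sum_stat(member_vals, null_vals)
            null_T = np.array([_rank_sum_stat(row, null_vals) for row in draw])
        p = (1.0 + np.count_nonzero(np.abs(null_T) >= abs(T))) / (B + 1.0)
        w.stats[comparison] = ComparisonResult(T=T, p=p)
    return list(windows)


def _rank_sum_stat(members: np.ndarray, null_vals: np.ndarray) -> float:
    """Centered mean rank of members within the pooled member+null sample."""
    pooled = np.concatenate([members, null_vals])
    ranks = pd.Series(pooled).rank().to_numpy()
    return float(ranks[: members.shape[0]].mean() - (pooled.shape[0] + 1) / 2.0)


def adjust_fdr(windows: Sequence[Window], comparisons: Optional[Sequence[str]] = None) -> list[Window]:
    """Benjamini–Hochberg adjustment across all tested windows, per comparison."""
    windows = list(windows)
    if comparisons is None:
        comparisons = sorted({c for w in windows for c in w.stats})
    for comp in comparisons:
        tested = [w for w in windows if comp in w.stats]
        if not tested:
            continue
        pvals = np.array([w.stats[comp].p for w in tested])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for w, q in zip(tested, qvals):
            w.stats[comp].q = float(q)
    return windows


def call_domains(
    windows: Sequence[Window],
    comparison: str = "low_vs_high",
    alpha: float = 0.05,
    require_direction: Optional[int] = 1,
    peaks=None,
    gene: Optional[str] = None,
    use_q: bool = False,
) -> list[DomainCall]:
    """Merge windows below ``alpha`` into candidate regulatory domains.

    Overlapping or abutting significant windows form one maximal interval.
    The call's direction is the sign of T at its best (minimum-p) window.
    Tier flags: ``nominal`` always set; ``on_target_direction`` set when the
    direction equals ``require_direction`` (positive T for a low-vs-high
    comparison means enrichment in the low-expression bin); ``atac_overlap``
    set when the interval intersects any peak in ``peaks``.
    """
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must lie in (0, 1]")
    sig = [
        w
        for w in windows
        if comparison in w.stats
        and (w.stats[comparison].q if use_q else w.stats[comparison].p) < alpha
    ]
    sig.sort(key=lambda w: (w.chrom, w.start, w.end))

    groups: list[list[Window]] = []
    for w in sig:
        if groups and w.chrom == groups[-1][-1].chrom and w.start <= max(
            x.end for x in groups[-1]
        ):
            groups[-1].append(w)
        else:
            groups.append([w])

    calls = []
    for grp in groups:
        best = min(
            grp,
            key=lambda w: (w.stats[comparison].p, -abs(w.stats[comparison].T), w.start),
        )
        res = best.stats[comparison]
        start = min(w.start for w in grp)
        end = max(w.end for w in grp)
        direction = res.direction
        flags = {
            "nominal": True,
            "on_target_direction": (
                require_direction is not None and direction == require_direction
            ),
            "atac_overlap": False,
        }
        if peaks is not None:
            from .annotate import overlap_peaks

            flags["atac_overlap"] = bool(
                overlap_peaks([(grp[0].chrom, start, end)], peaks)[0]
            )
        calls.append(
            DomainCall(
                gene=gene,
                comparison=comparison,
                chrom=grp[0].chrom,
                start=start,
                end=end,
                min_p=res.p,
                direction=direction,
                n_windows=len(grp),
                flags=flags,
            )
        )
    return calls


def filter_calls(calls: Sequence[DomainCall], tier: str) -> list[DomainCall]:
    """Keep calls whose ``tier`` flag is set (nominal / on_target_direction /
    atac_overlap)."""
    return [c for c in calls if c.flags.get(tier)]


def windows_frame(windows: Sequence[Window]) -> pd.DataFrame:
    """Flatten windows to one row per window per comparison."""
    rows = []
    for w in windows:
        for comp, res in sorted(w.stats.items()):
            rows.append(
                {
                    "chrom": w.chrom,
                    "start": w.start,
                    "end": w.end,
                    "n_guides": w.n_guides,
                    "comparison": comp,
                    "T": res.T,
                    "p": res.p,
                    "q": res.q,
                    "direction": res.direction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_guides", "comparison", "T", "p", "q", "direction"],
    )
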