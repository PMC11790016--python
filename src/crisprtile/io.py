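"""Readers and writers for the formats shared across the pipeline.

Library tables are TSV; features arrive as BED3+ or GFF3 (GFF3's 1-based
closed coordinates are converted to 0-based half-open on load); window scores
are exported as bedGraph; domain calls as BED with tier flags in the name
field.  Output files carry a comment header stamping the producing config
hash and seed when provided.
"""
from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import FeatureSet
from .errors import SchemaError, ValidationError
from .quant import CountTable
from .sim import CATEGORIES, GuideRecord
from .windows import DomainCall, Window, windows_frame

log = logging.getLogger("crisprtile")

LIBRARY_COLUMNS = ("guide_id", "spacer", "chrom", "start", "end", "strand", "category")

TRACK_FIELDS = ("T", "neglog10p")


def _header(config_hash: Optional[str], seed=None) -> str:
    if config_hash is None:
        return ""
    extra = f" seed={seed}" if seed is not None else ""
    return f"# crisprtile config_hash={config_hash}{extra}\n"


def write_library(library: Sequence[GuideRecord], path) -> None:
    rows = []
    for g in library:
        rows.append(
            {
                "guide_id": g.guide_id,
                "spacer": g.spacer,
                "chrom": g.chrom if g.chrom is not None else "",
                "start": "" if g.start is None else g.start,
                "end": "" if g.end is None else g.end,
                "strand": g.strand,
                "category": g.category,
            }
        )
    pd.DataFrame(rows, columns=list(LIBRARY_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_library(path) -> list[GuideRecord]:
    """Load and validate a library TSV; ambiguous matching keys are flagged.

    Raises a schema error naming any missing column and a validation error on
    duplicate guide ids.  Guides sharing a 15-mer key load successfully but
    are reported; quantification will route their reads to the ambiguous
    audit bucket.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": "string"})
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df["guide_id"].duplicated().any():
        dupes = df.loc[df["guide_id"].duplicated(), "guide_id"].unique()
        raise ValidationError(f"{path}: duplicate guide_id(s): {', '.join(map(str, dupes[:5]))}")
    library = []
    for rec in df.itertuples(index=False):
        chrom = None if pd.isna(rec.chrom) or rec.chrom == "" else str(rec.chrom)
        start = None if pd.isna(rec.start) else int(rec.start)
        end = None if pd.isna(rec.end) else int(rec.end)
        library.append(
            GuideRecord(
                guide_id=str(rec.guide_id),
                spacer=str(rec.spacer),
                chrom=chrom,
                start=start,
                end=end,
                strand=str(rec.strand),
                category=str(rec.category),
            )
        )
    keys = pd.Series([g.key for g in library])
    n_ambiguous = int(keys.duplicated(keep=False).sum())
    by_cat = {c: sum(1 for g in library if g.category == c) for c in CATEGORIES}
    log.info("loaded %d guides %s from %s", len(library), by_cat, path)
    if n_ambiguous:
        log.warning("%d guides share a 15-mer matching key (flagged ambiguous)", n_ambiguous)
    return library


def write_counts(table: CountTable, path, which: str = "raw", config_hash=None, seed=None) -> None:
    frame = table.raw if which == "raw" else table.normalized
    if frame is None:
        raise ValidationError(f"count table has no {which!r} matrix")
    with open(path, "w") as fh:
        fh.write(_header(config_hash, seed))
        frame.to_csv(fh, sep="\t")


def read_counts(path) -> CountTable:
    """Load a guide × sample raw count TSV (no read-level audit available)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no sample columns")
    return CountTable(raw=df.astype(np.int64))


def write_audit(table: CountTable, path, config_hash=None, seed=None) -> None:
    if table.audit is None:
        raise ValidationError("count table has no audit")
    with open(path, "w") as fh:
        fh.write(_header(config_hash, seed))
        table.audit.to_csv(fh, sep="\t")


_GFF_SUFFIXES = {".gff", ".gff3"}


def read_intervals(path, kind: str) -> FeatureSet:
    """Read features from BED3+ or GFF3 into a sorted FeatureSet.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    BED records with start >= end raise a validation error naming the line.
    """
    path = Path(path)
    if path.suffix.lower() in _GFF_SUFFIXES:
        return _read_gff3(path, kind)
    return _read_bed(path, kind)


def _read_bed(path: Path, kind: str) -> FeatureSet:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{ln}: BED record needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] else f"{kind}_{len(rows) + 1}"
            row = {"chrom": chrom, "start": start, "end": end, "name": name}
            if len(fields) > 5:
                row["strand"] = fields[5]
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name"])
    else:
        df = df.drop(columns=[c for c in ["strand"] if df[c].isna().all()])
    return FeatureSet(df=df, kind=kind)


_ATTR_RE = re.compile(r"(?:^|;)\s*(?:ID|Name)=([^;]+)")


def _read_gff3(path: Path, kind: str) -> FeatureSet:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        dtype={"seqid": str, "attributes": str},
    )
    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        m = _ATTR_RE.search(rec.attributes or "")
        name = m.group(1) if m else f"{kind}_{i + 1}"
        rows.append(
            {
                "chrom": rec.seqid,
                "start": int(rec.start) - 1,  # 1-based closed -> 0-based half-open
                "end": int(rec.end),
                "name": name,
                "strand": rec.strand,
            }
        )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return FeatureSet(df=out, kind=kind)


def write_features_bed(features: FeatureSet, path) -> None:
    with open(path, "w") as fh:
        for rec in features.df.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\n")


def write_track(
    windows: Sequence[Window],
    field: str,
    path,
    comparison: str = "low_vs_high",
    config_hash=None,
    seed=None,
) -> None:
    """Write a per-window bedGraph of T or −log10 p for one comparison.

    Overlapping windows are emitted as-is: the track is per-window, not
    per-base.
    """
    if field not in TRACK_FIELDS:
        raise ValidationError(f"unknown track field {field!r}; expected one of {TRACK_FIELDS}")
    with open(path, "w") as fh:
        fh.write(_header(config_hash, seed))
        fh.write(f'track type=bedGraph name="{comparison}.{field}"\n')
        for w in sorted(windows, key=lambda w: (w.chrom, w.start, w.end)):
            if comparison not in w.stats:
                continue
            res = w.stats[comparison]
            value = res.T if field == "T" else -math.log10(res.p)
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{value:.6g}\n")


def read_track(path) -> list[tuple]:
    """Re-parse a bedGraph written by :func:`write_track`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append((chrom, int(start), int(end), float(value)))
    return out


def write_windows_tsv(windows: Sequence[Window], path, config_hash=None, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_hash, seed))
        windows_frame(windows).to_csv(fh, sep="\t", index=False)


_FLAG_ORDER = ("nominal", "on_target_direction", "atac_overlap")


def write_domains_bed(calls: Sequence[DomainCall], path, config_hash=None, seed=None) -> None:
    """Domain calls as BED6+1: name carries gene|comparison|flags, score is
    −100·log10(min p) capped at 1000, strand encodes direction, column 7 the
    exact min p."""
    with open(path, "w") as fh:
        fh.write(_header(config_hash, seed))
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.comparison)):
            flags = ",".join(f for f in _FLAG_ORDER if c.flags.get(f))
            name = f"{c.gene or '.'}|{c.comparison}|{flags or 'none'}"
            score = min(1000, int(round(-100.0 * math.log10(c.min_p))))
            strand = "+" if c.direction >= 0 else "-"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{score}\t{strand}\t{c.min_p!r}\n"
            )


def read_domains_bed(path) -> list[DomainCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            gene, comparison, flag_str = fields[3].split("|")
            flags = {f: False for f in _FLAG_ORDER}
            if flag_str != "none":
                for f in flag_str.split(","):
                    flags[f] = True
            calls.append(
                DomainCall(
                    gene=None if gene == "." else gene,
                    comparison=comparison,
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    min_p=float(fields[6]) if len(fields) > 6 else math.nan,
                    direction=1 if fields[5] == "+" else -1,
                    n_windows=0,
                    flags=flags,
                )
            )
    return calls
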