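"""Guide quantification from per-bin sequencing reads.

A pooled CRISPRi screen is read out by amplicon sequencing of the integrated
guide cassette in each sorted cell population.  Every read that derives from a
guide contains the 20 nt protospacer followed immediately by the constant
scaffold sequence, so the guide identity can be recovered by text search: find
the scaffold anchor, take the 15 nt immediately upstream, and look that key up
in the library.  The 15-mer proximal to the scaffold (the 3' end of the
protospacer) is the matching key; two library guides sharing a key are flagged
ambiguous and their reads are audited but never counted toward either guide.

Counts are normalized to abundance per million reads (CPM) with an optional
pseudocount, and a sample-level PCA is provided as a quality-control summary
of bin separation.
"""
from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import DegenerateSampleError, FastqParseError, ValidationError

#: Constant scaffold sequence immediately downstream of the protospacer in the
#: guide expression cassette; used to locate the spacer within a read.
SCAFFOLD_ANCHOR = "GTTTAAGAGCTATGCTGGAA"

#: Length of the synthesized protospacer.
SPACER_LENGTH = 20

#: Length of the matching key: the spacer suffix proximal to the scaffold.
KEY_LENGTH = 15

AUDIT_COLUMNS = ("total_reads", "anchored", "matched", "ambiguous", "unmatched")


@dataclass
class CountTable:
    """Guide × sample abundances.

    Attributes
    ----------
    raw : pandas.DataFrame
        Integer read counts, guides as rows, samples as columns.
    audit : pandas.DataFrame or None
        Per-sample read accounting with columns ``total_reads``, ``anchored``,
        ``matched``, ``ambiguous``, ``unmatched``.  Satisfies
        ``anchored == matched + ambiguous + unmatched``.  ``None`` when counts
        were loaded from a table without read-level provenance.
    normalized : pandas.DataFrame or None
        Abundance per million reads; filled by :func:`normalize_counts`.
    pseudocount : float or None
        Pseudocount used to fill ``normalized``.
    fastq_paths : dict or None
        Paths of FASTQ files written alongside simulated counts, if any.
    """

    raw: pd.DataFrame
    audit: Optional[pd.DataFrame] = None
    normalized: Optional[pd.DataFrame] = None
    pseudocount: Optional[float] = None
    fastq_paths: Optional[dict] = None

    @property
    def guides(self) -> list:
        return list(self.raw.index)

    @property
    def samples(self) -> list:
        return list(self.raw.columns)

    @property
    def depth(self) -> pd.Series:
        """Total matched reads per sample (column sums of ``raw``)."""
        return self.raw.sum(axis=0)


def spacer_key(spacer: str) -> str:
    """Matching key of a spacer: the 15 nt proximal to the scaffold."""
    return spacer[-KEY_LENGTH:]


def library_key_index(library) -> tuple[dict, set]:
    """Map matching keys to guide ids; return also the set of ambiguous keys.

    A key claimed by more than one guide is ambiguous: reads carrying it are
    counted in the audit but attributed to no guide.
    """
    key_to_guide: dict[str, str] = {}
    ambiguous: set[str] = set()
    for g in library:
        k = spacer_key(g.spacer)
        if k in key_to_guide and key_to_guide[k] != g.guide_id:
            ambiguous.add(k)
        else:
            key_to_guide[k] = g.guide_id
    return key_to_guide, ambiguous


def extract_spacer(read_seq: str, hamming1_anchor: bool = False) -> Optional[str]:
    """Return the 15-mer immediately upstream of the first scaffold anchor.

    Returns ``None`` when the anchor is absent or fewer than 15 bases precede
    it.  With ``hamming1_anchor`` the search falls back to a single-mismatch
    anchor scan when no exact occurrence exists (off by default; exact text
    search is the reference behavior).
    """
    i = read_seq.find(SCAFFOLD_ANCHOR)
    if i < 0 and hamming1_anchor:
        i = _find_anchor_hamming1(read_seq)
    if i < KEY_LENGTH:  # covers "not found" (-1) and insufficient upstream
        return None
    return read_seq[i - KEY_LENGTH : i]


def _find_anchor_hamming1(seq: str) -> int:
    n, m = len(seq), len(SCAFFOLD_ANCHOR)
    for i in range(n - m + 1):
        mismatches = 0
        for a, b in zip(seq[i : i + m], SCAFFOLD_ANCHOR):
            if a != b:
                mismatches += 1
                if mismatches > 1:
                    break
        if mismatches <= 1:
            return i
    return -1


def _iter_fastq(path) -> Iterable[str]:
    """Yield read sequences from a FASTQ(.gz) file.

    Malformed records raise :class:`FastqParseError` naming the record number.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "rt") as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                _title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ at record {n + 1}: {exc}"
                ) from exc
            n += 1
            yield seq


def count_guides(
    fastq_per_sample: Mapping[str, object],
    library,
    hamming1_anchor: bool = False,
) -> CountTable:
    """Count guides per sample by text-search spacer extraction.

    Parameters
    ----------
    fastq_per_sample : mapping of sample label to FASTQ path (or list of paths)
    library : sequence of guide records (``guide_id``, ``spacer`` attributes)
    hamming1_anchor : allow one mismatch in the scaffold anchor (default off)
    """
    key_to_guide, ambiguous_keys = library_key_index(library)
    guide_ids = [g.guide_id for g in library]
    raw_cols = {}
    audit_rows = {}
    for sample, paths in fastq_per_sample.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        counts: Counter = Counter()
        total = anchored = matched = ambiguous = unmatched = 0
        for path in paths:
            for seq in _iter_fastq(path):
                total += 1
                key = extract_spacer(seq, hamming1_anchor=hamming1_anchor)
                if key is None:
                    continue
                anchored += 1
                if key in ambiguous_keys:
                    ambiguous += 1
                elif key in key_to_guide:
                    matched += 1
                    counts[key_to_guide[key]] += 1
                else:
                    unmatched += 1
        raw_cols[sample] = [counts.get(g, 0) for g in guide_ids]
        audit_rows[sample] = [total, anchored, matched, ambiguous, unmatched]
    raw = pd.DataFrame(raw_cols, index=pd.Index(guide_ids, name="guide_id"), dtype=np.int64)
    audit = pd.DataFrame.from_dict(
        audit_rows, orient="index", columns=list(AUDIT_COLUMNS)
    ).rename_axis("sample")
    return CountTable(raw=raw, audit=audit)


def concat_tables(tables: Sequence[CountTable]) -> CountTable:
    """Concatenate tables sample-wise (shared guide index required)."""
    if not tables:
        raise ValidationError("no tables to concatenate")
    raw = pd.concat([t.raw for t in tables], axis=1)
    if raw.isna().any().any():
        raise ValidationError("tables do not share a guide index")
    audits = [t.audit for t in tables]
    audit = pd.concat(audits) if all(a is not None for a in audits) else None
    fastqs: dict = {}
    for t in tables:
        if t.fastq_paths:
            fastqs.update(t.fastq_paths)
    return CountTable(raw=raw.astype(np.int64), audit=audit, fastq_paths=fastqs or None)


def normalize_counts(table: CountTable, pseudocount: float = 0.5) -> CountTable:
    """Fill per-million normalized abundances.

    ``normalized[g, s] = 1e6 * (raw[g, s] + pc) / (depth[s] + pc * n_guides)``

    With ``pseudocount == 0`` each column sums exactly to 1e6.  A zero-depth
    sample is degenerate and rejected.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    depth = table.depth
    zero = [str(s) for s in depth.index[depth == 0]]
    if zero:
        raise DegenerateSampleError(
            "zero sequencing depth in sample(s): " + ", ".join(zero)
        )
    n_guides = table.raw.shape[0]
    normalized = 1e6 * (table.raw + pseudocount) / (depth + pseudocount * n_guides)
    return replace(table, normalized=normalized, pseudocount=pseudocount)


@dataclass
class PCAResult:
    """Sample coordinates on principal components plus variance fractions."""

    coordinates: pd.DataFrame  # samples × components
    variance_ratio: np.ndarray


def qc_pca(table: CountTable, n_components: Optional[int] = None) -> PCAResult:
    """PCA of log2 normalized abundance across samples (QC for bin separation).

    Samples are observations, guides are features.  Components are ordered by
    explained variance; variance fractions sum to at most 1.
    """
    from sklearn.decomposition import PCA

    if table.raw.shape[1] < 2:
        raise ValidationError("PCA requires at least 2 samples")
    t = table if table.normalized is not None else normalize_counts(table)
    X = np.log2(t.normalized.to_numpy(dtype=float)).T
    k = n_components or max(1, min(X.shape[0] - 1, X.shape[1]))
    centered = X - X.mean(axis=0)
    if np.allclose(centered, 0):
        coords = np.zeros((X.shape[0], k))
        ratio = np.zeros(k)
    else:
        pca = PCA(n_components=k, svd_solver="full")
        coords = pca.fit_transform(X)
        ratio = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    frame = pd.DataFrame(coords, index=t.raw.columns, columns=cols).rename_axis("sample")
    return PCAResult(coordinates=frame, variance_ratio=np.asarray(ratio))
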