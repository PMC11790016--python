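"""End-to-end orchestration: simulate → count → analyze → annotate → overlap.

Every source of randomness is derived from the single config seed through a
seed tree, so re-running the same config is bit-identical.  Each output file
is stamped with the config hash; the run summary records the read-conservation
identities from quantification.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import annotate as ann
from . import io as tio
from . import quant, sim, windows as win
from .config import RunConfig
from .errors import CrisprTileError

log = logging.getLogger("crisprtile")

OVERLAP_TIERS = ("nominal", "on_target_direction", "atac_overlap")


@dataclass
class PipelineResult:
    """In-memory handles plus paths of everything a run produced."""

    config_hash: str
    outdir: Path
    paths: dict = field(default_factory=dict)
    library: list = field(default_factory=list)
    table: Optional[quant.CountTable] = None
    windows: dict = field(default_factory=dict)  # gene -> list[Window]
    calls: dict = field(default_factory=dict)  # (gene, comparison) -> list[DomainCall]
    overlap: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, outdir) -> PipelineResult:
    """Execute all stages of a screen run into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    result = PipelineResult(config_hash=chash, outdir=outdir)
    simc, anac, annc = config.simulate, config.analysis, config.annotate
    genes = simc.genes
    n_seeds = 1 + len(genes) * (2 + len(anac.comparisons))
    seeds = iter(np.random.SeedSequence(config.seed).spawn(n_seeds))

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CrisprTileError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    # --- simulate ---------------------------------------------------------
    log.info("simulate: library of %d+%d+%d guides over %s:%d-%d",
             simc.n_tiling, simc.n_nontargeting, simc.n_nonexpressed,
             simc.chrom, simc.region_start, simc.region_end)
    library = _stage(
        "simulate",
        sim.build_library,
        simc.region,
        simc.n_tiling,
        simc.n_nontargeting,
        simc.n_nonexpressed,
        seed=next(seeds),
        chrom=simc.chrom,
        jitter=simc.jitter,
    )
    result.library = library
    result.paths["library"] = outdir / "library.tsv"
    tio.write_library(library, result.paths["library"])

    tables = []
    test_seeds: dict = {}
    for gene in genes:
        truth_path = outdir / f"truth_{gene.name}.bed"
        sim.write_truth(gene.elements, truth_path)
        result.paths[f"truth_{gene.name}"] = truth_path
        pop = _stage(
            "simulate", sim.simulate_cells, library, gene.elements, simc.n_cells,
            simc.expr_cv, next(seeds), control_cv=simc.control_cv,
        )
        tallies = _stage("simulate", sim.sort_cells, pop)
        table_g = _stage(
            "simulate", sim.sequence_bins, tallies, simc.depth_per_bin, next(seeds),
            library=library,
            fastq_dir=(outdir / "fastq") if simc.write_fastq else None,
            sample_prefix=gene.name,
        )
        tables.append(table_g)
        test_seeds[gene.name] = [next(seeds) for _ in anac.comparisons]
    table = quant.concat_tables(tables)

    # --- count ------------------------------------------------------------
    if simc.write_fastq:
        log.info("count: re-quantifying %d samples from FASTQ", len(table.samples))
        table = _stage("count", quant.count_guides, table.fastq_paths, library)
    table = _stage("count", quant.normalize_counts, table, anac.pseudocount)
    result.table = table
    result.paths["counts"] = outdir / "counts.tsv"
    tio.write_counts(table, result.paths["counts"], "raw", chash, config.seed)
    result.paths["normalized"] = outdir / "counts_normalized.tsv"
    tio.write_counts(table, result.paths["normalized"], "normalized", chash, config.seed)
    result.paths["audit"] = outdir / "audit.tsv"
    tio.write_audit(table, result.paths["audit"], chash, config.seed)
    if table.audit is not None:
        conserved = bool(
            (
                table.audit["anchored"]
                == table.audit[["matched", "ambiguous", "unmatched"]].sum(axis=1)
            ).all()
        )
        log.info("count: read conservation identity holds: %s", conserved)
    else:
        conserved = None

    pca = _stage("count", quant.qc_pca, table)
    result.paths["pca"] = outdir / "pca.tsv"
    frame = pca.coordinates.copy()
    with open(result.paths["pca"], "w") as fh:
        fh.write(f"# crisprtile config_hash={chash} seed={config.seed}\n")
        fh.write("# variance_ratio=" + ",".join(f"{v:.6g}" for v in pca.variance_ratio) + "\n")
        frame.to_csv(fh, sep="\t")

    # --- annotate inputs --------------------------------------------------
    peaks = tio.read_intervals(annc.peaks, "atac_peak") if annc.peaks else None
    tss = tio.read_intervals(annc.tss, "tss") if annc.tss else None

    # --- analyze ----------------------------------------------------------
    null_ids = [g.guide_id for g in library if g.category == "nontargeting"]
    for gene in genes:
        wins = _stage(
            "analyze", win.assign_windows, library, simc.region,
            anac.window, anac.step, anac.min_guides,
        )
        for comp, test_seed in zip(anac.comparisons, test_seeds[gene.name]):
            bin_a, _, bin_b = comp.partition("_vs_")
            fc = _stage(
                "analyze", win.guide_log2fc, table,
                f"{gene.name}_{bin_a}", f"{gene.name}_{bin_b}",
            )
            _stage(
                "analyze", win.window_test, wins, fc, null_ids,
                comparison=comp, B=anac.B, seed=test_seed, statistic=anac.statistic,
            )
        win.adjust_fdr(wins)
        result.windows[gene.name] = wins
        log.info("analyze: %s — %d windows tested", gene.name, len(wins))
        path = outdir / f"windows_{gene.name}.tsv"
        tio.write_windows_tsv(wins, path, chash, config.seed)
        result.paths[f"windows_{gene.name}"] = path
        for comp in anac.comparisons:
            for field_name in tio.TRACK_FIELDS:
                tpath = outdir / f"track_{gene.name}_{comp}_{field_name}.bedgraph"
                tio.write_track(wins, field_name, tpath, comp, chash, config.seed)
                result.paths[f"track_{gene.name}_{comp}_{field_name}"] = tpath
            calls = _stage(
                "analyze", win.call_domains, wins, comp,
                alpha=anac.alpha, require_direction=anac.require_direction,
                peaks=peaks, gene=gene.name,
            )
            result.calls[(gene.name, comp)] = calls
            dpath = outdir / f"domains_{gene.name}_{comp}.bed"
            tio.write_domains_bed(calls, dpath, chash, config.seed)
            result.paths[f"domains_{gene.name}_{comp}"] = dpath
            if tss is not None and calls:
                annotated = ann.annotate_tss(calls, tss, annc.promoter_window)
                apath = outdir / f"domains_{gene.name}_{comp}_tss.tsv"
                annotated.to_csv(apath, sep="\t", index=False)
                result.paths[f"domains_{gene.name}_{comp}_tss"] = apath

    # --- overlap ----------------------------------------------------------
    overlap_doc: dict = {"config_hash": chash, "seed": config.seed}
    if len(genes) >= 2:
        g_a, g_b = genes[0].name, genes[1].name
        overlap_doc["genes"] = [g_a, g_b]
        tiers = list(OVERLAP_TIERS) if peaks is not None else list(OVERLAP_TIERS[:2])
        comparisons_doc = {}
        for comp in anac.comparisons:
            tier_doc = {}
            for tier in tiers:
                counts, shared = _stage(
                    "overlap", ann.domain_overlap,
                    result.calls[(g_a, comp)], result.calls[(g_b, comp)], tier,
                )
                tier_doc[tier] = {
                    **counts,
                    "shared_intervals": [list(s) for s in shared],
                }
            comparisons_doc[comp] = tier_doc
        overlap_doc["comparisons"] = comparisons_doc
        result.overlap = overlap_doc
    result.paths["overlap"] = outdir / "overlap.json"
    with open(result.paths["overlap"], "w") as fh:
        json.dump(overlap_doc, fh, sort_keys=True, indent=2)
        fh.write("\n")

    # --- summary ----------------------------------------------------------
    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_guides": len(library),
        "n_samples": len(table.samples),
        "read_conservation_ok": conserved,
        "n_windows": {g.name: len(result.windows[g.name]) for g in genes},
        "n_domains": {
            f"{g}|{c}": len(v) for (g, c), v in sorted(result.calls.items())
        },
        "outputs": sorted(str(p.relative_to(outdir)) for p in result.paths.values()),
    }
    result.paths["summary"] = outdir / "summary.json"
    with open(result.paths["summary"], "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    log.info("run complete: %s", outdir)
    return result
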