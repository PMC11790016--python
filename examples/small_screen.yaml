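# A 50 kb two-gene CRISPRi tiling screen, simulated end to end.
# Guide density (12/kb), sorting gates, sequencing depth (>250 reads per
# guide) and the 2 kb sliding-window analysis mirror the screen design this
# package models, at desk scale.
seed: 11
simulate:
  chrom: chr3
  region_start: 23000000
  region_end: 23050000
  n_tiling: 600
  n_nontargeting: 120
  n_nonexpressed: 60
  n_cells: 30000
  depth_per_bin: 120000
  expr_cv: 0.3
  control_cv: 0.1
  write_fastq: true
  genes:
    - name: UBE2E2
      elements:
        - {start: 23010000, end: 23011000, effect: 0.6}   # shared repressive element
        - {start: 23030000, end: 23031000, effect: -0.5}  # paradoxical activator
    - name: UBE2E1
      elements:
        - {start: 23010200, end: 23011200, effect: 0.5}   # overlaps the shared element
        - {start: 23040000, end: 23041000, effect: 0.6}   # gene-specific element
analysis:
  window: 2000
  step: 500
  min_guides: 5
  alpha: 0.05
  pseudocount: 0.5
  B: 2000
  comparisons: [low_vs_high, center_vs_high]
  require_direction: 1
annotate:
  peaks: atac_peaks.bed
  tss: gene_models.gff3
  promoter_window: 1000
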