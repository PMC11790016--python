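# Methods

## The generative model

The simulator (`crisprtile.sim`) emulates a FACS-bin CRISPRi tiling screen
closely enough that the downstream statistics can be validated against
planted ground truth, while staying deliberately simple where the biology is
not identifiable from this kind of data.

**Library.** Tiling guides are evenly spaced across the screened region with
uniform positional jitter (default: a quarter of the spacing), each with a
20 bp target footprint; nontargeting and nonexpressed-promoter controls
carry no coordinates. Spacers are random 20-mers constrained to have unique
15-mer scaffold-proximal matching keys, with a bounded retry budget
(generation fails loudly rather than silently degrading). The real screen
this design models tiled a 2 Mb locus at ~46 guides/kb with thousands of
both control classes; the desk-scale defaults used in tests and examples
keep the same structure at 12–20 guides/kb over 50–300 kb windows.

**Cells.** Every cell carries exactly one guide drawn uniformly. This
collapses low-MOI transduction plus selection (at MOI ~0.3 most transduced
cells carry a single integration) into the identifiable case; modeling
multiple integrations would confound guide effects without changing what
the statistics can recover. Baseline target expression is log-normal with
mean 1 and coefficient of variation `expr_cv` (default 0.3, a typical
mammalian expression CV). A cell whose guide midpoint lies inside a planted
element has expression multiplied by `1 − effect` (multiplicative across
overlapping elements); `effect = 1` silences completely, negative effects
model paradoxical activation through sequestration of repressive factors.
The ratio readout divides by a control-gene signal, modeled as independent
multiplicative log-normal noise (`control_cv`, default 0.1) — the simplest
strictly positive ratio model.

**Sorting.** Cells are ranked ascending by the ratio with ties broken by
stable cell index; gate `(a, b)` captures ranked positions
`[floor(a·n), floor(b·n))`. Floor boundaries and stable ties make sorting
exactly reproducible, which the gate-arithmetic and determinism tests rely
on. Defaults are the screen's gates: low 0–15%, center 35–65%, high
85–100%.

**Sequencing.** Per-bin counts are multinomial over the cell tallies at a
fixed depth; a Dirichlet-multinomial option adds overdispersion but is off
by default so the null-calibration tests run against a clean sampling model.
Optional FASTQ output embeds each spacer between a random 0–10 nt prefix
and the scaffold anchor, error-free with constant quality, so text-search
quantification can be validated read-for-read. Default depths in the
bundled configurations give ≳150–600 reads per guide per bin, consistent
with the >250 reads/guide average the screen design calls for.

**What the simulator does not model** — and hence what passing tests do not
show about real data: sequencing errors and quality variation, PCR jackpot
effects beyond multinomial noise, guide efficacy variation and off-target
activity, CRISPRi spreading beyond the guide midpoint, doxycycline
induction kinetics, staining/probe chemistry, and sorter impurity. The
analysis is expected to be robust to several of these (the empirical null
absorbs any noise shared between tiling and control guides), but that
robustness is not demonstrated here.

## The window test

The statistic is the mean member-guide log2 fold change; its null is built
by drawing, with replacement, size-matched sets from the nontargeting
guides' log2FCs and re-averaging, `B` times (default 10,000; 2,000 in the
bundled configurations). The two-sided empirical p uses the +1 correction,
so the smallest attainable value is `1/(B+1)`. This test was chosen because
it is assumption-light (no distributional form for guide-level log2FCs),
size-matched (window size enters the null directly), and exactly testable
(a degenerate null forces `p = 1`; an extreme window forces the floor). A
rank-sum variant is available via `statistic="rank_sum"` for heavy-tailed
count noise. Each window draws its own independent resampling matrix:
sharing draws across equal-sized windows would be cheaper but correlates
p-values within a screen, which the calibration checks would then
understate.

Windows default to 2,000 bp every 500 bp with at least 5 member guides; a
guide belongs to every window containing its midpoint (literal sliding-
window semantics, no partitioning). Setting `step = window` gives the
disjoint windows used for calibration. Only the two lower-expression bins
are each compared against the high bin; low-vs-center is not computed, as
it contrasts two partially suppressed populations and adds multiplicity
without a clear on-target interpretation.

Calls merge overlapping or abutting nominally significant windows
(`p < 0.05` strictly, the permissive first tier); the merged call inherits
direction from its minimum-p window (ties: larger |T|, then leftmost).
Benjamini–Hochberg q-values are computed per comparison across all tested
windows and can drive calling via `use_q`, but the nominal tier is the
default first filter, refined by the direction and chromatin-accessibility
tiers rather than by a stricter threshold.

## Conventions and numerical choices

- Coordinates are 0-based half-open throughout; GFF3 input is converted on
  load. Variants are 1 bp half-open intervals.
- TSS proximity uses the item midpoint and a symmetric ±1,000 bp window;
  a strand-aware upstream-only mode is available behind a flag, since
  regulatory screens routinely find signal on both flanks of a promoter.
- Distance from a position to a peak is the distance to the nearest covered
  base (0 inside a peak).
- Two-gene Venn counts: a domain is "shared" when it intersects ≥1 domain
  of the other gene; mutually intersecting groups count once (connected
  components), so `shared ≤ min(|A|, |B|)`. Shared intervals are the merged
  pairwise intersections and are symmetric under argument swap.
- CPM pseudocount 0.5 by default, so dropout guides have finite log2FCs;
  with pseudocount 0, normalized columns sum to exactly 10^6.
- Anchor matching is exact, first occurrence only; a Hamming-1 fallback
  exists behind a flag but is off so that quantification remains bitwise
  comparable to a naive substring scan.
- All randomness flows from one seed through a `SeedSequence` tree; file
  outputs avoid timestamps (gzip mtime fixed at 0), so a rerun of the same
  configuration is byte-identical.

## Problem sizes used in validation

Null calibration runs 20 replicate screens over 300 kb (1,200 tiling + 400
nontargeting guides, 40,000 cells, 5×10^5 reads/bin, 150 disjoint 2 kb
windows, `B = 2000`), pooling both comparisons. Element recovery and
direction checks use a 50 kb region at 20 guides/kb with a 1 kb planted
element (~20 member guides), 2×10^5 cells and 2×10^6 reads/bin over 20
seeds. These sizes make the checks sharp: recovery is essentially
deterministic, and the monotonicity check across effects 0.2–0.8 saturates
at the empirical-p floor for every effect — at this density and depth even a
20% expression shift is overwhelming evidence, so the non-decreasing check
binds only at substantially lower power. The sorting-based readout is
intrinsically sensitive: a modest multiplicative shift in expression moves a
large fraction of carrier cells across a percentile gate, which is the
design reason such screens work at all.

## Known limitations

- The empirical null assumes nontargeting guides are exchangeable with
  tiling guides under no effect; plate/batch structure that breaks this
  exchangeability is not modeled.
- Effect sizes of planted elements are not deconvolved from window
  statistics; `T` is a detection statistic, not an effect estimate.
- Overlapping windows are tested without accounting for their correlation;
  nominal p-values are calibrated marginally (verified on disjoint
  windows), and the q-values treat windows as independent.
- Guides are point-assigned by midpoint; a guide whose footprint straddles
  a window boundary contributes to membership solely via its midpoint.
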