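# Methods

This note records the models, conventions and numerical choices behind
`conscan`, and what the synthetic validation does and does not show.

## Coordinate conventions

All intervals are 0-based half-open internally; GFF3 (1-based closed) and
BED (0-based half-open) are converted at the file boundary. A gene's TSS
is its 5′-most transcribed position; multi-isoform genes collapse to the
5′-most TSS (the common promoter-scan convention — which representative
transcript the original analyses of this kind used is rarely stated, so
this is a deliberate, documented choice). Promoter sequences are handed
out 5′→3′ with respect to the gene, so a sequence offset `o` maps to the
TSS-relative coordinate `o − upstream_bp` on both strands; hit offsets are
reported TSS-relative with upstream negative. The promoter window covers
TSS-relative `[-upstream, +downstream)`: on the + strand the genomic
interval `[tss − up, tss + down)`, on the − strand
`[tss − down + 1, tss + up + 1)`, clipped to the chromosome with the
clipped spans recorded.

## Pairwise alignment

Orthologous promoters are aligned with a global affine-gap (Gotoh)
dynamic program: match +1, mismatch −1, first base of a gap −5, each
further base −1. These constants are configurable; the defaults penalize
gap opening heavily because the conserved blocks of interest are
substitution-dominated. Traceback tie-breaks are deterministic: diagonal,
then gap-in-B, then gap-in-A, and opening beats extending on equal score.
`N` mismatches everything.

The DP kernel (numba) stores a diagonal band: row `i` covers columns
`|j − i| ≤ band`, widened automatically to at least the length difference.
`band=None` computes the exact full alignment and is what the
small-string exhaustive-enumeration tests exercise; the pipeline default
(`align_band=100`) is appropriate for near-collinear orthologous windows
and makes a 15 kb pair align in milliseconds. A band can in principle
miss the optimum for sequences with very large structural offsets; such
promoter pairs are outside this tool's scope.

## Conserved-region extraction

Percent identity over a column range is
`100 × (matching non-gap, non-N columns) / (all columns)` — gaps and N
count in the denominator and never as matches, the conservative choice,
which makes every reported identity exactly recomputable from the raw
alignment. Extraction slides a 100-column window in 10-column steps
(window > threshold strictly), merges overlapping marked windows, strips
non-match flank columns, then greedily trims whichever end column leaves
the higher identity until the merged region's *overall* identity is
strictly above the threshold; merged regions shorter than 50 bp
(species-A span) are dropped. Window, step and minimum-length values are
module defaults chosen so a single ~100 bp conserved element is
recoverable; the ~2 kb aggregate conserved span seen in real mammalian
promoter comparisons is an empirical observation, not an enforced
constraint — the per-gene total is simply reported. Genes with no
ortholog are skipped by the filter, flagged `no_ortholog`, and can never
acquire hits in conservation-filtered mode.

If the requested window exceeds the alignment length, the whole alignment
is treated as the single window. Raising the identity threshold can only
shrink the reported conserved span (tested as a monotonicity property).

## PWM scoring and empirical calibration

The PFM plus a 0.25-per-cell pseudocount gives column probabilities;
log₂-odds are taken against the background composition (uniform by
default, overridable with e.g. the negative-set composition). A window's
match score is min-max normalized between the matrix's minimum and
maximum attainable log-odds sums, making thresholds comparable across
motifs; the consensus scores exactly 1, the anti-consensus exactly 0.
Windows containing `N` are unscorable (−∞), never background-imputed.
Both strands are always scanned; overlapping hits are kept separate.

The score cutoff is calibrated on a motif-free negative-control set
(the field's stand-in here: second-exon-like sequence, ~1.5 Mbp). With
`S` the pooled multiset of all window scores on both strands and
`N_allow = ⌊rate × total_bp / 10⁴⌋`, the threshold is the smallest score
in `S ∪ {1.0}` with `|{s ≥ t}| ≤ N_allow` — exact order statistics, no
grid, so `achieved_rate ≤ allowed_rate` holds by construction on the
calibration set. The per-10-kbp denominator is sequence bp, not 2× for
strands (a module convention; whether the original rule counted strands
jointly is unknowable from the published description). If even the
maximal score is attained too often, the threshold is set just above it
and noted. Transfer to independent sequence of the same composition is a
sampling question; the acceptance check allows three binomial standard
errors.

## Expression arithmetic and the DE gate

`FPKM[g,s] = counts[g,s] / ((length_bp[g]/10³) × (library_size[s]/10⁶))`,
with library sizes defaulting to column sums. Fold change is pooled-KO /
pooled-WT FPKM with a 0.1 floor applied first, keeping ratios finite for
silent genes without dropping them.

Replicate QC mirrors the r > 0.9 pooling rule: Pearson correlation of
per-gene FPKM for every within-genotype replicate pair, pooling (summing)
counts only when all pairs pass. Two refinements matter at small scale.
First, the gate compares the Fisher-z 95% upper confidence bound of each
r against the cutoff: on a genome-scale panel (where the rule originated)
the bound is indistinguishable from r, while on a 40-gene synthetic panel
the raw estimate has sampling error ≈ 1/√(n−3) ≈ 0.16 z-units and would
halt ~10% of perfectly healthy runs; the bound halts only replicates that
are convincingly uncorrelated. Second, the synthetic pipeline computes
the correlation on log1p(FPKM) (`qc_log`, switchable): on a small panel
the linear-scale Pearson is dominated by the one or two most-expressed
genes. On real genome-scale tables the linear-scale raw rule and this
gate agree.

Differential-expression *testing* is deliberately not reimplemented — in
the real workflow the p-values come from an external DE tool and enter as
an input column; classification is strict `p < 0.05`, direction from the
fold change, with `fc == 1`-but-significant genes flagged inconsistent.
For the synthetic path the package supplies p-values from a two-group
comparison of pooled counts: median-of-ratios size factors (robust to a
down-regulated target subset), a half-count continuity correction, and a
z-test on the log count ratio with variance `1/k + 1/w + α·2/n_rep` — the
delta-method variance of a log negative-binomial total. The global
dispersion `α` is estimated by method of moments on within-genotype
replicates, averaging `(s² − m)/m²` over genes with mean ≥ 10 (the mean,
not the median: at n = 2 replicates `s²` has one degree of freedom and a
median would be biased low by the χ²₁ skew). A pure exact binomial test
on pooled counts was considered and rejected: it ignores biological
overdispersion and calls essentially every gene significant at realistic
dispersions.

## Target calling

For each DE gene, the scan space is the union of its conserved regions
intersected with the proximal window (TSS-relative −1000..+1000); only
motif windows lying entirely inside that space can hit. A gene is a
predicted direct target iff it has ≥ 1 hit at the calibrated threshold.
`use_conservation=False` scans the raw proximal window instead, provided
for sensitivity analysis because published descriptions of this family of
pipelines are often ambiguous about whether the proximal scan is
conservation-restricted; the conservation-filtered mode is the default.
Every stored hit re-validates: rescoring the genome sequence at the
stored offset and strand reproduces the stored score to 1e-9 (tested).

## The synthetic-data generator

The generator emulates the input universe the method expects, not any
particular dataset:

* **Layout** — one chromosome per species; each gene gets a private block
  (promoter span + gene body + 500 bp spacer) on alternating strands;
  bodies have three exons with drawn lengths (exon 2 is the second-exon
  analogue), so annotation parsing, strand arithmetic and length-based
  FPKM all get exercised.
* **Orthology** — the species-B promoter is the species-A promoter with
  i.i.d. per-base substitutions: rate `1 − 0.95` inside designated
  conserved blocks (default four 500 bp blocks, the first always inside
  the proximal window), `1 − 0.60` elsewhere. Substitutions never restore
  the original base, so percent-identity ground truth is exact. Indels
  are off by default (an `indel_rate` exists) — this keeps the
  conservation oracle trivial and is the main idealization: real
  promoter alignments contain indels, repeats and lineage-specific
  insertions that make footprinting harder than these tests show.
* **Planted motifs** — target genes receive `1 + Poisson(rate − 1)` sites
  (mean = planting rate, never zero for rates ≥ 1) at uniform
  non-overlapping positions inside the proximal conserved block, strand
  uniform, letters drawn from the PWM's per-column distributions so true
  sites have a realistic score spread rather than all scoring 1.0.
* **Negative control** — i.i.d. background-composition sequence totalling
  1.5 Mbp in 100–2000 bp records; real second exons carry codon structure
  and composition bias this does not model, which matters only if the
  scanning background is set to differ from the simulation background.
* **Counts** — WT means log-normal (median 200, σ = 1); KO means scaled by
  the true fold change (default 0.25); per-sample depth factors
  U(0.7, 1.3); counts negative-binomial with dispersion 0.05 (typical of
  good laboratory replicates); two replicates per genotype, matching the
  experimental design the pipeline targets.
* **Determinism** — every generator consumes a `numpy` Generator seeded
  from the config seed; identical configs give byte-identical files.

Default sizes (40 genes, 10 targets) keep a full 20-seed end-to-end
validation under a minute on one core; they are the package's chosen
study conditions for parameter recovery, with the negative-control pool
kept at full 1.5 Mbp scale.

## What the validation shows — and does not

Passing tests demonstrate: the calibration allowance transfers to
independent sequence of the same composition; every reported conserved
region exceeds the identity threshold under independent recount; scanning
and alignment agree with exhaustive enumeration at small scale; and on
idealized two-species data with planted truth the full pipeline recovers
the target set with precision and recall ≥ 0.8 averaged over 20 seeds.
They do not demonstrate performance on real genomes: background
composition heterogeneity, repeats, indel-rich alignments, promoter
mis-annotation, and DE testing with a real tool's error characteristics
are all outside the synthetic model; a genome-scale analysis additionally
needs real genome assemblies, a curated matrix for the factor, and an
external differential-expression run.

## Known limitations

* Banded alignment trades exactness for speed on long promoters (exact
  mode is available).
* The identity denominator penalizes gap-rich conserved regions; an
  indel-aware identity variant is out of scope.
* The calibration guarantee is exact only on the calibration set;
  transfer is statistical.
* With two replicates, the dispersion estimate is global, not per-gene;
  a real analysis should take p-values from a dedicated DE tool.
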