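# conscan

Conservation-filtered prediction of direct transcription-factor target genes
from knockout RNA-seq — the classic recipe for mapping a regulator such as
RFX2 onto its direct targets (e.g. the cilia/flagella programme of mouse
spermiogenesis): genes that both respond to loss of the factor **and**
carry a conserved, high-scoring binding motif in their proximal promoter.

`conscan` is for regulatory-genomics analysts who have (i) a position
frequency matrix for a transcription factor, (ii) promoters from two
species linked by orthology, and (iii) a knockout-vs-wild-type expression
table, and who want a reproducible, testable implementation of the
classic phylogenetic-footprinting + empirically-calibrated-PWM pipeline —
plus a synthetic-data generator with planted ground truth so the whole
analysis runs and validates with no downloads.

## The method

1. **Promoter windows.** For each gene, the window 10 kbp upstream to
   5 kbp downstream of the TSS is extracted strand-aware (0-based
   half-open coordinates internally; offsets reported TSS-relative,
   upstream negative).
2. **Phylogenetic footprinting.** Orthologous promoter pairs are globally
   aligned (Gotoh affine-gap DP: match +1, mismatch −1, gap open −5, gap
   extend −1) and *conserved regions* are extracted with a 100-column
   sliding window: windows with identity > 80% are merged and trimmed so
   every reported region's overall identity also exceeds 80%. Gaps and N
   count in the denominator and never as matches.
3. **PWM scanning.** The PFM with pseudocount 0.25 per cell gives a
   log₂-odds matrix against the background composition; a window's *match
   score* is min-max normalized,

   `score = (Σⱼ logodds[bⱼ, j] − min) / (max − min) ∈ [0, 1]`,

   and both strands are always scanned.
4. **Empirical cutoff calibration.** The score threshold is the smallest
   attained score such that a motif-free negative-control set (~1.5 Mbp,
   emulating second exons of protein-coding genes) yields **no more than 3
   hits per 10 kbp** — computed by exact order statistics on the pooled
   window-score multiset, so the guarantee holds with no tuning grid.
5. **Expression arithmetic.** FPKM = count / (gene kb × library
   size/10⁶); replicates pool after a correlation QC gate (r > 0.9 rule on
   per-gene FPKM, applied through its Fisher-z confidence bound); fold
   change is the KO/WT ratio of pooled FPKM (floored at 0.1).
6. **Target calling.** A differentially expressed gene (externally
   supplied p-value < 0.05, strict) is a *predicted direct target* when
   the intersection of its conserved regions with the proximal promoter
   (−1000..+1000 of the TSS) contains ≥ 1 hit at the calibrated
   threshold.

The synthetic generator plants X-box-like motif instances (drawn from the
PWM's column distributions) inside 95%-identity conserved blocks of
designated target genes, surrounds them with 60%-identity sequence,
simulates negative-binomial counts with 4-fold knockout down-regulation,
and records the full truth table, so precision and recall of the final
target list are measurable.

## Worked example

End-to-end synthetic run (40 genes, 10 true targets, fold change 0.25):

```python
import conscan as cs

result = cs.run_synthetic_pipeline(cs.SimulationConfig(seed=1))
print(result.report_text)
print("precision %.2f recall %.2f" % result.precision_recall())
```

prints

```
conscan run report
==============================
          genes_detected: 40
                   de_up: 2
                 de_down: 10
                de_total: 12
       predicted_targets: 10
    predicted_targets_up: 0
  predicted_targets_down: 10
         score threshold: 0.747533
     allowed rate /10kbp: 3
    achieved rate /10kbp: 2.9667
         negative set bp: 1500000
predicted targets: geneA_000, geneA_001, geneA_002, ..., geneA_009

precision 1.00 recall 1.00
```

Reading this: 12 of the 40 simulated genes passed the DE cutoff (all 10
planted targets among the down-regulated, plus 2 false positives from
count noise); the calibrated match-score cutoff 0.7475 gave 2.97 hits per
10 kbp on the negative-control set (inside the allowance of 3); exactly the
10 genes with a planted conserved proximal motif were called targets.

The same run from a shell:

```bash
conscan run --seed 1 --out results/run1
```

writes `targets.tsv` (per-gene hits with TSS-relative offsets, strands,
scores and matched sites), `expression.tsv`, `summary.tsv`,
`calibration.json` and `report.txt`. Individual stages are exposed as
`conscan simulate / extract-promoters / conserve / calibrate / scan`.

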