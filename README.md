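# lrconfirm

Orthogonal confirmation of clinical variants from low-pass long-read
(Oxford-Nanopore-style) whole-genome alignments.

Clinical laboratories that discover variants by short-read WGS often must
confirm every reportable variant with an independent technology. A single
low-pass (~12x) long-read run can serve as that orthogonal assay for all
variant classes at once: `lrconfirm` takes candidate variants (VCF plus a
sidecar TSV for STR/CNV/aneuploidy/UPD queries), extracts per-class read
evidence from a coordinate-sorted BAM, and returns one of three verdicts
per variant — `confirmed`, `not_confirmed`, or `insufficient_coverage`.

## What it computes

- **Small sequence changes (SSC, ≤50 bp)** — per-read allele classification
  at the locus (edit distance of the aligned slice against reference and
  alternate windows). A variant is confirmed when alt reads ≥ 3 and
  ≥ 20% of local depth; loci under 12x (genomic) / 1000x (mitochondrial)
  are `insufficient_coverage` rather than refuted.
- **Mitochondrial heteroplasmy** — the alt fraction `alt/X` of the pileup,
  reported alongside the verdict (e.g. 658 alt / 1699 reads → 39%).
- **Phasing** — reads spanning two nearby heterozygous variants vote for
  *cis* vs *trans*, resolving compound heterozygotes without parental data.
- **STR expansions** — per-read repeat counting between the reference
  flanks of the locus: greedy motif-unit matching (≤1 mismatch per unit),
  interrupting units recorded and counted in the tract total, clipped
  reads contributing lower bounds. Confirmed when any read reaches the
  locus-specific reportable threshold; mosaic ranges are reported.
- **Structural variants** — deletions/duplications via in-read deletion
  operations or split reads with size- and orientation-consistent partners
  at both breakpoints; insertions (e.g. Alu elements) via spanning-read
  insertion operations within ±30% of the expected length, with the
  consensus inserted sequence emitted for external classification;
  inversions strictly via opposite-strand split reads.
- **CNV / aneuploidy** — windowed depth normalized by the autosomal
  median (diploid = 1.0, het deletion ≈ 0.5) and per-chromosome
  normalized ploidy (normal autosome ≈ 2).
- **UPD** — ≥ 20 informative loci (homozygous-alternate in the
  non-transmitting parent, reference in the source parent) spread across
  the region must all read reference-only in the proband, plus a
  normalized-copy rule-out of a masking deletion.
- **Validation statistics** — sensitivity = TP/(TP+FN), specificity =
  TN/(TN+FP), PPV = TP/(TP+FP), accuracy = (TP+TN)/N with exact
  Clopper–Pearson 95% intervals from beta quantiles.

A synthetic read generator (`lrconfirm.simulate`) emulates the assay —
~10 kb log-normal reads, 12x genomic / ≥1000x mitochondrial depth,
indel-rich ~Q16 errors with homopolymer enrichment, and aligner-style
split reads at SV junctions — so every confirmer is testable with no
external data.

## Worked example

Validation metrics from a confusion matrix (164 TP, 0 FP, 1 FN, 168 TN):

```
$ lrconfirm metrics --counts 164,0,1,168
sensitivity     0.99394 (95% CI = 0.9667-0.9998)
specificity     1.00000 (95% CI = 0.9783-1.0000)
ppv             1.00000
accuracy        0.99700 (95% CI = 0.9834-0.9999)
```

Heteroplasmy estimation on a simulated mitochondrial variant spiked at a
38.7% fraction and sequenced at ~1700x:

```python
from lrconfirm.scenarios import mito_heteroplasmy
from lrconfirm.small import heteroplasmy

sc = mito_heteroplasmy(seed=1)
result, est = heteroplasmy(sc["query"], sc["records"], sc["reference"])
print(result.status.value, est.alt_count, est.depth, est.percent_rounded)
# confirmed 681 1801 38
```

681 of 1801 classified reads carry the alternate allele — an estimated
38% heteroplasmy, within sampling error of the spiked 38.7% truth, and
the variant is confirmed because the depth clears the 1000x floor and
alt support is far above the 3-read minimum.

The confirmation pipeline itself runs from files:

```
lrconfirm confirm --alignments sample.bam --reference ref.fa \
    --queries candidates.vcf --sidecar candidates.tsv \
    --out report.tsv --min-depth 12 --min-mito-depth 1000
```

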