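# pgtdup

Preimplantation genetic testing (PGT) for **tandem microduplications**:
SNP haplotype linkage analysis with proband-anchored paternal phasing
(PGT-M), plus dual-resolution binned copy-number analysis with circular
binary segmentation (PGT-A), and a synthetic pedigree/embryo generator
for validating every stage without patient data.

## The problem

A parent carrying a sub-megabase pathogenic duplication — here a
~1.69 Mb duplication of 1q21.1–q21.2 (`chr1:146305863-147992406`,
GRCh37) — cannot be screened out of embryos by conventional aneuploidy
testing: the event is far below the ~4–5 Mb resolution of shallow
whole-genome PGT-A. When the duplication is arranged *in tandem* at its
original locus, its transmission can instead be tracked through linked
SNPs:

* **Flanking informative SNPs** (within 2 Mb of the duplication,
  heterozygous in the carrier father, homozygous in the mother): the
  paternal allele an embryo received is the embryo's genotype minus the
  obligate maternal allele.
* **Within-duplication informative SNPs** (father het, mother and an
  affected child homozygous for the same allele): the duplicated
  haplotype carries the mother-matching allele in two copies, so an
  embryo that inherited it types homozygous like the affected child,
  while the other paternal haplotype yields a heterozygote.

An affected proband anchors the phase: the paternal allele transmitted
to the proband defines **hap1** (high-risk, duplication-bearing); the
father's other allele defines **hap2** (low-risk). Each embryo votes
per SNP; a ≥90%-consistent majority over ≥3 votes spanning both flanks
yields a high-/low-risk verdict, and upstream/downstream flank
disagreement (possible recombination) forces "inconclusive".

In parallel, shallow read counts are tallied in 0-anchored grid bins
(1 Mb genome-wide, 400 kb targeted), normalized to the sample's median
bin (copy ratio `r`, copy number `2r`), segmented per chromosome with
**circular binary segmentation** (arc maximizing the two-sample
statistic, permutation p < α, recursive), and thresholded into
gain/loss calls (CN ≥ 2.5 / ≤ 1.5; reported at ≥4 Mb genome-wide,
≥1 Mb targeted). The two arms cross-check each other: a high-risk
embryo should show CN 3 in the target region.

## Worked example

Reproduce the packaged clinical-style case — a carrier-father trio
genotype table over 22 markers plus five biopsied embryos, with
matched simulated read counts:

```sh
pgtdup run --out demo --seed 1
```

prints (and writes to `demo/report.tsv`):

```
embryo grade                                                         cnv_findings  target_cn linkage_status  transfer_eligible  concordant
    E1   5BC                                    dup(1)(146.40-147.60Mb)(~1.20 Mb)          3       Affected              False        True
    E2   4BB                                                               Normal          2     Unaffected               True        True
    E3   4BB                                    dup(1)(146.40-147.60Mb)(~1.20 Mb)          3       Affected              False        True
    E4   4BC del(4)(138.00-191.15Mb)(~53.15 Mb);dup(1)(146.40-147.60Mb)(~1.20 Mb)          3       Affected              False        True
    E5   4BC                                                          -20;+21;-22          2     Unaffected              False        True
```

Reading the rows: E1/E3/E4 inherited the high-risk paternal haplotype
(linkage) and independently show a ~1.20 Mb gain at CN 3 in the target
region (dosage) — the targeted call spans the three 400-kb grid bins
fully contained in the 1.69 Mb duplication, hence 1.20 Mb. E4
additionally carries a ~53 Mb terminal 4q deletion; E5 is free of the
duplication but triple-aneuploid (−20, +21, −22). Only E2 is both
unaffected and euploid, so it is the single transfer-eligible embryo.
`concordant=True` means linkage verdict and target-region copy number
agree for every embryo.

Other subcommands: `pgtdup simulate` (synthetic cohort VCF + bin
counts), `pgtdup qc` (depth/allele-fraction filters), `pgtdup
haplotype` (phasing + verdicts from a VCF), `pgtdup cnv` (segmentation
and calls from a bin-count TSV). The library API mirrors the CLI; see
`docs/methods.md` for the model details.

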