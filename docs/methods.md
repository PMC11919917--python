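# Methods

This note documents the models, decision rules, parameters and
numerical choices behind `pgtdup`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Coordinate and genotype conventions

All coordinates are 1-based, inclusive at both ends (VCF convention);
BED export converts to 0-based half-open at the boundary. Genotypes
are unordered allele pairs (`C/G` ≡ `G/C`): phase is inferred by the
linkage analysis, never taken from input. A no-call is a distinct
state, spelled `./` or `./.` in tabular inputs. Only biallelic SNPs
are supported; multiallelic VCF records are rejected with an error
rather than silently split, because every decision rule downstream
assumes a two-allele site.

The packaged linkage fixture (`pgtdup/data/table1.tsv`) carries 22
chr1 markers for eight individuals. Two rsids appear in the source
table with stray thousands separators inside the identifier
("rs117176,741", "rs17581,597"); the fixture stores them comma-free,
a normalization of typography, not a reinterpretation. The table does
not distinguish reference from alternate allele, so the loader takes
the carrier male's allele order as REF/ALT; nothing downstream uses
that orientation.

## Genotype QC

Whole-genome-amplified biopsy DNA is genotyped at a few-fold mean
depth, so every observation is re-called from its allele depths with
one rule on the alt-allele fraction `af` (defaults):

| condition | outcome |
|---|---|
| depth < 4 reads | filtered (too shallow) |
| `af` ≤ 0.1 | hom-ref |
| `af` ≥ 0.9 | hom-alt |
| 0.2 ≤ `af` ≤ 0.8 | het |
| `af` ∈ (0.1, 0.2) ∪ (0.8, 0.9) | filtered (ambiguous dosage) |

The homozygote and heterozygote acceptance bands are stated
separately in the field's practice; unifying them into one partition
of [0, 1] is the only reading that keeps both operative at once, with
the two open gaps treated as unresolvable "low quality". Boundary
values are kept (0.1 and 0.9 are homozygous; 0.2 and 0.8 are
heterozygous). Variant-caller quality scores are out of scope: QC here
is purely depth/allele-fraction. Note the bands deliberately admit the
1/3 and 2/3 allele fractions of a heterozygous site inside a CN=3
duplicated segment, so duplication carriers still type het there.

## Informative-SNP selection, phasing, classification

*Selection.* Flanking class: father het, mother hom, within
`flank_bp` (default 2,000,000 bp) of a duplication boundary; the
signed distance is `pos − start` upstream (negative) and `pos − end`
downstream. Within-duplication class: father het, mother hom, affected
proband homozygous for the mother's allele, position inside the
region.

*Phasing.* Anchored on the affected proband. Flanking: the paternal
allele transmitted to the proband (proband genotype minus one obligate
maternal allele) is hap1; the father's other allele is hap2.
Within-duplication: hap1 is the mother-matching allele (present twice
on the duplicated haplotype), hap2 the father's other allele. Sites
whose proband call is missing or Mendelian-inconsistent with either
parent are dropped with a logged reason; zero phaseable sites is a
hard error.

*Embryo votes.* Flanking: subtract the maternal allele, map the
remaining paternal allele to hap1/hap2; embryos not carrying the
maternal allele (Mendelian-inconsistent, e.g. after allele dropout)
vote `no_call` rather than guessing. If selection is relaxed to a
heterozygous mother, a doubly-maternal-compatible het embryo is
likewise a `no_call`. Within-duplication: homozygous like the proband
→ hap1; heterozygous for the father's pair → hap2; anything else
`no_call`.

*Verdict.* The majority haplotype over all usable votes, accepted only
with ≥ 3 votes overall, ≥ 1 on each flank, and majority consistency
≥ 0.9; otherwise inconclusive. These thresholds are this package's
defaults — conservative clinical-style values for a two-flank design,
not published constants — and are configurable. If the upstream and
downstream flank majorities disagree, a recombination between markers
and duplication may have broken linkage: the verdict is forced to
inconclusive with a flag, never converted into a risk call. The
within-duplication vote uses the diploid-style call only; a 2:1
dosage check at those sites would be a natural extension but is not
part of the rule.

## Copy-number analysis

*Binning and normalization.* Reads are counted in fixed bins anchored
at coordinate 0 — 1 Mb for the genome-wide aneuploidy screen, 400 kb
for the targeted mode. The diploid baseline is the sample's own
genome-wide median autosomal bin count (no reference cohort is
assumed); copy ratio `r = count/baseline`, copy number `2r`. No
GC/mappability correction is applied (out of scope), so on real data
wavy-coverage artefacts would add structure the simulator does not
produce.

*Segmentation.* Circular binary segmentation per chromosome on
untransformed ratios: find the arc `(i, j]` maximizing
`|mean(arc) − mean(rest)| / (sd · sqrt(1/k + 1/(n−k)))` with `sd` the
global standard deviation of the chromosome's values (permutations
preserve the value multiset, so a global scale leaves the permutation
test invariant); accept the split when the permutation p-value
`(1 + exceedances)/(1 + n_perm)` is below `alpha`; recurse on the
pieces. Defaults: `alpha` 0.01, 1000 permutations, minimum arc 2 bins,
post-hoc merging of adjacent segments whose means differ by < 0.05
(ratio scale). Permutation chunks stop early as soon as enough
exceedances make acceptance impossible — the decision is identical to
running all permutations, only cheaper on null data. A fixed seed
makes segmentation deterministic. A log2-ratio mode is available via
the segment means if desired; the statistic itself operates on plain
ratios, and the brute-force oracle used in the tests is defined on the
same scale.

*Calling.* Segments with mean CN ≥ 2.5 are gain-state, ≤ 1.5
loss-state (midpoints between integer copy states of a non-mosaic
diploid; configurable). A **call is a maximal run of adjacent
same-state segments**: segmentation may cut one event at a noisy
boundary, but the event is the contiguous non-neutral run. Genome
mode reports calls ≥ 4 Mb (the conventional aneuploidy-screen floor);
targeted mode reports ≥ 1 Mb and requires the target region. A
segment run covering a whole chromosome is reported `±chrom`.

*Size convention (inner bins).* A targeted call overlapping the target
region is reported as the span of grid bins **fully contained** in the
region. With the 0-anchored 400-kb grid, the 1.69 Mb duplication
contains exactly three interior bins (146.4–147.6 Mb), so a carrier's
gain call reports ~1.20 Mb. Partially covered boundary bins carry
diluted signal and an uncertain breakpoint, so excluding them is the
conservative choice; it is a documented reconstruction of how a
1.69 Mb event comes to be reported near 1.2 Mb, not a claim about any
particular lab's software.

*Target copy number.* `round(2 × mean ratio)` over the fully contained
bins, ties rounding away from diploid (2.5 → 3, 1.5 → 1, the
direction that flags an aberration for review). No fully contained
bin is an error instructing a smaller bin size.

## Synthetic data generator

The generator emulates the study conditions: a carrier father (CN 3
over the duplication on haplotype 1), non-carrier mother, affected
proband inheriting paternal hap1, and any number of embryos.

* **Panel**: `n_snps_flank` positions uniform in each 2 Mb flank and
  `n_snps_inside` inside the region; allele frequencies uniform in
  `maf_range` (default 0.1–0.5); parental haplotype alleles drawn from
  them; the panel is redrawn (bounded retries) until each flank holds
  ≥ 1 informative site.
* **Meiosis**: transmitted haplotypes uniform; with probability
  `recomb_prob` (default 0.01) a single crossover lands uniformly in
  the simulated window. A single-crossover model suffices because the
  window is ~6 Mb and the pipeline only needs flank-discordance to be
  exercisable; a genetic-map model would add nothing testable here.
* **Allele depths**: total depth Poisson with mean `mean_site_depth`
  (default 30 — the targeted-SNP regime in which linkage calling is
  actually run; the genome-wide backbone of such assays is far
  shallower, and a 2–3× setting reproduces that for the QC tests);
  reads multinomial over the alleles present, weighted by copy dosage,
  so CN=3 het sites split 2:1; each distinct allele drops out
  independently with probability `ado_rate` (default 0.05, the
  standard WGA dropout abstraction) before reads are drawn; each read
  miscalls to the site's other allele with `false_allele_rate`
  (default 0.002).
* **Bin counts**: Poisson with mean `reads_per_bin × cn/2`, the copy
  number averaged over each bin by overlap length; `reads_per_bin`
  derives from `reads_total` (default 5×10⁶ genome-wide valid reads,
  treating the assay's quoted read yield as a read count) and the bin
  grid, or can be set directly. An optional gamma-Poisson
  overdispersion factor is exposed (default 1 = pure Poisson) since
  real MALBAC coverage is noisier than Poisson.

What passing tests therefore show: the decision rules and algorithms
recover planted truth under Poisson/multinomial noise with independent
per-site dropout. What they do not show: robustness to amplification
waviness, GC bias, correlated dropout, mosaicism or contamination —
none of which the generator produces.

## Problem sizes and determinism

Simulation-heavy checks run at sizes chosen to make their statistical
tolerances meaningful at interactive runtimes: 100-seed recovery runs
for the targeted gain call (baseline 500 reads per 400-kb bin on
chr1), 500-embryo classification recovery, 200-instance oracle
comparisons for CBS (≤ 50 bins, where exhaustive search is exact), and
200-run null calibration. Test-suite CBS runs use 200 permutations
(the early-stopping decision rule keeps this equivalent to more
permutations for clearly null splits; the acceptance script uses the
full 1000). Every stochastic component takes an explicit seed or
generator; identical seeds give byte-identical outputs, including the
end-to-end pipeline report.

## Known limitations

Paternal-carrier phasing only (an affected/carrier proband is
required; grandparent- or gamete-based phasing is out of scope); no
sex-chromosome ploidy handling; no mosaic (non-integer) CN calls; no
breakpoint refinement below bin resolution; CNV labels use Mb
coordinates rather than cytogenetic band names (band lookup tables are
deliberately not bundled); the transfer-eligibility flag is a boolean
summary, not clinical guidance.
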