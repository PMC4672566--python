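# Methods

## The identity test

The test asks whether two sets of sparse single-base observations are more
consistent with one diploid source or two independent ones. Its information
source is linkage disequilibrium (LD): within one individual, the allele a
read reveals at one SNP is correlated, through haplotype structure, with
alleles at nearby SNPs — across unrelated individuals it is not.

For one pair of observations A, B at two linked SNPs the two hypotheses give

    P2(A∧B) = f(A) f(B)
    P1(A∧B) = ½ f(AB) + ½ f(A) f(B)
    γ(A,B)  = log2(P1 / P2)        [bits]

where f(·) are population allele frequencies and f(AB) the two-site
haplotype frequency. The ½ in P1 reflects that two reads from one diploid
individual land on the same chromosome copy with probability ½ (then the
haplotype frequency applies) and on different copies otherwise (then the
observations are independent). Consequences used throughout:

* γ ≥ −1: P1 ≥ ½ P2, so a single discordant pair can never contribute more
  than one bit against identity;
* γ = 0 exactly when the panel shows linkage equilibrium (f(AB) = f(A)f(B));
* P1 and P2 each sum to 1 over the four allele combinations.

All frequencies are empirical panel proportions with **no pseudocounts**:
the minor-allele-count filter bounds marginal frequencies away from 0, and
P1 stays positive even when f(AB) = 0, so γ is always finite. Probabilities
are formed from integer haplotype counts with a single final division,
making the identities above exact in floating point; the γ formula in
counts is `log2((N·cAB + cA·cB) / (2·cA·cB))`, which returns exactly −1 and
exactly 0 in the boundary cases. `likelihood.enumeration_oracle_p1`
verifies P1 independently by exhaustive enumeration over all ordered
haplotype pairs and read origins (quadratic in panel size; used only in
verification).

## Aggregation and verdict

Single pairs are uninformative; the genome-wide statistic is

    Λ(S) = Σ_{(A,B) ∈ S} γ(A,B)

with S built to keep summands approximately independent: chromosomes are
tiled into non-overlapping 500-kb windows, candidate pairs (one observation
from each sample, same chromosome, 1–50 kb apart) are assigned to the
window containing their midpoint, and each bootstrap replicate draws
exactly one candidate per occupied window. The window width is deliberately
much larger than the pair span, so windows act as independent assessments;
a 3-Gb genome offers ~6000 of them. The bootstrap varies only the
within-window draw (windows are not resampled), giving the empirical
distribution of Λ induced by the arbitrary choice of pair.

The minimum pair distance (default 1 kb) guarantees that in within-sample
mode the two bases can never come from one sequenced fragment; the maximum
(50 kb) keeps pairs inside the range where background LD is informative.

Verdict rule: SAME if the empirical 2.5% quantile of Λ is above 0,
DIFFERENT if the 97.5% quantile is below 0, INCONCLUSIVE otherwise.
The sign convention is the scientific content; the interval rule is this
package's decision contract for reporting, and INCONCLUSIVE is the expected
outcome for mixtures, panel mismatch, or simply too little data. The
reported sd is the sample standard deviation (ddof = 1) of the bootstrap
replicates.

Randomness: one top-level seed; each bootstrap replicate uses a
`SeedSequence(seed, spawn_key=(replicate,))` substream and windows are
visited in sorted genomic order, so results are independent of container
iteration order and identical across runs. Candidate pairs are stored in a
canonical orientation (lower site index first — γ is symmetric) and sorted,
so swapping the two input samples is a no-op.

Non-autosomal chromosomes are excluded by default because the
single-individual model assumes diploidy at every site. Only recognised
sex/organelle names (X, Y, M/MT, W, Z, optionally "chr"-prefixed) are
excluded, so simulated pseudo-chromosomes and unusual contig names count as
autosomes.

## Reference panels

Panels are built from phased multi-sample VCFs and keep only biallelic
single-base substitutions that are polymorphic in the chosen sample subset
with minor allele count ≥ 10 (default). The MAC filter protects the
frequency estimates that enter γ; with 200 haplotypes it corresponds to
MAF ≥ 5%. Records with missing genotypes in the subset are dropped whole —
frequency estimates come from complete columns only. Heterozygous genotypes
must be phased ('|'); unphased heterozygotes reject the record (counted and
logged), while unphased homozygotes are accepted since their phase is
unambiguous. An optional mappability mask (BED, e.g. a 35-mer-uniqueness
track) restricts sites to uniquely mappable positions; the k-mer analysis
itself is assumed to be encoded in the BED. VCF positions are 1-based and
kept 1-based internally; BED intervals are 0-based half-open and converted
at the membership check.

The panel archive is a single zip with a JSON header, a plain-text site
table and a bit-packed haplotype matrix; a SHA-256 fingerprint over sites
and matrix ties observation sets to the exact panel they were made against,
and comparisons refuse mismatched fingerprints.

## Observations

From alignments: for each panel site, reads with mapping quality ≥ 30 and
base quality ≥ 20 (defaults; the appropriate thresholds are data-dependent
and configurable) are considered; deletions/refskips, secondary,
supplementary, duplicate-flagged and QC-fail reads are ignored. Sites
covered by more than `max_depth` (default 1) passing reads are omitted —
at genuinely low coverage, multiple overlapping reads suggest mismapping.
With the default depth the emission rule is exactly: one passing read whose
base equals the panel ref or alt emits that allele; other bases are
discarded. If `max_depth` is raised, a site emits only when all passing
reads agree on one panel allele. Transversion-only mode skips transition
SNPs entirely, which removes the C→T/G→A post-mortem deamination class of
errors at the cost of ~⅔ of sites.

The TSV interchange format (`chrom  pos  base`, '#'-comment header) applies
the same rules: off-panel rows and non-matching bases are rejected with
counts, and any position appearing twice is dropped entirely, mirroring the
multi-read omission.

## Synthetic data

`simulate` generates the full test bed without any downloads. Haplotypes
come from msprime (Hudson coalescent with recombination, binary mutation
model); each segment is an independent 500-kb pseudo-chromosome. Defaults
are the study conditions: 3000 segments (1.5 Gb), Ne = 10,000 constant,
200-haplotype panels, MAF ≥ 10% computed on the panel haplotypes (which
also guarantees the panel's polymorphism and MAC invariants), observation
rate 0.01 per chromosome copy. Mutation and recombination rates default to
human-typical 1.25e-8 and 1e-8 per bp per generation and are exposed in the
scenario config. Test individuals' haplotypes are drawn from columns
disjoint from the panel's. The split model replaces the single population
with a symmetric split of the ancestral population `split_generations` ago:
individuals from one daughter population, panel from the other, no
migration — genetic drift and independent recombination histories then
degrade the panel's usefulness in a controlled way.

Ref/alt bases are assigned uniformly at random (ref uniform on ACGT, alt on
the remaining three, so ⅓ of simulated SNPs are transitions); the
coalescent carries no base identities, and bases matter only so simulated
data flow through the same TSV/transversion code paths as real data.

Observation sampling draws each chromosome copy independently at the given
rate and discards sites where both copies were drawn (a single read cannot
show both), leaving an observed-site fraction of 2r(1−r) ≈ 0.0198 at
r = 0.01. `mate` produces a child from one recombinant gamete per parent
(Poisson crossovers at the genetic map rate), enabling parent-child and
sibling comparisons, which land between the same-individual and
different-individual extremes — first-degree relatives share one genome
copy, i.e. "half an identity".

What the generator does not emulate: sequencing and mapping errors, base
quality structure, DNA damage, contamination mixtures, variable read
lengths, and real human LD structure shaped by bottlenecks and expansions
(the constant-size model is conservative in this respect — it generates
*less* LD than recent human history does). Passing tests therefore
demonstrate the statistical machinery under clean observations, not
robustness to upstream artifacts, which is the role of the quality,
depth and transversion filters on real data.

## Problem sizes and numerical choices

The replicated studies in the test suite and acceptance script use 300
segments × 500 kb per replicate (a tenth of the default genome) with 20
(suite) or 10 (acceptance script) replicates, and 4–6 replicates per split
time for the divergence trend; at these sizes same/different mean Λ are
separated by ~15 bits with replicate-to-replicate spread of ~1 bit, so sign
consistency is a stable property rather than a marginal one. The
enumeration-oracle check uses panels of ≤ 16 haplotypes where the O(n²)
oracle is instant. Bootstrap default is 100 replicates. Λ additivity,
normalisation and the γ ≥ −1 bound are asserted exactly (no tolerance);
oracle agreement uses 1e-12.

## Known limitations

* The test reports identity vs non-identity; it has visible but unmodelled
  sensitivity to relatedness (relatives sit near 0) and no kinship-degree
  estimate.
* Panel choice matters: a diverged or admixed reference panel shrinks the
  separation and can push true-identity comparisons toward 0. Within-sample
  runs under candidate panels are the practical panel-selection tool.
* No error term inside the model: γ assumes observations are correct;
  erroneous bases are expected to be removed upstream by the quality,
  depth, allele-match and transversion filters.
* Windows are fixed tiles; a sliding-window variant would correlate
  adjacent windows and is deliberately not implemented.
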