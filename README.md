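# ldid — identity testing for extremely low-coverage DNA samples

`ldid` decides whether two shotgun DNA sequencing libraries derive from the
**same diploid individual**, even when each covers well under 1% of the
genome and the two libraries share essentially no sequenced positions. This
is the situation forensic, historical and ancient-DNA labs face when STR
profiling fails for lack of amplifiable template: each library yields only
scattered single reads, so genotypes cannot be called and alleles cannot be
compared directly between samples.

The test sidesteps direct comparison entirely. It collects single-base
observations at known SNP positions and evaluates **pairs of observations at
linked SNPs**: if both samples come from one individual, an allele observed
in one sample is predictive, through linkage disequilibrium (LD), of alleles
observed nearby in the other; if the samples come from different individuals
it is not. A phased reference haplotype panel (e.g. built from 1000
Genomes-style phased VCFs) supplies the allele and haplotype frequencies
that quantify this.

## The model

For a pair of base observations A and B at two linked SNPs, with population
allele frequencies f(A), f(B) and haplotype frequency f(AB):

* two independent individuals: `P2(A∧B) = f(A) f(B)`
* one diploid individual (each read lands on either chromosome copy with
  equal probability): `P1(A∧B) = ½ f(AB) + ½ f(A) f(B)`

Each pair contributes a log-likelihood ratio in bits,

```
γ(A,B) = log2( P1(A∧B) / P2(A∧B) ),       γ ≥ −1 always,
```

and pairs are aggregated genome-wide by tiling each chromosome into 500-kb
windows, drawing one eligible pair (1–50 kb apart) per window, and summing:

```
Λ(S) = Σ_{(A,B) ∈ S} γ(A,B)
```

Repeating the per-window draw (bootstrap) yields an empirical distribution
of Λ. Positive Λ favours a single diploid source; negative Λ favours two
individuals. Applied to a single library (within-sample mode), a positive Λ
doubles as a check against contamination/mixture.

## Worked example (synthetic cohort)

Simulate a cohort — a 200-haplotype reference panel plus two diploid
individuals A and B over 1000 independent 500-kb segments — and draw sparse
observation sets (rate 0.01 per chromosome copy, ~0.02-fold coverage):

```sh
printf 'n_segments = 1000\n' > scenario.cfg
ldid simulate --scenario scenario.cfg --seed 11 --outdir demo
# cohort: 556277 sites over 1000 segments -> demo
ldid compare --panel demo/panel.ldp --obs1 demo/A1.tsv --obs2 demo/A2.tsv --seed 1 --out same.tsv
# A1 vs A2: mean Lambda 22.579 bits [9.267, 41.230] over 1000 windows -> SAME
ldid compare --panel demo/panel.ldp --obs1 demo/A1.tsv --obs2 demo/B1.tsv --seed 1 --out diff.tsv
# A1 vs B1: mean Lambda -20.247 bits [-34.964, -8.565] over 1000 windows -> DIFFERENT
ldid compare --panel demo/panel.ldp --obs1 demo/A1.tsv --seed 1 --out within.tsv
# A1 vs A1: mean Lambda 18.493 bits [4.562, 31.783] over 990 windows -> SAME
```

A1 and A2 are two independent ~1000-observation subsamples of individual A;
their aggregated Λ is strongly positive (the 95% bootstrap interval excludes
0), so the verdict is SAME. Against individual B the Λ is symmetric and
negative: DIFFERENT. The within-sample run confirms library A1 is internally
consistent with one diploid source.

With real data the same pipeline starts from a phased VCF and indexed BAMs:

```sh
ldid panel-build --vcf phased.vcf.gz --population-list CEU.txt \
    --min-minor-count 10 --mask-bed map35_unique.bed --out ceu.ldp
ldid observe --bam sample1.bam --panel ceu.ldp --min-bq 20 --min-mq 30 --out s1.tsv
ldid observe --bam sample2.bam --panel ceu.ldp --transversions-only --out s2.tsv
ldid compare --panel ceu.ldp --obs1 s1.tsv --obs2 s2.tsv --seed 1 --out report.tsv
```

`--transversions-only` restricts to transversion SNPs, sidestepping the
C→T/G→A deamination artifacts of ancient DNA. `ldid compare --all-vs-all
--obs … --obs …` runs every unordered pair of samples plus all
self-comparisons (12 samples → 78 comparisons).

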