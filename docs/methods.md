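# Methods

This note documents the statistical model behind each analysis, the
simulator the package validates itself against, the defaults and why
they were chosen, and the limits of what passing tests demonstrate.

## Plasma mixture model

Maternal plasma cfDNA is modelled as a two-genome mixture: a fraction
`FF` (fetal fraction, dimensionless, typically 0.02–0.30) of fragments
derives from the feto-placental genome, the remainder from the mother.
At a biallelic SNP with maternal/fetal B-allele dosages `g_m, g_f ∈
{0, 1, 2}`, the expected plasma B-allele fraction is

```
f = (1 − FF) · g_m / 2 + FF · g_f / 2
```

adjusted for a symmetric per-read error rate `e` as
`f' = f(1 − e) + (1 − f)e`. The four maternal/fetal genotype
combinations imply expected minor-allele fractions 0, FF/2,
0.5 − FF/2 and 0.5. Only the mother-homozygous / fetus-heterozygous
combination moves with FF in the low-MAF region, which is what the
estimator exploits.

Assumptions: loci are independent (no linkage), genotypes are
Hardy–Weinberg at the locus's population frequency, the fetus inherits
one maternal allele uniformly and one independent population allele,
read counts at a locus are binomial given depth, and depth is Poisson
around the sample's mean coverage.

## Fetal-fraction estimator (MAF model)

1. Per locus, MAF = folded alternate-read fraction `min(f, 1 − f)`,
   keeping loci with depth ≥ 20 on autosomes other than 18 and 21 (the
   common-trisomy chromosomes, whose dosage would distort the MAF
   distribution).
2. Retain MAFs inside the closed window [0.02, 0.25]. The lower bound
   clears sequencing-error noise (at e = 0.1% and 150X, error loci
   essentially never reach MAF 0.02); the upper bound excludes the
   heterozygous cloud around 0.5 − FF/2 and 0.5.
3. Summarise the retained values as 101 evenly spaced quantiles plus the
   retained-locus fraction (weight 1.0). The count channel matters at
   low FF, where the informative cloud straddles the window edge and
   *how many* loci enter the window is as informative as *where* they
   sit.
4. Compare against a simulated library: candidate FFs 0–0.35 in steps
   of 0.005, 40 replicate samples per grid point, generated at the test
   sample's coverage bucket (nearest of 50/100/150/200/300/500X) and SNP
   number (within ×/÷1.5). The score at each grid point is the mean
   squared summary-vector distance, with components weighted by the
   inverse of their pooled replicate variance so the noisy extreme
   quantiles do not dominate.
5. The minimum is refined by a least-squares parabola over the arg-min
   point ± 2 grid neighbours fitted to the squared-distance curve
   (locally quadratic in the candidate FF), clipped to [0, 0.5].

Matching the library to the sample's own generative process makes the
estimator self-calibrating: truncation effects at the window edges bias
sample and library identically and cancel. At the MiSeq operating point
(150X, 2000 SNPs) the estimator recovers true FF with RMSE ≈ 0.0025,
r² ≈ 0.999 across FF 0.02–0.30, and median relative deviation ≈ 0 — at
the binomial information floor of ~370 informative loci at this depth
(per-locus MAF SD ≈ 0.02 ⇒ best-case FF SE ≈ 0.002).

Deliberately *not* implemented: per-locus binomial-mixture maximum
likelihood (the alternative family of SNP-based FF estimators); the
distribution-level fit needs no genotype-combination inference.

### Validator estimators

- **Fetal-specific alleles** (requires maternal genotype calls): at
  maternal-homozygous loci with depth ≥ 100 where the other allele is
  seen at ≥ 2 reads *and* ≥ 1% of depth (so 0.1% sequencing error cannot
  pass), the non-maternal allele fraction estimates FF/2; FF is twice
  the median over ≥ 10 informative loci. The median resists residual
  contamination; the 1% floor scales with depth, unlike a fixed read
  count.
- **chrY proportion** (male fetuses): FF = chrY proportion divided by
  the proportion a 100%-male genome yields on the same panel/platform.
  The male reference proportion is available analytically from the panel
  (hemizygous Y over diploid autosomes) and by simulation
  (`calibrate_male_chry_reference`); the two agree within 2%.

The accuracy metric for FF recovery is the degree of deviation
`(expected − fitted) / expected`.

## Chromosome dosage and calls

The dosage statistic for chromosome 21 is
`P = reads(21) / reads(autosomes − 21)`; for chrY it is
`reads(Y) / reads(autosomes)`. Reference cohorts (euploid pregnancies,
same platform; female-fetus pregnancies for chrY) are normalized by
removing samples outside three **raw** median absolute deviations of the
median — the MAD is deliberately unscaled (no 1.4826 normal-consistency
factor), which makes the fence ≈ 2.0σ for Gaussian spreads; `n_mad` is
configurable. The Z-score is the standard `(P − mean)/SD` using the
mean and SD of the retained reference samples.

Decision rules: T21 positive iff `z ≥ 3.0` (inclusive) and `FF ≥ 0.04`
(below the gate: no-call — insufficient fetal signal for a reliable
negative); male iff chrY `z ≥ 20`, chosen inside the wide empirical gap
between female (≈ −1 to 12) and male (≳ 26) Z-scores. Platform
stratification is enforced: test samples are only scored against
references with the same platform tag. Monosomy and trisomies 13/18 are
out of scope (the panel excludes chr18 from FF estimation but carries no
dosage probe set for it).

## Monogenic screen

Candidate de novo / paternally inherited fetal variants are rare
variants (maximum population frequency across the supplied databases
< 0.5%; a never-seen variant counts as frequency 0 and is flagged
`novel`) in a supplied disease gene set whose observed allele fraction
falls inside an exact binomial confidence interval (default 99%) for
proportion FF/2 at the variant's depth. The binomial window — rather
than a fixed tolerance — is essential at clinical depths: at 200X and
FF 0.13 an observed AF of 0.034 is still consistent with FF/2 = 0.065.
Out-of-window rare variants are annotated with a likely origin
(AF ≈ 0.5 maternal heterozygous; AF ≈ 0.5 − FF/2 maternal carrier with
homozygous-reference fetus); the screen emits candidates, never
pathogenicity classifications (ACMG interpretation is out of scope).

## Simulator

`sim_cohort` emulates every input the analyses consume:

- **SNP samples**: population B-allele frequencies uniform on
  [0.05, 0.5] (common panel SNPs; configurable sampler), sequencing
  error 0.1%, Poisson depth, binomial allele counts, genotype
  combinations recorded as truth. `ff = 0` denotes a non-pregnant
  individual, `ff = 1` a pure (child) genome, so the same machinery
  produces pregnancies, mothers and children.
- **Read-count tables**: multinomial over chromosomes with cell
  probabilities proportional to panel bases, chr21 weighted by
  `1 + FF/2` under trisomy, chrY = `FF · y_bases/2` for male fetuses
  plus a misalignment noise floor of 5e-7 of the autosomal mass (the
  scale observed in female-fetus pregnancies on such panels). Platform
  presets set the read totals (MiSeq 15M, HiSeq 100M) and coverage
  (150X / 500X). An optional Dirichlet-multinomial dispersion factor
  (default 1.0 = off) adds between-sample variance.
- **Panel**: 6739 SNP probes (~1.5 Mb) across autosomes minus 18/21,
  240 chr21 dosage probes (~33.5 kb), one SRY region on chrY, and a
  block of other probes on chr18 so all autosomes contribute reads.
- **Mocks**: a mother and child are simulated as individuals with
  genotypes linked by inheritance; a pregnancy mock at fraction `ff`
  draws each child read with probability `ff` and each maternal read
  with probability `1 − ff` (binomial thinning and recombination), for
  allelic depths and chromosome counts alike. This is the statistical
  equivalent of mixing the pair's FASTQ files; FASTQ-level mixing is a
  non-goal. Default mixing fractions 0.05–0.25 mimic the progressive
  rise of FF across gestation.
- **Reference cohorts**: n ≥ 5 euploid pregnancies at uniformly varied
  FF, female-fetus by default so one cohort serves both chr21 and chrY
  references.

What the simulator does **not** model — and therefore what passing
tests do not demonstrate about real data: GC and capture-efficiency
bias, per-probe variability, cfDNA fragment-length differences between
fetal and maternal molecules, PCR-duplicate structure, linkage between
loci, maternal copy-number variants, and placental mosaicism. Real
cohorts show more between-sample read-count variance than a
multinomial; the dispersion knob exists for sensitivity analyses, but no
default value is claimed because the data to calibrate it are cohort-
specific.

## Numerical and design choices

- Validation experiment sizes: FF recovery uses true FF on the even grid
  {0.02, 0.04, …, 0.30} × 21 replicates (315 samples) at 150X /
  2000 SNPs; T21 sensitivity 20 affected samples against a 54-sample
  reference; sex accuracy 40 + 40 samples against a 33-sample female
  reference; validator concordance 20 male mocks at 500X / 100M reads.
- The MAF window is treated as a closed interval; boundary behaviour at
  `z = 3.0` and the sex threshold is inclusive (≥).
- The Z-score denominator is the SD of the MAD-filtered reference, not
  the raw cohort.
- Degenerate inputs raise rather than guess: empty MAF windows
  ("unusable sample"), references that lose every sample or collapse to
  zero spread, zero autosomal denominators, FF = 0 in the monogenic
  screen (no fetal signal ⇒ no expected AF), mismatched mock loci.
- Coverage/SNP-number mismatch between a sample and its library warns
  but does not refuse, since the quantile summary is scale-free; the
  pipeline builds libraries per coverage bucket automatically.
- All randomness flows through numpy Generators; a fixed seed reproduces
  samples, libraries and reports bit-for-bit.

## Known limitations

- FF below ~0.02 is not reliably distinguishable from 0 at 150X: the
  informative cloud sits mostly below the MAF window. Clean non-pregnant
  samples can retain zero window loci and are reported unusable rather
  than fitted at 0.
- The chrY validator assumes a male fetus and a panel-matched male
  reference proportion; it returns nonsense for female fetuses (by
  design it is only consulted after a male sex call).
- The monogenic screen cannot see maternally inherited variants (a
  fetal het inherited from a het mother sits near 0.5 − FF/2 … 0.5,
  indistinguishable from maternal-only signal at these depths), nor
  intronic/CNV alleles.
- Decision thresholds (FF 0.04, z 3.0, sex z 20, rarity 0.5%) are
  assay-level conventions exposed in `RunConfig`; they are not
  re-derived from data by this package.
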