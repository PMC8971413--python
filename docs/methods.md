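# Methods

This note documents the models behind `hapdeficit`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## The deficit model

A window haplotype is an allele: the exact 0/1 string over 50 consecutive
biallelic SNPs on one chromosome copy. Haplotype identity is exact string
match — no mismatch tolerance — because the scan treats each string as a
segregating unit, and because the phased input is assumed error-free (the
simulator is its own phaser; real-data phasing and imputation are out of
scope).

For a target allele and a set of offspring with genotyped parents, the
per-offspring homozygosity probability is

* **trio** (sire and dam genotyped): π = t(s)·t(d), t(0)=0, t(1)=½, t(2)=1,
* **pgp** (sire and maternal grandsire genotyped):
  π = t(s) · (½·t(mgs) + ½·q),

where q is the allele's frequency in the genotyped population. The pgp
form makes the design's uncertainty explicit: the dam inherits one
haplotype from her sire (tracked, ½·t(mgs)) and one from her untracked dam
(modeled at the population frequency, ½·q). Setting the q-term to zero is
available as a switch for sensitivity analysis; it makes the test more
conservative because it ignores one source of homozygotes.

The number of live homozygotes among n offspring is a Poisson-binomial
count X = Σ Bernoulli(πᵢ). The deficit test is the exact one-sided lower
tail P(X ≤ observed), computed by dynamic-programming convolution
truncated at the observed count (cost O(n·observed); offspring with π = 0
drop out). This construction conditions on the realized matings — it is
exactly the information the trio/pgp designs provide — and reduces to a
binomial tail when all matings are alike. Exactness is verified against
brute-force enumeration over all 2ⁿ outcomes for n ≤ 12.

An allele is tested when its frequency is ≥ 0.01 (mirroring a MAF quality
floor) and its expected homozygote count is ≥ 10; expectations below 10
cannot produce a convincing deficit signal, and reporting them would only
dilute the multiple-testing correction. P-values are adjusted by
Benjamini–Yekutieli across all tested alleles of a scan (the BY correction
is valid under the arbitrary positive dependence created by overlapping
windows); adjusted p < 0.05 is called significant. Deficits are summarized
as round(100·(1 − observed/expected)) percent, rounded half-up.

Significant windows merge into a region when they overlap by at least one
SNP *and* their allele strings agree on the shared SNPs — overlap alone
would chain unrelated lineages. The region's best window is the lowest raw
p, ties broken by larger expected count, then leftmost position.

## The mixed model

Pseudo-phenotypes are deregressed EBVs: pseudo = EBV/r², weight
w = r²/(1 − r²) capped at 20 (a parent-average-corrected variant,
pseudo = PA + (EBV − PA)/r², sits behind a flag). Weights are only applied
as residual-variance weights when explicitly enabled; the default is
unweighted because the pseudo-phenotypes already share one reliability
scale in the synthetic data.

The association model is y = μ + βx + g + e with g ~ N(0, G σ²g),
e ~ N(0, I σ²e) and G the VanRaden method-1 GRM,
G = ZZᵀ / (2Σpⱼ(1−pⱼ)). REML is exact and spectral: G is
eigendecomposed once, the ratio δ = σ²e/σ²g is profiled on a log grid and
refined by bounded scalar minimization, and β's Wald test follows from the
GLS fit at the optimum. With G = I this reduces analytically to ordinary
least squares, which is asserted in the tests. A ridge of 1e-6 is added
(and logged) when G is numerically indefinite.

**Proximal contamination.** In the GWAS (`gwas_scan`), the tested SNP's own
signal is partly absorbed by the polygenic term because the SNP also
contributes to G. On a real 114k-SNP genome a 50-SNP region is 0.04 % of
the markers and the effect is negligible; on the miniature synthetic
genomes here it is not. A leave-one-chromosome-out (LOCO) option is
provided, but it is **off by default**: on few-chromosome genomes the
excluded chromosome carries so much family covariance that LOCO de-controls
the null (λ_GC ≈ 4 observed with 6 chromosomes and highly heritable
pseudo-phenotypes), whereas the single-GRM default is calibrated
(λ_GC ≈ 1). The packaged GWAS scenarios therefore use 6 chromosomes and the
single-GRM default, where top-SNP localization to the causal window is
≥ 80 % at a −1 SD haplotype effect. On real-scale data LOCO is the better
choice and the option exists for that purpose.

## Variant prioritization

Array-design rules inside a region expanded by ±2 Mb: hard-filter PASS
(consumed from the VCF FILTER column; quality models are not
re-implemented), at least one carrier of the target breed, carrier
fraction ≤ 0.75 (inclusive boundary), at most one homozygous-alt animal,
and — by default — a protein-changing consequence class (missense,
nonsense, frameshift, in-frame indel, splice, start-lost). Missing
genotypes are excluded pairwise from every denominator. Survivors are
ranked by squared Pearson correlation between variant dosage and haplotype
diplotype dosage (both coded 0/1/2), ties by smaller carrier fraction,
then position; an exact single-variant Hardy–Weinberg 1-df χ² is attached.

## The synthetic population

The generator produces the statistical structure the scan assumes, not a
calibrated cattle genome:

* **Founders** carry per-SNP allele frequencies Uniform(0.05, 0.95)
  (avoiding monomorphic windows, consistent with a MAF > 0.01 filter) and
  are in linkage equilibrium. One risk haplotype — a fixed allele string
  over a 50-SNP stretch in the middle of chromosome 1 — is written onto
  founder haplotypes, one copy per selected founder, to hit the target
  founder frequency.
* **Gene-drop**: each generation a small set of sires is drawn and used
  with geometrically decaying weights (AI overuse); every dam produces a
  fixed number of conceptions; meioses have Poisson crossover counts under
  Haldane's map (no interference) with uniform placement. SNP spacing is
  20 kb so a 50-SNP window spans ~1 Mb, and map lengths are set so a
  window is ~1 cM — the density regime of a 114k array.
* **Lethality** removes homozygous-risk conceptuses with probability
  `penetrance` *before* any record exists; the scan can only infer the
  loss from the deficit, as in reality.
* **Genotyping**: all males, females at `female_genotyping_rate`,
  reproducing the trio < pgp dataset-size asymmetry of breeding programs.
* **Traits**: the true breeding value is a genomic infinitesimal polygenic
  term (independent normal effects on every segregating SNP, total
  variance h²; trait variance 1) plus `hap_trait_effect` per risk-allele
  copy. The EBV is r·TBV + noise with noise variance r(1−r)h², so the
  squared correlation between EBV and TBV equals the declared reliability
  r, and the deregressed pseudo-phenotype EBV/r is an unbiased noisy TBV.
  A direct consequence used by the tests: the *genetic variance share of
  the deregressed pseudo-phenotype equals r*, so REML heritability
  recovery is checked at constant r = 0.5 against a target of 0.5.

What the generator does **not** emulate: realistic cattle LD structure and
allele-frequency spectra, selection on EBVs across generations, genotyping
error, imputation error, phasing error, X-linked loci, or non-equilibrium
demography. Passing tests therefore demonstrate the statistical machinery
under its own assumptions — Mendelian transmission, known phase, correct
pedigrees — not robustness to real-data artifacts.

## Study scenarios and their sizing

* **Default config** (`SimConfig()`): 200 founders, 4 generations, 8
  sires/generation, risk frequency 0.05 (within the 1–5 % band where such
  alleles are typically found). Configs whose expected number of
  carrier × carrier matings is below one are rejected outright — a scan on
  such a population would be vacuous.
* **Power scenario** (`power_scan_config`): 600 founders, 4 generations,
  25 sires/generation (decay 0.9), founder risk frequency 0.3,
  female genotyping 0.9 → ~2,400 genotyped animals and ≥ 20 expected
  homozygotes on the truth window in *both* designs in essentially every
  seed. Two effects drove the sizing and must be budgeted jointly: full
  lethality purges the allele deterministically (q → q/(1+q) each
  generation, so 0.3 has eroded to ~0.15 by the last generation), and the
  pgp design contributes no generation-1 records because founder dams have
  no recorded sire. The founder frequency is deliberately above the real
  1–5 % band: it buys at desk scale (~2.5k animals) the carrier-mating
  counts that a 50k-animal population provides at 2–5 %.
* **Null calibration scenario** (`null_calibration_config`): the same
  population with penetrance 0 and the 2,000 SNPs rearranged into forty
  50-SNP chromosomes — one window per chromosome. Overlapping step-1
  windows of a single haplotype lineage share one realized deficit, so a
  pooled false-positive count over sliding windows is dominated by a few
  correlated clusters; one window per chromosome makes the tested alleles
  effectively independent so binomial sampling theory applies to the
  pooled rate. The exact test is discrete and therefore conservative: the
  observed false-positive fraction at nominal 0.05 is typically 0.03–0.05.
* **Association scenario**: 200 founders, 2 generations, fully genotyped
  (~600 animals), used for REML heritability recovery (±0.1 of target on
  the 20-seed mean), haplotype-effect sign recovery at −0.5 SD, and the
  GWAS examples (6-chromosome variant).

## Numerical details

* Window haplotypes are grouped by exact uint64 bit-codes (one bit per
  SNP; windows ≤ 64 SNPs), falling back to row-wise grouping for wider
  windows.
* Deficiency percentages round half-up (`floor(x + 0.5)`), so e.g.
  observed 2 / expected 16 → 88 %.
* The Poisson-binomial DP accumulates only counts ≤ observed; p = 1 is
  returned exactly when observed ≥ the number of at-risk offspring.
* REML's profile grid spans δ ∈ [1e-5, 1e5] (40 log-spaced points) before
  bounded refinement; the optimizer's criterion value is asserted in tests
  to beat a 400-point fine grid.
* All randomness flows through one `numpy.random.Generator` per simulation
  seeded from `SimConfig.seed`; identical configs give byte-identical VCF,
  pedigree and trait outputs. Trait simulation inside
  `simulate_population` derives its seed from the same stream.
* Degenerate inputs fail loudly: constant covariates, unphased input to
  diplotype assignment, all-monomorphic GRM input, reliability outside
  (0, 1], trio scans without genotyped dams (the error points to pgp),
  unknown breed labels (the error lists the labels seen).

## Known limitations

* The transmission model ignores within-window recombination: a
  heterozygous parent transmits the intact 50-SNP allele with probability
  slightly below ½ (≈ ½·(1−c), c the window's crossover probability). At
  the simulated ~1 cM windows this overstates expectations by ~1 %; at
  real 114k density (~0.05 cM windows) it is negligible.
* `merge_regions` chains windows pairwise; two lineages that share a long
  identical stretch could in principle be chained through it.
* The pgp q-term uses the current population frequency for the granddam
  generation; under strong purging the ancestral frequency was higher, so
  pgp expectations are mildly conservative late in a purged pedigree.
* Association uses additive dosage coding only; a purely recessive lethal
  with no heterozygote effect yields no additive signal in living animals,
  which is why trait association complements rather than replaces the
  deficit scan.
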