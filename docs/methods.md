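# Methods

## The generative model

A simulated study is built in four layers, all driven by one seed.

**Ancestral frequencies.** Each of `n_sites` biallelic SNPs gets an
ancestral alt-allele frequency drawn i.i.d. from a truncated power law,
density ∝ x^(−α) on [1/(2H), 0.5], where H = `n_ancestral_haps`. α = 1
(the default) mimics the neutral 1/x site-frequency spectrum; α = 0 is
uniform. The lower truncation ties the rarest simulable allele to the
founder-pool size, as in a real finite population. Site positions are
distinct uniform draws on `region_length` (default 1 Mb), one
chromosome per simulation.

**Population divergence.** Each subpopulation i draws per-site
frequencies from the Balding–Nichols distribution
Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `fst_per_pop[i]` (F = 0 keeps the
ancestral frequency; F = 1 is rejected as degenerate). Two populations
each drifted at F from the shared ancestor show pairwise Hudson F_ST ≈
F: the estimator's numerator has expectation 2F·p(1−p) and its
denominator 2p(1−p), so the experiments labelled "F_ST = 0.05" use
symmetric drift at 0.05.

**Haplotypes.** Each population has a pool of H founder haplotypes
drawn i.i.d. Bernoulli at its drifted frequencies. Every emitted
haplotype — reference panel and target cohort alike — is a recombinant
mosaic of that pool: copying switches to a uniformly chosen founder
between adjacent sites with probability 1 − exp(−r·d) (r =
`recomb_rate`, per base; default 2×10⁻⁶), and each copied allele flips
with probability `flip_rate` (default 10⁻³, playing the role of
mutation/genotyping noise). This gives the two properties the
benchmark needs with very few parameters: LD (nearby sites are
co-copied from the same founder, so founder-pool drift correlations
persist locally and decay with distance) and ancestry match (a panel
built from the *same* founder pool as the targets shares identical
haplotype segments with them; a panel from another population shares
only frequencies). Coalescent-exact simulation is deliberately out of
scope — effect sizes here are meant to be controllable, not
demographically realistic.

**Cohort assembly.** Per population, `panel_size` diploid reference
samples and `pop_sizes[i]` diploid targets are drawn from the same
founders. Optionally, a fraction of admixed individuals is appended:
each of their two haplotypes comes from population A's generative
process with probability `admix_q`, else B's, and the realised
per-haplotype ancestry is recorded as ground truth. The "array" is the
set of every `array_spacing`-th site among sites with cohort MAF ≥
`array_maf_min` (defaults 2 and 0.05 — a common-variant grid covering
about half of the common sites, the regime genotyping arrays operate
in). Binary phenotypes follow a logistic model whose intercept is set
by bisection so the expected prevalence equals `case_fraction`.

Everything is emitted pre-phased. Phasing error is intentionally absent
so the benchmark isolates imputation accuracy; diploid imputation is
two haploid passes.

## The imputer

The copying model is the standard Li–Stephens HMM: hidden state =
which of the K panel haplotypes is being copied; between adjacent sites
the chain stays with probability 1 − s + s/K and moves to each specific
other state with probability s/K, where s = 1 − exp(−ρ·d/K) for
inter-site distance d. Typed sites emit the observed allele with
probability 1 − ε (ε = `err`, default 0.01); untyped sites emit
uniformly, which keeps them in the lattice (so their allele posterior
is exactly Σ_k γ_k(m)·panel_k(m)) at the cost of Minimac-style state
interpolation — a deliberate trade of speed for a model that an
exhaustive path-enumeration oracle can verify bit-for-bit on small
instances. The mismatch correction (1−ε)p + ε(1−p) is applied at typed
sites only.

The default ρ = 6×10⁻⁴ per base equals the generator's default
recombination intensity times its default panel size (2×10⁻⁶ × 300),
i.e. the copying chain is calibrated to switch about as often as the
mosaics it tracks actually recombine; it is overridable everywhere
(`--rho`). Forward–backward runs with per-site rescaling (normalised
forward vectors, max-rescaled backward vectors) and batches target
haplotypes with a cap of ~32M lattice cells per block to bound memory.

Per-variant confidence is the Minimac convention: with haploid allele
probabilities a₁..a_{2N}, R̂² = Var(a)/(p̂(1−p̂)) with the
population-variance denominator, clipped to [0, 1]; a monomorphic
estimate gets R̂² = 0. Hard calls take the argmax genotype probability
with ties resolved toward the smaller genotype code, and array-observed
genotypes override the posterior at typed sites.

## Accuracy metrics

**GCR** is per sample: the fraction of evaluation sites where the
imputed hard call equals the truth call, excluding truth-missing sites
from that sample's denominator (a missing imputed call counts as
discordant; the choice is stated in report headers since conventions
differ). Evaluation sites are the intersection of QCed truth sites
with every imputed dataset — which includes array-typed sites, exactly
as a WGS-validation design evaluates every site present in the imputed
VCFs. GCR restricted to an estimated-R² stratum simply recomputes this
on the stratum's variants; empty strata are reported NA, never 0.

**Per-AF-bin r²** pools all (sample, variant) dosage/truth pairs within
a bin into one squared Pearson correlation (the aggregation used by
GLIMPSE-style concordance tools), rather than averaging per-variant
r² — pooling is what makes sub-1% bins estimable at desk scale. Bins
are on the external AF table's (unfolded) alt-allele frequency by
default — the table plays the role of a population database such as
gnomAD — with `--fold-maf` and `--af-source cohort` as alternatives.
Zero-variance bins are NA.

**Yield tables** count variants with R̂² ≥ c for c ∈ {none, 0.2, 0.4,
0.6, 0.8}, split by variant class; the confidence histogram uses the
strata [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1].

## QC and harmonization

Array/panel reconciliation matches records on (chrom, pos) and decides
keep / strand-flip / ref-alt-swap / flip-and-swap by allele
identity under reverse complement and exchange; A/T and C/G
(palindromic) SNPs, where strand cannot be decided from alleles, are
oriented by allele frequency and excluded when MAF ≥ 0.40 (default
`palindromic_maf_max`); after orientation, records with
|AF_array − AF_panel| > 0.20 (default `af_diff_max`) are excluded as
discrepant. Both thresholds are conventional defaults, flagged in the
report header and overridable, since published pipelines vary.

Sample QC removes samples with missingness > 0.05 (strict), then
breaks relatedness: a GCTA-style standardized GRM,
A_jk = (1/M′) Σ (x_ij−2p_i)(x_ik−2p_i)/(2p_i(1−p_i)) over polymorphic
sites, pruned greedily (most offending pairs first; ties by higher
missingness, then later sample order) until no pair exceeds 0.5.
Truth-set site QC drops non-PASS FILTER rows, site missingness > 0.10,
and exact Hardy–Weinberg p < 10⁻⁶. The HWE test is the two-sided exact
conditional test, computed by the multiplicative recurrence between
adjacent heterozygote counts started at the mode (no factorials); a
configuration's p-value sums all null probabilities ≤ its own, with a
10⁻¹² relative slack for floating-point ties. A sex-concordance hook
exists but is a documented no-op: the simulation has no sex
chromosomes.

## Population structure and association

LD pruning follows the 50-variant/10-step/r² > 0.2 sliding-window
scheme; within a window the strongest offending pair is broken first,
removing its smaller-MAF member (tie: later position), which fixes a
deterministic output where tool versions differ. MDS is classical
Torgerson scaling of the IBS distance D_jk = mean(|x_j − x_k|)/2, with
axis signs normalised (first nonzero loading positive). Admixture
fits Q (n×K, rows on the simplex) and F (K×M) by EM on the binomial
likelihood with the classic expected ancestry-of-allele-count updates
— the same likelihood the block-relaxation tools maximise, chosen for
its guaranteed monotone trace (asserted to 10⁻⁸). F is clipped to
[10⁻⁶, 1−10⁻⁶]; missing genotypes drop out of the likelihood;
`n_starts` (default 3) random initialisations keep the best
likelihood; tolerance 10⁻⁶ on the log-likelihood gain, max 2000
iterations. K=2 label switching is resolved in evaluations by
correlating Q columns with the truth.

The association scan is the additive expected-dosage score test: fit
the logistic null (intercept + covariates, Newton with pseudo-inverse
so redundant covariates are harmless), then per variant
U = d′(y−ŷ), Var = d′Wd − d′WX(X′WX)⁻¹X′Wd, χ² = U²/Var on 1 df. On
hard genotypes with no covariates this is algebraically the
Cochran–Armitage trend test (asserted to 10⁻⁹). Monomorphic dosages
report (0, p=1). Variants with p < 5×10⁻⁸ are grouped greedily into
lead signals: the smallest p seeds a ±1 Mb region (window overridable),
absorbed variants are removed, repeat. LD between variants is the
composite r² of genotype dosages.

## Benchmark experiment conditions

The canned experiments in `bench` fix the study conditions:

* **Panel comparison** — 3000 sites / 1 Mb, 100 founders per
  population, panels of 150 diploids, 25 diploid pop-A targets,
  symmetric F = 0.05, 20 replicates. Reported per replicate: cohort
  median GCR per panel, the mismatched panel's pooled r² in the
  common/low-frequency/rare bins, and median GCR restricted to
  R̂² ≥ 0.8. The confidence-stratification comparison is made on the
  mismatched imputation: that is the regime where confidence filtering
  has errors to remove. A strongly matched panel in this generator sits
  near the concordance ceiling with its residual errors concentrated in
  common (hence high-confidence) variants, while rare variants are
  overwhelmingly concordant hom-ref calls — so filtering cannot raise
  its GCR, and the package does not claim it does.
* **Calibration** — 200 diploid targets, 2000 sites, founder pool (200)
  deliberately close to the panel size (150 diploids) so imputation
  quality varies across variants; pooled dosage-truth r² is computed
  within each estimated-R² decile (quantile bins; deciles with no
  dosage variance are NA and dropped) and summarised by the Spearman
  rank correlation with the decile index.
* **Admixture recovery** — 100 individuals (40 + 40 pure, 20 admixed at
  q = 0.5), 2000 sites, symmetric F = 0.1; RMSE between aligned Q and
  the realised per-individual ancestry fraction.
* **MDS separation** — 50 + 50 individuals at symmetric F = 0.1, 3000
  sites, LD-pruned; the two label groups' ranges on the first
  coordinate must be disjoint.

These sizes were chosen so the full acceptance battery runs in minutes
on one core while keeping every comparison comfortably out of the
noise; they are package defaults, not tuning knobs, and the test suite
runs them unchanged.

## Numerical choices and degenerate inputs

Probability simplex checks at 10⁻⁹; dosage ≡ P(het) + 2P(hom-alt)
enforced at dataset construction. Forward–backward normalisation per
site; enumeration oracle agreement required to 10⁻⁸. Undefined
statistics (zero-variance r², empty strata, zero-denominator GCR) are
NaN/NA, never 0. Genotype matrices use −1 for missing throughout.
Errors are raised for: F_ST = 1, empty typed set, unattainable
prevalence, typed sites absent from the panel, unphased targets, odd
haplotype counts, all-monomorphic GRM input, one phenotype class,
d > n−1 MDS dimensions, K < 1.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the evaluation
machinery depends on — frequency spectra with rare variants, LD decay,
ancestry-dependent haplotype sharing, admixture, common-variant
arrays — so a passing suite demonstrates the *pipeline* (QC, imputer,
metrics, structure, association) is correct and that the
matched-panel/frequency/confidence effects it measures behave as theory
predicts. It does not demonstrate performance on real data: founder
mosaics are not coalescent genealogies, flip noise is not a platform
error model, one 1 Mb chromosome is not a genome, sex chromosomes and
INDELs are absent (INDEL accuracy is also excluded from the metrics by
design), and the mismatched panel here shares *no* haplotype segments
with the targets — an extreme that real panels, which share deep
ancestry, do not reach. Absolute GCR/r² values from this benchmark
should therefore not be read as forecasts for any real panel; the
ordering and stratification effects are the transferable content.
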