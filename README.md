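# panelbench

Benchmarking genotype-imputation accuracy against reference panels, on
synthetic structured populations.

## The problem

Genotyping arrays observe a sparse set of common variants; imputation
fills in the rest by matching each target haplotype against a phased
reference panel. How well this works depends heavily on the panel: a
smaller panel whose populations are genetically close to the study
cohort can beat a much larger but ancestrally mismatched one, and
accuracy always degrades from common variants toward rare ones. Teams
choosing a panel for an underrepresented population need a way to
quantify these effects; `panelbench` provides the full evaluation
pipeline — and, because real cohorts and commercial panels are usually
access-restricted, a generator of synthetic cohorts with the relevant
structure (population divergence, linkage disequilibrium, admixture,
array-style site masking) so every stage can be exercised end to end at
desk scale.

## What's inside

| module | contents |
|---|---|
| `simdata` | structured-cohort generator: truncated power-law ancestral SFS, Balding–Nichols drift (`Beta(p(1−F)/F, (1−p)(1−F)/F)`), recombinant founder-mosaic haplotypes, admixed individuals, array masking, logistic phenotypes |
| `lsimpute` | Li–Stephens haplotype-copying HMM: forward–backward over K panel haplotypes, switch probability `1 − exp(−ρd/K)`, emission error ε; dosages `DS`, genotype probabilities `GP`, hard calls, and a Minimac-style per-variant estimated R² = Var(haploid allele probability)/p̂(1−p̂) |
| `harmonize` | array/panel variant reconciliation (strand flip, ref/alt swap, palindromic-SNP policy, AF-discrepancy filter), sample missingness, GRM relatedness pruning, exact Hardy–Weinberg test (Wigginton-style enumeration), truth-set site QC, evaluation-site intersection |
| `concordance` | per-sample genotype concordance rate (GCR), pooled dosage–truth r² per allele-frequency bin (common ≥ 0.05, 0.01 ≤ low-frequency < 0.05, rare < 0.01, plus fine sub-1% bins), variant yields by R² cutoff, GCR by confidence stratum |
| `popstruct` | LD pruning (50/10/0.2 sliding window), IBS distance, classical (Torgerson) MDS, K-population admixture by EM on the binomial likelihood |
| `assoc` | logistic score test on dosages (equals the Cochran–Armitage trend test on hard calls), genome scan with MAF/info filters, lead-signal grouping at p < 5×10⁻⁸, composite LD r² |
| `bench` | canned experiments wiring the above into the matched-vs-mismatched panel comparison and calibration/recovery studies |

## Worked example

Impute one population's samples from its own reference panel and from
an equally sized panel of a diverged population (both drifted at
F_ST = 0.05 from a shared ancestor), then score both:

```python
import numpy as np
import panelbench as pb

cfg = pb.SimConfig(seed=1, n_sites=2000, n_ancestral_haps=100,
                   panel_size=150, pop_sizes=(25, 25),
                   fst_per_pop=(0.05, 0.05))
cohort = pb.simulate_cohort(cfg)

params = pb.LSParams(rho=cfg.recomb_rate * 2 * cfg.panel_size)
targets = cohort.targets[:50]            # population-A haplotypes
truth = cohort.truth_genotypes()[:25]
ids = cohort.sample_ids[:25]
eval_idx = np.arange(cfg.n_sites)

for pop in ("A", "B"):
    ds = pb.impute_cohort(targets, cohort.typed_idx, cohort.panels[pop],
                          params, sample_ids=ids)
    report = pb.evaluate(ds, truth, cohort.ancestral_freqs, eval_idx)
    s = report.summary()
    r2 = report.per_bin_r2
    print(f"panel {pop}: median GCR {s['gcr_median']:.3f} "
          f"(IQR {s['gcr_q1']:.3f}-{s['gcr_q3']:.3f}), "
          f"r2 common/low/rare = "
          f"{r2['common']:.3f}/{r2['low_frequency']:.3f}/{r2['rare']:.3f}")
```

Output:

```
panel A: median GCR 0.993 (IQR 0.991-0.997), r2 common/low/rare = 0.965/0.905/0.792
panel B: median GCR 0.844 (IQR 0.841-0.849), r2 common/low/rare = 0.216/0.004/0.000
```

The ancestry-matched panel (A) shares founder haplotype segments with
the targets, so the copying model can track them and recover untyped
alleles; the mismatched panel (B) shares only drifted allele
frequencies, and accuracy collapses — fastest for rare variants, whose
carriers are exactly the haplotypes a mismatched panel cannot supply.

The same pipeline is available from the shell:

```sh
panelbench simulate --config cfg.yaml --seed 1 --out sim/
panelbench impute --array sim/truth.vcf --panel sim/panel_A.vcf --out imputed.vcf
panelbench concord --imputed imputed.vcf --truth sim/truth.vcf --af sim/af.tsv --out reports/
panelbench popstruct --geno sim/array.vcf --k 2 --out structure/
panelbench assoc --imputed imputed.vcf --pheno sim/pheno.tsv --out gwas/
```

All reports are TSV and byte-reproducible for a fixed seed.

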