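"""Reading and writing the pipeline's file formats.

VCF 4.2 throughout: truth and panel files carry phased ``GT``; the array
file carries unphased ``GT`` at typed sites; the imputed file carries
``GT``/``DS``/``GP`` per sample plus per-variant ``R2`` and ``TYPED``
INFO fields (the layout imputation servers emit).  Sidecar tables are
plain TSV: an allele-frequency table (``CHROM POS REF ALT AF``) and a
phenotype table (``SAMPLE STATUS``).

Writing goes through pysam, reading through cyvcf2.  Headers are fully
deterministic (no timestamps), so identical inputs give byte-identical
files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .lsimpute import ImputedDataset
from .simdata import HaplotypePanel, SimulatedCohort, VariantKey

__all__ = [
    "write_haplotype_vcf",
    "write_genotype_vcf",
    "write_imputed_vcf",
    "read_genotype_vcf",
    "read_haplotype_vcf",
    "read_imputed_vcf",
    "write_af_table",
    "read_af_table",
    "write_phenotypes",
    "read_phenotypes",
    "write_cohort",
]

MISSING = -1


def _make_header(variants: Sequence[VariantKey], sample_ids: Sequence[str],
                 fmts: Sequence[tuple[str, str, str, str]],
                 infos: Sequence[tuple[str, str, str, str]] = ()
                 ) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)
    for name, number, vtype, desc in infos:
        header.info.add(name, number, vtype, desc)
    for name, number, vtype, desc in fmts:
        header.formats.add(name, number, vtype, desc)
    for s in sample_ids:
        header.add_sample(s)
    return header


def _check_sorted(variants: Sequence[VariantKey]) -> None:
    keys = [(v.chrom, v.pos) for v in variants]
    if any(b <= a for a, b in zip(keys, keys[1:])):
        raise ValueError("variants must be strictly sorted by (chrom, pos)")


def write_haplotype_vcf(path, variants: Sequence[VariantKey],
                        haplotypes: np.ndarray,
                        sample_ids: Optional[Sequence[str]] = None) -> None:
    """Phased diploid VCF from a 2N x M haplotype matrix."""
    haplotypes = np.asarray(haplotypes)
    if haplotypes.shape[0] % 2:
        raise ValueError("haplotype count must be even")
    _check_sorted(variants)
    n = haplotypes.shape[0] // 2
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    header = _make_header(variants, sample_ids,
                          [("GT", "1", "String", "Genotype")])
    try:
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for j, v in enumerate(variants):
                rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                     alleles=(v.ref, v.alt), id=v.id)
                rec.filter.add("PASS")
                for i, s in enumerate(sample_ids):
                    rec.samples[s]["GT"] = (int(haplotypes[2 * i, j]),
                                            int(haplotypes[2 * i + 1, j]))
                    rec.samples[s].phased = True
                out.write(rec)
    except OSError as e:
        raise OSError(f"failed writing VCF {path}: {e}") from e


def write_genotype_vcf(path, variants: Sequence[VariantKey],
                       genotypes: np.ndarray,
                       sample_ids: Optional[Sequence[str]] = None,
                       filters: Optional[Sequence[str]] = None) -> None:
    """Unphased diploid VCF from an N x M 0/1/2 matrix (-1 = missing)."""
    genotypes = np.asarray(genotypes)
    _check_sorted(variants)
    n = genotypes.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    header = _make_header(variants, sample_ids,
                          [("GT", "1", "String", "Genotype")])
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    try:
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for j, v in enumerate(variants):
                rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                     alleles=(v.ref, v.alt), id=v.id)
                rec.filter.add(filters[j] if filters is not None else "PASS")
                for i, s in enumerate(sample_ids):
                    rec.samples[s]["GT"] = gt_map[int(genotypes[i, j])]
                out.write(rec)
    except OSError as e:
        raise OSError(f"failed writing VCF {path}: {e}") from e


def write_imputed_vcf(path, dataset: ImputedDataset) -> None:
    """Imputed VCF with GT/DS/GP per sample and R2/TYPED INFO fields."""
    _check_sorted(dataset.variants)
    header = _make_header(
        dataset.variants, dataset.sample_ids,
        [("GT", "1", "String", "Genotype"),
         ("DS", "1", "Float", "Estimated alternate allele dosage"),
         ("GP", "G", "Float", "Genotype posterior probabilities")],
        [("R2", "1", "Float", "Estimated imputation accuracy"),
         ("TYPED", "0", "Flag", "Site was genotyped on the array")])
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    try:
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for j, v in enumerate(dataset.variants):
                rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                     alleles=(v.ref, v.alt), id=v.id)
                rec.filter.add("PASS")
                rec.info["R2"] = round(float(dataset.est_r2[j]), 5)
                if bool(dataset.typed[j]):
                    rec.info["TYPED"] = True
                for i, s in enumerate(dataset.sample_ids):
                    rec.samples[s]["GT"] = gt_map[int(dataset.hard_calls[i, j])]
                    rec.samples[s]["DS"] = round(float(dataset.dosages[i, j]), 4)
                    rec.samples[s]["GP"] = tuple(
                        round(float(x), 4) for x in dataset.genotype_probs[i, j])
                out.write(rec)
    except OSError as e:
        raise OSError(f"failed writing VCF {path}: {e}") from e


def _keys_from_record(v) -> VariantKey:
    return VariantKey(v.CHROM, v.POS, v.REF, v.ALT[0])


def read_genotype_vcf(path) -> tuple[list[VariantKey], np.ndarray, list[str],
                                     list[str]]:
    """Read GT into an N x M 0/1/2 matrix (-1 missing).

    Returns (variants, genotypes, sample ids, FILTER values).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, cols, filts = [], [], []
    for v in vcf:
        variants.append(_keys_from_record(v))
        gts = np.array(v.genotypes, dtype=int)  # n x 3 (a1, a2, phased)
        col = np.where((gts[:, 0] < 0) | (gts[:, 1] < 0), MISSING,
                       gts[:, 0] + gts[:, 1])
        cols.append(col)
        filts.append(v.FILTER or "PASS")
    vcf.close()
    G = np.array(cols, dtype=np.int8).T if cols else np.empty((len(samples), 0),
                                                              dtype=np.int8)
    return variants, G, samples, filts


def read_haplotype_vcf(path) -> tuple[list[VariantKey], np.ndarray, list[str]]:
    """Read phased GT into a 2N x M 0/1 haplotype matrix."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, cols = [], []
    for v in vcf:
        variants.append(_keys_from_record(v))
        gts = np.array(v.genotypes, dtype=int)
        if (gts[:, 2] == 0).any():
            raise ValueError(f"unphased genotype in {path} at {v.POS}")
        cols.append(gts[:, :2].ravel())
    vcf.close()
    H = (np.array(cols, dtype=np.int8).T
         if cols else np.empty((2 * len(samples), 0), dtype=np.int8))
    return variants, H, samples


def read_imputed_vcf(path) -> ImputedDataset:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, ds, gp, hc, r2, typed = [], [], [], [], [], []
    for v in vcf:
        variants.append(_keys_from_record(v))
        gts = np.array(v.genotypes, dtype=int)
        hc.append(gts[:, 0] + gts[:, 1])
        ds.append(v.format("DS")[:, 0])
        gp.append(v.format("GP"))
        r2.append(v.INFO.get("R2"))
        typed.append(bool(v.INFO.get("TYPED")))
    vcf.close()
    gp_arr = np.array(gp, dtype=float).transpose(1, 0, 2)
    gp_arr /= gp_arr.sum(axis=2, keepdims=True)  # undo rounding drift
    ds_arr = gp_arr[:, :, 1] + 2.0 * gp_arr[:, :, 2]
    return ImputedDataset(variants, ds_arr, gp_arr,
                          np.array(hc, dtype=np.int8).T,
                          np.array(r2, dtype=float),
                          np.array(typed, dtype=bool), samples)


# ---------------------------------------------------------------------------
# TSV sidecars


def write_af_table(path, variants: Sequence[VariantKey],
                   af: np.ndarray) -> None:
    df = pd.DataFrame({"CHROM": [v.chrom for v in variants],
                       "POS": [v.pos for v in variants],
                       "REF": [v.ref for v in variants],
                       "ALT": [v.alt for v in variants],
                       "AF": np.round(np.asarray(af, dtype=float), 6)})
    df.to_csv(path, sep="\t", index=False)


def read_af_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    required = {"CHROM", "POS", "REF", "ALT", "AF"}
    if not required.issubset(df.columns):
        raise ValueError(f"AF table must have columns {sorted(required)}")
    return df


def af_lookup(af_table: pd.DataFrame,
              variants: Sequence[VariantKey]) -> np.ndarray:
    """Per-variant AF from the table; NaN where a variant is absent."""
    idx = {(r.CHROM, r.POS, r.REF, r.ALT): r.AF
           for r in af_table.itertuples(index=False)}
    return np.array([idx.get((v.chrom, v.pos, v.ref, v.alt), np.nan)
                     for v in variants])


def write_phenotypes(path, sample_ids: Sequence[str],
                     status: np.ndarray) -> None:
    pd.DataFrame({"SAMPLE": list(sample_ids),
                  "STATUS": np.asarray(status, dtype=int)}
                 ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"SAMPLE": str})
    if not {"SAMPLE", "STATUS"}.issubset(df.columns):
        raise ValueError("phenotype table must have SAMPLE and STATUS columns")
    return df.set_index("SAMPLE")["STATUS"]


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write a simulated cohort's full file set into ``outdir``.

    truth.vcf (phased targets), panel_<pop>.vcf per reference panel,
    array.vcf (unphased genotypes at typed sites), af.tsv (ancestral
    frequencies, playing the external-database role) and pheno.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["truth"] = outdir / "truth.vcf"
    write_haplotype_vcf(paths["truth"], cohort.variants, cohort.targets,
                        cohort.sample_ids)
    for pop, panel in cohort.panels.items():
        p = outdir / f"panel_{pop}.vcf"
        write_haplotype_vcf(p, panel.variants, panel.haplotypes,
                            [f"P{pop}{i:04d}" for i in range(panel.n_haplotypes // 2)])
        paths[f"panel_{pop}"] = p

    typed = cohort.typed_idx
    geno = cohort.truth_genotypes()[:, typed]
    arr_variants = [cohort.variants[j] for j in typed]
    paths["array"] = outdir / "array.vcf"
    write_genotype_vcf(paths["array"], arr_variants, geno, cohort.sample_ids)

    paths["af"] = outdir / "af.tsv"
    write_af_table(paths["af"], cohort.variants, cohort.ancestral_freqs)
    paths["pheno"] = outdir / "pheno.tsv"
    write_phenotypes(paths["pheno"], cohort.sample_ids, cohort.phenotypes)
    return paths
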