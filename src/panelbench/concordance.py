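"""Imputation-accuracy metrics.

Four views of accuracy, all comparing an imputed dataset to truth
genotypes on an evaluation site set:

* per-sample genotype concordance rate (GCR): the fraction of evaluated
  sites where the imputed hard call equals the truth call,
* pooled squared Pearson correlation (r^2) between imputed dosage and
  truth dosage within allele-frequency bins — the standard way to show
  that rare variants impute worse than common ones,
* variant yields above estimated-R^2 cutoffs (how many variants survive
  a confidence filter),
* GCR restricted to estimated-R^2 strata (does the confidence score
  track realised accuracy).

Truth genotypes use -1 for missing; missing truth is excluded from a
sample's GCR denominator, while a missing imputed hard call counts as
discordant.  Undefined statistics (empty bins, zero-variance bins) are
reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lsimpute import ImputedDataset
from .simdata import VariantKey

__all__ = [
    "BinSpec",
    "COARSE_BINS",
    "FINE_BINS",
    "R2_STRATA",
    "ConcordanceReport",
    "gcr_per_sample",
    "pooled_r2_by_bin",
    "yield_by_cutoff",
    "r2_histogram",
    "gcr_by_stratum",
    "evaluate",
]

MISSING = -1


@dataclass(frozen=True)
class BinSpec:
    """Allele-frequency bins from a strictly decreasing edge list.

    Edges (e1 > e2 > ... > ek) define bins [e2, e1], [e3, e2), ...,
    (0, ek): the top bin is closed at its upper edge, the bottom bin is
    open at 0, interior bins are left-closed.  Together with (0, ek)
    they partition (0, e1].
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 1 or any(b >= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly decreasing")
        if any(not 0.0 < x <= 1.0 for x in e):
            raise ValueError("edges must lie in (0, 1]")
        if self.labels and len(self.labels) != self.n_bins:
            raise ValueError("one label per bin required")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def bin_labels(self) -> tuple[str, ...]:
        if self.labels:
            return self.labels
        e = self.edges
        out = [f"[{e[i + 1]:g},{e[i]:g})" for i in range(len(e) - 1)]
        out = [f"[{e[1]:g},{e[0]:g}]"] + out[1:] if len(e) > 1 else []
        out.append(f"(0,{e[-1]:g})" if len(e) > 1 else f"(0,{e[0]:g}]")
        return tuple(out)

    def assign(self, af: np.ndarray) -> np.ndarray:
        """Bin index per AF (0 = highest-frequency bin); -1 if outside (0, e1]."""
        af = np.asarray(af, dtype=float)
        e = self.edges
        idx = np.full(af.shape, -1, dtype=int)
        ok = (af > 0) & (af <= e[0])
        for i in range(len(e)):
            if i == 0:
                lo = e[1] if len(e) > 1 else 0.0
                sel = ok & (af >= lo) if len(e) > 1 else ok
            elif i < len(e) - 1:
                sel = ok & (af >= e[i + 1]) & (af < e[i])
            else:
                sel = ok & (af < e[i])
            idx[sel] = i
        return idx


COARSE_BINS = BinSpec((1.0, 0.05, 0.01), ("common", "low_frequency", "rare"))
FINE_BINS = BinSpec((0.01, 0.009, 0.008, 0.007, 0.006, 0.005,
                     0.004, 0.003, 0.002, 0.001))

# estimated-R^2 confidence strata: half-open except the last, closed at 1
R2_STRATA = ((0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0))


@dataclass
class ConcordanceReport:
    per_sample_gcr: pd.Series
    per_bin_r2: pd.Series
    yields: pd.DataFrame
    r2_fractions: pd.Series
    gcr_by_stratum: pd.DataFrame
    n_eval_sites: int

    def summary(self) -> dict:
        g = self.per_sample_gcr.dropna()
        return {
            "n_eval_sites": self.n_eval_sites,
            "gcr_median": float(g.median()),
            "gcr_q1": float(g.quantile(0.25)),
            "gcr_q3": float(g.quantile(0.75)),
            "gcr_min": float(g.min()),
            "gcr_max": float(g.max()),
        }


def _stratum_mask(r2: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi >= 1.0:
        return (r2 >= lo) & (r2 <= 1.0)
    return (r2 >= lo) & (r2 < hi)


def gcr_per_sample(imputed_calls: np.ndarray, truth_calls: np.ndarray,
                   sample_ids: Sequence[str],
                   eval_idx: Optional[np.ndarray] = None) -> pd.Series:
    """Per-sample genotype concordance rate over the evaluation sites.

    The denominator is the number of evaluation sites with non-missing
    truth for that sample; a missing imputed call is discordant.  Samples
    with an empty denominator get NaN.
    """
    imp = np.asarray(imputed_calls)
    tru = np.asarray(truth_calls)
    if imp.shape != tru.shape:
        raise ValueError("imputed and truth matrices must align")
    if eval_idx is not None:
        imp = imp[:, eval_idx]
        tru = tru[:, eval_idx]
    ok = tru != MISSING
    match = ok & (imp == tru)
    denom = ok.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        gcr = np.where(denom > 0, match.sum(axis=1) / denom, np.nan)
    return pd.Series(gcr, index=list(sample_ids), name="gcr")


def _pooled_r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pooled_r2_by_bin(dosages: np.ndarray, truth: np.ndarray,
                     af: np.ndarray, bins: BinSpec = COARSE_BINS,
                     eval_idx: Optional[np.ndarray] = None,
                     fold_maf: bool = False) -> pd.Series:
    """Pooled squared Pearson correlation per AF bin.

    All (sample, variant) dosage/truth pairs of a bin's variants are
    pooled into one correlation; truth-missing pairs are dropped.
    Variants without an AF entry (NaN) are dropped.  Degenerate bins
    yield NaN.  Bins are on the (unfolded) alt-allele frequency by
    default; ``fold_maf`` folds the AF to the minor-allele frequency for
    bin membership only.
    """
    ds = np.asarray(dosages, dtype=float)
    tr = np.asarray(truth, dtype=float)
    af = np.asarray(af, dtype=float)
    if fold_maf:
        af = np.minimum(af, 1.0 - af)
    if eval_idx is not None:
        ds, tr, af = ds[:, eval_idx], tr[:, eval_idx], af[eval_idx]
    assign = np.where(np.isnan(af), -1, bins.assign(np.nan_to_num(af)))
    out = {}
    for i, label in enumerate(bins.bin_labels()):
        cols = assign == i
        if not cols.any():
            out[label] = float("nan")
            continue
        x = ds[:, cols].ravel()
        y = tr[:, cols].ravel()
        keep = y != MISSING
        out[label] = _pooled_r2(x[keep], y[keep])
    return pd.Series(out, name="r2")


def yield_by_cutoff(dataset: ImputedDataset,
                    cutoffs: Sequence[Optional[float]] = (None, 0.2, 0.4, 0.6, 0.8)
                    ) -> pd.DataFrame:
    """Variant counts surviving each estimated-R^2 cutoff, split by class."""
    r2 = np.asarray(dataset.est_r2)
    vclass = np.array([v.vclass for v in dataset.variants])
    rows = []
    for c in cutoffs:
        sel = np.ones(r2.size, dtype=bool) if c is None else r2 >= c
        rows.append({"cutoff": "none" if c is None else c,
                     "n_snp": int((sel & (vclass == "SNP")).sum()),
                     "n_indel": int((sel & (vclass == "INDEL")).sum()),
                     "n_total": int(sel.sum())})
    return pd.DataFrame(rows).set_index("cutoff")


def r2_histogram(dataset: ImputedDataset,
                 strata: Sequence[tuple[float, float]] = R2_STRATA) -> pd.Series:
    """Fraction of variants in each estimated-R^2 stratum (sums to 1)."""
    r2 = np.asarray(dataset.est_r2)
    out = {}
    for lo, hi in strata:
        label = f"[{lo:g},{hi:g}{']' if hi >= 1 else ')'}"
        out[label] = float(_stratum_mask(r2, lo, hi).mean()) if r2.size else float("nan")
    return pd.Series(out, name="fraction")


def gcr_by_stratum(dataset: ImputedDataset, truth_calls: np.ndarray,
                   eval_idx: np.ndarray,
                   strata: Sequence[tuple[float, float]] = R2_STRATA
                   ) -> pd.DataFrame:
    """Per-sample GCR recomputed within each estimated-R^2 stratum.

    Strata with no evaluation variants give NaN columns (flagged
    undefined, not computed through empty arrays).
    """
    eval_idx = np.asarray(eval_idx)
    r2 = np.asarray(dataset.est_r2)[eval_idx]
    cols = {}
    for lo, hi in strata:
        label = f"[{lo:g},{hi:g}{']' if hi >= 1 else ')'}"
        sub = eval_idx[_stratum_mask(r2, lo, hi)]
        if sub.size == 0:
            cols[label] = pd.Series(np.nan, index=dataset.sample_ids)
        else:
            cols[label] = gcr_per_sample(dataset.hard_calls, truth_calls,
                                         dataset.sample_ids, sub)
    return pd.DataFrame(cols)


def evaluate(dataset: ImputedDataset, truth_calls: np.ndarray,
             af: np.ndarray, eval_idx: np.ndarray,
             bins: BinSpec = COARSE_BINS,
             fold_maf: bool = False) -> ConcordanceReport:
    """Run the full accuracy battery on one imputed dataset."""
    eval_idx = np.asarray(eval_idx)
    gcr = gcr_per_sample(dataset.hard_calls, truth_calls,
                         dataset.sample_ids, eval_idx)
    r2b = pooled_r2_by_bin(dataset.dosages, truth_calls, af, bins, eval_idx,
                           fold_maf=fold_maf)
    return ConcordanceReport(
        per_sample_gcr=gcr,
        per_bin_r2=r2b,
        yields=yield_by_cutoff(dataset),
        r2_fractions=r2_histogram(dataset),
        gcr_by_stratum=gcr_by_stratum(dataset, truth_calls, eval_idx),
        n_eval_sites=int(eval_idx.size),
    )
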