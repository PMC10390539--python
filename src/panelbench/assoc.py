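"""Case-control association on imputed dosages.

Per variant, a 1-df score test of the additive dosage term in a logistic
model fitted under the null (intercept plus covariates):

    U   = d' (y - yhat)
    Var = d' W d - d' W X (X' W X)^{-1} X' W d,   W = diag(yhat (1 - yhat))
    chi2 = U^2 / Var  ~  chi-square(1) under H0.

With hard genotypes and no covariates this is algebraically the
Cochran–Armitage trend test.  Genome-wide significant variants
(p < 5e-8 by default) are grouped greedily into lead signals, and
pairwise composite LD (squared genotype correlation) annotates partners
of each lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .lsimpute import ImputedDataset
from .simdata import VariantKey

__all__ = [
    "AssocResult",
    "fit_null_model",
    "score_test",
    "genome_scan",
    "find_lead_signals",
    "ld_r2",
    "GENOME_WIDE_P",
]

GENOME_WIDE_P = 5e-8


@dataclass
class AssocResult:
    table: pd.DataFrame  # chrom,pos,ref,alt,stat,p,info,n
    lead_signals: pd.DataFrame
    n_filtered: dict = field(default_factory=dict)


def fit_null_model(y: np.ndarray, covariates: Optional[np.ndarray] = None,
                   max_iter: int = 50, tol: float = 1e-10
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Fit logistic(y ~ intercept + covariates) by Newton iterations.

    Returns (fitted probabilities, design matrix).  Rank-deficient
    designs (e.g. a duplicated constant column) are handled through the
    pseudo-inverse, so the fitted values are still well defined.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not (0 < y.sum() < n):
        raise ValueError("both phenotype classes must be present")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        step = np.linalg.pinv(H) @ grad
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    return p, X


def _score_stats(D: np.ndarray, y: np.ndarray, p0: np.ndarray,
                 X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised score statistic for each column of D (n x m)."""
    W = p0 * (1.0 - p0)
    U = D.T @ (y - p0)
    WX = X * W[:, None]
    XtWX_inv = np.linalg.pinv(X.T @ WX)
    DtWX = D.T @ WX  # m x c
    var = (D * D * W[:, None]).sum(axis=0) \
        - np.einsum("mc,cd,md->m", DtWX, XtWX_inv, DtWX)
    return U, var


def score_test(dosage: np.ndarray, y: np.ndarray,
               covariates: Optional[np.ndarray] = None
               ) -> tuple[float, float]:
    """1-df additive score test of one dosage vector.

    Returns (chi-square statistic, p-value).  A zero-variance score
    (monomorphic dosage, or dosage in the covariate span) gives
    (0.0, 1.0).
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    if d.size != y.size:
        raise ValueError("dosage and phenotype lengths differ")
    if d.size < 10:
        raise ValueError("need at least 10 samples")
    if np.any((d < 0) | (d > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    p0, X = fit_null_model(y, covariates)
    U, var = _score_stats(d[:, None], y, p0, X)
    if var[0] <= 1e-12:
        return 0.0, 1.0
    stat = float(U[0] ** 2 / var[0])
    return stat, float(chi2.sf(stat, df=1))


def genome_scan(dataset: ImputedDataset, phenotypes: pd.Series,
                covariates: Optional[np.ndarray] = None,
                min_info: float = 0.0, min_maf: float = 0.01,
                threshold: float = GENOME_WIDE_P,
                window_bp: int = 1_000_000) -> AssocResult:
    """Score-test every variant passing the confidence and MAF filters.

    ``phenotypes`` is indexed by sample id; samples present in both the
    dataset and the phenotype table are used.
    """
    common = [s for s in dataset.sample_ids if s in phenotypes.index]
    if not common:
        raise ValueError("no overlapping samples between dosages and phenotypes")
    rows = [dataset.sample_ids.index(s) for s in common]
    D = np.asarray(dataset.dosages, dtype=float)[rows]
    y = phenotypes.loc[common].to_numpy(dtype=float)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(common):
            covariates = covariates.T
        covariates = covariates[: len(common)]

    r2 = np.asarray(dataset.est_r2)
    af = D.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    sel = (r2 >= min_info) & (maf >= min_maf)
    n_filtered = {"info": int((r2 < min_info).sum()),
                  "maf": int(((r2 >= min_info) & (maf < min_maf)).sum()),
                  "tested": int(sel.sum())}

    recs = []
    if sel.any():
        p0, X = fit_null_model(y, covariates)
        U, var = _score_stats(D[:, sel], y, p0, X)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(var > 1e-12, U**2 / np.maximum(var, 1e-300), 0.0)
        pvals = np.where(var > 1e-12, chi2.sf(stat, df=1), 1.0)
        direction = np.sign(U)
        for j, col in enumerate(np.flatnonzero(sel)):
            v = dataset.variants[col]
            recs.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                         "alt": v.alt, "stat": float(stat[j]),
                         "p": float(pvals[j]),
                         "direction": int(direction[j]),
                         "info": float(r2[col]), "n": len(common)})
    table = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "stat",
                                        "p", "direction", "info", "n"])
    leads = find_lead_signals(table, threshold=threshold, window_bp=window_bp)
    return AssocResult(table, leads, n_filtered)


def find_lead_signals(table: pd.DataFrame, threshold: float = GENOME_WIDE_P,
                      window_bp: int = 1_000_000) -> pd.DataFrame:
    """Group significant variants into non-overlapping lead signals.

    Repeatedly seed a region of +/- window_bp around the smallest
    remaining p-value (same chromosome), absorb all significant variants
    inside it, and record the seed as the region's lead.  Output ordered
    by coordinate; invariant to input row order.
    """
    empty = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "p",
                                  "region_start", "region_end", "n_partners"])
    if table.empty:
        return empty
    sig = table[table["p"] < threshold].copy()
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort")
    leads = []
    while not sig.empty:
        lead = sig.iloc[0]
        lo, hi = lead.pos - window_bp, lead.pos + window_bp
        inside = (sig.chrom == lead.chrom) & (sig.pos >= lo) & (sig.pos <= hi)
        leads.append({"chrom": lead.chrom, "pos": int(lead.pos),
                      "ref": lead.ref, "alt": lead.alt, "p": float(lead.p),
                      "region_start": int(lo), "region_end": int(hi),
                      "n_partners": int(inside.sum() - 1)})
        sig = sig[~inside]
    if not leads:
        return empty
    return pd.DataFrame(leads).sort_values(["chrom", "pos"]).reset_index(drop=True)


def ld_r2(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages.

    NaN when either variant is monomorphic over the complete pairs.
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b)) & (a >= 0) & (b >= 0)
    if not ok.any():
        raise ValueError("no complete genotype pairs")
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
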