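"""Population-structure diagnostics.

LD pruning (sliding-window pairwise r^2), identity-by-state distances,
classical (Torgerson) multidimensional scaling, and a K-population
admixture model fitted by EM under the binomial likelihood

    L = sum_{i,m} [ g_im log(sum_k q_ik f_km)
                    + (2 - g_im) log(1 - sum_k q_ik f_km) ]

with per-individual ancestry proportions Q (rows on the simplex) and
per-population allele frequencies F.  The EM uses the classic
ancestry-of-allele expected-count updates, which increase the likelihood
monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MDSResult",
    "AdmixtureFit",
    "ld_prune",
    "ibs_distance",
    "classical_mds",
    "admixture_em",
    "align_q_columns",
]

MISSING = -1


@dataclass
class MDSResult:
    coordinates: np.ndarray  # n x d, column means 0
    eigenvalues: np.ndarray  # length d, descending
    n_markers_used: int


@dataclass
class AdmixtureFit:
    Q: np.ndarray  # n x K ancestry proportions
    F: np.ndarray  # K x M ancestral allele frequencies
    loglik_trace: np.ndarray
    converged: bool
    seed: int


def _pairwise_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Genotype-correlation r^2, pairwise-complete; NaN if degenerate."""
    ok = (col_a != MISSING) & (col_b != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = col_a[ok].astype(float), col_b[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _maf(col: np.ndarray) -> float:
    ok = col != MISSING
    if not ok.any():
        return 0.0
    p = col[ok].mean() / 2.0
    return min(p, 1.0 - p)


def _window_r2(G: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    """Pairwise-complete genotype r^2 among a window's columns."""
    X = G[:, cols].astype(float)
    X[G[:, cols] == MISSING] = np.nan
    if not np.isnan(X).any():
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(X, rowvar=False)
    else:
        import pandas as pd
        C = pd.DataFrame(X).corr(min_periods=2).to_numpy()
    C = np.atleast_2d(C) ** 2
    np.fill_diagonal(C, np.nan)
    return C


def ld_prune(G: np.ndarray, positions: Optional[np.ndarray] = None,
             window: int = 50, step: int = 10, r2_max: float = 0.2
             ) -> np.ndarray:
    """Sliding-window LD pruning, PLINK --indep-pairwise semantics.

    Within each window of ``window`` variants (advancing by ``step``),
    while any kept pair has r^2 > ``r2_max``, the strongest such pair is
    broken by removing its smaller-MAF member (tie: the later variant).
    Monomorphic variants never participate in r^2 and are retained.
    Returns kept variant indices in order; the greedy order makes the
    output deterministic.
    """
    G = np.asarray(G)
    m = G.shape[1]
    if m == 0:
        raise ValueError("need at least one variant")
    keep = np.ones(m, dtype=bool)
    mafs = np.array([_maf(G[:, j]) for j in range(m)])
    start = 0
    while True:
        end = min(start + window, m)
        idx = [j for j in range(start, end) if keep[j] and mafs[j] > 0]
        if len(idx) > 1:
            R2 = _window_r2(G, idx)
            alive = np.ones(len(idx), dtype=bool)
            while True:
                sub = np.where(alive[:, None] & alive[None, :], R2, np.nan)
                if np.all(np.isnan(sub)) or np.nanmax(sub) <= r2_max:
                    break
                ai, bi = np.unravel_index(np.nanargmax(sub), sub.shape)
                ai, bi = min(ai, bi), max(ai, bi)
                a, b = idx[ai], idx[bi]
                di = (bi if (mafs[b] < mafs[a]
                             or np.isclose(mafs[a], mafs[b])) else ai)
                alive[di] = False
                keep[idx[di]] = False
        if end >= m:
            break
        start += step
    return np.flatnonzero(keep)


def ibs_distance(G: np.ndarray) -> np.ndarray:
    """1 - mean allele-sharing fraction between sample pairs.

    Shared allele count at one site is 2 - |x_j - x_k| (0, 1 or 2), so
    D_jk = mean(|x_j - x_k|) / 2 over pairwise-complete sites.
    """
    G = np.asarray(G)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    X = np.where(G == MISSING, np.nan, G).astype(float)
    D = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(X[j] - X[j:])
        cnt = (~np.isnan(diff)).sum(axis=1)
        if (cnt == 0).any():
            raise ValueError("a sample pair shares no complete sites")
        D[j, j:] = np.nansum(diff, axis=1) / (2.0 * cnt)
        D[j:, j] = D[j, j:]
    np.fill_diagonal(D, 0.0)
    return D


def classical_mds(D: np.ndarray, d: int = 2) -> MDSResult:
    """Torgerson scaling of a distance matrix.

    Double-centers -D^2/2, takes the top-d eigenpairs, and scales
    eigenvectors by the square roots of the (nonnegative-clipped)
    eigenvalues.  Axis signs follow the convention that the first
    nonzero loading of each axis is positive.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("D must be a symmetric square matrix")
    if d > n - 1:
        raise ValueError("cannot extract more than n-1 coordinates")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:d]
    lam = np.clip(w[order], 0.0, None)
    coords = V[:, order] * np.sqrt(lam)
    for a in range(d):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    coords -= coords.mean(axis=0)
    return MDSResult(coords, lam, n_markers_used=0)


def _admixture_loglik(G: np.ndarray, mask: np.ndarray, Q: np.ndarray,
                      F: np.ndarray) -> float:
    P = np.clip(Q @ F, 1e-12, 1.0 - 1e-12)
    ll = G * np.log(P) + (2.0 - G) * np.log(1.0 - P)
    return float(ll[mask].sum())


def admixture_em(G: np.ndarray, K: int = 2, max_iter: int = 2000,
                 tol: float = 1e-6, seed: int = 0, n_starts: int = 3
                 ) -> AdmixtureFit:
    """Fit the K-population admixture model by EM.

    Missing genotypes are dropped from the likelihood.  ``n_starts``
    random initialisations are run from ``seed``; the best-likelihood
    fit is returned.  The per-iteration log-likelihood trace of the
    winning start is non-decreasing.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    mask = G != MISSING
    Gv = np.where(mask, G, 0.0)

    if K == 1:
        p = Gv.sum(axis=0) / np.maximum(2.0 * mask.sum(axis=0), 1.0)
        F = np.clip(p[None, :], 1e-6, 1.0 - 1e-6)
        Q = np.ones((n, 1))
        ll = _admixture_loglik(Gv, mask, Q, F)
        return AdmixtureFit(Q, F, np.array([ll]), True, seed)

    best: Optional[AdmixtureFit] = None
    for start in range(n_starts):
        rng = np.random.default_rng(seed + start)
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.clip(rng.random((K, m)), 1e-6, 1.0 - 1e-6)
        trace = []
        converged = False
        for it in range(max_iter):
            P = np.clip(Q @ F, 1e-12, 1.0 - 1e-12)
            # expected ancestry-of-allele counts
            #   alt alleles:  a_imk = g * q f / P
            #   ref alleles:  b_imk = (2-g) * q (1-f) / (1-P)
            GA = np.where(mask, Gv / P, 0.0)          # n x m
            GB = np.where(mask, (2.0 - Gv) / (1.0 - P), 0.0)
            A = (GA @ F.T) * Q                        # n x K alt counts
            B = (GB @ (1.0 - F).T) * Q                # n x K ref counts
            Q_new = (A + B)
            Q_new /= Q_new.sum(axis=1, keepdims=True)
            Fa = (Q.T @ (GA)) * F                     # K x m alt counts
            Fb = (Q.T @ (GB)) * (1.0 - F)             # K x m ref counts
            F_new = np.clip(Fa / np.maximum(Fa + Fb, 1e-300),
                            1e-6, 1.0 - 1e-6)
            Q, F = Q_new, F_new
            ll = _admixture_loglik(Gv, mask, Q, F)
            trace.append(ll)
            if it > 0 and trace[-1] - trace[-2] < tol:
                converged = True
                break
        fit = AdmixtureFit(Q, F, np.array(trace), converged, seed + start)
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    return best


def align_q_columns(Q: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Resolve K=2 label switching: return the Q column best matching
    ``q_true`` (by correlation; anti-correlated columns are swapped)."""
    if Q.shape[1] != 2:
        raise ValueError("label alignment implemented for K=2")
    c0 = np.corrcoef(Q[:, 0], q_true)[0, 1] if np.std(Q[:, 0]) > 0 else 0.0
    return Q[:, 0] if c0 >= 0 else Q[:, 1]
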