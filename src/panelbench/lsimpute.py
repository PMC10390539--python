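"""Minimal Li–Stephens haplotype-copying imputer.

A target haplotype observed only at array-typed sites is modelled as a
mosaic of the K reference-panel haplotypes.  The hidden state at each
site is the panel haplotype being copied; between adjacent sites the
chain stays with probability 1 - s + s/K and jumps to any particular
other state with probability s/K, where s = 1 - exp(-rho * d / K) for
inter-site distance d.  Typed sites emit the observed allele with
probability 1 - err on a match and err on a mismatch; untyped sites are
uninformative (uniform emission), so their allele posterior comes purely
from the copying states.

The posterior alt-allele probability at site m is
``sum_k gamma_k(m) * panel_k(m)``, with the mismatch correction
``(1-err)*p + err*(1-p)`` applied at typed sites.  Diploid imputation is
two haploid passes (targets are pre-phased); per-variant confidence is
the Minimac-style ratio of the empirical dosage variance to the binomial
variance p(1-p) expected under perfectly known genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .simdata import HaplotypePanel, VariantKey

__all__ = [
    "LSParams",
    "ImputedDataset",
    "ls_posteriors",
    "ls_allele_probs_batch",
    "impute_diploid",
    "impute_cohort",
    "hard_call",
    "estimate_r2",
]


@dataclass(frozen=True)
class LSParams:
    """Copying-model parameters.

    rho
        Per-base recombination intensity; switch probability over an
        interval of d bases with K panel haplotypes is 1 - exp(-rho*d/K).
        The default is calibrated to the synthetic generator's default
        recombination rate at its default panel size (2e-6 x 300), so
        that the copying chain switches about as often as the mosaics it
        is tracking actually recombine.
    err
        Emission mismatch probability, in (0, 0.5).
    genetic_map
        Optional explicit inter-site distances (length M-1), overriding
        physical distances.
    """

    rho: float = 6e-4
    err: float = 0.01
    genetic_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.err < 0.5:
            raise ValueError(f"err must be in (0, 0.5), got {self.err}")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")


@dataclass
class ImputedDataset:
    """Per-sample, per-variant imputation output.

    dosages : N x M expected alt-allele counts in [0, 2]
    genotype_probs : N x M x 3 (hom-ref, het, hom-alt), rows on the simplex
    hard_calls : N x M in {0, 1, 2} (argmax, ties toward the smaller code)
    est_r2 : per-variant estimated confidence in [0, 1]
    typed : per-variant bool, True at array-observed sites
    """

    variants: list[VariantKey]
    dosages: np.ndarray
    genotype_probs: np.ndarray
    hard_calls: np.ndarray
    est_r2: np.ndarray
    typed: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        assert self.genotype_probs.shape == (n, m, 3)
        assert self.hard_calls.shape == (n, m)
        assert self.est_r2.shape == (m,)
        if not np.allclose(self.genotype_probs.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("genotype probabilities must sum to 1")
        ds = self.genotype_probs[:, :, 1] + 2.0 * self.genotype_probs[:, :, 2]
        if not np.allclose(ds, self.dosages, atol=1e-9):
            raise ValueError("dosage must equal P(het) + 2 P(hom-alt)")


def _switch_probs(positions: np.ndarray, K: int, params: LSParams) -> np.ndarray:
    if params.genetic_map is not None:
        d = np.asarray(params.genetic_map, dtype=float)
        if d.shape != (len(positions) - 1,):
            raise ValueError("genetic_map must have M-1 intervals")
    else:
        d = np.diff(np.asarray(positions, dtype=float))
    return 1.0 - np.exp(-params.rho * d / K)


def ls_allele_probs_batch(obs: np.ndarray, panel_haps: np.ndarray,
                          positions: np.ndarray, params: LSParams,
                          return_posteriors: bool = False):
    """Forward–backward over the copying HMM for a batch of haplotypes.

    Parameters
    ----------
    obs : T x M int array, alleles 0/1 at typed sites and -1 elsewhere.
    panel_haps : K x M reference haplotypes (0/1).
    positions : length-M physical coordinates.

    Returns the T x M posterior alt-allele probabilities (mismatch
    correction applied at typed sites), plus the T x M x K copying-state
    posteriors when requested.
    """
    obs = np.atleast_2d(np.asarray(obs))
    H = np.asarray(panel_haps, dtype=np.float64)
    K, M = H.shape
    if K == 0:
        raise ValueError("empty reference panel")
    if obs.shape[1] != M:
        raise ValueError("observation length must match panel site count")
    T = obs.shape[0]
    eps = params.err
    s = _switch_probs(positions, K, params)  # length M-1

    # chunk over targets so the stored forward lattice stays modest
    max_cells = 32_000_000  # floats in the M x chunk x K forward array
    chunk = max(1, min(T, max_cells // max(1, M * K)))
    p_alt = np.empty((T, M))
    posts = np.empty((T, M, K)) if return_posteriors else None

    def emis(o_chunk: np.ndarray, j: int) -> np.ndarray:
        o = o_chunk[:, j]
        e = np.ones((o.size, K))
        typed = o >= 0
        if typed.any():
            match = H[:, j][None, :] == o[typed, None]
            e[typed] = np.where(match, 1.0 - eps, eps)
        return e

    for lo in range(0, T, chunk):
        oc = obs[lo:lo + chunk]
        t = oc.shape[0]
        fwd = np.empty((M, t, K))
        a = np.full((t, K), 1.0 / K) * emis(oc, 0)
        fwd[0] = a / a.sum(axis=1, keepdims=True)
        for j in range(1, M):
            sj = s[j - 1]
            a = ((1.0 - sj) * fwd[j - 1] + sj / K) * emis(oc, j)
            fwd[j] = a / a.sum(axis=1, keepdims=True)

        b = np.ones((t, K))
        g = fwd[M - 1]
        p_alt[lo:lo + chunk, M - 1] = g @ H[:, M - 1]
        if return_posteriors:
            posts[lo:lo + chunk, M - 1] = g
        for j in range(M - 2, -1, -1):
            sj = s[j]
            be = b * emis(oc, j + 1)
            b = (1.0 - sj) * be + (sj / K) * be.sum(axis=1, keepdims=True)
            b /= b.max(axis=1, keepdims=True)  # rescale against underflow
            g = fwd[j] * b
            g /= g.sum(axis=1, keepdims=True)
            p_alt[lo:lo + chunk, j] = g @ H[:, j]
            if return_posteriors:
                posts[lo:lo + chunk, j] = g

    typed_mask = obs >= 0
    p_alt[typed_mask] = (1.0 - eps) * p_alt[typed_mask] \
        + eps * (1.0 - p_alt[typed_mask])
    np.clip(p_alt, 0.0, 1.0, out=p_alt)
    if return_posteriors:
        return p_alt, posts
    return p_alt


def ls_posteriors(target_hap: np.ndarray, panel: HaplotypePanel,
                  params: LSParams) -> tuple[np.ndarray, np.ndarray]:
    """Copying-state posteriors and alt-allele probabilities for one
    haplotype.

    ``target_hap`` holds 0/1 at typed sites and -1 at untyped sites, on
    the panel's site grid.  Returns (M x K state posteriors, length-M
    allele probabilities).
    """
    obs = np.asarray(target_hap)
    if obs.shape != (panel.n_sites,):
        raise ValueError("target must be given on the panel's site grid")
    p_alt, post = ls_allele_probs_batch(obs[None, :], panel.haplotypes,
                                        panel.positions, params,
                                        return_posteriors=True)
    return post[0], p_alt[0]


def hard_call(probs) -> int:
    """Most probable genotype; ties resolved toward the smaller code."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("expected a genotype-probability triple")
    return int(np.argmax(p))  # argmax returns the first (smallest) maximiser


def _genotype_probs(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    gp = np.stack([(1 - a1) * (1 - a2),
                   a1 * (1 - a2) + a2 * (1 - a1),
                   a1 * a2], axis=-1)
    return gp / gp.sum(axis=-1, keepdims=True)


def impute_diploid(hap_pair: np.ndarray, panel: HaplotypePanel,
                   params: LSParams, typed_idx: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impute one pre-phased diploid from its typed-site alleles.

    ``hap_pair`` is 2 x (#typed sites).  Returns (dosage vector,
    genotype-probability matrix M x 3, haploid alt-probabilities 2 x M).
    """
    hap_pair = np.asarray(hap_pair)
    if hap_pair.ndim != 2 or hap_pair.shape[0] != 2:
        raise ValueError("a phased haplotype pair (2 x T) is required")
    obs = np.full((2, panel.n_sites), -1, dtype=np.int8)
    obs[:, typed_idx] = hap_pair
    a = ls_allele_probs_batch(obs, panel.haplotypes, panel.positions, params)
    gp = _genotype_probs(a[0], a[1])
    return a[0] + a[1], gp, a


def estimate_r2(hap_probs: np.ndarray) -> float:
    """Minimac-style confidence from haploid alt-allele probabilities.

    With probabilities a_1..a_{2N} across all haplotypes at one variant,
    p_hat = mean(a) and R2_hat = Var(a) / (p_hat (1 - p_hat)) using the
    population-variance denominator 2N.  A monomorphic estimate
    (p_hat in {0, 1}) returns 0; output clipped to [0, 1].
    """
    a = np.asarray(hap_probs, dtype=float).ravel()
    if a.size < 2:
        raise ValueError("need probabilities from at least two haplotypes")
    if np.ptp(a) == 0.0:
        return 0.0
    p = a.mean()
    denom = p * (1.0 - p)
    if denom <= 0.0:
        return 0.0
    return float(np.clip(a.var() / denom, 0.0, 1.0))


def impute_cohort(target_haps: np.ndarray, typed_idx: np.ndarray,
                  panel: HaplotypePanel, params: LSParams,
                  sample_ids: Optional[list[str]] = None) -> ImputedDataset:
    """Impute every diploid in a phased target matrix (2N x #typed).

    ``target_haps`` may be given either at typed sites only
    (2N x len(typed_idx)) or on the full site grid (2N x M), in which
    case it is subset to the typed sites.  Typed sites keep the observed
    genotype as the hard call.
    """
    target_haps = np.asarray(target_haps)
    M = panel.n_sites
    typed_idx = np.asarray(typed_idx)
    if typed_idx.size == 0:
        raise ValueError("no typed sites")
    if target_haps.shape[1] == M:
        target_haps = target_haps[:, typed_idx]
    elif target_haps.shape[1] != typed_idx.size:
        raise ValueError("target width matches neither typed nor all sites")
    n_haps = target_haps.shape[0]
    if n_haps % 2:
        raise ValueError("haplotype count must be even (phased diploids)")
    n = n_haps // 2

    obs = np.full((n_haps, M), -1, dtype=np.int8)
    obs[:, typed_idx] = target_haps
    a = ls_allele_probs_batch(obs, panel.haplotypes, panel.positions, params)
    a1, a2 = a[0::2], a[1::2]
    gp = _genotype_probs(a1, a2)
    dosages = gp[:, :, 1] + 2.0 * gp[:, :, 2]
    hard = np.argmax(gp, axis=2).astype(np.int8)
    # observed array genotypes override the posterior at typed sites
    obs_geno = (target_haps[0::2] + target_haps[1::2]).astype(np.int8)
    hard[:, typed_idx] = obs_geno

    p_hat = a.mean(axis=0)
    denom = p_hat * (1.0 - p_hat)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, a.var(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    typed = np.zeros(M, dtype=bool)
    typed[typed_idx] = True
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    return ImputedDataset(list(panel.variants), dosages, gp, hard, r2,
                          typed, sample_ids)
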