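"""Synthetic structured cohorts for imputation benchmarking.

The generator produces the statistical structure that panel-vs-target
imputation experiments rest on, with few parameters:

* an ancestral site-frequency spectrum drawn from a truncated power law,
* subpopulation divergence via Balding–Nichols drift (parameterised by
  F_ST),
* linkage disequilibrium via recombinant mosaic copying of a finite
  founder pool (targets and the matched reference panel share founders,
  mismatched panels do not),
* admixed individuals whose haplotypes are drawn from either parental
  population,
* a genotyping-array site mask (common, regularly spaced sites) that
  splits sites into "typed" (observed) and "untyped" (to be imputed),
* binary phenotypes from an additive logistic model.

Everything is a pure function of :class:`SimConfig` (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SimConfig",
    "VariantKey",
    "HaplotypePanel",
    "SimulatedCohort",
    "draw_ancestral_frequencies",
    "balding_nichols_freqs",
    "draw_founders",
    "mosaic_haplotypes",
    "simulate_subpopulation_panel",
    "simulate_admixed_individual",
    "mask_to_array",
    "simulate_phenotypes",
    "simulate_cohort",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic site: (chrom, pos, ref, alt)."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def vclass(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes with per-haplotype population labels.

    ``haplotypes`` is an H x M uint8 matrix (rows = haplotypes, columns =
    variants in coordinate order, alleles coded 0/1).  Two consecutive rows
    form one diploid individual when the panel represents samples.
    """

    variants: list[VariantKey]
    haplotypes: np.ndarray
    pop_labels: np.ndarray  # length H, one label per haplotype

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.pop_labels = np.asarray(self.pop_labels)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (H x M)")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("column count must equal number of variants")
        if len(self.pop_labels) != self.haplotypes.shape[0]:
            raise ValueError("one population label per haplotype required")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("alleles must be 0/1")
        pos = [(v.chrom, v.pos) for v in self.variants]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("variants must be strictly ordered by (chrom, pos)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def genotypes(self) -> np.ndarray:
        """Collapse consecutive haplotype pairs into an N x M 0/1/2 matrix."""
        if self.n_haplotypes % 2:
            raise ValueError("odd haplotype count cannot form diploids")
        h = self.haplotypes.astype(np.int16)
        return h[0::2] + h[1::2]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator.

    The defaults describe a desk-scale analogue of an array-plus-panel
    imputation study: two subpopulations diverged at modest F_ST, a
    reference panel and a target cohort per population, a sparse "array"
    of common sites, and the rest of the sites held out for evaluation.
    """

    seed: int = 0
    n_ancestral_haps: int = 100  # founder pool per population
    n_sites: int = 1000
    region_length: int = 1_000_000  # bp
    sfs_alpha: float = 1.0  # ancestral AF density ∝ x^(-alpha)
    fst_per_pop: tuple[float, ...] = (0.05, 0.05)
    recomb_rate: float = 2e-6  # per-base switch intensity of the mosaic
    flip_rate: float = 1e-3  # per-site allele flip during copying
    pop_sizes: tuple[int, ...] = (25, 25)  # diploid targets per pop
    panel_size: int = 150  # diploids per reference panel
    admixed_fraction: float = 0.0
    admix_q: float = 0.5
    array_maf_min: float = 0.05
    array_spacing: int = 3
    case_fraction: float = 0.3
    causal_effects: tuple[tuple[int, float], ...] = ()
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_ancestral_haps < 1:
            raise ConfigError("counts must be positive")
        if self.sfs_alpha < 0:
            raise ConfigError("sfs_alpha must be >= 0")
        for f in self.fst_per_pop:
            if not 0.0 <= f < 1.0:
                raise ConfigError(f"fst must be in [0,1), got {f}")
        for name in ("flip_rate", "admixed_fraction", "admix_q",
                     "array_maf_min", "case_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if len(self.pop_sizes) != len(self.fst_per_pop):
            raise ConfigError("pop_sizes and fst_per_pop must align")
        if any(n < 1 for n in self.pop_sizes) or self.panel_size < 1:
            raise ConfigError("sample counts must be positive")
        if self.array_spacing < 1:
            raise ConfigError("array_spacing must be >= 1")
        if self.region_length < self.n_sites:
            raise ConfigError("region shorter than the number of sites")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# frequency spectrum and drift


def draw_ancestral_frequencies(cfg: SimConfig,
                               rng: Optional[np.random.Generator] = None
                               ) -> np.ndarray:
    """Sample per-site ancestral alt-allele frequencies.

    Densities ∝ x^(-sfs_alpha) on [1/(2·n_ancestral_haps), 0.5], sampled by
    inverse-transform.  alpha = 1 mimics the neutral 1/x spectrum; alpha = 0
    is uniform on the truncation interval.
    """
    if cfg.n_sites < 1:
        raise ConfigError("n_sites must be positive")
    if cfg.sfs_alpha < 0:
        raise ConfigError("sfs_alpha must be >= 0")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo = 1.0 / (2.0 * cfg.n_ancestral_haps)
    hi = 0.5
    u = rng.random(cfg.n_sites)
    a = cfg.sfs_alpha
    if abs(a - 1.0) < 1e-12:
        # CDF ∝ log(x/lo)
        return lo * (hi / lo) ** u
    b = 1.0 - a
    return (lo**b + u * (hi**b - lo**b)) ** (1.0 / b)


def balding_nichols_freqs(ancestral: np.ndarray, fst: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Subpopulation allele frequencies drifted away from the ancestral ones.

    Beta(p(1-F)/F, (1-p)(1-F)/F) per site; F = 0 returns the ancestral
    frequencies unchanged.
    """
    if not 0.0 <= fst < 1.0:
        raise ConfigError(f"fst must be in [0,1), got {fst}")
    p = np.asarray(ancestral, dtype=float)
    if fst == 0.0:
        return p.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def draw_founders(freqs: np.ndarray, n_haps: int,
                  rng: np.random.Generator) -> np.ndarray:
    """i.i.d. Bernoulli founder haplotypes at the given site frequencies."""
    return (rng.random((n_haps, freqs.size)) < freqs).astype(np.uint8)


def mosaic_haplotypes(founders: np.ndarray, positions: np.ndarray,
                      n_out: int, recomb_rate: float, flip_rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Recombinant mosaics of a founder pool.

    Each output haplotype copies one founder at a time, switching to a
    uniformly chosen founder between adjacent sites with probability
    1 - exp(-recomb_rate * distance); each copied allele is flipped with
    probability flip_rate.  This is what creates LD (co-copied founder
    segments) and identity-by-descent sharing between cohorts built from
    the same founder pool.
    """
    n_f, m = founders.shape
    positions = np.asarray(positions, dtype=np.int64)
    d = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-recomb_rate * d)  # length m-1
    state = rng.integers(0, n_f, size=n_out)
    out = np.empty((n_out, m), dtype=np.uint8)
    out[:, 0] = founders[state, 0]
    for j in range(1, m):
        sw = rng.random(n_out) < p_switch[j - 1]
        if sw.any():
            state[sw] = rng.integers(0, n_f, size=int(sw.sum()))
        out[:, j] = founders[state, j]
    if flip_rate > 0.0:
        flips = rng.random(out.shape) < flip_rate
        out ^= flips.astype(np.uint8)
    return out


def _variant_keys(cfg: SimConfig, positions: np.ndarray) -> list[VariantKey]:
    # alternate ref/alt letters deterministically so keys are reproducible
    bases = ("A", "C", "G", "T")
    keys = []
    for i, pos in enumerate(positions):
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        keys.append(VariantKey(cfg.chrom, int(pos), ref, alt))
    return keys


def draw_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Distinct, sorted 1-based positions on the region."""
    pos = rng.choice(cfg.region_length, size=cfg.n_sites, replace=False)
    return np.sort(pos) + 1


def simulate_subpopulation_panel(ancestral_freqs: np.ndarray, fst: float,
                                 cfg: SimConfig, *,
                                 positions: np.ndarray,
                                 n_out: int,
                                 pop_label: str,
                                 rng: np.random.Generator,
                                 founders: Optional[np.ndarray] = None,
                                 ) -> tuple[HaplotypePanel, np.ndarray]:
    """Build a drifted subpopulation's haplotype panel.

    Returns the panel and its founder pool so that further cohorts (e.g.
    target samples matched to this panel) can be drawn from the same
    founders.
    """
    if fst >= 1.0:
        raise ConfigError("fst = 1 gives a degenerate Beta distribution")
    if founders is None:
        sub_freqs = balding_nichols_freqs(ancestral_freqs, fst, rng)
        founders = draw_founders(sub_freqs, cfg.n_ancestral_haps, rng)
    haps = mosaic_haplotypes(founders, positions, n_out,
                             cfg.recomb_rate, cfg.flip_rate, rng)
    panel = HaplotypePanel(_variant_keys(cfg, positions), haps,
                           np.repeat(pop_label, n_out))
    return panel, founders


def simulate_admixed_individual(foundersA: np.ndarray, foundersB: np.ndarray,
                                q: float, cfg: SimConfig,
                                positions: np.ndarray,
                                rng: np.random.Generator
                                ) -> tuple[np.ndarray, np.ndarray]:
    """One diploid with each haplotype drawn from pop A w.p. ``q`` else B.

    Returns (2 x M phased haplotypes, length-2 ancestry indicator with
    1 = pop A).  The per-haplotype ancestry is the ground truth consumed
    by admixture-recovery tests.
    """
    if not 0.0 <= q <= 1.0:
        raise ConfigError(f"q must be in [0,1], got {q}")
    anc = (rng.random(2) < q).astype(np.int8)
    haps = np.empty((2, positions.size), dtype=np.uint8)
    for h in range(2):
        pool = foundersA if anc[h] == 1 else foundersB
        haps[h] = mosaic_haplotypes(pool, positions, 1, cfg.recomb_rate,
                                    cfg.flip_rate, rng)[0]
    return haps, anc


def mask_to_array(genotypes: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Indices of "array-typed" sites: common sites kept on a regular grid.

    Eligible sites have cohort MAF >= ``array_maf_min``; every
    ``array_spacing``-th eligible site (in coordinate order) is typed.
    The complement is the untyped evaluation set.
    """
    g = np.asarray(genotypes, dtype=float)
    af = g.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    eligible = np.flatnonzero(maf >= cfg.array_maf_min)
    typed = eligible[:: cfg.array_spacing]
    if typed.size == 0:
        raise ConfigError("array mask selected no sites; imputation impossible")
    return typed


def simulate_phenotypes(genotypes: np.ndarray, cfg: SimConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> np.ndarray:
    """Binary phenotypes from an additive logistic model.

    logit P(case) = b0 + sum_j beta_j * dosage_j over ``causal_effects``;
    b0 is found by bisection so that the cohort-average case probability
    equals ``case_fraction``.  With no causal effects this reduces to
    i.i.d. Bernoulli(case_fraction).
    """
    rng = np.random.default_rng(cfg.seed + 7) if rng is None else rng
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    score = np.zeros(n)
    for idx, beta in cfg.causal_effects:
        if not 0 <= idx < g.shape[1]:
            raise ConfigError(f"causal site index {idx} out of range")
        score += beta * g[:, idx]

    target = cfg.case_fraction

    def prevalence(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + score)))))

    lo, hi = -50.0, 50.0
    if not prevalence(lo) <= target <= prevalence(hi):
        raise ConfigError(f"prevalence {target} unattainable with given effects")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(-(b0 + score)))
    return (rng.random(n) < p).astype(np.int8)


@dataclass
class SimulatedCohort:
    """Everything one imputation-benchmark run needs, bundled.

    ``panels`` maps population label to its reference HaplotypePanel.
    ``targets`` holds the phased truth haplotypes of the study samples
    (2N x M); ``target_pops`` labels each individual; ``hap_ancestry``
    gives the true per-haplotype ancestry indicator (1 = first
    population) from which ``true_q`` (per-individual ancestry
    proportion) is derived.
    """

    config: SimConfig
    variants: list[VariantKey]
    ancestral_freqs: np.ndarray
    panels: dict[str, HaplotypePanel]
    targets: np.ndarray
    target_pops: list[str]
    hap_ancestry: np.ndarray
    typed_idx: np.ndarray
    phenotypes: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.targets.shape[0] // 2)]

    def truth_genotypes(self) -> np.ndarray:
        h = self.targets.astype(np.int16)
        return h[0::2] + h[1::2]

    @property
    def true_q(self) -> np.ndarray:
        a = self.hap_ancestry.astype(float)
        return 0.5 * (a[0::2] + a[1::2])


POP_NAMES = ("A", "B", "C", "D", "E", "F")


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate the full study: panels, targets, array mask, phenotypes.

    Population i's targets are mosaics of the *same* founder pool as
    population i's reference panel, so a matched panel shares haplotype
    segments with its targets while a mismatched panel only shares the
    (drifted) allele frequencies.  Admixed individuals (between the first
    two populations) are appended after the pure-population targets.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = draw_positions(cfg, rng)
    anc = draw_ancestral_frequencies(cfg, rng)
    variants = _variant_keys(cfg, positions)

    panels: dict[str, HaplotypePanel] = {}
    founders: dict[str, np.ndarray] = {}
    target_blocks: list[np.ndarray] = []
    pops: list[str] = []
    ancestry: list[np.ndarray] = []

    for i, fst in enumerate(cfg.fst_per_pop):
        label = POP_NAMES[i]
        panel, fnd = simulate_subpopulation_panel(
            anc, fst, cfg, positions=positions, n_out=2 * cfg.panel_size,
            pop_label=label, rng=rng)
        panels[label] = panel
        founders[label] = fnd
        t = mosaic_haplotypes(fnd, positions, 2 * cfg.pop_sizes[i],
                              cfg.recomb_rate, cfg.flip_rate, rng)
        target_blocks.append(t)
        pops.extend([label] * cfg.pop_sizes[i])
        ancestry.append(np.full(2 * cfg.pop_sizes[i], 1 if i == 0 else 0,
                                dtype=np.int8))

    n_adm = int(round(cfg.admixed_fraction * sum(cfg.pop_sizes)))
    if n_adm > 0:
        if len(cfg.fst_per_pop) < 2:
            raise ConfigError("admixture needs at least two populations")
        fA, fB = founders[POP_NAMES[0]], founders[POP_NAMES[1]]
        adm_haps = np.empty((2 * n_adm, cfg.n_sites), dtype=np.uint8)
        adm_anc = np.empty(2 * n_adm, dtype=np.int8)
        for k in range(n_adm):
            haps, a = simulate_admixed_individual(fA, fB, cfg.admix_q, cfg,
                                                  positions, rng)
            adm_haps[2 * k: 2 * k + 2] = haps
            adm_anc[2 * k: 2 * k + 2] = a
        target_blocks.append(adm_haps)
        pops.extend(["ADM"] * n_adm)
        ancestry.append(adm_anc)

    targets = np.vstack(target_blocks)
    hap_ancestry = np.concatenate(ancestry)
    geno = targets[0::2].astype(np.int16) + targets[1::2].astype(np.int16)
    typed_idx = mask_to_array(geno, cfg)
    phen = simulate_phenotypes(geno, cfg, rng)
    return SimulatedCohort(cfg, variants, anc, panels, targets, pops,
                           hap_ancestry, typed_idx, phen)
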