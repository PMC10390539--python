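"""Pre-imputation harmonization and cohort QC.

Variant harmonization reconciles array records with the reference panel:
identical alleles are kept, reverse-complement pairs are strand-flipped,
exchanged ref/alt pairs are swapped, palindromic (A/T, C/G) sites are
kept only when their frequency makes the strand orientation unambiguous,
and records whose oriented allele frequency still disagrees with the
panel are excluded.

Cohort QC mirrors standard array/WGS practice: per-sample missingness
(> 0.05 removed), relatedness pruning on a standardized genomic
relationship matrix (pairs with relatedness > 0.5 broken greedily), and
per-site filters on a truth callset (FILTER column, missingness > 0.10,
exact Hardy–Weinberg p < 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simdata import VariantKey

__all__ = [
    "HarmonizationAction",
    "QCReport",
    "classify_variant",
    "harmonize_tables",
    "sample_missingness_filter",
    "genomic_relatedness_matrix",
    "relatedness_prune",
    "hwe_exact_test",
    "hwe_pvalues_for_counts",
    "wgs_site_qc",
    "intersect_evaluation_sites",
]

MISSING = -1  # genotype-matrix code for a missing call

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = ("keep", "strand_flip", "allele_swap", "flip_and_swap", "exclude")


@dataclass(frozen=True)
class HarmonizationAction:
    key: VariantKey
    action: str
    reason: Optional[str] = None  # set iff action == "exclude"

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action}")
        if (self.action == "exclude") != (self.reason is not None):
            raise ValueError("excluded variants (and only those) carry a reason")


@dataclass
class QCReport:
    """Reproducible record of what QC removed and why."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_sites: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)


def _revcomp(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError as e:
        raise ValueError(f"malformed allele {allele!r}") from e


def _is_palindromic(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and _COMPLEMENT.get(ref) == alt


def classify_variant(array_key: VariantKey, array_af: float,
                     panel_key: VariantKey, panel_af: float,
                     af_diff_max: float = 0.20,
                     palindromic_maf_max: float = 0.40) -> HarmonizationAction:
    """Decide how to orient one array record against the panel record.

    Records must already be matched on (chrom, pos).  AFs are alt-allele
    frequencies in each record's own orientation.  For palindromic sites
    strand cannot be determined from the alleles, so orientation is taken
    from the AFs and the site is excluded when its MAF is too close to
    0.5 to disambiguate.
    """
    if (array_key.chrom, array_key.pos) != (panel_key.chrom, panel_key.pos):
        return HarmonizationAction(array_key, "exclude", "position_mismatch")
    a_ref, a_alt = array_key.ref.upper(), array_key.alt.upper()
    p_ref, p_alt = panel_key.ref.upper(), panel_key.alt.upper()
    for al in (a_ref, a_alt, p_ref, p_alt):
        _revcomp(al)  # validates characters

    if _is_palindromic(a_ref, a_alt):
        maf = min(array_af, 1.0 - array_af)
        if maf >= palindromic_maf_max:
            return HarmonizationAction(array_key, "exclude",
                                       "palindromic_ambiguous")
        # orient by AF: same side of 0.5 -> keep, opposite -> swap
        keep_diff = abs(array_af - panel_af)
        swap_diff = abs(array_af - (1.0 - panel_af))
        if {a_ref, a_alt} != {p_ref, p_alt}:
            return HarmonizationAction(array_key, "exclude", "allele_mismatch")
        if keep_diff <= swap_diff:
            action, oriented_af = "keep", array_af
        else:
            action, oriented_af = "allele_swap", 1.0 - array_af
        if abs(oriented_af - panel_af) > af_diff_max:
            return HarmonizationAction(array_key, "exclude", "af_discrepant")
        return HarmonizationAction(array_key, action)

    if (a_ref, a_alt) == (p_ref, p_alt):
        action, oriented_af = "keep", array_af
    elif (a_alt, a_ref) == (p_ref, p_alt):
        action, oriented_af = "allele_swap", 1.0 - array_af
    elif (_revcomp(a_ref), _revcomp(a_alt)) == (p_ref, p_alt):
        action, oriented_af = "strand_flip", array_af
    elif (_revcomp(a_alt), _revcomp(a_ref)) == (p_ref, p_alt):
        action, oriented_af = "flip_and_swap", 1.0 - array_af
    else:
        return HarmonizationAction(array_key, "exclude", "allele_mismatch")
    if abs(oriented_af - panel_af) > af_diff_max:
        return HarmonizationAction(array_key, "exclude", "af_discrepant")
    return HarmonizationAction(array_key, action)


def apply_action(key: VariantKey, af: float,
                 action: HarmonizationAction) -> tuple[VariantKey, float]:
    """Re-orient an array record per its harmonization action."""
    ref, alt = key.ref, key.alt
    if action.action in ("strand_flip", "flip_and_swap"):
        ref, alt = _revcomp(ref), _revcomp(alt)
    if action.action in ("allele_swap", "flip_and_swap"):
        ref, alt = alt, ref
        af = 1.0 - af
    return VariantKey(key.chrom, key.pos, ref, alt), af


def harmonize_tables(array_records: Sequence[tuple[VariantKey, float]],
                     panel_records: Sequence[tuple[VariantKey, float]],
                     af_diff_max: float = 0.20,
                     palindromic_maf_max: float = 0.40
                     ) -> list[HarmonizationAction]:
    """Classify every array record against the panel, position-matched.

    Array records at positions absent from the panel are excluded with
    reason ``position_mismatch``; repeated array positions beyond the
    first are excluded as ``duplicate``.
    """
    panel_by_pos = {}
    for key, af in panel_records:
        panel_by_pos.setdefault((key.chrom, key.pos), (key, af))
    seen: set[tuple[str, int]] = set()
    out = []
    for key, af in array_records:
        loc = (key.chrom, key.pos)
        if loc in seen:
            out.append(HarmonizationAction(key, "exclude", "duplicate"))
            continue
        seen.add(loc)
        if loc not in panel_by_pos:
            out.append(HarmonizationAction(key, "exclude", "position_mismatch"))
            continue
        pkey, paf = panel_by_pos[loc]
        out.append(classify_variant(key, af, pkey, paf,
                                    af_diff_max, palindromic_maf_max))
    return out


# ---------------------------------------------------------------------------
# sample/site QC


def sample_missingness_filter(G: np.ndarray, sample_ids: Sequence[str],
                              max_miss: float = 0.05
                              ) -> tuple[np.ndarray, QCReport]:
    """Keep samples whose missing-call fraction is <= max_miss (strict >)."""
    G = np.asarray(G)
    miss = (G == MISSING).mean(axis=1)
    keep = miss <= max_miss
    report = QCReport(thresholds={"sample_max_miss": max_miss})
    for i in np.flatnonzero(~keep):
        report.removed_samples.append((sample_ids[i], "missingness"))
    return np.flatnonzero(keep), report


def genomic_relatedness_matrix(G: np.ndarray) -> np.ndarray:
    """GCTA-style standardized GRM.

    A_jk = (1/M') sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    over polymorphic sites with pairwise-complete data.
    """
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    if n < 2:
        raise ValueError("need at least two samples")
    X = np.where(G == MISSING, np.nan, G)
    p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic; relatedness undefined")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    valid = ~np.isnan(Z)
    Z0 = np.where(valid, Z, 0.0)
    num = Z0 @ Z0.T
    cnt = valid.astype(float) @ valid.astype(float).T
    if (cnt == 0).any():
        raise ValueError("a sample pair shares no complete sites")
    return num / cnt


def relatedness_prune(G: np.ndarray, sample_ids: Sequence[str],
                      cutoff: float = 0.5
                      ) -> tuple[np.ndarray, QCReport]:
    """Break all sample pairs with genomic relatedness > cutoff.

    Iteratively removes the sample participating in the most offending
    pairs; ties go to the sample with higher missingness, then to the
    later sample in input order.  Deterministic.
    """
    G = np.asarray(G)
    A = genomic_relatedness_matrix(G)
    n = A.shape[0]
    miss = (G == MISSING).mean(axis=1)
    active = np.ones(n, dtype=bool)
    report = QCReport(thresholds={"relatedness_cutoff": cutoff})
    over = (A > cutoff) & ~np.eye(n, dtype=bool)
    while True:
        deg = np.where(active, (over & active[None, :]).sum(axis=1), -1)
        if deg.max() <= 0:
            break
        top = deg == deg.max()
        cand = np.flatnonzero(top)
        cand = cand[miss[cand] == miss[cand].max()]
        drop = int(cand[-1])  # later sample order last tie-break
        active[drop] = False
        report.removed_samples.append((sample_ids[drop], "relatedness"))
    return np.flatnonzero(active), report


def sex_check(G: np.ndarray, sample_ids: Sequence[str]
              ) -> tuple[np.ndarray, QCReport]:
    """Genetic-vs-reported sex concordance hook.

    Sex chromosomes are outside this pipeline's scope, so the check
    keeps every sample; it exists so pipelines can call the full QC
    sequence uniformly.
    """
    return np.arange(np.asarray(G).shape[0]), QCReport(
        thresholds={"sex_check": "not_applicable"})


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def _hwe_het_distribution(n: int, n_minor: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities of every heterozygote count given n diploids and
    n_minor copies of the minor allele, under the exact HWE null.

    Uses the multiplicative recurrence between adjacent heterozygote
    counts,

        P(h+2) / P(h) = 4 n_aa n_bb / ((h+2)(h+1)),

    started from the modal count and normalized, which avoids factorial
    overflow without leaving plain arithmetic.
    """
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    # start near the mode to keep relative values in range
    h0 = int(round(2.0 * n_minor * (2 * n - n_minor) / (2.0 * n * 2.0 * n)))
    if (h0 - n_minor) % 2:
        h0 += 1
    h0 = min(max(h0, hs[0]), hs[-1])
    probs = {h0: 1.0}
    h = h0
    while h + 2 <= hs[-1]:
        n_aa = (n_minor - h) // 2
        n_bb = n - n_aa - h
        probs[h + 2] = probs[h] * 4.0 * n_aa * n_bb / ((h + 2.0) * (h + 1.0))
        h += 2
    h = h0
    while h - 2 >= hs[0]:
        n_aa = (n_minor - h) // 2 + 1
        n_bb = n - (n_minor - h) // 2 - h + 1
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * n_aa * n_bb)
        h -= 2
    p = np.array([probs[x] for x in hs])
    return hs, p / p.sum()


def hwe_pvalues_for_counts(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact HWE p-value for every admissible heterozygote count.

    Returns (het counts, p-values): p = sum of null probabilities of
    configurations no more probable than the observed one (two-sided,
    Wigginton-style), capped at 1.
    """
    h, probs = _hwe_het_distribution(n, n_minor)
    # p-value for each config: sum of probs <= its own prob (with slack
    # for floating-point ties between symmetric configurations)
    order = np.argsort(probs, kind="stable")
    sp = probs[order]
    cum = np.cumsum(sp)
    pos = np.searchsorted(sp, probs * (1.0 + 1e-12), side="right")
    pv = cum[np.maximum(pos, 1) - 1]
    return h, np.minimum(pv, 1.0)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy–Weinberg equilibrium.

    Conditions on the observed allele counts and sums the hypergeometric
    null probabilities of all heterozygote configurations no more likely
    than the observed one.  Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    h, pv = hwe_pvalues_for_counts(n, n_minor)
    return float(pv[h == n_Aa][0])


# ---------------------------------------------------------------------------
# truth-callset site QC and evaluation-set intersection


def wgs_site_qc(G: np.ndarray, variants: Sequence[VariantKey],
                filters: Optional[Sequence[str]] = None,
                max_site_miss: float = 0.10,
                hwe_p_min: float = 1e-6) -> tuple[np.ndarray, QCReport]:
    """Site QC on a truth callset.

    Drops sites with a non-PASS FILTER value, site missingness >
    ``max_site_miss`` (strict), or exact-HWE p < ``hwe_p_min``.  Returns
    kept site indices in input (coordinate) order.
    """
    G = np.asarray(G)
    n, m = G.shape
    report = QCReport(thresholds={"max_site_miss": max_site_miss,
                                  "hwe_p_min": hwe_p_min})
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        vid = variants[j].id
        if filters is not None and filters[j] not in ("PASS", ".", None):
            keep[j] = False
            report.removed_sites.append((vid, "filter"))
            continue
        col = G[:, j]
        obs = col[col != MISSING]
        if (n - obs.size) / n > max_site_miss:
            keep[j] = False
            report.removed_sites.append((vid, "missingness"))
            continue
        counts = np.bincount(obs, minlength=3)
        if obs.size and hwe_exact_test(int(counts[0]), int(counts[1]),
                                       int(counts[2])) < hwe_p_min:
            keep[j] = False
            report.removed_sites.append((vid, "hwe"))
    return np.flatnonzero(keep), report


def intersect_evaluation_sites(imputed_variant_lists: Sequence[Sequence[VariantKey]],
                               qc_truth_variants: Sequence[VariantKey]
                               ) -> list[VariantKey]:
    """QCed truth sites present in every imputed dataset, in coordinate order."""
    if not imputed_variant_lists:
        raise ValueError("need at least one imputed dataset")
    common = set(qc_truth_variants)
    for lst in imputed_variant_lists:
        common &= set(lst)
    return sorted(common, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
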