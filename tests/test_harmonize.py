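"""Harmonization actions, QC filters and the exact HWE test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

import panelbench.harmonize as hz
from panelbench.harmonize import (apply_action, classify_variant,
                                  genomic_relatedness_matrix, harmonize_tables,
                                  hwe_exact_test, intersect_evaluation_sites,
                                  relatedness_prune, sample_missingness_filter,
                                  wgs_site_qc)
from panelbench.simdata import VariantKey


def vk(ref, alt, pos=100, chrom="1"):
    return VariantKey(chrom, pos, ref, alt)


class TestClassifyVariant:
    @pytest.mark.parametrize("a,p,af_a,af_p,action", [
        (("A", "G"), ("A", "G"), 0.30, 0.31, "keep"),
        (("A", "G"), ("T", "C"), 0.30, 0.31, "strand_flip"),
        (("A", "G"), ("G", "A"), 0.30, 0.69, "allele_swap"),
        (("A", "G"), ("C", "T"), 0.30, 0.71, "flip_and_swap"),
    ])
    def test_orientation_actions(self, a, p, af_a, af_p, action):
        act = classify_variant(vk(*a), af_a, vk(*p), af_p)
        assert act.action == action
        assert act.reason is None

    def test_high_maf_palindrome_excluded(self):
        act = classify_variant(vk("A", "T"), 0.48, vk("A", "T"), 0.50,
                               palindromic_maf_max=0.40)
        assert (act.action, act.reason) == ("exclude", "palindromic_ambiguous")

    def test_low_maf_palindrome_oriented_by_frequency(self):
        keep = classify_variant(vk("A", "T"), 0.10, vk("A", "T"), 0.11)
        swap = classify_variant(vk("A", "T"), 0.10, vk("A", "T"), 0.89)
        assert keep.action == "keep"
        assert swap.action == "allele_swap"

    def test_discordant_frequency_excluded_after_orientation(self):
        act = classify_variant(vk("A", "G"), 0.05, vk("A", "G"), 0.60)
        assert (act.action, act.reason) == ("exclude", "af_discrepant")

    def test_incompatible_alleles_excluded(self):
        act = classify_variant(vk("A", "G"), 0.3, vk("A", "C"), 0.3)
        assert (act.action, act.reason) == ("exclude", "allele_mismatch")

    def test_malformed_allele_raises(self):
        with pytest.raises(ValueError):
            classify_variant(vk("A", "N"), 0.3, vk("A", "G"), 0.3)

    @given(st.sampled_from(["A", "C", "G", "T"]),
           st.sampled_from(["A", "C", "G", "T"]),
           st.floats(0.01, 0.99),
           st.sampled_from(["keep", "strand_flip", "allele_swap",
                            "flip_and_swap"]))
    @settings(max_examples=200, deadline=None)
    def test_applying_the_action_recovers_panel_orientation(
            self, ref, alt, af, scramble):
        """Orientation consistency: re-applying the classifier's action
        to the array record must reproduce the panel record exactly."""
        if ref == alt or hz._COMPLEMENT[ref] == alt:
            return  # invalid or palindromic; covered elsewhere
        panel = vk(ref, alt)
        arr_key, arr_af = panel, af
        # scramble the array record away from panel orientation
        inverse = {"keep": "keep", "strand_flip": "strand_flip",
                   "allele_swap": "allele_swap",
                   "flip_and_swap": "flip_and_swap"}[scramble]
        arr_key, arr_af = apply_action(
            panel, af, hz.HarmonizationAction(panel, inverse))
        act = classify_variant(arr_key, arr_af, panel, af)
        assert act.action != "exclude"
        fixed_key, fixed_af = apply_action(arr_key, arr_af, act)
        assert (fixed_key.ref, fixed_key.alt) == (panel.ref, panel.alt)
        assert fixed_af == pytest.approx(af)


def test_duplicates_and_unmatched_positions_flagged():
    arr = [(vk("A", "G", 100), 0.3), (vk("A", "G", 100), 0.3),
           (vk("C", "T", 500), 0.2)]
    panel = [(vk("A", "G", 100), 0.3)]
    actions = harmonize_tables(arr, panel)
    assert actions[0].action == "keep"
    assert actions[1].reason == "duplicate"
    assert actions[2].reason == "position_mismatch"


class TestSampleMissingness:
    def test_strict_threshold_boundary(self):
        G = np.zeros((3, 100), dtype=int)
        G[0, :6] = hz.MISSING   # 6% -> removed
        G[1, :5] = hz.MISSING   # exactly 5% -> kept
        kept, rep = sample_missingness_filter(G, ["a", "b", "c"], 0.05)
        assert list(kept) == [1, 2]
        assert rep.removed_samples == [("a", "missingness")]

    def test_complete_data_all_kept(self):
        G = np.ones((4, 10), dtype=int)
        kept, rep = sample_missingness_filter(G, list("abcd"))
        assert kept.size == 4 and not rep.removed_samples

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, (20, 50))
        G[rng.random(G.shape) < 0.03] = hz.MISSING
        ids = [str(i) for i in range(20)]
        kept1, _ = sample_missingness_filter(G, ids)
        kept2, _ = sample_missingness_filter(G[kept1],
                                             [ids[i] for i in kept1])
        assert kept2.size == kept1.size


class TestRelatedness:
    def test_grm_matches_direct_formula(self, rng):
        G = rng.integers(0, 3, size=(3, 4)).astype(float)
        # make all sites polymorphic
        G[:, 0] = [0, 1, 2]
        A = genomic_relatedness_matrix(G)
        p = G.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        expected = np.zeros((3, 3))
        for j in range(3):
            for k in range(3):
                terms = [(G[j, i] - 2 * p[i]) * (G[k, i] - 2 * p[i])
                         / (2 * p[i] * (1 - p[i]))
                         for i in np.flatnonzero(poly)]
                expected[j, k] = np.mean(terms)
        assert np.allclose(A, expected, atol=1e-12)

    def test_duplicate_sample_pruned_once(self, rng):
        G = rng.integers(0, 3, size=(6, 400))
        G[3] = G[0]  # exact duplicate
        kept, rep = relatedness_prune(G, [f"s{i}" for i in range(6)])
        assert kept.size == 5
        assert len(rep.removed_samples) == 1
        assert rep.removed_samples[0][0] in ("s0", "s3")

    def test_parent_offspring_exceed_cutoff_more_than_unrelated(self, rng):
        m = 5000
        freqs = rng.uniform(0.1, 0.9, m)
        def draw_pair():
            return (rng.random((2, m)) < freqs).astype(int)
        related, unrelated = [], []
        people = []
        for _ in range(8):
            pa, ma = draw_pair(), draw_pair()
            child = np.stack([pa[0], ma[0]])
            people += [pa.sum(0), ma.sum(0), child.sum(0)]
        G = np.array(people, dtype=float)
        A = genomic_relatedness_matrix(G)
        for f in range(8):
            i = 3 * f
            related += [A[i, i + 2], A[i + 1, i + 2]]
            j = 3 * ((f + 1) % 8)
            unrelated += [A[i, j], A[i + 1, j + 1]]
        # parent-offspring relatedness sits near 0.5 (deflated slightly
        # by sample-frequency standardisation); unrelated pairs near 0
        assert np.min(related) > 0.3
        assert np.max(unrelated) < 0.15
        assert np.mean(related) > np.mean(unrelated) + 0.3

    def test_unrelated_offdiagonal_near_zero(self, rng):
        n = 200
        freqs = rng.uniform(0.05, 0.95, 10_000)
        G = (rng.random((n, 10_000)) < freqs).astype(int) \
            + (rng.random((n, 10_000)) < freqs).astype(int)
        A = genomic_relatedness_matrix(G)
        off = A[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_monomorphic_only_is_an_error(self):
        with pytest.raises(ValueError):
            genomic_relatedness_matrix(np.zeros((3, 5)))


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent enumeration oracle via log-gamma multinomial weights."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nm = min(na, 2 * n - na)
    if nm == 0:
        return 1.0
    hs = np.arange(nm % 2, nm + 1, 2)
    naa = (nm - hs) // 2
    nbb = n - naa - hs
    logp = (gammaln(n + 1) - gammaln(naa + 1) - gammaln(hs + 1)
            - gammaln(nbb + 1) + hs * np.log(2.0)
            + gammaln(nm + 1) + gammaln(2 * n - nm + 1) - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hs == n_Aa][0]
    return float(min(p[p <= obs * (1 + 1e-12)].sum(), 1.0))


class TestHWE:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_extreme_heterozygote_excess(self):
        p = hwe_exact_test(0, 100, 0)
        assert p == pytest.approx(hwe_oracle(0, 100, 0), abs=1e-12)
        assert p < 1e-6

    def test_textbook_example(self):
        assert hwe_exact_test(21, 48, 31) == pytest.approx(
            hwe_oracle(21, 48, 31), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @given(st.integers(0, 80), st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(
            hwe_oracle(a, b, c), abs=1e-12)


class TestSiteQC:
    def make(self, n=20, m=5):
        variants = [VariantKey("1", 10 * (j + 1), "A", "G") for j in range(m)]
        G = np.zeros((n, m), dtype=int)
        G[: n // 2, :] = 1
        G[: n // 4, :] = 2  # roughly HWE-ish mix
        return variants, G

    def test_clean_input_unchanged(self):
        variants, G = self.make()
        kept, rep = wgs_site_qc(G, variants)
        assert kept.size == len(variants) and not rep.removed_sites

    def test_missingness_rule(self):
        variants, G = self.make(n=412)
        G[:46, 0] = hz.MISSING  # 11.2% missing
        kept, rep = wgs_site_qc(G, variants)
        assert 0 not in kept
        assert ("1:10:A:G", "missingness") in rep.removed_sites

    def test_hwe_rule(self):
        variants, G = self.make(n=100)
        G[:, 1] = 1  # all heterozygous
        kept, rep = wgs_site_qc(G, variants)
        assert 1 not in kept
        assert ("1:20:A:G", "hwe") in rep.removed_sites

    def test_filter_column_honored(self):
        variants, G = self.make()
        filters = ["PASS", "LowQ", "PASS", "PASS", "PASS"]
        kept, rep = wgs_site_qc(G, variants, filters)
        assert 1 not in kept
        assert ("1:20:A:G", "filter") in rep.removed_sites


class TestIntersection:
    def keys(self, positions):
        return [VariantKey("1", p, "A", "G") for p in positions]

    def test_identical_lists(self):
        truth = self.keys([10, 20, 30])
        assert intersect_evaluation_sites([truth, truth], truth) == truth

    def test_site_missing_from_one_dataset_dropped(self):
        truth = self.keys([10, 20, 30])
        out = intersect_evaluation_sites([truth, self.keys([10, 30])], truth)
        assert out == self.keys([10, 30])

    def test_disjoint_lists_empty(self):
        assert intersect_evaluation_sites(
            [self.keys([40, 50])], self.keys([10, 20])) == []
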