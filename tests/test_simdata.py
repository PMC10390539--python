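"""Generator sanity: frequency spectrum, drift, mosaics, masks, phenotypes."""

import numpy as np
import pytest
from scipy.stats import kstest

import panelbench.simdata as sd


def test_ancestral_frequencies_within_truncation_bounds():
    cfg = sd.SimConfig(seed=3, n_sites=1, n_ancestral_haps=50)
    f = sd.draw_ancestral_frequencies(cfg)
    assert f.shape == (1,)
    assert 1.0 / 100 <= f[0] <= 0.5


def test_flat_spectrum_is_uniform_on_truncation_interval():
    # alpha = 0 makes the density flat; KS against the uniform CDF
    cfg = sd.SimConfig(seed=5, n_sites=100_000, n_ancestral_haps=100,
                       sfs_alpha=0.0)
    f = sd.draw_ancestral_frequencies(cfg)
    lo, hi = 1.0 / 200, 0.5
    stat = kstest(f, lambda x: (x - lo) / (hi - lo))
    assert stat.pvalue > 1e-3


def test_neutral_spectrum_matches_truncated_reciprocal_cdf():
    cfg = sd.SimConfig(seed=6, n_sites=100_000, n_ancestral_haps=100,
                       sfs_alpha=1.0)
    f = np.sort(sd.draw_ancestral_frequencies(cfg))
    lo, hi = 1.0 / 200, 0.5
    analytic = np.log(f / lo) / np.log(hi / lo)
    empirical = np.arange(1, f.size + 1) / f.size
    assert np.max(np.abs(analytic - empirical)) < 0.01


def test_invalid_spectrum_config_rejected():
    with pytest.raises(sd.ConfigError):
        sd.SimConfig(seed=0, sfs_alpha=-1.0)
    with pytest.raises(sd.ConfigError):
        sd.SimConfig(seed=0, n_sites=0)


def test_balding_nichols_zero_fst_is_identity(rng):
    p = np.array([0.1, 0.3, 0.5])
    assert np.array_equal(sd.balding_nichols_freqs(p, 0.0, rng), p)


def test_balding_nichols_preserves_mean_frequency(rng):
    # expected subpopulation AF equals the ancestral AF: average over
    # replicate draws per site
    p = np.array([0.05, 0.2, 0.45])
    draws = np.array([sd.balding_nichols_freqs(p, 0.1, rng)
                      for _ in range(400)])
    se = np.sqrt(0.1 * p * (1 - p) / 400)
    assert np.all(np.abs(draws.mean(axis=0) - p) < 4 * se)


def test_degenerate_fst_rejected(rng):
    cfg = sd.SimConfig(seed=0, n_sites=10)
    pos = np.arange(1, 11) * 100
    with pytest.raises(sd.ConfigError):
        sd.simulate_subpopulation_panel(np.full(10, 0.3), 1.0, cfg,
                                        positions=pos, n_out=4,
                                        pop_label="A", rng=rng)


def test_no_drift_no_mosaic_reproduces_founders(rng):
    cfg = sd.SimConfig(seed=1, n_sites=50, n_ancestral_haps=8,
                       recomb_rate=0.0, flip_rate=0.0)
    pos = np.sort(rng.choice(10_000, 50, replace=False)) + 1
    anc = sd.draw_ancestral_frequencies(cfg, rng)
    panel, founders = sd.simulate_subpopulation_panel(
        anc, 0.0, cfg, positions=pos, n_out=30, pop_label="A", rng=rng)
    founder_set = {f.tobytes() for f in founders}
    for hap in panel.haplotypes:
        assert hap.tobytes() in founder_set


def test_half_flip_rate_decorrelates_output_from_founders(rng):
    cfg = sd.SimConfig(seed=2, n_sites=40, n_ancestral_haps=1,
                       recomb_rate=0.0, flip_rate=0.5)
    pos = np.arange(1, 41) * 100
    founders = rng.integers(0, 2, size=(1, 40)).astype(np.uint8)
    out = sd.mosaic_haplotypes(founders, pos, 4000, 0.0, 0.5, rng)
    # every output copies the single founder, then flips half the time:
    # per-site agreement should be ~0.5
    agree = (out == founders[0]).mean(axis=0)
    assert np.all(np.abs(agree - 0.5) < 0.05)


def hudson_fst(p1, p2, n1, n2):
    """Hudson's FST estimator (ratio of sums over sites).

    Numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1), denominator
    p1(1-p2) + p2(1-p1); sample sizes in haplotypes.
    """
    num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


def test_pairwise_fst_recovered_by_hudson_estimator():
    """Two panels drifted at F=0.05 from shared ancestral frequencies
    should show pairwise Hudson FST near 0.05."""
    rng = np.random.default_rng(77)
    cfg = sd.SimConfig(seed=77, n_sites=50_000, n_ancestral_haps=200,
                       region_length=50_000_000, recomb_rate=0.0,
                       flip_rate=0.0)
    anc = sd.draw_ancestral_frequencies(cfg, rng)
    ps = []
    for _ in range(2):
        freqs = sd.balding_nichols_freqs(anc, 0.05, rng)
        haps = sd.draw_founders(freqs, 200, rng)
        ps.append(haps.mean(axis=0))
    fst = hudson_fst(ps[0], ps[1], 200, 200)
    assert 0.04 < fst < 0.06


@pytest.mark.parametrize("q,expect_a", [(1.0, 2), (0.0, 0)])
def test_admixture_extremes_fix_haplotype_ancestry(q, expect_a, rng):
    cfg = sd.SimConfig(seed=0, n_sites=30, n_ancestral_haps=10)
    pos = np.arange(1, 31) * 10
    fA = rng.integers(0, 2, (10, 30)).astype(np.uint8)
    fB = rng.integers(0, 2, (10, 30)).astype(np.uint8)
    _, anc = sd.simulate_admixed_individual(fA, fB, q, cfg, pos, rng)
    assert anc.sum() == expect_a


def test_balanced_admixture_has_binomial_ancestry_fraction(rng):
    cfg = sd.SimConfig(seed=0, n_sites=20, n_ancestral_haps=5)
    pos = np.arange(1, 21) * 10
    fA = rng.integers(0, 2, (5, 20)).astype(np.uint8)
    fB = rng.integers(0, 2, (5, 20)).astype(np.uint8)
    n = 1500
    total = sum(sd.simulate_admixed_individual(fA, fB, 0.5, cfg, pos, rng)[1].sum()
                for _ in range(n))
    frac = total / (2 * n)
    se = np.sqrt(0.25 / (2 * n))
    assert abs(frac - 0.5) < 4 * se


class TestArrayMask:
    def test_everything_typed_when_unconstrained(self):
        cfg = sd.SimConfig(seed=0, array_maf_min=0.0, array_spacing=1)
        g = np.array([[0, 1, 2], [1, 1, 0]])
        assert np.array_equal(sd.mask_to_array(g, cfg), [0, 1, 2])

    def test_spacing_keeps_every_mth_eligible_site(self, rng):
        cfg = sd.SimConfig(seed=0, array_maf_min=0.0, array_spacing=5)
        g = rng.integers(0, 3, size=(40, 100))
        assert sd.mask_to_array(g, cfg).size == 20

    def test_maf_floor_respected(self, small_cohort):
        cfg = small_cohort.config
        g = small_cohort.truth_genotypes()
        af = g.mean(axis=0) / 2
        maf = np.minimum(af, 1 - af)
        assert np.all(maf[small_cohort.typed_idx] >= cfg.array_maf_min)

    def test_empty_mask_is_an_error(self):
        cfg = sd.SimConfig(seed=0, array_maf_min=0.4, array_spacing=1)
        g = np.zeros((10, 5), dtype=int)  # all monomorphic
        with pytest.raises(sd.ConfigError):
            sd.mask_to_array(g, cfg)


class TestPhenotypes:
    def test_null_model_hits_target_prevalence(self, rng):
        cfg = sd.SimConfig(seed=9, case_fraction=0.3)
        g = rng.integers(0, 3, size=(5000, 10))
        y = sd.simulate_phenotypes(g, cfg, rng)
        se = np.sqrt(0.3 * 0.7 / 5000)
        assert abs(y.mean() - 0.3) < 4 * se

    def test_huge_effect_makes_carriers_cases(self, rng):
        cfg = sd.SimConfig(seed=9, case_fraction=0.5,
                           causal_effects=((0, 10.0),))
        g = np.repeat([[0], [2]], 300, axis=0)
        y = sd.simulate_phenotypes(g, cfg, rng)
        carriers = g[:, 0] == 2
        assert y[carriers].mean() > 0.99

    def test_phenotypes_deterministic_given_seed(self, rng):
        cfg = sd.SimConfig(seed=4, case_fraction=0.2)
        g = rng.integers(0, 3, size=(200, 5))
        assert np.array_equal(sd.simulate_phenotypes(g, cfg),
                              sd.simulate_phenotypes(g, cfg))


def test_cohort_generation_is_deterministic():
    cfg = sd.SimConfig(seed=123, n_sites=120, pop_sizes=(8, 8),
                       panel_size=20, admixed_fraction=0.2)
    a = sd.simulate_cohort(cfg)
    b = sd.simulate_cohort(cfg)
    assert np.array_equal(a.targets, b.targets)
    assert np.array_equal(a.phenotypes, b.phenotypes)
    assert np.array_equal(a.typed_idx, b.typed_idx)
    for pop in a.panels:
        assert np.array_equal(a.panels[pop].haplotypes,
                              b.panels[pop].haplotypes)


def test_ld_decays_with_distance():
    """Mean pairwise r^2 between sites is non-increasing across distance
    deciles when haplotypes are recombinant founder mosaics."""
    rng = np.random.default_rng(15)
    cfg = sd.SimConfig(seed=15, n_sites=10_000, n_ancestral_haps=30,
                       region_length=1_000_000, recomb_rate=2e-5,
                       flip_rate=0.0)
    pos = sd.draw_positions(cfg, rng)
    anc = sd.draw_ancestral_frequencies(cfg, rng)
    freqs = sd.balding_nichols_freqs(anc, 0.02, rng)
    founders = sd.draw_founders(freqs, 30, rng)
    haps = sd.mosaic_haplotypes(founders, pos, 200, cfg.recomb_rate,
                                0.0, rng).astype(float)
    poly = haps.std(axis=0) > 0
    haps, pos_p = haps[:, poly], pos[poly]
    z = (haps - haps.mean(0)) / haps.std(0)
    n_pairs = 200_000
    i = rng.integers(0, z.shape[1], n_pairs)
    j = rng.integers(0, z.shape[1], n_pairs)
    keep = i != j
    i, j = i[keep], j[keep]
    r2 = ((z[:, i] * z[:, j]).mean(axis=0)) ** 2
    dist = np.abs(pos_p[i] - pos_p[j])
    edges = np.quantile(dist, np.linspace(0, 1, 11))
    decile = np.clip(np.searchsorted(edges[1:-1], dist), 0, 9)
    means = np.array([r2[decile == d].mean() for d in range(10)])
    assert np.all(np.diff(means) <= 1e-3)
    assert means[0] > means[-1]
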