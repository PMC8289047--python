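"""Unit and oracle tests for the population-genetic statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from altiscan import stats
from altiscan.sfs import fold_cell
from altiscan.types import FilterConfig

from conftest import make_vt


# ----------------------------------------------------------------------
# coverage threshold and allele frequencies


@pytest.mark.parametrize("depth,n,expected", [(6, 23, 138), (1, 1, 1), (6, 10, 60)])
def test_min_coverage_threshold(depth, n, expected):
    assert stats.min_coverage_threshold(depth, n) == expected


def test_min_coverage_threshold_rejects_nonpositive():
    with pytest.raises(ValueError):
        stats.min_coverage_threshold(0, 23)


@pytest.mark.parametrize("genos,expected", [
    ([[2], [2], [2]], 1.0),
    ([[0], [1], [2]], 0.5),
    ([[2], [1], [-1]], 0.75),
])
def test_allele_freqs(genos, expected):
    vt = make_vt(genos, ["p"] * len(genos))
    assert stats.allele_freqs(vt, "p")[0] == pytest.approx(expected)


def test_allele_freqs_unknown_population():
    vt = make_vt([[0]], ["p"])
    with pytest.raises(KeyError):
        stats.allele_freqs(vt, "nope")


# ----------------------------------------------------------------------
# Weir-Cockerham FST


def _wc_fst_scalar(g1, g2):
    """Independent scalar evaluation of the 1984 variance components."""
    def summarize(g):
        g = [x for x in g if x >= 0]
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        return n, p, h

    n1, p1, h1 = summarize(g1)
    n2, p2, h2 = summarize(g2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


def test_site_fst_fixed_difference(two_pop_vt):
    fst = stats.site_fst(two_pop_vt)
    assert fst[0] == pytest.approx(1.0)
    assert fst[1] == pytest.approx(1.0)


def test_site_fst_identical_pops_nonpositive():
    g = [[0, 1], [1, 0], [2, 1], [0, 1], [1, 0], [2, 1]]
    vt = make_vt(g, ["a"] * 3 + ["b"] * 3)
    fst = stats.site_fst(vt)
    assert np.all(fst[~np.isnan(fst)] <= 0)


def test_site_fst_matches_scalar_oracle():
    # pop1 alt count 8 of 20 alleles, pop2 2 of 20, near-HWE genotypes
    g1 = [2, 2, 1, 1, 1, 1, 0, 0, 0, 0]
    g2 = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
    vt = make_vt([[a] for a in g1 + g2], ["p1"] * 10 + ["p2"] * 10)
    expected = _wc_fst_scalar(g1, g2)
    assert stats.site_fst(vt)[0] == pytest.approx(expected, rel=1e-12)


def test_site_fst_requires_two_genotypes_per_pop():
    vt = make_vt([[2], [-1], [0], [0]], ["a", "a", "b", "b"])
    assert np.isnan(stats.site_fst(vt)[0])


def test_hudson_and_wc_agree_on_strong_differentiation(two_pop_vt):
    wc = stats.site_fst(two_pop_vt)
    hu = stats.hudson_fst(two_pop_vt)
    assert hu[0] == pytest.approx(1.0)
    assert np.sign(wc[2]) == np.sign(hu[2]) or abs(wc[2] - hu[2]) < 0.1


# ----------------------------------------------------------------------
# diversity and divergence


def test_windowed_pi_empty_window_zero():
    vt = make_vt(np.zeros((4, 0), dtype=int).tolist(), ["p"] * 4)
    # no sites at all -> no windows; a monomorphic site gives pi 0
    vt2 = make_vt([[0], [0], [0], [0]], ["p"] * 4)
    out = stats.windowed_pi(vt2, "p", window_bp=50_000)
    assert out["pi"].iloc[0] == 0.0


def test_windowed_pi_single_snp_hand_value():
    # allele counts 3:1 among 4 alleles -> (4/3)*2*(3/4)*(1/4) = 0.5 per site
    vt = make_vt([[2], [1]], ["p", "p"])
    out = stats.windowed_pi(vt, "p", window_bp=50_000)
    assert out["pi"].iloc[0] == pytest.approx(0.5 / 50_000)


def test_windowed_pi_sample_size_factor():
    # doubling individuals at the same frequency changes only n/(n-1)
    vt1 = make_vt([[2], [1]], ["p", "p"])          # n=4
    vt2 = make_vt([[2], [1]] * 2, ["p"] * 4)       # n=8, same p=3/4... no
    # same frequencies: duplicate the allele configuration exactly
    pi1 = stats.windowed_pi(vt1, "p", 1000)["pi"].iloc[0]
    pi2 = stats.windowed_pi(vt2, "p", 1000)["pi"].iloc[0]
    ratio = pi2 / pi1
    assert ratio == pytest.approx((8 / 7) / (4 / 3), rel=1e-12)


@pytest.mark.parametrize("g1,g2,expected", [
    ([[0], [0]], [[0], [0]], 0.0),                      # identical p=0
    ([[2], [2]], [[0], [0]], 1 / 50_000),               # fixed difference
    ([[2], [0]], [[1], [0]], (0.5 * 0.75 + 0.25 * 0.5) / 50_000),
])
def test_dxy_hand_values(g1, g2, expected):
    vt = make_vt([row for row in g1] + [row for row in g2],
                 ["a"] * len(g1) + ["b"] * len(g2))
    out = stats.dxy(vt, window_bp=50_000)
    assert out["dxy"].iloc[0] == pytest.approx(expected)


def test_tajimas_d_no_segregating_sites_undefined():
    vt = make_vt([[0], [0], [0]], ["p"] * 3)
    out = stats.tajimas_d(vt, "p", 50_000)
    assert np.isnan(out["tajimas_d"].iloc[0])


def test_tajimas_d_matches_scalar_constants():
    # n=4 haploid (2 diploids), 3 singleton sites: S=3, mean pairwise 1.5
    vt = make_vt([[1, 1, 1], [0, 0, 0]], ["p", "p"])
    out = stats.tajimas_d(vt, "p", 50_000)
    n = 4
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    S = 3
    pi_hat = 3 * 0.5
    expected = (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    assert out["tajimas_d"].iloc[0] == pytest.approx(expected, rel=1e-12)


# ----------------------------------------------------------------------
# linkage disequilibrium


def test_ld_r2_duplicated_site_is_one():
    vt = make_vt([[0, 0], [1, 1], [2, 2], [2, 2], [0, 0]], ["p"] * 5)
    out = stats.ld_r2(vt, max_dist_bp=20_000)
    assert out["r2"].iloc[0] == pytest.approx(1.0)


def test_ld_r2_hand_value():
    gi = np.array([0, 1, 2, 2, 0], float)
    gj = np.array([0, 1, 1, 2, 0], float)
    cov = ((gi - gi.mean()) * (gj - gj.mean())).mean()
    expected = cov ** 2 / (gi.var() * gj.var())
    vt = make_vt(np.column_stack([gi, gj]).astype(int).tolist(), ["p"] * 5)
    out = stats.ld_r2(vt, max_dist_bp=20_000)
    assert out["r2"].iloc[0] == pytest.approx(expected, rel=1e-12)


def test_ld_r2_orthogonal_zero():
    gi = [0, 0, 2, 2]
    gj = [0, 2, 0, 2]
    vt = make_vt(np.column_stack([gi, gj]).tolist(), ["p"] * 4)
    assert stats.ld_r2(vt, 20_000)["r2"].iloc[0] == pytest.approx(0.0)


def test_ld_prune_keeps_left_of_duplicate_pair():
    vt = make_vt([[0, 0], [1, 1], [2, 2], [0, 0]], ["p"] * 4, pos=[100, 200])
    kept = stats.ld_prune(vt, r2_threshold=0.5, window_bp=20_000)
    assert kept.tolist() == [0]


def test_ld_prune_chain_rule():
    # A~B and B~C correlated, A~C not, all within the window: keep {A, C}
    A = [1, 0, 0, 0, 0, 2, 1, 1]
    B = [1, 2, 1, 2, 2, 0, 1, 0]
    C = [0, 0, 1, 0, 0, 1, 1, 2]
    vt = make_vt(np.column_stack([A, B, C]).tolist(), ["p"] * 8,
                 pos=[100, 5000, 9000])
    r2 = stats.ld_r2(vt, 20_000).set_index(["pos_a", "pos_b"])["r2"]
    assert r2[(100, 5000)] >= 0.5 and r2[(5000, 9000)] >= 0.5
    assert r2[(100, 9000)] < 0.5
    kept = stats.ld_prune(vt, 0.5, 20_000)
    assert kept.tolist() == [0, 2]


def test_ld_prune_is_fixed_point():
    rng = np.random.default_rng(7)
    G = rng.integers(0, 3, size=(10, 40))
    pos = np.sort(rng.choice(50_000, 40, replace=False)) + 1
    vt = make_vt(G.tolist(), ["p"] * 10, pos=pos)
    kept = stats.ld_prune(vt)
    again = stats.ld_prune(vt.take_sites(kept))
    assert again.tolist() == list(range(len(kept)))


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test


def _hwe_brute(n_aa, n_ab, n_bb):
    """Full enumeration oracle over heterozygote counts."""
    n = n_aa + n_ab + n_bb
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n == 0 or n_rare == 0:
        return 1.0
    probs = {}
    for het in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        # multinomial genotype arrangements x 2^het phase choices; the
        # margin-dependent constant cancels after normalization
        probs[het] = (
            math.comb(n, hom_r) * math.comb(n - hom_r, het) * 2 ** het
        )
    tot = sum(probs.values())
    probs = {h: p / tot for h, p in probs.items()}
    p_obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


@pytest.mark.parametrize("counts", [(3, 4, 3), (5, 0, 5), (0, 10, 0), (2, 5, 1)])
def test_hwe_exact_matches_enumeration(counts):
    assert stats.hwe_exact_test(*counts) == pytest.approx(_hwe_brute(*counts), rel=1e-9)


def test_hwe_monomorphic_is_one():
    assert stats.hwe_exact_test(10, 0, 0) == 1.0
    assert stats.hwe_exact_test(0, 0, 7) == 1.0


@given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
@settings(deadline=None, max_examples=60)
def test_hwe_exact_exhaustive_small_tables(a, b, c):
    p = stats.hwe_exact_test(a, b, c)
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(_hwe_brute(a, b, c), rel=1e-9)


# ----------------------------------------------------------------------
# folded joint SFS


def test_fold_joint_sfs_counts_and_conservation(two_pop_vt):
    sfs = stats.fold_joint_sfs(two_pop_vt)
    assert sfs.n1 == 10 and sfs.n2 == 10
    assert sfs.total == 4  # all four sites segregate with complete data


def test_fold_joint_sfs_single_site_cell():
    # pooled minor allele counts (3 high, 1 low)
    g_high = [[2], [1], [0], [0], [0]]
    g_low = [[1], [0], [0], [0], [0]]
    vt = make_vt(g_high + g_low, ["high"] * 5 + ["low"] * 5)
    sfs = stats.fold_joint_sfs(vt, pops=("high", "low"))
    assert sfs.data[3, 1] == 1 and sfs.total == 1


def test_fold_invariance_under_allele_relabeling(two_pop_vt):
    sfs1 = stats.fold_joint_sfs(two_pop_vt)
    flipped = two_pop_vt.take_sites(np.arange(two_pop_vt.n_sites))
    flipped.genotypes = (2 - flipped.genotypes).astype(np.int8)
    sfs2 = stats.fold_joint_sfs(flipped)
    assert np.array_equal(sfs1.data, sfs2.data)


def test_fold_cell_tie_rule_deterministic():
    # pooled count exactly half the pooled sample: lexicographic min wins
    assert fold_cell(3, 2, 4, 6) == min((3, 2), (1, 4))


# ----------------------------------------------------------------------
# genotype PCA


def test_genotype_pca_two_clusters_separate():
    G = [[0] * 20] * 5 + [[2] * 20] * 5
    vt = make_vt(G, ["a"] * 5 + ["b"] * 5, pos=np.arange(1, 21) * 10)
    scores, frac = stats.genotype_pca(vt)
    side_a = scores[:5, 0]
    side_b = scores[5:, 0]
    assert (side_a.max() < side_b.min()) or (side_b.max() < side_a.min())
    assert frac[0] == pytest.approx(1.0, abs=1e-9)


def test_genotype_pca_duplicated_individuals_same_directions():
    rng = np.random.default_rng(0)
    G = rng.integers(0, 3, size=(6, 30))
    vt1 = make_vt(G.tolist(), ["p"] * 6, pos=np.arange(1, 31) * 10)
    vt2 = make_vt(np.vstack([G, G]).tolist(), ["p"] * 12, pos=np.arange(1, 31) * 10)
    s1, _ = stats.genotype_pca(vt1)
    s2, _ = stats.genotype_pca(vt2)
    c1 = s1[:, 0] - s1[:, 0].mean()
    c2 = s2[:6, 0] - s2[:6, 0].mean()
    corr = np.corrcoef(c1, c2)[0, 1]
    assert abs(corr) > 0.999


def test_genotype_pca_monomorphic_errors():
    vt = make_vt([[2], [2], [2]], ["p"] * 3)
    with pytest.raises(ValueError):
        stats.genotype_pca(vt)


# ----------------------------------------------------------------------
# filter cascade


def test_filter_variants_cascade_counts():
    # site 0: common, clean; site 1: MAF too low; site 2: too much missing
    G = [
        [1, 0, -1],
        [1, 0, -1],
        [0, 0, 0],
        [2, 0, 1],
        [1, 1, 1],
        [0, 0, 0],
        [1, 0, 0],
        [2, 0, 0],
        [0, 0, 0],
        [1, 0, 0],
    ]
    vt = make_vt(G, ["p"] * 10)
    cfg = FilterConfig(maf_min=0.1, max_missing_frac=0.1, hwe_p_min=0.01)
    out, report = stats.filter_variants(vt, cfg)
    assert report["fail_maf"] == 1
    assert report["fail_missing"] == 1
    assert report["input_sites"] == 3
    assert out.n_sites == report["output_sites"]
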