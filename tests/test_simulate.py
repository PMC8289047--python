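"""Coalescent correctness and synthetic-data generator tests."""

import numpy as np
import pytest
from scipy import stats as sps

from altiscan import simulate as sim
from altiscan import stats
from altiscan.types import DemographySpec, InvalidSpecError, SampleConfig


ONE_DEME_N1000 = DemographySpec(n_pops=1, N_high=1000.0)


# ----------------------------------------------------------------------
# genealogy basics


def test_single_lineage_trivial_genealogy():
    g = sim.simulate_genealogy(ONE_DEME_N1000, (1, 0), seed=1)
    assert g.n_coalescent_events == 0
    assert g.total_branch_length == 0.0


def test_invalid_spec_rejected():
    with pytest.raises(InvalidSpecError):
        DemographySpec(N_high=-5)
    with pytest.raises(InvalidSpecError):
        DemographySpec(mu=0)
    with pytest.raises(InvalidSpecError):
        sim.simulate_genealogy(ONE_DEME_N1000, (0, 0), seed=1)


def test_pair_tmrca_matches_2N():
    """E[TMRCA] for a pair in one deme of size N is 2N generations."""
    tm = [sim.simulate_genealogy(ONE_DEME_N1000, (2, 0), seed=s).tmrca
          for s in range(10_000)]
    assert np.mean(tm) == pytest.approx(2000.0, rel=0.05)


def test_degenerate_split_equals_single_deme():
    """Two demes with T_split=0 merge immediately into the ancestral deme."""
    split0 = DemographySpec(n_pops=2, N_high=500, N_low=500, N_anc=1000,
                            T_split=0.0, m_low_to_high=0, m_high_to_low=0)
    tm_split = [sim.simulate_genealogy(split0, (1, 1), seed=s).tmrca
                for s in range(4000)]
    tm_one = [sim.simulate_genealogy(ONE_DEME_N1000, (2, 0), seed=s).tmrca
              for s in range(4000)]
    # same distribution: compare means within Monte-Carlo error
    se = np.std(tm_one) / np.sqrt(len(tm_one))
    assert abs(np.mean(tm_split) - np.mean(tm_one)) < 4 * se


# ----------------------------------------------------------------------
# mutation dropping


def test_no_branch_length_no_mutations():
    g = sim.simulate_genealogy(ONE_DEME_N1000, (1, 0), seed=3)
    pos, carriers = sim.drop_mutations(g, mu=1e-8, locus_length=1000, seed=4)
    assert len(pos) == 0 and carriers.shape == (0, 1)


def test_watterson_expectation():
    """Mean segregating sites is theta * a_{n-1} (Watterson 1975)."""
    n = 10
    N, mu, L = 1000.0, 1e-7, 1000
    spec = DemographySpec(n_pops=1, N_high=N, mu=mu)
    theta_L = 4 * N * mu * L
    a_n = sum(1.0 / i for i in range(1, n))
    counts = []
    for s in range(5000):
        g = sim.simulate_genealogy(spec, (n, 0), seed=s)
        pos, _ = sim.drop_mutations(g, mu, L, seed=100_000 + s)
        counts.append(len(pos))
    expected = theta_L * a_n
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expected) < 3 * se + 0.02 * expected


def test_mutation_rate_linearity():
    spec = ONE_DEME_N1000
    tot1 = tot2 = 0
    for s in range(800):
        g = sim.simulate_genealogy(spec, (6, 0), seed=s)
        tot1 += len(sim.drop_mutations(g, 1e-7, 1000, seed=s + 1)[0])
        tot2 += len(sim.drop_mutations(g, 2e-7, 1000, seed=90_000 + s)[0])
    assert tot2 / tot1 == pytest.approx(2.0, rel=0.1)


# ----------------------------------------------------------------------
# dataset simulation


def test_empty_dataset_keeps_metadata():
    vt = sim.simulate_dataset(DemographySpec(), SampleConfig(n_high=2, n_low=2,
                                                             n_sites=0, seed=5))
    assert vt.n_sites == 0
    assert vt.n_samples == 4
    assert vt.metadata["seed"] == 5


@pytest.mark.parametrize("seed", [0, 7])
def test_dataset_determinism(seed):
    cfg = SampleConfig(n_high=4, n_low=4, n_sites=200, seed=seed)
    a = sim.simulate_dataset(DemographySpec(), cfg)
    b = sim.simulate_dataset(DemographySpec(), cfg)
    assert a.equals(b)


def test_panmixia_gives_near_zero_fst():
    spec = DemographySpec(n_pops=2, N_high=10_000, N_low=10_000, N_anc=10_000,
                          T_split=0.0)
    vt = sim.simulate_dataset(spec, SampleConfig(n_high=8, n_low=8,
                                                 n_sites=5000, seed=11))
    fst = stats.site_fst(vt)
    assert abs(np.nanmean(fst)) < 0.01


def test_fst_increases_with_split_time():
    """Drift accumulates: mean FST strictly increasing in T_split at m=0."""
    means = []
    for T in (500, 5000, 26_000):
        spec = DemographySpec(n_pops=2, N_high=85_058, N_low=85_058,
                              N_anc=85_058, T_split=float(T),
                              m_low_to_high=0.0, m_high_to_low=0.0)
        vt = sim.simulate_dataset(spec, SampleConfig(n_high=11, n_low=12,
                                                     n_sites=10_000, seed=23))
        means.append(np.nanmean(stats.site_fst(vt)))
    assert means[0] < means[1] < means[2]


def test_linked_locus_mode_contig_per_locus():
    spec = DemographySpec(n_pops=1, N_high=50_000, mu=1e-8)
    vt = sim.simulate_dataset(spec, SampleConfig(n_high=5, n_low=5, n_loci=4,
                                                 locus_length=20_000, seed=2))
    assert set(vt.contig) <= {"sim_1", "sim_2", "sim_3", "sim_4"}
    for ctg in set(vt.contig):
        p = vt.pos[vt.contig == ctg]
        assert np.all(np.diff(p) > 0) and p.max() <= 20_000


# ----------------------------------------------------------------------
# expected SFS


def test_expected_sfs_symmetric_demes_symmetric():
    from altiscan.sfs import fold_matrix
    spec = DemographySpec(n_pops=2, N_high=20_000, N_low=20_000, N_anc=20_000,
                          T_split=5000, m_low_to_high=0.5, m_high_to_low=0.5)
    s = sim.expected_sfs(spec, 8, 8, n_replicates=40_000, seed=9)
    # swap demes, then re-canonicalize the fold (tie cells move under a bare
    # transpose) before comparing
    swapped = fold_matrix(s.data.T)
    assert np.abs(s.data - swapped).sum() < 0.02


def test_expected_sfs_two_haploids_single_entry():
    s = sim.expected_sfs(ONE_DEME_N1000, 2, 0, n_replicates=500, seed=1)
    assert s.data[1, 0] == pytest.approx(1.0)


def test_expected_marginal_sfs_matches_neutral_law():
    """Folded single-deme SFS entry i is proportional to 1/i + 1/(n-i)."""
    n = 10
    s = sim.expected_sfs(ONE_DEME_N1000, n, 0, n_replicates=50_000, seed=3)
    got = np.array([s.data[i, 0] for i in range(1, n // 2 + 1)])
    law = np.array([1 / i + 1 / (n - i) for i in range(1, n // 2)] + [1 / (n // 2)])
    law = law / law.sum()
    assert np.allclose(got, law, atol=0.01)


def test_expected_sfs_crn_is_deterministic():
    spec = DemographySpec()
    a = sim.expected_sfs(spec, 6, 6, 2000, seed=42)
    b = sim.expected_sfs(spec, 6, 6, 2000, seed=42)
    assert np.array_equal(a.data, b.data)


def test_expected_sfs_cross_validated_against_msprime():
    """Independent coalescent implementation agrees on the folded marginal."""
    msprime = pytest.importorskip("msprime")
    spec = DemographySpec(n_pops=2, N_high=5_000, N_low=20_000, N_anc=20_000,
                          T_split=4_000, m_low_to_high=0.0, m_high_to_low=0.0)
    ours = sim.expected_sfs(spec, 10, 10, n_replicates=60_000, seed=5)

    dem = msprime.Demography()
    dem.add_population(name="high", initial_size=5_000)
    dem.add_population(name="low", initial_size=20_000)
    dem.add_population(name="anc", initial_size=20_000)
    dem.add_population_split(time=4_000, derived=["high", "low"], ancestral="anc")
    W = np.zeros((11, 11))
    reps = msprime.sim_ancestry(
        samples={"high": 5, "low": 5}, demography=dem, ploidy=2,
        num_replicates=3000, random_seed=17,
    )
    for ts in reps:
        high_set = set(ts.samples(population=0))
        for tree in ts.trees():
            for node in tree.nodes():
                if tree.parent(node) == -1 or node == tree.root:
                    continue
                leaves = list(tree.leaves(node))
                if len(leaves) == ts.num_samples:
                    continue
                i = sum(1 for l in leaves if l in high_set)
                j = len(leaves) - i
                W[i, j] += tree.branch_length(node)
    from altiscan.sfs import fold_matrix, JointSFS
    theirs = JointSFS(fold_matrix(W), 10, 10).normalized()
    assert np.abs(ours.data - theirs.data).max() < 0.01


# ----------------------------------------------------------------------
# single-deme neutrality suite


def test_neutral_equilibrium_pi_and_watterson():
    """pi ~= 4*N*mu and Watterson's estimator agrees in expectation.

    The Tajima's-D neutrality band is checked in the acceptance suite at
    higher replication, where the sampling error of the window mean is small
    relative to the band.
    """
    N, mu, L = 100_000.0, 2e-8, 25_000
    spec = DemographySpec(n_pops=1, N_high=N, mu=mu)
    n_loci = 400
    vt = sim.simulate_dataset(spec, SampleConfig(n_high=10, n_low=0,
                                                 n_loci=n_loci,
                                                 locus_length=L, seed=31))
    pi_win = stats.windowed_pi(vt, "high", window_bp=L)
    pi_hat = pi_win["pi"].mean()
    se = pi_win["pi"].std() / np.sqrt(len(pi_win))
    assert abs(pi_hat - 4 * N * mu) < 3 * se

    # Watterson from total S over total length
    n_hap = 20
    a_n = sum(1.0 / i for i in range(1, n_hap))
    theta_w = vt.n_sites / (a_n * n_loci * L)
    assert theta_w == pytest.approx(4 * N * mu, rel=0.05)


# ----------------------------------------------------------------------
# spiked divergent sites


def _neutral_panel(seed=13, n_sites=300):
    spec = DemographySpec()
    return sim.simulate_dataset(
        spec, SampleConfig(n_high=11, n_low=12, n_sites=n_sites, seed=seed)
    )


def test_spike_zero_is_identity():
    vt = _neutral_panel()
    out = sim.spike_divergent_sites(vt, 0, 1.0, ("sim_1", 0, 1000), seed=1)
    assert out.equals(vt)


def test_spike_fixed_differences_have_high_fst():
    vt = _neutral_panel()
    region = ("sim_1", 400_000, 450_000)
    out = sim.spike_divergent_sites(vt, 20, 1.0, region, seed=3)
    spiked_pos = {p for _, p in out.metadata["spiked_sites"]}
    mask = np.array([p in spiked_pos for p in out.pos])
    fst = stats.site_fst(out)[mask]
    assert np.all(fst >= 0.9)
    assert np.mean(fst == pytest.approx(1.0)) or fst.mean() > 0.95


def test_spike_region_too_short_errors():
    vt = _neutral_panel()
    with pytest.raises(ValueError):
        sim.spike_divergent_sites(vt, 50, 1.0, ("sim_1", 0, 10), seed=1)


def test_spike_is_local():
    vt = _neutral_panel()
    region = ("sim_1", 100_000, 150_000)
    out = sim.spike_divergent_sites(vt, 10, 0.8, region, seed=5)
    outside_before = vt.take_sites((vt.pos <= 100_000) | (vt.pos > 150_000))
    outside_after = out.take_sites((out.pos <= 100_000) | (out.pos > 150_000))
    assert np.array_equal(outside_before.genotypes, outside_after.genotypes)


# ----------------------------------------------------------------------
# phenotype and expression fixtures


def test_phenotypes_shape_and_groups():
    df = sim.make_phenotypes(4, 4, n_traits=3, effect=2.0, noise_sd=0.3, seed=0)
    assert df.shape == (8, 5)
    assert list(df["group"]) == ["high"] * 4 + ["low"] * 4


def test_null_effect_type_one_error_rate():
    """With no group effect, the PC1 group t-test rejects at ~5%."""
    from altiscan.phenoexpr import phenotype_pca
    rejections = 0
    n_reps = 200
    for s in range(n_reps):
        df = sim.make_phenotypes(5, 5, n_traits=3, effect=0.0, noise_sd=0.5,
                                 seed=s)
        pc1 = phenotype_pca(df)[0][:, 0]
        _, p = sps.ttest_ind(pc1[:5], pc1[5:])
        rejections += p < 0.05
    rate = rejections / n_reps
    # binomial 99.7% interval around 0.05 at n=200
    assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_reps) <= rate \
        <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_reps) + 0.01


def test_noise_free_coupling_gives_perfect_correlation():
    rng_scores = np.arange(8.0)
    expr, coupled = sim.make_expression(rng_scores, n_genes=5, n_coupled=2,
                                        coupling_r=1.0, seed=1)
    log_tpm = np.log(expr.loc[coupled[0]].to_numpy())
    r = np.corrcoef(log_tpm, rng_scores)[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-10)


def test_coupling_r_realized_mean():
    """Sample |r| of coupled genes averages near the target over replicates."""
    rs = []
    for s in range(200):
        scores = np.random.default_rng(1000 + s).normal(size=8)
        expr, coupled = sim.make_expression(scores, n_genes=3, n_coupled=3,
                                            coupling_r=0.8, seed=s)
        z = (scores - scores.mean()) / scores.std()
        for g in coupled:
            x = np.log(expr.loc[g].to_numpy())
            rs.append(abs(np.corrcoef(x, z)[0, 1]))
    se = np.std(rs) / np.sqrt(len(rs))
    # sample |r| is biased slightly below the population value at n=8
    assert abs(np.mean(rs) - 0.8) < 3 * se + 0.05
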