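"""Structured-coalescent simulation and synthetic-data generation.

This module is both the engine behind every null distribution and expected
SFS in the package and the generator of complete synthetic datasets: neutral
variant panels (unlinked sites or linked 50-kb loci), spiked divergent sites
as positive controls for the scan, and small phenotype/expression fixtures.

Two granularities are supported: fully unlinked sites, where every site draws
its own genealogy and carries exactly one mutation (appropriate for SFS work
and site-level null calibration), and linked loci, where one genealogy per
locus receives Poisson infinite-sites mutations (appropriate for windowed
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _coalescent as _ck
from .sfs import JointSFS, fold_matrix
from .types import DemographySpec, InvalidSpecError, SampleConfig
from .variants import VariantTable

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_dataset",
    "expected_sfs",
    "spike_divergent_sites",
    "make_phenotypes",
    "make_expression",
]

_SEED_MOD = 2 ** 29


def _kernel_seed(seed: int) -> int:
    """Map an arbitrary integer seed into the range the kernels accept."""
    return int(seed) % _SEED_MOD


def _stream_seed(seed: int, purpose: str) -> int:
    """Decorrelated kernel seed for a (user seed, purpose) pair.

    Kernel loops use consecutive seeds ``base + r`` for replicate streams, so
    bases for different datasets/purposes must be far apart; hashing the user
    seed with a purpose tag guarantees that while keeping the map
    deterministic.
    """
    h = np.random.SeedSequence(
        [int(seed) % (2 ** 31), *(ord(c) for c in purpose)]
    )
    return int(h.generate_state(1)[0]) % _SEED_MOD


@dataclass
class Genealogy:
    """A single coalescent genealogy over ``n0 + n1`` haploid lineages.

    Leaves ``0..n0-1`` were sampled in the highland deme, ``n0..n0+n1-1`` in
    the lowland deme.  ``parent[v]`` is the parent node of ``v`` (-1 for the
    root); internal nodes are indexed in coalescence order, so parent indices
    always exceed child indices.  ``node_time`` is in generations.
    """

    parent: np.ndarray
    node_time: np.ndarray
    n0: int
    n1: int
    n_migrations: int = 0

    @property
    def n_leaves(self) -> int:
        return self.n0 + self.n1

    @property
    def n_coalescent_events(self) -> int:
        return max(self.n_leaves - 1, 0)

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])

    @property
    def total_branch_length(self) -> float:
        return float(_ck.total_branch_length(self.parent, self.node_time))


def simulate_genealogy(spec: DemographySpec, n_lineages_per_deme, seed: int) -> Genealogy:
    """Draw one structured-coalescent genealogy under ``spec``.

    ``n_lineages_per_deme`` is ``(n_high, n_low)`` in haploid lineages; pass
    ``(n, 0)`` for a single-deme sample.
    """
    n0, n1 = (int(x) for x in n_lineages_per_deme)
    if n0 < 0 or n1 < 0 or n0 + n1 < 1:
        raise InvalidSpecError("need at least 1 lineage, none negative")
    epochs = spec.to_epochs()
    parent, ntime, n_mig = _ck.sim_tree(n0, n1, epochs, _kernel_seed(seed))
    return Genealogy(parent=parent, node_time=ntime, n0=n0, n1=n1, n_migrations=int(n_mig))


def drop_mutations(g: Genealogy, mu: float, locus_length: int, seed: int):
    """Place infinite-sites mutations on a genealogy.

    Mutation count is Poisson(mu * locus_length * total branch length); each
    mutation lands on a branch with probability proportional to its length and
    at a uniform position on ``[0, locus_length)``.  Returns ``(positions,
    carriers)`` with positions sorted ascending (0-based) and ``carriers`` an
    ``(n_mut, n_leaves)`` uint8 matrix of derived-allele flags.
    """
    if locus_length < 1:
        raise InvalidSpecError("locus_length must be >= 1")
    if g.n_leaves < 2 or g.total_branch_length == 0:
        return np.empty(0, dtype=np.int64), np.zeros((0, g.n_leaves), dtype=np.uint8)
    carriers = _ck.place_poisson_mutations(
        g.parent, g.node_time, mu * locus_length, _kernel_seed(seed)
    )
    n_mut = carriers.shape[0]
    rng = np.random.default_rng(seed)
    if n_mut > locus_length:
        # more mutations than sites cannot respect infinite sites; cap
        carriers = carriers[:locus_length]
        n_mut = locus_length
    positions = np.sort(rng.choice(locus_length, size=n_mut, replace=False))
    return positions.astype(np.int64), carriers


def sample_unlinked_carriers(epochs: np.ndarray, n0: int, n1: int,
                             n_sites: int, base_seed: int,
                             pool_factor: int = 4) -> np.ndarray:
    """Carrier flags for unlinked segregating sites.

    A segregating site's genealogy is length-biased (longer trees carry more
    mutations), so sites are drawn in two passes: a pool of genealogies is
    scored by total branch length, site genealogies are resampled from the
    pool proportionally to length, and one mutation is placed uniformly on
    each chosen tree.  Pool size is ``pool_factor * n_sites`` (at least
    10 000), trading a little resampling granularity for speed.
    """
    R = int(min(max(pool_factor * n_sites, 10_000), 2_000_000))
    lengths = _ck.genealogy_total_lengths(n0, n1, epochs, R, base_seed)
    rng = np.random.default_rng([base_seed, 0xA17])
    idx = rng.choice(R, size=n_sites, replace=True, p=lengths / lengths.sum())
    tree_seeds = (base_seed + idx).astype(np.int64)
    branch_seeds = (base_seed + R + np.arange(n_sites, dtype=np.int64))
    return _ck.carriers_for_sites(n0, n1, epochs, tree_seeds, branch_seeds)


def _carriers_to_genotypes(carriers: np.ndarray, n_high: int, n_low: int) -> np.ndarray:
    """Pair haplotypes sequentially (0-1, 2-3, ...) into diploid dosages."""
    n_sites = carriers.shape[0]
    hap = carriers.astype(np.int8)
    high = hap[:, : 2 * n_high]
    low = hap[:, 2 * n_high:]
    g_high = high[:, 0::2] + high[:, 1::2]
    g_low = low[:, 0::2] + low[:, 1::2]
    return np.concatenate([g_high, g_low], axis=1).T.copy()  # (n_indiv, n_sites)


def _sample_arrays(n_high: int, n_low: int):
    samples = [f"high_{i + 1}" for i in range(n_high)] + [
        f"low_{i + 1}" for i in range(n_low)
    ]
    pops = np.array(["high"] * n_high + ["low"] * n_low, dtype=object)
    return samples, pops


def simulate_dataset(spec: DemographySpec, cfg: SampleConfig,
                     site_spacing: int = 1000) -> VariantTable:
    """Simulate a diploid variant panel under ``spec``.

    With ``cfg.n_sites > 0``, generates that many unlinked segregating sites
    (one genealogy each) spaced ``site_spacing`` bp apart on contig ``sim_1``.
    With ``cfg.n_loci > 0``, generates linked loci of ``cfg.locus_length`` bp,
    one genealogy per locus with Poisson mutations, on contigs ``sim_1...``.
    Fully reproducible from ``cfg.seed``.
    """
    n0h, n1h = 2 * cfg.n_high, 2 * cfg.n_low
    samples, pops = _sample_arrays(cfg.n_high, cfg.n_low)
    epochs = spec.to_epochs()
    base = _stream_seed(cfg.seed, "dataset")

    if cfg.n_loci > 0:
        contigs, positions, gmats = [], [], []
        for l in range(cfg.n_loci):
            parent, ntime, _ = _ck.sim_tree(n0h, n1h, epochs, base + 2 * l)
            g = Genealogy(parent, ntime, n0h, n1h)
            pos0, carriers = drop_mutations(
                g, spec.mu, cfg.locus_length, base + 2 * l + 1
            )
            if len(pos0) == 0:
                continue
            contigs.append(np.repeat(f"sim_{l + 1}", len(pos0)))
            positions.append(pos0 + 1)  # to 1-based
            gmats.append(_carriers_to_genotypes(carriers, cfg.n_high, cfg.n_low))
        if contigs:
            contig = np.concatenate(contigs)
            pos = np.concatenate(positions)
            G = np.concatenate(gmats, axis=1)
        else:
            contig = np.empty(0, dtype=object)
            pos = np.empty(0, dtype=np.int64)
            G = np.zeros((cfg.n_high + cfg.n_low, 0), dtype=np.int8)
    else:
        n_sites = cfg.n_sites
        if n_sites > 0:
            carriers = sample_unlinked_carriers(epochs, n0h, n1h, n_sites, base)
            G = _carriers_to_genotypes(carriers, cfg.n_high, cfg.n_low)
        else:
            G = np.zeros((cfg.n_high + cfg.n_low, 0), dtype=np.int8)
        contig = np.repeat("sim_1", n_sites)
        pos = (np.arange(n_sites, dtype=np.int64) + 1) * site_spacing

    n_sites = len(pos)
    return VariantTable(
        contig=contig,
        pos=pos,
        ref=np.repeat("A", n_sites),
        alt=np.repeat("C", n_sites),
        genotypes=G,
        samples=samples,
        populations=pops,
        metadata={
            "spec": spec.to_dict(),
            "seed": int(cfg.seed),
            "linked": bool(cfg.n_loci > 0),
            "locus_length": int(cfg.locus_length) if cfg.n_loci else None,
            "spiked_sites": [],
        },
    )


def expected_sfs(spec: DemographySpec, n_high_hap: int, n_low_hap: int,
                 n_replicates: int, seed: int) -> JointSFS:
    """Monte-Carlo expected folded joint SFS (proportions over segregating sites).

    Each replicate genealogy contributes its full branch-length profile (the
    conditional site distribution given a mutation lands on the tree), which
    averages over mutation placement analytically rather than by drawing
    single sites.  The replicate stream is seeded ``seed + r``, so repeated
    calls with the same seed reuse a common genealogy stream across parameter
    values — likelihood differences between nearby parameter points are then
    far less noisy than with independent streams.
    """
    if n_replicates < 1:
        raise InvalidSpecError("n_replicates must be >= 1")
    if n_high_hap + n_low_hap < 2:
        raise InvalidSpecError("need at least 2 haploid samples")
    epochs = spec.to_epochs()
    W = np.zeros((n_high_hap + 1, n_low_hap + 1), dtype=np.float64)
    _ck.accumulate_sfs_weights(
        n_high_hap, n_low_hap, epochs, int(n_replicates),
        _stream_seed(seed, "expected_sfs"), W,
    )
    folded = fold_matrix(W)
    sfs = JointSFS(folded, n_high_hap, n_low_hap, counts=True)
    return sfs.normalized()


def spike_divergent_sites(vt: VariantTable, n_spiked: int, delta_freq: float,
                          region, seed: int) -> VariantTable:
    """Insert strongly divergent biallelic sites as positive controls.

    ``region`` is ``(contig, start, end)`` in 0-based half-open coordinates.
    Spiked sites mimic a completed highland sweep from standing variation:
    the alt allele is fixed in the highland sample (target frequency 1) and
    still segregates in the lowland sample at ``1 - delta_freq``, so the
    frequency difference is exactly ``delta_freq``, highland diversity at the
    site is depressed, and lowland diversity is retained (for
    ``delta_freq < 1``).  Genotypes are drawn Binomial(2, p); spiked
    positions are recorded in ``metadata['spiked_sites']``.
    """
    if not (0 < delta_freq <= 1):
        raise ValueError("delta_freq must be in (0, 1]")
    if n_spiked == 0:
        return vt.take_sites(np.arange(vt.n_sites))
    ctg, start, end = region
    if end - start < n_spiked:
        raise ValueError("region too short for the requested number of sites")
    rng = np.random.default_rng(seed)
    taken = set(vt.pos[vt.contig == ctg].tolist())
    avail = np.array(
        [p for p in range(start + 1, end + 1) if p not in taken], dtype=np.int64
    )  # 1-based positions inside [start, end)
    if len(avail) < n_spiked:
        raise ValueError("region too short after excluding occupied positions")
    new_pos = np.sort(rng.choice(avail, size=n_spiked, replace=False))

    p_high = 1.0
    p_low = 1.0 - delta_freq
    high = vt.populations == "high"
    probs = np.where(high, p_high, p_low)
    G_new = rng.binomial(2, probs[:, None], size=(vt.n_samples, n_spiked)).astype(np.int8)

    contig = np.concatenate([vt.contig, np.repeat(ctg, n_spiked)])
    pos = np.concatenate([vt.pos, new_pos])
    ref = np.concatenate([vt.ref, np.repeat("A", n_spiked)])
    alt = np.concatenate([vt.alt, np.repeat("C", n_spiked)])
    G = np.concatenate([vt.genotypes, G_new], axis=1)

    # restore position order within contigs, keeping contig blocks in
    # first-appearance order
    contig_order = {c: k for k, c in enumerate(dict.fromkeys(contig.tolist()))}
    order = np.lexsort((pos, np.array([contig_order[c] for c in contig])))

    meta = dict(vt.metadata)
    meta["spiked_sites"] = list(meta.get("spiked_sites", [])) + [
        (ctg, int(p)) for p in new_pos
    ]
    return VariantTable(
        contig=contig[order],
        pos=pos[order],
        ref=ref[order],
        alt=alt[order],
        genotypes=G[:, order],
        samples=list(vt.samples),
        populations=vt.populations.copy(),
        metadata=meta,
    )


# ----------------------------------------------------------------------
# phenotype / expression fixtures


def make_phenotypes(n_high: int, n_low: int, n_traits: int = 3,
                    effect: float = 2.0, noise_sd: float = 0.5,
                    seed: int = 0) -> pd.DataFrame:
    """Correlated muscle-phenotype table with one dominant axis.

    Each individual carries a latent score ``z`` (standard normal plus a group
    shift of ±``effect``/2); every trait is ``z`` plus independent
    N(0, noise_sd) noise.  Small ``noise_sd`` concentrates variance on the
    first principal component, emulating trait panels whose PC1 explains
    80–90% of variance.
    """
    rng = np.random.default_rng(seed)
    n = n_high + n_low
    group = np.array(["high"] * n_high + ["low"] * n_low, dtype=object)
    shift = np.where(group == "high", effect / 2, -effect / 2)
    z = shift + rng.normal(size=n)
    traits = z[:, None] + rng.normal(scale=noise_sd, size=(n, n_traits))
    df = pd.DataFrame(traits, columns=[f"trait_{t + 1}" for t in range(n_traits)])
    df.insert(0, "group", group)
    df.insert(0, "individual", [f"{g}_{i + 1}" for i, g in enumerate(group)])
    return df


def make_expression(pheno_pc_scores: np.ndarray, n_genes: int = 100,
                    n_coupled: int = 10, coupling_r: float = 0.8,
                    seed: int = 0, base_log_tpm: float = 5.0):
    """Expression matrix (genes x samples, TPM) with phenotype-coupled genes.

    The first ``n_coupled`` genes have log-TPM correlated with the
    standardized phenotype PC scores at population correlation ``coupling_r``;
    the rest are independent noise.  Returns ``(tpm_frame, coupled_gene_ids)``.
    """
    if not (-1 <= coupling_r <= 1):
        raise ValueError("coupling_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    scores = np.asarray(pheno_pc_scores, dtype=float)
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    n = len(z)
    genes = [f"gene_{g + 1:04d}" for g in range(n_genes)]
    log_tpm = np.empty((n_genes, n))
    for g in range(n_genes):
        eps = rng.normal(size=n)
        if g < n_coupled:
            log_tpm[g] = coupling_r * z + np.sqrt(max(0.0, 1 - coupling_r ** 2)) * eps
        else:
            log_tpm[g] = eps
    tpm = np.exp(base_log_tpm + log_tpm)
    cols = [f"s{i + 1}" for i in range(n)]
    return pd.DataFrame(tpm, index=genes, columns=cols), genes[:n_coupled]
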