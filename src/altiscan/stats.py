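"""Variant filtering and population-genetic summary statistics.

Per-site Weir & Cockerham (1984) FST (with the Hudson estimator as an
independent cross-check), windowed nucleotide diversity, DXY and Tajima's D,
LD r^2 and greedy LD pruning, the Wigginton exact Hardy-Weinberg test, the
folded joint SFS, and Patterson-normalized genotype PCA.

Coordinates are 1-based at the VCF-facing interface; windows are 0-based
half-open, fixed width, non-overlapping.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .sfs import JointSFS, fold_cell
from .types import FilterConfig
from .variants import VariantTable

__all__ = [
    "min_coverage_threshold",
    "allele_freqs",
    "site_fst",
    "hudson_fst",
    "windowed_pi",
    "dxy",
    "tajimas_d",
    "window_table",
    "ld_r2",
    "hwe_exact_test",
    "wc_components",
    "global_fst",
    "ld_prune",
    "fold_joint_sfs",
    "genotype_pca",
    "filter_variants",
]


def min_coverage_threshold(per_individual_depth: int, n_individuals: int) -> int:
    """Cohort minimum-depth cutoff: mean per-individual depth x cohort size."""
    if per_individual_depth <= 0 or n_individuals <= 0:
        raise ValueError("depth and individual count must be positive")
    return int(per_individual_depth) * int(n_individuals)


def _pop_counts(vt: VariantTable, population):
    """Per-site (alt-allele count, non-missing allele count, het count)."""
    g = vt.genotypes[vt.pop_mask(population)]
    miss = g < 0
    alt = np.where(miss, 0, g).sum(axis=0).astype(float)
    n_alleles = 2.0 * (~miss).sum(axis=0)
    het = np.where(miss, 0, g == 1).sum(axis=0).astype(float)
    return alt, n_alleles, het


def allele_freqs(vt: VariantTable, population) -> np.ndarray:
    """Per-site alt-allele frequency among non-missing genotypes (NaN if none)."""
    alt, n_alleles, _ = _pop_counts(vt, population)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def wc_components(vt: VariantTable, pops=None):
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals; sites where either population has
    fewer than 2 non-missing genotypes are NaN in all three.
    """
    p1_lab, p2_lab = pops if pops is not None else vt.pop_labels[:2]
    a1, m1, h1c = _pop_counts(vt, p1_lab)
    a2, m2, h2c = _pop_counts(vt, p2_lab)
    n1, n2 = m1 / 2.0, m2 / 2.0  # diploid counts
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = a1 / m1
        p2 = a2 / m2
        h1 = h1c / n1
        h2 = h2c / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
    bad = ~valid
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def site_fst(vt: VariantTable, pops=None) -> np.ndarray:
    """Per-site Weir & Cockerham (1984) FST between two populations.

    Raw (unclamped) theta-hat = a / (a + b + c); sites where either
    population has fewer than 2 non-missing genotypes, or where the total
    variance is zero (monomorphic), are NaN.
    """
    a, b, c = wc_components(vt, pops=pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        return np.where(np.isfinite(denom) & (denom != 0), a / denom, np.nan)


def global_fst(vt: VariantTable, pops=None) -> float:
    """Genome-wide weighted Weir-Cockerham FST: sum(a) / sum(a + b + c).

    The ratio-of-sums estimator is far less biased than averaging per-site
    ratios when differentiation is weak.
    """
    a, b, c = wc_components(vt, pops=pops)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den) if den != 0 else float("nan")


def hudson_fst(vt: VariantTable, pops=None) -> np.ndarray:
    """Per-site Hudson FST (Bhatia et al. ratio-of-estimates form)."""
    p1_lab, p2_lab = pops if pops is not None else vt.pop_labels[:2]
    a1, m1, _ = _pop_counts(vt, p1_lab)
    a2, m2, _ = _pop_counts(vt, p2_lab)
    valid = (m1 >= 2) & (m2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = a1 / m1, a2 / m2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (m1 - 1) - p2 * (1 - p2) / (m2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return np.where(valid & (den != 0), num / den, np.nan)


# ----------------------------------------------------------------------
# windowed statistics


def _window_index(vt: VariantTable, window_bp: int):
    """Window assignment: returns a frame of distinct (contig, start) windows
    and each site's row index into it.  Windows are 0-based half-open."""
    starts = ((vt.pos - 1) // window_bp) * window_bp
    keys = pd.DataFrame({"contig": vt.contig.astype(str), "start": starts})
    uniq = keys.drop_duplicates().reset_index(drop=True)
    uniq["end"] = uniq["start"] + window_bp
    lookup = {t: k for k, t in enumerate(zip(uniq["contig"], uniq["start"]))}
    site_win = np.array(
        [lookup[t] for t in zip(keys["contig"], keys["start"])], dtype=np.int64
    )
    return uniq, site_win


def _pi_site_terms(vt: VariantTable, population):
    """Per-site unbiased heterozygosity n/(n-1) * 2 p (1-p); NaN where n < 2."""
    alt, m, _ = _pop_counts(vt, population)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / m
        return np.where(m >= 2, (m / (m - 1)) * 2 * p * (1 - p), np.nan)


def windowed_pi(vt: VariantTable, population, window_bp: int = 50_000) -> pd.DataFrame:
    """Per-window nucleotide diversity per site (sum of site terms / window_bp)."""
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    uniq, site_win = _window_index(vt, window_bp)
    terms = np.nan_to_num(_pi_site_terms(vt, population))
    acc = np.zeros(len(uniq))
    np.add.at(acc, site_win, terms)
    out = uniq.copy()
    out["pi"] = acc / window_bp
    return out


def dxy(vt: VariantTable, window_bp: int = 50_000, pops=None) -> pd.DataFrame:
    """Per-window absolute divergence: sum_sites p1(1-p2) + p2(1-p1) / window_bp."""
    p1_lab, p2_lab = pops if pops is not None else vt.pop_labels[:2]
    p1 = allele_freqs(vt, p1_lab)
    p2 = allele_freqs(vt, p2_lab)
    terms = np.nan_to_num(p1 * (1 - p2) + p2 * (1 - p1))
    uniq, site_win = _window_index(vt, window_bp)
    acc = np.zeros(len(uniq))
    np.add.at(acc, site_win, terms)
    out = uniq.copy()
    out["dxy"] = acc / window_bp
    return out


def tajima_constants(n: int) -> dict:
    """The a1,a2,b1,b2,c1,c2,e1,e2 constants of Tajima (1989) for n sequences."""
    if n < 3:
        raise ValueError("Tajima's D needs at least 3 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(vt: VariantTable, population, window_bp: int = 50_000) -> pd.DataFrame:
    """Per-window Tajima's D.

    Sites with missing genotypes in the population are excluded so the sample
    size is constant within a window; windows with no segregating site (or
    fewer than 3 sequences) get NaN.
    """
    g = vt.genotypes[vt.pop_mask(population)]
    complete = (g >= 0).all(axis=0)
    n = 2 * g.shape[0]
    alt = g.clip(min=0).sum(axis=0).astype(float)
    p = alt / n
    seg = complete & (alt > 0) & (alt < n)
    pi_terms = np.where(seg, (n / (n - 1)) * 2 * p * (1 - p), 0.0)

    uniq, site_win = _window_index(vt, window_bp)
    S = np.zeros(len(uniq))
    np.add.at(S, site_win, seg.astype(float))
    pi_sum = np.zeros(len(uniq))
    np.add.at(pi_sum, site_win, pi_terms)

    out = uniq.copy()
    if n < 3:
        out["tajimas_d"] = np.nan
        return out
    k = tajima_constants(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = k["e1"] * S + k["e2"] * S * (S - 1)
        d = (pi_sum - S / k["a1"]) / np.sqrt(var)
    out["tajimas_d"] = np.where(S > 0, d, np.nan)
    return out


def window_table(vt: VariantTable, window_bp: int = 50_000, pops=None,
                 hd_flags=None) -> pd.DataFrame:
    """Combined per-window table: SNP count, pi per pop, DXY, Tajima's D per
    pop, and (optionally) HD-SNP count."""
    p1_lab, p2_lab = pops if pops is not None else vt.pop_labels[:2]
    uniq, site_win = _window_index(vt, window_bp)
    out = uniq.copy()
    n_snps = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(n_snps, site_win, 1)
    out["n_snps"] = n_snps
    for lab in (p1_lab, p2_lab):
        out[f"pi_{lab}"] = windowed_pi(vt, lab, window_bp)["pi"].to_numpy()
        out[f"tajd_{lab}"] = tajimas_d(vt, lab, window_bp)["tajimas_d"].to_numpy()
    out["dxy"] = dxy(vt, window_bp, pops=(p1_lab, p2_lab))["dxy"].to_numpy()
    if hd_flags is not None:
        hd = np.zeros(len(uniq), dtype=np.int64)
        np.add.at(hd, site_win, np.asarray(hd_flags, dtype=np.int64))
        out["hd_count"] = hd
    return out


# ----------------------------------------------------------------------
# linkage disequilibrium


def _pair_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    ok = (gi >= 0) & (gj >= 0)
    if ok.sum() < 2:
        return np.nan
    x, y = gi[ok].astype(float), gj[ok].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return np.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov ** 2 / (vx * vy))


def ld_r2(vt: VariantTable, max_dist_bp: int = 20_000) -> pd.DataFrame:
    """Pairwise dosage r^2 for same-contig site pairs within ``max_dist_bp``."""
    rows = []
    G = vt.genotypes
    for ctg in dict.fromkeys(vt.contig.tolist()):
        idx = np.flatnonzero(vt.contig == ctg)
        pos = vt.pos[idx]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if pos[b] - pos[a] > max_dist_bp:
                    break
                rows.append(
                    (ctg, int(pos[a]), int(pos[b]),
                     _pair_r2(G[:, idx[a]], G[:, idx[b]]))
                )
    return pd.DataFrame(rows, columns=["contig", "pos_a", "pos_b", "r2"])


def ld_prune(vt: VariantTable, r2_threshold: float = 0.5,
             window_bp: int = 20_000) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns retained site indices.

    A site is dropped iff its r^2 with any already-retained site within
    ``window_bp`` upstream reaches the threshold, so the leftmost site of a
    correlated pair always survives.
    """
    retained = []
    G = vt.genotypes
    for ctg in dict.fromkeys(vt.contig.tolist()):
        idx = np.flatnonzero(vt.contig == ctg)
        pos = vt.pos[idx]
        kept_local = []
        for a in range(len(idx)):
            drop = False
            for b in reversed(kept_local):
                if pos[a] - pos[b] > window_bp:
                    break
                r2 = _pair_r2(G[:, idx[a]], G[:, idx[b]])
                if not np.isnan(r2) and r2 >= r2_threshold:
                    drop = True
                    break
            if not drop:
                kept_local.append(a)
        retained.extend(idx[kept_local].tolist())
    return np.array(sorted(retained), dtype=np.int64)


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided HWE test (Wigginton et al. 2005).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the conditional probabilities not exceeding that of the
    observed configuration.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n == 0 or n_rare == 0:
        return 1.0

    def log_prob(het):
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1) - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2.0)
            + math.lgamma(n_rare + 1) + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[n_het]
    p = sum(q for q in probs.values() if q <= p_obs * (1 + 1e-12))
    return min(1.0, p)


# ----------------------------------------------------------------------
# joint SFS and PCA


def fold_joint_sfs(vt: VariantTable, pops=None) -> JointSFS:
    """Folded 2-D SFS of sites with complete genotypes in both populations.

    Each retained segregating site adds 1 to the cell indexed by its
    pooled-minor-allele counts per population.
    """
    p1_lab, p2_lab = pops if pops is not None else (
        vt.pop_labels[:2] if vt.n_samples else ("high", "low")
    )
    m1 = vt.pop_mask(p1_lab) if vt.n_samples else np.zeros(0, bool)
    m2 = vt.pop_mask(p2_lab) if vt.n_samples else np.zeros(0, bool)
    n1 = 2 * int(m1.sum())
    n2 = 2 * int(m2.sum())
    data = np.zeros((n1 + 1, n2 + 1))
    if vt.n_sites:
        g1 = vt.genotypes[m1]
        g2 = vt.genotypes[m2]
        complete = (vt.genotypes >= 0).all(axis=0)
        c1 = g1.clip(min=0).sum(axis=0)
        c2 = g2.clip(min=0).sum(axis=0)
        tot = c1 + c2
        seg = complete & (tot > 0) & (tot < n1 + n2)
        for i, j in zip(c1[seg], c2[seg]):
            fi, fj = fold_cell(int(i), int(j), n1, n2)
            data[fi, fj] += 1
    return JointSFS(data, n1, n2, counts=True)


def genotype_pca(vt: VariantTable, n_components: int = None):
    """Genotype PCA with Patterson normalization.

    Dosages are centered by twice the sample allele frequency and scaled by
    sqrt(p(1-p)); missing entries contribute 0 after centering.  Returns
    ``(scores, variance_fractions)`` with a deterministic sign convention:
    the largest-magnitude entry of each score vector is positive.
    """
    if vt.n_samples < 2:
        raise ValueError("PCA needs at least 2 individuals")
    G = vt.genotypes.astype(float)
    miss = G < 0
    G[miss] = np.nan
    p = np.nanmean(G, axis=0) / 2
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic site for PCA")
    G = G[:, poly]
    p = p[poly]
    M = (G - 2 * p) / np.sqrt(p * (1 - p))
    M[np.isnan(M)] = 0.0
    M -= M.mean(axis=0)  # center individuals after imputation
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    scores = U * s
    for k in range(scores.shape[1]):
        col = scores[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, k] = -col
    if n_components is not None:
        scores = scores[:, :n_components]
        frac = frac[:n_components]
    return scores, frac


# ----------------------------------------------------------------------
# filter cascade


def filter_variants(vt: VariantTable, cfg: FilterConfig,
                    site_depth=None) -> tuple:
    """Apply the structure-analysis filter cascade.

    Order: total depth (if per-site depths given) -> MAF -> missingness ->
    HWE exact test -> LD pruning.  Returns ``(filtered_table, report)`` where
    the report counts sites removed by each rule.
    """
    report = {"input_sites": vt.n_sites}
    keep = np.ones(vt.n_sites, dtype=bool)

    if site_depth is not None:
        depth_ok = np.asarray(site_depth) >= cfg.min_total_depth
        report["fail_depth"] = int((~depth_ok & keep).sum())
        keep &= depth_ok

    g = vt.genotypes
    miss = g < 0
    n_alleles = 2.0 * (~miss).sum(axis=0)
    alt = g.clip(min=0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    maf = np.minimum(p, 1 - p)
    maf_ok = maf > cfg.maf_min
    report["fail_maf"] = int((~maf_ok & keep).sum())
    keep &= maf_ok

    miss_frac = miss.mean(axis=0)
    miss_ok = miss_frac <= cfg.max_missing_frac
    report["fail_missing"] = int((~miss_ok & keep).sum())
    keep &= miss_ok

    hwe_ok = np.ones(vt.n_sites, dtype=bool)
    for s in np.flatnonzero(keep):
        col = g[:, s]
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        hwe_ok[s] = hwe_exact_test(*counts) > cfg.hwe_p_min
    report["fail_hwe"] = int((~hwe_ok & keep).sum())
    keep &= hwe_ok

    vt2 = vt.take_sites(keep)
    retained = ld_prune(vt2, cfg.ld_r2_threshold, cfg.ld_window_bp)
    report["fail_ld_prune"] = vt2.n_sites - len(retained)
    vt3 = vt2.take_sites(retained)
    report["output_sites"] = vt3.n_sites
    return vt3, report
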