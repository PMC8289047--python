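"""Simulation-calibrated divergence scan.

The scan nominates selection candidates by combining two signals against
simulation-derived null cutoffs: per-site FST above the upper quantile of a
neutral FST distribution ("HD-SNPs", highly divergent SNPs), and a windowed
within-population diversity shift (theta-pi lowland / theta-pi highland above
the null quantile).  Windows passing both criteria are merged into candidate
regions and annotated against gene models; a 2x2 over-representation test for
a gene category (e.g. muscle-related genes) is included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _coalescent as _ck
from .simulate import _stream_seed
from .stats import site_fst, window_table
from .types import DemographySpec, ScanConfig
from .variants import VariantTable

__all__ = [
    "NullCalibration",
    "calibrate_null",
    "classify_hd_snps",
    "window_outliers",
    "pi_ratio_filter",
    "combine_criteria",
    "annotate_genes",
    "enrichment_test",
    "ScanResult",
    "run_scan",
]


@dataclass
class NullCalibration:
    """Null-distribution cutoffs with full provenance.

    ``fst_cutoff`` is the empirical upper quantile (``fst_quantile``) of
    per-site FST over neutral simulations; ``pi_ratio_cutoff`` the
    ``pi_ratio_quantile`` of the per-window lowland/highland diversity ratio.
    Reference values may be pinned with :meth:`override` (e.g. the cutoffs
    published for a particular dataset) without losing the provenance of the
    simulated ones.
    """

    fst_cutoff: float
    pi_ratio_cutoff: float
    fst_quantile: float
    pi_ratio_quantile: float
    spec: dict
    n_loci: int
    sites_per_locus: int
    locus_length: int
    n_high: int
    n_low: int
    seed: int
    linked: bool = True
    overridden: dict = field(default_factory=dict)

    def override(self, fst_cutoff=None, pi_ratio_cutoff=None) -> "NullCalibration":
        """Pin externally published cutoff values, keeping provenance."""
        out = NullCalibration(**{**self.__dict__})
        out.overridden = dict(self.overridden)
        if fst_cutoff is not None:
            out.overridden["fst_cutoff"] = out.fst_cutoff
            out.fst_cutoff = float(fst_cutoff)
        if pi_ratio_cutoff is not None:
            out.overridden["pi_ratio_cutoff"] = out.pi_ratio_cutoff
            out.pi_ratio_cutoff = float(pi_ratio_cutoff)
        return out

    def to_json(self, path=None) -> str:
        import dataclasses
        payload = {f.name: getattr(self, f.name)
                   for f in dataclasses.fields(self)}
        s = json.dumps(payload, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "NullCalibration":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(**obj)


def calibrate_null(spec: DemographySpec, n_high: int = 11, n_low: int = 12,
                   n_loci: int = 2000, sites_per_locus: int = 410,
                   locus_length: int = 50_000, fst_quantile: float = 0.99,
                   pi_ratio_quantile: float = 0.95, seed: int = 0,
                   linked: bool = True,
                   keep_distributions: bool = False) -> NullCalibration:
    """Simulate neutral data under ``spec`` and extract scan cutoffs.

    By default each of ``n_loci`` loci is one 50-kb genealogy carrying
    ``sites_per_locus`` sites (mutations placed independently on the tree, so
    sites within a locus are linked through their shared genealogy).  The
    FST cutoff is the ``fst_quantile`` empirical quantile (linear
    interpolation) of all per-site FST values; the pi-ratio cutoff the
    ``pi_ratio_quantile`` quantile of per-locus theta-pi_low/theta-pi_high
    (loci with zero highland diversity excluded).  With ``linked=False``
    every site draws an independent genealogy (length-biased, matching the
    distribution of real unlinked SNPs) and loci are merely grouping units
    for the ratio windows.  ``keep_distributions`` retains the raw simulated
    per-site FST and per-window ratio values on the returned object
    (``fst_values``, ``ratio_values``) for diagnostics.
    """
    if n_loci < 2 or sites_per_locus < 1:
        raise ValueError("need at least 2 loci and 1 site per locus")
    for q in (fst_quantile, pi_ratio_quantile):
        if not (0 < q < 1):
            raise ValueError("quantile levels must be in (0, 1)")
    if n_loci * sites_per_locus * min(1 - fst_quantile, fst_quantile) < 1:
        raise ValueError("too few simulated sites for the requested quantile")
    n0, n1 = 2 * n_high, 2 * n_low
    epochs = spec.to_epochs()
    base = _stream_seed(seed, "null_calibration")
    fst_all = []
    ratios = []
    samples = [f"h{i}" for i in range(n_high)] + [f"l{i}" for i in range(n_low)]
    pops = np.array(["high"] * n_high + ["low"] * n_low, dtype=object)
    if not linked:
        from .simulate import sample_unlinked_carriers
        all_carriers = sample_unlinked_carriers(
            epochs, n0, n1, n_loci * sites_per_locus, base
        )
    for l in range(n_loci):
        if linked:
            tree_seeds = np.full(sites_per_locus, base + l, dtype=np.int64)
            branch_seeds = (
                base + n_loci + l * sites_per_locus
                + np.arange(sites_per_locus, dtype=np.int64)
            )
            carriers = _ck.carriers_for_sites(
                n0, n1, epochs, tree_seeds, branch_seeds
            )
        else:
            carriers = all_carriers[
                l * sites_per_locus:(l + 1) * sites_per_locus
            ]
        hap = carriers.astype(np.int8)
        G = np.concatenate(
            [hap[:, 0:n0:2] + hap[:, 1:n0:2], hap[:, n0::2] + hap[:, n0 + 1::2]],
            axis=1,
        ).T
        vt = VariantTable(
            contig=np.repeat(f"null_{l}", sites_per_locus),
            pos=np.arange(1, sites_per_locus + 1),
            ref=np.repeat("A", sites_per_locus),
            alt=np.repeat("C", sites_per_locus),
            genotypes=G,
            samples=samples,
            populations=pops,
        )
        fst_all.append(site_fst(vt, pops=("high", "low")))
        # per-locus diversity ratio over the 50-kb locus
        from .stats import _pi_site_terms
        pi_h = np.nansum(_pi_site_terms(vt, "high")) / locus_length
        pi_l = np.nansum(_pi_site_terms(vt, "low")) / locus_length
        if pi_h > 0:
            ratios.append(pi_l / pi_h)
    fst_all = np.concatenate(fst_all)
    fst_all = fst_all[~np.isnan(fst_all)]
    out = NullCalibration(
        fst_cutoff=float(np.quantile(fst_all, fst_quantile)),
        pi_ratio_cutoff=float(np.quantile(np.asarray(ratios), pi_ratio_quantile)),
        fst_quantile=fst_quantile,
        pi_ratio_quantile=pi_ratio_quantile,
        spec=spec.to_dict(),
        n_loci=n_loci,
        sites_per_locus=sites_per_locus,
        locus_length=locus_length,
        n_high=n_high,
        n_low=n_low,
        seed=int(seed),
        linked=linked,
    )
    if keep_distributions:
        out.fst_values = fst_all
        out.ratio_values = np.asarray(ratios)
    return out


def classify_hd_snps(fst_values, calibration: NullCalibration) -> np.ndarray:
    """HD flags: strictly above the calibrated cutoff; NaN FST never flags."""
    fst_values = np.asarray(fst_values, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(fst_values), False,
                        fst_values > calibration.fst_cutoff)


def window_outliers(windows: pd.DataFrame, cfg: ScanConfig) -> np.ndarray:
    """Outlier-window flags from HD-SNP counts.

    Windows are ranked by HD count descending with ties broken by genomic
    order (contig appearance, then start); at most ``max_outlier_windows``
    are kept, and only those with HD count >= ``hd_min_per_window``.
    """
    if "hd_count" not in windows:
        raise ValueError("window table lacks an hd_count column")
    hd = windows["hd_count"].to_numpy()
    contig_rank = pd.factorize(windows["contig"])[0]
    order = np.lexsort((windows["start"].to_numpy(), contig_rank, -hd))
    flags = np.zeros(len(windows), dtype=bool)
    kept = 0
    for i in order:
        if kept >= cfg.max_outlier_windows:
            break
        if hd[i] >= cfg.hd_min_per_window:
            flags[i] = True
            kept += 1
    return flags


def pi_ratio_filter(windows: pd.DataFrame, calibration: NullCalibration,
                    pops=("high", "low")) -> np.ndarray:
    """Diversity-shift flags: theta-pi_low / theta-pi_high above the cutoff.

    Zero highland diversity with positive lowland diversity flags (the most
    conservative reading of a highland diversity drop); zero in both does not.
    """
    hi, lo = pops
    pi_h = windows[f"pi_{hi}"].to_numpy(dtype=float)
    pi_l = windows[f"pi_{lo}"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pi_l / pi_h
    flags = np.where(
        pi_h > 0, ratio > calibration.pi_ratio_cutoff, pi_l > 0
    )
    return flags.astype(bool)


def combine_criteria(windows: pd.DataFrame, outlier_flags, ratio_flags) -> pd.DataFrame:
    """Merge windows passing both criteria into maximal candidate regions.

    Adjacent passing windows (same contig, touching coordinates) merge;
    returns a BED-style frame (contig, start, end, n_windows), 0-based
    half-open.
    """
    passing = windows[np.asarray(outlier_flags) & np.asarray(ratio_flags)]
    passing = passing.sort_values(
        ["contig", "start"],
        key=lambda s: s if s.name == "start" else pd.Series(
            pd.factorize(s)[0], index=s.index
        ),
    )
    regions = []
    for _, row in passing.iterrows():
        if regions and regions[-1][0] == row["contig"] and regions[-1][2] >= row["start"]:
            regions[-1][2] = max(regions[-1][2], row["end"])
            regions[-1][3] += 1
        else:
            regions.append([row["contig"], int(row["start"]), int(row["end"]), 1])
    return pd.DataFrame(regions, columns=["contig", "start", "end", "n_windows"])


def annotate_genes(regions: pd.DataFrame, genes: pd.DataFrame):
    """Intersect candidate regions with gene models (0-based half-open).

    ``genes`` needs columns contig, start, end, name.  Returns
    ``(gene_table, region_table)``: genes with >= 1 bp overlap (each gene
    reported once even if it spans several regions, with total overlap bp),
    and the regions with a ``has_gene`` flag (regions without genes are
    intergenic).
    """
    for frame, label in ((regions, "region"), (genes, "gene")):
        if len(frame) and (frame["end"] <= frame["start"]).any():
            raise ValueError(f"malformed {label} interval (end <= start)")
    gene_rows = {}
    has_gene = np.zeros(len(regions), dtype=bool)
    for ri, r in enumerate(regions.itertuples(index=False)):
        g_ctg = genes[genes["contig"] == r.contig]
        for g in g_ctg.itertuples(index=False):
            ov = min(r.end, g.end) - max(r.start, g.start)
            if ov > 0:
                has_gene[ri] = True
                if g.name in gene_rows:
                    gene_rows[g.name]["overlap_bp"] += int(ov)
                    gene_rows[g.name]["n_regions"] += 1
                else:
                    gene_rows[g.name] = {
                        "gene": g.name, "contig": g.contig,
                        "start": int(g.start), "end": int(g.end),
                        "overlap_bp": int(ov), "n_regions": 1,
                    }
    gene_table = pd.DataFrame(
        list(gene_rows.values()),
        columns=["gene", "contig", "start", "end", "overlap_bp", "n_regions"],
    )
    region_table = regions.copy()
    region_table["has_gene"] = has_gene
    return gene_table, region_table


def enrichment_test(k_in_set: int, n_selected: int, K_in_set_background: int,
                    N_background: int) -> dict:
    """2x2 over-representation test (selected vs rest) x (in-set vs not).

    Returns Pearson chi-square (df=1, no continuity correction) with its
    two-sided p, and the two-sided Fisher exact p as a cross-check.
    """
    k, n, K, N = k_in_set, n_selected, K_in_set_background, N_background
    if not (0 <= k <= n and k <= K <= N and n <= N):
        raise ValueError("inconsistent contingency inputs")
    table = np.array([[k, n - k], [K - k, (N - n) - (K - k)]])
    if (table < 0).any():
        raise ValueError("negative cell in contingency table")
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        chi2, p_chi2 = 0.0, 1.0
    else:
        chi2, p_chi2, _, _ = sps.chi2_contingency(table, correction=False)
    _, p_fisher = sps.fisher_exact(table, alternative="two-sided")
    return {
        "chi2": float(chi2),
        "p_chi2": float(p_chi2),
        "p_fisher": float(p_fisher),
        "table": table.tolist(),
    }


@dataclass
class ScanResult:
    """Everything the scan produces, window grid aligned."""

    fst: np.ndarray
    hd_flags: np.ndarray
    windows: pd.DataFrame
    outlier_flags: np.ndarray
    ratio_flags: np.ndarray
    regions: pd.DataFrame
    genes: pd.DataFrame = None
    enrichment: dict = None


def run_scan(vt: VariantTable, calibration: NullCalibration,
             cfg: ScanConfig = None, genes: pd.DataFrame = None,
             pops=("high", "low")) -> ScanResult:
    """Full scan: FST -> HD flags -> windows -> both criteria -> regions."""
    cfg = cfg or ScanConfig()
    fst = site_fst(vt, pops=pops)
    hd = classify_hd_snps(fst, calibration)
    windows = window_table(vt, cfg.window_bp, pops=pops, hd_flags=hd)
    outl = window_outliers(windows, cfg)
    ratio = pi_ratio_filter(windows, calibration, pops=pops)
    regions = combine_criteria(windows, outl, ratio)
    gene_table = None
    if genes is not None:
        gene_table, regions = annotate_genes(regions, genes)
    return ScanResult(
        fst=fst, hd_flags=hd, windows=windows, outlier_flags=outl,
        ratio_flags=ratio, regions=regions, genes=gene_table,
    )
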