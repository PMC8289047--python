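"""Adaptive-allele dosage: counting highland-major alleles per individual.

At each highly divergent SNP the allele that is the highland major allele
(frequency > 0.5 among highland birds) is declared the high-elevation
adaptive allele; each individual's dosage is the total count of adaptive
alleles over the site set.  Because sites are ascertained for divergence,
highland dosages exceed lowland dosages by construction — the statistic
describes the separation, it is not itself evidence of selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import allele_freqs
from .variants import VariantTable

__all__ = ["adaptive_alleles", "dosage_per_individual", "dosage_test",
           "DosageResult", "run_dosage"]


def adaptive_alleles(vt: VariantTable, highland_pop="high") -> pd.DataFrame:
    """Adaptive-allele table: one allele per site with highland AF > 0.5.

    Missing genotypes are ignored in the frequency; sites at exactly 0.5 (or
    with no highland data) are dropped.  ``allele`` is "alt" or "ref";
    ``adaptive_is_alt`` is a convenience flag.
    """
    if vt.n_sites == 0:
        return pd.DataFrame(
            columns=["contig", "pos", "allele", "highland_af", "adaptive_is_alt"]
        )
    p_alt = allele_freqs(vt, highland_pop)
    keep = ~np.isnan(p_alt) & (p_alt != 0.5)
    is_alt = p_alt > 0.5
    af = np.where(is_alt, p_alt, 1 - p_alt)
    return pd.DataFrame({
        "contig": vt.contig[keep],
        "pos": vt.pos[keep],
        "allele": np.where(is_alt[keep], "alt", "ref"),
        "highland_af": af[keep],
        "adaptive_is_alt": is_alt[keep],
    })


def dosage_per_individual(vt: VariantTable, adaptive: pd.DataFrame) -> pd.DataFrame:
    """Per-individual adaptive-allele counts over the adaptive site set.

    A missing genotype contributes 0 and is tallied in ``n_missing_sites``.
    """
    key = {(c, p): alt for c, p, alt in zip(
        adaptive["contig"], adaptive["pos"], adaptive["adaptive_is_alt"]
    )}
    site_idx, site_is_alt = [], []
    for s in range(vt.n_sites):
        t = (vt.contig[s], vt.pos[s])
        if t in key:
            site_idx.append(s)
            site_is_alt.append(key.pop(t))
    if key:
        raise ValueError(f"{len(key)} adaptive sites absent from the table")
    site_idx = np.asarray(site_idx, dtype=int)
    site_is_alt = np.asarray(site_is_alt, dtype=bool)
    g = vt.genotypes[:, site_idx].astype(float)
    miss = g < 0
    adaptive_copies = np.where(site_is_alt, g, 2 - g)
    adaptive_copies[miss] = 0
    return pd.DataFrame({
        "individual": vt.samples,
        "population": vt.populations,
        "dosage": adaptive_copies.sum(axis=1).astype(int),
        "n_sites": len(site_idx),
        "n_missing_sites": miss.sum(axis=1).astype(int),
    })


def dosage_test(high_counts, low_counts, equal_var: bool = False) -> dict:
    """Two-sided t-test comparing dosage distributions (Welch by default)."""
    hi = np.asarray(high_counts, dtype=float)
    lo = np.asarray(low_counts, dtype=float)
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >= 2 individuals per group")
    if hi.var() == 0 and lo.var() == 0 and hi.mean() == lo.mean():
        return {"t": 0.0, "p": 1.0, "mean_high": float(hi.mean()),
                "mean_low": float(lo.mean())}
    t, p = sps.ttest_ind(hi, lo, equal_var=equal_var)
    return {"t": float(t), "p": float(p), "mean_high": float(hi.mean()),
            "mean_low": float(lo.mean())}


@dataclass
class DosageResult:
    adaptive: pd.DataFrame
    dosages: pd.DataFrame
    test: dict


def run_dosage(vt: VariantTable, hd_site_mask=None, highland_pop="high",
               lowland_pop="low", equal_var: bool = False) -> DosageResult:
    """Adaptive-allele pipeline on (a subset of) a variant table."""
    sub = vt.take_sites(hd_site_mask) if hd_site_mask is not None else vt
    adaptive = adaptive_alleles(sub, highland_pop)
    dosages = dosage_per_individual(sub, adaptive)
    hi = dosages.loc[dosages["population"] == highland_pop, "dosage"]
    lo = dosages.loc[dosages["population"] == lowland_pop, "dosage"]
    test = dosage_test(hi, lo, equal_var=equal_var)
    return DosageResult(adaptive=adaptive, dosages=dosages, test=test)
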