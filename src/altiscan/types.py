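"""Shared domain types: demographic specifications and stage configurations.

The deme convention throughout the package is deme 0 = highland, deme 1 =
lowland.  Population sizes are diploid effective sizes (individuals); times are
in generations before present; migration is parameterized as the expected
number of migrant lineages per generation entering the recipient deme (the
``Nm`` reading), from which the per-lineage backward trace rate is derived as
``Nm / N_recipient``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "DemographySpec",
    "SampleConfig",
    "FilterConfig",
    "ScanConfig",
    "InvalidSpecError",
]

#: mutation rate per site per generation estimated for passerine birds
DEFAULT_MU = 3.3e-9
#: default nuisance sizes for the lowland and ancestral demes; chosen so that
#: neutral diversity 4*N*mu is on the 1e-3 scale observed in wild passerines
DEFAULT_N_LOW = 350_000.0
DEFAULT_N_ANC = 350_000.0


class InvalidSpecError(ValueError):
    """Raised when a demographic specification violates its invariants."""


@dataclass(frozen=True)
class DemographySpec:
    """One- or two-population isolation-with-migration demography.

    Parameters
    ----------
    n_pops
        1 (panmictic) or 2 (highland/lowland split).
    N_high, N_low, N_anc
        Diploid effective sizes of the highland deme, lowland deme, and the
        ancestral deme into which all lineages merge at ``T_split``.
    T_split
        Split (colonization) time in generations before present.  Ignored for
        one-population specs.
    m_low_to_high, m_high_to_low
        Expected migrant lineages per generation into the highland / lowland
        deme respectively (forward-time direction names; Nm units).
    size_changes
        Optional instantaneous size steps, each ``(time, deme, new_size)``
        with ``deme`` one of ``"high"``, ``"low"``, ``"anc"``.  Steps in
        daughter demes must predate ``T_split``; ``"anc"`` steps postdate it.
    mu
        Mutation rate per site per generation.
    gen_time_years
        Years per generation, used only for reporting times in years.
    """

    n_pops: int = 2
    N_high: float = 85_058.0
    N_low: float = DEFAULT_N_LOW
    N_anc: float = DEFAULT_N_ANC
    T_split: float = 2_598.0
    m_low_to_high: float = 0.08
    m_high_to_low: float = 0.0
    size_changes: tuple = ()
    mu: float = DEFAULT_MU
    gen_time_years: float = 1.0

    def __post_init__(self):
        if self.n_pops not in (1, 2):
            raise InvalidSpecError(f"n_pops must be 1 or 2, got {self.n_pops}")
        for name in ("N_high", "N_low", "N_anc"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0")
        if self.T_split < 0:
            raise InvalidSpecError("T_split must be >= 0")
        if self.m_low_to_high < 0 or self.m_high_to_low < 0:
            raise InvalidSpecError("migration rates must be >= 0")
        if self.mu <= 0:
            raise InvalidSpecError("mu must be > 0")
        for t, deme, n in self.size_changes:
            if n <= 0:
                raise InvalidSpecError("size-change sizes must be > 0")
            if deme not in ("high", "low", "anc"):
                raise InvalidSpecError(f"unknown deme {deme!r} in size change")
            if t < 0:
                raise InvalidSpecError("size-change times must be >= 0")

    # ------------------------------------------------------------------
    def to_epochs(self) -> np.ndarray:
        """Piecewise-constant epoch table for the coalescent kernel.

        Returns an array of shape ``(E, 5)`` with columns
        ``(t_start, N0, N1, m0, m1)`` where ``N1 <= 0`` marks the lowland deme
        as inactive (all its lineages move to deme 0 at that epoch start) and
        ``m0``/``m1`` are backward per-lineage trace rates for lineages in
        deme 0 / deme 1.
        """
        changes = sorted(self.size_changes, key=lambda c: c[0])
        if self.n_pops == 1:
            # single deme of size N_high, optional steps (deme label ignored)
            breaks = [0.0] + [float(t) for t, _, _ in changes]
            rows = []
            n0 = float(self.N_high)
            i = 0
            for b in breaks:
                while i < len(changes) and changes[i][0] <= b:
                    n0 = float(changes[i][2])
                    i += 1
                rows.append((b, n0, -1.0, 0.0, 0.0))
            return np.asarray(rows, dtype=np.float64)

        t_split = float(self.T_split)
        pre = [c for c in changes if c[0] < t_split and c[1] in ("high", "low")]
        post = [c for c in changes if c[1] == "anc" and c[0] >= t_split]
        breaks = sorted({0.0} | {float(c[0]) for c in pre} | {t_split}
                        | {float(c[0]) for c in post})
        n_high, n_low, n_anc = float(self.N_high), float(self.N_low), float(self.N_anc)
        rows = []
        for b in breaks:
            for t, deme, n in pre:
                if t <= b:
                    if deme == "high":
                        n_high = float(n)
                    else:
                        n_low = float(n)
            for t, _, n in post:
                if t <= b:
                    n_anc = float(n)
            if b < t_split:
                m0 = self.m_low_to_high / n_high   # backward: high -> low
                m1 = self.m_high_to_low / n_low    # backward: low -> high
                rows.append((b, n_high, n_low, m0, m1))
            else:
                rows.append((b, n_anc, -1.0, 0.0, 0.0))
        return np.asarray(rows, dtype=np.float64)

    def with_params(self, **kwargs) -> "DemographySpec":
        d = asdict(self)
        d.update(kwargs)
        d["size_changes"] = tuple(d["size_changes"])
        return DemographySpec(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_changes"] = [list(c) for c in self.size_changes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemographySpec":
        d = dict(d)
        d["size_changes"] = tuple(tuple(c) for c in d.get("size_changes", ()))
        return cls(**d)


@dataclass(frozen=True)
class SampleConfig:
    """Sampling layout for a simulated dataset.

    ``n_sites`` requests fully unlinked segregating sites (one genealogy per
    site); alternatively ``n_loci`` x ``locus_length`` requests linked blocks
    with a single genealogy per locus and Poisson mutation placement.
    """

    n_high: int = 11
    n_low: int = 12
    n_sites: int = 0
    n_loci: int = 0
    locus_length: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.n_high < 0 or self.n_low < 0:
            raise InvalidSpecError("sample counts must be >= 0")
        if self.n_high + self.n_low < 1:
            raise InvalidSpecError("at least one diploid must be sampled")
        if self.n_sites < 0 or self.n_loci < 0 or self.locus_length < 1:
            raise InvalidSpecError("site/locus counts must be valid")


@dataclass
class FilterConfig:
    """SNP filter thresholds used before structure analyses.

    Defaults follow the resequencing-panel cascade: cohort minimum depth from
    6 reads per individual, MAF > 0.1 retained, <= 10% missing individuals,
    HWE exact p > 0.01, LD pruning at r^2 >= 0.5 within 20 kb.
    """

    min_total_depth: int = 138
    maf_min: float = 0.1
    max_missing_frac: float = 0.10
    hwe_p_min: float = 0.01
    ld_r2_threshold: float = 0.5
    ld_window_bp: int = 20_000

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 <= self.max_missing_frac <= 1):
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not (0 <= self.hwe_p_min <= 1):
            raise ValueError("hwe_p_min must be in [0, 1]")
        if not (0 <= self.ld_r2_threshold <= 1):
            raise ValueError("ld_r2_threshold must be in [0, 1]")


@dataclass
class ScanConfig:
    """Windowed divergence-scan parameters."""

    window_bp: int = 50_000
    hd_min_per_window: int = 13
    max_outlier_windows: int = 1_000
    fst_quantile: float = 0.99
    pi_ratio_quantile: float = 0.95

    def __post_init__(self):
        if self.window_bp < 1 or self.hd_min_per_window < 0 or self.max_outlier_windows < 0:
            raise ValueError("scan sizes must be positive")
        for q in (self.fst_quantile, self.pi_ratio_quantile):
            if not (0 < q < 1):
                raise ValueError("quantile levels must be in (0, 1)")
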