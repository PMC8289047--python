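"""The VariantTable container: diploid genotypes at biallelic SNPs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VariantTable"]

MISSING = -1


@dataclass
class VariantTable:
    """Biallelic diploid genotypes with positions and population labels.

    Attributes
    ----------
    contig : (n_sites,) str array
    pos : (n_sites,) int64, 1-based positions (VCF convention), strictly
        increasing within each contig
    ref, alt : (n_sites,) str arrays of alleles
    genotypes : (n_samples, n_sites) int8 alt-allele dosage, ``-1`` missing
    samples : list of sample ids
    populations : (n_samples,) str array of population labels
    metadata : free-form provenance (generator spec, seed, spiked positions)
    """

    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list
    populations: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (samples x sites) array")
        if self.genotypes.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        g = self.genotypes
        if g.size and (g.min() < -1 or g.max() > 2):
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        for ctg in dict.fromkeys(self.contig.tolist()):
            p = self.pos[self.contig == ctg]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {ctg}")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pop_mask(self, population) -> np.ndarray:
        mask = self.populations == population
        if not mask.any():
            raise KeyError(f"unknown population label {population!r}")
        return mask

    @property
    def pop_labels(self) -> list:
        """Distinct population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations.tolist()))

    def take_sites(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            contig=self.contig[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[:, idx],
            samples=list(self.samples),
            populations=self.populations.copy(),
            metadata=dict(self.metadata),
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            np.array_equal(self.contig, other.contig)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.genotypes, other.genotypes)
            and list(self.samples) == list(other.samples)
            and np.array_equal(self.populations, other.populations)
        )
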