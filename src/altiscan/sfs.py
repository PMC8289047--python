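"""Folded two-dimensional site-frequency spectra.

Folding is defined on the pooled two-population sample: each site is keyed by
the counts of the globally minor allele in each population, the convention of
SFS-based demographic fitting tools.  When the pooled allele count is exactly
half the pooled sample size the minor allele is ambiguous; the lexicographically
smaller of the two conjugate cells is used, deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["JointSFS", "fold_cell", "fold_matrix"]


def fold_cell(i: int, j: int, n1: int, n2: int) -> tuple:
    """Canonical folded cell for derived/alt counts ``(i, j)``."""
    tot = i + j
    alt = (n1 + n2) - tot
    if tot < alt:
        return (i, j)
    if tot > alt:
        return (n1 - i, n2 - j)
    return min((i, j), (n1 - i, n2 - j))


def fold_matrix(unfolded: np.ndarray) -> np.ndarray:
    """Fold an (n1+1, n2+1) unfolded joint SFS in place-free fashion."""
    n1 = unfolded.shape[0] - 1
    n2 = unfolded.shape[1] - 1
    folded = np.zeros_like(unfolded, dtype=np.float64)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            fi, fj = fold_cell(i, j, n1, n2)
            folded[fi, fj] += unfolded[i, j]
    return folded


@dataclass
class JointSFS:
    """Folded 2-D SFS over two population samples.

    ``data[i, j]`` is the mass at ``i`` copies of the pooled minor allele in
    population 1 (haploid size ``n1``) and ``j`` copies in population 2
    (``n2``).  ``counts=True`` means raw segregating-site counts; otherwise
    proportions over segregating cells.
    """

    data: np.ndarray
    n1: int
    n2: int
    counts: bool = True

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError(
                f"SFS shape {self.data.shape} != ({self.n1 + 1}, {self.n2 + 1})"
            )
        if (self.data < 0).any():
            raise ValueError("SFS entries must be >= 0")

    # ------------------------------------------------------------------
    def segregating_mask(self) -> np.ndarray:
        """Mask of folded cells corresponding to segregating sites."""
        mask = np.zeros_like(self.data, dtype=bool)
        for i in range(self.n1 + 1):
            for j in range(self.n2 + 1):
                if (i, j) == fold_cell(i, j, self.n1, self.n2) and 0 < i + j:
                    mask[i, j] = True
        mask[0, 0] = False
        return mask

    @property
    def total(self) -> float:
        return float(self.data.sum())

    def normalized(self) -> "JointSFS":
        """Proportions over segregating cells (sums to 1)."""
        tot = self.total
        if tot <= 0:
            raise ValueError("cannot normalize an empty SFS")
        return JointSFS(self.data / tot, self.n1, self.n2, counts=False)

    def marginal(self, pop: int) -> np.ndarray:
        """Folded marginal spectrum for population 1 or 2 (by pooled-minor key)."""
        return self.data.sum(axis=1 if pop == 1 else 0)

    def swap_pops(self) -> "JointSFS":
        return JointSFS(self.data.T.copy(), self.n2, self.n1, counts=self.counts)

    # ------------------------------------------------------------------
    def to_json(self, path=None) -> str:
        obj = {
            "n1": self.n1,
            "n2": self.n2,
            "counts": self.counts,
            "data": self.data.tolist(),
        }
        s = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "JointSFS":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            np.asarray(obj["data"], dtype=np.float64),
            int(obj["n1"]),
            int(obj["n2"]),
            counts=bool(obj["counts"]),
        )
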