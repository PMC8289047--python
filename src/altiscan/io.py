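"""Readers and writers for the restricted formats the pipeline speaks.

VCF here is a deliberately narrow dialect: biallelic SNPs, GT-only FORMAT,
diploid genotypes.  Multi-allelic or indel records are skipped with a count
(default) or rejected in strict mode.  BED is 0-based half-open; the
population map is a two-column TSV (sample, population).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variants import VariantTable

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_bed",
    "write_bed",
    "read_tsv_matrix",
]

_GT_MAP = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": -1, ".|.": -1, ".": -1,
}

_SNP_ALLELES = {"A", "C", "G", "T"}


class VcfFormatError(ValueError):
    pass


def read_vcf(path, populations: dict = None, strict: bool = False) -> VariantTable:
    """Read a biallelic-SNP VCF into a VariantTable.

    ``populations`` maps sample id -> population label (e.g. from
    :func:`read_popmap`); samples absent from the map raise.  Returns a table
    plus a ``skipped_records`` count in its metadata.
    """
    contigs, poss, refs, alts, gts = [], [], [], [], []
    samples = None
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise VcfFormatError(f"line {ln}: no sample columns")
                samples = cols[9:]
                continue
            if samples is None:
                raise VcfFormatError(f"line {ln}: data before #CHROM header")
            f = line.split("\t")
            if len(f) != 9 + len(samples):
                raise VcfFormatError(f"line {ln}: wrong number of columns")
            ref, alt = f[3], f[4]
            if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
                if strict:
                    raise VcfFormatError(
                        f"line {ln}: not a biallelic SNP ({ref}>{alt})"
                    )
                skipped += 1
                continue
            fmt = f[8].split(":")
            if "GT" not in fmt:
                raise VcfFormatError(f"line {ln}: FORMAT lacks GT")
            gt_i = fmt.index("GT")
            row = []
            for s in f[9:]:
                token = s.split(":")[gt_i]
                if token not in _GT_MAP:
                    raise VcfFormatError(f"line {ln}: unparseable GT {token!r}")
                row.append(_GT_MAP[token])
            contigs.append(f[0])
            poss.append(int(f[1]))
            refs.append(ref)
            alts.append(alt)
            gts.append(row)
    if samples is None:
        raise VcfFormatError("no #CHROM header found")
    if populations is not None:
        missing = [s for s in samples if s not in populations]
        if missing:
            raise KeyError(f"samples missing from population map: {missing}")
        pops = np.array([populations[s] for s in samples], dtype=object)
    else:
        pops = np.array(["pop1"] * len(samples), dtype=object)
    G = (np.array(gts, dtype=np.int8).T if gts
         else np.zeros((len(samples), 0), dtype=np.int8))
    return VariantTable(
        contig=np.array(contigs, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=G,
        samples=samples,
        populations=pops,
        metadata={"skipped_records": skipped, "source": str(path)},
    )


def write_vcf(vt: VariantTable, path) -> None:
    """Write a VariantTable as VCF 4.2 (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=altiscan\n")
        for ctg in dict.fromkeys(vt.contig.tolist()):
            length = int(vt.pos[vt.contig == ctg].max()) if vt.n_sites else 0
            fh.write(f"##contig=<ID={ctg},length={max(length, 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.samples) + "\n"
        )
        rev = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for s in range(vt.n_sites):
            gt = "\t".join(rev[int(g)] for g in vt.genotypes[:, s])
            fh.write(
                f"{vt.contig[s]}\t{vt.pos[s]}\t.\t{vt.ref[s]}\t{vt.alt[s]}"
                f"\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_popmap(path) -> dict:
    """Two-column TSV (sample, population) -> dict."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"popmap line {ln}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_popmap(vt: VariantTable, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(vt.samples, vt.populations):
            fh.write(f"{s}\t{p}\n")


def read_bed(path) -> pd.DataFrame:
    """BED (contig, start, end[, name]); 0-based half-open, zero-length rejected."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"BED line {ln}: fewer than 3 columns")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"BED line {ln}: empty interval {start}-{end}")
            rows.append((f[0], start, end, f[3] if len(f) > 3 else f"feat_{ln}"))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])


def write_bed(frame: pd.DataFrame, path, name_col: str = None) -> None:
    with open(path, "w") as fh:
        for r in frame.itertuples(index=False):
            name = getattr(r, name_col) if name_col else None
            cols = [str(r.contig), str(int(r.start)), str(int(r.end))]
            if name is not None:
                cols.append(str(name))
            fh.write("\t".join(cols) + "\n")


def read_tsv_matrix(path, index_col: int = 0) -> pd.DataFrame:
    """Numeric TSV matrix with row ids in the first column (e.g. TPM)."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ValueError(f"non-numeric matrix columns: {bad}")
    return df
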