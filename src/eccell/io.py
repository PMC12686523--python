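"""Shared readers/writers: fragments TSV, barcode lists, chrom.sizes, matrices."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import GenomicInterval

log = logging.getLogger("eccell")

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "support"]


def read_fragments(path: str) -> pd.DataFrame:
    """Read a 10x-style fragments file (BED-like TSV, optionally gzipped).

    Columns: chrom, start, end, barcode, support; 0-based half-open.
    Comment lines starting with '#' are skipped.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=FRAGMENT_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "barcode": str, "support": np.int64},
    )
    return df


def write_fragments(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=FRAGMENT_COLUMNS)


def read_barcodes(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_barcodes(barcodes: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for bc in barcodes:
            fh.write(bc + "\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_gene_bed(path: str) -> list[tuple[str, GenomicInterval, str]]:
    """Read genes from BED6 (name in col 4, strand in col 6)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            genes.append((name, GenomicInterval(chrom, start, end), strand))
    return genes


def write_gene_bed(genes: Sequence[tuple[str, GenomicInterval, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, iv, strand in genes:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def write_dense_matrix(matrix: np.ndarray, row_names: Sequence[str],
                       col_names: Sequence[str], path: str) -> None:
    pd.DataFrame(matrix, index=list(row_names), columns=list(col_names)).to_csv(
        path, sep="\t")


def read_dense_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
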