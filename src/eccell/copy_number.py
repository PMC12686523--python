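"""Per-cell copy-number signal over genome-wide sliding windows.

A 5 Mb window slid in 1 Mb steps tiles each chromosome; per cell, fragment
midpoints are counted per window, log2(1 + CPM) values are z-scored against
the cell's own (trimmed) window background, and a copy estimate scales the
window CPM by the cell's median window CPM with diploid = 2.  Named marker
intervals (the classic glioblastoma/colorectal amplicon windows around EGFR,
PDGFRA, MDM4, MDM2 and MYC) can be read off the matching grid window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import GenomicInterval

log = logging.getLogger("eccell")

# 1-based inclusive printed intervals, converted to 0-based half-open
DEFAULT_MARKERS = {
    "EGFR": GenomicInterval("chr7", 51_000_000, 56_000_000),
    "PDGFRA": GenomicInterval("chr4", 52_000_000, 57_000_000),
    "MDM4": GenomicInterval("chr1", 203_000_000, 208_000_000),
    "MDM2": GenomicInterval("chr12", 64_000_000, 69_000_000),
    "MYC": GenomicInterval("chr8", 124_000_000, 129_000_000),
}


@dataclass
class WindowGrid:
    windows: list[GenomicInterval]
    window: int
    step: int
    markers: dict[str, GenomicInterval] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def marker_window_index(self, name: str) -> int:
        """Index of the grid window matching (or nearest to) a marker."""
        iv = self.markers[name]
        best, best_d = None, None
        for i, w in enumerate(self.windows):
            if w.chrom != iv.chrom:
                continue
            d = abs(w.start - iv.start)
            if best_d is None or d < best_d:
                best, best_d = i, d
        if best is None:
            raise KeyError(f"no grid window on {iv.chrom} for marker {name}")
        return best


def build_windows(chrom_sizes: Mapping[str, int], window: int = 5_000_000,
                  step: int = 1_000_000,
                  markers: Mapping[str, GenomicInterval] | None = None) -> WindowGrid:
    """Sliding windows at starts 0, step, 2*step, ... while start < chrom
    length; terminal windows are clipped to the chromosome end."""
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    windows = []
    for chrom in sorted(chrom_sizes):
        clen = chrom_sizes[chrom]
        for start in range(0, clen, step):
            windows.append(GenomicInterval(chrom, start, min(start + window, clen)))
    marks = dict(DEFAULT_MARKERS if markers is None else markers)
    marks = {name: iv for name, iv in marks.items() if iv.chrom in chrom_sizes}
    return WindowGrid(windows=windows, window=window, step=step, markers=marks)


def window_cell_counts(fragments: pd.DataFrame, grid: WindowGrid,
                       whitelist: Sequence[str] | None = None
                       ) -> tuple[np.ndarray, list[str]]:
    """Windows x cells integer matrix of fragment-midpoint counts.

    The midpoint rule makes each fragment contribute exactly once per tiling
    phase of the overlapping grid, so per-cell totals over one
    non-overlapping phase are conserved.
    """
    if whitelist is not None:
        fragments = fragments[fragments["barcode"].isin(set(whitelist))]
        barcodes = list(whitelist)
    else:
        barcodes = sorted(fragments["barcode"].unique())
    bc_index = {bc: j for j, bc in enumerate(barcodes)}

    step = grid.step
    k = grid.window // step
    # per-chromosome step-bin counts, then a rolling sum of k step bins
    counts = np.zeros((grid.n_windows, len(barcodes)), dtype=np.int64)
    start_idx: dict[str, int] = {}
    for i, w in enumerate(grid.windows):
        start_idx.setdefault(w.chrom, i)
    order = sorted(start_idx, key=start_idx.get)
    n_per_chrom = {c: sum(1 for w in grid.windows if w.chrom == c) for c in order}

    for chrom in order:
        sub = fragments[fragments["chrom"] == chrom]
        if len(sub) == 0:
            continue
        mid = ((sub["start"].values + sub["end"].values) // 2).astype(np.int64)
        sb = mid // step
        nb = n_per_chrom[chrom]
        cell = np.array([bc_index[b] for b in sub["barcode"].values])
        keep = sb < nb
        sb, cell = sb[keep], cell[keep]
        stepbin = np.zeros((nb, len(barcodes)), dtype=np.int64)
        np.add.at(stepbin, (sb, cell), 1)
        csum = np.concatenate([np.zeros((1, len(barcodes)), dtype=np.int64),
                               np.cumsum(stepbin, axis=0)])
        base = start_idx[chrom]
        for j in range(nb):
            hi = min(j + k, nb)
            counts[base + j] = csum[hi] - csum[j]
    return counts, barcodes


@dataclass
class CnvResult:
    grid: WindowGrid
    barcodes: list[str]
    zscores: np.ndarray         # windows x cells
    copy_estimate: np.ndarray   # windows x cells
    excluded: list[str]

    def marker_table(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.grid.markers):
            idx = self.grid.marker_window_index(name)
            for j, bc in enumerate(self.barcodes):
                rows.append((bc, name, self.zscores[idx, j], self.copy_estimate[idx, j]))
        return pd.DataFrame(rows, columns=["barcode", "marker", "z", "copy_estimate"])


def _trimmed_sd(values: np.ndarray, trim: float) -> np.ndarray:
    """Per-column SD after symmetric trimming (columns = cells)."""
    v = np.sort(values, axis=0)
    n = v.shape[0]
    lo = int(np.floor(n * trim))
    hi = n - lo
    core = v[lo:hi]
    return core.std(axis=0)


def cnv_zscore(counts: np.ndarray, grid: WindowGrid, barcodes: Sequence[str],
               trim: float = 0.1) -> CnvResult:
    """Window z-scores and copy estimates per cell.

    Per cell: v = log2(1 + CPM per window); z = (v - trimmed mean of the
    cell's windows) / (trimmed SD); copy estimate = 2 * window CPM / median
    window CPM of the cell.  Cells with zero total counts are excluded
    (logged).  Copy estimates are invariant to per-cell sequencing depth.
    """
    counts = np.asarray(counts)
    if counts.shape[0] < 30:
        raise ValueError("need >= 30 windows per cell for a stable background")
    # per-cell totals from one non-overlapping tiling phase
    phase = np.array([w.start % grid.window == 0 for w in grid.windows])
    totals = counts[phase].sum(axis=0).astype(float)
    keep = totals > 0
    excluded = [bc for bc, k in zip(barcodes, keep) if not k]
    if excluded:
        log.info("excluded %d cells with zero total counts", len(excluded))
    counts = counts[:, keep]
    totals = totals[keep]
    kept_barcodes = [bc for bc, k in zip(barcodes, keep) if k]

    cpm = counts / totals * 1e6
    v = np.log2(1.0 + cpm)
    tmean = stats.trim_mean(v, trim, axis=0)
    # tiny floor so a perfectly flat background still gives z = 0 exactly
    # while a lone amplified window scores arbitrarily high
    tsd = np.maximum(_trimmed_sd(v, trim), 1e-8)
    z = (v - tmean) / tsd

    med = np.median(cpm, axis=0)
    copy = np.full_like(cpm, 2.0)
    nzm = med > 0
    copy[:, nzm] = 2.0 * cpm[:, nzm] / med[nzm]

    return CnvResult(grid=grid, barcodes=kept_barcodes, zscores=z,
                     copy_estimate=copy, excluded=excluded)
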