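"""Simulators for circular-amplicon (ecDNA) benchmarking.

Two protocols:

1. Read-level: randomly composed circular amplicons are planted on a
   (synthetic or real) reference; paired-end reads are drawn uniformly from
   the circular sequence and projected back to reference coordinates, so
   pairs straddling a ligation junction become discordant records and reads
   crossing a junction become soft-clipped records with base-accurate clip
   positions.  A uniform background paired-end library (default ~4x, 50 bp
   reads) emulates the accessibility background of a healthy single-cell
   library.  Records are emitted pre-aligned (coordinate-sorted BAM); the
   projection arithmetic replaces an external read simulator + aligner while
   preserving exactly the discordant/clip signal the detector consumes.
   Optional FASTQ emission supports end-to-end runs through a real aligner.

2. Count-matrix: bin-by-cell matrices X_ij ~ Poisson(sparse_fac * C_ij *
   lambda_ij) where lambda is a sparse per-bin/per-cell Poisson baseline and
   C is a copy-number matrix (diploid C=2; cells in the first m of n_groups
   equal groups carry C = 2*copy_ratio on ecDNA-overlapping bins).

All entry points are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genomic_core import (
    FORWARD, LEFT, REVERSE, RIGHT,
    Breakend, BreakpointJunction, EcDNACandidate, GenomicInterval, OrientedSegment,
)

log = logging.getLogger("eccell")

DEFAULT_GENOME = {"chrS1": 30_000_000, "chrS2": 30_000_000,
                  "chrS3": 30_000_000, "chrS4": 30_000_000}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimStructureConfig:
    """Random circular-amplicon structures.

    ``reference`` is either a mapping of chromosome name -> length (synthetic
    mini-genome) or a FASTA path.  Sizes default to the 500 kb - 10 Mb regime
    of full-genome runs; desk-scale runs pass a scaled-down range.
    """

    n_circles: int = 100
    size_range: tuple[int, int] = (500_000, 10_000_000)
    max_segments_per_circle: int = 3
    reference: Mapping[str, int] | str = field(default_factory=lambda: dict(DEFAULT_GENOME))
    segment_margin: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_range[0] >= self.size_range[1]:
            raise ValueError("size_range low must be < high")
        if self.n_circles < 0:
            raise ValueError("n_circles must be >= 0")
        if self.max_segments_per_circle < 1:
            raise ValueError("max_segments_per_circle must be >= 1")

    def chrom_sizes(self) -> dict[str, int]:
        if isinstance(self.reference, str):
            with pysam.FastaFile(self.reference) as fa:
                return dict(zip(fa.references, fa.lengths))
        return dict(self.reference)


@dataclass
class SimReadConfig:
    """Paired-end library over a reference with planted circles."""

    read_length: int = 50
    insert_mean: int = 300
    insert_sd: int = 30
    background_depth: float = 4.0
    circle_local_depth: float | Sequence[float] = 10.0
    barcodes: Sequence[str] = ("BC0001",)
    circle_membership: Mapping[str, Sequence[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        depths = np.atleast_1d(np.asarray(self.circle_local_depth, dtype=float))
        if self.background_depth < 0 or (depths < 0).any():
            raise ValueError("depths must be >= 0")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must exceed twice the read length")


@dataclass
class SimMatrixConfig:
    """Bin-by-cell Poisson count-matrix simulation of focal amplification."""

    n_cells: int = 1000
    n_groups: int = 5
    m: int = 1
    copy_ratio: float = 5.0
    bin_size: int = 10_000
    sparse_fac: float = 0.5
    baseline_source: str = "synthetic"       # or "learned"
    n_bins: int = 30_000
    peak_fraction: float = 0.10
    peak_lambda_logmean: float = float(np.log(0.25))
    peak_lambda_logsd: float = 1.0
    offpeak_lambda: float = 0.005
    cell_depth_logsd: float = 0.35
    n_ecdna: int = 100
    size_range: tuple[int, int] = (50_000, 10_000_000)
    min_peak_overlap: float = 0.03
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells % self.n_groups != 0:
            raise ValueError("n_cells must be divisible by n_groups")
        if not 0 <= self.m < self.n_groups:
            raise ValueError("m must satisfy 0 <= m < n_groups")
        if self.copy_ratio <= 1:
            raise ValueError("copy_ratio must be > 1")
        if not 0 < self.sparse_fac <= 1:
            raise ValueError("sparse_fac must lie in (0, 1]")
        if self.baseline_source not in ("synthetic", "learned"):
            raise ValueError("baseline_source must be 'synthetic' or 'learned'")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _segment_lengths(total: int, n_seg: int, rng: np.random.Generator) -> list[int]:
    """Partition ``total`` bp into n_seg parts, none vanishingly small."""
    if n_seg == 1:
        return [total]
    for _ in range(50):
        frac = rng.dirichlet(np.full(n_seg, 3.0))
        lengths = np.maximum(1, np.round(frac * total).astype(int))
        lengths[-1] = total - int(lengths[:-1].sum())
        if (lengths >= max(1, total // (4 * n_seg))).all():
            return [int(x) for x in lengths]
    # fall back to an even split
    base = total // n_seg
    lengths = [base] * n_seg
    lengths[-1] += total - base * n_seg
    return lengths


def _tail_breakend(seg: OrientedSegment) -> Breakend:
    iv = seg.interval
    if seg.orientation == FORWARD:
        return Breakend(iv.chrom, iv.end, RIGHT)
    return Breakend(iv.chrom, iv.start, LEFT)


def _head_breakend(seg: OrientedSegment) -> Breakend:
    iv = seg.interval
    if seg.orientation == FORWARD:
        return Breakend(iv.chrom, iv.start, LEFT)
    return Breakend(iv.chrom, iv.end, RIGHT)


def circle_junctions(segments: Sequence[OrientedSegment]) -> list[BreakpointJunction]:
    """Ligation junctions closing the circle: tail of each segment to the
    head of the next (cyclically)."""
    n = len(segments)
    return [
        BreakpointJunction(_tail_breakend(segments[i]), _head_breakend(segments[(i + 1) % n]))
        for i in range(n)
    ]


def simulate_ecdna_structures(cfg: SimStructureConfig) -> list[EcDNACandidate]:
    """Randomly compose circular amplicons over the reference.

    Segments are drawn genome-wide with random ligation direction, mutually
    disjoint (with ``segment_margin`` spacing) so that detection truth is
    unambiguous.  Raises if the requested sizes cannot be placed.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.chrom_sizes()
    chroms = sorted(sizes)
    if cfg.n_circles > 0 and cfg.size_range[1] > max(sizes.values()):
        raise ValueError("size_range exceeds the longest reference sequence")
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    placed: list[GenomicInterval] = []
    out: list[EcDNACandidate] = []
    for k in range(cfg.n_circles):
        n_seg = int(rng.integers(1, cfg.max_segments_per_circle + 1))
        total = int(rng.uniform(*cfg.size_range))
        lengths = _segment_lengths(total, n_seg, rng)
        segs: list[OrientedSegment] = []
        trial: list[GenomicInterval] = []
        for length in lengths:
            for attempt in range(1000):
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                room = sizes[chrom] - length
                if room <= 0:
                    continue
                start = int(rng.integers(0, room))
                iv = GenomicInterval(chrom, start, start + length)
                pad = GenomicInterval(chrom, max(0, start - cfg.segment_margin),
                                      start + length + cfg.segment_margin)
                if not any(pad.overlaps(p) for p in placed + trial):
                    trial.append(iv)
                    orientation = FORWARD if rng.random() < 0.5 else REVERSE
                    segs.append(OrientedSegment(iv, orientation))
                    break
            else:
                raise ValueError(
                    "could not place circle segments: reference too small for "
                    f"{cfg.n_circles} circles of size {cfg.size_range}"
                )
        placed.extend(trial)
        out.append(EcDNACandidate(
            id=f"truth_{k:04d}", segments=segs, junctions=circle_junctions(segs),
        ))
    return out


def write_synthetic_fasta(chrom_sizes: Mapping[str, int], path: str, seed: int = 0) -> str:
    """Random nucleotide FASTA for a synthetic mini-genome (for FASTQ runs)."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f">{chrom}\n")
            seq = bases[rng.integers(0, 4, size=chrom_sizes[chrom])].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    pysam.faidx(path)
    return path


# ---------------------------------------------------------------------------
# read-level library
# ---------------------------------------------------------------------------

# structured dtype for one aligned record before serialisation
_READ_DTYPE = np.dtype([
    ("ref", np.int32), ("pos", np.int64),
    ("match_len", np.int32), ("clip_len", np.int32), ("clip_side", np.int8),
    ("reverse", np.int8),
    ("mate_ref", np.int32), ("mate_pos", np.int64), ("mate_reverse", np.int8),
    ("pair_id", np.int64), ("read1", np.int8), ("barcode", np.int32),
])


class CircleProjector:
    """Map circle coordinates of one amplicon back to the reference."""

    def __init__(self, candidate: EcDNACandidate):
        self.segments = candidate.segments
        self.lengths = np.array([s.interval.size() for s in self.segments], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(self.lengths)])
        self.total = int(self.cum[-1])

    def segment_of(self, c: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.cum, c, side="right") - 1

    def project_point(self, c: int) -> tuple[str, int]:
        """Reference (chrom, position) of circle coordinate c."""
        i = int(self.segment_of(np.asarray([c]))[0])
        seg = self.segments[i]
        off = c - int(self.cum[i])
        iv = seg.interval
        if seg.orientation == FORWARD:
            return iv.chrom, iv.start + off
        return iv.chrom, iv.end - 1 - off

    def project_read(self, c: int, length: int, circle_forward: bool
                     ) -> tuple[int, int, int, int, int, bool]:
        """Project a read occupying circle coords [c, c+length) (mod circle).

        Returns (segment_index, ref_start, match_len, clip_len, clip_side,
        is_reverse) of the single emitted alignment; ``clip_side`` is 0 for
        none, 1 left, 2 right (reference orientation).  Reads crossing a
        junction keep their longer piece aligned and soft-clip the rest at
        the junction breakend.
        """
        idx, rs, ml, cl, cs, rev = _project_reads(
            self, np.asarray([c], dtype=np.int64), length, circle_forward)
        return (int(idx[0]), int(rs[0]), int(ml[0]), int(cl[0]), int(cs[0]),
                bool(rev[0]))


def _project_reads(projector: CircleProjector, starts: np.ndarray, length: int,
                   circle_forward: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                                  np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised projection of many same-length reads.

    Returns arrays (seg_idx, ref_start, match_len, clip_len, clip_side,
    is_reverse); clip_side: 0 none, 1 left, 2 right.
    """
    n = len(starts)
    total = projector.total
    c = starts % total
    end = c + length
    seg_i = projector.segment_of(c)
    seg_end = projector.cum[seg_i + 1]
    first_len = np.minimum(end, seg_end) - c
    second_len = length - first_len
    use_tail = second_len > first_len

    n_segs = len(projector.segments)
    idx = np.where(use_tail, (seg_i + 1) % n_segs, seg_i)
    offset = np.where(use_tail, 0, c - projector.cum[seg_i])
    match_len = np.where(use_tail, second_len, first_len)
    clip_len = length - match_len

    starts_arr = np.array([s.interval.start for s in projector.segments], dtype=np.int64)
    ends_arr = np.array([s.interval.end for s in projector.segments], dtype=np.int64)
    fwd = np.array([s.orientation == FORWARD for s in projector.segments])

    seg_fwd = fwd[idx]
    ref_start = np.where(seg_fwd,
                         starts_arr[idx] + offset,
                         ends_arr[idx] - offset - match_len)
    is_reverse = np.where(seg_fwd, not circle_forward, circle_forward)

    # clip side in reference orientation:
    # head pieces (use_tail=False, clip_len>0): read continues past the
    # segment's circle tail -> reference right if forward else left.
    # tail pieces (use_tail=True): earlier read part lies before the
    # segment's circle head -> reference left if forward else right.
    clip_side = np.zeros(n, dtype=np.int8)
    has_clip = clip_len > 0
    head_piece = has_clip & ~use_tail
    tail_piece = has_clip & use_tail
    clip_side[head_piece & seg_fwd] = 2
    clip_side[head_piece & ~seg_fwd] = 1
    clip_side[tail_piece & seg_fwd] = 1
    clip_side[tail_piece & ~seg_fwd] = 2
    return idx, ref_start, match_len.astype(np.int64), clip_len.astype(np.int64), \
        clip_side, is_reverse


def _sample_inserts(rng: np.random.Generator, n: int, cfg: SimReadConfig) -> np.ndarray:
    ins = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)
    return np.clip(np.round(ins), 2 * cfg.read_length, None).astype(np.int64)


def simulate_library(structures: Sequence[EcDNACandidate], cfg: SimReadConfig,
                     chrom_sizes: Mapping[str, int], out_bam: str,
                     fasta: str | None = None, out_fastq_prefix: str | None = None
                     ) -> str:
    """Write a coordinate-sorted, indexed BAM of background + circle reads.

    Background pairs are uniform over the reference at ``background_depth``;
    circle pairs are uniform over each circular sequence at its local depth
    and projected back to reference coordinates.  Every record carries a CB
    (cell barcode) tag.  Returns the BAM path.
    """
    depths = np.atleast_1d(np.asarray(cfg.circle_local_depth, dtype=float))
    if len(structures) == 0 and (depths > 0).any():
        raise ValueError("no structures to simulate at positive circle depth")
    if len(depths) not in (1, max(1, len(structures))):
        raise ValueError("circle_local_depth must be scalar or one value per circle")
    if len(depths) == 1:
        depths = np.repeat(depths, max(1, len(structures)))

    rng = np.random.default_rng(cfg.seed)
    chroms = sorted(chrom_sizes)
    ref_ids = {c: i for i, c in enumerate(chroms)}
    rl = cfg.read_length
    barcodes = list(cfg.barcodes)

    chunks: list[np.ndarray] = []
    pair_counter = 0

    def _pair_records(ref1, pos1, m1, cl1, cs1, rev1, ref2, pos2, m2, cl2, cs2, rev2,
                      bc_idx, pair_ids):
        n = len(pos1)
        rec = np.zeros(2 * n, dtype=_READ_DTYPE)
        for k, (ref, pos, m, cl, cs, rev, oref, opos, orev, r1) in enumerate([
            (ref1, pos1, m1, cl1, cs1, rev1, ref2, pos2, rev2, 1),
            (ref2, pos2, m2, cl2, cs2, rev2, ref1, pos1, rev1, 0),
        ]):
            sl = slice(k * n, (k + 1) * n)
            rec["ref"][sl] = ref
            rec["pos"][sl] = pos
            rec["match_len"][sl] = m
            rec["clip_len"][sl] = cl
            rec["clip_side"][sl] = cs
            rec["reverse"][sl] = rev
            rec["mate_ref"][sl] = oref
            rec["mate_pos"][sl] = opos
            rec["mate_reverse"][sl] = orev
            rec["pair_id"][sl] = pair_ids
            rec["read1"][sl] = r1
            rec["barcode"][sl] = bc_idx
        return rec

    # --- background ---
    if cfg.background_depth > 0:
        for chrom in chroms:
            clen = chrom_sizes[chrom]
            n_pairs = int(round(cfg.background_depth * clen / (2 * rl)))
            if n_pairs == 0:
                continue
            ins = _sample_inserts(rng, n_pairs, cfg)
            s = rng.integers(0, np.maximum(1, clen - ins), size=n_pairs)
            bc = rng.integers(0, len(barcodes), size=n_pairs)
            pid = np.arange(pair_counter, pair_counter + n_pairs)
            pair_counter += n_pairs
            rid = np.full(n_pairs, ref_ids[chrom], dtype=np.int32)
            zeros = np.zeros(n_pairs, dtype=np.int64)
            chunks.append(_pair_records(
                rid, s, np.full(n_pairs, rl), zeros, zeros.astype(np.int8),
                np.zeros(n_pairs, dtype=np.int8),
                rid, s + ins - rl, np.full(n_pairs, rl), zeros, zeros.astype(np.int8),
                np.ones(n_pairs, dtype=np.int8),
                bc, pid))

    # --- circles ---
    for circ, depth in zip(structures, depths):
        if depth <= 0:
            continue
        proj = CircleProjector(circ)
        n_pairs = int(round(depth * proj.total / (2 * rl)))
        if n_pairs == 0:
            continue
        ins = _sample_inserts(rng, n_pairs, cfg)
        c = rng.integers(0, proj.total, size=n_pairs)
        if cfg.circle_membership and circ.id in cfg.circle_membership:
            pool = [barcodes.index(b) for b in cfg.circle_membership[circ.id]]
            bc = np.asarray(pool)[rng.integers(0, len(pool), size=n_pairs)]
        else:
            bc = rng.integers(0, len(barcodes), size=n_pairs)
        seg1, p1, m1, cl1, cs1, rev1 = _project_reads(proj, c, rl, circle_forward=True)
        seg2, p2, m2, cl2, cs2, rev2 = _project_reads(proj, c + ins - rl, rl,
                                                      circle_forward=False)
        chrom_arr = np.array([ref_ids[s.interval.chrom] for s in proj.segments],
                             dtype=np.int32)
        pid = np.arange(pair_counter, pair_counter + n_pairs)
        pair_counter += n_pairs
        chunks.append(_pair_records(
            chrom_arr[seg1], p1, m1, cl1, cs1, rev1.astype(np.int8),
            chrom_arr[seg2], p2, m2, cl2, cs2, rev2.astype(np.int8),
            bc, pid))

    records = (np.concatenate(chunks) if chunks
               else np.zeros(0, dtype=_READ_DTYPE))
    order = np.argsort(records, order=("ref", "pos"), kind="stable")
    records = records[order]

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
    }
    mode = "wb" if out_bam.endswith(".bam") else "w"
    cols = {name: records[name].tolist() for name in records.dtype.names}
    n_rec = len(records)
    with pysam.AlignmentFile(out_bam, mode, header=header) as bam:
        hdr = bam.header
        write = bam.write
        seg = pysam.AlignedSegment
        for i in range(n_rec):
            a = seg(hdr)
            a.query_name = "p%010d" % cols["pair_id"][i]
            ref = cols["ref"][i]
            pos = cols["pos"][i]
            a.reference_id = ref
            a.reference_start = pos
            a.mapping_quality = 60
            m = cols["match_len"][i]
            cl = cols["clip_len"][i]
            if cl > 0:
                a.cigartuples = [(4, cl), (0, m)] if cols["clip_side"][i] == 1 \
                    else [(0, m), (4, cl)]
            else:
                a.cigartuples = [(0, m)]
            # paired(1) + strand(16) + mate strand(32) + read1(64)/read2(128)
            a.flag = (1 | (16 if cols["reverse"][i] else 0)
                      | (32 if cols["mate_reverse"][i] else 0)
                      | (64 if cols["read1"][i] else 128))
            mref = cols["mate_ref"][i]
            mpos = cols["mate_pos"][i]
            a.next_reference_id = mref
            a.next_reference_start = mpos
            if ref == mref:
                tlen = max(pos + m, mpos + m) - min(pos, mpos)
                a.template_length = tlen if pos <= mpos else -tlen
            a.set_tag("CB", barcodes[cols["barcode"][i]])
            write(a)
    if out_bam.endswith(".bam"):
        pysam.index(out_bam)
    if out_fastq_prefix is not None:
        if fasta is None:
            raise ValueError("FASTQ emission requires a reference FASTA")
        _emit_fastq(records, chroms, barcodes, fasta, rl, out_fastq_prefix)
    return out_bam


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def _emit_fastq(records: np.ndarray, chroms: list[str], barcodes: list[str],
                fasta: str, read_length: int, prefix: str) -> None:
    """Reconstruct full read sequences (aligned part + clipped continuation
    approximated by random bases) and emit R1/R2 FASTQ."""
    rng = np.random.default_rng(0)
    qual = "I" * read_length
    with pysam.FastaFile(fasta) as fa, \
            open(prefix + "_R1.fastq", "w") as f1, open(prefix + "_R2.fastq", "w") as f2:
        for r in records:
            chrom = chroms[int(r["ref"])]
            m = int(r["match_len"])
            seq = fa.fetch(chrom, int(r["pos"]), int(r["pos"]) + m).upper()
            pad = "".join("ACGT"[i] for i in rng.integers(0, 4, int(r["clip_len"])))
            seq = (pad + seq) if int(r["clip_side"]) == 1 else (seq + pad)
            if r["reverse"]:
                seq = _revcomp(seq)
            out = f1 if r["read1"] else f2
            out.write(f"@p{int(r['pair_id']):010d}:{barcodes[int(r['barcode'])]}\n"
                      f"{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# count-matrix protocol
# ---------------------------------------------------------------------------

@dataclass
class CountMatrixBundle:
    lam: np.ndarray                 # bins x cells Poisson baseline
    C: np.ndarray                   # bins x cells copy numbers (diploid = 2)
    X: np.ndarray                   # bins x cells simulated counts
    truth_labels: np.ndarray        # per-cell amplified flag (bool)
    ecdna_bins: list[np.ndarray]    # one bin-index array per kept ecDNA region
    barcodes: list[str]
    bin_size: int

    def __post_init__(self) -> None:
        if self.lam.shape != self.C.shape or self.C.shape != self.X.shape:
            raise ValueError("lambda, C and X shapes must agree")
        if (self.X < 0).any() or not np.issubdtype(self.X.dtype, np.integer):
            raise ValueError("X must contain non-negative integers")


def _sample_region_bins(cfg: SimMatrixConfig, rng: np.random.Generator) -> list[np.ndarray]:
    regions = []
    for _ in range(cfg.n_ecdna):
        size = rng.uniform(*cfg.size_range)
        nb = max(1, int(round(size / cfg.bin_size)))
        nb = min(nb, cfg.n_bins)
        start = int(rng.integers(0, cfg.n_bins - nb + 1))
        regions.append(np.arange(start, start + nb))
    return regions


def make_baseline_lambda(cfg: SimMatrixConfig, template_matrix: np.ndarray | None = None
                         ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Baseline Poisson means plus the kept ecDNA bin sets.

    Synthetic source: per-bin magnitudes are a Bernoulli "peak" mask times a
    log-normal, off-peak bins carry a small floor, and each cell has a
    log-normal depth factor — emulating the sparsity of 10 kb scATAC bins.
    Learned source: lambda is the rank-one moment match of a template
    bins x cells count matrix (per-bin mean x per-cell depth factor).

    Candidate ecDNA regions whose bins overlap the peak (nonzero-baseline)
    bins by less than ``min_peak_overlap`` are discarded.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.baseline_source == "learned":
        if template_matrix is None:
            raise ValueError("learned baseline requires a template matrix")
        template_matrix = np.asarray(template_matrix, dtype=float)
        if template_matrix.ndim != 2:
            raise ValueError("template matrix must be 2-D (bins x cells)")
        bin_mean = template_matrix.mean(axis=1)
        depth = template_matrix.mean(axis=0)
        grand = template_matrix.mean()
        if grand <= 0:
            raise ValueError("template matrix is all zero")
        lam = np.outer(bin_mean, depth) / grand
        peak_bins = bin_mean > 0
        n_bins = template_matrix.shape[0]
    else:
        peak_bins = rng.random(cfg.n_bins) < cfg.peak_fraction
        magnitude = np.where(
            peak_bins,
            rng.lognormal(cfg.peak_lambda_logmean, cfg.peak_lambda_logsd, cfg.n_bins),
            cfg.offpeak_lambda,
        )
        depth = rng.lognormal(0.0, cfg.cell_depth_logsd, cfg.n_cells)
        lam = np.outer(magnitude, depth)
        n_bins = cfg.n_bins

    regions = _sample_region_bins(
        cfg if cfg.baseline_source == "synthetic" else
        SimMatrixConfig(**{**cfg.__dict__, "n_bins": n_bins}), rng)
    kept = [
        r for r in regions
        if peak_bins[r].mean() >= cfg.min_peak_overlap
    ]
    n_drop = len(regions) - len(kept)
    if n_drop:
        log.info("dropped %d/%d ecDNA regions below %.0f%% peak overlap",
                 n_drop, len(regions), 100 * cfg.min_peak_overlap)
    return lam, kept


def make_copy_number_matrix(cfg: SimMatrixConfig, ecdna_bins: Sequence[np.ndarray],
                            n_bins: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Copy-number matrix C and per-cell truth labels.

    Cells are split into ``n_groups`` equal groups; the first ``m`` groups
    are amplified: C = 2 * copy_ratio on (ecDNA bins x amplified cells) and
    C = 2 (diploid) elsewhere, so the expected count of an amplified entry is
    copy_ratio times its baseline (with sparse_fac = 0.5).
    """
    if cfg.m >= cfg.n_groups:
        raise ValueError("m must be < n_groups")
    group_size = cfg.n_cells // cfg.n_groups
    n_amp = cfg.m * group_size
    if n_bins is None:
        n_bins = cfg.n_bins
    C = np.full((n_bins, cfg.n_cells), 2.0)
    truth = np.zeros(cfg.n_cells, dtype=bool)
    truth[:n_amp] = True
    for region in ecdna_bins:
        C[np.ix_(region, np.arange(n_amp))] = 2.0 * cfg.copy_ratio
    return C, truth


def simulate_count_matrix(lam: np.ndarray, C: np.ndarray, sparse_fac: float,
                          seed: int = 0) -> np.ndarray:
    """X_ij ~ Poisson(sparse_fac * C_ij * lambda_ij), independent entries."""
    lam = np.asarray(lam, dtype=float)
    if (lam < 0).any():
        raise ValueError("lambda must be non-negative")
    if not 0 < sparse_fac <= 1:
        raise ValueError("sparse_fac must lie in (0, 1]")
    if lam.shape != np.asarray(C).shape:
        raise ValueError("lambda and C shapes must agree")
    rng = np.random.default_rng(seed)
    return rng.poisson(sparse_fac * np.asarray(C, dtype=float) * lam)


def simulate_matrix_bundle(cfg: SimMatrixConfig,
                           template_matrix: np.ndarray | None = None
                           ) -> CountMatrixBundle:
    """Full count-matrix protocol: baseline -> C -> X, with truth attached."""
    lam, regions = make_baseline_lambda(cfg, template_matrix)
    C, truth = make_copy_number_matrix(cfg, regions, n_bins=lam.shape[0])
    X = simulate_count_matrix(lam, C, cfg.sparse_fac, seed=cfg.seed + 1)
    barcodes = [f"CELL{j:05d}" for j in range(cfg.n_cells)]
    return CountMatrixBundle(lam=lam, C=C, X=X, truth_labels=truth,
                             ecdna_bins=regions, barcodes=barcodes,
                             bin_size=cfg.bin_size)


def fragments_from_counts(X: np.ndarray, bin_size: int, barcodes: Sequence[str],
                          chrom: str = "chrS1", fragment_len: int = 100) -> pd.DataFrame:
    """Expand a bin-by-cell count matrix into fragment records (one fragment
    per count, centred in its bin) — plumbing for window/fragment consumers."""
    bins, cells = np.nonzero(X)
    counts = X[bins, cells]
    bins = np.repeat(bins, counts)
    cells = np.repeat(cells, counts)
    mid = bins * bin_size + bin_size // 2
    start = np.maximum(0, mid - fragment_len // 2)
    return pd.DataFrame({
        "chrom": chrom,
        "start": start,
        "end": start + fragment_len,
        "barcode": np.asarray(list(barcodes))[cells],
        "support": 1,
    })


def mix_cells(pop_pos: Sequence[str], pop_neg: Sequence[str], proportion: float,
              n: int = 1000, seed: int = 0) -> tuple[list[str], np.ndarray]:
    """Sample a mixture of round(proportion*n) positive and the rest negative
    cells, without replacement.  Returns (barcodes, truth labels)."""
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must lie in [0, 1]")
    n_pos = int(round(proportion * n))
    n_neg = n - n_pos
    if n_pos > len(pop_pos) or n_neg > len(pop_neg):
        raise ValueError("insufficient pool for the requested mixture")
    rng = np.random.default_rng(seed)
    pos = list(rng.choice(np.asarray(pop_pos, dtype=object), size=n_pos, replace=False))
    neg = list(rng.choice(np.asarray(pop_neg, dtype=object), size=n_neg, replace=False))
    cells = [str(b) for b in pos + neg]
    truth = np.zeros(n, dtype=bool)
    truth[:n_pos] = True
    return cells, truth
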