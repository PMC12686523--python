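"""Pseudo-bulk ecDNA detection from barcoded alignment records.

The whole single-cell library is treated as one bulk accessibility library:

    coverage segmentation -> discordant-pair clustering -> clip refinement
    -> breakpoint-graph cycle assembly -> QC filtering

The genome is processed in chunks (default 64 Mb) purely as an I/O batching
device; junction evidence is merged globally before clustering, so the
result is independent of the chunk size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median_low
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from .genomic_core import (
    FORWARD, LEFT, REVERSE, RIGHT,
    Breakend, BreakpointGraph, BreakpointJunction, EcDNACandidate,
    GenomicInterval, OrientedSegment, merge_intervals,
)

log = logging.getLogger("eccell")

_SKIP_FLAGS = 0x4 | 0x100 | 0x800       # unmapped, secondary, supplementary
_MIN_CLIP_LEN = 5                       # soft clips shorter than this are alignment noise


@dataclass
class DetectorConfig:
    chunk_size: int = 64_000_000
    bin_size: int = 1_000
    depth_floor: float = 5.0
    enrich_factor: float = 2.0
    merge_gap: int = 10_000
    insert_cutoff: int = 1_000
    cluster_window: int = 500
    min_discordant_support: int = 3
    max_segments_per_circle: int = 10
    size_min: int = 10_000
    size_max: int = 20_000_000
    min_depth_mean: float = 5.0
    min_high_coverage: float = 0.1
    snap_window: int | None = None      # default: cluster_window + 2 * bin_size

    def __post_init__(self) -> None:
        if self.size_min >= self.size_max:
            raise ValueError("size_min must be < size_max")
        for name in ("chunk_size", "bin_size", "merge_gap", "insert_cutoff",
                     "cluster_window", "min_discordant_support",
                     "max_segments_per_circle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.snap_window is None:
            # amplified-segment boundaries are bin-quantised, so junctions can
            # sit up to ~bin_size away from a called segment end
            self.snap_window = self.cluster_window + 2 * self.bin_size


@dataclass
class CoverageTrack:
    chrom: str
    bin_size: int
    values: np.ndarray      # mean per-base depth per bin

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage values must be >= 0")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def compute_coverage(alignments: Iterable, chrom: str, chrom_length: int,
                     config: DetectorConfig) -> CoverageTrack:
    """Binned mean per-base depth of primary aligned reads on one chromosome.

    Bin value = (total overlap bp of reads with the bin) / bin_size.  The
    stream must be coordinate-sorted; secondary/supplementary/unmapped
    records are excluded.
    """
    if chrom_length is None or chrom_length <= 0:
        raise ValueError(f"unknown length for chromosome {chrom!r}")
    bs = config.bin_size
    n_bins = math.ceil(chrom_length / bs)
    values = np.zeros(n_bins, dtype=float)
    last = -1
    for r in alignments:
        if r.flag & _SKIP_FLAGS:
            continue
        s = r.reference_start
        if s < last:
            raise ValueError("alignment stream is not coordinate-sorted")
        last = s
        _add_coverage(values, s, r.reference_end, bs, chrom_length)
    values /= bs
    return CoverageTrack(chrom=chrom, bin_size=bs, values=values)


def _add_coverage(values: np.ndarray, start: int, end: int, bin_size: int,
                  chrom_length: int) -> None:
    end = min(end, chrom_length)
    if end <= start:
        return
    b0 = start // bin_size
    b1 = (end - 1) // bin_size
    if b0 == b1:
        values[b0] += end - start
        return
    values[b0] += (b0 + 1) * bin_size - start
    if b1 > b0 + 1:
        values[b0 + 1:b1] += bin_size
    values[b1] += end - b1 * bin_size


def amplified_threshold(global_median: float, config: DetectorConfig) -> float:
    """Depth cutoff for "amplified": an absolute floor tied to the published
    depth_mean filter, guarded by a relative enrichment over the genome-wide
    median so it stays meaningful in deep libraries."""
    return max(config.depth_floor, config.enrich_factor * global_median)


def call_amplified_segments(track: CoverageTrack, config: DetectorConfig,
                            global_median: float | None = None
                            ) -> list[GenomicInterval]:
    """Maximal runs of bins at/above the amplified-depth cutoff, with runs
    separated by <= merge_gap merged; returned sorted."""
    if track.values.size == 0:
        raise ValueError("empty coverage track")
    if global_median is None:
        global_median = float(np.median(track.values))
    cutoff = amplified_threshold(global_median, config)
    above = track.values >= cutoff
    if not above.any():
        return []
    # run-length extraction on the boolean mask
    diff = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    bs = track.bin_size
    intervals = [GenomicInterval(track.chrom, int(s) * bs, int(e) * bs)
                 for s, e in zip(starts, ends)]
    return merge_intervals(intervals, max_gap=config.merge_gap)


# ---------------------------------------------------------------------------
# discordant pairs and clipped reads
# ---------------------------------------------------------------------------

@dataclass
class _PairEvidence:
    breakend_a: Breakend
    breakend_b: Breakend
    barcode: str | None = None

    def __post_init__(self) -> None:
        a, b = self.breakend_a, self.breakend_b
        if (b.chrom, b.position, b.side) < (a.chrom, a.position, a.side):
            self.breakend_a, self.breakend_b = b, a


@dataclass(frozen=True)
class ClipEvidence:
    chrom: str
    position: int
    side: str
    barcode: str | None = None


def _is_discordant(r, mate_chrom_same: bool, config: DetectorConfig) -> bool:
    if not mate_chrom_same:
        return True
    if r.is_reverse == r.mate_is_reverse:
        return True
    if abs(r.template_length) > config.insert_cutoff:
        return True
    # outward-facing: the leftmost read of the pair is on the reverse strand
    if r.reference_start <= r.next_reference_start:
        return r.is_reverse
    return not r.is_reverse


def _read_breakend(chrom: str, start: int, end: int, is_reverse: bool) -> Breakend:
    """Breakend implied by one read of a discordant pair: a forward read
    points right (junction past its 3' end), a reverse read points left."""
    if is_reverse:
        return Breakend(chrom, start, LEFT)
    return Breakend(chrom, end, RIGHT)


def pair_evidence_from_record(r, ref_names: Sequence[str], config: DetectorConfig
                              ) -> _PairEvidence | None:
    """Discordant-pair evidence from a single (read1) record; mate geometry
    is reconstructed from the record's mate fields."""
    chrom = ref_names[r.reference_id]
    mate_chrom = ref_names[r.next_reference_id]
    if not _is_discordant(r, chrom == mate_chrom, config):
        return None
    own = _read_breakend(chrom, r.reference_start, r.reference_end, r.is_reverse)
    approx_len = r.reference_length or 0
    mate = _read_breakend(mate_chrom, r.next_reference_start,
                          r.next_reference_start + approx_len, r.mate_is_reverse)
    barcode = r.get_tag("CB") if r.has_tag("CB") else None
    return _PairEvidence(own, mate, barcode)


def clip_evidence_from_record(r, chrom: str, min_clip: int = _MIN_CLIP_LEN
                              ) -> list[ClipEvidence]:
    cig = r.cigartuples
    if cig is None:
        return []
    barcode = r.get_tag("CB") if r.has_tag("CB") else None
    out = []
    if cig[0][0] == 4 and cig[0][1] >= min_clip:
        out.append(ClipEvidence(chrom, r.reference_start, LEFT, barcode))
    if cig[-1][0] == 4 and cig[-1][1] >= min_clip:
        out.append(ClipEvidence(chrom, r.reference_end, RIGHT, barcode))
    return out


@dataclass
class _Cluster:
    pos_a: list[int] = field(default_factory=list)
    pos_b: list[int] = field(default_factory=list)

    def medians(self) -> tuple[int, int]:
        return median_low(self.pos_a), median_low(self.pos_b)


def cluster_breakend_pairs(pairs: Sequence[_PairEvidence], config: DetectorConfig
                           ) -> list[BreakpointJunction]:
    """Greedy single-pass clustering of canonically ordered breakend pairs.

    A pair joins the first open cluster (same chrom/side on both ends) whose
    current median positions are both within cluster_window; clusters below
    min_discordant_support are dropped; junction position = member median.
    """
    w = config.cluster_window
    groups: dict[tuple, list[_PairEvidence]] = {}
    for p in pairs:
        key = (p.breakend_a.chrom, p.breakend_a.side,
               p.breakend_b.chrom, p.breakend_b.side)
        groups.setdefault(key, []).append(p)

    junctions: list[BreakpointJunction] = []
    for key in sorted(groups):
        chrom_a, side_a, chrom_b, side_b = key
        members = sorted(groups[key],
                         key=lambda p: (p.breakend_a.position, p.breakend_b.position))
        open_clusters: list[_Cluster] = []
        closed: list[_Cluster] = []
        for p in members:
            pa, pb = p.breakend_a.position, p.breakend_b.position
            still_open = []
            for cl in open_clusters:
                if pa - cl.medians()[0] > w:
                    closed.append(cl)
                else:
                    still_open.append(cl)
            open_clusters = still_open
            for cl in open_clusters:
                ma, mb = cl.medians()
                if abs(pa - ma) <= w and abs(pb - mb) <= w:
                    cl.pos_a.append(pa)
                    cl.pos_b.append(pb)
                    break
            else:
                open_clusters.append(_Cluster([pa], [pb]))
        closed.extend(open_clusters)
        for cl in closed:
            if len(cl.pos_a) < config.min_discordant_support:
                continue
            ma, mb = cl.medians()
            junctions.append(BreakpointJunction(
                Breakend(chrom_a, ma, side_a), Breakend(chrom_b, mb, side_b),
                discordant_support=len(cl.pos_a),
            ))
    junctions.sort(key=lambda j: j.canonical())
    return junctions


def cluster_discordant_pairs(alignments: Iterable, ref_names: Sequence[str],
                             config: DetectorConfig) -> list[BreakpointJunction]:
    """Classify read pairs as discordant and cluster them into junctions.

    A pair is discordant iff the mates map to different chromosomes, or to
    the same chromosome with same-strand/outward orientation, or with
    |insert| > insert_cutoff.  Records without mate information are skipped
    (count logged).
    """
    pairs = []
    n_skipped = 0
    for r in alignments:
        if r.flag & _SKIP_FLAGS or not r.is_read1:
            continue
        if not r.is_paired or r.mate_is_unmapped:
            n_skipped += 1
            continue
        ev = pair_evidence_from_record(r, ref_names, config)
        if ev is not None:
            pairs.append(ev)
    if n_skipped:
        log.info("skipped %d records without usable mate information", n_skipped)
    return cluster_breakend_pairs(pairs, config)


def _modal_position(positions: Sequence[int]) -> tuple[int, int]:
    """(mode, count); ties broken by the smaller coordinate."""
    counts: dict[int, int] = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    best = min(counts, key=lambda p: (-counts[p], p))
    return best, counts[best]


def refine_breakpoints_with_clips(junctions: Sequence[BreakpointJunction],
                                  clips: Sequence[ClipEvidence],
                                  config: DetectorConfig) -> list[BreakpointJunction]:
    """Move each junction breakend to the modal nearby clip position.

    If >= 1 clipped read has its clip position within cluster_window of a
    breakend (matching chrom and side), the breakend position becomes the
    modal clip position and the clip count is recorded; otherwise the
    breakend is unchanged.  The junction's clip_support is the summed modal
    count over its two breakends.
    """
    w = config.cluster_window
    by_key: dict[tuple[str, str], list[int]] = {}
    for c in clips:
        by_key.setdefault((c.chrom, c.side), []).append(c.position)

    def refine(be: Breakend) -> tuple[Breakend, int]:
        near = [p for p in by_key.get((be.chrom, be.side), ())
                if abs(p - be.position) <= w]
        if not near:
            return be, 0
        mode, count = _modal_position(near)
        return Breakend(be.chrom, mode, be.side), count

    out = []
    for j in junctions:
        a, ca = refine(j.breakend_a)
        b, cb = refine(j.breakend_b)
        out.append(BreakpointJunction(a, b, discordant_support=j.discordant_support,
                                      clip_support=ca + cb))
    return out


# ---------------------------------------------------------------------------
# breakpoint-graph cycle assembly
# ---------------------------------------------------------------------------

def _snap_breakend(be: Breakend, segments: Sequence[GenomicInterval],
                   window: int) -> tuple[int, str] | None:
    """Nearest segment end matching the breakend's chrom and side, within
    ``window``; side=right matches segment ends, side=left segment starts."""
    best = None
    best_dist = window + 1
    for i, seg in enumerate(segments):
        if seg.chrom != be.chrom:
            continue
        anchor = seg.end if be.side == RIGHT else seg.start
        dist = abs(anchor - be.position)
        if dist < best_dist:
            best_dist = dist
            best = (i, RIGHT if be.side == RIGHT else LEFT)
    return best


def build_breakpoint_graph(segments: Sequence[GenomicInterval],
                           junctions: Sequence[BreakpointJunction],
                           config: DetectorConfig) -> BreakpointGraph:
    """Snap junction breakends to amplified-segment ends; junctions not near
    any segment end are discarded (they do not seed new segments)."""
    graph = BreakpointGraph(segments=list(segments))
    for j in junctions:
        na = _snap_breakend(j.breakend_a, segments, config.snap_window)
        nb = _snap_breakend(j.breakend_b, segments, config.snap_window)
        if na is None or nb is None:
            continue
        graph.add_junction(na, nb, j)
    return graph


def enumerate_cycles(graph: BreakpointGraph, max_segments: int
                     ) -> list[tuple[list[tuple[int, str]], list[int]]]:
    """All simple cycles alternating segment and junction edges.

    Returns, per cycle, the traversal as a list of (segment_index,
    orientation) plus the junction-edge indices in traversal order (the edge
    leaving each segment).  Each segment is used at most once per cycle;
    cycles are deduplicated over rotation and reflection by anchoring at
    their smallest segment index.
    """
    adj: dict[tuple[int, str], list[tuple[int, tuple[int, str]]]] = {}
    for e_idx, (na, nb, _j) in enumerate(graph.junction_edges):
        adj.setdefault(na, []).append((e_idx, nb))
        if nb != na:
            adj.setdefault(nb, []).append((e_idx, na))

    seen: set[tuple] = set()
    results = []

    def other_side(node: tuple[int, str]) -> tuple[int, str]:
        return (node[0], RIGHT if node[1] == LEFT else LEFT)

    def orientation(entry_side: str) -> str:
        return FORWARD if entry_side == LEFT else REVERSE

    n_seg = len(graph.segments)
    for start_seg in range(n_seg):
        for entry_side in (LEFT, RIGHT):
            entry0 = (start_seg, entry_side)
            path = [(start_seg, orientation(entry_side))]
            edges: list[int] = []
            used = {start_seg}

            def dfs(exit_node: tuple[int, str]) -> None:
                for e_idx, nxt in adj.get(exit_node, ()):
                    seg_j, side_j = nxt
                    if nxt == entry0 and len(edges) == len(path) - 1:
                        # closing edge completes the alternating cycle
                        edges.append(e_idx)
                        segs = tuple(path)
                        rev = (segs[:1] + tuple(reversed(segs[1:])))
                        flip = tuple((s, FORWARD if o == REVERSE else REVERSE)
                                     for s, o in rev)
                        key = min(segs, flip)
                        if key not in seen:
                            seen.add(key)
                            results.append((list(path), list(edges)))
                        edges.pop()
                        continue
                    if seg_j in used or len(path) >= max_segments:
                        continue
                    if seg_j < start_seg:
                        continue        # anchored at the smallest segment index
                    used.add(seg_j)
                    path.append((seg_j, orientation(side_j)))
                    edges.append(e_idx)
                    dfs(other_side(nxt))
                    edges.pop()
                    path.pop()
                    used.remove(seg_j)

            dfs(other_side(entry0))
    return results


def _segment_depth_stats(intervals: Sequence[GenomicInterval],
                         tracks: Mapping[str, CoverageTrack],
                         cutoff: float) -> tuple[float, float]:
    """(depth_mean, high_coverage) over intervals, bin-resolution."""
    total_bp = 0
    total_depth = 0.0
    high_bp = 0
    for iv in intervals:
        track = tracks.get(iv.chrom)
        if track is None:
            continue
        bs = track.bin_size
        b0 = iv.start // bs
        b1 = (iv.end - 1) // bs + 1
        for b in range(b0, min(b1, track.values.size)):
            lo = max(iv.start, b * bs)
            hi = min(iv.end, (b + 1) * bs)
            span = hi - lo
            total_bp += span
            total_depth += span * track.values[b]
            if track.values[b] >= cutoff:
                high_bp += span
    if total_bp == 0:
        return 0.0, 0.0
    return total_depth / total_bp, high_bp / total_bp


def assemble_circles(segments: Sequence[GenomicInterval],
                     junctions: Sequence[BreakpointJunction],
                     config: DetectorConfig,
                     tracks: Mapping[str, CoverageTrack] | None = None,
                     depth_cutoff: float | None = None) -> list[EcDNACandidate]:
    """Emit every simple alternating cycle of the breakpoint graph as an
    ecDNA candidate, with boundaries refined to the junction positions and
    QC metrics computed from the coverage tracks."""
    graph = build_breakpoint_graph(segments, junctions, config)
    cycles = enumerate_cycles(graph, config.max_segments_per_circle)

    candidates = []
    for idx, (path, edge_ids) in enumerate(cycles):
        # per-node refined positions from the junction breakends
        node_pos: dict[tuple[int, str], int] = {}
        for e_idx in edge_ids:
            na, nb, j = graph.junction_edges[e_idx]
            # breakend_a maps to the node whose side matches and is nearest
            for be in (j.breakend_a, j.breakend_b):
                for node in (na, nb):
                    seg = graph.segments[node[0]]
                    if seg.chrom != be.chrom:
                        continue
                    if (be.side == RIGHT) != (node[1] == RIGHT):
                        continue
                    anchor = seg.end if node[1] == RIGHT else seg.start
                    if abs(anchor - be.position) <= config.snap_window:
                        prev = node_pos.get(node)
                        if prev is None or abs(anchor - be.position) < abs(anchor - prev):
                            node_pos[node] = be.position
        oriented = []
        for seg_idx, orient in path:
            seg = graph.segments[seg_idx]
            start = node_pos.get((seg_idx, LEFT), seg.start)
            end = node_pos.get((seg_idx, RIGHT), seg.end)
            if start >= end:        # inconsistent refinement; keep called bounds
                start, end = seg.start, seg.end
            oriented.append(OrientedSegment(GenomicInterval(seg.chrom, start, end), orient))
        intervals = [s.interval for s in oriented]
        if tracks is not None:
            cutoff = depth_cutoff if depth_cutoff is not None else config.depth_floor
            depth_mean, high_cov = _segment_depth_stats(intervals, tracks, cutoff)
        else:
            depth_mean, high_cov = 0.0, 0.0
        candidates.append(EcDNACandidate(
            id=f"ecdna_{idx:04d}",
            segments=oriented,
            junctions=[graph.junction_edges[e][2] for e in edge_ids],
            depth_mean=depth_mean,
            high_coverage=high_cov,
        ))
    candidates.sort(key=lambda c: (c.segments[0].interval.chrom,
                                   c.segments[0].interval.start, c.id))
    for i, c in enumerate(candidates):
        c.id = f"ecdna_{i:04d}"
    return candidates


def filter_candidates(candidates: Sequence[EcDNACandidate], config: DetectorConfig
                      ) -> list[EcDNACandidate]:
    """QC filter: size within [size_min, size_max], depth_mean above the
    floor and high_coverage above the minimum (both strict)."""
    return [
        c for c in candidates
        if config.size_min <= c.size <= config.size_max
        and c.depth_mean > config.min_depth_mean
        and c.high_coverage > config.min_high_coverage
    ]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _chunk_spans(length: int, chunk_size: int) -> Iterator[tuple[int, int]]:
    for s in range(0, length, chunk_size):
        yield s, min(s + chunk_size, length)


def detect_ecdna(alignment_file: str, config: DetectorConfig | None = None,
                 chrom_sizes: Mapping[str, int] | None = None
                 ) -> list[EcDNACandidate]:
    """Run the full pseudo-bulk detection pipeline on a coordinate-sorted,
    indexed alignment file.  Deterministic; output is independent of
    chunk_size (junctions are merged globally across chunks)."""
    config = config or DetectorConfig()
    with pysam.AlignmentFile(alignment_file) as bam:
        if not bam.has_index():
            raise ValueError(f"{alignment_file} has no index; sort and index it first")
        ref_names = list(bam.references)
        lengths = dict(zip(ref_names, bam.lengths))
        if chrom_sizes is not None:
            for chrom, size in chrom_sizes.items():
                if chrom in lengths and lengths[chrom] != size:
                    raise ValueError(
                        f"contradictory length for {chrom}: header {lengths[chrom]}, "
                        f"provided {size}")

        tracks: dict[str, CoverageTrack] = {}
        pairs: list[_PairEvidence] = []
        clips: list[ClipEvidence] = []
        n_no_mate = 0

        for chrom in ref_names:
            clen = lengths[chrom]
            values = np.zeros(math.ceil(clen / config.bin_size), dtype=float)
            for cs, ce in _chunk_spans(clen, config.chunk_size):
                for r in bam.fetch(chrom, cs, ce):
                    if r.flag & _SKIP_FLAGS:
                        continue
                    if r.reference_start < cs:
                        continue        # handled by the previous chunk
                    _add_coverage(values, r.reference_start, r.reference_end,
                                  config.bin_size, clen)
                    cig = r.cigartuples
                    if cig and (cig[0][0] == 4 or cig[-1][0] == 4):
                        clips.extend(clip_evidence_from_record(r, chrom))
                    if r.is_read1:
                        if not r.is_paired or r.mate_is_unmapped:
                            n_no_mate += 1
                            continue
                        ev = pair_evidence_from_record(r, ref_names, config)
                        if ev is not None:
                            pairs.append(ev)
            values /= config.bin_size
            tracks[chrom] = CoverageTrack(chrom, config.bin_size, values)

        if n_no_mate:
            log.info("skipped %d read1 records without mate information", n_no_mate)

    all_values = np.concatenate([t.values for t in tracks.values()])
    global_median = float(np.median(all_values))
    cutoff = amplified_threshold(global_median, config)
    log.info("global median depth %.2f, amplified cutoff %.2f", global_median, cutoff)

    segments: list[GenomicInterval] = []
    for chrom in ref_names:
        segments.extend(call_amplified_segments(tracks[chrom], config, global_median))

    junctions = cluster_breakend_pairs(pairs, config)
    junctions = refine_breakpoints_with_clips(junctions, clips, config)
    log.info("%d amplified segments, %d junctions (>= %d discordant pairs)",
             len(segments), len(junctions), config.min_discordant_support)

    candidates = assemble_circles(segments, junctions, config, tracks, cutoff)
    kept = filter_candidates(candidates, config)
    log.info("%d cycles assembled, %d pass QC filters", len(candidates), len(kept))
    return kept
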