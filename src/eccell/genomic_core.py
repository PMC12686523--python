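"""Coordinate-aware domain types shared by the whole pipeline.

All coordinates are 0-based half-open internally.  SAM records (1-based) and
human-readable interval strings such as ``chr7:51,000,001-56,000,000``
(1-based inclusive) are converted at I/O boundaries only.

Junction ``side`` semantics: ``side="right"`` means the amplified segment
continues to the *left* of the breakpoint position, i.e. the breakpoint sits
at a segment's 3' end on the forward strand; ``side="left"`` is the mirror
case.  This convention makes segment orientations round-trip unambiguously
through the breakpoint graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

FORWARD = "forward"
REVERSE = "reverse"
LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class OrientedSegment:
    interval: GenomicInterval
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    @property
    def strand(self) -> str:
        return "+" if self.orientation == FORWARD else "-"


@dataclass(frozen=True, order=True)
class Breakend:
    chrom: str
    position: int
    side: str

    def __post_init__(self) -> None:
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"side must be left/right, got {self.side!r}")


@dataclass(frozen=True)
class BreakpointJunction:
    """A putative adjacency between two breakends, with read evidence.

    Breakends are stored in canonical order (lexicographic by chrom, then
    position, then side) so equality and hashing are well-defined.
    """

    breakend_a: Breakend
    breakend_b: Breakend
    discordant_support: int = 0
    clip_support: int = 0

    def __post_init__(self) -> None:
        if self.discordant_support < 0 or self.clip_support < 0:
            raise ValueError("support counts must be non-negative")
        a, b = self.breakend_a, self.breakend_b
        if (b.chrom, b.position, b.side) < (a.chrom, a.position, a.side):
            object.__setattr__(self, "breakend_a", b)
            object.__setattr__(self, "breakend_b", a)

    def canonical(self) -> tuple:
        a, b = self.breakend_a, self.breakend_b
        return (a.chrom, a.position, a.side, b.chrom, b.position, b.side)


@dataclass
class EcDNACandidate:
    """An ordered, oriented circular amplicon with QC metrics."""

    id: str
    segments: list[OrientedSegment]
    junctions: list[BreakpointJunction]
    depth_mean: float = 0.0
    high_coverage: float = 0.0

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise ValueError("a candidate needs at least one segment")
        if len(self.junctions) != len(self.segments):
            raise ValueError(
                f"cycle invariant violated: {len(self.segments)} segments but "
                f"{len(self.junctions)} junctions"
            )
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not 0.0 <= self.high_coverage <= 1.0:
            raise ValueError("high_coverage must lie in [0, 1]")

    @property
    def size(self) -> int:
        return sum(seg.interval.size() for seg in self.segments)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [seg.interval for seg in self.segments]

    @property
    def discordant_support_total(self) -> int:
        return sum(j.discordant_support for j in self.junctions)


@dataclass
class BreakpointGraph:
    """Graph over segment ends: two nodes per amplified segment.

    Nodes are ``(segment_index, side)`` with side in {left, right}.
    ``segment_edges`` (implicit: left end <-> right end of each segment) form
    a perfect matching over the nodes; ``junction_edges`` connect ends of
    possibly distinct segments.
    """

    segments: list[GenomicInterval]
    junction_edges: list[tuple[tuple[int, str], tuple[int, str], BreakpointJunction]] = field(
        default_factory=list
    )

    @property
    def nodes(self) -> list[tuple[int, str]]:
        return [(i, side) for i in range(len(self.segments)) for side in (LEFT, RIGHT)]

    def add_junction(self, node_a: tuple[int, str], node_b: tuple[int, str],
                     junction: BreakpointJunction) -> None:
        valid = set(self.nodes)
        if node_a not in valid or node_b not in valid:
            raise ValueError("junction edge endpoint is not a node of the graph")
        self.junction_edges.append((node_a, node_b, junction))


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval], max_gap: int = 0
                    ) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``max_gap`` (per chromosome).

    The output is sorted, pairwise gaps exceed ``max_gap``, and the union of
    the output covers the union of the input.  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= max_gap:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(iv)
    return merged


def _total_bp(intervals: Sequence[GenomicInterval]) -> int:
    return sum(iv.size() for iv in merge_intervals(intervals))


def _intersection_bp(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    am = merge_intervals(a)
    bm = merge_intervals(b)
    total = 0
    for x in am:
        for y in bm:
            if x.chrom == y.chrom:
                total += max(0, min(x.end, y.end) - max(x.start, y.start))
    return total


def reciprocal_overlap(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> float:
    """min(|a&b|/|a|, |a&b|/|b|) over total base pairs; symmetric in a, b."""
    a = list(a)
    b = list(b)
    if not a or not b:
        raise ValueError("reciprocal_overlap requires two non-empty interval sets")
    inter = _intersection_bp(a, b)
    return min(inter / _total_bp(a), inter / _total_bp(b))


# ---------------------------------------------------------------------------
# external interfaces: candidate TSV + BED
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "id", "n_segments", "segments", "size",
    "depth_mean", "high_coverage", "discordant_support_total",
]


def _segments_to_str(segments: Sequence[OrientedSegment]) -> str:
    return ",".join(
        f"{s.interval.chrom}:{s.interval.start}-{s.interval.end}:{s.strand}"
        for s in segments
    )


def _segments_from_str(text: str) -> list[OrientedSegment]:
    out = []
    for token in text.split(","):
        loc, strand = token.rsplit(":", 1)
        chrom, span = loc.rsplit(":", 1)
        start, end = span.split("-")
        out.append(OrientedSegment(
            GenomicInterval(chrom, int(start), int(end)),
            FORWARD if strand == "+" else REVERSE,
        ))
    return out


def candidates_to_frame(candidates: Sequence[EcDNACandidate]) -> pd.DataFrame:
    rows = [
        {
            "id": c.id,
            "n_segments": len(c.segments),
            "segments": _segments_to_str(c.segments),
            "size": c.size,
            "depth_mean": c.depth_mean,
            "high_coverage": c.high_coverage,
            "discordant_support_total": c.discordant_support_total,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates_tsv(candidates: Sequence[EcDNACandidate], path: str) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str) -> list[EcDNACandidate]:
    """Read a candidate TSV back into (junction-less) candidate records.

    Junction evidence lives in the per-junction TSV; here a self-closing
    placeholder junction per segment keeps the cycle invariant satisfied.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        segments = _segments_from_str(row["segments"])
        junctions = [
            BreakpointJunction(
                Breakend(s.interval.chrom, s.interval.start, LEFT),
                Breakend(s.interval.chrom, s.interval.end, RIGHT),
            )
            for s in segments
        ]
        out.append(EcDNACandidate(
            id=str(row["id"]),
            segments=segments,
            junctions=junctions,
            depth_mean=float(row["depth_mean"]),
            high_coverage=float(row["high_coverage"]),
        ))
    return out


def write_candidates_bed(candidates: Sequence[EcDNACandidate], path: str) -> None:
    """BED6: one line per segment, candidate id in the name field."""
    with open(path, "w") as fh:
        for c in candidates:
            for seg in c.segments:
                fh.write(
                    f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}"
                    f"\t{c.id}\t0\t{seg.strand}\n"
                )


JUNCTION_COLUMNS = [
    "chrom_a", "pos_a", "side_a", "chrom_b", "pos_b", "side_b",
    "discordant_support", "clip_support",
]


def write_junctions_tsv(junctions: Sequence[BreakpointJunction], path: str) -> None:
    rows = [
        {
            "chrom_a": j.breakend_a.chrom, "pos_a": j.breakend_a.position,
            "side_a": j.breakend_a.side,
            "chrom_b": j.breakend_b.chrom, "pos_b": j.breakend_b.position,
            "side_b": j.breakend_b.side,
            "discordant_support": j.discordant_support,
            "clip_support": j.clip_support,
        }
        for j in junctions
    ]
    pd.DataFrame(rows, columns=JUNCTION_COLUMNS).to_csv(path, sep="\t", index=False)
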