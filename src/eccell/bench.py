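"""Evaluation harness: detection, mixture-classifier and cell-mixing
benchmarks against simulated truth, with shared scoring utilities.

All benchmark tables are reproducible row-for-row from (config, seed): every
stochastic entry point derives child seeds from the one passed in.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .cell_assign import (
    AssignConfig, assign_by_gmm, assign_ecdna, fit_two_component_gmm, log2_eccpm,
)
from .ecdna_sim import (
    CountMatrixBundle, SimMatrixConfig, SimReadConfig, SimStructureConfig,
    mix_cells, simulate_ecdna_structures, simulate_library, simulate_matrix_bundle,
)
from .genomic_core import EcDNACandidate, reciprocal_overlap
from .pseudobulk_detect import DetectorConfig, detect_ecdna

log = logging.getLogger("eccell")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision/recall/F1 with the convention 0 when undefined."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def binary_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int]:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    return tp, fp, fn


def match_detections(detected: Sequence[EcDNACandidate],
                     truth: Sequence[EcDNACandidate],
                     min_reciprocal: float = 0.5
                     ) -> tuple[int, int, int, list[tuple[int, int, float]]]:
    """Greedy 1-to-1 matching by descending reciprocal overlap.

    A (detection, truth) pair matches iff their segment sets overlap
    reciprocally by >= min_reciprocal; each side is used at most once.
    Returns (tp, fp, fn, matches) where matches holds (det_idx, truth_idx,
    overlap).  Order-invariant w.r.t. input permutations (ties broken by
    overlap, then indices).
    """
    scored = []
    for i, det in enumerate(detected):
        for j, tru in enumerate(truth):
            ov = reciprocal_overlap(det.intervals, tru.intervals)
            if ov >= min_reciprocal:
                scored.append((ov, i, j))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_det: set[int] = set()
    used_truth: set[int] = set()
    matches = []
    for ov, i, j in scored:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        matches.append((i, j, ov))
    tp = len(matches)
    fp = len(detected) - tp
    fn = len(truth) - tp
    return tp, fp, fn, matches


# ---------------------------------------------------------------------------
# detection benchmark (read-level simulation)
# ---------------------------------------------------------------------------

DESK_GENOME = {"chrB1": 25_000_000, "chrB2": 25_000_000,
               "chrB3": 25_000_000, "chrB4": 25_000_000}


def run_detection_benchmark(depths: Sequence[float],
                            n_circles: int = 24,
                            size_range: tuple[int, int] = (100_000, 1_000_000),
                            chrom_sizes: Mapping[str, int] | None = None,
                            background_depth: float = 4.0,
                            max_segments: int = 3,
                            min_reciprocal: float = 0.5,
                            seed: int = 0,
                            detector_config: DetectorConfig | None = None,
                            workdir: str | None = None,
                            depth_jitter: float = 0.0) -> pd.DataFrame:
    """Detection precision/recall/F1 over a grid of circle local depths.

    For each depth a fresh set of circles is planted on a clean synthetic
    background library, the detector runs with its default filters, and
    detections are scored against truth by greedy reciprocal-overlap
    matching.  ``depth_jitter`` > 0 draws per-circle depths uniformly from
    [depth, depth + depth_jitter].
    """
    chrom_sizes = dict(chrom_sizes or DESK_GENOME)
    rows = []
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir or tmp)
        base.mkdir(parents=True, exist_ok=True)
        for gi, depth in enumerate(depths):
            sub_seed = seed * 1000 + gi
            structures = simulate_ecdna_structures(SimStructureConfig(
                n_circles=n_circles, size_range=size_range,
                max_segments_per_circle=max_segments,
                reference=chrom_sizes, seed=sub_seed))
            rng = np.random.default_rng(sub_seed + 1)
            if depth_jitter > 0:
                circle_depths = rng.uniform(depth, depth + depth_jitter, n_circles)
            else:
                circle_depths = np.full(n_circles, float(depth))
            bam = str(base / f"lib_depth{gi}.bam")
            simulate_library(structures, SimReadConfig(
                background_depth=background_depth,
                circle_local_depth=circle_depths,
                barcodes=[f"BC{i:04d}" for i in range(64)],
                seed=sub_seed + 2,
            ), chrom_sizes, bam)
            detected = detect_ecdna(bam, detector_config)
            tp, fp, fn, _ = match_detections(detected, structures, min_reciprocal)
            precision, recall, f1 = precision_recall_f1(tp, fp, fn)
            rows.append(dict(experiment="detection", depth=float(depth),
                             seed=sub_seed, tp=tp, fp=fp, fn=fn,
                             precision=precision, recall=recall, f1=f1,
                             n_truth=len(structures), n_detected=len(detected)))
            log.info("detection depth %.0fx: P=%.3f R=%.3f F1=%.3f (%d det / %d truth)",
                     depth, precision, recall, f1, len(detected), len(structures))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixture-model benchmark (count-matrix simulation)
# ---------------------------------------------------------------------------

def classify_region_cells(bundle: CountMatrixBundle, region: np.ndarray,
                          pseudocount: float = 1.0) -> np.ndarray | None:
    """GMM classification of amplified cells for one simulated ecDNA region:
    per-cell log2 CPM over the region's bins, two-component fit, higher-mean
    responsibility > 0.5.  Returns None when the signal is degenerate."""
    in_region = bundle.X[region].sum(axis=0)
    totals = bundle.X.sum(axis=0)
    ok = totals > 0
    vals = np.array([
        log2_eccpm(int(c), int(t), pseudocount)
        for c, t in zip(in_region[ok], totals[ok])
    ])
    if np.ptp(vals) == 0:
        return None
    fit = fit_two_component_gmm(vals)
    labels = np.zeros(bundle.X.shape[1], dtype=bool)
    labels[ok] = assign_by_gmm(fit)
    return labels


def run_gmm_benchmark(base_cfg: SimMatrixConfig | None = None,
                      ms: Sequence[int] = (1, 2, 3, 4),
                      copy_ratios: Sequence[float] = (3, 5, 10, 20),
                      n_repeats: int | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Classifier metrics over the m x copy-ratio grid.

    For each grid cell and repeat: draw a sparse baseline over a genome-scale
    bin space, then for each simulated ecDNA region independently build the
    copy-number matrix (first m groups amplified at the copy ratio on that
    region's bins), simulate the Poisson counts, classify cells with the
    two-component GMM and score against the amplified-group truth; rows hold
    the per-region average of precision/recall/F1.
    """
    from .ecdna_sim import make_baseline_lambda

    base_cfg = base_cfg or SimMatrixConfig(n_ecdna=8)
    n_repeats = n_repeats if n_repeats is not None else base_cfg.n_repeats
    rows = []
    for m in ms:
        for ratio in copy_ratios:
            for rep in range(n_repeats):
                sub_seed = seed * 100_000 + m * 10_000 + int(ratio) * 100 + rep
                cfg = replace(base_cfg, m=m, copy_ratio=float(ratio), seed=sub_seed)
                lam, regions = make_baseline_lambda(cfg)
                lam_total = lam.sum(axis=0)
                group = cfg.n_cells // cfg.n_groups
                truth = np.zeros(cfg.n_cells, dtype=bool)
                truth[:m * group] = True
                rng = np.random.default_rng(sub_seed + 1)
                per_region = []
                for region in regions:
                    # the classifier consumes only per-cell region counts and
                    # totals; both are Poisson with exactly known means, so
                    # sample the sums directly (independent across regions)
                    lam_region = lam[region].sum(axis=0)
                    mean_region = cfg.sparse_fac * 2.0 * lam_region * \
                        np.where(truth, ratio, 1.0)
                    mean_rest = cfg.sparse_fac * 2.0 * (lam_total - lam_region)
                    in_region = rng.poisson(mean_region)
                    totals = in_region + rng.poisson(mean_rest)
                    ok = totals > 0
                    vals = np.log2((in_region[ok] + 1.0) / totals[ok] * 1e6)
                    labels = np.zeros(cfg.n_cells, dtype=bool)
                    if np.ptp(vals) > 0 and ok.sum() >= 10:
                        fit = fit_two_component_gmm(vals)
                        labels[ok] = assign_by_gmm(fit)
                    tp, fp, fn = binary_metrics(labels, truth)
                    per_region.append(precision_recall_f1(tp, fp, fn))
                if not per_region:
                    continue
                arr = np.array(per_region)
                rows.append(dict(
                    experiment="gmm", m=m, copy_ratio=float(ratio), repeat=rep,
                    seed=sub_seed, n_regions=len(per_region),
                    precision=float(arr[:, 0].mean()),
                    recall=float(arr[:, 1].mean()),
                    f1=float(arr[:, 2].mean()),
                ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixture-of-cells benchmark (full assignment path)
# ---------------------------------------------------------------------------

def fragments_from_bam(bam_path: str, max_insert: int = 2000) -> pd.DataFrame:
    """Fragment records from concordant read pairs (each pair is anchored at
    its leftmost mate; fragment span = template length)."""
    rows = {"chrom": [], "start": [], "end": [], "barcode": []}
    with pysam.AlignmentFile(bam_path) as bam:
        for r in bam.fetch():
            if (r.flag & 0x904) or r.mate_is_unmapped:
                continue
            tlen = r.template_length
            if tlen <= 0 or tlen > max_insert:
                continue
            if r.reference_id != r.next_reference_id:
                continue
            if not r.has_tag("CB"):
                continue
            rows["chrom"].append(r.reference_name)
            rows["start"].append(r.reference_start)
            rows["end"].append(r.reference_start + tlen)
            rows["barcode"].append(r.get_tag("CB"))
    df = pd.DataFrame(rows)
    df["support"] = 1
    return df


@dataclass
class MixturePopulations:
    """Fixed ecDNA+/- cell pools sharing one simulated library."""
    bam_path: str
    fragments: pd.DataFrame
    candidate: EcDNACandidate
    pop_pos: list[str]
    pop_neg: list[str]


def build_mixture_populations(n_pos: int = 700, n_neg: int = 700,
                              chrom_sizes: Mapping[str, int] | None = None,
                              circle_size: int = 300_000,
                              background_depth: float = 3.0,
                              circle_depth: float = 12.0,
                              workdir: str | None = None,
                              seed: int = 0) -> MixturePopulations:
    """One planted circle; positive cells contribute its local reads (and
    hence its discordant junction evidence), negatives only background."""
    chrom_sizes = dict(chrom_sizes or {"chrM1": 6_000_000})
    pop_pos = [f"POS{i:05d}" for i in range(n_pos)]
    pop_neg = [f"NEG{i:05d}" for i in range(n_neg)]
    structures = simulate_ecdna_structures(SimStructureConfig(
        n_circles=1, size_range=(circle_size, circle_size + 1),
        max_segments_per_circle=2, reference=chrom_sizes, seed=seed))
    workdir = workdir or tempfile.mkdtemp(prefix="eccell_mix_")
    bam = str(Path(workdir) / "mixture.bam")
    simulate_library(structures, SimReadConfig(
        background_depth=background_depth, circle_local_depth=circle_depth,
        barcodes=pop_pos + pop_neg,
        circle_membership={structures[0].id: pop_pos},
        seed=seed + 1,
    ), chrom_sizes, bam)
    fragments = fragments_from_bam(bam)
    return MixturePopulations(bam_path=bam, fragments=fragments,
                              candidate=structures[0],
                              pop_pos=pop_pos, pop_neg=pop_neg)


def run_mixture_benchmark(pops: MixturePopulations | None = None,
                          proportions: Sequence[float] = tuple(np.round(
                              np.arange(0.1, 0.95, 0.1), 2)),
                          n: int = 1000, repeats: int = 10,
                          assign_config: AssignConfig | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Classification metrics of the full assignment path on mixed
    ecDNA+/ecDNA- cell populations across a grid of positive proportions."""
    pops = pops or build_mixture_populations(seed=seed)
    rows = []
    for pi, prop in enumerate(proportions):
        for rep in range(repeats):
            sub_seed = seed * 10_000 + pi * 100 + rep
            cells, truth = mix_cells(pops.pop_pos, pops.pop_neg, prop, n=n,
                                     seed=sub_seed)
            cfg = assign_config or AssignConfig(n_boot=200)
            cfg = replace(cfg, seed=sub_seed)
            result = assign_ecdna(pops.fragments, pops.bam_path, pops.candidate,
                                  cells, config=cfg)
            idx = {bc: i for i, bc in enumerate(cells)}
            pred = np.zeros(len(cells), dtype=bool)
            for bc, lab in zip(result.barcodes, result.labels):
                pred[idx[bc]] = lab
            covered = np.array([bc in set(result.barcodes) for bc in cells])
            tp, fp, fn = binary_metrics(pred[covered], truth[covered])
            precision, recall, f1 = precision_recall_f1(tp, fp, fn)
            rows.append(dict(experiment="mixture", proportion=float(prop),
                             repeat=rep, seed=sub_seed, method=result.method,
                             tp=tp, fp=fp, fn=fn,
                             precision=precision, recall=recall, f1=f1))
    return pd.DataFrame(rows)
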