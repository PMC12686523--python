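"""Assigning an ecDNA candidate to individual cells.

Per-cell accessibility within the candidate region is summarised as
log2(ecCPM) = log2((reads within ecDNA + pseudocount) / all mapped reads x 1e6).
Hartigan's dip test decides whether that signal is multimodal: if it is, a
two-component Gaussian mixture is fitted by EM and cells with high posterior
for the higher-mean component are called ecDNA+; otherwise k-means (k=2) on
a gene-level accessibility score matrix of genes located on the candidate is
used.  Cells carrying discordant/clipped reads at the candidate junctions
form a gold-standard set, and a one-sided Fisher's exact test checks that
predicted ecDNA+ cells are enriched for them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.cluster import KMeans

from .genomic_core import (
    LEFT, RIGHT, BreakpointJunction, EcDNACandidate, GenomicInterval,
    merge_intervals,
)
from .pseudobulk_detect import (
    DetectorConfig, _SKIP_FLAGS, clip_evidence_from_record, pair_evidence_from_record,
)

log = logging.getLogger("eccell")


# ---------------------------------------------------------------------------
# per-cell signals
# ---------------------------------------------------------------------------

@dataclass
class CellSignal:
    barcode: str
    reads_in_ecdna: int
    total_reads: int
    log2_eccpm: float

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if not 0 <= self.reads_in_ecdna <= self.total_reads:
            raise ValueError("need 0 <= reads_in_ecdna <= total_reads")


def log2_eccpm(reads_in: int, total: int, pseudocount: float = 1.0) -> float:
    return math.log2((reads_in + pseudocount) / total * 1e6)


def _overlap_mask(frag: pd.DataFrame, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    mask = np.zeros(len(frag), dtype=bool)
    for iv in merge_intervals(intervals):
        mask |= ((frag["chrom"].values == iv.chrom)
                 & (frag["start"].values < iv.end)
                 & (frag["end"].values > iv.start))
    return mask


def compute_cell_signals(fragments: pd.DataFrame, ecdna: EcDNACandidate,
                         whitelist: Sequence[str], pseudocount: float = 1.0
                         ) -> list[CellSignal]:
    """Per-barcode read counts and log2 ecCPM within the candidate region.

    Barcodes are restricted to the whitelist of qualified cells; cells with
    zero total fragments are excluded.  A fragment counts if it overlaps any
    candidate segment; each fragment record counts once (the support column
    is not used as a weight).
    """
    whitelist = list(whitelist)
    if not whitelist:
        raise ValueError("whitelist of qualified barcodes is empty")
    wset = set(whitelist)
    frag = fragments[fragments["barcode"].isin(wset)]
    totals = frag.groupby("barcode").size()
    inside = frag[_overlap_mask(frag, ecdna.intervals)].groupby("barcode").size()
    out = []
    for bc in whitelist:
        total = int(totals.get(bc, 0))
        if total == 0:
            continue
        n_in = int(inside.get(bc, 0))
        out.append(CellSignal(bc, n_in, total, log2_eccpm(n_in, total, pseudocount)))
    return out


def signals_frame(signals: Sequence[CellSignal]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.barcode, s.reads_in_ecdna, s.total_reads, s.log2_eccpm) for s in signals],
        columns=["barcode", "reads_in_ecdna", "total_reads", "log2_eccpm"],
    )


# ---------------------------------------------------------------------------
# Hartigan dip statistic and Monte-Carlo dip test
# ---------------------------------------------------------------------------

def _distinct_cdf(x_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct sample values with the empirical CDF's left limits (flo) and
    values (fhi) at each."""
    n = x_sorted.size
    ux, first = np.unique(x_sorted, return_index=True)
    last = np.concatenate([first[1:], [n]])
    return ux, first / n, last / n


@njit
def _convex_misfit(ux, flo, fhi, j):
    """Misfit of the best convex (left-flank) fit to F on ux[0..j], the mode
    sitting at ux[j] where only the CDF's left limit constrains the fit.

    A convex non-decreasing G within sup-distance d of F on (-inf, ux_j]
    exists iff the lower convex hull of the left-limit values (ux_t, flo_t)
    clears fhi_t - 2d at every t < j (and flo_j - 2d at the mode); the
    minimal d is half the largest such gap.
    """
    hx = np.empty(j + 1)
    hy = np.empty(j + 1)
    hs = 0
    for i in range(j + 1):
        while hs >= 2:
            # pop the top if slope(top-1, top) >= slope(top, i)
            if (hy[hs - 1] - hy[hs - 2]) * (ux[i] - hx[hs - 1]) >= \
                    (flo[i] - hy[hs - 1]) * (hx[hs - 1] - hx[hs - 2]):
                hs -= 1
            else:
                break
        hx[hs] = ux[i]
        hy[hs] = flo[i]
        hs += 1
    gap = 0.0
    seg = 0
    for t in range(j + 1):
        while seg < hs - 1 and hx[seg + 1] < ux[t]:
            seg += 1
        if seg < hs - 1 and hx[seg + 1] > hx[seg]:
            fit = hy[seg] + (hy[seg + 1] - hy[seg]) * (ux[t] - hx[seg]) \
                / (hx[seg + 1] - hx[seg])
        else:
            fit = hy[seg]
        target = fhi[t] if t < j else flo[j]
        if target - fit > gap:
            gap = target - fit
    return gap / 2.0


@njit
def _concave_misfit(ux, flo, fhi, j):
    """Mirror image of :func:`_convex_misfit` for the right flank ux[j..]."""
    m = len(ux) - j
    hx = np.empty(m)
    hy = np.empty(m)
    hs = 0
    for i in range(j, len(ux)):
        while hs >= 2:
            if (hy[hs - 1] - hy[hs - 2]) * (ux[i] - hx[hs - 1]) <= \
                    (fhi[i] - hy[hs - 1]) * (hx[hs - 1] - hx[hs - 2]):
                hs -= 1
            else:
                break
        hx[hs] = ux[i]
        hy[hs] = fhi[i]
        hs += 1
    gap = 0.0
    seg = 0
    for t in range(j, len(ux)):
        while seg < hs - 1 and hx[seg + 1] < ux[t]:
            seg += 1
        if seg < hs - 1 and hx[seg + 1] > hx[seg]:
            fit = hy[seg] + (hy[seg + 1] - hy[seg]) * (ux[t] - hx[seg]) \
                / (hx[seg + 1] - hx[seg])
        else:
            fit = hy[seg]
        target = flo[t] if t > j else fhi[j]
        if fit - target > gap:
            gap = fit - target
    return gap / 2.0


@njit
def _h_min(ux, flo, fhi, j, d):
    """Minimal achievable left limit G(ux_j^-) over convex non-decreasing
    fits of the left flank within tube half-width d (convexity forces the
    end value up via chords through earlier tube boxes)."""
    h = flo[j] - d
    for t in range(j):
        a_t = fhi[t] - d
        if a_t > h:
            h = a_t
    for t in range(1, j):
        a_t = fhi[t] - d
        smax = -np.inf
        for i in range(t):
            s = (a_t - (flo[i] + d)) / (ux[t] - ux[i])
            if s > smax:
                smax = s
        cand = a_t + smax * (ux[j] - ux[t])
        if cand > h:
            h = cand
    return h


@njit
def _g_max(ux, flo, fhi, j, d):
    """Maximal achievable value G(ux_j) over concave non-decreasing fits of
    the right flank within tube half-width d."""
    m = len(ux)
    g = fhi[j] + d
    for t in range(j + 1, m):
        b_t = flo[t] + d
        if b_t < g:
            g = b_t
    for t in range(j + 1, m - 1):
        b_t = flo[t] + d
        smax = -np.inf
        for i in range(t + 1, m):
            s = (b_t - (fhi[i] - d)) / (ux[t] - ux[i])
            if s > smax:
                smax = s
        cand = b_t + smax * (ux[j] - ux[t])
        if cand < g:
            g = cand
    return g


def dip_statistic(values: Sequence[float]) -> float:
    """Hartigan & Hartigan's dip: the maximum deviation of the empirical CDF
    from the closest unimodal CDF.

    For each candidate mode value, the best convex fit to the left flank and
    the best concave fit to the right flank are computed via the greatest
    convex minorant / least concave majorant of the empirical CDF (CDF jumps
    enter through their left limits).  The left misfit is non-decreasing and
    the right misfit non-increasing in the mode position, so the crossing is
    located by bisection; modes are then examined outward in ascending
    flank-misfit order until the two flank fits are mutually compatible
    (the convex fit can end below where the concave fit starts).  Satisfies
    1/(2n) <= dip <= 0.25, with equality at 1/(2n) for equally spaced points.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("dip statistic needs at least 4 values")
    if not np.isfinite(x).all():
        raise ValueError("dip statistic needs finite values")
    if x[0] == x[-1]:
        raise ValueError("dip statistic is undefined for constant data")

    ux, flo, fhi = _distinct_cdf(x)
    m = len(ux)
    if m == 1:      # unreachable given the constant-data guard
        return 1.0 / (2 * n)

    def left(j: int) -> float:
        return _convex_misfit(ux, flo, fhi, j)

    def right(j: int) -> float:
        return _concave_misfit(ux, flo, fhi, j)

    def flank(j: int) -> float:
        return max(left(j), right(j))

    def compatible(j: int, d: float) -> bool:
        return _h_min(ux, flo, fhi, j, d) <= _g_max(ux, flo, fhi, j, d) + 1e-12

    # bisect the crossing of the monotone flank misfits
    lo, hi = 0, m - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if left(mid) >= right(mid):
            hi = mid
        else:
            lo = mid

    # walk outward in ascending flank-misfit order until compatible
    lval, rval = flank(lo), flank(hi)
    best = None
    while lo >= 0 or hi <= m - 1:
        if hi > m - 1 or (lo >= 0 and lval <= rval):
            j, d = lo, lval
            lo -= 1
            lval = flank(lo) if lo >= 0 else np.inf
        else:
            j, d = hi, rval
            hi += 1
            rval = flank(hi) if hi <= m - 1 else np.inf
        if compatible(j, d):
            best = d
            break
    if best is None:        # theoretically unreachable; be safe
        best = min(flank(j) for j in range(m))
    return float(best)


def dip_test(values: Sequence[float], n_boot: int = 2000, seed: int = 0
             ) -> tuple[float, float]:
    """Monte-Carlo dip test of unimodality.

    The null distribution is simulated from uniform(0,1) samples of the same
    size (the dip depends on the data only through ranks, so any continuous
    unimodal null gives the same reference distribution asymptotically).
    Returns (p_value, dip).
    """
    observed = dip_statistic(values)
    n = len(values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        if dip_statistic(rng.random(n)) >= observed:
            count += 1
    return count / n_boot, observed


# ---------------------------------------------------------------------------
# two-component Gaussian mixture (EM)
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    w: float                    # weight of component 1 (the lower-mean one)
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    responsibilities: np.ndarray   # per-cell posterior for component 2
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if not 0 < self.w < 1:
            raise ValueError("component weight must lie in (0, 1)")
        if self.mu1 > self.mu2:
            raise ValueError("components must be ordered mu1 <= mu2")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component SDs must be positive")
        r = np.asarray(self.responsibilities)
        if ((r < 0) | (r > 1)).any():
            raise ValueError("responsibilities must lie in [0, 1]")


def _split_1d_kmeans(x_sorted: np.ndarray) -> int:
    """Exact 1-D 2-means: the split index minimising within-cluster SSE."""
    n = x_sorted.size
    csum = np.concatenate([[0.0], np.cumsum(x_sorted)])
    csq = np.concatenate([[0.0], np.cumsum(x_sorted ** 2)])
    ks = np.arange(1, n)
    sse_left = csq[ks] - csum[ks] ** 2 / ks
    sse_right = (csq[n] - csq[ks]) - (csum[n] - csum[ks]) ** 2 / (n - ks)
    return int(ks[np.argmin(sse_left + sse_right)])


def _log_normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)


def fit_two_component_gmm(values: Sequence[float], sigma_floor: float = 1e-3,
                          tol: float = 1e-8, max_iter: int = 1000,
                          seed: int = 0) -> MixtureFit:
    """EM fit of w*N(mu1, sigma1^2) + (1-w)*N(mu2, sigma2^2).

    Initialised from the exact 1-D 2-means partition; converges when the
    relative log-likelihood change drops below ``tol``.  The log-likelihood
    is non-decreasing across iterations.  Components are reported with
    mu1 <= mu2 and responsibilities for the higher-mean component.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("mixture fit needs at least 10 values")
    if not np.isfinite(x).all():
        raise ValueError("mixture fit needs finite values")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: no mixture structure")

    xs = np.sort(x)
    k = _split_1d_kmeans(xs)
    mu = np.array([xs[:k].mean(), xs[k:].mean()])
    sigma = np.maximum([xs[:k].std(), xs[k:].std()], sigma_floor)
    w = np.array([k / x.size, 1 - k / x.size])
    w = np.clip(w, 1e-6, 1 - 1e-6)
    w /= w.sum()

    loglik_prev = -np.inf
    trace = []
    resp2 = np.zeros_like(x)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        logp = np.stack([
            np.log(w[0]) + _log_normal_pdf(x, mu[0], sigma[0]),
            np.log(w[1]) + _log_normal_pdf(x, mu[1], sigma[1]),
        ])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        loglik = float(lse.sum())
        trace.append(loglik)
        resp = np.exp(logp - lse)
        resp2 = resp[1]
        if loglik - loglik_prev <= tol * max(1.0, abs(loglik)) and n_iter > 1:
            break
        loglik_prev = loglik
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = np.clip(nk / x.size, 1e-6, 1 - 1e-6)
        w /= w.sum()
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        sigma = np.maximum(np.sqrt(var), sigma_floor)

    if mu[0] > mu[1]:
        mu = mu[::-1]
        sigma = sigma[::-1]
        w = w[::-1]
        resp2 = 1.0 - resp2

    return MixtureFit(
        w=float(w[0]), mu1=float(mu[0]), mu2=float(mu[1]),
        sigma1=float(sigma[0]), sigma2=float(sigma[1]),
        loglik=float(trace[-1]), responsibilities=resp2, n_iter=n_iter,
        loglik_trace=np.asarray(trace),
    )


def assign_by_gmm(fit: MixtureFit, threshold: float = 0.5) -> np.ndarray:
    """ecDNA+ iff the posterior for the higher-mean component exceeds the
    threshold (strict inequality)."""
    return np.asarray(fit.responsibilities) > threshold


# ---------------------------------------------------------------------------
# gene scores and k-means fallback
# ---------------------------------------------------------------------------

def gene_score_matrix(fragments: pd.DataFrame,
                      genes: Sequence[tuple[str, GenomicInterval, str]],
                      whitelist: Sequence[str],
                      promoter_ext: int = 2000) -> pd.DataFrame:
    """Cells x genes accessibility scores.

    score(cell, gene) = log2(1 + CPM of fragments overlapping the gene body
    extended ``promoter_ext`` bp upstream), standardised per gene (zero mean,
    unit variance across cells).  Genes with zero fragments in all cells are
    dropped (logged).  This is a deliberately simple gene-level summary of
    local accessibility, not a re-implementation of any specific toolkit's
    distance-weighted model.
    """
    if not genes:
        raise ValueError("gene list is empty")
    whitelist = list(whitelist)
    frag = fragments[fragments["barcode"].isin(set(whitelist))]
    totals = frag.groupby("barcode").size().reindex(whitelist).fillna(0)
    totals = np.maximum(totals.values.astype(float), 1.0)

    cols = {}
    dropped = []
    for name, iv, strand in genes:
        if strand == "-":
            region = GenomicInterval(iv.chrom, iv.start, iv.end + promoter_ext)
        else:
            region = GenomicInterval(iv.chrom, max(0, iv.start - promoter_ext), iv.end)
        sel = frag[(frag["chrom"] == region.chrom)
                   & (frag["start"] < region.end)
                   & (frag["end"] > region.start)]
        counts = sel.groupby("barcode").size().reindex(whitelist).fillna(0).values
        if counts.sum() == 0:
            dropped.append(name)
            continue
        cpm = counts / totals * 1e6
        score = np.log2(1.0 + cpm)
        sd = score.std()
        cols[name] = (score - score.mean()) / sd if sd > 0 else score - score.mean()
    if dropped:
        log.info("dropped %d gene columns with zero fragments: %s",
                 len(dropped), ", ".join(dropped[:5]))
    if not cols:
        raise ValueError("no gene has any overlapping fragment")
    return pd.DataFrame(cols, index=whitelist)


def kmeans_assign(scores: pd.DataFrame | np.ndarray, k: int = 2,
                  n_restarts: int = 10, seed: int = 0) -> np.ndarray:
    """Best-of-restarts k-means partition of the score matrix; the cluster
    with the higher mean row-sum is called ecDNA+ (boolean per row)."""
    mat = scores.values if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("scores must be a cells x genes matrix")
    if mat.shape[0] < k:
        raise ValueError(f"need at least {k} cells for k-means with k={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(mat)
    row_sums = mat.sum(axis=1)
    means = [row_sums[labels == c].mean() for c in range(k)]
    positive_cluster = int(np.argmax(means))
    return labels == positive_cluster


# ---------------------------------------------------------------------------
# discordant gold standard and Fisher's exact test
# ---------------------------------------------------------------------------

def extract_discordant_barcodes(alignment_file: str,
                                junctions: Sequence[BreakpointJunction],
                                window: int = 500,
                                config: DetectorConfig | None = None) -> set[str]:
    """Barcodes owning >= 1 discordant pair or clipped read whose breakend
    falls within ``window`` of any candidate junction (set semantics)."""
    import pysam

    config = config or DetectorConfig()
    breakends = [be for j in junctions for be in (j.breakend_a, j.breakend_b)]
    gold: set[str] = set()
    with pysam.AlignmentFile(alignment_file) as bam:
        ref_names = list(bam.references)
        lengths = dict(zip(ref_names, bam.lengths))
        seen_regions = set()
        for be in breakends:
            if be.chrom not in lengths:
                continue
            lo = max(0, be.position - window - 200)
            hi = min(lengths[be.chrom], be.position + window + 200)
            key = (be.chrom, lo // 1000, hi // 1000)
            if key in seen_regions:
                continue
            seen_regions.add(key)
            for r in bam.fetch(be.chrom, lo, hi):
                if r.flag & _SKIP_FLAGS or not r.has_tag("CB"):
                    continue
                chrom = ref_names[r.reference_id]
                for c in clip_evidence_from_record(r, chrom):
                    if _near_any(c.chrom, c.position, breakends, window):
                        gold.add(r.get_tag("CB"))
                        break
                else:
                    if r.is_paired and not r.mate_is_unmapped:
                        ev = pair_evidence_from_record(r, ref_names, config)
                        if ev is not None and (
                            _near_any(ev.breakend_a.chrom, ev.breakend_a.position,
                                      breakends, window)
                            or _near_any(ev.breakend_b.chrom, ev.breakend_b.position,
                                         breakends, window)):
                            gold.add(r.get_tag("CB"))
    return gold


def _near_any(chrom: str, pos: int, breakends: Sequence, window: int) -> bool:
    return any(be.chrom == chrom and abs(be.position - pos) <= window
               for be in breakends)


def fisher_exact(table: Sequence[Sequence[int]], alternative: str = "greater"
                 ) -> tuple[float, float]:
    """Exact hypergeometric tail probability plus the sample odds ratio
    (a*d)/(b*c), reported as inf when b*c = 0 and a*d > 0, and nan (flagged
    undefined) when a row or column margin is zero (p = 1 then)."""
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0, float("nan")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
    return p, odds


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class AssignConfig:
    alpha: float = 0.05
    n_boot: int = 2000
    pseudocount: float = 1.0
    gmm_threshold: float = 0.5
    sigma_floor: float = 1e-3
    promoter_ext: int = 2000
    kmeans_restarts: int = 10
    discordant_window: int = 500
    min_cells: int = 10
    n_pseudo_genes: int = 10
    seed: int = 0


@dataclass
class AssignmentResult:
    barcodes: list[str]
    labels: np.ndarray              # True = ecDNA+
    method: str                     # "gmm" or "kmeans"
    dip_p: float
    fisher_p: float
    odds_ratio: float
    gold_standard_barcodes: set[str]
    signals: list[CellSignal]
    mixture: MixtureFit | None = None

    def __post_init__(self) -> None:
        if self.method not in ("gmm", "kmeans"):
            raise ValueError("method must be gmm or kmeans")
        if len(self.labels) != len(self.barcodes):
            raise ValueError("labels must cover exactly the input barcodes")

    def to_frame(self) -> pd.DataFrame:
        df = signals_frame(self.signals)
        df["label"] = np.where(self.labels, "ecDNA+", "ecDNA-")
        if self.mixture is not None:
            df["responsibility"] = self.mixture.responsibilities
        return df


def _pseudo_genes(candidate: EcDNACandidate, n: int
                  ) -> list[tuple[str, GenomicInterval, str]]:
    """Tile the candidate segments into n roughly equal windows, used as
    score features when no gene annotation is supplied."""
    genes = []
    total = candidate.size
    per_seg = [max(1, round(n * s.interval.size() / total)) for s in candidate.segments]
    for seg, k in zip(candidate.segments, per_seg):
        iv = seg.interval
        edges = np.linspace(iv.start, iv.end, k + 1).astype(int)
        for i in range(k):
            if edges[i + 1] > edges[i]:
                genes.append((f"{iv.chrom}:{edges[i]}",
                              GenomicInterval(iv.chrom, int(edges[i]), int(edges[i + 1])),
                              "+"))
    return genes


def assign_ecdna(fragments: pd.DataFrame, alignment_file: str | None,
                 candidate: EcDNACandidate, whitelist: Sequence[str],
                 config: AssignConfig | None = None,
                 genes: Sequence[tuple[str, GenomicInterval, str]] | None = None
                 ) -> AssignmentResult:
    """Full assignment pipeline for one candidate.

    Computes per-cell signals, tests multimodality of log2 ecCPM, labels
    cells by GMM (dip p < alpha) or by k-means on gene scores otherwise,
    extracts discordant gold-standard barcodes from the alignment file, and
    tests their enrichment among predicted ecDNA+ cells (one-sided Fisher).
    """
    config = config or AssignConfig()
    signals = compute_cell_signals(fragments, candidate, whitelist,
                                   pseudocount=config.pseudocount)
    if len(signals) < config.min_cells:
        raise ValueError(
            f"only {len(signals)} qualified cells with signal; "
            f"need >= {config.min_cells} for assignment")
    barcodes = [s.barcode for s in signals]
    vals = np.array([s.log2_eccpm for s in signals])

    dip_p, _ = dip_test(vals, n_boot=config.n_boot, seed=config.seed)
    mixture = None
    if dip_p < config.alpha:
        method = "gmm"
        mixture = fit_two_component_gmm(vals, sigma_floor=config.sigma_floor,
                                        seed=config.seed)
        labels = assign_by_gmm(mixture, threshold=config.gmm_threshold)
    else:
        method = "kmeans"
        feature_genes = genes or _pseudo_genes(candidate, config.n_pseudo_genes)
        on_ecdna = [g for g in feature_genes
                    if any(g[1].overlaps(iv) for iv in candidate.intervals)]
        scores = gene_score_matrix(fragments, on_ecdna or feature_genes, barcodes,
                                   promoter_ext=config.promoter_ext)
        labels = kmeans_assign(scores, k=2, n_restarts=config.kmeans_restarts,
                               seed=config.seed)

    if alignment_file is not None:
        gold = extract_discordant_barcodes(
            alignment_file, candidate.junctions,
            window=config.discordant_window)
        gold &= set(barcodes)
    else:
        gold = set()
    in_gold = np.array([bc in gold for bc in barcodes])
    a = int((labels & in_gold).sum())
    b = int((labels & ~in_gold).sum())
    c = int((~labels & in_gold).sum())
    d = int((~labels & ~in_gold).sum())
    fisher_p, odds = fisher_exact([[a, b], [c, d]], alternative="greater")

    return AssignmentResult(
        barcodes=barcodes, labels=np.asarray(labels, dtype=bool), method=method,
        dip_p=dip_p, fisher_p=fisher_p, odds_ratio=odds,
        gold_standard_barcodes=gold, signals=signals, mixture=mixture,
    )
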