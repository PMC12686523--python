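import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from eccell.cell_assign import (
    AssignConfig, CellSignal, assign_by_gmm, assign_ecdna, compute_cell_signals,
    dip_statistic, dip_test, extract_discordant_barcodes, fisher_exact,
    fit_two_component_gmm, gene_score_matrix, kmeans_assign, log2_eccpm,
)
from eccell.genomic_core import GenomicInterval


# ---------------------------------------------------------------------------
# per-cell signals
# ---------------------------------------------------------------------------

def make_fragments(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "support"])


def make_candidate(chrom="chr1", start=1_000_000, end=1_200_000):
    from eccell.genomic_core import (Breakend, BreakpointJunction,
                                     EcDNACandidate, OrientedSegment)
    seg = OrientedSegment(GenomicInterval(chrom, start, end))
    jx = BreakpointJunction(Breakend(chrom, start, "left"),
                            Breakend(chrom, end, "right"))
    return EcDNACandidate("cand", [seg], [jx], depth_mean=10, high_coverage=0.9)


class TestCellSignals:
    def test_formula_anchors(self):
        assert log2_eccpm(100, 10**6, pseudocount=0) == pytest.approx(math.log2(100))
        assert log2_eccpm(0, 10**6, pseudocount=1) == 0.0

    def test_matches_group_by_counting_oracle(self):
        rng = np.random.default_rng(0)
        barcodes = [f"B{i}" for i in range(12)]
        rows = []
        for _ in range(600):
            bc = barcodes[int(rng.integers(12))]
            start = int(rng.integers(0, 2_000_000))
            rows.append(("chr1", start, start + 100, bc, 1))
        frag = make_fragments(rows)
        cand = make_candidate()
        signals = compute_cell_signals(frag, cand, barcodes)
        # naive oracle
        for s in signals:
            sub = [r for r in rows if r[3] == s.barcode]
            inside = [r for r in sub if r[1] < 1_200_000 and r[2] > 1_000_000]
            assert s.total_reads == len(sub)
            assert s.reads_in_ecdna == len(inside)
            assert s.log2_eccpm == pytest.approx(
                math.log2((len(inside) + 1) / len(sub) * 1e6))

    def test_monotone_in_reads_inside(self):
        vals = [log2_eccpm(k, 10_000) for k in range(0, 50, 5)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            compute_cell_signals(make_fragments([]), make_candidate(), [])

    def test_zero_total_cells_excluded(self):
        frag = make_fragments([("chr1", 0, 100, "A", 1)])
        signals = compute_cell_signals(frag, make_candidate(), ["A", "B"])
        assert [s.barcode for s in signals] == ["A"]

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CellSignal("x", 5, 4, 0.0)
        with pytest.raises(ValueError):
            CellSignal("x", 0, 0, 0.0)


# ---------------------------------------------------------------------------
# dip statistic: LP oracle straight from the definition
# ---------------------------------------------------------------------------

def dip_lp_oracle(values):
    """min over unimodal CDFs G of sup|F_n - G| via one LP per candidate mode
    (distinct value with an atom allowed there): variables are G at distinct
    values plus the left limit at the mode; convex slopes before the mode,
    concave after; two-sided tube constraints implement the CDF jumps."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    ux, first = np.unique(x, return_index=True)
    last = np.concatenate([first[1:], [n]])
    flo, fhi = first / n, last / n
    m = len(ux)
    best = np.inf
    for J in range(m):
        nv = m + 2
        H, D = m, m + 1
        A, b = [], []

        def le(coeffs, rhs):
            row = np.zeros(nv)
            for idx, cc in coeffs:
                row[idx] += cc
            A.append(row)
            b.append(rhs)

        for t in range(m - 1):
            le([(t, 1), (t + 1, -1)], 0)
        if J > 0:
            le([(J - 1, 1), (H, -1)], 0)
        le([(H, 1), (J, -1)], 0)
        for t in range(m):
            if t == J:
                le([(t, 1), (D, -1)], fhi[t])
                le([(t, -1), (D, -1)], -fhi[t])
            else:
                le([(t, -1), (D, -1)], -fhi[t])
                le([(t, 1), (D, -1)], flo[t])
        le([(H, 1), (D, -1)], flo[J])
        le([(H, -1), (D, -1)], -flo[J])
        chain = [(ux[t], t) for t in range(J)] + [(ux[J], H)]
        for i in range(len(chain) - 2):
            (x1, v1), (x2, v2), (x3, v3) = chain[i], chain[i + 1], chain[i + 2]
            le([(v2, (x3 - x2) + (x2 - x1)), (v1, -(x3 - x2)), (v3, -(x2 - x1))], 0)
        chain = [(ux[t], t) for t in range(J, m)]
        for i in range(len(chain) - 2):
            (x1, v1), (x2, v2), (x3, v3) = chain[i], chain[i + 1], chain[i + 2]
            le([(v2, -((x3 - x2) + (x2 - x1))), (v1, (x3 - x2)), (v3, (x2 - x1))], 0)
        res = linprog(np.eye(nv)[D], A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * (m + 1) + [(0, 0.5)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


class TestDipStatistic:
    @pytest.mark.parametrize("n", [4, 7, 25, 100])
    def test_equally_spaced_attains_lower_bound(self, n):
        assert dip_statistic(np.arange(1, n + 1)) == pytest.approx(1 / (2 * n))

    def test_two_point_masses_attain_maximum(self):
        assert dip_statistic([0.0] * 50 + [10.0] * 50) == pytest.approx(0.25)

    def test_bounds_hold_on_random_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 300))
            d = dip_statistic(rng.normal(size=n))
            assert 1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    def test_invariance_under_affine_maps(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        d = dip_statistic(x)
        assert dip_statistic(3.5 * x - 7) == pytest.approx(d)
        assert dip_statistic(-x) == pytest.approx(d)

    def test_matches_lp_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(24):
            kind = trial % 4
            n = int(rng.integers(5, 14))
            if kind == 0:
                x = rng.normal(size=n)
            elif kind == 1:
                x = np.concatenate([rng.normal(-4, 0.5, n), rng.normal(4, 0.5, n)])
            elif kind == 2:
                x = rng.uniform(size=n)
            else:
                x = np.round(rng.normal(size=n), 1)    # with ties
            if len(np.unique(x)) < 2:
                continue
            assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-7)

    def test_small_or_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            dip_statistic([5.0] * 10)


class TestDipTest:
    def test_unimodal_sample_not_rejected(self):
        rng = np.random.default_rng(4)
        p, _ = dip_test(rng.normal(size=500), n_boot=200, seed=0)
        assert p > 0.05

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(8, 1, 250)])
        p, _ = dip_test(x, n_boot=200, seed=0)
        assert p < 0.05

    def test_seeded_and_reproducible(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        assert dip_test(x, n_boot=100, seed=7) == dip_test(x, n_boot=100, seed=7)


# ---------------------------------------------------------------------------
# two-component mixture
# ---------------------------------------------------------------------------

class TestGmm:
    def test_separated_clusters(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.05, 400), rng.normal(5, 0.05, 600)])
        fit = fit_two_component_gmm(x)
        assert fit.w == pytest.approx(0.4, abs=0.02)
        assert fit.mu1 == pytest.approx(0, abs=0.05)
        assert fit.mu2 == pytest.approx(5, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parameter_recovery(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(round(0.6 * 2000))
        x = np.concatenate([rng.normal(0, 1, n1), rng.normal(5, 1, 2000 - n1)])
        fit = fit_two_component_gmm(x)
        assert abs(fit.mu1 - 0) < 0.2
        assert abs(fit.mu2 - 5) < 0.2
        assert abs(fit.w - 0.6) < 0.05
        assert abs(fit.sigma1 - 1) < 0.2 and abs(fit.sigma2 - 1) < 0.2

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(2.5, 1.5, 300)])
        fit = fit_two_component_gmm(x)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(4, 1, 200)])
        f0 = fit_two_component_gmm(x)
        f1 = fit_two_component_gmm(x + 100.0)
        assert f1.mu1 == pytest.approx(f0.mu1 + 100, abs=1e-6)
        assert f1.mu2 == pytest.approx(f0.mu2 + 100, abs=1e-6)
        assert f1.w == pytest.approx(f0.w, abs=1e-6)
        assert f1.sigma1 == pytest.approx(f0.sigma1, abs=1e-6)

    def test_agrees_with_reference_em(self):
        # independent route: scikit-learn's EM on the same model
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(4, 1.5, 500)])
        fit = fit_two_component_gmm(x, tol=1e-10)
        gm = GaussianMixture(2, tol=1e-10, max_iter=2000, n_init=5,
                             random_state=0).fit(x[:, None])
        means = np.sort(gm.means_.ravel())
        assert fit.mu1 == pytest.approx(means[0], abs=0.05)
        assert fit.mu2 == pytest.approx(means[1], abs=0.05)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_two_component_gmm([1.0] * 50)
        with pytest.raises(ValueError):
            fit_two_component_gmm([1.0, 2.0])


class TestAssignByGmm:
    def test_threshold_is_strict(self):
        from eccell.cell_assign import MixtureFit
        fit = MixtureFit(w=0.5, mu1=0, mu2=5, sigma1=1, sigma2=1, loglik=0,
                         responsibilities=np.array([0.99, 0.5, 0.01]), n_iter=1)
        labels = assign_by_gmm(fit, threshold=0.5)
        assert labels.tolist() == [True, False, False]

    def test_accuracy_on_separated_simulation(self):
        rng = np.random.default_rng(4)
        truth = np.repeat([False, True], 500)
        x = np.where(truth, rng.normal(6, 1, 1000), rng.normal(0, 1, 1000))
        fit = fit_two_component_gmm(x)
        labels = assign_by_gmm(fit)
        assert (labels == truth).mean() >= 0.99


# ---------------------------------------------------------------------------
# gene scores and k-means
# ---------------------------------------------------------------------------

class TestGeneScores:
    def genes(self):
        return [("gA", GenomicInterval("chr1", 10_000, 20_000), "+"),
                ("gB", GenomicInterval("chr1", 50_000, 60_000), "-")]

    def test_single_gene_concentration(self):
        frag = make_fragments([("chr1", 12_000, 12_100, "A", 1),
                               ("chr1", 13_000, 13_100, "B", 1)])
        scores = gene_score_matrix(frag, self.genes(), ["A", "B"])
        assert list(scores.columns) == ["gA"]     # gB empty -> dropped

    def test_matches_overlap_count_oracle(self):
        rng = np.random.default_rng(5)
        barcodes = ["A", "B", "C"]
        rows = []
        for _ in range(300):
            start = int(rng.integers(0, 80_000))
            rows.append(("chr1", start, start + 100,
                         barcodes[int(rng.integers(3))], 1))
        frag = make_fragments(rows)
        scores = gene_score_matrix(frag, self.genes(), barcodes, promoter_ext=2000)
        for name, gi, strand in self.genes():
            if name not in scores.columns:
                continue
            lo = gi.start - 2000 if strand == "+" else gi.start
            hi = gi.end if strand == "+" else gi.end + 2000
            raw = []
            for bc in barcodes:
                sub = [r for r in rows if r[3] == bc]
                cnt = sum(1 for r in sub if r[1] < hi and r[2] > lo)
                raw.append(math.log2(1 + cnt / len(sub) * 1e6))
            raw = np.asarray(raw)
            expected = (raw - raw.mean()) / raw.std()
            np.testing.assert_allclose(scores[name].values, expected, atol=1e-9)

    def test_promoter_extension_follows_strand(self):
        frag = make_fragments([("chr1", 8_500, 8_600, "A", 1),   # upstream of gA (+)
                               ("chr1", 61_000, 61_100, "B", 1)])  # upstream of gB (-)
        scores = gene_score_matrix(frag, self.genes(), ["A", "B"])
        assert set(scores.columns) == {"gA", "gB"}


class TestKmeansAssign:
    def test_recovers_separated_groups(self):
        rng = np.random.default_rng(6)
        truth = np.repeat([False, True], 50)
        scores = rng.normal(0, 0.2, size=(100, 4)) + truth[:, None] * 3.0
        labels = kmeans_assign(scores, seed=0)
        assert (labels == truth).all()

    def test_positive_label_is_higher_mean_cluster(self):
        # flip sign: positives must follow the mean, not the cluster index
        rng = np.random.default_rng(7)
        truth = np.repeat([True, False], 50)
        scores = rng.normal(0, 0.2, size=(100, 4)) + truth[:, None] * 3.0
        labels = kmeans_assign(scores, seed=0)
        assert (labels == truth).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            kmeans_assign(np.zeros((1, 3)))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_enumeration_oracle(a, b, c, d):
    """Exact one-sided (greater) p by summing hypergeometric probabilities
    with integer arithmetic."""
    r1, c1, N = a + b, a + c, a + b + c + d
    denom = math.comb(N, c1)
    p = Fraction(0)
    for k in range(a, min(r1, c1) + 1):
        if c1 - k > N - r1 or c1 - k < 0:
            continue
        p += Fraction(math.comb(r1, k) * math.comb(N - r1, c1 - k), denom)
    return float(p)


class TestFisherExact:
    def test_no_association(self):
        p, odds = fisher_exact([[5, 5], [5, 5]])
        # a balanced table carries no signal: one-sided p is the upper
        # hypergeometric tail at its own mean, and the odds ratio is 1
        assert p == pytest.approx(fisher_enumeration_oracle(5, 5, 5, 5))
        assert p > 0.5
        assert odds == pytest.approx(1.0)

    def test_perfect_association(self):
        p, odds = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(1 / math.comb(20, 10))
        assert odds == math.inf

    def test_wrong_direction(self):
        p, _ = fisher_exact([[0, 10], [10, 0]])
        assert p == pytest.approx(1.0)

    def test_zero_margin(self):
        p, odds = fisher_exact([[0, 0], [3, 4]])
        assert p == 1.0
        assert math.isnan(odds)

    def test_agrees_with_enumeration_small_tables(self):
        # exhaustive over all tables with total <= 16
        for n in range(1, 17):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        p, _ = fisher_exact([[a, b], [c, d]])
                        assert p == pytest.approx(
                            fisher_enumeration_oracle(a, b, c, d), rel=1e-9)

    def test_agrees_with_enumeration_random_margins_to_30(self):
        rng = np.random.default_rng(8)
        for _ in range(400):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, 4))
            if min(a + b, c + d, a + c, b + d) == 0 or max(a + b, c + d) > 30:
                continue
            p, _ = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d),
                                      rel=1e-9)

    def test_rejects_negative_or_fractional(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 2]])


# ---------------------------------------------------------------------------
# discordant gold standard and end-to-end assignment
# ---------------------------------------------------------------------------

class TestExtractDiscordantBarcodes:
    def test_planted_barcodes_recovered(self, mini_library):
        truth = mini_library["truth"][0]
        gold = extract_discordant_barcodes(mini_library["bam"], truth.junctions)
        members = set(mini_library["members"])
        assert gold == members     # set semantics, exactly the planted cells

    def test_no_junctions_no_barcodes(self, mini_library):
        assert extract_discordant_barcodes(mini_library["bam"], []) == set()


def _signal_fragments(n_pos, n_neg, seed=0):
    """Fragments with a bimodal region signal: positives carry extra
    fragments in the candidate region.  Per-cell totals vary (log-normal
    depth factors) as in real libraries."""
    rng = np.random.default_rng(seed)
    rows = []
    barcodes = []
    for i in range(n_pos + n_neg):
        bc = f"C{i:04d}"
        barcodes.append(bc)
        pos = i < n_pos
        depth = rng.lognormal(0, 0.3)
        for _ in range(int(rng.poisson(140 * depth))):
            start = int(rng.integers(0, 5_000_000))
            rows.append(("chr1", start, start + 100, bc, 1))
        extra = rng.poisson((60 if pos else 8) * depth)
        for _ in range(int(extra)):
            start = int(rng.integers(1_000_000, 1_199_900))
            rows.append(("chr1", start, start + 100, bc, 1))
    return make_fragments(rows), barcodes


class TestAssignEcdna:
    def test_bimodal_signal_uses_gmm_branch(self):
        frag, barcodes = _signal_fragments(60, 140)
        result = assign_ecdna(frag, None, make_candidate(), barcodes,
                              config=AssignConfig(n_boot=200, seed=0))
        assert result.method == "gmm"
        truth = np.array([bc < "C0060" for bc in result.barcodes])
        assert (result.labels == truth).mean() > 0.95
        assert result.dip_p < 0.05

    def test_unimodal_signal_uses_kmeans_branch(self):
        frag, barcodes = _signal_fragments(0, 200)
        result = assign_ecdna(frag, None, make_candidate(), barcodes,
                              config=AssignConfig(n_boot=200, seed=0))
        assert result.method == "kmeans"
        assert result.dip_p >= 0.05

    def test_labels_cover_input_barcodes(self):
        frag, barcodes = _signal_fragments(30, 70)
        result = assign_ecdna(frag, None, make_candidate(), barcodes,
                              config=AssignConfig(n_boot=100, seed=1))
        assert set(result.barcodes) <= set(barcodes)
        assert len(result.labels) == len(result.barcodes)

    def test_underpowered_input_rejected(self):
        frag, barcodes = _signal_fragments(2, 3)
        with pytest.raises(ValueError, match="cells"):
            assign_ecdna(frag, None, make_candidate(), barcodes[:5],
                         config=AssignConfig(seed=0))

    def test_gold_standard_enrichment_with_alignments(self, mini_library):
        from eccell.bench import fragments_from_bam
        frag = fragments_from_bam(mini_library["bam"])
        truth = mini_library["truth"][0]
        result = assign_ecdna(frag, mini_library["bam"], truth,
                              mini_library["barcodes"],
                              config=AssignConfig(n_boot=200, seed=0))
        members = set(mini_library["members"])
        predicted = {bc for bc, lab in zip(result.barcodes, result.labels) if lab}
        assert predicted == members
        assert result.fisher_p < 0.01
        assert result.gold_standard_barcodes <= members
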