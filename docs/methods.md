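# Methods

## Model and assumptions

The pipeline rests on three assumptions about ecDNA in scATAC-seq data:
(1) ecDNA amplification produces many more copies than linear amplification,
so its genomic footprint shows a pronounced pseudo-bulk coverage excess;
(2) the footprint is contiguously accessible, so coverage segmentation
recovers whole segments rather than isolated peaks; (3) where ecDNA is
present it dominates the copy count of its region, so per-cell accessibility
within the region separates carriers from non-carriers. Cells are treated as
exchangeable at detection time (one pooled library) and independent at
assignment time.

## Detection

- **Coverage segmentation.** Mean per-base depth in `bin_size` (1 kb) bins.
  A bin is amplified when depth >= `max(depth_floor, enrich_factor x global
  median)` with `depth_floor = 5` and `enrich_factor = 2`. The floor is tied
  to the candidate-level mean-depth filter (> 5) so segmentation and QC are
  self-consistent; the relative guard keeps the cutoff meaningful in deep
  libraries. Runs separated by <= `merge_gap` (10 kb) merge, bridging
  nucleosome-scale dropouts without joining distinct amplicons.
- **Discordant pairs.** A pair is discordant when mates map to different
  chromosomes, share a strand, face outward, or have |insert| >
  `insert_cutoff` (1 kb) — standard structural-variant practice. Each read
  of a discordant pair implies a breakend (forward read: its 3' end, side
  "right"; reverse read: its 5' end, side "left"). Breakend pairs are
  clustered greedily in canonical order; a pair joins the first open cluster
  whose median positions are both within `cluster_window` (500 bp); clusters
  need `min_discordant_support` (3) pairs. Junction positions are member
  medians, replaced by the modal soft-clip position when >= 1 clipped read
  falls within the window (ties to the smaller coordinate, for determinism).
- **Cycle assembly.** Junction breakends snap to the nearest amplified
  segment end of matching side within `snap_window`. Because called segment
  boundaries are bin-quantised, a snap window equal to the clip-scale
  `cluster_window` alone would miss true junctions purely through binning
  error; the default is therefore `cluster_window + 2 x bin_size` (2.5 kb).
  Junctions that snap to no segment end are discarded rather than seeding
  segments (assumption 2). Simple cycles alternating segment and junction
  edges, each segment used once and at most `max_segments_per_circle` (10)
  segments, are enumerated by depth-first search anchored at each cycle's
  smallest segment index (deduplicating rotations and reflections); segment
  boundaries are refined to the junction positions, which is what makes the
  emitted boundaries base-accurate on simulated data.
- **QC filters.** size in [10 kb, 20 Mb], depth_mean > 5, high_coverage >
  0.1, where high_coverage is the fraction of candidate bases at or above
  the segmentation cutoff. All three strict.
- **Chunking.** The genome is scanned in `chunk_size` (64 Mb) windows purely
  as an I/O batching device; coverage bins are addressed in absolute
  coordinates and junction evidence is pooled before clustering, so the
  output is provably independent of the chunk size (asserted in tests).

## Cell assignment

- **Signal.** `log2((reads_in_region + pseudocount) / total_reads x 1e6)`
  per whitelisted cell, counting fragment records (the support column is not
  a weight). The pseudocount (default 1) exists because zero-signal cells
  otherwise map to -inf, which no mixture fit can ingest; it is configurable.
- **Dip test.** The dip statistic — the sup-distance from the empirical CDF
  to the nearest unimodal CDF — is computed exactly: for every candidate
  mode, the best convex fit to the left flank and concave fit to the right
  flank follow from the greatest convex minorant / least concave majorant of
  the CDF (jumps enter through left limits); flank misfits are monotone in
  the mode position, so the crossing is found by bisection, and modes are
  examined outward in ascending misfit order until the two flank fits are
  mutually compatible (the convex fit can end below where the concave fit
  starts — the coupling that makes naive per-flank minimisation a strict
  lower bound). The implementation is validated against a linear-programming
  oracle that solves the defining minimisation directly, and against the
  analytic anchors dip = 1/(2n) for equally spaced points and 0.25 for
  balanced two-point masses. The p-value is Monte-Carlo: the fraction of
  `n_boot` (2000) uniform samples of the same size with dip at least the
  observed value — table-free and reproducible under the given seed. The
  dip depends only on ranks, so the uniform null is representative of
  continuous unimodal nulls; note that heavily tied (coarsely discrete)
  signals genuinely raise the dip, which is the correct behaviour of the
  statistic, not an artefact.
- **Mixture.** EM for w N(mu1, sigma1^2) + (1-w) N(mu2, sigma2^2),
  initialised from the exact 1-D two-means split (prefix-sum search over the
  sorted data — deterministic), with `sigma_floor = 1e-3` against collapse,
  convergence when the relative log-likelihood gain drops below `tol = 1e-8`
  (the trace is non-decreasing, asserted in tests), components reported with
  mu1 <= mu2. Cells are ecDNA+ iff the posterior for the higher-mean
  component strictly exceeds 0.5 — higher mean, never component index.
- **k-means fallback** (dip p >= 0.05): scikit-learn k-means (k = 2,
  best of 10 restarts, seeded) on a cells x genes score matrix:
  log2(1 + CPM) of fragments over the gene body extended 2 kb upstream,
  z-scored per gene. This gene score is a deliberately simple local
  accessibility summary (documented, swappable), not a re-implementation of
  any toolkit's distance-weighted model. When no annotation is supplied the
  candidate is tiled into 10 pseudo-gene windows. The cluster with the
  higher mean row-sum is ecDNA+.
- **Gold standard and Fisher.** Barcodes with >= 1 discordant pair or
  clipped read within 500 bp of a candidate junction. The 2x2 table
  (label x gold membership) is tested one-sided ("greater"): the hypothesis
  is directional — discordant evidence should concentrate in predicted
  carriers. Odds ratio is the sample (a d)/(b c) with inf when bc = 0 and
  ad > 0, and an undefined (NaN) flag with p = 1 on degenerate margins.

## Simulators

- **Read-level.** Circles are composed of 1..3 random segments (total size
  uniform in `size_range`, Dirichlet split, random orientation), placed
  mutually disjoint with a 50 kb margin so detection truth is unambiguous.
  Reads are drawn uniformly on the circle with N(300, 30) inserts, 50 bp
  ends, and projected to the reference: pairs straddling a ligation junction
  become discordant records, reads crossing one become soft-clipped records
  clipped exactly at the breakend. Emitting pre-aligned records keeps the
  discordant/clip geometry exact while avoiding a read-level error model;
  optional FASTQ emission (random synthetic reference) supports end-to-end
  runs through a real aligner. The simulator does not model mapping
  ambiguity, GC or Tn5 bias, duplicates, or peak structure in the
  background (it is uniform), so detector scores on it bound what clean
  signal supports, not performance on real libraries.
- **Count-matrix.** X_ij ~ Poisson(sparse_fac C_ij lambda_ij) with
  sparse_fac 0.5 and diploid C = 2, so the diploid mean is exactly lambda
  and an amplified entry's mean is copy_ratio x lambda (C = 2 x ratio
  encodes "Poisson mean multiplied by the copy ratio" literally;
  configurable). The synthetic baseline lambda is a per-bin Bernoulli(0.1)
  peak mask times log-normal magnitudes (median 0.25 per peak bin) with a
  small off-peak floor (0.005) and per-cell log-normal depth factors
  (sd 0.35) — matching the qualitative sparsity of 10 kb scATAC bins at
  ~1k-cell scale; a "learned" mode rank-one moment-matches a template
  matrix instead. The bin space defaults to 30,000 bins (300 Mb at 10 kb):
  large enough that amplifying one region leaves per-cell totals — the CPM
  denominator — nearly unchanged, as in a genome-wide matrix. Candidate
  ecDNA regions with < 3% of bins in peaks are discarded. Region sizes
  default to 50 kb - 10 Mb (the matrix-protocol range; the read-level
  protocol uses 500 kb - 10 Mb, scaled down proportionally for desk-scale
  references).
- **Mixtures.** `mix_cells` samples round(p n) positive and (1-p) n negative
  barcodes without replacement, p = 0.1..0.9; the mixture benchmark reuses
  one fixed simulated library (positives carry the circle's local reads and
  junction evidence) and varies only the whitelist, mirroring how fixed
  cell-line pools are resampled.

## Benchmarks and problem sizes

- Detection: 24 circles of 100-800 kb on a 100 Mb four-chromosome synthetic
  reference (sizes scaled ~1/10 from the full-genome protocol so the
  amplicon-to-genome ratio stays modest), clean 4x background; local depth
  10-30x for the main run and 5x for the near-background run; greedy 1-to-1
  matching at >= 50% reciprocal overlap (the matching rule is this package's
  choice; precision is 0 by convention when nothing is detected). The test
  suite runs the same harness at 40 Mb / 22 circles.
- Mixture classifier: 1000 cells, 5 groups, m in {1..4}, ratios {3,5,10,20},
  3 repeats, 8 simulated regions per repeat (a scaled-down stand-in for the
  100-region protocol). Since the classifier consumes only per-cell region
  counts and totals — both sums of independent Poissons, hence Poisson with
  known means — the benchmark samples those sufficient statistics directly;
  this is distribution-exact and keeps each region's experiment independent.
- Expected behaviour reproduced: recall stays high across the grid,
  precision (hence F1) degrades at copy ratio 3 where carrier and
  non-carrier count distributions overlap, and both recover from ratio 5 up.

## Known limitations

- Segmentation has bin-size resolution; boundaries are base-accurate only
  where junction evidence exists.
- No GC/mappability correction anywhere; no BFB or linear-amplicon
  classification; small eccDNA microcircles (< 10 kb) are out of scope by
  the size filter.
- The dip test loses power when one population is a small minority (the
  k-means fallback covers that regime, as the mixture benchmark shows at
  90% positives).
- Copy estimates are a per-cell median-ratio scale (diploid = 2), a
  documented surrogate — not calibrated absolute copy counts.
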