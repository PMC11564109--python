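# Methods

`mosaictissue` implements an analysis framework for multi-modal spatial
expression data of the kind produced when serial sections of one tumor biopsy
are profiled with several assays (whole-transcriptome capture beads,
combinatorial single-molecule FISH, targeted in situ sequencing, multiplexed
antibody imaging) alongside matched sc/snRNA-seq. This note documents the
models, conventions and numerical choices; nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Common data model and harmonization

All assays are reduced to one container (`SpatialDataset`): an observation x
feature matrix (counts for sequencing/molecule methods, nonnegative real
intensities for antibody imaging), per-observation (x, y) coordinates in um,
a method tag, and per-observation metadata. Observations are segmented cells,
capture beads or square bins; features are official gene aliases for all
methods so panels intersect cleanly.

Conventions, fixed package-wide:

- coordinates are continuous um with y increasing upward; after rescaling
  (`rescale_coordinates`, um-per-pixel factor then origin shift) each section
  starts at (0, 0);
- every bin lattice (10 um expression bins, 100 um neighborhood bins) is
  anchored at the origin with half-open intervals `[k*b, (k+1)*b)`, so each
  molecule or cell belongs to exactly one bin and binning conserves counts
  exactly;
- rigid transforms apply flip -> scale -> rotate -> translate about a stated
  pivot. The order is a convention (manual registration workflows rarely
  state one); it is fixed, documented, and the analytic inverse
  (`RigidTransform.invert`) is exact to < 1e-6 um round trip;
- registration parameters live in a declarative YAML config keyed by
  (sample, method, replicate) and the applied transform is logged on the
  dataset, so registration is reproducible rather than interactive;
- mask clipping uses closed polygon boundaries: an observation exactly on the
  edge of the reference H&E outline is retained. Overlapping sub-regions
  resolve to the first polygon in mask order;
- empty bins are omitted (sparse representation).

## Quality control

Three procedures, mirroring standard practice for the respective data types:

1. **Group-median filtering** (sc/snRNA-seq). Hard caps first (mitochondrial
   fraction < 0.50, genes < 8,000, UMIs < 20,000), then each filter group
   (cell type x protocol x chemistry) picks its low thresholds from a ladder
   based on the group median computed on cap-surviving members: gene medians
   > 1,300 / > 600 / otherwise map to low thresholds 700 / 300 / 100; UMI
   medians > 1,800 / > 900 / otherwise map to 1,100 / 600 / 300. Thresholds
   are strict (keep iff metric > threshold); a group median exactly at a
   ladder cutoff falls to the lower rung. This makes lenient thresholds for
   intrinsically low-RNA populations (immune cells) and stringent ones for
   high-RNA populations explicit and auditable — the chosen thresholds are
   returned per group.
2. **Adaptive minimum-counts filtering** (beads and sc/sn). Starting at
   min_counts = 30 (min_genes = 30 held fixed), the counts threshold rises in
   steps of +10 until at most 35% of retained observations have fewer than
   100 total counts, erroring if the dataset empties first. The step size is
   a package choice (configurable); only min_counts escalates. The result is
   provably identical to a brute-force scan over the threshold grid, and the
   tests check that equivalence on randomized datasets.
3. **Sample gates**: mean counts per bead >= 150 (bead assays), mean counts
   per segmented cell >= 50 (molecule assays), and — when a matched reference
   pseudobulk is available — Pearson r >= 0.60 between log1p mean expression
   profiles over shared features. All applicable gates must pass; boundaries
   are inclusive.

## Panel design

The collect-and-filter selection reduces a literature/data-driven candidate
pool to an experimental panel size:

- *variability* of a gene = fraction of cells with |z-scaled expression| > 1;
  for standard-normal expression this is 2*Phi(-1) ~ 0.317, which the tests
  use as a closed-form oracle;
- *cumulative-weight selection*: per cell-type class, classifier feature
  weights are made nonnegative and normalized to sum 1, genes ranked by
  descending weight, and a gene is kept iff the cumulative weight of strictly
  higher-ranked genes is below the budget (0.4/0.45 for the first pass,
  0.3/0.35 for priority assignment, 0.8 for intrinsic-subtype refinement).
  The gene whose prefix crosses the budget is included — this matches the
  reading "all top-weighted genes that together account for the budget".
  Ties break lexicographically by gene id for determinism. The classifier
  itself is pluggable: any per-class weight vector is accepted;
- *inclusion formula*: include iff
  `(expr > 0.15 OR variability > 0.025 OR categories > 1) AND
  (1.5 < expr < 4 OR variability > 0.25 OR priority == 1 OR categories > 1)`,
  where `expr` is mean normalized expression in the gene's highest-expressing
  (or epithelial) cell type. The formula is monotone in priority and category
  count, which the tests check by property.

## Codebooks, barcodes and probes

Combinatorial FISH genes get binary codewords of length 22, Hamming weight 4
and pairwise distance >= 4 (detects 2-bit errors, corrects 1); unassigned
codewords are *blanks* used to estimate false-positive decoding rates.
Targeted in situ sequencing genes get length-7 barcodes over {0,1,2,3} with
pairwise distance >= 3.

Construction is a deterministic seeded search: greedy passes over randomly
ordered candidates followed by a remove-and-readd augmentation loop, with all
search randomness drawn from a fixed internal seed so the packing is
reproducible; the caller's seed only shuffles which codeword each gene gets.
Plain lexicographic greedy is insufficient here — it is maximal at 263
constant-weight words (need >= 292) and at 256 quaternary words (the
[7,4,3] lexicode; need 297) — while the augmented search packs ~309 and
>= 297 respectively. The combinatorial optimum for the 22/4/4 code is 385
(Johnson bound, attained by Steiner quadruple systems); the package does not
promise the optimum, asserts the ceiling, and reports however many blanks
remain beyond the requested genes. Every generated instance is verified
exhaustively (weights, all-pairs distances, single-error correction).

Decoding: exact match, else unique codeword within radius floor((d-1)/2),
else reject (including ties at equal distance).

Probe homology search slides a 30-mer window along each transcript and
excludes windows with homopolymer runs > 5, fewer than 4 distinct bases, GC
outside [0.40, 0.65], either 15-nt arm's melting temperature below threshold
(nearest-neighbor thermodynamics, SantaLucia 2004 tables via Biopython
`Tm_NN`; default threshold 37 degC, configurable per gene), arm Tm difference
> 8 degC, or a >= 6-bp reverse-complement self-match (a deliberately simple
hairpin/dimer proxy). Windows are taken greedily without overlap from the 5'
end, keeping the first 16 (all if fewer). Cross-transcript homology
screening is a pluggable callable, disabled by default. Encoding probes pair
each region with 3 readout sequences chosen round-robin from the gene's 4
on-bits (usage balanced within one) plus constant primer flanks; sequential
(non-combinatorial) genes get 48 single-readout probes without primers.

## Spatial statistics

- **Composition grids**: cell-type frequencies per 100 x 100-um bin on a
  universal lattice with a fixed type union, so sections are comparable.
  Cross-method agreement is the per-bin Pearson correlation of composition
  vectors, summarized by the median per method pair; bins empty in either
  section are dropped pairwise, and bins with a constant composition vector
  (undefined correlation) are excluded but counted. Note that with only two
  cell types every correlation is trivially +/-1; the statistic is
  informative from three types up.
- **Co-occurrence**: for anchor type a, partner b, distance bin k,
  `score = log2[ P(partner=b | center=a, bin k) / P(partner=b | any center,
  bin k) ]`, with pseudocount alpha = 1 added to every ordered
  (center, partner, bin) pair count. Base 2 and alpha are configurable. Pair
  counting is exact (k-d tree accelerated, intended for <= 50k observations)
  and the tests require bit-exact agreement with an O(n^2) enumeration
  oracle. Distance bins default to 10 linear bins over [0, 500] um.
  Under complete spatial randomness the score is 0; positive means
  attraction, negative exclusion/repulsion.
- **Strength and range**: strength = signed score of the first interval;
  range = center of the first interval where |score| has decayed to 25% of
  |strength| (maximum distance if never). The range is reported as a
  distance in um; the alternative reading ("the score at that interval") is
  ambiguous, and the distance is what the dot-plot size encodes in practice.
  Zero strength yields a degenerate, flagged summary.
- **ARI congruence**: sklearn's `adjusted_rand_score` (the standard
  contingency-table implementation) with bootstrap resampling (default 10
  iterations, mean +/- sd). Tests verify it against the raw pair-counting
  definition exhaustively on small partitions.
- **Contingency ratios**: observed / (row_sum * col_sum / total), the
  normalization used for cell-type frequencies where closure effects are
  strong (few types, unlike ~20k genes).
- **Annotation transfer**: a deliberately simple baseline — nonnegative least
  squares of each observation profile against reference cell-type centroids,
  renormalized to the simplex, argmax for the categorical label. It stands in
  for heavier transfer methods in simulations; it is not an optimal-transport
  or count-model method and is documented as such.

## Neighborhood and phenotype analyses

- **Signature scoring**: mean expression of signature genes minus mean of
  expression-matched controls (25 average-expression bins, 50 controls per
  signature gene, seeded draws excluding signature genes). Control matching
  makes the score exactly invariant to adding a constant to all genes. The
  EMT program is carried as a 50-gene signature of which 20 survive on the
  imaging panel; `Signature.restrict` performs the intersection and errors if
  empty.
- **Spatial EMT phenotype**: each sample is called low / patched / high from
  the malignant-cell mean score m and patchiness pi = Moran's I (queen
  contiguity on occupied 100-um bins, binary weights). Defaults:
  high if m > 0.4, low if m < -0.1, else patched if pi > 0.3, else the nearer
  pole. The original assignment of such phenotypes is manual; this rule-based
  surrogate is tuned on simulations only and every threshold is configurable.
  Fewer than 10 occupied bins is refused as unclassifiable.
- **Neighborhoods**: bins strictly above / below the per-sample median bin
  score; ties at the median are unassigned (strict inequalities), and an
  all-tied sample is flagged degenerate.
- **Composition differences** between neighborhood classes: center log-ratio
  transform (pseudocount = half the smallest nonzero proportion in the
  table), per-type two-sided Mann-Whitney test, Benjamini-Hochberg across
  types, log-FC = difference of mean CLR values. CLR rows sum to 0 by
  construction.
- **Phenotype expression differences**: each sample is split into two
  equal-extent halves along y (capturing within-sample variability), per
  split a mean pseudobulk is CLR-normalized across genes, and per gene a
  two-sided Welch's t-test compares the groups' splits, BH-corrected.
  Equal-extent (not equal-count) halves keep the split purely positional.
- **T/NK proximity**: malignant cells are *proximal* iff their 100-um bin
  contains at least one T or NK cell. Per gene, two-sided rank-sum test
  proximal vs distal, BH-corrected, run per sample and pooled; genes whose
  pooled direction is opposed by any per-sample direction are reported
  explicitly, never silently merged — pooling can invert patient-specific
  signals (Simpson's paradox), and the tests construct exactly such a
  fixture.
- Benjamini-Hochberg is the standard step-up with enforced monotonicity,
  cross-checked against statsmodels on random inputs.

## Synthetic data generator

The generator defines the study conditions for all recovery tests. Defaults:
a 3 x 3 mm rectangular tissue with 4,000-10,000 cells (desk-scale run times)
over five types (malignant 0.50, fibroblast 0.20, macrophage 0.15, T/NK
0.10, endothelial 0.05 — a composition typical of carcinoma biopsies).

- **Patterns**: `intermixed` (independent uniform; CSR between types),
  `short_range` (partner cells uniform in a 20-um disc around random anchor
  cells), `long_range_islands` (a type confined to planted discs). The
  planted radius, island centers and masks are recorded in the ground truth.
- **Expression**: per-cell expected log-expression = type profile (markers at
  log-level 1.5 over a -1.0 baseline, small seeded wiggle) + patient shift
  (N(0, 0.5) per gene, malignant cells only, seeded from a stable hash of the
  patient id so patients reproducibly separate) + signature loading x field
  value. Fields: constant low (0), constant high (1 on malignant cells), or
  patched (1 inside planted discs). The planted structure mirrors the
  empirical regularity that malignant cells group by patient while
  non-malignant cells group by type.
- **Capture**: counts ~ Poisson(efficiency x exp(log-expression)); a
  gamma-Poisson option (`nb_alpha`) adds overdispersion when wanted, Poisson
  being the analytically tractable default. Molecule modes scatter molecules
  N(0, 2 um) around cell centers; bin mode aggregates them on a 10-um
  lattice; bead mode captures only molecules within a 5-um footprint of grid
  beads spaced 10 um (so some molecules are lost, as in real bead capture);
  intensity mode emits a noisy linear transform of a marker subset (no
  imaging point-spread model). Bead/bin observations are labeled with the
  majority contributing cell type.
- **Serial sections**: independent captures of the same truth, each with
  positional jitter (0.5 um) and a random rigid perturbation (rotation
  N(0, 5 deg), translation N(0, 50 um) about the tissue center); the exact
  inverse transform is emitted for registration tests.

What the simulator does **not** emulate: segmentation errors, cell-shape and
density heterogeneity, spatially varying capture efficiency, ambient
RNA/doublets, imaging artifacts, and real panel biology. Passing recovery
tests therefore demonstrates correctness of the statistics under the stated
generative model, not robustness to every failure mode of real data.

## Problem sizes and numerics

Test and acceptance workloads are sized for a single CPU: co-occurrence
oracle comparisons at <= 3,000 observations, codebook verification over all
~47k codeword pairs, null calibrations with 100 replicates, recovery suites
with 20 seeded replicates at 4,000-8,000 cells. Degenerate inputs are
handled explicitly rather than silently: empty molecule tables, empty filter
groups, all-tied neighborhood bins, zero-strength curves, all-zero profiles
and zero contingency marginals all raise or flag. Floating-point tolerances
follow the contract of each operation (exact for counts and pair counts,
1e-9 for transform algebra, 1e-6 for round trips through inverses).

## Known limitations

- The codebook search is heuristic; it guarantees >= the requested genes plus
  at least one blank, not the 385-word optimum, so fewer blanks are available
  than a maximum-size code would give.
- The EMT phenotype thresholds are simulation-tuned surrogates for a manual
  call and should be recalibrated before use on real data.
- The NNLS annotation transfer ignores count noise models and platform
  effects; it is a baseline, not a replacement for dedicated transfer tools.
- Exact all-pairs co-occurrence counting is quadratic in dense regions;
  datasets beyond ~50k observations need subsampling.
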