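# Methods

## Problem setting

When the centromeric histone H3 variant CENP-A is present in excess over
its dedicated chaperone, it is deposited outside centromeres — sharply at
high-turnover sites (promoters, DNase-hypersensitive regions) and broadly
at subtelomeric fragile sites such as 8q24. The quantity of interest is
**ectopic peak coverage**: the number of bases (reported in kb) inside
ChIP-seq enrichment regions that lie *completely outside* annotated
centromere boundaries, computed per experimental condition and partitioned
against a control into coverage that is *common* and *newly acquired*.
Imaging provides orthogonal read-outs at single loci: colocalization
percentages, monopolar-spindle distance shifts, and locus copy counts.

All genomic coordinates are 0-based half-open throughout (SAM's 1-based
positions are converted on read). Internal arithmetic is integer bases; kb
values are formatted with one decimal only at the reporting boundary.

## Peak calling

The caller is a deliberately simple, fully specified local-Poisson test of
ChIP against matched input. It is a stand-in for a MACS-style caller, not a
re-implementation of one; externally called peaks in BED can be swapped in
anywhere a peak set is accepted.

* **Pileup.** Each read is extended to the nominal fragment length
  (`fragment_extension`, default 147 bp — a mononucleosome from a native
  MNase preparation) from its 5′ end: `[start, start+d)` on the plus
  strand, `[end-d, end)` on the minus strand, clipped to the chromosome.
* **Candidate test.** The genome is scanned in `bin_size` = 10 bp bins.
  The test statistic per bin is the number of extended fragments
  overlapping it, which is exactly Poisson under a locally uniform
  background. Its expectation is

      lambda_local = r * max(rate_genome, rate_window, rate_1k, rate_5k, rate_10k) * w

  where the rates are input fragment-start densities (genome-wide, in the
  candidate's own footprint window, and in 1/5/10 kb windows centred on
  it), `w` is the candidate footprint width (`bin_size + d - 1`), and `r`
  is the ChIP/input scale. Including the candidate window's own input rate
  makes the caller exactly null when ChIP and input coincide, including at
  shared artefactual spikes.
* **Depth scale `r`.** An immunoprecipitated library spends a substantial
  fraction of its reads inside enriched regions, so the raw read-count
  ratio overstates the ChIP background density and costs sensitivity. By
  default `r` is estimated from background-dominated 1 kb windows (those
  at or below the 90th percentile of ChIP counts), analogous to
  background-proportion normalization; the plain total-count ratio is
  available via `depth_scale="total"`.
* **Broad domains.** A weak broad domain (e.g. 5-fold over background
  across tens of kb) leaves too little mass in any single 10 bp bin. A
  coarse scan tests 1 kb windows (`broad_window`) of ChIP fragment starts
  against the same lambda construction; inside significant windows,
  individual bins are kept when their fine-scale count exceeds
  `lambda + refine_z * sqrt(lambda)` (default z = 2), so domain edges stay
  sharp and isolated noise bins cannot seed peaks on their own.
* **Peaks.** Bins with Poisson tail probability ≤ `p_cutoff` (default
  1e-5) are merged when separated by ≤ `merge_gap` (100 bp); regions
  shorter than `min_length` (147 bp) are dropped. The summit is the argmax
  of the unbinned pileup (leftmost on ties); the score is the max −log10 p
  over the region, computed by regularised incomplete gamma with a
  log-space series fallback when the tail underflows doubles. The caller
  contains no randomness.

## Consensus, ectopic filter, partition

Replicate peaks are pooled and merged (gap 0) into a reference set; a
reference interval is *replicated* when peaks from at least `min_support`
distinct replicates share ≥ 1 base with it (kept or dropped whole). The
default support is 3 when ≥ 3 replicates exist, otherwise all replicates —
the strictest defensible reading for duplicate experiments; it is
configurable. Overlap is any shared base; no minimum-fraction rule.

The ectopic filter removes every peak with any base overlap with the
centromere mask — boundary-straddling peaks are removed whole, never
trimmed. Chromosomes absent from the mask count as fully ectopic
territory (logged). The common/new partition is computed by exact
base-level intersection/subtraction, so `common + new = treatment
coverage` holds identically; the package enforces this at construction, so reported
partition components always sum exactly to the reported total.

## Depth equalization

Sequencing depth, paired- vs single-end chemistry and replicate number are
removed before comparison: first-of-mate reads are extracted from paired
sets, the two highest-depth replicates are pooled per condition, and
fixed-depth subsamples are drawn uniformly without replacement (seeded
permutation; per-trial sub-seeds are `seed + trial`). Peak calling, the
ectopic filter and coverage run per trial; the summary is mean ± sample SD
(n−1) across trials, compared between conditions with an equal-variance
Student t-test (Welch via flag). The input pool is redrawn per trial.
Production-scale depths (tens of millions of reads) are configuration
values; package defaults are scaled to the toy genome.

With only three trials per condition, and trials drawn from a shared pool,
the t-test's null calibration is approximate: pool-level variation is not
reflected in the within-condition trial variance. On the toy scale the
empirical false-positive rate at p < 0.01 stays within a few percent
(asserted ≤ 5% in the acceptance suite); real-scale comparisons should
treat borderline p-values with the same caution.

## Imaging quantifications

Inputs are per-cell object tables: `(cell_id, experiment_id, condition,
object_class ∈ {fish_locus, if_mark, centromere_point}, probe, x_um,
y_um)`. Pixel-level colocalization scoring is replaced by an explicit
distance criterion: a cell is colocalized when ≥ 1 locus of the probe has
a marker within `radius` (default 0.5 μm, sub-diffraction proximity).
Percentages are aggregated per independent experiment; SEM is across
experiments (sd/√n); two conditions are compared by Student t on
per-experiment fractions. Coordinates are 2-D; z-stacks are assumed
collapsed upstream.

For monopolar-spindle geometry, the centromere point cloud of each cell is
enclosed in its minimal-area ellipse (Khachiyan multiplicative update,
tolerance 1e-3; centroid fallback, flagged in the log, below 5 points) and
Euclidean distances from its centre to each FISH locus are grouped by
whether the locus carries a marker (ectopic-kinetochore positive vs
negative). Loci counts per cell are summarised per condition with SEM
across experiments. All statistics are invariant under rigid motions of
each cell's coordinates.

## Synthetic data

The generators define the package's study conditions and are pure
functions of (parameters, seed):

* **Genome** — by default 1–4 chromosomes of 0.3–2.5 Mb with one centrally
  placed centromere covering ~10% of each chromosome. Toy scale keeps every
  stage well inside a desktop minute budget.
* **Truth** — sharp ectopic peaks (default 1 kb) placed uniformly outside
  the centromere mask, plus one broad subtelomeric domain near the right
  end of the last chromosome. Features keep a 2 kb margin from the mask
  and from each other so that whole-peak centromere exclusion and peak
  merging act on well-separated features rather than placement artefacts.
  A condition can *extend* another condition's truth (a knockdown adds new
  sites on top of the control's), which makes the common/new partition
  meaningful. Planted ectopic truth never overlaps the mask (asserted
  per run).
* **Reads** — fragment 5′ starts from a mixture: uniform background plus
  excess mass over features proportional to per-class enrichment folds
  (defaults 20× centromere, 10× sharp, 5× domain — exercise parameters,
  not estimates of real enrichment). Total depth is fixed per replicate,
  so the realised background share shrinks as enrichment mass grows — the
  same dilution real IP libraries show, and the reason the caller
  estimates its depth scale from background windows. Replicate depths
  default to a 1–3× spread (mirroring, scaled down, the ~3× spread of the
  real experiments); 10% of reads draw MAPQ < 10 to exercise the quality
  filter; paired mode emits both mates. Read length is 76 bp with no
  fragment-length jitter.
* **Cells** — per-cell centromere clouds (25 points, σ 1.5 μm), Poisson
  loci counts, loci placed at inner (3.4 μm) or outer (4.5 μm) radii by
  attachment status, an IF mark planted on one locus in a truth-known
  fraction of cells and a decoy mark near the cloud centre otherwise.

What the generators do **not** emulate: sequence content and mappability
bias, GC effects, duplicated fragments, copy-number changes underlying the
8q24 amplification, 3-D nuclear geometry, or segmentation error in spot
detection. Passing tests therefore demonstrate the correctness of the
*computations* under controlled truth, not the biology of any particular
dataset.

## Problem sizes used in the test and acceptance runs

Chosen as the package's default desk-scale study conditions: interval
oracles on ≤ 50 kb chromosomes (500 random instances); caller recovery on
1 × 400 kb genomes at 60 k reads; end-to-end comparisons on 2 × 1 Mb
genomes with 100 kb (control) vs 250 kb (knockdown) planted ectopic truth,
3 replicates at 120–360 k reads; subsampling calibration on 1 × 200 kb
genomes over 200 seeded comparisons; imaging on 3 experiments × 200 cells
(50 seeds for the colocalization scenario).

## Known limitations

* The caller makes no attempt to match any specific MACS version's output;
  equivalence is not claimed, and model-based fragment-size estimation,
  broad/gapped peak modes and duplicate removal are out of scope.
* Reads are not deduplicated anywhere (the upstream protocol's duplicate
  handling is unknown; deduplication would be a caller-level extension).
* The t-test caveat above: tiny trial counts and shared pools make
  subsampling p-values approximate.
* The colocalization radius is a surrogate for intensity-overlap scoring;
  absolute percentages depend on it, though condition contrasts are robust
  across a wide radius range (colocalization is monotone in the radius).
* Interval algebra is exact but assumes in-memory peak sets; the package
  is not designed for million-peak atlases.
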