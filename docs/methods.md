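# Methods

## Model and procedure

`txcoloc` tests spatial association between two region sets by Monte
Carlo permutation in transcript coordinate space. A transcript
annotation defines, per isoform, five *backgrounds*: the unspliced
pre-mRNA span, the spliced mRNA (exons), and the 5'UTR/CDS/3'UTR
partition of the mRNA in transcript orientation. Every isoform is an
independent coordinate system; overlap is only defined between regions
on the same transcript. All internal coordinates are 0-based half-open;
GTF input (1-based inclusive) is converted at the I/O boundary and BED
passes through unchanged.

Given features (possibly isoform-ambiguous genomic intervals) and
isoform-resolved ROIs, the test:

1. resolves each feature to its compatible isoform set — the transcripts
   whose chosen background it overlaps (strand must match; unstranded
   features match both strands), or the single transcript named in its
   BED record;
2. computes an observed statistic (default: the weighted overlap count
   C_weigh = Σ c(i)/n(i));
3. generates `ntimes` randomized region sets under a null model and
   evaluates each against the ROIs (default: count of random regions
   hitting an ROI on their own transcript — a 0/1 contribution per
   region, the same scale as c(i)/n(i));
4. reports the empirical p-value, z-score, and optionally BH-corrected
   grouped tests and shifted-z profiles.

Features that resolve to no transcript are dropped from both the
observed and the null side, so the statistic's range (0..S) is identical
across the comparison; drop counts are logged and reported.

## Null models

- **Whole-transcriptome**: placement is *slot-uniform* — a slot is a
  (transcript, start) pair with start ∈ [0, L − w]; slots are pooled
  over all transcripts and drawn uniformly, so every admissible position
  is equally likely and longer transcripts attract proportionally more
  regions. Region length is the feature's merged genomic span width.
- **Isoform-aware** (default): each feature is re-placed only on
  isoforms in its compatible set. The isoform is drawn uniformly
  (`length_weighted_isoform=True` switches to background-length
  weighting); the region length is the feature's projected exonic width
  on the drawn isoform (its genomic span width for the pre-mRNA
  background), so size is preserved in the coordinate system being
  permuted. Isoforms where the feature has zero projected width or does
  not fit are redrawn from the remainder; a feature placeable nowhere is
  excluded with a warning. Uniform isoform choice was picked because,
  absent expression information, each compatible isoform is an equally
  plausible origin, mirroring the 1/n(i) weighting of the observed
  statistic.
- **Custom transcript set**: slot-uniform placement restricted to a
  user-supplied transcript pool.

Reproducibility: generators take explicit integer seeds; batch
generation derives permutation k's stream from `SeedSequence([seed, k])`
so any one permutation is reproducible independently of how many were
requested. Identical inputs and seeds give bit-identical outputs.

## Evaluation

`count_overlaps_tx` counts A-regions with ≥1 same-transcript hit in B
(each A-region at most once — the regioneR-style "number of overlapping
regions" unit; pair-counting is available through the custom-metric
hook). The overlap threshold is one shared nucleotide; no
minimum-fraction option. `C_weigh` counts, per feature, the compatible
isoforms on which its projection hits an ROI, divided by n(i) — c(i) is
a sum of per-isoform 0/1 indicators, which keeps each term in [0, 1]
(counting multiple ROIs per isoform could exceed 1 and would break the
shared scale with the null). `W_weigh` replaces the indicator with
overlapping-nucleotide counts. Projected (genome-level) counting and a
custom-metric contract (any pure function of two region sets returning a
number, applied identically to observed and null sides) round out the
metrics. ROIs must be isoform-resolved; internally each ROI is a
transcript interval plus its genomic blocks.

## Significance

- Empirical p-value: add-one estimator (r+1)/(n+1) with ties counted as
  extreme, never 0, floor 1/(ntimes+1); two-sided = 2·min(tails) capped
  at 1 (no mid-p). This deliberately replaces a naive "percent more
  extreme", which can return 0.
- t-test option: one-sample t of the null sample against the observed
  value as fixed hypothesized mean ("greater" = observed above the null
  mean); it requires ≥2 null values with positive variance and can go
  below the empirical floor.
- z-score: (obs − mean)/sd with n−1 denominator; sd = 0 gives 0 when the
  observed equals the null mean, signed infinity (with a warning)
  otherwise.
- BH-FDR: candidates p(i)·m/i on the sorted p-values, step-down running
  minimum from the (m−1)-th item, capped at 1, returned in input order;
  the rejection rule finds the largest k with p(k) ≤ (k/m)α. The grouped
  multi-test report evaluates 0.05/0.1/0.2 plus any user α.

## Shifted z-scores

ROIs are shifted by d nucleotides along their own transcript's mRNA
coordinates (positive toward 3') for d on a symmetric grid of step
multiples up to the window; observed and null statistics are recomputed
against the shifted ROIs *reusing the stored randomized sets*, so the
offset-0 value is bit-identical to the base z-score. ROIs pushed across
a transcript boundary are dropped for that offset rather than clipped —
a partial ROI would change the statistic's meaning — and the per-offset
retained ROI count is recorded in the profile.

## Synthetic data

The generator targets the combinatorial structure of the problem, not
biological realism. Genes (default 30, on chromosomes `chrS1…`, 10 per
chromosome, never overlapping) carry a chain of exon slots; each slot
has one gene-level template exon plus a private lane per isoform, and an
isoform reuses the template with probability `shared_exon_prob`
(default 0.8) or takes its private exon. Sharing probability 1 forces
identical isoforms (maximal ambiguity), 0 forces disjoint ones (none).
Defaults: 3 isoforms per gene, 2–5 exons of 80–300 nt, introns
100–1000 nt, every transcript given a CDS occupying the middle ~60% of
its mRNA. ROIs default to 9-nt windows centered on the CDS 3' boundary —
a stop-codon-analog category, one per CDS-bearing transcript.
`plant_features` places a controlled fraction of features over ROIs (in
transcript coordinates, so they may span junctions) and the rest
uniformly on non-ROI background by rejection sampling, emitting genomic
spans with or without transcript IDs and a ground-truth table.
`sample_null_features` draws features from the null itself: an initial
slot-uniform set fixes the ambiguity structure, one isoform-aware redraw
produces the tested features.

What this does not emulate: realistic exon/intron length distributions,
expression-weighted isoform usage, GC or mappability biases, clustered
features, or noisy peak boundaries. Passing tests therefore demonstrate
the statistical machinery is correct under its own model, not that any
particular biological dataset is enriched.

## Numerical choices and scales

- Weighted statistics are accumulated as exact rationals
  (`fractions.Fraction`) and converted to float at the interface, so
  bound checks (0 ≤ C_weigh ≤ S) and the n(i)=1 reduction are exact.
- Overlap queries use per-chromosome interval trees for transcript
  lookup and sorted-array scans per transcript for evaluation; the
  brute-force double loop exists only as a test oracle.
- Simulation sizes in tests and the acceptance script (200 calibration
  replicates and 50 power replicates at S=100, ntimes=99; 100 region-set
  pairs of 100 regions) are the package's chosen desk-scale study
  conditions: large enough for 3-binomial-SD calibration bands and
  decisive t-tests, small enough to run in minutes on one CPU.

## Known limitations

- No expression-weighted isoform sampling or covariate matching beyond
  length preservation; no distance-based statistics (nearest-neighbour,
  Jaccard); no FWER procedures.
- The CDS span per transcript is a single genomic interval (min–max of
  CDS records); whether the stop codon is inside follows the GTF as
  given, with no ±3 nt adjustment.
- `COUNT_TX`/`COVERAGE_TX` require isoform-resolved features; ambiguous
  inputs must use the weighted metrics.
- Genome-level counting in the region-pair sampler is strand-agnostic
  (merged backgrounds pool both strands); the transcript-level counter
  is inherently strand-aware through transcript identity.
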