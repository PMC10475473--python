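# txcoloc

Transcriptome-aware colocalization analysis of region sets with
isoform-aware permutation tests.

## The problem

Colocalization (co-occurrence) analysis asks whether two sets of regions
— say RNA-methylation sites and stop codons — sit closer together than
chance would allow, by comparing an observed overlap statistic against a
null distribution of randomized region placements. Standard tools shuffle
regions over the linear genome. Transcriptome elements break that model
in two ways:

- **Transcriptome heterogeneity.** A gene expresses multiple isoforms
  that share exons on the genome but are independent coordinate systems
  as RNAs. Two regions that coincide genomically but belong to different
  isoforms do not actually overlap.
- **Isoform ambiguity.** Most technologies report transcriptome features
  (e.g. m6A sites from MeRIP-seq) as genomic coordinates without saying
  which isoform they came from.

`txcoloc` runs the permutation test in transcript coordinate space. It
shuffles regions within per-transcript backgrounds (pre-mRNA, mRNA,
5'UTR, CDS or 3'UTR), re-placing each feature only on the isoforms it is
compatible with (the isoform-aware null), and scores overlap with
weighted statistics that stay well-defined under isoform ambiguity.

## The statistics

For S features, where feature *i* is compatible with n(i) isoforms and
overlaps ROIs (isoform-resolved regions of interest) on c(i) of them,
the weighted overlap count is

    C_weigh = Σᵢ c(i) / n(i),        0 ≤ c(i)/n(i) ≤ 1,

and the weighted coverage replaces the 0/1 indicator by the
overlapping-nucleotide count w_j(i) averaged over isoforms:

    W_weigh = Σᵢ Σⱼ w_j(i) / n(i).

Each randomized region is isoform-resolved and contributes 0 or 1 to the
null count — the same scale as c(i)/n(i) — so observed and null values
are directly comparable. Significance comes from the add-one empirical
p-value (or a one-sample t-test), strength from the z-score
(observed − null mean)/null sd. Multiple grouped tests are corrected by
Benjamini–Hochberg FDR, and shifted z-score profiles (ROIs slid along
mRNA coordinates) test whether an association is tied to exact
positions.

## Worked example

`examples/01_permutation_test.py` builds a 30-gene synthetic
transcriptome (3 isoforms per gene, shared exons), plants 100 features
so that 80% fall on stop-codon-analog ROIs, and runs the isoform-aware
test:

```
100 features resolved (0 dropped); 90 ROIs
observed C_weigh = 67.17
null mean        = 9.04
p-value          = 0.0100  (empirical, add-one)
z-score          = 19.40
```

The observed weighted count (67 of a possible 100) dwarfs the ~9
overlaps expected under the isoform-aware null; the p-value sits at the
1/(ntimes+1) floor. The other examples cover the ambiguity weighting
itself (`02`), grouped multiple testing (`03`), shifted z-scores (`04`,
a sharp peak at offset 0 for planted enrichment) and the
genome-versus-transcriptome null contrast (`05`).

A thin CLI mirrors the library: `txcoloc test|multi|shiftz|simulate`
(see `txcoloc --help`), reading GTF annotation plus BED feature/ROI
files and writing JSON/TSV results with a config echo.

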