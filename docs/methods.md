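# Methods

## Scope and model of the data

`dropkit` analyses droplet single-cell RNA-seq runs of the Drop-seq type.
Read 1 of every fragment is 20 bp: a 12 bp cell barcode identifying the
bead/droplet, followed by an 8 bp unique molecular identifier (UMI).
Distinct UMIs per (cell barcode, gene) count mRNA molecules and collapse
PCR duplicates; the genes x barcodes table of distinct-UMI counts is the
digital gene expression (DGE) matrix, the substrate for everything
downstream.

UMI collapse is exact string match only. Merging UMIs within edit
distance 1 (as some upstream pipelines do) is deliberately out of scope:
it is an upstream correction, and exact collapse keeps the counting
operation verifiable against a trivial set-cardinality oracle. Likewise,
reads whose barcode or UMI contains an N or has the wrong length are
dropped and tallied, never corrected.

## Knee-point cell selection

Droplet loading is Poisson-limited: the large majority of beads (>95 % at
typical concentrations) are exposed only to ambient RNA and collect few
reads. Ordering barcodes by descending read count and plotting the
cumulative read fraction yields a curve whose inflection point ("knee")
separates cell-containing beads from ambient-only beads.

The visual inflection is formalized as follows: ranks are normalized to
[0, 1]; the cumulative fraction is smoothed with a centred rolling median
(window 5, identity on monotone stretches, so an exact step curve is not
displaced); the knee is the rank maximizing the perpendicular distance to
the chord joining the first and last points of the smoothed curve. The
chord-distance construction was chosen because it is deterministic,
scale-free, and needs no tuned parameters; the window (5) and the
weak-knee cutoff (maximum distance < 0.05, below which the curve is
essentially straight and the result is flagged `weak`) are both
configurable. On simulated runs with separation ratio (median cell reads
/ median ambient reads) >= 50 the knee recovers the true cell number
within +-10 %, and in practice exactly, across seeds.

Tie-breaks throughout (equal read totals, equal UMI totals in
`keep_best_cells`) are lexicographic by barcode, making every ranking
operation fully deterministic.

## Filtering rules and QC

Cells are discarded when they have *fewer than* a threshold number of
UMIs — the boundary cell is kept. The threshold is bound to a sample
profile: 3500 UMIs for cultured cell lines, 1000 for fly embryo cells,
300 for mouse brain cells; all overridable. Gene filtering drops genes
whose total count across retained cells falls below a minimum.

Cell-level filters (UMI threshold, top-n selection) commute with each
other, because a cell's total does not depend on which other cells are
present. The gene filter does not commute with cell filters — removing
genes changes cell totals — so pipeline order matters and the CLI applies
the cell filter first; reported medians always describe the matrix
actually passed to `cell_qc`, so genes-per-cell can be computed before or
after filtering by choosing where in the chain QC is run.

The non-mitochondrial content of a cell is
`100 x (total UMIs - mitochondrial UMIs) / total UMIs`. Low values
indicate broken cells leaking cytoplasmic mRNA; values at or near 100 %
indicate bare nuclei, which carry no mitochondria. Candidate nuclei are
flagged when the mitochondrial percentage is strictly below
`max_mito_percent`, default 1 % — "substantial" mitochondrial expression
has no canonical definition, so the threshold is surfaced in every
report. Zero-UMI cells get a NaN percentage and are excluded from
medians rather than raising, since QC may legitimately run before any
filtering.

## Barnyard doublet estimation

For a two-species mixture the per-barcode UMIs are split by species
(disjoint gene namespaces, species-prefixed identifiers with the
annotation table authoritative). Purity is the majority species' share
of the barcode's UMIs. A barcode below the UMI threshold is
`below_threshold`; otherwise purity >= 0.90 declares the majority
species — the boundary is inclusive, so exactly 90 of 100 UMIs declares
the cell — and anything less pure is a cross-species doublet. The UMI
threshold is applied before doublet classification.

Same-species doublets are invisible to this readout. Under random
co-encapsulation with mixing proportions (p, q) a doublet is
cross-species with probability 2pq, so the total doublet rate is
estimated as `cross_fraction / (2pq)`, where `cross_fraction` is
doublets / (doublets + singlets) among classified barcodes. Ambient
cross-species UMIs are not subtracted before classification; with heavy
ambient contamination this biases the doublet fraction upward, which is
why the summary reports raw label counts alongside the estimate.

## Normalization and correlations

ATPM (average transcripts per million): each cell's counts are divided by
that cell's total UMIs and multiplied by the maximum total over cells in
the library, so all normalized cell totals are equal. ATPM is
homogeneous of degree 1 — multiplying every raw count by a common factor
multiplies ATPM values by the same factor — while each cell's relative
composition is invariant; a single-cell matrix is a fixed point.
Zero-total cells are dropped with a warning rather than producing
undefined columns.

Cross-sample correlations subset both profiles to the intersection of
genes captured in both libraries, transform as log2(value + 1) (base 2,
pseudocount 1), and compute Pearson's r. Single-cell samples are
aggregated to pseudobulk by summing raw counts per gene *before* the
transform; normalizing per cell and then summing is intentionally not
done. Bulk comparators are converted to RPKM,
`count / (length/1000) / (total_mapped_reads/1e6)`, with gene length
taken as the mean of the gene's isoform lengths, supplied as annotation
metadata (computing it from a GFF is a helper concern, not core).

## The simulator

`simulate_run` emulates the structure of a droplet run with full ground
truth, so every stage above can be validated by parameter recovery rather
than against external data. Per barcode:

* **Cells.** `n_cells` barcodes contain a cell; each cell's species is
  drawn from `species_proportions`, its library size (total molecules)
  log-normal with `library_size_log_mean`/`_sd`, and its molecules'
  genes multinomial from the species' expression profile. Profiles are
  log-normal per-gene means (spread `expression_profile_dispersion` in
  log space) normalized to sum to 1, with the mitochondrial gene block
  rescaled to carry expected mass `mito_expression_fraction`.
* **Doublets.** With probability `doublet_rate` a cell barcode receives a
  second, independently drawn cell (species drawn from the mixing
  proportions), mirroring co-encapsulation. Cross-species doublets are
  therefore a 2pq fraction of all doublets.
* **UMIs.** Distinct 8-mers per (barcode, gene), drawn uniformly with
  collision re-draw; each molecule is emitted as `1 + Poisson(mean - 1)`
  duplicate reads, guaranteeing every molecule is seen at least once.
* **Ambient beads.** `n_ambient_barcodes` beads draw
  `Poisson(ambient_reads_mean / reads_per_umi_mean)` molecules from the
  pooled pseudobulk of all species, then duplicate like cell molecules,
  so their mean read count is `ambient_reads_mean`.
* **Bead-synthesis defect.** With probability `last_base_t_error_prob`
  the 12th barcode base is overwritten with T for *all* reads of the
  bead (the defect originates in bead synthesis, so it is a property of
  the bead, not the read). Post-corruption barcode collisions are
  regenerated so the truth ledger stays one row per observed barcode.
  The defect's magnitude is not quantified anywhere authoritative; the
  default 0.05 is a deliberately modest rate, and the diagnostic
  (`barcode_base_composition`) measures the induced T excess
  `freq(T, pos 12) - mean freq(T, pos 1-11)`, with expectation
  `0.75 x error_prob` for otherwise-uniform barcodes.

Randomness uses one master seed with named sub-streams per component
(profiles, cells, ambient, UMIs, duplication, barcodes), so e.g. adding
ambient barcodes never perturbs the cell draws, and identical parameters
give byte-identical output.

Default parameters describe a desk-scale two-species cell-line run: 150
cells against 3000 ambient beads (>95 % of beads ambient-only), 2000
genes per species, median ~5000 UMIs and ~4 reads per molecule per cell
(~20 000 reads per cell), 10 % doublets, 1 % of genes mitochondrial
carrying 10 % of expression. Validation runs scale these down or up as
stated in each test: knee recovery uses 100 cells / 2000 ambient beads at
median ~2000-UMI libraries (separation ratio well above 50); doublet
recovery uses 1000-cell equal-mix barnyards with ~1000-UMI libraries and
a 250-UMI classification threshold (libraries deep relative to the
threshold, so no singlet is lost to it).

### What the simulator does not emulate

No sequencing errors in UMIs or cDNA, no transcript sequences, no
droplet physics beyond Poisson intuition, no ambient contamination
*inside* cell-containing droplets, no gene-length or GC capture bias,
and no cross-species homology (namespaces are perfectly disjoint).
Passing parameter-recovery tests therefore demonstrates the estimators
are correct under the generative model, not that real libraries satisfy
that model; in real data ambient contamination inflates the doublet
fraction and softens the knee, which is why the species-call summary and
knee result carry their diagnostics (label counts, confidence flag)
rather than bare point estimates.

## Numerical and degenerate-input choices

* Counting and filters are integer-exact; ATPM conservation holds to
  1e-9 relative, limited only by float division.
* `find_knee` requires >= 3 barcodes; an all-equal-counts curve returns
  rank 1 with a `weak` flag instead of failing.
* A profile correlated with itself returns exactly 1.0 (short-circuited
  before floating-point accumulation).
* Empty read streams produce an empty 0 x 0 DGE matrix, not an error;
  an all-zero matrix rejects ATPM normalization.
* DGE I/O validates on read — duplicate identifiers, negative,
  fractional or missing entries are rejected with the offending gene and
  line number — so round trips are the identity on valid matrices in
  both the dense TSV and Matrix Market triplet dialects.
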