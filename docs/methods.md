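# Methods

## Data model

A methylation call is stored as the 5-tuple
`(sample_id, chromosome, position, statistic, read_id)` with a 1-based
single-nucleotide position at the CpG cytosine on the reported strand
and a natural-log likelihood ratio (LLR) as the statistic — positive
values favor methylation. The LLR convention follows nanopolish; the
methylation probability is recovered by the sigmoid transform
`p = 1/(1 + e^{-LLR})`.

Caller dialects map onto this record as follows:

* **nanopolish / f5c** report a 0-based `start` at the first CpG of a
  call, so the first motif maps to `start + 1`. A call may cover
  `num_motifs > 1` CpGs; the CG offsets of the reported `sequence`
  context give the spacing of the remaining motifs. Each split motif
  inherits the group's LLR unchanged: the group statistic is a joint
  likelihood ratio and there is no principled way to apportion it
  additively across motifs, so copying preserves the evidence sign and
  magnitude at every covered site. f5c emits identical columns and is
  parsed by the same code path.
* **Megalodon** reports per-site natural-log probabilities of the
  modified and canonical base. The statistic is
  `mod_log_prob − can_log_prob`, which makes
  `sigmoid(statistic) = e^{mlp}/(e^{mlp}+e^{clp})` an exact identity —
  the normalized modification probability. Columns are located by header
  name because Megalodon's column order varies between versions.
  Strand collapsing (shifting minus-strand calls −1 bp onto the
  forward-strand cytosine) is available but off by default, preserving
  the caller's coordinates.

Parsing is lenient by default — malformed lines are counted and skipped,
since real caller output commonly ends in a truncated line — and strict
mode turns them into errors carrying the line number.

## Storage

Records are sorted by chromosome (plain lexicographic byte order; tabix
only requires chromosomes to be grouped, and byte order is reproducible
everywhere) and numeric position, using an external merge sort with a
configurable in-memory chunk (default 10⁶ rows) so arbitrarily large
inputs convert in bounded memory. The sorted TSV is bgzip-compressed and
tabix-indexed (sequence column 2, begin/end column 3, 1-based), making
the file readable by any htslib tooling. Statistics are serialized with
6 significant digits (relative round-trip error ≤ 1e-6). Queries are
1-based fully closed, matching the stored coordinate; a chromosome
missing from the index returns an empty result with a warning rather
than an error. The sample manifest (sample → group) lives in a small
sidecar TSV so the indexed file keeps its minimal 5-column shape.

## Counting and export

Binarization of an LLR into a methylated/unmethylated call uses the sign
of the statistic with an optional symmetric dead-zone `t`
(`> +t` methylated, `< −t` unmethylated, `|LLR| ≤ t` discarded).
The default is `t = 0` — the minimal-assumption rule; `t = 2` is a
common confidence filter for nanopolish-style output and is exposed as a
parameter. Counts feed three export shapes: per-sample `(chr, pos, N, X)`
tables (DSS-style), a wide paired `Me_*/Un_*` table (edgeR-style), and
coordinate + methylation + coverage matrices (bsseq-style).

The log-methylation-ratio is `log2((Me + c)/(Un + c))` with prior count
`c = 2`, following the log-ratio-of-counts convention of the edgeR
bisulfite workflow; the pseudocount keeps every entry finite. Sites
whose total coverage over all samples falls below a threshold (default
1 call) are dropped so all-pseudocount rows cannot dominate variance
ranking.

## Profiles

Smoothing operates on probabilities and uses degree-1 locally weighted
regression with tricube weights (lowess, via statsmodels), no
robustifying iterations, evaluated at the input positions and clamped to
[0, 1]. Two reductions keep it tractable and well-behaved:

* **Per-site means before smoothing.** All reads at a site are averaged
  first, so the smoother's cost scales with the number of distinct sites
  rather than the number of calls. Note the averaging consequence: two
  reads confidently called 0.99 and 0.01 average to 0.5, the same value
  a single low-confidence call produces — biological heterogeneity and
  caller uncertainty are deliberately confounded in these views and are
  not de-confounded here.
* **Binned means on the relative axis.** For aggregate profiles each
  feature body is mapped linearly to [0, 1] and fixed-width flanks
  (default 2000 bp) to [−f, 0) and (1, 1+f] with display fraction
  f = 1/3, minus-strand features mirrored so 0 is always the 5′ end.
  Because bodies contain far more data points per axis unit than flanks,
  a nearest-neighbour smoother would borrow almost all its points from
  the body near the boundary; equal-width binned means (default 100
  bins over the full [−f, 1+f] axis) restore uniform density. Empty
  bins are omitted rather than interpolated so sparse flanks do not
  invent signal.

Aggregate profiles are a two-stage average: binned means within each
feature, then an unweighted per-bin mean across features. Every feature
therefore carries equal weight regardless of read depth — a
100×-covered gene influences the curve no more than a 1×-covered one —
which is verified by a duplication-invariance test. Default smoothing
spans are 0.2 for region trends and 0.3 for aggregates; per-read
spaghetti lines are smoothed independently per read, and curves with
fewer than 5 points pass through unsmoothed with a flag. Features with
strand "." are treated as "+".

## Embeddings

Sample embeddings operate on the log-methylation-ratio matrix restricted
to the `k` most variable sites (default 500, sample variance with
denominator n−1, ties broken by coordinate order; sites with zero
coverage in any sample are removed first since their ratios are pure
pseudocount). The pairwise sample distance is the root-mean-square
difference over the retained sites, computed on one common site set by
default; per-pair re-selection of the most different sites is available
behind a flag. Classical (Torgerson) multidimensional scaling —
double-centering of squared distances followed by eigendecomposition,
dimensions ordered by eigenvalue — embeds the samples; a site-centered
PCA via SVD (coordinates `U·S`, explained fractions `s_i²/Σs²`) is the
alternative. Both fix signs so the largest-magnitude coordinate of each
dimension is positive, making plots reproducible across runs. An
all-equal-sample input yields zero coordinates with a `degenerate`
flag rather than an error.

## Figures

Spaghetti plots draw thin per-read smoothed lines and thick per-group
trends, CpG tick marks at every distinct called site, merged exon boxes
below the axis, and shading for the top-n DMRs by rank (default 500,
larger rank = more differential) that overlap the window (closed-
coordinate intersection). Read heatmaps show one unsmoothed colored
cell per call on a fixed diverging scale anchored at p = 0.5, with reads
packed into lanes by first-fit in ascending start order (ties by read
id) — optimal on interval graphs, so the lane count equals the maximum
overlap depth. Cells default to fixed pixel width because CpG spacing
makes bp-proportional cells invisibly thin at gene scale; a
bp-proportional mode exists. Groups render in sample-sheet order, and a
group with no data in the window is warned about and omitted, never
fatal. `save_figure` pins matplotlib's SVG hash salt and suppresses the
date stamp so vector output is byte-reproducible.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume: a
per-group methylation landscape (background level with interval
overrides for promoter-like dips and DMR-like group differences), CpG
sites fixed per landscape (explicit positions or random at 0.02/bp,
about one CpG per 50 bp, with ≥2 bp spacing), reads with lognormal
lengths (median 5 kb, σ = 0.55) and uniform starts at a target coverage,
one Bernoulli(μ) methylation state per (read, site) so single molecules
are internally consistent, and a two-component call-noise model:
methylated states emit LLR ~ N(+m, s), unmethylated N(−m, s) with
defaults m = 4, s = 1.5 — mostly confident calls with a realistic
ambiguous tail near p = 0.5. A configurable fraction of emitted
nanopolish rows (default 0.2) are grouped multi-motif calls whose
sequence contexts contain the CG motifs at the correct offsets; the
Megalodon file carries the same realized calls site-by-site. Everything
is deterministic given the seed, including site placement (hashed per
chromosome with a stable CRC so results do not depend on the process
hash seed).

What the generator does **not** model: sequence composition beyond CG
placement, mapping and alignment artefacts, strand asymmetry,
position-dependent caller error, or correlated methylation along a
molecule (states are independent across sites within a read, except
within grouped calls). Passing tests therefore demonstrate correctness
of the data path and the statistical machinery under a clean generative
model, not robustness to the full error structure of real flow-cell
data.

Note one edge effect used deliberately in the evaluation sizing: reads
start uniformly along the chromosome and truncate at its ends, so
realized depth near the edges (and on average) falls below the nominal
coverage parameter. Recovery checks that condition on a per-site depth
of ≥ 50 therefore simulate at nominal coverage 65 so that qualifying
sites span all methylation levels instead of only the
upward-fluctuating interior.

## Evaluation sizes and numerical choices

The automated checks run on one CPU in a few minutes: a 10⁵-record
store with 200 random queries against a linear-scan oracle; 100 seeded
two-group simulations (150 sites, 3+3 samples, Δμ = 0.4, coverage 50)
for MDS separation; 1,000 random interval sets for packing optimality;
and a 50 kb chromosome at coverage 65 for end-to-end truth recovery.
Streaming memory is checked with tracemalloc on a 2×10⁵-line generated
stream, a size chosen to keep the suite fast while still two orders of
magnitude above the parser's working set.

Tolerances: sigmoid/logit identities at 1e-12; MDS planar recovery and
permutation invariance at 1e-8 (Procrustes); lowess-vs-least-squares at
1e-6 on exactly linear input; aggregate duplication invariance at
1e-12; stored statistics at 1e-6 relative. Degenerate inputs are
defined rather than rejected where a sensible value exists: a single-bp
feature body maps to relative position 0.5, the last bin of a binned
domain is closed, and an all-zero distance matrix yields a flagged zero
embedding.

## Known limitations

* DMR detection itself is out of scope; the package exports DMR-tool
  inputs and consumes a DMR table for shading only.
* No FAST5/POD5 signal handling, basecalling, alignment or haplotyping;
  haplotype enters only as a sample group label.
* Stores are immutable: updates are rebuilds, not edits.
* Plots are static (PNG/SVG/PDF); no interactive output.
* The flank display fraction, smoothing spans and heatmap color scale
  are conventional choices exposed as parameters, not estimates.
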