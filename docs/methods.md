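# Methods

## Scope and data model

All computation is transcript-relative: one canonical isoform per gene,
represented as a contiguous sequence partitioned into 5′UTR, CDS (including
the stop codon) and 3′UTR. Coordinates are 0-based and half-open
throughout; codon *k* occupies CDS nucleotides [3k, 3k+3). Where an
annotation carries several isoforms, one is reduced per gene by: canonical
tag, else longest CDS, else longest transcript, else lexicographically
smallest id. Genome-space mapping, splice junctions and multi-isoform
quantification are out of scope.

## Read preprocessing

Adapter trimming removes, from each read's 3′ end, the earliest suffix that
exactly matches a prefix of the adapter (minimum overlap 3 nt, both
configurable); reads shorter than a minimum length afterwards are
discarded. Matching is exact — no error tolerance is attempted, since
trimming dialects differ between tools and the downstream analysis is
insensitive to a nucleotide of slack. Quality filtering keeps reads whose
*mean* Phred score exceeds the threshold (default 33); a `min` mode
requiring every base to pass is available, since "quality score > t" is
ambiguous between the two readings.

The layered alignment filter consumes per-fragment annotations produced by
an external aligner — a contaminant flag (rRNA/tRNA/snRNA alignment) and a
transcriptome-hit count — and applies, in order: drop contaminants, keep
unique mappers. Survivor counts of each layer are recorded per library.
The filter's contract is the layering order and the bookkeeping, not the
alignment itself.

## A-site assignment and counting

Ribosome-protected fragments are attributed to the codon in the ribosomal
A site by a length-dependent offset from the fragment 5′ end:

| fragment length | offset |
|---|---|
| ≤ 29 nt | +14 |
| 30–31 nt | +15 |
| 32–35 nt | +16 |
| ≥ 36 nt | +17 |

Fragments whose A site falls outside the transcript are dropped (and
counted), not clipped; dropping keeps the position distribution honest at
the 3′ edge. RNA-Seq reads carry no ribosome, but they are positioned by
the same length-based rule so that Ribo and RNA libraries are counted over
byte-identical windows — the TE ratio then cancels any windowing artefact.

Gene-level counts sum A sites inside the CDS minus its first 15 and last 5
codons. The 5′ mask removes the initiation-proximal pileup that
cycloheximide-arrested ribosomes produce; the 3′ mask removes termination
artefacts. Genes whose CDS cannot accommodate the 60-nt mask are excluded
and logged.

## Library QC

Four diagnostics characterize a footprint library: the fragment-length
histogram (a discrete mode near 30 nt), the 5′UTR/CDS/3′UTR partition of
A sites (CDS-dominated for genuine footprints), the frame distribution of
CDS A sites ((A − CDS start) mod 3; strongly phased for elongating
ribosomes), and metagene profiles of per-nucleotide density over
[−30, +150) around the CDS start and [−150, +30) around the CDS end.
Metagene genes must have 5′UTR ≥ 50 nt, 3′UTR ≥ 50 nt, CDS ≥ 500 nt and at
least 300 assigned reads (inclusive), so the windows never cross a second
region boundary and sparse genes do not dominate; each gene's counts are
divided by its total assigned reads before averaging, making the profile
invariant to any one gene's expression level. Libraries are pooled by
default; computing per replicate is a matter of subsetting the fragment
table.

## The TE model

Counts follow a negative binomial with mean/dispersion parameterization
(Var = μ + αμ²; α = 0 is Poisson). Per library, log μ is the sum of a
log size factor offset and a linear predictor over: intercept, library-type
indicator (Ribo = 1), drop-first replicate indicators, and, in the
two-tissue analysis, a tissue indicator plus the library × tissue
interaction. The library-type coefficient divided by ln 2 is log2 TE; the
interaction coefficient divided by ln 2 is Δlog2 TE (second tissue minus
first, in the order tissues appear in the design — the convention is
recorded on the results object).

Size factors are DESeq median-of-ratios: per library, the median across
genes of the count over the gene's geometric mean across libraries, using
only genes with no zero anywhere; factors are normalized to geometric
mean 1. If no gene is everywhere-nonzero the estimator refuses, and a
`fallback_positive` flag switches the reference to the geometric mean over
positive counts only.

Coefficients are maximum-likelihood via iteratively reweighted least
squares with log link, batched across genes (working weights
W = μ/(1 + αμ)); the inverse Fisher information at convergence supplies the
Wald covariance. Genes with all-zero counts in either library type are
excluded before fitting (TE is undefined for them) and reported as NA with
class `none`. Non-converged genes (50 iterations, step tolerance 1e-8) are
likewise NA.

### Dispersion

Three estimators are provided; all are deterministic.

* **per-gene** — each gene's (adjusted) profile likelihood is maximized on
  a 61-point log-spaced grid over [1e-8, 10], refined by a local quadratic
  in log α; likelihood ties (flat at tiny α) resolve to the smallest α, so
  zero-variance genes sit at the floor.
* **trend** (default) — the mean–dispersion trend α(μ) = a₀ + a₁/μ is
  fitted by maximizing the summed adjusted profile likelihood jointly
  across genes (Nelder–Mead over log parameters, seeded by a constant-α
  scan), and every gene receives its fitted value.
* **maximum** — elementwise maximum of the two, the conservative sharing
  rule.

The Cox–Reid adjustment (−½ log det X′WX) is applied by default: in the
standard six-library design only ~2 residual degrees of freedom remain per
gene, and unadjusted ML underestimates α several-fold, which would inflate
Wald type-I error far above nominal. Even adjusted per-gene estimates are
too noisy to plug into a normal Wald test at this replication level —
doing so produces heavy, t-like tails — which is why the fitted trend is
the default: with thousands of genes the two trend parameters are
estimated with negligible error, and the null Wald p < 0.05 rate lands at
its nominal 0.05 (checked by the calibration experiment below). Genuine
gene-to-gene dispersion variation beyond the trend is not captured in
trend mode; `maximum` is the guarded alternative when that is a concern.

### Testing and classification

Each gene's log2 TE is compared against the cross-gene median by
z = (log2TE − median)/SE with the median treated as a constant — across
thousands of genes its sampling error is negligible relative to per-gene
SEs. Two-sided normal p-values are Benjamini–Hochberg adjusted per
analysis. Classes: **TE-low** requires FDR < 0.05 and
log2TE ≤ median − log2 3; **TE-high** is symmetric. Between tissues,
Δlog2 TE is tested against zero; tissue-specific classes require FDR < 0.2
and |Δlog2 TE| ≥ 1. All four thresholds are arguments.

TE classes can be cross-tabulated against sequence features (5′UTR and
3′UTR length, uAUG count) with per-class medians and a two-sided
Mann–Whitney test of TE-low genes against the rest; classes with fewer
than two members report summaries only.

## uORF annotation and mutagenesis

The scanner reports two kinds of upstream initiation sites in a 5′UTR:
every AUG regardless of context, and the nine near-cognate codons (Hamming
distance 1 from AUG: CUG GUG UUG ACG AGG AAG AUA AUC AUU, configurable)
when their Kozak context is favourable. The default favourability rule is
G at −1 and A/G at +3 with the codon occupying positions 0–2 (the first
base *after* the codon is +3); the classical convention — A/G at −3, G at
the position after the codon under 1-based numbering — is available as
`convention="standard"`. Missing context at a sequence edge is
unfavourable. The context window may extend into the CDS for sites near
the boundary.

Each site's frame is translated codon-by-codon through the UTR and into
the CDS until the first stop (UAA/UAG/UGA). A **uORF** requires that stop
to lie *entirely within the 5′UTR*; a frame whose first stop straddles the
UTR/CDS junction or lies beyond it overlaps the main ORF and is an
**oORF** when out of frame with the main start, or an **in-frame
extension** at frame offset 0 (a straddling stop cannot occur in frame 0,
since in-frame codons align with the CDS start). The entirely-within rule
is what makes frameshift arithmetic exact: inserting k nt immediately 5′
of the CDS shifts every no-stop frame by k mod 3 and leaves true uORFs
untouched, so a +1 followed by a +2 insertion provably restores every
AUG site's class. Near-cognate sites in the last codons of the UTR are
*not* insertion-stable — their +3 context base is the inserted nucleotide
itself — which is a property of context-dependent initiation, not of the
implementation.

Mutagenesis operations mirror reporter dissections: start-codon point
mutation (AUG → AAG/CAG), stop-codon point mutation (e.g. ugUGA → ugAGA,
which fuses a uORF into the downstream frame), and insertion of C/CC just
before the CDS for frameshifts. Each returns the mutated sequence with a
fresh annotation; replacements that themselves create a new AUG are
allowed but flagged. uAUG clustering is reported descriptively as groups
separated by more than a configurable gap (default 50 nt); no statistical
model of clustering is implied.

Sequences may be DNA or RNA; annotation is invariant under T↔U.

## Reporter and polysome statistics

Reporter TE is (Fluc/Rluc activity)/(Fluc/Rluc RNA) referenced to the same
quantity for a control-UTR construct measured in the same batch, so the
reference maps to 1 and any per-batch rescaling of all four quantities
cancels. Batches are referenced individually, then averaged, with the SD
across batches reported.

Polysome association corrects each sucrose-gradient fraction's qPCR
quantity by its spike-in recovery, then reports the heavy-fraction share
of the corrected total in percent. Which fractions are "heavy" is an input
label — gradient geometry is apparatus-specific — with a helper marking
fractions at or beyond a given index. Changes between samples are reported
as log2 ratios of the percentages. Group comparisons use the two-sided
two-sample t-test (equal-variance by default, Welch by flag) with
conventional stars (** p<0.01, * p<0.05, NS).

## The synthetic-data generator

The generator emulates the structure of a replicated embryonic
profiling experiment: up to two tissues × three biological replicates ×
{Ribo-Seq, RNA-Seq}. Counts are NB draws (gamma–Poisson mixture; α = 0
degenerates to exact Poisson) with mean
s_j · μ_g · 2^(log2TE_{g,tissue} · [j is Ribo]), fully determined by the
seed. Transcripts are random sequences whose CDS starts with AUG, ends
with a stop and contains no internal in-frame stop; 5′UTRs are generated
AUG-free and uAUGs are then planted at recorded positions (planting an ATG
into an ATG-free sequence cannot create a second one), so the planted set
is exactly what a scanner must report — the recoverability tests rest on
this construction.

Positional fragments are placed A-site-first: the A site falls in the CDS
with probability `cds_fraction` (default 0.8), else in the UTRs
proportional to length; within the CDS, the first 15 codons carry
`ramp_fold` (default 3.0) times the interior density and the within-codon
position follows `frame_bias` (default 0.7/0.15/0.15); fragment lengths
follow a distribution over 26–36 nt with mode 30. The 5′ end is the A site
minus the length-dependent offset; placements that would leave the
transcript are resampled with the region assignment retained, so the
realized CDS fraction matches the target exactly rather than drifting with
edge rejections. RNA fragments are uniform over the transcript. Defaults
were chosen once to resemble a good-quality footprint library — a sharp
~30-nt mode, strong but imperfect phasing, ~80% CDS occupancy, a
several-fold initiation-proximal ramp — and are deliberately configurable
rather than calibrated to any particular deposited dataset.

What the generator does **not** emulate: sequencing errors, rRNA
contamination reads (the layered filter is exercised with labelled flags),
multimapping, genome alignment, isoform mixtures, positional biases beyond
the ramp (codon-specific dwell times, GC bias), or mean-dependent
dispersion trends (α is set per gene). Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to every artefact of real libraries.

## Validation experiments and problem sizes

`ribote.validation` fixes the study scale used by the test suite and the
acceptance script: 2,000 genes, 3 replicates per condition, NB dispersion
0.05; mean CDS count 200 for single-tissue analyses and 500 for the
two-tissue interaction (interaction SEs are twice as wide, so the
between-tissue experiment is run at the depth a practitioner would demand
of it); 10% of genes planted per shifted stratum, mirroring the roughly
one-in-ten TE-regulated genes reported in embryonic tissue. QC recovery
uses 100 transcripts × 1,000 footprints (~10⁵ fragments). At these sizes
the full pipeline — size factors, trend dispersion, batched IRLS, testing,
classification — completes in seconds per experiment on one core.

## Numerical choices

* IRLS linear predictors are clipped to ±40 before exponentiation; means
  are floored at 1e-10 in the working response.
* The NB log-likelihood switches to its Poisson limit below α = 1e-6,
  where the exact gamma-function form loses floating-point precision and
  the NB correction is far below likelihood differences that matter.
* Dispersion grid: 61 log-spaced points on [1e-8, 10]; quadratic
  refinement only at interior maxima; ties break to the smallest α.
* The A-site offset function is piecewise-constant and non-decreasing;
  fragments are counted by A-site membership, never by overlap.
* Degenerate inputs have defined outcomes: empty fragment tables give
  empty histograms/zero tables; metagene with no surviving genes returns
  an all-zero profile with `n_genes_used = 0`; unreplicated designs refuse
  dispersion estimation rather than returning a number.

## Known limitations

* The TE model assumes a single canonical isoform per gene; isoform
  switching between libraries will masquerade as TE change.
* The median-TE reference makes per-gene TE a relative quantity; a global
  shift of translation affects all genes' absolute TE but no gene's call.
* Trend-mode dispersion ignores gene-specific overdispersion beyond the
  fitted mean trend (see Dispersion above for the alternatives).
* The uORF scanner evaluates sequence context only; it does not use
  initiation-site profiling evidence, conservation or RNA structure.
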