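# Methods

## Scope and design

`mirnet` re-implements the plant miRNA annotation-and-network analysis
chain as a desk-scale, fully deterministic library. External tools that
a production pipeline would call (a read mapper, a miRNA predictor, a
target predictor, a degradome classifier, a collinearity scanner) are
replaced by functionally equivalent simplified stages implemented here,
so that every inference is inspectable and testable against planted
ground truth. The synthetic-data module is first-class code: it defines
the study conditions the tests and the acceptance script run under.

## Synthetic data: what it emulates, what it does not

`synthio` generates a random genome with two kinds of planted loci.

**miRNA hairpins.** Each precursor is built as
`ext5 + arm5 + loop + arm3 + ext3`: a duplex whose arms pair over m−2
positions with the canonical 2-nt 3′ overhang geometry, an 8–40 nt
A/C-only loop, and a complementary lower stem (`ext3 = revcomp(ext5)`
with up to two planted mismatches). Mature length is drawn from
{20: 10%, 21: 60%, 22: 15%, 23: 10%, 24: 5%} and the first nucleotide
is U with probability 0.6, matching the length/first-nt preferences of
plant miRNAs. Total precursor length is drawn so that 80% fall below
150 nt (90–149 nt vs 150–220 nt), reproducing the short-precursor bias
of real annotations. The mature arm is 5′ or 3′ with equal probability;
a configurable fraction of loci share a family (identical mature
sequence re-embedded in a fresh hairpin).

Sequence constraints at the duplex junctions matter: an RNA duplex is
near-palindromic, and if the unpaired 2-nt tails can pair with the
facing lower stem, the loop, or the mature 5′ end, the minimum-free-
energy structure slides the duplex register by 1–3 nt relative to the
design. The generator therefore (i) chooses tail and junction bases
from non-pairing alphabets and (ii) folds every designed precursor and
rejection-samples (up to 200 draws) until the MFE structure reproduces
the planted duplex exactly, under the same star-derivation convention
the caller uses. The planted truth is thus structurally self-consistent
by construction, which is what makes exact star-interval recovery a
meaningful test rather than a coin flip over thermodynamic ties.

**Sequencing reads.** Per-locus abundance is lognormal with
σ_log = 1.5 (matching the several-orders-of-magnitude RPM range of real
miRNA panels), optionally modulated by a per-tissue lognormal effect
(σ = 0.8) derived from the truth seed so replicate libraries share
locus means. Counts are negative binomial with dispersion 0.05 (mild
overdispersion: replicate count correlation stays above 0.9 at the
reference depth, consistent with technical-plus-biological replicate
behaviour). A locus's reads are split by the `precision` parameter:
signal reads start exactly at the mature (75%) or star (25%) 5′ end;
the remainder are random-offset 20–24-mers from the precursor. siRNA
loci emit uniformly dispersed 24-mers on both strands; leftover depth
is genome-wide background. No sequencing-error or quality model is
included (quality strings are a constant placeholder), so tests say
nothing about error-tolerant mapping.

**Targets, degradome, expression, TF inputs.** Each planted target
transcript carries one perfect-complement site; the cleavage position
is the base opposite miRNA position 10 (1-based
`site_start + m − 9`). Degradome tables put `signal_reads` counts at
each planted cleavage position plus uniform noise. Expression profiles
are lognormal per tissue; an exact `round(f·n)` subset of pairs gets a
target profile that is an affine negative transform of its miRNA
profile (Pearson r = −1 over tissue means at zero noise); the rest are
independent. Because profiles are heavy-tailed (spiky), chance strict
anti-correlation among independent pairs is rare (~1% at 4 tissues),
so the planted fraction is recoverable within binomial error — a
property that would not hold for near-Gaussian profiles, whose 4-point
correlation is uniform on [−1, 1]. PWMs put weight 0.85 on a random
consensus; planted promoter sites are exact consensus instances.

## Discovery

Stacks map to the genome by exact match on both strands via an 18-mer
prefix index (one linear scan of the genome); stacks with more than 20
placements are flagged multi-mapped and excluded from seeding. Each
qualifying placement (count ≥ 5) seeds two windows, `[start−250, end)`
and `[start, end+250)`; overlapping windows merge while the merged span
stays ≤ 300 nt. Windows whose read signature cannot reach the precision
threshold (an upper bound from the two strongest 5′-end positions) are
rejected before folding, which keeps whole-genome discovery at the
reference scale under ~15 s.

Duplex calling takes the most abundant stack as the mature, collects
the structure partners of its first m−2 bases (the 3′ overhang is not
part of the duplex), clusters them to the dominant contiguous run
(stray pairings into flanks or the loop are scored as mismatches), and
derives the star as that span extended 2 nt at its 3′ edge; overhang
partners within 2 nt of the span are included, which absorbs the
one-pair register shifts MFE folding produces at bulged junctions.
Precision counts reads whose 5′ ends lie within ±1 nt of the mature or
star 5′ end. Acceptance thresholds (all configurable): precision
≥ 0.75, mature 20–24 nt, duplex mismatches ≤ 5, asymmetric bulge
≤ 3 nt, ≥ 10 reads, ≥ 1 miR\* read. The miR\* requirement follows the
published plant criteria and is what separates genuine hairpins from
occasional fold-competent read stacks inside siRNA regions.

Because a hairpin's reverse complement is also a hairpin and duplex
reads map to both strands (shifted by the overhang), one locus can
surface as two calls; deduplication keeps, per overlapping genomic
duplex span, the call with more supporting reads (the true orientation
captures all signal reads, the antisense twin only the palindromic
subset), then higher precision. Reported precursor intervals extend
the duplex span outward along enclosing base pairs (≤ 4-nt unpaired
tolerance), recovering the lower stem. Families co-name loci whose
matures are within 2 mismatches (equal length), via union-find.

Folding is pluggable: ViennaRNA MFE when the bindings import, else an
internal Nussinov base-pair maximization (minimum loop 3; AU/GC/GU
pairs; traceback prefers the outermost pairing, which yields clean
stems on designed hairpins).

## Conservation, context, expression, targets, correlation, network

*Conservation*: query set = mature plus all ≤ 1-nt end
extensions/truncations/shifts drawn from the precursor (≤ 9 variants);
a hit is an equal-length catalog entry within 2 mismatches (ungapped —
the reference aligner for this task is ungapped). No hit →
species-specific; hits only in other focal-clade species →
clade-specific; otherwise conserved, and the locus family takes the
best-matching catalog name.

*Clusters* chain loci whose start-to-start distance is ≤ 10 kb
(transitively); a span mode caps the whole region instead, since the
10-kb rule is ambiguous between gap and span readings — both are
provided, gap is the default. *Synteny blocks* are extracted from a
homolog-anchor table by repeated longest-collinear-chain dynamic
programming (O(n²); ascending or descending partner ranks; rank gaps
≤ 25; chains < 5 anchors discarded; ties prefer the lexicographically
smallest index sequence — this deterministic greedy extraction is the
module's own design, verified against an independent oracle). Homology
itself is an input, not computed.

*Expression*: RPM counts reads placed inside the precursor with 5′
ends within 2 nt of the mature 5′ end; FPKM is
count/(length/10³)/(total/10⁶). Pattern classes use tissue means with
the <10 / >500 RPM rules. Profile clustering is k-means (k = 16
default, k-means++ with 50 restarts, fixed seed) on per-entity z-scored
tissue means — shapes, not magnitudes. Differential expression uses a
two-sided Fisher exact test on pooled tissue counts against library
totals with BH correction and |log2FC| ≥ 1 on mean RPM (pseudocount
0.5); with two replicates per tissue a count-based exact test is the
defensible choice, and the test is on pooled counts so it measures
abundance shifts, not replicate variance.

*Targeting*: the genome-scale expectation scan is ungapped and
vectorised (every window of miRNA length); the full penalty scheme
including gaps applies in `score_site`, which scores an explicit site
up to 2 nt longer by trying all transcript-bulge placements. Candidate
sites for the multi-method run come from the expectation scan at twice
the cutoff so hybrid- or degradome-only evidence can still surface. The
hybrid energy uses a reduced 16-entry nearest-neighbor stack table
(standard Watson–Crick RNA stacking values folded by strand symmetry;
stacks involving a G:U pair scaled by 0.5); only the ratio to the
perfect complement crosses a threshold, and ratios are robust to the
reduced table. Degradome category means are computed over positions
with ≥ 1 read, which matches the standard category definitions on
sparse transcripts.

*Correlation*: replicates are averaged before correlating, so n is the
number of tissues; with 4 tissues df = 2 and p < 0.05 requires
|r| > 0.95 (the analytic threshold √(t²/(t²+2)) at t = t₀.₉₇₅,₂ equals
0.9500). Zero-variance profiles are flagged degenerate and excluded
from summaries rather than zero-filled, which would bias the bins.

*Network*: promoters are the 2000 nt upstream (strand-aware, truncated
at edges). PWM hits use log-odds against the background with a
fraction-of-maximum threshold (default 0.85) — transparent and
configurable where a p-value calibration would be opaque — plus a
strictly positive score, so a zero-information matrix never fires;
overlapping hits of one PWM merge to the best. TTI scanning is
restricted to promoters of genes that are miRNA targets, which is the
FFL universe of interest and bounds compute. Cascade/FFL enumeration is
a hash join, linear in output size; self-loops (a TF that is itself a
target) are permitted and visible in the tables.

## Pipeline and problem sizes

`run_all` wires the stages in dependency order from one config whose
keys carry every threshold named above. Default problem sizes — 1 Mb
genome, 30 miRNA + 30 siRNA loci, 4 tissues × 2 replicates at 50,000
reads per library (200,000 reads for the single-library discovery
reference), 1,000 miRNA–target pairs for correlation — were chosen so a
full run completes in well under a minute on one CPU while keeping
per-locus read depths and per-pair tissue panels at realistic
magnitudes. Every output is a plain-text file stamped with the config
hash and seed; reruns with an identical config are byte-identical.

## Known limitations

* Exact-match mapping only: no mismatches, no isomiR-aware counting
  beyond the ±2-nt 5′ shift rule.
* The fallback folding engine maximizes pairs, not free energy;
  structure-sensitive conclusions should use the ViennaRNA engine.
* The expectation scan does not search bulged sites genome-wide by
  default (gapped scoring is available per site); deeply bulged targets
  would need the bulge-aware scan enabled at higher cost.
* Synthetic reads carry no sequencing errors, adapters are planted only
  by the cleaning tests, and degradome noise is uniform — passing tests
  demonstrate correctness of the inference rules under their stated
  assumptions, not robustness to real-library artefacts.
* Synteny takes precomputed anchors; orthology inference is out of
  scope.
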