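# Methods

## Data model and conventions

The unit of observation is a CpG site with counts of
methylation-supportive and non-methylation-supportive reads; the
methylation level is the ratio N_me / (N_me + N_non-me) and is undefined
at zero depth (uncovered sites are excluded upstream, never imputed as 0).
Coordinates are 0-based half-open internally; the Bismark-coverage dialect
(1-based inclusive) is converted at the I/O boundary and its percent
column is always recomputed from counts.  CpGs are keyed by the
forward-strand C; if symmetric-strand counts should be merged, that is
assumed done before import — the package does not re-merge, since its
inputs are already per-CpG-site count tables.

## Per-site testing and DMR calling

Each paired CpG (depth >= `min_depth` = 4 in both samples) gets a
two-sided Fisher exact p for the 2x2 table (donor meth/unmeth vs clone
meth/unmeth), computed by the total-probability method: the sum of
hypergeometric probabilities of all tables with the observed margins whose
probability is at most the observed table's, with a relative tie tolerance
of 1e-7 (the convention of standard implementations).  The p-values are
evaluated in-package with vectorised log-gamma arithmetic and an LRU cache
over count tables, which keeps genome-scale scans fast; the test suite
checks the values against exhaustive exact-rational enumeration and
against `scipy.stats.fisher_exact` as two independent routes.  A two-sided
test is used because the seed criterion is direction-agnostic
(|Δlevel| >= 0.2).  No multiplicity correction enters the calling rules —
the fixed per-site cutoff p <= 0.01 *is* the procedure — but a
Benjamini-Hochberg column is emitted in the per-site table for
information.

The sliding-window scan proceeds left to right per chromosome:

1. **Seed**: p <= 0.01 and |Δlevel| >= 0.2.  The leftmost eligible seed
   wins; extension is downstream-only, so the seed is the region's first
   member.
2. **Extension** accepts the next surviving CpG when the gap to the
   previous accepted CpG is <= 200 bp and the span from the seed stays
   <= 2000 bp.  Significant CpGs (p <= 0.01) must share the seed's
   tendency (sign of clone − donor); a significant opposite CpG
   terminates the region.  Non-significant CpGs of either tendency are
   accepted, except that two consecutive opposite-tendency CpGs are not
   allowed: the second terminates the region.  A CpG with exactly equal
   levels has tendency 0 and is treated as non-opposite.  Reaching the
   2000-bp span cap terminates extension (the region so far is kept and
   filtered) rather than rejecting the region — the cap is an extension
   criterion, not an emission filter.
3. **Trimming** removes trailing non-significant CpGs until the region
   ends on a significant one; the seed itself is never trimmed.
4. **Final filters**: >= 5 member CpGs, pooled |Δlevel| >= 0.2, and
   length >= 200 bp, where length = last member position − first member
   position + 1 (BED export uses the half-open equivalent).

Sites failing the depth filter in either sample are removed before the
scan; adjacency and the 200-bp gap rule apply to the surviving sites,
since the per-site criteria are only defined where both samples are
covered.  Accepted regions are emitted and scanning resumes at the first
site after them, so output regions never overlap.  Region-level
methylation is pooled (depth-weighted): Σmeth/Σdepth per sample, not the
mean of per-site levels — robust to depth variation and invariant to
splitting a region.

Promoters for DMR annotation default to 2 kb upstream of the strand-aware
TSS with no downstream extent; both bounds are parameters, since the
underlying definition is conventional rather than fixed.  Recurrence
across donor-clone pairs counts, per gene, the number of pairs whose DMR
set touches it; "recurrent" means >= 2 pairs.

## Summaries and clustering

Element summaries pool counts over the union of a region set's intervals,
counting each CpG once.  CGI shores are derived on demand as the +-2 kb
flanks of merged CpG islands minus the islands themselves.  The metagene
profile uses fixed 100-bp flank bins (default 2 kb each side) and 20
length-scaled gene-body bins, flipping minus-strand genes so bin 0 is
always most-upstream; genes shorter than the bin count are skipped.

Sample clustering uses dissimilarity 1 − Pearson correlation of per-CpG
levels over CpGs covered at depth >= 4 in *all* samples, with
average-linkage agglomeration — the defaults of the pvclust-style
workflow this reproduces.  Branch support is the ordinary bootstrap
probability (BP): CpG sites are resampled with replacement B times
(default 100) and a node's support is the fraction of replicates
containing the identical leaf-set bipartition.  Multiscale bootstrap
(AU p-values) is deliberately not implemented; BP suffices to establish
the donor-clone pairing structure and keeps the dependency surface small.
Ties in the linkage are resolved deterministically by scipy's ordering,
so identical inputs always give identical trees.

## BSP clone scoring

The expected fully-converted template replaces every non-CpG C with T and
marks CpG cytosines as two-state (C if methylated, T if converted).
Clone reads are globally aligned to this template (match +1, mismatch −1,
linear gap −2, via Biopython's PairwiseAligner with a substitution matrix
in which the two-state letter matches both C and T); both orientations
are tried and the higher-scoring kept, so reverse-complement clones are
handled automatically.  Alignments under 60% identity are rejected as
not deriving from the amplicon.  At each CpG column, C calls methylated,
T unmethylated, and a gap or other base is ambiguous.  Conversion
efficiency is the fraction of non-CpG C positions read as T among those
aligned to a base: CpG positions cannot inform it because a conversion
failure there is indistinguishable from methylation.  The >= 95%
conversion filter is inclusive ("a minimum of 95%").  Site fractions
count methylated over non-ambiguous calls.  A consequence for
validation: the expected *observed* methylated fraction at a site with
true probability π under conversion rate c is π + (1 − π)(1 − c), and
recovery tests compare against this effective probability.

## Variant triage

The rules are pure per-variant predicates, applied in a fixed order only
so that the audit can name the *first* failed rule; the surviving set is
order-independent.  "More than"/"larger than" thresholds are strict,
"at least" is inclusive: donor and clone depth must lie in [5, 100];
somatic calls need clone variant frequency > 0.2; LOH calls need
frequency > 0.75 or < 0.25 (the frequency rule is clone-side for both
classes); >= 2 clone reads must support the variant.  The supporting-read
rule is applied clone-side only.  Two-callset intersection is keyed on
(chrom, pos, ref, alt, class).  Known-site and repeat-region subtraction
uses half-open BED semantics.  Read QC (fail when more than 50% of bases
are under Q20 or more than 10% are N) operates at the FASTQ level, where
it belongs in the workflow; variant-level base-quality re-checks would
require pileups and are out of scope, as is variant calling itself.

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes.  A toy genome places CpGs as a clustered point process:
background spacing uniform in [80, 120] bp (mean 100 bp, configurable),
CpG islands of 500–1500 bp with 8–20-bp spacing at about one island per
30 kb, and non-overlapping random-strand gene models.  True levels are
bimodal: Beta(1, 9) inside CGIs, Beta(9, 1) elsewhere.  Read depth is
Poisson (default λ = 30, a typical deep-WGBS per-strand coverage)
truncated at >= 1; counts are Binomial(depth, level) — binomial rather
than beta-binomial by default, matching the assumption implicit in
per-site Fisher testing (an overdispersed generator would be the natural
extension but is not required by any consumer here).  Implanted DMRs
shift a run of consecutive CpG levels by a signed delta, clipped to
[0, 1]; the truth interval spans the first to last shifted CpG.  Because
non-CGI levels sit near 0.9, benchmark implants use negative deltas
(clone hypomethylation): a +0.4 shift would clip at 1.0 and erase its own
signal.  Null pairs draw two independent count samplings from identical
levels.  The three-pair clustering fixture perturbs one shared base
methylome once per pair (Gaussian on the level scale, sd 0.15, clipped)
and resamples each pair member independently, giving within-pair
correlation exceeding between-pair correlation.  All generators draw from
named substreams of a single master seed, so outputs are bit-reproducible
and adding a generator never perturbs another's draws.

What the simulations do *not* emulate: strand asymmetry, non-CpG
contexts, mappability and coverage biases, bisulfite over-conversion
damage, PCR duplicates, or LD-like spatial correlation of methylation
beyond the implanted regions.  Passing the recovery benchmarks therefore
demonstrates correctness of the calling rules under the model's
assumptions, not calling performance on real WGBS libraries.

## Benchmark problem sizes and expectations

The packaged benchmarks use two 300-kb chromosomes (~12k CpGs at 50-bp
spacing) for implant recovery with 50 implanted 10-CpG DMRs, and two
4-Mb chromosomes (~100k paired CpGs) for the null-replicate contrast —
sizes chosen so the whole suite and the acceptance script each run in
seconds while keeping per-scenario counts statistically meaningful.  At
|Δ| = 0.4 and depth 30 the expected sensitivity at 50% reciprocal overlap
is >= 90%; at |Δ| = 1.0 and depth 50, 100% (an occasional seed passes a
spurious flanking seed that widens a call enough to fail the reciprocal
overlap; this is a property of the overlap metric, not a missed region).
On null pairs the per-site seed rate at p <= 0.01 stays well under 1.5% —
Fisher on discrete counts is conservative — and whole DMRs essentially
never assemble, mirroring the contrast between donor-clone pairs
(~10^4 DMRs genome-wide) and technical replicates (tens) that motivates
the design.

## Known limitations

- One-vs-one comparisons only; no replicate groups, no smoothing or HMM
  segmentation, no beta-binomial dispersion modelling.
- The promoter definition and the CGI-shore width are conventions, not
  inferences; both are parameters.
- BSP scoring assumes near-full-length Sanger reads; chromatogram
  parsing and primer design are out of scope.
- The variant module filters caller *output*; it does not call variants,
  realign, or detect structural variants.
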