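# Methods

## Domain model and coordinates

All computation is amplicon-local: coordinates are 0-based, half-open, on
the single PCR amplicon spanning the edited region. Cut sites are inter-base
coordinates (the blunt cut falls between positions `cut_site−1` and
`cut_site`). When a guide is specified by protospacer rather than
coordinate, the cut is placed 3 bp 5′ of the NGG PAM on the protospacer
strand — the canonical SpCas9 geometry. The protospacer must occur exactly
once across both strands with an adjacent NGG; anything else is an error
(not found / ambiguous / no PAM), because a misplaced cut site silently
corrupts every downstream assignment. Guides may also be configured directly
by `cut_site`, which takes precedence when both are given, so non-NGG or
empirically determined sites remain usable.

Size arithmetic is deterministic: a pair's expected deletion is the distance
between its cut sites, and the expected PCR band is the WT product size
minus the deletion size. These identities (conservation, strict
monotonicity) are property-tested.

## Synthetic libraries

The generator emulates a pooled dual-guide MiSeq amplicon library. Reads
are single-end windows of the amplicon starting a fixed
`read_anchor_offset` (default 50 bp) upstream of an upstream-guide cut
site, mirroring the pooled sequencing-primer design in which one primer sits
~50 bp upstream of each cut site. Each molecule is:

- **wild type** (probability `wt_fraction`): an unmodified window, anchored
  at a uniformly chosen upstream cut site;
- **deletion** (per-pair probabilities `pair_fractions`): the reference with
  the inter-cut-site interval excised. Each breakpoint is jittered by an
  integer-rounded Gaussian (`jitter_sd`, default 5 bp), emulating end
  resection around the cut; with probability `insert_junction_prob`
  (default 0.1) 1–5 uniform random bases are inserted at the junction,
  emulating end-joining scars;
- **garbage** (the remaining probability mass): i.i.d. uniform ACGT,
  standing in for unmappable material.

Substitution errors are applied uniformly per base (`subst_error_rate`,
default 0.003, a typical MiSeq point-error scale); qualities are constant
Q30. Read length defaults to 150 bp, single-end. One seeded NumPy generator
drives the whole library, so a (config, seed) pair is byte-reproducible; the
seed is echoed in every FASTQ header comment.

What the generator does *not* model — and what passing tests therefore do
not show about real data: PCR chimeras and primer carry-over, quality-score
error profiles and indel sequencing errors, microhomology-biased NHEJ
outcome spectra, paired-end overlap, and coverage bias among primers. The
truth table records each read's class, pair, and realized (jittered)
breakpoints, and `truth_efficiencies` converts it to per-pair fractions of
non-garbage reads — the oracle for recovery tests.

## Split alignment

Each read must be explained by at most one internal deletion. The model is
two collinear, non-overlapping, *gapless* local segments separated by a free
reference gap (the junction), optionally with a short run of unaligned read
bases at the junction; or a single gapless local segment; or nothing
(unmapped). Scoring is match +1, mismatch −1; the junction is free; inserted
junction bases cost `4 + 0.5·(k−1)` (affine). Within-segment indels are
deliberately not modeled: an amplicon read is a window of the reference with
at most one excision, so the space of single-deletion placements with
gapless flanks is exactly the hypothesis space, and the optimum over it can
be found exactly rather than approximately. The test suite checks this
optimum against an independent plain-Python enumeration of all
(deletion start, length) placements.

Search: for every candidate diagonal (`ref_pos − read_pos`), cumulative-sum
prefix/suffix maxima give the best segment ending / starting at every read
position in O(read length); a running maximum across diagonals combines any
earlier diagonal with any later one, enforcing a strictly positive reference
gap, so the chain optimum is exact over the candidate set. For small
problems (|read|·|ref| ≤ 150 000) *all* diagonals are enumerated — provably
exact. At amplicon scale, candidate diagonals come from exact 13-mer seeds
sampled every 4 bp along the read (a BLAT-style index of the reference);
with ≤ 0.5 % substitution error the probability that a ≥ 20 bp flank
contains no intact seed is negligible, and random reads essentially never
seed (expected spurious 13-mer hit rate ≈ 2500/4¹³ per k-mer), which is what
makes 10⁵-read libraries tractable in pure NumPy. Both orientations are
attempted and the better score wins (ties prefer +); the default `auto`
strand mode skips the reverse orientation when the forward alignment already
passes all filters, which cannot change any classification.

Tie-breaks: equal-scoring placements prefer the smaller junction, then the
leftmost junction start. With junction microhomology (the bases left of the
junction equal those right of it) several placements are exactly equivalent;
the reported junction is then the leftmost representative, which shifts both
breakpoints jointly by the homology length and never changes the deletion
size. Similarly, small junction insertions (≤ 5 bp) are usually absorbed as
near-junction mismatches because that scores higher than the affine
insertion penalty; this shifts the junction by at most the scar length —
well inside the 60 bp assignment window — and is the score-optimal
representation, not an error.

## Spliced-read extraction

A read is **spliced** iff its junction is strictly larger than `min_junction`
(default 2 bp — "larger than 2 bp") *and* its rest-of-read alignment ratio
is strictly above `min_aligned_ratio` (default 0.95 — "above 95 %"), where
the ratio counts read bases placed in aligned segments over read bases
outside the junction insertion. Two additional guards are applied: identity
(matches / aligned bases) ≥ 0.95 and each flank ≥ 20 bp. A local aligner
without them will happily chain two short spurious segments of a random
read; BLAT-style mappers impose both implicitly. All four thresholds are
parameters and are echoed into the run manifest. A read failing the spliced
test but aligning well overall is wild-type-mapped; everything else is
unmapped. Classification is monotone under threshold tightening by
construction (fuzz-tested).

## Assignment and efficiency

A junction is assigned to the guide pair whose US and DS cut sites are
*both* within `window` (default 60 bp) of the respective breakpoints —
two-sided matching, chosen over one-sided because one-sided matching
double-counts nested pairs sharing a guide; a one-sided mode exists behind a
flag. Among several candidates the smallest summed breakpoint distance
wins; an exact tie is reported as **ambiguous** and counted in no pair's
numerator (conservative and reproducible, rather than fractional splitting).

Per library, `efficiency(pair) = assigned spliced reads / mapped reads`
with mapped = wild-type-mapped + spliced; unmapped reads are excluded from
the denominator. One shared mapped-read denominator is used for every pair.
Wilson 95 % score intervals accompany each estimate (they behave correctly
at zero counts). Replicate aggregation reports the arithmetic mean and
sample SD across libraries; a pair absent from a library counts as 0 there
with a logged warning, and a single library yields SD 0 with a warning.
Count conservation (total = mapped + unmapped, mapped = wt + spliced,
spliced = Σ assigned + ambiguous + unassigned) is asserted in tests at every
stage. The deletion spectrum lists distinct (start, end) junctions by count
and, per pair, the SD of each breakpoint around its cut site — the
dispersion that cut-site error bars on a deletion map visualize.

## Expression statistics

**Comparative CT.** Technical replicates of a (sample, gene) are averaged
to one Cq; ΔCt = Cq(target) − Cq(housekeeping); ΔΔCt subtracts the mean ΔCt
of the calibrator; fold change = 2^(−ΔΔCt), i.e. amplification efficiency
fixed at 2.0 (pure Livak; no Pfaffl efficiency correction). Two schemes:
`global_calibrator` normalizes every sample to one (group, condition) cell;
`condition_matched` normalizes each sample to the calibrator group within
its own condition. The two are linked by an exact identity — the matched
fold change equals the global one divided by the condition's control fold
change — which the tests verify to 1e−9.

**Percent change** of an intensity measure between two (group, condition)
cells, after optional per-replicate division by a normalizer measure (e.g.
blot bands by α-tubulin): `100·(mean_ctrl − mean_treat)/mean_ctrl`, positive
= decrease, matching how staining/blot reductions are conventionally
reported. Scale-invariant by construction.

**Transduction efficiency** is the mean of per-replicate
mCherry/brightfield count ratios (not the pooled-count ratio, which would
weight replicates by cell count); ratios above 1 are allowed with a warning.

**t tests** are Welch by default (the safer choice under unequal variances;
pooled available by flag), two-sided, returning (t, Welch–Satterthwaite df,
p). Two all-constant groups are degenerate for the statistic; the limit
(t = 0, p = 1 on equal means) is returned. No multiple-testing adjustment is
applied by default, matching the unadjusted pairwise reporting convention
for this assay family; a Holm option exists in `statsmodels` for users who
want it.

## Pipeline and reproducibility

`run_pipeline` executes simulate → align → quantify → report with per-stage
TSV hand-off, so stages are independently inspectable and replaceable. The
manifest records the package version, seed, every threshold in force
(junction, ratio, identity, flank, window), per-library counts, and SHA-256
checksums of all inputs. Exit codes: 0 success, 2 configuration error,
3 data error. Reruns with a fixed seed are byte-identical.

## Problem sizes and numerical choices

Tests and the acceptance script use a 2 500 bp synthetic amplicon with a
3×3 guide design and libraries of 10³–10⁴ reads; recovery checks use 20
seeds per condition, which puts the binomial sampling floor
(≈ 0.005 absolute at n = 10⁴) well below the 0.01 mean-absolute-error
criterion. Statistical assertions on stochastic quantities use 4σ binomial
bands, giving per-assertion false-alarm rates around 6×10⁻⁵. Floating-point
score comparisons use a 1e−9 tolerance; all simulations are driven by
seeded `numpy.random.default_rng` generators.

## Known limitations

- Only one internal deletion per read; inversions, duplications and
  multi-cut alleles are out of scope.
- Within-segment indels are not modeled; sequencing indel errors near a
  junction would perturb the junction coordinate by a few bases (absorbed by
  the 60 bp window) and slightly depress identity.
- The aligner targets a single amplicon reference, not genome-wide mapping.
- Deletion efficiency is a read-level proxy: PCR amplifies shorter deletion
  alleles more efficiently than the WT allele, so read fractions can
  overstate allele fractions in real libraries; the simulator does not model
  this amplification bias.
- qPCR fold changes assume perfect doubling per cycle; no melt-curve or
  efficiency QC is performed.
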