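# Methods

## Detection model

Induced prophages replicate intracellularly, so after whole-culture
sequencing and mapping, their chromosomal region accumulates read depth
above the host background. Detection treats the per-base depth profile
of each contig as the observable and asks where it exceeds a locally
estimated background.

**Background statistics.** For every contig of at least 80 kb the
background is summarized by the median depth and a *corrected* standard
deviation: the population SD (divisor *n*; the divisor is immaterial at
segment sizes of 10⁵–10⁶ bases) computed after discarding bases with
depth above 3× the median. The truncation keeps actively excising
elements — exactly the signal being hunted — from inflating the spread
that defines the calling threshold. Contigs above 350 kb are sliced into
`ceil(L / 300 kb)` equal pieces so that slow coverage skew along long
replicons does not blur the local background; a window is thresholded
against the statistics of the slice containing its midpoint (when an
element spans a slice boundary, the slice of its midpoint decides — the
neighboring slice's statistics differ negligibly at these sizes).

**Window calling.** Mean depth is computed over 250-bp windows every
50 bp (trailing partial windows dropped). Two passes capture a
length/stringency trade-off: maximal runs of windows each exceeding
median + 1σ are kept when their base span (first window start to last
window end) exceeds 1500 bp; runs exceeding median + 3σ are kept at
spans of 500–1500 bp. Each member window must individually exceed the
threshold; overlapping calls from the two passes describe the same
region and are unioned. A single window (span 250 bp) can never form an
element, so no call is shorter than 500 bp. When the corrected SD is
zero (flat background), any excess over the median qualifies; this is
logged.

**Plasmid rule.** Contigs of 5–80 kb are too short for stable window
statistics but are natural homes for phage-plasmids; such a contig is
recorded high-coverage as a whole iff its median depth strictly exceeds
the genome median plus one contig-level corrected SD. The genome median
is taken over all contigs of ≥ 80 kb (falling back to all bases when
none exist). Contigs under 5 kb are ignored for calling and logged —
window statistics are meaningless near the window size.

**Merging.** Same-contig calls separated by less than 1000 bp merge.
Calls facing each other across consecutive contig ends (closer than
1000 bp to the junction) are cross-linked by id but never coordinate-
concatenated: contig order in draft assemblies is arbitrary, and a
fabricated joint interval would poison downstream coordinates.

**Border refinement** is hierarchical, most precise evidence first:

1. *Clipped reads.* Reads spanning the circularization junction of an
   excised phage map partly to the host and are clipped exactly at the
   integration border. If ≥ 3 clip positions agree within ±5 bp inside a
   500-bp search radius of a candidate border, the modal clip position is
   the border. The three constants are not dictated by the underlying
   statistics of any published protocol; they were chosen to be robust
   at ~30× coverage and sit in `DetectionParams`.
2. *Coverage step.* For induction-derived elements without clip support,
   each border moves to the position maximizing the contrast between the
   mean of the next 250 bp and the previous 250 bp within ±500 bp. This
   estimator peaks exactly at an ideal step; a box-smoothed gradient
   would be flat-topped over a full window width and ambiguous to
   ±125 bp.
3. *Gene span.* Inactive elements (genomic islands) are clamped to their
   first-to-last gene, discarding non-coding ends.

If no tier applies, raw window borders are kept and flagged.

The manual inspection step that a human analyst would normally add on
top of a coverage screen (rescuing slightly elevated elements, nudging
borders by eye) is deliberately absent: the pipeline is deterministic
end to end, and everything it reports is reproducible from inputs and
parameters alone.

**Alignment contract.** Upstream mapping is out of scope; the filters
operate on parsed records: primary alignments only, identity ≥ 99%
(matching columns / alignment columns), aligned length ≥ 50 bp, ≥ 80% of
the read aligned. Samples enter only with strictly more than 250 000
reads.

## Curation rules

An element is a putative prophage iff it has ≥ 5 genes and (a) any gene
carries a realm marker label — terminase (large/endonuclease subunit) or
major capsid protein (tailed), pI-like ATPase / zonular occludens toxin
homologs (filamentous), double jelly-roll capsid protein (tailless) — or
(b) ≥ 2 *distinct genes* match viral keywords (coat, capsid, head, tail,
virion, phage, holin, terminase, replication, packaging, plus
filamentous-phage-specific identifiers). A gene matching two keywords
counts once; matching is case-insensitive substring over annotation
label text (HMM/BLAST searching itself is an input, not a stage).

Realm precedence on marker conflict is tailless > filamentous > tailed;
conflicts are logged — they arise in mis-merged co-integrated phage
pairs, which do occur at shared integration hotspots. Realm size
minimums (filamentous/other 4 kb, tailless 10 kb, tailed 25 kb) are
inclusive (≥): the sources of these constants give no boundary
semantics, and inclusivity makes the filter monotone with no boundary
surprises.

**dif sites.** Filamentous (and some tailless) phages integrate at the
chromosome-dimer-resolution *dif* motifs. Queries (20–40 bp, supplied as
FASTA — the reference motifs are inputs) are located by exhaustive
vectorized Hamming comparison at every position on both strands,
reporting placements with ≤ 4 mismatches. The scan is exhaustive rather
than seed-pruned: with 4 mismatches allowed in a 28-bp motif, no clean
12-mer is guaranteed to survive, so any fixed-length seeding scheme can
miss valid placements; at motif scale the full scan costs microseconds.
Ungapped comparison is appropriate because *dif* sites are short,
conserved motifs.

## Activity model

`PtoH = mean(prophage depth) / median(neighborhood depth)` with the
neighborhood statistics of the enclosing background segment. Classes:
high-active at mean ≥ median + 3σ, low-active at ≥ median + 1σ, else
inactive (thresholds inclusive; σ = 0 degenerates to "any excess over
the median is high-active", logged). For plasmid-borne prophages the
ratio is taken against the whole-genome median and divided by the
plasmid copy number measured from non-induced sequencing; the correction
applies only to multi-copy plasmids, so it can only lower the ratio —
single-copy plasmids pass through untouched. The correction is division
by copy number, the simplest reading consistent with that constraint,
and is isolated in one function for easy revision.

Note one systematic property of the estimator: dividing by the *median*
of a right-skewed background (negative binomial with size 5 has median
≈ 0.94 × mean) biases PtoH upward by ~6% relative to the planted
mean-fold. This is inherent to the median-based definition, not an
implementation artifact, and stays well inside the ±10% recovery band
the tests enforce.

Group comparison: Shapiro–Wilk per group, then the two-sided Wilcoxon
rank-sum (Mann–Whitney U), exact when both groups have ≤ 25 observations
and the pooled sample is tie-free, otherwise the tie-corrected normal
approximation with continuity correction. An all-tied comparison has
p = 1 by symmetry. Filamentous prophages receive PtoH values but should
not be compared against dsDNA realms: their ssDNA virions are largely
invisible to standard double-stranded library preparation, so their
ratios reflect only the double-stranded replicative form.

## Similarity and dereplication

ANI between two prophage genomes is estimated fragment-wise: the query
is cut into consecutive 1000-bp fragments (a trailing fragment is kept
at ≥ 500 bp); a fragment maps iff it shares an exact 15-mer with the
target (this rejects unrelated sequence before any alignment and keeps
coverage between random sequences near zero) and its best infix
alignment stays within 30% edit distance. ANI is the pooled identity
over mapped fragment bases, `100 · (aligned − edits) / aligned`,
averaged over both mapping directions; coverage is the mapped fraction
of the shorter sequence's fragments. For substitution-only divergence
the infix edit distance equals the substitution count, so ANI is exactly
`100 · (L − k) / L` — the 99.9% retention boundary between 10 and 11
substitutions in 10 kb is decided algebraically, with a 10⁻⁹ epsilon
guarding threshold comparisons against float rounding (99.9 is not
exactly representable in binary).

"Complete coverage" for transfer pairs means every fragment of the
shorter sequence maps (coverage = 1.0). Dereplication is greedy
longest-first (ties by id, so deterministic): each sequence joins the
first representative at ANI ≥ 99.9% with ≥ 80% coverage, else founds a
cluster. The 80% dereplication coverage has no stated counterpart
upstream and is exposed in `SimilarityParams`.

## Gene families and the variable locus

Edge weights of the protein similarity graph are
`min(ceil(−log10 e), 200)`; e-values of 0 (search-tool underflow) take
the cap, reciprocal hits collapse to the maximum weight. MCL is the
canonical algorithm: self-loops at each node's maximum incident weight
(1 for isolated nodes — a standard regularization), column
normalization, then expansion (matrix square) alternating with inflation
(elementwise power 3, renormalize) and pruning of entries below 10⁻⁶,
until the matrix changes by less than 10⁻⁸. Clusters are read as
connected components of the converged matrix support — a partition by
construction, deterministic under sorted node order, and never coarser
than the graph's connected components (expansion cannot create
probability flow between disconnected parts). Prune/tolerance values
are chosen for stability at protein-collection scale (10²–10⁴ nodes,
dense arithmetic) and are parameters.

Family frequency within a phage cluster is the fraction of member
genomes carrying ≥ 1 gene of the family: core strictly above 0.8,
variable at or below 0.3, intermediate otherwise. Clusters with fewer
than 5 members are excluded from locus analysis — below that size the
frequency thresholds cannot distinguish core from variable. Within each
genome, maximal runs of non-core genes that contain at least one
variable gene and are enclosed by core-family genes on both sides yield
one locus each, spanning first to last variable gene; an
intermediate-only run yields no locus, and a variable gene at the
element edge (unflanked) is not a locus. Fine-grained phage clusters
can be supplied externally or built by single-linkage on pairwise
ANI ≥ 80% (`cluster_prophages_by_ani`); this stands in for
protein-profile-based viral clustering and is not claimed to reproduce
any particular external clustering.

Defense flagging is annotation-driven: a locus is a complete system if
an external defense-detection tool says so (accepted as an input flag)
or adjacent genes carry toxin and antitoxin labels; any defense-related
label (abortive infection, toxin, antitoxin, restriction, retron)
without completeness marks an incomplete system. "antitoxin" is
excluded when testing for "toxin" so the substring rules stay disjoint.

## Synthetic data: what it emulates, what it does not

Backgrounds are i.i.d. negative binomial per base, parameterized by mean
(default 50 reads/base — mid-range for induction libraries of this
depth) and size (default 5, i.e. variance = mean + mean²/5, strongly
overdispersed as sequencing depth is); a Poisson switch exists for the
equidispersed limit. Planted elements multiply the mean by their fold —
the ground-truth phage-to-host ratio — and plasmid contigs by their copy
number. Clip evidence is generated directly as alignment records at
planted borders rather than by read simulation; depth is likewise
generated directly, for speed.

Real depth profiles are *not* i.i.d.: mappability, GC bias and origin-
proximity effects correlate neighboring bases, and excision boundaries
blur over partially induced populations. Passing detection tests
therefore demonstrate correctness of the statistical machinery under
the stated noise model, not performance on any particular sequencing
run. The generators also do not model sequencing error, read-level
artifacts, or the systematic under-recovery of ssDNA filamentous phage
genomes.

Determinism is a contract: every generator takes an explicit seed,
identical configurations produce identical bytes, and file headers
record seed and config hash.

## Problem sizes

The shipped test and acceptance runs use 1-Mb single-contig genomes
(hundreds of simulations), 120-kb contigs for ratio recovery, 5–20 kb
sequences for ANI, clusters of 8–10 genomes for locus recovery, and
1000 replicates for rank-sum calibration — sizes at which every suite
completes in well under its time budget on one core while keeping
sampling error far from the asserted margins.

## Known limitations

* Detection operates per contig; prophages split across assembly breaks
  are cross-linked, not reassembled.
* The coverage border estimator assumes a step-like profile; partial
  induction in a minority of cells produces shallow ramps where tier-2
  precision degrades to the window scale.
* ANI fragment mapping assumes mostly-collinear genomes; heavy
  rearrangement between close relatives would lower coverage and can
  drop pairs that a rearrangement-aware aligner would keep.
* Curation is entirely annotation-text-driven; unannotated or
  idiosyncratically labeled genes are invisible to both the marker and
  keyword rules.
* Tandem (adjacent) prophages merged by the < 1-kb rule are not
  separated; doing so requires synteny comparison against related
  prophages, which is out of scope.
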