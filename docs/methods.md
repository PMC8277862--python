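# Methods

This note documents the models, conventions and numerical choices behind
`packtir`, in the order the pipeline runs.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand;
1-based-inclusive formats (RepeatMasker `.out`, GFF3, VCF) are converted at
the I/O boundary and nowhere else.  Minus-strand RepeatMasker rows list
their consensus coordinates as `(left) end begin`; these are normalized on
read so `cons_start <= cons_end` always holds on the consensus forward
strand, with the raw triplet retained for provenance.  Heterozygous diploid
genotypes are treated as missing when panels are read: the panels this
models are inbred lines, where residual heterozygosity flags unreliable
(typically inversion-associated) regions, and treating it as missing avoids
inventing a diploid π estimator the analysis does not need.

## Homology search and alignment scoring

Parental-copy assignment uses exact 11-mer seeding on both strands,
diagonal clustering, and realignment of each cluster window with an optimal
local aligner (match +1, mismatch −1, −1 per gap opening with free
extension — the psl-style convention under which the published thresholds
"minimum score 100, minimum identity 90" are meaningful).  Identity is
`100·matches/(matches+mismatches+gap_opens)`.  Overlapping window hits are
deduplicated keeping the best scorer; ties sort by (chromosome, start) so
results are deterministic.  One consequence of per-opening gap costs worth
knowing: a whole-sequence optimizer could "chain" two distant loci through
one cheap gap; the windowed search deliberately does not, which is the
biologically intended behavior for parent assignment.

## The scan

A candidate is a pair of same-consensus TE fragments on one chromosome with
an internal gap strictly between 100 and 5,000 bp that overlaps no other TE
annotation.  "Same element" means same consensus name; where the
annotation provides fragment linkage ids, mismatched ids reject the pair.
Both fragments must lie in one orientation (a flag relaxes this) and each
must cover the consensus terminus facing away from the captured segment
through ≥ 10 bp — the geometry of an intact element interrupted by a
capture.  Simple-repeat/low-complexity annotation classes never nucleate
candidates (configurable).  Candidates or parents containing runs of ≥ 10 N
are filtered as assembly gaps, the automatic proxy for a by-eye gap check.

Parent assignment requires a best external hit passing score/identity, a
captured-to-parent length ratio in [0.80, 1.20], and a strictly unique top
score.  Hits inside the candidate's own element span are never parents;
hits inside *another* candidate's element span are treated as co-duplicates
of the same capture rather than competing parents.  Without that rule, the
members of a multicopy family — identical captures at several loci — would
tie each other into `ambiguous_parent` and the family could never be
observed; with it, each member resolves to the shared parental locus and
the family emerges from grouping.  Relaxed mode waives the parent
requirement entirely (`pass_relaxed`), mirroring the survey variant that
drops the parental-copy condition.

Confound filters: a parent with any TE annotated within ±100 bp is a
putative segmental duplication; a parent overlapping ≥ 2 exons of one
transcript whose internal-vs-parent alignment shows a ≥ 30-bp deletion with
both ends within 5 bp of intron boundaries is a retroduplicate (an
mRNA-derived copy, not a TE capture).

TSD calling returns the longest exact string (2–25 bp) that ends
immediately 5′ of the element's outer left boundary and begins immediately
3′ of its outer right boundary.  Families: two passing candidates join when
their internal sequences reciprocally align at ≥ 90 % identity over ≥ 80 %
of the shorter one and their parent hits overlap; copy number counts
distinct insertion loci, and `multicopy` additionally requires ≥ 2 distinct
TSD strings — identical TSDs at distinct loci are flagged ambiguous instead
(they could be one locus mis-assembled twice).

## Junction forensics

Switch points come from aligning each flanking fragment to its consensus:
bp5 is where the 5′ fragment's alignment ends, bp3 where the 3′ fragment's
begins (1-based consensus coordinates; minus-strand elements are
reverse-complemented into consensus orientation first).  Fragments under
60 % identity exclude the candidate from junction analyses; bp5 ≥ bp3 flags
an incoherent junction.

Microhomology at a junction is the outward run of identity (TE bases just
inside the junction vs the filler's parental flank) plus the inward run
(consensus continuation vs the filler's first bases), each capped at a
50-bp window.  The filler is located inside the internal segment by
aligning it to the parental locus plus flanks of half its length per side;
unaligned internal bases at a junction are reported as de novo insertion
length.  The resampling null redraws, per replicate, a uniform fragment of
the filler's length from that same template and a uniform switch point on
the consensus, measures microhomology with the observed-data procedure, and
reports the *exact* count ratio `n_ge/n_reps` (no continuity correction).
Replicate i consumes (fragment start, switch point) in that order from one
seeded generator, so independent implementations can replay the stream.

Positional skew: each switch point's relative position is folded onto the
5′ half (`x` if ≤ 0.5 else `1−x`) and the per-candidate statistic is the
smaller of the two folded values — conservatively, the breakpoint closer to
a terminal.  The null draws two independent uniforms per record and applies
the identical transform; its folded-min has the closed-form CDF
`F(x) = 1 − (1−2x)²` on [0, ½], which the Monte-Carlo sampler matches to
sup-norm < 0.02 at 10⁵ draws.  The observed-vs-null comparison is a
two-sided two-sample KS test (asymptotic p; exact below n = 5).

## Population statistics

Fisher exact tests use the point-probability criterion for two-sided p
(sum of margin-fixed tables no more likely than the observed — the dominant
convention); one-sided takes the tail in the observed direction of
association.  The capture-rate regression is OLS with the F-test on
(1, n−2) d.f.  Per-site diversity is the unbiased haploid estimator
`2a(k−a)/(k(k−1))`; window π sums per-site values over a window and divides
by window length (1,000-bp windows, 500-bp step by default).

The sweep test compares summed window π between carrier and noncarrier
lines over the affected span and asks how often frequency- and
recombination-matched synonymous sites (each within 95–105 % of the focal
values, same chromosome) produce an equally low ratio when lines are split
by their alleles.  Replicate spans are centered on the matched site and
clipped at chromosome ends exactly as the observed span is, preserving
comparability.  When fewer eligible sites than replicates exist, sampling
is with replacement and logged.  The empirical p is again an exact count
ratio.

Substitution counting is pairwise against a designated outgroup with NG86
conventions: each codon's 9 single-nucleotide changes define fractional
synonymous/nonsynonymous site counts (changes to stops count
nonsynonymous); multi-hit codons average over all shortest mutational
pathways that avoid stop codons.  This is the standard desk-scale stand-in
for likelihood branch counting, stated rather than hidden.  Expected
per-region proportions come from the outgroup's site counts and are tested
one-sided binomially.  GC comparisons use the Wilcoxon rank-sum test
(normal approximation with tie correction at n ≥ 8 per group, exact
enumeration otherwise).

## The synthetic-data generator

The generator's defaults are the study conditions the analysis is
calibrated against: consensus length log-normal with median 374 bp and true
terminal inverted repeats; per-copy divergence exponential with median
18.3 %; captured-segment length log-normal with median 224 bp inside the
strict (100, 5,000) bp band; junction microhomology 0 with probability 0.3,
else geometric with median 2 bp; donor distance exponential with mean
5,770 bp (median ≈ 4 kb) and a 0.6 intrachromosomal fraction; switch-point
centers Beta(0.75, 0.75) with a log-normal gap of median 4.6 % of the
consensus (the Beta shape was solved once so the folded-min median lands
near 0.2, interior-biased relative to the uniform null's 0.146); insertion
singleton fraction 0.658; and a default scene of 1 Mb over 3 chromosomes
with 150 TE copies, 30 gap-fill captures and one 3-copy FoSTeST family.
The SNP panel plants 80 haploid lines at 0.03 SNPs/bp over 120 kb with a
1/i frequency spectrum; a sweep reduces carrier diversity k-fold over a
10-kb span by homogenizing carrier alleles with probability 1−1/k.

Microhomology is engineered by overwriting donor-flank bases (and forcing a
mismatch one base beyond), so each event's truth value is exact rather than
a rejection-sampled draw; the base just inside each junction is likewise
forced to differ so chance extension cannot inflate the truth.  Copy
divergence applies to standalone TE copies only; capture arms are pristine
at the default zero-divergence condition so TSDs and switch points are
recoverable verbatim — divergence on captures is exercised through the
`capture_divergence` and `post_insertion_divergence` knobs.  The divergence
model is substitutions only (no indels), keeping truth coordinates exact.

What the simulator does *not* emulate: real TE family phylogenies and
nested/fragmented annotation noise, coalescent linkage structure in the
panel (sites are exchangeable given their frequencies), indel divergence,
assembly errors, and sequencing artifacts.  Passing recovery tests
therefore demonstrate correctness of the measurement machinery under the
stated generative assumptions, not robustness to annotation error in real
genomes.

## Problem sizes and determinism

The bundled tests and the acceptance script run the default 1-Mb scene,
100-replicate junction nulls, 1,000-replicate sweep tests, and 100-panel
calibration sweeps — sizes chosen so a full desk-scale verification
completes in a few minutes on one CPU while keeping every empirical p an
exact integer ratio.  All randomness descends from a single seed through
named per-stage substreams (`SeedSequence` spawn keys derived from stage
names), so reruns are byte-identical and one stage's draws never perturb
another's.

## Known limitations

- End-bypass/transduction captures (parent linked to the TE) are outside
  the detection model, as are cross-species orthology dating and
  maximum-likelihood Ka/Ks.
- The uniqueness rule resolves exact-copy families only because
  co-candidate hits are excluded; on real data with near-tied paralogs the
  `ambiguous_parent` filter is deliberately conservative.
- The folded-position KS calibration is slightly discrete below ~100
  candidates; the asymptotic p is then conservative.
- `local_search` is desk-scale (tens of Mb); it indexes whole chromosomes
  in memory and does not stream.
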