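"""The Pack-TIR identification pipeline.

A Pack-TIR is a non-TE sequence flanked on both sides by fragments of one
TIR TE.  The scan proceeds in the order the underlying survey used:

1. flanked-candidate detection from a TE annotation (same-consensus fragment
   pairs with a TE-free internal gap strictly between the length bounds,
   each fragment covering the outward-facing consensus terminus);
2. parental-copy assignment by local homology search of the internal
   sequence against the genome (score/identity thresholds, length-ratio
   band, top-hit uniqueness);
3. confound filters: segmental duplications (TEs in the parent's flanks),
   retroduplicates (multiexonic parent, intronless capture), assembly gaps;
4. target-site-duplication calling at the element's outer boundaries;
5. family grouping and copy-number classification via distinct TSDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

from .homology import AlignmentHit, GenomeIndex, SearchParams, align_pair, local_search
from .io import ConsensusTE, GeneModel, GenomeSequence, TEAnnotationRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass
class ScanParams:
    min_internal_len: int = 100          # exclusive
    max_internal_len: int = 5000         # exclusive
    terminal_cover: int = 10
    parent_min_score: int = 100
    parent_min_identity: float = 90.0
    len_ratio_low: float = 0.80
    len_ratio_high: float = 1.20
    parent_flank_window: int = 100
    internal_te_overlap_max: float = 0.0
    relaxed_parent: bool = False
    tsd_min: int = 2
    tsd_max: int = 25
    require_same_orientation: bool = True
    exclude_simple_repeats: bool = True
    gap_run_min: int = 10                # >= this many Ns flags an assembly gap

    def __post_init__(self) -> None:
        if not 0 < self.min_internal_len < self.max_internal_len:
            raise ValueError("need 0 < min_internal_len < max_internal_len")
        if not 0 < self.len_ratio_low < 1 < self.len_ratio_high:
            raise ValueError("len_ratio bounds must bracket 1")


@dataclass
class TSDCall:
    seq: str
    left_pos: int          # genomic start of the left copy
    right_pos: int         # genomic start of the right copy

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ParentHit:
    hit: AlignmentHit
    distance_to_candidate: int | str     # bp gap, or "interchromosomal"
    second_best_score: int | None
    len_ratio: float


@dataclass
class PackTIRCandidate:
    id: str
    chrom: str
    left_te: TEAnnotationRecord
    right_te: TEAnnotationRecord
    internal_span: tuple[int, int]
    internal_seq: str
    consensus: ConsensusTE
    strand: str = "+"
    parent: ParentHit | None = None
    tsd: TSDCall | None = None
    status: str = "candidate"

    @property
    def element_span(self) -> tuple[int, int]:
        return self.left_te.start, self.right_te.end

    @property
    def passed(self) -> bool:
        return self.status in ("pass", "pass_relaxed")

    def oriented_internal_seq(self) -> str:
        """Internal sequence in consensus orientation."""
        return self.internal_seq if self.strand == "+" else revcomp(self.internal_seq)

    def filter(self, reason: str) -> None:
        self.status = f"filtered:{reason}"
        logger.info("candidate %s filtered: %s", self.id, reason)


@dataclass
class PackTIRFamily:
    family_id: str
    member_ids: list[str]
    parent_locus: tuple[str, int, int]
    copy_number: int
    distinct_tsds: list[str]
    classification: str                  # single-copy | multicopy
    ambiguous_identical_tsds: bool = False


_EXCLUDED_CLASSES = ("Simple_repeat", "Low_complexity", "Satellite")


# ---------------------------------------------------------------------------
# step 1: flanked candidates
# ---------------------------------------------------------------------------

def _terminal_ok(rec: TEAnnotationRecord, L: int, which: str, cover: int) -> bool:
    """Does this fragment's consensus alignment cover the given terminus
    through at least ``cover`` bp?  ``which`` is "5p" (positions [1, cover])
    or "3p" (positions [L-cover+1, L])."""
    if which == "5p":
        return rec.cons_start <= 1 and rec.cons_end >= cover
    return rec.cons_end >= L and rec.cons_start <= L - cover + 1


def _has_gap_run(seq: str, n: int) -> bool:
    return "N" * n in seq


def find_flanked_candidates(annotations: list[TEAnnotationRecord],
                            genome: dict[str, GenomeSequence],
                            consensus_lib: dict[str, ConsensusTE],
                            params: ScanParams | None = None
                            ) -> list[PackTIRCandidate]:
    """Detect same-element flanked candidates from a TE annotation.

    For every pair of same-consensus fragments on a chromosome whose
    internal gap is strictly inside the length bounds, a candidate is
    emitted iff the gap's TE overlap is within tolerance and each fragment
    covers the consensus terminus facing away from the internal segment
    (orientation-aware).  Fragments annotated as simple/low-complexity
    repeats never nucleate candidates.
    """
    params = params or ScanParams()
    by_chrom: dict[str, list[TEAnnotationRecord]] = {}
    trees: dict[str, IntervalTree] = {}
    for rec in annotations:
        by_chrom.setdefault(rec.chrom, []).append(rec)
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec)

    candidates: list[PackTIRCandidate] = []
    counter = 0
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: (r.start, r.end))
        for i, left in enumerate(recs):
            if params.exclude_simple_repeats and left.family in _EXCLUDED_CLASSES:
                continue
            for right in recs[i + 1:]:
                gap = right.start - left.end
                if gap >= params.max_internal_len:
                    break
                if right.consensus_name != left.consensus_name:
                    continue
                if params.exclude_simple_repeats and right.family in _EXCLUDED_CLASSES:
                    continue
                if right.start < left.end:       # nested/overlapping pair
                    continue
                if not params.min_internal_len < gap < params.max_internal_len:
                    continue
                if params.require_same_orientation and left.strand != right.strand:
                    continue
                if (left.linkage_id is not None and right.linkage_id is not None
                        and left.linkage_id != right.linkage_id):
                    continue
                strand = left.strand
                cand = _make_candidate(chrom, left, right, strand, genome,
                                       consensus_lib, trees[chrom], params,
                                       counter)
                if cand is not None:
                    candidates.append(cand)
                    counter += 1
    return candidates


def _make_candidate(chrom, left, right, strand, genome, consensus_lib,
                    tree, params, counter) -> PackTIRCandidate | None:
    cons = consensus_lib.get(left.consensus_name)
    span = (left.end, right.start)
    gap = span[1] - span[0]
    # internal gap must be essentially TE-free
    overlap = 0
    for iv in tree.overlap(*span):
        overlap += min(iv.end, span[1]) - max(iv.begin, span[0])
    if cons is not None:
        if overlap > params.internal_te_overlap_max * gap:
            return None
        L = cons.length
        # outward-facing termini: plus-strand element reads 5'->3' left to
        # right on the genome; minus-strand elements are mirrored
        if strand == "+":
            ok = (_terminal_ok(left, L, "5p", params.terminal_cover)
                  and _terminal_ok(right, L, "3p", params.terminal_cover))
        else:
            ok = (_terminal_ok(left, L, "3p", params.terminal_cover)
                  and _terminal_ok(right, L, "5p", params.terminal_cover))
        if not ok:
            return None
    seq = genome[chrom].seq[span[0]:span[1]]
    cand = PackTIRCandidate(
        id=f"PT{counter:05d}", chrom=chrom, left_te=left, right_te=right,
        internal_span=span, internal_seq=seq,
        consensus=cons if cons is not None
        else ConsensusTE(left.consensus_name, ""), strand=strand)
    if cons is None:
        cand.filter("no_consensus")
    elif _has_gap_run(seq, params.gap_run_min):
        cand.filter("assembly_gap")
    return cand


# ---------------------------------------------------------------------------
# step 2: parental assignment
# ---------------------------------------------------------------------------

def assign_parent(candidate: PackTIRCandidate,
                  genome: dict[str, GenomeSequence],
                  params: ScanParams | None = None,
                  index: GenomeIndex | None = None,
                  other_candidate_spans: list[tuple[str, int, int]] | None = None
                  ) -> PackTIRCandidate:
    """Assign the parental copy of the internal sequence.

    The internal sequence is searched against the genome; hits overlapping
    the candidate's own element span are excluded, as are hits that fall
    inside another candidate's element span (those are co-duplicates of the
    same capture, not parental sources).  ``pass`` requires a best hit,
    a length ratio inside the configured band, and a strictly unique top
    score; in relaxed mode the parent requirement is waived entirely.
    """
    params = params or ScanParams()
    if candidate.status.startswith("filtered"):
        return candidate
    if params.relaxed_parent:
        candidate.status = "pass_relaxed"
        return candidate
    sp = SearchParams(min_score=params.parent_min_score,
                      min_identity=params.parent_min_identity)
    if len(candidate.internal_seq) < sp.k:
        candidate.filter("no_parent")
        return candidate
    hits = local_search(candidate.internal_seq, genome, sp, index=index)
    es, ee = candidate.element_span
    margin = params.tsd_max

    def overlaps(h: AlignmentHit, chrom, lo, hi) -> bool:
        return (h.target_chrom == chrom and h.target_span[0] < hi + margin
                and lo - margin < h.target_span[1])

    external = [h for h in hits if not overlaps(h, candidate.chrom, es, ee)]
    competing = [h for h in external
                 if not any(overlaps(h, c, s, e)
                            for c, s, e in (other_candidate_spans or []))]
    if not competing:
        candidate.filter("no_parent")
        return candidate
    best = competing[0]
    second = competing[1].score if len(competing) > 1 else None
    if second is not None and second >= best.score:
        candidate.filter("ambiguous_parent")
        return candidate
    ratio = len(candidate.internal_seq) / best.target_len
    if not params.len_ratio_low <= ratio <= params.len_ratio_high:
        candidate.filter("len_ratio")
        return candidate
    if best.target_chrom != candidate.chrom:
        distance: int | str = "interchromosomal"
    else:
        distance = max(0, max(best.target_span[0], candidate.internal_span[0])
                       - min(best.target_span[1], candidate.internal_span[1]))
    pseq = genome[best.target_chrom].seq[best.target_span[0]:best.target_span[1]]
    if _has_gap_run(pseq, params.gap_run_min):
        candidate.filter("assembly_gap")
        return candidate
    candidate.parent = ParentHit(best, distance, second, ratio)
    candidate.status = "pass"
    return candidate


# ---------------------------------------------------------------------------
# step 3: confound filters
# ---------------------------------------------------------------------------

def apply_confound_filters(candidate: PackTIRCandidate,
                           annotations: list[TEAnnotationRecord],
                           gene_models: list[GeneModel],
                           params: ScanParams | None = None
                           ) -> PackTIRCandidate:
    """Segmental-duplication and retroduplicate confound filters.

    ``segdup_flank_te``: any TE annotated within ``parent_flank_window`` bp
    of the parent span.  ``retroduplicate``: the parent overlaps >= 2 exons
    of one transcript AND the internal-vs-parent alignment has a deletion
    >= 30 bp whose both ends land within 5 bp of annotated intron
    boundaries (the capture lacks the intron).
    """
    params = params or ScanParams()
    if candidate.parent is None or not candidate.passed:
        return candidate
    hit = candidate.parent.hit
    pchrom, (ps, pe) = hit.target_chrom, hit.target_span
    w = params.parent_flank_window
    for rec in annotations:
        if rec.chrom != pchrom:
            continue
        if rec.start < pe + w and ps - w < rec.end:
            # the parent's own interior may legitimately be TE-free; any
            # overlap with the widened window flags a segmental duplication
            candidate.filter("segdup_flank_te")
            return candidate
    for gm in gene_models:
        if gm.chrom != pchrom or not gm.multiexonic:
            continue
        n_exons_hit = sum(1 for es, ee in gm.exons if es < pe and ps < ee)
        if n_exons_hit < 2:
            continue
        if _capture_lacks_intron(candidate, hit, gm):
            candidate.filter("retroduplicate")
            return candidate
    return candidate


def _capture_lacks_intron(candidate: PackTIRCandidate, hit: AlignmentHit,
                          gm: GeneModel, min_del: int = 30,
                          tol: int = 5) -> bool:
    """True iff aligning internal vs parent shows a >= ``min_del`` bp
    deletion with both ends within ``tol`` bp of an intron boundary."""
    ps, pe = hit.target_span
    # deletions in the query appear as unaligned target stretches
    query = candidate.internal_seq if hit.strand == "+" \
        else revcomp(candidate.internal_seq)
    parent_seq_holder = getattr(candidate, "_parent_seq_cache", None)
    if parent_seq_holder is None:
        return False
    aln = align_pair(query, parent_seq_holder)
    if aln is None:
        return False
    # reconstruct unaligned target gaps from a fresh alignment
    from .homology import _aligner
    a = _aligner.align(query, parent_seq_holder)[0]
    tblocks = a.aligned[1]
    for i in range(len(tblocks) - 1):
        g0, g1 = int(tblocks[i][1]), int(tblocks[i + 1][0])
        if g1 - g0 < min_del:
            continue
        for istart, iend in gm.introns():
            rel_s, rel_e = istart - ps, iend - ps
            if abs(g0 - rel_s) <= tol and abs(g1 - rel_e) <= tol:
                return True
    return False


def attach_parent_seq(candidate: PackTIRCandidate,
                      genome: dict[str, GenomeSequence]) -> None:
    if candidate.parent is not None:
        ps, pe = candidate.parent.hit.target_span
        candidate._parent_seq_cache = \
            genome[candidate.parent.hit.target_chrom].seq[ps:pe]


# ---------------------------------------------------------------------------
# step 4: TSD calling
# ---------------------------------------------------------------------------

def detect_tsd(candidate: PackTIRCandidate,
               genome: dict[str, GenomeSequence],
               params: ScanParams | None = None) -> TSDCall | None:
    """Longest exact direct repeat immediately flanking the element.

    The string must end immediately 5' of the outer left boundary and begin
    immediately 3' of the outer right boundary; the longest such string of
    length in [tsd_min, tsd_max] is unique by construction.  Returns None
    when nothing >= tsd_min matches.
    """
    params = params or ScanParams()
    es, ee = candidate.element_span
    seq = genome[candidate.chrom].seq
    limit = params.tsd_max
    if es < limit or ee + limit > len(seq):
        logger.warning("candidate %s near contig end; TSD search truncated",
                       candidate.id)
        limit = min(es, len(seq) - ee)
    best = 0
    for k in range(limit, 0, -1):
        if seq[es - k:es] == seq[ee:ee + k]:
            best = k
            break
    if best < params.tsd_min:
        return None
    call = TSDCall(seq[es - best:es], es - best, ee)
    candidate.tsd = call
    return call


# ---------------------------------------------------------------------------
# step 5: family grouping
# ---------------------------------------------------------------------------

def group_into_families(candidates: list[PackTIRCandidate]
                        ) -> list[PackTIRFamily]:
    """Group passing candidates that share a capture event.

    Two candidates join one family iff their internal sequences reciprocally
    align at >= 90% identity and their parent hits overlap.  Copy number is
    the number of distinct insertion loci; a family is multicopy iff it has
    >= 2 loci with >= 2 distinct TSD strings (identical TSDs at distinct
    loci are flagged ambiguous instead — they could be one locus mis-split).
    """
    passing = [c for c in candidates if c.passed and c.parent is not None]
    n = len(passing)
    parent_ix = list(range(n))

    def find(i):
        while parent_ix[i] != i:
            parent_ix[i] = parent_ix[parent_ix[i]]
            i = parent_ix[i]
        return i

    def union(i, j):
        parent_ix[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            if _same_family(passing[i], passing[j]):
                union(i, j)

    groups: dict[int, list[PackTIRCandidate]] = {}
    for i, c in enumerate(passing):
        groups.setdefault(find(i), []).append(c)

    families = []
    for k, (root, members) in enumerate(sorted(groups.items())):
        loci = {(c.chrom, c.element_span[0]) for c in members}
        tsds = sorted({c.tsd.seq for c in members if c.tsd is not None})
        multicopy = len(loci) >= 2 and len(tsds) >= 2
        ambiguous = len(loci) >= 2 and len(tsds) < 2
        rep = members[0].parent.hit
        families.append(PackTIRFamily(
            family_id=f"FAM{k:04d}",
            member_ids=sorted(c.id for c in members),
            parent_locus=(rep.target_chrom, *rep.target_span),
            copy_number=len(loci),
            distinct_tsds=tsds,
            classification="multicopy" if multicopy else "single-copy",
            ambiguous_identical_tsds=ambiguous))
    return families


def _same_family(a: PackTIRCandidate, b: PackTIRCandidate,
                 min_identity: float = 90.0) -> bool:
    ha, hb = a.parent.hit, b.parent.hit
    if ha.target_chrom != hb.target_chrom:
        return False
    if (min(ha.target_span[1], hb.target_span[1])
            <= max(ha.target_span[0], hb.target_span[0])):
        return False
    for x, y in ((a.oriented_internal_seq(), b.oriented_internal_seq()),
                 (b.oriented_internal_seq(), a.oriented_internal_seq())):
        aln = align_pair(x, y)
        if aln is None or aln.identity_pct < min_identity:
            return False
        if aln.matches < 0.8 * min(len(x), len(y)):
            return False
    return True


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_scan(annotations: list[TEAnnotationRecord],
             genome: dict[str, GenomeSequence],
             consensus_lib: dict[str, ConsensusTE],
             gene_models: list[GeneModel] | None = None,
             params: ScanParams | None = None
             ) -> tuple[list[PackTIRCandidate], list[PackTIRFamily]]:
    """Full scan: detect, assign parents, filter, call TSDs, group."""
    params = params or ScanParams()
    candidates = find_flanked_candidates(annotations, genome, consensus_lib,
                                         params)
    index = GenomeIndex(genome, SearchParams().k)
    spans = [(c.chrom, *c.element_span) for c in candidates]
    for i, cand in enumerate(candidates):
        others = spans[:i] + spans[i + 1:]
        assign_parent(cand, genome, params, index=index,
                      other_candidate_spans=others)
        attach_parent_seq(cand, genome)
        apply_confound_filters(cand, annotations, gene_models or [], params)
        detect_tsd(cand, genome, params)
    families = group_into_families(candidates)
    return candidates, families


def validate_pass_set(candidates: list[PackTIRCandidate],
                      params: ScanParams) -> None:
    """Assert every passing candidate satisfies the numeric bounds."""
    for c in candidates:
        if not c.passed:
            continue
        n = len(c.internal_seq)
        assert params.min_internal_len < n < params.max_internal_len, c.id
        if c.parent is not None:
            assert (params.len_ratio_low <= c.parent.len_ratio
                    <= params.len_ratio_high), c.id
            assert c.parent.hit.score >= params.parent_min_score, c.id
            assert c.parent.hit.identity_pct >= params.parent_min_identity, c.id
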