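"""Local homology search for parental-copy assignment and family grouping.

The scoring convention mirrors the psl convention of the classic seed-and-
extend genome searchers: ``score = matches - mismatches - gap openings`` on
either side (gap extension is free), and
``identity = 100 * matches / (matches + mismatches + gap_opens)``.  The
published thresholds the pipeline emulates (minimum score 100, minimum
identity 90) are meaningful only under a stated convention, so it is fixed
here rather than left to an aligner default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import GenomeSequence, revcomp

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass
class SearchParams:
    """Seeding/extension parameters for :func:`local_search`."""

    k: int = 11
    min_score: int = 100
    min_identity: float = 90.0
    max_hits: int = 50
    band_width: int = 50

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed word size k must be >= 8")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


@dataclass
class AlignmentHit:
    query_span: tuple[int, int]
    target_chrom: str
    target_span: tuple[int, int]
    strand: str
    matches: int
    mismatches: int
    gap_opens_query: int
    gap_opens_target: int

    @property
    def score(self) -> int:
        return (self.matches - self.mismatches
                - self.gap_opens_query - self.gap_opens_target)

    @property
    def identity_pct(self) -> float:
        denom = (self.matches + self.mismatches
                 + self.gap_opens_query + self.gap_opens_target)
        return 100.0 * self.matches / denom if denom else 0.0

    @property
    def target_len(self) -> int:
        return self.target_span[1] - self.target_span[0]


_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -1
_aligner.extend_gap_score = 0


def align_pair(a: str, b: str) -> AlignmentHit | None:
    """Optimal local alignment of ``a`` (query) against ``b`` (target).

    match +1, mismatch -1, -1 per gap opening (extension free), with full
    traceback.  Returns None when the best local score is <= 0 (no positive-
    scoring local alignment exists).  Ties are broken deterministically by
    the aligner's traceback order (first reported alignment).
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    if len(a) > 20_000 or len(b) > 20_000:
        raise ValueError("align_pair is for sequences <= 20 kb")
    if _aligner.score(a, b) <= 0:
        return None
    aln = _aligner.align(a, b)[0]
    qblocks, tblocks = aln.aligned[0], aln.aligned[1]
    matches = mismatches = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        for qa, tb in zip(a[qs:qe], b[ts:te]):
            if qa == tb:
                matches += 1
            else:
                mismatches += 1
    gap_q = gap_t = 0
    for i in range(len(qblocks) - 1):
        if qblocks[i + 1][0] > qblocks[i][1]:
            gap_t += 1     # unaligned query bases: gap opened in target
        if tblocks[i + 1][0] > tblocks[i][1]:
            gap_q += 1     # unaligned target bases: gap opened in query
    return AlignmentHit(
        query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
        target_chrom="", target_span=(int(tblocks[0][0]), int(tblocks[-1][1])),
        strand="+", matches=matches, mismatches=mismatches,
        gap_opens_query=gap_q, gap_opens_target=gap_t)


class GenomeIndex:
    """Exact k-mer index over the forward strand of an assembly.

    Coded k-mers (base-4 integers) are stored sorted with their positions, so
    lookups are two binary searches.  K-mers containing N are absent.
    """

    def __init__(self, genome: dict[str, GenomeSequence], k: int = 11):
        self.k = k
        self.genome = genome
        self.chrom_names = sorted(genome)
        codes_all, pos_all, chrom_idx_all = [], [], []
        for ci, name in enumerate(self.chrom_names):
            seq = genome[name].seq
            codes, positions = _kmer_codes(seq, k)
            codes_all.append(codes)
            pos_all.append(positions)
            chrom_idx_all.append(np.full(len(codes), ci, dtype=np.int32))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = (np.concatenate(pos_all)[order]
                     if pos_all else np.empty(0, np.int64))
        self._chrom = (np.concatenate(chrom_idx_all)[order]
                       if chrom_idx_all else np.empty(0, np.int32))

    def lookup(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._chrom[lo:hi], self._pos[lo:hi]


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    valid = arr != 255
    ok = np.ones(n, dtype=bool)
    # a window is valid iff it contains no N
    bad_cum = np.concatenate([[0], np.cumsum(~valid)])
    ok = (bad_cum[k:] - bad_cum[:-k]) == 0
    codes = np.zeros(n, dtype=np.int64)
    a = arr.astype(np.int64)
    for i in range(k):
        codes = codes * 4 + a[i:i + n]
    positions = np.nonzero(ok)[0].astype(np.int64)
    return codes[ok], positions


def local_search(query: str, genome: dict[str, GenomeSequence],
                 params: SearchParams | None = None,
                 index: GenomeIndex | None = None) -> list[AlignmentHit]:
    """Seed-and-extend search of ``query`` against both strands of ``genome``.

    Exact k-mer seeds are clustered by diagonal; each cluster's target window
    is realigned with :func:`align_pair` (banded implicitly by the window).
    Hits below ``min_score`` or ``min_identity`` are dropped; the remainder
    are sorted by score descending with (chrom, start) tie-break.
    """
    params = params or SearchParams()
    if len(query) < params.k:
        raise ValueError(f"query shorter than seed size k={params.k}")
    if index is None:
        index = GenomeIndex(genome, params.k)
    elif index.k != params.k:
        raise ValueError("index built with different k")

    hits: list[AlignmentHit] = []
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        clusters = _seed_clusters(q, index, params)
        for ci, tlo, thi in clusters:
            chrom = index.chrom_names[ci]
            tseq = genome[chrom].seq[tlo:thi]
            if not tseq:
                continue
            aln = align_pair(q, tseq)
            if aln is None:
                continue
            ts, te = aln.target_span
            qs, qe = aln.query_span
            if strand == "-":
                qs, qe = len(query) - qe, len(query) - qs
            hit = AlignmentHit(
                query_span=(qs, qe), target_chrom=chrom,
                target_span=(tlo + ts, tlo + te), strand=strand,
                matches=aln.matches, mismatches=aln.mismatches,
                gap_opens_query=aln.gap_opens_query,
                gap_opens_target=aln.gap_opens_target)
            if hit.score >= params.min_score and hit.identity_pct >= params.min_identity:
                hits.append(hit)
    hits = _dedup_hits(hits)
    hits.sort(key=lambda h: (-h.score, h.target_chrom, h.target_span[0]))
    return hits[:params.max_hits]


def _seed_clusters(q: str, index: GenomeIndex,
                   params: SearchParams) -> list[tuple[int, int, int]]:
    """Cluster seed hits by (chrom, diagonal band) into target windows."""
    k = params.k
    qcodes, qpos = _kmer_codes(q, k)
    if len(qcodes) == 0:
        return []
    # sample query seeds at stride k/2 to bound work on long queries
    stride = max(1, k // 2)
    keep = np.zeros(len(qpos), dtype=bool)
    keep[::stride] = True
    keep[-1] = True
    buckets: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for code, qp in zip(qcodes[keep], qpos[keep]):
        chroms, tpos = index.lookup(int(code))
        if len(tpos) > 200:      # over-represented seed; skip
            continue
        for ci, tp in zip(chroms, tpos):
            diag = int(tp) - int(qp)
            buckets.setdefault((int(ci), diag // max(params.band_width, 1)),
                               []).append((int(tp), int(qp)))
    # merge adjacent diagonal buckets on the same chromosome
    merged: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for (ci, db), seeds in sorted(buckets.items()):
        key = (ci, db)
        prev = (ci, db - 1)
        if prev in merged:
            merged[prev].extend(seeds)
            merged[key] = merged[prev]
        else:
            merged[key] = seeds
    clusters = []
    seen: set[int] = set()
    for (ci, _db), seeds in merged.items():
        if id(seeds) in seen:
            continue
        seen.add(id(seeds))
        tmin = min(tp - qp2 for tp, qp2 in seeds)
        tmax = max(tp - qp2 for tp, qp2 in seeds)
        chrom_len = index.genome[index.chrom_names[ci]].length
        lo = max(0, tmin - params.band_width)
        hi = min(chrom_len, tmax + len(q) + params.band_width)
        clusters.append((ci, lo, hi))
    return _merge_windows(clusters)


def _merge_windows(clusters: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    clusters.sort()
    out: list[tuple[int, int, int]] = []
    for ci, lo, hi in clusters:
        if out and out[-1][0] == ci and lo <= out[-1][2]:
            out[-1] = (ci, out[-1][1], max(out[-1][2], hi))
        else:
            out.append((ci, lo, hi))
    return out


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose target span largely duplicates a better hit."""
    hits = sorted(hits, key=lambda h: (-h.score, h.target_chrom, h.target_span[0]))
    kept: list[AlignmentHit] = []
    for h in hits:
        dup = False
        for g in kept:
            if g.target_chrom != h.target_chrom:
                continue
            lo = max(g.target_span[0], h.target_span[0])
            hi = min(g.target_span[1], h.target_span[1])
            if hi - lo > 0.5 * h.target_len:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept
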