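"""Junction forensics for captured segments.

Each Pack-TIR has two template-switch junctions on its consensus TE: the
point where the 5' TE arm gives way to filler (bp5) and the point where
filler gives way to the 3' arm (bp3), both in 1-based consensus
coordinates.  This module locates those switch points, measures the
junction microhomology shared between the TE template and the filler's
parental flanks, estimates a per-junction chance-level null by resampling
random fragments and switch points, and tests whether switch points are
positionally skewed relative to a uniform null after folding onto the 5'
half of the element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .homology import align_pair
from .io import ConsensusTE, revcomp
from .scan import PackTIRCandidate

logger = logging.getLogger(__name__)


@dataclass
class SwitchPointPair:
    candidate_id: str
    bp5: int                     # 1-based on consensus
    bp3: int
    L: int

    def __post_init__(self) -> None:
        if not 1 <= self.bp5 < self.bp3 <= self.L:
            raise ValueError("need 1 <= bp5 < bp3 <= L")

    @property
    def gap_fraction(self) -> float:
        return (self.bp3 - self.bp5) / self.L


@dataclass
class MicrohomologyCall:
    candidate_id: str
    side: str                    # left | right
    mh_len: int
    mh_seq: str
    denovo_insert_len: int = 0

    @property
    def blunt(self) -> bool:
        return self.mh_len == 0 and self.denovo_insert_len == 0


@dataclass
class NullSimResult:
    candidate_id: str
    side: str
    observed_mh: int
    n_reps: int
    n_ge: int
    seed: int

    @property
    def empirical_p(self) -> float:
        return self.n_ge / self.n_reps


@dataclass
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# switch points
# ---------------------------------------------------------------------------

def infer_switch_points(candidate: PackTIRCandidate,
                        consensus: ConsensusTE | None = None,
                        min_identity: float = 60.0) -> SwitchPointPair | None:
    """Locate the two switch points by aligning each flanking fragment to
    the consensus.

    bp5 is where the consensus-5' fragment's alignment ends (inward side);
    bp3 is where the consensus-3' fragment's alignment begins.  Fragments
    failing to align at ``min_identity`` exclude the candidate (returns
    None); overlapping alignments (bp5 >= bp3) flag an incoherent junction.
    """
    consensus = consensus or candidate.consensus
    # fragment sequences in consensus orientation
    lseq = candidate_fragment_seq(candidate, "left")
    rseq = candidate_fragment_seq(candidate, "right")
    if candidate.strand == "+":
        frag5, frag3 = lseq, rseq
    else:
        frag5, frag3 = revcomp(rseq), revcomp(lseq)
    a5 = align_pair(frag5, consensus.seq)
    a3 = align_pair(frag3, consensus.seq)
    for a, frag in ((a5, frag5), (a3, frag3)):
        if a is None or a.identity_pct < min_identity:
            logger.info("candidate %s: fragment fails to align to consensus",
                        candidate.id)
            return None
    bp5 = a5.target_span[1]           # 0-based exclusive == 1-based inclusive
    bp3 = a3.target_span[0] + 1       # 0-based start -> 1-based
    if bp5 >= bp3:
        candidate.status = "flagged:incoherent_junction"
        logger.info("candidate %s: incoherent junction (bp5 %d >= bp3 %d)",
                    candidate.id, bp5, bp3)
        return None
    return SwitchPointPair(candidate.id, bp5, bp3, consensus.length)


def candidate_fragment_seq(candidate: PackTIRCandidate, which: str,
                           genome=None) -> str:
    """Genomic sequence of a flanking TE fragment.

    Candidates built by the scan keep the fragment spans; the sequence is
    sliced from the internal-seq's chromosome context stored on the record.
    """
    rec = candidate.left_te if which == "left" else candidate.right_te
    seq = getattr(candidate, "_chrom_seq_cache", None)
    if seq is None:
        if genome is None:
            raise ValueError("attach chromosome sequence with attach_chrom_seq "
                             "or pass genome=")
        seq = genome[candidate.chrom].seq
    return seq[rec.start:rec.end]


def attach_chrom_seq(candidate: PackTIRCandidate, genome) -> None:
    candidate._chrom_seq_cache = genome[candidate.chrom].seq


# ---------------------------------------------------------------------------
# microhomology
# ---------------------------------------------------------------------------

def _match_run(a: str, b: str, cap: int) -> int:
    """Length of the common prefix of a and b, capped."""
    n = 0
    for x, y in zip(a, b):
        if x != y or n >= cap:
            break
        n += 1
    return n


def _junction_mh(cons: str, switch_1based: int, side: str,
                 filler: str, flank_out: str, window: int) -> tuple[int, str]:
    """Microhomology at one junction.

    For the left junction (TE -> filler) at consensus position ``s``:
    outward = run of identity between the TE bases ending at s and the
    parental bases immediately preceding the filler (both read outward from
    the junction); inward = run of identity between the consensus
    continuation after s and the filler's first bases.  The right junction
    (filler -> TE) is the mirror image.  Returns (length, sequence).
    """
    s = switch_1based
    if side == "left":
        te_out = cons[:s][::-1]              # outward = leftward
        te_in = cons[s:]                     # consensus continuation
        out = _match_run(te_out, flank_out[::-1], window)
        inw = _match_run(te_in, filler, window)
        seq = cons[s - out:s] + filler[:inw]
    else:
        te_out = cons[s - 1:]                # outward = rightward from bp3
        te_in = cons[:s - 1][::-1]           # consensus before bp3, leftward
        out = _match_run(te_out, flank_out, window)
        inw = _match_run(te_in, filler[::-1], window)
        seq = filler[len(filler) - inw:] + cons[s - 1:s - 1 + out]
    return out + inw, seq


def measure_microhomology(candidate: PackTIRCandidate,
                          consensus: ConsensusTE | None = None,
                          parent_locus_seq: str | None = None,
                          switch_points: SwitchPointPair | None = None,
                          window: int = 50) -> list[MicrohomologyCall]:
    """Measure junction microhomology on both sides of a candidate.

    The internal sequence is aligned to the parental locus to locate the
    filler within it; unaligned internal bases at a junction are reported
    as de novo insertions.  Microhomology is the outward run (TE bases vs
    the filler's parental flank) plus the inward run (consensus
    continuation vs filler), each capped at ``window``.
    """
    consensus = consensus or candidate.consensus
    if parent_locus_seq is None:
        parent_locus_seq = getattr(candidate, "_parent_seq_cache", None)
        if parent_locus_seq is None:
            raise ValueError("parent locus sequence required")
    sp = switch_points or infer_switch_points(candidate, consensus)
    if sp is None:
        return []
    internal = candidate.oriented_internal_seq()
    # orient the parent locus to match the filler as embedded in the element
    aln_f = align_pair(internal, parent_locus_seq)
    aln_r = align_pair(internal, revcomp(parent_locus_seq))
    if aln_f is None and aln_r is None:
        return []
    if aln_r is not None and (aln_f is None or aln_r.score > aln_f.score):
        parent_locus_seq = revcomp(parent_locus_seq)
        aln = aln_r
    else:
        aln = aln_f
    qs, qe = aln.query_span
    ts, te = aln.target_span
    filler = internal[qs:]              # filler as embedded in the element
    flank_left = parent_locus_seq[:ts]  # parental bases preceding the filler
    filler_right = internal[:qe]
    flank_right = parent_locus_seq[te:]
    mh_l, seq_l = _junction_mh(consensus.seq, sp.bp5, "left",
                               filler, flank_left, window)
    mh_r, seq_r = _junction_mh(consensus.seq, sp.bp3, "right",
                               filler_right, flank_right, window)
    return [
        MicrohomologyCall(candidate.id, "left", mh_l, seq_l if mh_l else "",
                          denovo_insert_len=qs),
        MicrohomologyCall(candidate.id, "right", mh_r, seq_r if mh_r else "",
                          denovo_insert_len=len(internal) - qe),
    ]


# ---------------------------------------------------------------------------
# microhomology null
# ---------------------------------------------------------------------------

def microhomology_null_pvalue(parent_locus_seq: str,
                              consensus: ConsensusTE,
                              filler_len: int,
                              observed_mh: int,
                              side: str = "left",
                              n_reps: int = 100,
                              seed: int = 0,
                              candidate_id: str = "",
                              window: int = 50) -> NullSimResult:
    """Chance-level null for one junction's microhomology.

    The template is the parental copy together with flanks of half its
    length on each side (the caller supplies that string).  Each replicate
    draws a uniform fragment of ``filler_len`` from the template and a
    uniform switch point on the consensus, and measures microhomology at
    the focal side with the observed-data procedure; the empirical p-value
    is exactly n_ge / n_reps, the fraction of replicates with microhomology
    >= observed.  Replicate i consumes (fragment_start, switch_point) from
    one seeded generator, in that order.
    """
    if filler_len > len(parent_locus_seq):
        raise ValueError("filler_len longer than the template")
    rng = np.random.default_rng(seed)
    L = consensus.length
    n_ge = 0
    max_start = len(parent_locus_seq) - filler_len
    for _ in range(n_reps):
        fs = int(rng.integers(0, max_start + 1))
        s = int(rng.integers(2, L))          # switch point, 1-based interior
        fragment = parent_locus_seq[fs:fs + filler_len]
        if side == "left":
            flank = parent_locus_seq[:fs]
            mh, _ = _junction_mh(consensus.seq, s, "left", fragment, flank,
                                 window)
        else:
            flank = parent_locus_seq[fs + filler_len:]
            mh, _ = _junction_mh(consensus.seq, s, "right", fragment, flank,
                                 window)
        if mh >= observed_mh:
            n_ge += 1
    return NullSimResult(candidate_id, side, observed_mh, n_reps, n_ge, seed)


# ---------------------------------------------------------------------------
# breakpoint position folding and KS test
# ---------------------------------------------------------------------------

def fold(rel: float) -> float:
    """Fold a relative position onto the 5' half: rel if <= 0.5 else 1-rel."""
    return rel if rel <= 0.5 else 1.0 - rel


def fold_breakpoint_positions(pairs: list[SwitchPointPair]) -> np.ndarray:
    """Per candidate, the folded position of the switch point closer to a
    terminal: min(fold(bp5/L), fold(bp3/L))."""
    return np.array([min(fold(p.bp5 / p.L), fold(p.bp3 / p.L)) for p in pairs])


def folded_min_null_cdf(x: np.ndarray) -> np.ndarray:
    """Analytic CDF of min(fold(U1), fold(U2)) for independent uniforms:
    F(x) = 1 - (1 - 2x)^2 on [0, 1/2]."""
    x = np.asarray(x, dtype=float)
    return np.clip(1.0 - (1.0 - 2.0 * np.clip(x, 0, 0.5)) ** 2, 0.0, 1.0)


def sample_folded_min_null(n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.random((n, 2))
    folded = np.minimum(u, 1.0 - u)
    return folded.min(axis=1)


def ks_uniform_null_test(folded_sample: np.ndarray,
                         n_sim: int | None = None,
                         seed: int = 0) -> KSResult:
    """Two-sample two-sided KS test of the observed folded-min sample
    against a simulated uniform-breakpoint null passed through the same
    fold-and-min transform.  Small samples (< 5) use the exact p-value."""
    obs = np.asarray(folded_sample, dtype=float)
    if obs.size == 0:
        raise ValueError("empty folded sample")
    n_sim = n_sim if n_sim is not None else obs.size
    rng = np.random.default_rng(seed)
    null = sample_folded_min_null(n_sim, rng)
    method = "exact" if obs.size < 5 else "asymp"
    if obs.size < 5:
        logger.warning("KS sample size %d < 5; using exact p", obs.size)
    res = stats.ks_2samp(obs, null, method=method)
    return KSResult(float(res.statistic), float(res.pvalue),
                    obs.size, n_sim)


def ks_two_sample_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Plain two-sample KS statistic (sup over thresholds)."""
    res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def parent_locus_with_flanks(candidate: PackTIRCandidate, genome,
                             flank_frac: float = 0.5) -> str | None:
    """Parental copy plus flanks of ``flank_frac`` of its length per side —
    the template used by both measurement and the resampling null."""
    if candidate.parent is None:
        return None
    hit = candidate.parent.hit
    ps, pe = hit.target_span
    ext = int(round(flank_frac * (pe - ps)))
    seq = genome[hit.target_chrom].seq
    return seq[max(0, ps - ext):min(len(seq), pe + ext)]


def run_breakpoint_analysis(candidates, genome, n_reps: int = 100,
                            seed: int = 0):
    """Switch points, microhomology and per-junction nulls for every
    passing candidate; returns (switch_pairs, mh_calls, null_results)."""
    pairs, calls, nulls = [], [], []
    for i, cand in enumerate(c for c in candidates if c.passed):
        attach_chrom_seq(cand, genome)
        sp = infer_switch_points(cand)
        if sp is None:
            continue
        pairs.append(sp)
        template = parent_locus_with_flanks(cand, genome)
        if template is None:
            continue
        mh = measure_microhomology(cand, parent_locus_seq=template,
                                   switch_points=sp)
        calls.extend(mh)
        flen = len(cand.internal_seq)
        for call in mh:
            if call.mh_len == 0 or call.denovo_insert_len > 0:
                continue
            nulls.append(microhomology_null_pvalue(
                template, cand.consensus, min(flen, len(template)),
                call.mh_len, side=call.side, n_reps=n_reps,
                seed=seed + 7919 * i, candidate_id=cand.id))
    return pairs, calls, nulls
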