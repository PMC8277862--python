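"""Synthetic-genome generator with truth tables.

Emulates the data the pipeline assumes: assemblies carrying diverged TIR-TE
copies with target-site duplications, gap-filling captures with cis-biased
donor distance and engineered junction microhomology, FoSTeST multicopy
insertions with distinct TSDs, haploid SNP panels with and without a
selective sweep linked to an insertion allele, and insertion
presence/absence matrices.  Every generated dataset comes with a
:class:`TruthRecord` table that downstream recovery tests treat as the
oracle: all planted coordinates, switch points, TSDs and microhomology
lengths are re-extractable verbatim from the emitted sequences at zero
post-insertion divergence.

Generative defaults follow the summaries the analysis is calibrated
against: consensus length median 374 bp, per-copy divergence median 18.3%,
captured-segment length median 224 bp, junction microhomology median 2 bp,
switch-point gap median ~4.6% of the consensus, and a 65.8% singleton
fraction for segregating insertions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ConsensusTE, GeneModel, GenomeSequence, VariantPanel,
                 revcomp, write_fasta, write_gff3, write_rm_out, write_vcf)

_BASES = np.array(list("ACGT"))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent named substream of the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(zlib.crc32(stage.encode()),)))


@dataclass
class PanelConfig:
    n_lines: int = 80
    snp_density: float = 0.03        # SNPs per bp
    region_len: int = 120_000
    sweep_span: int = 10_000
    sweep_reduction: float = 5.0     # fold reduction of carrier diversity
    carrier_fraction: float = 0.25
    syn_fraction: float = 0.5
    recomb_rate: float = 2.0         # cM/Mb, constant


@dataclass
class PresenceConfig:
    n_insertions: int = 500
    n_lines: int = 83
    singleton_target: float = 0.658
    focal_frequency: float = 0.25


@dataclass
class SimulationConfig:
    genome_len: int = 1_000_000
    n_chroms: int = 3
    gc_content: float = 0.41
    n_te_families: int = 6
    consensus_len_median: int = 374
    tir_len: int = 30
    n_te_copies: int = 150
    copy_divergence_median: float = 0.183
    tsd_len_range: tuple[int, int] = (4, 10)
    n_packtirs: int = 30
    filler_len_range: tuple[int, int] = (101, 4999)
    filler_len_median: int = 224
    donor_distance_decay: float = 5770.0   # exponential mean, bp (median ~4 kb)
    intra_fraction: float = 0.6
    microhomology_median: int = 2
    mh_blunt_prob: float = 0.3
    breakpoint_beta_params: tuple[float, float] = (0.75, 0.75)
    gap_fraction_median: float = 0.046
    n_multicopy_families: int = 1
    multicopy_copy_count: int = 3
    n_retro_confounds: int = 0
    capture_divergence: float = 0.0
    post_insertion_divergence: float = 0.0
    minus_strand_prob: float = 0.5
    panel: PanelConfig = field(default_factory=PanelConfig)
    te_presence: PresenceConfig = field(default_factory=PresenceConfig)

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if self.tir_len * 2 >= self.consensus_len_median:
            raise ValueError("tir_len must be < consensus length / 2")
        lo, hi = self.filler_len_range
        if not 100 < lo < hi < 5000:
            raise ValueError("filler_len_range must lie within (100, 5000)")


@dataclass
class TruthRecord:
    event_id: str
    type: str                      # te_copy | packtir_gapfill | packtir_fostest | retro_confound
    chrom: str
    start: int                     # element outer span, final coordinates
    end: int
    strand: str
    consensus_name: str
    consensus_len: int
    internal_start: int = -1
    internal_end: int = -1
    donor_chrom: str = ""
    donor_start: int = -1
    donor_end: int = -1
    bp5: int = -1                  # 1-based on consensus
    bp3: int = -1
    mh_left: int = -1
    mh_right: int = -1
    tsd: str = ""
    family_id: str = ""
    divergence: float = 0.0


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def build_te_library(config: SimulationConfig,
                     seed: int = 0) -> list[ConsensusTE]:
    """Random consensus sequences whose last ``tir_len`` bases are the
    reverse complement of the first ``tir_len`` (true terminal inverted
    repeats); lengths are log-normal around the configured median."""
    rng = stage_rng(seed, "library")
    out = []
    for i in range(config.n_te_families):
        L = int(round(np.exp(rng.normal(np.log(config.consensus_len_median), 0.35))))
        L = max(L, config.tir_len * 2 + 40)
        codes = random_seq(rng, L, config.gc_content)
        seq = _to_str(codes)
        seq = seq[:L - config.tir_len] + revcomp(seq[:config.tir_len])
        out.append(ConsensusTE(f"TIRTE{i + 1}", seq, superfamily="hAT-like"))
    return out


# ---------------------------------------------------------------------------
# genome planting
# ---------------------------------------------------------------------------

class _Reserver:
    """Per-chromosome reserved intervals with margin, for collision-free planning."""

    def __init__(self) -> None:
        self.spans: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, lo: int, hi: int) -> bool:
        for s, e in self.spans.get(chrom, []):
            if lo < e and s < hi:
                return False
        return True

    def reserve(self, chrom: str, lo: int, hi: int) -> None:
        self.spans.setdefault(chrom, []).append((lo, hi))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, float]:
    if rate <= 0:
        return seq, 0.0
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    idx = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in idx:
        old = lut[codes[i]]
        codes[i] = ord(_BASES[(old + rng.integers(1, 4)) % 4])
    return codes.tobytes().decode(), len(idx) / max(len(seq), 1)


def _pick_base_not(rng: np.random.Generator, forbidden: str) -> str:
    choices = [b for b in "ACGT" if b != forbidden]
    return choices[rng.integers(0, 3)]


@dataclass
class _PlannedInsertion:
    chrom: str
    pos: int           # background coordinate of insertion point
    text: str          # element + right TSD copy
    element_len: int
    tsd: str
    truth: TruthRecord


def plant_genome(config: SimulationConfig, seed: int = 0):
    """Generate a genome, RepeatMasker-style annotation, gene models and a
    truth table.  Returns ``(genome, annotations, genes, library, truths)``.

    Events are planned in background coordinates with collision-free
    reservations, then materialized in one pass; truth coordinates are
    reported in final (post-insertion) coordinates.
    """
    library = build_te_library(config, seed)
    lib = {c.name: c for c in library}
    rng = stage_rng(seed, "plant")

    chrom_len = config.genome_len // config.n_chroms
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    background = {name: random_seq(rng, chrom_len, config.gc_content)
                  for name in chrom_names}
    bg = {name: list(_to_str(codes)) for name, codes in background.items()}

    reserver = _Reserver()
    insertions: list[_PlannedInsertion] = []
    genes: list[GeneModel] = []
    truths: list[TruthRecord] = []
    linkage_counter = [0]

    def sample_free_point(chrom: str, width: int, tries: int = 200) -> int | None:
        for _ in range(tries):
            p = int(rng.integers(200, chrom_len - 200 - width))
            if reserver.free(chrom, p - 60, p + width + 60):
                return p
        return None

    def plan_tsd(chrom: str, pos: int) -> str:
        tlen = int(rng.integers(config.tsd_len_range[0],
                                config.tsd_len_range[1] + 1))
        return "".join(bg[chrom][pos - tlen:pos])

    est_need = (config.n_te_copies * (config.consensus_len_median + 100)
                + (config.n_packtirs + config.n_multicopy_families
                   * config.multicopy_copy_count)
                * (config.consensus_len_median + config.filler_len_median + 400))
    if est_need > 0.6 * config.genome_len:
        raise ValueError("requested events exceed genome capacity")

    # --- plain TE copies -------------------------------------------------
    for i in range(config.n_te_copies):
        cons = library[int(rng.integers(len(library)))]
        div = min(float(rng.exponential(config.copy_divergence_median / np.log(2))), 0.45)
        seq, realized = _mutate(rng, cons.seq, div)
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        if strand == "-":
            seq = revcomp(seq)
        chrom = chrom_names[int(rng.integers(config.n_chroms))]
        pos = sample_free_point(chrom, len(seq))
        if pos is None:
            continue
        tsd = plan_tsd(chrom, pos)
        reserver.reserve(chrom, pos - 30, pos + len(seq) + 30)
        truth = TruthRecord(
            event_id=f"te{i:04d}", type="te_copy", chrom=chrom,
            start=pos, end=pos + len(seq), strand=strand,
            consensus_name=cons.name, consensus_len=cons.length,
            divergence=realized)
        insertions.append(_PlannedInsertion(chrom, pos, seq + tsd,
                                            len(seq), tsd, truth))
        truths.append(truth)

    # --- gap-filling captures -------------------------------------------
    def draw_switch_points(L: int) -> tuple[int, int]:
        a, b = config.breakpoint_beta_params
        for _ in range(100):
            center = rng.beta(a, b)
            gap = np.exp(rng.normal(np.log(config.gap_fraction_median), 0.6))
            bp5 = int(round((center - gap / 2) * L))
            bp3 = int(round((center + gap / 2) * L))
            if 20 <= bp5 < bp3 <= L - 20:
                return bp5, bp3
        return L // 3, L // 3 + max(4, int(config.gap_fraction_median * L))

    def draw_mh(rng) -> int:
        if rng.random() < config.mh_blunt_prob:
            return 0
        return int(min(rng.geometric(0.3), 36))

    def draw_filler_len(rng) -> int:
        lo, hi = config.filler_len_range
        for _ in range(100):
            n = int(round(np.exp(rng.normal(np.log(config.filler_len_median), 0.8))))
            if lo <= n <= hi:
                return n
        return config.filler_len_median

    def pick_donor(flen: int) -> tuple[str, int] | None:
        margin = 100
        for _ in range(300):
            chrom = chrom_names[int(rng.integers(config.n_chroms))]
            d = int(rng.integers(200, chrom_len - 200 - flen))
            if reserver.free(chrom, d - margin - 40, d + flen + margin + 40):
                return chrom, d
        return None

    def engineer_junctions(cons: ConsensusTE, bp5: int, bp3: int,
                           dchrom: str, d: int, flen: int,
                           mh_l: int, mh_r: int) -> None:
        """Overwrite donor-flank and boundary bases so the measured
        microhomology at each junction equals the configured truth exactly."""
        cseq = cons.seq
        row = bg[dchrom]
        # left junction: outward run of mh_l, then a forced break
        if mh_l > 0:
            row[d - mh_l:d] = list(cseq[bp5 - mh_l:bp5])
        row[d - mh_l - 1] = _pick_base_not(rng, cseq[bp5 - mh_l - 1])
        # left inward break: filler[0] must differ from consensus continuation
        if row[d] == cseq[bp5]:
            row[d] = _pick_base_not(rng, cseq[bp5])
        # right junction: outward run (filler tail vs consensus before bp3)
        if mh_r > 0:
            row[d + flen - mh_r:d + flen] = list(cseq[bp3 - 1 - mh_r:bp3 - 1])
        if flen > mh_r:
            row[d + flen - mh_r - 1] = _pick_base_not(rng, cseq[bp3 - 2 - mh_r])
        # right inward break: downstream flank vs consensus at bp3
        if row[d + flen] == cseq[bp3 - 1]:
            row[d + flen] = _pick_base_not(rng, cseq[bp3 - 1])

    def build_chimera(cons: ConsensusTE, bp5: int, bp3: int,
                      dchrom: str, d: int, flen: int) -> tuple[str, str]:
        filler = "".join(bg[dchrom][d:d + flen])
        if config.capture_divergence > 0:
            filler, _ = _mutate(rng, filler, config.capture_divergence)
        return cons.seq[:bp5] + filler + cons.seq[bp3 - 1:], filler

    def plan_capture(idx: int, etype: str, family_id: str,
                     forced_filler: tuple[str, int, int] | None = None,
                     n_copies: int = 1) -> list[TruthRecord]:
        cons = library[int(rng.integers(len(library)))]
        L = cons.length
        bp5, bp3 = draw_switch_points(L)
        made: list[TruthRecord] = []
        if forced_filler is not None:
            dchrom, d, flen = forced_filler
        else:
            flen = draw_filler_len(rng)
            donor = pick_donor(flen)
            if donor is None:
                return made
            dchrom, d = donor
        mh_l, mh_r = draw_mh(rng), draw_mh(rng)
        mh_l = min(mh_l, bp5 - 2)
        mh_r = min(mh_r, flen - 2, L - bp3 - 1)
        mh_l, mh_r = max(mh_l, 0), max(mh_r, 0)
        engineer_junctions(cons, bp5, bp3, dchrom, d, flen, mh_l, mh_r)
        reserver.reserve(dchrom, d - 60, d + flen + 60)
        chimera, _filler = build_chimera(cons, bp5, bp3, dchrom, d, flen)
        for ci in range(n_copies):
            strand = "-" if rng.random() < config.minus_strand_prob else "+"
            text = chimera if strand == "+" else revcomp(chimera)
            if n_copies > 1:
                chrom = chrom_names[ci % config.n_chroms]
            elif forced_filler is not None:
                chrom = dchrom
            else:
                chrom = dchrom if rng.random() < config.intra_fraction else \
                    chrom_names[int(rng.integers(config.n_chroms))]
            pos = None
            for _ in range(300):
                if chrom == dchrom and n_copies == 1 and forced_filler is None \
                        and rng.random() < 0.9:
                    cand = d + int(rng.exponential(config.donor_distance_decay)
                                   * (1 if rng.random() < 0.5 else -1))
                else:
                    cand = int(rng.integers(200, chrom_len - 200 - len(text)))
                if not 200 <= cand < chrom_len - 200 - len(text):
                    continue
                if reserver.free(chrom, cand - 60, cand + len(text) + 60):
                    pos = cand
                    break
            if pos is None:
                continue
            tsd = plan_tsd(chrom, pos)
            if n_copies > 1:
                # distinct TSDs are the multicopy hallmark; redraw on collision
                tries = 0
                while any(t.tsd == tsd for t in made) and tries < 50:
                    pos = sample_free_point(chrom, len(text))
                    if pos is None:
                        break
                    tsd = plan_tsd(chrom, pos)
                    tries += 1
                if pos is None:
                    continue
            reserver.reserve(chrom, pos - 30, pos + len(text) + 30)
            truth = TruthRecord(
                event_id=f"{etype[:4]}{idx:03d}" + (f"c{ci}" if n_copies > 1 else ""),
                type=etype, chrom=chrom, start=pos, end=pos + len(text),
                strand=strand, consensus_name=cons.name, consensus_len=L,
                donor_chrom=dchrom, donor_start=d, donor_end=d + flen,
                bp5=bp5, bp3=bp3, mh_left=mh_l, mh_right=mh_r,
                tsd=tsd, family_id=family_id)
            insertions.append(_PlannedInsertion(chrom, pos, text + tsd,
                                                len(text), tsd, truth))
            made.append(truth)
        truths.extend(made)
        return made

    for i in range(config.n_packtirs):
        plan_capture(i, "packtir_gapfill", family_id=f"F{i:03d}")

    # --- FoSTeST multicopy families -------------------------------------
    for i in range(config.n_multicopy_families):
        plan_capture(i, "packtir_fostest", family_id=f"MC{i:02d}",
                     n_copies=config.multicopy_copy_count)

    # --- retroduplicate confounds ---------------------------------------
    for i in range(config.n_retro_confounds):
        exon, intron = 500, 200
        glen = exon * 2 + intron
        gchrom = chrom_names[int(rng.integers(config.n_chroms))]
        gpos = sample_free_point(gchrom, glen + 200)
        if gpos is None:
            continue
        reserver.reserve(gchrom, gpos - 60, gpos + glen + 60)
        genes.append(GeneModel(
            f"gene{i}", f"gene{i}.t1", gchrom, "+",
            [(gpos, gpos + exon), (gpos + exon + intron, gpos + glen)]))
        # the capture carries the spliced (intronless) product of the gene
        cons = library[int(rng.integers(len(library)))]
        L = cons.length
        bp5, bp3 = draw_switch_points(L)
        filler = ("".join(bg[gchrom][gpos:gpos + exon])
                  + "".join(bg[gchrom][gpos + exon + intron:gpos + glen]))
        chimera = cons.seq[:bp5] + filler + cons.seq[bp3 - 1:]
        chrom = chrom_names[int(rng.integers(config.n_chroms))]
        pos = sample_free_point(chrom, len(chimera))
        if pos is None:
            continue
        tsd = plan_tsd(chrom, pos)
        reserver.reserve(chrom, pos - 30, pos + len(chimera) + 30)
        truth = TruthRecord(
            event_id=f"retro{i:02d}", type="retro_confound", chrom=chrom,
            start=pos, end=pos + len(chimera), strand="+",
            consensus_name=cons.name, consensus_len=L,
            donor_chrom=gchrom, donor_start=gpos, donor_end=gpos + glen,
            bp5=bp5, bp3=bp3, tsd=tsd)
        insertions.append(_PlannedInsertion(chrom, pos, chimera + tsd,
                                            len(chimera), tsd, truth))
        truths.append(truth)

    # --- materialize ------------------------------------------------------
    genome: dict[str, GenomeSequence] = {}
    offsets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chrom_names:
        ins = sorted((p for p in insertions if p.chrom == chrom),
                     key=lambda p: p.pos)
        parts, cuts, shifts = [], [], []
        last, shift = 0, 0
        for p in ins:
            parts.append("".join(bg[chrom][last:p.pos]))
            parts.append(p.text)
            cuts.append(p.pos)
            shift += len(p.text)
            shifts.append(shift)
            last = p.pos
        parts.append("".join(bg[chrom][last:]))
        genome[chrom] = GenomeSequence(chrom, "".join(parts))
        offsets[chrom] = (np.array(cuts, dtype=np.int64),
                          np.array(shifts, dtype=np.int64))

    def final_pos(chrom: str, x: int, inclusive: bool = False) -> int:
        cuts, shifts = offsets[chrom]
        side = "right" if inclusive else "left"
        i = int(np.searchsorted(cuts, x, side=side))
        return x + (int(shifts[i - 1]) if i > 0 else 0)

    # shift truth/gene coordinates to final space
    for p in insertions:
        t = p.truth
        fs = final_pos(p.chrom, p.pos)
        t.start, t.end = fs, fs + p.element_len
    for t in truths:
        if t.donor_start >= 0:
            ds = final_pos(t.donor_chrom, t.donor_start, inclusive=True)
            t.donor_end = ds + (t.donor_end - t.donor_start)
            t.donor_start = ds
        if t.type in ("packtir_gapfill", "packtir_fostest", "retro_confound"):
            L, bp5, bp3 = t.consensus_len, t.bp5, t.bp3
            ilen = (t.end - t.start) - bp5 - (L - bp3 + 1)
            if t.strand == "+":
                t.internal_start = t.start + bp5
            else:
                t.internal_start = t.start + (L - bp3 + 1)
            t.internal_end = t.internal_start + ilen
    for g in genes:
        g.exons = [(final_pos(g.chrom, s, inclusive=True),
                    final_pos(g.chrom, s, inclusive=True) + (e - s))
                   for s, e in g.exons]

    # post-insertion divergence applies to everything, last
    if config.post_insertion_divergence > 0:
        for chrom in chrom_names:
            seq, _ = _mutate(rng, genome[chrom].seq,
                             config.post_insertion_divergence)
            genome[chrom] = GenomeSequence(chrom, seq)

    annotations = _truths_to_annotations(truths, lib, linkage_counter)
    return genome, annotations, genes, library, truths


def _truths_to_annotations(truths, lib, counter):
    from .io import TEAnnotationRecord

    records = []
    for t in truths:
        if t.type == "te_copy":
            counter[0] += 1
            records.append(TEAnnotationRecord(
                chrom=t.chrom, start=t.start, end=t.end, strand=t.strand,
                consensus_name=t.consensus_name, family="DNA/TIR",
                cons_start=1, cons_end=t.consensus_len,
                divergence_pct=round(100 * t.divergence, 1),
                linkage_id=counter[0]))
        elif t.type in ("packtir_gapfill", "packtir_fostest", "retro_confound"):
            counter[0] += 1
            L, bp5, bp3 = t.consensus_len, t.bp5, t.bp3
            len5, len3 = bp5, L - bp3 + 1
            ilen = (t.end - t.start) - len5 - len3
            if t.strand == "+":
                spans = [(t.start, t.start + len5, 1, bp5),
                         (t.start + len5 + ilen, t.end, bp3, L)]
            else:
                spans = [(t.start, t.start + len3, bp3, L),
                         (t.start + len3 + ilen, t.end, 1, bp5)]
            for gs, ge, cs, ce in spans:
                records.append(TEAnnotationRecord(
                    chrom=t.chrom, start=gs, end=ge, strand=t.strand,
                    consensus_name=t.consensus_name, family="DNA/TIR",
                    cons_start=cs, cons_end=ce, divergence_pct=0.0,
                    linkage_id=counter[0]))
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def truth_table(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truths])


# ---------------------------------------------------------------------------
# variant panel
# ---------------------------------------------------------------------------

def simulate_variant_panel(config: SimulationConfig, seed: int = 0,
                           insertion_locus: int | None = None,
                           chrom: str = "chrP"):
    """Haploid SNP panel around an insertion locus.

    Carrier lines share a recent haplotype over ``sweep_span`` centered on
    the insertion: within the span, each site's carrier alleles are
    homogenized with probability 1 - 1/sweep_reduction, which reduces
    carrier pairwise diversity by roughly that factor.  Returns
    ``(panel, carrier_line_ids)``.
    """
    pc = config.panel
    if pc.n_lines < 4:
        raise ValueError("panel needs at least 4 lines")
    rng = stage_rng(seed, "panel")
    if insertion_locus is None:
        insertion_locus = pc.region_len // 2
    positions = np.nonzero(rng.random(pc.region_len) < pc.snp_density)[0]
    n_sites = len(positions)
    line_ids = [f"L{i:03d}" for i in range(pc.n_lines)]
    geno = np.zeros((n_sites, pc.n_lines), dtype=np.int8)
    # neutral-ish frequency spectrum: carrier counts ~ 1/i
    counts = np.arange(1, pc.n_lines)
    w = 1.0 / counts
    w /= w.sum()
    site_counts = rng.choice(counts, size=n_sites, p=w)
    for i, c in enumerate(site_counts):
        geno[i, rng.choice(pc.n_lines, size=c, replace=False)] = 1

    n_car = max(2, int(round(pc.carrier_fraction * pc.n_lines)))
    carriers = rng.choice(pc.n_lines, size=n_car, replace=False)
    if pc.sweep_reduction > 1:
        span_lo = insertion_locus - pc.sweep_span // 2
        span_hi = insertion_locus + pc.sweep_span // 2
        in_span = (positions >= span_lo) & (positions < span_hi)
        p_fix = 1.0 - 1.0 / pc.sweep_reduction
        for i in np.nonzero(in_span)[0]:
            if rng.random() < p_fix:
                geno[i, carriers] = 0
    syn = rng.random(n_sites) < pc.syn_fraction
    rr = np.full(n_sites, pc.recomb_rate)
    panel = VariantPanel(line_ids, np.array([chrom] * n_sites, dtype=object),
                         positions.astype(np.int64), geno, syn, rr)
    return panel, [line_ids[i] for i in sorted(carriers)]


# ---------------------------------------------------------------------------
# insertion presence/absence
# ---------------------------------------------------------------------------

def simulate_te_presence(config: SimulationConfig, seed: int = 0) -> pd.DataFrame:
    """Presence/absence matrix (lines x insertions) whose expected singleton
    fraction equals ``singleton_target``; the ``focal`` insertion gets an
    elevated frequency."""
    tc = config.te_presence
    if not 0 < tc.singleton_target <= 1:
        raise ValueError("singleton_target must be in (0, 1]")
    rng = stage_rng(seed, "presence")
    n, m = tc.n_lines, tc.n_insertions
    mat = np.zeros((n, m), dtype=np.int8)
    names = []
    for j in range(m):
        if j == 0:
            c = max(2, int(round(tc.focal_frequency * n)))
            names.append("focal")
        elif rng.random() < tc.singleton_target:
            c = 1
            names.append(f"ins{j:04d}")
        else:
            c = int(min(2 + rng.geometric(0.35) - 1, n))
            names.append(f"ins{j:04d}")
        mat[rng.choice(n, size=c, replace=False), j] = 1
    return pd.DataFrame(mat, index=[f"L{i:03d}" for i in range(n)],
                        columns=names)


def simulate_species_counts(n_species: int = 55, rate: float = 2e-4,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-species TE counts and Poisson capture counts at the given rate
    (events per TE copy), for regression-recovery checks."""
    rng = stage_rng(seed, "species")
    x = np.round(10 ** rng.uniform(3.5, 5.2, size=n_species)).astype(int)
    y = rng.poisson(rate * x)
    return x, y


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_simulation(config: SimulationConfig, seed: int, outdir: str | Path):
    """Run the full generator and emit genome.fa, te.out, consensus.fa,
    genes.gff3, panel.vcf, presence.tsv and truth.tsv.  Returns the outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotations, genes, library, truths = plant_genome(config, seed)
    write_fasta(genome.values(), outdir / "genome.fa")
    write_fasta(library, outdir / "consensus.fa")
    write_rm_out(annotations, outdir / "te.out",
                 {c.name: c.length for c in library})
    write_gff3(genes, outdir / "genes.gff3")
    panel, carriers = simulate_variant_panel(config, seed)
    write_vcf(panel, outdir / "panel.vcf",
              {"chrP": config.panel.region_len})
    with open(outdir / "carriers.txt", "w") as fh:
        fh.write("\n".join(carriers) + "\n")
    presence = simulate_te_presence(config, seed)
    presence.to_csv(outdir / "presence.tsv", sep="\t")
    truth_table(truths).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir
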