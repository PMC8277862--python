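"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are normalized at this boundary to a single internal
convention: 0-based, half-open, on the forward strand.  Printed formats that
use 1-based inclusive coordinates (RepeatMasker ``.out``, GFF3, VCF) are
converted on read and re-converted on write; nothing downstream ever branches
on a dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """One chromosome or scaffold of an assembly."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class TEAnnotationRecord:
    """One repeat-annotation row, in internal coordinates.

    ``cons_start``/``cons_end`` are 1-based inclusive on the consensus
    forward strand with ``cons_start <= cons_end`` regardless of the genomic
    strand; the raw minus-strand coordinate triplet is kept in ``raw_cons``
    for provenance.
    """

    chrom: str
    start: int
    end: int
    strand: str
    consensus_name: str
    family: str = "Unknown"
    cons_start: int = 1
    cons_end: int = 1
    divergence_pct: float = 0.0
    linkage_id: int | None = None
    raw_cons: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty TE span {self.chrom}:{self.start}-{self.end}")
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError(f"divergence {self.divergence_pct} outside [0, 100]")
        if self.cons_start > self.cons_end:
            raise ValueError("cons_start > cons_end after normalization")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusTE:
    """A family-representative repeat sequence from the consensus library."""

    name: str
    seq: str
    superfamily: str = "Unknown"

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """One transcript: an ordered list of exon spans (internal convention)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons.sort()
        for (s1, e1), (s2, _e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}")

    @property
    def multiexonic(self) -> bool:
        return len(self.exons) >= 2

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_s1, e1), (s2, _e2)
                in zip(self.exons, self.exons[1:])]


@dataclass
class VariantPanel:
    """A haploid SNP panel: lines x sites with optional per-site metadata.

    ``genotypes`` is an int8 matrix of shape (n_sites, n_lines) with values
    0, 1 or -1 (missing).  ``is_synonymous`` and ``recomb_rate`` are optional
    per-site vectors used by the matched-resampling sweep test.
    """

    line_ids: list[str]
    chroms: np.ndarray          # object array of str, per site
    positions: np.ndarray       # int64, internal 0-based, per site
    genotypes: np.ndarray       # int8, (n_sites, n_lines)
    is_synonymous: np.ndarray | None = None   # bool per site
    recomb_rate: np.ndarray | None = None     # float per site, cM/Mb

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def site_mask(self, chrom: str) -> np.ndarray:
        return self.chroms == chrom


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID = set("ACGTN")


def _clean_seq(raw: str) -> str:
    s = raw.upper()
    if set(s) - _VALID:
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def read_genome_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a FASTA file into named uppercase sequences.

    Non-ACGTN characters are mapped to N; the record name is the first
    whitespace-delimited token of the header.  Duplicate names and empty
    files are format errors.
    """
    records: dict[str, GenomeSequence] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = GenomeSequence(name, _clean_seq("".join(chunks)))
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                name = header.split()[0]
                if name in records:
                    raise FormatError(
                        f"{path}: duplicate sequence name {name!r} at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}")
                chunks.append(line.strip())
    if name is not None:
        records[name] = GenomeSequence(name, _clean_seq("".join(chunks)))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[GenomeSequence | ConsensusTE],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_consensus_library(path: str | Path) -> dict[str, ConsensusTE]:
    """Read a consensus TE library FASTA; header may carry ``name#superfamily``."""
    out: dict[str, ConsensusTE] = {}
    for name, rec in read_genome_fasta(path).items():
        if "#" in name:
            base, sf = name.split("#", 1)
        else:
            base, sf = name, "Unknown"
        out[base] = ConsensusTE(base, rec.seq, superfamily=sf)
    return out


# ---------------------------------------------------------------------------
# RepeatMasker .out / BED repeat annotations
# ---------------------------------------------------------------------------

def read_repeatmasker_annotations(path: str | Path,
                                  dialect: str = "rm_out") -> list[TEAnnotationRecord]:
    """Read TE annotations from RepeatMasker ``.out`` or BED6+.

    ``.out`` genomic coordinates are 1-based inclusive and converted to the
    internal convention; minus-strand rows (marked ``C``) list consensus
    coordinates in the order (left), end, begin and are normalized so that
    ``cons_start <= cons_end`` on the consensus forward strand.
    """
    if dialect == "rm_out":
        return _read_rm_out(path)
    if dialect == "bed":
        return _read_te_bed(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _strip_paren(tok: str) -> int:
    return int(tok.strip("()"))


def _read_rm_out(path: str | Path) -> list[TEAnnotationRecord]:
    records: list[TEAnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3:          # two header lines + one blank
                continue
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) < 14:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 14 columns, got {len(toks)}")
            try:
                div = float(toks[1])
                chrom = toks[4]
                gstart = int(toks[5])
                gend = int(toks[6])
                strand_tok = toks[8]
                name = toks[9]
                family = toks[10]
                c1, c2, c3 = toks[11], toks[12], toks[13]
                linkage = int(toks[14]) if len(toks) > 14 and toks[14].isdigit() else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if strand_tok == "C":
                strand = "-"
                # order on minus strand: (left) end begin
                cons_end = int(c2)
                cons_start = int(c3)
                raw = (_strip_paren(c1), int(c2), int(c3))
            else:
                strand = "+"
                cons_start = int(c1)
                cons_end = int(c2)
                raw = (int(c1), int(c2), _strip_paren(c3))
            records.append(TEAnnotationRecord(
                chrom=chrom, start=gstart - 1, end=gend, strand=strand,
                consensus_name=name, family=family,
                cons_start=cons_start, cons_end=cons_end,
                divergence_pct=div, linkage_id=linkage, raw_cons=raw))
    return records


def _read_te_bed(path: str | Path) -> list[TEAnnotationRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            records.append(TEAnnotationRecord(
                chrom=toks[0], start=int(toks[1]), end=int(toks[2]),
                strand=toks[5], consensus_name=toks[3]))
    return records


def write_rm_out(records: Sequence[TEAnnotationRecord], path: str | Path,
                 consensus_lengths: dict[str, int] | None = None) -> None:
    """Emit annotations in the RepeatMasker ``.out`` dialect (3 header lines)."""
    consensus_lengths = consensus_lengths or {}
    with open(path, "w") as fh:
        fh.write("   SW   perc perc perc  query      position in query"
                 "           matching repeat       position in repeat\n")
        fh.write("score   div. del. ins.  sequence   begin end    (left)"
                 "   repeat  class/family   begin  end (left)  ID\n")
        fh.write("\n")
        for i, r in enumerate(records, 1):
            L = consensus_lengths.get(r.consensus_name, r.cons_end)
            left = L - r.cons_end
            if r.strand == "+":
                cons_cols = f"{r.cons_start} {r.cons_end} ({left})"
                strand_tok = "+"
            else:
                cons_cols = f"({left}) {r.cons_end} {r.cons_start}"
                strand_tok = "C"
            linkage = r.linkage_id if r.linkage_id is not None else i
            fh.write(
                f"{1000} {r.divergence_pct:.1f} 0.0 0.0 {r.chrom} "
                f"{r.start + 1} {r.end} (0) {strand_tok} {r.consensus_name} "
                f"{r.family} {cons_cols} {linkage}\n")


# ---------------------------------------------------------------------------
# gene models (GFF3 / BED12)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def _gff3_attrs(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: str | Path) -> list[GeneModel]:
    tx: dict[str, GeneModel] = {}
    tx_gene: dict[str, str] = {}
    exon_rows: list[tuple[int, str, int, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = toks
            a = _gff3_attrs(attrs)
            if ftype in ("mRNA", "transcript"):
                tid = a.get("ID", f"tx{lineno}")
                tx_gene[tid] = a.get("Parent", a.get("gene_id", tid))
            elif ftype == "exon":
                parent = a.get("Parent")
                if parent is None:
                    raise FormatError(
                        f"{path}:{lineno}: exon without Parent transcript")
                exon_rows.append(
                    (lineno, chrom, int(start) - 1, int(end), strand, parent))
    for lineno, chrom, s, e, strand, parent in exon_rows:
        for tid in parent.split(","):
            if tid not in tx_gene:
                raise FormatError(
                    f"{path}:{lineno}: exon Parent {tid!r} has no transcript record")
            model = tx.setdefault(tid, GeneModel(tx_gene[tid], tid, chrom, strand, []))
            model.exons.append((s, e))
    out = []
    for model in tx.values():
        out.append(GeneModel(model.gene_id, model.transcript_id,
                             model.chrom, model.strand, sorted(model.exons)))
    return out


def _read_bed12(path: str | Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start = toks[0], int(toks[1])
            name, strand = toks[3], toks[5]
            n_blocks = int(toks[9])
            sizes = [int(x) for x in toks[10].rstrip(",").split(",")]
            starts = [int(x) for x in toks[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            out.append(GeneModel(name, name, chrom, strand, exons))
    return out


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(f"{m.chrom}\tpacktir\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t."
                     f"\tID={m.gene_id}\n")
            fh.write(f"{m.chrom}\tpacktir\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t."
                     f"\tID={m.transcript_id};Parent={m.gene_id}\n")
            for es, ee in m.exons:
                fh.write(f"{m.chrom}\tpacktir\texon\t{es + 1}\t{ee}\t.\t{m.strand}"
                         f"\t.\tParent={m.transcript_id}\n")


# ---------------------------------------------------------------------------
# variant panels (VCF subset / TSV)
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path, dialect: str = "vcf") -> VariantPanel:
    """Read a haploid SNP panel.

    Genotypes map to {0, 1, -1}; heterozygous diploid calls become missing
    (the panels this models are inbred lines, where residual heterozygosity
    marks unreliable regions).  Multiallelic sites are skipped with a
    counted warning.  Optional INFO/extra columns SYN (0/1) and RR
    (recombination rate) populate the matching metadata.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_panel_tsv(path)
    raise ValueError(f"unknown panel dialect {dialect!r}")


def _read_vcf(path: str | Path) -> VariantPanel:
    import pysam

    vf = pysam.VariantFile(str(path))
    line_ids = list(vf.header.samples)
    chroms, positions, rows, syn, rr = [], [], [], [], []
    n_multi = 0
    has_syn = "SYN" in vf.header.info
    has_rr = "RR" in vf.header.info
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        row = np.full(len(line_ids), -1, dtype=np.int8)
        for j, sample in enumerate(line_ids):
            gt = rec.samples[sample].get("GT")
            if gt is None:
                continue
            alleles = [a for a in gt if a is not None]
            if not alleles:
                continue
            if len(set(alleles)) > 1:    # heterozygous -> missing
                continue
            row[j] = alleles[0]
        chroms.append(rec.chrom)
        positions.append(rec.pos - 1)
        rows.append(row)
        if has_syn:
            syn.append(bool(rec.info.get("SYN", 0)))
        if has_rr:
            rr.append(float(rec.info.get("RR", np.nan)))
    vf.close()
    if n_multi:
        logger.warning("%s: skipped %d multiallelic sites", path, n_multi)
    return _assemble_panel(line_ids, chroms, positions, rows,
                           syn if has_syn else None, rr if has_rr else None)


def _read_panel_tsv(path: str | Path) -> VariantPanel:
    df = pd.read_csv(path, sep="\t", comment=None)
    meta = {"chrom", "pos", "SYN", "RR"}
    line_ids = [c for c in df.columns if c not in meta]
    chroms = list(df["chrom"].astype(str))
    positions = list(df["pos"].astype(int))
    rows = []
    for _, r in df[line_ids].iterrows():
        row = np.array([-1 if (pd.isna(v) or v == ".") else int(v) for v in r],
                       dtype=np.int8)
        rows.append(row)
    syn = [bool(v) for v in df["SYN"]] if "SYN" in df.columns else None
    rr = [float(v) for v in df["RR"]] if "RR" in df.columns else None
    return _assemble_panel(line_ids, chroms, positions, rows, syn, rr)


def _assemble_panel(line_ids, chroms, positions, rows, syn, rr) -> VariantPanel:
    if not rows:
        return VariantPanel(line_ids, np.array([], dtype=object),
                            np.array([], dtype=np.int64),
                            np.zeros((0, len(line_ids)), dtype=np.int8))
    chroms = np.array(chroms, dtype=object)
    positions = np.array(positions, dtype=np.int64)
    geno = np.vstack(rows)
    order = np.lexsort((positions, chroms.astype(str)))
    if not np.array_equal(order, np.arange(len(order))):
        logger.warning("panel positions unsorted; sorting")
    chroms, positions, geno = chroms[order], positions[order], geno[order]
    syn_arr = np.array(syn, dtype=bool)[order] if syn is not None else None
    rr_arr = np.array(rr, dtype=float)[order] if rr is not None else None
    return VariantPanel(line_ids, chroms, positions, geno, syn_arr, rr_arr)


def write_vcf(panel: VariantPanel, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a panel as a minimal VCF v4.2 with homozygous diploid GTs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in sorted(set(panel.chroms.tolist())):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##INFO=<ID=SYN,Number=1,Type=Integer,'
                 'Description="Synonymous site flag">\n')
        fh.write('##INFO=<ID=RR,Number=1,Type=Float,'
                 'Description="Recombination rate (cM/Mb)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.line_ids) + "\n")
        for i in range(panel.n_sites):
            info = []
            if panel.is_synonymous is not None:
                info.append(f"SYN={int(panel.is_synonymous[i])}")
            if panel.recomb_rate is not None:
                info.append(f"RR={panel.recomb_rate[i]:g}")
            info_s = ";".join(info) if info else "."
            gts = "\t".join(
                "./." if g < 0 else f"{g}/{g}" for g in panel.genotypes[i])
            fh.write(f"{panel.chroms[i]}\t{panel.positions[i] + 1}\t.\tA\tT\t.\t"
                     f"PASS\t{info_s}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, version: str, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# packtir {version} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_report_tables(results: dict[str, pd.DataFrame], outdir: str | Path,
                        version: str = "0.1.0", seed=None) -> list[str]:
    """Write the pipeline's result tables and return the file manifest.

    ``results`` maps a table name (``packtirs``, ``families``, ``breakpoints``,
    ``stats`` ...) to a DataFrame; ``packtirs`` additionally produces a BED
    file of the internal-segment spans.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name, df in results.items():
        path = outdir / f"{name}.tsv"
        _write_tsv(df, path, version, seed)
        manifest.append(path.name)
        if name == "packtirs":
            bed = outdir / "packtirs.bed"
            with open(bed, "w") as fh:
                for _, row in df.iterrows():
                    if {"chrom", "internal_start", "internal_end", "id"} <= set(df.columns):
                        fh.write(f"{row['chrom']}\t{row['internal_start']}\t"
                                 f"{row['internal_end']}\t{row['id']}\n")
            manifest.append(bed.name)
    return manifest
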