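"""Sequence and annotation IO plus strand-aware promoter coordinate arithmetic.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed) and
BED (0-based half-open) are converted at the boundary.  Promoter sequences
are handed out 5'-to-3' with respect to the gene, so that an offset ``o`` in
the extracted sequence maps to the TSS-relative position ``o - upstream_bp``
on both strands (upstream negative, the field's usual convention).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import reverse_complement


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene's coordinate anchor: TSS, exons in transcription order, ortholog.

    ``tss`` is the 5'-most transcribed position (0-based); for multi-isoform
    genes the 5'-most TSS across isoforms is used.  ``second_exon`` is the
    second exon of the representative (5'-most) isoform, when it has one.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[GenomicInterval] = field(default_factory=list)
    second_exon: GenomicInterval | None = None
    ortholog_id: str | None = None

    @property
    def length_bp(self) -> int:
        """Transcript length: summed exon lengths."""
        return sum(len(e) for e in self.exons)


class FastaStore:
    """In-memory indexed sequence store with strand-aware interval lookup."""

    def __init__(self, sequences: dict[str, str] | None = None):
        self._seqs: dict[str, str] = {}
        for name, seq in (sequences or {}).items():
            self.add(name, seq)

    @classmethod
    def from_file(cls, path) -> "FastaStore":
        store = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            store.add(rec.id, str(rec.seq))
        return store

    def add(self, name: str, seq: str) -> None:
        self._seqs[name] = seq.upper()

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def length(self, chrom: str) -> int:
        if chrom not in self._seqs:
            raise KeyError(f"no record named {chrom!r}")
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Uppercase sequence of a half-open interval; '-' returns the
        reverse complement."""
        if chrom not in self._seqs:
            raise KeyError(f"no record named {chrom!r}")
        n = len(self._seqs[chrom])
        if start < 0 or end > n or start >= end:
            raise ValueError(
                f"interval [{start}, {end}) outside record {chrom!r} (length {n})"
            )
        seq = self._seqs[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end, iv.strand)

    def write(self, path, wrap: int = 60) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self._seqs.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
            writer.write_file(records)


def write_fasta(store: FastaStore, path, wrap: int = 60) -> None:
    store.write(path, wrap=wrap)


def read_fasta(path) -> FastaStore:
    return FastaStore.from_file(path)


def _validate_gff3_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 feature ({len(cols)} columns)"
                )
            if cols[6] not in "+-":
                raise ValueError(
                    f"{path}:{lineno}: missing or invalid strand {cols[6]!r}"
                )
            if not (cols[3].isdigit() and cols[4].isdigit()):
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates")


def _read_gff3(path) -> list[GeneModel]:
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        strand = g.strand
        transcripts = list(db.children(g, featuretype=("mRNA", "transcript")))
        if transcripts:
            # representative isoform = the 5'-most TSS
            def t_tss(t):
                return t.start - 1 if strand == "+" else t.end - 1

            rep = min(transcripts, key=t_tss) if strand == "+" else max(
                transcripts, key=t_tss
            )
            tss = t_tss(rep)
            exon_feats = list(db.children(rep, featuretype="exon"))
        else:
            tss = g.start - 1 if strand == "+" else g.end - 1
            exon_feats = list(db.children(g, featuretype="exon"))
        exons = [
            GenomicInterval(g.seqid, e.start - 1, e.end, strand) for e in exon_feats
        ]
        exons.sort(key=lambda iv: iv.start, reverse=(strand == "-"))
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=strand,
                tss=tss,
                exons=exons,
                second_exon=exons[1] if len(exons) > 1 else None,
            )
        )
    return genes


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def _read_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected BED12 (got {df.shape[1]} columns)")
    df.columns = _BED12_COLS[: df.shape[1]]
    genes = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if row.strand not in "+-":
            raise ValueError(f"{path}:{lineno}: missing or invalid strand")
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        exons = [
            GenomicInterval(row.chrom, row.start + s, row.start + s + z, row.strand)
            for s, z in zip(starts, sizes)
        ]
        exons.sort(key=lambda iv: iv.start, reverse=(row.strand == "-"))
        tss = row.start if row.strand == "+" else row.end - 1
        genes.append(
            GeneModel(
                gene_id=str(row.name),
                chrom=row.chrom,
                strand=row.strand,
                tss=tss,
                exons=exons,
                second_exon=exons[1] if len(exons) > 1 else None,
            )
        )
    return genes


def read_annotation(path) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12, dispatched on file extension."""
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return _read_gff3(p)
    if p.endswith(".bed"):
        return _read_bed12(p)
    raise ValueError(f"unrecognized annotation format: {p}")


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter interval plus how much of the requested span survived clipping."""

    interval: GenomicInterval
    upstream_bp: int   # effective upstream span after clipping
    downstream_bp: int  # effective downstream span after clipping
    clipped: bool


def promoter_window(
    gene: GeneModel,
    upstream_bp: int,
    downstream_bp: int,
    chrom_length: int | None = None,
) -> PromoterWindow:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    Covers TSS-relative positions [-upstream_bp, +downstream_bp), with
    position 0 the TSS itself.  On the + strand this is the genomic interval
    [tss - up, tss + down); on the - strand [tss - down + 1, tss + up + 1).
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window spans must be non-negative")
    if upstream_bp == 0 and downstream_bp == 0:
        raise ValueError("empty promoter window")
    if gene.strand == "+":
        start, end = gene.tss - upstream_bp, gene.tss + downstream_bp
    else:
        start, end = gene.tss - downstream_bp + 1, gene.tss + upstream_bp + 1
    lo, hi = max(0, start), end if chrom_length is None else min(end, chrom_length)
    if lo >= hi:
        raise ValueError(
            f"promoter window of {gene.gene_id} entirely off chromosome {gene.chrom}"
        )
    clipped = (lo != start) or (hi != end)
    if gene.strand == "+":
        up_eff = gene.tss - lo
        down_eff = hi - gene.tss
    else:
        up_eff = hi - 1 - gene.tss
        down_eff = gene.tss - lo + 1
    return PromoterWindow(
        GenomicInterval(gene.chrom, lo, hi, gene.strand), up_eff, down_eff, clipped
    )


def extract_promoter(
    store: FastaStore,
    gene: GeneModel,
    upstream_bp: int,
    downstream_bp: int,
) -> tuple[str, PromoterWindow]:
    """Promoter sequence in gene orientation (5'->3') plus its window.

    Offset ``o`` of the returned sequence is TSS-relative position
    ``o - window.upstream_bp``.
    """
    win = promoter_window(
        gene, upstream_bp, downstream_bp, chrom_length=store.length(gene.chrom)
    )
    return store.fetch_interval(win.interval), win


def tss_relative(offset: int, window: PromoterWindow) -> int:
    """TSS-relative coordinate of a promoter-sequence offset (upstream < 0)."""
    return offset - window.upstream_bp


def write_bed6(rows, path) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
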