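"""Genome and annotation handling: sequence classes and background tiles.

Reads a genome (FASTA) and a gene annotation (GFF3), selects one
representative isoform per gene, and extracts the strand-oriented sequence
classes that the methylation scan scores — concatenated CDS, exons, introns,
pooled UTRs, and the full gene body — plus fixed-length genomic background
fragments used as the permutation null.

Internally all intervals are 0-based half-open; GFF3 and BED I/O convert at
the boundary (GFF3 is 1-based inclusive, BED is 0-based half-open).
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: uppercase sequence over the {A,C,G,T,N} alphabet."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One gene reduced to its representative (longest) isoform.

    All intervals are 0-based half-open genomic coordinates, sorted and
    pairwise disjoint; ``cds`` lies within the union of ``exons``.
    """

    gene_id: str
    contig_id: str
    strand: str
    transcript_span: Interval
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    isoform_id: str = ""

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def validate(self) -> None:
        lo, hi = self.transcript_span
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = getattr(self, name)
            for s, e in ivs:
                if not (lo <= s < e <= hi):
                    raise ValueError(
                        f"{self.gene_id}: {name} interval [{s},{e}) outside "
                        f"transcript span [{lo},{hi})"
                    )
        for i in range(len(self.exons) - 1):
            if self.exons[i][1] > self.exons[i + 1][0]:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        exon_points = {
            p for s, e in self.exons for p in range(s, e)
        } if sum(e - s for s, e in self.exons) < 1_000_000 else None
        if exon_points is not None:
            for s, e in self.cds:
                if not set(range(s, e)) <= exon_points:
                    raise ValueError(f"{self.gene_id}: CDS outside exons")


@dataclass(frozen=True)
class FeatureSequence:
    """Strand-oriented sequence of one feature class of one gene."""

    gene_id: str
    feature_class: str  # CDS | exon | intron | UTR | gene_body
    sequence: str


@dataclass(frozen=True)
class BackgroundFragment:
    contig_id: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers


def read_genome(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a FASTA genome; uppercase, map ambiguity codes other than N to N.

    Raises ValueError for an empty file or a file whose first record line is
    not a FASTA header, naming the offending line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header '>'"
                    )
                break
        else:
            raise ValueError(f"{path}: line 1: empty FASTA file")

    records: list[GenomeSequence] = []
    n_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            n_ambiguous += sum(seq.count(ch) for ch in bad)
            seq = seq.translate(str.maketrans({ch: "N" for ch in bad}))
        records.append(GenomeSequence(contig_id=rec.id, sequence=seq))
    if n_ambiguous:
        logger.warning("mapped %d IUPAC ambiguity bases to N", n_ambiguous)
    if not records:
        raise ValueError(f"{path}: line 1: no FASTA records found")
    return records


def _summed_length(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def read_annotation(
    path: str | os.PathLike, genome: Sequence[GenomeSequence]
) -> list[GeneModel]:
    """Read GFF3 gene models, one per gene via its longest mRNA.

    The longest isoform is chosen by summed exon length, ties broken
    lexicographically by mRNA ID. Genes on contigs absent from the genome are
    rejected with a single error listing the offending gene IDs.
    """
    contigs = {g.contig_id for g in genome}
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    missing_contig: list[str] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if not mrnas:
            logger.warning("gene %s has no mRNA children; skipped", gene.id)
            continue
        if gene.seqid not in contigs:
            missing_contig.append(gene.id)
            continue

        def exon_ivs(m) -> list[Interval]:
            return sorted(
                (f.start - 1, f.end) for f in db.children(m, featuretype="exon")
            )

        best = min(mrnas, key=lambda m: (-_summed_length(exon_ivs(m)), m.id))
        exons = exon_ivs(best)
        cds = sorted((f.start - 1, f.end) for f in db.children(best, featuretype="CDS"))
        utr5 = sorted(
            (f.start - 1, f.end)
            for f in db.children(best, featuretype="five_prime_UTR")
        )
        utr3 = sorted(
            (f.start - 1, f.end)
            for f in db.children(best, featuretype="three_prime_UTR")
        )
        model = GeneModel(
            gene_id=gene.id,
            contig_id=gene.seqid,
            strand=best.strand if best.strand in "+-" else gene.strand,
            transcript_span=(best.start - 1, best.end),
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
            isoform_id=best.id,
        )
        model.validate()
        genes.append(model)
    if missing_contig:
        raise ValueError(
            "genes on contigs absent from the genome: " + ", ".join(missing_contig)
        )
    return genes


# ---------------------------------------------------------------------------
# feature extraction


def _oriented(seq_parts: list[str], strand: str) -> str:
    joined = "".join(seq_parts)
    return joined if strand == "+" else reverse_complement(joined)


def extract_feature_sequences(
    genes: Iterable[GeneModel], genome: Sequence[GenomeSequence]
) -> list[FeatureSequence]:
    """Concatenated, strand-oriented CDS/exon/intron/UTR/gene-body sequences.

    Intervals are concatenated in genomic order and the whole string is
    reverse-complemented for minus-strand genes, which equals concatenation in
    transcript (5'->3') order of the per-interval reverse complements. Feature
    classes with no annotated intervals are absent from the output, not empty.
    """
    by_contig = {g.contig_id: g.sequence for g in genome}
    out: list[FeatureSequence] = []
    for gene in genes:
        contig = by_contig[gene.contig_id]

        def seq_of(ivs: list[Interval]) -> str:
            return _oriented([contig[s:e] for s, e in ivs], gene.strand)

        cds_seq = seq_of(gene.cds)
        if cds_seq and len(cds_seq) % 3 != 0:
            logger.warning(
                "gene %s: CDS length %d not a multiple of 3", gene.gene_id, len(cds_seq)
            )
        for feature_class, ivs in (
            ("CDS", gene.cds),
            ("exon", gene.exons),
            ("intron", gene.introns),
            ("UTR", gene.utr5 + gene.utr3),
            ("gene_body", [gene.transcript_span]),
        ):
            if not ivs:
                continue
            out.append(
                FeatureSequence(
                    gene_id=gene.gene_id,
                    feature_class=feature_class,
                    sequence=seq_of(sorted(ivs)),
                )
            )
    return out


def tile_background(
    genome: Sequence[GenomeSequence],
    fragment_size: int = 1000,
    max_n_fraction: float = 0.5,
    exclude: Iterable[tuple[str, int, int]] | None = None,
) -> list[BackgroundFragment]:
    """Non-overlapping fixed-length tiles from the start of each contig.

    The trailing partial tile is discarded, as are tiles whose N fraction
    exceeds ``max_n_fraction`` and (optionally) tiles overlapping any excluded
    region — by default genic regions are included in the background.
    """
    if fragment_size < 2:
        raise ValueError("fragment_size must be >= 2")
    excluded_by_contig: dict[str, list[Interval]] = {}
    for contig_id, s, e in exclude or ():
        excluded_by_contig.setdefault(contig_id, []).append((s, e))
    tiles: list[BackgroundFragment] = []
    n_dropped_n = 0
    n_dropped_excl = 0
    for g in genome:
        regions = excluded_by_contig.get(g.contig_id, [])
        for start in range(0, g.length - fragment_size + 1, fragment_size):
            end = start + fragment_size
            seq = g.sequence[start:end]
            if seq.count("N") / fragment_size > max_n_fraction:
                n_dropped_n += 1
                continue
            if any(s < end and start < e for s, e in regions):
                n_dropped_excl += 1
                continue
            tiles.append(BackgroundFragment(g.contig_id, start, end, seq))
    if n_dropped_n:
        logger.info("dropped %d N-heavy background tiles", n_dropped_n)
    if n_dropped_excl:
        logger.info("dropped %d tiles overlapping excluded regions", n_dropped_excl)
    return tiles


# ---------------------------------------------------------------------------
# writers


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_bed(
    fragments: Iterable[BackgroundFragment], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f"{frag.contig_id}\t{frag.start}\t{frag.end}\n")


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models back to GFF3 (1-based inclusive coordinates)."""

    def row(seqid, ftype, s, e, strand, attrs):
        return f"{seqid}\tmethylscan\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s0, e0 = g.transcript_span
            mrna_id = g.isoform_id or f"{g.gene_id}.t1"
            fh.write(row(g.contig_id, "gene", s0, e0, g.strand, f"ID={g.gene_id}"))
            fh.write(
                row(
                    g.contig_id,
                    "mRNA",
                    s0,
                    e0,
                    g.strand,
                    f"ID={mrna_id};Parent={g.gene_id}",
                )
            )
            for ftype, ivs in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in ivs:
                    fh.write(row(g.contig_id, ftype, s, e, g.strand, f"Parent={mrna_id}"))
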