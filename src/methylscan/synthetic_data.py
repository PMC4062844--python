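"""Synthetic genomes, families, divergent pairs, and variant tables with truth.

Every generator is a pure function of (config, seed) built on a single
``numpy.random.default_rng`` stream, so identical inputs give byte-identical
output files. Each simulation also emits the ground truth needed to score
downstream recovery — which genes were "methylated", the planted family
partition, every injected substitution and its class, and the planted
private/shared variant sites.

The genome generator emulates the statistical structure the methylation scan
assumes: an i.i.d. background at a configurable G+C content with embedded
multi-exon protein-coding genes (intact ORFs), a known subset of which is
subjected to CpG -> TpG deamination at a per-site rate delta. It does not
attempt splice motifs, repeats, codon-usage bias, or isochore structure.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genetic_code import STOP_CODONS, synonymous_alternatives
from .genome_features import GeneModel, GenomeSequence, reverse_complement

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults are the desk-scale recovery conditions: a 5-Mb genome with 200
    genes, half of them methylated, deaminated at delta = 0.5. Gene geometry
    (300-700 codons, 3-6 exons, 80-500 bp introns, 50-300 bp UTRs, >= 200 bp
    intergenic spacing) is insect-typical.
    """

    genome_length: int = 5_000_000
    n_contigs: int = 1
    n_genes: int = 200
    background_gc: float = 0.40
    methylated_fraction: float = 0.5
    deamination_rate: float = 0.5
    cds_codons: tuple[int, int] = (300, 700)
    n_exons: tuple[int, int] = (3, 6)
    intron_length: tuple[int, int] = (80, 500)
    utr_length: tuple[int, int] = (50, 300)
    min_intergenic: int = 200

    def __post_init__(self) -> None:
        for name in ("background_gc", "methylated_fraction", "deamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class VariantSimConfig:
    contig: str = "sim1"
    contig_length: int = 1_000_000
    n_private_a: int = 100
    n_private_b: int = 80
    n_shared: int = 50
    fail_fraction: float = 0.0  # fraction of records given a filter-violating annotation
    sample_a: str = "indivA"
    sample_b: str = "indivB"


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside every simulation."""

    methylated_gene_ids: list[str] = field(default_factory=list)
    planted_families: list[list[str]] = field(default_factory=list)
    substitutions: list[dict] = field(default_factory=list)
    private_a_sites: list[int] = field(default_factory=list)
    private_b_sites: list[int] = field(default_factory=list)
    shared_sites: list[int] = field(default_factory=list)
    failing_sites: list[int] = field(default_factory=list)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome + annotation


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=probs)
    return "".join(np.array(list("ACGT"))[idx]) if n else ""


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n sense codons drawn base-wise at the background G+C content."""
    out: list[str] = []
    while len(out) < n:
        chunk = _random_bases(rng, 3 * (n - len(out)), gc)
        out.extend(
            c
            for i in range(0, len(chunk), 3)
            if (c := chunk[i : i + 3]) not in STOP_CODONS
        )
    return "".join(out[:n])


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Random composition of ``total`` into ``parts`` positive lengths."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def _map_transcript_interval(
    t_start: int, t_end: int, exon_chunks: list[tuple[int, int, int]]
) -> list[Interval]:
    """Map a transcript-coordinate interval to concat-frame genomic intervals.

    ``exon_chunks`` holds (transcript_start, transcript_end, concat_start)
    per exon.
    """
    out = []
    for ts, te, cs in exon_chunks:
        lo, hi = max(t_start, ts), min(t_end, te)
        if lo < hi:
            out.append((cs + lo - ts, cs + hi - ts))
    return out


def _mirror(ivs: list[Interval], length: int) -> list[Interval]:
    return sorted((length - e, length - s) for s, e in ivs)


@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    genomic_seq: str  # forward-strand sequence of the gene span
    exons: list[Interval]  # offsets within the span
    cds: list[Interval]
    utr5: list[Interval]
    utr3: list[Interval]


def _plan_gene(rng: np.random.Generator, gene_id: str, config: SimulationConfig) -> _GenePlan:
    n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
    u5 = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
    u3 = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    cds = "ATG" + _random_codons(rng, n_codons, config.background_gc) + stop
    transcript = (
        _random_bases(rng, u5, config.background_gc)
        + cds
        + _random_bases(rng, u3, config.background_gc)
    )
    t_len = len(transcript)
    k = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
    exon_lens = _split_lengths(rng, t_len, k)
    intron_lens = [
        int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        for _ in range(k - 1)
    ]
    pieces: list[str] = []
    exon_chunks: list[tuple[int, int, int]] = []  # (t_start, t_end, concat_start)
    t_pos = c_pos = 0
    for i, el in enumerate(exon_lens):
        pieces.append(transcript[t_pos : t_pos + el])
        exon_chunks.append((t_pos, t_pos + el, c_pos))
        t_pos += el
        c_pos += el
        if i < k - 1:
            pieces.append(_random_bases(rng, intron_lens[i], config.background_gc))
            c_pos += intron_lens[i]
    concat = "".join(pieces)
    exons = [(cs, cs + (te - ts)) for ts, te, cs in exon_chunks]
    cds_ivs = _map_transcript_interval(u5, u5 + len(cds), exon_chunks)
    utr5_ivs = _map_transcript_interval(0, u5, exon_chunks)
    utr3_ivs = _map_transcript_interval(u5 + len(cds), t_len, exon_chunks)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        g_len = len(concat)
        concat = reverse_complement(concat)
        exons = _mirror(exons, g_len)
        cds_ivs = _mirror(cds_ivs, g_len)
        utr5_ivs = _mirror(utr5_ivs, g_len)
        utr3_ivs = _mirror(utr3_ivs, g_len)
    return _GenePlan(
        gene_id=gene_id,
        strand=strand,
        genomic_seq=concat,
        exons=sorted(exons),
        cds=sorted(cds_ivs),
        utr5=sorted(utr5_ivs),
        utr3=sorted(utr3_ivs),
    )


def simulate_genome_annotation(
    config: SimulationConfig, seed: int
) -> tuple[list[GenomeSequence], list[GeneModel], SyntheticTruth]:
    """Random genome with embedded multi-exon genes and a methylated subset.

    Genes carry intact ORFs (ATG start, no internal stops, stop codon) and
    are placed non-overlapping with at least ``min_intergenic`` bp spacing,
    uniformly over feasible positions. The truth lists which genes are
    labeled methylated; deamination itself is a separate step.
    """
    rng = np.random.default_rng(seed)
    contig_len = config.genome_length // config.n_contigs
    genes_per_contig = [
        config.n_genes // config.n_contigs
        + (1 if c < config.n_genes % config.n_contigs else 0)
        for c in range(config.n_contigs)
    ]
    genomes: list[GenomeSequence] = []
    genes: list[GeneModel] = []
    gene_no = 0
    for c in range(config.n_contigs):
        contig_id = f"scaffold{c + 1}"
        plans = []
        for _ in range(genes_per_contig[c]):
            gene_no += 1
            plans.append(_plan_gene(rng, f"Lsim_{gene_no:05d}", config))
        total_gene_len = sum(len(p.genomic_seq) for p in plans)
        n = len(plans)
        slack = contig_len - total_gene_len - (n + 1) * config.min_intergenic
        if slack < 0:
            raise ValueError(
                f"infeasible geometry: genes need {total_gene_len} bp plus spacing "
                f"on a {contig_len} bp contig"
            )
        extra = (
            np.diff(
                np.concatenate(
                    [[0], np.sort(rng.integers(0, slack + 1, size=n)), [slack]]
                )
            )
            if n
            else np.array([slack])
        )
        background = _random_bases(rng, contig_len, config.background_gc)
        buf = bytearray(background.encode("ascii"))
        pos = 0
        for i, plan in enumerate(plans):
            pos += config.min_intergenic + int(extra[i])
            span = (pos, pos + len(plan.genomic_seq))
            buf[span[0] : span[1]] = plan.genomic_seq.encode("ascii")

            def shift(ivs: list[Interval]) -> list[Interval]:
                return [(s + span[0], e + span[0]) for s, e in ivs]

            model = GeneModel(
                gene_id=plan.gene_id,
                contig_id=contig_id,
                strand=plan.strand,
                transcript_span=span,
                exons=shift(plan.exons),
                cds=shift(plan.cds),
                utr5=shift(plan.utr5),
                utr3=shift(plan.utr3),
                isoform_id=f"{plan.gene_id}.t1",
            )
            genes.append(model)
            pos = span[1]
        genomes.append(GenomeSequence(contig_id=contig_id, sequence=buf.decode("ascii")))
    n_meth = round(config.methylated_fraction * config.n_genes)
    methylated = sorted(
        rng.choice([g.gene_id for g in genes], size=n_meth, replace=False)
    ) if n_meth else []
    truth = SyntheticTruth(methylated_gene_ids=list(methylated))
    return genomes, genes, truth


def apply_methylation_deamination(
    genomes: Sequence[GenomeSequence],
    genes: Sequence[GeneModel],
    methylated_gene_ids: Sequence[str],
    delta: float,
    seed: int,
    synonymous_only: bool = False,
) -> tuple[list[GenomeSequence], int]:
    """CpG -> TpG deamination inside methylated genes at per-site rate delta.

    Each CpG within a methylated gene's span has its C replaced by T
    independently with probability delta, on the forward strand (CpG is its
    own reverse complement, so forward-strand replacement depletes CpG
    symmetrically). With ``synonymous_only`` the edit is restricted to CDS
    CpGs whose C->T change (transcript sense) is synonymous. Returns the
    mutated genomes and the number of edits.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    buffers = {g.contig_id: bytearray(g.sequence.encode("ascii")) for g in genomes}
    methylated = set(methylated_gene_ids)
    n_edits = 0
    for gene in genes:
        if gene.gene_id not in methylated:
            continue
        buf = buffers[gene.contig_id]
        if synonymous_only:
            n_edits += _deaminate_synonymous(rng, buf, gene, delta)
            continue
        s, e = gene.transcript_span
        region = buf[s:e].decode("ascii")
        positions = [i for i in range(len(region) - 1) if region[i : i + 2] == "CG"]
        if not positions:
            continue
        hits = rng.random(len(positions)) < delta
        for p, hit in zip(positions, hits):
            if hit:
                buf[s + p] = ord("T")
                n_edits += 1
    out = [
        GenomeSequence(g.contig_id, buffers[g.contig_id].decode("ascii")) for g in genomes
    ]
    return out, n_edits


def _cds_position_map(gene: GeneModel) -> list[int]:
    """Genomic positions of CDS bases in transcript (5'->3') order."""
    positions = [p for s, e in gene.cds for p in range(s, e)]
    return positions if gene.strand == "+" else positions[::-1]


def _deaminate_synonymous(
    rng: np.random.Generator, buf: bytearray, gene: GeneModel, delta: float
) -> int:
    from .genetic_code import CODON_TO_AA

    gpos = _cds_position_map(gene)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n_edits = 0
    cds = [
        chr(buf[p]) if gene.strand == "+" else comp[chr(buf[p])] for p in gpos
    ]
    for j in range(len(cds) - 1):
        if cds[j] == "C" and cds[j + 1] == "G":
            codon_i, offset = divmod(j, 3)
            codon = "".join(cds[3 * codon_i : 3 * codon_i + 3])
            mutated = codon[:offset] + "T" + codon[offset + 1 :]
            if CODON_TO_AA.get(mutated) != CODON_TO_AA.get(codon) or codon not in CODON_TO_AA:
                continue
            if rng.random() < delta:
                cds[j] = "T"
                buf[gpos[j]] = ord("T" if gene.strand == "+" else comp["T"])
                n_edits += 1
    return n_edits


# ---------------------------------------------------------------------------
# divergent coding pairs


@dataclass
class DivergentPair:
    gene_id: str
    seq_a: str
    seq_b: str
    truth: SyntheticTruth


def simulate_divergent_pair(
    cds: str,
    syn_rate: float = 0.06,
    nonsyn_rate: float = 0.02,
    seed: int = 0,
    gene_id: str = "",
) -> DivergentPair:
    """Diverged copy of a CDS with per-site substitution rates by class.

    Rejection sampling: each site independently proposes one of its three
    alternative bases uniformly; the proposal is classified against the code
    table and accepted with probability ``syn_rate`` if synonymous or
    ``nonsyn_rate`` if nonsynonymous (proposals creating stop codons are
    always rejected). The per-site rate of realized changes in each class is
    therefore the class rate times the site's fractional opportunity for that
    class. The truth records every substitution with its class.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    for rate in (syn_rate, nonsyn_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    subs: list[dict] = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS or len(set(codon) - set("ACGT")) > 0:
            out.append(codon)
            continue
        cur = codon
        for pos in range(3):
            alts = [b for b in "ACGT" if b != cur[pos]]
            proposal = alts[int(rng.integers(3))]
            u = rng.random()
            nxt = cur[:pos] + proposal + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                continue
            syn = synonymous_alternatives(cur, pos)
            klass = "synonymous" if nxt in syn else "nonsynonymous"
            accept_rate = syn_rate if klass == "synonymous" else nonsyn_rate
            if u >= accept_rate:
                continue
            subs.append(
                {
                    "position": i + pos,
                    "class": klass,
                    "from": cur[pos],
                    "to": proposal,
                }
            )
            cur = nxt
        out.append(cur)
    truth = SyntheticTruth(substitutions=subs)
    return DivergentPair(gene_id=gene_id, seq_a=cds, seq_b="".join(out), truth=truth)


# ---------------------------------------------------------------------------
# planted-family hit tables


@dataclass
class HitTableSim:
    hits: list  # AlignmentHit
    self_scores: dict[str, float]
    truth: SyntheticTruth


def simulate_hit_table(
    family_sizes: Sequence[int],
    seed: int = 0,
    within_h: tuple[float, float] = (60.0, 90.0),
    between_h: tuple[float, float] = (0.0, 5.0),
    self_score: float = 1000.0,
    n_species: int = 1,
) -> HitTableSim:
    """Alignment hits realizing a planted family partition.

    Within-family pairs get H-scores in ``within_h`` and aligned fractions
    above 1/3; one hit between each pair of families gets an H-score in
    ``between_h`` and fractions below 1/3. The ranges must be disjoint. With
    ``n_species`` > 1, genes carry a species prefix ``s<k>_`` assigned
    round-robin within each family.
    """
    from .gene_family_clustering import AlignmentHit

    if between_h[1] >= within_h[0]:
        raise ValueError("within/between H-score ranges must be disjoint")
    rng = np.random.default_rng(seed)
    families: list[list[str]] = []
    gene_no = 0
    for f, size in enumerate(family_sizes):
        fam = []
        for j in range(size):
            prefix = f"s{j % n_species}_" if n_species > 1 else ""
            fam.append(f"{prefix}fam{f:03d}_g{gene_no:04d}")
            gene_no += 1
        families.append(fam)
    self_scores = {g: float(self_score) for fam in families for g in fam}
    hits: list[AlignmentHit] = []
    for fam in families:
        for a_i in range(len(fam)):
            for b_i in range(a_i + 1, len(fam)):
                h = rng.uniform(*within_h)
                hits.append(
                    AlignmentHit(
                        query_id=fam[a_i],
                        target_id=fam[b_i],
                        raw_score=h / 100.0 * self_score,
                        frac_query=float(rng.uniform(0.40, 0.95)),
                        frac_target=float(rng.uniform(0.40, 0.95)),
                    )
                )
    for f_i in range(len(families)):
        for f_j in range(f_i + 1, len(families)):
            a = families[f_i][int(rng.integers(len(families[f_i])))]
            b = families[f_j][int(rng.integers(len(families[f_j])))]
            h = rng.uniform(*between_h)
            hits.append(
                AlignmentHit(
                    query_id=a,
                    target_id=b,
                    raw_score=h / 100.0 * self_score,
                    frac_query=float(rng.uniform(0.05, 0.30)),
                    frac_target=float(rng.uniform(0.05, 0.30)),
                )
            )
    truth = SyntheticTruth(planted_families=[sorted(f) for f in families])
    return HitTableSim(hits=hits, self_scores=self_scores, truth=truth)


def write_hits_tsv(sim: HitTableSim, hits_path, self_path) -> None:
    with open(hits_path, "w") as fh:
        for h in sim.hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.raw_score:.4f}"
                f"\t{h.frac_query:.4f}\t{h.frac_target:.4f}\n"
            )
    with open(self_path, "w") as fh:
        for gene, score in sorted(sim.self_scores.items()):
            fh.write(f"{gene}\t{score:.4f}\n")


# ---------------------------------------------------------------------------
# two-sample variant tables


_FAIL_VALUES = {
    "QD": 1.0,
    "FS": 80.0,
    "MQ": 30.0,
    "HaplotypeScore": 20.0,
    "MappingQualityRankSum": -20.0,
    "ReadPosRankSum": -10.0,
}


@dataclass
class VariantSim:
    records: list  # VariantRecord
    samples: tuple[str, str]
    truth: SyntheticTruth


def simulate_variant_calls(spec: VariantSimConfig, seed: int = 0) -> VariantSim:
    """Two-sample SNP table with planted private and shared sites.

    ``fail_fraction`` of the records are given one annotation value that
    violates a hard-filter threshold, cycling through the six criteria; the
    truth lists their positions.
    """
    from .divergence_popgen import VariantRecord

    for n in (spec.n_private_a, spec.n_private_b, spec.n_shared):
        if n < 0:
            raise ValueError("variant counts must be nonnegative")
    total = spec.n_private_a + spec.n_private_b + spec.n_shared
    if total > spec.contig_length:
        raise ValueError("more variants than contig positions")
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(np.arange(1, spec.contig_length + 1), size=total, replace=False)
    )
    categories = np.array(
        ["A"] * spec.n_private_a + ["B"] * spec.n_private_b + ["S"] * spec.n_shared
    )
    rng.shuffle(categories)
    n_fail = round(spec.fail_fraction * total)
    fail_idx = set(rng.choice(total, size=n_fail, replace=False)) if n_fail else set()
    bases = "ACGT"
    records = []
    truth = SyntheticTruth()
    fail_keys = list(_FAIL_VALUES)
    fail_no = 0
    for i, (pos, cat) in enumerate(zip(positions, categories)):
        ref = bases[int(rng.integers(4))]
        alt = bases[([b for b in range(4) if bases[b] != ref])[int(rng.integers(3))]]
        if cat == "A":
            gts = {spec.sample_a: (0, 1), spec.sample_b: (0, 0)}
            truth.private_a_sites.append(int(pos))
        elif cat == "B":
            gts = {spec.sample_a: (0, 0), spec.sample_b: (0, 1)}
            truth.private_b_sites.append(int(pos))
        else:
            gts = {spec.sample_a: (0, 1), spec.sample_b: (1, 1)}
            truth.shared_sites.append(int(pos))
        ann = {
            "QD": float(rng.uniform(10, 30)),
            "FS": float(rng.uniform(0, 10)),
            "MQ": float(rng.uniform(50, 60)),
            "HaplotypeScore": float(rng.uniform(0, 5)),
            "MappingQualityRankSum": float(rng.uniform(-2, 2)),
            "ReadPosRankSum": float(rng.uniform(-2, 2)),
        }
        if i in fail_idx:
            key = fail_keys[fail_no % len(fail_keys)]
            ann[key] = _FAIL_VALUES[key]
            fail_no += 1
            truth.failing_sites.append(int(pos))
        records.append(
            VariantRecord(
                contig=spec.contig,
                position=int(pos),
                ref=ref,
                alt=alt,
                genotypes=gts,
                qd=ann["QD"],
                fs=ann["FS"],
                mq=ann["MQ"],
                haplotype_score=ann["HaplotypeScore"],
                mq_rank_sum=ann["MappingQualityRankSum"],
                read_pos_rank_sum=ann["ReadPosRankSum"],
            )
        )
    return VariantSim(records=records, samples=(spec.sample_a, spec.sample_b), truth=truth)


def write_vcf(sim: VariantSim, path, contig_length: int | None = None) -> None:
    """Write the simulated records as an uncompressed VCF v4.2 file."""
    sample_a, sample_b = sim.samples
    contig = sim.records[0].contig if sim.records else "sim1"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_length:
            fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        else:
            fh.write(f"##contig=<ID={contig}>\n")
        for key, desc in (
            ("QD", "Quality by depth"),
            ("FS", "FisherStrand"),
            ("MQ", "RMS mapping quality"),
            ("HaplotypeScore", "Haplotype score"),
            ("MappingQualityRankSum", "MQ rank sum"),
            ("ReadPosRankSum", "Read position rank sum"),
        ):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_a}\t{sample_b}\n"
        )
        for rec in sim.records:
            info = (
                f"QD={rec.qd:.2f};FS={rec.fs:.2f};MQ={rec.mq:.2f};"
                f"HaplotypeScore={rec.haplotype_score:.2f};"
                f"MappingQualityRankSum={rec.mq_rank_sum:.2f};"
                f"ReadPosRankSum={rec.read_pos_rank_sum:.2f}"
            )
            gt_a = "/".join(str(a) for a in rec.genotypes[sample_a])
            gt_b = "/".join(str(a) for a in rec.genotypes[sample_b])
            fh.write(
                f"{rec.contig}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                f"{info}\tGT\t{gt_a}\t{gt_b}\n"
            )
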