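"""Four-fold-site diversity, NG86 Ka/Ks, window scans, and variant bookkeeping.

Per-site Watterson's theta is estimated from segregating sites at four-fold
degenerate positions (theta = S / (a_n * L) with a_n the harmonic number over
n-1). Pairwise Ka/Ks follows Nei & Gojobori (1986): per-codon expected
synonymous/nonsynonymous site fractions averaged over both sequences,
observed differences averaged over all minimal substitution pathways that
avoid stop codons, and proportions corrected with the Jukes-Cantor formula
d = -(3/4) ln(1 - 4p/3). Significance of omega != 1 per gene is a two-sided
Fisher exact test on the rounded site/difference table, FDR-adjusted across
genes. The module also applies the study's published VCF hard-filter
thresholds and counts SNPs private to each of two resequenced individuals.
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cpg_methylation import bh_fdr
from .genetic_code import CODON_TO_AA, FOURFOLD_CODONS, STOP_CODONS

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# four-fold degenerate sites & Watterson's theta


def fourfold_sites(cds: str) -> list[int]:
    """0-based positions in an in-frame CDS that are four-fold degenerate.

    A third codon position qualifies when all four third-position bases
    encode the same amino acid. Codons containing N or gaps are skipped.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    sites = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if not set(codon) <= _ACGT:
            continue
        if codon in FOURFOLD_CODONS:
            sites.append(i + 2)
    return sites


@dataclass(frozen=True)
class DiversityEstimate:
    S: int
    n: int
    L: int
    a_n: float
    theta_per_site: float


def watterson_theta(S: int, n: int, L: int) -> DiversityEstimate:
    """Watterson's per-site theta from S segregating sites among n sequences."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if L < 1:
        raise ValueError("need at least 1 surveyed site")
    if S < 0:
        raise ValueError("segregating-site count must be nonnegative")
    a_n = sum(1.0 / i for i in range(1, n))
    return DiversityEstimate(S=S, n=n, L=L, a_n=a_n, theta_per_site=S / (a_n * L))


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


@dataclass
class KaKsResult:
    gene_id: str
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ka: float
    ks: float
    omega: float | None
    n_codons: int
    saturated: bool = False
    p: float | None = None
    q: float | None = None


def _syn_site_fraction(codon: str) -> float:
    """Expected synonymous sites of one sense codon (0..3).

    Mutations to stop codons count as nonsynonymous, so synonymous plus
    nonsynonymous sites always sum to 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        n_syn = sum(
            1
            for b in "ACGT"
            if b != codon[pos]
            and CODON_TO_AA.get(codon[:pos] + b + codon[pos + 1 :]) == aa
        )
        s += n_syn / 3.0
    return s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged over all orderings of the differing positions; orderings passing
    through a stop codon are excluded (all orderings are used if every one
    passes through a stop).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            else:
                steps.append(CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:  # every ordering crosses a stop: fall back to counting anyway
        for order in permutations(diff_pos):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                steps.append(
                    cur not in STOP_CODONS
                    and nxt not in STOP_CODONS
                    and CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt)
                )
                cur = nxt
            paths.append(steps)
    syn = sum(sum(p) for p in paths) / len(paths)
    total = len(diff_pos)
    return syn, total - syn


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); NaN when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # normalize -0.0


def ng86_kaks(seq1: str, seq2: str, gene_id: str = "") -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for one codon-aligned sequence pair.

    Codons containing gaps, N, or a stop in either sequence are skipped.
    ``omega`` is None when Ks = 0; ``saturated`` flags an uncorrectable
    proportion (p >= 3/4).
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    if len(seq1) % 3 != 0:
        raise ValueError("alignment length must be a multiple of 3")
    syn_sites = nonsyn_sites = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (set(c1) <= _ACGT and set(c2) <= _ACGT):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            logger.warning("%s: stop codon at alignment position %d skipped", gene_id, i)
            continue
        n_codons += 1
        s = (_syn_site_fraction(c1) + _syn_site_fraction(c2)) / 2.0
        syn_sites += s
        nonsyn_sites += 3.0 - s
        sd, nd = _pathway_diffs(c1, c2)
        syn_diffs += sd
        nonsyn_diffs += nd
    ps = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = math.isnan(ks) or math.isnan(ka)
    omega: float | None
    if saturated or ks == 0.0:
        omega = None
    else:
        omega = ka / ks
    return KaKsResult(
        gene_id=gene_id,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_diffs,
        nonsyn_diffs=nonsyn_diffs,
        ka=ka,
        ks=ks,
        omega=omega,
        n_codons=n_codons,
        saturated=saturated,
    )


def kaks_significance(result: KaKsResult) -> float:
    """Two-sided Fisher exact p-value for omega != 1.

    The 2x2 table contrasts observed differences with remaining sites in the
    synonymous and nonsynonymous classes, counts rounded to nearest integer.
    """
    nd = round(result.nonsyn_diffs)
    sd = round(result.syn_diffs)
    nn = round(result.nonsyn_sites) - nd
    sn = round(result.syn_sites) - sd
    if min(nd, sd, nn, sn) < 0:
        raise ValueError("negative cell after rounding")
    return float(stats.fisher_exact([[nd, sd], [nn, sn]], alternative="two-sided")[1])


def adjust_kaks(results: Sequence[KaKsResult]) -> list[KaKsResult]:
    """Attach per-gene Fisher p-values and BH-adjusted q-values."""
    ps = [kaks_significance(r) for r in results]
    qs = bh_fdr(ps)
    return [replace(r, p=p, q=q) for r, p, q in zip(results, ps, qs)]


# ---------------------------------------------------------------------------
# sliding windows


def sliding_windows(
    values: Iterable[tuple[str, int, float]],
    window: int = 100_000,
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Non-overlapping window aggregates of (contig, 1-based position, value).

    Windows run from each contig start in ``window``-bp increments; empty
    windows are emitted with count 0 (out to the contig length when known,
    else to the last observed position).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    binned: dict[tuple[str, int], list[float]] = {}
    max_pos: dict[str, int] = {}
    for contig, pos, value in values:
        if pos < 1:
            raise ValueError(f"position {pos} is not 1-based")
        if contig_lengths and pos > contig_lengths.get(contig, math.inf):
            raise ValueError(f"position {pos} beyond contig {contig}")
        binned.setdefault((contig, (pos - 1) // window), []).append(value)
        max_pos[contig] = max(max_pos.get(contig, 0), pos)
    contigs = dict(contig_lengths or {})
    for contig, pos in max_pos.items():
        contigs.setdefault(contig, pos)
    rows = []
    for contig in sorted(contigs):
        n_windows = max(1, math.ceil(contigs[contig] / window))
        for w in range(n_windows):
            vals = binned.get((contig, w), [])
            rows.append(
                {
                    "contig": contig,
                    "start": w * window,
                    "end": (w + 1) * window,
                    "count": len(vals),
                    "mean": float(np.mean(vals)) if vals else math.nan,
                    "max": float(np.max(vals)) if vals else math.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variant filtering and private-SNP comparison


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP row with the GATK annotations the hard filter uses.

    ``genotypes`` maps sample name to a tuple of allele indices (0 = ref,
    >0 = alt, -1 = missing).
    """

    contig: str
    position: int  # 1-based, per the VCF standard
    ref: str
    alt: str
    genotypes: dict[str, tuple[int, ...]] = field(default_factory=dict)
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    haplotype_score: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


#: (reason label, annotation attribute, predicate on the value) — a record
#: fails when ANY predicate holds; missing annotations pass their criterion.
HARD_FILTERS: tuple[tuple[str, str], ...] = (
    ("QD<2.0", "qd"),
    ("FS>60.0", "fs"),
    ("MQ<40.0", "mq"),
    ("HaplotypeScore>13.0", "haplotype_score"),
    ("MappingQualityRankSum<-12.5", "mq_rank_sum"),
    ("ReadPosRankSum<-8.0", "read_pos_rank_sum"),
)

_PREDICATES = {
    "qd": lambda v: v < 2.0,
    "fs": lambda v: v > 60.0,
    "mq": lambda v: v < 40.0,
    "haplotype_score": lambda v: v > 13.0,
    "mq_rank_sum": lambda v: v < -12.5,
    "read_pos_rank_sum": lambda v: v < -8.0,
}


def filter_reasons(record: VariantRecord) -> list[str]:
    """Labels of all hard-filter criteria the record violates."""
    reasons = []
    for label, attr in HARD_FILTERS:
        value = getattr(record, attr)
        if value is not None and _PREDICATES[attr](value):
            reasons.append(label)
    return reasons


def hard_filter_variants(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, list[str]]]]:
    """Partition records into (passed, [(failed, reasons)])."""
    passed, failed = [], []
    n_missing = 0
    for rec in records:
        n_missing += sum(1 for _, attr in HARD_FILTERS if getattr(rec, attr) is None)
        reasons = filter_reasons(rec)
        if reasons:
            failed.append((rec, reasons))
        else:
            passed.append(rec)
    if n_missing:
        logger.info("%d missing annotations treated as passing", n_missing)
    return passed, failed


@dataclass(frozen=True)
class PrivateVariantCounts:
    private_a: int
    private_b: int
    sites_a: tuple[tuple[str, int], ...]
    sites_b: tuple[tuple[str, int], ...]
    n_excluded: int


def private_variants(
    records: Iterable[VariantRecord], sample_a: str, sample_b: str
) -> PrivateVariantCounts:
    """SNPs private to each sample relative to the other and the reference.

    A site is private to A when A carries at least one non-reference allele
    while B is homozygous reference (and vice versa). Sites with a missing
    genotype in either sample are excluded and counted.
    """
    sites_a, sites_b = [], []
    n_excluded = 0
    for rec in records:
        gt_a = rec.genotypes.get(sample_a)
        gt_b = rec.genotypes.get(sample_b)
        if gt_a is None or gt_b is None or -1 in gt_a or -1 in gt_b:
            n_excluded += 1
            continue
        a_alt = any(al > 0 for al in gt_a)
        b_alt = any(al > 0 for al in gt_b)
        if a_alt and not b_alt:
            sites_a.append((rec.contig, rec.position))
        elif b_alt and not a_alt:
            sites_b.append((rec.contig, rec.position))
    if n_excluded:
        logger.info("excluded %d sites with missing genotypes", n_excluded)
    return PrivateVariantCounts(
        private_a=len(sites_a),
        private_b=len(sites_b),
        sites_a=tuple(sites_a),
        sites_b=tuple(sites_b),
        n_excluded=n_excluded,
    )


def read_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], list[str]]:
    """Read SNP records and sample names from a VCF (v4.x) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for var in vcf:
        if var.ALT is None or len(var.ALT) == 0:
            continue
        genotypes = {
            sample: tuple(int(a) for a in gt[:-1])
            for sample, gt in zip(samples, var.genotypes)
        }

        def info(key):
            v = var.INFO.get(key)
            return float(v) if v is not None else None

        records.append(
            VariantRecord(
                contig=var.CHROM,
                position=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                genotypes=genotypes,
                qd=info("QD"),
                fs=info("FS"),
                mq=info("MQ"),
                haplotype_score=info("HaplotypeScore"),
                mq_rank_sum=info("MappingQualityRankSum"),
                read_pos_rank_sum=info("ReadPosRankSum"),
            )
        )
    return records, samples


def kaks_to_frame(results: Sequence[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                **{k: v for k, v in r.__dict__.items() if k != "omega"},
                "omega": math.nan if r.omega is None else r.omega,
            }
            for r in results
        ]
    )
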