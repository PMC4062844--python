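"""Normalized CpG/GpC content and the permutation-based methylation caller.

Historically methylated CpG sites deaminate to TpG, so gene bodies that were
methylated in the germline are depleted of CpG dinucleotides relative to
neutral expectation. The observed/expected ratio

    CpG O/E = P_CpG / (P_C * P_G)

measures that depletion; GpC O/E is the compositionally matched negative
control, unaffected by methylation-driven mutation. A gene is called a
methylation candidate when its CpG O/E is significantly lower than an
empirical null of fixed-length genomic fragments (FDR-adjusted) while its
GpC O/E is not.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: left-closed G+C strata accounting for the GC / CpG-O/E correlation
GC_BIN_EDGES: tuple[float, ...] = (0.0, 0.35, 0.45, 0.50, 0.55, 1.0)


@dataclass(frozen=True)
class CompositionStats:
    """Mono- and dinucleotide composition of one sequence unit.

    ``L`` counts non-N bases; dinucleotide counts use overlapping windows
    whose two members are both non-N (``D`` of them). ``cpg_oe``/``gpc_oe``
    are None (undefined) when the sequence has no C, no G, or no valid
    window.
    """

    unit_id: str
    L: int
    n_C: int
    n_G: int
    n_CpG: int
    n_GpC: int
    D: int
    gc: float
    cpg_oe: float | None
    gpc_oe: float | None


@dataclass(frozen=True)
class MethylationCall:
    gene_id: str
    cpg_oe: float
    gpc_oe: float
    p_cpg: float
    p_gpc: float
    q_cpg: float
    q_gpc: float
    candidate: bool


@dataclass(frozen=True)
class BackgroundDistribution:
    """Null distribution of O/E ratios over background fragments."""

    values: np.ndarray  # sorted
    size: int

    @classmethod
    def from_values(cls, values: Iterable[float | None]) -> "BackgroundDistribution":
        vals = list(values)
        arr = np.array([v for v in vals if v is not None], dtype=float)
        n_dropped = len(vals) - arr.size
        if n_dropped:
            logger.info("excluded %d undefined background ratios", n_dropped)
        if arr.size == 0:
            raise ValueError("background distribution is empty")
        return cls(values=np.sort(arr), size=int(arr.size))


@dataclass(frozen=True)
class CandidateReport:
    n_genes: int
    n_excluded: int
    n_cpg_sig: int
    n_gpc_sig: int
    n_both: int
    n_candidates: int


def composition_stats(sequence: str, unit_id: str = "") -> CompositionStats:
    """Count nucleotides and overlapping dinucleotides, excluding N positions."""
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = ~(is_c | is_g | (arr == ord("A")) | (arr == ord("T")))
    L = int(arr.size - is_n.sum())
    n_c = int(is_c.sum())
    n_g = int(is_g.sum())
    if arr.size > 1:
        D = int((~is_n[:-1] & ~is_n[1:]).sum())
        n_cpg = int((is_c[:-1] & is_g[1:]).sum())
        n_gpc = int((is_g[:-1] & is_c[1:]).sum())
    else:
        D = n_cpg = n_gpc = 0
    gc = (n_c + n_g) / L if L else 0.0
    cpg_oe = gpc_oe = None
    if n_c > 0 and n_g > 0 and D > 0:
        p_c, p_g = n_c / L, n_g / L
        cpg_oe = (n_cpg / D) / (p_c * p_g)
        gpc_oe = (n_gpc / D) / (p_c * p_g)
    return CompositionStats(
        unit_id=unit_id,
        L=L,
        n_C=n_c,
        n_G=n_g,
        n_CpG=n_cpg,
        n_GpC=n_gpc,
        D=D,
        gc=gc,
        cpg_oe=cpg_oe,
        gpc_oe=gpc_oe,
    )


def gc_bin(gc: float) -> int:
    """Stratum index 1..5 for a G+C ratio; boundaries are left-closed."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc ratio {gc} outside [0, 1]")
    return min(bisect_right(GC_BIN_EDGES, gc, 1, len(GC_BIN_EDGES) - 1), 5)


def empirical_p(focal: float, background: BackgroundDistribution) -> float:
    """Fraction of background values strictly lower than the focal value.

    Ties count as not lower, which is conservative for a lower-tail test.
    """
    if background.size < 1:
        raise ValueError("background distribution is empty")
    return float(np.searchsorted(background.values, focal, side="left")) / background.size


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def candidate_counts(n_cpg_sig: int, n_gpc_sig: int, n_both: int) -> int:
    """Candidates = CpG-significant genes minus those also GpC-significant."""
    if n_both > min(n_cpg_sig, n_gpc_sig):
        raise ValueError("dual-significant count exceeds a marginal count")
    return n_cpg_sig - n_both


def call_candidates(
    gene_stats: Sequence[CompositionStats],
    background_cpg: BackgroundDistribution,
    background_gpc: BackgroundDistribution,
    alpha: float = 0.2,
) -> tuple[list[MethylationCall], CandidateReport]:
    """Call potentially methylated genes against the genomic background.

    A candidate has FDR-adjusted CpG O/E depletion (q_cpg < alpha) but no
    significant GpC O/E depletion (the negative control). Genes with
    undefined ratios are excluded and counted.
    """
    usable = [s for s in gene_stats if s.cpg_oe is not None and s.gpc_oe is not None]
    n_excluded = len(gene_stats) - len(usable)
    if n_excluded:
        logger.info("excluded %d genes with undefined O/E ratios", n_excluded)
    if not usable:
        return [], CandidateReport(0, n_excluded, 0, 0, 0, 0)
    p_cpg = [empirical_p(s.cpg_oe, background_cpg) for s in usable]
    p_gpc = [empirical_p(s.gpc_oe, background_gpc) for s in usable]
    q_cpg = bh_fdr(p_cpg)
    q_gpc = bh_fdr(p_gpc)
    calls = []
    for s, pc, pg, qc, qg in zip(usable, p_cpg, p_gpc, q_cpg, q_gpc):
        calls.append(
            MethylationCall(
                gene_id=s.unit_id,
                cpg_oe=s.cpg_oe,
                gpc_oe=s.gpc_oe,
                p_cpg=pc,
                p_gpc=pg,
                q_cpg=qc,
                q_gpc=qg,
                candidate=(qc < alpha) and not (qg < alpha),
            )
        )
    n_cpg_sig = int(sum(c.q_cpg < alpha for c in calls))
    n_gpc_sig = int(sum(c.q_gpc < alpha for c in calls))
    n_both = int(sum(c.q_cpg < alpha and c.q_gpc < alpha for c in calls))
    report = CandidateReport(
        n_genes=len(usable),
        n_excluded=n_excluded,
        n_cpg_sig=n_cpg_sig,
        n_gpc_sig=n_gpc_sig,
        n_both=n_both,
        n_candidates=candidate_counts(n_cpg_sig, n_gpc_sig, n_both),
    )
    return calls, report


class RankTestResult(NamedTuple):
    statistic: float
    pvalue: float
    direction: int  # sign of median(x) - median(y)


def compare_to_background(
    feature_values: Sequence[float], background_values: Sequence[float]
) -> RankTestResult:
    """Two-sided Mann-Whitney U rank test of feature vs background ratios.

    Exact null distribution below a combined sample size of 12 when the
    pooled data are tie-free; normal approximation with tie correction
    otherwise.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size < 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(x) - np.median(y)))
    return RankTestResult(float(res.statistic), float(res.pvalue), direction)


def binned_summary(
    units: Sequence[CompositionStats], background: Sequence[CompositionStats]
) -> pd.DataFrame:
    """Per-GC-stratum medians and unit-vs-background rank tests.

    Strata with fewer than two defined members on either side carry NaN
    p-values (test not applicable).
    """
    rows = []
    for b in range(1, 6):
        u = [s for s in units if s.cpg_oe is not None and gc_bin(s.gc) == b]
        g = [s for s in background if s.cpg_oe is not None and gc_bin(s.gc) == b]
        row = {
            "gc_bin": b,
            "gc_lower": GC_BIN_EDGES[b - 1],
            "gc_upper": GC_BIN_EDGES[b],
            "n_units": len(u),
            "n_background": len(g),
            "median_unit_cpg_oe": float(np.median([s.cpg_oe for s in u])) if u else np.nan,
            "median_bg_cpg_oe": float(np.median([s.cpg_oe for s in g])) if g else np.nan,
            "median_unit_gpc_oe": float(np.median([s.gpc_oe for s in u])) if u else np.nan,
            "median_bg_gpc_oe": float(np.median([s.gpc_oe for s in g])) if g else np.nan,
            "p_cpg": np.nan,
            "p_gpc": np.nan,
            "direction_cpg": 0,
            "direction_gpc": 0,
        }
        if len(u) >= 2 and len(g) >= 2:
            res_c = compare_to_background([s.cpg_oe for s in u], [s.cpg_oe for s in g])
            res_g = compare_to_background([s.gpc_oe for s in u], [s.gpc_oe for s in g])
            row.update(
                p_cpg=res_c.pvalue,
                p_gpc=res_g.pvalue,
                direction_cpg=res_c.direction,
                direction_gpc=res_g.direction,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
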