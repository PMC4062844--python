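"""Functional-category enrichment between a gene set and its background.

For each term a 2x2 contingency table (in set / not in set vs annotated /
not annotated) is tested two-sided: chi-square without continuity correction
when all expected cell counts are at least 5, Fisher's exact test otherwise
(Cochran's rule). P-values are Benjamini-Hochberg adjusted across terms.
Term identifiers (GO/IPR/KEGG style) are treated as opaque labels.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cpg_methylation import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # term genes in the set
    n: int  # set size
    K: int  # term genes in the background
    N: int  # background size
    fold: float
    p: float
    q: float
    test_used: str  # "chi-square" | "fisher"
    significant: bool


def _term_test(k: int, n: int, K: int, N: int) -> tuple[float, str]:
    table = np.array([[k, n - k], [K - k, (N - n) - (K - k)]])
    if table.min() < 0:
        raise ValueError("inconsistent contingency table")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    if (expected < 5).any():
        return float(stats.fisher_exact(table, alternative="two-sided")[1]), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), "chi-square"


def enrichment_test(
    set_genes: Sequence[str],
    background_genes: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-term association tests of a gene set against its background.

    The set must be contained in the background. Terms annotating no
    background gene are skipped with a log entry. ``significant`` marks
    results with q < alpha; both over- and under-representation are tested
    (two-sided).
    """
    gene_set = set(set_genes)
    background = set(background_genes)
    offenders = sorted(gene_set - background)
    if offenders:
        raise ValueError(f"set genes absent from background: {', '.join(offenders)}")
    n, N = len(gene_set), len(background)
    rows = []
    for term_id in sorted(term_map):
        term_genes = set(term_map[term_id]) & background
        K = len(term_genes)
        if K == 0:
            logger.info("term %s annotates no background gene; skipped", term_id)
            continue
        k = len(term_genes & gene_set)
        p, test_used = _term_test(k, n, K, N)
        fold = (k / n) / (K / N) if n else 0.0
        rows.append((term_id, k, K, fold, p, test_used))
    qs = bh_fdr([r[4] for r in rows])
    return [
        EnrichmentResult(
            term_id=term_id,
            k=k,
            n=n,
            K=K,
            N=N,
            fold=fold,
            p=p,
            q=q,
            test_used=test_used,
            significant=q < alpha,
        )
        for (term_id, k, K, fold, p, test_used), q in zip(rows, qs)
    ]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.sort_values("q", kind="stable").reset_index(drop=True) if len(df) else df


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_term_map(path: str | os.PathLike) -> dict[str, list[str]]:
    """Two-column TSV (term_id, gene_id) -> term -> gene list."""
    df = pd.read_csv(path, sep="\t", names=["term_id", "gene_id"], header=None, comment="#")
    out: dict[str, list[str]] = {}
    for term, gene in zip(df.term_id, df.gene_id):
        out.setdefault(str(term), []).append(str(gene))
    return out
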