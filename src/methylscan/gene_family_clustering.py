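"""Gene-family construction from all-vs-all alignment hits.

Genes are nodes; an edge connects two genes when more than one-third of each
gene's length is covered by their alignment, weighted by the H-score

    H = 100 * score(G1,G2) / max(score(G1,G1), score(G2,G2))

(raw alignment scores), which normalizes the cross score by the stronger
self-alignment and lies in [0, 100]. Families are built by average-linkage
agglomeration on H-scores (absent edges count as 0), accepting a merge only
while the merged family keeps average linkage above a floor and an edge
density above a floor — so every emitted multi-gene family satisfies both
constraints by construction.
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

MIN_ALIGNED_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class AlignmentHit:
    """One directed alignment hit between two genes.

    ``frac_query``/``frac_target`` are the aligned fractions of the query and
    target gene lengths, in [0, 1].
    """

    query_id: str
    target_id: str
    raw_score: float
    frac_query: float
    frac_target: float

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("raw_score must be nonnegative")
        for f in (self.frac_query, self.frac_target):
            if not 0.0 <= f <= 1.0:
                raise ValueError("aligned fractions must lie in [0, 1]")


@dataclass
class GeneFamilySet:
    """Disjoint families covering all clustered genes.

    ``mean_h`` is the average H-score over all unordered within-family pairs
    (absent edges counted as 0); ``density`` is existing edges over
    k(k-1)/2. Both are None for singletons.
    """

    families: list[frozenset[str]]
    mean_h: list[float | None] = field(default_factory=list)
    density: list[float | None] = field(default_factory=list)


def h_score(raw_cross: float, self_query: float, self_target: float) -> float:
    """Normalized similarity in [0, 100]."""
    if self_query <= 0 or self_target <= 0:
        raise ValueError("self-alignment scores must be positive")
    if raw_cross < 0:
        raise ValueError("cross score must be nonnegative")
    # divide before scaling so an exact self-comparison yields exactly 100
    return min(100.0, 100.0 * (raw_cross / max(self_query, self_target)))


def build_graph(
    hits: Iterable[AlignmentHit],
    self_scores: Mapping[str, float],
    min_aligned_fraction: float = MIN_ALIGNED_FRACTION,
) -> nx.Graph:
    """H-score-weighted similarity graph from merged alignment hits.

    Hits for the same unordered pair are joined before the fraction test:
    aligned fractions are summed per gene (treating hits as non-overlapping
    alignment blocks, capped at 1) and raw scores merged by maximum. An edge
    requires the joined fraction to exceed ``min_aligned_fraction`` strictly
    in *both* genes. Self-hits are ignored.
    """
    merged_raw: dict[tuple[str, str], float] = {}
    merged_frac: dict[tuple[str, str], list[float]] = {}
    for hit in hits:
        if hit.query_id == hit.target_id:
            continue
        for gene in (hit.query_id, hit.target_id):
            if gene not in self_scores:
                raise ValueError(f"missing self score for gene {gene}")
        a, b = sorted((hit.query_id, hit.target_id))
        fa, fb = (
            (hit.frac_query, hit.frac_target)
            if a == hit.query_id
            else (hit.frac_target, hit.frac_query)
        )
        key = (a, b)
        merged_raw[key] = max(merged_raw.get(key, 0.0), hit.raw_score)
        acc = merged_frac.setdefault(key, [0.0, 0.0])
        acc[0] = min(1.0, acc[0] + fa)
        acc[1] = min(1.0, acc[1] + fb)

    graph = nx.Graph()
    graph.add_nodes_from(self_scores)
    for (a, b), raw in merged_raw.items():
        fa, fb = merged_frac[(a, b)]
        if fa > min_aligned_fraction and fb > min_aligned_fraction:
            graph.add_edge(a, b, weight=h_score(raw, self_scores[a], self_scores[b]))
    return graph


def cluster_families(
    graph: nx.Graph, min_h: float = 10.0, min_density: float = 0.34
) -> GeneFamilySet:
    """Average-linkage agglomeration gated by linkage and edge density.

    At each step the highest-linkage cluster pair whose linkage exceeds
    ``min_h`` and whose merged cluster would keep edge density above
    ``min_density`` is merged; ties are broken by the lexicographically
    smallest pair of cluster representatives (smallest member ID). Nodes
    never merged remain singleton families. Because every accepted merge
    satisfies both constraints, every emitted multi-gene family does too.
    """
    clusters: dict[int, set[str]] = {i: {n} for i, n in enumerate(sorted(graph.nodes))}
    # pairwise cross-weight sums and cross-edge counts between live clusters
    wsum: dict[tuple[int, int], float] = {}
    ecount: dict[tuple[int, int], int] = {}
    internal_w: dict[int, float] = {i: 0.0 for i in clusters}
    internal_e: dict[int, int] = {i: 0 for i in clusters}
    index_of = {n: i for i, c in clusters.items() for n in c}
    for u, v, w in graph.edges(data="weight"):
        key = tuple(sorted((index_of[u], index_of[v])))
        wsum[key] = wsum.get(key, 0.0) + w
        ecount[key] = ecount.get(key, 0) + 1

    def rep(i: int) -> str:
        return min(clusters[i])

    while True:
        best: tuple[float, str, str, int, int] | None = None
        for (i, j), total in wsum.items():
            linkage = total / (len(clusters[i]) * len(clusters[j]))
            if linkage <= min_h:
                continue
            k = len(clusters[i]) + len(clusters[j])
            edges = internal_e[i] + internal_e[j] + ecount[(i, j)]
            density = edges / (k * (k - 1) / 2)
            if density <= min_density:
                continue
            ra, rb = sorted((rep(i), rep(j)))
            cand = (-linkage, ra, rb, i, j)
            if best is None or cand < best:
                best = cand
        if best is None:
            break
        _, _, _, i, j = best
        # merge j into i
        clusters[i] |= clusters[j]
        internal_w[i] += internal_w[j] + wsum[(min(i, j), max(i, j))]
        internal_e[i] += internal_e[j] + ecount[(min(i, j), max(i, j))]
        del clusters[j], internal_w[j], internal_e[j]
        for key in [k for k in wsum if i in k or j in k]:
            a, b = key
            other = b if a in (i, j) else a
            if other in (i, j):
                del wsum[key], ecount[key]
                continue
            if j in key:
                new_key = tuple(sorted((i, other)))
                wsum[new_key] = wsum.get(new_key, 0.0) + wsum.pop(key)
                ecount[new_key] = ecount.get(new_key, 0) + ecount.pop(key)

    families, mean_h, density = [], [], []
    for i in sorted(clusters, key=rep):
        members = clusters[i]
        families.append(frozenset(members))
        k = len(members)
        if k == 1:
            mean_h.append(None)
            density.append(None)
        else:
            pairs = k * (k - 1) / 2
            mean_h.append(internal_w[i] / pairs)
            density.append(internal_e[i] / pairs)
    return GeneFamilySet(families=families, mean_h=mean_h, density=density)


def family_overlap_counts(
    families: Sequence[frozenset[str] | set[str]],
    species_of: Mapping[str, str] | Callable[[str], str],
) -> dict[frozenset[str], int]:
    """Venn-cell counts: families containing >= 1 gene of each species subset."""
    getter = species_of.__getitem__ if isinstance(species_of, Mapping) else species_of
    counts: dict[frozenset[str], int] = {}
    species_seen: set[str] = set()
    for fam in families:
        present = frozenset(getter(g) for g in fam)
        species_seen |= present
        counts[present] = counts.get(present, 0) + 1
    if len(species_seen) < 2:
        raise ValueError("family overlap requires >= 2 species")
    return counts


# ---------------------------------------------------------------------------
# tabular I/O


def read_hits(path: str | os.PathLike) -> list[AlignmentHit]:
    """Tab-separated hit table: query, target, raw_score, frac_query, frac_target."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["query_id", "target_id", "raw_score", "frac_query", "frac_target"],
        header=None,
        comment="#",
    )
    return [AlignmentHit(**row) for row in df.to_dict("records")]


def read_self_scores(path: str | os.PathLike) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", names=["gene_id", "score"], header=None, comment="#")
    return dict(zip(df.gene_id, df.score.astype(float)))


def families_to_frame(result: GeneFamilySet) -> pd.DataFrame:
    rows = []
    for idx, fam in enumerate(result.families):
        for gene in sorted(fam):
            rows.append(
                {
                    "family_id": f"FAM{idx:05d}",
                    "gene_id": gene,
                    "family_size": len(fam),
                    "mean_h": result.mean_h[idx] if result.mean_h[idx] is not None else math.nan,
                    "edge_density": result.density[idx]
                    if result.density[idx] is not None
                    else math.nan,
                }
            )
    return pd.DataFrame(rows)
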