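"""PWM similarity, threshold clustering of pooled motifs, regulon assembly.

Similarity between two column-stochastic PWMs is the best, over relative
offsets (overlap of at least ``min_overlap`` columns) and both orientations,
of the mean per-column term ``1 - ||a_c - b_c||_2 / sqrt(2)``; identical
PWMs score 1 and maximally different deterministic columns score 0.

Clustering follows Kruskal's scheme: edges sorted by similarity descending
are merged through a union-find while similarity stays at or above the
threshold, which is exactly the connected components of the thresholded
similarity graph (and therefore order-independent).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class MotifSimilarityEdge:
    motif_a: str
    motif_b: str
    similarity: float
    best_offset: int
    orientation: str  # fwd | rc


@dataclass
class Regulon:
    """A motif cluster plus the operons and genes carrying its motifs."""

    regulon_id: int
    member_motifs: frozenset[str]
    operon_ids: frozenset[str]
    gene_ids: frozenset[str]
    source_cems: frozenset[str]
    tier: str                      # highly_reliable | relatively_reliable
    child_regulons: tuple[int, ...] = ()


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in self.parent}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return True

    def groups(self) -> list[set]:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return list(out.values())


def _rc_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def _directional_similarity(a: np.ndarray, b: np.ndarray, min_overlap: int):
    """Best (similarity, offset) over relative offsets for fixed orientation.

    Offset o positions b's first column under a's column o (negative o
    shifts b left of a).
    """
    wa, wb = a.shape[1], b.shape[1]
    best, best_off = -1.0, 0
    for o in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, o), min(wa, o + wb)
        if hi_a - lo_a < min_overlap:
            continue
        cols_a = a[:, lo_a:hi_a]
        cols_b = b[:, lo_a - o:hi_a - o]
        terms = 1.0 - np.linalg.norm(cols_a - cols_b, axis=0) / SQRT2
        s = float(terms.mean())
        if s > best:
            best, best_off = s, o
    return best, best_off


def motif_similarity(a, b, min_overlap: int = 6) -> MotifSimilarityEdge:
    """Symmetric similarity in [0, 1] between two PWM motifs.

    Accepts Motif / TFBSLibraryEntry objects or bare 4 x w arrays. The
    minimum overlap is reduced to the smaller width when comparing against
    a library motif narrower than ``min_overlap``; two width-``w`` pipeline
    motifs with w < min_overlap are a configuration error.
    """
    pa = np.asarray(getattr(a, "pwm", a), dtype=float)
    pb = np.asarray(getattr(b, "pwm", b), dtype=float)
    if min(pa.shape[1], pb.shape[1]) < min_overlap:
        if pa.shape[1] == pb.shape[1]:
            raise ValueError(
                f"motif width {pa.shape[1]} cannot satisfy overlap >= {min_overlap}"
            )
        min_overlap = min(pa.shape[1], pb.shape[1])
    s_fwd, o_fwd = _directional_similarity(pa, pb, min_overlap)
    s_rc, o_rc = _directional_similarity(pa, _rc_pwm(pb), min_overlap)
    if s_rc > s_fwd:
        sim, off, orient = s_rc, o_rc, "rc"
    else:
        sim, off, orient = s_fwd, o_fwd, "fwd"
    return MotifSimilarityEdge(
        motif_a=str(getattr(a, "motif_id", "a")),
        motif_b=str(getattr(b, "motif_id", "b")),
        similarity=max(0.0, min(1.0, sim)),
        best_offset=off,
        orientation=orient,
    )


def all_pairwise_edges(motifs: Sequence, min_overlap: int = 6) -> list[MotifSimilarityEdge]:
    edges = []
    for i in range(len(motifs)):
        for j in range(i + 1, len(motifs)):
            edges.append(motif_similarity(motifs[i], motifs[j], min_overlap))
    return edges


def kruskal_cluster(
    motif_ids: Sequence[str],
    edges: Sequence[MotifSimilarityEdge],
    threshold: float,
) -> list[frozenset[str]]:
    """Partition motifs by merging edges with similarity >= threshold.

    Edges are processed in descending similarity (Kruskal order); the
    result equals the connected components of the similarity->=threshold
    graph, so it does not depend on tie-breaking.
    """
    uf = UnionFind(motif_ids)
    for e in sorted(edges, key=lambda e: -e.similarity):
        if e.similarity < threshold:
            break
        uf.union(e.motif_a, e.motif_b)
    return [frozenset(g) for g in uf.groups()]


def assemble_regulons(
    clusters_t1: Sequence[frozenset[str]],
    clusters_t2: Sequence[frozenset[str]],
    motifs: Sequence,
    operon_genes: dict[str, Sequence[str]] | None = None,
    cem_of_motif: dict[str, str] | None = None,
) -> list[Regulon]:
    """Build regulons from the T1 partition, with T2-only merges tiered.

    Every T1 cluster becomes a highly reliable regulon whose operon set is
    the exact union of its member motifs' site operons. A T2 cluster that
    merges two or more T1 clusters is additionally recorded as a relatively
    reliable regulon referencing its T1 children. Regulon ids are assigned
    deterministically: T1 regulons first, ordered by descending operon
    count then smallest member motif id; T2 merges after, same ordering.
    """
    by_id = {m.motif_id: m for m in motifs}

    def materialize(cluster: frozenset[str]):
        operon_ids: set[str] = set()
        for mid in cluster:
            operon_ids.update(oid for oid, _, _ in by_id[mid].sites)
        gene_ids: set[str] = set()
        if operon_genes:
            for oid in operon_ids:
                gene_ids.update(operon_genes.get(oid, ()))
        cems = frozenset(
            cem_of_motif[mid] for mid in cluster
        ) if cem_of_motif else frozenset()
        return frozenset(operon_ids), frozenset(gene_ids), cems

    order_key = lambda c: (-len(materialize(c)[0]), min(c))
    t1_sorted = sorted(clusters_t1, key=order_key)
    regulons: list[Regulon] = []
    t1_id_of_cluster: dict[frozenset, int] = {}
    for i, cluster in enumerate(t1_sorted, start=1):
        operon_ids, gene_ids, cems = materialize(cluster)
        t1_id_of_cluster[cluster] = i
        regulons.append(
            Regulon(i, frozenset(cluster), operon_ids, gene_ids, cems, "highly_reliable")
        )

    merges = [c2 for c2 in clusters_t2
              if sum(1 for c1 in t1_sorted if c1 <= c2) >= 2]
    next_id = len(t1_sorted) + 1
    for c2 in sorted(merges, key=order_key):
        operon_ids, gene_ids, cems = materialize(c2)
        children = tuple(sorted(
            t1_id_of_cluster[c1] for c1 in t1_sorted if c1 <= c2
        ))
        regulons.append(
            Regulon(next_id, frozenset(c2), operon_ids, gene_ids, cems,
                    "relatively_reliable", children)
        )
        next_id += 1
    return regulons


def write_regulons_tsv(regulons: Sequence[Regulon], path: str | Path) -> None:
    lines = ["regulon_id\ttier\tmotifs\toperons\tn_operons\tn_genes"]
    for r in regulons:
        lines.append(
            f"{r.regulon_id}\t{r.tier}\t{','.join(sorted(r.member_motifs))}\t"
            f"{','.join(sorted(r.operon_ids))}\t{len(r.operon_ids)}\t{len(r.gene_ids)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cluster_json(clusters: Sequence[frozenset[str]], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([sorted(c) for c in clusters], indent=1) + "\n"
    )
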