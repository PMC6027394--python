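"""Differential expression and co-expression module (CEM) construction.

Differential expression uses the Wilcoxon signed-rank test on paired
control/treatment log-ratios. For n <= 25 informative pairs the exact null
distribution of the positive-rank sum W+ is computed by convolution over the
observed (mid-)ranks, which stays exact in the presence of ties; beyond that
a normal approximation with continuity and tie correction is used.

Co-expression modules are built by agglomerative clustering of operon-level
mean profiles under Euclidean distance, cutting the dendrogram at
``h = cut_fraction * max(pairwise distance)``, then discarding oversized
clusters and singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata, ranksums
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .core_io import ExpressionMatrix, Operon

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25


@dataclass(frozen=True)
class DEGResult:
    gene_id: str
    statistic: float          # W+ = sum of ranks of positive differences
    p_value: float
    adjusted_p: float | None
    direction: str            # up | down | none
    effect: float             # median paired difference (treatment - control)
    degenerate: bool = False


@dataclass(frozen=True)
class CoexpressionModule:
    cem_id: str
    operon_ids: frozenset[str]
    gene_ids: frozenset[str]
    profile: np.ndarray       # mean operon profile across samples
    size: int


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ given the observed |difference| ranks.

    Conditions on the observed ranks (hence valid with midranks): each rank
    is positive or negative with probability 1/2 under H0, so the null pmf
    of W+ is the convolution of 1/2*(delta_0 + delta_r) over ranks r.
    Ranks are doubled so midranks (k + 0.5) become integers.
    """
    r2 = np.rint(ranks * 2).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(w_plus * 2))
    lower = pmf[: w2 + 1].sum()
    upper = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(control, treatment) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-sided p).

    Differences are treatment - control; zero differences are dropped
    (standard convention) and ties among |differences| are mid-ranked.
    If every difference is zero the test is degenerate and p = 1.
    """
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if control.shape != treatment.shape or control.ndim != 1:
        raise ValueError("control and treatment must be equal-length 1-d vectors")
    d = treatment - control
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        return w_plus, _exact_two_sided_p(ranks, w_plus)
    # Normal approximation with tie correction and continuity correction.
    mean = n * (n + 1) / 4.0
    var = float((ranks**2).sum()) / 4.0
    if var == 0:
        return w_plus, 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * norm.sf(abs(z))))


def call_degs(expr: ExpressionMatrix, config: PipelineConfig) -> list[DEGResult]:
    """Per-gene paired signed-rank tests with BH-adjusted p-values.

    The default significance rule is raw p < ``deg_alpha``; adjusted values
    are always reported alongside. Direction is the sign of the median
    paired difference (ties give ``none``). ``config.paired=False`` falls
    back to an unpaired rank-sum test.
    """
    genes = expr.gene_ids
    if not genes:
        return []
    ctrl, trt = expr.paired_arrays()
    stats, pvals, effects, degenerate = [], [], [], []
    for i in range(len(genes)):
        c, t = ctrl[i], trt[i]
        if config.paired:
            w, p = wilcoxon_signed_rank(c, t)
        else:
            res = ranksums(t, c)
            w, p = float(res.statistic), float(res.pvalue)
        d = t - c
        stats.append(w)
        pvals.append(p)
        effects.append(float(np.median(d)))
        degenerate.append(bool(np.all(d == 0)))
    adj = multipletests(pvals, method="fdr_bh")[1]
    out = []
    for g, w, p, a, e, dg in zip(genes, stats, pvals, adj, effects, degenerate):
        if p < config.deg_alpha and e > 0:
            direction = "up"
        elif p < config.deg_alpha and e < 0:
            direction = "down"
        else:
            direction = "none"
        out.append(DEGResult(g, w, p, float(a), direction, e, dg))
    return out


def deg_table(degs: list[DEGResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": d.gene_id, "W": d.statistic, "p": d.p_value,
             "p_adj": d.adjusted_p, "direction": d.direction, "effect": d.effect}
            for d in degs
        ]
    )


def operon_profiles(expr: ExpressionMatrix, operons: list[Operon]) -> pd.DataFrame:
    """Operon x sample matrix: arithmetic mean of member-gene profiles.

    Operons with no gene in the expression matrix are dropped and logged.
    """
    rows, index = [], []
    present = set(expr.gene_ids)
    for op in operons:
        members = [g for g in op.gene_ids if g in present]
        if not members:
            logger.info("operon %s: no expressed genes, dropped", op.operon_id)
            continue
        rows.append(expr.values.loc[members].mean(axis=0).to_numpy())
        index.append(op.operon_id)
    return pd.DataFrame(rows, index=index, columns=expr.sample_ids)


def build_cems(
    profiles: pd.DataFrame, config: PipelineConfig,
    operon_genes: dict[str, tuple[str, ...]] | None = None,
) -> tuple[list[CoexpressionModule], dict]:
    """Cluster operon profiles into co-expression modules.

    Returns (modules, log) where ``log`` records removed oversize clusters
    and dropped singletons. Modules are renumbered deterministically by
    descending size, then by their lexicographically smallest operon id,
    and the result is invariant to input row order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 operon profiles to cluster")
    profiles = profiles.sort_index()  # row-order invariance
    X = profiles.to_numpy(dtype=float)
    dists = pdist(X, metric="euclidean")
    h = config.cut_fraction * float(dists.max())
    Z = linkage(X, method=config.linkage, metric="euclidean")
    labels = fcluster(Z, t=h, criterion="distance")

    groups: dict[int, list[str]] = {}
    for oid, lab in zip(profiles.index, labels):
        groups.setdefault(int(lab), []).append(oid)

    removed, singletons, kept = [], [], []
    for lab, members in groups.items():
        if len(members) > config.max_cem_size:
            removed.append(sorted(members))
            logger.info("cluster of %d operons exceeds max_cem_size, removed", len(members))
        elif len(members) < 2:
            singletons.extend(members)
        else:
            kept.append(sorted(members))

    kept.sort(key=lambda m: (-len(m), m[0]))
    modules = []
    for i, members in enumerate(kept, start=1):
        gene_ids: set[str] = set()
        if operon_genes:
            for oid in members:
                gene_ids.update(operon_genes.get(oid, ()))
        modules.append(
            CoexpressionModule(
                cem_id=f"CEM{i:03d}",
                operon_ids=frozenset(members),
                gene_ids=frozenset(gene_ids),
                profile=profiles.loc[members].mean(axis=0).to_numpy(),
                size=len(members),
            )
        )
    log = {
        "cut_height": h,
        "n_clusters_raw": len(groups),
        "removed_oversize": removed,
        "singletons": sorted(singletons),
    }
    return modules, log
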