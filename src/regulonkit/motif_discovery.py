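"""De novo fixed-width motif discovery within a co-expression module's promoters.

The finder follows a deterministic seed-extend-refine design:

1. *Seed*: every exact 8-mer over-represented in the promoter set relative
   to an order-0 genome background (count >= expectation + 2 Poisson sigma)
   is a candidate; the ``seed_cap`` seeds with the smallest Poisson tail
   probabilities are carried forward.
2. *Extend*: each seed word is centered in a width-``w`` window and turned
   into an initial PWM; the best-matching window per promoter (both
   strands, zero-or-one occurrence per sequence) seeds refinement.
3. *Refine*: hard-assignment EM — alternately pick the best window per
   promoter under the current PWM and re-estimate the PWM from those
   windows — for at most ``em_max_iter`` passes or until the total
   log-likelihood moves by less than ``em_tol``.
4. *Score*: sum over accepted sites of log2 P(site|PWM)/P(site|background);
   a window is a site only when this log-odds reaches half the PWM's
   maximum achievable log-odds (refined PWMs overfit their training
   windows, so a positive log-odds alone is far too permissive a site
   definition).
5. *Significance*: the per-window probability q of reaching the site
   threshold under the background is computed exactly (discretized score
   distribution), giving an expected site count lambda = q x windows
   scanned; the site-count p-value is the Poisson upper tail of the
   observed site count. Because the refined PWM was trained on the very
   windows it counts, this tail alone is anti-conservative, so the
   reported p is floored by the seed word's own exact count tail (which
   involves no refinement); the adjustment multiplies by the full
   enumerated seed family (4^8 words), covering the whole search.
6. *Deduplicate*: near-identical motifs (similarity > ``dedup_similarity``)
   collapse to the higher-scoring one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import poisson

from .config import PipelineConfig
from .core_io import BASE_INDEX, BASES, GenomeRecord

logger = logging.getLogger(__name__)

SEED_WIDTH = 8
_SCORE_SCALE = 200  # discretization for the exact background score distribution


@dataclass(frozen=True)
class BackgroundModel:
    """Order-0 base composition of the whole genome (the control set)."""

    freqs: np.ndarray  # A,C,G,T

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        f = np.maximum(f, 1e-6)
        f = f / f.sum()
        object.__setattr__(self, "freqs", f)

    @classmethod
    def from_genome(cls, genome: GenomeRecord) -> "BackgroundModel":
        counts = np.array([genome.sequence.count(b) for b in BASES], dtype=float)
        return cls(counts / counts.sum())

    @property
    def gc(self) -> float:
        return float(self.freqs[1] + self.freqs[2])


@dataclass
class Motif:
    """A fixed-width PWM with its supporting sites and significance."""

    motif_id: str
    pwm: np.ndarray                      # 4 x w column-stochastic
    sites: list[tuple[str, int, str]]    # (operon_id, offset in promoter, fwd|rc)
    score: float                         # sum of per-site log2 odds
    p_value: float
    adjusted_p: float

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))

    @property
    def information_content(self) -> float:
        """Total IC in bits relative to the uniform background, in [0, 2w]."""
        p = np.clip(self.pwm, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=0)).sum())

    def reverse_complement(self) -> "Motif":
        return Motif(
            motif_id=self.motif_id + "_rc",
            pwm=self.pwm[::-1, ::-1].copy(),
            sites=list(self.sites),
            score=self.score,
            p_value=self.p_value,
            adjusted_p=self.adjusted_p,
        )


# ---------------------------------------------------------------------------
# Encoding helpers
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _window_matrix(codes: list[np.ndarray], w: int):
    """All width-w windows of every promoter on both strands.

    Returns (X, prom_idx, offsets, strands, per_prom) where windows are
    grouped by promoter: for each promoter first the forward windows left
    to right, then the reverse-complement windows. All promoters must have
    equal length so the per-promoter window count is constant.
    """
    lengths = {len(c) for c in codes}
    if len(lengths) != 1:
        raise ValueError("promoters must have equal length")
    L = lengths.pop()
    if L < w:
        raise ValueError(f"promoter length {L} shorter than motif width {w}")
    n_off = L - w + 1
    rows, prom_idx, offsets, strands = [], [], [], []
    idx = np.arange(n_off)[:, None] + np.arange(w)[None, :]
    for pi, c in enumerate(codes):
        fwd = c[idx]
        rc = (3 - c[::-1])[idx]  # windows of the reverse-complemented promoter
        rows.append(fwd)
        rows.append(rc)
        prom_idx.extend([pi] * (2 * n_off))
        offsets.extend(range(n_off))
        # rc window at position j covers forward positions L-j-w .. L-j-1
        offsets.extend(L - np.arange(n_off) - w)
        strands.extend(["fwd"] * n_off + ["rc"] * n_off)
    X = np.concatenate(rows, axis=0)
    return X, np.array(prom_idx), np.array(offsets), np.array(strands), 2 * n_off


def _pwm_from_windows(windows: np.ndarray, bg: np.ndarray, pseudo: float = 1.0) -> np.ndarray:
    w = windows.shape[1]
    counts = np.zeros((4, w))
    for b in range(4):
        counts[b] = (windows == b).sum(axis=0)
    counts += pseudo * bg[:, None]
    return counts / counts.sum(axis=0, keepdims=True)


def _log_odds(pwm: np.ndarray, bg: np.ndarray) -> np.ndarray:
    return np.log2(np.clip(pwm, 1e-12, None)) - np.log2(bg)[:, None]


def _score_windows(X: np.ndarray, lo: np.ndarray) -> np.ndarray:
    w = lo.shape[1]
    return lo[X, np.arange(w)[None, :]].sum(axis=1)


def _tail_prob_ge(lo: np.ndarray, bg: np.ndarray, threshold: float = 0.0) -> float:
    """Exact P(log-odds score >= threshold) for a random background window.

    Column score distributions are convolved on an integer grid
    (scores x _SCORE_SCALE, rounded), which bounds the discretization error
    at w / (2 * _SCORE_SCALE) score units.
    """
    ints = np.rint((lo - threshold / lo.shape[1]) * _SCORE_SCALE).astype(np.int64)
    lows = ints.min(axis=0)
    spans = ints - lows  # 4 x w, non-negative
    total_span = int(spans.max(axis=0).sum())
    pmf = np.zeros(total_span + 1)
    pmf[0] = 1.0
    for c in range(ints.shape[1]):
        new = np.zeros_like(pmf)
        for b in range(4):
            s = int(spans[b, c])
            if s:
                new[s:] += bg[b] * pmf[: len(pmf) - s]
            else:
                new += bg[b] * pmf
        pmf = new
    base = int(lows.sum())  # grid index 0 corresponds to this scaled score
    # P(shifted score >= 0)  <=>  grid index >= -base
    cut = -base
    if cut <= 0:
        return 1.0
    if cut >= len(pmf):
        return 0.0
    return float(pmf[cut:].sum())


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_counts(codes: list[np.ndarray], k: int) -> np.ndarray:
    """Counts of every k-mer over both strands of every promoter."""
    counts = np.zeros(4**k, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for c in codes:
        for arr in (c, 3 - c[::-1]):
            if len(arr) < k:
                continue
            idx = np.lib.stride_tricks.sliding_window_view(arr.astype(np.int64), k)
            counts += np.bincount(idx @ weights, minlength=4**k)
    return counts


def _kmer_expected(bg: np.ndarray, k: int, n_positions: int) -> np.ndarray:
    logp = np.zeros(4**k)
    for pos in range(k):
        digit = (np.arange(4**k) // (4 ** (k - 1 - pos))) % 4
        logp += np.log(bg[digit])
    return n_positions * np.exp(logp)


def _decode_kmer(code: int, k: int) -> np.ndarray:
    return np.array([(code // 4**(k - 1 - i)) % 4 for i in range(k)], dtype=np.int8)


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

def find_motifs(
    promoters: Sequence, background: BackgroundModel, config: PipelineConfig,
    cem_id: str = "CEM",
) -> list[Motif]:
    """Ranked significant width-``w`` motifs in one module's promoter set.

    ``promoters`` are PromoterSeq objects or (operon_id, sequence) pairs.
    Returns motifs with adjusted p below ``config.motif_alpha``, ranked by
    adjusted p then score; an empty list is a valid outcome.
    """
    pairs = [
        (p.operon_id, p.sequence) if hasattr(p, "sequence") else tuple(p)
        for p in promoters
    ]
    if len(pairs) < 2:
        raise ValueError("motif finding requires at least 2 promoters")
    ids = [oid for oid, _ in pairs]
    codes = [_encode(seq) for _, seq in pairs]
    w = config.motif_width
    bg = background.freqs

    X, prom_idx, offsets, strands, per_prom = _window_matrix(codes, w)
    valid = (X >= 0).all(axis=1)  # windows containing N are never sites
    n_prom = len(codes)
    n_windows = int(valid.sum())

    # --- seeds ---------------------------------------------------------
    counts = _kmer_counts(codes, SEED_WIDTH)
    n_positions = sum(2 * max(len(c) - SEED_WIDTH + 1, 0) for c in codes)
    expected = _kmer_expected(bg, SEED_WIDTH, n_positions)
    over = counts >= expected + 2.0 * np.sqrt(expected)
    cand = np.flatnonzero(over & (counts >= 2))
    if cand.size == 0:
        return []
    tails = poisson.sf(counts[cand] - 1, expected[cand])
    order = np.argsort(tails, kind="stable")
    seeds = cand[order[: config.seed_cap]]
    seed_tail = dict(zip(cand.tolist(), tails.tolist()))
    n_family = 4**SEED_WIDTH  # Bonferroni family: every enumerated word

    scores_neg_inf = np.full(X.shape[0], -np.inf)
    motifs: list[Motif] = []
    for seed_code in seeds:
        seed = _decode_kmer(int(seed_code), SEED_WIDTH)
        # center the seed in a width-w PWM; flanks at background
        pwm = np.tile(bg[:, None], (1, w)).astype(float)
        off = (w - SEED_WIDTH) // 2
        for j, b in enumerate(seed):
            col = np.full(4, 0.05)
            col[b] = 0.85
            pwm[:, off + j] = col
        prev_obj = -np.inf
        best = None
        for _ in range(config.em_max_iter):
            lo = _log_odds(pwm, bg)
            sc = _score_windows(X, lo)
            sc = np.where(valid, sc, scores_neg_inf)
            per = sc.reshape(n_prom, per_prom)
            best = per.argmax(axis=1) + np.arange(n_prom) * per_prom
            obj = float(sc[best].sum())
            pwm = _pwm_from_windows(X[best], bg, pseudo=2.0)
            if abs(obj - prev_obj) < config.em_tol * max(1.0, abs(prev_obj)):
                break
            prev_obj = obj
        lo = _log_odds(pwm, bg)
        sc = _score_windows(X, lo)
        sc = np.where(valid, sc, scores_neg_inf)
        per = sc.reshape(n_prom, per_prom)
        best = per.argmax(axis=1) + np.arange(n_prom) * per_prom
        site_threshold = 0.5 * float(lo.max(axis=0).sum())
        site_mask = sc[best] >= site_threshold
        k_sites = int(site_mask.sum())
        if k_sites < 2:
            continue
        site_rows = best[site_mask]
        site_proms = np.flatnonzero(site_mask)
        q = _tail_prob_ge(lo, bg, site_threshold)
        lam = q * n_windows
        p = max(float(poisson.sf(k_sites - 1, lam)), seed_tail[int(seed_code)])
        adj = min(1.0, p * n_family)
        motifs.append(
            Motif(
                motif_id="",
                pwm=_pwm_from_windows(X[site_rows], bg, pseudo=2.0),
                sites=[
                    (ids[pi], int(offsets[ri]), str(strands[ri]))
                    for pi, ri in zip(site_proms, site_rows)
                ],
                score=float(sc[site_rows].sum()),
                p_value=p,
                adjusted_p=adj,
            )
        )

    # --- deduplicate and rank ------------------------------------------
    from .motif_clustering import motif_similarity  # local import avoids a cycle

    motifs = [m for m in motifs if m.adjusted_p < config.motif_alpha]
    motifs.sort(key=lambda m: (-m.score, m.adjusted_p))
    kept: list[Motif] = []
    for m in motifs:
        if all(
            motif_similarity(m, other).similarity <= config.dedup_similarity
            for other in kept
        ):
            kept.append(m)
    kept.sort(key=lambda m: (m.adjusted_p, -m.score))
    for rank, m in enumerate(kept, start=1):
        m.motif_id = f"{cem_id}_m{rank}"
    return kept


def top_k_motifs(motifs: Sequence[Motif], k: int) -> list[Motif]:
    """First min(k, len) motifs of an already-ranked list."""
    if len(motifs) < k:
        logger.info("only %d significant motifs available (top_k=%d)", len(motifs), k)
    return list(motifs[:k])


def write_sites_tsv(motifs: Sequence[Motif], path: str | Path) -> None:
    lines = ["motif_id\toperon_id\toffset\tstrand"]
    for m in motifs:
        for oid, off, strand in m.sites:
            lines.append(f"{m.motif_id}\t{oid}\t{off}\t{strand}")
    Path(path).write_text("\n".join(lines) + "\n")
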