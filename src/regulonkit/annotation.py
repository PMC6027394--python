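"""Regulon validation and filtering.

Stages, mirroring the study design this package implements:

* match each regulon's motifs against a library of known TF binding sites,
  with an E-value from a column-shuffle null of the similarity metric;
* map the matched template TFs onto the target proteome by local protein
  alignment (BLOSUM62, affine gaps) with a Karlin-Altschul E-value;
* keep as computationally verified only regulons that both contain
  differentially expressed genes and have a mapped TF;
* score DEG enrichment per regulon with an exact hypergeometric upper tail;
* map literature-curated acid-response genes onto the proteome at a
  stricter cutoff and assign them to regulons;
* compare the computational and literature-supported regulon sets
  (false-positive fraction, insignificant-but-supported fraction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom

from .config import PipelineConfig
from .core_io import TFBSLibraryEntry, ValidationError
from .motif_clustering import Regulon, motif_similarity

logger = logging.getLogger(__name__)

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Karlin-Altschul parameters for gapped BLOSUM62, gap open 11 / extend 1
# (the standard published values used by protein BLAST).
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class TFBSMatch:
    regulon_id: int
    query_motif_id: str
    library_motif_id: str
    tf_name: str
    organism: str
    similarity: float
    e_value: float


@dataclass(frozen=True)
class TFMapping:
    template_tf: str
    target_gene: str
    score_bits: float
    e_value: float


@dataclass
class AnnotatedRegulon:
    regulon: Regulon
    deg_genes: frozenset[str] = frozenset()
    has_deg: bool = False
    tf_matches: list[TFBSMatch] = field(default_factory=list)
    mapped_tf: TFMapping | None = None
    hypergeom_p: float = 1.0
    verdict: str = "excluded"   # computationally_verified | candidate | excluded

    @property
    def regulon_id(self) -> int:
        return self.regulon.regulon_id


@dataclass
class LiteratureGene:
    template_gene: str
    template_organism: str
    functional_module: str
    mapped_locus_tags: tuple[str, ...] = ()
    regulons_hit: frozenset = frozenset()


# ---------------------------------------------------------------------------
# TFBS library matching (shuffle-null E-values)
# ---------------------------------------------------------------------------

def _shuffled_similarities(
    query_pwm: np.ndarray, target_pwm: np.ndarray,
    perms: np.ndarray, min_overlap: int,
) -> np.ndarray:
    """Similarity of each column-permuted query against the target.

    Exploits the fact that permuting query columns only permutes rows of
    the per-column term matrix C[i, j] = 1 - ||q_i - t_j|| / sqrt(2), so C
    is computed once and gathered per permutation.
    """
    wq, wt = query_pwm.shape[1], target_pwm.shape[1]
    mo = min(min_overlap, wq, wt)
    sims = np.full(perms.shape[0], -1.0)
    for target in (target_pwm, target_pwm[::-1, ::-1]):
        diff = query_pwm[:, :, None] - target[:, None, :]
        C = 1.0 - np.linalg.norm(diff, axis=0) / np.sqrt(2.0)  # wq x wt
        for o in range(-(wt - mo), wq - mo + 1):
            lo_q, hi_q = max(0, o), min(wq, o + wt)
            if hi_q - lo_q < mo:
                continue
            qi = np.arange(lo_q, hi_q)
            tj = qi - o
            vals = C[perms[:, qi], tj].mean(axis=1)
            np.maximum(sims, vals, out=sims)
    return sims


def match_tfbs(
    regulon: Regulon,
    motifs_by_id: dict,
    library: list[TFBSLibraryEntry],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> list[TFBSMatch]:
    """Matches between a regulon's motifs and the TFBS library with E < cutoff.

    The null for each (query, library entry) pair is ``shuffle_n`` column
    permutations of the query PWM: p = (1 + #null >= observed) / (N + 1),
    E = p * library size.
    """
    if not library:
        logger.warning("empty TFBS library: no matches possible")
        return []
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    N = config.shuffle_n
    matches = []
    for mid in sorted(regulon.member_motifs):
        motif = motifs_by_id[mid]
        qpwm = np.asarray(motif.pwm, dtype=float)
        w = qpwm.shape[1]
        perms = np.array([rng.permutation(w) for _ in range(N)])
        for entry in library:
            obs = motif_similarity(motif, entry, config.min_overlap).similarity
            null = _shuffled_similarities(qpwm, entry.pwm, perms, config.min_overlap)
            p = (1.0 + float((null >= obs - 1e-12).sum())) / (N + 1.0)
            e = p * len(library)
            if e < config.tfbs_evalue:
                matches.append(
                    TFBSMatch(regulon.regulon_id, mid, entry.motif_id,
                              entry.tf_name, entry.organism, obs, e)
                )
    matches.sort(key=lambda m: (m.e_value, -m.similarity))
    return matches


# ---------------------------------------------------------------------------
# Protein mapping (built-in Smith-Waterman scan + tabular adapter)
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def _check_protein(name: str, seq: str) -> None:
    bad = set(seq) - AA20
    if bad:
        raise ValidationError(f"{name}: non-standard amino acids {sorted(bad)}")


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E = K m n exp(-lambda S) with the standard gapped BLOSUM62 parameters."""
    return float(KA_K * m * n * np.exp(-KA_LAMBDA * score))


def map_tf(
    template_name: str,
    template_seq: str,
    proteome: dict[str, str],
    evalue_cutoff: float,
) -> TFMapping | None:
    """Best local-alignment hit of a template protein in the proteome.

    Returns None when the proteome is empty or no hit clears the cutoff.
    """
    if not proteome:
        return None
    _check_protein(template_name, template_seq)
    aligner = _aligner()
    n_total = sum(len(s) for s in proteome.values())
    best_gene, best_score = None, -np.inf
    for gene, seq in sorted(proteome.items()):
        _check_protein(gene, seq)
        score = float(aligner.score(template_seq, seq))
        if score > best_score:
            best_gene, best_score = gene, score
    e = karlin_altschul_evalue(best_score, len(template_seq), n_total)
    if e >= evalue_cutoff:
        return None
    bits = (KA_LAMBDA * best_score - np.log(KA_K)) / np.log(2.0)
    return TFMapping(template_name, best_gene, float(bits), e)


def read_tabular_alignments(path: str | Path) -> dict[str, TFMapping]:
    """Adapter for 12-column tabular alignment output (qseqid sseqid pident
    length mismatch gapopen qstart qend sstart send evalue bitscore):
    best hit (lowest E, then highest bit score) per query."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    best: dict[str, TFMapping] = {}
    for row in df.sort_values(["qseqid", "evalue", "bitscore"],
                              ascending=[True, True, False]).itertuples():
        if row.qseqid not in best:
            best[row.qseqid] = TFMapping(
                str(row.qseqid), str(row.sseqid),
                float(row.bitscore), float(row.evalue),
            )
    return best


# ---------------------------------------------------------------------------
# DEG filtering and enrichment
# ---------------------------------------------------------------------------

def hypergeom_test(n: int, k: int, N: int, K: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked,
    n drawn), computed exactly."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def filter_regulons(
    annotated: list[AnnotatedRegulon],
    deg_set: set[str],
    universe: set[str] | None = None,
    universe_degs: set[str] | None = None,
) -> dict:
    """Apply the DEG/TF sieve and set verdicts in place.

    A regulon is computationally verified iff it contains at least one DEG
    and has a mapped TF; TFBS-matched regulons failing that are candidates;
    regulons with no TFBS match are excluded. When a gene universe is
    given, DEG enrichment p-values are filled in. Returns the stage counts
    (TFBS-matched -> DEG-containing -> TF-mapped -> verified).
    """
    for ar in annotated:
        genes = ar.regulon.gene_ids
        ar.deg_genes = frozenset(genes & deg_set)
        ar.has_deg = bool(ar.deg_genes)
        if universe:
            K = len((universe_degs if universe_degs is not None else deg_set) & universe)
            n = len(genes & universe)
            k = len(ar.deg_genes & universe)
            ar.hypergeom_p = hypergeom_test(n, k, len(universe), K) if n else 1.0
        if not ar.tf_matches:
            ar.verdict = "excluded"
        elif ar.has_deg and ar.mapped_tf is not None:
            ar.verdict = "computationally_verified"
        else:
            ar.verdict = "candidate"
    sig = [ar for ar in annotated if ar.tf_matches]
    counts = {
        "total": len(annotated),
        "tfbs_matched": len(sig),
        "deg_containing": sum(1 for ar in sig if ar.has_deg),
        "tf_mapped": sum(1 for ar in sig if ar.mapped_tf is not None),
        "verified": sum(1 for ar in annotated if ar.verdict == "computationally_verified"),
    }
    logger.info("regulon sieve: %s", counts)
    return counts


# ---------------------------------------------------------------------------
# Literature mapping and set comparison
# ---------------------------------------------------------------------------

def map_literature_genes(
    templates: list[tuple[LiteratureGene, str]],
    proteome: dict[str, str],
    regulons: list[Regulon],
    evalue_cutoff: float,
) -> list[LiteratureGene]:
    """Map (literature gene, protein sequence) templates onto the proteome
    and assign mapped locus tags to the regulons containing them."""
    out = []
    for lit, seq in templates:
        mapping = map_tf(lit.template_gene, seq, proteome, evalue_cutoff)
        tags = (mapping.target_gene,) if mapping else ()
        hits = frozenset(
            r.regulon_id for r in regulons if set(tags) & set(r.gene_ids)
        )
        out.append(
            LiteratureGene(lit.template_gene, lit.template_organism,
                           lit.functional_module, tags, hits)
        )
    return out


def compare_regulon_sets(
    computational: set,
    literature: set,
    all_regulons: set,
    significant: set,
) -> dict:
    """False-positive and insignificant-but-supported fractions.

    FP fraction: computationally verified regulons without literature
    support, over all computationally verified. Insignificant-but-supported
    fraction: literature-supported regulons among those that never matched
    a known TFBS, over all such insignificant regulons.
    """
    if not computational <= all_regulons or not literature <= all_regulons:
        raise ValueError("regulon sets must be subsets of the full regulon set")
    fp_ids = sorted(computational - literature)
    insignificant = all_regulons - significant
    supported_insig = sorted(literature & insignificant)
    return {
        "fp_fraction": (len(fp_ids) / len(computational)) if computational else None,
        "fp_ids": fp_ids,
        "n_computational": len(computational),
        "insignificant_supported_fraction": (
            len(supported_insig) / len(insignificant) if insignificant else None
        ),
        "insignificant_supported_ids": supported_insig,
        "n_insignificant": len(insignificant),
    }


# ---------------------------------------------------------------------------
# Packaged annotation tables (L. lactis MG1363 acid-stress study)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("regulonkit").joinpath("data", name)

def load_regulon_tf_table() -> pd.DataFrame:
    """Curated table of TFBS-matched regulons for the L. lactis MG1363
    acid-stress study: operon counts, DEG status, template TF, mapped TF."""
    with resources.as_file(_data_path("regulon_tf_table.tsv")) as p:
        # keep_default_na=False: "N/A" is a meaningful label (no TF hit)
        return pd.read_csv(p, sep="\t", dtype={"regulon_id": int},
                           keep_default_na=False)


def load_literature_gene_table() -> pd.DataFrame:
    """Curated literature-supported acid-response genes mapped to MG1363,
    with functional modules and the regulons their orthologs fall in."""
    with resources.as_file(_data_path("literature_gene_table.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    return df


def load_network_curation() -> pd.DataFrame:
    """Curated non-computational network elements (proton sensor, global
    initiator TF, transmembrane proteins) with uncertain-edge typing."""
    with resources.as_file(_data_path("network_curation.tsv")) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def regulon_name_to_ids(tf_table: pd.DataFrame) -> dict[str, set[int]]:
    """Map regulon display names (mapped TF names, template names for
    unmapped rows, Regulon<N>) to numeric regulon ids.

    A TF name that tags several regulons (e.g. a TF hitting both a
    DEG-containing and a DEG-free regulon) resolves to the DEG-containing
    representatives only, matching the convention of naming the retained
    regulon after its TF.
    """
    names: dict[str, set[int]] = {}
    for name_col in ("mapped_tf", "tf_template"):
        groups: dict[str, list] = {}
        for row in tf_table.itertuples():
            name = str(getattr(row, name_col))
            if name == "N/A":
                continue
            groups.setdefault(name, []).append((int(row.regulon_id), row.deg == "Y"))
        for name, rows in groups.items():
            with_deg = {rid for rid, deg in rows if deg}
            names.setdefault(name, set()).update(
                with_deg or {rid for rid, _ in rows}
            )
    for row in tf_table.itertuples():
        names.setdefault(f"Regulon{int(row.regulon_id)}", set()).add(int(row.regulon_id))
    return names


def annotate_from_tf_table(tf_table: pd.DataFrame) -> list[AnnotatedRegulon]:
    """Build annotated regulons from the curated TF table (every row is
    TFBS-matched by construction; gene sets are not materialized)."""
    out = []
    for row in tf_table.itertuples():
        rid = int(row.regulon_id)
        reg = Regulon(rid, frozenset(), frozenset(), frozenset(), frozenset(),
                      "highly_reliable")
        match = TFBSMatch(rid, f"R{rid}_m1", f"lib_{row.tf_template}",
                          str(row.tf_template), "", 1.0, 0.0)
        mapped = None
        if row.mapped_tf != "N/A":
            mapped = TFMapping(str(row.tf_template), str(row.mapped_locus), 0.0, 0.0)
        ar = AnnotatedRegulon(regulon=reg, has_deg=(row.deg == "Y"),
                              tf_matches=[match], mapped_tf=mapped)
        ar.verdict = ("computationally_verified"
                      if ar.has_deg and mapped is not None else "candidate")
        out.append(ar)
    return out


def literature_genes_from_table(table: pd.DataFrame) -> list[LiteratureGene]:
    name_map_needed = []
    for row in table.itertuples():
        regs = frozenset(r for r in str(row.regulons).split(";") if r)
        name_map_needed.append(
            LiteratureGene(str(row.template_gene), str(row.template_organism),
                           str(row.functional_module), (str(row.mapped_locus),), regs)
        )
    return name_map_needed


def write_matches_tsv(matches: list[TFBSMatch], path: str | Path) -> None:
    pd.DataFrame([m.__dict__ for m in matches]).to_csv(path, sep="\t", index=False)


def write_verdicts_tsv(annotated: list[AnnotatedRegulon], path: str | Path) -> None:
    rows = []
    for ar in annotated:
        rows.append({
            "regulon_id": ar.regulon_id,
            "tier": ar.regulon.tier,
            "n_operons": len(ar.regulon.operon_ids),
            "n_genes": len(ar.regulon.gene_ids),
            "n_degs": len(ar.deg_genes),
            "has_deg": ar.has_deg,
            "mapped_tf": ar.mapped_tf.target_gene if ar.mapped_tf else "N/A",
            "hypergeom_p": ar.hypergeom_p,
            "verdict": ar.verdict,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
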