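"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the structure of a bacterial acid-stress study:
a circular genome with a chosen GC content, non-overlapping operons with
intergenic room for promoter extraction, regulon-structured expression
(a shared latent profile per regulon and replicate pair, plus per-gene
noise, with a treatment shift for differentially expressed regulons), and
planted binding-site motifs in member promoters. Everything is
deterministic given the scenario seed, and the emitted files use exactly
the formats the readers consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    BASES, ExpressionMatrix, Gene, GenomeRecord, Operon, TFBSLibraryEntry,
    reverse_complement, write_expression, write_fasta, write_motifs_meme,
    write_operons,
)

GENE_LEN_RANGE = (120, 180)
INTRA_OPERON_GAP = 20
MIN_INTERGENIC_GAP = 400  # leaves the 300 bp promoter window intergenic


@dataclass
class SyntheticScenario:
    """Study conditions for the generator (defaults are the conditions the
    package's own validation runs use)."""

    rng_seed: int = 0
    genome_length: int = 200_000
    gc_content: float = 0.35
    n_regulons: int = 10
    operons_per_regulon: int = 20
    background_operons: int = 100
    planted_pwm_ic: float = 1.5     # bits per column
    site_rate: float = 0.9          # fraction of member promoters with a site
    n_pairs: int = 8
    de_effect: float = 2.0          # log-ratio treatment shift
    noise_sd: float = 0.5
    de_regulon_fraction: float = 0.5
    motif_width: int = 12
    profile_scale: float = 15.0     # regulon latent-profile amplitude
    n_decoy_motifs: int = 10
    genes_per_operon_max: int = 2

    def __post_init__(self):
        if min(self.genome_length, self.n_regulons, self.operons_per_regulon,
               self.n_pairs) < 1 or self.background_operons < 0:
            raise ValueError("all counts must be positive")
        if not 0 < self.site_rate <= 1:
            raise ValueError("site_rate must be in (0, 1]")
        if not 0 <= self.de_regulon_fraction <= 1:
            raise ValueError("de_regulon_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted: per-regulon PWM, membership, sites, DE flag; the
    true per-gene direction."""

    regulons: list[dict]
    gene_direction: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regulons": [
                {**r, "pwm": np.asarray(r["pwm"]).tolist()} for r in self.regulons
            ],
            "gene_direction": self.gene_direction,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        for r in payload["regulons"]:
            r["pwm"] = np.asarray(r["pwm"], dtype=float)
            r["member_operons"] = list(r["member_operons"])
        return cls(payload["regulons"], payload["gene_direction"])


@dataclass
class SyntheticDataset:
    genome: GenomeRecord
    operons: list[Operon]
    expression: ExpressionMatrix
    tfbs_library: list[TFBSLibraryEntry]
    literature: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "operons": outdir / "operons.tsv",
            "expression": outdir / "expression.tsv",
            "design": outdir / "design.tsv",
            "tfbs_library": outdir / "tfbs_library.meme",
            "literature": outdir / "literature.tsv",
            "truth": outdir / "ground_truth.json",
        }
        write_fasta({self.genome.id: self.genome.sequence}, paths["genome"])
        write_operons(self.operons, paths["operons"])
        write_expression(self.expression, paths["expression"], paths["design"])
        write_motifs_meme(self.tfbs_library, paths["tfbs_library"])
        self.literature.to_csv(paths["literature"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        return paths


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _column_for_ic(ic_bits: float, consensus: int) -> np.ndarray:
    """Column with the consensus base weighted to hit a target per-column IC
    (uniform background), solved by bisection on the dominant probability."""
    target_h = 2.0 - ic_bits
    lo, hi = 0.25, 1.0 - 1e-9
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        col = np.full(4, (1.0 - mid) / 3.0)
        col[consensus] = mid
        if _entropy_bits(col) > target_h:
            lo = mid
        else:
            hi = mid
    col = np.full(4, (1.0 - hi) / 3.0)
    col[consensus] = hi
    return col


def sample_planted_pwm(rng: np.random.Generator, width: int, ic_bits: float) -> np.ndarray:
    """Width-w PWM with per-column IC near the target: a Dirichlet draw
    sharpened by replacing the dominant mass with the IC-solving weight."""
    pwm = np.empty((4, width))
    for c in range(width):
        raw = rng.dirichlet(np.ones(4))
        pwm[:, c] = _column_for_ic(ic_bits, int(raw.argmax()))
    return pwm


def _sample_site(rng: np.random.Generator, pwm: np.ndarray) -> str:
    return "".join(
        BASES[rng.choice(4, p=pwm[:, c])] for c in range(pwm.shape[1])
    )


def generate(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate the full ground-truthed input set for one scenario."""
    rng = np.random.default_rng(scenario.rng_seed)
    sc = scenario
    n_operons = sc.n_regulons * sc.operons_per_regulon + sc.background_operons

    # --- operon layout -------------------------------------------------
    genes_per_operon = rng.integers(1, sc.genes_per_operon_max + 1, size=n_operons)
    gene_lengths = [
        rng.integers(GENE_LEN_RANGE[0], GENE_LEN_RANGE[1] + 1, size=k)
        for k in genes_per_operon
    ]
    spans = np.array([
        int(gl.sum()) + INTRA_OPERON_GAP * (len(gl) - 1) for gl in gene_lengths
    ])
    needed = int(spans.sum()) + MIN_INTERGENIC_GAP * n_operons
    if needed > sc.genome_length:
        raise ValueError(
            f"{n_operons} operons need >= {needed} bp; genome_length "
            f"{sc.genome_length} too small - increase it or reduce operon counts"
        )
    slack = sc.genome_length - needed
    extra = rng.multinomial(slack, np.ones(n_operons) / n_operons)

    # --- genome --------------------------------------------------------
    p_bg = np.array([
        (1 - sc.gc_content) / 2, sc.gc_content / 2,
        sc.gc_content / 2, (1 - sc.gc_content) / 2,
    ])
    genome_arr = rng.choice(4, size=sc.genome_length, p=p_bg)

    operons: list[Operon] = []
    pos = 0
    gene_counter = 0
    starts = []
    for i in range(n_operons):
        pos += MIN_INTERGENIC_GAP + int(extra[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes = []
        gpos = pos
        for gl in gene_lengths[i]:
            gene_counter += 1
            genes.append(Gene(f"g{gene_counter:04d}", gpos + 1, gpos + int(gl), strand))
            gpos += int(gl) + INTRA_OPERON_GAP
        operons.append(Operon(f"op{i + 1:04d}", tuple(genes), strand))
        starts.append(pos)
        pos += int(spans[i])

    # --- planted regulons and sites ------------------------------------
    order = rng.permutation(n_operons)
    truth_regulons = []
    sites_to_plant: list[tuple[int, str]] = []  # (genome position, site string on +)
    occupied: set[int] = set()  # genome positions already carrying a planted site
    de_flags = []
    n_de = int(round(sc.de_regulon_fraction * sc.n_regulons))
    for r in range(sc.n_regulons):
        members = sorted(order[r * sc.operons_per_regulon:(r + 1) * sc.operons_per_regulon])
        pwm = sample_planted_pwm(rng, sc.motif_width, sc.planted_pwm_ic)
        de = r < n_de
        de_flags.append(de)
        sites = []
        for mi in members:
            if rng.random() > sc.site_rate:
                continue
            op = operons[mi]
            site = _sample_site(rng, pwm)
            first = op.first_transcribed_gene
            placed = False
            for _attempt in range(10):  # avoid collisions in shared intergenic DNA
                offset = int(rng.integers(0, 300 - sc.motif_width + 1))
                site_strand = "fwd" if rng.random() < 0.5 else "rc"
                if op.strand == "+":
                    prom_start = first.start - 1 - 300  # 0-based promoter start
                    gpos = prom_start + offset
                    planted = site if site_strand == "fwd" else reverse_complement(site)
                else:
                    # promoter read 5'->3' on -; offset o maps to + positions
                    # end+300-o-w .. end+300-o-1
                    gpos = first.end + 300 - offset - sc.motif_width
                    planted = reverse_complement(site) if site_strand == "fwd" else site
                span = {p % sc.genome_length
                        for p in range(gpos, gpos + sc.motif_width)}
                if not span & occupied:
                    occupied.update(span)
                    placed = True
                    break
            if not placed:
                continue
            sites_to_plant.append((gpos, planted))
            sites.append({"operon_id": op.operon_id, "offset": offset,
                          "strand": site_strand})
        truth_regulons.append({
            "regulon_id": f"planted{r + 1:02d}",
            "pwm": pwm,
            "consensus": "".join(BASES[b] for b in pwm.argmax(axis=0)),
            "member_operons": [operons[mi].operon_id for mi in members],
            "tf_name": f"synTF{r + 1:02d}",
            "de": de,
            "sites": sites,
        })

    for gpos, site in sorted(sites_to_plant):
        idx = [BASES.index(b) for b in site]
        positions = (np.arange(gpos, gpos + len(idx)) % sc.genome_length)
        genome_arr[positions] = idx  # modular: a promoter may wrap the origin
    genome = GenomeRecord(
        id="synthetic_chromosome",
        sequence="".join(BASES[b] for b in genome_arr),
        circular=True,
    )

    # --- expression ----------------------------------------------------
    n_samples = 2 * sc.n_pairs
    sample_ids = [f"ctrl_{i + 1}" for i in range(sc.n_pairs)] + \
                 [f"trt_{i + 1}" for i in range(sc.n_pairs)]
    design = pd.DataFrame({
        "sample": sample_ids,
        "condition": ["control"] * sc.n_pairs + ["treatment"] * sc.n_pairs,
        "pair": list(range(1, sc.n_pairs + 1)) * 2,
    })
    member_of = {}
    for r, tr in enumerate(truth_regulons):
        for oid in tr["member_operons"]:
            member_of[oid] = r
    latent = rng.normal(0.0, sc.profile_scale, size=(sc.n_regulons, sc.n_pairs))
    values = {}
    gene_direction = {}
    for i, op in enumerate(operons):
        r = member_of.get(op.operon_id)
        if r is None:
            base = rng.normal(0.0, sc.profile_scale, size=sc.n_pairs)
            de = False
        else:
            base = latent[r]
            de = de_flags[r]
        for g in op.genes:
            noise = rng.normal(0.0, sc.noise_sd, size=n_samples)
            row = np.concatenate([base, base]) + noise
            if de:
                row[sc.n_pairs:] += sc.de_effect
            values[g.locus_tag] = row
            gene_direction[g.locus_tag] = (
                "up" if de and sc.de_effect > 0
                else "down" if de else "none"
            )
    expr = ExpressionMatrix(
        values=pd.DataFrame.from_dict(values, orient="index", columns=sample_ids),
        design=design,
    )

    # --- TFBS library: planted PWMs (named TFs) plus decoys -------------
    library = [
        TFBSLibraryEntry(f"lib_{tr['tf_name']}", tr["tf_name"], "synthetic",
                         np.asarray(tr["pwm"]))
        for tr in truth_regulons
    ]
    for d in range(sc.n_decoy_motifs):
        library.append(
            TFBSLibraryEntry(
                f"lib_decoy{d + 1:02d}", f"decoyTF{d + 1:02d}", "synthetic",
                sample_planted_pwm(rng, sc.motif_width, sc.planted_pwm_ic),
            )
        )

    modules = ["LDH", "GAD", "ADI pathway", "F0/F1ATPase", "Acid response",
               "Protein repair and protease", "Envelope alterations",
               "DNA repair", "Urea degradation"]
    lit_rows = []
    for r, tr in enumerate(truth_regulons):
        first_op = tr["member_operons"][0]
        first_gene = next(op for op in operons
                          if op.operon_id == first_op).genes[0].locus_tag
        lit_rows.append({
            "template_gene": f"lit_{tr['tf_name']}",
            "template_organism": "synthetic",
            "functional_module": modules[r % len(modules)],
            "mapped_locus": first_gene,
            "regulons": tr["regulon_id"],
        })
    literature = pd.DataFrame(lit_rows)

    truth = GroundTruth(truth_regulons, gene_direction)
    return SyntheticDataset(genome, operons, expr, library, literature, truth)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def consensus_hamming(found: str, planted: str, max_shift: int = 2) -> int:
    """Smallest mismatch count between two consensus words over shifts up to
    ``max_shift`` columns and both orientations; overhanging columns count
    as mismatches."""
    best = len(planted)
    for cand in (found, reverse_complement(found)):
        for shift in range(-max_shift, max_shift + 1):
            mism = abs(shift)
            for i in range(len(planted)):
                j = i + shift
                if 0 <= j < len(cand):
                    mism += cand[j] != planted[i]
            best = min(best, mism)
    return best


def evaluate_recovery(truth: GroundTruth, inferred, jaccard_threshold: float = 0.5) -> dict:
    """Match each planted regulon to its best-Jaccard inferred regulon.

    ``inferred`` is a sequence of Regulon objects (or anything with
    ``operon_ids`` and optionally ``member_motifs``/consensus info).
    """
    per = []
    for tr in truth.regulons:
        planted_ops = set(tr["member_operons"])
        best_j, best_reg = 0.0, None
        for reg in inferred:
            j = _jaccard(planted_ops, set(reg.operon_ids))
            if j > best_j:
                best_j, best_reg = j, reg
        per.append({
            "planted": tr["regulon_id"],
            "jaccard": best_j,
            "matched": getattr(best_reg, "regulon_id", None),
        })
    recovered = sum(1 for p in per if p["jaccard"] >= jaccard_threshold)
    return {
        "per_regulon": per,
        "recovered_fraction": recovered / len(truth.regulons) if truth.regulons else 0.0,
        "n_planted": len(truth.regulons),
        "n_inferred": len(list(inferred)),
    }
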