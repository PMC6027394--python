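"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: 1-based inclusive on disk (GenBank/DOOR2 style),
0-based half-open in memory. :func:`to_internal` / :func:`to_disk` convert
and are mutually inverse.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed records violate a domain invariant."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_disk(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeRecord:
    """A single (by default circular) bacterial replicon."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValidationError("genome sequence must be non-empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"illegal character {self.sequence[pos]!r} at position {pos + 1}"
            )
        n_frac = self.sequence.count("N") / len(self.sequence)
        if n_frac == 1.0:
            raise ValidationError("genome sequence is entirely N")
        if n_frac > 0:
            logger.info("genome %s: N fraction %.4f", self.id, n_frac)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene located on the genome (1-based inclusive coords)."""

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str | None = None

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"gene {self.locus_tag}: require 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.locus_tag}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class Operon:
    """An ordered run of same-strand genes transcribed from one promoter."""

    operon_id: str
    genes: tuple[Gene, ...]
    strand: str

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"operon {self.operon_id}: no genes")
        strands = {g.strand for g in self.genes}
        if strands != {self.strand}:
            raise ValidationError(
                f"operon {self.operon_id}: mixed or mismatched strands {strands}"
            )
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValidationError(f"operon {self.operon_id}: genes not sorted by start")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.locus_tag for g in self.genes)

    @property
    def first_transcribed_gene(self) -> Gene:
        """Leftmost gene on +, rightmost on - (the gene whose start is the TLS)."""
        return self.genes[0] if self.strand == "+" else self.genes[-1]


@dataclass
class ExpressionMatrix:
    """Log-ratio expression values, genes x samples, with a paired design.

    ``design`` has one row per sample with columns ``sample``, ``condition``
    (control/treatment) and ``pair`` (replicate pairing index).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    flagged_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite expression values")
        required = {"sample", "condition", "pair"}
        if not required <= set(self.design.columns):
            raise ValidationError(f"design must have columns {sorted(required)}")
        bad_cond = set(self.design["condition"]) - {"control", "treatment"}
        if bad_cond:
            raise ValidationError(f"unknown condition labels {bad_cond}")
        for cond, sub in self.design.groupby("condition"):
            if sub["pair"].duplicated().any():
                raise ValidationError(f"pair index repeated within condition {cond}")
        ctrl = set(self.design.loc[self.design.condition == "control", "pair"])
        trt = set(self.design.loc[self.design.condition == "treatment", "pair"])
        if ctrl != trt:
            raise ValidationError(
                f"unpaired design: control pairs {sorted(ctrl)} vs "
                f"treatment pairs {sorted(trt)}"
            )
        missing = set(self.design["sample"]) - set(self.values.columns)
        if missing:
            raise ValidationError(f"design samples absent from matrix: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pairs(self) -> int:
        return self.design["pair"].nunique()

    def paired_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(control, treatment) gene x pair matrices, pair-aligned."""
        d = self.design
        pairs = sorted(d["pair"].unique())
        ctrl_cols = [
            d.loc[(d.condition == "control") & (d.pair == p), "sample"].iloc[0]
            for p in pairs
        ]
        trt_cols = [
            d.loc[(d.condition == "treatment") & (d.pair == p), "sample"].iloc[0]
            for p in pairs
        ]
        return (
            self.values[ctrl_cols].to_numpy(dtype=float),
            self.values[trt_cols].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class TFBSLibraryEntry:
    """A known transcription-factor binding-site model from a public library."""

    motif_id: str
    tf_name: str
    organism: str
    pwm: np.ndarray  # 4 x width, column-stochastic, rows A,C,G,T

    def __post_init__(self):
        pwm = np.asarray(self.pwm, dtype=float)
        object.__setattr__(self, "pwm", pwm)
        if pwm.shape[0] != 4 or pwm.shape[1] < 4:
            raise ValidationError(
                f"library motif {self.motif_id}: need 4 x width>=4 PWM, got {pwm.shape}"
            )
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValidationError(f"library motif {self.motif_id}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genome(path: str | Path, circular: bool = True) -> GenomeRecord:
    """Read the first record of a FASTA file as a genome.

    Multi-record files use the first record (plasmids etc. are out of scope)
    and log a warning. The sequence is uppercased.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if len(records) > 1:
        logger.warning(
            "%s: %d records, using first (%s)", path, len(records), records[0].id
        )
    rec = records[0]
    return GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


_OPERON_COLUMNS = ["operon_id", "locus_tag", "start", "end", "strand"]


def read_operons(path: str | Path, genome: GenomeRecord) -> list[Operon]:
    """Read a DOOR2-style operon table (TSV) and validate against the genome."""
    df = pd.read_csv(path, sep="\t", dtype={"operon_id": str, "locus_tag": str})
    missing = set(_OPERON_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["locus_tag"].duplicated().any():
        dup = df.loc[df["locus_tag"].duplicated(), "locus_tag"].iloc[0]
        raise ValidationError(f"duplicate locus_tag {dup}")
    operons = []
    for oid, sub in df.groupby("operon_id", sort=True):
        genes = []
        for row in sub.itertuples():
            if not 1 <= row.start <= row.end <= len(genome):
                raise ValidationError(
                    f"gene {row.locus_tag}: coordinates [{row.start}, {row.end}] "
                    f"out of range for genome of length {len(genome)}"
                )
            product = getattr(row, "product", None)
            genes.append(
                Gene(row.locus_tag, int(row.start), int(row.end), row.strand,
                     product if isinstance(product, str) else None)
            )
        strands = {g.strand for g in genes}
        if len(strands) > 1:
            raise ValidationError(f"operon {oid}: mixed strands")
        genes.sort(key=lambda g: g.start)
        operons.append(Operon(str(oid), tuple(genes), strands.pop()))
    return operons


def write_operons(operons: Sequence[Operon], path: str | Path) -> None:
    rows = [
        {"operon_id": op.operon_id, "locus_tag": g.locus_tag,
         "start": g.start, "end": g.end, "strand": g.strand}
        for op in operons for g in op.genes
    ]
    pd.DataFrame(rows, columns=_OPERON_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression(
    path: str | Path,
    design_path: str | Path,
    known_genes: set[str] | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples log-ratio TSV plus a sample design TSV.

    ``known_genes`` (e.g. the operon table's locus tags) lets the reader flag
    matrix genes absent from the annotation; they are retained, not dropped.
    """
    try:
        values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    design = pd.read_csv(design_path, sep="\t")
    unmatched = set(design.get("sample", [])) - set(values.columns)
    if unmatched:
        raise ValidationError(f"design samples not in matrix: {sorted(unmatched)}")
    flagged = frozenset()
    if known_genes is not None:
        flagged = frozenset(set(values.index) - set(known_genes))
        if flagged:
            logger.info("%d expression genes absent from operon table", len(flagged))
    return ExpressionMatrix(values=values, design=design, flagged_genes=flagged)


def write_expression(expr: ExpressionMatrix, path: str | Path, design_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    expr.design.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME-minimal motif format
# ---------------------------------------------------------------------------
# A deliberately small dialect: version line, ALPHABET, strands, background,
# then one "MOTIF <id> [alt]" block per motif with a letter-probability
# matrix. Biopython's minimal parser round-trips probabilities through
# integer site counts, which breaks the identity contract, so the dialect is
# parsed directly here.

def write_motifs_meme(
    motifs: Sequence,
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write motifs (anything with .pwm 4xw and ids) as MEME-minimal text.

    Accepts the pipeline's Motif objects, TFBSLibraryEntry, or (id, pwm)
    pairs. Refuses PWMs whose columns do not sum to 1 within 1e-6.
    """
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, background)), "",
    ]
    for m in motifs:
        if isinstance(m, tuple):
            mid, pwm, alt = m[0], np.asarray(m[1], float), ""
        else:
            mid = getattr(m, "motif_id")
            pwm = np.asarray(getattr(m, "pwm"), float)
            alt = getattr(m, "tf_name", "") or ""
            organism = getattr(m, "organism", "")
            if alt and organism:
                alt = f"{alt}/{organism}"
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
            raise ValidationError(f"motif {mid}: PWM columns do not sum to 1")
        nsites = len(getattr(m, "sites", []) or []) or 20
        evalue = getattr(m, "adjusted_p", None)
        lines.append(f"MOTIF {mid} {alt}".rstrip())
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.shape[1]} "
            f"nsites= {nsites} E= {evalue if evalue is not None else 0:g}"
        )
        for col in pwm.T:
            lines.append(" ".join(f"{p:.8f}" for p in col))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)(?:\s+(\S+))?")
_MATRIX_RE = re.compile(r"letter-probability matrix:.*w=\s*(\d+)")


def read_motifs_meme(path: str | Path) -> list[TFBSLibraryEntry]:
    """Read MEME-minimal motifs as library entries (organism from alt name
    when formatted ``tfname/organism``, else empty).

    Count matrices (columns summing to n > 1) are normalized to
    probabilities, so JASPAR-style counts converted to this dialect load
    cleanly.
    """
    lines = Path(path).read_text().splitlines()
    entries: list[TFBSLibraryEntry] = []
    i = 0
    while i < len(lines):
        m = _MOTIF_RE.match(lines[i])
        if not m:
            i += 1
            continue
        motif_id, alt = m.group(1), m.group(2) or ""
        i += 1
        while i < len(lines) and not _MATRIX_RE.search(lines[i]):
            if _MOTIF_RE.match(lines[i]):
                raise FormatError(f"{path}: motif {motif_id} has no matrix")
            i += 1
        if i == len(lines):
            raise FormatError(f"{path}: motif {motif_id} has no matrix")
        width = int(_MATRIX_RE.search(lines[i]).group(1))
        i += 1
        cols = []
        while len(cols) < width:
            if i >= len(lines):
                raise FormatError(f"{path}: motif {motif_id}: truncated matrix")
            row = lines[i].split()
            if len(row) == 4:
                cols.append([float(x) for x in row])
            elif lines[i].strip():
                raise FormatError(f"{path}: motif {motif_id}: bad matrix row {lines[i]!r}")
            i += 1
        pwm = np.array(cols, dtype=float).T
        sums = pwm.sum(axis=0)
        if (sums <= 0).any():
            raise FormatError(f"{path}: motif {motif_id}: zero column")
        pwm = pwm / sums  # normalizes count matrices too
        tf_name, _, organism = alt.partition("/")
        entries.append(TFBSLibraryEntry(motif_id, tf_name or motif_id, organism, pwm))
    return entries


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id, uppercased."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(records: dict[str, str] | Sequence[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    if isinstance(records, dict):
        records = list(records.items())
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
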