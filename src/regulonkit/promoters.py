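"""Strand-aware extraction of fixed-length operon promoters on a circular genome.

The promoter of an operon is the ``U`` bases immediately upstream of the
translation start of its first transcribed gene (leftmost gene on the +
strand, rightmost on -), reverse-complemented for - strand operons so the
returned string always reads 5'->3' with its 3' end abutting the start codon.
On a circular genome the window may wrap the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .core_io import GenomeRecord, Operon, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterSeq:
    operon_id: str
    sequence: str
    genome_interval: tuple[int, int]  # 0-based half-open on the + strand; end may exceed L if wrapping
    strand: str
    wraps_origin: bool = False
    truncated: bool = False


def extract_promoter(operon: Operon, genome: GenomeRecord, upstream: int) -> PromoterSeq:
    """Extract the ``upstream``-bp promoter of one operon.

    Raises ``ValueError`` when ``upstream`` exceeds the genome length. On a
    linear genome with insufficient upstream sequence the promoter is
    truncated and flagged.
    """
    L = len(genome)
    if upstream < 1:
        raise ValueError("upstream length must be >= 1")
    if upstream > L:
        raise ValueError(f"upstream length {upstream} exceeds genome length {L}")
    first = operon.first_transcribed_gene
    if operon.strand == "+":
        end0 = first.start - 1          # half-open end = base before the start codon
        start0 = end0 - upstream
    else:
        start0 = first.end              # base after the gene end, 0-based
        end0 = start0 + upstream

    out_of_range = start0 < 0 or end0 > L
    truncated = False
    if out_of_range and not genome.circular:
        start0c, end0c = max(start0, 0), min(end0, L)
        seq = genome.sequence[start0c:end0c]
        truncated = True
        logger.warning(
            "operon %s: promoter truncated to %d bp (linear genome)",
            operon.operon_id, len(seq),
        )
        start0, end0 = start0c, end0c
        wraps = False
    else:
        # Index into the doubled genome string: any window of length <= L
        # on the circle is a substring of genome+genome.
        s = start0 % L
        seq = (genome.sequence * 2)[s:s + upstream]
        start0, end0 = s, s + upstream
        wraps = end0 > L
    if operon.strand == "-":
        seq = reverse_complement(seq)
    return PromoterSeq(
        operon_id=operon.operon_id,
        sequence=seq,
        genome_interval=(start0, end0),
        strand=operon.strand,
        wraps_origin=wraps,
        truncated=truncated,
    )


def extract_all_promoters(
    operons: Sequence[Operon], genome: GenomeRecord, upstream: int
) -> list[PromoterSeq]:
    """One promoter per operon, input order preserved.

    Operon ids must be unique. Duplicate genomic intervals (divergent
    operons sharing upstream DNA) are legitimate and only logged.
    """
    ids = [op.operon_id for op in operons]
    if len(set(ids)) != len(ids):
        raise ValueError("operon ids not unique")
    proms = [extract_promoter(op, genome, upstream) for op in operons]
    seen: dict[tuple[int, int], str] = {}
    for p in proms:
        if p.genome_interval in seen:
            logger.info(
                "operons %s and %s share promoter interval %s",
                seen[p.genome_interval], p.operon_id, p.genome_interval,
            )
        seen[p.genome_interval] = p.operon_id
    return proms


def write_promoter_intervals(promoters: Sequence[PromoterSeq], path: str | Path) -> None:
    """BED-like TSV of promoter intervals (1-based inclusive on disk)."""
    lines = ["operon_id\tstart\tend\tstrand\twraps_origin"]
    for p in promoters:
        s0, e0 = p.genome_interval
        lines.append(f"{p.operon_id}\t{s0 + 1}\t{e0}\t{p.strand}\t{int(p.wraps_origin)}")
    Path(path).write_text("\n".join(lines) + "\n")
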