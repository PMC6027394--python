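"""End-to-end orchestration: promoters -> DEGs/CEMs -> motifs -> clustering
-> annotation -> network, with per-stage outputs and a run report.

Every stochastic stage draws from the single ``rng_seed`` in the config, so
a rerun with the same inputs and config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import core_io, expression as expr_mod, grn as grn_mod
from . import motif_clustering as mc
from . import motif_discovery as md
from . import promoters as prom_mod
from .config import ConfigError, PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    counts: dict
    config: dict
    rng_seed: int
    stages: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"counts": self.counts, "config": self.config,
             "rng_seed": self.rng_seed, "stages": self.stages},
            indent=1) + "\n")

    def check_sieve(self) -> None:
        c = self.counts
        chain = [c["regulons_t1"], c["tfbs_matched"], c["deg_containing"],
                 c["verified"]]
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"sieve counts increase left to right: {chain}")


def run_all(
    config: PipelineConfig,
    genome_path: str | Path,
    operons_path: str | Path,
    expression_path: str | Path,
    design_path: str | Path,
    outdir: str | Path,
    tfbs_library_path: str | Path | None = None,
    proteome_path: str | Path | None = None,
    tf_templates_path: str | Path | None = None,
    literature_path: str | Path | None = None,
) -> RunReport:
    """Run every stage in order, writing intermediates to ``outdir``.

    Optional inputs switch on the corresponding annotation stages: a TFBS
    library enables library matching, a proteome plus TF-template FASTA
    enables TF mapping, a literature table enables literature assignment.
    Any stage failure aborts with the stage name; prior outputs remain.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    stages: list = []
    t0 = time.time()

    def stage(name):
        stages.append({"stage": name, "t": round(time.time() - t0, 3)})
        logger.info("stage: %s", name)

    try:
        stage("read_inputs")
        genome = core_io.read_genome(genome_path)
        operons = core_io.read_operons(operons_path, genome)
        operon_genes = {op.operon_id: op.gene_ids for op in operons}
        expr = core_io.read_expression(
            expression_path, design_path,
            known_genes={g for op in operons for g in op.gene_ids},
        )
        counts["operons_read"] = len(operons)
        counts["genes_read"] = sum(len(op.genes) for op in operons)
    except Exception as e:
        raise StageError("read_inputs", e) from e

    try:
        stage("promoters")
        proms = prom_mod.extract_all_promoters(operons, genome, config.upstream_length)
        prom_by_operon = {p.operon_id: p for p in proms}
        prom_mod.write_promoter_intervals(proms, outdir / "promoter_intervals.tsv")
        core_io.write_fasta([(p.operon_id, p.sequence) for p in proms],
                            outdir / "promoters.fasta")
        counts["promoters"] = len(proms)
    except Exception as e:
        raise StageError("promoters", e) from e

    try:
        stage("differential_expression")
        degs = expr_mod.call_degs(expr, config)
        expr_mod.deg_table(degs).to_csv(outdir / "deg_table.tsv", sep="\t",
                                        index=False, float_format="%.6g")
        deg_set = {d.gene_id for d in degs if d.direction != "none"}
        counts["degs_up"] = sum(1 for d in degs if d.direction == "up")
        counts["degs_down"] = sum(1 for d in degs if d.direction == "down")
    except Exception as e:
        raise StageError("differential_expression", e) from e

    try:
        stage("coexpression_modules")
        profiles = expr_mod.operon_profiles(expr, operons)
        cems, cem_log = expr_mod.build_cems(profiles, config, operon_genes)
        pd.DataFrame(
            [(c.cem_id, oid) for c in cems for oid in sorted(c.operon_ids)],
            columns=["cem_id", "operon_id"],
        ).to_csv(outdir / "cems.tsv", sep="\t", index=False)
        (outdir / "removed_clusters.log").write_text(
            json.dumps({"removed_oversize": cem_log["removed_oversize"],
                        "singletons": cem_log["singletons"]}, indent=1) + "\n")
        counts["cems_kept"] = len(cems)
        counts["cems_removed_oversize"] = len(cem_log["removed_oversize"])
        counts["cem_singletons"] = len(cem_log["singletons"])
    except Exception as e:
        raise StageError("coexpression_modules", e) from e

    try:
        stage("motif_discovery")
        background = md.BackgroundModel.from_genome(genome)
        all_motifs: list[md.Motif] = []
        cem_of_motif: dict[str, str] = {}
        for cem in cems:
            cem_proms = [prom_by_operon[oid] for oid in sorted(cem.operon_ids)]
            found = md.find_motifs(cem_proms, background, config, cem_id=cem.cem_id)
            for m in md.top_k_motifs(found, config.top_k):
                all_motifs.append(m)
                cem_of_motif[m.motif_id] = cem.cem_id
        core_io.write_motifs_meme(all_motifs, outdir / "motifs.meme",
                                  background=background.freqs)
        md.write_sites_tsv(all_motifs, outdir / "motif_sites.tsv")
        counts["motifs_found"] = len(all_motifs)
    except Exception as e:
        raise StageError("motif_discovery", e) from e

    try:
        stage("motif_clustering")
        ids = [m.motif_id for m in all_motifs]
        edges = mc.all_pairwise_edges(all_motifs, config.min_overlap)
        clusters_t1 = mc.kruskal_cluster(ids, edges, config.t1)
        clusters_t2 = mc.kruskal_cluster(ids, edges, config.t2)
        regulons = mc.assemble_regulons(clusters_t1, clusters_t2, all_motifs,
                                        operon_genes, cem_of_motif)
        mc.write_regulons_tsv(regulons, outdir / "regulons.tsv")
        mc.write_cluster_json(clusters_t1, outdir / "motif_clusters_t1.json")
        mc.write_cluster_json(clusters_t2, outdir / "motif_clusters_t2.json")
        counts["regulons_t1"] = sum(1 for r in regulons if r.tier == "highly_reliable")
        counts["regulons_t2_merges"] = sum(
            1 for r in regulons if r.tier == "relatively_reliable")
    except Exception as e:
        raise StageError("motif_clustering", e) from e

    try:
        stage("annotation")
        t1_regulons = [r for r in regulons if r.tier == "highly_reliable"]
        motifs_by_id = {m.motif_id: m for m in all_motifs}
        annotated = [ann.AnnotatedRegulon(regulon=r) for r in t1_regulons]
        library = (core_io.read_motifs_meme(tfbs_library_path)
                   if tfbs_library_path else [])
        if library:
            rng = np.random.default_rng(config.rng_seed)
            matches_all = []
            for ar in annotated:
                m = ann.match_tfbs(ar.regulon, motifs_by_id, library, config, rng)
                ar.tf_matches = m
                matches_all.extend(m)
            ann.write_matches_tsv(matches_all, outdir / "tfbs_matches.tsv")
        if proteome_path and tf_templates_path:
            proteome = core_io.read_protein_fasta(proteome_path)
            templates = core_io.read_protein_fasta(tf_templates_path)
            mapping_rows = []
            for ar in annotated:
                if not ar.tf_matches:
                    continue
                tf_name = ar.tf_matches[0].tf_name
                if tf_name in templates:
                    ar.mapped_tf = ann.map_tf(tf_name, templates[tf_name],
                                              proteome, config.tf_map_evalue)
                    if ar.mapped_tf:
                        mapping_rows.append(ar.mapped_tf.__dict__)
            pd.DataFrame(mapping_rows).to_csv(outdir / "tf_mappings.tsv",
                                              sep="\t", index=False)
        universe = {g for cem in cems for g in cem.gene_ids}
        sieve = ann.filter_regulons(annotated, deg_set, universe)
        ann.write_verdicts_tsv(annotated, outdir / "regulon_verdicts.tsv")
        counts.update({k: sieve[k] for k in
                       ("tfbs_matched", "deg_containing", "tf_mapped", "verified")})
    except Exception as e:
        raise StageError("annotation", e) from e

    try:
        stage("network")
        lit_genes: list[ann.LiteratureGene] = []
        if literature_path:
            lit_df = pd.read_csv(literature_path, sep="\t").fillna("")
            for row in lit_df.itertuples():
                tags = tuple(t for t in str(row.mapped_locus).split(";") if t)
                hits = frozenset(
                    r.regulon_id for r in t1_regulons
                    if set(tags) & set(r.gene_ids)
                )
                lit_genes.append(ann.LiteratureGene(
                    str(row.template_gene), str(row.template_organism),
                    str(row.functional_module), tags, hits))
        network = grn_mod.build_grn(annotated, lit_genes)
        grn_mod.export_network(network, outdir / "grn.json", "json")
        grn_mod.export_network(network, outdir / "grn.graphml", "graphml")
        grn_mod.export_network(network, outdir / "grn_edges.tsv", "edge-tsv")
        counts["grn_nodes"] = network.number_of_nodes()
        counts["grn_edges"] = network.number_of_edges()
    except Exception as e:
        raise StageError("network", e) from e

    report = RunReport(counts=counts, config=config.snapshot(),
                       rng_seed=config.rng_seed, stages=stages)
    report.check_sieve()
    report.to_json(outdir / "run_report.json")
    return report


def read_regulons_tsv(path: str | Path) -> list[mc.Regulon]:
    """Reload regulons.tsv (id, tier, motif and operon memberships)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        out.append(mc.Regulon(
            int(row.regulon_id),
            frozenset(str(row.motifs).split(",")) if row.motifs else frozenset(),
            frozenset(str(row.operons).split(",")) if row.operons else frozenset(),
            frozenset(), frozenset(), str(row.tier),
        ))
    return out
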