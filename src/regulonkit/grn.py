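"""Assembly and export of the typed acid-response regulatory network.

Nodes are typed (regulon, tf_gene, functional_module, gene,
transmembrane_protein, sensor) and edges are typed (regulates, contains,
maps_to, uncertain) with per-edge provenance (computational, literature,
both). Curated literature-only elements (the proton sensor, the global
initiator TF, transmembrane proteins) enter through a curation table as
``uncertain`` edges, never as computed output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .annotation import AnnotatedRegulon, LiteratureGene

NODE_TYPES = {"regulon", "tf_gene", "functional_module", "gene",
              "transmembrane_protein", "sensor"}
EDGE_TYPES = {"regulates", "contains", "maps_to", "uncertain"}
REGULATOR_TYPES = {"regulon", "tf_gene", "sensor"}


def _node_id(ntype: str, name) -> str:
    return f"{ntype}:{name}"


def resolve_literature_regulons(
    lit_genes: Sequence[LiteratureGene], name_to_ids: dict[str, set[int]]
) -> list[LiteratureGene]:
    """Replace name-based regulon references (e.g. a TF name covering two
    regulons) with numeric regulon ids."""
    out = []
    for lg in lit_genes:
        ids: set[int] = set()
        for r in lg.regulons_hit:
            if isinstance(r, int):
                ids.add(r)
            elif str(r) in name_to_ids:
                ids.update(name_to_ids[str(r)])
            elif str(r).startswith("Regulon"):
                ids.add(int(str(r)[len("Regulon"):]))
        out.append(LiteratureGene(lg.template_gene, lg.template_organism,
                                  lg.functional_module, lg.mapped_locus_tags,
                                  frozenset(ids)))
    return out


def _add_edge(g: nx.DiGraph, u: str, v: str, etype: str, provenance: str) -> None:
    if u == v:
        return  # no self-loops
    if g.has_edge(u, v):
        prev = g.edges[u, v]["provenance"]
        if prev != provenance:
            g.edges[u, v]["provenance"] = "both"
        return
    g.add_edge(u, v, etype=etype, provenance=provenance)


def build_grn(
    annotated: Sequence[AnnotatedRegulon],
    literature: Sequence[LiteratureGene],
    curation: pd.DataFrame | None = None,
    regulon_display_names: dict[int, str] | None = None,
) -> nx.DiGraph:
    """Assemble the typed regulatory network.

    Regulon nodes: every computationally verified regulon plus every
    regulon hit by a literature gene. Module nodes: every functional module
    with at least one mapped gene (modules hitting no regulon stay as
    orphans). Gene nodes: every mapped locus tag. Edges: regulon
    ``regulates`` module where the module's genes fall in the regulon,
    module ``contains`` gene, regulon ``maps_to`` its TF gene; curated rows
    add their declared nodes and (typically ``uncertain``) edges.
    """
    g = nx.DiGraph()
    display = regulon_display_names or {}

    verified = {ar.regulon_id for ar in annotated
                if ar.verdict == "computationally_verified"}
    lit_hits: set[int] = set()
    for lg in literature:
        lit_hits.update(int(r) for r in lg.regulons_hit)
    for rid in sorted(verified | lit_hits):
        g.add_node(_node_id("regulon", rid), ntype="regulon",
                   name=display.get(rid, f"Regulon{rid}"))

    regulon_genes = {ar.regulon_id: set(ar.regulon.gene_ids) for ar in annotated}
    for lg in literature:
        if not lg.mapped_locus_tags:
            continue
        mnode = _node_id("functional_module", lg.functional_module)
        g.add_node(mnode, ntype="functional_module", name=lg.functional_module)
        for tag in lg.mapped_locus_tags:
            gnode = _node_id("gene", tag)
            g.add_node(gnode, ntype="gene", name=tag)
            _add_edge(g, mnode, gnode, "contains", "literature")
        for rid in sorted(int(r) for r in lg.regulons_hit):
            rnode = _node_id("regulon", rid)
            prov = ("both" if set(lg.mapped_locus_tags) & regulon_genes.get(rid, set())
                    else "literature")
            _add_edge(g, rnode, mnode, "regulates", prov)

    # computed regulates edges: module genes inside a verified regulon's gene set
    module_genes: dict[str, set[str]] = {}
    for lg in literature:
        module_genes.setdefault(lg.functional_module, set()).update(lg.mapped_locus_tags)
    for ar in annotated:
        if ar.verdict != "computationally_verified":
            continue
        rnode = _node_id("regulon", ar.regulon_id)
        for module, genes in module_genes.items():
            if genes & set(ar.regulon.gene_ids):
                _add_edge(g, rnode, _node_id("functional_module", module),
                          "regulates", "computational")
        if ar.mapped_tf is not None:
            tnode = _node_id("tf_gene", ar.mapped_tf.target_gene)
            g.add_node(tnode, ntype="tf_gene", name=ar.mapped_tf.target_gene)
            _add_edge(g, rnode, tnode, "maps_to", "computational")

    if curation is not None:
        for row in curation.itertuples():
            snode = _node_id(str(row.source_type), str(row.source_id))
            g.add_node(snode, ntype=str(row.source_type), name=str(row.source_id))
            if str(row.edge_type) == "node" or not str(row.target_id):
                continue
            tnode = _node_id(str(row.target_type), str(row.target_id))
            if not g.has_node(tnode):
                g.add_node(tnode, ntype=str(row.target_type), name=str(row.target_id))
            _add_edge(g, snode, tnode, str(row.edge_type), str(row.provenance))

    _validate(g)
    return g


def _validate(g: nx.DiGraph) -> None:
    for node, data in g.nodes(data=True):
        if data.get("ntype") not in NODE_TYPES:
            raise ValueError(f"node {node}: unknown type {data.get('ntype')!r}")
    for u, v, data in g.edges(data=True):
        if data["etype"] not in EDGE_TYPES:
            raise ValueError(f"edge {u}->{v}: unknown type {data['etype']!r}")
        if u == v:
            raise ValueError(f"self-loop on {u}")
        if data["etype"] in ("regulates", "uncertain"):
            if g.nodes[u].get("ntype") not in REGULATOR_TYPES | {"transmembrane_protein"}:
                raise ValueError(
                    f"{data['etype']} edge from non-regulator node {u}"
                )


def node_counts(g: nx.DiGraph) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, data in g.nodes(data=True):
        counts[data["ntype"]] = counts.get(data["ntype"], 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(g: nx.DiGraph, path: str | Path, fmt: str) -> None:
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "json":
        payload = {
            "nodes": [{"id": n, **d} for n, d in sorted(g.nodes(data=True))],
            "edges": [{"source": u, "target": v, **d}
                      for u, v, d in sorted(g.edges(data=True))],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif fmt == "edge-tsv":
        lines = ["source\ttarget\tedge_type\tprovenance"]
        for u, v, d in sorted(g.edges(data=True)):
            lines.append(f"{u}\t{v}\t{d['etype']}\t{d['provenance']}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_network_json(path: str | Path) -> nx.DiGraph:
    payload = json.loads(Path(path).read_text())
    g = nx.DiGraph()
    for node in payload["nodes"]:
        node = dict(node)
        g.add_node(node.pop("id"), **node)
    for edge in payload["edges"]:
        edge = dict(edge)
        g.add_edge(edge.pop("source"), edge.pop("target"), **edge)
    return g


def networks_equal(a: nx.DiGraph, b: nx.DiGraph) -> bool:
    return (dict(a.nodes(data=True)) == dict(b.nodes(data=True))
            and {(u, v): d for u, v, d in a.edges(data=True)}
            == {(u, v): d for u, v, d in b.edges(data=True)})
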