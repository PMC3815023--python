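"""Readers and writers for the pipeline's file formats.

Gene tables travel as 6-column BED-like TSV or GFF3; ontologies as
minimal OBO (id, name, namespace, is_a); annotations as 3-column TSV
(gene, term, evidence code); gene-set collections as GMT; expression as
TSV with a sidecar sample-group TSV; networks as SIF or GraphML; pair
lists, truth lists and manifests as TSV/JSON.

Coordinates are normalized to 0-based half-open on read: BED is taken
as-is, GFF3 (1-based, closed) start is decremented.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .geometry import DpgPair, GeneModel
from .netmap import FunctionalSetCollection, SetNetwork
from .ontology import AnnotationCorpus, OntologyGraph
from .scores import ExpressionMatrix

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_pairs",
    "write_pairs",
    "read_gmt",
    "write_gmt",
    "write_obo",
    "read_obo",
    "read_annotations",
    "write_annotations",
    "read_expression",
    "write_expression",
    "write_sif",
    "write_graphml",
    "read_graphml",
    "write_json",
    "read_json",
]


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes as 6-column BED (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_table(
    path: str | Path,
    format: str = "bed",
    gff_id_attribute: str = "ID",
    gff_feature_type: str = "gene",
) -> list[GeneModel]:
    """Read a gene table from BED (0-based half-open) or GFF3 (1-based closed).

    Malformed rows raise with the offending line number; strands other
    than '+'/'-' are rejected.
    """
    if format not in ("bed", "gff3"):
        raise ValueError(f"unknown gene table format {format!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    if len(fields) < 6:
                        raise ValueError("expected 6 BED columns")
                    chrom, start, end, name, _, strand = fields[:6]
                    g = GeneModel(name, chrom, strand, int(start), int(end))
                else:
                    if len(fields) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
                    if ftype != gff_feature_type:
                        continue
                    parsed = _parse_gff3_attributes(attrs)
                    if gff_id_attribute not in parsed:
                        raise ValueError(f"missing {gff_id_attribute!r} attribute")
                    g = GeneModel(
                        parsed[gff_id_attribute], chrom, strand, int(start) - 1, int(end)
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            genes.append(g)
    return genes


def write_pairs(pairs: Sequence[DpgPair], path: str | Path) -> None:
    """Write DPG pairs as TSV with signed TSS distance and distance class."""
    with open(path, "w") as fh:
        fh.write("minus_gene\tplus_gene\tchromosome\ttss_distance\tdistance_class\n")
        for p in pairs:
            fh.write(
                f"{p.minus_gene}\t{p.plus_gene}\t{p.chromosome}\t{p.tss_distance}\t{p.distance_class}\n"
            )


def read_pairs(path: str | Path) -> list[DpgPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        DpgPair(r.minus_gene, r.plus_gene, r.chromosome, int(r.tss_distance))
        for r in df.itertuples()
    ]


def write_gmt(collection: FunctionalSetCollection, path: str | Path) -> None:
    """Write a collection as GMT (name, description/source, members...)."""
    with open(path, "w") as fh:
        for name in collection.names():
            src = collection.sources.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{src}\t{members}\n")


def read_gmt(path: str | Path) -> FunctionalSetCollection:
    sets: dict[str, set[str]] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT row at line {lineno} has <3 columns")
            name, src = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
            sources[name] = src
    return FunctionalSetCollection(sets=sets, sources=sources)


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Write a minimal OBO file (id, name, namespace, is_a stanzas)."""
    ns_names = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(graph.terms):
            name, ns = graph.terms[term]
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {name}\n")
            fh.write(f"namespace: {ns_names.get(ns, ns)}\n")
            for p in graph.parents[term]:
                fh.write(f"is_a: {p} ! {graph.terms[p][0]}\n")
            fh.write("\n")


def read_obo(path: str | Path, include_part_of: bool = False) -> OntologyGraph:
    """Read an OBO ontology (is_a edges; part_of optionally folded in)."""
    g = obonet.read_obo(str(path))
    ns_short = {"biological_process": "BP", "cellular_component": "CC", "molecular_function": "MF"}
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, list[str]] = {}
    for node, data in g.nodes(data=True):
        ns = data.get("namespace", "default")
        terms[node] = (data.get("name", node), ns_short.get(ns, ns))
        ps = list(data.get("is_a", []))
        if include_part_of:
            for rel in data.get("relationship", []):
                kind, target = rel.split(" ", 1)
                if kind == "part_of":
                    ps.append(target.strip())
        parents[node] = ps
    return OntologyGraph(terms, parents)


def write_annotations(corpus: AnnotationCorpus, path: str | Path) -> None:
    """Write annotations as 3-column TSV: gene, term, evidence code."""
    with open(path, "w") as fh:
        fh.write("gene\tterm\tevidence\n")
        for gene, term, ev in corpus.assignments:
            fh.write(f"{gene}\t{term}\t{ev}\n")


def read_annotations(path: str | Path, include_iea: bool = True) -> AnnotationCorpus:
    df = pd.read_csv(path, sep="\t")
    corpus = AnnotationCorpus(include_iea=include_iea)
    for r in df.itertuples():
        corpus.add(r.gene, r.term, r.evidence)
    return corpus


def write_expression(matrix: ExpressionMatrix, path: str | Path, groups_path: str | Path) -> None:
    """Write the log2 matrix as TSV plus a sidecar sample/group/tissue TSV."""
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6f")
    with open(groups_path, "w") as fh:
        fh.write("sample\tgroup\ttissue\n")
        for s in matrix.values.columns:
            tissue = matrix.tissues.get(s, "")
            fh.write(f"{s}\t{matrix.groups[s]}\t{tissue}\n")


def read_expression(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene")
    meta = pd.read_csv(groups_path, sep="\t", keep_default_na=False)
    groups = dict(zip(meta["sample"], meta["group"]))
    tissues = {
        s: t for s, t in zip(meta["sample"], meta.get("tissue", "")) if t
    }
    return ExpressionMatrix(values=values, groups=groups, tissues=tissues)


def write_sif(network: SetNetwork, path: str | Path) -> None:
    """Write network edges in SIF (node, interaction type, node)."""
    kind = network.map_kind
    with open(path, "w") as fh:
        for a, b in sorted(network.graph.edges):
            fh.write(f"{a}\t{kind}\t{b}\n")


def _serializable_graph(network: SetNetwork) -> nx.Graph:
    g = nx.Graph(map_kind=network.map_kind, cutoff=network.cutoff)
    for n, data in network.graph.nodes(data=True):
        g.add_node(n, **data)
    for a, b, data in network.graph.edges(data=True):
        attrs = {k: v for k, v in data.items() if k != "bridging_pairs"}
        if "bridging_pairs" in data:
            attrs["bridging_pairs"] = ";".join(
                f"{p.minus_gene}|{p.plus_gene}" for p in data["bridging_pairs"]
            )
        g.add_edge(a, b, **attrs)
    return g


def write_graphml(network: SetNetwork, path: str | Path) -> None:
    """Write the network as GraphML; bridging pairs flatten to a string attribute."""
    nx.write_graphml(_serializable_graph(network), str(path))


def read_graphml(path: str | Path) -> SetNetwork:
    g = nx.read_graphml(str(path))
    map_kind = g.graph.get("map_kind", "interaction")
    cutoff = float(g.graph.get("cutoff", 0.0))
    return SetNetwork(graph=g, map_kind=map_kind, cutoff=cutoff)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
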