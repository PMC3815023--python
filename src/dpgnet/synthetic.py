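"""Synthetic inputs with known ground truth for every pipeline stage.

Four seeded generators emulate the statistical structure of the real
inputs — a gene-coordinate table with planted head-to-head pairs, a
three-namespace ontology DAG with tunable within-pair annotation
similarity, term-derived functional gene sets, and a log2 expression
matrix with planted differential-expression and housekeeping /
tissue-specific profiles — so downstream detection, similarity,
networking, and scoring can be validated against planted truth without
external downloads.

Defaults mirror the scale of the human analysis the package targets:
864 planted head-to-head pairs (682 with positive, 182 with negative
TSS distance) inside a larger gene complement, within-pair annotation
similarity high for cellular-component and molecular-function analogues
and low for biological-process, expression on log2 scale.

Coordinates are 0-based half-open; TSS is ``start`` on the plus strand
and ``end - 1`` on the minus strand.  Each generator is deterministic in
its config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import DpgPair, GeneModel
from .netmap import FunctionalSetCollection
from .ontology import AnnotationCorpus, OntologyGraph
from .scores import ExpressionMatrix

__all__ = [
    "GenomeSimConfig",
    "OntologySimConfig",
    "ExpressionSimConfig",
    "gen_genome",
    "gen_ontology",
    "gen_genesets",
    "gen_expression",
    "stage_seeds",
]

NAMESPACES = ("BP", "CC", "MF")


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Expand one global seed into independent per-generator substreams."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


@dataclass
class GenomeSimConfig:
    """Layout of the simulated genome and its planted head-to-head pairs."""

    n_chromosomes: int = 12
    chromosome_lengths: list[int] | None = None  # None: sized to fit
    n_genes: int = 4000
    n_planted_pairs: int = 864
    n_positive_pairs: int | None = 682  # None: sign drawn from the range
    planted_tss_distance_range: tuple[int, int] = (-999, 999)
    min_intergene_gap: int = 5000
    gene_length_range: tuple[int, int] = (500, 3000)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.planted_tss_distance_range
        if not (-1000 < lo <= hi < 1000):
            raise ValueError("planted_tss_distance_range must lie inside (-1000, 1000)")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise ValueError("planted pairs need 2*n_planted_pairs <= n_genes")
        if self.n_positive_pairs is not None and not (
            0 <= self.n_positive_pairs <= self.n_planted_pairs
        ):
            raise ValueError("n_positive_pairs must lie in [0, n_planted_pairs]")
        if self.n_chromosomes < 1 or self.min_intergene_gap <= 0:
            raise ValueError("need >=1 chromosome and a positive intergene gap")
        if self.min_intergene_gap < 1000:
            raise ValueError("min_intergene_gap below the 1 kb pairing window would plant spurious pairs")
        if self.gene_length_range[0] < 2:
            raise ValueError("genes must be at least 2 bp")
        if self.chromosome_lengths is not None:
            if len(self.chromosome_lengths) != self.n_chromosomes:
                raise ValueError("chromosome_lengths length must equal n_chromosomes")
            if any(c <= 0 for c in self.chromosome_lengths):
                raise ValueError("chromosome lengths must be positive")


def gen_genome(config: GenomeSimConfig) -> tuple[list[GeneModel], list[DpgPair]]:
    """Simulate gene coordinates with planted head-to-head pairs.

    Exactly ``n_planted_pairs`` adjacent opposite-strand pairs are placed
    with signed TSS distance inside ``planted_tss_distance_range``; all
    other genes sit at least ``min_intergene_gap`` apart (farther than the
    1 kb pairing window) and share no head-to-head arrangement.  Returns
    the gene list and the planted-pair truth list.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_singles = config.n_genes - 2 * config.n_planted_pairs
    glo, ghi = config.gene_length_range
    gap = config.min_intergene_gap

    # signed distances for the planted pairs
    lo, hi = config.planted_tss_distance_range
    n_pairs = config.n_planted_pairs
    if config.n_positive_pairs is not None:
        n_pos = config.n_positive_pairs
        if hi < 1 and n_pos > 0:
            raise ValueError("positive pairs requested but range has no positive part")
        if lo > -1 and n_pos < n_pairs:
            raise ValueError("negative pairs requested but range has no negative part")
        pos = rng.integers(max(lo, 1), hi + 1, size=n_pos)
        neg = rng.integers(lo, min(hi, -1) + 1, size=n_pairs - n_pos)
        distances = np.concatenate([pos, neg])
        rng.shuffle(distances)
    else:
        span = [d for d in range(lo, hi + 1) if d != 0]
        distances = rng.choice(span, size=n_pairs)

    # interleave pair-units and single-units, spread over chromosomes
    units = ["P"] * n_pairs + ["S"] * n_singles
    rng.shuffle(units)
    unit_chrom = np.sort(rng.integers(0, config.n_chromosomes, size=len(units)))

    genes: list[GeneModel] = []
    truth: list[DpgPair] = []
    cursors = [gap] * config.n_chromosomes
    pair_idx = 0
    gene_idx = 0

    def next_id() -> str:
        nonlocal gene_idx
        gene_idx += 1
        return f"g{gene_idx:05d}"

    for unit, c in zip(units, unit_chrom):
        chrom = f"chr{c + 1}"
        cur = cursors[c]
        if unit == "S":
            length = int(rng.integers(glo, ghi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(next_id(), chrom, strand, cur, cur + length))
            cursors[c] = cur + length + gap
        else:
            d = int(distances[pair_idx])
            pair_idx += 1
            l_minus = int(rng.integers(glo, ghi + 1))
            l_plus = int(rng.integers(glo, ghi + 1))
            # minus gene occupies [cur, cur+l_minus); its TSS is the right end
            minus_start = cur
            minus_tss = minus_start + l_minus - 1
            plus_start = minus_tss + d
            if plus_start <= 0:
                raise ValueError("infeasible packing: negative coordinate for planted pair")
            mg = GeneModel(next_id(), chrom, "-", minus_start, minus_start + l_minus)
            pg = GeneModel(next_id(), chrom, "+", plus_start, plus_start + l_plus)
            genes.append(mg)
            genes.append(pg)
            truth.append(DpgPair(mg.gene_id, pg.gene_id, chrom, d))
            cursors[c] = max(mg.end, pg.end) + gap

    if config.chromosome_lengths is not None:
        for c, (cur, length) in enumerate(zip(cursors, config.chromosome_lengths)):
            if cur > length:
                raise ValueError(
                    f"infeasible packing: chr{c + 1} needs {cur} bp but has {length}"
                )
    return genes, truth


@dataclass
class OntologySimConfig:
    """Shape of the simulated ontology and its gene annotations.

    ``pair_similarity`` maps each namespace to the probability q that the
    two members of a planted pair are forced to share at least one
    specific (deep, non-root) term — the knob behind the
    cellular-component-versus-biological-process similarity contrast.
    """

    n_terms_per_namespace: int = 60
    max_depth: int = 4
    branching: float = 3.0
    annotations_per_gene: tuple[int, int] = (10, 18)
    pair_similarity: Mapping[str, float] = field(
        default_factory=lambda: {"BP": 0.1, "CC": 0.9, "MF": 0.9}
    )
    seed: int = 0

    def validate(self) -> None:
        for ns, q in self.pair_similarity.items():
            if ns not in NAMESPACES:
                raise ValueError(f"unknown namespace {ns!r}")
            if not 0.0 <= q <= 1.0:
                raise ValueError("pair_similarity probabilities must lie in [0,1]")
        if self.max_depth < 1 or self.n_terms_per_namespace < 1:
            raise ValueError("need max_depth >= 1 and at least one term per namespace")
        a, b = self.annotations_per_gene
        if not 1 <= a <= b:
            raise ValueError("annotations_per_gene must be a positive range")


def gen_ontology(
    config: OntologySimConfig,
    genes: Sequence[str],
    pairs: Sequence[DpgPair] = (),
) -> tuple[OntologyGraph, AnnotationCorpus]:
    """Simulate a rooted DAG per namespace and annotate every gene.

    The DAG is built by layered random attachment: terms in layer *l*
    pick 1-2 parents from layer *l - 1*, which guarantees acyclicity and
    a unique root.  Genes receive direct annotations drawn uniformly from
    non-root terms; for each planted pair and namespace, with probability
    ``pair_similarity[ns]`` both members additionally receive one shared
    non-root term.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, list[str]] = {}
    layers_by_ns: dict[str, list[list[str]]] = {}
    for ns in NAMESPACES:
        root = f"{ns}:0000000"
        terms[root] = (f"{ns} root", ns)
        parents[root] = []
        layers = [[root]]
        remaining = config.n_terms_per_namespace - 1
        # layer sizes grow geometrically with the branching factor
        weights = np.array([config.branching**l for l in range(1, config.max_depth + 1)])
        sizes = np.maximum(1, np.round(remaining * weights / weights.sum()).astype(int))
        # adjust rounding drift on the deepest layer
        sizes[-1] += remaining - sizes.sum()
        counter = 0
        for depth, size in enumerate(sizes, start=1):
            layer: list[str] = []
            for _ in range(max(size, 0)):
                counter += 1
                tid = f"{ns}:{counter:07d}"
                terms[tid] = (f"{ns} term {counter}", ns)
                n_par = 1 + int(rng.random() < 0.3)
                prev = layers[depth - 1]
                chosen = rng.choice(len(prev), size=min(n_par, len(prev)), replace=False)
                parents[tid] = [prev[i] for i in chosen]
                layer.append(tid)
            if layer:
                layers.append(layer)
        layers_by_ns[ns] = layers

    graph = OntologyGraph(terms, parents)
    corpus = AnnotationCorpus()
    a, b = config.annotations_per_gene
    for ns in NAMESPACES:
        non_root = [t for layer in layers_by_ns[ns][1:] for t in layer]
        for g in genes:
            k = int(rng.integers(a, b + 1))
            for i in rng.choice(len(non_root), size=min(k, len(non_root)), replace=False):
                ev = "IEA" if rng.random() < 0.5 else "IDA"
                corpus.add(g, non_root[i], ev)
        q = config.pair_similarity.get(ns, 0.0)
        for p in pairs:
            if rng.random() < q:
                shared = non_root[int(rng.integers(0, len(non_root)))]
                corpus.add(p.minus_gene, shared, "IEA")
                corpus.add(p.plus_gene, shared, "IEA")
    return graph, corpus


def gen_genesets(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    n_sets: int = 20,
    min_size: int = 1,
    max_size_fraction: float = 0.5,
    n_random_sets: int = 0,
    random_set_size: int = 20,
    seed: int = 0,
) -> FunctionalSetCollection:
    """Derive functional gene sets from term memberships.

    Each term-derived set contains every gene annotated to the term or
    any of its descendants.  Candidate terms must annotate at least
    ``min_size`` genes and at most ``max_size_fraction`` of the annotated
    genes (near-root terms cover almost everything and would make every
    category redundant).  Optional random sets draw genes uniformly.
    """
    rng = np.random.default_rng(seed)
    term_genes: dict[str, set[str]] = {}
    for ns in sorted(graph.roots):
        gene_terms = corpus.gene_terms(graph, ns)
        for g, ts in gene_terms.items():
            propagated: set[str] = set()
            for t in ts:
                propagated |= graph.ancestors(t)
            for t in propagated:
                term_genes.setdefault(t, set()).add(g)
    n_annotated = len(corpus.genes())
    candidates = sorted(
        t
        for t, gs in term_genes.items()
        if min_size <= len(gs) <= max_size_fraction * n_annotated
        and t not in graph.roots.values()
    )
    if len(candidates) < n_sets:
        raise ValueError(f"only {len(candidates)} candidate terms for {n_sets} sets")
    chosen = [candidates[i] for i in rng.choice(len(candidates), size=n_sets, replace=False)]
    sets = {t: set(term_genes[t]) for t in chosen}
    sources = {t: graph.namespace(t) for t in chosen}
    all_genes = sorted(corpus.genes())
    for i in range(n_random_sets):
        name = f"random_set_{i + 1}"
        idx = rng.choice(len(all_genes), size=min(random_set_size, len(all_genes)), replace=False)
        sets[name] = {all_genes[j] for j in idx}
        sources[name] = "random"
    return FunctionalSetCollection(sets=sets, sources=sources)


@dataclass
class ExpressionSimConfig:
    """Shape of the simulated log2 expression matrix.

    The first entry of ``groups`` is the control/reference group; planted
    differential-expression shifts and the DPG-specific extra shift apply
    to every other group.  When ``groups_are_tissues`` is set, each group
    doubles as a tissue label and per-tissue gene effects are added:
    housekeeping genes get a high baseline and nearly constant tissue
    profile, tissue-specific genes a strongly varying one.
    """

    n_genes: int = 1000
    groups: Sequence[tuple[str, int]] = (("control", 10), ("case", 10))
    baseline_log_mean: float = 8.0
    noise_sd: float = 0.5
    planted_de_sets: Sequence[tuple[str, float]] = ()
    planted_dpg_extra_shift: float = 0.0
    housekeeping_fraction: float = 0.0
    tissue_specific_fraction: float = 0.0
    groups_are_tissues: bool = False
    gene_baseline_sd: float = 1.5
    housekeeping_baseline_shift: float = 2.5
    tissue_effect_sd: dict | None = None  # class -> sd of per-tissue effects
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for _, n in self.groups) or len(self.groups) < 2:
            raise ValueError("need >=2 groups with >=2 samples each")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for frac in (self.housekeeping_fraction, self.tissue_specific_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if self.housekeeping_fraction + self.tissue_specific_fraction > 1.0:
            raise ValueError("housekeeping and tissue-specific fractions overlap")


def gen_expression(
    config: ExpressionSimConfig,
    sets: Mapping[str, set[str]] | FunctionalSetCollection | None = None,
    pairs: Sequence[DpgPair] = (),
    genes: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Simulate a log2 expression matrix with planted effects.

    Values are ``baseline + gene offset + group/tissue effects + noise``.
    Genes in ``planted_de_sets`` shift by the stated log2 fold change in
    every non-control group; members of ``pairs`` additionally shift by
    ``planted_dpg_extra_shift``.  Returns the matrix and the planted
    gene-class truth (housekeeping / tissue_specific lists).
    """
    config.validate()
    set_map = sets.sets if isinstance(sets, FunctionalSetCollection) else (sets or {})
    for name, _ in config.planted_de_sets:
        if name not in set_map:
            raise ValueError(f"planted DE set {name!r} not in the collection")
    rng = np.random.default_rng(config.seed)

    if genes is None:
        genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    genes = list(genes)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # gene classes for the tissue simulation
    n_hk = int(round(config.housekeeping_fraction * n))
    n_ts = int(round(config.tissue_specific_fraction * n))
    perm = rng.permutation(n)
    hk_idx, ts_idx = perm[:n_hk], perm[n_hk : n_hk + n_ts]
    truth = {
        "housekeeping": sorted(genes[i] for i in hk_idx),
        "tissue_specific": sorted(genes[i] for i in ts_idx),
    }
    gene_class = np.full(n, "ordinary", dtype=object)
    gene_class[hk_idx] = "housekeeping"
    gene_class[ts_idx] = "tissue_specific"

    offsets = rng.normal(0.0, config.gene_baseline_sd, size=n)
    offsets[hk_idx] = rng.normal(config.housekeeping_baseline_shift, 0.5, size=n_hk)

    tissue_sd = {"housekeeping": 0.1, "ordinary": 1.2, "tissue_specific": 2.5}
    if config.tissue_effect_sd:
        tissue_sd.update(config.tissue_effect_sd)

    dpg_members = {g for p in pairs for g in p.genes}
    de_shift = np.zeros(n)
    for name, lfc in config.planted_de_sets:
        for g in set_map[name]:
            if g in gene_pos:
                de_shift[gene_pos[g]] += lfc
    if config.planted_dpg_extra_shift:
        for g in dpg_members:
            if g in gene_pos:
                de_shift[gene_pos[g]] += config.planted_dpg_extra_shift

    control_label = config.groups[0][0]
    columns: list[str] = []
    col_group: dict[str, str] = {}
    col_tissue: dict[str, str] = {}
    blocks = []
    for label, n_samples in config.groups:
        effect = np.zeros(n)
        if label != control_label:
            effect = effect + de_shift
        if config.groups_are_tissues:
            for cls, sd in tissue_sd.items():
                mask = gene_class == cls
                effect = effect + np.where(mask, rng.normal(0.0, sd, size=n), 0.0)
        block = (
            config.baseline_log_mean
            + offsets[:, None]
            + effect[:, None]
            + rng.normal(0.0, config.noise_sd, size=(n, n_samples))
        )
        blocks.append(block)
        for k in range(n_samples):
            s = f"{label}_{k + 1}"
            columns.append(s)
            col_group[s] = label
            if config.groups_are_tissues:
                col_tissue[s] = label
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    matrix = ExpressionMatrix(values=values, groups=col_group, tissues=col_tissue)
    return matrix, truth
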