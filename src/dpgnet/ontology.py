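"""Information-content semantic similarity of gene pairs over an ontology.

Implements the Schlicker relevance similarity between terms — a Lin-style
IC ratio at the most informative common ancestor, weighted by
``1 - p(ancestor)`` so that shallow (near-root) ancestors contribute
little — combined across two genes' term sets with the ``rcmax.avg``
rule (mean of all row maxima and column maxima of the pairwise matrix).
Gene-pair score distributions are contrasted against a uniformly sampled
random-pair background with a two-sample Kolmogorov-Smirnov test, and
hypergeometric term enrichment with Benjamini-Hochberg correction is
provided for gene lists.

Information content is natural-log: ``IC(t) = -ln p(t)`` where ``p(t)``
is the fraction of annotated genes carrying ``t`` or any descendant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ks_2samp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OntologyGraph",
    "AnnotationCorpus",
    "IcTable",
    "build_ic",
    "term_similarity_rel",
    "combine_rcmax_avg",
    "gene_pair_similarity",
    "sample_background",
    "compare_ks",
    "SimilarityComparison",
    "exclude_paralog_pairs",
    "term_enrichment",
]


class OntologyGraph:
    """A rooted DAG of terms per namespace, linked by is_a edges.

    Parameters
    ----------
    terms : mapping term id -> (name, namespace)
    parents : mapping term id -> list of parent term ids (is_a)
    """

    def __init__(self, terms: Mapping[str, tuple[str, str]], parents: Mapping[str, Sequence[str]]):
        self.terms = dict(terms)
        self.parents = {t: list(parents.get(t, [])) for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"term {t} has unknown parent {p}")
        self.children: dict[str, list[str]] = {t: [] for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                self.children[p].append(t)
        self.roots: dict[str, str] = {}
        for t, (name, ns) in self.terms.items():
            if not self.parents[t]:
                if ns in self.roots:
                    raise ValueError(f"namespace {ns} has multiple roots")
                self.roots[ns] = t
        self._check_acyclic()
        self._anc_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            state[t] = 1
            for p in self.parents[t]:
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"cycle through term {p}")
                if s == 0:
                    visit(p, stack)
            state[t] = 2

        for t in self.terms:
            if state.get(t, 0) == 0:
                visit(t, [])

    def namespace(self, term: str) -> str:
        return self.terms[term][1]

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        for p in self.parents[term]:
            out |= self.ancestors(p)
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def descendants(self, term: str) -> set[str]:
        """All descendants of ``term`` including the term itself."""
        out = {term}
        stack = [term]
        while stack:
            for c in self.children[stack.pop()]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return [t for t, (_, ns) in self.terms.items() if ns == namespace]


@dataclass
class AnnotationCorpus:
    """Direct gene -> term annotations with evidence codes.

    ``include_iea`` keeps electronically inferred (IEA) assignments; the
    default follows common practice of including them for coverage.
    """

    assignments: list[tuple[str, str, str]] = field(default_factory=list)  # gene, term, evidence
    include_iea: bool = True

    def add(self, gene: str, term: str, evidence: str = "IEA") -> None:
        self.assignments.append((gene, term, evidence))

    def _kept(self) -> Iterable[tuple[str, str, str]]:
        for gene, term, ev in self.assignments:
            if not self.include_iea and ev == "IEA":
                continue
            yield gene, term, ev

    def gene_terms(self, graph: OntologyGraph, namespace: str) -> dict[str, set[str]]:
        """Direct term sets per gene, restricted to one namespace."""
        out: dict[str, set[str]] = {}
        for gene, term, _ in self._kept():
            if graph.namespace(term) == namespace:
                out.setdefault(gene, set()).add(term)
        return out

    def genes(self) -> set[str]:
        return {g for g, _, _ in self._kept()}


@dataclass
class IcTable:
    """Per-term annotation probability and information content for one namespace."""

    namespace: str
    p: dict[str, float]
    ic: dict[str, float]
    n_genes: int

    def defined(self, term: str) -> bool:
        return term in self.ic


def build_ic(graph: OntologyGraph, corpus: AnnotationCorpus, namespace: str) -> IcTable:
    """Annotation-frequency information content for one namespace.

    ``p(term)`` counts genes annotated to the term or any of its
    descendants, over all genes annotated anywhere in the namespace;
    ``IC = -ln p``.  Terms with no annotated gene are left out and are
    thereby excluded from similarity.
    """
    gene_terms = corpus.gene_terms(graph, namespace)
    if not gene_terms:
        raise ValueError(f"no annotations in namespace {namespace}")
    n_genes = len(gene_terms)
    counts: dict[str, int] = {}
    for terms in gene_terms.values():
        propagated: set[str] = set()
        for t in terms:
            propagated |= graph.ancestors(t)
        for t in propagated:
            counts[t] = counts.get(t, 0) + 1
    p = {t: c / n_genes for t, c in counts.items()}
    ic = {t: float(-np.log(v)) for t, v in p.items()}
    return IcTable(namespace=namespace, p=p, ic=ic, n_genes=n_genes)


def term_similarity_rel(t1: str, t2: str, ic: IcTable, graph: OntologyGraph) -> float:
    """Schlicker relevance similarity between two terms.

    ``max over common ancestors a of [2 IC(a) / (IC(t1)+IC(t2))] * [1 - p(a)]``,
    0 when both terms carry zero IC (e.g. both are the root).
    """
    if graph.namespace(t1) != graph.namespace(t2):
        raise ValueError("terms from different namespaces are not comparable")
    if not (ic.defined(t1) and ic.defined(t2)):
        raise ValueError("similarity requires terms with defined IC")
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0.0:
        return 0.0
    common = graph.ancestors(t1) & graph.ancestors(t2)
    best = 0.0
    for a in common:
        if not ic.defined(a):
            continue
        score = (2.0 * ic.ic[a] / denom) * (1.0 - ic.p[a])
        if score > best:
            best = score
    return min(best, 1.0)


def combine_rcmax_avg(sim_matrix: np.ndarray) -> float:
    """Combine a term-set x term-set similarity matrix by ``rcmax.avg``.

    Returns ``(sum of row maxima + sum of column maxima) / (n_rows + n_cols)``.
    """
    m = np.asarray(sim_matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("similarity matrix must be non-empty and 2-D")
    return float((m.max(axis=1).sum() + m.max(axis=0).sum()) / (m.shape[0] + m.shape[1]))


class _PairSimCache:
    """Memoizes term-pair similarities across many gene-pair evaluations."""

    def __init__(self, ic: IcTable, graph: OntologyGraph):
        self.ic = ic
        self.graph = graph
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        val = self._cache.get(key)
        if val is None:
            val = term_similarity_rel(t1, t2, self.ic, self.graph)
            self._cache[key] = val
        return val


def gene_pair_similarity(
    g1: str,
    g2: str,
    namespace: str,
    corpus: AnnotationCorpus,
    ic: IcTable,
    graph: OntologyGraph,
    _gene_terms: Mapping[str, set[str]] | None = None,
    _cache: _PairSimCache | None = None,
) -> float | None:
    """Semantic similarity of two genes in one namespace, or None.

    The term-set matrix is built from the genes' direct annotations
    (ancestors enter only through the common-ancestor search) and combined
    with ``rcmax.avg``.  Returns None (undefined) when either gene has no
    usable annotation: no terms, or only the namespace root.
    """
    gene_terms = _gene_terms if _gene_terms is not None else corpus.gene_terms(graph, namespace)
    root = graph.roots.get(namespace)
    sim = _cache if _cache is not None else _PairSimCache(ic, graph)
    ts1 = [t for t in gene_terms.get(g1, ()) if t != root and ic.defined(t)]
    ts2 = [t for t in gene_terms.get(g2, ()) if t != root and ic.defined(t)]
    if not ts1 or not ts2:
        return None
    m = np.empty((len(ts1), len(ts2)))
    for i, a in enumerate(ts1):
        for j, b in enumerate(ts2):
            m[i, j] = sim(a, b)
    return combine_rcmax_avg(m)


def pairwise_similarities(
    pairs: Sequence[tuple[str, str]],
    namespace: str,
    corpus: AnnotationCorpus,
    ic: IcTable,
    graph: OntologyGraph,
) -> tuple[list[float], int]:
    """Scores for many gene pairs; returns (defined scores, n undefined)."""
    gene_terms = corpus.gene_terms(graph, namespace)
    cache = _PairSimCache(ic, graph)
    scores: list[float] = []
    undefined = 0
    for g1, g2 in pairs:
        s = gene_pair_similarity(
            g1, g2, namespace, corpus, ic, graph, _gene_terms=gene_terms, _cache=cache
        )
        if s is None:
            undefined += 1
        else:
            scores.append(s)
    return scores, undefined


def sample_background(
    genes: Sequence[str], n_pairs: int = 100_000, seed: int | None = None
) -> list[tuple[str, str]]:
    """Uniform random unordered distinct-gene pairs (with replacement across pairs)."""
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to sample pairs")
    rng = np.random.default_rng(seed)
    first = rng.integers(0, len(genes), size=n_pairs)
    offset = rng.integers(1, len(genes), size=n_pairs)
    second = (first + offset) % len(genes)
    return [(genes[i], genes[j]) for i, j in zip(first, second)]


@dataclass
class SimilarityComparison:
    """KS contrast of DPG-pair scores against a random-pair background."""

    namespace: str
    dpg_scores: list[float]
    background_scores: list[float]
    ks_D: float
    ks_p: float
    n_undefined_dpg: int = 0
    n_undefined_background: int = 0


def compare_ks(
    dpg_scores: Sequence[float], background_scores: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic two-sided p."""
    if len(dpg_scores) == 0 or len(background_scores) == 0:
        raise ValueError("both score lists must be non-empty")
    res = ks_2samp(dpg_scores, background_scores, method="asymp")
    return float(res.statistic), float(res.pvalue)


def exclude_paralog_pairs(
    pairs: Sequence[tuple[str, str]], paralog_families: Mapping[str, str]
) -> list[tuple[str, str]]:
    """Drop pairs whose members share a paralog-family label.

    Mirrors the removal of histone-family pairs before re-testing whether a
    high-similarity subgroup drives a distribution shift.
    """
    out = []
    for g1, g2 in pairs:
        f1 = paralog_families.get(g1)
        f2 = paralog_families.get(g2)
        if f1 is not None and f1 == f2:
            continue
        out.append((g1, g2))
    return out


def term_enrichment(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    namespace: str | None = None,
    min_term_genes: int = 2,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a study gene list.

    Annotations are propagated to ancestors; for each term the upper-tail
    hypergeometric probability of the observed study overlap is computed,
    with BH adjustment across tested terms.  Terms annotating fewer than
    ``min_term_genes`` background genes are skipped.
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study:
        raise ValueError("study set is empty")
    if not study <= background:
        raise ValueError("study genes must be a subset of the background")

    namespaces = [namespace] if namespace else sorted(graph.roots)
    term_genes: dict[str, set[str]] = {}
    for ns in namespaces:
        for gene, terms in corpus.gene_terms(graph, ns).items():
            if gene not in background:
                continue
            propagated: set[str] = set()
            for t in terms:
                propagated |= graph.ancestors(t)
            for t in propagated:
                term_genes.setdefault(t, set()).add(gene)

    rows = []
    M, n = len(background), len(study)
    for term, genes_t in sorted(term_genes.items()):
        K = len(genes_t)
        if K < min_term_genes:
            continue
        k = len(genes_t & study)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append((term, graph.terms[term][0], graph.namespace(term), K, k, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term", "name", "namespace", "n_background", "n_study", "p_value"]
    )
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adjusted"] = []
    return df
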