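"""Shared fixtures: toy ontologies, gene tables, and oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dpgnet.geometry import DpgPair, GeneModel
from dpgnet.ontology import AnnotationCorpus, OntologyGraph


@pytest.fixture
def toy_ontology():
    """A small two-namespace DAG with hand-checkable structure.

    BP namespace::

        root ── a ── c
             └─ b ─┘ └─ d      (c has parents a and b; d child of c)
    """
    terms = {
        "BP:root": ("bp root", "BP"),
        "BP:a": ("a", "BP"),
        "BP:b": ("b", "BP"),
        "BP:c": ("c", "BP"),
        "BP:d": ("d", "BP"),
        "CC:root": ("cc root", "CC"),
        "CC:x": ("x", "CC"),
        "CC:y": ("y", "CC"),
    }
    parents = {
        "BP:root": [],
        "BP:a": ["BP:root"],
        "BP:b": ["BP:root"],
        "BP:c": ["BP:a", "BP:b"],
        "BP:d": ["BP:c"],
        "CC:root": [],
        "CC:x": ["CC:root"],
        "CC:y": ["CC:x"],
    }
    return OntologyGraph(terms, parents)


@pytest.fixture
def toy_corpus():
    """Ten genes annotated so BP:a's subtree covers five of them."""
    corpus = AnnotationCorpus()
    # genes 1-5 under a (2 via c/d, 3 directly), 6-10 under b only
    corpus.add("g1", "BP:a", "IDA")
    corpus.add("g2", "BP:a", "IDA")
    corpus.add("g3", "BP:a", "IEA")
    corpus.add("g4", "BP:c", "IDA")
    corpus.add("g5", "BP:d", "IDA")
    for g in ["g6", "g7", "g8", "g9", "g10"]:
        corpus.add(g, "BP:b", "IDA")
    for i, g in enumerate(["g1", "g2", "g6"]):
        corpus.add(g, "CC:y" if i % 2 else "CC:x", "IDA")
    return corpus


def brute_force_dpgs(genes: list[GeneModel], window: int = 1000) -> list[DpgPair]:
    """Independent DPG caller: exhaustive all-pairs predicate scan.

    Applies the same stated rule as the production caller — opposite
    strands, 0 < |tss(plus) - tss(minus)| < window, no third TSS strictly
    between, greedy one-to-one by smallest |distance| then lexicographic
    ids — but via direct enumeration of all gene pairs.
    """
    cands = []
    for a, b in itertools.combinations(genes, 2):
        if a.chromosome != b.chromosome or a.strand == b.strand:
            continue
        minus, plus = (a, b) if a.strand == "-" else (b, a)
        d = plus.tss - minus.tss
        if d == 0 or abs(d) >= window:
            continue
        lo, hi = min(a.tss, b.tss), max(a.tss, b.tss)
        blocked = any(
            g.chromosome == a.chromosome and lo < g.tss < hi
            for g in genes
            if g.gene_id not in (a.gene_id, b.gene_id)
        )
        if blocked:
            continue
        key = tuple(sorted((minus.gene_id, plus.gene_id)))
        cands.append((abs(d), key[0], key[1], minus, plus, d))
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    used: set[str] = set()
    out = []
    for _, _, _, minus, plus, d in cands:
        if minus.gene_id in used or plus.gene_id in used:
            continue
        used.update((minus.gene_id, plus.gene_id))
        out.append(DpgPair(minus.gene_id, plus.gene_id, minus.chromosome, d))
    return sorted(out, key=lambda p: (p.chromosome, p.minus_gene, p.plus_gene))


def brute_force_schlicker(t1: str, t2: str, graph: OntologyGraph, p: dict[str, float]) -> float:
    """Relevance similarity by exhaustive enumeration of common ancestors."""
    ic = {t: -np.log(v) for t, v in p.items()}
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    common = set(graph.ancestors(t1)) & set(graph.ancestors(t2))
    return max(
        ((2 * ic[a] / denom) * (1 - p[a]) for a in common if a in ic),
        default=0.0,
    )


def brute_force_ks_D(x, y) -> float:
    """Two-sample KS statistic: sup |ECDF1 - ECDF2| over the pooled grid."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    grid = np.concatenate([x, y])
    best = 0.0
    for v in grid:
        f1 = np.mean(x <= v)
        f2 = np.mean(y <= v)
        best = max(best, abs(f1 - f2))
    return best


def brute_force_cohesiveness(members, graph, penalty) -> float:
    """Cohesiveness by direct edge enumeration."""
    v = set(members)
    w_in = sum(
        d.get("weight", 1.0) for a, b, d in graph.edges(data=True) if a in v and b in v
    )
    w_bound = sum(
        d.get("weight", 1.0)
        for a, b, d in graph.edges(data=True)
        if (a in v) != (b in v)
    )
    denom = w_in + w_bound + penalty * len(v)
    return w_in / denom if denom else 0.0


def brute_force_quartile_mean(values) -> float:
    """(Q1+Q2+Q3)/3 with linear interpolation, written out long-hand."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def q(frac):
        if n == 1:
            return v[0]
        pos = frac * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    return (q(0.25) + q(0.5) + q(0.75)) / 3.0


def brute_force_bh(pvals):
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
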