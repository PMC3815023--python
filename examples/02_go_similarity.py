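"""Contrast within-pair GO similarity against random gene pairs.

Simulates an ontology in which paired genes share cellular-component
(CC) terms often (q=0.9) but biological-process (BP) terms rarely
(q=0.1), then compares Schlicker/rcmax.avg similarity distributions of
the pairs against a sampled random-pair background with a KS test.
"""

import numpy as np

from dpgnet import (
    GenomeSimConfig,
    OntologySimConfig,
    build_ic,
    compare_ks,
    find_dpgs,
    gen_genome,
    gen_ontology,
    sample_background,
)
from dpgnet.ontology import pairwise_similarities

genes, _ = gen_genome(
    GenomeSimConfig(n_genes=800, n_planted_pairs=300, n_positive_pairs=240, seed=1)
)
gene_ids = [g.gene_id for g in genes]
pairs = find_dpgs(genes)
graph, corpus = gen_ontology(OntologySimConfig(seed=2), gene_ids, pairs)
background = sample_background(gene_ids, n_pairs=10_000, seed=3)

for ns in ("BP", "CC", "MF"):
    ic = build_ic(graph, corpus, ns)
    pair_scores, _ = pairwise_similarities(
        [(p.minus_gene, p.plus_gene) for p in pairs], ns, corpus, ic, graph
    )
    bg_scores, _ = pairwise_similarities(background, ns, corpus, ic, graph)
    d, p = compare_ks(pair_scores, bg_scores)
    print(
        f"{ns}: mean pair similarity {np.mean(pair_scores):.3f} "
        f"vs background {np.mean(bg_scores):.3f}, KS D={d:.3f}, p={p:.3g}"
    )
# CC and MF should be strongly right-shifted (tiny p), BP indistinguishable
# (p > 0.05): paired genes co-localize but diverge in process.
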