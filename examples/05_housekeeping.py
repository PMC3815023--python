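"""Housekeeping-gene calling and tissue-variance summaries.

Simulates a multi-tissue expression matrix with planted housekeeping
(high, stable expression) and tissue-specific (highly variable) genes,
calls housekeeping genes, bins per-set tissue variance, and reports
overlap of housekeeping lists with the DPG gene universe.
"""

from dpgnet import (
    DpgPair,
    ExpressionSimConfig,
    call_housekeeping,
    gen_expression,
    list_overlap_stats,
    tissue_variance_bins,
)

config = ExpressionSimConfig(
    n_genes=600,
    groups=[(t, 3) for t in ["cerebellum", "cortex", "liver", "muscle", "lung", "kidney"]],
    housekeeping_fraction=0.2,
    tissue_specific_fraction=0.2,
    groups_are_tissues=True,
    seed=5,
)
matrix, truth = gen_expression(config)
called = set(call_housekeeping(matrix))
planted = set(truth["housekeeping"])
print(f"planted housekeeping genes: {len(planted)}, called: {len(called)}")
print(f"recall {len(called & planted) / len(planted):.2f}, "
      f"precision {len(called & planted) / len(called):.2f}")
# A housekeeping gene must exceed the expression median in every tissue
# and keep its across-tissue variance under 0.5 (log2 scale).

bins = tissue_variance_bins(
    matrix,
    {"housekeeping_set": planted, "tissue_specific_set": set(truth["tissue_specific"])},
)
print("\nper-set across-tissue variance bins:")
print(bins.to_string(index=False))

# overlap of two housekeeping lists with a toy DPG pairing
pairs = [DpgPair(a, b, "chr1", 100) for a, b in zip(sorted(planted)[:20], sorted(planted)[20:40])]
report = list_overlap_stats({"called": sorted(called), "planted": sorted(planted)}, pairs)
print(f"\nlist intersection {report['intersection_size']}, union {report['union_size']}; "
      f"{report['genes_in_complete_pairs']} union genes form complete DPG pairs")
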