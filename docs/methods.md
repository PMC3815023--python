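# Methods

This note records the models, conventions, and design choices behind
`dpgnet`, and what the synthetic studies do and do not demonstrate.

## Coordinates and DPG calling

Gene coordinates are 0-based, half-open (BED convention) everywhere;
GFF3 input (1-based, closed) is converted on read.  The TSS is `start`
for a plus-strand gene and `end − 1` for a minus-strand gene.  The
signed TSS distance of a candidate head-to-head pair is
`tss(plus) − tss(minus)`: positive when the TSSs diverge without
overlap, negative when the 5′ regions overlap.  A DPG pair requires
opposite strands and `0 < |d| < window` (default window 1 kb, both
interval ends open, so `d = 0` and `|d| = 1000` are excluded).

Two conventions close gaps the distance rule leaves open:

- **Adjacency**: the two TSSs must be adjacent in TSS order — no third
  gene's TSS strictly between them.  This matches the neighbouring-pair
  reading of bidirectional promoters and can be disabled
  (`require_adjacent=False`).
- **One-to-one pairing**: when a gene has several candidate partners,
  the candidate list is committed greedily in order of increasing
  `|d|`, ties broken by lexicographic gene id.  This makes the pairing
  deterministic and independent of input row order.

Chromosome enrichment uses gene counts per chromosome as the density
normalizer: for each chromosome, a hypergeometric tail probability of
the observed DPG-gene count when drawing that chromosome's gene count
from the genome-wide pool; the smaller tail is reported with its
direction, Benjamini–Hochberg-adjusted across chromosomes.  Chromosome
length is deliberately not modeled beyond its effect on gene count.

## Ontology similarity

Information content is natural-log annotation frequency:
`p(t)` = genes annotated to `t` or any descendant / genes annotated
anywhere in the namespace; `IC(t) = −ln p(t)`.  The base cancels in the
IC ratio, and the `1 − p(a)` weight is base-free, so natural log is a
pure convention.  Terms with no annotation are excluded from
similarity.

Term similarity is the Schlicker relevance measure: the Lin-style IC
ratio at the best common ancestor, weighted by `1 − p(a)` to discount
shallow ancestors (the "shallow annotation" correction).  Gene-pair
similarity builds the term-pair matrix from **direct** annotations only
(ancestors act through the common-ancestor search, which is where
propagation belongs in IC methods) and combines it with `rcmax.avg`.
Genes with no annotation, or annotated only to the namespace root, are
*undefined* rather than zero — root-only genes would otherwise pile up
an artificial spike at 0.  Undefined pairs are excluded from
distributions and counted in run manifests.

The random-pair background samples unordered distinct-gene pairs
uniformly with replacement across pairs (default 100,000) from the
genes present in both the gene table and the annotation corpus.  The
distribution comparison uses the two-sample KS statistic with the
asymptotic p-value; at the sample sizes involved (hundreds of pairs
against thousands of background pairs) the asymptotic form is accurate.
Evidence-code filtering keeps IEA annotations by default (coverage over
certainty), switchable via `include_iea`.

## Set networks and modules

The overlap rate and the module-merge criterion both use the Simpson
coefficient `|A∩B| / min(|A|,|B|)`.  The interaction rate counts DPG
pairs with one member exclusive to each set (a pair inside the
intersection bridges nothing) and divides by `min(|A|,|B|)`.  The
min-normalization is a design decision: it parallels the Simpson
convention used for overlaps and keeps the rate in [0, 1]; a
geometric-mean denominator is available via the library if a flatter
normalization is wanted.  Category filtering keeps sets with more than
5 genes whose Simpson overlap with every already-kept set is below 0.8,
considered in descending size order (ties by name) so the filter is
reproducible.  Edge cutoffs are strict inequalities (defaults:
interaction 0.07, overlap 0.30).

Module detection is greedy cohesiveness maximisation:
`f(V) = w_in / (w_in + w_bound + p·|V|)` with edge weights equal to the
interaction rate and penalty `p = 2` (the standard default of
cohesiveness-based complex detection; configurable).  Groups grow from
the highest-weighted-degree uncovered node by single add/remove moves
while `f` strictly increases; seeding repeats until every node is
covered (multi-pass); grown groups merge transitively when their
Simpson coefficient reaches 0.8; modules below 3 members are dropped.
The algorithm is deterministic.  Each module carries a one-sided
Mann–Whitney p-value comparing internal against boundary edge weights
(exact for small counts), the natural quality measure for a
cohesiveness optimum; a module with internal edges and no boundary
edges gets p = 0 by convention.

## Differential expression and pathway scores

Expression input is gene-level log2 (microarray-style); no
normalization or probe mapping is attempted.  Per-gene case/control
testing uses a moderated t: the pooled two-sample variance `s²_g` on
`d_g` residual df is shrunk to
`s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g)`, with the prior `(d₀, s₀²)`
fitted by matching the first two moments of `log s²_g` to a scaled-F
distribution (digamma/trigamma inversion; genes with zero residual df
excluded; when the observed spread does not exceed chi-square sampling
spread, `d₀ = ∞` and the posterior variance is `s₀²` with normal
reference).  The moderated t is referred to `d₀ + d_g` df.  A plain
pooled t is available (`moderated=False`).  A gene constant in both
groups with zero difference gets p = 1.  The implementation was
verified during development against an independent reference
empirical-Bayes fit on a frozen fixture (agreement to 1e-15 in p when
the prior df is finite).

Gene score: `−log10 p` ("−log" is read as log10, forced by the printed
threshold 1.301 = −log10 0.05).  Absolute pathway score: mean of the
three quartiles (Q1+Q2+Q3)/3 of member-gene scores — quartiles use
linear interpolation between order statistics, the common default; the
convention is recorded in run manifests.  Levels are left-closed,
right-open bins [0,1.301), [1.301,2), [2,3), [3,4), [4,6), [6,∞) →
0…5.

The relative score asks whether a set's scored members (its DPG genes)
are more perturbed than random same-size gene samples: the observed
absolute score is compared with `n_perm = 10,000` samples drawn without
replacement, counting permutations the observation **strictly**
exceeds; score = count/n_perm, levels [0,0.5), [0.5,0.6), …, [0.9,1] →
0…5.  The statistic and its null are design decisions (the underlying
formulas are not published in closed form); both are flagged in
outputs.  Two null pools are exposed: all measured genes
(`null_pool="all"`, the default, a genome-wide reference) or the set's
own measured genes (`null_pool="set"`, the literal within-pathway
DPG-versus-non-DPG contrast).  Under exchangeability the score is
uniform on [0,1] by construction — the package's null-calibration study
checks this (level-5 rate 0.10 ± 0.02 at 1,000 draws against a shared
seeded 10,000-permutation null, computed by the same `PathwayScoreNull`
path used for real scoring).  A direct consequence: a set whose members
moved *together with* its null pool (uniform perturbation) has
P(level ≤ 1) = 0.6, no more — the relative score can flag DPG-specific
perturbation but cannot actively certify uniformity.

Pair correlation summaries report the quartile mean of |Pearson r|
between pair members across all samples, per labelled pair group
(e.g. interaction-rate strata and modules); constant-profile or
unmeasured pairs are skipped and counted.  Tissue-variance bins use the
variance (ddof = 1) of per-tissue mean expression per gene, summarized
per set by the quartile mean, binned below-threshold/low/mid/high at
0.4, 0.5, 0.7 (the variance could alternatively be taken over all
samples; per-tissue means were chosen as the cleaner between-tissue
signal, and the choice is a one-line knob).  Housekeeping calling:
per-tissue mean above a presence threshold (default: the matrix
median) in **every** tissue and across-tissue variance below 0.5 on
log2 scale; both knobs explicit because no published rule exists.

## Synthetic generators: what they emulate

The generators define the study conditions under which the pipeline is
validated:

- **Genome**: 864 planted head-to-head pairs, 682 with positive and 182
  with negative TSS distance (the scale and split of the human DPG
  complement), placed on 12 chromosomes among filler genes kept
  ≥ 5 kb apart so no spurious pair can arise; distances drawn uniformly
  inside (−1 kb, 1 kb).  Chromosome lengths auto-size to fit unless
  given (explicit lengths that cannot hold the genes raise an
  infeasible-packing error).
- **Ontology**: one rooted DAG per namespace (BP/CC/MF), built by
  layered random attachment (each term takes 1–2 parents from the
  previous layer), which guarantees acyclicity and a unique root.  Each
  gene gets 10–18 direct annotations per namespace, drawn uniformly
  from non-root terms — a density in the range of real GO corpora.
  With probability `q(namespace)` a planted pair receives one shared
  non-root term on top of independent annotation.  The density matters:
  it sets how much one shared term moves the rcmax.avg combination, and
  at 10–18 terms the knob behaves as intended — q = 0.1 sits below KS
  detectability at 500 pairs vs 10,000 background while q = 0.9 is
  unmistakable.  Defaults q_BP = 0.1, q_CC = q_MF = 0.9 encode the
  co-localized-but-process-divergent structure of head-to-head pairs.
- **Gene sets**: memberships of sampled ontology terms (annotated genes
  of the term's subtree), restricted to terms covering at most half the
  annotated genes, since near-root terms make every category redundant;
  optional uniform random sets.
- **Expression**: log2 values = baseline + per-gene offset + group and
  tissue effects + Gaussian noise.  The first group is the
  control/reference; planted set shifts and the DPG-specific extra
  shift apply to all other groups.  In tissue mode, housekeeping genes
  get a raised baseline (+2.5) and nearly flat tissue profile
  (sd 0.1), tissue-specific genes a strongly varying one (sd 2.5),
  ordinary genes sd 1.2 — separations wide enough that class recovery
  is a test of the caller, not of luck.

One global seed expands into per-stage substreams
(`numpy.random.SeedSequence.spawn`), so each stage is individually
reproducible.

What passing the synthetic studies does **not** show: the generators
have no chromosome-length realism, no GC/CpG promoter structure, no
correlated annotation between related genes beyond the pair knob, no
array normalization artifacts, and Gaussian homoscedastic noise within
gene classes.  Recovery rates here bound the pipeline's correctness,
not its power on real, messier data.

## Problem sizes in the default studies

The seeded studies used by the test suite and the acceptance script run
at desk scale, chosen as the package's own defaults: similarity
contrast at 500 pairs vs 10,000 background pairs over 50 runs; planted
differential expression at 400–600 genes, 10 samples per group, 20
runs; relative-score nulls at 10,000 permutations and 1,000 draws.  The
`sample_background` default remains 100,000 pairs for real analyses.

## Known limitations

- One TSS per gene; no transcript isoforms.
- The exact published pairing rule behind the curated DPG catalogues is
  not recoverable; the caller documents its own deterministic rule.
- The interaction-rate denominator and the relative-score statistic are
  decided conventions (flagged in outputs), not published formulas.
- The KS p-value is asymptotic; exact small-sample computation is not
  the default.
- `part_of` ontology edges are ignored unless explicitly folded in at
  OBO read time.
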