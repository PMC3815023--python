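# dpgnet

Functional analysis of **divergently paired genes** (DPGs) — adjacent
head-to-head gene pairs whose transcription start sites (TSSs) face away
from each other within 1 kb and typically share a bidirectional
promoter.  The package is aimed at computational biologists who want to
ask, for a genome's DPG complement: do the two members of a pair do the
same thing, which functional categories do the pairs connect, and how do
those categories respond to a perturbation?

It provides, as a plain Python library:

- **DPG detection** from gene coordinates (BED/GFF3): signed TSS
  distance `d = tss(+ gene) − tss(− gene)` with pairs called for
  `0 < |d| < 1 kb`, one-to-one nearest-TSS pairing, and per-chromosome
  hypergeometric enrichment.
- **GO semantic similarity** of gene pairs per namespace: information
  content `IC(t) = −ln p(t)`, Schlicker relevance term similarity
  `max_a [2·IC(a)/(IC(t₁)+IC(t₂))]·[1−p(a)]` over common ancestors `a`,
  combined across term sets by `rcmax.avg` (mean of all row and column
  maxima), contrasted against a sampled random-pair background with a
  two-sample Kolmogorov–Smirnov test.
- **DPG-bridged set networks**: overlap maps (Simpson rate
  `|A∩B|/min(|A|,|B|)`) and interaction maps (rate of DPG pairs with one
  member exclusive to each set, min-normalized; default edge cutoff
  0.07), with greedy cohesiveness module detection
  (`f(V) = w_in/(w_in + w_bound + p·|V|)`, multi-pass seeding, Simpson
  merging).
- **Pathway perturbation scores**: moderated-t differential expression,
  gene scores `−log10 p`, absolute pathway score `(Q1+Q2+Q3)/3` of member
  scores with perturbation levels 0–5 (boundaries 1.301, 2, 3, 4, 6),
  and a permutation relative score (fraction of 10,000 equal-size random
  gene samples the observed score strictly exceeds; levels at 0.5…0.9) —
  plus pair expression-correlation quartile summaries, tissue-variance
  bins, and housekeeping-gene calling.
- **Synthetic data generators** for all of the above with planted ground
  truth, so every stage is testable without external downloads.

## Worked example

`examples/02_go_similarity.py` plants 300 head-to-head pairs whose
members share cellular-component terms with probability 0.9 but
biological-process terms with probability 0.1, then contrasts the pairs
against 10,000 random background pairs:

```
BP: mean pair similarity 0.169 vs background 0.161, KS D=0.068, p=0.127
CC: mean pair similarity 0.195 vs background 0.171, KS D=0.165, p=2.06e-07
MF: mean pair similarity 0.191 vs background 0.168, KS D=0.170, p=8.76e-08
```

CC and MF are significantly right-shifted while BP is indistinguishable
from random pairing — pair members tend to co-localize and share
molecular function while diverging in biological process.

`examples/04_pathway_scores.py` scores two gene sets in a simulated
case/control contrast: one whose DPG members carry an extra
DPG-specific shift, one shifted uniformly:

```
              set  n_members_measured  absolute_score  absolute_level  relative_score  relative_level
      dpg_shifted                  10        4.981502               4          1.0000               5
uniformly_shifted                  10       14.797479               5          0.1275               0
```

The uniformly shifted set is strongly differentially expressed (high
absolute level) but its DPG members do not stand out from the rest of
the set (low relative level); the DPG-shifted set is the reverse
pattern, which is exactly what the relative score is built to isolate.

The other examples cover DPG calling and chromosome enrichment (01),
module recovery on a planted three-block interaction map (03),
housekeeping-gene calling and tissue-variance bins (05), and the full
pipeline with all file outputs and a run manifest (06).

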