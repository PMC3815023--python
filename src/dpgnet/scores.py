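"""Differential-expression pathway perturbation scores and expression summaries.

Per-gene differential expression between two sample groups uses a
moderated t-statistic: sample variances are shrunk toward a pooled prior
fitted by moment-matching a scaled-F distribution (the closed-form core
of empirical-Bayes variance moderation).  Gene p-values become scores
``-log10 p``; a pathway's *absolute score* is the mean of the three
quartiles (Q1, Q2, Q3) of its member scores, discretized into
perturbation levels 0-5; its *relative score* is the fraction of
equal-size random gene samples whose absolute score falls strictly below
the observed one, discretized into levels 0-5.  Additional summaries:
pair expression-correlation quartile means, per-set tissue-variance
bins, housekeeping-gene calling, and gene-list overlap reports.

All expression input is assumed gene-level log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .geometry import DpgPair

__all__ = [
    "ExpressionMatrix",
    "moderated_de",
    "gene_score",
    "absolute_level",
    "relative_level",
    "quartile_mean",
    "pathway_absolute_score",
    "PathwayScoreNull",
    "pathway_relative_score",
    "score_collection",
    "pair_correlation_summary",
    "tissue_variance_bins",
    "call_housekeeping",
    "list_overlap_stats",
]

# absolute-level bin edges: -log10(0.05), then p = 0.01, 1e-3, 1e-4, 1e-6
_ABS_EDGES = (np.log10(20.0), 2.0, 3.0, 4.0, 6.0)
_REL_EDGES = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with sample group (and tissue) labels."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    groups: dict[str, str]  # sample -> group label
    tissues: dict[str, str] = field(default_factory=dict)  # sample -> tissue label

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]

    def tissue_means(self) -> pd.DataFrame:
        """Per-gene mean expression per tissue label."""
        if not self.tissues:
            raise ValueError("expression matrix has no tissue labels")
        cols = pd.Series({s: self.tissues[s] for s in self.values.columns})
        return self.values.T.groupby(cols).mean().T


def _fit_var_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F variance distribution.

    Uses the log-variance moments: with z = log s^2,
    E z = log s0^2 + digamma(df/2) - log(df/2) + log(d0/2) - digamma(d0/2)
    Var z = trigamma(df/2) + trigamma(d0/2);
    d0 solves trigamma(d0/2) = Var z - trigamma(df/2) by Newton inversion.
    Returns (inf, exp(mean adjustment)) when the observed spread does not
    exceed the chi-square sampling spread (complete shrinkage).
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    mean_e = float(np.mean(e))
    if n > 1:
        var_e = float(np.sum((e - mean_e) ** 2) / (n - 1)) - float(
            special.polygamma(1, df / 2.0)
        )
    else:
        var_e = 0.0
    if var_e <= 0:
        return np.inf, float(np.exp(mean_e))
    # invert trigamma by Newton on x: polygamma(1, x) = var_e
    x = 0.5 + 1.0 / var_e  # starting value per Smyth's inversion
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        delta = tri * (1.0 - tri / var_e) / float(special.polygamma(2, x))
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_sq = float(np.exp(mean_e + special.digamma(x) - np.log(x)))
    return d0, s0_sq


def moderated_de(
    matrix: ExpressionMatrix,
    case_group: str,
    control_group: str,
    moderated: bool = True,
) -> pd.DataFrame:
    """Per-gene differential expression between two sample groups.

    With ``moderated`` (default) the residual variance of each gene is
    replaced by the posterior ``(d0*s0^2 + df*s^2) / (d0 + df)`` with the
    prior fitted across genes, and the t-statistic is referred to a
    t-distribution on ``d0 + df`` degrees of freedom.  With
    ``moderated=False`` an ordinary pooled-variance two-sample t is used.

    Returns a DataFrame with columns gene, effect (case - control log2
    difference), p, score (= -log10 p).
    """
    case = matrix.group_samples(case_group)
    ctrl = matrix.group_samples(control_group)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("both groups need at least 2 samples")
    x = matrix.values[case].to_numpy(dtype=float)
    y = matrix.values[ctrl].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    df_resid = n1 + n2 - 2
    diff = x.mean(axis=1) - y.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    se_factor = 1.0 / n1 + 1.0 / n2

    positive = s2 > 0
    if moderated and positive.any():
        d0, s0_sq = _fit_var_prior(s2[positive], float(df_resid))
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
    else:
        s2_post = s2.copy()
        df_total = float(df_resid)

    p = np.ones(len(diff))
    se = np.sqrt(s2_post * se_factor)
    ok = se > 0
    t = np.zeros(len(diff))
    t[ok] = diff[ok] / se[ok]
    if np.isinf(df_total):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)
    # zero variance everywhere: p=1 when also zero difference, else tiny p
    degenerate = (~ok) & (np.abs(diff) > 0)
    p[degenerate] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "effect": diff,
            "p": p,
            "score": -np.log10(p),
        }
    )


def gene_score(p: float) -> float:
    """Score transform ``-log10(p)``; ``p = 0.05`` maps to 1.301."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return float(-np.log10(p))


def quartile_mean(values: Sequence[float]) -> float:
    """Mean of the three quartiles (Q1, Q2, Q3), linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quartile_mean of an empty sequence is undefined")
    q = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return float(q.mean())


def absolute_level(score: float) -> int:
    """Perturbation level 0-5 for an absolute pathway score.

    Bins (left-closed, right-open): [0, 1.301) -> 0, [1.301, 2) -> 1,
    [2, 3) -> 2, [3, 4) -> 3, [4, 6) -> 4, [6, inf) -> 5; 1.301 is
    ``-log10(0.05)``.
    """
    return int(np.searchsorted(_ABS_EDGES, score, side="right"))


def relative_level(score: float) -> int:
    """Perturbation level 0-5 for a relative score in [0, 1].

    Bins: [0, 0.5) -> 0, then 0.1-wide bins to [0.9, 1] -> 5.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError("relative score must lie in [0, 1]")
    return int(np.searchsorted(_REL_EDGES, score, side="right"))


def pathway_absolute_score(member_scores: Sequence[float]) -> tuple[float, int]:
    """Absolute pathway score and level: quartile mean of member gene scores."""
    s = quartile_mean(member_scores)
    return s, absolute_level(s)


class PathwayScoreNull:
    """Null distribution of the absolute score for random member sets.

    Draws ``n_perm`` gene samples of a given size without replacement from
    all measured gene scores and records each sample's quartile-mean
    score.  Shared by ``pathway_relative_score`` so that many sets of the
    same size can be scored against one seeded null.
    """

    def __init__(
        self,
        all_scores: Sequence[float],
        size: int,
        n_perm: int = 10_000,
        seed: int | None = None,
    ):
        scores = np.asarray(all_scores, dtype=float)
        if size > scores.size:
            raise ValueError("member size exceeds the number of measured genes")
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        chunk = max(1, min(n_perm, int(4e7 // max(scores.size, 1)) or 1))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            keys = rng.random((m, scores.size))
            idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
            sample = scores[idx]
            q = np.quantile(sample, [0.25, 0.5, 0.75], axis=1, method="linear")
            null[done : done + m] = q.mean(axis=0)
            done += m
        self.null_scores = null
        self.size = size
        self.n_perm = n_perm

    def relative_score(self, observed: float) -> tuple[float, int]:
        """Fraction of permutations strictly below ``observed``, with level."""
        freq = int(np.sum(observed > self.null_scores))
        score = freq / self.n_perm
        return score, relative_level(score)


def pathway_relative_score(
    member_scores: Sequence[float],
    all_scores: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    null: PathwayScoreNull | None = None,
) -> tuple[float, int]:
    """Relative pathway score by permutation.

    The observed statistic is the absolute pathway score of the member
    genes; the null recomputes it on ``n_perm`` random same-size gene
    samples drawn without replacement from all measured genes.  The score
    is the fraction of permutations the observed statistic strictly
    exceeds, in [0, 1], with its level 0-5.
    """
    observed = quartile_mean(member_scores)
    if null is None:
        null = PathwayScoreNull(all_scores, size=len(member_scores), n_perm=n_perm, seed=seed)
    elif null.size != len(member_scores):
        raise ValueError("null distribution size does not match member count")
    return null.relative_score(observed)


def score_collection(
    de: pd.DataFrame,
    sets: Mapping[str, set[str]],
    dpg_genes: Iterable[str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    null_pool: str = "all",
) -> pd.DataFrame:
    """Absolute and relative perturbation scores for every set in a collection.

    When ``dpg_genes`` is given, a set's members are restricted to its DPG
    genes (the scored unit of the pathway analysis).  The relative-score
    null draws same-size gene samples from all measured genes
    (``null_pool="all"``, default) or from the set's own measured genes
    (``null_pool="set"``, the literal DPG-vs-non-DPG within-pathway
    contrast).  Sets with no measured member yield a flagged row with NaN
    scores.
    """
    if null_pool not in ("all", "set"):
        raise ValueError("null_pool must be 'all' or 'set'")
    score_by_gene = dict(zip(de["gene"], de["score"]))
    all_scores = de["score"].to_numpy()
    dpg = set(dpg_genes) if dpg_genes is not None else None
    rng = np.random.default_rng(seed)
    nulls: dict[int, PathwayScoreNull] = {}
    rows = []
    for name in sets:
        members = sets[name] if dpg is None else sets[name] & dpg
        measured = sorted(m for m in members if m in score_by_gene)
        if not measured:
            rows.append((name, 0, np.nan, -1, np.nan, -1))
            continue
        member_scores = [score_by_gene[m] for m in measured]
        abs_score, abs_lvl = pathway_absolute_score(member_scores)
        size = len(measured)
        if null_pool == "set":
            pool = np.asarray(
                [score_by_gene[m] for m in sorted(sets[name]) if m in score_by_gene]
            )
            null = PathwayScoreNull(
                pool, size=size, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
            )
        else:
            if size not in nulls:
                nulls[size] = PathwayScoreNull(
                    all_scores, size=size, n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                )
            null = nulls[size]
        rel_score, rel_lvl = pathway_relative_score(
            member_scores, all_scores, null=null
        )
        rows.append((name, size, abs_score, abs_lvl, rel_score, rel_lvl))
    return pd.DataFrame(
        rows,
        columns=[
            "set",
            "n_members_measured",
            "absolute_score",
            "absolute_level",
            "relative_score",
            "relative_level",
        ],
    )


def pair_correlation_summary(
    matrix: ExpressionMatrix,
    pair_groups: Mapping[str, Sequence[DpgPair]],
) -> pd.DataFrame:
    """Quartile-mean of |Pearson r| for labelled groups of gene pairs.

    Per pair, the two member genes' expression profiles are correlated
    across all samples; per group, the mean of the three quartiles of the
    absolute correlations is reported.  Pairs with a constant profile or
    an unmeasured member are skipped and counted.
    """
    values = matrix.values
    rows = []
    for label, pairs in pair_groups.items():
        rs = []
        skipped = 0
        for p in pairs:
            if p.minus_gene not in values.index or p.plus_gene not in values.index:
                skipped += 1
                continue
            a = values.loc[p.minus_gene].to_numpy(dtype=float)
            b = values.loc[p.plus_gene].to_numpy(dtype=float)
            if np.std(a) == 0 or np.std(b) == 0:
                skipped += 1
                continue
            rs.append(abs(float(np.corrcoef(a, b)[0, 1])))
        summary = quartile_mean(rs) if rs else np.nan
        rows.append((label, len(rs), skipped, summary))
    return pd.DataFrame(
        rows, columns=["group", "n_pairs", "n_skipped", "quartile_mean_abs_r"]
    )


def tissue_variance_bins(
    matrix: ExpressionMatrix,
    sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-set across-tissue expression variance with display bins.

    Per gene: variance (ddof=1) of the per-tissue mean expression.  Per
    set: quartile mean of member variances.  Bins follow the display
    ranges low 0.4-0.5, mid 0.5-0.7, high >0.7, with anything under 0.4
    labelled below-threshold.
    """
    tmeans = matrix.tissue_means()
    if tmeans.shape[1] < 3:
        raise ValueError("tissue variance needs at least 3 tissues")
    gene_var = tmeans.var(axis=1, ddof=1)
    rows = []
    for name, members in sets.items():
        vs = gene_var.reindex(sorted(members)).dropna()
        if vs.empty:
            rows.append((name, 0, np.nan, "unmeasured"))
            continue
        v = quartile_mean(vs.to_numpy())
        if v < 0.4:
            b = "below-threshold"
        elif v <= 0.5:
            b = "low"
        elif v <= 0.7:
            b = "mid"
        else:
            b = "high"
        rows.append((name, len(vs), v, b))
    return pd.DataFrame(rows, columns=["set", "n_members_measured", "variance", "bin"])


def call_housekeeping(
    matrix: ExpressionMatrix,
    presence_threshold: float | None = None,
    variance_cap: float = 0.5,
) -> list[str]:
    """Call housekeeping genes from multi-tissue expression.

    A gene is housekeeping when its per-tissue mean exceeds the presence
    threshold in *every* tissue (default threshold: the matrix-wide
    median) and the variance of its per-tissue means stays below
    ``variance_cap`` (log2 scale).
    """
    tmeans = matrix.tissue_means()
    if tmeans.shape[1] < 2:
        raise ValueError("housekeeping calling needs at least 2 tissues")
    if presence_threshold is None:
        presence_threshold = float(np.median(matrix.values.to_numpy()))
    present = (tmeans > presence_threshold).all(axis=1)
    stable = tmeans.var(axis=1, ddof=1) < variance_cap
    return sorted(tmeans.index[present & stable])


def list_overlap_stats(
    lists: Mapping[str, Iterable[str]],
    dpg_pairs: Sequence[DpgPair],
) -> dict:
    """Overlap of labelled gene lists with the DPG gene universe.

    Reports, per list, the overlap count and fraction against the DPG
    genes; across lists, the intersection and union sizes; and, of the
    union's DPG genes, how many are organized as complete DPG pairs (both
    members present).
    """
    if not lists:
        raise ValueError("need at least one gene list")
    dpg_genes = {g for p in dpg_pairs for g in p.genes}
    sets = {label: set(genes) for label, genes in lists.items()}
    per_list = {}
    for label, s in sets.items():
        overlap = len(s & dpg_genes)
        per_list[label] = {
            "n_genes": len(s),
            "n_overlap_dpg": overlap,
            "fraction_of_list": overlap / len(s) if s else 0.0,
        }
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    union_dpg = union & dpg_genes
    complete = sum(
        1 for p in dpg_pairs if p.minus_gene in union_dpg and p.plus_gene in union_dpg
    )
    return {
        "per_list": per_list,
        "intersection_size": len(inter),
        "union_size": len(union),
        "union_dpg_genes": len(union_dpg),
        "complete_pairs": complete,
        "genes_in_complete_pairs": 2 * complete,
    }
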