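"""Immune microenvironment scoring, subtyping and expression analysis.

Cell-type abundance is proxied by single-sample rank-based gene-set
enrichment (ssGSEA with weight exponent 0.25), scored per sample over a
collection of immune cell-type marker sets. Samples are subtyped by
k-means on z-scored enrichment values, with the number of clusters
chosen by a consensus vote of four selection criteria (elbow,
silhouette, gap statistic, Calinski-Harabasz) and the final assignment
taken from the most stable of many random-restart runs as judged by a
consensus co-assignment matrix. Clusters are labelled immune hot /
suppressed / moderate / cold from their lymphoid and myeloid score
means. Differential expression (Wilcoxon rank-sum with BH adjustment on
log2 fold changes) and pre-ranked GSEA complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "enrichment_scores",
    "ClusterAssignment",
    "consensus_kmeans",
    "label_clusters",
    "neutrophil_tcell_ratio",
    "differential_expression",
    "gsea_preranked",
]


def enrichment_scores(
    expr: ExpressionMatrix, sets: GeneSetCollection, alpha: float = 0.25
) -> pd.DataFrame:
    """ssGSEA-style enrichment scores (samples x sets).

    Per sample, genes are ranked by expression (descending); the score
    is the integrated difference between the weighted ECDF of in-set
    genes (weights = rank position ** alpha) and the unweighted ECDF of
    out-of-set genes, normalized by the number of genes. Missing set
    genes are dropped with a warning; a set with no overlap raises.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    genes = list(expr.genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    X = expr.values.to_numpy(dtype=float)
    # ranks[i, j]: descending rank (1 = highest) of gene i in sample j
    order = np.argsort(-X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    col = np.arange(X.shape[1])
    ranks[order, col] = np.arange(1, n_genes + 1)[:, None]

    scores = {}
    for name in sets.names():
        members = [g for g in sets[name] if g in gene_pos]
        dropped = len(sets[name]) - len(members)
        if not members:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if dropped:
            logger.warning("set %s: %d genes absent from the matrix", name, dropped)
        idx = np.array([gene_pos[g] for g in members])
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[idx] = True
        out = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            # walk the ranking once, accumulating the running-sum statistic
            r = ranks[:, j]
            pos = np.empty(n_genes, dtype=np.int64)
            pos[r - 1] = np.arange(n_genes)
            hit = in_set[pos]  # hits in ranking order
            w = (np.arange(1, n_genes + 1, dtype=float)[::-1]) ** alpha
            w_hit = np.where(hit, w, 0.0)
            p_hit = np.cumsum(w_hit) / max(w_hit.sum(), 1e-300)
            p_miss = np.cumsum(~hit) / max(n_genes - len(members), 1)
            out[j] = float((p_hit - p_miss).sum() / n_genes)
        scores[name] = out
    return pd.DataFrame(scores, index=list(expr.samples))


@dataclass
class ClusterAssignment:
    """Consensus clustering result."""

    labels: pd.Series  # sample -> cluster id (1..k)
    k: int
    votes: dict  # method -> chosen k
    stability: float  # mean consensus co-assignment of the chosen run
    cluster_labels: dict = field(default_factory=dict)  # id -> semantic label


def _wss(X: np.ndarray, k: int, seed: int) -> float:
    km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(X)
    return float(km.inertia_)


def _gap_statistic(
    X: np.ndarray, ks: Sequence[int], n_refs: int, rng: np.random.Generator
) -> int:
    """Tibshirani gap statistic: smallest k with gap(k) >= gap(k+1) - s(k+1)."""
    mins, maxs = X.min(axis=0), X.max(axis=0)
    log_w = {k: np.log(_wss(X, k, int(rng.integers(2**31)))) for k in ks}
    ref_log_w = {k: np.empty(n_refs) for k in ks}
    for b in range(n_refs):
        ref = rng.uniform(mins, maxs, size=X.shape)
        for k in ks:
            ref_log_w[k][b] = np.log(_wss(ref, k, int(rng.integers(2**31))))
    gap = {k: ref_log_w[k].mean() - log_w[k] for k in ks}
    s = {k: ref_log_w[k].std(ddof=0) * np.sqrt(1 + 1 / n_refs) for k in ks}
    ks = sorted(ks)
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - s[ks[i + 1]]:
            return k
    return ks[-1]


def consensus_kmeans(
    scores: pd.DataFrame,
    k_range: Sequence[int] = range(2, 9),
    n_perm: int = 1000,
    n_gap_refs: int = 50,
    seed: int = 0,
) -> ClusterAssignment:
    """Consensus k-means subtyping of samples x cell-type scores.

    Cell-type scores are z-scored before clustering. Four k-selection
    votes are collected: elbow (maximum second difference of
    within-cluster SS), mean silhouette, gap statistic and
    Calinski-Harabasz; the chosen k needs >= 3 agreeing votes, else the
    silhouette winner is used with a warning. The final assignment is
    the most stable of ``n_perm`` random-restart k-means runs, where a
    run's stability is the mean consensus-matrix co-assignment
    frequency over its same-cluster pairs.
    """
    ks = sorted(k_range)
    n = scores.shape[0]
    if n < max(ks) + 1:
        raise ValueError("k_range too large for the sample count")
    X = scores.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)

    wss = np.array([_wss(X, k, int(rng.integers(2**31))) for k in ks])
    if len(ks) >= 3:
        second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]
        elbow_k = ks[1 + int(np.argmax(second_diff))]
    else:
        elbow_k = ks[0]
    sil, ch = {}, {}
    for k in ks:
        lab = KMeans(n_clusters=k, n_init=5,
                     random_state=int(rng.integers(2**31))).fit_predict(X)
        sil[k] = silhouette_score(X, lab, metric="euclidean")
        ch[k] = calinski_harabasz_score(X, lab)
    sil_k = max(ks, key=lambda k: sil[k])
    ch_k = max(ks, key=lambda k: ch[k])
    gap_k = _gap_statistic(X, ks, n_gap_refs, rng)
    votes = {"elbow": elbow_k, "silhouette": sil_k, "gap": gap_k,
             "calinski_harabasz": ch_k}
    counts = pd.Series(list(votes.values())).value_counts()
    if counts.iloc[0] >= 3:
        chosen = int(counts.index[0])
    else:
        chosen = sil_k
        logger.warning(
            "no k reached 3/4 votes (%s); falling back to silhouette k=%d",
            votes, chosen,
        )

    runs = np.empty((n_perm, n), dtype=np.int64)
    for r in range(n_perm):
        runs[r] = KMeans(
            n_clusters=chosen, n_init=1, init="random",
            random_state=int(rng.integers(2**31)),
        ).fit_predict(X)
    consensus = np.zeros((n, n))
    for r in range(n_perm):
        same = runs[r][:, None] == runs[r][None, :]
        consensus += same
    consensus /= n_perm
    iu = np.triu_indices(n, k=1)
    best_run, best_stab = 0, -1.0
    for r in range(n_perm):
        same = runs[r][:, None] == runs[r][None, :]
        mask = same[iu]
        if mask.sum() == 0:
            continue
        stab = float(consensus[iu][mask].mean())
        if stab > best_stab:
            best_run, best_stab = r, stab
    final = runs[best_run]
    # relabel 1..k by decreasing cluster size (ties by first occurrence)
    sizes = pd.Series(final).value_counts()
    remap = {old: i + 1 for i, old in enumerate(sizes.index)}
    labels = pd.Series([remap[v] for v in final], index=scores.index, name="cluster")
    return ClusterAssignment(labels, chosen, votes, best_stab)


def label_clusters(
    scores: pd.DataFrame,
    assignment: ClusterAssignment,
    lymphoid: Sequence[str],
    myeloid: Sequence[str],
) -> ClusterAssignment:
    """Attach semantic labels {hot, suppressed, moderate, cold} for k=4.

    hot = max(lymphoid mean + myeloid mean); suppressed = max(myeloid -
    lymphoid) among the rest; cold = min overall mean among the rest;
    the remaining cluster is moderate. Ties break by cluster id. For
    k != 4, clusters fall back to labels C1..Ck.
    """
    ids = sorted(assignment.labels.unique())
    if len(ids) != 4:
        assignment.cluster_labels = {c: f"C{c}" for c in ids}
        return assignment
    lym = [c for c in lymphoid if c in scores.columns]
    mye = [c for c in myeloid if c in scores.columns]
    z = (scores - scores.mean()) / scores.std(ddof=0).replace(0, 1.0)
    stats_ = {}
    for c in ids:
        rows = z.loc[assignment.labels[assignment.labels == c].index]
        stats_[c] = (
            rows[lym].to_numpy().mean(),
            rows[mye].to_numpy().mean(),
            rows.to_numpy().mean(),
        )
    remaining = list(ids)
    hot = max(remaining, key=lambda c: (stats_[c][0] + stats_[c][1], -c))
    remaining.remove(hot)
    suppressed = max(remaining, key=lambda c: (stats_[c][1] - stats_[c][0], -c))
    remaining.remove(suppressed)
    cold = min(remaining, key=lambda c: (stats_[c][2], c))
    remaining.remove(cold)
    moderate = remaining[0]
    assignment.cluster_labels = {
        hot: "hot", suppressed: "suppressed", cold: "cold", moderate: "moderate",
    }
    return assignment


def neutrophil_tcell_ratio(
    scores: pd.DataFrame,
    neutrophil: str = "Neutrophils",
    cd4: str = "T_cells_CD4",
    cd8: str = "T_cells_CD8",
) -> pd.Series:
    """Per-sample neutrophil / (CD4 + CD8) T-cell score ratio.

    Enrichment scores can be negative, so all three columns are shifted
    by the global minimum before the ratio; zero denominators give NaN.
    """
    cols = [neutrophil, cd4, cd8]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise KeyError(f"missing cell types {missing}")
    block = scores[cols]
    shift = min(block.to_numpy().min(), 0.0)
    shifted = block - shift
    denom = shifted[cd4] + shifted[cd8]
    ratio = shifted[neutrophil] / denom.replace(0, np.nan)
    ratio.name = "neutrophil_tcell_ratio"
    ratio.attrs["shift"] = -shift
    return ratio


def differential_expression(
    expr: ExpressionMatrix,
    labels: pd.Series,
    cluster: int,
    pseudocount: float = 1.0,
    logfc_cut: float = 1.5,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Cluster-versus-rest differential expression.

    log2 fold change of (mean + pseudocount); two-sided Wilcoxon
    rank-sum p-values, BH adjusted. ``significant`` marks genes with
    \\|logFC\\| > 1.5 and q < 0.05. Both groups need >= 3 samples.
    """
    labels = labels.reindex(expr.samples)
    in_grp = labels == cluster
    if in_grp.sum() < 3 or (~in_grp).sum() < 3:
        raise ValueError("both groups need at least 3 samples")
    A = expr.values.loc[:, in_grp.to_numpy()].to_numpy(dtype=float)
    B = expr.values.loc[:, (~in_grp).to_numpy()].to_numpy(dtype=float)
    logfc = np.log2(A.mean(axis=1) + pseudocount) - np.log2(B.mean(axis=1) + pseudocount)
    res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {"logFC": logfc, "p": p, "q": q}, index=expr.genes
    )
    df["significant"] = (df["logFC"].abs() > logfc_cut) & (df["q"] < q_cut)
    return df


def gsea_preranked(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA with the classic weighted running-sum statistic.

    ``ranking`` maps genes to scores (e.g. log fold changes); genes are
    sorted descending, in-set steps are weighted by \\|score\\|, and the
    enrichment score (ES) is the maximum-deviation of the running sum.
    The null is gene-label permutation; NES divides ES by the mean
    \\|null ES\\| of the same sign and q-values are BH-adjusted per sign.
    Sets without any gene in the ranking are skipped with a warning.
    """
    if ranking.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    rng = np.random.default_rng(seed)
    order = np.argsort(-ranking.to_numpy(dtype=float), kind="stable")
    ranked_genes = ranking.index.to_numpy()[order]
    weights = np.abs(ranking.to_numpy()[order])
    gene_pos = {g: i for i, g in enumerate(ranked_genes)}
    n = len(ranked_genes)

    def es_of(idx_mask: np.ndarray) -> float:
        w = np.where(idx_mask, weights, 0.0)
        total = w.sum()
        if total == 0:
            w = idx_mask.astype(float)
            total = w.sum()
        n_miss = n - int(idx_mask.sum())
        running = np.cumsum(w / total - (~idx_mask) / max(n_miss, 1))
        i = int(np.argmax(np.abs(running)))
        return float(running[i])

    rows = []
    for name in sets.names():
        members = [g for g in sets[name] if g in gene_pos]
        if not members:
            logger.warning("set %s has no genes in the ranking; skipped", name)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        es = es_of(mask)
        m = len(members)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=m, replace=False)] = True
            null[b] = es_of(perm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / max(denom, 1e-300)
        if es >= 0:
            p = (np.sum(null >= es) + 1) / (n_perm + 1)
        else:
            p = (np.sum(null <= es) + 1) / (n_perm + 1)
        rows.append((name, es, nes, float(p), m))
    df = pd.DataFrame(rows, columns=["set", "ES", "NES", "p", "n_genes"]).set_index("set")
    if not df.empty:
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
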