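"""Individual-level structure: distance trees and DAPC assignment.

Distances between individuals use the Provesti / allele-sharing metric
(mean over shared non-missing loci of |dosage difference| / 2).  Trees are
UPGMA (average linkage, ultrametric) with bootstrap-over-loci clade support.

DAPC (discriminant analysis of principal components) reduces the scaled
genotype matrix by PCA, then finds linear discriminant axes maximizing
between-group over within-group variance on the retained PC scores.
Membership probabilities are the softmax of -1/2 x squared Mahalanobis
distance to the group centroids in discriminant space (pooled within-group
covariance) — the Gaussian-posterior reading of the discriminant model.
The number of clusters comes from k-means + BIC; the number of retained
PCs from a-score (alpha) optimization, which penalizes overfitting by
comparing reassignment rates against label-permuted refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger("wrassepop")


# ---------------------------------------------------------------------------
# Distances and UPGMA
# ---------------------------------------------------------------------------

def individual_distances(g: GenotypeMatrix, metric: str = "provesti") -> np.ndarray:
    """Pairwise Provesti distance: mean over complete loci of |gi - gj| / 2."""
    if metric != "provesti":
        raise ValueError(f"unknown metric {metric!r}")
    codes = g.codes.astype(float)
    obs = g.codes != MISSING
    n = g.n_individuals
    d = np.zeros((n, n))
    for i in range(n):
        both = obs[i][None, :] & obs[i + 1:]
        shared = both.sum(axis=1)
        if (shared == 0).any():
            bad = i + 1 + int(np.flatnonzero(shared == 0)[0])
            raise ValueError(
                f"individuals {g.individuals[i]} and {g.individuals[bad]} "
                "share no non-missing loci"
            )
        diff = np.abs(codes[i][None, :] - codes[i + 1:]) / 2.0
        diff[~both] = 0.0
        d[i, i + 1:] = d[i + 1:, i] = diff.sum(axis=1) / shared
    return d


@dataclass
class TreeNode:
    """Binary UPGMA tree node; leaves carry ``index``/``name``."""

    height: float = 0.0
    index: int | None = None
    name: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.index is not None

    def leaves(self) -> frozenset[int]:
        if self.is_leaf:
            return frozenset([self.index])
        return self.left.leaves() | self.right.leaves()

    def clades(self) -> list[frozenset[int]]:
        """Leaf sets of all internal nodes (including the root)."""
        if self.is_leaf:
            return []
        return [self.leaves()] + self.left.clades() + self.right.clades()

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def newick(self, min_support: float | None = None) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name or node.index}:{bl:.6g}"
            inner = f"({fmt(node.left, node.height)},{fmt(node.right, node.height)})"
            label = ""
            if node.support is not None and (
                min_support is None or node.support >= min_support
            ):
                label = f"{node.support:g}"
            return f"{inner}{label}:{bl:.6g}"

        if self.is_leaf:
            return f"{self.name or self.index};"
        body = f"({fmt(self.left, self.height)},{fmt(self.right, self.height)})"
        label = ""
        if self.support is not None and (
            min_support is None or self.support >= min_support
        ):
            label = f"{self.support:g}"
        return f"{body}{label};"


def upgma_tree(d: np.ndarray, names: list[str] | None = None) -> TreeNode:
    """Average-linkage (UPGMA) agglomeration with ultrametric heights.

    Ties are broken by the lexicographically lowest active-cluster index
    pair, making the topology deterministic.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix of size >= 2")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, index=i, name=names[i] if names else str(i))
        for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            ((dist[(min(a, b), max(a, b))], (a, b))
             for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        dmin, (a, b) = best
        new = TreeNode(
            height=dmin / 2.0, left=nodes[a], right=nodes[b]
        )
        nodes[next_id] = new
        sizes[next_id] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            dist[(min(c, next_id), max(c, next_id))] = (
                sizes[a] * dac + sizes[b] * dbc
            ) / (sizes[a] + sizes[b])
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return nodes[active[0]]


def bootstrap_support(
    g: GenotypeMatrix, n_boot: int = 100, seed: int = 0,
    metric: str = "provesti",
) -> TreeNode:
    """UPGMA tree with clade support from bootstrap resampling of loci.

    Support = percentage of replicate trees containing the same leaf set
    as a clade.  With ``n_boot=0`` the tree is returned unannotated.
    """
    tree = upgma_tree(individual_distances(g, metric), names=list(g.individuals))
    if n_boot == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[int], int] = {c: 0 for c in tree.clades()}
    for _ in range(n_boot):
        idx = rng.integers(0, g.n_loci, g.n_loci)
        db = _distances_on_loci(g, idx)
        tb = upgma_tree(db)
        present = set(tb.clades())
        for c in counts:
            if c in present:
                counts[c] += 1
    for node in tree.internal_nodes():
        node.support = 100.0 * counts[node.leaves()] / n_boot
    return tree


def _distances_on_loci(g: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    codes = g.codes[:, idx].astype(float)
    obs = g.codes[:, idx] != MISSING
    n = g.n_individuals
    d = np.zeros((n, n))
    for i in range(n):
        both = obs[i][None, :] & obs[i + 1:]
        shared = np.maximum(both.sum(axis=1), 1)
        diff = np.abs(codes[i][None, :] - codes[i + 1:]) / 2.0
        diff[~both] = 0.0
        d[i, i + 1:] = d[i + 1:, i] = diff.sum(axis=1) / shared
    return d


# ---------------------------------------------------------------------------
# Genotype scaling / PCA plumbing
# ---------------------------------------------------------------------------

def scale_genotypes(
    codes: np.ndarray, center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center by locus mean, scale by sqrt(p(1-p)); missing -> locus mean.

    Returns (scaled matrix, center, scale) so held-out data can reuse the
    training statistics.
    """
    x = codes.astype(float)
    miss = codes == MISSING
    x[miss] = np.nan
    if center is None:
        center = np.nanmean(x, axis=0)
        center = np.where(np.isnan(center), 0.0, center)
        p = center / 2.0
        scale = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    x = np.where(np.isnan(x), center[None, :], x)
    return (x - center[None, :]) / scale[None, :], center, scale


# ---------------------------------------------------------------------------
# Cluster number by k-means + BIC
# ---------------------------------------------------------------------------

def find_clusters(
    g: GenotypeMatrix, k_max: int = 10, n_pcs: int | None = None,
    variance_kept: float = 0.95, seed: int = 0, n_init: int = 10,
) -> tuple[np.ndarray, int, np.ndarray]:
    """BIC over K = 1..k_max from k-means on PCA scores.

    BIC = n * ln(WSS / n) + K * ln(n).  Returns (bic array, best K,
    cluster labels at best K).
    """
    if g.n_individuals <= k_max:
        raise ValueError("need more individuals than k_max")
    x, _, _ = scale_genotypes(g.codes)
    pca = PCA(n_components=min(g.n_individuals - 1, g.n_loci), random_state=seed)
    scores = pca.fit_transform(x)
    if n_pcs is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, variance_kept) + 1)
    s = scores[:, :n_pcs]
    n = s.shape[0]
    bics = np.empty(k_max)
    labels_by_k = []
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((s - s.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(s)
            wss = float(km.inertia_)
            labels = km.labels_
        bics[k - 1] = n * np.log(wss / n) + k * np.log(n)
        labels_by_k.append(labels)
    best_k = int(np.argmin(bics) + 1)
    return bics, best_k, labels_by_k[best_k - 1]


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcModel:
    n_pcs_retained: int
    groups: list[str]
    center: np.ndarray
    scale: np.ndarray
    pc_loadings: np.ndarray        # (loci, n_pcs)
    discriminant_axes: np.ndarray  # (n_pcs, n_da)
    group_centroids: np.ndarray    # (n_groups, n_da)
    within_cov: np.ndarray         # pooled within-group covariance in DA space
    membership: np.ndarray         # training individuals x groups
    pca_mean: np.ndarray = field(default=None, repr=False)
    pc_scores: np.ndarray = field(default=None, repr=False)

    def assignments(self) -> np.ndarray:
        return np.asarray(self.groups)[np.argmax(self.membership, axis=1)]


def dapc_fit(
    g: GenotypeMatrix, groups: list[str] | np.ndarray | None = None,
    n_pcs: int = 5, ridge: float = 1e-8,
) -> DapcModel:
    """Fit DAPC: PCA to ``n_pcs`` scores, then linear discriminants."""
    labels = np.asarray(groups if groups is not None else g.populations)
    group_names = list(dict.fromkeys(labels))
    n_groups = len(group_names)
    if n_pcs >= g.n_individuals - n_groups:
        raise ValueError("n_pcs must be < n_individuals - n_groups")
    x, center, scale = scale_genotypes(g.codes)
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # x is centered by scale_genotypes; PCA re-centers

    # scatter matrices on PC scores
    overall_mean = scores.mean(axis=0)
    W = np.zeros((n_pcs, n_pcs))
    B = np.zeros((n_pcs, n_pcs))
    means = {}
    for gn in group_names:
        s = scores[labels == gn]
        mu = s.mean(axis=0)
        means[gn] = mu
        W += (s - mu).T @ (s - mu)
        B += len(s) * np.outer(mu - overall_mean, mu - overall_mean)
    W /= len(labels) - n_groups
    tries = 0
    while True:
        try:
            evals, evecs = sla.eigh(B, W + np.eye(n_pcs) * (ridge if tries else 0))
            break
        except sla.LinAlgError:
            tries += 1
            if tries > 3:
                raise
            logger.warning("singular within-group scatter; adding ridge %g", ridge)
    order = np.argsort(evals)[::-1]
    n_da = min(n_groups - 1, n_pcs)
    axes = evecs[:, order[:n_da]]

    da_scores = scores @ axes
    centroids = np.stack([means[gn] @ axes for gn in group_names])
    Wd = np.zeros((n_da, n_da))
    for i, gn in enumerate(group_names):
        s = da_scores[labels == gn] - centroids[i]
        Wd += s.T @ s
    Wd /= len(labels) - n_groups
    Wd += np.eye(n_da) * ridge

    membership = _memberships(da_scores, centroids, Wd)
    model = DapcModel(
        n_pcs_retained=n_pcs, groups=group_names, center=center, scale=scale,
        pc_loadings=loadings, discriminant_axes=axes,
        group_centroids=centroids, within_cov=Wd, membership=membership,
        pca_mean=pca.mean_, pc_scores=scores,
    )
    return model


def _memberships(
    da_scores: np.ndarray, centroids: np.ndarray, within_cov: np.ndarray
) -> np.ndarray:
    prec = np.linalg.inv(within_cov)
    d2 = np.stack([
        np.einsum("ij,jk,ik->i", da_scores - c, prec, da_scores - c)
        for c in centroids
    ], axis=1)
    logp = -0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def dapc_assign(model: DapcModel, g_new: GenotypeMatrix) -> np.ndarray:
    """Membership probabilities of new individuals sharing the locus set."""
    x, _, _ = scale_genotypes(g_new.codes, model.center, model.scale)
    scores = (x - model.pca_mean[None, :]) @ model.pc_loadings
    da = scores @ model.discriminant_axes
    return _memberships(da, model.group_centroids, model.within_cov)


def alpha_optimize(
    g: GenotypeMatrix, groups: list[str] | np.ndarray | None = None,
    pc_grid: list[int] | None = None, n_perm: int = 10, seed: int = 0,
) -> tuple[dict[int, float], int]:
    """a-score per candidate PC count; optimum = argmax.

    a-score = mean over groups of (observed correct self-reassignment rate
    minus the mean rate after refitting on permuted labels).
    """
    labels = np.asarray(groups if groups is not None else g.populations)
    n_groups = len(dict.fromkeys(labels))
    max_pcs = g.n_individuals - n_groups - 1
    if pc_grid is None:
        pc_grid = list(range(1, min(max_pcs, 20) + 1))
    rng = np.random.default_rng(seed)
    scores: dict[int, float] = {}
    for npc in pc_grid:
        if npc >= g.n_individuals - n_groups:
            continue
        model = dapc_fit(g, labels, n_pcs=npc)
        obs = _group_rates(model.assignments(), labels)
        null_rates = []
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            pm = dapc_fit(g, perm, n_pcs=npc)
            null_rates.append(_group_rates(pm.assignments(), perm))
        scores[npc] = float(np.mean(obs) - np.mean(null_rates))
    if not scores:
        raise ValueError("no feasible PC count in grid")
    optimum = max(scores, key=lambda k: (scores[k], -k))
    return scores, optimum


def _group_rates(assigned: np.ndarray, labels: np.ndarray) -> np.ndarray:
    names = list(dict.fromkeys(labels))
    return np.array([
        float(np.mean(assigned[labels == gn] == gn)) for gn in names
    ])


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-cell held-out assignment accuracies over the resampling grid."""

    table: "object"  # pandas DataFrame: train_frac, locus_frac, rep, per-pop + overall accuracy

    @property
    def n_tests(self) -> int:
        return len(self.table)


def monte_carlo_cv(
    g: GenotypeMatrix,
    groups: list[str] | np.ndarray | None = None,
    train_fracs: tuple[float, ...] = (0.5, 0.7, 0.9),
    locus_fracs: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0),
    n_reps: int = 30,
    n_pcs: int = 5,
    seed: int = 0,
) -> CvResult:
    """Monte-Carlo cross-validated assignment over a resampling grid.

    Per cell: stratified training sample, loci ranked by training-set
    pairwise FST (monomorphic-in-training loci rank as 0), top fraction
    kept, DAPC fitted and held-out individuals assigned.  Locus ranking
    sees only training individuals.
    """
    import pandas as pd

    from .popgen_core import per_locus_fst

    labels = np.asarray(groups if groups is not None else g.populations)
    names = list(dict.fromkeys(labels))
    if len(names) != 2:
        raise ValueError("cross-validation grid expects exactly 2 populations")
    rng = np.random.default_rng(seed)
    rows = []
    for tf in train_fracs:
        for lf in locus_fracs:
            for rep in range(n_reps):
                train_idx = []
                for gn in names:
                    idx = np.flatnonzero(labels == gn)
                    n_train = max(2, int(round(tf * len(idx))))
                    n_train = min(n_train, len(idx) - 1)
                    train_idx.append(rng.choice(idx, n_train, replace=False))
                train_idx = np.sort(np.concatenate(train_idx))
                test_idx = np.setdiff1d(np.arange(g.n_individuals), train_idx)

                g_train = g.subset_individuals(train_idx)
                fst = per_locus_fst(g_train, (names[0], names[1]))
                fst = np.where(np.isnan(fst), 0.0, fst)
                n_keep = max(2, int(round(lf * g.n_loci)))
                order = np.argsort(-fst, kind="stable")[:n_keep]
                order = np.sort(order)

                model = dapc_fit(
                    g_train.subset_loci(order), labels[train_idx],
                    n_pcs=min(n_pcs, len(train_idx) - len(names) - 1),
                )
                memb = dapc_assign(model, g.subset_individuals(test_idx).subset_loci(order))
                assigned = np.asarray(model.groups)[np.argmax(memb, axis=1)]
                truth = labels[test_idx]
                row = dict(train_frac=tf, locus_frac=lf, rep=rep)
                for gn in names:
                    m = truth == gn
                    row[f"acc_{gn}"] = float(np.mean(assigned[m] == gn)) if m.any() else np.nan
                row["acc_overall"] = float(np.mean(assigned == truth))
                rows.append(row)
    return CvResult(pd.DataFrame(rows))
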