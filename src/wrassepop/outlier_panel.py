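"""PCA-based outlier scanning and diagnostic SNP-panel design/validation.

The scan follows the PCA-regression recipe: scale genotypes, extract K
principal components, regress each locus on the K PC score vectors to get
K z-scores, take a robust Mahalanobis distance of the z-vector (minimum
covariance determinant), rescale by the genomic inflation factor
(median D² over the chi-square_K median), convert to chi-square_K upper-tail
p-values and then to Storey q-values.  A locus is an outlier when q falls
below the threshold (0.1 by default); loci under the MAF floor (0.05) are
excluded beforehand.

Panel design picks, per scaffold, the SNP with the highest pairwise FST for
a target population pair, ranks candidates by FST and truncates the ranked
list at a floor (~0.15).  Validation metrics compare discovery and
validation genotypes cell-wise, correlate the two FST estimates, count
significantly differentiated loci by label permutation, and cut a robust
subset on per-population mean mapping quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from sklearn.decomposition import PCA

from .io_formats import MISSING, GenotypeMatrix
from .popgen_core import (
    fdr_bh,
    minor_allele_frequencies,
    per_locus_fst,
    wc_components,
)
from .structure_assignment import scale_genotypes

logger = logging.getLogger("wrassepop")


@dataclass
class OutlierReport:
    locus_ids: list[str]           # loci that entered the scan (post-MAF)
    zscores: np.ndarray            # (loci, K)
    mahalanobis: np.ndarray
    gif: float
    pvalues: np.ndarray
    qvalues: np.ndarray
    is_outlier: np.ndarray
    q_threshold: float
    maf_filtered_ids: list[str]
    explained_variance: np.ndarray
    contigs: list[str]

    def outlier_ids(self) -> list[str]:
        return [lid for lid, o in zip(self.locus_ids, self.is_outlier) if o]


@dataclass
class PanelSelection:
    pair: tuple[str, str]
    candidates: pd.DataFrame   # per-scaffold max-FST SNPs
    ranked: pd.DataFrame       # candidates above the floor, FST-descending
    fst_floor: float

    @property
    def panel(self) -> list[str]:
        return self.ranked["locus"].tolist()


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalues(
    p: np.ndarray, lambdas: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values with cubic-smoother pi0 estimation.

    pi0 is estimated on a lambda grid (0.05..0.95), smoothed with a cubic
    polynomial and read off at the largest lambda, then clipped to (0, 1].
    q = pi0 * BH step-up adjustment, enforced monotone in p.
    Returns (q, pi0).
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_raw = np.array([
        (p > lam).sum() / (n * (1 - lam)) for lam in lambdas
    ])
    if n < 100:
        pi0 = 1.0
    else:
        coeffs = np.polyfit(lambdas, pi0_raw, 3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    pi0 = float(np.clip(pi0, 1e-8, 1.0))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * ranked * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, pi0


# ---------------------------------------------------------------------------
# PCA outlier scan
# ---------------------------------------------------------------------------

def pca_outlier_scan(
    g: GenotypeMatrix,
    k: int | None = None,
    maf_min: float = 0.05,
    q_threshold: float = 0.1,
    seed: int = 0,
) -> OutlierReport:
    """Genome scan for selection outliers by PCA regression + robust D².

    ``k`` is the number of retained PCs; when None, the largest drop in the
    explained-variance series (elbow) chooses it.  The explained-variance
    series is returned so the choice can be made from a scree plot instead.
    """
    maf = minor_allele_frequencies(g)
    keep = maf >= maf_min
    dropped = [l.id for l, k_ in zip(g.loci, keep) if not k_]
    gs = g.subset_loci(keep)
    x, _, _ = scale_genotypes(gs.codes)

    n, L = x.shape
    n_comp = min(n - 1, 20)
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(x)
    evr = pca.explained_variance_ratio_
    if k is None:
        k = int(np.argmax(-np.diff(evr)) + 1)
    k = max(1, min(k, n_comp))

    # per-locus multiple regression of genotype on the K PC score vectors;
    # columns of `scores` are orthogonal, so coefficients decouple
    s = scores[:, :k]
    ss = (s ** 2).sum(axis=0)
    beta = (s.T @ x) / ss[:, None]               # (k, loci)
    resid = x - s @ beta
    dof = max(n - k - 1, 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (beta / np.sqrt(sigma2[None, :] / ss[:, None])).T  # (loci, k)
    zero_var = ~np.isfinite(z).all(axis=1)
    if zero_var.any():
        logger.warning("%d loci with degenerate regression excluded", zero_var.sum())
        z[zero_var] = 0.0

    mcd = MinCovDet(random_state=seed).fit(z)
    d2 = mcd.mahalanobis(z)
    gif = float(np.median(d2) / stats.chi2.ppf(0.5, k))
    pvals = stats.chi2.sf(d2 / gif, k)
    qvals, _ = storey_qvalues(pvals)
    flags = qvals < q_threshold
    return OutlierReport(
        locus_ids=[l.id for l in gs.loci],
        zscores=z,
        mahalanobis=d2,
        gif=gif,
        pvalues=pvals,
        qvalues=qvals,
        is_outlier=flags,
        q_threshold=q_threshold,
        maf_filtered_ids=dropped,
        explained_variance=evr,
        contigs=[l.contig for l in gs.loci],
    )


def outlier_concordance(a: set[str], b: set[str]) -> dict[str, int]:
    """Intersection report between two outlier-locus sets."""
    a, b = set(a), set(b)
    return {
        "both": len(a & b),
        "only_a": len(a - b),
        "only_b": len(b - a),
    }


def contig_outlier_clusters(
    report: OutlierReport, min_outliers: int = 3
) -> list[str]:
    """Contigs carrying more than two (>= min_outliers) flagged loci."""
    flagged = pd.Series(report.contigs)[report.is_outlier]
    counts = flagged.value_counts()
    return sorted(counts.index[counts >= min_outliers].tolist())


# ---------------------------------------------------------------------------
# Panel selection and validation
# ---------------------------------------------------------------------------

def select_panel(
    g: GenotypeMatrix, pair: tuple[str, str], fst_floor: float = 0.15
) -> PanelSelection:
    """Per scaffold, the max-pairwise-FST SNP; ranked descending, cut at floor.

    Ties within a scaffold go to the lowest position; the cross-scaffold
    ranking breaks FST ties by (contig, pos), so the result does not depend
    on locus input order.
    """
    fst = per_locus_fst(g, pair)
    df = pd.DataFrame({
        "locus": [l.id for l in g.loci],
        "contig": [l.contig for l in g.loci],
        "pos": [l.pos for l in g.loci],
        "fst": np.where(np.isnan(fst), -np.inf, fst),
    })
    df = df.sort_values(["contig", "fst", "pos"], ascending=[True, False, True])
    candidates = df.groupby("contig", sort=True).head(1).reset_index(drop=True)
    ranked = candidates[candidates["fst"] >= fst_floor].sort_values(
        ["fst", "contig", "pos"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if ranked.empty:
        logger.warning("no locus reaches the FST floor %.3f", fst_floor)
    return PanelSelection(pair=pair, candidates=candidates, ranked=ranked,
                          fst_floor=fst_floor)


def genotype_concordance(
    discovery: GenotypeMatrix, validation: GenotypeMatrix
) -> dict[str, float]:
    """Matching / missing / non-matching genotype percentages.

    Compared cell-wise over the shared (individual, locus) intersection;
    a cell missing in either matrix counts as missing.  The three
    percentages sum to 100.
    """
    ind = [i for i in discovery.individuals if i in set(validation.individuals)]
    loc = [l.id for l in discovery.loci
           if l.id in {m.id for m in validation.loci}]
    if not ind or not loc:
        raise ValueError("no shared individuals x loci between the matrices")
    di = {s: i for i, s in enumerate(discovery.individuals)}
    vi = {s: i for i, s in enumerate(validation.individuals)}
    dl = {l.id: j for j, l in enumerate(discovery.loci)}
    vl = {l.id: j for j, l in enumerate(validation.loci)}
    a = discovery.codes[np.ix_([di[s] for s in ind], [dl[x] for x in loc])]
    b = validation.codes[np.ix_([vi[s] for s in ind], [vl[x] for x in loc])]
    miss = (a == MISSING) | (b == MISSING)
    match = (~miss) & (a == b)
    total = a.size
    return {
        "matching": 100.0 * match.sum() / total,
        "missing": 100.0 * miss.sum() / total,
        "non_matching": 100.0 * (total - match.sum() - miss.sum()) / total,
        "n_cells": total,
    }


def fst_method_correlation(
    fst_a: np.ndarray, fst_b: np.ndarray
) -> tuple[float, float]:
    """OLS R² between two per-locus FST vectors and its F-test p-value."""
    a = np.asarray(fst_a, dtype=float)
    b = np.asarray(fst_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need >= 3 paired loci")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an FST vector")
    res = stats.linregress(a, b)
    return float(res.rvalue ** 2), float(res.pvalue)


def locuswise_fst_significance(
    g: GenotypeMatrix, pair: tuple[str, str], n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Permutation p-value per locus for pairwise theta > 0.

    Population labels are permuted over individuals; p = (1 + #{perm theta
    >= observed}) / (n_perm + 1).  Monomorphic loci get p = 1.
    """
    pops = np.asarray(g.populations)
    mask = np.isin(pops, list(pair))
    codes = g.codes[mask]
    labels = np.searchsorted(np.sort(list(pair)), pops[mask])
    rng = np.random.default_rng(seed)

    def theta(lab: np.ndarray) -> np.ndarray:
        a, b, c = wc_components(codes, lab)
        with np.errstate(invalid="ignore", divide="ignore"):
            return a / (a + b + c)

    obs = theta(labels)
    exceed = np.zeros(codes.shape[1])
    for _ in range(n_perm):
        t = theta(rng.permutation(labels))
        exceed += np.where(np.isnan(t), 0, t >= obs - 1e-15)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[np.isnan(obs)] = 1.0
    return np.clip(p, 0.0, 1.0)


def robust_subset(
    panel: list[str],
    mean_mapq_by_pop: pd.DataFrame,
    thresholds: dict[str, float],
) -> list[str]:
    """Panel loci whose per-population mean mapping quality is strictly
    above every population's threshold.

    ``mean_mapq_by_pop``: DataFrame indexed by locus id, one column per
    population.  Loci with a missing quality value are excluded and logged.
    """
    out = []
    for lid in panel:
        if lid not in mean_mapq_by_pop.index:
            logger.warning("locus %s has no quality record; excluded", lid)
            continue
        row = mean_mapq_by_pop.loc[lid]
        vals = {p: row.get(p, np.nan) for p in thresholds}
        if any(pd.isna(v) for v in vals.values()):
            logger.warning("locus %s missing a population quality; excluded", lid)
            continue
        if all(vals[p] > thr for p, thr in thresholds.items()):
            out.append(lid)
    return out
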