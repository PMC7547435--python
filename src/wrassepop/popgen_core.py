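"""Locus filtering and diversity / differentiation statistics.

The filter chain mirrors a genome-wide SNP selection workflow: per-population
site-quality bounds (QUAL, DP, MQ), a pooled minor-allele-frequency cutoff,
per-population Hardy–Weinberg exact tests with Benjamini–Hochberg FDR, and
distance thinning to ~1 SNP/kb.  Statistics: gene diversity Hs (with the
n/(n-1) small-sample correction), observed heterozygosity Ho, FIS = 1 - Ho/Hs,
multi-locus Weir–Cockerham theta (ratio of summed variance components) with
percentile bootstrap-over-loci confidence intervals, composite genotype-r²
linkage surveys, and the paired per-locus heterozygote-deficit t-test.

Missing genotypes are handled by per-locus / pairwise deletion everywhere;
nothing is imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MISSING, GenotypeMatrix, SiteRecord, records_to_matrix

logger = logging.getLogger("wrassepop")


@dataclass
class FilterConfig:
    """Per-population site-acceptance bounds and downstream filter knobs."""

    min_qual: float = 600.0
    min_dp: float = 20.0
    max_dp: float = 999.0
    min_mq: float = 0.0
    max_mq: float = 90.0
    maf_min: float = 0.01
    hwe_alpha: float = 0.05
    hwe_min_pops: int = 2
    thin_bp: int = 1000

    def __post_init__(self) -> None:
        if self.min_dp > self.max_dp or self.min_mq > self.max_mq:
            raise ValueError("min bound exceeds max bound")
        if self.thin_bp < 0:
            raise ValueError("thin_bp must be >= 0")


@dataclass
class DiversityTable:
    """Per-population and overall Hs, Ho and FIS (FIS with a bootstrap CI)."""

    table: pd.DataFrame  # index: population (+ 'overall'); cols hs, ho, fis, fis_ci_low, fis_ci_high


@dataclass
class FstResult:
    pop_names: list[str]
    pairwise: np.ndarray
    overall: float
    per_locus: np.ndarray          # overall per-locus theta (nan where undefined)
    ci_low: np.ndarray             # pairwise CI bounds
    ci_high: np.ndarray
    overall_ci: tuple[float, float]
    n_boot: int


@dataclass
class LdSurvey:
    same_contig_mean: float
    same_contig_sd: float
    random_mean: float
    random_sd: float
    n_same_contig_pairs: int
    n_random_pairs: int
    nearest_excluded_means: dict[int, float] = field(default_factory=dict)
    nearest_excluded_sds: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def filter_sites(
    records: Iterable[SiteRecord],
    cfg: FilterConfig,
    individuals: Sequence[str],
    population_map: dict[str, str],
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Keep sites whose quality aggregates pass the bounds in every population.

    QUAL and MQ are site-level and shared by all populations; DP is the
    per-population mean of per-sample depths when the VCF carries FORMAT/DP,
    else the site-level depth.  Rejections are tallied by the first failing
    criterion (qual, then dp, then mq) so the counts sum to the number of
    rejected sites.
    """
    pops = np.asarray([population_map[s] for s in individuals])
    pop_names = list(dict.fromkeys(pops))
    for p in dict.fromkeys(population_map.values()):
        if p not in pop_names:
            raise ValueError(f"population {p} has zero samples")
    pop_masks = {p: pops == p for p in pop_names}

    kept: list[SiteRecord] = []
    tally = {"qual": 0, "dp": 0, "mq": 0}
    for rec in records:
        if rec.qual < cfg.min_qual:
            tally["qual"] += 1
            continue
        if rec.sample_depths is not None:
            dp_by_pop = [
                float(np.nanmean(np.where(rec.sample_depths[m] < 0, np.nan,
                                          rec.sample_depths[m])))
                for m in pop_masks.values()
            ]
        else:
            dp_by_pop = [rec.depth] * len(pop_names)
        if any(not (cfg.min_dp <= d <= cfg.max_dp) for d in dp_by_pop):
            tally["dp"] += 1
            continue
        if not (cfg.min_mq <= rec.mapq <= cfg.max_mq):
            tally["mq"] += 1
            continue
        kept.append(rec)
    g = records_to_matrix(kept, individuals, population_map)
    return g, tally


def maf_filter(
    g: GenotypeMatrix, maf_min: float = 0.01
) -> tuple[GenotypeMatrix, int]:
    """Drop loci whose pooled minor-allele frequency is strictly below maf_min."""
    maf = minor_allele_frequencies(g)
    keep = maf >= maf_min
    removed = int((~keep).sum())
    if removed == g.n_loci:
        logger.warning("MAF filter removed every locus")
    return g.subset_loci(keep), removed


def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Pooled MAF per locus over non-missing genotypes."""
    codes = g.codes
    obs = codes != MISSING
    alt = np.where(obs, codes, 0).sum(axis=0)
    n2 = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n2 > 0, alt / np.maximum(n2, 1), 0.0)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# Hardy–Weinberg
# ---------------------------------------------------------------------------

def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact HWE test on the heterozygote count.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed the
    observed one (the standard exact formulation).  Monomorphic samples
    return p = 1.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n == 0 or n_a == 0 or n_a == 2 * n:
        return 1.0
    rare = min(n_a, 2 * n - n_a)
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def logprob(h: np.ndarray) -> np.ndarray:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1) - gammaln(hom_rare + 1) - gammaln(h + 1)
            - gammaln(hom_common + 1) + h * np.log(2.0)
            - (gammaln(2 * n + 1) - gammaln(rare + 1)
               - gammaln(2 * n - rare + 1))
        )
    lp = logprob(hets)
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[hets == min(n_ab, rare)][0] if (n_ab % 2) == (rare % 2) else 0.0
    return float(np.clip(probs[probs <= obs * (1 + 1e-12)].sum(), 0.0, 1.0))


def hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit test of HWE genotype proportions."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


def hwe_test(
    g: GenotypeMatrix, per_population: bool = True, method: str = "exact"
) -> pd.DataFrame:
    """HWE p-values per locus (columns = populations, or a single 'all')."""
    test = {"exact": hwe_exact_p, "chi2": hwe_chi2_p}[method]
    groups = g.pop_indices() if per_population else {"all": np.arange(g.n_individuals)}
    out = {}
    for name, idx in groups.items():
        sub = g.codes[idx]
        pvals = np.empty(g.n_loci)
        for j in range(g.n_loci):
            col = sub[:, j]
            col = col[col != MISSING]
            if len(col) < 2:
                pvals[j] = 1.0
                continue
            pvals[j] = test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
        out[name] = pvals
    return pd.DataFrame(out, index=[l.id for l in g.loci])


def fdr_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hwe_prune(
    g: GenotypeMatrix,
    hwe_pvals: pd.DataFrame,
    alpha: float = 0.05,
    min_pops: int = 2,
) -> tuple[GenotypeMatrix, int]:
    """Drop loci out of HWE (after per-population BH-FDR) in >= min_pops pops."""
    adj = hwe_pvals.apply(lambda col: fdr_bh(col.to_numpy()), axis=0)
    n_violations = (adj.to_numpy() < alpha).sum(axis=1)
    keep = n_violations < min_pops
    return g.subset_loci(keep), int((~keep).sum())


def thin_by_distance(g: GenotypeMatrix, thin_bp: int = 1000) -> GenotypeMatrix:
    """Greedy left-to-right per-contig thinning: keep a locus iff it is
    >= thin_bp from the last kept locus on the same contig."""
    keep = np.zeros(g.n_loci, dtype=bool)
    last_contig, last_pos = None, None
    for j, loc in enumerate(g.loci):
        if loc.contig != last_contig or loc.pos - last_pos >= thin_bp:
            keep[j] = True
            last_contig, last_pos = loc.contig, loc.pos
    return g.subset_loci(keep)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def _hs_ho_per_locus(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Hs (n/(n-1)-corrected), Ho and valid-locus mask for one sample."""
    obs = codes != MISSING
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n)
        hs = 2 * p * (1 - p) * n / (n - 1)
        ho = np.where(obs, codes == 1, 0).sum(axis=0) / n
    valid = n >= 2
    return hs, ho, valid


def diversity(
    g: GenotypeMatrix, n_boot: int = 1000, seed: int = 0
) -> DiversityTable:
    """Hs, Ho and FIS per population and overall, FIS CI by bootstrap over loci."""
    rng = np.random.default_rng(seed)
    rows = {}
    groups = dict(g.pop_indices())
    groups["overall"] = np.arange(g.n_individuals)
    for name, idx in groups.items():
        hs, ho, valid = _hs_ho_per_locus(g.codes[idx])
        hs, ho = hs[valid], ho[valid]
        mean_hs, mean_ho = float(np.mean(hs)), float(np.mean(ho))
        fis = 1.0 - mean_ho / mean_hs if mean_hs > 0 else np.nan
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bi = rng.integers(0, len(hs), len(hs))
            bhs = hs[bi].mean()
            boots[b] = 1.0 - ho[bi].mean() / bhs if bhs > 0 else np.nan
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        rows[name] = dict(hs=mean_hs, ho=mean_ho, fis=fis,
                          fis_ci_low=float(lo), fis_ci_high=float(hi))
    return DiversityTable(pd.DataFrame(rows).T)


def het_deficit_ttest(g: GenotypeMatrix) -> tuple[float, int, float]:
    """Paired t-test of per-locus (Hs - Ho) over all samples pooled.

    Returns (t, df, p) with df = n_loci - 1.
    """
    hs, ho, valid = _hs_ho_per_locus(g.codes)
    diff = (hs - ho)[valid]
    if len(diff) < 2:
        raise ValueError("need >= 2 informative loci")
    t, p = stats.ttest_1samp(diff, 0.0)
    return float(t), len(diff) - 1, float(p)


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

def wc_components(
    codes: np.ndarray, pops: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) per-locus variance components a, b, c.

    ``codes``: (individuals x loci) dosages with -1 missing; ``pops``:
    integer population label per individual.  Components are nan for loci
    monomorphic (or data-less) across the included populations.
    Vectorized over loci.
    """
    pop_ids = np.unique(pops)
    r_max = len(pop_ids)
    n_loci = codes.shape[1]
    n_i = np.zeros((r_max, n_loci))
    p_i = np.zeros((r_max, n_loci))
    h_i = np.zeros((r_max, n_loci))
    for k, pid in enumerate(pop_ids):
        sub = codes[pops == pid]
        obs = sub != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, sub, 0).sum(axis=0) / (2 * np.maximum(n, 1e-300))
            h = np.where(obs, sub == 1, 0).sum(axis=0) / np.maximum(n, 1e-300)
        n_i[k], p_i[k], h_i[k] = n, p, h

    informative = n_i > 0  # population contributes at this locus
    r = informative.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.sum(axis=0) / r
        n_c = (n_i.sum(axis=0) - (n_i ** 2).sum(axis=0) / n_i.sum(axis=0)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar[None, :]) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2

    poly = (p_bar > 0) & (p_bar < 1) & (r >= 2) & (n_bar > 1)
    a = np.where(poly, a, np.nan)
    b = np.where(poly, b, np.nan)
    c = np.where(poly, c, np.nan)
    return a, b, c


def _theta_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    ok = ~np.isnan(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    return float(a[ok].sum() / denom) if denom != 0 else np.nan


def wc_fst(
    g: GenotypeMatrix,
    pair: tuple[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> FstResult:
    """Multi-locus Weir–Cockerham theta, pairwise and overall, with
    percentile bootstrap-over-loci 95% CIs.

    Negative estimates are reported as computed (not truncated)."""
    pops = np.asarray(g.populations)
    names = [p for p in g.pop_names] if pair is None else list(pair)
    if pair is not None:
        keep = np.isin(pops, names)
        g = g.subset_individuals(keep)
        pops = np.asarray(g.populations)
    for nm in names:
        if (pops == nm).sum() < 2:
            raise ValueError(f"population {nm} needs >= 2 individuals")
    codes = g.codes
    pop_int = np.searchsorted(np.sort(names), pops)

    rng = np.random.default_rng(seed)
    k = len(names)
    pairwise = np.full((k, k), np.nan)
    ci_low = np.full((k, k), np.nan)
    ci_high = np.full((k, k), np.nan)

    def boot_ci(a, b, c) -> tuple[float, float]:
        ok = ~np.isnan(a)
        aa, bb, cc = a[ok], b[ok], c[ok]
        if len(aa) == 0 or n_boot == 0:
            return (np.nan, np.nan)
        idx = rng.integers(0, len(aa), size=(n_boot, len(aa)))
        num = aa[idx].sum(axis=1)
        den = (aa + bb + cc)[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            thetas = num / den
        lo, hi = np.nanpercentile(thetas, [2.5, 97.5])
        return float(lo), float(hi)

    sorted_names = list(np.sort(names))
    for i in range(k):
        for j in range(i + 1, k):
            mask = np.isin(pops, [names[i], names[j]])
            a, b, c = wc_components(codes[mask], pop_int[mask])
            th = _theta_from_components(a, b, c)
            pairwise[i, j] = pairwise[j, i] = th
            lo, hi = boot_ci(a, b, c)
            ci_low[i, j] = ci_low[j, i] = lo
            ci_high[i, j] = ci_high[j, i] = hi

    a, b, c = wc_components(codes, pop_int)
    overall = _theta_from_components(a, b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
    overall_ci = boot_ci(a, b, c)
    return FstResult(
        pop_names=names, pairwise=pairwise, overall=overall,
        per_locus=per_locus, ci_low=ci_low, ci_high=ci_high,
        overall_ci=overall_ci, n_boot=n_boot,
    )


def per_locus_fst(g: GenotypeMatrix, pair: tuple[str, str]) -> np.ndarray:
    """Per-locus Weir–Cockerham theta for one population pair (nan where
    monomorphic)."""
    pops = np.asarray(g.populations)
    mask = np.isin(pops, list(pair))
    codes = g.codes[mask]
    pop_int = np.searchsorted(np.sort(list(pair)), pops[mask])
    a, b, c = wc_components(codes, pop_int)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / (a + b + c)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 3:
        return np.nan
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_survey(
    g: GenotypeMatrix,
    n_random_pairs: int = 100_000,
    exclude_nearest: Sequence[int] = (),
    seed: int = 0,
    max_same_contig_pairs: int | None = None,
) -> LdSurvey:
    """r² summaries: all same-contig pairs vs random cross-contig pairs.

    ``exclude_nearest`` gives n values for which the same-contig mean is
    recomputed excluding pairs within n positions in per-contig sorted order.
    """
    rng = np.random.default_rng(seed)
    contigs = np.asarray([l.contig for l in g.loci])
    codes = g.codes

    same_vals: list[float] = []
    same_gaps: list[int] = []
    for contig in pd.unique(contigs):
        idx = np.flatnonzero(contigs == contig)
        if len(idx) < 2:
            continue
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                r2 = genotype_r2(codes[:, idx[ii]], codes[:, idx[jj]])
                if not np.isnan(r2):
                    same_vals.append(r2)
                    same_gaps.append(jj - ii)
    same_vals_arr = np.asarray(same_vals)
    same_gaps_arr = np.asarray(same_gaps)
    if max_same_contig_pairs and len(same_vals_arr) > max_same_contig_pairs:
        pick = rng.choice(len(same_vals_arr), max_same_contig_pairs, replace=False)
        same_vals_arr, same_gaps_arr = same_vals_arr[pick], same_gaps_arr[pick]

    rand_vals: list[float] = []
    n_loci = g.n_loci
    attempts = 0
    while len(rand_vals) < n_random_pairs and attempts < 20 * n_random_pairs:
        attempts += 1
        i, j = rng.integers(0, n_loci, 2)
        if i == j or contigs[i] == contigs[j]:
            continue
        r2 = genotype_r2(codes[:, i], codes[:, j])
        if not np.isnan(r2):
            rand_vals.append(r2)
    rand_arr = np.asarray(rand_vals)

    near_means, near_sds = {}, {}
    for n in exclude_nearest:
        mask = same_gaps_arr > n
        if mask.any():
            near_means[n] = float(same_vals_arr[mask].mean())
            near_sds[n] = float(same_vals_arr[mask].std())
    return LdSurvey(
        same_contig_mean=float(same_vals_arr.mean()) if len(same_vals_arr) else np.nan,
        same_contig_sd=float(same_vals_arr.std()) if len(same_vals_arr) else np.nan,
        random_mean=float(rand_arr.mean()) if len(rand_arr) else np.nan,
        random_sd=float(rand_arr.std()) if len(rand_arr) else np.nan,
        n_same_contig_pairs=len(same_vals_arr),
        n_random_pairs=len(rand_arr),
        nearest_excluded_means=near_means,
        nearest_excluded_sds=near_sds,
    )
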