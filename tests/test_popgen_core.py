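"""Filters and statistics against hand arithmetic and brute-force oracles."""

import itertools

import numpy as np
import pytest

from wrassepop import (
    MISSING,
    FilterConfig,
    GenotypeMatrix,
    Locus,
    PopSimConfig,
    SiteRecord,
    diversity,
    fdr_bh,
    filter_sites,
    genotype_r2,
    het_deficit_ttest,
    hwe_prune,
    hwe_test,
    ld_survey,
    maf_filter,
    simulate_populations,
    thin_by_distance,
    wc_components,
    wc_fst,
)
from wrassepop.popgen_core import hwe_chi2_p, hwe_exact_p


def make_matrix(codes, pops, positions=None, contigs=None):
    codes = np.asarray(codes, dtype=np.int8)
    n_ind, n_loc = codes.shape
    positions = positions or [100 * (j + 1) for j in range(n_loc)]
    contigs = contigs or ["c1"] * n_loc
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(n_ind)],
        populations=list(pops),
        loci=[Locus(c, p) for c, p in zip(contigs, positions)],
        codes=codes,
    )


# ---------------------------------------------------------------------------
# Weir–Cockerham oracle
# ---------------------------------------------------------------------------

def wc_theta_oracle(codes, pops):
    """Independent scalar-loop Weir-Cockerham (1984) multi-locus theta."""
    pops = np.asarray(pops)
    pop_names = sorted(set(pops))
    r = len(pop_names)
    sum_a = sum_abc = 0.0
    for j in range(codes.shape[1]):
        n_i, p_i, h_i = [], [], []
        for pn in pop_names:
            col = codes[pops == pn, j]
            col = col[col != MISSING]
            if len(col) == 0:
                continue
            n_i.append(len(col))
            p_i.append(col.sum() / (2 * len(col)))
            h_i.append(np.mean(col == 1))
        ri = len(n_i)
        if ri < 2:
            continue
        n_i, p_i, h_i = map(np.asarray, (n_i, p_i, h_i))
        n_bar = n_i.mean()
        if n_bar <= 1:
            continue
        p_bar = (n_i * p_i).sum() / (ri * n_bar)
        if p_bar in (0.0, 1.0):
            continue
        n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (ri - 1)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((ri - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (ri * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (ri - 1) / ri * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (ri - 1) / ri * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc if sum_abc else np.nan


def test_wc_fst_matches_oracle_small_table():
    rng = np.random.default_rng(5)
    codes = rng.integers(0, 3, (10, 5))
    pops = ["A"] * 5 + ["B"] * 5
    g = make_matrix(codes, pops)
    res = wc_fst(g, n_boot=0)
    assert res.overall == pytest.approx(wc_theta_oracle(codes, pops), abs=1e-12)


def test_wc_fst_fuzz_against_oracle():
    """200 random 6-individual x 3-locus tables agree with the oracle to 1e-10."""
    rng = np.random.default_rng(17)
    for _ in range(200):
        codes = rng.integers(0, 3, (6, 3)).astype(np.int8)
        # sprinkle missing values in ~10% of cells
        codes[rng.random(codes.shape) < 0.1] = MISSING
        pops = ["A", "A", "A", "B", "B", "B"]
        g = make_matrix(codes, pops)
        expect = wc_theta_oracle(codes, pops)
        got = wc_fst(g, n_boot=0).overall
        if np.isnan(expect):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expect, abs=1e-10)


def test_fixed_difference_gives_theta_one():
    codes = np.array([[0] * 3] * 4 + [[2] * 3] * 4)
    g = make_matrix(codes, ["A"] * 4 + ["B"] * 4)
    a, b, c = wc_components(g.codes, np.array([0] * 4 + [1] * 4))
    np.testing.assert_allclose(a / (a + b + c), 1.0)


def test_identical_populations_near_zero():
    rng = np.random.default_rng(2)
    half = rng.integers(0, 3, (8, 50))
    codes = np.vstack([half, half])
    g = make_matrix(codes, ["A"] * 8 + ["B"] * 8)
    assert wc_fst(g, n_boot=0).overall <= 0.005


def test_bootstrap_ci_brackets_estimate(two_pop_sim):
    res = wc_fst(two_pop_sim, n_boot=200, seed=3)
    assert res.ci_low[0, 1] <= res.pairwise[0, 1] <= res.ci_high[0, 1]
    assert res.pairwise[0, 1] == pytest.approx(res.pairwise[1, 0])


# ---------------------------------------------------------------------------
# HWE
# ---------------------------------------------------------------------------

def hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Full enumeration of the conditional heterozygote-count distribution."""
    from math import factorial

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a in (0, 2 * n):
        return 1.0
    rare = min(n_a, 2 * n - n_a)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            continue
        # multinomial count of genotype configurations over ordered alleles
        ways = (
            factorial(n)
            // (factorial(hom_r) * factorial(h) * factorial(hom_c))
        ) * 2 ** h
        probs[h] = ways
    total = sum(probs.values())
    obs = min(n_ab, rare)
    p_obs = probs.get(obs, 0)
    return sum(v for v in probs.values() if v <= p_obs) / total


@pytest.mark.parametrize("counts", [
    (10, 0, 0),       # monomorphic -> 1
    (5, 0, 5),
    (1, 2, 1),        # modal configuration -> 1
    (3, 4, 3),
    (0, 10, 0),
    (7, 1, 2),
])
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(hwe_exact_oracle(*counts), abs=1e-10)


def test_hwe_modal_and_monomorphic_conventions():
    assert hwe_exact_p(10, 0, 0) == 1.0
    assert hwe_exact_p(1, 2, 1) == pytest.approx(1.0)
    assert hwe_chi2_p(10, 0, 0) == 1.0


def test_hwe_chi2_agrees_with_direct_computation():
    from scipy.stats import chi2

    n_aa, n_ab, n_bb = 20, 10, 20
    n = 50
    p = (2 * n_aa + n_ab) / (2 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    stat = (((np.array([n_aa, n_ab, n_bb]) - exp) ** 2) / exp).sum()
    assert hwe_chi2_p(n_aa, n_ab, n_bb) == pytest.approx(chi2.sf(stat, 1))


def test_hwe_test_frame_shape(two_pop_sim):
    df = hwe_test(two_pop_sim, method="exact")
    assert df.shape == (two_pop_sim.n_loci, 2)
    assert ((df.to_numpy() >= 0) & (df.to_numpy() <= 1)).all()


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_oracle(p):
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def test_bh_hand_example():
    np.testing.assert_allclose(
        fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_against_oracle_and_properties():
    rng = np.random.default_rng(8)
    p = rng.random(50)
    adj = fdr_bh(p)
    np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
    # monotone in p; identity on singletons and all-ones
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert fdr_bh([0.3])[0] == pytest.approx(0.3)
    np.testing.assert_allclose(fdr_bh(np.ones(5)), 1.0)
    assert fdr_bh([]).size == 0


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def site(qual=650.0, dp=100.0, mq=60.0, gts=(0, 1, 2), pos=1, sample_dp=None):
    return SiteRecord(
        contig="c1", pos=pos, ref_allele="A", alt_allele="G",
        qual=qual, depth=dp, mapq=mq,
        genotypes=np.array(gts, dtype=np.int8),
        sample_depths=None if sample_dp is None else np.asarray(sample_dp, float),
    )


def test_filter_sites_tally_and_bookkeeping():
    cfg = FilterConfig()
    pmap = {"s1": "A", "s2": "A", "s3": "B"}
    records = [
        site(pos=1),                                  # kept
        site(pos=2, qual=599),                        # qual
        site(pos=3, sample_dp=[30, 30, 15]),          # dp in pop B
        site(pos=4, mq=95),                           # mq
        site(pos=5),                                  # kept
        site(pos=6, qual=100, dp=5, mq=99),           # first-fail: qual
        site(pos=7, dp=1500),                         # dp (site-level)
    ]
    g, tally = filter_sites(records, cfg, ["s1", "s2", "s3"], pmap)
    assert g.n_loci == 2
    assert tally == {"qual": 2, "dp": 2, "mq": 1}
    assert g.n_loci + sum(tally.values()) == len(records)


def test_filter_sites_empty_population_errors():
    with pytest.raises(ValueError, match="zero samples"):
        filter_sites([site()], FilterConfig(), ["s1"], {"s1": "A", "ghost": "B"})


def test_maf_filter_boundary_and_counts():
    # 50 diploids: locus 0 monomorphic (removed); locus 1 one het -> MAF
    # exactly 1/100 = 0.01, kept under the strict < rule; locus 2 two hets
    codes = np.zeros((50, 3), dtype=np.int8)
    codes[0, 1] = 1
    codes[0, 2] = 1
    codes[1, 2] = 1
    g = make_matrix(codes, ["A"] * 25 + ["B"] * 25)
    kept, removed = maf_filter(g, maf_min=0.01)
    assert removed == 1
    assert [l.pos for l in kept.loci] == [200, 300]

    # 60 diploids, one het: MAF = 1/120 ~ 0.0083 < 0.01 -> removed
    g60 = make_matrix(np.zeros((60, 1), np.int8), ["A"] * 60)
    g60.codes[0, 0] = 1
    kept, removed = maf_filter(g60, maf_min=0.01)
    assert removed == 1


def test_hwe_prune_requires_two_populations():
    # locus 0: het excess in pops A and B -> removed; locus 1: only pop A -> kept
    a_v = [1] * 12          # all hets in A at both loci
    b_v = [1] * 12          # all hets in B at locus 0, HWE-ish at locus 1
    codes = np.zeros((24, 2), dtype=np.int8)
    codes[:12, 0] = a_v
    codes[12:, 0] = b_v
    codes[:12, 1] = a_v
    codes[12:, 1] = [0, 0, 0, 1, 1, 2, 0, 1, 0, 1, 2, 0]
    g = make_matrix(codes, ["A"] * 12 + ["B"] * 12)
    pvals = hwe_test(g)
    pruned, removed = hwe_prune(g, pvals, alpha=0.05, min_pops=2)
    assert removed == 1
    assert pruned.n_loci == 1 and pruned.loci[0].pos == 200


def test_thin_by_distance_greedy_trace():
    g = make_matrix(
        np.zeros((2, 3), np.int8), ["A", "B"], positions=[100, 900, 1100]
    )
    thinned = thin_by_distance(g, 1000)
    assert [l.pos for l in thinned.loci] == [100, 1100]
    # exact spacing kept; one locus per contig always kept
    g2 = make_matrix(
        np.zeros((2, 3), np.int8), ["A", "B"],
        positions=[1, 1001, 2001],
    )
    assert thin_by_distance(g2, 1000).n_loci == 3
    g3 = make_matrix(
        np.zeros((2, 3), np.int8), ["A", "B"],
        positions=[10, 10, 10], contigs=["c1", "c2", "c3"],
    )
    assert thin_by_distance(g3, 1000).n_loci == 3


# ---------------------------------------------------------------------------
# Diversity / heterozygote deficit
# ---------------------------------------------------------------------------

def test_diversity_hand_example():
    """Genotypes (0,0,1,1): p=0.25, Hs = 2*0.25*0.75*(4/3) = 0.5, Ho=0.5, FIS=0."""
    g = make_matrix([[0], [0], [1], [1]], ["A"] * 4)
    tab = diversity(g, n_boot=10, seed=0).table
    assert tab.loc["A", "hs"] == pytest.approx(0.5)
    assert tab.loc["A", "ho"] == pytest.approx(0.5)
    assert tab.loc["A", "fis"] == pytest.approx(0.0)


def test_all_heterozygote_ho_one():
    g = make_matrix([[1], [1], [1], [1]], ["A"] * 4)
    tab = diversity(g, n_boot=10).table
    assert tab.loc["A", "ho"] == 1.0


def test_fis_null_recovery():
    """HWE (F=0) data: population FIS within 0.02 of zero at n=50."""
    g = simulate_populations(PopSimConfig(
        n_pops=1, n_per_pop=50, n_loci=5000, target_fst=1e-6,
        missing_rate=0.0, seed=6,
    ))
    tab = diversity(g, n_boot=50, seed=1).table
    assert abs(tab.loc["pop1", "fis"]) < 0.02


def test_het_deficit_ttest_properties():
    g = make_matrix(
        np.array([[0, 1], [1, 1], [1, 0], [2, 1]], dtype=np.int8), ["A"] * 4
    )
    t, df, p = het_deficit_ttest(g)
    assert df == 1
    # closed-form check: constant mean/sd of per-locus Hs-Ho differences
    rng = np.random.default_rng(0)
    diffs = rng.normal(0.01, 0.01, 100)
    t_expect = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(100))
    assert t_expect == pytest.approx(10.0, abs=3.0)  # sanity of the construction
    from scipy import stats as st

    assert st.ttest_1samp(diffs, 0).statistic == pytest.approx(t_expect)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_r2_hand_example_and_duplicate():
    # hand Pearson: cov = 1.25, var_x = var_y = 2.75 -> r = 5/11, r^2 = 25/121
    x = np.array([0, 1, 2, 0], dtype=np.int8)
    y = np.array([0, 1, 2, 2], dtype=np.int8)
    assert genotype_r2(x, y) == pytest.approx(25 / 121)
    assert genotype_r2(x, x) == pytest.approx(1.0)
    assert np.isnan(genotype_r2(x[:2], y[:2]))  # < 3 complete pairs


def test_ld_survey_null_mean(two_pop_sim):
    g = two_pop_sim.subset_individuals(np.arange(30))  # one population
    survey = ld_survey(g, n_random_pairs=2000, exclude_nearest=(1, 5), seed=0,
                       max_same_contig_pairs=2000)
    n = 30
    assert abs(survey.random_mean - 1 / (n - 1)) < 0.015
    assert 0 <= survey.same_contig_mean <= 1
    assert set(survey.nearest_excluded_means) == {1, 5}


def test_ld_survey_detects_linkage():
    from wrassepop import simulate_linked_pair

    g = simulate_linked_pair(0.8, n=100, maf=0.3, seed=3)
    survey = ld_survey(g, n_random_pairs=0, seed=0)
    assert survey.n_same_contig_pairs == 1
    assert survey.same_contig_mean > 0.5
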