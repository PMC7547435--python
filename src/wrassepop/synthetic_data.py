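"""Synthetic genotype datasets and k-mer spectra.

The genotype generator follows the Balding–Nichols model: each locus draws
an ancestral allele frequency ``p`` from an ascertainment-aware law
(uniform on [0.05, 0.5] by default), and each population draws its own
frequency from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` so that the expected
between-population variance is ``p(1-p)F`` — i.e. F is the target FST.
Genotypes are then binomial(2, population frequency).  This reproduces the
allele-frequency divergence structure the downstream statistics act on
without simulating sequence or demography.

The spectrum generator tallies distinct k-mers from four classes —
sequencing-error k-mers with negative-binomial multiplicities, haploid
(heterozygous) k-mers at Poisson(lambda), diploid k-mers at Poisson(2*lambda),
and repeat k-mers at Poisson(2*lambda*copy) — matching the mixture the
EM fitter assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, KmerHistogram, Locus

DEFAULT_MAF_LOW = 0.05
DEFAULT_MAF_HIGH = 0.5


@dataclass
class PopSimConfig:
    """Design of a multi-population Balding–Nichols genotype simulation.

    Defaults mirror the discovery design the pipeline targets: four
    populations of 15 diploid individuals, a genome-wide panel of loci at
    moderate divergence, thinning-compatible coordinates and a small
    missing-genotype rate.
    """

    n_pops: int = 4
    n_per_pop: int = 15
    n_loci: int = 20_000
    target_fst: float = 0.06
    maf_low: float = DEFAULT_MAF_LOW
    maf_high: float = DEFAULT_MAF_HIGH
    n_outliers: int = 0
    outlier_fst: float = 0.3
    missing_rate: float = 0.02
    contig_length: int = 100_000
    snp_spacing: int = 1_500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0, 1)")
        if self.n_outliers and not 0 < self.outlier_fst < 1:
            raise ValueError("outlier_fst must be in (0, 1)")
        if self.n_outliers > self.n_loci:
            raise ValueError("n_outliers cannot exceed n_loci")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SpectrumSimConfig:
    """Design of a synthetic k-mer frequency spectrum.

    ``mean_coverage_haploid`` is the Poisson mean of a k-mer present on one
    haplotype only; homozygous (diploid) k-mers see twice that coverage and
    a repeat of copy number c sees 2*c times.
    """

    genome_size: int = 6_000_000
    mean_coverage_haploid: float = 15.0
    het_sites: int = 100_000
    k: int = 32
    error_kmers: int = 300_000
    error_nb_mean: float = 1.2
    error_nb_dispersion: float = 0.5
    repeat_fraction: float = 0.0
    repeat_copy_law: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size <= 0 or self.mean_coverage_haploid <= 0:
            raise ValueError("genome_size and coverage must be positive")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")
        if self.repeat_fraction > 0 and not self.repeat_copy_law:
            self.repeat_copy_law = {2: 0.6, 3: 0.25, 4: 0.15}


def simulate_populations(cfg: PopSimConfig) -> GenotypeMatrix:
    """Draw a GenotypeMatrix under the Balding–Nichols model.

    Outlier loci (the last ``cfg.n_outliers`` positions in locus order are
    deliberately NOT used; outliers are spread deterministically across the
    panel so contig-clustering reports stay honest) use ``outlier_fst``.
    Locus ids of planted outliers carry the suffix ``_out``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ind = cfg.n_pops * cfg.n_per_pop
    p_anc = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_loci)

    # Background loci follow Balding-Nichols: population frequencies are Beta
    # draws around the ancestral frequency with variance p(1-p)F.  Planted
    # outliers instead get a deterministic +/- sqrt(F p(1-p)) displacement
    # (alternating across populations), so every planted locus actually
    # realizes the target divergence — a Beta draw at elevated F leaves half
    # the planted loci with near-background divergence, which would make
    # recovery of "planted" loci an ill-posed notion.
    outlier_idx = np.array([], dtype=int)
    if cfg.n_outliers:
        outlier_idx = np.linspace(
            0, cfg.n_loci - 1, cfg.n_outliers, dtype=int
        )
        # ancestral frequencies of planted loci are redrawn high enough that
        # the displaced frequencies stay inside (0, 1)
        p_anc[outlier_idx] = rng.uniform(
            max(cfg.maf_low, 0.25), cfg.maf_high, size=len(outlier_idx)
        )

    codes = np.empty((n_ind, cfg.n_loci), dtype=np.int8)
    scale = (1.0 - cfg.target_fst) / cfg.target_fst
    d_out = np.sqrt(cfg.outlier_fst * p_anc * (1.0 - p_anc))
    for ip in range(cfg.n_pops):
        # Beta(p(1-F)/F, (1-p)(1-F)/F); as F -> 0 this degenerates to p itself,
        # which the huge-parameter Beta draw approaches numerically
        p_pop = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
        if cfg.n_outliers:
            sign = 1.0 if ip % 2 == 0 else -1.0
            p_pop[outlier_idx] = np.clip(
                p_anc[outlier_idx] + sign * d_out[outlier_idx], 0.005, 0.995
            )
        rows = slice(ip * cfg.n_per_pop, (ip + 1) * cfg.n_per_pop)
        codes[rows] = rng.binomial(
            2, p_pop[None, :], size=(cfg.n_per_pop, cfg.n_loci)
        ).astype(np.int8)

    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = MISSING

    loci = []
    snps_per_contig = max(1, cfg.contig_length // cfg.snp_spacing)
    width = len(str(max(1, (cfg.n_loci - 1) // snps_per_contig)))
    for j in range(cfg.n_loci):
        contig = f"contig{j // snps_per_contig:0{width}d}"
        pos = (j % snps_per_contig) * cfg.snp_spacing + 1
        suffix = "_out" if j in set(outlier_idx.tolist()) else ""
        loci.append(Locus(contig, pos, f"{contig}:{pos}{suffix}"))

    individuals = [
        f"pop{ip + 1}_ind{i + 1:02d}"
        for ip in range(cfg.n_pops)
        for i in range(cfg.n_per_pop)
    ]
    populations = [
        f"pop{ip + 1}" for ip in range(cfg.n_pops) for _ in range(cfg.n_per_pop)
    ]
    return GenotypeMatrix(individuals, populations, loci, codes)


def simulate_linked_pair(
    r2_target: float, n: int, maf: float, seed: int = 0
) -> GenotypeMatrix:
    """Two loci with expected squared genotype correlation ``r2_target``.

    Haplotypes are drawn from a two-locus distribution with equal allele
    frequencies ``maf`` at both loci and disequilibrium D = r * maf(1-maf),
    where r = sqrt(r2_target); genotypes are sums of two haplotypes.
    """
    if not 0 <= r2_target <= 1:
        raise ValueError("r2_target must be in [0, 1]")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = maf
    r = float(np.sqrt(r2_target))
    D = r * p * (1 - p)
    freqs = np.array([
        p * p + D,            # AB (minor-minor)
        p * (1 - p) - D,      # Ab
        p * (1 - p) - D,      # aB
        (1 - p) * (1 - p) + D,
    ])
    if (freqs < -1e-12).any():
        raise ValueError(
            f"r2_target={r2_target} infeasible at maf={maf}: "
            f"requires haplotype frequency {freqs.min():.4f} < 0"
        )
    freqs = np.clip(freqs, 0, None)
    freqs /= freqs.sum()
    hap = rng.choice(4, size=(n, 2), p=freqs)
    carries_a = np.isin(hap, (0, 1)).sum(axis=1)  # minor allele at locus 1
    carries_b = np.isin(hap, (0, 2)).sum(axis=1)
    if r2_target == 1.0:
        carries_b = carries_a.copy()
    codes = np.stack([carries_a, carries_b], axis=1).astype(np.int8)
    individuals = [f"ind{i + 1:03d}" for i in range(n)]
    loci = [Locus("contigA", 1, "contigA:1"), Locus("contigA", 1001, "contigA:1001")]
    return GenotypeMatrix(individuals, ["pop1"] * n, loci, codes)


def simulate_kmer_spectrum(cfg: SpectrumSimConfig) -> KmerHistogram:
    """Tally a synthetic k-mer multiplicity histogram from the 4-class model.

    Class sizes (distinct k-mers):
      error    : cfg.error_kmers, multiplicity ~ NB(mean, dispersion)
      haploid  : 2 * k * het_sites, multiplicity ~ Poisson(lambda)
      diploid  : genome_size*(1-repeat_fraction) - k*het_sites, ~ Poisson(2*lambda)
      repeat c : bp_share_c * genome_size * repeat_fraction / c, ~ Poisson(2*lambda*c)
    Unsampled k-mers (multiplicity 0) are dropped, as real counters do.
    """
    rng = np.random.default_rng(cfg.seed)
    lam = cfg.mean_coverage_haploid
    n_hap = 2 * cfg.k * cfg.het_sites
    n_dip = int(round(cfg.genome_size * (1 - cfg.repeat_fraction))) - cfg.k * cfg.het_sites
    if n_dip < 0:
        raise ValueError("heterozygous sites exceed the non-repeat genome")

    draws = []
    if cfg.error_kmers:
        # numpy NB: n = dispersion (size), p = n / (n + mean)
        size = cfg.error_nb_dispersion
        prob = size / (size + cfg.error_nb_mean)
        draws.append(rng.negative_binomial(size, prob, cfg.error_kmers))
    if n_hap:
        draws.append(rng.poisson(lam, n_hap))
    if n_dip:
        draws.append(rng.poisson(2 * lam, n_dip))
    if cfg.repeat_fraction > 0:
        repeat_bp = cfg.genome_size * cfg.repeat_fraction
        for copy, share in sorted(cfg.repeat_copy_law.items()):
            n_rep = int(round(repeat_bp * share / copy))
            if n_rep:
                draws.append(rng.poisson(2 * lam * copy, n_rep))

    mult = np.concatenate(draws)
    mult = mult[mult > 0]
    tally = np.bincount(mult)
    entries = {int(m): int(c) for m, c in enumerate(tally) if m >= 1 and c > 0}
    return KmerHistogram(k=cfg.k, entries=entries)
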