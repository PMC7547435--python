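"""Estimate coverage, genome size and heterozygosity from a k-mer spectrum.

Simulates the k-mer frequency histogram of a small heterozygous genome
(6 Mb, 1% heterozygous sites, 15x per-haplotype coverage, sequencing-error
k-mers), fits the four-class EM mixture and prints the derived estimates.
"""

from wrassepop import (
    SpectrumSimConfig,
    estimate_genome_size,
    estimate_het_sites,
    fit_spectrum,
    simulate_kmer_spectrum,
)

cfg = SpectrumSimConfig(
    genome_size=6_000_000,
    mean_coverage_haploid=15.0,
    het_sites=60_000,
    error_kmers=300_000,
    seed=1,
)
hist = simulate_kmer_spectrum(cfg)
fit = fit_spectrum(hist)

print(f"distinct k-mers observed : {hist.total_distinct:,}")
print(f"EM converged in {fit.n_iter} iterations (loglik {fit.loglik:.0f})")
print(f"haploid coverage lambda  : {fit.lambda_hap:.2f}  (true {cfg.mean_coverage_haploid})")
print(f"genome size estimate     : {estimate_genome_size(fit)/1e6:.2f} Mb  (true 6.00 Mb)")
print(f"heterozygous sites       : {estimate_het_sites(fit, hist):,.0f}  (true {cfg.het_sites:,})")
print("component weights        :",
      {n: round(w, 3) for n, w in zip(fit.component_names, fit.weights)})
# The haploid/diploid weight ratio reflects heterozygosity: each heterozygous
# site turns k diploid k-mers into 2k haploid-specific ones.
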