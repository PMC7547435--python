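"""EM fit of the four-class mixture to a k-mer frequency spectrum.

A whole-genome-sequencing k-mer spectrum is modelled as a mixture over
distinct k-mers of:

* an error class with negative-binomial multiplicities (low coverage,
  overdispersed),
* a haploid class, Poisson(lambda): k-mers present on one haplotype only
  (spanning heterozygous sites),
* a diploid class, Poisson(2*lambda): k-mers shared by both haplotypes,
* repeat classes, Poisson(2*lambda*c) for copy number c = 2, 3, ...

All Poisson classes share one coverage parameter lambda; the diploid mean
is hard-constrained to 2*lambda and repeats to 2*lambda*c, because the
class means differ only through copy number.  Component pmfs are
zero-truncated (a k-mer counter never reports multiplicity 0) and
multiplicities above a ceiling are pooled into a single tail bin.

From the fit: genome size G = (k-mer observations attributed to non-error
classes) / (2*lambda), and heterozygous-site count = (distinct haploid-class
k-mers) / (2k) — an isolated SNP creates k novel k-mers on each haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .io_formats import KmerHistogram


@dataclass
class SpectrumFit:
    lambda_hap: float
    error_mean: float
    error_dispersion: float
    weights: np.ndarray  # (error, haploid, diploid, repeat_2, ...)
    n_repeat_classes: int
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    responsibilities: np.ndarray | None = None  # (n_bins, n_components)
    bin_mults: np.ndarray | None = None
    bin_counts: np.ndarray | None = None
    bin_obs: np.ndarray | None = None  # exact m*count per bin incl. pooled tail
    tail_start: int | None = None

    @property
    def component_names(self) -> list[str]:
        return ["error", "haploid", "diploid"] + [
            f"repeat{c}x" for c in range(2, 2 + self.n_repeat_classes)
        ]


def _log_trunc(log_p0: float) -> float:
    """log P(X >= 1) from log P(X = 0)."""
    return float(np.log1p(-np.exp(min(log_p0, -1e-12))))


def _nb_log_col(body: np.ndarray, tail_start: int | None,
                mean: float, dispersion: float) -> np.ndarray:
    """Zero-truncated NB log bin probabilities (direct formulas for speed)."""
    r = dispersion
    p = r / (r + mean)
    logpmf = (
        special.gammaln(body + r) - special.gammaln(r)
        - special.gammaln(body + 1.0) + r * np.log(p) + body * np.log1p(-p)
    )
    log_p0 = r * np.log(p)
    col = logpmf - _log_trunc(log_p0)
    if tail_start is not None:
        log_tail = stats.nbinom.logsf(tail_start - 1, r, p)
        col = np.append(col, log_tail - _log_trunc(log_p0))
    return col


def _poisson_log_cols(body: np.ndarray, tail_start: int | None,
                      means: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson log bin probabilities for several means.

    Returns (n_bins, len(means)).
    """
    lgam = special.gammaln(body + 1.0)
    logpmf = body[:, None] * np.log(means)[None, :] - means[None, :] - lgam[:, None]
    log_p0 = -means
    log_norm = np.log1p(-np.exp(np.minimum(log_p0, -1e-12)))
    cols = logpmf - log_norm[None, :]
    if tail_start is not None:
        log_tail = stats.poisson.logsf(tail_start - 1, means)
        cols = np.vstack([cols, (log_tail - log_norm)[None, :]])
    return cols


def _component_log_bin_probs(
    mults: np.ndarray,
    tail_start: int | None,
    lam: float,
    err_mean: float,
    err_disp: float,
    n_repeat: int,
) -> np.ndarray:
    """Log P(bin | component), zero-truncated, with an optional pooled tail.

    Returns (n_bins, n_components).  When ``tail_start`` is set the last bin
    is the pooled mass P(X >= tail_start | X >= 1).
    """
    body = (mults if tail_start is None else mults[:-1]).astype(float)
    means = np.array([lam, 2 * lam] + [2 * lam * c for c in range(2, 2 + n_repeat)])
    nb = _nb_log_col(body, tail_start, err_mean, err_disp)
    poi = _poisson_log_cols(body, tail_start, means)
    out = np.column_stack([nb, poi])
    return np.clip(out, -745.0, 0.0)


def _mixture_loglik(
    counts: np.ndarray, log_probs: np.ndarray, weights: np.ndarray
) -> float:
    lw = np.log(np.clip(weights, 1e-300, None))
    return float(
        (counts * special.logsumexp(log_probs + lw[None, :], axis=1)).sum()
    )


def _init_lambda(mults: np.ndarray, counts: np.ndarray) -> float:
    """Coverage initializer from the spectrum's local maxima above multiplicity 4.

    A heterozygous genome shows peaks near lambda (haploid) and 2*lambda
    (diploid).  If two prominent local maxima sit at a ~1:2 position ratio,
    the lower one is the haploid mode; a single peak is read as the diploid
    mode (lambda = peak / 2), which also covers the homozygous limit.
    """
    mask = mults > 4
    if not mask.any():
        return max(float(mults[np.argmax(counts)]) / 2.0, 1.0)
    m, c = mults[mask], counts[mask]
    peaks = [
        i for i in range(len(m))
        if (i == 0 or c[i] >= c[i - 1]) and (i == len(m) - 1 or c[i] > c[i + 1])
    ]
    peaks = [i for i in peaks if c[i] >= 0.2 * c.max()]
    if len(peaks) >= 2:
        top2 = sorted(sorted(peaks, key=lambda i: c[i], reverse=True)[:2])
        m1, m2 = float(m[top2[0]]), float(m[top2[1]])
        if 1.6 <= m2 / m1 <= 2.5:
            return max(m1, 1.0)
    return max(float(m[np.argmax(c)]) / 2.0, 1.0)


def fit_spectrum(
    hist: KmerHistogram,
    n_repeat_classes: int = 4,
    tol: float = 1e-8,
    max_iter: int = 2000,
    init: dict | None = None,
    tail_ceiling_factor: float = 10.0,
) -> SpectrumFit:
    """Fit the error + haploid + diploid + repeats mixture by (generalized) EM.

    ``tol`` is the relative log-likelihood change declaring convergence.
    M-steps for lambda and the NB parameters are bounded 1-D maximizations
    of the expected complete-data log-likelihood, accepted only when they
    improve it, so the observed log-likelihood is monotone non-decreasing.
    """
    mults_all = hist.multiplicities.astype(np.int64)
    counts_all = hist.counts.astype(np.float64)
    if len(mults_all) < 5:
        raise ValueError("histogram needs >= 5 distinct multiplicities")
    if counts_all.sum() <= 0:
        raise ValueError("histogram has zero total count")

    init = dict(init or {})
    lam = float(init.get("lambda_hap", _init_lambda(mults_all, counts_all)))
    # error NB initialized from the sub-lambda/2 region
    low = mults_all < max(lam / 2.0, 2.0)
    if low.any() and counts_all[low].sum() > 0:
        err_mean = float(
            np.average(mults_all[low], weights=counts_all[low])
        )
    else:
        err_mean = 1.0
    err_mean = float(init.get("error_mean", max(err_mean, 0.3)))
    err_disp = float(init.get("error_dispersion", 0.5))

    ceiling = int(np.ceil(tail_ceiling_factor * lam))
    pooled = mults_all > ceiling
    obs_all = mults_all.astype(float) * counts_all
    if pooled.any():
        tail_start = ceiling + 1
        body = ~pooled
        mults = np.append(mults_all[body], tail_start)
        counts = np.append(counts_all[body], counts_all[pooled].sum())
        bin_obs = np.append(obs_all[body], obs_all[pooled].sum())
    else:
        tail_start = None
        mults, counts = mults_all, counts_all
        bin_obs = obs_all

    n_comp = 3 + n_repeat_classes
    weights = np.asarray(
        init.get("weights", np.full(n_comp, 1.0 / n_comp)), dtype=float
    )
    weights = weights / weights.sum()

    log_probs = _component_log_bin_probs(
        mults, tail_start, lam, err_mean, err_disp, n_repeat_classes
    )
    ll = _mixture_loglik(counts, log_probs, weights)
    trace = [ll]
    converged = False
    resp = None
    it = 0

    for it in range(1, max_iter + 1):
        # E-step
        lw = np.log(np.clip(weights, 1e-300, None))
        joint = log_probs + lw[None, :]
        norm = special.logsumexp(joint, axis=1, keepdims=True)
        resp = np.exp(joint - norm)

        # M-step: weights (closed form)
        wc = (resp * counts[:, None]).sum(axis=0)
        weights = wc / wc.sum()

        body = (mults if tail_start is None else mults[:-1]).astype(float)
        mult_factors = np.array(
            [1.0, 2.0] + [2.0 * c for c in range(2, 2 + n_repeat_classes)]
        )
        w_poi = resp[:, 1:] * counts[:, None]

        # M-step: lambda (generalized, 1-D)
        def neg_q_lambda(log_lam: float) -> float:
            lp = _poisson_log_cols(
                body, tail_start, float(np.exp(log_lam)) * mult_factors
            )
            return -float((w_poi * np.clip(lp, -745.0, 0.0)).sum())

        q0 = -neg_q_lambda(np.log(lam))
        res = optimize.minimize_scalar(
            neg_q_lambda,
            bounds=(np.log(lam) - 0.7, np.log(lam) + 0.7),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun >= q0:
            lam = float(np.exp(res.x))

        # M-step: NB error parameters (two bounded 1-D passes)
        w_err = resp[:, 0] * counts

        def neg_q_err_mean(log_m: float) -> float:
            lp = _nb_log_col(body, tail_start, float(np.exp(log_m)), err_disp)
            return -float((w_err * np.clip(lp, -745.0, 0.0)).sum())

        q0 = -neg_q_err_mean(np.log(err_mean))
        res = optimize.minimize_scalar(
            neg_q_err_mean,
            bounds=(np.log(err_mean) - 0.7, np.log(err_mean) + 0.7),
            method="bounded", options={"xatol": 1e-10},
        )
        if -res.fun >= q0:
            err_mean = float(np.exp(res.x))

        def neg_q_err_disp(log_d: float) -> float:
            lp = _nb_log_col(body, tail_start, err_mean, float(np.exp(log_d)))
            return -float((w_err * np.clip(lp, -745.0, 0.0)).sum())

        q0 = -neg_q_err_disp(np.log(err_disp))
        res = optimize.minimize_scalar(
            neg_q_err_disp,
            bounds=(np.log(err_disp) - 0.7, np.log(err_disp) + 0.7),
            method="bounded", options={"xatol": 1e-10},
        )
        if -res.fun >= q0:
            err_disp = float(np.exp(res.x))

        log_probs = _component_log_bin_probs(
            mults, tail_start, lam, err_mean, err_disp, n_repeat_classes
        )
        new_ll = _mixture_loglik(counts, log_probs, weights)
        trace.append(new_ll)
        if abs(new_ll - ll) <= tol * (abs(ll) + 1e-12):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    # final responsibilities at the converged parameters
    lw = np.log(np.clip(weights, 1e-300, None))
    joint = log_probs + lw[None, :]
    resp = np.exp(joint - special.logsumexp(joint, axis=1, keepdims=True))

    return SpectrumFit(
        lambda_hap=lam,
        error_mean=err_mean,
        error_dispersion=err_disp,
        weights=weights,
        n_repeat_classes=n_repeat_classes,
        loglik=ll,
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
        responsibilities=resp,
        bin_mults=mults,
        bin_counts=counts,
        bin_obs=bin_obs,
        tail_start=tail_start,
    )


def estimate_genome_size(fit: SpectrumFit, hist: KmerHistogram | None = None) -> float:
    """Haploid genome size G = (non-error k-mer observations) / (2*lambda).

    Every genomic position contributes 2*lambda sequenced k-mer copies per
    haploid-genome equivalent (a heterozygous position splits its 2*lambda
    across two haploid-class k-mers, a c-copy repeat concentrates 2*lambda*c
    on 1/c as many distinct k-mers), so the attribution needs no per-class
    correction.
    """
    if fit.lambda_hap <= 0:
        raise ValueError("lambda must be positive")
    if fit.responsibilities is None:
        raise ValueError("fit carries no responsibilities")
    non_error = 1.0 - fit.responsibilities[:, 0]
    total = float((fit.bin_obs * non_error).sum())
    return total / (2.0 * fit.lambda_hap)


def estimate_het_sites(
    fit: SpectrumFit, hist: KmerHistogram | None = None, k: int | None = None,
    kmers_per_site: float | None = None,
) -> float:
    """Heterozygous-site count from the haploid-class distinct-k-mer mass.

    The default conversion divides by 2k (k novel k-mers per haplotype per
    isolated SNP); ``kmers_per_site`` overrides that divisor for other
    conventions.
    """
    if fit.responsibilities is None:
        raise ValueError("fit carries no responsibilities")
    if k is None and hist is not None:
        k = hist.k
    if kmers_per_site is None:
        if not k or k <= 0:
            raise ValueError("k must be positive")
        kmers_per_site = 2.0 * k
    hap_distinct = float((fit.bin_counts * fit.responsibilities[:, 1]).sum())
    return hap_distinct / kmers_per_site
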