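"""Parametric linkage-disequilibrium simulation and LD statistics.

Haplotypes are drawn from a Gaussian copula: a latent multivariate normal
vector with exponentially decaying inter-SNP correlation is thresholded at
the normal quantile of each allele frequency, giving correlated 0/1 allele
indicators.  Two haplotypes per individual are summed to genotypes in
{0, 1, 2}.  The decay parameter can be calibrated by bisection so that the
panel hits a target mean pairwise r-squared (default 0.14, a typical value
for a dense panel of low-frequency variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "LDPanel",
    "LDStats",
    "make_ld_panel",
    "simulate_haplotypes",
    "simulate_ld_genotypes",
    "ld_statistics",
    "calibrate_decay",
]


@dataclass
class LDPanel:
    """Latent-correlation description of a haplotype panel.

    ``correlation_profile[j]`` is the latent correlation between adjacent
    SNPs j and j+1; the full latent correlation matrix is the product of the
    adjacent correlations along the path (first-order autoregressive
    structure), which is always positive definite for entries in [0, 1).
    """

    n_haplotype_snps: int
    correlation_profile: np.ndarray  # (n_snps - 1,) adjacent latent correlations
    allele_freqs: np.ndarray  # per-SNP allele frequency

    def __post_init__(self) -> None:
        self.correlation_profile = np.asarray(self.correlation_profile, dtype=float)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if self.correlation_profile.shape != (self.n_haplotype_snps - 1,):
            raise ValueError("correlation_profile must have n_snps - 1 entries")
        if np.any((self.correlation_profile < 0) | (self.correlation_profile >= 1)):
            raise ValueError("latent correlations must lie in [0, 1)")
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")

    def latent_correlation(self) -> np.ndarray:
        """Full latent correlation matrix from the adjacent-pair profile."""
        n = self.n_haplotype_snps
        # cumulative log-products give rho_ij = prod of adjacent rhos between i and j
        with np.errstate(divide="ignore"):
            logs = np.concatenate([[0.0], np.cumsum(np.log(np.maximum(self.correlation_profile, 1e-300)))])
        corr = np.exp(-np.abs(logs[:, None] - logs[None, :]))
        # exact zeros in the profile break the chain entirely
        zero = np.flatnonzero(self.correlation_profile == 0.0)
        for z in zero:
            corr[: z + 1, z + 1 :] = 0.0
            corr[z + 1 :, : z + 1] = 0.0
        np.fill_diagonal(corr, 1.0)
        return corr


def make_ld_panel(
    n_snps: int,
    decay: float,
    rng: np.random.Generator,
    freq_bounds: tuple[float, float] = (0.05, 0.2),
) -> LDPanel:
    """Build a panel with constant adjacent latent correlation ``decay``
    and allele frequencies drawn uniformly within ``freq_bounds``."""
    freqs = rng.uniform(freq_bounds[0], freq_bounds[1], size=n_snps)
    return LDPanel(
        n_haplotype_snps=n_snps,
        correlation_profile=np.full(n_snps - 1, decay),
        allele_freqs=freqs,
    )


def simulate_haplotypes(
    n_haplotypes: int, panel: LDPanel, rng: np.random.Generator
) -> np.ndarray:
    """Draw 0/1 haplotypes from the thresholded latent-normal model."""
    corr = panel.latent_correlation()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("latent correlation matrix is not positive definite") from exc
    z = rng.standard_normal((n_haplotypes, panel.n_haplotype_snps)) @ chol.T
    thresholds = norm.ppf(panel.allele_freqs)
    return (z < thresholds).astype(np.int8)


def simulate_ld_genotypes(
    n_individuals: int, panel: LDPanel, rng: np.random.Generator
) -> np.ndarray:
    """Sum two haplotypes per individual into genotypes in {0, 1, 2}."""
    haps = simulate_haplotypes(2 * n_individuals, panel, rng)
    return (haps[::2] + haps[1::2]).astype(np.int8)


@dataclass
class LDStats:
    mean_dprime: float
    sd_dprime: float
    mean_rsq: float
    sd_rsq: float
    n_pairs: int
    n_skipped: int  # pairs with a monomorphic member (D', r^2 undefined)


def _pairwise_d(freq: np.ndarray, cov_alleles: np.ndarray) -> np.ndarray:
    """D' from allelic covariance D and the frequency-bound maximum."""
    p = freq[:, None]
    q = freq[None, :]
    d = cov_alleles
    dmax = np.where(
        d >= 0,
        np.minimum(p * (1 - q), (1 - p) * q),
        np.minimum(p * q, (1 - p) * (1 - q)),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(d) / dmax


def ld_statistics(data: np.ndarray, kind: str = "genotype") -> LDStats:
    """Mean and SD of pairwise D' and r-squared over all SNP pairs.

    ``kind='haplotype'``: rows are 0/1 haplotypes; D is the allelic
    covariance and r^2 the squared haplotype correlation.  ``kind='genotype'``:
    rows are 0/1/2 genotypes; r^2 is the squared allele-count correlation and
    D is estimated by the composite (Burrows) covariance cov(g_i, g_j)/2,
    which is unbiased under HWE.  Pairs with a monomorphic member are skipped.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 SNP columns")
    if kind not in ("genotype", "haplotype"):
        raise ValueError("kind must be 'genotype' or 'haplotype'")
    ploidy = 2.0 if kind == "genotype" else 1.0
    freq = data.mean(axis=0) / ploidy
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / data.shape[0]
    var = np.diag(cov).copy()
    poly = var > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(var[:, None] * var[None, :])
    rsq = corr**2
    dprime = _pairwise_d(freq, cov / (ploidy if kind == "genotype" else 1.0))
    iu = np.triu_indices(data.shape[1], k=1)
    keep = poly[iu[0]] & poly[iu[1]]
    rsq_v = rsq[iu][keep]
    dp_v = np.clip(dprime[iu][keep], 0.0, 1.0)
    n_pairs = int(keep.sum())
    return LDStats(
        mean_dprime=float(np.mean(dp_v)) if n_pairs else float("nan"),
        sd_dprime=float(np.std(dp_v, ddof=1)) if n_pairs > 1 else float("nan"),
        mean_rsq=float(np.mean(rsq_v)) if n_pairs else float("nan"),
        sd_rsq=float(np.std(rsq_v, ddof=1)) if n_pairs > 1 else float("nan"),
        n_pairs=n_pairs,
        n_skipped=int((~keep).sum()),
    )


def calibrate_decay(
    target_mean_rsq: float,
    n_snps: int,
    rng: np.random.Generator,
    n_individuals: int = 2000,
    tol: float = 0.005,
    max_iter: int = 30,
) -> float:
    """Bisection on the adjacent latent correlation so that a simulated panel
    attains the target mean pairwise genotype r-squared.

    Mean r^2 is monotone in the decay parameter; each evaluation re-simulates
    with a child seed, so the returned decay is accurate to Monte-Carlo error
    plus ``tol``.
    """
    if not (0.0 < target_mean_rsq < 1.0):
        raise ValueError("target_mean_rsq must lie in (0, 1)")
    ss = np.random.SeedSequence(rng.integers(2**31))
    lo, hi = 0.0, 0.999

    def mean_rsq(decay: float, seed_seq) -> float:
        r = np.random.default_rng(seed_seq)
        panel = make_ld_panel(n_snps, decay, r)
        g = simulate_ld_genotypes(n_individuals, panel, r)
        return ld_statistics(g, kind="genotype").mean_rsq

    seeds = ss.spawn(max_iter)
    decay = 0.5
    for i in range(max_iter):
        decay = 0.5 * (lo + hi)
        val = mean_rsq(decay, seeds[i])
        if abs(val - target_mean_rsq) < tol:
            break
        if val < target_mean_rsq:
            lo = decay
        else:
            hi = decay
    return decay
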