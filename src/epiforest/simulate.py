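"""Simulation of SNP case-control data under two-locus interaction models.

Genotypes are minor-allele counts in {0, 1, 2} drawn under Hardy-Weinberg
equilibrium.  A binary phenotype is generated from an additive logit model in
which two designated SNPs interact according to one of five genetic models
(*interaction only*, *modifier SNP*, *no interaction*, *redundant*,
*synergistic*), a block of marginal-only SNPs contributes per-allele log-odds
``beta_M``, and the remaining SNPs are pure noise.  The baseline log-odds
``beta_0`` is calibrated by exact enumeration of the effect-SNP genotype
distribution so that the expected disease prevalence hits a target (0.5 by
default, i.e. balanced cases and controls).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import binom

__all__ = [
    "INTERACTION_MODELS",
    "ScenarioConfig",
    "GenotypeMatrix",
    "SimulatedDataset",
    "PenetranceTable",
    "sample_noise_frequencies",
    "sample_genotypes",
    "interaction_term",
    "linear_predictor",
    "calibrate_baseline",
    "penetrance_table",
    "sample_phenotypes",
    "simulate_dataset",
    "export_dataset",
    "import_dataset",
]

# Per-model coefficients on the additive (allele-count) coding, as multiples
# of the single interaction-model coefficient beta_I:
# (marginal SNP1, marginal SNP2, product term g1*g2).
INTERACTION_MODELS: dict[str, tuple[float, float, float]] = {
    "interaction_only": (0.0, 0.0, 1.0),
    "modifier_snp": (0.0, 1.0, 1.0),
    "no_interaction": (1.0, 1.0, 0.0),
    "redundant": (1.0, 1.0, -1.0),
    "synergistic": (1.0, 1.0, 1.0),
}

ROLE_INTERACTING = "interacting"
ROLE_MARGINAL = "marginal"
ROLE_NOISE = "noise"


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulation scenario.

    Defaults follow the base design: n=1000 individuals, 2 interacting SNPs,
    5 marginal-only SNPs, 93 noise SNPs, 500 trees.
    """

    model: str = "interaction_only"
    beta_M: float = 0.4
    beta_I: float = 0.4
    maf_M: float = 0.2
    maf_I: float = 0.2
    n_individuals: int = 1000
    n_marginal: int = 5
    n_noise: int = 93
    mtry: int = 50
    n_trees: int = 500
    n_replicates: int = 100
    seed: int = 0
    target_prevalence: float = 0.5
    beta_0: float | None = None
    # linkage-disequilibrium mode: all SNP columns come from a Gaussian-copula
    # haplotype panel instead of independent HWE draws
    ld: bool = False
    ld_decay: float | None = None  # adjacent latent correlation; None = calibrate
    ld_target_rsq: float = 0.14

    def __post_init__(self) -> None:
        if self.model not in INTERACTION_MODELS:
            raise ValueError(
                f"unknown interaction model {self.model!r}; "
                f"expected one of {sorted(INTERACTION_MODELS)}"
            )
        for name, maf in (("maf_M", self.maf_M), ("maf_I", self.maf_I)):
            if not (0.0 < maf <= 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5], got {maf}")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie in (0, 1)")
        for name in ("n_individuals", "n_marginal", "n_noise", "mtry",
                     "n_trees", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mtry > self.n_snps:
            raise ValueError(
                f"mtry={self.mtry} exceeds total SNP count {self.n_snps}"
            )

    @property
    def n_snps(self) -> int:
        return 2 + self.n_marginal + self.n_noise

    def with_baseline(self, beta_0: float) -> "ScenarioConfig":
        return replace(self, beta_0=beta_0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


@dataclass
class GenotypeMatrix:
    """Genotype matrix (minor-allele counts) with per-SNP roles."""

    values: np.ndarray  # (n_individuals, n_snps) int8 in {0,1,2}
    allele_freqs: np.ndarray  # per-SNP generating allele frequency
    roles: np.ndarray  # per-SNP role label (object/str array)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if self.values.shape[1] != self.roles.shape[0]:
            raise ValueError("roles length must equal the number of SNP columns")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def columns_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotype: np.ndarray  # (n_individuals,) int8 in {0,1}; case=1
    scenario: ScenarioConfig

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.phenotype.shape[0] != self.genotypes.n_individuals:
            raise ValueError("phenotype length must equal genotype row count")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype entries must be in {0, 1}")


@dataclass
class PenetranceTable:
    """3x3 disease probabilities indexed by the two interacting genotypes."""

    values: np.ndarray  # (3, 3); rows = genotype of SNP1, cols = SNP2
    model: str
    beta_I: float
    beta_0: float

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        labels = ["0", "1", "2"]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)


# ---------------------------------------------------------------------------
# genotype generation


def sample_noise_frequencies(count: int, rng: np.random.Generator) -> np.ndarray:
    """Draw allele frequencies for noise SNPs, Uniform(0, 1) each.

    Values above 0.5 are permitted: the frequency is used as-is as the
    generating allele frequency.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    return rng.uniform(0.0, 1.0, size=count)


def sample_genotypes(
    n_individuals: int, allele_freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample a genotype matrix under HWE: entries ~ Binomial(2, freq)."""
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    if np.any((allele_freqs <= 0.0) | (allele_freqs >= 1.0)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    return rng.binomial(
        2, allele_freqs, size=(n_individuals, allele_freqs.shape[0])
    ).astype(np.int8)


# ---------------------------------------------------------------------------
# logit disease model


def interaction_term(g1, g2, model: str, beta_I: float):
    """Log-odds contribution of the two interacting SNPs.

    Additive coding: ``m1*g1 + m2*g2 + i12*g1*g2`` with per-model
    coefficient multiples of ``beta_I``.  Accepts scalars or arrays.
    """
    try:
        m1, m2, i12 = INTERACTION_MODELS[model]
    except KeyError:
        raise ValueError(f"unknown interaction model {model!r}") from None
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if not (np.isin(g1, (0, 1, 2)).all() and np.isin(g2, (0, 1, 2)).all()):
        raise ValueError("genotypes must be in {0, 1, 2}")
    out = beta_I * (m1 * g1 + m2 * g2 + i12 * g1 * g2)
    return out if out.ndim else float(out)


def linear_predictor(genotypes: GenotypeMatrix, scenario: ScenarioConfig) -> np.ndarray:
    """Per-individual log-odds eta under the scenario's logit model."""
    if scenario.beta_0 is None:
        raise ValueError("scenario.beta_0 is not set; calibrate or supply it")
    inter = genotypes.columns_with_role(ROLE_INTERACTING)
    if inter.shape[0] != 2:
        raise ValueError("genotype matrix must label exactly 2 interacting SNPs")
    marg = genotypes.columns_with_role(ROLE_MARGINAL)
    g = genotypes.values
    eta = np.full(genotypes.n_individuals, scenario.beta_0, dtype=float)
    if marg.size:
        eta += scenario.beta_M * g[:, marg].sum(axis=1)
    eta += interaction_term(
        g[:, inter[0]], g[:, inter[1]], scenario.model, scenario.beta_I
    )
    return eta


def _effect_distribution(scenario: ScenarioConfig):
    """Exact joint distribution of (g1, g2, sum of marginal genotypes).

    The marginal-only SNPs are iid Binomial(2, maf_M), so their genotype sum
    is Binomial(2*n_marginal, maf_M); together with the 3x3 interacting-SNP
    distribution this enumerates the full effect-SNP genotype space.
    """
    g = np.arange(3)
    p_i = binom.pmf(g, 2, scenario.maf_I)
    s = np.arange(2 * scenario.n_marginal + 1)
    p_s = binom.pmf(s, 2 * scenario.n_marginal, scenario.maf_M)
    g1, g2, sm = np.meshgrid(g, g, s, indexing="ij")
    prob = p_i[g1] * p_i[g2] * p_s[sm]
    eta_no_b0 = scenario.beta_M * sm + interaction_term(
        g1, g2, scenario.model, scenario.beta_I
    )
    return prob.ravel(), np.asarray(eta_no_b0, dtype=float).ravel()


def expected_prevalence(scenario: ScenarioConfig, beta_0: float) -> float:
    """E[expit(eta)] under the exact effect-SNP genotype distribution."""
    prob, eta = _effect_distribution(scenario)
    return float(prob @ expit(beta_0 + eta))


def calibrate_baseline(
    scenario: ScenarioConfig, target_prevalence: float | None = None
) -> float:
    """Solve for beta_0 so the expected prevalence equals the target.

    expit is strictly increasing in beta_0, so the root is unique; brentq on
    a wide bracket converges to |prevalence error| < 1e-10.
    """
    target = scenario.target_prevalence if target_prevalence is None else target_prevalence
    if not (0.0 < target < 1.0):
        raise ValueError("target_prevalence must lie in (0, 1)")
    prob, eta = _effect_distribution(scenario)

    def f(b0: float) -> float:
        return float(prob @ expit(b0 + eta)) - target

    return float(brentq(f, -60.0, 60.0, xtol=1e-12, rtol=8.9e-16))


def penetrance_table(model: str, beta_I: float, beta_0: float) -> PenetranceTable:
    """Disease probability for each of the 9 two-locus genotype combinations."""
    g = np.arange(3)
    g1, g2 = np.meshgrid(g, g, indexing="ij")
    values = expit(beta_0 + interaction_term(g1, g2, model, beta_I))
    return PenetranceTable(values=values, model=model, beta_I=beta_I, beta_0=beta_0)


def sample_phenotypes(eta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(expit(eta)) case/control labels, independent given eta."""
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("eta must be finite")
    return (rng.uniform(size=eta.shape) < expit(eta)).astype(np.int8)


# ---------------------------------------------------------------------------
# dataset assembly


def _roles_vector(n_marginal: int, n_noise: int) -> np.ndarray:
    return np.array(
        [ROLE_INTERACTING] * 2 + [ROLE_MARGINAL] * n_marginal + [ROLE_NOISE] * n_noise,
        dtype=object,
    )


def simulate_dataset(
    scenario: ScenarioConfig, rng: np.random.Generator | int | None = None
) -> SimulatedDataset:
    """Simulate one full dataset for a scenario.

    Column order is fixed: [interacting 1, interacting 2, marginal 1..m,
    noise 1..k].  Noise-SNP frequencies are redrawn for every dataset.
    beta_0 is calibrated to the target prevalence unless the scenario
    supplies it.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(scenario.seed if rng is None else rng)
    if scenario.ld:
        return _simulate_ld_dataset(scenario, rng)
    freqs = np.concatenate([
        np.full(2, scenario.maf_I),
        np.full(scenario.n_marginal, scenario.maf_M),
        sample_noise_frequencies(scenario.n_noise, rng),
    ])
    # guard the open-interval requirement for uniform draws at the boundary
    freqs = np.clip(freqs, 1e-12, 1 - 1e-12)
    values = sample_genotypes(scenario.n_individuals, freqs, rng)
    genotypes = GenotypeMatrix(
        values=values,
        allele_freqs=freqs,
        roles=_roles_vector(scenario.n_marginal, scenario.n_noise),
    )
    if scenario.beta_0 is None:
        scenario = scenario.with_baseline(calibrate_baseline(scenario))
    eta = linear_predictor(genotypes, scenario)
    phenotype = sample_phenotypes(eta, rng)
    return SimulatedDataset(genotypes=genotypes, phenotype=phenotype, scenario=scenario)


def _simulate_ld_dataset(
    scenario: ScenarioConfig, rng: np.random.Generator
) -> SimulatedDataset:
    """LD-mode dataset: every SNP column comes from a correlated haplotype
    panel; the first columns carry the effect roles.

    The exact-enumeration baseline calibration assumes independent effect
    SNPs at known frequencies, which no longer holds, so beta_0 is instead
    solved on the realized linear predictors (empirical calibration, exact
    for the drawn genotypes and monotone in beta_0).
    """
    from .ld import calibrate_decay, make_ld_panel, simulate_ld_genotypes

    decay = scenario.ld_decay
    if decay is None:
        decay = calibrate_decay(
            scenario.ld_target_rsq, scenario.n_snps, rng
        )
    panel = make_ld_panel(scenario.n_snps, decay, rng)
    values = simulate_ld_genotypes(scenario.n_individuals, panel, rng)
    genotypes = GenotypeMatrix(
        values=values,
        allele_freqs=panel.allele_freqs,
        roles=_roles_vector(scenario.n_marginal, scenario.n_noise),
    )
    if scenario.beta_0 is None:
        eta0 = linear_predictor(genotypes, scenario.with_baseline(0.0))
        b0 = brentq(
            lambda b: float(np.mean(expit(b + eta0))) - scenario.target_prevalence,
            -60.0, 60.0, xtol=1e-12,
        )
        scenario = scenario.with_baseline(float(b0))
    eta = linear_predictor(genotypes, scenario)
    phenotype = sample_phenotypes(eta, rng)
    return SimulatedDataset(genotypes=genotypes, phenotype=phenotype, scenario=scenario)


# ---------------------------------------------------------------------------
# import / export


def _snp_ids(roles: np.ndarray) -> list[str]:
    counts: dict[str, int] = {}
    ids = []
    for role in roles:
        counts[role] = counts.get(role, 0) + 1
        ids.append(f"snp{len(ids) + 1}_{role}")
    return ids


def export_dataset(dataset: SimulatedDataset, path: str | Path) -> None:
    """Write a tab-separated raw-genotype table plus a JSON scenario sidecar.

    Header row: SNP ids with role suffixes, then ``phenotype``.  One row per
    individual; genotype entries 0/1/2; final column phenotype 0/1.
    """
    path = Path(path)
    ids = _snp_ids(dataset.genotypes.roles)
    with open(path, "w") as fh:
        fh.write("\t".join(ids + ["phenotype"]) + "\n")
        for row, y in zip(dataset.genotypes.values, dataset.phenotype):
            fh.write("\t".join(map(str, row.tolist() + [int(y)])) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(dataset.scenario.to_dict(), fh, indent=2)


def import_dataset(path: str | Path) -> SimulatedDataset:
    """Read a dataset written by :func:`export_dataset`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    data = np.array(rows, dtype=np.int8)
    roles = np.array([h.rsplit("_", 1)[1] for h in header[:-1]], dtype=object)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        scenario = ScenarioConfig.from_dict(json.load(fh))
    freqs = np.concatenate([
        np.full(2, scenario.maf_I),
        np.full(scenario.n_marginal, scenario.maf_M),
        np.full(scenario.n_noise, np.nan),  # noise freqs are not persisted
    ])
    genotypes = GenotypeMatrix(values=data[:, :-1], allele_freqs=freqs, roles=roles)
    return SimulatedDataset(
        genotypes=genotypes, phenotype=data[:, -1], scenario=scenario
    )
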