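"""Synthetic study generator for evaluating GRS weighting regimes.

Genotypes are independent biallelic SNPs drawn under Hardy-Weinberg
equilibrium: dosage_ij ~ Binomial(2, MAF_j).  A panel holds ``k_risk``
risk SNPs (first columns, by convention) followed by ``k_noise`` noise
SNPs with no effect on the outcome.  Risk SNPs act through a dominant
indicator D_j = 1{dosage >= 1}.

Outcome scenarios (gaussian by default, eps ~ N(0, noise_sd^2)):

* predominant-interaction ("a"):
      y_i = sum_j beta_int * D_ij * E_i + eps_i.
  With the default Bernoulli(0.5) exposure this induces an *implicit*
  marginal effect of each risk SNP of beta_int/2 (0.75 for the default
  1.5) without any explicit main-effect term, i.e. the interaction is
  predominant and the marginal effect smaller and not separately set.
* predominant-marginal ("b"):
      y_i = sum_j beta_marg * D_ij
            + sum_j (secondary_effect_fraction * beta_marg) * D_ij * E_i
            + eps_i,
  a strong marginal effect with a smaller additional interaction
  (default fraction 0.5, i.e. 0.75).
* null: scenario (b) with the interaction terms removed — marginal
  effects present, zero interaction, the null under which type I error
  is assessed.

For a binomial outcome the linear predictor is passed through the
inverse logit and y_i ~ Bernoulli(p_i).

External studies ("perfect", "underestimating", "overestimating"
weights) are simulated by :func:`simulate_external_study`; the matching
generating process for the *sample* under each mode comes from
:func:`sample_config_for_external_mode`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix, WeightVector, recode_genotypes

SCENARIOS = ("predominant-interaction", "predominant-marginal", "null")
_SCENARIO_ALIASES = {"a": "predominant-interaction", "b": "predominant-marginal"}
EXTERNAL_MODES = ("perfect", "underestimating", "overestimating")


@dataclass
class ScenarioConfig:
    """One simulated study condition.

    Defaults reproduce the core condition of the evaluation design: six
    risk SNPs, MAFs uniform on (0.01, 0.45), dominant inheritance,
    interaction / marginal effect size 1.5, Bernoulli(0.5) exposure,
    unit gaussian noise.
    """

    n: int = 1000
    k_risk: int = 6
    k_noise: int = 6
    maf_range: tuple[float, float] = (0.01, 0.45)
    maf_fixed: float | None = None  # fixes all risk-SNP MAFs (MAF sweeps)
    scenario: str = "predominant-interaction"
    interaction_effect: float = 1.5
    marginal_effect: float = 1.5
    secondary_effect_fraction: float = 0.5
    exposure_dist: str = "bernoulli"  # or "standard-normal"
    noise_sd: float = 1.0
    family: str = "gaussian"
    n_active_risk: int | None = None  # None = all risk SNPs carry effects
    seed: int = 0

    def __post_init__(self) -> None:
        self.scenario = _SCENARIO_ALIASES.get(self.scenario, self.scenario)
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.k_risk < 1:
            raise ValueError("k_risk must be >= 1")
        if self.k_noise < 0:
            raise ValueError("k_noise must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.maf_fixed is not None and not 0.0 < self.maf_fixed <= 0.5:
            raise ValueError("maf_fixed must lie in (0, 0.5]")
        if self.exposure_dist not in ("bernoulli", "standard-normal"):
            raise ValueError(f"unknown exposure_dist {self.exposure_dist!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if not all(
            np.isfinite([self.interaction_effect, self.marginal_effect,
                         self.secondary_effect_fraction])
        ):
            raise ValueError("effect sizes must be finite")
        if self.n_active_risk is not None and not 1 <= self.n_active_risk <= self.k_risk:
            raise ValueError("n_active_risk must be in [1, k_risk]")

    @property
    def k(self) -> int:
        return self.k_risk + self.k_noise


@dataclass
class ExternalStudyConfig:
    """How a simulated external weight source relates to the sample.

    perfect: identical generating process.  underestimating: the
    *sample's* risk-SNP effects are ``inflation`` times (default 1.3,
    i.e. 30% larger than) the external ones.  overestimating: only
    ``active_risk_snps_in_sample`` (default 1) of the external risk SNPs
    carry any effect in the sample's generating process.
    ``size_factor`` scales the external sample size (1 or 4 in the
    evaluation design).
    """

    mode: str = "perfect"
    size_factor: int = 1
    inflation: float = 1.3
    active_risk_snps_in_sample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in EXTERNAL_MODES:
            raise ValueError(f"unknown external mode {self.mode!r}")
        if self.size_factor < 1:
            raise ValueError("size_factor must be >= 1")


@dataclass
class SimulatedStudy:
    """Genotypes, exposure, outcome and the generating truth."""

    genotypes: GenotypeMatrix
    exposure: np.ndarray
    phenotype: np.ndarray
    truth: dict


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, mafs, seed=0) -> GenotypeMatrix:
    """Independent Hardy-Weinberg SNPs: dosage_ij ~ Binomial(2, maf_j)."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    dosages = rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(mafs.size)],
        maf=mafs,
    )


def simulate_exposure(n: int, dist: str = "bernoulli", seed=0) -> np.ndarray:
    """Environmental exposure: Bernoulli(0.5) (default) or standard normal."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    if dist == "bernoulli":
        return rng.binomial(1, 0.5, size=n).astype(float)
    if dist == "standard-normal":
        return rng.standard_normal(n)
    raise ValueError(f"unknown exposure distribution {dist!r}")


def true_effects(cfg: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (marginal, interaction) generating coefficients on the
    dominant-indicator scale.  Scenario (a)'s marginal column is the
    *explicit* term (zero); its implicit marginal effect under a
    Bernoulli exposure is interaction_effect * E[E]."""
    marg = np.zeros(cfg.k)
    inter = np.zeros(cfg.k)
    active = cfg.k_risk if cfg.n_active_risk is None else cfg.n_active_risk
    if cfg.scenario == "predominant-interaction":
        inter[:active] = cfg.interaction_effect
    elif cfg.scenario == "predominant-marginal":
        marg[:active] = cfg.marginal_effect
        inter[:active] = cfg.secondary_effect_fraction * cfg.marginal_effect
    else:  # null: marginal effects only
        marg[:active] = cfg.marginal_effect
    return marg, inter


def simulate_phenotype(G: GenotypeMatrix, E, cfg: ScenarioConfig, seed=0) -> np.ndarray:
    """Outcome under the configured scenario; risk SNPs are the first
    ``k_risk`` columns and act through their dominant indicator."""
    if cfg.k_risk > G.k:
        raise ValueError(f"k_risk={cfg.k_risk} exceeds SNP count {G.k}")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    E = np.asarray(E, dtype=float)
    D = np.minimum(G.dosages, 1).astype(float)
    marg, inter = true_effects(cfg)
    eta = D @ marg + (D @ inter) * E
    if cfg.family == "gaussian":
        return eta + cfg.noise_sd * rng.standard_normal(G.n)
    p = 1.0 / (1.0 + np.exp(-eta))
    return rng.binomial(1, p).astype(float)


def simulate_study(cfg: ScenarioConfig, seed=None) -> SimulatedStudy:
    """Draw MAFs, genotypes, exposure and outcome for one replicate."""
    rng = _rng(cfg.seed if seed is None else seed)
    mafs = rng.uniform(*cfg.maf_range, size=cfg.k)
    if cfg.maf_fixed is not None:
        mafs[: cfg.k_risk] = cfg.maf_fixed
    G = simulate_genotypes(cfg.n, mafs, rng)
    E = simulate_exposure(cfg.n, cfg.exposure_dist, rng)
    y = simulate_phenotype(G, E, cfg, rng)
    marg, inter = true_effects(cfg)
    truth = {
        "scenario": cfg.scenario,
        "marginal": marg.tolist(),
        "interaction": inter.tolist(),
        "truth_sign": 0 if cfg.scenario == "null" else (1 if np.any(inter > 0) else -1),
        "mafs": mafs.tolist(),
    }
    return SimulatedStudy(genotypes=G, exposure=E, phenotype=y, truth=truth)


def marginal_effect_estimates(G: GenotypeMatrix, y, family: str = "gaussian") -> np.ndarray:
    """Per-SNP univariate marginal effect estimates (dominant coding):
    the slope of y on D_j, the quantity an external study would publish."""
    D = np.minimum(G.dosages, 1).astype(float)
    y = np.asarray(y, dtype=float)
    if family == "gaussian":
        Dc = D - D.mean(axis=0)
        var = (Dc**2).mean(axis=0)
        var = np.where(var == 0, np.nan, var)
        est = (Dc * (y - y.mean())[:, None]).mean(axis=0) / var
        return np.nan_to_num(est)
    import statsmodels.api as sm

    out = np.zeros(G.k)
    for j in range(G.k):
        X = sm.add_constant(D[:, j])
        try:
            out[j] = sm.GLM(y, X, family=sm.families.Binomial()).fit().params[1]
        except Exception:
            out[j] = 0.0
    return out


def sample_config_for_external_mode(
    ext: ExternalStudyConfig, base: ScenarioConfig
) -> tuple[ScenarioConfig, ScenarioConfig]:
    """(sample_cfg, external_cfg) generating processes for a mode.

    ``base`` describes the external study's process; the sample deviates
    from it as the mode dictates.
    """
    external_cfg = dataclasses.replace(base, n=base.n * ext.size_factor)
    if ext.mode == "perfect":
        sample_cfg = dataclasses.replace(base)
    elif ext.mode == "underestimating":
        sample_cfg = dataclasses.replace(
            base,
            interaction_effect=base.interaction_effect * ext.inflation,
            marginal_effect=base.marginal_effect * ext.inflation,
        )
    else:  # overestimating
        sample_cfg = dataclasses.replace(
            base, n_active_risk=ext.active_risk_snps_in_sample
        )
    return sample_cfg, external_cfg


def simulate_external_study(
    ext: ExternalStudyConfig, base: ScenarioConfig, seed=None
) -> tuple[WeightVector, SimulatedStudy]:
    """Simulate the external dataset and estimate external GRS weights.

    The external data are drawn from ``base`` (scaled to
    ``size_factor * n`` rows); weights are the per-SNP marginal effect
    estimates in that dataset, provenance "external".
    """
    _, external_cfg = sample_config_for_external_mode(ext, base)
    study = simulate_study(external_cfg, seed=ext.seed if seed is None else seed)
    est = marginal_effect_estimates(study.genotypes, study.phenotype, base.family)
    return (
        WeightVector(
            weights=est, snp_ids=list(study.genotypes.snp_ids),
            provenance="external",
            scale_note="log-OR" if base.family == "binomial" else "linear-coefficient",
        ),
        study,
    )
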