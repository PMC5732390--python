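"""Replicated evaluation of power, type I error and sign-misspecification.

Each replicate simulates a fresh study, builds GRS weights under a
chosen regime, runs the GRS-by-exposure Wald test and classifies the
outcome at the two-sided 0.05 level:

* true positive — significant with the sign of the fitted interaction
  coefficient matching the generating interaction sign;
* sign-misspecified — significant with the wrong sign;
* non-significant — everything else, including replicates whose
  penalized fit shrank every weight to zero (degenerate GRS; these are
  never dropped silently and are tallied separately).

Power is the true-positive proportion, sign-misspecification the
wrong-sign significant proportion, and under the null scenario the type
I error is the significant proportion regardless of sign.  By
construction power + sign_misspec = significant_fraction in non-null
scenarios.  Replicates are seeded by a counter-based derivation from the
master seed, so each is individually reproducible and sweeps over
ratios, methods or MAFs share identical data streams (common random
numbers).

The interaction-training regime scores and tests exclusively on the
test half of its split; marginal-internal and external regimes use the
full sample.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, WeightVector, compute_grs, recode_genotypes
from .gxe import DegenerateGRSError, RankDeficientError, test_grs_by_e
from .simulation import (
    ExternalStudyConfig,
    ScenarioConfig,
    sample_config_for_external_mode,
    simulate_external_study,
    simulate_study,
)
from .weighting import weights_interaction_training, weights_marginal_internal

ALPHA_LEVEL = 0.05  # two-sided significance threshold of the power definition


@dataclass
class MethodConfig:
    """A weighting pipeline: regime plus its tuning knobs."""

    method: str  # external | marginal-internal | interaction-training
    ratio: tuple[int, int] = (1, 1)
    alpha: float = 0.5
    cv_folds: int = 10
    coding: str = "dominant"
    external: ExternalStudyConfig | None = None
    n_lambdas: int = 100

    def __post_init__(self) -> None:
        if self.method not in ("external", "marginal-internal", "interaction-training"):
            raise ValueError(f"unknown method {self.method!r}")
        self.ratio = tuple(int(r) for r in self.ratio)

    @property
    def label(self) -> str:
        if self.method == "interaction-training":
            return f"interaction-training ({self.ratio[0]}:{self.ratio[1]})"
        if self.method == "external":
            ext = self.external or ExternalStudyConfig()
            return f"external ({ext.mode}, 1:{ext.size_factor})"
        return self.method


@dataclass
class EvaluationSummary:
    """Aggregate classification proportions over R replications."""

    method: str
    scenario: str
    replications: int
    power: float
    type1_error: float | None
    sign_misspec: float
    significant_fraction: float
    n_degenerate: int
    n_nonconverged: int
    config_hash: str
    seed: int
    ratio: str = ""
    maf_fixed: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def mc_standard_error(p: float, R: int) -> float:
    """Binomial Monte-Carlo standard error sqrt(p(1-p)/R) of a proportion
    estimated from R replications (e.g. p=0.9, R=100 -> 0.03, i.e. the
    familiar ~3-percentage-point sampling error at 100 replications)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if R < 1:
        raise ValueError("R must be >= 1")
    return float(np.sqrt(p * (1.0 - p) / R))


def _config_hash(scenario_cfg, method_cfg, R) -> str:
    payload = json.dumps(
        [dataclasses.asdict(scenario_cfg), dataclasses.asdict(method_cfg), R],
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _replicate_seeds(master_seed: int, r: int):
    """Three independent child seeds (data, pipeline, external) for
    replicate r, derived counter-style so replicate streams are
    independent, individually reproducible and shared across methods."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, r])
    data_ss, pipe_ss, ext_ss = ss.spawn(3)
    pipe_seed = int(pipe_ss.generate_state(1)[0] % (2**31))
    ext_seed = int(ext_ss.generate_state(1)[0] % (2**31))
    return data_ss, pipe_seed, ext_ss, ext_seed


def run_single_replicate(
    scenario_cfg: ScenarioConfig, method_cfg: MethodConfig, master_seed: int, r: int
) -> dict:
    """One simulate -> weight -> score -> test pass; returns the
    classification record for replicate ``r``."""
    m = method_cfg
    data_ss, pipe_seed, ext_ss, _ = _replicate_seeds(master_seed, r)

    if m.method == "external":
        ext = m.external or ExternalStudyConfig()
        sample_cfg, _ = sample_config_for_external_mode(ext, scenario_cfg)
        study = simulate_study(sample_cfg, seed=data_ss)
        w, _ = simulate_external_study(ext, scenario_cfg, seed=ext_ss)
    else:
        study = simulate_study(scenario_cfg, seed=data_ss)

    G = recode_genotypes(study.genotypes, m.coding)
    E, y = study.exposure, study.phenotype
    truth_sign = study.truth["truth_sign"]
    fit_kw = dict(family=scenario_cfg.family, n_lambdas=m.n_lambdas)

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # degenerate-weight warnings are tallied
        if m.method == "interaction-training":
            w, split = weights_interaction_training(
                G, E, y, m.ratio, m.alpha, m.cv_folds, seed=pipe_seed, **fit_kw
            )
            idx = split.test_indices
        elif m.method == "marginal-internal":
            w = weights_marginal_internal(
                G, y, m.alpha, m.cv_folds, seed=pipe_seed, **fit_kw
            )
            idx = np.arange(G.n)
        else:
            idx = np.arange(G.n)

    if isinstance(w, WeightVector) and w.degenerate:
        return {"outcome": "degenerate", "p": None, "sign": "0"}
    grs = compute_grs(G.subset_samples(idx), w)
    try:
        res = test_grs_by_e(grs, E[idx], y[idx], family=scenario_cfg.family)
    except (DegenerateGRSError, RankDeficientError):
        # constant or near-constant score: no interaction estimable
        return {"outcome": "degenerate", "p": None, "sign": "0"}
    if not res.converged:
        return {"outcome": "nonconverged", "p": None, "sign": "0"}
    sig = res.p_value < ALPHA_LEVEL
    if not sig:
        outcome = "ns"
    elif truth_sign == 0:
        outcome = "fp"  # false positive under the null
    elif (res.sign == "+") == (truth_sign > 0):
        outcome = "tp"
    else:
        outcome = "sm"
    return {"outcome": outcome, "p": res.p_value, "sign": res.sign}


def run_replications(
    scenario_cfg: ScenarioConfig,
    method_cfg: MethodConfig,
    R: int,
    seed: int = 0,
) -> EvaluationSummary:
    """Aggregate R replicate classifications into an EvaluationSummary."""
    if R < 1:
        raise ValueError("R must be >= 1")
    counts = {"tp": 0, "sm": 0, "fp": 0, "ns": 0, "degenerate": 0, "nonconverged": 0}
    for r in range(R):
        rec = run_single_replicate(scenario_cfg, method_cfg, seed, r)
        counts[rec["outcome"]] += 1
    null = scenario_cfg.scenario == "null"
    sig = counts["fp"] if null else counts["tp"] + counts["sm"]
    return EvaluationSummary(
        method=method_cfg.label,
        scenario=scenario_cfg.scenario,
        replications=R,
        power=0.0 if null else counts["tp"] / R,
        type1_error=(counts["fp"] / R) if null else None,
        sign_misspec=0.0 if null else counts["sm"] / R,
        significant_fraction=sig / R,
        n_degenerate=counts["degenerate"],
        n_nonconverged=counts["nonconverged"],
        config_hash=_config_hash(scenario_cfg, method_cfg, R),
        seed=int(seed),
        ratio=f"{method_cfg.ratio[0]}:{method_cfg.ratio[1]}"
        if method_cfg.method == "interaction-training"
        else "",
        maf_fixed=scenario_cfg.maf_fixed,
    )


def sweep_balance(
    ratios,
    scenario_cfg: ScenarioConfig,
    R: int,
    seed: int = 0,
    *,
    method_cfg: MethodConfig | None = None,
) -> list[EvaluationSummary]:
    """Interaction-training power/type-I across train:test balances.

    All ratios share the same master seed, hence identical simulated
    data streams per replicate (common random numbers), sharpening the
    between-ratio comparison.
    """
    if not ratios:
        raise ValueError("ratios must be nonempty")
    base = method_cfg or MethodConfig(method="interaction-training")
    out = []
    for ratio in ratios:
        m = dataclasses.replace(base, method="interaction-training", ratio=tuple(ratio))
        out.append(run_replications(scenario_cfg, m, R, seed))
    return out


def sweep_maf(
    maf_values,
    scenario_cfg: ScenarioConfig,
    methods,
    R: int,
    seed: int = 0,
) -> list[EvaluationSummary]:
    """Fix all risk-SNP MAFs to each value in turn (noise-SNP MAFs stay
    random) and evaluate every method under common random numbers."""
    out = []
    for maf in maf_values:
        cfg = dataclasses.replace(scenario_cfg, maf_fixed=float(maf))
        for m in methods:
            out.append(run_replications(cfg, m, R, seed))
    return out


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Long-format table, one row per EvaluationSummary."""
    return pd.DataFrame([s.to_dict() for s in summaries])
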