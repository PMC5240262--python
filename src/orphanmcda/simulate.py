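"""Synthetic drug cohorts with a planted score-cost relationship.

Real per-drug MCDA inputs (criterion scores and list-price annual costs)
are scattered across SPCs, formularies and figures, so the pipeline is
exercised on synthetic cohorts that reproduce the statistical structure the
analysis assumes:

* each drug's nine criterion scores are drawn independently from a
  categorical distribution over {1, 2, 3} (optionally tilted by a shared
  per-drug latent severity factor to induce criterion correlation);
* the annual cost is log-linear in the aggregate score with Gaussian noise,

      cost_j = exp(alpha + beta * S_j + eps_j),   eps_j ~ N(0, sigma^2),

  which keeps costs positive and lets them span the orders of magnitude
  orphan-drug prices do.

The population R^2 of log-cost on the aggregate score S is
``beta^2 Var(S) / (beta^2 Var(S) + sigma^2)``; :func:`calibrate_noise`
inverts this so a cohort can be generated at any target R^2 (the default
configuration targets 0.79). All randomness flows through one
``numpy.random.default_rng`` seeded per cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .framework import default_framework
from .scoring import DrugProfile, WeightScenario, aggregate_score

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "calibrate_noise",
    "theoretical_score_sd",
    "default_config",
]

#: The paper-scale cohort: six drugs, as in prototype orphan-drug MCDA
#: evaluations.
DEFAULT_N_DRUGS = 6
#: Default target for the population R^2 of log-cost on score.
DEFAULT_TARGET_R2 = 0.79
#: Log-scale intercept/slope placing annual costs in the tens-of-thousands
#: to hundreds-of-thousands of euros across the raw-sum score range [9, 27].
DEFAULT_ALPHA = 8.5
DEFAULT_BETA = 0.12

_UNIFORM = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic cohort.

    ``score_probs`` maps criterion id -> probability vector over scores
    (1, 2, 3); criteria not listed use the uniform distribution.
    ``score_scale_for_cost`` selects which aggregate drives the cost model:
    the raw sum (range [9, 27]) or the weighted score (range [1, 3]) under
    ``scenario``. ``latent_weight`` in [0, 1) mixes a shared per-drug
    uniform latent into every criterion draw (0 = independent criteria).
    """

    n_drugs: int = DEFAULT_N_DRUGS
    score_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    cost_intercept: float = DEFAULT_ALPHA
    cost_slope: float = DEFAULT_BETA
    noise_sd: float = 0.0
    score_scale_for_cost: str = "raw_sum"  # or "weighted"
    scenario: WeightScenario | None = None
    latent_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1:
            raise InputError(f"n_drugs must be >= 1, got {self.n_drugs}")
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.score_scale_for_cost not in ("raw_sum", "weighted"):
            raise InputError(
                f"score_scale_for_cost must be 'raw_sum' or 'weighted', got {self.score_scale_for_cost!r}"
            )
        if not 0.0 <= self.latent_weight < 1.0:
            raise InputError(f"latent_weight must be in [0, 1), got {self.latent_weight}")
        for cid, probs in self.score_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise InputError(
                    f"score_probs[{cid!r}] must be 3 non-negative probabilities summing to 1, got {probs!r}"
                )

    def probs_for(self, criterion_id: str) -> tuple[float, float, float]:
        return self.score_probs.get(criterion_id, _UNIFORM)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated drug profiles plus the config that produced them."""

    profiles: tuple[DrugProfile, ...]
    provenance: SyntheticConfig

    @property
    def aggregate_scores(self) -> np.ndarray:
        """The aggregate S_j on the configured cost scale, recomputed."""
        return np.array([_aggregate(p, self.provenance) for p in self.profiles])

    @property
    def costs(self) -> np.ndarray:
        return np.array([p.annual_cost for p in self.profiles])


def _aggregate(profile: DrugProfile, config: SyntheticConfig) -> float:
    if config.score_scale_for_cost == "raw_sum":
        return float(sum(profile.scores.values()))
    scenario = config.scenario
    if scenario is None:
        from .scoring import builtin_scenarios

        scenario = builtin_scenarios()[0]
    return aggregate_score(profile, scenario).weighted_score


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort of drug profiles with planted log-linear costs.

    Deterministic for a fixed config (including seed): the same config
    always yields an identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    ids = default_framework().criterion_ids
    n = config.n_drugs
    width = max(2, len(str(n)))

    # Per-criterion categorical draws via the inverse CDF of score_probs,
    # optionally mixed with a shared per-drug latent (Gaussian-copula-free
    # ordinal tilt): v = (1-lw)*u_ij + lw*u_j stays uniform-ish but induces
    # positive correlation across criteria within a drug.
    latent = rng.uniform(size=n)
    profiles = []
    score_draws = {cid: rng.uniform(size=n) for cid in ids}
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    for j in range(n):
        scores = {}
        for cid in ids:
            p1, p2, _ = config.probs_for(cid)
            v = (1.0 - config.latent_weight) * score_draws[cid][j] + config.latent_weight * latent[j]
            scores[cid] = 1 if v < p1 else (2 if v < p1 + p2 else 3)
        profile = DrugProfile(
            drug_id=f"SYN-{j + 1:0{width}d}",
            indication=f"synthetic indication {j + 1}",
            scores=scores,
        )
        s = _aggregate(profile, config)
        cost = math.exp(config.cost_intercept + config.cost_slope * s + noise[j])
        profiles.append(replace(profile, annual_cost=cost))
    return SyntheticCohort(profiles=tuple(profiles), provenance=config)


def calibrate_noise(target_r2: float, beta: float, score_sd: float) -> float:
    """Noise SD sigma achieving a population R^2 of log-cost on score.

    From R^2 = beta^2 sd^2 / (beta^2 sd^2 + sigma^2):

        sigma = |beta| * score_sd * sqrt(1/target_r2 - 1)

    ``target_r2`` must lie in (0, 1]; 1 gives sigma = 0 (noiseless).
    """
    if not 0.0 < target_r2 <= 1.0:
        raise InputError(f"target_r2 must be in (0, 1], got {target_r2!r}")
    if beta == 0:
        raise InputError("beta must be nonzero: with no score effect no noise level attains the target")
    if not score_sd > 0:
        raise InputError(f"score_sd must be > 0, got {score_sd!r}")
    return abs(beta) * score_sd * math.sqrt(1.0 / target_r2 - 1.0)


def theoretical_score_sd(config: SyntheticConfig) -> float:
    """Population SD of the aggregate score under independent criteria.

    Sums per-criterion variances (raw-sum scale) or weight-squared
    variances (weighted scale). Valid for ``latent_weight = 0``; a positive
    latent weight increases the true variance beyond this value.
    """
    ids = default_framework().criterion_ids
    if config.score_scale_for_cost == "weighted":
        scenario = config.scenario
        if scenario is None:
            from .scoring import builtin_scenarios

            scenario = builtin_scenarios()[0]
        weights = {cid: scenario.weights.get(cid, 0.0) for cid in ids}
    else:
        weights = {cid: 1.0 for cid in ids}
    var = 0.0
    for cid in ids:
        p = np.asarray(config.probs_for(cid))
        s = np.array([1.0, 2.0, 3.0])
        mu = float(p @ s)
        var += weights[cid] ** 2 * float(p @ (s - mu) ** 2)
    return math.sqrt(var)


def default_config(seed: int = 0, n_drugs: int = DEFAULT_N_DRUGS,
                   target_r2: float = DEFAULT_TARGET_R2) -> SyntheticConfig:
    """The study-condition configuration: uniform score distributions,
    raw-sum cost scale, and noise calibrated to the target R^2."""
    base = SyntheticConfig(n_drugs=n_drugs, seed=seed)
    sigma = calibrate_noise(target_r2, base.cost_slope, theoretical_score_sd(base))
    return replace(base, noise_sd=sigma)
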