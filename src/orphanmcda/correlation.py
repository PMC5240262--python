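"""Score-cost regression and cross-scenario rank comparison.

Two questions drive this module: does a drug's aggregate MCDA score track
its average annual cost per patient (simple OLS of cost — optionally
log10-transformed — on score, summarised by R^2), and how stable is the
drug ranking when criterion weights change (Kendall tau-b between the rank
vectors of two scenarios, plus an explicit list of rank changes)?

R^2 is reported for the simple two-variable regression only; no adjusted
R^2 and no inference, since with a handful of drugs the statistic is
descriptive. Kendall tau-b is used because competition ranking produces
ties, which tau-b corrects for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .scoring import Ranking

__all__ = ["RegressionResult", "RankComparison", "fit_score_cost", "compare_rankings"]


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS of (possibly log10) annual cost on aggregate score."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    y_scale: str  # "linear" or "log10"

    def predict(self, score: float) -> float:
        """Fitted cost at ``score``, back-transformed to the cost scale."""
        y = self.intercept + self.slope * score
        return 10.0**y if self.y_scale == "log10" else y


@dataclass(frozen=True)
class RankComparison:
    """Agreement between two scenario rankings of the same drugs."""

    scenario_a: str
    scenario_b: str
    kendall_tau: float
    rank_changes: tuple[tuple[str, int, int], ...]

    @property
    def identical(self) -> bool:
        return not self.rank_changes


def fit_score_cost(
    points: Sequence[tuple[float, float]], y_scale: str = "linear"
) -> RegressionResult:
    """Ordinary least squares of annual cost on aggregate score.

    ``points`` are (score, cost) pairs; with ``y_scale="log10"`` the cost is
    log10-transformed before fitting (all costs must then be positive).
    Requires at least three points and non-constant scores.
    """
    if y_scale not in ("linear", "log10"):
        raise InputError(f"y_scale must be 'linear' or 'log10', got {y_scale!r}")
    if len(points) < 3:
        raise InputError(f"regression requires at least 3 points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("scores and costs must be finite")
    if np.ptp(x) == 0:
        raise InputError("zero variance in scores: regression line is undefined")
    if y_scale == "log10":
        if np.any(y <= 0):
            raise InputError("log10 scale requires all costs to be positive")
        y = np.log10(y)
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    return RegressionResult(
        n=len(points),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r * r,
        pearson_r=r,
        y_scale=y_scale,
    )


def compare_rankings(a: Ranking, b: Ranking) -> RankComparison:
    """Kendall tau-b between two rankings of the same drug set.

    ``rank_changes`` lists every drug whose competition rank differs,
    as (drug_id, rank_in_a, rank_in_b). Tau is NaN when fewer than two
    drugs are ranked (no pairs to compare).
    """
    if a.drug_ids != b.drug_ids:
        raise InputError(
            f"rankings cover different drug sets: only in first {sorted(a.drug_ids - b.drug_ids)}, "
            f"only in second {sorted(b.drug_ids - a.drug_ids)}"
        )
    drugs = sorted(a.drug_ids)
    ranks_a = [a.rank_of(d) for d in drugs]
    ranks_b = [b.rank_of(d) for d in drugs]
    if len(drugs) < 2:
        tau = math.nan
    else:
        tau = float(stats.kendalltau(ranks_a, ranks_b, variant="b").statistic)
    changes = tuple(
        (d, ra, rb) for d, ra, rb in zip(drugs, ranks_a, ranks_b) if ra != rb
    )
    return RankComparison(
        scenario_a=a.scenario,
        scenario_b=b.scenario,
        kendall_tau=tau,
        rank_changes=changes,
    )
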