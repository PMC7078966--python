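"""Joint superiority probabilities and P-scores across several outcomes.

The probability that treatment ``i`` beats ``j`` on all of ``K`` outcomes
simultaneously is a multivariate-normal orthant probability: with
standardized contrasts ``b_k = (d_ij^k - civ_k) / s_ij^k`` and a
between-outcome correlation matrix ``rho``,

    P(i > j on all outcomes) = Phi_K(b_1, ..., b_K; rho).

Averaging these joint probabilities over competitors (equal weights) gives
the multi-outcome P-score.  Fixing a benefit margin on one outcome and
sweeping a harm tolerance on another traces benefit-risk curves showing how
the hierarchy re-orders with the trade-off a decision-maker accepts.

``rho`` must come from outside the model — multivariate NMA estimation,
expert opinion, or a sensitivity range — since outcome-specific NMA fits do
not identify it (:func:`correlation_strategy`).  The same ``rho`` applies
to every treatment pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal, norm

from .civ import CivCurveSet, CivSpec, _all_crossings
from .effects import CorrelationSpec, EffectsError, OutcomeEffects
from .ranking import PscoreResult

__all__ = [
    "JointEffects",
    "joint_pairwise_prob",
    "multi_pscores",
    "benefit_risk_curves",
    "correlation_strategy",
    "mvn_upper_cdf",
]

#: More outcomes than this would need a different integration strategy.
MAX_OUTCOMES = 6

#: Absolute tolerance for the multivariate-normal CDF quadrature.
_MVN_ABSEPS = 1e-6


@dataclass(frozen=True)
class JointEffects:
    """Several outcomes' NMA estimates over one common treatment set.

    All outcomes must share the same treatments (same order) and reference,
    be oriented, and their count must match the correlation matrix.
    """

    outcomes: tuple[OutcomeEffects, ...]
    correlation: CorrelationSpec

    def __post_init__(self) -> None:
        outcomes = tuple(self.outcomes)
        object.__setattr__(self, "outcomes", outcomes)
        if not 1 <= len(outcomes) <= MAX_OUTCOMES:
            raise EffectsError(
                f"need between 1 and {MAX_OUTCOMES} outcomes, got {len(outcomes)}"
            )
        base = outcomes[0]
        for oc in outcomes[1:]:
            if oc.treatments != base.treatments:
                extra = set(oc.treatments) ^ set(base.treatments)
                raise EffectsError(
                    f"outcome {oc.outcome_name!r} treatment set differs from "
                    f"{base.outcome_name!r}"
                    + (f" (mismatch: {sorted(extra)})" if extra else
                       " (same labels, different order)")
                )
            if oc.reference != base.reference:
                raise EffectsError("outcomes disagree on the reference treatment")
        names = tuple(oc.outcome_name for oc in outcomes)
        if len(set(names)) != len(names):
            raise EffectsError(f"duplicate outcome names: {names}")
        if self.correlation.outcome_names != names:
            raise EffectsError(
                f"correlation outcomes {self.correlation.outcome_names} do not "
                f"match joint outcomes {names}"
            )

    @property
    def k(self) -> int:
        return len(self.outcomes)

    @property
    def treatments(self) -> tuple[str, ...]:
        return self.outcomes[0].treatments

    def outcome(self, name: str) -> OutcomeEffects:
        for oc in self.outcomes:
            if oc.outcome_name == name:
                return oc
        raise EffectsError(f"unknown outcome {name!r}")

    def subset(self, names) -> "JointEffects":
        """Restrict to the named outcomes (in the given order)."""
        return JointEffects(
            outcomes=tuple(self.outcome(n) for n in names),
            correlation=self.correlation.submatrix(tuple(names)),
        )


def mvn_upper_cdf(upper: np.ndarray, rho: np.ndarray) -> float:
    """P(Z_k < upper_k for all k) for Z ~ N(0, rho).

    K = 1 uses the univariate CDF; K = 2 uses scipy's deterministic
    bivariate algorithm (singular rho = +/-1 handled exactly); K >= 3 uses
    numerical integration with absolute tolerance 1e-6 and a fixed
    integration rng so repeated calls agree.
    """
    upper = np.asarray(upper, dtype=float)
    k = upper.size
    if k == 1:
        return float(norm.cdf(upper[0]))
    val = multivariate_normal.cdf(
        upper,
        mean=np.zeros(k),
        cov=rho,
        allow_singular=True,
        abseps=_MVN_ABSEPS,
        rng=np.random.default_rng(0),
    )
    return float(min(1.0, max(0.0, val)))


def joint_pairwise_prob(
    je: JointEffects, i: str, j: str, civs=None
) -> float:
    """Certainty that ``i`` beats ``j`` by the per-outcome margins on all outcomes.

    ``civs`` is a length-K vector of clinically important values on the
    oriented scales (defaults to all zero).  K = 1 reduces exactly to the
    single-outcome pairwise probability.
    """
    civs = np.zeros(je.k) if civs is None else np.asarray(civs, dtype=float)
    if civs.shape != (je.k,):
        raise EffectsError(f"civs must have length {je.k}, got {civs.shape}")
    ii = je.outcomes[0].index(i)
    jj = je.outcomes[0].index(j)
    if ii == jj:
        raise EffectsError("joint probability needs two distinct treatments")
    upper = np.empty(je.k)
    for k_idx, oc in enumerate(je.outcomes):
        if not oc.oriented:
            raise EffectsError(
                f"outcome {oc.outcome_name!r} must be oriented"
            )
        d = oc.mu[ii] - oc.mu[jj]
        s = oc.pairwise_se()[ii, jj]
        if s <= 0.0:
            raise EffectsError(
                f"non-positive pairwise SE for ({i}, {j}) on "
                f"{oc.outcome_name!r}"
            )
        upper[k_idx] = (d - civs[k_idx]) / s
    return mvn_upper_cdf(upper, je.correlation.rho)


def multi_pscores(je: JointEffects, civs=None) -> PscoreResult:
    """Multi-outcome P-scores: mean joint superiority over all competitors.

    ``score_i = (1/(I-1)) * sum_{j != i} Phi_K(...)``.  Joint probabilities
    are bounded by each marginal, so scores shrink as outcomes are added;
    the CIV = 0, K = 1 case recovers the plain P-score.
    """
    treatments = je.treatments
    if len(treatments) < 2:
        raise EffectsError("P-scores need at least two treatments")
    civs = np.zeros(je.k) if civs is None else np.asarray(civs, dtype=float)
    scores = np.zeros(len(treatments))
    for a, ta in enumerate(treatments):
        total = 0.0
        for b, tb in enumerate(treatments):
            if a == b:
                continue
            total += joint_pairwise_prob(je, ta, tb, civs)
        scores[a] = total / (len(treatments) - 1)
    return PscoreResult(
        treatments=treatments,
        scores=scores,
        civ=tuple(float(c) for c in civs),
        outcome_context=tuple(oc.outcome_name for oc in je.outcomes),
        method="analytic",
    )


def benefit_risk_curves(
    je: JointEffects,
    benefit_outcome: str,
    risk_outcome: str,
    benefit_civ: float,
    risk_grid: CivSpec,
) -> CivCurveSet:
    """Joint P-score curves over a grid of harm tolerances at a fixed benefit.

    For each tolerance ``g`` in the grid the scores are the two-outcome
    joint P-scores with CIVs ``(benefit_civ, g)`` on the oriented scales
    (negative ``g`` tolerates a deficit on the risk outcome).  Crossings of
    the resulting curves mark the tolerances at which the benefit-risk
    hierarchy re-orders.
    """
    if benefit_outcome == risk_outcome:
        raise EffectsError("benefit and risk outcomes must differ")
    sub = je.subset((benefit_outcome, risk_outcome))
    grid = risk_grid.grid
    treatments = sub.treatments
    scores = np.empty((len(treatments), grid.size))
    for g, tol in enumerate(grid):
        scores[:, g] = multi_pscores(
            sub, civs=(float(benefit_civ), float(tol))
        ).scores
    return CivCurveSet(
        treatments=treatments,
        grid=grid,
        scores=scores,
        mean_curve=scores.mean(axis=0),
        crossings=_all_crossings(treatments, grid, scores),
        benefit_civ=float(benefit_civ),
        outcome_context=(benefit_outcome, risk_outcome),
    )


def correlation_strategy(mode: str, **kwargs):
    """Build between-outcome correlation specs for the supported strategies.

    ``mode="zero"``
        Analyze outcomes as uncorrelated: identity matrix.  Requires
        ``outcome_names``.
    ``mode="fixed"``
        A user-supplied (e.g. expert-informed) matrix, validated PSD.
        Requires ``outcome_names`` and ``matrix``.
    ``mode="range"``
        Sensitivity analysis over a grid of a single off-diagonal value
        (two outcomes only).  Requires ``outcome_names``, ``lo``, ``hi``,
        ``step``; returns a list of specs.
    """
    if mode == "zero":
        names = tuple(kwargs["outcome_names"])
        return CorrelationSpec(names, np.eye(len(names)))
    if mode == "fixed":
        names = tuple(kwargs["outcome_names"])
        return CorrelationSpec(names, np.asarray(kwargs["matrix"], dtype=float))
    if mode == "range":
        names = tuple(kwargs["outcome_names"])
        if len(names) != 2:
            raise EffectsError("range mode supports exactly two outcomes")
        lo, hi = float(kwargs["lo"]), float(kwargs["hi"])
        step = float(kwargs["step"])
        if not (-1.0 < lo <= hi < 1.0):
            raise EffectsError("range endpoints must lie inside (-1, 1)")
        if step <= 0.0:
            raise EffectsError("range step must be positive")
        n = int(round((hi - lo) / step)) + 1
        specs = []
        for r in lo + step * np.arange(n):
            rho = np.array([[1.0, r], [r, 1.0]])
            specs.append(CorrelationSpec(names, rho))
        return specs
    raise EffectsError(f"unknown correlation strategy {mode!r}")
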