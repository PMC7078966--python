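"""Single-outcome ranking metrics: pairwise superiority probabilities,
analytic P-scores, simulated rank distributions, SUCRA, mean rank, Pbest.

Everything here operates on the internal oriented scale (larger is better);
see :func:`civrank.effects.orient`.  With the relative effects assumed
normal, the certainty that treatment ``i`` beats ``j`` by at least ``civ``
is ``Phi((d_ij - civ) / s_ij)``, and the P-score of ``i`` averages this
over its competitors with equal weights.  SUCRA is the simulation-based
equivalent: the surface under the cumulative ranking curve of the rank
distribution, identical to the P-score when the true probabilities are
known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effects import EffectsError, OutcomeEffects

__all__ = [
    "RankDistribution",
    "PscoreResult",
    "pairwise_prob",
    "pscores",
    "simulate_ranks",
    "sucra",
    "mean_rank",
    "pbest",
]


@dataclass(frozen=True)
class RankDistribution:
    """Rank probabilities ``P[i, r-1]`` that treatment ``i`` takes rank ``r``.

    Rank 1 is best.  The matrix is doubly stochastic: each treatment has
    exactly one rank per draw and each rank is taken by exactly one
    treatment, so rows and columns both sum to one.
    """

    treatments: tuple[str, ...]
    P: np.ndarray
    n_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        P = np.asarray(self.P, dtype=float)
        i = len(self.treatments)
        if P.shape != (i, i):
            raise EffectsError(f"rank matrix shape {P.shape}, expected {(i, i)}")
        if np.any(P < -1e-12) or np.any(P > 1.0 + 1e-12):
            raise EffectsError("rank probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise EffectsError("rank-probability rows must sum to 1")
        if not np.allclose(P.sum(axis=0), 1.0, atol=1e-9):
            raise EffectsError("rank-probability columns must sum to 1")
        object.__setattr__(self, "P", P)

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def cumulative(self) -> np.ndarray:
        """Cumulative rank distribution ``F[i, r-1] = P(rank_i <= r)``."""
        return np.cumsum(self.P, axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format rankogram: columns treatment, rank, probability."""
        i = self.n_treatments
        return pd.DataFrame(
            {
                "treatment": np.repeat(self.treatments, i),
                "rank": np.tile(np.arange(1, i + 1), i),
                "probability": self.P.ravel(),
            }
        )


@dataclass(frozen=True)
class PscoreResult:
    """Per-treatment ranking scores with the context that produced them."""

    treatments: tuple[str, ...]
    scores: np.ndarray
    civ: tuple[float, ...]
    outcome_context: tuple[str, ...]
    method: str = "analytic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(self, "outcome_context", tuple(self.outcome_context))
        civ = self.civ if isinstance(self.civ, tuple) else (float(self.civ),)
        object.__setattr__(self, "civ", tuple(float(c) for c in civ))
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.treatments),):
            raise EffectsError("scores length must match treatments")
        if np.any(scores < -1e-12) or np.any(scores > 1.0 + 1e-12):
            raise EffectsError("P-scores must lie in [0, 1]")
        object.__setattr__(self, "scores", np.clip(scores, 0.0, 1.0))
        if self.method not in ("analytic", "simulated"):
            raise EffectsError(f"unknown method {self.method!r}")

    def ranks(self) -> np.ndarray:
        """Integer ranks 1..I by descending score; ties broken alphabetically."""
        order = sorted(
            range(len(self.treatments)),
            key=lambda i: (-self.scores[i], self.treatments[i]),
        )
        ranks = np.empty(len(order), dtype=int)
        for pos, i in enumerate(order, start=1):
            ranks[i] = pos
        return ranks

    def to_frame(self) -> pd.DataFrame:
        """Table with treatment, pscore, percent, rank and a tie flag."""
        scores = self.scores
        tied = np.array(
            [
                np.any(np.isclose(np.delete(scores, i), scores[i], atol=1e-12))
                for i in range(len(scores))
            ]
        )
        return pd.DataFrame(
            {
                "treatment": self.treatments,
                "pscore": scores,
                "percent": 100.0 * scores,
                "rank": self.ranks(),
                "tied": tied,
            }
        )


def pairwise_prob(d_ij, s_ij, civ=0.0):
    """Certainty that one treatment beats another by at least ``civ``.

    ``Phi((d_ij - civ) / s_ij)`` for the oriented pairwise contrast ``d_ij``
    with standard error ``s_ij``.  ``civ = 0`` recovers the plain
    superiority probability; a negative ``civ`` tolerates a deficit of that
    size.  Vectorised over array inputs.
    """
    d = np.asarray(d_ij, dtype=float)
    s = np.asarray(s_ij, dtype=float)
    if np.any(s <= 0.0):
        raise EffectsError("pairwise standard error must be positive")
    out = norm.cdf((d - np.asarray(civ, dtype=float)) / s)
    return float(out) if out.ndim == 0 else out


def pscores(effects: OutcomeEffects, civ: float = 0.0) -> PscoreResult:
    """Analytic P-scores: mean certainty of beating each competitor by ``civ``.

    ``score_i = (1/(I-1)) * sum_{j != i} Phi((d_ij - civ) / s_ij)``.
    At ``civ = 0`` the scores average to exactly 0.5 across treatments,
    because each pairwise term and its mirror sum to one.
    """
    if not effects.oriented:
        raise EffectsError("effects must be oriented before scoring")
    i_count = effects.n_treatments
    if i_count < 2:
        raise EffectsError("P-scores need at least two treatments")
    d = effects.pairwise_diff()
    s = effects.pairwise_se()
    off = ~np.eye(i_count, dtype=bool)
    if np.any(s[off] <= 0.0):
        raise EffectsError("all pairwise standard errors must be positive")
    probs = np.zeros((i_count, i_count))
    probs[off] = norm.cdf((d[off] - float(civ)) / s[off])
    scores = probs.sum(axis=1) / (i_count - 1)
    return PscoreResult(
        treatments=effects.treatments,
        scores=scores,
        civ=(float(civ),),
        outcome_context=(effects.outcome_name,),
        method="analytic",
    )


def _sample_mvn(mu: np.ndarray, sigma: np.ndarray, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Draw from N(mu, sigma) allowing a singular covariance.

    The reference row/column of an NMA covariance is exactly zero, so the
    factorisation goes through the eigendecomposition with negative rounding
    noise clipped.
    """
    w, v = np.linalg.eigh(sigma)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    z = rng.standard_normal((n, len(mu)))
    return mu + z @ factor.T


def simulate_ranks(
    effects: OutcomeEffects, n_samples: int = 100_000, seed: int | None = None
) -> RankDistribution:
    """Estimate the rank distribution by resampling the summary estimates.

    Draws ``n_samples`` effect vectors from ``N(mu, sigma)``, ranks each
    draw best-first on the oriented scale and tallies rank frequencies.
    Exact ties (possible only under a degenerate covariance) are broken by
    an independent uniform key, i.e. uniformly at random within the tied
    set, which keeps the tallied matrix doubly stochastic in expectation.
    Deterministic for a given ``seed``.
    """
    if not effects.oriented:
        raise EffectsError("effects must be oriented before simulation")
    if effects.sigma is None:
        raise EffectsError(
            "rank simulation needs the full covariance; reconstruct it with "
            "covariance_from_league first"
        )
    if n_samples < 1:
        raise EffectsError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    i_count = effects.n_treatments
    draws = _sample_mvn(effects.mu, effects.sigma, n_samples, rng)
    tiebreak = rng.random((n_samples, i_count))
    # best-first ordering per draw; uniform keys decide exact ties
    order = np.lexsort((tiebreak, -draws), axis=-1)
    counts = np.zeros((i_count, i_count))
    rank_pos = np.tile(np.arange(i_count), n_samples)
    np.add.at(counts, (order.ravel(), rank_pos), 1.0)
    return RankDistribution(
        treatments=effects.treatments,
        P=counts / n_samples,
        n_samples=n_samples,
        seed=seed,
    )


def sucra(rd: RankDistribution) -> np.ndarray:
    """Surface under the cumulative ranking curve for each treatment.

    ``SUCRA_i = (1/(I-1)) * sum_{r=1..I-1} F(i, r)`` — the proportion of
    competitors a treatment beats on average.  1 means always best, 0 always
    worst.  The result satisfies the mean-rank identity
    ``SUCRA_i = (I - E[rank_i]) / (I - 1)`` to floating-point accuracy.
    """
    i_count = rd.n_treatments
    if i_count < 2:
        raise EffectsError("SUCRA needs at least two treatments")
    f = rd.cumulative()
    values = f[:, : i_count - 1].sum(axis=1) / (i_count - 1)
    # internal consistency with the mean-rank form of the same quantity
    identity = (i_count - mean_rank(rd)) / (i_count - 1)
    assert np.allclose(values, identity, atol=1e-12)
    return values


def mean_rank(rd: RankDistribution) -> np.ndarray:
    """Expected rank ``E[rank_i]`` of each treatment (1 = best)."""
    ranks = np.arange(1, rd.n_treatments + 1)
    return rd.P @ ranks


def pbest(rd: RankDistribution) -> np.ndarray:
    """Probability of each treatment taking the top rank."""
    return rd.P[:, 0].copy()
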