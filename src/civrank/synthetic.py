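"""Synthetic NMA summary estimates with known ground truth, plus Monte-Carlo
oracles and a compact report table.

No public deposit of the motivating antipsychotics network's summary
estimates exists, so testing and examples run on generated networks that
mimic the shape of NMA output: a vector of relative effects versus a
reference with a positive semi-definite covariance, for one to several
correlated outcomes.  Effect sizes default to the dynamic range typical of
drug-class networks on the SMD scale (spread 0.6, pairwise SEs 0.05-0.3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .effects import CorrelationSpec, EffectsError, OutcomeEffects, orient, to_smd
from .multi import JointEffects, multi_pscores
from .ranking import pscores

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "mc_joint_prob_oracle",
    "table1_style_report",
    "load_example_network",
]

# Fraction of each basic-parameter variance carried by a shared factor; it
# induces the positive covariance between contrasts that a connected
# network's common comparator creates, while keeping sigma PSD by
# construction (diagonal plus rank-one).
_COMMON_FACTOR = 0.3


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated network, reproducible from its seed."""

    treatments: tuple[str, ...]
    true_mu: tuple[np.ndarray, ...]
    sigma: tuple[np.ndarray, ...]
    rho: CorrelationSpec
    seed: int


def generate_network(
    I: int,
    K: int = 1,
    effect_spread: float = 0.6,
    precision_range: tuple[float, float] = (0.05, 0.3),
    rho: CorrelationSpec | None = None,
    seed: int = 0,
) -> tuple[JointEffects, SyntheticTruth]:
    """Generate a synthetic network of NMA summary estimates.

    True relative effects are drawn uniformly in ``[-spread, spread]``
    (reference pinned at 0).  Each outcome's covariance is built from a
    star geometry — independent per-treatment standard errors drawn from
    ``precision_range`` — plus a shared rank-one component, giving a
    positive semi-definite matrix resembling the correlation structure a
    common comparator induces.  Outcomes are emitted already oriented
    (larger is better, SMD scale).  Deterministic for a given seed.
    """
    if I < 2:
        raise EffectsError("need at least two treatments")
    if K < 1:
        raise EffectsError("need at least one outcome")
    lo, hi = precision_range
    if not (0.0 < lo <= hi):
        raise EffectsError("precision_range must satisfy 0 < lo <= hi")
    if effect_spread <= 0.0:
        raise EffectsError("effect_spread must be positive")
    rng = np.random.default_rng(seed)
    treatments = tuple(f"T{i + 1:02d}" for i in range(I))
    names = tuple(f"outcome_{k + 1}" for k in range(K))
    if rho is None:
        rho = CorrelationSpec(names, np.eye(K))
    elif rho.k != K:
        raise EffectsError(f"rho is {rho.k}x{rho.k} but K={K}")
    else:
        rho = CorrelationSpec(names, rho.rho)
    outcomes = []
    true_mu = []
    sigmas = []
    for name in names:
        mu = rng.uniform(-effect_spread, effect_spread, size=I)
        mu[0] = 0.0
        s = rng.uniform(lo, hi, size=I)
        s[0] = 0.0
        sigma = _COMMON_FACTOR * np.outer(s, s)
        np.fill_diagonal(sigma, s * s)
        outcomes.append(
            OutcomeEffects(
                outcome_name=name,
                treatments=treatments,
                reference=treatments[0],
                mu=mu,
                sigma=sigma,
                measure="SMD",
                direction="higher_better",
                oriented=True,
            )
        )
        true_mu.append(mu.copy())
        sigmas.append(sigma.copy())
    je = JointEffects(outcomes=tuple(outcomes), correlation=rho)
    truth = SyntheticTruth(
        treatments=treatments,
        true_mu=tuple(true_mu),
        sigma=tuple(sigmas),
        rho=rho,
        seed=seed,
    )
    return je, truth


def mc_joint_prob_oracle(
    d, s, civs, rho, n: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Brute-force estimate of the joint superiority probability.

    Samples ``n`` contrast vectors ``X_k = d_k + s_k Z_k`` with
    ``Z ~ N(0, rho)`` and counts the fraction satisfying all K shifted
    inequalities ``X_k - civ_k > 0``.  Returns the fraction and an
    Agresti-Coull binomial standard error (which stays positive even at
    empirical 0 or 1, so "within 3 standard errors" remains a meaningful
    comparison in the tails).
    """
    if n < 1000:
        raise EffectsError("oracle needs at least 1000 samples")
    d = np.atleast_1d(np.asarray(d, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    civs = np.atleast_1d(np.asarray(civs, dtype=float))
    rho = np.asarray(rho, dtype=float)
    k = d.size
    if s.size != k or civs.size != k or rho.shape != (k, k):
        raise EffectsError("d, s, civs and rho dimensions disagree")
    if np.any(s <= 0.0):
        raise EffectsError("standard errors must be positive")
    w, v = np.linalg.eigh(0.5 * (rho + rho.T))
    if w[0] < -1e-8 * max(w[-1], 1e-300):
        raise EffectsError(f"rho is not PSD (smallest eigenvalue {w[0]:.3g})")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k)) @ factor.T
    x = d + s * z
    hits = int(np.all(x - civs > 0.0, axis=1).sum())
    p = hits / n
    p_ac = (hits + 2.0) / (n + 4.0)
    se = float(np.sqrt(p_ac * (1.0 - p_ac) / n))
    return p, se


def table1_style_report(je: JointEffects, civs=None) -> pd.DataFrame:
    """Side-by-side P-scores (as %) and ranks per outcome, plus joint columns.

    One row per treatment; for each outcome a percentage column (rounded to
    integers, mirroring how such tables are usually printed) and a rank
    column; when K > 1, trailing columns hold the joint P-score over all
    outcomes together.  ``civs`` (oriented scale, default all zero) applies
    to both the per-outcome and the joint scores.
    """
    civs = np.zeros(je.k) if civs is None else np.asarray(civs, dtype=float)
    data: dict[str, object] = {"treatment": list(je.treatments)}
    for k_idx, oc in enumerate(je.outcomes):
        res = pscores(oc, civ=float(civs[k_idx]))
        data[f"{oc.outcome_name} P-score (%)"] = np.round(
            100.0 * res.scores
        ).astype(int)
        data[f"{oc.outcome_name} rank"] = res.ranks()
    if je.k > 1:
        joint = multi_pscores(je, civs=civs)
        data["joint P-score (%)"] = np.round(100.0 * joint.scores).astype(int)
        data["joint rank"] = joint.ranks()
    return pd.DataFrame(data)


def load_example_network(oriented: bool = True):
    """Load the packaged synthetic 16-treatment, 3-outcome example network.

    The fixture (``data/antipsychotics_like.json``) is a seed-generated,
    clearly synthetic stand-in shaped like a published antipsychotics
    network: 15 active treatments plus placebo; a higher-better efficacy
    outcome (SMD), a lower-better discontinuation outcome (log-OR) and a
    lower-better weight-gain outcome (SMD), with an illustrative
    between-outcome correlation matrix.

    With ``oriented=True`` (default) the log-OR outcome is rescaled to SMD
    and every outcome is oriented larger-is-better, returning a
    :class:`JointEffects` ready for scoring.  With ``oriented=False`` the
    raw published-scale outcomes and the correlation spec are returned as a
    tuple ``(outcomes, correlation)``.
    """
    raw = json.loads(
        resources.files("civrank")
        .joinpath("data/antipsychotics_like.json")
        .read_text()
    )
    treatments = tuple(raw["treatments"])
    outcomes = []
    for entry in raw["outcomes"]:
        outcomes.append(
            OutcomeEffects(
                outcome_name=entry["name"],
                treatments=treatments,
                reference=raw["reference"],
                mu=np.asarray(entry["mu"], dtype=float),
                sigma=np.asarray(entry["sigma"], dtype=float),
                measure=entry["measure"],
                direction=entry["direction"],
            )
        )
    correlation = CorrelationSpec(
        tuple(raw["correlation"]["outcomes"]),
        np.asarray(raw["correlation"]["matrix"], dtype=float),
    )
    if not oriented:
        return tuple(outcomes), correlation
    ready = tuple(orient(to_smd(oc)) for oc in outcomes)
    return JointEffects(outcomes=ready, correlation=correlation)
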