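"""Data model and I/O for network meta-analysis (NMA) summary estimates.

An NMA of ``I`` treatments summarises the evidence as a vector of relative
effects versus a chosen reference treatment together with the covariance
matrix of those estimates (the *basic parameters*), or equivalently as a
*league table* of all pairwise contrasts with their standard errors.  This
module provides both representations, conversion between them, rescaling of
log odds-ratios to the standardized-mean-difference (SMD) scale, and the
orientation step that puts every outcome on a common "larger is better"
scale so that downstream ranking code never needs to know the published
direction of an outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectsError",
    "OutcomeEffects",
    "LeagueTable",
    "CorrelationSpec",
    "read_outcome",
    "read_league_csv",
    "covariance_from_league",
    "or_to_smd",
    "to_smd",
    "orient",
    "orient_civ",
    "LOG_OR_TO_SMD",
]

#: Rescaling factor from the log odds-ratio scale to the SMD scale,
#: sqrt(3)/pi, from the logistic-to-normal variance identity (Chinn's
#: conversion).
LOG_OR_TO_SMD: float = math.sqrt(3.0) / math.pi

# Relative eigenvalue tolerance below which a covariance reconstructed from
# a (possibly rounded) published league table is rejected as inconsistent.
_PSD_RTOL = 1e-8


class EffectsError(ValueError):
    """Invalid or inconsistent NMA summary data."""


def _validate_psd(sigma: np.ndarray, *, what: str = "covariance") -> np.ndarray:
    """Check symmetry and positive semi-definiteness; clip tiny negatives.

    Eigenvalues above ``-_PSD_RTOL * max_eigenvalue`` are treated as rounding
    noise and clipped to zero; anything more negative raises ``EffectsError``
    reporting the smallest eigenvalue.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise EffectsError(f"{what} must be a square matrix, got {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=1e-10, rtol=0.0):
        raise EffectsError(f"{what} is not symmetric")
    sigma = 0.5 * (sigma + sigma.T)
    w, v = np.linalg.eigh(sigma)
    scale = max(float(w[-1]), 1.0e-300)
    if w[0] < -_PSD_RTOL * scale:
        raise EffectsError(
            f"{what} is not positive semi-definite: smallest eigenvalue "
            f"{w[0]:.6g} (largest {w[-1]:.6g})"
        )
    if w[0] < 0.0:
        w = np.clip(w, 0.0, None)
        sigma = (v * w) @ v.T
        sigma = 0.5 * (sigma + sigma.T)
    return sigma


@dataclass(frozen=True)
class OutcomeEffects:
    """One outcome's NMA estimates: effects versus a reference, plus spread.

    Parameters
    ----------
    outcome_name
        Label for the outcome (e.g. ``"efficacy"``).
    treatments
        Ordered treatment labels; length ``I``.
    reference
        Label of the reference treatment (must be one of ``treatments``).
        The reference is an ordinary competitor for ranking purposes; its
        effect is pinned at zero with zero variance.
    mu
        Length-``I`` vector of relative effects versus the reference on a
        common continuous scale; ``mu[reference] == 0``.
    sigma
        ``I x I`` covariance matrix of ``mu`` (reference row/column zero), or
        ``None`` when the outcome was loaded from a league table whose
        covariance could not be or was not reconstructed.  Analytic P-scores
        need only the pairwise standard errors; rank simulation needs
        ``sigma``.
    measure
        ``"SMD"`` or ``"logOR"``.
    direction
        ``"higher_better"`` or ``"lower_better"`` on the published scale.
    oriented
        ``True`` once :func:`orient` has mapped the outcome onto the internal
        larger-is-better scale.
    se_matrix
        Optional ``I x I`` matrix of pairwise standard errors ``s_ij``.  When
        present (league-table input) it is authoritative for analytic
        scoring; otherwise ``s_ij`` is derived from ``sigma`` as
        ``sqrt(sigma_ii + sigma_jj - 2 sigma_ij)``.
    """

    outcome_name: str
    treatments: tuple[str, ...]
    reference: str
    mu: np.ndarray
    sigma: np.ndarray | None
    measure: str = "SMD"
    direction: str = "higher_better"
    oriented: bool = False
    se_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        treatments = tuple(str(t) for t in self.treatments)
        object.__setattr__(self, "treatments", treatments)
        if len(set(treatments)) != len(treatments):
            dupes = sorted({t for t in treatments if treatments.count(t) > 1})
            raise EffectsError(f"duplicate treatment labels: {dupes}")
        if len(treatments) < 2:
            raise EffectsError("need at least two treatments")
        if self.reference not in treatments:
            raise EffectsError(
                f"reference {self.reference!r} is not among treatments {treatments}"
            )
        if self.measure not in ("SMD", "logOR"):
            raise EffectsError(f"unknown effect measure {self.measure!r}")
        if self.direction not in ("higher_better", "lower_better"):
            raise EffectsError(f"unknown direction {self.direction!r}")
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (len(treatments),):
            raise EffectsError(
                f"mu has shape {mu.shape}, expected ({len(treatments)},)"
            )
        r = treatments.index(self.reference)
        if abs(mu[r]) > 1e-12:
            raise EffectsError(
                f"effect of the reference {self.reference!r} must be 0, got {mu[r]}"
            )
        mu = mu.copy()
        mu[r] = 0.0
        object.__setattr__(self, "mu", mu)
        if self.sigma is not None:
            sigma = _validate_psd(self.sigma, what=f"sigma[{self.outcome_name}]")
            if sigma.shape != (len(treatments),) * 2:
                raise EffectsError("sigma dimensions do not match treatments")
            if np.any(np.diag(sigma) < -1e-12):
                raise EffectsError("sigma has a negative diagonal entry")
            if not (np.allclose(sigma[r], 0.0) and np.allclose(sigma[:, r], 0.0)):
                raise EffectsError("reference row/column of sigma must be zero")
            object.__setattr__(self, "sigma", sigma)
        if self.se_matrix is not None:
            se = np.asarray(self.se_matrix, dtype=float)
            if se.shape != (len(treatments),) * 2:
                raise EffectsError("se_matrix dimensions do not match treatments")
            if not np.allclose(se, se.T, atol=1e-10):
                raise EffectsError("se_matrix must be symmetric")
            if np.any(se[~np.eye(len(treatments), dtype=bool)] <= 0.0):
                raise EffectsError("pairwise standard errors must be positive")
            object.__setattr__(self, "se_matrix", 0.5 * (se + se.T))

    # -- basic queries -------------------------------------------------

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def index(self, label: str) -> int:
        try:
            return self.treatments.index(label)
        except ValueError:
            raise EffectsError(
                f"unknown treatment {label!r}; known: {self.treatments}"
            ) from None

    def pairwise_diff(self) -> np.ndarray:
        """Matrix ``d[i, j] = mu_i - mu_j`` of all pairwise contrasts."""
        return self.mu[:, None] - self.mu[None, :]

    def pairwise_se(self) -> np.ndarray:
        """Matrix of pairwise standard errors ``s_ij`` (zero diagonal).

        Uses the league-table standard errors when they were the input,
        otherwise derives ``s_ij^2 = sigma_ii + sigma_jj - 2 sigma_ij``.
        """
        if self.se_matrix is not None:
            return self.se_matrix.copy()
        if self.sigma is None:
            raise EffectsError(
                "no covariance or pairwise standard errors available"
            )
        v = np.diag(self.sigma)
        s2 = v[:, None] + v[None, :] - 2.0 * self.sigma
        return np.sqrt(np.clip(s2, 0.0, None))


@dataclass(frozen=True)
class LeagueTable:
    """All pairwise relative effects with standard errors for one outcome.

    ``rows`` hold one entry per *unordered* treatment pair; if the input
    reported both ``(i, j)`` and ``(j, i)``, the constructor checks that the
    two are antisymmetric in the effect and symmetric in the standard error
    and keeps a single canonical row.
    """

    outcome_name: str
    rows: tuple[tuple[str, str, float, float], ...]
    _lookup: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lookup: dict[frozenset, tuple[float, float]] = {}
        canonical = []
        for ti, tj, diff, se in self.rows:
            ti, tj = str(ti), str(tj)
            diff, se = float(diff), float(se)
            if ti == tj:
                raise EffectsError(f"self-comparison {ti!r} vs itself")
            if se <= 0.0:
                raise EffectsError(f"non-positive SE {se} for pair ({ti}, {tj})")
            key = frozenset((ti, tj))
            if key in lookup:
                prev_diff, prev_se = lookup[key]
                # prev stored with the lexicographically first label first
                a, _ = sorted((ti, tj))
                want = diff if ti == a else -diff
                if not math.isclose(prev_diff, want, abs_tol=1e-10):
                    raise EffectsError(
                        f"league rows for ({ti}, {tj}) are not antisymmetric: "
                        f"{prev_diff} vs {want}"
                    )
                if not math.isclose(prev_se, se, abs_tol=1e-10):
                    raise EffectsError(
                        f"league rows for ({ti}, {tj}) disagree on SE: "
                        f"{prev_se} vs {se}"
                    )
                continue
            a, b = sorted((ti, tj))
            lookup[key] = (diff if ti == a else -diff, se)
            canonical.append((a, b, lookup[key][0], se))
        object.__setattr__(self, "rows", tuple(canonical))
        object.__setattr__(self, "_lookup", lookup)

    def treatments(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a, b, _, _ in self.rows:
            for t in (a, b):
                if t not in seen:
                    seen.append(t)
        return tuple(seen)

    def diff(self, i: str, j: str) -> float:
        """Relative effect of ``i`` versus ``j``."""
        key = frozenset((i, j))
        if key not in self._lookup:
            raise EffectsError(f"league table has no comparison ({i}, {j})")
        d, _ = self._lookup[key]
        a, _b = sorted((i, j))
        return d if i == a else -d

    def se(self, i: str, j: str) -> float:
        key = frozenset((i, j))
        if key not in self._lookup:
            raise EffectsError(f"league table has no comparison ({i}, {j})")
        return self._lookup[key][1]


@dataclass(frozen=True)
class CorrelationSpec:
    """Between-outcome correlation matrix for joint superiority probabilities."""

    outcome_names: tuple[str, ...]
    rho: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.outcome_names)
        object.__setattr__(self, "outcome_names", names)
        rho = np.asarray(self.rho, dtype=float)
        k = len(names)
        if rho.shape != (k, k):
            raise EffectsError(
                f"correlation matrix shape {rho.shape} does not match "
                f"{k} outcomes"
            )
        if not np.allclose(np.diag(rho), 1.0, atol=1e-10):
            raise EffectsError("correlation matrix must have unit diagonal")
        if np.any(np.abs(rho) > 1.0 + 1e-12):
            raise EffectsError("correlation entries must lie in [-1, 1]")
        rho = _validate_psd(rho, what="correlation matrix")
        np.fill_diagonal(rho, 1.0)
        object.__setattr__(self, "rho", np.clip(rho, -1.0, 1.0))

    @property
    def k(self) -> int:
        return len(self.outcome_names)

    def submatrix(self, names: Sequence[str]) -> "CorrelationSpec":
        idx = [self.outcome_names.index(n) for n in names]
        return CorrelationSpec(tuple(names), self.rho[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def or_to_smd(log_or, se_log_or):
    """Rescale a log odds-ratio (and its SE) to the SMD scale.

    The conversion multiplies by ``sqrt(3)/pi``; being linear, the standard
    error is rescaled by the same factor.  Accepts scalars or arrays.
    """
    log_or = np.asarray(log_or, dtype=float)
    se_log_or = np.asarray(se_log_or, dtype=float)
    if np.any(se_log_or < 0.0):
        raise EffectsError("standard errors must be non-negative")
    smd = LOG_OR_TO_SMD * log_or
    se_smd = LOG_OR_TO_SMD * se_log_or
    if smd.ndim == 0:
        return float(smd), float(se_smd)
    return smd, se_smd


def to_smd(effects: OutcomeEffects) -> OutcomeEffects:
    """Convert a log-OR outcome to the SMD scale (mean, covariance and SEs).

    The covariance rescales by the squared factor because the conversion is
    a fixed linear map of the estimates.  SMD outcomes pass through
    unchanged.
    """
    if effects.measure == "SMD":
        return effects
    c = LOG_OR_TO_SMD
    return replace(
        effects,
        mu=c * effects.mu,
        sigma=None if effects.sigma is None else c * c * effects.sigma,
        se_matrix=None if effects.se_matrix is None else c * effects.se_matrix,
        measure="SMD",
    )


def orient(effects: OutcomeEffects) -> OutcomeEffects:
    """Map an outcome onto the internal larger-is-better scale.

    For a ``lower_better`` outcome the effect vector is negated (the
    covariance is invariant under a global sign flip of the estimates); for
    ``higher_better`` the values pass through.  Orientation is applied
    exactly once — a second call raises, preventing silent double negation.
    """
    if effects.oriented:
        raise EffectsError(
            f"outcome {effects.outcome_name!r} is already oriented"
        )
    if effects.direction == "higher_better":
        return replace(effects, oriented=True)
    return replace(effects, mu=-effects.mu, oriented=True)


def orient_civ(civ, direction: str):
    """Re-sign a published-scale clinically important value for orientation.

    Configurations declare CIVs on the published scale of each outcome; the
    internal scale is larger-is-better, so CIVs for ``lower_better``
    outcomes flip sign together with the effects.
    """
    if direction not in ("higher_better", "lower_better"):
        raise EffectsError(f"unknown direction {direction!r}")
    arr = np.asarray(civ, dtype=float)
    out = arr if direction == "higher_better" else -arr
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# league table -> covariance
# ---------------------------------------------------------------------------


def covariance_from_league(
    league: LeagueTable,
    reference: str,
    *,
    measure: str = "SMD",
    direction: str = "higher_better",
) -> OutcomeEffects:
    """Reconstruct basic parameters (mu, sigma) from a full league table.

    With the reference effect pinned at zero, ``mu_i = diff(i, ref)`` and
    ``sigma_ii = se(i, ref)^2``; off-diagonal covariances follow from the
    pairwise-variance identity ``s_ij^2 = sigma_ii + sigma_jj - 2 sigma_ij``.
    Published tables are rounded, so the reconstruction is validated as
    positive semi-definite within tolerance (tiny negative eigenvalues are
    clipped; larger ones are an error reporting the smallest eigenvalue).
    """
    labels = league.treatments()
    if reference not in labels:
        raise EffectsError(
            f"reference {reference!r} does not appear in the league table"
        )
    treatments = (reference,) + tuple(t for t in labels if t != reference)
    i_count = len(treatments)
    mu = np.zeros(i_count)
    sigma = np.zeros((i_count, i_count))
    se = np.zeros((i_count, i_count))
    for a in range(1, i_count):
        mu[a] = league.diff(treatments[a], reference)
        sigma[a, a] = league.se(treatments[a], reference) ** 2
    for a in range(1, i_count):
        for b in range(a + 1, i_count):
            s_ab = league.se(treatments[a], treatments[b])
            sigma[a, b] = sigma[b, a] = 0.5 * (
                sigma[a, a] + sigma[b, b] - s_ab * s_ab
            )
    for a in range(i_count):
        for b in range(i_count):
            if a != b:
                se[a, b] = league.se(treatments[a], treatments[b])
    sigma = _validate_psd(sigma, what=f"covariance reconstructed from league "
                                      f"table {league.outcome_name!r}")
    return OutcomeEffects(
        outcome_name=league.outcome_name,
        treatments=treatments,
        reference=reference,
        mu=mu,
        sigma=sigma,
        measure=measure,
        direction=direction,
        se_matrix=se,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_league_csv(path: str | Path, outcome_name: str = "") -> LeagueTable:
    """Read a league table CSV with columns treatment_i,treatment_j,diff,se."""
    df = pd.read_csv(path)
    required = {"treatment_i", "treatment_j", "diff", "se"}
    if not required.issubset(df.columns):
        raise EffectsError(
            f"league CSV {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    rows = tuple(
        (str(r.treatment_i), str(r.treatment_j), float(r.diff), float(r.se))
        for r in df.itertuples()
    )
    return LeagueTable(outcome_name or Path(path).stem, rows)


def _read_covariance_csv(path: str | Path, treatments: Sequence[str]) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [t for t in treatments if t not in df.index or t not in df.columns]
    if missing:
        raise EffectsError(
            f"covariance CSV {path} is missing treatments {missing}"
        )
    return df.loc[list(treatments), list(treatments)].to_numpy(dtype=float)


def read_outcome(effects_csv_path: str | Path, config_entry: dict) -> OutcomeEffects:
    """Load one outcome from CSV according to its configuration entry.

    Two schemas are accepted and auto-detected from the header:

    * basic-parameter form — columns ``treatment,effect`` plus a companion
      covariance CSV (``config_entry["covariance"]``), a square matrix with
      treatment labels as header row and column;
    * league form — columns ``treatment_i,treatment_j,diff,se``, converted
      through :func:`covariance_from_league`.

    ``config_entry`` must declare ``measure``, ``direction`` and
    ``reference`` (and ``name``; defaults to the file stem).
    """
    path = Path(effects_csv_path)
    name = str(config_entry.get("name", path.stem))
    measure = config_entry["measure"]
    direction = config_entry["direction"]
    reference = str(config_entry["reference"])
    header = pd.read_csv(path, nrows=0).columns
    if {"treatment_i", "treatment_j", "diff", "se"}.issubset(header):
        league = read_league_csv(path, name)
        return covariance_from_league(
            league, reference, measure=measure, direction=direction
        )
    if not {"treatment", "effect"}.issubset(header):
        raise EffectsError(
            f"{path}: expected columns treatment,effect (basic form) or "
            f"treatment_i,treatment_j,diff,se (league form); found "
            f"{list(header)}"
        )
    df = pd.read_csv(path)
    treatments = tuple(str(t) for t in df["treatment"])
    mu = df["effect"].to_numpy(dtype=float)
    if reference not in treatments:
        raise EffectsError(
            f"reference {reference!r} not among treatments in {path}"
        )
    cov_path = config_entry.get("covariance")
    if cov_path is None:
        raise EffectsError(
            f"basic-parameter outcome {name!r} needs a companion "
            "'covariance' CSV in its config entry"
        )
    sigma = _read_covariance_csv(cov_path, treatments)
    return OutcomeEffects(
        outcome_name=name,
        treatments=treatments,
        reference=reference,
        mu=mu,
        sigma=sigma,
        measure=measure,
        direction=direction,
    )
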