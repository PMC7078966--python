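"""P-score curves over a grid of clinically important values (CIVs).

A plain P-score counts any superiority, however small.  Conditioning on a
CIV asks instead for the certainty that a treatment beats its competitors
by at least that margin: positive CIVs demand a clinically meaningful
benefit, negative CIVs (on the oriented scale) tolerate a bounded harm.
Sweeping the CIV over a grid traces, for every treatment, a non-increasing
curve whose crossings show where the treatment hierarchy re-orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import EffectsError, OutcomeEffects
from .ranking import pscores

__all__ = ["CivSpec", "CivCurveSet", "civ_curve", "find_crossings"]


@dataclass(frozen=True)
class CivSpec:
    """A grid of CIV values for one outcome, on that outcome's declared scale."""

    outcome_name: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise EffectsError("CIV grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(grid)):
            raise EffectsError("CIV grid must be finite")
        if np.any(np.diff(grid) <= 0.0):
            raise EffectsError("CIV grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)

    @classmethod
    def from_range(cls, outcome_name: str, lo: float, hi: float,
                   step: float = 0.05) -> "CivSpec":
        """Inclusive regular grid from ``lo`` to ``hi`` with the given step."""
        if step <= 0.0 or hi < lo:
            raise EffectsError("need step > 0 and hi >= lo")
        n = int(round((hi - lo) / step)) + 1
        return cls(outcome_name, lo + step * np.arange(n))


@dataclass(frozen=True)
class CivCurveSet:
    """P-score curves over a CIV grid, with mean curve and pair crossings.

    ``scores[i, g]`` is treatment ``i``'s P-score at grid point ``g``;
    ``crossings`` lists ``(treatment_a, treatment_b, civ)`` where the two
    curves change order, located by linear interpolation between grid
    points.  ``benefit_civ`` is set when the grid sweeps a risk tolerance at
    a fixed benefit margin (benefit-risk curves).
    """

    treatments: tuple[str, ...]
    grid: np.ndarray
    scores: np.ndarray
    mean_curve: np.ndarray
    crossings: tuple[tuple[str, str, float], ...] = ()
    benefit_civ: float | None = None
    outcome_context: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        grid = np.asarray(self.grid, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.treatments), grid.size):
            raise EffectsError(
                f"scores shape {scores.shape} does not match "
                f"({len(self.treatments)}, {grid.size})"
            )
        if np.any(scores < -1e-12) or np.any(scores > 1.0 + 1e-12):
            raise EffectsError("curve scores must lie in [0, 1]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "scores", np.clip(scores, 0.0, 1.0))
        object.__setattr__(self, "mean_curve", np.asarray(self.mean_curve, float))
        object.__setattr__(self, "crossings", tuple(self.crossings))

    def curve(self, treatment: str) -> np.ndarray:
        if treatment not in self.treatments:
            raise EffectsError(f"unknown treatment {treatment!r}")
        return self.scores[self.treatments.index(treatment)]

    def to_frame(self) -> pd.DataFrame:
        """Long format: treatment, civ, pscore (plus benefit_civ if set)."""
        g = self.grid.size
        df = pd.DataFrame(
            {
                "treatment": np.repeat(self.treatments, g),
                "civ": np.tile(self.grid, len(self.treatments)),
                "pscore": self.scores.ravel(),
            }
        )
        if self.benefit_civ is not None:
            df.insert(1, "benefit_civ", self.benefit_civ)
        return df

    def crossings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.crossings, columns=["treatment_a", "treatment_b", "civ"]
        )


def _pair_crossings(grid: np.ndarray, fa: np.ndarray, fb: np.ndarray) -> list[float]:
    """CIV values where the sign of ``fa - fb`` changes along the grid.

    A sign change between adjacent grid points is located by linear
    interpolation; a sign change across an exact zero at a grid point is
    reported at that point.  Touching zero without changing sign does not
    count as a crossing.
    """
    diff = fa - fb
    signs = np.sign(diff)
    out: list[float] = []
    nz = np.flatnonzero(signs != 0)
    for a, b in zip(nz[:-1], nz[1:]):
        if signs[a] * signs[b] >= 0:
            continue
        if b == a + 1:
            # linear interpolation within the bracketing cell
            t = diff[a] / (diff[a] - diff[b])
            out.append(float(grid[a] + t * (grid[b] - grid[a])))
        else:
            # the curves pass through equality at grid point(s); report the
            # midpoint of the zero run
            out.append(float(0.5 * (grid[a + 1] + grid[b - 1])))
    return out


def _all_crossings(treatments: tuple[str, ...], grid: np.ndarray,
                   scores: np.ndarray) -> tuple[tuple[str, str, float], ...]:
    found: list[tuple[str, str, float]] = []
    for i in range(len(treatments)):
        for j in range(i + 1, len(treatments)):
            for civ in _pair_crossings(grid, scores[i], scores[j]):
                found.append((treatments[i], treatments[j], civ))
    return tuple(sorted(found, key=lambda c: (c[2], c[0], c[1])))


def civ_curve(effects: OutcomeEffects, spec: CivSpec) -> CivCurveSet:
    """Analytic P-score curves for one outcome over a CIV grid.

    Each grid column is the P-score vector at that CIV; because the
    standard-normal CDF is increasing and its argument decreases in the
    CIV, every curve is non-increasing (asserted on every run).  The mean
    curve equals 0.5 exactly at CIV = 0.
    """
    if not effects.oriented:
        raise EffectsError("effects must be oriented before scoring")
    grid = spec.grid
    scores = np.empty((effects.n_treatments, grid.size))
    for g, civ in enumerate(grid):
        scores[:, g] = pscores(effects, civ=float(civ)).scores
    assert np.all(np.diff(scores, axis=1) <= 1e-12), \
        "P-score curves must be non-increasing in the CIV"
    return CivCurveSet(
        treatments=effects.treatments,
        grid=grid,
        scores=scores,
        mean_curve=scores.mean(axis=0),
        crossings=_all_crossings(effects.treatments, grid, scores),
        outcome_context=(effects.outcome_name,),
    )


def find_crossings(curves: CivCurveSet, pair: tuple[str, str]) -> list[float]:
    """CIV values at which the two named treatments' curves change order."""
    a, b = pair
    return _pair_crossings(curves.grid, curves.curve(a), curves.curve(b))


def plot_curves(curves: CivCurveSet, path, *, title: str | None = None):
    """Export a line chart of the curves (one line per treatment, dotted mean).

    Requires matplotlib; the CSV outputs remain the numeric contract and
    styling is intentionally minimal.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, t in enumerate(curves.treatments):
        ax.plot(curves.grid, curves.scores[i], lw=1.0, label=t)
    ax.plot(curves.grid, curves.mean_curve, "k:", lw=1.5, label="mean P-score")
    ax.set_xlabel("clinically important value (CIV)")
    ax.set_ylabel("P-score")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
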