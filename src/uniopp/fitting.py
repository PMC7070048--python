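"""Grid search over the (alpha, beta) simplex and behavioural sweeps.

The SSI objective surface over the simplex is generally non-smooth, so
fitting is an exhaustive evaluation of every grid point rather than a
continuous optimisation -- mirroring how the model family is calibrated
in practice.  Evaluations at different grid points are independent and
order-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import ModelParams
from .landscape import Landscape, intervening_opportunities, pairwise_distances
from .metrics import average_travel_distance, normalized_entropy, rmse, ssi
from .model import choice_probabilities

__all__ = [
    "SimplexGrid",
    "FitResult",
    "simplex_grid",
    "fit_parameters",
    "behavior_sweep",
]

_TIE_TOL = 1e-12
_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class SimplexGrid:
    """Regular grid on the simplex alpha, beta >= 0, alpha + beta <= 1."""

    step: float
    points: np.ndarray  # (k, 2) rows of (alpha, beta)

    def __len__(self) -> int:
        return len(self.points)


def simplex_grid(step: float) -> SimplexGrid:
    """All (alpha, beta) multiples of ``step`` inside the simplex.

    For ``step = 1/k`` the grid has (k+1)(k+2)/2 points.  Points are
    ordered by (alpha, beta), which fixes the tie-breaking order of
    :func:`fit_parameters`.
    """
    if not (0 < step <= 1):
        raise ValueError(f"grid step must be in (0, 1], got {step}")
    n_max = int(np.floor(1.0 / step + _SIMPLEX_TOL))
    vals = np.arange(n_max + 1) * step
    pts = [
        (a, b)
        for a in vals
        for b in vals
        if a + b <= 1.0 + _SIMPLEX_TOL
    ]
    return SimplexGrid(step=step, points=np.array(pts, dtype=float))


@dataclass
class FitResult:
    """Argmax of an objective over a simplex grid, with the full surface."""

    best_alpha: float
    best_beta: float
    best_score: float
    objective: str
    surface: pd.DataFrame  # columns alpha, beta, value
    ties: list = field(default_factory=list)
    grid_step: float = np.nan


def fit_parameters(
    landscape: Landscape,
    t_obs: np.ndarray,
    grid: SimplexGrid,
    objective: str = "ssi",
    *,
    metric: str = "euclidean",
    tie_policy: str = "strict",
    ssi_policy: str = "exclude",
    sij: np.ndarray | None = None,
) -> FitResult:
    """Exhaustive grid search for the (alpha, beta) best reproducing
    ``t_obs``.

    If the landscape carries no outflows, observed row sums are used as
    trip productions, the production-constrained convention under which a
    perfect model attains SSI = 1.  Ties on the objective (within 1e-12)
    are broken toward the smallest alpha, then smallest beta, and all tied
    points are reported.
    """
    if objective not in ("ssi", "neg_rmse"):
        raise ValueError(f"unknown objective {objective!r}")
    t_obs = np.asarray(t_obs, dtype=float)
    n = landscape.n_zones
    if t_obs.shape != (n, n):
        raise ValueError(f"observed matrix shape {t_obs.shape} != ({n}, {n})")
    t_obs = t_obs.copy()
    np.fill_diagonal(t_obs, 0.0)
    if not np.any(t_obs > 0):
        raise ValueError("observed flux matrix is empty (no positive entries)")
    if landscape.outflow is None:
        landscape = landscape.with_outflow(t_obs.sum(axis=1))
    if sij is None:
        d = pairwise_distances(landscape, metric=metric)
        sij = intervening_opportunities(landscape, d, tie_policy=tie_policy)
    outflow = landscape.outflow

    values = np.empty(len(grid))
    for k, (a, b) in enumerate(grid.points):
        p = choice_probabilities(landscape, sij, ModelParams(a, b))
        t_pred = outflow[:, None] * p
        if objective == "ssi":
            values[k] = ssi(t_pred, t_obs, zero_pair_policy=ssi_policy)
        else:
            values[k] = -rmse(t_pred, t_obs)

    best = values.max()
    tied_idx = np.flatnonzero(values >= best - _TIE_TOL)
    # grid points are sorted by (alpha, beta): first tie wins
    winner = tied_idx[0]
    surface = pd.DataFrame(
        {"alpha": grid.points[:, 0], "beta": grid.points[:, 1], "value": values}
    )
    return FitResult(
        best_alpha=float(grid.points[winner, 0]),
        best_beta=float(grid.points[winner, 1]),
        best_score=float(values[winner]),
        objective=objective,
        surface=surface,
        ties=[tuple(map(float, grid.points[i])) for i in tied_idx],
        grid_step=grid.step,
    )


def behavior_sweep(
    landscape: Landscape,
    grid: SimplexGrid,
    quantities: tuple = ("avg_distance", "entropy"),
    *,
    metric: str = "euclidean",
    tie_policy: str = "strict",
) -> dict[str, pd.DataFrame]:
    """Landscape-mean diagnostics at every grid point.

    For each (alpha, beta) computes the choice probabilities and the
    landscape means of the requested diagnostics ('avg_distance' and/or
    'entropy').  Returns one surface frame per quantity.
    """
    known = {"avg_distance", "entropy"}
    bad = set(quantities) - known
    if bad:
        raise ValueError(f"unknown sweep quantities: {sorted(bad)}")
    d = pairwise_distances(landscape, metric=metric)
    sij = intervening_opportunities(landscape, d, tie_policy=tie_policy)
    cols: dict[str, np.ndarray] = {q: np.empty(len(grid)) for q in quantities}
    for k, (a, b) in enumerate(grid.points):
        p = choice_probabilities(landscape, sij, ModelParams(a, b))
        if "avg_distance" in cols:
            cols["avg_distance"][k] = average_travel_distance(p, d, "mean")
        if "entropy" in cols:
            cols["entropy"][k] = float(normalized_entropy(p).mean())
    out = {}
    for q, vals in cols.items():
        out[q] = pd.DataFrame(
            {"alpha": grid.points[:, 0], "beta": grid.points[:, 1], "value": vals}
        )
    return out
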