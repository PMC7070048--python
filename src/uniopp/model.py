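"""Destination-choice probabilities, flux prediction, and the
statsmodels-style model/results pair for fitting the UO model to an
observed origin-destination matrix.
"""

from __future__ import annotations

import logging
from functools import cached_property

import numpy as np
import pandas as pd

from .kernels import ModelParams, uo_weight
from .landscape import Landscape, intervening_opportunities, pairwise_distances

__all__ = [
    "choice_probabilities",
    "predict_flux",
    "UniversalOpportunityModel",
    "UOResults",
]

logger = logging.getLogger(__name__)


def choice_probabilities(
    landscape: Landscape,
    sij: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Row-stochastic destination-choice probability matrix P.

    ``P[i, j]`` is the UO weight ``Q[i, j]`` normalised over destinations
    ``j != i``; self-choice is excluded (``P[i, i] = 0``).

    An origin whose weights are all zero cannot distribute trips: if the
    landscape assigns it positive outflow this raises, otherwise the row
    is left all-zero and a warning is logged.
    """
    n = landscape.n_zones
    sij = np.asarray(sij, dtype=float)
    if sij.shape != (n, n):
        raise ValueError(f"s matrix shape {sij.shape} does not match {n} zones")
    m = landscape.m
    q = uo_weight(m[:, None], m[None, :], sij, params)
    np.fill_diagonal(q, 0.0)
    row_sums = q.sum(axis=1)
    dead = row_sums == 0
    if np.any(dead):
        if landscape.outflow is not None:
            bad = dead & (landscape.outflow > 0)
            if np.any(bad):
                ids = landscape.zone_ids[bad].tolist()
                raise ValueError(
                    f"origins {ids} have positive outflow but all-zero "
                    "selection weights (no reachable opportunities)"
                )
        logger.warning(
            "origins %s have all-zero selection weights; probability rows "
            "left at zero",
            landscape.zone_ids[dead].tolist(),
        )
    p = np.divide(q, row_sums[:, None], out=np.zeros_like(q), where=~dead[:, None])
    return p


def predict_flux(
    landscape: Landscape,
    params: ModelParams,
    *,
    metric: str = "euclidean",
    tie_policy: str = "strict",
    sij: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted OD flux matrix ``T[i, j] = O_i * P[i, j]``.

    Requires the landscape to carry outflows.  ``sij`` may be passed to
    reuse a precomputed intervening-opportunity matrix; otherwise it is
    derived from the landscape with the given metric and tie policy.
    """
    if landscape.outflow is None:
        raise ValueError("predict_flux requires a landscape with outflow values")
    if sij is None:
        d = pairwise_distances(landscape, metric=metric)
        sij = intervening_opportunities(landscape, d, tie_policy=tie_policy)
    p = choice_probabilities(landscape, sij, params)
    return landscape.outflow[:, None] * p


class UniversalOpportunityModel:
    """Universal opportunity model of an observed OD flux matrix.

    The model holds the observed fluxes together with the landscape that
    generated them, precomputes the distance and intervening-opportunity
    matrices once, and exposes prediction and fitting.  ``fit`` performs
    an exhaustive grid search over the (alpha, beta) simplex maximising
    the Sorensen similarity index (or minimising RMSE) between predicted
    and observed fluxes, returning a :class:`UOResults`.

    Parameters
    ----------
    flux : ndarray (n, n)
        Observed OD trip counts; diagonal ignored (self-flows undefined).
    landscape : Landscape
        Zones, coordinates and opportunity counts.  If the landscape has
        no outflows, observed row sums are used as trip productions (the
        standard production-constrained convention).
    metric, tie_policy : str
        Distance metric and equidistance handling for the
        intervening-opportunity matrix.
    ssi_policy : str
        'exclude' (default) drops pairs with no flux in either matrix
        from the similarity average; 'literal' divides by N(N-1).
    """

    def __init__(
        self,
        flux: np.ndarray,
        landscape: Landscape,
        *,
        metric: str = "euclidean",
        tie_policy: str = "strict",
        ssi_policy: str = "exclude",
    ) -> None:
        flux = np.asarray(flux, dtype=float)
        n = landscape.n_zones
        if flux.shape != (n, n):
            raise ValueError(
                f"flux matrix shape {flux.shape} does not match {n} zones"
            )
        if np.any(flux < 0):
            raise ValueError("observed fluxes must be non-negative")
        self.flux = flux.copy()
        np.fill_diagonal(self.flux, 0.0)
        if not np.any(self.flux > 0):
            raise ValueError("observed flux matrix has no positive entries")
        if landscape.outflow is None:
            landscape = landscape.with_outflow(self.flux.sum(axis=1))
        self.landscape = landscape
        self.metric = metric
        self.tie_policy = tie_policy
        self.ssi_policy = ssi_policy

    @classmethod
    def from_csv(cls, zones_path, od_path, **kwargs) -> "UniversalOpportunityModel":
        """Build from a zone CSV and a long-format OD CSV."""
        from .io import read_od, read_zones

        landscape = read_zones(zones_path)
        flux = read_od(od_path, landscape)
        return cls(flux, landscape, **kwargs)

    @cached_property
    def distances(self) -> np.ndarray:
        return pairwise_distances(self.landscape, metric=self.metric)

    @cached_property
    def sij(self) -> np.ndarray:
        return intervening_opportunities(
            self.landscape, self.distances, tie_policy=self.tie_policy
        )

    def probabilities(self, params: ModelParams) -> np.ndarray:
        """Destination-choice probability matrix at ``params``."""
        return choice_probabilities(self.landscape, self.sij, params)

    def predict(self, params: ModelParams) -> np.ndarray:
        """Predicted flux matrix at ``params``."""
        return self.landscape.outflow[:, None] * self.probabilities(params)

    def score(self, params: ModelParams, objective: str = "ssi") -> float:
        """Objective value of ``params`` against the observed fluxes."""
        from .metrics import rmse, ssi

        t_pred = self.predict(params)
        if objective == "ssi":
            return ssi(t_pred, self.flux, zero_pair_policy=self.ssi_policy)
        if objective == "neg_rmse":
            return -rmse(t_pred, self.flux)
        raise ValueError(f"unknown objective {objective!r}")

    def fit(self, grid_step: float = 0.05, objective: str = "ssi") -> "UOResults":
        """Exhaustive grid search over the (alpha, beta) simplex."""
        from .fitting import fit_parameters, simplex_grid

        grid = simplex_grid(grid_step)
        result = fit_parameters(
            self.landscape,
            self.flux,
            grid,
            objective=objective,
            metric=self.metric,
            tie_policy=self.tie_policy,
            ssi_policy=self.ssi_policy,
            sij=self.sij,
        )
        return UOResults(self, result)


class UOResults:
    """Results of fitting a :class:`UniversalOpportunityModel`.

    Carries the fitted (alpha, beta), the objective surface over the whole
    simplex grid, ties, and goodness-of-fit measures; prediction,
    simulation and plotting run at the fitted parameters.
    """

    def __init__(self, model: UniversalOpportunityModel, fit_result) -> None:
        self.model = model
        self._fit = fit_result
        self.params = ModelParams(fit_result.best_alpha, fit_result.best_beta)
        self.objective = fit_result.objective
        self.best_score = fit_result.best_score
        self.surface: pd.DataFrame = fit_result.surface
        self.ties = fit_result.ties
        self.grid_step = fit_result.grid_step

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def beta(self) -> float:
        return self.params.beta

    @cached_property
    def fittedvalues(self) -> np.ndarray:
        """Predicted OD flux matrix at the fitted parameters."""
        return self.model.predict(self.params)

    @cached_property
    def ssi(self) -> float:
        from .metrics import ssi

        return ssi(
            self.fittedvalues,
            self.model.flux,
            zero_pair_policy=self.model.ssi_policy,
        )

    @cached_property
    def rmse(self) -> float:
        from .metrics import rmse

        return rmse(self.fittedvalues, self.model.flux)

    def predict(self, params: ModelParams | None = None) -> np.ndarray:
        return self.model.predict(params or self.params)

    def simulate(self, trips_per_origin: int, seed=None) -> np.ndarray:
        """Multinomial trip sample from the fitted choice probabilities."""
        from .synthetic import sample_trips

        return sample_trips(
            self.model.landscape,
            self.params,
            trips_per_origin,
            seed=seed,
            metric=self.model.metric,
            tie_policy=self.model.tie_policy,
        )

    def diagnostics(self) -> "pd.DataFrame":
        """Per-origin normalized entropy and average travel distance."""
        from .metrics import average_travel_distance, normalized_entropy

        p = self.model.probabilities(self.params)
        return pd.DataFrame(
            {
                "zone_id": self.model.landscape.zone_ids,
                "entropy": normalized_entropy(p),
                "avg_distance": average_travel_distance(p, self.model.distances),
            }
        )

    def plot_surface(self, ax=None, **scatter_kw):
        """Objective value over the (alpha, beta) simplex as a heatmap."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = ax.scatter(
            self.surface["alpha"],
            self.surface["beta"],
            c=self.surface["value"],
            **scatter_kw,
        )
        ax.plot(self.alpha, self.beta, "k*", markersize=12)
        ax.set_xlabel(r"$\alpha$ (exploratory)")
        ax.set_ylabel(r"$\beta$ (cautious)")
        ax.figure.colorbar(sc, ax=ax, label=self.objective)
        return ax

    def summary(self) -> str:
        """Plain-text fit summary."""
        n = self.model.landscape.n_zones
        lines = [
            "Universal Opportunity Model Results",
            "=" * 43,
            f"{'No. zones:':<28}{n}",
            f"{'Observed trips:':<28}{self.model.flux.sum():.10g}",
            f"{'Objective:':<28}{self.objective}",
            f"{'Grid step:':<28}{self.grid_step}",
            f"{'Grid points:':<28}{len(self.surface)}",
            "-" * 43,
            f"{'alpha (exploratory):':<28}{self.alpha:.4f}",
            f"{'beta (cautious):':<28}{self.beta:.4f}",
            f"{'Best score:':<28}{self.best_score:.6f}",
            f"{'SSI at optimum:':<28}{self.ssi:.6f}",
            f"{'RMSE at optimum:':<28}{self.rmse:.6f}",
        ]
        if len(self.ties) > 1:
            lines.append(f"{'Tied optima:':<28}{len(self.ties)}")
        lines.append("=" * 43)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<UOResults alpha={self.alpha:.3f} beta={self.beta:.3f} "
            f"{self.objective}={self.best_score:.4f}>"
        )
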