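"""Synthetic landscapes and trip samples.

Regular-lattice landscapes with uniform or random opportunity counts are
the controlled setting in which the behavioural regularities of the model
family are studied; multinomial trip sampling from a ground-truth
parameter pair closes the loop for parameter-recovery experiments.  All
randomness is driven by explicit seeds -- no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import ModelParams
from .landscape import Landscape, intervening_opportunities, pairwise_distances
from .model import choice_probabilities

__all__ = [
    "LandscapeSpec",
    "make_grid_landscape",
    "sample_trips",
    "fixture_landscape",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for a regular nx-by-ny lattice of zones.

    ``opportunity_mode='uniform'`` gives every zone ``m_const``
    opportunities; ``'random'`` draws i.i.d. uniform on
    ``[m_low, m_high]``.  Defaults (15 x 15 lattice, unit spacing,
    m_const = 100, random range [50, 150]) give landscapes large enough
    for distance and entropy surfaces to show their corner structure while
    staying cheap to evaluate.
    """

    nx: int = 15
    ny: int = 15
    spacing: float = 1.0
    opportunity_mode: str = "random"
    m_low: float = 50.0
    m_high: float = 150.0
    m_const: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.nx * self.ny < 2:
            raise ValueError("lattice must contain at least 2 zones")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.opportunity_mode not in ("uniform", "random"):
            raise ValueError(
                f"unknown opportunity_mode {self.opportunity_mode!r}"
            )
        if self.m_low > self.m_high:
            raise ValueError("m_low must not exceed m_high")
        if min(self.m_low, self.m_high, self.m_const) < 0:
            raise ValueError("opportunity values must be >= 0")


def make_grid_landscape(spec: LandscapeSpec) -> Landscape:
    """Materialise a lattice landscape from its spec."""
    jj, ii = np.meshgrid(np.arange(spec.ny), np.arange(spec.nx), indexing="ij")
    coords = np.column_stack(
        [ii.ravel() * spec.spacing, jj.ravel() * spec.spacing]
    ).astype(float)
    n = spec.nx * spec.ny
    width = len(str(n - 1))
    ids = np.array([f"z{k:0{width}d}" for k in range(n)])
    if spec.opportunity_mode == "uniform":
        m = np.full(n, float(spec.m_const))
    else:
        rng = np.random.default_rng(spec.seed)
        m = rng.uniform(spec.m_low, spec.m_high, size=n)
    return Landscape(zone_ids=ids, coords=coords, m=m)


def sample_trips(
    landscape: Landscape,
    params: ModelParams,
    trips_per_origin: int,
    seed=None,
    *,
    metric: str = "euclidean",
    tie_policy: str = "strict",
) -> np.ndarray:
    """Multinomial OD sample from the ground-truth choice probabilities.

    Each origin independently draws ``trips_per_origin`` destinations from
    its choice distribution, so every row of the returned matrix sums to
    ``trips_per_origin`` exactly.
    """
    if trips_per_origin <= 0:
        raise ValueError("trips_per_origin must be a positive integer")
    d = pairwise_distances(landscape, metric=metric)
    sij = intervening_opportunities(landscape, d, tie_policy=tie_policy)
    p = choice_probabilities(landscape, sij, params)
    dead = p.sum(axis=1) == 0
    if np.any(dead):
        ids = landscape.zone_ids[dead].tolist()
        raise ValueError(
            f"cannot sample trips: origins {ids} have all-zero choice "
            "probabilities"
        )
    rng = np.random.default_rng(seed)
    t = rng.multinomial(trips_per_origin, p).astype(float)
    return t


def fixture_landscape() -> Landscape:
    """Canonical 3-zone collinear landscape used across examples.

    Zones A, B, C at x = 0, 1, 2 on a line, opportunities (5, 7, 11) and
    100 outgoing trips each.  From A, zone B intervenes before C, so
    s[A, C] = 7; every other pair has no intervening mass except
    s[C, A] = 7 by the mirrored argument.
    """
    return Landscape(
        zone_ids=np.array(["A", "B", "C"]),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
        m=np.array([5.0, 7.0, 11.0]),
        outflow=np.array([100.0, 100.0, 100.0]),
    )
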