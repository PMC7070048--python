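"""Zone landscapes: coordinates, opportunity counts, distances and
intervening opportunities.

A landscape is the spatial substrate shared by every
intervening-opportunities model in this package: a set of zones, each with
a 2-D centroid, an opportunity count ``m`` (jobs, services, POIs -- any
attractor whose benefit a traveller samples) and optionally a trip
production ``outflow``.  From the landscape and a distance metric we derive
the intervening-opportunity matrix ``s[i, j]``: the total opportunity mass
at zones strictly closer to origin ``i`` than destination ``j``.  In this
model class ``s`` replaces distance itself as the deterrence variable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "EARTH_RADIUS_KM",
    "Landscape",
    "pairwise_distances",
    "intervening_opportunities",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Landscape:
    """An immutable set of zones.

    Parameters
    ----------
    zone_ids : array-like of str or int
        Unique zone identifiers, one per zone.
    coords : array-like, shape (n, 2)
        Zone centroids.  Planar ``(x, y)`` for the euclidean metric, or
        ``(lon, lat)`` in degrees for the haversine metric.
    m : array-like, shape (n,)
        Non-negative opportunity count per zone.
    outflow : array-like, shape (n,), optional
        Trip production ``O_i`` per zone.  Required only for flux
        prediction; fitting falls back to observed row sums.
    """

    zone_ids: np.ndarray
    coords: np.ndarray
    m: np.ndarray
    outflow: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.zone_ids)
        coords = np.asarray(self.coords, dtype=float)
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "zone_ids", ids)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "m", m)
        if ids.ndim != 1 or ids.size < 2:
            raise ValueError("a landscape needs at least 2 zones")
        if len(np.unique(ids)) != ids.size:
            dupes = pd.Series(ids).value_counts()
            dupes = dupes[dupes > 1].index.tolist()
            raise ValueError(f"duplicate zone_ids: {dupes}")
        if coords.shape != (ids.size, 2):
            raise ValueError(
                f"coords must have shape ({ids.size}, 2), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if m.shape != (ids.size,):
            raise ValueError("m must be one value per zone")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("opportunity counts m must be finite and >= 0")
        if self.outflow is not None:
            outflow = np.asarray(self.outflow, dtype=float)
            object.__setattr__(self, "outflow", outflow)
            if outflow.shape != (ids.size,):
                raise ValueError("outflow must be one value per zone")
            if not np.all(np.isfinite(outflow)) or np.any(outflow < 0):
                raise ValueError("outflow must be finite and >= 0")

    @property
    def n_zones(self) -> int:
        return self.zone_ids.size

    def index_of(self, zone_id) -> int:
        """Position of ``zone_id`` in the landscape ordering."""
        hits = np.flatnonzero(self.zone_ids == zone_id)
        if hits.size == 0:
            raise KeyError(f"unknown zone id: {zone_id!r}")
        return int(hits[0])

    def with_outflow(self, outflow) -> "Landscape":
        """A copy of this landscape with ``outflow`` replaced."""
        return replace(self, outflow=outflow)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Landscape":
        """Build from a frame with columns zone_id, x, y, m[, outflow]."""
        required = {"zone_id", "x", "y", "m"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing zone columns: {sorted(missing)}")
        outflow = df["outflow"].to_numpy() if "outflow" in df.columns else None
        return cls(
            zone_ids=df["zone_id"].to_numpy(),
            coords=df[["x", "y"]].to_numpy(dtype=float),
            m=df["m"].to_numpy(dtype=float),
            outflow=outflow,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "zone_id": self.zone_ids,
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
            "m": self.m,
        }
        if self.outflow is not None:
            data["outflow"] = self.outflow
        return pd.DataFrame(data)


def pairwise_distances(landscape: Landscape, metric: str = "euclidean") -> np.ndarray:
    """Pairwise zone-centroid distances.

    ``metric='euclidean'`` treats coordinates as planar; ``'haversine'``
    treats them as ``(lon, lat)`` degrees and returns great-circle
    kilometres on a sphere of radius 6371 km.
    """
    coords = landscape.coords
    if metric == "euclidean":
        d = cdist(coords, coords)
    elif metric == "haversine":
        from sklearn.metrics.pairwise import haversine_distances

        lon, lat = coords[:, 0], coords[:, 1]
        if np.any(np.abs(lat) > 90):
            raise ValueError("haversine metric requires |lat| <= 90 degrees")
        latlon = np.radians(np.column_stack([lat, lon]))
        d = haversine_distances(latlon) * EARTH_RADIUS_KM
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'euclidean' or 'haversine'")
    np.fill_diagonal(d, 0.0)
    return d


def intervening_opportunities(
    landscape: Landscape,
    distances: np.ndarray,
    tie_policy: str = "strict",
) -> np.ndarray:
    """Intervening-opportunity matrix ``s[i, j]``.

    ``s[i, j]`` sums the opportunities of all third zones ``k`` (neither
    origin nor destination) lying strictly closer to origin ``i`` than the
    destination ``j`` does.  Under ``tie_policy='half'`` a third zone
    exactly equidistant with the destination contributes half its
    opportunities, a smoother convention for lattices where exact ties are
    common.  The diagonal is defined as 0.
    """
    if tie_policy not in ("strict", "half"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    n = landscape.n_zones
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (n, n):
        raise ValueError(
            f"distance matrix shape {distances.shape} does not match {n} zones"
        )
    m = landscape.m
    s = np.empty((n, n))
    for i in range(n):
        di = distances[i]
        # closer[k, j] <=> zone k strictly closer to i than j is
        closer = di[:, None] < di[None, :]
        s_i = m @ closer
        # remove the origin itself (d_ii = 0 counts wherever d_ij > 0);
        # k == j never satisfies d_ik < d_ij
        s_i -= m[i] * (di > 0)
        if tie_policy == "half":
            ties = di[:, None] == di[None, :]
            np.fill_diagonal(ties, False)  # k == j: trivially tied
            ties[i, :] = False  # k == i: the origin
            s_i = s_i + 0.5 * (m @ ties)
        s[i] = s_i
    np.fill_diagonal(s, 0.0)
    return s
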