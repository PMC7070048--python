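"""CSV interchange for landscapes and OD matrices.

Zone CSV: header ``zone_id,x,y,m[,outflow]``, one row per zone; ``x,y``
are lon,lat degrees when the haversine metric is used.  OD CSV: long
format ``origin,destination,flux``; unlisted pairs are zero, self-pairs
are invalid.  Numeric output uses 10 significant digits so files
round-trip through read/write unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landscape import Landscape

__all__ = ["read_zones", "write_zones", "read_od", "write_od"]

FLOAT_FMT = "%.10g"


def read_zones(path) -> Landscape:
    """Read and validate a zone CSV into a :class:`Landscape`."""
    df = pd.read_csv(path)
    required = ["zone_id", "x", "y", "m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"zone file {path}: missing columns {missing}")
    dup = df["zone_id"].duplicated(keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        ids = sorted(df.loc[dup, "zone_id"].unique().tolist())
        raise ValueError(
            f"zone file {path}: duplicate zone_id {ids} at rows {rows}"
        )
    neg = df["m"] < 0
    if neg.any():
        rows = (df.index[neg] + 2).tolist()
        raise ValueError(f"zone file {path}: negative m at rows {rows}")
    try:
        return Landscape.from_dataframe(df)
    except ValueError as exc:
        raise ValueError(f"zone file {path}: {exc}") from exc


def write_zones(landscape: Landscape, path) -> None:
    landscape.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_od(path, landscape: Landscape) -> np.ndarray:
    """Read a long-format OD CSV into a dense flux matrix.

    Pair ordering follows the landscape's zone order; unlisted pairs are
    zero.  Unknown zone ids, negative fluxes and self-pairs are rejected.
    Duplicate pairs are summed.
    """
    df = pd.read_csv(path)
    required = ["origin", "destination", "flux"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"OD file {path}: missing columns {missing}")
    n = landscape.n_zones
    index = {zid: k for k, zid in enumerate(landscape.zone_ids.tolist())}
    t = np.zeros((n, n))
    if len(df) == 0:
        return t
    for col in ("origin", "destination"):
        unknown = ~df[col].isin(index)
        if unknown.any():
            bad = sorted(df.loc[unknown, col].astype(str).unique().tolist())
            raise ValueError(f"OD file {path}: unknown {col} zone ids {bad}")
    if (df["flux"] < 0).any():
        rows = (df.index[df["flux"] < 0] + 2).tolist()
        raise ValueError(f"OD file {path}: negative flux at rows {rows}")
    selfp = df["origin"] == df["destination"]
    if selfp.any():
        rows = (df.index[selfp] + 2).tolist()
        raise ValueError(f"OD file {path}: self-pairs at rows {rows}")
    oi = df["origin"].map(index).to_numpy()
    dj = df["destination"].map(index).to_numpy()
    np.add.at(t, (oi, dj), df["flux"].to_numpy(dtype=float))
    return t


def write_od(t: np.ndarray, landscape: Landscape, path) -> None:
    """Write the nonzero off-diagonal entries of a flux matrix.

    Rows are sorted by (origin, destination) in landscape order.  A
    nonzero diagonal is rejected: self-flows are undefined in this model
    family.
    """
    t = np.asarray(t, dtype=float)
    n = landscape.n_zones
    if t.shape != (n, n):
        raise ValueError(f"flux matrix shape {t.shape} does not match {n} zones")
    if np.any(np.diagonal(t) != 0):
        bad = landscape.zone_ids[np.diagonal(t) != 0].tolist()
        raise ValueError(f"refusing to write self-pair fluxes for zones {bad}")
    oi, dj = np.nonzero(t)
    df = pd.DataFrame(
        {
            "origin": landscape.zone_ids[oi],
            "destination": landscape.zone_ids[dj],
            "flux": t[oi, dj],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
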