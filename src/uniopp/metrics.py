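"""Evaluation metrics and behavioural diagnostics for OD flux models.

Scalar goodness-of-fit: the Sorensen similarity index (SSI) between a
predicted and an observed flux matrix, and the root-mean-square error
(RMSE).  Behavioural diagnostics per origin: normalized entropy of the
destination-choice distribution (heterogeneity of selection) and average
travel distance (bulk density of selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ssi",
    "rmse",
    "normalized_entropy",
    "average_travel_distance",
    "MetricReport",
    "metric_report",
]

_ROW_TOL = 1e-9


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _check_pair(t_pred, t_obs) -> tuple[np.ndarray, np.ndarray]:
    t_pred = np.asarray(t_pred, dtype=float)
    t_obs = np.asarray(t_obs, dtype=float)
    if t_pred.shape != t_obs.shape:
        raise ValueError(
            f"matrix shapes differ: {t_pred.shape} vs {t_obs.shape}"
        )
    if t_pred.ndim != 2 or t_pred.shape[0] != t_pred.shape[1]:
        raise ValueError("flux matrices must be square")
    return t_pred, t_obs


def ssi(t_pred, t_obs, zero_pair_policy: str = "exclude") -> float:
    """Sorensen similarity index between two OD flux matrices.

    Each ordered pair ``i != j`` contributes
    ``2 * min(T, T') / (T + T')``; the index averages these terms and is 1
    exactly when the matrices coincide and 0 when their supports are
    disjoint.  Under the default ``'exclude'`` policy pairs with zero flux
    in both matrices are dropped from the average, so both boundary
    statements hold exactly; ``'literal'`` divides by N(N-1) with
    both-zero pairs contributing 0.
    """
    if zero_pair_policy not in ("exclude", "literal"):
        raise ValueError(f"unknown zero_pair_policy {zero_pair_policy!r}")
    t_pred, t_obs = _check_pair(t_pred, t_obs)
    n = t_pred.shape[0]
    off = _offdiag_mask(n)
    a, b = t_pred[off], t_obs[off]
    tot = a + b
    live = tot > 0
    terms = np.zeros_like(tot)
    terms[live] = 2.0 * np.minimum(a[live], b[live]) / tot[live]
    if zero_pair_policy == "literal":
        return float(terms.sum() / (n * (n - 1)))
    if not np.any(live):
        raise ValueError("both matrices are identically zero off-diagonal")
    return float(terms[live].mean())


def rmse(t_pred, t_obs) -> float:
    """Root-mean-square error over all ordered pairs ``i != j``.

    Structural zeros are included: every off-diagonal cell counts, whether
    or not either matrix has flux there.
    """
    t_pred, t_obs = _check_pair(t_pred, t_obs)
    off = _offdiag_mask(t_pred.shape[0])
    diff = t_pred[off] - t_obs[off]
    return float(np.sqrt(np.mean(diff**2)))


def normalized_entropy(p: np.ndarray, origin: int | None = None):
    """Normalized entropy of destination choice, per origin.

    For origin ``i`` with choice probabilities ``p_ij`` over the other
    ``N - 1`` zones,

        E_i = -sum_j p_ij * log(p_ij) / log(N - 1),

    with ``0 * log 0 := 0``, so ``E_i`` is 0 for a degenerate choice and 1
    for a uniform one.  With exactly two zones the normaliser vanishes;
    the degenerate single-destination row is defined as 1 (it is the only
    achievable distribution), anything else is an error.

    Returns the vector of all origins, or a scalar if ``origin`` given.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("probability matrix must be square")
    n = p.shape[0]
    rows = np.arange(n) if origin is None else np.array([origin])
    sub = p[rows]
    sums = sub.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _ROW_TOL):
        bad = rows[np.abs(sums - 1.0) > _ROW_TOL].tolist()
        raise ValueError(f"probability rows {bad} do not sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(sub > 0, sub * np.log(sub), 0.0)
    raw = -plogp.sum(axis=1)
    if n == 2:
        # single destination: only p = 1 is a valid distribution
        if np.any(np.abs(raw) > _ROW_TOL):
            raise ValueError(
                "normalized entropy undefined for a 2-zone landscape with "
                "a non-degenerate row"
            )
        e = np.ones_like(raw)
    else:
        e = raw / np.log(n - 1)
    if origin is not None:
        return float(e[0])
    return e


def average_travel_distance(
    p: np.ndarray,
    d: np.ndarray,
    aggregate: str = "per_origin",
):
    """Expected travel distance under the choice probabilities.

    Per origin, ``<d>_i = sum_j p_ij * d_ij``; ``aggregate='mean'``
    averages unweighted over origins.
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    if p.shape != d.shape:
        raise ValueError(f"shape mismatch: P {p.shape} vs d {d.shape}")
    per_origin = (p * d).sum(axis=1)
    if aggregate == "per_origin":
        return per_origin
    if aggregate == "mean":
        return float(per_origin.mean())
    raise ValueError(f"unknown aggregate {aggregate!r}")


@dataclass
class MetricReport:
    """Bundle of fit metrics and per-origin diagnostics."""

    ssi: float
    rmse: float
    entropy: np.ndarray | None = None
    avg_distance: np.ndarray | None = None
    mean_entropy: float | None = field(default=None)
    mean_avg_distance: float | None = field(default=None)

    def to_dict(self) -> dict:
        out = {"ssi": self.ssi, "rmse": self.rmse}
        if self.entropy is not None:
            out["entropy"] = list(map(float, self.entropy))
            out["mean_entropy"] = self.mean_entropy
        if self.avg_distance is not None:
            out["avg_distance"] = list(map(float, self.avg_distance))
            out["mean_avg_distance"] = self.mean_avg_distance
        return out


def metric_report(
    t_pred,
    t_obs,
    distances: np.ndarray | None = None,
    zero_pair_policy: str = "exclude",
) -> MetricReport:
    """Score a predicted flux matrix against an observed one.

    Entropy and average travel distance are computed from the predicted
    matrix's row-normalised choice probabilities; rows with no predicted
    flux are skipped (NaN).  Distance diagnostics require ``distances``.
    """
    t_pred, t_obs = _check_pair(t_pred, t_obs)
    report = MetricReport(
        ssi=ssi(t_pred, t_obs, zero_pair_policy=zero_pair_policy),
        rmse=rmse(t_pred, t_obs),
    )
    row_sums = t_pred.sum(axis=1)
    live = row_sums > 0
    if np.any(live):
        p = np.divide(
            t_pred, row_sums[:, None], out=np.zeros_like(t_pred),
            where=live[:, None],
        )
        ent = np.full(t_pred.shape[0], np.nan)
        # dead rows have no choice distribution; pad them so the row-sum
        # validator passes, then mask out
        ent_live = normalized_entropy(_pad_rows(p, live))
        ent[live] = ent_live[live]
        report.entropy = ent
        report.mean_entropy = float(np.nanmean(ent))
        if distances is not None:
            ad = np.full(t_pred.shape[0], np.nan)
            ad_all = average_travel_distance(p, np.asarray(distances, float))
            ad[live] = ad_all[live]
            report.avg_distance = ad
            report.mean_avg_distance = float(np.nanmean(ad))
    return report


def _pad_rows(p: np.ndarray, live: np.ndarray) -> np.ndarray:
    """Replace dead rows with a valid uniform row so the entropy
    validator passes; callers mask those entries out afterwards."""
    q = p.copy()
    n = p.shape[0]
    if n > 1 and np.any(~live):
        fill = np.full(n, 1.0 / (n - 1))
        for i in np.flatnonzero(~live):
            q[i] = fill
            q[i, i] = 0.0
    return q
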