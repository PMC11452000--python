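"""Effective bandwidth of a spline smoother.

Two estimators of the spatial scale implied by df unpenalized splines:

* minimum-radius ("new"): for each location i, order the smoothing
  weights S[:, i] by the distances D[:, i] and take the smallest distance
  whose weight is negative; the effective bandwidth k_hat is the median
  of these first-negative distances.  It reads as the approximate minimum
  radius of the area each point is smoothed over.

* loess ("original"): per location, smooth the weights as a function of
  distance with a local quadratic loess fit, predict on a regular distance
  grid, and take the first distance at which the across-location median
  predicted weight goes negative — an average rather than minimum radius,
  which is why it tends to come out larger.

Both are swept over df on a single nested basis, so the whole df range
costs one eigendecomposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    BandwidthUndefinedError,
    InvalidParameterError,
    SpanTooSmallError,
)
from .geometry import DistanceMatrix, PointSet, pairwise_distances, subsample_points
from .tprs import SmootherMatrix, build_tprs_basis

logger = logging.getLogger(__name__)

__all__ = [
    "WEIGHT_SIGN_TOL",
    "BandwidthResult",
    "SweepTable",
    "first_negative_distance",
    "effective_bandwidth",
    "loess_effective_bandwidth",
    "bandwidth_sweep",
    "df_for_target_bandwidth",
]

#: a weight counts as negative only below -WEIGHT_SIGN_TOL, so exact zeros
#: perturbed by floating-point noise cannot trigger a crossing
WEIGHT_SIGN_TOL = 1e-12


def first_negative_distance(weights, distances) -> float | None:
    """Smallest distance whose paired smoothing weight is negative.

    Order-independent: equivalent to sorting the weights by distance and
    scanning for the first strictly negative one.  Returns ``None`` when no
    weight is negative.
    """
    w = np.asarray(weights, dtype=float)
    d = np.asarray(distances, dtype=float)
    if w.shape != d.shape:
        raise InvalidParameterError(
            f"weights and distances differ in length: {w.shape} vs {d.shape}"
        )
    if np.any(d < 0):
        raise InvalidParameterError("distances must be nonnegative")
    neg = w < -WEIGHT_SIGN_TOL
    if not neg.any():
        return None
    return float(d[neg].min())


@dataclass(frozen=True)
class BandwidthResult:
    """Effective bandwidth at one df.

    ``per_point`` holds each location's first-negative distance (NaN where
    no weight is negative); it is ``None`` for the loess variant, whose
    median is taken over predicted curves rather than per-point distances.
    ``k_hat`` uses the standard median convention (mean of the two central
    order statistics for an even count).
    """

    k_hat: float
    df: int
    n_undefined: int
    per_point: np.ndarray | None = None
    method: str = "new"
    span: float | None = None
    unit_label: str = "units"

    @property
    def n_defined(self) -> int | None:
        if self.per_point is None:
            return None
        return int(np.isfinite(self.per_point).sum())


def effective_bandwidth(
    smoother: SmootherMatrix, distances: DistanceMatrix
) -> BandwidthResult:
    """Minimum-radius effective bandwidth of a smoother.

    Applies :func:`first_negative_distance` to every column i of S against
    column i of D and returns the median over the locations where a
    negative weight exists.  Locations with no negative weight are excluded
    from the median and counted in ``n_undefined``; if they are more than
    half of all locations (in particular when S is the identity and no
    weight is negative at all) the bandwidth is declared undefined and a
    :class:`BandwidthUndefinedError` is raised.
    """
    S = smoother.values
    D = distances.values
    if S.shape != D.shape:
        raise InvalidParameterError("smoother and distance matrix shapes differ")
    n = S.shape[0]
    candidates = np.where(S < -WEIGHT_SIGN_TOL, D, np.inf)
    per_point = candidates.min(axis=0)
    defined = np.isfinite(per_point)
    n_undefined = int(n - defined.sum())
    per_point = np.where(defined, per_point, np.nan)
    if n_undefined == n:
        raise BandwidthUndefinedError(
            f"no negative smoothing weights at df={smoother.df}; "
            "effective bandwidth is undefined at this df"
        )
    if n_undefined > n / 2:
        raise BandwidthUndefinedError(
            f"{n_undefined}/{n} locations have no negative smoothing weight at "
            f"df={smoother.df}; effective bandwidth is undefined at this df"
        )
    if n_undefined:
        logger.info(
            "df=%d: %d/%d locations without a negative weight excluded from the median",
            smoother.df, n_undefined, n,
        )
    k_hat = float(np.median(per_point[defined]))
    return BandwidthResult(
        k_hat=k_hat,
        df=smoother.df,
        n_undefined=n_undefined,
        per_point=per_point,
        method="new",
        unit_label=smoother.unit_label,
    )


def loess_effective_bandwidth(
    smoother: SmootherMatrix,
    distances: DistanceMatrix,
    span: float,
    n_eval: int = 1000,
) -> BandwidthResult:
    """Loess-based (average-radius) effective bandwidth.

    Per location i the weights S[:, i] are smoothed against D[:, i] with a
    local quadratic regression (tricube kernel, neighborhood = the
    ``ceil(span * n)`` nearest points by distance) and predicted at
    ``n_eval`` evenly spaced distances on [0, max(D)].  k_hat is the
    smallest evaluation distance at which the across-location median
    prediction is negative.
    """
    if not 0 < span <= 1:
        raise InvalidParameterError(f"span must be in (0, 1], got {span}")
    if n_eval < 2:
        raise InvalidParameterError(f"n_eval must be >= 2, got {n_eval}")
    S = smoother.values
    D = distances.values
    if S.shape != D.shape:
        raise InvalidParameterError("smoother and distance matrix shapes differ")
    n = S.shape[0]
    k = math.ceil(span * n)
    if k < 3:
        raise SpanTooSmallError(
            f"span={span} keeps only {k} point(s) per local quadratic fit; "
            f"use span >= {3 / n:.3f} for n={n}"
        )
    grid = np.linspace(0.0, D.max(), n_eval)
    preds = np.empty((n, n_eval))
    for i in range(n):
        preds[i] = _loess_predict(D[:, i], S[:, i], grid, k, span)
    med = np.median(preds, axis=0)
    crossing = med < -WEIGHT_SIGN_TOL
    n_undefined = int((~(preds < -WEIGHT_SIGN_TOL).any(axis=1)).sum())
    if not crossing.any():
        raise BandwidthUndefinedError(
            f"median predicted smoothing weight never goes negative at "
            f"df={smoother.df} (span={span}); effective bandwidth is undefined"
        )
    k_hat = float(grid[int(np.argmax(crossing))])
    return BandwidthResult(
        k_hat=k_hat,
        df=smoother.df,
        n_undefined=n_undefined,
        per_point=None,
        method="loess",
        span=span,
        unit_label=smoother.unit_label,
    )


def _loess_predict(
    d: np.ndarray, y: np.ndarray, grid: np.ndarray, k: int, span: float
) -> np.ndarray:
    """Local quadratic tricube-weighted fit of y on d, evaluated at ``grid``.

    Vectorized over evaluation points: for each grid value the local
    bandwidth is the distance to the k-th nearest abscissa, the abscissae
    are centered and scaled by it, and the weighted quadratic normal
    equations (3x3, built from kernel-weighted moments) are solved in a
    batch.
    """
    A = np.abs(d[:, None] - grid[None, :])                  # (n, m)
    h = np.partition(A, k - 1, axis=0)[k - 1]               # (m,)
    h = np.where(h > 0, h, np.finfo(float).tiny ** 0.25)
    u = A / h
    w = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)           # tricube
    t = (d[:, None] - grid[None, :]) / h                    # scaled local coords
    # kernel-weighted moments of t up to order 4 and of y up to order 2
    powers = [w, w * t, w * t * t]
    powers.append(powers[2] * t)
    powers.append(powers[3] * t)
    s = [p.sum(axis=0) for p in powers]                     # s0..s4, each (m,)
    b = [(w * y[:, None]).sum(axis=0),
         (w * t * y[:, None]).sum(axis=0),
         (w * t * t * y[:, None]).sum(axis=0)]
    M = np.empty((grid.size, 3, 3))
    M[:, 0, 0], M[:, 0, 1], M[:, 0, 2] = s[0], s[1], s[2]
    M[:, 1, 0], M[:, 1, 1], M[:, 1, 2] = s[1], s[2], s[3]
    M[:, 2, 0], M[:, 2, 1], M[:, 2, 2] = s[2], s[3], s[4]
    rhs = np.stack(b, axis=1)[..., None]
    # tied distances can make individual local fits rank deficient; the
    # pseudoinverse then gives the minimum-norm local polynomial, which
    # still predicts sensibly at the window center
    beta = (np.linalg.pinv(M, rcond=1e-10) @ rhs)[..., 0]
    if not np.all(np.isfinite(beta)):
        raise SpanTooSmallError(
            f"local quadratic fit is ill-conditioned at span={span}; "
            "increase the span"
        )
    return beta[:, 0]  # fitted value at the (centered) evaluation point


@dataclass(frozen=True)
class SweepTable:
    """df -> k_hat table produced by :func:`bandwidth_sweep`.

    Wraps a DataFrame with columns
    ``df, k_hat, method, span, n_points, n_undefined, seed``; one row per
    df from 3 to max_df, df strictly increasing.  A df at which the
    bandwidth is undefined keeps its row with ``k_hat`` = NaN.
    """

    data: pd.DataFrame
    unit_label: str = "units"

    COLUMNS = ("df", "k_hat", "method", "span", "n_points", "n_undefined", "seed")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise InvalidParameterError(f"sweep table is missing columns: {missing}")
        dfs = self.data["df"].to_numpy()
        if len(dfs) and not np.all(np.diff(dfs) > 0):
            raise InvalidParameterError("df values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    def k_hat(self, df: int) -> float:
        row = self.data.loc[self.data["df"] == df, "k_hat"]
        if row.empty:
            raise InvalidParameterError(f"df={df} not present in the sweep table")
        return float(row.iloc[0])

    def to_csv(self, path: str | Path) -> None:
        # %.17g makes the floats round-trip exactly
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, unit_label: str = "units") -> "SweepTable":
        data = pd.read_csv(path, float_precision="round_trip")
        data = data[list(cls.COLUMNS)]
        return cls(data=data, unit_label=unit_label)


def bandwidth_sweep(
    points: PointSet,
    max_df: int,
    method: str = "new",
    span: float | None = None,
    subsample_to: int | None = None,
    seed: int | None = None,
    n_eval: int = 1000,
) -> SweepTable:
    """Effective bandwidth for every df from 3 to ``max_df``.

    Subsampling (when ``subsample_to`` is below the point count) happens
    once, before basis construction, and applies to the entire
    computation; it requires a seed so the run is reproducible.  A single
    nested basis is built at ``max_df`` and the projection is updated
    incrementally (rank-one per df), which matches the direct projection
    to floating-point accuracy.
    """
    if method not in ("new", "loess"):
        raise InvalidParameterError(f"method must be 'new' or 'loess', got {method!r}")
    if method == "loess" and span is None:
        raise InvalidParameterError("span is required when method='loess'")
    if method == "new" and span is not None:
        raise InvalidParameterError("span only applies to method='loess'")

    used_seed: int | None = None
    if subsample_to is not None and subsample_to < len(points):
        if seed is None:
            raise InvalidParameterError(
                "seed is required when subsampling is triggered"
            )
        points = subsample_points(points, subsample_to, seed)
        used_seed = seed
    n = len(points)
    if max_df > n - 1:
        raise InvalidParameterError(
            f"max_df={max_df} exceeds n - 1 = {n - 1}: the number of splines "
            "may not exceed the number of coordinates"
        )

    distances = pairwise_distances(points)
    basis = build_tprs_basis(points, max_df, distances=distances)
    Q = basis.orthonormal

    rows = []
    S = Q[:, :4] @ Q[:, :4].T
    S = (S + S.T) / 2.0
    for df in range(3, max_df + 1):
        if df > 3:
            q = Q[:, df]
            S += np.outer(q, q)
        smoother = SmootherMatrix(values=S, df=df, unit_label=points.unit_label)
        try:
            if method == "new":
                res = effective_bandwidth(smoother, distances)
            else:
                res = loess_effective_bandwidth(smoother, distances, span, n_eval)
            k_hat, n_undef = res.k_hat, res.n_undefined
        except BandwidthUndefinedError as exc:
            logger.warning("df=%d: %s", df, exc)
            k_hat, n_undef = np.nan, n
        rows.append(
            {
                "df": df,
                "k_hat": k_hat,
                "method": method,
                "span": span,
                "n_points": n,
                "n_undefined": n_undef,
                "seed": used_seed,
            }
        )
    data = pd.DataFrame(rows, columns=list(SweepTable.COLUMNS))
    return SweepTable(data=data, unit_label=points.unit_label)


def df_for_target_bandwidth(table: SweepTable, target: float) -> int | None:
    """Smallest df whose effective bandwidth is at or below ``target``.

    The rule is boundary-inclusive (k_hat == target qualifies); rows with
    an undefined bandwidth are skipped.  Returns ``None`` when no df in
    the table reaches the target.
    """
    if len(table) == 0:
        raise InvalidParameterError("sweep table is empty")
    data = table.data.dropna(subset=["k_hat"])
    hit = data.loc[data["k_hat"] <= target, "df"]
    if hit.empty:
        return None
    return int(hit.min())
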