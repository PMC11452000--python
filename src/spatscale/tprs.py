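"""Unpenalized thin-plate regression spline (TPRS) basis and its smoother.

The basis for a planar point set follows the standard low-rank
thin-plate construction (as in mgcv's ``bs="tp"``).  With
E[i,j] = eta(D[i,j]) for the thin-plate radial function
eta(r) = r^2 log r and the polynomial null space T = [1, x, y]:

1. eigendecompose the symmetric matrix E and retain the max_df+1
   eigenpairs (U, lambda) of largest absolute eigenvalue;
2. restrict the radial coefficients to satisfy the thin-plate side
   condition T' delta = 0: Z is an orthonormal null-space basis of
   T' U (computed by a full QR), giving spline columns U diag(lambda) Z;
3. prepend the trend, H = [1, x, y, U diag(lambda) Z].

A model with df spatial splines uses the first df+1 columns of H, and
its hat (smoothing) matrix is the orthogonal projection

    S = H (H'H)^{-1} H',

computed through a QR orthonormalization of H rather than the explicit
normal-equations inverse.  S depends only on column spans, so the scale
of eta and eigenvector signs are immaterial; the eigenvalue scaling of
the spline columns does matter for the *nested* (prefix) spans the df
sweep uses, which is why it is kept.  Prefix spans are invariant under
rigid motions of the points: E is distance-only, span{1, x, y} is closed
under rigid motions, and a rotation changes the null-space QR only in
its leading 3 x 3 block, flipping Z columns at most in sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import InvalidParameterError, RankDeficiencyError
from .geometry import DistanceMatrix, PointSet, pairwise_distances

__all__ = ["tps_eta", "SplineBasis", "SmootherMatrix", "build_tprs_basis", "smoothing_matrix"]

#: singular values below RANK_TOL x largest count as zero
RANK_TOL = 1e-10
#: relative eigenvalue gap below which the retain/discard boundary is flagged
GAP_TOL = 1e-10


def tps_eta(r):
    """Thin-plate radial basis function eta(r) = r^2 log r (2-D, second order).

    Accepts a scalar or array of nonnegative distances; eta(0) = 0 (the
    removable singularity).  Any positive constant multiple would give the
    same smoother, so no normalizing constant is carried.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError("distances must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(arr > 0, arr * arr * np.log(np.where(arr > 0, arr, 1.0)), 0.0)
    return float(out) if np.isscalar(r) else out


@dataclass(frozen=True)
class SplineBasis:
    """Nested TPRS design matrix for every df from 3 up to ``max_df``.

    Attributes
    ----------
    design
        The n x (max_df+1) matrix H with columns
        [intercept, x, y, spline_1 ... spline_{max_df-2}].
    eigenvalues
        The max_df+1 retained eigenvalues of E, by descending absolute
        value (the spline columns are constrained combinations of the
        corresponding eigenvectors).
    max_df
        Largest number of splines this basis supports.
    orthonormal
        QR orthonormalization Q of H.  Because R is triangular, the first
        j columns of Q span the first j columns of H, so one factorization
        serves every nested df.
    """

    design: np.ndarray
    eigenvalues: np.ndarray
    max_df: int
    orthonormal: np.ndarray
    unit_label: str = "units"

    @property
    def n(self) -> int:
        return self.design.shape[0]


@dataclass(frozen=True)
class SmootherMatrix:
    """Orthogonal projection S = H(H'H)^{-1}H' for a given number of splines.

    S is symmetric and idempotent, has trace df+1 (the column count of the
    projected basis) and unit row sums (the intercept lies in the span).
    """

    values: np.ndarray
    df: int
    unit_label: str = "units"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, tol_idem: float = 1e-8, tol_trace: float = 1e-6,
                 tol_rows: float = 1e-8) -> None:
        """Assert the projection invariants, raising ``AssertionError`` on failure."""
        S = self.values
        assert np.abs(S - S.T).max() <= tol_idem, "smoother is not symmetric"
        assert np.abs(S @ S - S).max() <= tol_idem, "smoother is not idempotent"
        assert abs(np.trace(S) - (self.df + 1)) <= tol_trace, "trace != df + 1"
        assert np.abs(S.sum(axis=1) - 1.0).max() <= tol_rows, "row sums != 1"


_COLUMN_NAMES = ["intercept", "x", "y"]


def _column_name(j: int) -> str:
    return _COLUMN_NAMES[j] if j < 3 else f"spline{j - 2}"


def build_tprs_basis(
    points: PointSet,
    max_df: int,
    distances: DistanceMatrix | None = None,
) -> SplineBasis:
    """Construct the nested unpenalized TPRS basis up to ``max_df`` splines.

    Requires ``3 <= max_df <= n - 1`` and non-degenerate geometry (points
    not all on one line).  Eigenpairs of E are retained by descending
    absolute eigenvalue (E is indefinite); ties are broken by the original
    eigenvalue index, and a near-degenerate retain/discard boundary
    (relative gap < 1e-10) is reported as a warning because the spanned
    space is then implementation-dependent.
    """
    n = len(points)
    if max_df < 3:
        raise InvalidParameterError(f"max_df must be >= 3, got {max_df}")
    if max_df > n - 1:
        raise InvalidParameterError(
            f"max_df must be <= n - 1 = {n - 1} (the number of splines may not "
            f"exceed the number of coordinates), got {max_df}"
        )
    if distances is None:
        distances = pairwise_distances(points)
    D = distances.values
    if D.shape[0] != n:
        raise InvalidParameterError("distance matrix does not match the point set")

    E = tps_eta(D)
    eigvals, eigvecs = np.linalg.eigh(E)
    order = np.argsort(-np.abs(eigvals), kind="stable")
    k = max_df + 1  # retained eigenpairs; the side condition removes 3 dims
    kept = order[:k]
    if k < n:
        lo, hi = np.abs(eigvals[order[k]]), np.abs(eigvals[order[k - 1]])
        scale = max(hi, np.abs(eigvals).max(), 1e-300)
        if (hi - lo) / scale < GAP_TOL:
            warnings.warn(
                f"near-degenerate eigenvalue pair at the retain/discard boundary "
                f"(|lambda_{k}| ~ |lambda_{k + 1}|); the df={max_df} span may be "
                "implementation-dependent",
                RuntimeWarning,
                stacklevel=2,
            )

    T = np.column_stack([np.ones(n), points.coords])
    U = eigvecs[:, kept]
    lam = eigvals[kept]
    # thin-plate side condition T' delta = 0: orthonormal null basis of T'U
    C = T.T @ U  # (3, k)
    Qc, _ = np.linalg.qr(C.T, mode="complete")
    Z = Qc[:, 3:]  # (k, k-3)
    splines = (U * lam) @ Z
    H = np.column_stack([T, splines])

    # rank check on column-normalized H so units do not skew the tolerance
    norms = np.linalg.norm(H, axis=0)
    norms[norms == 0] = 1.0
    _, R, piv = scipy.linalg.qr(H / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    bad = piv[diag < RANK_TOL * diag.max()]
    if bad.size:
        names = ", ".join(_column_name(j) for j in sorted(bad))
        raise RankDeficiencyError(
            f"design matrix is rank deficient (collinear or duplicated geometry); "
            f"offending column(s): {names}"
        )

    Q, _ = np.linalg.qr(H)
    return SplineBasis(
        design=H,
        eigenvalues=eigvals[kept],
        max_df=max_df,
        orthonormal=Q,
        unit_label=points.unit_label,
    )


def smoothing_matrix(basis: SplineBasis, df: int) -> SmootherMatrix:
    """Projection onto the first ``df + 1`` basis columns.

    ``df`` ranges over ``2..max_df``: df >= 3 are the spline models the
    bandwidth sweep uses, while df = 2 is the plain polynomial trend
    [1, x, y] (the ordinary planar-regression hat matrix), exposed for
    diagnostics and cross-checks.
    """
    if not 2 <= df <= basis.max_df:
        raise InvalidParameterError(
            f"df must be in [2, {basis.max_df}] for this basis, got {df}"
        )
    Q = basis.orthonormal[:, : df + 1]
    S = Q @ Q.T
    S = (S + S.T) / 2.0
    return SmootherMatrix(values=S, df=df, unit_label=basis.unit_label)
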