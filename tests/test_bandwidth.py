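import numpy as np
import pandas as pd
import pytest

import spatscale as ss
from spatscale.bandwidth import SweepTable
from spatscale.exceptions import (
    BandwidthUndefinedError,
    InvalidParameterError,
    SpanTooSmallError,
)
from spatscale.geometry import DistanceMatrix
from spatscale.tprs import SmootherMatrix



def brute_force_k_hat(S, D):
    """Independent minimum-radius pass: sort each column by distance, scan
    for the first strictly negative weight, take the median."""
    n = S.shape[0]
    firsts = []
    for i in range(n):
        order = np.argsort(D[:, i], kind="stable")
        found = None
        for j in order:
            if S[j, i] < -1e-12:
                found = D[j, i]
                break
        if found is not None:
            firsts.append(found)
    assert firsts
    return float(np.median(firsts)), n - len(firsts), firsts


# ------------------------------------------------- first_negative_distance

@pytest.mark.parametrize(
    "weights,distances,expected",
    [
        ((0.5, 0.2, -0.1, -0.3), (0, 1, 2, 3), 2.0),
        ((0.1, 0.2, 0.0, 0.3), (0, 1, 2, 3), None),
        ((-0.3, 0.5, -0.1, 0.2), (3, 0, 2, 1), 2.0),  # order-independent
    ],
)
def test_first_negative_distance(weights, distances, expected):
    assert ss.first_negative_distance(weights, distances) == expected


def test_first_negative_distance_length_mismatch():
    with pytest.raises(InvalidParameterError):
        ss.first_negative_distance([1.0, -1.0], [0.0])


def test_first_negative_distance_ignores_sign_noise():
    # weights within the -1e-12 guard do not count as negative
    assert ss.first_negative_distance([-1e-13, -0.5], [1.0, 2.0]) == 2.0


# --------------------------------------------------- minimum-radius method

def test_effective_bandwidth_matches_brute_force_oracle(random_points):
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(12, 41))
        df = int(rng.integers(3, min(11, n - 1)))
        pts = random_points(n, seed=int(rng.integers(0, 2**31)))
        D = ss.pairwise_distances(pts)
        basis = ss.build_tprs_basis(pts, df, distances=D)
        smoother = ss.smoothing_matrix(basis, df)
        res = ss.effective_bandwidth(smoother, D)
        k_oracle, n_undef_oracle, firsts = brute_force_k_hat(smoother.values, D.values)
        assert res.k_hat == k_oracle
        assert res.n_undefined == n_undef_oracle
        # every defined per-point value occurs in its distance column
        defined = np.isfinite(res.per_point)
        for i in np.flatnonzero(defined):
            assert res.per_point[i] in D.values[:, i]


def test_median_convention_mean_of_middle_two():
    # 4 columns with first-negative distances 1, 2, 4, 10 -> median 3.0
    S = np.full((4, 4), 0.1)
    D = np.zeros((4, 4))
    for i, d in enumerate([1.0, 2.0, 4.0, 10.0]):
        S[i, i] = -0.2
        D[i, i] = d  # the only negative weight in column i sits at distance d
    res = ss.effective_bandwidth(SmootherMatrix(values=S, df=3), DistanceMatrix(D))
    assert res.k_hat == 3.0


def test_identity_smoother_is_undefined(grid7):
    n = len(grid7)
    basis = ss.build_tprs_basis(grid7, n - 1)
    smoother = ss.smoothing_matrix(basis, n - 1)
    with pytest.raises(BandwidthUndefinedError, match="undefined"):
        ss.effective_bandwidth(smoother, ss.pairwise_distances(grid7))


def test_majority_undefined_rule():
    # 3 of 4 columns have no negative weight -> undefined; 2 of 4 is fine
    D = np.arange(16, dtype=float).reshape(4, 4)
    S = np.full((4, 4), 0.1)
    S[0, 0] = -0.2
    with pytest.raises(BandwidthUndefinedError, match="3/4"):
        ss.effective_bandwidth(SmootherMatrix(values=S, df=3), DistanceMatrix(D))
    S[1, 1] = -0.2
    res = ss.effective_bandwidth(SmootherMatrix(values=S, df=3), DistanceMatrix(D))
    assert res.n_undefined == 2


# ------------------------------------------------------------ loess method

def test_loess_undefined_for_all_positive_weights():
    n = 30
    d = np.linspace(0, 50, n)
    D = np.tile(d[:, None], (1, n))
    S = np.full((n, n), 0.05)
    with pytest.raises(BandwidthUndefinedError):
        ss.loess_effective_bandwidth(
            SmootherMatrix(values=S, df=5), DistanceMatrix(D), span=0.5, n_eval=100
        )


@pytest.mark.parametrize("span", [0.2, 0.5, 1.0])
def test_loess_recovers_exact_linear_crossing(span):
    # weights follow w(d) = 0.2 - 0.002 d, crossing zero at d = 100
    n = 80
    d = np.linspace(0, 200, n)
    D = np.tile(d[:, None], (1, n))
    S = 0.2 - 0.002 * D
    res = ss.loess_effective_bandwidth(
        SmootherMatrix(values=S, df=5), DistanceMatrix(D), span=span, n_eval=401
    )
    step = 200.0 / 400
    assert abs(res.k_hat - 100.0) <= step + 1e-9
    assert res.method == "loess" and res.span == span


def test_loess_span_too_small():
    n = 30
    D = np.abs(np.subtract.outer(np.arange(n, dtype=float), np.arange(n, dtype=float)))
    S = np.eye(n)
    with pytest.raises(SpanTooSmallError, match="span"):
        ss.loess_effective_bandwidth(
            SmootherMatrix(values=S, df=5), DistanceMatrix(D), span=0.05, n_eval=50
        )


def test_loess_at_least_minimum_radius_on_fixture():
    grid5 = ss.make_rect_grid(40, 40, 10)
    D = ss.pairwise_distances(grid5)
    basis = ss.build_tprs_basis(grid5, 5, distances=D)
    smoother = ss.smoothing_matrix(basis, 5)
    new = ss.effective_bandwidth(smoother, D).k_hat
    loess = ss.loess_effective_bandwidth(smoother, D, span=0.5, n_eval=500).k_hat
    assert loess >= new


# ------------------------------------------------------------------- sweeps

def test_sweep_row_count_and_monotone_bandwidth(grid20):
    table = ss.bandwidth_sweep(grid20, 25)
    assert len(table) == 23
    assert list(table.data["df"]) == list(range(3, 26))
    k = table.data["k_hat"].to_numpy()
    assert np.all(np.diff(k) <= 1e-9), "k_hat should not increase with df"


def test_sweep_matches_per_df_projections(random_points):
    """The incremental rank-one update must agree with direct projections."""
    pts = random_points(40, seed=21)
    D = ss.pairwise_distances(pts)
    basis = ss.build_tprs_basis(pts, 10, distances=D)
    table = ss.bandwidth_sweep(pts, 10)
    for df in range(3, 11):
        direct = ss.effective_bandwidth(ss.smoothing_matrix(basis, df), D)
        assert table.k_hat(df) == pytest.approx(direct.k_hat, abs=1e-8)


def test_sweep_subsample_determinism(random_points):
    pts = random_points(300, seed=2)
    a = ss.bandwidth_sweep(pts, 10, subsample_to=100, seed=1)
    b = ss.bandwidth_sweep(pts, 10, subsample_to=100, seed=1)
    pd.testing.assert_frame_equal(a.data, b.data)
    assert (a.data["n_points"] == 100).all()
    assert (a.data["seed"] == 1).all()


def test_sweep_requires_seed_when_subsampling(random_points):
    pts = random_points(50, seed=0)
    with pytest.raises(InvalidParameterError, match="seed"):
        ss.bandwidth_sweep(pts, 5, subsample_to=20)
    # no subsampling triggered -> no seed needed
    ss.bandwidth_sweep(pts, 5, subsample_to=100)


def test_sweep_rejects_excess_df(random_points):
    with pytest.raises(InvalidParameterError, match="may not exceed"):
        ss.bandwidth_sweep(random_points(10, seed=0), 15)


def test_sweep_rejects_span_for_new_method(random_points):
    with pytest.raises(InvalidParameterError, match="span"):
        ss.bandwidth_sweep(random_points(30, seed=0), 5, method="new", span=0.5)
    with pytest.raises(InvalidParameterError, match="span"):
        ss.bandwidth_sweep(random_points(30, seed=0), 5, method="loess")


def test_sweep_flags_undefined_rows_and_continues():
    grid3 = ss.make_rect_grid(20, 20, 10)  # n = 9
    table = ss.bandwidth_sweep(grid3, 8)
    assert len(table) == 6
    assert np.isnan(table.k_hat(8))  # S = identity at df + 1 = n
    assert np.isfinite(table.k_hat(3))


def test_k_hat_rigid_motion_invariance(random_points, rigid_motion):
    pts = random_points(60, seed=3)
    moved = rigid_motion(pts, theta=0.7, shift=(37.0, -12.0))
    t1 = ss.bandwidth_sweep(pts, 12)
    t2 = ss.bandwidth_sweep(moved, 12)
    np.testing.assert_allclose(
        t1.data["k_hat"].to_numpy(), t2.data["k_hat"].to_numpy(), atol=1e-8
    )


def test_loess_sweep_runs(random_points):
    pts = random_points(40, seed=6)
    table = ss.bandwidth_sweep(pts, 5, method="loess", span=0.6, n_eval=200)
    assert (table.data["method"] == "loess").all()
    assert (table.data["span"] == 0.6).all()
    assert np.isfinite(table.data["k_hat"]).all()


# --------------------------------------------------------------- df lookup

def test_df_for_target_bandwidth_rule():
    data = pd.DataFrame(
        {
            "df": [5, 10],
            "k_hat": [130.0, 92.2],
            "method": "new",
            "span": None,
            "n_points": 100,
            "n_undefined": 0,
            "seed": None,
        }
    )
    table = SweepTable(data=data)
    assert ss.df_for_target_bandwidth(table, 92.2) == 10  # boundary inclusive
    assert ss.df_for_target_bandwidth(table, 100.0) == 10
    assert ss.df_for_target_bandwidth(table, 150.0) == 5
    assert ss.df_for_target_bandwidth(table, 50.0) is None


def test_sweep_table_csv_round_trip(tmp_path, random_points):
    table = ss.bandwidth_sweep(random_points(40, seed=1), 8)
    path = tmp_path / "sweep.csv"
    table.to_csv(path)
    back = SweepTable.from_csv(path)
    np.testing.assert_array_equal(back.data["df"], table.data["df"])
    np.testing.assert_array_equal(back.data["k_hat"], table.data["k_hat"])
    assert list(back.data.columns) == list(table.data.columns)
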