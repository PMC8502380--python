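import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from urchinwalk import (
    SimulationConfig,
    classify_diffusion,
    moment_curve,
    simulate_trajectory,
    zeta_exponents,
    zeta_slope,
)
from urchinwalk.diffusion import MomentCurve, log_spaced_taus
from urchinwalk.errors import InsufficientDataError

from conftest import make_traj


def brute_force_moments(positions, q_grid, taus):
    """Independent oracle: explicit double loop over all ordered pairs."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    out = np.empty((len(q_grid), len(taus)))
    for j, tau in enumerate(taus):
        tau = int(tau)
        mods = []
        for t in range(n - tau):
            d = positions[t + tau] - positions[t]
            mods.append(np.sqrt(d[0] ** 2 + d[1] ** 2))
        for i, q in enumerate(q_grid):
            out[i, j] = np.mean([m**q for m in mods])
    return out


class TestMomentCurve:
    def test_hand_computed_small_path(self):
        # three unit steps; two sqrt(2) displacements at lag 2
        pts = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2), (3, 3), (4, 3)]
        curve = moment_curve(make_traj(pts), q_grid=[2.0], max_tau_fraction=0.3)
        j1 = list(curve.tau_grid).index(1)
        j2 = list(curve.tau_grid).index(2)
        assert curve.moments[0, j1] == pytest.approx(1.0)
        assert curve.moments[0, j2] == pytest.approx(2.0)

    def test_constant_velocity_moments_analytic(self):
        v = 0.7
        pts = [(v * t, 0.0) for t in range(40)]
        curve = moment_curve(make_traj(pts))
        for i, q in enumerate(curve.q_grid):
            np.testing.assert_allclose(
                curve.moments[i], (v * curve.tau_grid) ** q, rtol=1e-12
            )

    def test_stationary_path_flagged_degenerate(self):
        curve = moment_curve(make_traj([(1, 1)] * 10))
        assert curve.degenerate
        assert np.all(curve.moments == 0.0)

    def test_too_short_trajectory(self):
        with pytest.raises(InsufficientDataError):
            moment_curve(make_traj([(i, 0) for i in range(7)]))

    def test_matches_brute_force_oracle(self, rng):
        """All-pairs overlapping average equals an explicit double loop."""
        q_grid = [0.5, 1.0, 2.0, 3.0]
        for _ in range(100):
            n = rng.integers(8, 51)
            pts = rng.normal(size=(n, 2)).cumsum(axis=0)
            curve = moment_curve(make_traj(pts), q_grid=q_grid)
            expected = brute_force_moments(pts, q_grid, list(curve.tau_grid))
            np.testing.assert_allclose(curve.moments, expected, atol=1e-10, rtol=1e-10)

    def test_tau_grid_log_spaced_unique_integers(self):
        taus = log_spaced_taus(200, 12, 0.25)
        assert np.all(taus == np.unique(taus))
        assert taus[0] == 1 and taus[-1] == 50
        assert np.issubdtype(taus.dtype, np.integer)


class TestZetaExponents:
    def test_constant_velocity_gives_zeta_q(self):
        pts = [(1.3 * t, 0.9 * t) for t in range(100)]
        zf = zeta_exponents(moment_curve(make_traj(pts)))
        np.testing.assert_allclose(zf.zeta, zf.q_grid, atol=1e-9)
        assert zf.slope == pytest.approx(1.0, abs=1e-9)

    def test_synthetic_half_scaling_recovered_exactly(self):
        q = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        taus = np.array([1, 2, 4, 8, 16, 32])
        M = taus[None, :].astype(float) ** (q[:, None] / 2.0)
        curve = MomentCurve(q_grid=q, tau_grid=taus, moments=M,
                            n_pairs=np.full(taus.size, 100))
        zf = zeta_exponents(curve)
        np.testing.assert_allclose(zf.zeta, q / 2, atol=1e-12)
        assert zf.slope == pytest.approx(0.5, abs=1e-12)

    def test_zero_moment_taus_dropped_with_record(self):
        q = np.array([1.0])
        taus = np.array([1, 2, 4, 8, 16])
        M = taus[None, :].astype(float)
        M[0, 2] = 0.0
        zf = zeta_exponents(MomentCurve(q, taus, M, np.full(5, 10)))
        assert zf.dropped_taus == {1.0: [4]}
        assert zf.zeta[0] == pytest.approx(1.0)

    def test_fewer_than_three_taus_gives_nan(self):
        q = np.array([1.0, 2.0])
        taus = np.array([1, 2, 4])
        M = np.vstack([taus.astype(float), taus.astype(float) ** 2])
        M[0, :2] = 0.0  # q=1 keeps only one tau
        zf = zeta_exponents(MomentCurve(q, taus, M, np.full(3, 10)))
        assert np.isnan(zf.zeta[0])
        # summary slope uses the surviving q only: zeta(2) = 2 -> slope 1
        assert zf.zeta[1] == pytest.approx(2.0)
        assert zf.slope == pytest.approx(1.0)

    def test_unit_invariance(self, rng):
        pts = rng.normal(size=(60, 2)).cumsum(axis=0)
        a = zeta_exponents(moment_curve(make_traj(pts)))
        b = zeta_exponents(moment_curve(make_traj(pts * 37.2)))
        np.testing.assert_allclose(a.zeta, b.zeta, atol=1e-10)
        assert a.slope == pytest.approx(b.slope, abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_zeta_nondecreasing_in_q(self, seed):
        """Concavity of moment scaling: zeta(q) never decreases with q."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(120, 2)).cumsum(axis=0)
        zf = zeta_exponents(moment_curve(make_traj(pts)))
        assert np.all(np.diff(zf.zeta) >= -1e-9)

    def test_brownian_slope_half_small_ensemble(self, rng):
        slopes = []
        for _ in range(40):
            pts = rng.normal(size=(501, 2)).cumsum(axis=0)
            slopes.append(zeta_exponents(moment_curve(make_traj(pts))).slope)
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)

    def test_regime_recovery_ordering(self):
        """Brownian < CRW(kappa=5) < ballistic slopes, correctly ordered."""
        n_rep, n_steps = 40, 200
        slopes = {}
        for i, (model, kw) in enumerate([
            ("brownian", {}),
            ("crw", {"persistence": 5.0}),
            ("ballistic", {}),
        ]):
            vals = [
                zeta_slope(simulate_trajectory(SimulationConfig(
                    model=model, n_steps=n_steps, seed=1000 * i + r, **kw)))
                for r in range(n_rep)
            ]
            slopes[model] = np.asarray(vals)
        ordered = (slopes["brownian"] < slopes["crw"]) & (
            slopes["crw"] < slopes["ballistic"]
        )
        assert ordered.mean() >= 0.95
        assert np.median(slopes["crw"]) > np.median(slopes["brownian"])
        assert np.median(slopes["crw"]) < np.median(slopes["ballistic"])


class TestClassifyDiffusion:
    @pytest.mark.parametrize(
        "slope, label",
        [
            (0.5, "brownian"),
            (1.0, "ballistic"),
            (0.75, "superdiffusive"),
            (0.3, "subdiffusive"),
            (0.449, "subdiffusive"),
            (0.54, "brownian"),
            (0.951, "ballistic"),
            (1.2, "ballistic"),
        ],
    )
    def test_band_taxonomy(self, slope, label):
        assert classify_diffusion(slope).label == label

    def test_nonfinite_slope_rejected(self):
        with pytest.raises(ValueError):
            classify_diffusion(float("nan"))

    def test_band_halfwidth_bounds(self):
        with pytest.raises(ValueError):
            classify_diffusion(0.5, band_halfwidth=0.3)
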