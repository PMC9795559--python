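"""Area per lipid, equilibration detection, unwrapping, MSD, and diffusion."""

import numpy as np
import pytest

import bilayerlab as bl
from bilayerlab.area_dynamics import default_lag_grid
from bilayerlab.exceptions import DomainError
from bilayerlab.synthetic_data import BrownianModel, gen_brownian_bilayer

from conftest import make_frames


def area_series(values, dt=10.0):
    n = len(values)
    frames = bl.FrameSeries(
        times=np.arange(n) * dt,
        coords=np.zeros((n, 1, 3)) + 1.0,
        box=np.column_stack([np.sqrt(values) , np.sqrt(values), np.full(n, 5.0)]),
    )
    return bl.area_per_lipid(frames, 1)


class TestAreaPerLipid:
    def test_arithmetic(self):
        frames = make_frames(np.ones((1, 1, 3)), box=(8.0, 8.0, 5.0))
        series = bl.area_per_lipid(frames, 100)
        assert series.a_l[0] == pytest.approx(0.64)

    def test_linearity_in_area_and_inverse_in_leaflet_count(self):
        frames = make_frames(np.ones((1, 1, 3)), box=(6.0, 4.0, 5.0))
        a100 = bl.area_per_lipid(frames, 100).a_l[0]
        a50 = bl.area_per_lipid(frames, 50).a_l[0]
        assert a50 == pytest.approx(2 * a100)
        doubled = make_frames(np.ones((1, 1, 3)), box=(12.0, 4.0, 5.0))
        assert bl.area_per_lipid(doubled, 100).a_l[0] == pytest.approx(2 * a100)

    def test_constant_box_constant_series(self):
        frames = make_frames(np.ones((5, 1, 3)), box=(7.0, 7.0, 5.0))
        series = bl.area_per_lipid(frames, 100)
        assert np.all(series.a_l == series.a_l[0])

    def test_nonpositive_leaflet_count_rejected(self):
        frames = make_frames(np.ones((1, 1, 3)))
        with pytest.raises(DomainError):
            bl.area_per_lipid(frames, 0)


class TestEquilibrationWindow:
    def test_constant_series_full_window(self):
        series = area_series(np.full(200, 0.64))
        w = bl.equilibration_window(series)
        assert w.equilibrated
        assert w.t_start == series.times[0] and w.t_end == series.times[-1]

    def test_changepoint_detected_within_ten_percent(self):
        rng = np.random.default_rng(5)
        n = 1000
        change = n // 2
        values = np.concatenate(
            [
                np.linspace(0.75, 0.64, change),
                np.full(n - change, 0.64),
            ]
        ) + rng.normal(0, 0.002, n)
        series = area_series(values)
        w = bl.equilibration_window(series, tolerance_sd=1.0)
        assert w.equilibrated
        true_t = series.times[change]
        span = series.times[-1] - series.times[0]
        assert abs(w.t_start - true_t) <= 0.1 * span

    def test_monotone_drift_flags_non_equilibrated(self):
        values = np.linspace(0.60, 0.75, 500)
        series = area_series(values)
        w = bl.equilibration_window(series)
        assert not w.equilibrated

    def test_short_series_rejected(self):
        series = area_series(np.full(50, 0.6))
        with pytest.raises(DomainError):
            bl.equilibration_window(series)


class TestWindowedAnalysis:
    def _frames_of_span(self, span_ns, dt_ps=100.0):
        n = int(span_ns * 1000 / dt_ps) + 1
        return make_frames(np.ones((n, 1, 3)), dt=dt_ps)

    def test_ten_times_100ns_parts(self):
        windows = bl.windowed_analysis(self._frames_of_span(1000), 100.0)
        assert len(windows) == 10
        assert windows[0].t_start == 0.0
        assert windows[-1].t_end == pytest.approx(1_000_000.0)

    def test_single_full_window(self):
        windows = bl.windowed_analysis(self._frames_of_span(1000), 1000.0)
        assert len(windows) == 1

    def test_remainder_dropped(self):
        windows = bl.windowed_analysis(self._frames_of_span(950), 100.0)
        assert len(windows) == 9
        assert windows[-1].t_end == pytest.approx(900_000.0)

    def test_bad_window_length(self):
        with pytest.raises(DomainError):
            bl.windowed_analysis(self._frames_of_span(100), 0.0)


class TestComTrajectories:
    def _single_atom_lipids(self, coords, box=(4.0, 4.0, 4.0)):
        n = coords.shape[1]
        atoms = [bl.AtomRecord(i, "P", "P", 720.0, 15) for i in range(n)]
        topo = bl.BilayerTopology(atoms=atoms, leaflet={i: "upper" for i in range(n)}, n_lipids=n)
        return topo, make_frames(coords, box=box)

    def test_stationary_lipids_constant_paths(self):
        coords = np.tile(np.array([[[1.0, 2.0, 1.0]]]), (5, 1, 1))
        topo, frames = self._single_atom_lipids(coords)
        paths = bl.com_trajectories(frames, topo)
        assert np.all(paths == paths[0])

    def test_boundary_crossing_unwrapped(self):
        # atom walks +0.3 nm/frame through the +x boundary of a 4 nm box
        x = 3.0 + 0.3 * np.arange(8)
        coords = np.zeros((8, 1, 3))
        coords[:, 0, 0] = np.mod(x, 4.0)
        coords[:, 0, 1] = 1.0
        topo, frames = self._single_atom_lipids(coords)
        paths = bl.com_trajectories(frames, topo)
        np.testing.assert_allclose(paths[:, 0, 0], x, atol=1e-12)

    def test_rewrapping_recovers_wrapped_input(self):
        rng = np.random.default_rng(2)
        steps = rng.normal(0, 0.3, (20, 3, 2))
        xy = np.cumsum(steps, axis=0) + 2.0
        coords = np.zeros((20, 3, 3))
        coords[:, :, :2] = np.mod(xy, 4.0)
        coords[:, :, 2] = 1.0
        topo, frames = self._single_atom_lipids(coords)
        paths = bl.com_trajectories(frames, topo)
        np.testing.assert_allclose(np.mod(paths, 4.0), coords[:, :, :2], atol=1e-9)

    def test_common_drift_removed(self):
        model = BrownianModel(d_true=1e-12, n_lipids=10, n_frames=200, dt=100.0, seed=7)
        topo, frames, _ = gen_brownian_bilayer(model)
        drifted = BrownianModel(
            d_true=1e-12, n_lipids=10, n_frames=200, dt=100.0, seed=7, drift=(2e-4, -1e-4)
        )
        topo_d, frames_d, _ = gen_brownian_bilayer(drifted)
        p0 = bl.com_trajectories(frames, topo, remove_system_com=True)
        p1 = bl.com_trajectories(frames_d, topo_d, remove_system_com=True)
        m0 = bl.lateral_msd(p0, frames.times, n_subgroups=5)
        m1 = bl.lateral_msd(p1, frames_d.times, n_subgroups=5)
        np.testing.assert_allclose(m1.msd, m0.msd, atol=1e-9)


def brute_force_msd(paths, lag_steps):
    """Naive double loop over time origins — the reference estimator."""
    n_frames, n_lipids, _ = paths.shape
    out = np.zeros(len(lag_steps))
    for i, m in enumerate(lag_steps):
        if m == 0:
            continue
        acc = 0.0
        count = 0
        for t0 in range(n_frames - m):
            for lip in range(n_lipids):
                d = paths[t0 + m, lip] - paths[t0, lip]
                acc += d @ d
                count += 1
        out[i] = acc / count
    return out


class TestLateralMSD:
    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(9)
        paths = np.cumsum(rng.normal(0, 0.1, (50, 5, 2)), axis=0)
        times = np.arange(50) * 100.0
        lags_ns = np.array([0.0, 0.1, 0.5, 1.0, 2.0])
        curve = bl.lateral_msd(paths, times, lag_grid=lags_ns, n_subgroups=5)
        ref = brute_force_msd(paths, [0, 1, 5, 10, 20])
        np.testing.assert_allclose(curve.msd, ref, atol=1e-12)

    def test_stationary_lipids_zero_msd(self):
        paths = np.ones((30, 10, 2))
        curve = bl.lateral_msd(paths, np.arange(30) * 10.0, n_subgroups=5)
        assert np.all(curve.msd == 0.0)
        assert np.all(curve.sem == 0.0)

    def test_subgroup_split_sizes(self):
        paths = np.zeros((10, 200, 2))
        curve = bl.lateral_msd(paths, np.arange(10) * 10.0, n_subgroups=5)
        assert curve.subgroup_msd.shape[1] == 5  # 5 groups of 40

    def test_indivisible_split_names_counts(self):
        paths = np.zeros((10, 7, 2))
        with pytest.raises(DomainError, match="7"):
            bl.lateral_msd(paths, np.arange(10) * 10.0, n_subgroups=5)

    def test_einstein_relation_on_brownian_walks(self):
        model = BrownianModel(d_true=5e-12, n_lipids=100, n_frames=2000, dt=100.0, seed=13)
        topo, frames, _ = gen_brownian_bilayer(model)
        paths = bl.com_trajectories(frames, topo)
        curve = bl.lateral_msd(paths, frames.times)
        expected = 4 * 5e-12 * 1e6 * curve.lags * 1000.0  # nm^2, lag in ns
        mask = (curve.lags > 0) & (curve.lags <= 50.0)
        assert np.all(
            np.abs(curve.msd[mask] - expected[mask]) <= 3 * curve.sem[mask] + 1e-6
        )


class TestFitDiffusion:
    def _line_curve(self, d_si, sem=0.0, lags=None):
        if lags is None:
            lags = np.linspace(10, 60, 11)
        slope = 4 * d_si / 1e-9  # nm^2/ns
        msd = slope * lags
        return bl.MSDCurve(
            lags=lags,
            msd=msd,
            sem=np.full_like(lags, sem),
            n_subgroups=5,
        )

    def test_exact_line_recovered(self):
        curve = self._line_curve(1e-12)
        est = bl.fit_diffusion(curve, (10.0, 60.0))
        assert est.d == pytest.approx(1e-12, rel=1e-12)
        assert est.d_low == pytest.approx(est.d, rel=1e-9)
        assert est.d_high == pytest.approx(est.d, rel=1e-9)

    def test_band_width_monotone_in_sem(self):
        widths = []
        for eps in (0.001, 0.01, 0.05):
            est = bl.fit_diffusion(self._line_curve(1e-12, sem=eps), (10.0, 60.0))
            widths.append(est.d_high - est.d_low)
        assert widths[0] < widths[1] < widths[2]

    def test_band_matches_brute_force_line_search(self):
        rng = np.random.default_rng(3)
        lags = np.linspace(10, 60, 8)
        msd = np.abs(0.02 * lags + rng.normal(0, 0.004, lags.size))
        sem = np.full(lags.size, 0.02)
        curve = bl.MSDCurve(lags=lags, msd=msd, sem=sem, n_subgroups=5)
        est = bl.fit_diffusion(curve, (10.0, 60.0))
        # brute force: scan slope/intercept grid for feasible lines
        slopes = np.linspace(0.0, 0.05, 2001)
        feasible = []
        for s in slopes:
            b_lo = np.max(msd - sem - s * lags)
            b_hi = np.min(msd + sem - s * lags)
            if b_lo <= b_hi + 1e-12:
                feasible.append(s)
        assert min(feasible) * 0.25e-9 == pytest.approx(est.d_low, abs=2e-14)
        assert max(feasible) * 0.25e-9 == pytest.approx(est.d_high, abs=2e-14)

    def test_too_few_lags_rejected(self):
        curve = self._line_curve(1e-12, lags=np.array([10.0, 20.0, 30.0]))
        with pytest.raises(DomainError):
            bl.fit_diffusion(curve, (25.0, 30.0))

    def test_default_lag_grid_caps_at_half_span(self):
        grid = default_lag_grid(1000, 0.1)
        assert grid[0] == 0.0
        assert grid[-1] <= 1000 * 0.1 / 2 + 1e-9
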