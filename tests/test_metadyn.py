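"""Langevin sampling, hill deposition and free-energy reconstruction."""

import numpy as np
import pytest
import scipy.stats as st

import torsionkit as tk
from torsionkit.constants import KB_KCAL, KJ_PER_KCAL
from torsionkit.metadyn import averaged_pmf, bias_potential
from torsionkit.model import DihedralSeries, DihedralTerm


def boltzmann_bin_probs(potential, edges, kT, n_quad=20001):
    xs = np.linspace(-np.pi, np.pi, n_quad)
    dens = np.exp(-tk.evaluate_series(potential, xs) / kT)
    probs = []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (xs >= a) & (xs <= b)
        probs.append(np.trapezoid(dens[m], xs[m]))
    probs = np.asarray(probs)
    return probs / probs.sum()


class TestUnbiasedLangevin:
    def test_flat_potential_samples_uniformly(self):
        flat = DihedralSeries((DihedralTerm(0.0, 1, 0.0),))
        cfg = tk.MetaDConfig(height_kj=0.0, n_steps=2_000_000, seed=1,
                             record_stride=2000)
        traj, hills = tk.run_wtmetad(flat, cfg)
        assert len(hills) == 0
        edges = np.linspace(-np.pi, np.pi, 13)
        obs, _ = np.histogram(traj.positions, bins=edges)
        n, p = obs.sum(), 1.0 / 12
        sd = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(obs - n * p) < 3 * sd + 3)

    def test_boltzmann_distribution_chi2(self):
        """Stationary distribution matches exp(-U/kT)/Z by quadrature."""
        pot = DihedralSeries((DihedralTerm(0.5, 1, 0.0),))
        cfg = tk.MetaDConfig(height_kj=0.0, n_steps=12_000_000, seed=3,
                             record_stride=10_000, x0=np.pi / 2)
        traj, _ = tk.run_wtmetad(pot, cfg)
        edges = np.linspace(-np.pi, np.pi, 25)
        p = boltzmann_bin_probs(pot, edges, cfg.kT)
        obs, _ = np.histogram(traj.positions, bins=edges)
        _, pval = st.chisquare(obs, p * obs.sum())
        assert pval > 0.01

    def test_occupancy_mean_matches_quadrature(self):
        """Circular mean of an asymmetric single well vs Boltzmann average."""
        pot = DihedralSeries((DihedralTerm(1.5, 1, 0.7), DihedralTerm(0.8, 2, 0.3)))
        cfg = tk.MetaDConfig(height_kj=0.0, n_steps=4_000_000, seed=8,
                             record_stride=2000, x0=0.7)
        traj, _ = tk.run_wtmetad(pot, cfg)
        mean, std, _ = tk.torsion_occupancy_stats(traj, (-np.pi, np.pi))
        xs = np.linspace(-np.pi, np.pi, 40001)
        dens = np.exp(-tk.evaluate_series(pot, xs) / cfg.kT)
        ref_mean = np.angle(np.trapezoid(dens * np.exp(1j * xs), xs))
        assert abs(tk.wrap_angle(mean - ref_mean)) < 0.05
        assert std > 0


class TestOccupancyStats:
    def test_constant_positions(self):
        traj = tk.SamplerTrajectory(np.arange(5.0), np.full(5, 0.5), np.zeros(5))
        mean, std, frac = tk.torsion_occupancy_stats(traj, (0.4, 0.6))
        assert mean == pytest.approx(0.5)
        assert std == pytest.approx(0.0, abs=1e-8)
        assert frac == 1.0

    def test_uniform_positions_window_fraction(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-np.pi, np.pi, 200_000)
        traj = tk.SamplerTrajectory(np.arange(x.size, dtype=float), x, np.zeros_like(x))
        _, _, frac = tk.torsion_occupancy_stats(traj, (-1.0, 1.0))
        assert frac == pytest.approx(2.0 / (2 * np.pi), abs=0.01)
        # wrapped window through the boundary
        _, _, frac = tk.torsion_occupancy_stats(traj, (2.5, -2.5))
        assert frac == pytest.approx((2 * np.pi - 5.0) / (2 * np.pi), abs=0.01)


class TestBiasReconstruction:
    def test_single_hill_closed_form(self):
        hills = tk.HillsLog([1.0], [0.3], [0.05], [0.02])
        at_center = bias_potential(hills, [0.3])[0]
        far = bias_potential(hills, [0.3 + np.pi])[0]
        assert at_center == pytest.approx(0.02)
        assert far == 0.0
        gamma = 15.0
        # F depth at the center vs far field is (gamma/(gamma-1)) * h
        grid = np.sort(np.append(np.linspace(-np.pi, np.pi, 360, endpoint=False), 0.3))
        F = tk.reconstruct_pmf(hills, gamma, grid)
        depth = F.energies.max() - F.energies.min()
        assert depth == pytest.approx(gamma / (gamma - 1.0) * 0.02, rel=1e-6)

    def test_bias_is_linear_in_hills(self):
        two = tk.HillsLog([1.0, 2.0], [0.3, 0.3], [0.05, 0.05], [0.02, 0.02])
        one = tk.HillsLog([1.0], [0.3], [0.05], [0.02])
        x = np.linspace(-np.pi, np.pi, 100)
        assert bias_potential(two, x) == pytest.approx(2 * bias_potential(one, x))

    def test_gamma_must_exceed_one(self):
        hills = tk.HillsLog([1.0], [0.0], [0.05], [0.02])
        with pytest.raises(ValueError, match="gamma"):
            tk.reconstruct_pmf(hills, 1.0, np.linspace(-np.pi, np.pi, 10, endpoint=False))


class TestWellTemperedRun:
    def test_heights_obey_tempering_identity(self, double_well_metad_run):
        """h_i = w0 * exp(-V(c_i)/(kB*(gamma-1)*T)), recomputable from the log."""
        _, config, _, hills = double_well_metad_run
        w0 = config.height_kcal
        dkT = config.delta_kT
        for i in (1, 10, len(hills) // 2, len(hills) - 1):
            prior = hills.upto(hills.times[i - 1])
            v = bias_potential(prior, [hills.centers[i]])[0]
            assert hills.heights[i] == pytest.approx(w0 * np.exp(-v / dkT), rel=1e-9)

    def test_heights_bounded_and_decaying_in_wells(self, double_well_metad_run):
        _, config, _, hills = double_well_metad_run
        assert np.all(hills.heights <= config.height_kcal + 1e-12)
        # in the late tempered regime hills have shrunk substantially
        assert hills.heights[-100:].max() < 0.5 * config.height_kcal

    def test_recovers_double_well_within_03_kcal(self, double_well_metad_run):
        potential, config, _, hills = double_well_metad_run
        grid = np.linspace(-np.pi, np.pi, 360, endpoint=False)
        rec = averaged_pmf(hills, config.biasfactor, grid)
        truth = tk.evaluate_series(potential, grid)
        truth -= truth.min()
        assert np.max(np.abs(rec.energies - truth)) < 0.3

    def test_same_seed_bit_identical(self):
        pot = DihedralSeries((DihedralTerm(1.0, 2, 0.0),))
        cfg = tk.MetaDConfig(height_kj=0.5, sigma=0.1, biasfactor=10.0, pace=200,
                             n_steps=100_000, seed=21, record_stride=500)
        t1, h1 = tk.run_wtmetad(pot, cfg)
        t2, h2 = tk.run_wtmetad(pot, cfg)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(h1.centers, h2.centers)
        assert np.array_equal(h1.heights, h2.heights)

    def test_large_biasfactor_is_standard_metad(self):
        """gamma -> inf: heights stay ~w0 (relative decay < 1% over 100 hills)."""
        flat = DihedralSeries((DihedralTerm(0.0, 1, 0.0),))
        cfg = tk.MetaDConfig(height_kj=0.1, sigma=0.05, biasfactor=1e6, pace=100,
                             n_steps=10_000, seed=2, record_stride=100)
        _, hills = tk.run_wtmetad(flat, cfg)
        assert len(hills) == 100
        assert hills.heights.min() > 0.99 * cfg.height_kcal

    def test_non_periodic_tabulated_potential_rejected(self):
        x = np.linspace(-np.pi, np.pi, 100, endpoint=False)
        ramp = tk.TorsionProfile(x, 2.0 * x)  # not periodic
        cfg = tk.MetaDConfig(height_kj=0.0, n_steps=1000)
        with pytest.raises(ValueError, match="not periodic"):
            tk.run_wtmetad(ramp, cfg)

    def test_tabulated_potential_matches_series(self):
        """A tabulated copy of a series samples the same distribution."""
        pot = DihedralSeries((DihedralTerm(0.8, 2, 0.0),))
        grid = np.linspace(-np.pi, np.pi, 240, endpoint=False)
        tab = tk.series_profile(pot, grid)
        cfg = tk.MetaDConfig(height_kj=0.0, n_steps=1_000_000, seed=6,
                             record_stride=1000)
        traj_s, _ = tk.run_wtmetad(pot, cfg)
        traj_t, _ = tk.run_wtmetad(tab, cfg)
        edges = np.linspace(-np.pi, np.pi, 13)
        h_s, _ = np.histogram(traj_s.positions, bins=edges)
        h_t, _ = np.histogram(traj_t.positions, bins=edges)
        assert np.abs(h_s - h_t).max() < 5 * np.sqrt(h_s.max())


class TestConvergence:
    def test_final_checkpoint_deviation_zero(self, double_well_metad_run):
        _, config, _, hills = double_well_metad_run
        grid = np.linspace(-np.pi, np.pi, 180, endpoint=False)
        out = tk.convergence_series(hills, config.biasfactor, grid, [hills.times[-1]])
        assert out[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_deviation_eventually_non_increasing(self, double_well_metad_run):
        _, config, _, hills = double_well_metad_run
        grid = np.linspace(-np.pi, np.pi, 180, endpoint=False)
        cps = np.linspace(0.2, 1.0, 9) * hills.times[-1]
        out = tk.convergence_series(hills, config.biasfactor, grid, cps)
        devs = [d for _, _, d in out]
        assert devs[-1] <= devs[-2] <= devs[-3]

    def test_converged_run_final_deviation_small(self, double_well_metad_run):
        """On a decile checkpoint ladder, the last pre-final deviation of a
        full-length run stays below 0.2 kcal/mol."""
        _, config, _, hills = double_well_metad_run
        grid = np.linspace(-np.pi, np.pi, 180, endpoint=False)
        cps = np.linspace(0.1, 1.0, 10) * hills.times[-1]
        out = tk.convergence_series(hills, config.biasfactor, grid, cps)
        assert out[-1][2] == pytest.approx(0.0, abs=1e-12)
        assert out[-2][2] < 0.2

    def test_checkpoints_outside_range_rejected(self, double_well_metad_run):
        _, config, _, hills = double_well_metad_run
        grid = np.linspace(-np.pi, np.pi, 90, endpoint=False)
        with pytest.raises(ValueError, match="within the hills time range"):
            tk.convergence_series(hills, config.biasfactor, grid, [hills.times[-1] + 1.0])
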