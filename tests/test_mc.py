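"""Confined worm-like-chain Monte Carlo: invariants, oracles, limits."""

import numpy as np
import pytest
from scipy import integrate, stats

from nucleocompact import mc
from nucleocompact._mc_kernels import bend_angles
from nucleocompact.mc import Channel, MoveParams


def sample_statistic(chain, channel, n_chunks, sweeps_per_chunk, seed, stat):
    """Run in chunks and evaluate ``stat(chain)`` after each chunk."""
    out = []
    for k in range(n_chunks):
        mc.run(
            chain,
            channel,
            sweeps_per_chunk,
            seed=seed * 100_000 + k,
            warn_acceptance=False,
            move_params=MoveParams(tune_sweeps=0),
        )
        out.append(stat(chain))
    return np.asarray(out)


class TestInitChain:
    def test_bond_lengths_exact(self):
        for init in ("straight", "grow"):
            ch = mc.init_chain(1000.0, 5.0, Channel(150, 250), init=init, seed=1)
            bonds = np.linalg.norm(np.diff(ch.beads, axis=0), axis=1)
            np.testing.assert_allclose(bonds, 5.0, atol=1e-9)
            assert len(ch.beads) == 201

    def test_grown_chain_inside_walls_and_overlap_free(self):
        ch = mc.init_chain(
            2000.0, 5.0, Channel(100, 150), effective_width_nm=5.0, init="grow", seed=3
        )
        assert np.all(np.abs(ch.beads[:, 0]) <= 50.0)
        assert np.all(np.abs(ch.beads[:, 1]) <= 75.0)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(ch.beads))
        ii, jj = np.triu_indices(len(ch.beads), k=2)
        assert d[ii, jj].min() >= 5.0 - 1e-9

    def test_different_seeds_differ_same_bond_spectrum(self):
        c1 = mc.init_chain(500.0, 5.0, Channel(200, 300), seed=1)
        c2 = mc.init_chain(500.0, 5.0, Channel(200, 300), seed=2)
        assert not np.allclose(c1.beads, c2.beads)
        b1 = np.linalg.norm(np.diff(c1.beads, axis=0), axis=1)
        b2 = np.linalg.norm(np.diff(c2.beads, axis=0), axis=1)
        np.testing.assert_allclose(b1, b2, atol=1e-9)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            mc.init_chain(100.0, 200.0, Channel(150, 250))
        with pytest.raises(ValueError):
            mc.init_chain(1000.0, 200.0, Channel(150, 250))


class TestRunInvariants:
    def test_bonds_walls_and_excluded_volume_hold_every_sweep(self):
        channel = Channel(100, 150)
        ch = mc.init_chain(
            400.0, 5.0, channel, persistence_nm=50.0, effective_width_nm=5.0, seed=2
        )
        # check_invariants asserts bond lengths, walls and hard cores per sweep
        traj, info = mc.run(
            ch, channel, 40, seed=9, check_invariants=True, warn_acceptance=False
        )
        assert len(traj) == 40
        assert 0 < info["acceptance_reptation"] <= 1.0

    def test_same_seed_reproduces_trajectory(self):
        channel = Channel(200, 300)
        t1, _ = mc.run(
            mc.init_chain(500.0, 5.0, channel, seed=4), channel, 60, seed=77,
            warn_acceptance=False,
        )
        t2, _ = mc.run(
            mc.init_chain(500.0, 5.0, channel, seed=4), channel, 60, seed=77,
            warn_acceptance=False,
        )
        np.testing.assert_array_equal(t1, t2)


class TestUnconfinedStatistics:
    def test_mean_square_end_to_end_matches_closed_form(self):
        """<R_ee^2> agrees with the discrete WLC closed form within 3 SE."""
        n_bonds, b, P = 80, 5.0, 50.0
        ch = mc.init_chain(n_bonds * b, b, None, persistence_nm=P, init="straight")
        mc.run(ch, None, 300, seed=5, warn_acceptance=False)  # equilibrate
        r2 = sample_statistic(
            ch, None, 250, 4, seed=6, stat=lambda c: float(np.sum((c.beads[-1] - c.beads[0]) ** 2))
        )
        se = mc.blocking_stderr(r2)
        c = mc.mean_cos_quadratic(P / (2 * b))
        expected = mc.discrete_chain_mean_square_ee(n_bonds, b, c)
        assert abs(r2.mean() - expected) < 3 * se
        # and the continuous WLC form evaluated at the chain's effective P
        P_eff = mc.effective_persistence(b, P_nm=P)
        assert abs(r2.mean() - mc.wlc_mean_square_ee(n_bonds * b, P_eff)) < 3.5 * se

    def test_rigid_rod_limit_extension_equals_contour(self):
        # a free rod tumbles, so the axial span is only pinned to L when a
        # narrow channel keeps the rod aligned
        channel = Channel(50, 50)
        ch = mc.init_chain(500.0, 5.0, channel, persistence_nm=1e5, init="straight")
        traj, _ = mc.run(ch, channel, 300, seed=8, warn_acceptance=False)
        est = mc.mean_extension(traj)
        assert est.mean_extension_nm == pytest.approx(500.0, rel=0.02)

    @pytest.mark.parametrize("seed", range(10))
    def test_bend_angle_distribution_is_boltzmann(self, seed):
        """Joint angles follow sin(t) exp(-P t^2 / (2b)) (KS, 10 seeds)."""
        n_bonds, b, P = 50, 5.0, 50.0
        kappa = P / (2 * b)
        ch = mc.init_chain(n_bonds * b, b, None, persistence_nm=P, init="grow", seed=seed)
        samples = []
        for k in range(8):
            mc.run(ch, None, 40, seed=seed * 1000 + k, warn_acceptance=False,
                   move_params=MoveParams(tune_sweeps=0))
            samples.append(bend_angles(ch.beads, b))
        pooled = np.concatenate(samples)
        t = np.linspace(0, np.pi, 2001)
        pdf = np.sin(t) * np.exp(-kappa * t * t)
        cdf = integrate.cumulative_trapezoid(pdf, t, initial=0.0)
        cdf /= cdf[-1]
        res = stats.kstest(pooled, lambda x: np.interp(x, t, cdf))
        assert res.pvalue > 0.01


class TestConfinedBehaviour:
    def test_narrower_channel_stretches_self_avoiding_chain(self):
        means = {}
        for w in (150.0, 300.0):
            vals = []
            for seed in (1, 2):
                ch = mc.init_chain(
                    1500.0, 5.0, Channel(w, 300), persistence_nm=50.0,
                    effective_width_nm=5.0, seed=seed,
                )
                traj, _ = mc.run(ch, Channel(w, 300), 2000, seed=seed, warn_acceptance=False)
                vals.append(mc.mean_extension(traj).mean_extension_nm)
            means[w] = np.mean(vals)
        assert means[150.0] > means[300.0]

    def test_extension_independent_of_discretization(self):
        channel = Channel(200, 300)
        est = {}
        for seg in (2.5, 5.0, 10.0):
            vals, errs = [], []
            for seed in (3, 4):
                ch = mc.init_chain(1500.0, seg, channel, persistence_nm=50.0, seed=seed)
                traj, _ = mc.run(ch, channel, 2500, seed=seed, warn_acceptance=False)
                e = mc.mean_extension(traj)
                vals.append(e.mean_extension_nm)
                errs.append(e.stderr_nm)
            est[seg] = (np.mean(vals), np.sqrt(np.sum(np.square(errs))) / len(errs))
        segs = list(est)
        for a in range(len(segs)):
            for b_ in range(a + 1, len(segs)):
                (m1, s1), (m2, s2) = est[segs[a]], est[segs[b_]]
                assert abs(m1 - m2) < 3.5 * np.hypot(s1, s2) + 0.05 * max(m1, m2)


class TestMeanExtension:
    def test_constant_trajectory_zero_stderr(self):
        est = mc.mean_extension(np.full(100, 7.0), burn_in=10)
        assert est.stderr_nm == 0.0
        assert est.mean_extension_nm == 7.0
        assert est.stationary

    def test_straight_rod_spans_contour(self):
        ch = mc.init_chain(800.0, 5.0, None, init="straight")
        assert np.ptp(ch.beads[:, 2]) == pytest.approx(800.0, abs=1e-9)

    def test_blocking_recovers_ar1_error(self):
        rng = np.random.default_rng(12)
        phi, n = 0.9, 8192
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(0, 1, n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        se_blocking = mc.blocking_stderr(x)
        var_x = 1.0 / (1 - phi**2)
        se_true = np.sqrt(var_x * (1 + phi) / (1 - phi) / n)
        assert se_blocking == pytest.approx(se_true, rel=0.3)

    def test_burn_in_longer_than_trajectory_rejected(self):
        with pytest.raises(ValueError):
            mc.mean_extension(np.ones(10), burn_in=10)


class TestStretchChange:
    def test_no_change_gives_zero_within_error(self):
        res = mc.stretch_change_experiment(
            Channel(200, 300), 1000.0, 50.0, 50.0, 0.0, seeds=[1, 2],
            n_sweeps=1200, effective_width_nm=5.0,
        )
        assert abs(res.decrease_pct) < max(3 * res.stderr_pct, 8.0)

    def test_halving_contour_halves_near_rod_extension(self):
        res = mc.stretch_change_experiment(
            Channel(50, 50), 500.0, 1e5, 1e5, 0.5, seeds=[3],
            n_sweeps=400, effective_width_nm=0.0,
        )
        assert res.decrease_pct == pytest.approx(50.0, abs=3.0)
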