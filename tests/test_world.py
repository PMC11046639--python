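import numpy as np
import pytest

from flockinf.cli_io import RunConfig, make_fixture
from flockinf.generative_model import ModelParams
from flockinf.world import (
    SensoryFrame,
    SwarmState,
    assign_sectors,
    init_state,
    observe,
    run,
    run_simulation,
    sense_all,
    step,
    true_hidden_state,
)

from conftest import random_scene


def pair_state(d=3.0, params=None):
    params = params or ModelParams()
    pos = np.array([[0.0, 0.0], [d, 0.0]])
    head = np.array([[0.0, 1.0], [0.0, 1.0]])
    mu = np.zeros((2, params.L, params.n_orders_x))
    xh, _, mask, _ = sense_all(pos, head, params)
    mu[:, :, 0] = np.where(mask, xh, params.eta)
    return SwarmState(pos, head, mu, np.full(2, params.lambda_z), np.zeros(2, bool))


class TestSwarmState:
    def test_rejects_non_unit_headings(self):
        with pytest.raises(ValueError, match="unit"):
            SwarmState(np.zeros((1, 2)), np.array([[1.0, 1.0]]),
                       np.zeros((1, 4, 3)), np.ones(1), np.zeros(1, bool))

    def test_rejects_nonfinite_positions(self):
        with pytest.raises(ValueError):
            SwarmState(np.array([[np.nan, 0.0]]), np.array([[1.0, 0.0]]),
                       np.zeros((1, 4, 3)), np.ones(1), np.zeros(1, bool))

    def test_beliefs_property_shapes(self, rng):
        informed = np.array([True, False, False])
        st = random_scene(rng, 3, informed_mask=informed, target=[5.0, 0.0])
        bels = st.beliefs
        assert bels[0].mu.shape == (5, 3) and bels[0].informed
        assert bels[1].mu.shape == (4, 3) and not bels[1].informed


class TestAssignSectors:
    def test_bearing_zero_in_first_forward_sector(self, params):
        st = pair_state(1.0)
        st.headings[0] = [1.0, 0.0]
        mem = assign_sectors(st, 0, params)
        assert list(mem[2]) == [1]  # sector [0, 60)

    def test_beyond_radius_excluded(self, params):
        st = pair_state(6.0)
        st.headings[0] = [1.0, 0.0]
        mem = assign_sectors(st, 0, params)
        assert all(len(ix) == 0 for ix in mem)

    def test_blind_zone_excluded(self, params):
        st = pair_state(1.0)
        st.headings[0] = [-1.0, 0.0]  # neighbor now at bearing 180
        mem = assign_sectors(st, 0, params)
        assert all(len(ix) == 0 for ix in mem)

    def test_self_excluded(self, params):
        st = pair_state(1.0)
        for l in range(4):
            assert 0 not in assign_sectors(st, 0, params)[l]

    def test_half_open_boundaries(self, params):
        # neighbor exactly at bearing +60 falls in [60, 120), not [0, 60)
        pos = np.array([[0.0, 0.0], [np.cos(np.pi / 3), np.sin(np.pi / 3)]])
        head = np.array([[1.0, 0.0], [1.0, 0.0]])
        st = SwarmState(pos, head, np.zeros((2, 4, 3)), np.ones(2), np.zeros(2, bool))
        mem = assign_sectors(st, 0, params)
        assert list(mem[3]) == [1] and len(mem[2]) == 0

    def test_matches_vectorized_sensing(self, rng, params):
        for _ in range(10):
            st = random_scene(rng, 12)
            xh_all, xp_all, mask_all, _ = sense_all(st.positions, st.headings, params)
            for focal in range(12):
                mem = assign_sectors(st, focal, params)
                xh, xp, mask = true_hidden_state(st, focal, mem, params)
                assert np.array_equal(mask, mask_all[focal])
                assert np.allclose(xh, xh_all[focal])
                assert np.allclose(xp, xp_all[focal])


class TestTrueHiddenState:
    def test_no_relative_motion(self, params):
        st = pair_state(2.0)
        mem = [np.array([1])] + [np.array([], int)] * 3
        xh, xp, mask = true_hidden_state(st, 0, mem, params)
        assert xh[0] == pytest.approx(2.0)
        assert xp[0] == pytest.approx(0.0)

    def test_radial_separation_rate(self, params):
        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        head = np.array([[0.0, 1.0], [1.0, 0.0]])  # focal moves tangentially
        st = SwarmState(pos, head, np.zeros((2, 4, 3)), np.ones(2), np.zeros(2, bool))
        mem = [np.array([1])] + [np.array([], int)] * 3
        xh, xp, _ = true_hidden_state(st, 0, mem, params)
        # relative velocity (1, -1); radial component along +x is 1
        assert xh[0] == pytest.approx(2.0)
        assert xp[0] == pytest.approx(1.0)

    def test_empty_sector_marked_missing(self, params):
        st = pair_state(1.0)
        _, _, mask = true_hidden_state(st, 0, [np.array([], int)] * 4, params)
        assert not mask.any()

    def test_matches_finite_difference_derivative(self, rng, params):
        # oracle: numerical d(mean distance)/dt with membership held fixed
        for _ in range(10):
            st = random_scene(rng, 5)
            mem = assign_sectors(st, 0, params)
            if all(len(ix) == 0 for ix in mem):
                continue
            xh0, xp0, mask = true_hidden_state(st, 0, mem, params)
            h = 1e-7
            pos2 = st.positions + st.headings * params.speed * h
            st2 = SwarmState(pos2, st.headings, st.mu, st.learned_lambda_z, st.informed_mask)
            xh1, _, _ = true_hidden_state(st2, 0, mem, params)
            for l in range(4):
                if mask[l]:
                    assert xp0[l] == pytest.approx((xh1[l] - xh0[l]) / h, rel=1e-5, abs=1e-5)


class TestObserve:
    def test_noiseless_exact(self, rng):
        p = ModelParams(sigma2_z=0.0, sigma2_zprime=0.0)
        xh, xp = np.array([1.0, 2, 3, 4]), np.array([0.1, 0.2, 0.3, 0.4])
        fr = observe(xh, xp, np.ones(4, bool), p, rng)
        assert np.array_equal(fr.y[:, 0], xh)
        assert np.array_equal(fr.y[:, 1], xp)

    def test_deterministic_given_seed(self, params):
        xh, xp, mask = np.ones(4), np.zeros(4), np.ones(4, bool)
        f1 = observe(xh, xp, mask, params, np.random.default_rng(5))
        f2 = observe(xh, xp, mask, params, np.random.default_rng(5))
        assert np.array_equal(f1.y, f2.y)

    def test_rate_noise_variance(self):
        # 1e5 draws: sample variance of y' - x' within 3 SE of 0.01
        p = ModelParams(sigma2_z=0.0, sigma2_zprime=0.01)
        rng = np.random.default_rng(11)
        n = 25000  # x 4 sectors = 1e5 samples
        resid = np.concatenate([
            observe(np.zeros(4), np.zeros(4), np.ones(4, bool), p, rng).y[:, 1]
            for _ in range(n)
        ])
        var = resid.var()
        se = 0.01 * np.sqrt(2.0 / (len(resid) - 1))
        assert abs(var - 0.01) < 3 * se

    def test_target_observation(self, rng):
        p = ModelParams(sigma2_z=0.0, sigma2_zprime=0.0, sigma2_z_target=0.0)
        fr = observe(np.ones(4), np.zeros(4), np.ones(4, bool), p, rng,
                     target_x=(7.0, -0.5))
        assert np.allclose(fr.y_target, [7.0, -0.5])


class TestStep:
    def test_single_agent_straight_line(self, params):
        p = params.with_(sigma2_z=0.0, sigma2_zprime=0.0, sigma2_a=0.0)
        mu = np.full((1, 4, 3), 0.0)
        mu[:, :, 0] = p.eta
        st = SwarmState(np.zeros((1, 2)), np.array([[1.0, 0.0]]), mu,
                        np.ones(1), np.zeros(1, bool))
        rng = np.random.default_rng(0)
        for _ in range(100):
            st = step(st, p, rng)
        assert np.allclose(st.headings[0], [1.0, 0.0])
        assert st.positions[0, 0] == pytest.approx(100 * p.dt * p.speed)
        assert st.positions[0, 1] == pytest.approx(0.0)

    def test_determinism_bit_identical(self, params):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            st = init_state(10, params, rng)
            for _ in range(50):
                st = step(st, params, rng)
            outs.append((st.positions.copy(), st.headings.copy(), st.mu.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])

    def test_heading_norms_after_steps(self, params, rng):
        st = init_state(20, params, rng)
        for _ in range(50):
            st = step(st, params, rng)
            assert np.allclose(np.linalg.norm(st.headings, axis=1), 1.0, atol=1e-9)

    def test_two_agents_converge_to_eta(self, params):
        # zero noise: stationary spacing within 10% of eta
        p = params.with_(sigma2_z=0.0, sigma2_zprime=0.0, sigma2_a=0.0)
        st = pair_state(3.0, p)
        rng = np.random.default_rng(0)
        rec = run(st, p, 30.0, rng)
        nn = rec.nearest_neighbor_distances()
        assert abs(nn[-1, 0] - p.eta) < 0.1 * p.eta

    def test_nonfinite_belief_raises_with_agent(self, params):
        st = pair_state(3.0)
        st.mu[1] = np.inf
        with pytest.raises(FloatingPointError, match=r"agent\(s\) \[1\]"):
            step(st, params, np.random.default_rng(0))

    def test_equivariance_under_rotation_translation(self, params):
        # zero-noise trajectories co-rotate/translate with the initial scene
        p = params.with_(sigma2_z=0.0, sigma2_zprime=0.0, sigma2_a=0.0)
        rng = np.random.default_rng(3)
        st = random_scene(rng, 6, params=p)
        theta, shiftv = 0.9, np.array([3.0, -2.0])
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        st2 = SwarmState(st.positions @ R.T + shiftv, st.headings @ R.T,
                         st.mu.copy(), st.learned_lambda_z.copy(), st.informed_mask.copy())
        a, b = st, st2
        r1, r2 = np.random.default_rng(0), np.random.default_rng(0)
        for _ in range(200):
            a = step(a, p, r1)
            b = step(b, p, r2)
        assert np.allclose(a.positions @ R.T + shiftv, b.positions, atol=1e-8)
        assert np.allclose(a.headings @ R.T, b.headings, atol=1e-8)


class TestRunSimulation:
    def test_records_1500_steps(self):
        cfg = RunConfig(n_agents=10, duration_s=15.0)
        rec = run_simulation(cfg, seed=0)
        assert len(rec.times) == 1501  # initial state + 1500 integration steps
        assert rec.positions.shape == (1501, 10, 2)

    def test_zero_duration_initial_state_only(self):
        cfg = RunConfig(n_agents=5, duration_s=0.0)
        rec = run_simulation(cfg, seed=1)
        assert len(rec.times) == 1

    def test_metadata_embeds_seed_and_config(self):
        cfg = RunConfig(n_agents=5, duration_s=0.1)
        rec = run_simulation(cfg, seed=42)
        assert rec.metadata["seed"] == 42
        assert rec.metadata["config"]["n_agents"] == 5


class TestTrajectoryRecord:
    def test_csv_roundtrip(self, params, tmp_path):
        rng = np.random.default_rng(0)
        st = init_state(5, params, rng)
        rec = run(st, params, 0.5, rng)
        path = tmp_path / "traj.csv"
        rec.to_csv(path)
        back = type(rec).from_csv(path)
        assert np.allclose(back.positions, rec.positions)
        assert np.allclose(back.headings, rec.headings)
        assert np.allclose(back.times, rec.times)


class TestFastBackend:
    def test_matches_reference_backend(self, rng):
        # the accelerated kernel must reproduce the plain-numpy reference
        # step exactly (same noise arrays fed to both)
        from flockinf.world import _advance, _draw_noise

        params = ModelParams(kappa_a=2.0, sigma2_a=0.1)
        for trial in range(5):
            informed = rng.random(12) < 0.4
            st = random_scene(rng, 12, informed_mask=informed, target=[8.0, 3.0],
                              params=params)
            noise = _draw_noise(12, params, True, np.random.default_rng(trial))
            stim = rng.normal(0, 1, (12, 4))
            args = (st.positions, st.headings, st.mu, st.learned_lambda_z,
                    st.informed_mask, st.target, params)
            ref = _advance(*args, *noise, stim=stim, plasticity=True, reference=True)
            fast = _advance(*args, *noise, stim=stim, plasticity=True, reference=False)
            for a, b in zip(ref, fast):
                assert np.allclose(a, b, atol=1e-12, rtol=0)

    def test_run_deterministic_across_calls(self, params):
        recs = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            st = init_state(12, params, rng)
            recs.append(run(st, params, 1.0, rng))
        assert np.array_equal(recs[0].positions, recs[1].positions)
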