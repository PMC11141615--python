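"""Swarm synthesis: placement, kinetics, rendering, ground truth."""

import numpy as np
import pytest

from mtswarm.errors import RangeError, ValidationError
from mtswarm.swarm import (
    MIN_LENGTH_UM,
    RenderParams,
    SwarmParams,
    _deposit,
    generate_movie,
    init_world,
    render_frame,
    step,
)


def small_params(**kw):
    defaults = dict(arena=(32.0, 32.0), n_filaments=15, seed=1)
    defaults.update(kw)
    return SwarmParams(**defaults)


class TestInitWorld:
    def test_empty_world(self):
        world = init_world(small_params(n_filaments=0))
        assert world.n == 0

    def test_same_seed_gives_identical_worlds(self):
        a = init_world(small_params(seed=9))
        b = init_world(small_params(seed=9))
        for attr in ("x", "y", "theta", "length", "speed"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))

    def test_length_distribution_matches_nominal_mean(self):
        params = SwarmParams(arena=(4000.0, 4000.0), n_filaments=5000, seed=2)
        world = init_world(params)
        lengths = world.length
        assert lengths.min() >= MIN_LENGTH_UM
        se = lengths.std(ddof=1) / np.sqrt(lengths.size)
        # truncation at 0.5 μm shifts the mean of N(6.2, 2.2) by < 0.01 μm
        assert abs(lengths.mean() - 6.2) < 3 * se + 0.01

    def test_overcrowded_arena_is_rejected(self):
        from mtswarm.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            init_world(SwarmParams(arena=(10.0, 10.0), n_filaments=500, seed=0))


class TestStep:
    def test_filament_count_is_conserved(self):
        world = init_world(small_params())
        n0 = world.n
        for _ in range(5):
            step(world, 0.5, 20.0, 5.0)
            assert world.n == n0

    def test_no_linker_means_no_bonds(self):
        world = init_world(small_params())
        for _ in range(10):
            step(world, 0.5, 0.0, 0.0)
        assert world.bonds == set()

    def test_bound_fraction_nondecreasing_without_dissociator(self):
        # bonds can only be added when the dissociator is absent; verify the
        # bound fraction trend across many independent worlds
        for seed in range(20):
            world = init_world(small_params(seed=seed, sticking_rate=0.0))
            prev = 0.0
            for _ in range(8):
                step(world, 0.5, 50.0, 0.0)
                frac = np.mean(world.bundle_ids() >= 0)
                assert frac >= prev
                prev = frac

    def test_invalid_step_arguments(self):
        world = init_world(small_params())
        with pytest.raises(ValidationError):
            step(world, 0.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            step(world, 0.5, -1.0, 0.0)

    def test_free_gliding_recovers_nominal_speed(self):
        params = small_params(
            n_filaments=25, rotational_diffusion=0.001, sticking_rate=0.0, speed_sd=0.0
        )
        world = init_world(params)
        dt = 1.0 / 3.0
        disp = []
        for _ in range(120):
            x0, y0 = world.x.copy(), world.y.copy()
            step(world, dt, 0.0, 0.0)
            dx = world.x - x0
            dy = world.y - y0
            dx -= params.arena[0] * np.round(dx / params.arena[0])
            dy -= params.arena[1] * np.round(dy / params.arena[1])
            disp.append(np.hypot(dx, dy).mean())
        speed_est = np.mean(disp) / dt
        assert abs(speed_est - params.speed_mean) / params.speed_mean < 0.05

    def test_stuck_fraction_follows_exponential_saturation(self):
        rate = 0.02
        params = SwarmParams(
            arena=(600.0, 600.0), n_filaments=400, sticking_rate=rate, seed=4
        )
        world = init_world(params)
        dt, n_steps = 0.5, 40
        for k in range(n_steps):
            step(world, dt, 0.0, 0.0)
        t = n_steps * dt
        expected = 1.0 - np.exp(-rate * t)
        n = world.n
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(world.stuck.mean() - expected) < 3 * sd

    def test_stuck_filaments_do_not_move(self):
        world = init_world(small_params(sticking_rate=0.0))
        world.stuck[:] = True
        x0, y0 = world.x.copy(), world.y.copy()
        step(world, 1.0, 0.0, 0.0)
        np.testing.assert_array_equal(world.x, x0)
        np.testing.assert_array_equal(world.y, y0)


class TestRender:
    def test_empty_world_renders_black_frames(self):
        world = init_world(small_params(n_filaments=0))
        img = render_frame(world, RenderParams(), noise=False)
        assert img.shape[0] == 2
        assert np.all(img == 0.0)

    def test_noiseless_intensity_proportional_to_length(self):
        rp = RenderParams(photon_scale=10.0)
        totals = {}
        for L in (3.0, 9.0):
            params = small_params(n_filaments=1, length_mean=L, length_sd=1e-6)
            world = init_world(params)
            world.length[:] = L
            img = render_frame(world, rp, noise=False)
            totals[L] = img[0].sum()
        # blur and splatting conserve deposited mass: total ∝ length
        assert abs(totals[9.0] / totals[3.0] - 3.0) < 0.02 * 3.0

    def test_render_determinism(self):
        a = render_frame(init_world(small_params(seed=5)), RenderParams(), noise=True)
        b = render_frame(init_world(small_params(seed=5)), RenderParams(), noise=True)
        np.testing.assert_array_equal(a, b)

    def test_noisy_render_is_integer_valued_and_bounded(self):
        img = render_frame(init_world(small_params()), RenderParams(), noise=True)
        assert np.all(img >= 0)
        assert np.all(img <= np.iinfo(np.uint16).max)
        np.testing.assert_array_equal(img, np.round(img))


class TestGenerateMovie:
    def test_requested_frame_count_is_delivered(self):
        rp = RenderParams(n_frames=30)
        movie, log = generate_movie(small_params(), rp, None)
        assert movie.n_frames == 30
        assert movie.data.shape[1] == 2
        assert log.summary.shape[0] == 30

    def test_short_controller_trajectory_is_rejected(self):
        from mtswarm.controller import build_controller_network, simulate

        traj = simulate(build_controller_network(), 5.0)
        with pytest.raises(RangeError):
            generate_movie(small_params(), RenderParams(n_frames=60), traj)

    def test_noninteracting_contact_fraction_sits_at_random_overlap(self):
        rp = RenderParams(n_frames=25)
        params = small_params(n_filaments=25, sticking_rate=0.0, seed=6)
        movie, log = generate_movie(params, rp, None)
        observed = log.summary.contact_fraction.to_numpy()
        # permutation baseline: decorrelate the channels by translating one
        # occupancy mask by half the arena
        world = init_world(params)
        g = _deposit(world, rp, 0) > 0
        m = _deposit(world, rp, 1) > 0
        m_shift = np.roll(m, m.shape[0] // 2, axis=0)
        baseline = np.count_nonzero(g & m_shift) / np.count_nonzero(g | m_shift)
        assert abs(observed.mean() - baseline) < 3 * observed.std(ddof=1) + 0.02

    def test_movie_and_log_are_deterministic(self):
        rp = RenderParams(n_frames=8)
        m1, l1 = generate_movie(small_params(seed=7), rp, None)
        m2, l2 = generate_movie(small_params(seed=7), rp, None)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert l1.summary.equals(l2.summary)
        assert l1.filaments.equals(l2.filaments)
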