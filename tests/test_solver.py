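import numpy as np
import pytest

from dotstripe.geometry import DigitGeometry, GridSpec, GrowthSchedule, full_masks
from dotstripe.models import FourSpeciesModel, SHModel
from dotstripe.solver import (
    SimulationError,
    SolverConfig,
    explicit_reaction_step,
    implicit_diffusion_step,
    implicit_sh_linear_step,
    initialize_state,
    neumann_laplacian_eigenvalues,
    simulate,
)


def cosine_mode(n, m):
    """Discrete Neumann eigenmode cos(pi m (i + 1/2) / n)."""
    i = np.arange(n)
    return np.cos(np.pi * m * (i + 0.5) / n)


class TestImplicitDiffusion:
    def test_uniform_field_unchanged(self):
        grid = GridSpec(32, 16, 1.0)
        f = np.full(grid.shape, 3.7)
        out = implicit_diffusion_step(f, D=2.0, dt=0.5, grid=grid)
        assert np.allclose(out, 3.7, atol=1e-12)

    def test_eigenmode_decay_factor_exact(self):
        # discrete Neumann eigenmode algebra: mode m of N has eigenvalue
        # (2/h^2)(1 - cos(pi m / N)); a backward-Euler step scales it by
        # exactly 1/(1 + dt D lambda).  The m=1, N=4 eigenvalue gives the
        # closed-form factor 0.6306; the grid run checks the same algebra
        # at N=8.
        lam4 = 2.0 * (1 - np.cos(np.pi / 4))
        assert abs(1 / (1 + lam4) - 0.6306) < 1e-4
        grid = GridSpec(8, 8, 1.0)
        mode = np.tile(cosine_mode(8, 1), (8, 1))
        out = implicit_diffusion_step(mode, D=1.0, dt=1.0, grid=grid)
        lam8 = 2.0 * (1 - np.cos(np.pi / 8))
        assert np.allclose(out, mode / (1 + lam8), atol=1e-10)

    def test_mass_conserved_on_random_field(self, rng):
        grid = GridSpec(48, 24, 0.5)
        f = rng.random(grid.shape)
        out = implicit_diffusion_step(f, D=5.0, dt=0.2, grid=grid)
        assert out.sum() == pytest.approx(f.sum(), abs=1e-10)

    def test_2d_eigenmode_product(self):
        grid = GridSpec(8, 12, 1.0)
        mode = np.outer(cosine_mode(12, 2), cosine_mode(8, 3))
        lam_mode = (
            2 * (1 - np.cos(np.pi * 3 / 8)) + 2 * (1 - np.cos(np.pi * 2 / 12))
        )
        out = implicit_diffusion_step(mode, D=1.5, dt=0.3, grid=grid)
        assert np.allclose(out, mode / (1 + 0.3 * 1.5 * lam_mode), atol=1e-10)


class TestImplicitSHLinear:
    def test_uniform_field_halves_at_unit_dt(self):
        grid = GridSpec(16, 16, 1.0)
        f = np.full(grid.shape, 2.0)
        out = implicit_sh_linear_step(f, ell=1.7, dt=1.0, grid=grid)
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_band_centre_mode_untouched(self):
        # pick a discrete mode whose eigenvalue matches 1/ell^2 exactly, so
        # the operator symbol vanishes and the step is the identity on it
        grid = GridSpec(32, 8, 1.0)
        m = 5
        lam_m = 2 * (1 - np.cos(np.pi * m / 32))
        ell = 1.0 / np.sqrt(lam_m)
        mode = np.tile(cosine_mode(32, m), (8, 1))
        out = implicit_sh_linear_step(mode, ell=ell, dt=0.7, grid=grid)
        assert np.allclose(out, mode, atol=1e-10)

    def test_linearity(self, rng):
        grid = GridSpec(16, 16, 1.0)
        f = rng.normal(size=grid.shape)
        a = 3.3
        out1 = implicit_sh_linear_step(a * f, ell=2.0, dt=0.1, grid=grid)
        out2 = a * implicit_sh_linear_step(f, ell=2.0, dt=0.1, grid=grid)
        assert np.allclose(out1, out2, atol=1e-12)


class TestExplicitReaction:
    def test_zero_rates_identity(self, rng):
        f = {"A": rng.random((8, 8))}
        out = explicit_reaction_step(f, lambda fl: {"A": np.zeros((8, 8))}, 0.1)
        assert np.array_equal(out["A"], f["A"])

    def test_clipping_to_zero(self):
        f = {"A": np.full((4, 4), 0.1)}
        out = explicit_reaction_step(
            f, lambda fl: {"A": np.full((4, 4), -5.0)}, 0.1, clip_negative=True
        )
        assert np.all(out["A"] == 0.0)

    def test_first_order_convergence_on_smooth_ode(self):
        # dy/dt = -y from 1: Richardson check against exp(-1); halving dt
        # roughly halves the error
        def run(dt):
            f = {"y": np.ones((2, 2))}
            for _ in range(int(round(1.0 / dt))):
                f = explicit_reaction_step(f, lambda fl: {"y": -fl["y"]}, dt)
            return f["y"][0, 0]

        err1 = abs(run(0.01) - np.exp(-1))
        err2 = abs(run(0.005) - np.exp(-1))
        assert err1 / err2 == pytest.approx(2.0, rel=0.05)

    def test_nan_aborts_with_step_index(self):
        f = {"A": np.ones((2, 2))}
        with pytest.raises(SimulationError, match="step 17"):
            explicit_reaction_step(
                f, lambda fl: {"A": np.full((2, 2), np.nan)}, 0.1, step_index=17
            )


class TestInitialization:
    def test_zero_noise_gives_uniform_steady_state(self):
        grid = GridSpec(16, 16, 1.0)
        model = FourSpeciesModel()
        cfg = SolverConfig(noise_amp=0.0, seed=1)
        fields = initialize_state(model, full_masks(grid), cfg, grid)
        A, S, B, I = model.steady_state
        assert np.allclose(fields["A"], A)
        assert np.allclose(fields["B"], B)

    def test_same_seed_bit_identical(self):
        grid = GridSpec(16, 16, 1.0)
        model = FourSpeciesModel()
        f1 = initialize_state(model, full_masks(grid), SolverConfig(seed=9), grid)
        f2 = initialize_state(model, full_masks(grid), SolverConfig(seed=9), grid)
        for k in f1:
            assert np.array_equal(f1[k], f2[k])

    def test_different_seeds_differ(self):
        grid = GridSpec(16, 16, 1.0)
        model = FourSpeciesModel()
        f1 = initialize_state(model, full_masks(grid), SolverConfig(seed=1), grid)
        f2 = initialize_state(model, full_masks(grid), SolverConfig(seed=2), grid)
        assert not np.array_equal(f1["A"], f2["A"])


class _NoReactionModel(FourSpeciesModel):
    """Four diffusing species with all reactions switched off."""

    def local_rates(self, fields, masks):
        return {}


class TestSimulate:
    def test_pure_diffusion_conserves_mass(self):
        grid = GridSpec(32, 16, 1.0)
        model = _NoReactionModel()
        cfg = SolverConfig(dt=0.1, T=100.0, seed=3, noise_amp=0.2, snapshot_every=1000)
        traj = simulate(model, grid, cfg)
        for name in model.species:
            first = traj.snapshots[0][name].sum()
            last = traj.snapshots[-1][name].sum()
            assert last == pytest.approx(first, abs=1e-8 * max(1, abs(first)))

    def test_determinism_bit_identical_snapshots(self):
        grid = GridSpec(32, 16, 1.0)
        cfg = SolverConfig(dt=0.05, T=5.0, seed=11, snapshot_every=50)
        t1 = simulate(FourSpeciesModel(), grid, cfg)
        t2 = simulate(FourSpeciesModel(), grid, cfg)
        assert t1.times == t2.times
        for s1, s2 in zip(t1.snapshots, t2.snapshots):
            for k in s1:
                assert np.array_equal(s1[k], s2[k])

    def test_committed_bins_frozen_while_active_bins_move(self):
        grid = GridSpec(64, 32, 1.0)
        geom = DigitGeometry(L0=40, L=40, W=10, eps=5, anchor=(8.0, 16.0))
        cfg = SolverConfig(dt=0.05, T=10.0, seed=5, noise_amp=0.02, snapshot_every=40)
        traj = simulate(FourSpeciesModel(), grid, cfg, geom=geom, L_P=20.0)
        committed = traj.masks[-1].committed
        active = traj.masks[-1].active
        assert committed.any() and active.any()
        first, last = traj.snapshots[1], traj.snapshots[-1]
        assert np.array_equal(first["A"][committed], last["A"][committed])
        assert not np.array_equal(first["A"][active], last["A"][active])

    def test_overflow_guard_aborts_with_dt_advice(self):
        grid = GridSpec(16, 16, 1.0)

        class Exploding(FourSpeciesModel):
            def local_rates(self, fields, masks):
                return {"A": 1e4 * fields["A"] ** 2}

        cfg = SolverConfig(dt=0.5, T=50.0, seed=1, noise_amp=0.0)
        with pytest.raises(SimulationError, match="reduce dt"):
            simulate(Exploding(), grid, cfg)

    def test_sh_model_runs_and_stays_finite(self):
        grid = GridSpec(32, 32, 1.0)
        cfg = SolverConfig(dt=0.05, T=10.0, seed=2, noise_amp=0.05,
                           clip_negative=False, snapshot_every=100)
        traj = simulate(SHModel(), grid, cfg)
        for snap in traj.snapshots:
            for arr in snap.values():
                assert np.all(np.isfinite(arr))

    def test_growth_schedule_must_fit_run(self):
        grid = GridSpec(64, 32, 1.0)
        geom = DigitGeometry(L0=20, L=40, W=10, eps=5, anchor=(8.0, 16.0))
        sched = GrowthSchedule(mode="tip", T=100.0, T_i=10.0)
        cfg = SolverConfig(dt=0.05, T=50.0)
        with pytest.raises(ValueError, match="finish by"):
            simulate(FourSpeciesModel(), grid, cfg, geom=geom, sched=sched)
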