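import dataclasses
import math

import numpy as np
import pytest

from cubicdock import engine as eng
from cubicdock import fixtures as fx
from cubicdock import symmetry as sym
from cubicdock.engine import DEConfig, Individual, make_context
from cubicdock.symmetry import RigidBodyParams


@pytest.fixture(scope="module")
def t3_ctx():
    sub, _, sd = fx.cached_toy_native("T", 3)
    cfg = DEConfig(population_size=8, generations=2, seed=7)
    ctx = make_context([sub], sd, "recapitulate", cfg)
    return sub, sd, ctx


def make_pop(ctx, rng, n=8):
    return [
        ctx.evaluate(
            Individual(backbone_id=0, params=ctx.bounds.sample(rng))
        )
        for _ in range(n)
    ]


class TestInitialization:
    def test_deterministic(self, t3_ctx):
        sub, sd, ctx = t3_ctx
        p1 = eng.initialize_population(ctx, np.random.default_rng(5))
        p2 = eng.initialize_population(ctx, np.random.default_rng(5))
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.params.as_array(), b.params.as_array())
            assert a.iscore == b.iscore

    def test_within_bounds(self, t3_ctx):
        _, _, ctx = t3_ctx
        pop = eng.initialize_population(ctx, np.random.default_rng(2))
        assert all(ctx.bounds.contains(ind.params) for ind in pop)

    def test_global_mode_flip_split(self):
        sub, _, sd = fx.cached_toy_native("T", 3)
        cfg = DEConfig(population_size=10, generations=1, seed=1)
        ctx = make_context([sub], sd, "global", cfg, center=sd.params)
        pop = eng.initialize_population(ctx, np.random.default_rng(0))
        flips = sum(ind.flipped for ind in pop)
        assert flips == 5

    def test_empty_ensemble_raises(self):
        _, _, sd = fx.cached_toy_native("T", 3)
        with pytest.raises(eng.EngineError):
            make_context([], sd, "recapitulate", DEConfig())


class TestDeStep:
    def test_cr_zero_changes_one_parameter(self, t3_ctx, rng):
        _, _, ctx = t3_ctx
        cfg = dataclasses.replace(ctx.cfg, recombination_rate=0.0)
        pop = make_pop(ctx, rng)
        trials = eng.de_step(pop, cfg, np.random.default_rng(3))
        for parent, trial in zip(pop, trials):
            diff = parent.params.as_array() != trial.params.as_array()
            assert diff.sum() == 1

    def test_cr_one_full_donor(self, t3_ctx, rng):
        _, _, ctx = t3_ctx
        cfg = dataclasses.replace(ctx.cfg, recombination_rate=1.0)
        pop = make_pop(ctx, rng)
        rng2 = np.random.default_rng(3)
        trials = eng.de_step(pop, cfg, rng2)
        # full donor vector: trial must differ from target in all coords
        # where donor differs (i.e. equals the donor vector everywhere)
        for parent, trial in zip(pop, trials):
            assert not np.array_equal(
                parent.params.as_array(), trial.params.as_array()
            )

    def test_crossover_fraction_monte_carlo(self, t3_ctx):
        _, _, ctx = t3_ctx
        cfg = dataclasses.replace(ctx.cfg, recombination_rate=0.7)
        rng = np.random.default_rng(11)
        pop = make_pop(ctx, rng, n=10)
        taken = 0
        total = 0
        rows = 20000
        trials_rng = np.random.default_rng(12)
        for _ in range(rows // len(pop)):
            trials = eng.de_step(pop, cfg, trials_rng)
            for parent, trial in zip(pop, trials):
                diff = parent.params.as_array() != trial.params.as_array()
                taken += diff.sum()
                total += 6
        frac = taken / total
        # binomial scheme with forced donor coordinate:
        # E = CR + (1 - CR) / 6
        assert frac == pytest.approx(0.7 + 0.3 / 6, abs=0.01)

    def test_small_population_raises(self, t3_ctx):
        _, _, ctx = t3_ctx
        with pytest.raises(eng.EngineError):
            eng.de_step([], ctx.cfg, np.random.default_rng(0))


class TestSlide:
    def test_step_displacement(self, t3_ctx):
        sub, sd, ctx = t3_ctx
        scorer = ctx.scorer(0)
        far = dataclasses.replace(sd.params, z=sd.params.z + 4.0)
        ind = ctx.evaluate(Individual(0, far))
        com_before = scorer.com(ind.params)
        slid, steps = eng.slide(ind, ctx, max_steps=1)
        com_after = scorer.com(slid.params)
        moved = np.linalg.norm(com_after - com_before)
        # one accepted step along one axis moves the COM by the step size
        assert moved >= ctx.cfg.slide_step - 1e-9

    def test_already_clashing_takes_no_step(self, t3_ctx):
        sub, sd, ctx = t3_ctx
        crushed = dataclasses.replace(sd.params, z=sd.params.z - 4.0, x=sd.params.x - 2.0)
        assert ctx.scorer(0).n_clashes(crushed) > 0
        ind = ctx.evaluate(Individual(0, crushed))
        slid, steps = eng.slide(ind, ctx)
        np.testing.assert_allclose(
            slid.params.as_array(), crushed.as_array(), atol=1e-9
        )

    def test_never_clashing_caps_at_100(self):
        sub, _, sd0 = fx.cached_toy_native("T", 3)
        sd = sym.SymmetryDefinition(kind="T", setup_fold=3)
        cfg = DEConfig(population_size=4, generations=1, seed=0)
        center = RigidBodyParams(z=500.0, x=50.0)
        ctx = make_context([sub], sd, "global", cfg, center=center)
        ctx.scorers[0].set_subsystem(None)
        ind = ctx.evaluate(Individual(0, center))
        _, steps = eng.slide(ind, ctx)
        assert max(steps.values()) == 100


class TestLocalSearchAndSelection:
    def test_metropolis_always_accepts_improvement(self, rng):
        assert eng._metropolis(-5.0, 1.0, rng)

    def test_local_search_never_worse(self, t3_ctx, rng):
        _, sd, ctx = t3_ctx
        ind = ctx.evaluate(Individual(0, sd.params))
        out = eng.local_search(ind, ctx, np.random.default_rng(4))
        assert out.iscore <= ind.iscore + 1e-9

    def test_mc_subroutine_move_count(self, t3_ctx, monkeypatch):
        _, sd, ctx = t3_ctx
        calls = {"n": 0}
        orig = eng._metropolis

        def counting(delta, t, rng):
            calls["n"] += 1
            return orig(delta, t, rng)

        monkeypatch.setattr(eng, "_metropolis", counting)
        ind = ctx.evaluate(Individual(0, sd.params))
        eng.local_search(ind, ctx, np.random.default_rng(4))
        # in-bounds proposals each face exactly one Metropolis decision
        assert calls["n"] <= ctx.cfg.mc_subroutine_moves
        assert calls["n"] > 0

    def test_select_lower_wins_and_tie_keeps_parent(self):
        p = Individual(0, RigidBodyParams(), iscore=-3.0)
        t = Individual(0, RigidBodyParams(), iscore=-5.0)
        assert eng.select(p, t) is t
        t2 = Individual(0, RigidBodyParams(), iscore=-3.0)
        assert eng.select(p, t2) is p


class TestBbTrial:
    def test_probability_zero_is_identity(self, rng):
        sub, _, sd = fx.cached_toy_native("T", 3)
        cfg = DEConfig(population_size=4, generations=1, seed=0,
                       bb_trial_probability=0.0)
        ctx = make_context([sub, sub], sd, "recapitulate", cfg)
        ind = ctx.evaluate(Individual(0, sd.params))
        out = eng.bb_trial(ind, ctx, np.random.default_rng(0))
        assert out is ind

    def test_probability_one_two_member_ensemble(self):
        sub, _, sd = fx.cached_toy_native("T", 3)
        worse = dataclasses.replace(
            sub, coords=sub.coords + np.random.default_rng(1).normal(0, 1.5, sub.coords.shape)
        )
        cfg = DEConfig(population_size=4, generations=1, seed=0,
                       bb_trial_probability=1.0)
        ctx = make_context([sub, worse], sd, "recapitulate", cfg)
        ind = ctx.evaluate(Individual(0, sd.params))
        out = eng.bb_trial(ind, ctx, np.random.default_rng(2))
        # either the swap improved (new backbone kept) or it reverted
        assert out.iscore <= ind.iscore + 1e-9
        assert out.backbone_id in (0, 1)


class TestPerturbParams:
    def test_zero_range_is_center(self, rng):
        center = RigidBodyParams(psi=3, theta=4, phi=5, z=6, x=7, lam=8)
        got = eng.perturb_params(center, np.zeros(6), rng)
        np.testing.assert_allclose(got.as_array(), center.as_array())

    def test_sampling_statistics(self):
        rng = np.random.default_rng(0)
        center = RigidBodyParams(z=20, x=8)
        ranges = np.array([5.0, 5.0, 5.0, 2.0, 2.0, 10.0])
        draws = np.array(
            [eng.perturb_params(center, ranges, rng).as_array() for _ in range(10000)]
        )
        lo = center.as_array() - ranges
        hi = center.as_array() + ranges
        assert np.all(draws >= lo - 1e-12) and np.all(draws <= hi + 1e-12)
        np.testing.assert_allclose(draws.mean(axis=0), center.as_array(), atol=0.3)

    def test_respects_bounds_clipping(self, t3_ctx, rng):
        _, sd, ctx = t3_ctx
        got = eng.perturb_params(sd.params, np.full(6, 500.0), rng, bounds=ctx.bounds)
        assert ctx.bounds.contains(got)


class TestRunDocking:
    def test_determinism_and_monotone_log(self):
        sub, _, sd = fx.cached_toy_native("T", 3)
        cfg = DEConfig(population_size=6, generations=3, seed=42)
        r1 = eng.run_docking([sub], sd, "recapitulate", cfg)
        r2 = eng.run_docking([sub], sd, "recapitulate", cfg)
        assert r1.log.best_iscores == r2.log.best_iscores
        b = r1.log.best_iscores
        assert all(x >= y - 1e-9 for x, y in zip(b, b[1:]))
        assert len(r1.archive) == len(r2.archive)

    def test_invalid_mode(self):
        sub, _, sd = fx.cached_toy_native("T", 3)
        with pytest.raises(eng.EngineError):
            eng.run_docking([sub], sd, "bogus", DEConfig())
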