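import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cubicdock import evaluation as ev
from cubicdock import fixtures as fx
from cubicdock import geometry as geo
from cubicdock import symmetry as sym
from cubicdock.structure_io import Assembly


class TestSymmetricRmsd:
    def test_self_zero(self, toy_native):
        _, asm, _ = toy_native("T", 3)
        assert ev.symmetric_rmsd(asm, asm, "T", 3) < 1e-9

    def test_fold_rotation_equivalence(self, toy_native):
        _, asm, _ = toy_native("I", 5)
        rotated = asm.transformed(geo.rot_z(72.0))
        assert ev.symmetric_rmsd(rotated, asm, "I", 5) < 1e-8

    def test_five_configurations_tried(self, toy_native):
        _, asm, _ = toy_native("I", 5)
        angles = []
        ev.symmetric_rmsd(asm, asm, "I", 5, tried_angles=angles)
        assert angles == [0.0, 72.0, 144.0, 216.0, 288.0]

    def test_rigid_motion_invariance(self, toy_native):
        _, asm, _ = toy_native("T", 3)
        r = Rotation.random(random_state=3).as_matrix()
        moved = asm.transformed(r, np.array([5.0, -2.0, 8.0]))
        assert ev.symmetric_rmsd(moved, asm, "T", 3) < 1e-6

    def test_size_mismatch_raises(self, toy_native):
        _, t, _ = toy_native("T", 3)
        _, o, _ = toy_native("O", 4)
        with pytest.raises(ev.EvaluationError):
            ev.symmetric_rmsd(t, o, "T", 3)

    def test_not_larger_than_identity_mapping(self, toy_native, rng):
        _, asm, _ = toy_native("T", 3)
        noisy = Assembly(
            [
                dataclasses.replace(
                    c, coords=c.coords + rng.normal(0, 1.0, c.coords.shape)
                )
                for c in asm.chains
            ]
        )
        nat = np.vstack([c.ca_coords() for c in asm.chains])
        mod = np.vstack([c.ca_coords() for c in noisy.chains])
        identity = geo.superposed_rmsd(mod, nat)
        assert ev.symmetric_rmsd(noisy, asm, "T", 3) <= identity + 1e-12


class TestDockQ:
    def _pair(self, toy_native):
        _, asm, sd = toy_native("T", 3)
        j = ev._fold_partner(asm, "T", 3)
        assert j is not None
        return asm.chains[0], asm.chains[j]

    def test_identical_is_one(self, toy_native):
        a, b = self._pair(toy_native)
        assert ev.dockq((a, b), (a, b)) == pytest.approx(1.0)

    def test_displaced_near_zero(self, toy_native):
        a, b = self._pair(toy_native)
        far = b.translated(np.array([100.0, 0.0, 0.0]))
        assert ev.dockq((a, far), (a, b)) < 0.05

    def test_no_native_contacts_raises(self, toy_native):
        a, b = self._pair(toy_native)
        far = b.translated(np.array([100.0, 0.0, 0.0]))
        with pytest.raises(ev.EvaluationError):
            ev.dockq((a, b), (a, far))

    def test_agrees_with_independent_implementation(self, toy_native, rng):
        from scipy.spatial.distance import cdist

        a, b = self._pair(toy_native)

        def simple_dockq(mpair, npair):
            # straightforward second implementation, kept deliberately plain
            ma, mb = mpair
            na, nb = npair
            nat = {
                (int(i), int(j))
                for i, j in zip(*np.nonzero(cdist(na.coords, nb.coords) < 5.0))
            }
            natres = {
                (int(na.res_ids[i]), int(nb.res_ids[j])) for i, j in nat
            }
            modres = {
                (int(ma.res_ids[i]), int(mb.res_ids[j]))
                for i, j in zip(*np.nonzero(cdist(ma.coords, mb.coords) < 5.0))
            }
            fnat = len(natres & modres) / len(natres)
            d = cdist(na.coords, nb.coords)
            ra = sorted({int(r) for r in na.res_ids[np.any(d < 10, axis=1)]})
            rb = sorted({int(r) for r in nb.res_ids[np.any(d < 10, axis=0)]})

            def bb(ch, keep):
                m = np.isin(ch.atom_names, ["N", "CA", "C", "O"]) & np.isin(
                    ch.res_ids, keep
                )
                return ch.coords[m]

            nat_i = np.vstack([bb(na, ra), bb(nb, rb)])
            mod_i = np.vstack([bb(ma, ra), bb(mb, rb)])
            irms = geo.superposed_rmsd(mod_i, nat_i)
            allres = sorted(set(int(r) for r in na.res_ids))
            rec_n, lig_n = (na, nb)
            rec_m, lig_m = (ma, mb)
            r, t = geo.kabsch(bb(rec_m, allres), bb(rec_n, allres))
            lrms = geo.rmsd(
                (r @ bb(lig_m, allres).T).T + t, bb(lig_n, allres)
            )
            return (
                fnat + 1 / (1 + (irms / 1.5) ** 2) + 1 / (1 + (lrms / 8.5) ** 2)
            ) / 3

        for k in range(5):
            rot = Rotation.from_rotvec(
                rng.normal(0, 0.05, 3)
            ).as_matrix()
            shift = rng.normal(0, 0.8, 3)
            mb = b.transformed(rot, shift)
            got = ev.dockq((a, mb), (a, b))
            want = simple_dockq((a, mb), (a, b))
            assert got == pytest.approx(want, abs=0.01)


class TestDeltaSasa:
    def test_non_contacting_near_zero(self, toy_native):
        _, asm, _ = toy_native("T", 3)
        far = Assembly(
            [asm.chains[0], asm.chains[1].translated(np.array([300.0, 0, 0]))]
        )
        assert abs(ev.delta_sasa(far, (0, 1))) < 1.0

    def test_contacting_positive(self, toy_native):
        _, asm, _ = toy_native("T", 3)
        j = ev._fold_partner(asm, "T", 3)
        assert ev.delta_sasa(asm, (0, j)) > 50.0

    def test_monotone_under_separation(self, toy_native):
        _, asm, _ = toy_native("T", 3)
        j = ev._fold_partner(asm, "T", 3)
        a = asm.chains[0]
        b = asm.chains[j]
        normal = b.com() - a.com()
        normal /= np.linalg.norm(normal)
        values = []
        for pull in (0.0, 2.0, 5.0, 12.0):
            moved = Assembly([a, b.translated(normal * pull)])
            values.append(ev.delta_sasa(moved, (0, 1)))
        assert all(x >= y - 1.0 for x, y in zip(values, values[1:]))


class TestPairwiseDockQ:
    def test_perfect_model(self, toy_native):
        _, asm, _ = toy_native("T", 3)
        score, evals = ev.pairwise_dockq(asm, asm, "T", 3)
        assert score == pytest.approx(1.0)
        assert {e.fold for e in evals} <= {2, 3}
        weights = [e.delta_sasa for e in evals]
        assert sum(w / sum(weights) for w in weights) == pytest.approx(1.0)

    def test_uniform_weights_average(self):
        # Eq. with equal dSASA: (0.2 + 0.5 + 0.8) / 3
        evals = [
            ev.InterfaceEval(2, (0, 1), (0, 1), q, 100.0) for q in (0.2, 0.5, 0.8)
        ]
        total = sum(e.delta_sasa for e in evals)
        score = sum(e.dockq * e.delta_sasa / total for e in evals)
        assert score == pytest.approx(0.5)


class TestTmScore:
    def test_identical_one(self, toy_native):
        _, asm, _ = toy_native("T", 3)
        assert ev.tm_score_assembly(asm, asm, "T", 3) == pytest.approx(1.0)

    def test_rigid_motion_invariant(self, toy_native):
        _, asm, _ = toy_native("T", 3)
        r = Rotation.random(random_state=11).as_matrix()
        moved = asm.transformed(r, np.array([10.0, 5.0, -3.0]))
        assert ev.tm_score_assembly(moved, asm, "T", 3) == pytest.approx(1.0, abs=1e-6)

    def test_scrambled_low(self, toy_native, rng):
        _, asm, _ = toy_native("T", 3)
        scores = []
        for _ in range(20):
            scrambled = Assembly(
                [
                    dataclasses.replace(
                        c,
                        coords=rng.uniform(-30, 30, c.coords.shape),
                    )
                    for c in asm.chains
                ]
            )
            scores.append(ev.tm_score_assembly(scrambled, asm, "T", 3))
        assert max(scores) < 0.3


class TestClassification:
    def test_highly_accurate(self):
        assert ev.classify_quality(0.99, 0.85) == "highly-accurate"

    def test_low_dockq_not_successful(self):
        assert ev.classify_quality(0.95, 0.10) == "none"

    def test_tm_below_cut_not_successful(self):
        assert ev.classify_quality(0.89, 0.90) not in ("successful", "highly-accurate")

    def test_monotone(self):
        order = ["none", "acceptable", "successful", "highly-accurate"]
        prev = -1
        for dq in (0.1, 0.3, 0.85):
            cls = ev.classify_quality(0.95, dq)
            assert order.index(cls) >= prev
            prev = order.index(cls)


class TestBootstrap:
    def test_all_success(self, rng):
        runs = fx.make_runs_table(100, 100, 1.0, 20.0, seed=1)
        out = ev.success_bootstrap(runs, num_runs_range=[1, 5, 10], rng=rng)
        assert all(p == 1.0 for p in out["probabilities"].values())

    def test_no_success(self, rng):
        runs = fx.make_runs_table(100, 0, 1.0, 20.0, seed=1)
        out = ev.success_bootstrap(runs, num_runs_range=[1, 5], rng=rng)
        assert all(p == 0.0 for p in out["probabilities"].values())

    def test_half_success_binomial(self, rng):
        runs = fx.make_runs_table(100, 50, 1.0, 20.0, seed=1)
        out = ev.success_bootstrap(runs, num_runs_range=[1], reps=100, rng=rng)
        assert out["probabilities"][1] == pytest.approx(0.5, abs=0.1)

    def test_runs_needed_reported(self, rng):
        runs = fx.make_runs_table(100, 50, 1.0, 20.0, seed=1)
        out = ev.success_bootstrap(runs, num_runs_range=range(1, 30), rng=rng)
        assert out["runs_needed"][99] is None or out["runs_needed"][99] >= 1
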