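import dataclasses

import numpy as np
import pytest

from cubicdock import ensemble as ens
from cubicdock import fixtures as fx
from cubicdock import symmetry as sym
from cubicdock.ensemble import EnsembleConfig
from cubicdock.structure_io import Assembly, ManifestRecord, ScoreManifest


class TestModelConfidence:
    def test_both_one(self):
        assert ens.model_confidence(1.0, 1.0) == pytest.approx(1.0)

    def test_iptm_only(self):
        assert ens.model_confidence(0.0, 1.0) == pytest.approx(0.8)

    def test_mixed(self):
        assert ens.model_confidence(0.5, 0.9) == pytest.approx(0.82)

    def test_out_of_range(self):
        with pytest.raises(ens.EnsembleError):
            ens.model_confidence(1.2, 0.5)


class TestConfidenceFilter:
    def _models(self, hairpin, records):
        manifest = ScoreManifest(records)
        models = {r.model_id: hairpin for r in records}
        return models, manifest

    def test_monomer_plddt_floor(self, hairpin):
        models, manifest = self._models(
            hairpin,
            [
                ManifestRecord("low", 89.9, 0.9, None),
                ManifestRecord("high", 90.0, 0.9, None),
            ],
        )
        kept = ens.filter_by_confidence(models, manifest, multimer=False)
        assert set(kept) == {"high"}

    def test_multimer_confidence_floor(self, hairpin):
        models, manifest = self._models(
            hairpin,
            [
                ManifestRecord("a", 95.0, 0.9, 0.88),  # conf 0.884 < 0.9
                ManifestRecord("b", 95.0, 0.9, 0.95),  # conf 0.94
            ],
        )
        kept = ens.filter_by_confidence(models, manifest, multimer=True)
        assert set(kept) == {"b"}

    def test_empty_result_warns(self, hairpin):
        models, manifest = self._models(
            hairpin, [ManifestRecord("a", 10.0, 0.1, 0.1)]
        )
        with pytest.warns(UserWarning):
            kept = ens.filter_by_confidence(models, manifest)
        assert kept == {}

    def test_missing_record_raises(self, hairpin):
        manifest = ScoreManifest([ManifestRecord("a", 95.0, 0.9, 0.95)])
        with pytest.raises(ens.EnsembleError, match="other"):
            ens.filter_by_confidence({"other": hairpin}, manifest)


class TestResidueMetrics:
    def test_constant_plddt(self, hairpin):
        chain = dataclasses.replace(
            hairpin, bfactors=np.full(len(hairpin.bfactors), 90.0)
        )
        metrics = ens.residue_metric_profiles([chain, chain])
        np.testing.assert_allclose(metrics.avg_plddt, 90.0)

    def test_hairpin_connectivity_interior(self, hairpin):
        metrics = ens.residue_metric_profiles([hairpin])
        # the two antiparallel helices contact each other at |di| >= 10
        assert metrics.connectivity_pct.max() == 100.0

    def test_isolated_terminal_disconnected(self, hairpin):
        moved = hairpin.coords.copy()
        first = hairpin.res_ids == hairpin.residue_numbers[0]
        moved[first] += 40.0
        chain = dataclasses.replace(hairpin, coords=moved)
        metrics = ens.residue_metric_profiles([chain])
        assert metrics.connectivity_pct[0] == 0.0

    def test_mid_helix_ss_100(self, helix16):
        metrics = ens.residue_metric_profiles([helix16])
        assert metrics.ss_pct[len(metrics.ss_pct) // 2] == 100.0
        # an ideal helix is helical everywhere with terminal inheritance
        np.testing.assert_allclose(metrics.ss_pct, 100.0)

    def test_length_mismatch(self, helix16, hairpin):
        with pytest.raises(ens.EnsembleError):
            ens.residue_metric_profiles([helix16, hairpin])


def make_metrics(n, plddt=95.0, conn=100.0, ss=100.0):
    return ens.ResidueMetrics(
        avg_plddt=np.full(n, plddt),
        connectivity_pct=np.full(n, conn),
        ss_pct=np.full(n, ss),
    )


class TestTrim:
    def test_no_trim_when_all_pass(self, hairpin):
        metrics = make_metrics(hairpin.sequence_length)
        out = ens.trim_termini([hairpin], metrics)
        assert out[0].sequence_length == hairpin.sequence_length

    def test_low_plddt_n_terminus(self, hairpin):
        n = hairpin.sequence_length
        metrics = make_metrics(n)
        metrics.avg_plddt[:5] = 50.0
        out = ens.trim_termini([hairpin], metrics)
        assert out[0].sequence_length == n - 5
        assert out[0].residue_numbers[0] == hairpin.residue_numbers[5]

    def test_last_threshold_crossed_rule(self):
        # first passes at indices 3, 5, 4 -> cut at 5
        n = 20
        metrics = make_metrics(n)
        metrics.avg_plddt[:3] = 0.0
        metrics.connectivity_pct[:5] = 0.0
        metrics.ss_pct[:4] = 0.0
        n_cut, c_cut = ens.trim_cut_positions(metrics)
        assert n_cut == 5
        assert c_cut == 0

    def test_all_fail_raises(self):
        metrics = make_metrics(10, plddt=10.0)
        with pytest.raises(ens.EnsembleError):
            ens.trim_cut_positions(metrics)

    def test_equal_lengths_and_idempotence(self, hairpin, rng):
        models, _ = fx.make_synthetic_ensemble(
            hairpin, 4, np.full(hairpin.sequence_length, 95.0), seed=5
        )
        metrics = make_metrics(hairpin.sequence_length)
        metrics.avg_plddt[:2] = 0.0
        out = ens.trim_termini(models, metrics)
        lengths = {c.sequence_length for c in out}
        assert len(lengths) == 1
        again = ens.trim_termini(out, make_metrics(out[0].sequence_length))
        assert again[0].sequence_length == out[0].sequence_length


class TestPrune:
    def test_identical_pair_keeps_better(self, hairpin):
        survivors = ens.prune_redundant(
            [hairpin, hairpin], [80.0, 95.0], EnsembleConfig(min_ensemble=1)
        )
        assert survivors == [1]

    def test_diverse_survive(self, hairpin, rng):
        models, _ = fx.make_synthetic_ensemble(
            hairpin, 8, np.full(hairpin.sequence_length, 95.0), seed=2, jitter=1.0
        )
        models.append(models[-1])  # one duplicate pair
        scores = list(np.linspace(90, 95, 9))
        survivors = ens.prune_redundant(models, scores, EnsembleConfig(min_ensemble=1))
        assert len(survivors) == 8

    def test_threshold_relaxation(self, hairpin):
        # all models mutually within 0.1 A but > 0.02 A apart
        models = []
        for i in range(6):
            coords = hairpin.coords.copy()
            coords[:, 0] += 0.03 * i
            models.append(dataclasses.replace(hairpin, coords=coords))
        cfg = EnsembleConfig(min_ensemble=4, redundancy_step=0.01,
                             redundancy_max_steps=18)
        survivors = ens.prune_redundant(models, list(range(6)), cfg)
        assert len(survivors) >= 4

    def test_never_removes_both(self, hairpin):
        survivors = ens.prune_redundant(
            [hairpin, hairpin, hairpin],
            [1.0, 2.0, 3.0],
            EnsembleConfig(min_ensemble=1),
        )
        assert survivors == [2]


class TestOligomerParams:
    def test_round_trip_trimer(self, hairpin):
        params = sym.RigidBodyParams(psi=12, theta=35, phi=-20, z=0, x=9, lam=0)
        olig = fx.make_cn_oligomer(hairpin, 3, params)
        got = ens.extract_oligomer_params(olig, "I", 3, subunit=hairpin)
        assert abs(got.psi - 12) < 0.5
        assert abs(got.theta - 35) < 0.5
        assert abs(got.phi + 20) < 0.5
        assert abs(got.x - 9) < 0.1

    def test_dimer_tolerance(self, hairpin):
        params = sym.RigidBodyParams(x=9)
        olig = fx.make_cn_oligomer(hairpin, 2, params)
        # perturb chain B slightly so the rotation is ~178 degrees
        b = olig.chains[1].transformed(
            sym.geo.euler_to_matrix(1.5, 0.0, 0.0)
        )
        got = ens.extract_oligomer_params(
            Assembly([olig.chains[0], b]), "I", 2, subunit=hairpin
        )
        assert abs(got.axis_angle - 180.0) < 10.0

    def test_monomer_raises(self, hairpin):
        with pytest.raises(ens.EnsembleError):
            ens.extract_oligomer_params(Assembly([hairpin]), "I", 2)

    @pytest.mark.parametrize("kind,fold", [("T", 2), ("T", 3), ("O", 4), ("I", 5)])
    def test_identity_over_folds(self, hairpin, kind, fold):
        params = sym.RigidBodyParams(psi=5, theta=25, phi=10, z=0, x=11, lam=0)
        olig = fx.make_cn_oligomer(hairpin, fold, params)
        got = ens.extract_oligomer_params(olig, kind, fold, subunit=hairpin)
        assert abs(got.psi - 5) < 0.5
        assert abs(got.theta - 25) < 0.5
        assert abs(got.phi - 10) < 0.5
        assert abs(got.x - 11) < 0.1
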