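import numpy as np
import pytest

from graphema.ebm import logit
from graphema.structure import build_graph
from graphema.synthetic import (DecoySpec, fold_label, generate_decoy_set,
                                generate_toy_complex, interface_label,
                                make_embedding_dataset, make_graph_dataset,
                                perturb_decoy, tm_d0, write_pdb)

from conftest import rigid_transform


class TestGenerator:
    def test_dimer_has_interface_contacts(self):
        s = generate_toy_complex(DecoySpec(n_chains=2, chain_length=20, seed=0))
        g = build_graph(s)
        assert s.n_residues == 40
        assert g.cross_chain_mask.sum() >= 1

    def test_same_seed_byte_identical_pdb(self, tmp_path):
        spec = DecoySpec(n_chains=2, chain_length=10, seed=3)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb(generate_toy_complex(spec), p1)
        write_pdb(generate_toy_complex(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_chain_count_round_trips(self, tmp_path, trimer):
        path = tmp_path / "t.pdb"
        write_pdb(trimer, path)
        from graphema.structure import parse_structure
        assert parse_structure(path).n_chains == 3

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            DecoySpec(chain_length=3)


class TestPerturbation:
    def test_null_perturbation_identity(self, dimer):
        spec = DecoySpec(rigid_rotation_max=0, rigid_translation_max=0,
                         jitter_sd=0)
        decoy = perturb_decoy(dimer, spec, np.random.default_rng(0))
        for rn, rd in zip(dimer.residues(), decoy.residues()):
            for k in rn.atoms:
                assert np.allclose(rn.atoms[k], rd.atoms[k], atol=1e-12)

    def test_jitter_rms_matches_sd(self, dimer):
        spec = DecoySpec(rigid_rotation_max=0, rigid_translation_max=0,
                         jitter_sd=0.1)
        rng = np.random.default_rng(1)
        disp = []
        for _ in range(30):
            decoy = perturb_decoy(dimer, spec, rng)
            for rn, rd in zip(dimer.residues(), decoy.residues()):
                disp.extend(np.linalg.norm(rn.atoms[k] - rd.atoms[k])
                            for k in rn.atoms)
        rms = np.sqrt(np.mean(np.square(disp)))
        assert rms == pytest.approx(0.1 * np.sqrt(3), rel=0.05)

    def test_larger_translation_degrades_interface(self, dimer):
        rng = np.random.default_rng(2)
        small, large = [], []
        for _ in range(50):
            s_spec = DecoySpec(rigid_rotation_max=0, jitter_sd=0,
                               rigid_translation_max=0.5)
            l_spec = DecoySpec(rigid_rotation_max=0, jitter_sd=0,
                               rigid_translation_max=6.0)
            small.append(interface_label(dimer, perturb_decoy(dimer, s_spec, rng)))
            large.append(interface_label(dimer, perturb_decoy(dimer, l_spec, rng)))
        assert np.mean(large) < np.mean(small)


class TestFoldLabel:
    def test_identity_scores_one(self, dimer):
        assert fold_label(dimer, dimer) == pytest.approx(1.0)

    def test_rigid_motion_scores_one(self, dimer):
        assert fold_label(dimer, rigid_transform(dimer, 5)) == pytest.approx(
            1.0, abs=1e-9)

    def test_d0_formula(self):
        assert tm_d0(120) == pytest.approx(1.24 * 105 ** (1 / 3) - 1.8, abs=1e-9)
        assert tm_d0(120) == pytest.approx(4.050, abs=1e-3)
        assert tm_d0(10) == 0.5

    def test_length_mismatch_rejected(self, dimer, trimer):
        with pytest.raises(ValueError):
            fold_label(dimer, trimer)


class TestInterfaceLabel:
    def test_identity_scores_one(self, dimer):
        assert interface_label(dimer, dimer) == 1.0

    def test_separated_chains_score_zero(self, dimer):
        from graphema.structure import ComplexStructure, ResidueRecord
        cid, recs = dimer.chains[1]
        moved = [ResidueRecord(r.chain_id, r.seq_pos, r.aa,
                               {k: v + np.array([100.0, 0, 0])
                                for k, v in r.atoms.items()}) for r in recs]
        far = ComplexStructure("far", [dimer.chains[0], (cid, moved)])
        assert interface_label(dimer, far) == 0.0

    def test_matches_manual_jaccard_on_toy(self, dimer):
        spec = DecoySpec(jitter_sd=0.5, rigid_translation_max=2.0,
                         rigid_rotation_max=5.0)
        decoy = perturb_decoy(dimer, spec, np.random.default_rng(7))

        def contacts(s):
            out = set()
            residues = s.residues()
            for i, ri in enumerate(residues):
                for j, rj in enumerate(residues):
                    if i < j and ri.chain_id != rj.chain_id:
                        if np.linalg.norm(ri.rep_coord() - rj.rep_coord()) <= 8:
                            out.add(((ri.chain_id, ri.seq_pos),
                                     (rj.chain_id, rj.seq_pos)))
            return out
        a, b = contacts(dimer), contacts(decoy)
        assert interface_label(dimer, decoy) == pytest.approx(
            len(a & b) / len(a | b))

    def test_invariant_under_joint_rigid_motion(self, dimer):
        decoy = perturb_decoy(dimer, DecoySpec(jitter_sd=0.3),
                              np.random.default_rng(8))
        assert interface_label(rigid_transform(dimer, 9),
                               rigid_transform(decoy, 9)) == pytest.approx(
            interface_label(dimer, decoy))


class TestDecoySets:
    def test_labels_degrade_with_perturbation(self):
        spec = DecoySpec(n_chains=2, chain_length=16,
                         rigid_rotation_max=25.0, rigid_translation_max=6.0,
                         jitter_sd=0.6, seed=4)
        _, decoys = generate_decoy_set(spec, 30)
        folds = np.array([f for _, f, _ in decoys])
        # graded magnitudes: first third should beat last third on average
        assert folds[:10].mean() > folds[-10:].mean()

    def test_end_to_end_pipeline_smoke(self):
        from graphema.backbone import Backbone, BackboneConfig, predict
        from graphema.pipeline import featurize_structure
        spec = DecoySpec(n_chains=2, chain_length=10, seed=5)
        _, decoys = generate_decoy_set(spec, 3)
        bb = Backbone(BackboneConfig(hidden=16, n_layers=1, seed=5))
        for decoy, _, _ in decoys:
            score, _ = predict(bb, featurize_structure(decoy))
            assert 0.0 < score < 1.0


class TestEmbeddingDataset:
    def test_noiseless_scores_are_sigmoid_linear(self):
        x, y, m = make_embedding_dataset(50, 8, noise_sd=0.0, seed=6)
        expected = 1.0 / (1.0 + np.exp(-(x @ m["w"] + m["b"])))
        assert np.allclose(y, np.clip(expected, 1e-4, 1 - 1e-4), atol=1e-12)

    def test_same_seed_identical(self):
        a = make_embedding_dataset(20, 4, 0.05, seed=7)
        b = make_embedding_dataset(20, 4, 0.05, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_regression_recovers_mapping(self):
        x, y, m = make_embedding_dataset(10_000, 6, noise_sd=0.0, seed=8)
        keep = (y > 1e-3) & (y < 1 - 1e-3)  # drop clamped rows
        coef, *_ = np.linalg.lstsq(
            np.hstack([x[keep], np.ones((keep.sum(), 1))]),
            logit(y[keep]), rcond=None)
        assert np.allclose(coef[:-1], m["w"], rtol=0.05)

    def test_graph_dataset_labels_are_cross_chain_fraction(self):
        data = make_graph_dataset(3, seed=9)
        assert all(0.0 <= g.label <= 1.0 for g in data)
        assert all(g.x.shape[1] == 83 for g in data)
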