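import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from polyforge.backmapping import (
    backmap_molecule,
    backmap_system,
    connector_map,
    orient_template,
    place_residue,
    worst_clash,
)
from polyforge.residue_graphs import parse_sequence
from polyforge.synthetic import build_fixture, melt_spec
from polyforge.templates import make_templates
from polyforge.topology_gen import gen_params


class TestConnectorMap:
    def test_two_residue_chain(self, vinyl3):
        mol = gen_params(parse_sequence("VNL:2"), vinyl3)
        connectors = connector_map(mol)
        # C2 of residue 0 bonds to C1 of residue 1
        assert connectors[0] == [(1, 1, 3)]
        assert connectors[1] == [(3, 0, 1)]


class TestOrientTemplate:
    def test_no_connectors_is_identity(self):
        rotation = orient_template(np.empty((0, 3)), np.empty((0, 3)))
        assert np.allclose(rotation.as_matrix(), np.eye(3))

    def test_single_connector_aligns_axis(self):
        rotation = orient_template([[0, 1.0, 0]], [[2.0, 0, 0]])
        aligned = rotation.apply([0, 1.0, 0])
        assert np.allclose(aligned, [1, 0, 0], atol=1e-10)

    def test_recovers_synthetic_rotation(self, rng):
        truth = Rotation.random(random_state=11)
        offsets = rng.normal(size=(3, 3))
        rotation = orient_template(offsets, truth.apply(offsets))
        assert np.allclose(rotation.as_matrix(), truth.as_matrix(),
                           atol=1e-8)

    def test_objective_beats_random_rotations(self, vinyl3, rng):
        templates = make_templates(vinyl3)
        offsets = templates["VNL"].array() \
            - templates["VNL"].array().mean(axis=0)
        targets = rng.normal(size=(3, 3))
        best = orient_template(offsets, targets)

        def objective(rot):
            return np.sum((rot.apply(offsets) - targets) ** 2)

        best_val = objective(best)
        random_rots = Rotation.random(1000, random_state=2)
        assert all(best_val <= objective(r) + 1e-9 for r in random_rots)


class TestPlaceResidue:
    def test_fudge_scales_offsets(self, vinyl3):
        template = make_templates(vinyl3)["VNL"]
        placed = place_residue(template, Rotation.identity(),
                               np.zeros(3), fudge=0.45)
        for name, pos in template.positions.items():
            centered = pos - template.array().mean(axis=0)
            assert np.allclose(placed[name], 0.45 * centered)

    def test_unit_fudge_preserves_distances(self, vinyl3):
        template = make_templates(vinyl3)["VNL"]
        placed = place_residue(template, Rotation.random(random_state=5),
                               np.array([3.0, 2.0, 1.0]), fudge=1.0)
        d_in = np.linalg.norm(template.positions["C1"]
                              - template.positions["C2"])
        d_out = np.linalg.norm(placed["C1"] - placed["C2"])
        assert d_out == pytest.approx(d_in, abs=1e-12)

    def test_center_of_geometry_on_bead(self, vinyl3, rng):
        template = make_templates(vinyl3)["VNL"]
        bead = rng.uniform(0, 10, 3)
        placed = place_residue(template, Rotation.random(random_state=8),
                               bead)
        cog = np.mean(list(placed.values()), axis=0)
        assert np.allclose(cog, bead, atol=1e-12)


class TestBackmapSystem:
    def test_single_one_atom_residue_on_bead(self, nucleotide1):
        mol = gen_params(parse_sequence("T:1"), nucleotide1, name="DNA")
        templates = make_templates(nucleotide1, r_a=0.43)
        box = np.array([5.0, 5.0, 5.0])
        coords = backmap_molecule(mol, templates,
                                  {0: np.array([1.0, 2.0, 3.0])}, box)
        assert np.allclose(coords[0], [1.0, 2.0, 3.0])

    def test_connectors_face_each_other(self, vinyl3):
        mol = gen_params(parse_sequence("VNL:2"), vinyl3)
        templates = make_templates(vinyl3)
        box = np.array([10.0, 10.0, 10.0])
        beads = {0: np.array([4.0, 5.0, 5.0]), 1: np.array([4.6, 5.0, 5.0])}
        coords = backmap_molecule(mol, templates, beads, box)
        # the inter-residue connector atoms (C2 of res0, C1 of res1) are the
        # closest pair across the two residues
        cross = {(i, j): np.linalg.norm(coords[i] - coords[j])
                 for i in range(3) for j in range(3, 6)}
        assert min(cross, key=cross.get) == (1, 3)

    def test_melt_cog_conservation_and_scaling(self, vinyl3):
        system, ctx = build_fixture(melt_spec(10, 5, volume_fraction=0.3,
                                              seed=2, library="vinyl3"))
        positions, meta = backmap_system(system, ctx["top_model"],
                                         ctx["templates"])
        assert len(positions) == 10 * 5 * 3
        template = ctx["templates"]["VNL"]
        centered = template.array() - template.array().mean(axis=0)
        k = 0
        for _name, beads in system.molecules:
            for resid in sorted(beads):
                chunk = positions[k:k + 3]
                assert np.allclose(chunk.mean(axis=0), beads[resid],
                                   atol=1e-12)
                for a in range(3):
                    for b in range(a + 1, 3):
                        got = np.linalg.norm(chunk[a] - chunk[b])
                        want = 0.45 * np.linalg.norm(centered[a] - centered[b])
                        assert got == pytest.approx(want, abs=1e-12)
                k += 3

    def test_melt_has_no_hard_clashes(self, vinyl3):
        system, ctx = build_fixture(melt_spec(20, 10, volume_fraction=0.3,
                                              seed=4, library="vinyl3"))
        positions, meta = backmap_system(system, ctx["top_model"],
                                         ctx["templates"])
        n_bad, min_d = worst_clash(positions, system.box,
                                   same_residue=np.asarray(meta["resids"]))
        assert n_bad == 0, f"{n_bad} atom pairs closer than 0.05 nm ({min_d})"
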