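import numpy as np
import pytest

from polyforge.errors import InputError
from polyforge.io_formats import parse_library_text
from polyforge.templates import (
    build_supercg,
    derive_sigma,
    embed_residue,
    enforce_chirality,
    make_template,
    radius_of_gyration,
    _dihedral_angle,
)
from polyforge.topology_gen import gen_params
from polyforge.residue_graphs import parse_sequence

_TETRA = """
[ moleculetype ]
TET 1
[ atoms ]
1 C 1 TET C0 1 0.0 12.0
2 H 1 TET H1 2 0.0 1.0
3 H 1 TET H2 3 0.0 1.0
4 H 1 TET H3 4 0.0 1.0
[ bonds ]
C0 H1 1 0.15 8000
C0 H2 1 0.15 8000
C0 H3 1 0.15 8000
[ angles ]
H1 C0 H2 1 109.47 200
H2 C0 H3 1 109.47 200
H1 C0 H3 1 109.47 200
[ dihedrals ]
H1 H2 H3 C0 2 35.0 200
"""


@pytest.fixture(scope="module")
def tetra_block():
    return parse_library_text(_TETRA).blocks["TET"]


class TestEmbedResidue:
    def test_single_atom_at_origin(self, nucleotide1):
        positions = embed_residue(nucleotide1.blocks["T"])
        assert np.allclose(positions["B1"], 0.0)

    def test_two_atom_bond_length(self):
        lib = parse_library_text(
            "[ moleculetype ]\nDUO 1\n[ atoms ]\n"
            "1 A 1 DUO A1 1 0.0 1.0\n2 A 1 DUO A2 2 0.0 1.0\n"
            "[ bonds ]\nA1 A2 1 0.47 5000\n"
        )
        positions = embed_residue(lib.blocks["DUO"])
        assert np.linalg.norm(positions["A1"] - positions["A2"]) == \
            pytest.approx(0.47, abs=1e-3)

    def test_three_atom_apex_distance(self, vinyl3):
        # two 0.15 nm bonds with a 109.47 deg angle between them
        positions = embed_residue(vinyl3.blocks["VNL"])
        apex = np.linalg.norm(positions["C2"] - positions["S1"])
        expected = 2 * 0.15 * np.sin(np.deg2rad(109.47 / 2))
        assert apex == pytest.approx(expected, abs=2e-3)

    def test_deterministic_for_fixed_seed(self, vinyl3):
        a = embed_residue(vinyl3.blocks["VNL"], seed=42)
        b = embed_residue(vinyl3.blocks["VNL"], seed=42)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_nonbonded_atoms_separated(self, tetra_block):
        positions = embed_residue(tetra_block)
        names = list(positions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert np.linalg.norm(positions[a] - positions[b]) > 0.08


class TestRadiusOfGyration:
    def test_point_is_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_points_half_distance(self):
        assert radius_of_gyration([[0, 0, 0], [0, 0, 0.8]]) == \
            pytest.approx(0.4)

    def test_unit_square(self):
        square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        assert radius_of_gyration(square) == pytest.approx(np.sqrt(2) / 2)


class TestDeriveSigma:
    def test_point_residue_collapses_to_atomic_diameter(self):
        rho, sigma = derive_sigma(0.0, r_a=0.21)
        assert sigma == pytest.approx(0.42)

    def test_formula_value(self):
        rho, sigma = derive_sigma(0.2, r_a=0.21)
        assert rho == pytest.approx(np.sqrt(5 / 3) * 0.2 + 0.21, abs=1e-4)
        assert sigma == pytest.approx(2 * rho)

    def test_monotone_in_rg_and_rotation_invariant(self, vinyl3, rng):
        template = make_template(vinyl3.blocks["VNL"])
        doubled = radius_of_gyration(2.0 * template.array())
        assert doubled == pytest.approx(2 * template.rg)
        assert derive_sigma(doubled)[1] > derive_sigma(template.rg)[1]
        # rigid rotation leaves rg (hence sigma) unchanged
        from scipy.spatial.transform import Rotation

        rotated = Rotation.random(random_state=3).apply(template.array())
        assert radius_of_gyration(rotated + 1.7) == \
            pytest.approx(template.rg, abs=1e-12)


class TestEnforceChirality:
    def test_target_sign_obtained(self, tetra_block):
        template = make_template(tetra_block)
        pos = template.positions
        xi = _dihedral_angle(pos["H1"], pos["H2"], pos["H3"], pos["C0"])
        assert 0.0 < np.rad2deg(xi) < 90.0

    def test_mirror_image_corrected(self, tetra_block):
        positions = embed_residue(tetra_block)
        mirrored = {k: v * np.array([1.0, 1.0, -1.0])
                    for k, v in positions.items()}
        fixed = enforce_chirality(tetra_block, mirrored)
        xi = _dihedral_angle(fixed["H1"], fixed["H2"], fixed["H3"],
                             fixed["C0"])
        assert np.sign(xi) == 1.0

    def test_identity_without_impropers(self, vinyl3):
        positions = embed_residue(vinyl3.blocks["VNL"])
        assert enforce_chirality(vinyl3.blocks["VNL"], positions) is positions


def test_supercg_carries_rho(bead_spring):
    from polyforge.templates import make_templates

    mol = gen_params(parse_sequence("B:4"), bead_spring)
    templates = make_templates(bead_spring)
    model = build_supercg(mol, templates)
    assert all(model.graph.nodes[n]["rho"] == pytest.approx(0.21)
               for n in model.graph.nodes)
    assert model.sigma(0, 1) == pytest.approx(0.42)
    assert model.epsilon == 1.0


def test_missing_template_is_an_error(bead_spring):
    mol = gen_params(parse_sequence("B:2"), bead_spring)
    with pytest.raises(InputError, match="'B'"):
        build_supercg(mol, {})
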