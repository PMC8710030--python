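"""Z-matrix parsing, Cartesian embedding and torsion bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torscan.geom import (
    GeometryError,
    TorsionVector,
    ZMatrixError,
    circular_distance,
    format_zmatrix,
    measure_dihedral,
    measure_dihedral_signed,
    measure_torsions,
    nearest_template,
    parse_zmatrix,
    substitute_torsions,
    write_xyz,
    zmatrix_to_cartesian,
)


class TestTorsionVector:
    def test_canonicalises_to_0_360(self):
        v = TorsionVector([-10.0, 370.0, 180.0])
        assert np.allclose(v.values, [350.0, 10.0, 180.0])

    def test_immutable(self):
        v = TorsionVector([10.0])
        with pytest.raises(AttributeError):
            v.values = np.array([20.0])

    @pytest.mark.parametrize(
        "a, b, expected",
        [((350.0,), (10.0,), 20.0), ((0.0,), (180.0,), 180.0), ((5.0,), (5.0,), 0.0)],
    )
    def test_wraparound_distance(self, a, b, expected):
        assert TorsionVector(a).distance(TorsionVector(b)) == pytest.approx(expected)


class TestParser:
    def test_water_like_without_torsions_rejected(self):
        text = "O\nH 1 0.96\nH 1 0.96 2 104.5\n"
        with pytest.raises(ZMatrixError, match="K >= 1"):
            parse_zmatrix(text)

    def test_minimal_chain_single_torsion(self, chain_zmat):
        zk1 = parse_zmatrix(
            "C\nC 1 1.5\nC 2 1.5 1 120.0\nC 3 1.5 2 120.0 1 d1\n\nd1 45.0 *\n"
        )
        assert zk1.k == 1
        (t,) = zk1.target_torsions
        assert t.atoms == (3, 2, 1, 0)
        assert zk1.torsion_values() == TorsionVector([45.0])

    def test_glycine_like_reference_flags_three_backbone_torsions(self, amino_zmat):
        assert amino_zmat.k == 3
        labels = [a.label for a in amino_zmat.atoms]
        chains = [
            tuple(labels[i] for i in t.atoms) for t in amino_zmat.target_torsions
        ]
        # phi1 = H5-O1-C1-C2, phi2 = O1-C1-C2-N, phi3 = C1-C2-N-H1
        # (dihedral i-j-k-l is stored with the defining atom first)
        assert chains[0] == ("C2", "C1", "O1", "H5")
        assert chains[1] == ("N", "C2", "C1", "O1")
        assert chains[2] == ("H1", "N", "C2", "C1")

    def test_malformed_line_names_line_number(self):
        with pytest.raises(ZMatrixError, match="line 2"):
            parse_zmatrix("C\nC 1\nC 2 1.5 1 120.0\n")

    def test_missing_target_dihedral_is_definition_error(self):
        text = "C\nC 1 1.5\nC 2 1.5 1 120.0\nC 3 1.5 2 120.0 1 d1\n\nd1 45.0\nd9 0.0 *\n"
        with pytest.raises(ZMatrixError, match="d9"):
            parse_zmatrix(text)

    def test_duplicate_torsion_about_same_bond_rejected(self):
        # two target dihedrals sharing the central 3-2 bond
        text = (
            "C\nC 1 1.5\nC 2 1.5 1 120.0\n"
            "C 3 1.5 2 120.0 1 d1\nC 3 1.5 2 120.0 1 d2\n\n"
            "d1 45.0 *\nd2 165.0 *\n"
        )
        with pytest.raises(ZMatrixError, match="twice|once"):
            parse_zmatrix(text)

    def test_dummy_atom_cannot_be_torsion_target(self):
        text = (
            "C\nC 1 1.5\nC 2 1.5 1 120.0\nX 3 1.0 2 90.0 1 d1\n\nd1 45.0 *\n"
        )
        with pytest.raises(ZMatrixError, match="dummy"):
            parse_zmatrix(text)

    def test_forward_reference_rejected(self):
        with pytest.raises(ZMatrixError):
            parse_zmatrix("C\nC 3 1.5\nC 2 1.5 1 120.0\n", require_torsions=False)

    def test_roundtrip_through_formatter(self, amino_zmat):
        again = parse_zmatrix(format_zmatrix(amino_zmat))
        assert again.k == amino_zmat.k
        assert [a.element for a in again.atoms] == [a.element for a in amino_zmat.atoms]
        assert np.allclose(
            again.torsion_values().values, amino_zmat.torsion_values().values
        )


class TestEmbedding:
    def test_two_atom_convention(self):
        g = zmatrix_to_cartesian(parse_zmatrix("H\nH 1 1.0\n", require_torsions=False))
        assert np.allclose(g.coords[0], [0, 0, 0])
        assert np.allclose(g.coords[1], [0, 0, 1.0])

    def test_third_atom_in_xz_plane(self):
        g = zmatrix_to_cartesian(
            parse_zmatrix("O\nH 1 0.96\nH 1 0.96 2 104.5\n", require_torsions=False)
        )
        assert abs(g.coords[2][1]) < 1e-12
        assert g.coords[2][0] >= 0

    @pytest.mark.parametrize("phi", [0.0, 60.0, 180.0, 300.0, 359.5])
    def test_dihedral_roundtrip(self, chain_zmat, phi):
        z = substitute_torsions(chain_zmat, TorsionVector([phi, 120.0]))
        g = zmatrix_to_cartesian(z)
        assert float(
            circular_distance(measure_dihedral(g, 3, 2, 1, 0), phi)
        ) < 1e-6

    def test_internal_coordinate_roundtrip(self, amino_zmat):
        """Every bond, angle and dihedral survives the Cartesian embedding."""
        g = zmatrix_to_cartesian(amino_zmat)
        for i, atom in enumerate(amino_zmat.atoms):
            if atom.r is not None:
                assert g.distance(i, atom.refs[0]) == pytest.approx(atom.r, abs=1e-8)
            if atom.theta is not None:
                assert g.angle(i, atom.refs[0], atom.refs[1]) == pytest.approx(
                    atom.theta, abs=1e-6
                )
            if atom.phi is not None:
                measured = measure_dihedral(g, i, *atom.refs)
                assert float(circular_distance(measured, atom.phi)) < 1e-6

    def test_colinear_dihedral_frame_rejected(self):
        text = "C\nC 1 1.5\nC 2 1.5 1 179.9999999\nC 3 1.5 2 120.0 1 d1\n\nd1 45.0 *\n"
        with pytest.raises(GeometryError, match="colinear"):
            zmatrix_to_cartesian(parse_zmatrix(text))


class TestMeasureDihedral:
    def _planar(self, phi):
        z = parse_zmatrix(
            "C\nC 1 1.5\nC 2 1.5 1 110.0\nC 3 1.5 2 110.0 1 d1\n\nd1 0.0 *\n"
        )
        return zmatrix_to_cartesian(
            substitute_torsions(z, TorsionVector([phi]))
        )

    def test_planar_cis_is_zero(self):
        assert measure_dihedral(self._planar(0.0), 3, 2, 1, 0) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_planar_trans_is_180(self):
        assert measure_dihedral(self._planar(180.0), 3, 2, 1, 0) == pytest.approx(
            180.0, abs=1e-9
        )

    @given(phi=st.floats(1.0, 359.0))
    @settings(max_examples=25, deadline=None)
    def test_reflection_negates(self, phi):
        g = self._planar(phi)
        coords = np.array(g.coords)
        coords[:, 0] = -coords[:, 0]
        gm = type(g)(g.elements, coords)
        d, dm = measure_dihedral(g, 3, 2, 1, 0), measure_dihedral(gm, 3, 2, 1, 0)
        assert float(circular_distance(dm, (360.0 - d) % 360.0)) < 1e-9

    @given(
        phi=st.floats(0.0, 360.0, exclude_max=True),
        axis=st.integers(0, 2),
        angle=st.floats(-180.0, 180.0),
        shift=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, phi, axis, angle, shift):
        from scipy.spatial.transform import Rotation

        g = self._planar(phi)
        rot = Rotation.from_euler("xyz"[axis], angle, degrees=True)
        coords = rot.apply(np.array(g.coords)) + shift
        gt = type(g)(g.elements, coords)
        assert float(
            circular_distance(
                measure_dihedral(g, 3, 2, 1, 0), measure_dihedral(gt, 3, 2, 1, 0)
            )
        ) < 1e-6

    def test_colinear_triple_rejected(self):
        from torscan.geom import CartesianGeometry

        g = CartesianGeometry(
            ("C", "C", "C", "C"),
            np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [1, 0, 3]], float),
        )
        with pytest.raises(GeometryError, match="colinear"):
            measure_dihedral_signed(g, 0, 1, 2, 3)


class TestSubstitution:
    def test_identity(self, chain_zmat):
        out = substitute_torsions(chain_zmat, chain_zmat.torsion_values())
        assert out.atoms == chain_zmat.atoms

    def test_changes_exactly_k_fields(self, chain_zmat):
        out = substitute_torsions(chain_zmat, TorsionVector([180.0, 300.0]))
        changed = [
            i
            for i, (a, b) in enumerate(zip(chain_zmat.atoms, out.atoms))
            if a != b
        ]
        assert changed == [t.atom for t in chain_zmat.target_torsions]
        for a, b in zip(chain_zmat.atoms, out.atoms):
            assert (a.r, a.theta, a.refs, a.element) == (b.r, b.theta, b.refs, b.element)

    def test_length_mismatch(self, chain_zmat):
        with pytest.raises(ZMatrixError, match="length"):
            substitute_torsions(chain_zmat, TorsionVector([1.0]))

    @given(
        phis=st.lists(st.floats(0.0, 360.0, exclude_max=True), min_size=2, max_size=2)
    )
    @settings(max_examples=25, deadline=None)
    def test_substitute_measure_roundtrip(self, phis):
        chain = (
            "C\nC 1 1.52\nC 2 1.52 1 132.0\nC 3 1.52 2 132.0 1 t1\n"
            "C 4 1.52 3 132.0 2 t2\n\nt1 60.0 *\nt2 60.0 *\n"
        )
        z = substitute_torsions(parse_zmatrix(chain), TorsionVector(phis))
        measured = measure_torsions(zmatrix_to_cartesian(z), z)
        assert all(
            float(circular_distance(m, p)) < 1e-6
            for m, p in zip(measured.values, phis)
        )


class _StubConformer:
    def __init__(self, zmatrix, torsions):
        self.zmatrix = zmatrix
        self.torsions = torsions


class _StubPool:
    def __init__(self, reference, conformers):
        self.reference = reference
        self.conformers = conformers


class TestNearestTemplate:
    def test_empty_pool_uses_reference(self, chain_zmat):
        phi = TorsionVector([10.0, 20.0])
        out = nearest_template(_StubPool(chain_zmat, []), phi)
        assert np.allclose(out.torsion_values().values, [10.0, 20.0])

    def test_picks_circularly_closest(self, chain_zmat):
        pool = _StubPool(
            chain_zmat,
            [
                _StubConformer(
                    substitute_torsions(chain_zmat, TorsionVector(v)), TorsionVector(v)
                )
                for v in ([0.0, 0.0], [180.0, 180.0])
            ],
        )
        out = nearest_template(pool, TorsionVector([170.0, 190.0]))
        # template from (180,180), with the new torsions substituted
        assert np.allclose(out.torsion_values().values, [170.0, 190.0])
        # non-target internals come from the chosen conformer (identical here)

    def test_wraparound_distance_used(self, chain_zmat):
        near = _StubConformer(
            substitute_torsions(chain_zmat, TorsionVector([350.0, 0.0])),
            TorsionVector([350.0, 0.0]),
        )
        far = _StubConformer(
            substitute_torsions(chain_zmat, TorsionVector([180.0, 0.0])),
            TorsionVector([180.0, 0.0]),
        )
        phi = TorsionVector([10.0, 0.0])
        assert phi.distance(near.torsions) == pytest.approx(20.0)
        out = nearest_template(_StubPool(chain_zmat, [far, near]), phi)
        assert np.allclose(out.torsion_values().values, phi.values)


def test_write_xyz_format(chain_zmat):
    g = zmatrix_to_cartesian(chain_zmat)
    text = write_xyz(g, comment="test")
    lines = text.splitlines()
    assert lines[0] == "5"
    assert lines[1] == "test"
    assert len(lines) == 7
    assert lines[2].split()[0] == "C"
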