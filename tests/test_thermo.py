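"""MS-HO thermochemistry, N90 statistics and backbone classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import constants as sc

from torscan.geom import GeometryError, CartesianGeometry
from torscan.thermo import (
    BackboneAngles,
    ConformerThermo,
    backbone_angles_from_geometry,
    classify_backbone,
    conformer_weights,
    identify_backbone,
    lone_pair_direction,
    msho_partition,
    n90,
    read_conformer_dataset,
    rrho_partition,
    summary_table,
    write_conformer_dataset,
)

INERTIA = (50.0, 60.0, 70.0)


def _conf(u, freqs=(100.0,), inertia=INERTIA, **kw):
    return ConformerThermo(u=u, frequencies=tuple(freqs), inertia=inertia, **kw)


def _rt_kcal(t):
    return sc.R * t / (sc.calorie * 1000.0)


class TestRRHO:
    def test_stiff_mode_vibrational_factor_tends_to_one(self):
        soft = _conf(0.0, freqs=())
        stiff = _conf(0.0, freqs=(30000.0,))
        ratio = rrho_partition(stiff, 300.0, freq_scale=1.0) / rrho_partition(
            soft, 300.0, freq_scale=1.0
        )
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_rotational_factor_scales_as_inertia_to_three_halves(self):
        q1 = rrho_partition(_conf(0.0, freqs=()), 300.0, freq_scale=1.0)
        q2 = rrho_partition(
            _conf(0.0, freqs=(), inertia=tuple(2 * i for i in INERTIA)),
            300.0,
            freq_scale=1.0,
        )
        assert q2 / q1 == pytest.approx(2.0 ** 1.5, rel=1e-12)

    def test_vibrational_factor_closed_form(self):
        t, nu = 300.0, 100.0
        theta = sc.h * sc.c * 100.0 * nu / (sc.k * t)
        expected = 1.0 / (1.0 - math.exp(-theta))
        ratio = rrho_partition(_conf(0.0, (nu,)), t, freq_scale=1.0) / rrho_partition(
            _conf(0.0, ()), t, freq_scale=1.0
        )
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_frequency_scaling_applied(self):
        t = 300.0
        q_scaled = rrho_partition(_conf(0.0, (100.0,)), t, freq_scale=0.973)
        q_manual = rrho_partition(_conf(0.0, (97.3,)), t, freq_scale=1.0)
        assert q_scaled == pytest.approx(q_manual, rel=1e-12)

    def test_symmetry_number_divides_rotation(self):
        q1 = rrho_partition(_conf(0.0, ()), 300.0, freq_scale=1.0, sigma=1)
        q2 = rrho_partition(_conf(0.0, ()), 300.0, freq_scale=1.0, sigma=3)
        assert q1 / q2 == pytest.approx(3.0, rel=1e-12)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            rrho_partition(_conf(0.0, (-50.0,)), 300.0)


class TestMSHO:
    def test_single_conformer_equals_rrho(self):
        c = _conf(0.0)
        assert msho_partition([c], 300.0) == pytest.approx(
            rrho_partition(c, 300.0), rel=1e-14
        )

    def test_two_identical_conformers_double(self):
        c = _conf(0.0)
        assert msho_partition([c, c], 300.0) == pytest.approx(
            2 * rrho_partition(c, 300.0), rel=1e-14
        )

    def test_low_temperature_limit_concentrates_on_global_minimum(self):
        confs = [_conf(0.0), _conf(1.0)]
        w_cold = conformer_weights(confs, 20.0)
        w_hot = conformer_weights(confs, 2000.0)
        assert w_cold[0] > 0.999999
        assert w_hot[0] < 0.7

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            msho_partition([], 300.0)

    def test_unzeroed_energies_rejected(self):
        with pytest.raises(ValueError, match="zeroed"):
            msho_partition([_conf(0.5)], 300.0)


class TestWeights:
    def test_single_conformer_weight_is_one(self):
        assert conformer_weights([_conf(0.0)], 300.0)[0] == pytest.approx(1.0, abs=1e-15)

    def test_rt_ln2_gap_gives_two_thirds_one_third(self):
        t = 300.0
        du = _rt_kcal(t) * math.log(2.0)
        w = conformer_weights([_conf(0.0), _conf(du)], t)
        assert w[0] == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert w[1] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_permutation_equivariance(self):
        confs = [_conf(0.0), _conf(0.3, freqs=(80.0,)), _conf(1.1, freqs=(120.0,))]
        w = conformer_weights(confs, 300.0)
        w_perm = conformer_weights([confs[2], confs[0], confs[1]], 300.0)
        assert np.allclose(w_perm, [w[2], w[0], w[1]], atol=1e-15)

    @given(seed=st.integers(0, 1000), t=st.sampled_from([100.0, 300.0, 1000.0]))
    @settings(max_examples=30, deadline=None)
    def test_normalisation_to_machine_precision(self, seed, t):
        rng = np.random.default_rng(seed)
        confs = [
            _conf(
                0.0 if i == 0 else float(rng.uniform(0, 8)),
                freqs=tuple(rng.uniform(40, 3500, size=5)),
                inertia=tuple(rng.uniform(20, 400, size=3)),
            )
            for i in range(int(rng.integers(1, 12)))
        ]
        assert abs(conformer_weights(confs, t).sum() - 1.0) < 1e-12


class TestN90:
    def test_prefix_sum_example(self):
        """Weights engineered to (0.5, 0.3, 0.15, 0.05) in energy order:
        three conformers reach 90%."""
        t = 300.0
        rt = _rt_kcal(t)
        target = [0.5, 0.3, 0.15, 0.05]
        confs = [_conf(-rt * math.log(x / target[0]) if i else 0.0)
                 for i, x in enumerate(target)]
        w = conformer_weights(confs, t)
        assert np.allclose(w, target, atol=1e-12)
        assert n90(confs, t, 0.9) == 3

    def test_single_conformer(self):
        assert n90([_conf(0.0)], 300.0, 0.9) == 1

    def test_nonincreasing_toward_low_temperature(self):
        rng = np.random.default_rng(7)
        confs = [_conf(0.0)] + [_conf(float(u)) for u in sorted(rng.uniform(0.2, 4, 9))]
        counts = [n90(confs, t, 0.9) for t in (1000.0, 300.0, 100.0, 30.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            n90([_conf(0.0)], 300.0, 1.5)


class TestClassification:
    @pytest.mark.parametrize(
        "angles, expected",
        [
            ((0.0, 0.0, 0.0), "II"),
            ((180.0, 0.0, 180.0), "III"),
            ((90.0, 90.0, 90.0), "IV"),
            ((33.0, 180.0, 180.0), "I"),     # phi1 is free for type I
        ],
    )
    def test_reference_assignments(self, angles, expected):
        assert classify_backbone(BackboneAngles(*angles)).name == expected

    def test_type_iv_distances_match_hand_arithmetic(self):
        d = classify_backbone(BackboneAngles(90.0, 90.0, 90.0)).distances
        assert d[0] == pytest.approx(math.sqrt(2 * 90.0**2))
        assert d[1] == pytest.approx(math.sqrt(3 * 90.0**2))
        assert d[2] == pytest.approx(math.sqrt(3 * 90.0**2))

    @given(
        phi1=st.floats(0, 360, exclude_max=True),
        phi2=st.floats(0, 360, exclude_max=True),
        phi3=st.floats(0, 360, exclude_max=True),
        shifts=st.tuples(
            st.integers(-2, 2), st.integers(-2, 2), st.integers(-2, 2)
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_360_shifts(self, phi1, phi2, phi3, shifts):
        base = classify_backbone(BackboneAngles(phi1, phi2, phi3)).name
        shifted = classify_backbone(
            BackboneAngles(
                phi1 + 360 * shifts[0], phi2 + 360 * shifts[1], phi3 + 360 * shifts[2]
            )
        ).name
        assert base == shifted

    def test_threshold_controls_type_iv(self):
        a = BackboneAngles(90.0, 90.0, 90.0)
        assert classify_backbone(a, threshold=75.0).name == "IV"
        assert classify_backbone(a, threshold=200.0).name == "I"


class TestLonePair:
    def _pyramidal(self):
        # N at origin, three neighbours arranged symmetrically below the z-axis
        coords = [[0.0, 0.0, 0.0]]
        for ang in (0, 120, 240):
            coords.append(
                [
                    math.cos(math.radians(ang)) * 0.94,
                    math.sin(math.radians(ang)) * 0.94,
                    -0.35,
                ]
            )
        return CartesianGeometry(("N", "H", "H", "H"), np.array(coords))

    def test_symmetric_amine_lp_along_axis(self):
        lp = lone_pair_direction(self._pyramidal(), 0, [1, 2, 3])
        assert np.allclose(lp, [0.0, 0.0, 1.0], atol=1e-12)

    def test_planar_nitrogen_rejected(self):
        coords = [[0.0, 0.0, 0.0]]
        for ang in (0, 120, 240):
            coords.append(
                [math.cos(math.radians(ang)), math.sin(math.radians(ang)), 0.0]
            )
        flat = CartesianGeometry(("N", "H", "H", "H"), np.array(coords))
        with pytest.raises(GeometryError, match="planar"):
            lone_pair_direction(flat, 0, [1, 2, 3])

    def test_wrong_neighbour_count_rejected(self):
        with pytest.raises(GeometryError, match="3 neighbours"):
            lone_pair_direction(self._pyramidal(), 0, [1, 2])

    def test_mirror_equivariance(self):
        g = self._pyramidal()
        coords = np.array(g.coords)
        coords[:, 0] = -coords[:, 0]
        gm = CartesianGeometry(g.elements, coords)
        lp = lone_pair_direction(g, 0, [1, 2, 3])
        lpm = lone_pair_direction(gm, 0, [1, 2, 3])
        assert np.allclose(lpm, lp * np.array([-1.0, 1.0, 1.0]), atol=1e-12)


class TestBackboneFromGeometry:
    def test_identifies_amino_backbone(self, amino_fixture):
        from torscan.geom import zmatrix_to_cartesian

        g = zmatrix_to_cartesian(amino_fixture.zmatrix)
        atoms = identify_backbone(g)
        labels = [a.label for a in amino_fixture.zmatrix.atoms]
        assert labels[atoms.c1] == "C1"
        assert labels[atoms.ca] == "C2"
        assert labels[atoms.n] == "N"
        assert labels[atoms.h] == "H5"

    def test_classification_runs_end_to_end(self, amino_fixture):
        from torscan.geom import TorsionVector, substitute_torsions, zmatrix_to_cartesian

        # phi1=0 puts O=C-O-H anti and H-O-C1-Ca syn: a type-II-like frame
        z = substitute_torsions(
            amino_fixture.zmatrix, TorsionVector([0.0, 180.0, 180.0])
        )
        angles = backbone_angles_from_geometry(zmatrix_to_cartesian(z))
        assert classify_backbone(angles).name in {"I", "II", "III", "IV"}


class TestDatasetIO:
    def _text(self):
        return (
            "conformer a\nenergy 0.0\ninertia 50 60 70\nzpe 10.0\n"
            "freqs 100 200\n300 400\n\n"
            "conformer b\nenergy 1.5\ninertia 55 65 75\ndipole 1.3\n"
            "origin stochastic\nfreqs 150\n"
        )

    def test_reader_parses_blocks_and_wrapped_freqs(self):
        confs = read_conformer_dataset(self._text())
        assert [c.label for c in confs] == ["a", "b"]
        assert confs[0].frequencies == (100.0, 200.0, 300.0, 400.0)
        assert confs[0].zpe == 10.0
        assert confs[1].origin == "stochastic"

    def test_strict_mode_raises_on_missing_energy(self):
        bad = "conformer x\ninertia 50 60 70\nfreqs 100\n"
        with pytest.raises(ValueError, match="energy"):
            read_conformer_dataset(bad, strict=True)

    def test_tolerant_mode_skips_malformed_blocks(self):
        text = self._text() + "\nconformer broken\ninertia 1 2 3\n"
        confs = read_conformer_dataset(text, strict=False)
        assert [c.label for c in confs] == ["a", "b"]

    def test_writer_reader_roundtrip(self, amino_fixture):
        from torscan.geom import zmatrix_to_cartesian

        g = zmatrix_to_cartesian(amino_fixture.zmatrix)
        orig = [
            ConformerThermo(
                u=0.0, frequencies=(101.5, 300.25), inertia=(50.0, 60.0, 70.0),
                zpe=49.9, label="g1", geometry=g, origin="preconditioned",
            )
        ]
        back = read_conformer_dataset(write_conformer_dataset(orig))
        assert back[0].u == orig[0].u
        assert back[0].frequencies == orig[0].frequencies
        assert back[0].origin == "preconditioned"
        assert np.allclose(back[0].geometry.coords, g.coords, atol=1e-7)


def test_summary_table_orders_by_energy(amino_fixture):
    from torscan.geom import zmatrix_to_cartesian

    g = zmatrix_to_cartesian(amino_fixture.zmatrix)
    confs = [
        _conf(1.0, geometry=g, label="hi"),
        _conf(0.0, geometry=g, label="lo"),
    ]
    df = summary_table(confs, 300.0)
    assert list(df["id"]) == ["lo", "hi"]
    assert df["cumulative_chi"].iloc[-1] == pytest.approx(1.0, abs=1e-12)
    assert set(df["type"]) <= {"I", "II", "III", "IV", ""}
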