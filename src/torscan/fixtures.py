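"""Synthetic desk-scale test systems: toy molecules + toy torsional PESs.

Each fixture bundles a Z-matrix with K flagged torsions, the analytic PES
parameters driving the toy backend, the brute-force-enumerated minimum list
(the independent oracle output) and the preconditioned seed menu.  Kinds:

* ``separable-3fold`` — independent 3-fold wells; minima exactly on the
  {0, 120, 240}^K grid regardless of the seeded well depths.
* ``coupled`` — mixed 2-/3-fold terms plus pairwise cosine couplings; the
  minimum set is whatever the oracle enumerates.
* ``cs-symmetric`` — reflection-symmetric PES (every phase 0 or 180, even
  couplings); the minimum set is closed under Phi -> -Phi, exercising the
  conformational-enantiomer machinery.
* ``amino-backbone-toy`` — a glycine-like H-O-C(=O)-Ca(-H2)-N(-H2) skeleton
  with the three backbone torsions flagged, so umbrella repair, enantiomer
  renumbering and backbone classification run end to end.

The skeleton geometries are plain carbon chains (or the amino backbone) with
generous bond lengths so that no torsion combination creates a spurious
contact under the default bonding criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import ToyPESParams, brute_force_minima
from .geom import TorsionVector, ZMatrix, parse_zmatrix
from .search import SP3_SEEDS, TWOFOLD_SEEDS, TorsionSpec
from .validate import TorsionSymmetry

__all__ = ["Fixture", "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "separable-3fold",
    "coupled",
    "cs-symmetric",
    "amino-backbone-toy",
)


@dataclass(frozen=True)
class Fixture:
    kind: str
    zmatrix: ZMatrix
    params: ToyPESParams
    expected_minima: tuple[TorsionVector, ...]
    spec: TorsionSpec
    torsion_symmetry: tuple[TorsionSymmetry, ...] | None = None
    amine: tuple[int, int, int, int] | None = None


def _chain_zmatrix(k: int) -> ZMatrix:
    """A C_(K+3) chain whose last K atoms each define one target dihedral.

    The 132-degree backbone angle keeps every non-adjacent pair clear of the
    default bonding threshold at *all* torsion combinations for K <= 3, so
    the chain realises a pure torsional PES: the connectivity test never
    interferes with the toy energetics (verified by grid scan in the tests).
    The terminal nitrogen breaks the head-tail graph symmetry so that every
    atom is uniquely identified by element + connectivity (required by the
    enantiomer renumbering).
    """
    lines = ["C", "C 1 1.52", "C 2 1.52 1 132.0"]
    varlines = []
    for i in range(k):
        a = 4 + i
        el = "N" if i == k - 1 else "C"
        lines.append(f"{el} {a - 1} 1.52 {a - 2} 132.0 {a - 3} t{i + 1}")
        varlines.append(f"t{i + 1} 180.0 *")
    return parse_zmatrix("\n".join(lines) + "\n\n" + "\n".join(varlines) + "\n")


_AMINO_BODY = """\
O1
H5 1 0.96
C1 1 1.34 2 106.0
C2 3 1.52 1 111.0 2 phi1
O2 3 1.20 4 123.0 1 doco
N  4 1.45 3 110.0 1 phi2
H1 6 1.01 4 110.0 3 phi3
H2 6 1.01 4 110.0 7 dnh
H3 4 1.09 3 108.0 6 dh3
H4 4 1.09 3 108.0 6 dh4

phi1 180.0 *
doco 180.0
phi2 180.0 *
phi3 60.0 *
dnh 120.0
dh3 120.0
dh4 240.0
"""


def amino_backbone_zmatrix() -> ZMatrix:
    """Glycine-like reference: targets phi1 = H5-O1-C1-C2 (carboxyl O-H),
    phi2 = O1-C1-C2-N, phi3 = C1-C2-N-H1 (amine)."""
    return parse_zmatrix(_AMINO_BODY)


def generate_fixture(kind: str, k: int, rng_seed: int = 0) -> Fixture:
    """Build a deterministic toy system of the requested kind.

    ``rng_seed`` controls the sampled well depths / couplings; the expected
    minimum list is enumerated by the brute-force oracle at generation time
    (grid + local descent + epsilon deduplication), not assumed.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if not (1 <= k <= 6):
        raise ValueError(f"K must be within 1..6, got {k}")
    rng = np.random.default_rng(rng_seed)

    sym = None
    amine = None
    if kind == "separable-3fold":
        zmat = _chain_zmatrix(k)
        terms = tuple(
            ((float(1.5 + rng.uniform(0.0, 1.0)), 3, 0.0),) for _ in range(k)
        )
        params = ToyPESParams(terms=terms)
        spec = TorsionSpec.sp3(k)
    elif kind == "coupled":
        zmat = _chain_zmatrix(k)
        terms = []
        menus = []
        for _ in range(k):
            n = int(rng.choice([2, 3]))
            v = float(rng.uniform(1.0, 3.0))
            gamma = float(rng.choice([0.0, 180.0]))
            terms.append(((v, n, gamma),))
            menus.append(SP3_SEEDS if n == 3 else TWOFOLD_SEEDS)
        couplings = []
        for i in range(k):
            for j in range(i + 1, k):
                if rng.uniform() < 0.7:
                    couplings.append((i, j, float(rng.uniform(-0.35, 0.35))))
        params = ToyPESParams(terms=tuple(terms), couplings=tuple(couplings))
        spec = TorsionSpec(seeds=tuple(menus))
    elif kind == "cs-symmetric":
        zmat = _chain_zmatrix(k)
        # phases restricted to {0, 180} and even couplings => E(-Phi) = E(Phi)
        terms = []
        menus = []
        for _ in range(k):
            n = int(rng.choice([2, 3]))
            v = float(rng.uniform(1.5, 3.0))
            terms.append(((v, n, 0.0),))
            menus.append(SP3_SEEDS if n == 3 else TWOFOLD_SEEDS)
        couplings = tuple(
            (i, j, float(rng.uniform(-0.3, 0.3)))
            for i in range(k)
            for j in range(i + 1, k)
        )
        params = ToyPESParams(terms=tuple(terms), couplings=couplings)
        spec = TorsionSpec(seeds=tuple(menus))
        sym = tuple(TorsionSymmetry("in_plane") for _ in range(k))
    else:  # amino-backbone-toy
        if k != 3:
            raise ValueError("amino-backbone-toy fixture has exactly K=3 torsions")
        zmat = amino_backbone_zmatrix()
        params = ToyPESParams(
            terms=(
                ((2.5, 2, 0.0),),        # carboxyl O-H: syn/anti
                ((2.0, 3, 0.0),),        # C1-Ca
                ((1.8, 3, 0.0),),        # Ca-N (amine)
            ),
            couplings=((0, 1, 0.15),),
        )
        spec = TorsionSpec(seeds=(TWOFOLD_SEEDS, SP3_SEEDS, SP3_SEEDS))
        # phi1/phi2 are in-plane at the Cs configuration; phi3's partner is
        # the other amine hydrogen: phibar3 = C1-C2-N-H2 = atoms (8,6,4,3)
        sym = (
            TorsionSymmetry("in_plane"),
            TorsionSymmetry("in_plane"),
            TorsionSymmetry("out_of_plane", partner_atoms=(7, 5, 3, 2)),
        )
        amine = (6, 7, 3, 5)       # (H1, H2, Calpha, N), 0-based

    minima = tuple(brute_force_minima(params, grid_step=5.0 if k <= 2 else 15.0))
    return Fixture(
        kind=kind,
        zmatrix=zmat,
        params=params,
        expected_minima=minima,
        spec=spec,
        torsion_symmetry=sym,
        amine=amine,
    )
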