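"""Optimized-geometry validation battery and symmetry handling.

Four tests decide whether an optimized structure becomes a conformer:
connectivity (elsewhere), redundancy against the stored equilibrium vectors,
user constraints (hard: all must hold; soft: at least one must hold), and the
Hessian test (all vibrational frequencies real).  This module also implements
the amine umbrella-inversion repair (relabelling the two amine hydrogens when
the improper torsion H1-H2-Calpha-N flipped sign during optimization) and the
conformational-enantiomer machinery for molecules with an accessible mirror
plane: the torsion-vector image Phi -> Phi* and the mirrored, renumbered
Cartesian geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import AdjacencyMatrix
from .geom import (
    CartesianGeometry,
    GeometryError,
    TorsionVector,
    circular_distance,
    measure_dihedral_signed,
    wrap360,
)

__all__ = [
    "Constraint",
    "ConstraintSet",
    "ConstraintError",
    "SymmetryError",
    "check_constraints",
    "redundancy_test",
    "hessian_test",
    "umbrella_repair",
    "TorsionSymmetry",
    "enantiomer_vector",
    "enantiomer_geometry",
    "DEFAULT_IMAG_TOL",
]

#: imaginary modes weaker than this magnitude (cm^-1) are numerical noise
DEFAULT_IMAG_TOL = 5.0


class ConstraintError(ValueError):
    pass


class SymmetryError(ValueError):
    """Ambiguity the enantiomer renumbering procedure cannot resolve."""


# --------------------------------------------------------------------------
# constraints
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    """One geometric constraint: distance (2 atoms, Angstrom), angle
    (3 atoms, degrees) or dihedral (4 atoms, degrees, circular interval).

    For dihedrals the interval is read on the circle: (330, 30) means the
    60-degree arc through 0.
    """

    kind: str                    # "distance" | "angle" | "dihedral"
    atoms: tuple[int, ...]       # 0-based
    lo: float
    hi: float

    def __post_init__(self):
        n = {"distance": 2, "angle": 3, "dihedral": 4}.get(self.kind)
        if n is None:
            raise ConstraintError(f"unknown constraint kind {self.kind!r}")
        if len(self.atoms) != n:
            raise ConstraintError(
                f"{self.kind} constraint needs {n} atoms, got {len(self.atoms)}"
            )
        if self.kind != "dihedral" and self.lo > self.hi:
            raise ConstraintError("interval bounds out of order")

    def holds(self, geom: CartesianGeometry) -> bool:
        for a in self.atoms:
            if not (0 <= a < geom.n_atoms):
                raise ConstraintError(
                    f"constraint references atom {a + 1}, system has "
                    f"{geom.n_atoms} atoms"
                )
        if self.kind == "distance":
            return self.lo <= geom.distance(*self.atoms) <= self.hi
        if self.kind == "angle":
            return self.lo <= geom.angle(*self.atoms) <= self.hi
        value = wrap360(measure_dihedral_signed(geom, *self.atoms))
        lo, hi = wrap360(self.lo), wrap360(self.hi)
        if lo <= hi:
            return bool(lo <= value <= hi)
        return bool(value >= lo or value <= hi)


@dataclass(frozen=True)
class ConstraintSet:
    hard: tuple[Constraint, ...] = ()
    soft: tuple[Constraint, ...] = ()

    @property
    def empty(self) -> bool:
        return not self.hard and not self.soft


def check_constraints(geom: CartesianGeometry, cs: ConstraintSet) -> bool:
    """All hard constraints AND (soft list empty OR at least one soft)."""
    if not all(c.holds(geom) for c in cs.hard):
        return False
    if cs.soft and not any(c.holds(geom) for c in cs.soft):
        return False
    return True


# --------------------------------------------------------------------------
# redundancy and Hessian tests
# --------------------------------------------------------------------------

def redundancy_test(phi_opt: TorsionVector, eq_vectors, epsilon: float = 2.0) -> bool:
    """True iff ``phi_opt`` is a new conformer.

    For every stored equilibrium vector some torsion must differ by more than
    ``epsilon`` degrees (wrap-around metric); otherwise the candidate
    duplicates a stored conformer.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    vecs = getattr(eq_vectors, "eq_vectors", eq_vectors)
    for p in vecs:
        ref = p.torsions if hasattr(p, "torsions") else p
        if phi_opt.max_component_distance(ref) <= epsilon:
            return False
    return True


def hessian_test(frequencies, imag_tol: float = DEFAULT_IMAG_TOL) -> bool:
    """True iff all frequencies are real up to numerical-Hessian noise.

    Imaginary modes are encoded as negative cm^-1 values; magnitudes below
    ``imag_tol`` are tolerated as noise.
    """
    freqs = list(frequencies)
    if not freqs:
        raise ValueError("empty frequency list")
    return all(f >= -imag_tol for f in freqs)


# --------------------------------------------------------------------------
# umbrella inversion
# --------------------------------------------------------------------------

def _improper(geom: CartesianGeometry, idx) -> float:
    h1, h2, ca, n = idx
    phi12 = measure_dihedral_signed(geom, h1, h2, ca, n)
    if min(abs(phi12), abs(abs(phi12) - 180.0)) < 1e-6:
        raise GeometryError(
            "improper torsion H1-H2-Calpha-N is planar-degenerate "
            f"({phi12:.6f} deg); umbrella sign is undefined"
        )
    return phi12


def umbrella_repair(
    trial: CartesianGeometry,
    optimized: CartesianGeometry,
    amine: tuple[int, int, int, int],
) -> CartesianGeometry:
    """Undo an amine umbrella inversion that occurred during optimization.

    ``amine`` gives 0-based (H1, H2, Calpha, N).  If the improper torsion
    phi12 = H1-H2-Calpha-N kept its sign, the optimized geometry is returned
    unchanged; if it flipped, H1 and H2 swapped roles during the optimization
    and their labels are exchanged so that the proper amine torsion
    C1-Calpha-N-H1 remains unambiguous.
    """
    s_trial = np.sign(_improper(trial, amine))
    s_opt = np.sign(_improper(optimized, amine))
    if s_trial == s_opt:
        return optimized
    h1, h2 = amine[0], amine[1]
    coords = np.array(optimized.coords)
    coords[[h1, h2]] = coords[[h2, h1]]
    elements = list(optimized.elements)
    elements[h1], elements[h2] = elements[h2], elements[h1]
    return CartesianGeometry(tuple(elements), coords)


# --------------------------------------------------------------------------
# conformational enantiomers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionSymmetry:
    """Mirror behaviour of one target torsion in a Cs-capable molecule.

    ``in_plane`` torsions (all four atoms in the mirror plane at the symmetric
    configuration) map as phi* = -phi.  ``out_of_plane`` torsions have a
    partner dihedral phi_bar over the reflection-equivalent atom (e.g. the
    other amine hydrogen), and map as phi* = -phi_bar; the partner is
    identified by its four 0-based atom indices so its value can be measured
    on the optimized geometry.
    """

    kind: str                                   # "in_plane" | "out_of_plane"
    partner_atoms: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        if self.kind not in ("in_plane", "out_of_plane"):
            raise ValueError(f"unknown torsion symmetry {self.kind!r}")
        if self.kind == "out_of_plane" and self.partner_atoms is None:
            raise ValueError(
                "out-of-plane torsion requires its partner dihedral atoms"
            )


def enantiomer_vector(
    phi: TorsionVector,
    sym: tuple[TorsionSymmetry, ...] | None = None,
    partner_values=None,
) -> TorsionVector:
    """Torsion vector of the mirror-image conformer.

    Component-wise: in-plane torsions give -phi_i; out-of-plane torsions give
    -phi_bar_i, where ``partner_values`` supplies the measured partner
    dihedrals (required for any out-of-plane component).  With ``sym=None``
    every torsion is treated as in-plane.
    """
    if sym is None:
        sym = tuple(TorsionSymmetry("in_plane") for _ in range(len(phi)))
    if len(sym) != len(phi):
        raise ValueError("one symmetry tag per torsion required")
    out = []
    for i, (s, v) in enumerate(zip(sym, phi.values)):
        if s.kind == "in_plane":
            out.append(-v)
        else:
            if partner_values is None or partner_values[i] is None:
                raise ValueError(
                    f"torsion {i}: out-of-plane image needs the partner "
                    "dihedral value"
                )
            out.append(-float(partner_values[i]))
    return TorsionVector(out)


def _wl_classes(adjacency: AdjacencyMatrix) -> list[int]:
    """Iterated neighbour-element refinement (1-D Weisfeiler-Lehman).

    Returns a stable integer colour per atom; atoms sharing a colour are
    indistinguishable by element + connectivity alone.
    """
    colors = list(adjacency.elements)
    n = adjacency.n_atoms
    for _ in range(n):
        new = []
        for i in range(n):
            neigh = sorted(colors[j] for j in adjacency.neighbors(i))
            new.append(f"{colors[i]}|{','.join(map(str, neigh))}")
        # canonicalise to small ints to keep strings bounded
        order = {c: r for r, c in enumerate(sorted(set(new)))}
        refined = [order[c] for c in new]
        if len(set(refined)) == len(set(_ints(colors))):
            return refined
        colors = refined
    return _ints(colors)


def _ints(colors):
    order = {c: r for r, c in enumerate(sorted(set(map(str, colors))))}
    return [order[str(c)] for c in colors]


def _dihedral_signature(geom, a, p, q, r):
    return measure_dihedral_signed(geom, a, p, q, r)


def enantiomer_geometry(
    geom: CartesianGeometry, adjacency: AdjacencyMatrix
) -> CartesianGeometry:
    """Mirror image of a conformer, renumbered onto the original atom order.

    The geometry is reflected through the YZ plane (x -> -x) and its atoms
    are re-identified in three steps: (1) correlation by element, (2)
    refinement by graph connectivity (iterated neighbour-class comparison),
    (3) resolution of the remaining ambiguity classes by comparing signed
    improper/dihedral signatures, which reflection negates.  The result has
    the same adjacency matrix as the input.
    """
    if geom.n_atoms != adjacency.n_atoms or tuple(geom.elements) != adjacency.elements:
        raise SymmetryError("geometry and adjacency matrix are inconsistent")
    mirrored = np.array(geom.coords)
    mirrored[:, 0] = -mirrored[:, 0]
    mgeom = CartesianGeometry(geom.elements, mirrored)

    colors = _wl_classes(adjacency)
    classes: dict[int, list[int]] = {}
    for i, c in enumerate(colors):
        classes.setdefault(c, []).append(i)

    perm = np.full(geom.n_atoms, -1, dtype=int)   # mirrored index -> new slot
    resolved = set()
    for members in classes.values():
        if len(members) == 1:
            perm[members[0]] = members[0]
            resolved.add(members[0])

    # step 3: signature matching inside ambiguous classes
    for members in classes.values():
        if len(members) == 1:
            continue
        anchors = _anchor_chain(members, adjacency, resolved)
        if anchors is None:
            raise SymmetryError(
                f"cannot anchor ambiguous atom class {sorted(m + 1 for m in members)}"
            )
        p, q, r = anchors
        orig_sig = {m: _dihedral_signature(geom, m, p, q, r) for m in members}
        mirr_sig = {m: _dihedral_signature(mgeom, m, p, q, r) for m in members}
        # reflection negates the signed signature; match each mirrored atom to
        # the original atom carrying its negated value
        taken = set()
        for m in members:
            cands = sorted(
                (float(circular_distance(wrap360(mirr_sig[m]),
                                         wrap360(orig_sig[o]))), o)
                for o in members if o not in taken
            )
            best_d, best_o = cands[0]
            if len(cands) > 1 and cands[1][0] - best_d < 1e-3:
                raise SymmetryError(
                    f"ambiguous correlation for atoms "
                    f"{sorted(x + 1 for x in members)} (signature tie)"
                )
            perm[m] = best_o
            taken.add(best_o)
        resolved.update(members)

    if np.any(perm < 0):
        raise SymmetryError("atom correlation incomplete")

    out = np.empty_like(mirrored)
    # mirrored atom m plays the role of original atom perm[m]
    for m, slot in enumerate(perm):
        out[slot] = mirrored[m]
    result = CartesianGeometry(geom.elements, out)
    return result


def _anchor_chain(members, adjacency: AdjacencyMatrix, resolved):
    """Three resolved reference atoms (p, q, r) for signature dihedrals.

    p is the common parent of the class members, q a resolved neighbour of p
    outside the class, r a resolved neighbour of q distinct from p (falling
    back to a second resolved neighbour of p).
    """
    parents = [set(adjacency.neighbors(m)) - set(members) for m in members]
    common = set.intersection(*parents) & resolved
    if not common:
        return None
    p = min(common)
    q_cands = [
        q for q in adjacency.neighbors(p) if q in resolved and q not in members
    ]
    if not q_cands:
        return None
    for q in q_cands:
        r_cands = [
            r for r in adjacency.neighbors(q)
            if r in resolved and r not in members and r != p
        ]
        if r_cands:
            return p, q, min(r_cands)
    if len(q_cands) >= 2:
        return p, q_cands[0], q_cands[1]
    return None
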