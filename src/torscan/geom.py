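"""Z-matrix and Cartesian geometry handling.

The conformer search operates on a molecule defined in internal coordinates
(a Gaussian-style Z-matrix) in which the K rotatable torsions of interest are
flagged.  This module provides the parser for that dialect, the conversion to
Cartesian coordinates, dihedral measurement, torsion substitution (building a
guess geometry from the reference one by replacing the flagged dihedrals), and
the closest-conformer template lookup that replaces the rigid-rotor
approximation during the search.

Conventions (fixed package-wide):

* angles are stored in degrees, canonicalised to the interval ``[0, 360)``;
* atom indices are 0-based internally and 1-based in files and messages;
* the Cartesian embedding places atom 1 at the origin, atom 2 on +z and
  atom 3 in the xz-plane, so conversions are bit-stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TorsionVector",
    "ZAtom",
    "ZMatrix",
    "CartesianGeometry",
    "ZMatrixError",
    "GeometryError",
    "wrap360",
    "signed_angle",
    "circular_difference",
    "circular_distance",
    "parse_zmatrix",
    "zmatrix_to_cartesian",
    "measure_dihedral",
    "measure_dihedral_signed",
    "substitute_torsions",
    "nearest_template",
    "write_xyz",
]


class ZMatrixError(ValueError):
    """Malformed Z-matrix text or inconsistent torsion definitions."""


class GeometryError(ValueError):
    """Degenerate geometry (colinear reference atoms, bad dihedral frame)."""


# --------------------------------------------------------------------------
# angle arithmetic on the circle
# --------------------------------------------------------------------------

def wrap360(angle):
    """Reduce an angle (or array of angles) in degrees to [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def signed_angle(angle):
    """Map an angle in degrees to the signed interval (-180, 180]."""
    a = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0) + 180.0
    return a


def circular_difference(a, b):
    """Signed circular difference a - b in (-180, 180] degrees."""
    return signed_angle(np.asarray(a, float) - np.asarray(b, float))


def circular_distance(a, b):
    """Unsigned wrap-around distance between angles in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.minimum(d, 360.0 - d)


class TorsionVector:
    """K dihedral angles in degrees on the circle [0, 360).

    Immutable value object; supports len(), indexing and iteration.
    """

    __slots__ = ("values",)

    def __init__(self, values):
        arr = wrap360(np.atleast_1d(np.asarray(values, dtype=float)))
        # snap values within rounding noise of 360 back onto 0
        arr = np.where(arr >= 360.0 - 1e-9, 0.0, arr)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("torsion vector must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("torsion vector components must be finite")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __setattr__(self, *a):  # immutability
        raise AttributeError("TorsionVector is immutable")

    def __len__(self):
        return self.values.size

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, i):
        return self.values[i]

    def __repr__(self):
        comps = ", ".join(f"{v:.2f}" for v in self.values)
        return f"TorsionVector(({comps}))"

    def __eq__(self, other):
        if not isinstance(other, TorsionVector):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.all(self.values == other.values)
        )

    def __hash__(self):
        return hash(self.values.tobytes())

    def distance(self, other: "TorsionVector") -> float:
        """Euclidean norm of component-wise circular differences (degrees)."""
        return float(
            np.sqrt(np.sum(circular_distance(self.values, other.values) ** 2))
        )

    def max_component_distance(self, other: "TorsionVector") -> float:
        return float(np.max(circular_distance(self.values, other.values)))


@dataclass(frozen=True)
class ZAtom:
    """One Z-matrix row: element, reference atoms and internal coordinates.

    ``refs`` holds 0-based indices of the bond/angle/dihedral reference atoms
    (length 0, 1, 2 or 3 depending on the row).  ``names`` carries the symbolic
    variable name of each coordinate where the input used one (else None).
    """

    label: str                      # as written, e.g. "C2" or "H"
    element: str                    # chemical symbol, e.g. "C"
    refs: tuple[int, ...]
    r: float | None = None          # bond length, Angstrom
    theta: float | None = None      # bond angle, degrees
    phi: float | None = None        # dihedral, degrees in [0, 360)
    names: tuple[str | None, str | None, str | None] = (None, None, None)


@dataclass(frozen=True)
class TargetTorsion:
    """A flagged proper torsion: the dihedral entry of one Z-matrix row."""

    name: str          # variable name, e.g. "phi1"
    atom: int          # 0-based index of the row owning the dihedral entry
    # 0-based atoms (i, j, k, l) of the dihedral i-j-k-l; the torsion is about
    # the central j-k bond
    atoms: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))


@dataclass(frozen=True)
class ZMatrix:
    """Internal-coordinate molecular definition with flagged target torsions."""

    atoms: tuple[ZAtom, ...]
    target_torsions: tuple[TargetTorsion, ...] = ()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def k(self) -> int:
        return len(self.target_torsions)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def torsion_values(self) -> TorsionVector:
        """The current values of the K flagged dihedrals, Phi."""
        return TorsionVector([self.atoms[t.atom].phi for t in self.target_torsions])

    def validate(self) -> None:
        for i, atom in enumerate(self.atoms):
            if any(r >= i or r < 0 for r in atom.refs):
                raise ZMatrixError(
                    f"atom {i + 1} references atom outside 1..{i} (forward reference)"
                )
            if len(set(atom.refs)) != len(atom.refs):
                raise ZMatrixError(f"atom {i + 1} has duplicate reference atoms")
        bonds = set()
        for t in self.target_torsions:
            if len(self.atoms[t.atom].refs) != 3:
                raise ZMatrixError(
                    f"target torsion {t.name!r} does not own a dihedral entry"
                )
            bond = frozenset(t.atoms[1:3])
            if bond in bonds:
                raise ZMatrixError(
                    f"torsion about bond {sorted(i + 1 for i in bond)} defined twice"
                )
            bonds.add(bond)


@dataclass(frozen=True)
class CartesianGeometry:
    """Elements plus an N x 3 coordinate array in Angstrom."""

    elements: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.elements), 3):
            raise GeometryError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if len(self.elements) < 2:
            raise GeometryError("geometry needs at least 2 atoms")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def angle(self, i: int, j: int, k: int) -> float:
        """Bond angle i-j-k in degrees."""
        u = self.coords[i] - self.coords[j]
        v = self.coords[k] - self.coords[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_ELEMENT_RE = re.compile(r"^([A-Z][a-z]?)(\d*)$")


def _element_of(label: str) -> str:
    m = _ELEMENT_RE.match(label)
    if not m:
        raise ZMatrixError(f"unrecognised atom label {label!r}")
    return m.group(1)


def _parse_value(tok: str, variables: dict[str, float], line_no: int):
    """A coordinate token: numeric literal or symbolic variable name."""
    try:
        return float(tok), None
    except ValueError:
        if tok in variables:
            return variables[tok], tok
        raise ZMatrixError(
            f"line {line_no}: undefined variable {tok!r} in Z-matrix"
        ) from None


def parse_zmatrix(text: str, require_torsions: bool = True) -> ZMatrix:
    """Parse the supported Gaussian-style Z-matrix dialect.

    Layout: one atom per line (``label [ref r ref theta ref phi]``, references
    1-based), a blank line, then a variables block of ``name value`` lines.  A
    trailing ``*`` on a variables-block line flags that dihedral as a target
    torsion; targets are ordered as flagged.  Values may also be given inline
    as numbers.  Raises :class:`ZMatrixError` with a 1-based line number on
    malformed input.
    """
    lines = text.splitlines()
    # split body / variables block at the first blank line after some content
    body: list[tuple[int, str]] = []
    varlines: list[tuple[int, str]] = []
    section = 0
    for ln, raw in enumerate(lines, start=1):
        stripped = raw.split("#", 1)[0].split("!", 1)[0].strip()
        if not stripped:
            if body:
                section = 1
            continue
        (body if section == 0 else varlines).append((ln, stripped))
    if not body:
        raise ZMatrixError("empty Z-matrix")

    variables: dict[str, float] = {}
    targets_order: list[str] = []
    for ln, s in varlines:
        toks = s.replace("=", " ").split()
        starred = False
        if toks and toks[-1] == "*":
            starred = True
            toks = toks[:-1]
        if len(toks) != 2:
            raise ZMatrixError(f"line {ln}: malformed variable definition {s!r}")
        name = toks[0]
        try:
            value = float(toks[1])
        except ValueError:
            raise ZMatrixError(
                f"line {ln}: non-numeric value for variable {name!r}"
            ) from None
        if name in variables:
            raise ZMatrixError(f"line {ln}: variable {name!r} defined twice")
        variables[name] = value
        if starred:
            targets_order.append(name)

    atoms: list[ZAtom] = []
    dihedral_owner: dict[str, list[int]] = {}
    for i, (ln, s) in enumerate(body):
        toks = s.split()
        expected = {0: 1, 1: 3, 2: 5}.get(i, 7)
        if len(toks) != expected:
            raise ZMatrixError(
                f"line {ln}: expected {expected} fields for atom {i + 1}, "
                f"got {len(toks)}"
            )
        label = toks[0]
        element = _element_of(label)
        refs: list[int] = []
        vals: list[float | None] = [None, None, None]
        names: list[str | None] = [None, None, None]
        for slot in range((len(toks) - 1) // 2):
            try:
                ref = int(toks[1 + 2 * slot])
            except ValueError:
                raise ZMatrixError(
                    f"line {ln}: reference atom {toks[1 + 2 * slot]!r} "
                    "is not an integer"
                ) from None
            if not (1 <= ref <= i):
                raise ZMatrixError(
                    f"line {ln}: atom {i + 1} references atom {ref}, "
                    f"allowed range 1..{i}"
                )
            refs.append(ref - 1)
            vals[slot], names[slot] = _parse_value(
                toks[2 + 2 * slot], variables, ln
            )
        r, theta, phi = vals
        if theta is not None and not (0.0 < theta < 180.0):
            raise ZMatrixError(
                f"line {ln}: bond angle {theta} outside (0, 180) degrees"
            )
        if r is not None and r <= 0:
            raise ZMatrixError(f"line {ln}: non-positive bond length {r}")
        if phi is not None:
            phi = float(wrap360(phi))
        atoms.append(
            ZAtom(
                label=label,
                element=element,
                refs=tuple(refs),
                r=r,
                theta=theta,
                phi=phi,
                names=tuple(names),
            )
        )
        if names[2] is not None:
            dihedral_owner.setdefault(names[2], []).append(i)

    targets: list[TargetTorsion] = []
    for name in targets_order:
        owners = dihedral_owner.get(name, [])
        if not owners:
            raise ZMatrixError(
                f"target torsion {name!r} does not appear as a dihedral entry"
            )
        if len(owners) > 1:
            raise ZMatrixError(
                f"target torsion {name!r} appears in {len(owners)} dihedral "
                "entries; it must be defined exactly once"
            )
        a = owners[0]
        j, k, l = atoms[a].refs
        if any(atoms[i].element == "X" for i in (a, j, k, l)):
            raise ZMatrixError(
                f"target torsion {name!r} involves a dummy atom; dummies are "
                "excluded from torsion targets"
            )
        targets.append(TargetTorsion(name=name, atom=a, atoms=(a, j, k, l)))

    zmat = ZMatrix(atoms=tuple(atoms), target_torsions=tuple(targets))
    zmat.validate()
    if require_torsions and zmat.k == 0:
        raise ZMatrixError(
            "no target torsions flagged (mark dihedral variables with '*'); "
            "K >= 1 is required for a conformer search"
        )
    return zmat


def format_zmatrix(zmat: ZMatrix, numeric: bool = False) -> str:
    """Serialise back to the dialect read by :func:`parse_zmatrix`.

    With ``numeric=True`` all coordinates are written inline (no variables
    block), which drops the torsion flags — used for embedding in external
    input decks.
    """
    lines = []
    varlines = []
    used: dict[str, float] = {}
    target_names = {t.name for t in zmat.target_torsions}
    for i, atom in enumerate(zmat.atoms):
        toks = [atom.label]
        for slot, val in enumerate((atom.r, atom.theta, atom.phi)):
            if slot >= len(atom.refs):
                break
            toks.append(str(atom.refs[slot] + 1))
            name = atom.names[slot]
            if numeric or name is None:
                toks.append(f"{val:.8f}")
            else:
                toks.append(name)
                used[name] = val
        lines.append(" ".join(toks))
    if not numeric:
        for name, val in used.items():
            star = " *" if name in target_names else ""
            varlines.append(f"{name} {val:.8f}{star}")
        return "\n".join(lines) + "\n\n" + "\n".join(varlines) + "\n"
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Cartesian embedding
# --------------------------------------------------------------------------

def zmatrix_to_cartesian(zmat: ZMatrix) -> CartesianGeometry:
    """Embed a Z-matrix in Cartesian space.

    Convention: atom 1 at the origin, atom 2 on +z, atom 3 in the xz-plane
    (x >= 0).  Raises :class:`GeometryError` if the three reference atoms of a
    dihedral are colinear (bond angle within 1e-6 deg of 0 or 180).
    """
    n = zmat.n_atoms
    coords = np.zeros((n, 3))
    for i, atom in enumerate(zmat.atoms):
        if i == 0:
            continue
        if i == 1:
            coords[1] = (0.0, 0.0, atom.r)
            continue
        if i == 2:
            j, k = atom.refs
            u = coords[k] - coords[j]
            u /= np.linalg.norm(u)
            t = np.radians(atom.theta)
            # perpendicular to the z-axis frame: +x
            coords[2] = coords[j] + atom.r * (np.cos(t) * u + np.sin(t) * np.array([1.0, 0.0, 0.0]))
            continue
        j, k, l = atom.refs
        coords[i] = _place_atom(
            coords[j], coords[k], coords[l], atom.r, atom.theta, atom.phi, i
        )
    return CartesianGeometry(elements=tuple(zmat.elements), coords=coords)


def _place_atom(b, c, d, r, theta, phi, index):
    """Position atom i with bond to b, angle i-b-c, dihedral i-b-c-d."""
    bc = c - b
    nbc = np.linalg.norm(bc)
    cd = d - c
    bc_u = bc / nbc
    # check colinearity of the b-c-d frame
    cross = np.cross(bc, cd)
    if np.linalg.norm(cross) / (nbc * np.linalg.norm(cd)) < np.sin(np.radians(1e-6)):
        raise GeometryError(
            f"atom {index + 1}: dihedral reference atoms are colinear "
            "(angle within 1e-6 deg of 0 or 180)"
        )
    t = np.radians(theta)
    p = np.radians(phi)
    # orthonormal frame at b: x along b->c, n perpendicular to the b,c,d plane
    n_u = cross / np.linalg.norm(cross)
    m_u = np.cross(n_u, bc_u)
    # local displacement: start anti to bc, rotate by theta in the bcd plane,
    # then by phi about bc
    disp = r * (
        np.cos(t) * bc_u
        + np.sin(t) * (np.cos(p) * m_u - np.sin(p) * n_u)
    )
    return b + disp


def measure_dihedral_signed(
    geom: CartesianGeometry, i: int, j: int, k: int, l: int
) -> float:
    """Signed dihedral i-j-k-l in (-180, 180] degrees (IUPAC sign)."""
    if len({i, j, k, l}) != 4:
        raise GeometryError("dihedral atoms must be distinct")
    p = geom.coords
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    for v, pair in ((n1, (i, j, k)), (n2, (j, k, l))):
        if np.linalg.norm(v) < 1e-10:
            raise GeometryError(
                f"colinear atom triple {tuple(x + 1 for x in pair)} "
                "in dihedral measurement"
            )
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    return float(np.degrees(np.arctan2(y, x)))


def measure_dihedral(geom: CartesianGeometry, i: int, j: int, k: int, l: int) -> float:
    """Dihedral i-j-k-l mapped to [0, 360) degrees."""
    return float(wrap360(measure_dihedral_signed(geom, i, j, k, l)))


def measure_torsions(geom: CartesianGeometry, zmat: ZMatrix) -> TorsionVector:
    """Measure the K flagged torsions of ``zmat`` on a Cartesian geometry."""
    return TorsionVector(
        [measure_dihedral(geom, *t.atoms) for t in zmat.target_torsions]
    )


# --------------------------------------------------------------------------
# torsion substitution and template lookup
# --------------------------------------------------------------------------

def substitute_torsions(base: ZMatrix, phi: TorsionVector) -> ZMatrix:
    """Replace the K flagged dihedrals of ``base`` by the components of ``phi``.

    Everything else (bond lengths, angles, non-target dihedrals) is untouched:
    the guess geometry is the reference internals with the target torsional
    sub-vector swapped out.
    """
    if len(phi) != base.k:
        raise ZMatrixError(
            f"torsion vector length {len(phi)} does not match K={base.k}"
        )
    atoms = list(base.atoms)
    for t, value in zip(base.target_torsions, phi.values):
        atoms[t.atom] = replace(atoms[t.atom], phi=float(wrap360(value)))
    return ZMatrix(atoms=tuple(atoms), target_torsions=base.target_torsions)


def nearest_template(pool, phi: TorsionVector) -> ZMatrix:
    """Z-matrix template for a new guess vector.

    If the ensemble ``pool`` is empty the reference Z-matrix is used;
    otherwise the stored conformer minimising the circular torsional distance
    to ``phi`` supplies its internals (improved bond lengths/angles), with the
    flagged dihedrals then replaced by ``phi``.  Exact distance ties go to the
    lowest-index conformer.
    """
    conformers = list(pool.conformers) if hasattr(pool, "conformers") else list(pool)
    if not conformers:
        return substitute_torsions(pool.reference, phi)
    dists = [phi.distance(c.torsions) for c in conformers]
    best = int(np.argmin(dists))  # argmin returns first minimum: lowest index
    return substitute_torsions(conformers[best].zmatrix, phi)


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def write_xyz(geom: CartesianGeometry, comment: str = "") -> str:
    """Standard XYZ text: count line, comment line, element x y z rows."""
    lines = [str(geom.n_atoms), comment.replace("\n", " ")]
    for el, xyz in zip(geom.elements, geom.coords):
        lines.append(f"{el:<3s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}")
    return "\n".join(lines) + "\n"
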