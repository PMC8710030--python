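"""MS-HO conformer thermochemistry and backbone-type classification.

Given an ensemble of conformers, each characterised by its relative
electronic energy U_j (kcal/mol above the global minimum), scaled harmonic
frequencies and principal moments of inertia, the multi-structural
harmonic-oscillator rovibrational partition function is

    Q_MS-HO(T) = sum_j Q_RRHO_j(T) * exp(-U_j / kT)

with Q_RRHO the product of the classical rigid-rotor rotational partition
function and the zero-point-referenced harmonic vibrational partition
function.  The fractional contribution of conformer i is
chi_i = Q_RRHO_i exp(-U_i beta) / Q_MS-HO, summing to one; N90 is the number
of lowest-electronic-energy conformers whose cumulative chi reaches 90%.

Amino-acid backbones are classified by the proximity (circular Euclidean
metric, 75 deg threshold) of the three backbone dihedrals
phi1 = H-O-C1-Ca, phi2 = O-C1-Ca-N, phi3 = C1-Ca-N-lp (lp = nitrogen
lone-pair direction) to three hydrogen-bond motifs:
type I (x, 180, 180), type II (0, 0, 0), type III (180, 0, 180); anything
farther than the threshold from all three is type IV.

A reader/writer pair handles the plain-text per-conformer dataset format
(relative energy, moments of inertia, dipole, ZPE, frequencies, Cartesian
coordinates) used by the classification and msho subcommands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants as sc

from .connectivity import AdjacencyMatrix, adjacency_matrix
from .geom import (
    CartesianGeometry,
    GeometryError,
    TorsionVector,
    circular_distance,
    measure_dihedral,
)

__all__ = [
    "ConformerThermo",
    "BackboneAngles",
    "BackboneType",
    "DEFAULT_FREQ_SCALE",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_CLASS_THRESHOLD",
    "rrho_partition",
    "msho_partition",
    "conformer_weights",
    "n90",
    "lone_pair_direction",
    "classify_backbone",
    "backbone_angles_from_geometry",
    "read_conformer_dataset",
    "write_conformer_dataset",
    "summary_table",
]

#: recommended harmonic frequency scale factor for the HL model chemistry
DEFAULT_FREQ_SCALE = 0.973
DEFAULT_TEMPERATURE = 300.0
DEFAULT_CLASS_THRESHOLD = 75.0

_KCAL_PER_MOL_J = sc.calorie * 1000.0 / sc.Avogadro   # J per (kcal/mol)
_AMU_A2_KG_M2 = sc.atomic_mass * 1e-20                # kg m^2 per amu*A^2


@dataclass(frozen=True)
class ConformerThermo:
    """Per-conformer data entering the MS-HO sum.

    ``u`` is the relative electronic energy in kcal/mol (0 for the global
    minimum), ``frequencies`` the harmonic frequencies in cm^-1 (unscaled),
    ``inertia`` the three principal moments in amu*Angstrom^2.
    """

    u: float
    frequencies: tuple[float, ...]
    inertia: tuple[float, float, float]
    zpe: float | None = None          # kcal/mol
    dipole: float | None = None       # Debye
    label: str = ""
    geometry: CartesianGeometry | None = None
    origin: str = ""                  # "preconditioned" | "stochastic" | ""

    def __post_init__(self):
        if self.u < 0:
            raise ValueError(f"relative energy must be >= 0, got {self.u}")
        if any(i <= 0 for i in self.inertia):
            raise ValueError("moments of inertia must be positive")


def rrho_partition(
    thermo: ConformerThermo,
    t: float,
    freq_scale: float = DEFAULT_FREQ_SCALE,
    sigma: int = 1,
) -> float:
    """Rigid-rotor harmonic-oscillator rovibrational partition function.

    Classical rotational factor sqrt(pi I_A I_B I_C) / sigma * (8 pi^2 kT /
    h^2)^(3/2); vibrational factor prod_m 1/(1 - exp(-h c nu_m / kT)) with the
    energy zero at each conformer's vibrational ground state (ZPE-referenced),
    frequencies multiplied by ``freq_scale`` before use.  The electronic
    energy offset is *not* included (it enters the MS-HO sum through U_j).
    """
    if t <= 0:
        raise ValueError(f"temperature must be positive, got {t}")
    nus = freq_scale * np.asarray(thermo.frequencies, dtype=float)
    if nus.size and np.any(nus <= 0):
        raise ValueError(
            f"conformer {thermo.label or '?'}: non-positive frequency after "
            "scaling (should have failed the Hessian test)"
        )
    kt = sc.k * t
    rot_const = 8.0 * math.pi**2 * kt / sc.h**2      # 1 / (kg m^2)
    i_si = np.array(thermo.inertia) * _AMU_A2_KG_M2
    q_rot = (math.sqrt(math.pi) / sigma) * math.sqrt(
        np.prod(rot_const * i_si)
    )
    theta = sc.h * sc.c * 100.0 * nus / kt           # h c nu / kT
    q_vib = float(np.prod(1.0 / (1.0 - np.exp(-theta))))
    return q_rot * q_vib


def _boltzmann_terms(thermos, t, freq_scale, sigma):
    if not thermos:
        raise ValueError("empty conformer list")
    us = np.array([c.u for c in thermos])
    if abs(us.min()) > 1e-9:
        raise ValueError(
            f"relative energies must be zeroed at the global minimum "
            f"(min U = {us.min():.6f} kcal/mol)"
        )
    beta_u = us * _KCAL_PER_MOL_J * sc.Avogadro / (sc.R * t)
    q = np.array([rrho_partition(c, t, freq_scale, sigma) for c in thermos])
    return q * np.exp(-beta_u)


def msho_partition(
    thermos,
    t: float,
    freq_scale: float = DEFAULT_FREQ_SCALE,
    sigma: int = 1,
) -> float:
    """Boltzmann-weighted sum of per-conformer RR-HO partition functions."""
    return float(np.sum(_boltzmann_terms(thermos, t, freq_scale, sigma)))


def conformer_weights(
    thermos,
    t: float,
    freq_scale: float = DEFAULT_FREQ_SCALE,
    sigma: int = 1,
) -> np.ndarray:
    """Fractional contributions chi_i(T); sums to 1 by construction."""
    terms = _boltzmann_terms(thermos, t, freq_scale, sigma)
    return terms / terms.sum()


def n90(
    thermos,
    t: float,
    f: float = 0.9,
    freq_scale: float = DEFAULT_FREQ_SCALE,
    sigma: int = 1,
) -> int:
    """Conformers needed (in increasing-U order) to reach a fraction ``f``
    of the MS-HO partition function."""
    if not (0.0 < f < 1.0):
        raise ValueError(f"target fraction must be in (0, 1), got {f}")
    chi = conformer_weights(thermos, t, freq_scale, sigma)
    order = np.argsort([c.u for c in thermos], kind="stable")
    csum = np.cumsum(chi[order])
    return int(np.searchsorted(csum, f) + 1)


# --------------------------------------------------------------------------
# backbone classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneAngles:
    """The (phi1, phi2, phi3) backbone dihedral triple, degrees [0, 360)."""

    phi1: float
    phi2: float
    phi3: float

    def __post_init__(self):
        for name in ("phi1", "phi2", "phi3"):
            object.__setattr__(self, name, float(getattr(self, name)) % 360.0)

    def as_array(self):
        return np.array([self.phi1, self.phi2, self.phi3])


@dataclass(frozen=True)
class BackboneType:
    """Classification outcome: one of I / II / III / IV plus the distances."""

    name: str
    distances: tuple[float, float, float]
    threshold: float = DEFAULT_CLASS_THRESHOLD


# reference (phi1, phi2, phi3); None = free component (type I's phi1)
_TYPE_REFS = {
    "I": (None, 180.0, 180.0),
    "II": (0.0, 0.0, 0.0),
    "III": (180.0, 0.0, 180.0),
}


def classify_backbone(
    angles: BackboneAngles,
    threshold: float = DEFAULT_CLASS_THRESHOLD,
) -> BackboneType:
    """Assign the nearest hydrogen-bond motif by circular Euclidean distance.

    The type-I reference leaves phi1 free (its term is omitted).  If the
    distances to all three references exceed ``threshold`` the conformer is
    type IV.  Exact ties break in the order I < II < III.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    phis = angles.as_array()
    dists = []
    for name in ("I", "II", "III"):
        refs = _TYPE_REFS[name]
        acc = 0.0
        for phi, ref in zip(phis, refs):
            if ref is None:
                continue
            acc += float(circular_distance(phi, ref)) ** 2
        dists.append(math.sqrt(acc))
    dists = tuple(dists)
    if all(d > threshold for d in dists):
        return BackboneType("IV", dists, threshold)
    best = ("I", "II", "III")[int(np.argmin(dists))]   # argmin: first wins
    return BackboneType(best, dists, threshold)


def lone_pair_direction(
    geom: CartesianGeometry, n_index: int, neighbors
) -> np.ndarray:
    """Unit vector along the nitrogen lone pair.

    Defined as the negated, normalised sum of the three unit vectors from N
    to its bonded neighbours; a (near-)planar sp2 nitrogen leaves a vanishing
    sum and is rejected.
    """
    neighbors = list(neighbors)
    if len(neighbors) != 3:
        raise GeometryError(
            f"lone-pair rule needs exactly 3 neighbours on atom "
            f"{n_index + 1}, got {len(neighbors)}"
        )
    n_pos = geom.coords[n_index]
    acc = np.zeros(3)
    for a in neighbors:
        u = geom.coords[a] - n_pos
        acc += u / np.linalg.norm(u)
    norm = np.linalg.norm(acc)
    if norm < 1e-6:
        raise GeometryError(
            f"planar nitrogen at atom {n_index + 1}: lone-pair direction "
            "undefined"
        )
    return -acc / norm


@dataclass(frozen=True)
class BackboneAtoms:
    """Indices (0-based) of the backbone atoms used by the classification."""

    h: int       # hydroxyl hydrogen
    o_h: int     # hydroxyl oxygen
    o_c: int     # carbonyl oxygen
    c1: int      # carboxyl carbon
    ca: int      # alpha carbon
    n: int       # amine nitrogen


def identify_backbone(
    geom: CartesianGeometry, adjacency: AdjacencyMatrix | None = None
) -> BackboneAtoms:
    """Locate the H-O-C1(=O)-Ca-N backbone from the adjacency matrix.

    C1 is the carbon bonded to two oxygens, Ca the carbon bonded to C1 and a
    nitrogen, the hydroxyl oxygen the C1-bonded oxygen that carries a
    hydrogen.  Raises :class:`GeometryError` when the motif is absent or
    ambiguous; callers may bypass this with an explicit override map.
    """
    adj = adjacency if adjacency is not None else adjacency_matrix(geom)
    els = geom.elements

    def neigh(i, symbol=None):
        out = adj.neighbors(i)
        return [j for j in out if symbol is None or els[j] == symbol]

    candidates = []
    for i, el in enumerate(els):
        if el != "C" or len(neigh(i, "O")) != 2:
            continue
        for ca in neigh(i, "C"):
            for n in neigh(ca, "N"):
                candidates.append((i, ca, n))
    if len(candidates) != 1:
        raise GeometryError(
            f"backbone identification found {len(candidates)} "
            "C1(O,O)-Ca-N motifs; supply an override map"
        )
    c1, ca, n = candidates[0]
    o_with_h = [o for o in neigh(c1, "O") if neigh(o, "H")]
    if len(o_with_h) != 1:
        raise GeometryError(
            "carboxyl group does not have exactly one O-H oxygen "
            "(zwitterion or deprotonated form?)"
        )
    o_h = o_with_h[0]
    o_c = next(o for o in neigh(c1, "O") if o != o_h)
    h = neigh(o_h, "H")[0]
    return BackboneAtoms(h=h, o_h=o_h, o_c=o_c, c1=c1, ca=ca, n=n)


def backbone_angles_from_geometry(
    geom: CartesianGeometry,
    adjacency: AdjacencyMatrix | None = None,
    atoms: BackboneAtoms | None = None,
) -> BackboneAngles:
    """Measure (phi1, phi2, phi3) on a Cartesian conformer.

    phi3 is measured against a lone-pair pseudo-atom placed 1 Angstrom from N
    along the lone-pair direction.
    """
    adj = adjacency if adjacency is not None else adjacency_matrix(geom)
    if atoms is None:
        atoms = identify_backbone(geom, adj)
    phi1 = measure_dihedral(geom, atoms.h, atoms.o_h, atoms.c1, atoms.ca)
    phi2 = measure_dihedral(geom, atoms.o_c, atoms.c1, atoms.ca, atoms.n)
    lp = lone_pair_direction(geom, atoms.n, adj.neighbors(atoms.n))
    pseudo = geom.coords[atoms.n] + lp
    ext = CartesianGeometry(
        tuple(geom.elements) + ("X",),
        np.vstack([geom.coords, pseudo]),
    )
    phi3 = measure_dihedral(ext, atoms.c1, atoms.ca, atoms.n, geom.n_atoms)
    return BackboneAngles(phi1=phi1, phi2=phi2, phi3=phi3)


# --------------------------------------------------------------------------
# dataset format
# --------------------------------------------------------------------------

def read_conformer_dataset(text: str, strict: bool = True):
    """Parse the per-conformer block dataset format.

    Blocks look like::

        conformer gly_001
        energy   0.000        # kcal/mol relative to the global minimum
        inertia  51.2 186.3 223.4
        zpe      49.95        # optional, kcal/mol
        dipole   1.21         # optional, Debye
        origin   stochastic   # optional provenance tag
        freqs    63.1 250.4 ... (free wrapping across lines)
        geom
        N   0.0000  0.0000  0.0000
        ...
        end

    ``strict=True`` raises on any malformed block; ``strict=False`` skips
    malformed blocks and returns what parsed (tolerant mode).
    Returns a list of :class:`ConformerThermo`.
    """
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.split()[0].lower() == "conformer":
            current = [line]
            blocks.append(current)
        elif current is not None:
            current.append(line)
        elif strict:
            raise ValueError(f"content before first 'conformer' header: {line!r}")
    out = []
    for block in blocks:
        try:
            out.append(_parse_block(block))
        except Exception:
            if strict:
                raise
    return out


def _parse_block(lines: list[str]) -> ConformerThermo:
    label = lines[0].split(maxsplit=1)[1] if len(lines[0].split()) > 1 else ""
    fields: dict[str, str] = {}
    freqs: list[float] = []
    geom_rows: list[tuple[str, float, float, float]] = []
    mode = None
    for line in lines[1:]:
        toks = line.split()
        key = toks[0].lower()
        if mode == "freqs" and _all_floats(toks):
            freqs.extend(map(float, toks))
            continue
        if mode == "geom":
            if key == "end":
                mode = None
                continue
            if len(toks) != 4:
                raise ValueError(f"bad geometry row: {line!r}")
            geom_rows.append(
                (toks[0], float(toks[1]), float(toks[2]), float(toks[3]))
            )
            continue
        if key == "freqs":
            mode = "freqs"
            freqs.extend(map(float, toks[1:]))
        elif key == "geom":
            mode = "geom"
        else:
            mode = None
            fields[key] = " ".join(toks[1:])
    if "energy" not in fields:
        raise ValueError(f"conformer {label!r}: missing energy")
    if "inertia" not in fields:
        raise ValueError(f"conformer {label!r}: missing inertia")
    inertia = tuple(float(x) for x in fields["inertia"].split())
    if len(inertia) != 3:
        raise ValueError(f"conformer {label!r}: need 3 moments of inertia")
    geometry = None
    if geom_rows:
        geometry = CartesianGeometry(
            tuple(r[0] for r in geom_rows),
            np.array([r[1:] for r in geom_rows]),
        )
    return ConformerThermo(
        u=float(fields["energy"]),
        frequencies=tuple(freqs),
        inertia=inertia,       # type: ignore[arg-type]
        zpe=float(fields["zpe"]) if "zpe" in fields else None,
        dipole=float(fields["dipole"]) if "dipole" in fields else None,
        label=label,
        geometry=geometry,
        origin=fields.get("origin", ""),
    )


def _all_floats(toks):
    try:
        [float(t) for t in toks]
        return True
    except ValueError:
        return False


def write_conformer_dataset(thermos) -> str:
    """Serialise conformers back to the block format (round-trips the reader)."""
    chunks = []
    for i, c in enumerate(thermos):
        lines = [f"conformer {c.label or i + 1}"]
        lines.append(f"energy {c.u:.6f}")
        lines.append("inertia " + " ".join(f"{x:.6f}" for x in c.inertia))
        if c.zpe is not None:
            lines.append(f"zpe {c.zpe:.6f}")
        if c.dipole is not None:
            lines.append(f"dipole {c.dipole:.6f}")
        if c.origin:
            lines.append(f"origin {c.origin}")
        if c.frequencies:
            lines.append("freqs " + " ".join(f"{f:.4f}" for f in c.frequencies))
        if c.geometry is not None:
            lines.append("geom")
            for el, xyz in zip(c.geometry.elements, c.geometry.coords):
                lines.append(
                    f"{el} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}"
                )
            lines.append("end")
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"


def summary_table(
    thermos,
    t: float = DEFAULT_TEMPERATURE,
    freq_scale: float = DEFAULT_FREQ_SCALE,
    threshold: float = DEFAULT_CLASS_THRESHOLD,
):
    """Tidy per-conformer summary (pandas DataFrame): id, U, type, chi, cum-chi.

    Conformers are reported in increasing-U order; classification is only
    attempted when the conformer carries a geometry with a recognisable
    backbone, else the type column holds ''.
    """
    import pandas as pd

    chi = conformer_weights(thermos, t, freq_scale)
    order = np.argsort([c.u for c in thermos], kind="stable")
    rows = []
    cum = 0.0
    for rank, idx in enumerate(order):
        c = thermos[idx]
        cum += chi[idx]
        btype = ""
        if c.geometry is not None:
            try:
                btype = classify_backbone(
                    backbone_angles_from_geometry(c.geometry), threshold
                ).name
            except GeometryError:
                btype = ""
        rows.append(
            {
                "id": c.label or str(idx),
                "U_kcal_mol": c.u,
                "type": btype,
                "chi": float(chi[idx]),
                "cumulative_chi": float(cum),
            }
        )
    return pd.DataFrame(rows)
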