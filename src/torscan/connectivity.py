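"""Covalent-radii bond perception and adjacency-matrix comparison.

A pair of atoms (A, B) is considered bonded when their distance is strictly
smaller than ``fc * (r_A + r_B)``, with r the tabulated single-bond covalent
radii and ``fc`` a user-controlled dimensionless scale factor (default 1.3; a
larger value makes bonding more permissive).  The resulting 0/1 adjacency
matrix identifies the constitutional isomer: geometries whose adjacency
differs from the reference one (bond broken, bond formed, proton transferred)
are discarded by the search.

Only 0/1 adjacency is perceived here — no bond orders, no aromaticity.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .geom import CartesianGeometry

__all__ = [
    "RadiiTable",
    "AdjacencyMatrix",
    "ConnectivityError",
    "DEFAULT_FC",
    "adjacency_matrix",
    "same_connectivity",
]

#: Default bond-criterion scale factor (exposed in config as connectivity.fc).
DEFAULT_FC = 1.3


class ConnectivityError(ValueError):
    pass


@dataclass(frozen=True)
class RadiiTable:
    """Element symbol -> single-bond covalent radius in Angstrom."""

    radii: dict

    @classmethod
    def bundled(cls) -> "RadiiTable":
        """The packaged radii table (see data file header for provenance)."""
        table = {}
        text = (
            resources.files("torscan.data")
            .joinpath("covalent_radii.tsv")
            .read_text()
        )
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sym, val = line.split()
            radius = float(val)
            table[sym] = radius
        return cls(radii=table)

    def with_overrides(self, **overrides: float) -> "RadiiTable":
        merged = dict(self.radii)
        merged.update(overrides)
        return RadiiTable(radii=merged)

    def radius(self, element: str) -> float:
        try:
            r = self.radii[element]
        except KeyError:
            raise ConnectivityError(
                f"element {element!r} missing from the covalent-radii table"
            ) from None
        if r < 0:
            raise ConnectivityError(f"negative radius for element {element!r}")
        return r


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric N x N 0/1 connectivity matrix with its element labels."""

    entries: np.ndarray
    elements: tuple[str, ...]

    def __post_init__(self):
        a = np.asarray(self.entries, dtype=np.int8)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConnectivityError("adjacency matrix must be square")
        if a.shape[0] != len(self.elements):
            raise ConnectivityError("element list does not match matrix size")
        if not np.array_equal(a, a.T):
            raise ConnectivityError("adjacency matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ConnectivityError("adjacency matrix must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ConnectivityError("adjacency entries must be 0 or 1")
        a.setflags(write=False)
        object.__setattr__(self, "entries", a)

    @property
    def n_atoms(self) -> int:
        return self.entries.shape[0]

    def neighbors(self, i: int) -> list[int]:
        return [int(j) for j in np.flatnonzero(self.entries[i])]

    def bonds(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_atoms, k=1)
        mask = self.entries[iu] == 1
        return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))


def adjacency_matrix(
    geom: CartesianGeometry,
    radii: RadiiTable | None = None,
    fc: float = DEFAULT_FC,
) -> AdjacencyMatrix:
    """Perceive bonds with the scaled covalent-radii criterion.

    Entry (A, B) is 1 iff ``d_AB < fc * (r_A + r_B)`` for A != B; the
    inequality is strict, so a pair exactly at the threshold is unbonded.
    """
    if fc <= 0:
        raise ConnectivityError(f"scale factor fc must be positive, got {fc}")
    if radii is None:
        radii = RadiiTable.bundled()
    r = np.array([radii.radius(el) for el in geom.elements])
    d = squareform(pdist(geom.coords))
    thresh = fc * (r[:, None] + r[None, :])
    entries = (d < thresh).astype(np.int8)
    np.fill_diagonal(entries, 0)
    return AdjacencyMatrix(entries=entries, elements=tuple(geom.elements))


def same_connectivity(a: AdjacencyMatrix, b: AdjacencyMatrix) -> bool:
    """Entry-wise equality of two adjacency matrices of the same system."""
    if a.n_atoms != b.n_atoms or a.elements != b.elements:
        raise ConnectivityError(
            "adjacency matrices describe different systems "
            f"({a.n_atoms} atoms {a.elements!r} vs {b.n_atoms} atoms "
            f"{b.elements!r})"
        )
    return bool(np.array_equal(a.entries, b.entries))
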