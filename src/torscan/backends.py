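"""Energy backends: the optimization/Hessian contract consumed by the search.

Two backends are provided:

* :class:`ToyBackend` — an analytic torsional potential (per-torsion cosine
  series plus optional pairwise cosine couplings) over the K flagged
  dihedrals, with all remaining internal coordinates held at their template
  values.  It makes the entire search loop testable at desk scale and supplies
  the brute-force enumeration oracle used by the property tests.
* :class:`GaussianAdapter` — a file-level interface that writes opt/freq
  input decks and parses log files.  It never executes an external program;
  running the electronic-structure code and feeding the log text back is the
  caller's job, so the package builds and tests without any QM installed.

Toy energies are in arbitrary "toy units"; toy frequencies map torsional
Hessian eigenvalues lambda to ``sign(lambda) * C * sqrt(|lambda|)`` cm^-1 with
an arbitrary fixed constant C, preserving the only property the validation
battery uses (the sign pattern, i.e. the index of the stationary point).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .geom import (
    CartesianGeometry,
    TorsionVector,
    ZMatrix,
    format_zmatrix,
    substitute_torsions,
    wrap360,
    zmatrix_to_cartesian,
)

__all__ = [
    "BackendResult",
    "ToyPESParams",
    "ToyBackend",
    "toy_energy",
    "toy_gradient",
    "toy_hessian",
    "toy_optimize",
    "toy_frequencies",
    "brute_force_minima",
    "GaussianAdapter",
    "write_gaussian_input",
    "parse_gaussian_log",
]

#: cm^-1 per sqrt(toy-energy-unit)/rad of curvature — arbitrary, fixed.
_FREQ_SCALE_CM = 350.0

#: central-difference step for the numerical torsional Hessian, radians
_HESS_STEP = 1e-3

_MAXITER = 10_000


@dataclass
class BackendResult:
    """Outcome of one optimization (and optional Hessian) call."""

    zmatrix: ZMatrix | None
    geometry: CartesianGeometry | None
    energy: float
    converged: bool
    frequencies: list[float] | None = None   # cm^-1, negative = imaginary
    level: str = "toy"

    @property
    def torsions(self) -> TorsionVector:
        return self.zmatrix.torsion_values()


# --------------------------------------------------------------------------
# analytic toy torsional PES
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyPESParams:
    """Cosine-series torsional potential.

    ``terms[i]`` is the series of torsion i: tuples (V_n, n, gamma_deg) each
    contributing ``(V_n / 2) * (1 - cos(n * (phi_i - gamma)))``.  ``couplings``
    holds (i, j, c) contributions ``c * cos(phi_i - phi_j)``.  The potential is
    exactly 360-periodic in every component; it is reflection-symmetric
    (E(-Phi) = E(Phi)) whenever every gamma is 0 or 180 deg, since the cosine
    couplings are even.
    """

    terms: tuple[tuple[tuple[float, int, float], ...], ...]
    couplings: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self):
        for i, series in enumerate(self.terms):
            if not any(n >= 1 for _, n, _ in series):
                raise ValueError(f"torsion {i}: needs at least one n >= 1 term")
        for i, j, _ in self.couplings:
            k = len(self.terms)
            if not (0 <= i < k and 0 <= j < k and i != j):
                raise ValueError(f"bad coupling indices ({i}, {j}) for K={k}")

    @property
    def k(self) -> int:
        return len(self.terms)


def _as_rad(phi_deg) -> np.ndarray:
    return np.radians(np.atleast_2d(np.asarray(phi_deg, dtype=float)))


def toy_energy(phi_deg, params: ToyPESParams):
    """Energy at one torsion vector (degrees) or a batch of them.

    Accepts shape (K,) or (M, K); returns a scalar or shape (M,).
    """
    x = _as_rad(phi_deg)                       # (M, K)
    e = np.zeros(x.shape[0])
    for i, series in enumerate(params.terms):
        for v, n, g in series:
            e += 0.5 * v * (1.0 - np.cos(n * (x[:, i] - np.radians(g))))
    for i, j, c in params.couplings:
        e += c * np.cos(x[:, i] - x[:, j])
    return e if np.asarray(phi_deg).ndim == 2 else float(e[0])


def toy_gradient(phi_deg, params: ToyPESParams):
    """dE/dphi in toy-units per radian; shape matches the input batch."""
    x = _as_rad(phi_deg)
    g = np.zeros_like(x)
    for i, series in enumerate(params.terms):
        for v, n, gam in series:
            g[:, i] += 0.5 * v * n * np.sin(n * (x[:, i] - np.radians(gam)))
    for i, j, c in params.couplings:
        s = np.sin(x[:, i] - x[:, j])
        g[:, i] -= c * s
        g[:, j] += c * s
    return g if np.asarray(phi_deg).ndim == 2 else g[0]


def toy_hessian(phi_deg, params: ToyPESParams):
    """Analytic Hessian in toy-units per radian^2; (K, K) or (M, K, K)."""
    x = _as_rad(phi_deg)
    m, k = x.shape
    h = np.zeros((m, k, k))
    for i, series in enumerate(params.terms):
        for v, n, gam in series:
            h[:, i, i] += 0.5 * v * n * n * np.cos(n * (x[:, i] - np.radians(gam)))
    for i, j, c in params.couplings:
        cc = np.cos(x[:, i] - x[:, j])
        h[:, i, i] -= c * cc
        h[:, j, j] -= c * cc
        h[:, i, j] += c * cc
        h[:, j, i] += c * cc
    return h if np.asarray(phi_deg).ndim == 2 else h[0]


def _minimize(x0_rad: np.ndarray, params: ToyPESParams,
              gtol: float = 1e-9, maxiter: int = _MAXITER):
    """Damped Newton descent with gradient-step fallback. Deterministic.

    Returns (x_rad, converged); converged guarantees a gradient norm below
    1e-8.  A start whose gradient norm is below 1e-10 (an exact stationary
    point, e.g. a cosine maximum) is first displaced by +0.1 deg on every
    torsion so that the escape direction is reproducible.  Near an exact
    minimum the energy decrement underflows double precision before the
    gradient reaches ``gtol``; a line-search failure with gradient norm
    already below 1e-8 therefore still counts as converged.
    """
    x = np.array(x0_rad, dtype=float)
    deg = np.degrees
    g = toy_gradient(deg(x), params)
    if np.linalg.norm(g) < 1e-10:
        x = x + np.radians(0.1)
    for _ in range(maxiter):
        g = toy_gradient(deg(x), params)
        if np.linalg.norm(g) < gtol:
            return x, True
        h = toy_hessian(deg(x), params)
        step = None
        try:
            np.linalg.cholesky(h)        # positive definite -> Newton
            step = np.linalg.solve(h, -g)
        except np.linalg.LinAlgError:
            pass
        if step is None or np.dot(step, g) >= 0:
            step = -g
        # cap the step (0.5 rad) so near-inflection curvature cannot launch
        # the iterate across basin boundaries
        norm = np.linalg.norm(step)
        if norm > 0.5:
            step = step * (0.5 / norm)
        # backtracking line search on the energy
        e0 = toy_energy(deg(x), params)
        t = 1.0
        for _ls in range(60):
            xn = x + t * step
            if toy_energy(deg(xn), params) < e0 + 1e-4 * t * np.dot(g, step):
                break
            t *= 0.5
        else:
            return x, bool(np.linalg.norm(g) < 1e-8)
        x = xn
    return x, bool(np.linalg.norm(toy_gradient(deg(x), params)) < 1e-8)


def toy_optimize(zmat: ZMatrix, params: ToyPESParams) -> BackendResult:
    """Minimise the toy PES over the K flagged torsions of ``zmat``.

    Non-target internals are frozen at their template values (the harmonic
    restraints are infinitely stiff in this idealisation).  The returned
    gradient norm is below 1e-8; failure to converge within the iteration cap
    flags the result unconverged.
    """
    if zmat.k != params.k:
        raise ValueError(f"Z-matrix has K={zmat.k} torsions, PES has {params.k}")
    phi0 = zmat.torsion_values()
    x, ok = _minimize(np.radians(phi0.values), params)
    phi = TorsionVector(wrap360(np.degrees(x)))
    new_zmat = substitute_torsions(zmat, phi)
    return BackendResult(
        zmatrix=new_zmat,
        geometry=zmatrix_to_cartesian(new_zmat),
        energy=toy_energy(phi.values, params),
        converged=bool(ok),
        level="toy",
    )


def toy_frequencies(result: BackendResult, params: ToyPESParams,
                    step: float = _HESS_STEP) -> list[float]:
    """Frequencies from the central-difference torsional Hessian.

    Eigenvalues are mapped to cm^-1 preserving sign, so a saddle shows up as
    exactly one negative (imaginary) entry.
    """
    phi = np.radians(result.torsions.values)
    k = phi.size
    h = np.empty((k, k))
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k); ea[a] = step
            eb = np.zeros(k); eb[b] = step
            if a == b:
                f = toy_energy(np.degrees(phi + ea), params)
                m = toy_energy(np.degrees(phi - ea), params)
                c = toy_energy(np.degrees(phi), params)
                h[a, a] = (f - 2 * c + m) / step**2
            else:
                pp = toy_energy(np.degrees(phi + ea + eb), params)
                pm = toy_energy(np.degrees(phi + ea - eb), params)
                mp = toy_energy(np.degrees(phi - ea + eb), params)
                mm = toy_energy(np.degrees(phi - ea - eb), params)
                h[a, b] = h[b, a] = (pp - pm - mp + mm) / (4 * step**2)
    eig = np.linalg.eigvalsh(h)
    return [float(np.sign(l) * _FREQ_SCALE_CM * np.sqrt(abs(l))) for l in eig]


@dataclass
class ToyBackend:
    """Optimization/Hessian backend over an analytic torsional PES.

    Counts its optimization calls (``n_optimizations``) so tests can verify
    how much work the screening tests and the enantiomer bookkeeping save.
    """

    params: ToyPESParams
    name: str = "toy"
    n_optimizations: int = field(default=0, init=False)

    def optimize(self, zmat: ZMatrix) -> BackendResult:
        self.n_optimizations += 1
        res = toy_optimize(zmat, self.params)
        res.level = self.name
        return res

    def frequencies(self, result: BackendResult) -> list[float]:
        return toy_frequencies(result, self.params)

    def energy_of_geometry(self, zmat: ZMatrix) -> float:
        return toy_energy(zmat.torsion_values().values, self.params)


# --------------------------------------------------------------------------
# brute-force enumeration oracle
# --------------------------------------------------------------------------

def brute_force_minima(
    params: ToyPESParams,
    grid_step: float = 5.0,
    epsilon: float = 2.0,
) -> list[TorsionVector]:
    """Enumerate all minima of the toy PES: descend from every grid point.

    Dense ``grid_step``-degree grid over [0, 360)^K; every grid point is
    relaxed (vectorised gradient descent, then a damped-Newton polish of the
    deduplicated candidates); stationary points with non-positive-definite
    Hessians are re-escaped exactly as :func:`toy_optimize` would.  Duplicates
    are merged at the circular tolerance ``epsilon``.  Independent of the
    search loop: no seeds, no screening tests.
    """
    k = params.k
    axes = [np.arange(0.0, 360.0, grid_step)] * k
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
    x = np.radians(grid)

    # vectorised descent with per-point adaptive step ("bold driver");
    # converged points are retired from the active set as they settle
    active = np.arange(x.shape[0])
    lr = np.full(x.shape[0], 0.02)
    e = toy_energy(np.degrees(x), params)
    for _ in range(3000):
        xa = x[active]
        g = toy_gradient(np.degrees(xa), params)
        done = np.max(np.abs(g), axis=1) < 1e-7
        if done.any():
            active = active[~done]
            if active.size == 0:
                break
            xa = x[active]
            g = g[~done]
        xn = xa - lr[active, None] * g
        en = toy_energy(np.degrees(xn), params)
        worse = en > e[active]
        lr[active[worse]] *= 0.5
        lr[active[~worse]] *= 1.05
        np.clip(lr, 1e-6, 0.05, out=lr)
        keep = active[~worse]
        x[keep] = xn[~worse]
        e[keep] = en[~worse]

    # deduplicate candidates coarsely (1-degree binning collapses each
    # converged cluster), then polish each representative
    binned = np.round(wrap360(np.degrees(x))).astype(int) % 360
    found = [c.astype(float) for c in np.unique(binned, axis=0)]
    minima: list[np.ndarray] = []
    for cand in found:
        xf, ok = _minimize(np.radians(cand), params)
        if not ok:
            continue
        h = toy_hessian(np.degrees(xf), params)
        if np.min(np.linalg.eigvalsh(h)) <= 1e-10:
            # landed on a saddle/maximum: nudge and re-descend
            xf, ok = _minimize(xf + np.radians(0.2), params)
            if not ok:
                continue
            h = toy_hessian(np.degrees(xf), params)
            if np.min(np.linalg.eigvalsh(h)) <= 1e-10:
                continue
        v = wrap360(np.degrees(xf))
        if not any(np.all(_circ_close(v, m, epsilon)) for m in minima):
            minima.append(v)
    minima.sort(key=lambda v: tuple(np.round(v, 6)))
    return [TorsionVector(v) for v in minima]


def _circ_close(a, b, tol):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d) <= tol


# --------------------------------------------------------------------------
# Gaussian-dialect file adapter (write inputs, parse logs; no execution)
# --------------------------------------------------------------------------

def write_gaussian_input(
    zmat: ZMatrix,
    route: str = "#P HF/3-21G opt",
    charge: int = 0,
    multiplicity: int = 1,
    title: str = "torscan generated deck",
) -> str:
    """A syntactically valid opt/freq input deck embedding the Z-matrix."""
    block = format_zmatrix(zmat)
    return (
        f"{route}\n\n{title}\n\n{charge} {multiplicity}\n{block}\n"
    )


_SCF_RE = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_FREQ_RE = re.compile(r"Frequencies\s*--\s*(.*)")
_COORD_BLOCK_RE = re.compile(
    r"(?:Standard|Input) orientation:\s*\n\s*-{20,}\n.*?\n\s*-{20,}\n(.*?)\n\s*-{20,}",
    re.S,
)

_Z = {
    1: "H", 2: "He", 6: "C", 7: "N", 8: "O", 9: "F", 15: "P", 16: "S",
    17: "Cl", 35: "Br", 53: "I",
}


def parse_gaussian_log(text: str) -> BackendResult:
    """Extract the final geometry, energy, convergence flag and frequencies.

    Convergence requires both an optimization-completed stamp and a normal
    termination; a missing termination stamp yields ``converged=False``
    rather than an exception, so failed jobs flow through the search loop as
    skipped seeds.
    """
    energies = _SCF_RE.findall(text)
    energy = float(energies[-1]) if energies else np.nan

    converged = (
        "Stationary point found" in text and "Normal termination" in text
    )

    geometry = None
    blocks = _COORD_BLOCK_RE.findall(text)
    if blocks:
        elements, rows = [], []
        for line in blocks[-1].strip().splitlines():
            toks = line.split()
            if len(toks) < 6:
                raise ValueError(f"unparsable orientation row: {line!r}")
            z = int(toks[1])
            elements.append(_Z.get(z, f"Z{z}"))
            rows.append([float(t) for t in toks[-3:]])
        geometry = CartesianGeometry(tuple(elements), np.array(rows))
    elif converged:
        raise ValueError("converged log carries no orientation block")

    freqs: list[float] | None = None
    hits = _FREQ_RE.findall(text)
    if hits:
        freqs = [float(t) for line in hits for t in line.split()]

    return BackendResult(
        zmatrix=None,
        geometry=geometry,
        energy=energy,
        converged=converged,
        frequencies=freqs,
        level="gaussian",
    )


@dataclass
class GaussianAdapter:
    """File-level backend half: deck writer + log parser, no execution."""

    route_opt: str = "#P HF/3-21G opt"
    route_freq: str = "#P HF/3-21G freq"
    charge: int = 0
    multiplicity: int = 1
    name: str = "gaussian"

    def write_opt_input(self, zmat: ZMatrix) -> str:
        return write_gaussian_input(
            zmat, self.route_opt, self.charge, self.multiplicity
        )

    def write_freq_input(self, zmat: ZMatrix) -> str:
        return write_gaussian_input(
            zmat, self.route_freq, self.charge, self.multiplicity
        )

    @staticmethod
    def parse_log(text: str) -> BackendResult:
        return parse_gaussian_log(text)
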