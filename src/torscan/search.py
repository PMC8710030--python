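"""Seed generation, screening and the main conformer-search loop.

The search samples the K-dimensional torsional space in two stages.  The
preconditioned stage enumerates the Cartesian product of chemically expected
per-torsion seed angles (gauche/anti for sp3-like torsions, syn/anti for
2-fold ones).  The stochastic stage draws uniform random torsion vectors and
screens each against every previously visited vector (the similarity test):
only seeds that land outside the d-degree domain of all saved vectors are
optimized.  Each surviving seed is turned into a trial geometry using the
internals of the closest already-optimized conformer, validated (connectivity
and constraints), optimized by the energy backend, and re-validated
(connectivity, redundancy at the tighter epsilon threshold, constraints,
Hessian test) before being stored as a conformer.

Both screening thresholds use the wrap-around circular metric on angles, so
1 deg and 359 deg are 2 deg apart.

Parallelism follows the batch-splitting model: the deterministic seed list
can be partitioned into M near-equal groups processed by independent
executions; within one invocation everything is sequential.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .backends import BackendResult
from .connectivity import (
    DEFAULT_FC,
    AdjacencyMatrix,
    RadiiTable,
    adjacency_matrix,
    same_connectivity,
)
from .geom import (
    CartesianGeometry,
    TorsionVector,
    ZMatrix,
    measure_dihedral,
    nearest_template,
    zmatrix_to_cartesian,
)
from .validate import (
    DEFAULT_IMAG_TOL,
    ConstraintSet,
    TorsionSymmetry,
    check_constraints,
    enantiomer_vector,
    hessian_test,
    redundancy_test,
    umbrella_repair,
)

__all__ = [
    "TorsionSpec",
    "SeedPool",
    "SearchConfig",
    "Conformer",
    "ConformerEnsemble",
    "SeedRecord",
    "preconditioned_seeds",
    "stochastic_seed",
    "similarity_test",
    "split_batches",
    "run_search",
    "refine_ensemble",
]

# fallback per-torsion seed menus: sp3-like 3-fold and 2-fold (syn/anti)
SP3_SEEDS = (60.0, 180.0, 300.0)
TWOFOLD_SEEDS = (0.0, 180.0)


@dataclass(frozen=True)
class TorsionSpec:
    """Per-torsion preconditioned seed angles, degrees in [0, 360)."""

    seeds: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        for i, s in enumerate(self.seeds):
            if len(s) == 0:
                raise ValueError(f"torsion {i + 1}: empty seed list")
        object.__setattr__(
            self,
            "seeds",
            tuple(tuple(float(a) % 360.0 for a in s) for s in self.seeds),
        )

    @classmethod
    def sp3(cls, k: int) -> "TorsionSpec":
        return cls(seeds=tuple(SP3_SEEDS for _ in range(k)))


class SeedPool:
    """The two vector pools of the search bookkeeping.

    ``saved`` ({Phi^sv}) collects every torsional vector associated with an
    initial or optimized geometry (including enantiomeric images when mirror
    handling is on); the similarity test screens against it.  ``eq``
    ({Phi^eq}) collects the accepted conformers' vectors; the redundancy test
    screens against it.
    """

    def __init__(self):
        self.saved: list[TorsionVector] = []
        self.eq: list[TorsionVector] = []

    def add_saved(self, phi: TorsionVector) -> None:
        self.saved.append(phi)

    def add_eq(self, phi: TorsionVector) -> None:
        self.eq.append(phi)
        self.saved.append(phi)


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds, constraints and bookkeeping switches for one search."""

    d: float = 15.0               # similarity domain, degrees
    epsilon: float = 2.0          # redundancy tolerance, degrees
    n_stochastic: int = 0         # random seeds this invocation
    rng_seed: int = 0
    fc: float = DEFAULT_FC        # adjacency scale factor
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    enantiomers: bool = False     # Cs-capable molecule: store Phi* images
    torsion_symmetry: tuple[TorsionSymmetry, ...] | None = None
    count_enantiomers: bool = False  # also count images as conformers
    amine: tuple[int, int, int, int] | None = None  # (H1, H2, Calpha, N)
    imag_tol: float = DEFAULT_IMAG_TOL
    batch: tuple[int, int] | None = None  # (M, m), 1-based group index
    radii: RadiiTable | None = None

    def __post_init__(self):
        if not (0 < self.epsilon < self.d):
            raise ValueError(
                f"thresholds must satisfy 0 < epsilon < d, got "
                f"epsilon={self.epsilon}, d={self.d}"
            )
        if self.n_stochastic < 0:
            raise ValueError("n_stochastic must be >= 0")
        if self.batch is not None:
            m_groups, m = self.batch
            if not (1 <= m <= m_groups):
                raise ValueError(
                    f"batch index must satisfy 1 <= m <= M, got M={m_groups}, m={m}"
                )


@dataclass(frozen=True)
class Conformer:
    """An accepted equilibrium structure with its provenance."""

    index: int
    zmatrix: ZMatrix
    geometry: CartesianGeometry
    torsions: TorsionVector
    energy: float
    frequencies: tuple[float, ...]
    origin: str                   # "preconditioned" | "stochastic" | "refined"
    level: str                    # backend name, e.g. "toy-LL" / "gaussian"
    enantiomer_image: bool = False


@dataclass
class SeedRecord:
    """One manifest row: the full verdict trail of a seed."""

    seed_index: int
    origin: str
    phi: TorsionVector
    verdict: str = "pending"      # accepted | rejected:<test> | failed-opt
                                  # | skipped:<test>
    conformer: int | None = None
    energy: float | None = None

    def as_tsv(self) -> str:
        phi = ",".join(f"{v:.4f}" for v in self.phi.values)
        conf = "" if self.conformer is None else str(self.conformer)
        e = "" if self.energy is None else f"{self.energy:.10g}"
        return f"{self.seed_index}\t{self.origin}\t{phi}\t{self.verdict}\t{conf}\t{e}"


class ConformerEnsemble:
    """Accepted conformers plus the search bookkeeping that produced them."""

    def __init__(self, reference: ZMatrix):
        self.reference = reference
        self.conformers: list[Conformer] = []
        self.pool = SeedPool()
        self.records: list[SeedRecord] = []

    def __len__(self):
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    @property
    def eq_vectors(self) -> list[TorsionVector]:
        return self.pool.eq

    def add(self, conformer: Conformer) -> None:
        self.conformers.append(conformer)
        self.pool.add_eq(conformer.torsions)

    def sorted_by_energy(self) -> list[Conformer]:
        return sorted(self.conformers, key=lambda c: (c.energy, c.index))

    def manifest_tsv(self) -> str:
        header = "seed\torigin\tphi\tverdict\tconformer\tenergy"
        return "\n".join([header] + [r.as_tsv() for r in self.records]) + "\n"


# --------------------------------------------------------------------------
# seed generation and screening
# --------------------------------------------------------------------------

def preconditioned_seeds(spec: TorsionSpec) -> list[TorsionVector]:
    """Full Cartesian product of the per-torsion menus, lexicographic order."""
    return [TorsionVector(combo) for combo in itertools.product(*spec.seeds)]


def stochastic_seed(rng: np.random.Generator, k: int) -> TorsionVector:
    """One uniform random torsion vector on [0, 360)^K."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return TorsionVector(rng.uniform(0.0, 360.0, size=k))


def similarity_test(phi: TorsionVector, pool, d: float = 15.0) -> bool:
    """True iff ``phi`` lies outside the d-domain of every saved vector.

    For each saved vector there must exist at least one torsion whose circular
    distance to the corresponding component of ``phi`` exceeds ``d``; a vector
    within d on *all* torsions of some saved point is redundant.  An empty
    pool accepts everything.
    """
    if d <= 0:
        raise ValueError(f"similarity domain d must be positive, got {d}")
    vecs = getattr(pool, "saved", pool)
    for p in vecs:
        if phi.max_component_distance(p) <= d:
            return False
    return True


def split_batches(seeds, m_groups: int, m: int):
    """Deterministic partition of the seed list into M near-equal groups.

    Groups are contiguous; sizes differ by at most one; the union over
    m = 1..M is the original sequence with no duplicates.  ``m`` is 1-based.
    """
    seeds = list(seeds)
    if not (1 <= m <= m_groups):
        raise ValueError(f"batch index must satisfy 1 <= m <= M (M={m_groups}, m={m})")
    bounds = np.linspace(0, len(seeds), m_groups + 1).astype(int)
    return seeds[bounds[m - 1]: bounds[m]]


# --------------------------------------------------------------------------
# the main loop
# --------------------------------------------------------------------------

class BackendError(RuntimeError):
    """A backend raised instead of reporting failure; aborts with context."""


def _measure_partner_values(geom, sym):
    if sym is None:
        return None
    vals = []
    for s in sym:
        if s.kind == "out_of_plane":
            vals.append(measure_dihedral(geom, *s.partner_atoms))
        else:
            vals.append(None)
    return vals


def run_search(
    config: SearchConfig,
    backend,
    zmat: ZMatrix,
    spec: TorsionSpec | None = None,
    stages: str = "both",
) -> ConformerEnsemble:
    """Execute the two-stage conformer search.

    ``stages`` selects "preconditioned", "stochastic" or "both"; the
    preconditioned stage always precedes the stochastic one.  ``spec``
    defaults to the gauche/anti sp3 menu per torsion.  An optimization that
    the backend reports as unconverged logs the seed as failed and the search
    continues; an exception raised by the backend aborts with context.
    """
    zmat.validate()
    if zmat.k < 1:
        raise ValueError("reference Z-matrix flags no target torsions")
    if spec is None:
        spec = TorsionSpec.sp3(zmat.k)

    radii = config.radii or RadiiTable.bundled()
    ref_geom = zmatrix_to_cartesian(zmat)
    a_ref = adjacency_matrix(ref_geom, radii, config.fc)

    ensemble = ConformerEnsemble(reference=zmat)
    seeds: list[tuple[str, TorsionVector]] = []
    if stages in ("both", "preconditioned"):
        prec = preconditioned_seeds(spec)
        if config.batch is not None:
            prec = split_batches(prec, *config.batch)
        seeds += [("preconditioned", p) for p in prec]
    if stages in ("both", "stochastic"):
        rng = np.random.default_rng(config.rng_seed)
        seeds += [
            ("stochastic", stochastic_seed(rng, zmat.k))
            for _ in range(config.n_stochastic)
        ]

    for i, (origin, phi) in enumerate(seeds):
        record = SeedRecord(seed_index=i, origin=origin, phi=phi)
        ensemble.records.append(record)
        _process_seed(
            record, origin, phi, config, backend, zmat, ensemble, a_ref, radii
        )
    return ensemble


def _process_seed(record, origin, phi, config, backend, zmat, ensemble,
                  a_ref, radii):
    pool = ensemble.pool

    # --- initial-geometry validation -----------------------------------
    template = nearest_template(ensemble, phi)
    geom = zmatrix_to_cartesian(template)
    a_init = adjacency_matrix(geom, radii, config.fc)
    if not same_connectivity(a_ref, a_init):
        record.verdict = "skipped:connectivity"
        return
    if not similarity_test(phi, pool, config.d):
        record.verdict = "skipped:similarity"
        return
    if not check_constraints(geom, config.constraints):
        record.verdict = "skipped:constraints"
        return

    # the seed becomes a trial structure: its vector is saved either way,
    # together with its mirror image when enantiomer handling is on
    pool.add_saved(phi)
    if config.enantiomers:
        partners = _measure_partner_values(geom, config.torsion_symmetry)
        pool.add_saved(enantiomer_vector(phi, config.torsion_symmetry, partners))

    # --- optimization ---------------------------------------------------
    try:
        result: BackendResult = backend.optimize(template)
    except Exception as exc:
        raise BackendError(
            f"backend {getattr(backend, 'name', backend)!r} raised while "
            f"optimizing seed {record.seed_index} ({origin}, {phi})"
        ) from exc
    if not result.converged:
        record.verdict = "failed-opt"
        return

    phi_opt = result.torsions
    pool.add_saved(phi_opt)
    opt_geom = result.geometry or zmatrix_to_cartesian(result.zmatrix)
    record.energy = result.energy
    if config.enantiomers:
        partners = _measure_partner_values(opt_geom, config.torsion_symmetry)
        pool.add_saved(
            enantiomer_vector(phi_opt, config.torsion_symmetry, partners)
        )

    # --- optimized-geometry validation ----------------------------------
    a_opt = adjacency_matrix(opt_geom, radii, config.fc)
    if not same_connectivity(a_ref, a_opt):
        record.verdict = "rejected:connectivity"
        return
    if not redundancy_test(phi_opt, pool.eq, config.epsilon):
        record.verdict = "rejected:redundancy"
        return
    if not check_constraints(opt_geom, config.constraints):
        record.verdict = "rejected:constraints"
        return
    freqs = backend.frequencies(result)
    if not hessian_test(freqs, config.imag_tol):
        record.verdict = "rejected:hessian"
        return

    # --- umbrella repair -------------------------------------------------
    if config.amine is not None:
        opt_geom = umbrella_repair(geom, opt_geom, config.amine)

    conformer = Conformer(
        index=len(ensemble.conformers),
        zmatrix=result.zmatrix,
        geometry=opt_geom,
        torsions=phi_opt,
        energy=float(result.energy),
        frequencies=tuple(freqs),
        origin=origin,
        level=result.level,
    )
    ensemble.add(conformer)
    record.verdict = "accepted"
    record.conformer = conformer.index

    # --- enantiomeric image ----------------------------------------------
    # The mirror vector joins {Phi^eq} so the redundancy test rejects the
    # mirror minimum if a later optimization lands on it; by default it is
    # bookkeeping only (not counted as a located conformer).
    if config.enantiomers:
        partners = _measure_partner_values(opt_geom, config.torsion_symmetry)
        phi_star = enantiomer_vector(phi_opt, config.torsion_symmetry, partners)
        if not redundancy_test(phi_star, pool.eq, config.epsilon):
            return  # self-mirror conformer: image coincides with the original
        if config.count_enantiomers:
            image = replace(
                conformer,
                index=len(ensemble.conformers),
                torsions=phi_star,
                enantiomer_image=True,
            )
            ensemble.add(image)
        else:
            pool.add_eq(phi_star)


# --------------------------------------------------------------------------
# dual-level refinement
# --------------------------------------------------------------------------

def refine_ensemble(
    ll_ensemble: ConformerEnsemble,
    hl_backend,
    config: SearchConfig,
) -> ConformerEnsemble:
    """Re-optimize every low-level conformer with the high-level backend.

    Each accepted LL structure seeds one HL optimization; the HL result must
    pass the full optimized-geometry validation battery (connectivity at the
    HL geometry, redundancy against the HL ensemble, constraints, Hessian
    test) to be stored.  Distinct LL minima that collapse onto the same HL
    minimum are merged by the redundancy test, so the HL count can be lower.
    """
    radii = config.radii or RadiiTable.bundled()
    ref = ll_ensemble.reference
    a_ref = adjacency_matrix(zmatrix_to_cartesian(ref), radii, config.fc)
    hl = ConformerEnsemble(reference=ref)
    for i, conf in enumerate(ll_ensemble.conformers):
        record = SeedRecord(seed_index=i, origin="refined", phi=conf.torsions)
        hl.records.append(record)
        try:
            result = hl_backend.optimize(conf.zmatrix)
        except Exception as exc:
            raise BackendError(
                f"HL backend raised while refining conformer {conf.index}"
            ) from exc
        if not result.converged:
            record.verdict = "failed-opt"
            continue
        phi_opt = result.torsions
        hl.pool.add_saved(conf.torsions)
        hl.pool.add_saved(phi_opt)
        opt_geom = result.geometry or zmatrix_to_cartesian(result.zmatrix)
        record.energy = result.energy
        if not same_connectivity(a_ref, adjacency_matrix(opt_geom, radii, config.fc)):
            record.verdict = "rejected:connectivity"
            continue
        if not redundancy_test(phi_opt, hl.pool.eq, config.epsilon):
            record.verdict = "rejected:redundancy"
            continue
        if not check_constraints(opt_geom, config.constraints):
            record.verdict = "rejected:constraints"
            continue
        freqs = hl_backend.frequencies(result)
        if not hessian_test(freqs, config.imag_tol):
            record.verdict = "rejected:hessian"
            continue
        new = Conformer(
            index=len(hl.conformers),
            zmatrix=result.zmatrix,
            geometry=opt_geom,
            torsions=phi_opt,
            energy=float(result.energy),
            frequencies=tuple(freqs),
            origin=conf.origin,
            level=result.level,
        )
        hl.add(new)
        record.verdict = "accepted"
        record.conformer = new.index
    return hl
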