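# Methods

This note documents the models, numerical choices and deliberate design
decisions behind torscan, and what the synthetic test systems do and do not
establish.

## Coordinates and conventions

All angles are degrees on `[0, 360)`; every angular comparison (similarity,
redundancy, template lookup, classification) uses the wrap-around metric
`min(|Δ| mod 360, 360 − |Δ| mod 360)`, so 1° and 359° are 2° apart.  The
alternative — plain absolute differences — would treat vectors across the
0°/360° seam as distant, which has no chemical meaning; the circular metric
is applied uniformly even where a formula could be read literally with
plain differences.

Z-matrices follow a Gaussian-style dialect (element label, reference atoms,
bond/angle/dihedral, symbolic variables in a trailing block); a `*` after a
variable value flags that dihedral as a target torsion.  A torsion about a
given bond may be flagged only once; non-target dihedrals may share bonds
freely (several hydrogens on one carbon).  Dummy atoms (`X`) are accepted by
the parser but carry zero covalent radius, so they never enter adjacency,
and they may not be flagged as torsion targets — a documented assumption,
since their handling is otherwise unspecified.  Atom indices are 1-based in
files and error messages, 0-based in the API.  The Cartesian embedding fixes
atom 1 at the origin, atom 2 on +z and atom 3 in the xz-plane; the
convention is arbitrary but makes conversions bit-stable for testing.

## Bond perception

A pair (A, B) is bonded iff `d_AB < f_c · (r_A + r_B)` with strict `<` (a
pair exactly at the threshold is unbonded).  The bundled radii are the
Cordero 2008 single-bond covalent radii (sp³ carbon); the source is stated
in the data file header and every entry can be overridden.  The default
scale factor f_c = 1.3 is a permissive literature-typical value — the
criterion itself prescribes no default — and is exposed as
`connectivity.fc`.

## Search loop

Preconditioned seeds are the full Cartesian product of per-torsion menus in
lexicographic order; the default menus are {60, 180, 300}° for sp³-like
torsions and {0, 180}° for 2-fold ones (carboxylic, amide-like), fully
overridable per torsion.  Preconditioned seeds are always processed before
stochastic ones.  Stochastic seeds are uniform on the torus from a single
per-invocation PRNG whose seed is recorded in the manifest, making reruns
byte-identical.  The stochastic stage runs a fixed, user-chosen number of
seeds per invocation; no automatic termination heuristic is applied.

Each surviving seed is realised as a trial geometry using the internals of
the circularly closest already-accepted conformer (Euclidean norm of
component-wise circular differences; exact ties go to the lowest-index
conformer; the reference Z-matrix is used while the ensemble is empty).
This replaces the rigid-rotor practice of always reusing the reference
internals and matters increasingly with K.

Initial-geometry tests run in the order connectivity → similarity →
constraints; optimized-geometry tests in the order connectivity →
redundancy → constraints → Hessian, so no Hessian is computed for a
structure that is already rejected.  Trial vectors are recorded in the
saved pool whether or not the optimization later succeeds, so the
stochastic stage never revisits a failed region; a failed optimization is
not retried from a different template (a known divergence risk, accepted
for determinism).  Batch parallelism follows the independent-execution
model: the deterministic seed list is split into M contiguous near-equal
groups and group m is processed by one invocation; no in-process
multiprocessing.

## Umbrella inversion and enantiomers

The improper torsion φ₁₂ = H1-H2-Cα-N changes sign when the amine umbrella
inverts during optimization; when the trial and optimized signs differ the
two amine hydrogens are relabelled, keeping the proper torsion
C1-Cα-N-H1 unambiguous.  φ₁₂ within 1e-6° of planarity is refused as
degenerate.

Enantiomer handling activates only when the user declares the molecule
Cs-capable and supplies per-torsion mirror tags; there is no automatic
symmetry detection (only the single-mirror-plane case is supported).  The
image of every visited vector — trial and optimized — is stored in the
saved pool, and the image of every accepted conformer additionally enters
the equilibrium pool, so both the similarity and the redundancy tests see
the mirror half of the torus for free.  By default the image is
bookkeeping only: it is not counted as a located conformer
(`count_enantiomers` flips this, and then conformer totals include the
images).  Mirror geometries are produced by negating x and renumbering in
three steps: element classes, iterated neighbour-class refinement
(a 1-dimensional Weisfeiler–Lehman pass, cross-checked in the tests against
element-coloured graph-automorphism orbits), and signed dihedral-signature
matching for the residual ambiguity classes, using the fact that reflection
negates signed dihedrals.  Unresolvable classes (e.g. a graph-symmetric
chain with no distinguishing anchor) raise a symmetry error listing the
ambiguous atoms.

## Toy potential and optimizer

The built-in backend minimises `V(Φ) = Σ_i Σ_n (V_n/2)(1 − cos n(φ_i − γ_n))
+ Σ_(i<j) c_ij cos(φ_i − φ_j)` over the K flagged torsions, holding all
other internals at their template values (the idealised limit of infinitely
stiff restraints).  The minimiser is a damped Newton descent with analytic
gradient and Hessian, an Armijo backtracking line search, a 0.5 rad trust
cap on the step (near-inflection curvature would otherwise catapult the
iterate across basin boundaries), and a 10⁴ iteration cap; convergence
guarantees a gradient norm below 1e-8.  Near an exact minimum the energy
decrement underflows double precision before the gradient does, so a
line-search failure with the gradient already below 1e-8 counts as
converged.  A start with gradient norm below 1e-10 (an exact stationary
point, e.g. a preconditioned seed sitting on a cosine maximum) is displaced
by +0.1° on *every* torsion before optimizing.  Perturbing a single torsion
was considered and rejected: on a separable surface the remaining
components would stay exactly on their maxima (their gradient components
are identically zero under any quasi-Newton update), and every
preconditioned seed of a 3-fold surface would relax to a saddle and fail
the Hessian test.  Perturbing all components keeps the escape deterministic
and sends the {60, 180, 300}ᴷ seeds one-to-one onto the {120, 240, 0}ᴷ
minima.

Toy frequencies map the eigenvalues λ of a central-difference torsional
Hessian (step 1e-3 rad) to `sign(λ)·350·sqrt(|λ|)` cm⁻¹; the constant is
arbitrary — only the sign pattern feeds the Hessian test — and the step is
small enough that halving it changes frequencies by < 1e-6 relative.

The brute-force oracle enumerates minima independently of the search:
descend from *every* point of a dense grid (5° for the acceptance checks),
deduplicate at ε, polish each representative with the scalar minimiser, and
discard stationary points whose Hessian is not positive definite (after one
deterministic re-escape).  The descent is a vectorised adaptive-step
gradient scheme with an active-set retirement of converged points, which is
what keeps a 72³-point K = 3 grid tractable.

## Synthetic fixtures

The chain fixtures place K + 3 atoms on a 1.52 Å backbone with 132° angles
and a terminal nitrogen.  The wide angle keeps every non-adjacent pair
clear of the default bonding threshold at *all* torsion combinations for
K ≤ 3 (verified by grid scan), so the chain realises a pure torsional PES
and the connectivity test never interferes with the toy energetics; the
terminal N breaks the head–tail graph symmetry so the enantiomer
renumbering can anchor every atom.  The amino-backbone fixture is a
glycine-like H-O-C(=O)-Cα(H₂)-N(H₂) skeleton with φ₁ = H5-O1-C1-C2,
φ₂ = O1-C1-C2-N and φ₃ = C1-C2-N-H1 flagged; the second amine hydrogen sits
at a 120° dihedral offset from the first so that the 3-fold φ₃ well is
exactly consistent with the out-of-plane mirror rule φ₃* = −φ̄₃.  Well
depths are sampled in the 1–3 (toy unit) range and couplings within ±0.35,
i.e. couplings perturb but do not destroy the cosine well structure —
typical of real torsional profiles, where pair couplings are a fraction of
the well depth.

What a green search test establishes: the loop finds exactly the minimum
set of a smooth, bounded, analytically known torsional surface free of
geometric side effects.  What it does not establish: behaviour on real
electronic-structure surfaces with coupled bond/angle relaxation, flat or
fused basins, optimizer failures, or ring degrees of freedom (rings are out
of scope throughout).

The enantiomer-halving check runs the stochastic stage to saturation
(2000 seeds): the ~50% optimization saving is a coverage property of the
saved-vector domains, and at small seed counts both modes necessarily
optimize every fresh region they encounter, giving intermediate ratios.

## Thermochemistry

Q_RRHO is the product of the classical rigid-rotor factor
`(√π/σ)·(8π²k_BT/h²)^{3/2}·√(I_A I_B I_C)` and the ZPE-referenced harmonic
vibrational factor `Π (1 − e^{−hcν/k_BT})^{-1}`.  The vibrational zero is
each conformer's vibrational ground state while U_j is the *relative
electronic* energy; this keeps U and ZPE from being double-counted and
matches the electronic-energy ordering used for N90.  (A bottom-of-well
convention with ZPE folded into U is the natural alternative; weights are
insensitive to the common-mode choice but not to mixing conventions, which
is why the N90/χ numbers of external tables are reproducible only to the
extent their convention is known.)  Frequencies are scaled by 0.973 by
default — the recommended factor for the high-level model chemistry the
published amino-acid dataset uses — and σ = 1 throughout (C₁ conformers).
Defaults: T = 300 K, 90% target fraction.

Backbone atoms are identified from the adjacency matrix: C1 is the carbon
bonded to two oxygens, Cα the carbon bonded to C1 and N, the hydroxyl
oxygen the C1-oxygen carrying a hydrogen; φ₂ is measured against the
carbonyl oxygen.  The nitrogen lone pair is the negated normalised sum of
the three N→neighbour unit vectors, realised as a pseudo-atom 1 Å from N; a
planar nitrogen (vector sum < 1e-6) is refused.  Secondary amines
(proline-like nitrogens with ring bonds still give three neighbours, but
genuinely two-neighbour or four-neighbour nitrogens do not) fall outside
the rule; an explicit backbone-override map is the supported escape hatch,
with the behaviour otherwise undefined.  Classification ties between two
reference types are broken in the order I < II < III; exact ties are
measure-zero.

Enantiomeric degeneracy does not multiply Q: each dataset record is one
structure.

## Known limitations

* Ring-puckering conformations are not searched; rings can only be handled
  by flagging torsions inside the ring by hand.
* Zwitterionic and charged forms are rejected by the backbone identifier
  (no O-H oxygen) rather than classified.
* The Gaussian adapter is a file-format interface; it has not been
  validated against live quantum-chemistry runs, and route-card details
  beyond generic opt/freq decks are the caller's responsibility.
* The toy backend optimizes torsions only; it cannot model conformers that
  exist solely through non-torsional relaxation.
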