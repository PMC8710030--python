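# torscan

Torsional conformer search for flexible acyclic molecules, with the
downstream multi-structural thermochemistry needed to say which of the
located conformers actually matter at a given temperature.

## The problem

A molecule with K rotatable single bonds lives on a K-dimensional torus of
torsion angles Φ = (φ₁, …, φ_K); each local minimum of the potential energy
surface (PES) on that torus is a conformer.  For molecules like amino acids
(K = 3 for glycine, up to 9 for arginine) the number of minima runs from a
handful to thousands, and properties such as partition functions require
locating essentially all of them.  torscan implements a two-stage search:

* **Preconditioned stage** — systematic enumeration of chemically expected
  seeds (the Cartesian product of per-torsion menus, e.g. gauche/anti
  {60°, 180°, 300°} for sp³ bonds, syn/anti {0°, 180°} for carboxylic ones).
* **Stochastic stage** — uniform random torsion vectors, run second, to find
  the conformers chemical intuition misses.

Every candidate passes a validation battery before and after optimization:

* *connectivity* — the 0/1 adjacency matrix (bond iff d_AB < f_c·(r_A + r_B),
  covalent radii, default f_c = 1.3) must equal the reference one, so the
  structure never drifts into another constitutional isomer;
* *similarity* — a seed is optimized only if, for every previously visited
  vector, at least one torsion differs by more than d (default 15°,
  wrap-around metric): no region is optimized twice;
* *constraints* — user-defined hard (all must hold) and soft (at least one
  must hold) distance/angle/dihedral windows;
* *redundancy* — an optimized vector within ε (default 2°) of a stored
  conformer on every torsion is a duplicate;
* *Hessian* — all vibrational frequencies real (small imaginary modes below
  5 cm⁻¹ are treated as numerical noise).

Amine umbrella inversion is detected through the sign of the improper
torsion φ₁₂ = H1-H2-Cα-N and repaired by relabelling the two amine
hydrogens.  For molecules with an accessible mirror plane (conformational
enantiomers, e.g. glycine) every visited vector is stored together with its
image Φ* (in-plane torsions φ* = −φ, out-of-plane ones φ* = −φ̄ via the
partner dihedral), which roughly halves the number of optimizations.  A
dual-level driver re-optimizes and re-validates a cheap-level ensemble with
a second, more accurate backend.

Energy backends are pluggable.  The built-in analytic toy PES
(V(φ) = Σ (V_n/2)(1 − cos n(φ − γ)) per torsion plus cosine couplings) makes
the entire loop runnable and testable on a laptop; a file-level Gaussian
adapter writes opt/freq input decks and parses log files (it never executes
the program itself).

For a located ensemble, the multi-structural harmonic-oscillator partition
function and conformer weights are

    Q_MS-HO(T) = Σ_j Q_RRHO,j(T) · exp(−U_j β),
    χ_i(T) = Q_RRHO,i e^(−U_i β) / Q_MS-HO,    Σ χ_i = 1,

with U_j the relative electronic energy and β = 1/k_BT; N90 is the number of
lowest-energy conformers whose cumulative χ reaches 90%.  Amino-acid
backbones are typed I–IV by the circular Euclidean distance of
(φ₁, φ₂, φ₃) = (H-O-C1-Cα, O-C1-Cα-N, C1-Cα-N-lp) to the reference motifs
I = (x, 180, 180), II = (0, 0, 0), III = (180, 0, 180), with a 75° cutoff
(type IV beyond it).

## Worked example

Generate a two-torsion toy system with separable 3-fold wells, search it,
and look at the results:

```
$ torscan fixtures separable-3fold --k 2 --rng-seed 0 --out fixture
separable-3fold: K=2, 9 oracle minima -> fixture

$ torscan stoc fixture/reference.zmat fixture/pes.json 50 --out out
accepted 9 conformers

$ head -4 out/conformers.tsv
conformer  origin          level  energy        phi
0000       preconditioned  toy    0.0000000000  120.0000,120.0000
0001       preconditioned  toy    0.0000000000  120.0000,240.0000
0002       preconditioned  toy    0.0000000000  120.0000,0.0000
```

All nine minima of the {0°, 120°, 240°}² grid are found by the nine
preconditioned seeds alone (each seed sits on a 3-fold maximum and relaxes
into a distinct well); the 50 stochastic seeds are either screened by the
similarity test or optimized into a well that the redundancy test
recognises as already found, so `origin` is `preconditioned` throughout.
`out/manifest.tsv` records one verdict per seed, and each accepted
conformer is written as an XYZ file.

Thermochemistry and backbone typing of a small dataset (three conformers of
the bundled glycine-like toy backbone):

```
$ torscan msho demo_dataset.txt --T 300
T = 300.00 K
Q_MS-HO = 3.963826e+05
N90 = 2
chi_max = 69.1%
id  U_kcal_mol  type  chi        cumulative_chi
c1  0           II    0.690896   0.690896
c2  0.62        IV    0.244204   0.935099
c3  1.41        I     0.0649006  1
```

The lowest conformer contributes 69.1% of the partition function at 300 K
and the two lowest together already exceed 90%, hence N90 = 2.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch: it generates a random coupled
two-torsion surface from the seed, enumerates its minima with the
brute-force grid oracle, runs the preconditioned + stochastic search,
refines the ensemble at a second level, and evaluates the MS-HO analytics
on a synthetic ensemble, printing each stage's numbers.  The JSON output it
writes is an empty object.
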