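# Amino-acid conformer dataset (not bundled)

The dataset-level checks in `tests/test_acceptance.py` expect one file per
amino acid here (`Gly.txt`, `Ala.txt`, ..., `HisD.txt`, `HisE.txt`, `Lys.txt`),
each in the block format read by `torscan.thermo.read_conformer_dataset`:

```
conformer <id>
energy   <kcal/mol relative to the most stable conformer>
inertia  <I1> <I2> <I3>        # amu * Angstrom^2
zpe      <kcal/mol>            # optional
dipole   <Debye>               # optional
origin   <preconditioned|stochastic>   # optional
freqs    <cm^-1 values, free line wrapping>
geom
<El> <x> <y> <z>               # Angstrom
...
end
```

The published 6 508-conformer dataset is distributed as supplementary
material of the original study and via its public repository; it is not
redistributable here and this environment has no network access, so the
corresponding acceptance test reports the data as missing instead of
passing vacuously.
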