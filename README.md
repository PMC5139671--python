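# ums — unfolding mutation screen

`ums` performs an exhaustive in-silico saturation mutagenesis of a protein
3D structure. For every position it places all 20 amino acids (19 missense
substitutions plus the identity) from a rotamer library, scores each variant
with a deterministic heavy-atom energy function, and converts the resulting
ΔΔG values to **unfolding propensities** on a universal 0–1 scale so that
different proteins can be compared directly. It is aimed at structural
biologists and clinical researchers who want a quick, reproducible map of
which missense mutations a fold can tolerate — e.g. for triaging variants of
unknown significance in disease genes.

## The model

For a substitution with folding free-energy change ΔΔG (kcal/mol, positive
= destabilizing), the mutant's stability under the linear extrapolation
model is

```
ΔG_mut = ΔG_wt − m·[D] − ΔΔG
```

and its equilibrium unfolded fraction — the unfolding propensity — is the
two-state Boltzmann population

```
P_u = 1 / (1 + exp(ΔG_mut / RT))
```

so `P_u = 0` means fully stable, `P_u = 0.5` the folding–unfolding
equilibrium (ΔG_mut = 0), and `P_u = 1` a completely unfolded protein.
Defaults: ΔG_wt = 5.0 kcal/mol, RT = 0.593 kcal/mol (298 K), m = 1.0
kcal/mol/M, [D] = 0; all configurable.

ΔΔG itself comes from a documented, pluggable scorer (soft steric clash +
hydrophobicity contact potential + rotamer prior + hydrophobic burial;
see `docs/methods.md`), minimized over library rotamers of the target
residue with neighbours held fixed.

Each scan also produces per-residue descriptors — average missense
propensity, **foldability** (1 − severe-mutation fraction; low values flag
folding-critical residues), Shannon entropy of the propensity distribution,
and residue depth below the solvent-accessible surface — plus a
rotamer-based **internal control** (every residue "mutated" to itself across
alternative rotamers; a well-refined model yields self-ΔΔG centered on 0).

## Worked example

No downloads needed — the package generates synthetic structures:

```
$ ums fixture --kind helix --n 20 --seed 1 --out helix20.pdb
wrote helix fixture (20 residues) to helix20.pdb

$ ums scan --pdb helix20.pdb --out results
INFO ums: scan complete: 20 sites, 400 mutation records
INFO ums: pipeline complete: 20 sites scanned, 400 mutations evaluated, control n=43, accepted=False
f36649099474  helix20_matrix.txt
772013f041d1  helix20_descriptor.txt
...
```

The scan writes five artifacts: the N×20 mutation matrix, the descriptor
table, standard and clustered heat-map HTML pages (blue 0 → white 0.5 → red
1, hover for values), and a UCSF-Chimera script + attribute file coloring
the structure by foldability.

```
$ head -4 results/helix20_matrix.txt | cut -c1-70
res     A       C       D       E       F       G       H       I       K
L1      0.000   0.000   0.001   0.002   0.001   0.000   0.002   0.000   0.002
M2      0.000   0.000   0.001   0.001   0.000   0.000   0.000   0.000   0.001
S3      0.000   0.000   0.001   0.000   0.000   0.000   0.000   0.000   0.001
```

Row `M2` reads: mutating Met2 to Ala has propensity 0.000 (tolerated),
while `M2 → P` is 1.000 (a proline here clashes irreparably — fully
destabilizing). In the descriptor file,

```
$ head -3 results/helix20_descriptor.txt
sequence        avg_propensity  foldability     entropy depth
L1      0.001   1.000   0.000   3.059
M2      0.053   0.947   0.286   3.071
```

Met2 has one severe mutation out of 19 (foldability 18/19 ≈ 0.947), low
average propensity, 0.286 bits of entropy (mostly-uniform outcomes), and
sits ~3.1 Å below the solvent-accessible surface (a surface residue).

The internal control for a model is run with:

```
$ ums control --pdb helix20.pdb
structure helix20: n=43 mean=39.2654 sd=79.3149 p=0.002299 ci95=(14.8559, 63.6749) accepted=False
```

(A tightly packed helix rejects alternative rotamers — large positive mean —
so the model is *not* accepted by the mean≈0 criterion; a dilute structure
with non-interacting side chains is accepted with mean 0.) Predictions can
be scored against an experimental ΔΔG table with
`ums validate --pred pred.tsv --exp exp.tsv` (percent matching and a
fit-score on the shared propensity scale).

## Acceptance script

`scripts/acceptance.py` recomputes the package's analytic anchors from
scratch — the propensity at the folding–unfolding equilibrium point, the
identity-substitution ΔΔG over every position of a library-conformation
helix fixture, and the supremum of the propensity over a ±100 kcal/mol ΔΔG
sweep — and writes them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
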