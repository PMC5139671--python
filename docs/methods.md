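# Methods

This note documents the models, numerical choices and limitations behind
`ums`. It is the package's own account of its science; every number quoted
here is computed by the test suite or the acceptance script, not asserted.

## 1. Structure model

PDB input goes through Biopython's parser: first MODEL only, standard
residues only (MSE mapped to Met; other non-standard residues excluded and
tallied), waters/heteroatoms dropped, hydrogens ignored (the energy terms
are heavy-atom based, and homology models usually lack hydrogens). Altloc
conflicts keep the highest-occupancy conformer, ties broken by label order.
Author numbering (chain, residue number, insertion code) is preserved in
every report; internally sites are indexed ordinally. A site is *scannable*
when all four backbone atoms (N, CA, C, O) are present; incomplete sites
are flagged and skipped, never scanned silently.

## 2. Side-chain construction and the rotamer library

Side chains are built atom-by-atom from ideal internal coordinates (bond
lengths/angles typical of high-resolution structures) via natural-extension
reference-frame placement, with torsions taken from the rotamer library.
The packaged library is coarse and backbone-independent: at most 5 rotamers
per amino acid with rounded, field-typical chi angles and frequencies;
Gly/Ala have a single empty-chi entry. Any tab-delimited file with the same
columns (aa, chi1..chi4, probability) can be substituted. Limitations:
five-membered/aromatic rings are placed from ideal internal coordinates
without refining the closing bond, and the backbone strain of X→Pro is not
modelled.

## 3. The energy function (a replacement, by design)

The original screen's free-energy machinery is not public, so ΔΔG here
comes from a deliberately simple, deterministic, term-separable scorer:

```
E(site) = w_clash · Σ_pairs max(0, 0.85·(r_i + r_j) − d_ij)²      (soft sterics)
        + w_contact · Σ_partners −(h_a + h_b)/2                    (contacts)
        + w_rot · (−ln p_rotamer)                                  (rotamer prior)
        + w_burial · ĥ(aa) · burial_fraction                       (burial)
```

* **Clash**: heavy-atom pairs between the site and *other* residues within
  6 Å; van der Waals radii by element; the peptide-bond 1-2/1-3 pairs to
  chain neighbours are excluded. Intra-residue strain is not double-counted
  (it is absorbed by the rotamer prior).
* **Contact**: residue partners whose CB atoms (CA for Gly) are within
  6.5 Å, excluding immediate chain neighbours. The pair energy is the
  additive hydrophobicity approximation of knowledge-based contact
  potentials, with h the Kyte–Doolittle index rescaled to [0, 1]: two
  hydrophobic residues in contact score −1, two polar ones 0.
* **Rotamer prior**: −ln p of the library rotamer nearest (by maximum
  circular chi deviation) to the site's current conformation.
* **Burial**: burial_fraction = min(1, n/40) with n the environment heavy
  atoms within 8 Å of the side-chain centroid; ĥ(aa) = −KD(aa)/4.5, so
  burying Ile is rewarded and burying Arg penalized.

Default weights (10, 1, 0.6, 0.5) put a hard clash (1 Å overlap) far above
any contact reward. All knobs live in `ScanConfig`; the propensity
transform downstream is agnostic to the scorer, which can be swapped.

ΔΔG(site → aa) = min over the target's library rotamers of E(variant) −
E(wild type), with all neighbours held fixed (no repacking — a documented
limitation that buys determinism and speed). For identity substitutions the
native conformation itself is among the candidates, so identity ΔΔG ≤ 0
always, and exactly 0 whenever the native conformation is per-site optimal.

## 4. Propensity transform

`P_u = 1/(1 + exp(ΔG_mut/RT))` with `ΔG_mut = ΔG_wt − m·[D] − ΔΔG`. The
two-state Boltzmann form is adopted because it reproduces the scale's three
stated anchors (0 stable, 0.5 equilibrium, 1 unfolded) and is the standard
population interpretation of the linear extrapolation model. **ΔG_wt = 5.0
kcal/mol is a calibration choice** (a typical globular-protein stability),
not a measured value: it puts the wild type near fully folded
(P_u ≈ 2.2·10⁻⁴) and the 0.5 crossing at ΔΔG = 5 kcal/mol. RT = 0.593
kcal/mol fixes T = 298 K; no heat-capacity (ΔCp) temperature dependence is
modelled. [D] defaults to 0 M; raising it shifts every propensity upward
(m ≥ 0), never downward. Overflow is guarded by clamping the exponent at
±700, so extreme ΔΔG saturates cleanly at 0/1 without NaN.

## 5. Descriptors

* **Average propensity** and **foldability** use the 19 missense entries
  only — the identity column describes no substitution. Foldability =
  1 − n_severe/19 with severity threshold 0.9 (configurable). This
  count-based formula is a *reconstruction* of a qualitatively described
  quantity: it tallies severe mutations while remaining insensitive to the
  magnitudes of sub-threshold ones.
* **Entropy** needs a discretization of continuous propensities: entries
  are rounded to bins of width 0.1 (11 bins; configurable), and H = Σ
  P(x)·log₂(1/P(x)) over the 20-entry distribution (identity included by
  default, switchable). Any bin width reproduces the canonical closed
  forms: one bin → 0 bits, a 10/10 split between 0 and 1 → 1 bit, 20
  distinct bins → log₂20 ≈ 4.32 bits; and at equal averages a 0/1-split row
  is always more entropic than a uniform-0.5 row.
* **Residue depth** replaces the MSMS binary with probe-sphere sampling:
  each atom's sphere is expanded by the probe radius (1.4 Å) and sampled at
  960 quasi-uniform directions; points inside any other expanded sphere are
  discarded; an atom's depth is its distance to the nearest surviving
  surface point and a residue's depth the mean over its heavy atoms. Note
  this convention gives an isolated exposed atom depth ≈ r_vdw + 1.4 Å, not
  0. Sampling directions are taken in a pose-canonical frame (centroid +
  sign-fixed principal axes), which makes depth rigid-motion invariant to
  machine precision rather than to sampling tolerance; the frame is
  ill-defined only for exactly symmetric point sets, which real structures
  are not. Accuracy against a brute-force all-pairs oracle is ≤ 0.25 Å at
  default sampling on the packaged fixtures.

## 6. Internal control and validation scoring

The internal control swaps each residue's side chain for every *other*
library rotamer of the same amino acid and records the interaction-energy
change (clash + contact + burial). The rotamer-prior term is deliberately
excluded: the control asks whether the model's geometry accommodates
alternative conformations (expected ΔΔG ≈ 0 for a well-refined model), and
the prior would bias every alternative of a correctly placed
high-probability rotamer positive. Statistics: mean, sample SD, two-sided
one-sample t-test against 0, and the 95% t-interval. The published
acceptance wording ("significant p, then small CI with mean near 0") is
internally inconsistent — a significant t-test against 0 is evidence the
mean is *not* 0 — so acceptance here is: |mean| ≤ 0.5 kcal/mol AND CI
half-width ≤ 1.0 kcal/mol (both configurable), with the raw p-value always
reported so users can apply the literal screen instead. Zero-variance
convention: p = 1 when mean = 0, else p = 0.

Validation against an experimental ΔΔG table converts experiments to
propensities with the same transform and reports (a) percent matching over
three classes (stabilized < 0.4, neutral, destabilized > 0.6 at the default
0.1 band) and (b) a fit-score, 1 − mean|Δpropensity| — a reconstruction,
labelled as such in the output.

## 7. Synthetic fixtures — what they do and do not establish

`make_fixture` builds helices (ideal φ/ψ = −57°/−47°), hairpins (two
extended strands and a turn) and compact balls (a serpentine lattice walk,
4.3 Å spacing, randomized backbone orientations) with sequences drawn
uniformly unless given. Side chains are placed at library rotamers and then
relaxed by greedy coordinate descent to the per-site optimal rotamer (each
accepted move strictly lowers the total energy, so the descent terminates);
consequently identity re-placement is bit-exact and identity ΔΔG is exactly
0, which is what the identity-null checks exercise. The compact ball
guarantees buried residues (depth > 3 Å for n ≥ ~30) for depth and burial
tests. These fixtures emulate packing density and library-conformation side
chains; they do **not** emulate real secondary-structure packing, hydrogen
bonding, ligands, or crystallographic noise — so a green test establishes
the machinery's contracts (counts, nulls, invariances, oracle agreement),
not predictive accuracy on real proteins.

## 8. Determinism and numerical conventions

The scan is a pure function of (structure, library, config): no randomness
anywhere in scoring, exhaustive rotamer minimization with strict-improvement
tie-breaking (ties keep the earlier candidate, so the native conformation
wins ties in identity scans). Text outputs print 3 decimals; full precision
is kept internally. Heat maps are self-contained HTML+SVG (hover tooltips
via SVG `<title>`), byte-identical across reruns; clustering uses SciPy
agglomerative linkage (Euclidean, average by default) with SciPy's
deterministic leaf ordering. Degenerate inputs: a 1-row matrix falls back
to the standard map with a warning; n < 2 control values yield undefined
statistics and a rejected model; an empty structure is a parse error.
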