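# cgmem

Coarse-grained energy functions and evaluation tools for membrane proteins,
disulfide-rich proteins and protein–DNA complexes — for people building or
studying transferable coarse-grained force fields who need the surrounding
machinery small, testable and self-contained.

The package provides, as a library and a CLI:

- **Membrane-depth-dependent contacts.** Residue pairs switch smoothly
  between water-mediated and lipid-mediated well depths with the burial of
  both partners:
  `V(i,j) = (1 − α_i α_j) V_water(i,j) + k_rel α_i α_j V_mem(i,j)`,
  `α_i = ½[tanh(η(z_i+b)) + tanh(η(b−z_i))]`, plus a hydrophobicity-weighted
  membrane burial energy `Σ_i A(σ_i) Θ(z_i, z_m)`.
- **A saturable many-body disulfide bond.** The pair attraction
  `α(r) = ½(tanh(κ(r−r_c)) − 1)` between cysteine CBs is gated by two
  switches on the smoothed cysteine coordination density, so each cysteine
  forms at most one bond; analytic forces included.
- **Z-score decoy optimization.** Rigid-body decoys (12 rotations × 20
  z-shifts = 240 per protein), burial-similarity decoy weights (1 − θ_d),
  and an optimizer for the energy coefficients maximizing
  `|Z| = |E_native − ⟨E⟩_mg| / σ(E_mg)` in the funneled direction.
- **Protein–DNA interface scoring.** Debye–Hückel electrostatics between
  charged residues and phosphates plus soft excluded volume, and the
  symmetrized native-contact metric (CB within 18 Å of any phosphate in
  both reference and model).
- **Q-value metrics** (global / water / membrane region modes), χ burial
  fractions, disulfide detection, and a BAOAB Langevin simulated-annealing
  engine (800 K → 200 K default schedule).

Synthetic fixture generators (ideal helices, cysteine toys, idealized
B-DNA) make the whole package testable without downloading any structure.

## Worked example

Score a disulfide toy and anneal it shut:

```sh
cgmem fixtures cys-toy --pair-distance 3.8 --out toy.pdb
cgmem energy --terms disulfide --disulfide-k 1.0 --per-pair toy.pdb
```

prints

```
disulfide	-0.999003
total	-0.999003
i	j	r_ij	V_ij
0	1	3.800	-0.999003
```

i.e. at the crystallographic CB–CB distance of 3.8 Å the bond sits at
essentially its full depth (−k·1): the distance well `α(3.8) ≈ −0.9997` and
both saturation switches ≈ 0.9997 each. Placing a third cysteine 3.8 Å from
one partner of the bonded pair collapses its pair term to ~10⁻²⁸·k — the
intruder feels no attraction, which is the many-body saturation at work.

The same from Python, plus a Z-score round trip:

```python
import numpy as np
from cgmem import (make_helix_fixture, generate_decoys, ContactParams,
                   MembraneSlab, HydrophobicityScale, phi_features,
                   optimize_coefficients)

# hydrophobic helix straddling the slab: its native placement is funneled
native = make_helix_fixture(20, z_offset=5.0, sequence="L" * 20)
decoys = generate_decoys(native)                # 240 rotations x shifts
params = ContactParams.uniform(1.0)
slab, scale = MembraneSlab(), HydrophobicityScale.wimley_white_octanol()
nat = phi_features(native, params, slab, scale)
result = optimize_coefficients([(nat, decoys)], params=params, slab=slab,
                               scale=scale)
print(result.coefficients, round(result.z, 2))
```

prints `(1.0, 0.0, 5.5) -2.33`: with uniform contact matrices the membrane
contact feature carries no discrimination (the optimizer sends k_mem to 0),
while weighting the burial of the poly-Leu helix (k_memburial = 5.5) puts
the native placement 2.33 decoy standard deviations below the misplaced
ensemble — a funneled, negative Z.

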