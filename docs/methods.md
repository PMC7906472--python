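# Methods

`cgmem` implements a family of coarse-grained energy functions and
evaluation tools for membrane proteins, disulfide-rich proteins and
protein–DNA complexes, together with the machinery used to train and test
such energy functions: rigid-body decoy generation, burial-weighted Z-score
optimization, structural similarity metrics, and a small Langevin annealing
engine. Everything runs on synthetic fixtures; no external data is needed.

## Coarse-grained representation

Proteins are reduced to three sites per residue — CA, the side-chain site CB
(CA stands in for glycine, following the usual one-bead-side-chain
convention), and the carbonyl O. DNA is reduced to phosphate (P), sugar (S =
C4′) and base (B = N1/N9) sites; of these only P enters any energy term
here, so the S/B proxy choice is cosmetic. Lengths are in Å, energies in
kcal/mol-equivalent reduced units, temperatures in K. PDB input goes through
Biopython (first model, altloc ''/'A', HETATM/waters/hydrogens ignored).
Sequence separation |i−j| is the per-chain author-numbering difference;
interchain pairs are treated as unboundedly separated.

## Membrane-depth-dependent contact potential

The implicit membrane is the slab |z| < z_m (z_m = 15 Å) centered at z = 0.
Each residue carries a smooth membrane-interior indicator of its CA height,

    α_i = ½[tanh(η(z_i + b)) + tanh(η(b − z_i))],   b = 15 Å, η = 1 Å⁻¹,

and each eligible pair (separation > 9, or interchain) contributes

    V(i,j) = (1 − α_i α_j) V_water(i,j) + k_rel · α_i α_j V_membrane(i,j).

A pair is membrane-mediated only when *both* partners are buried; a split
pair interacts as if in water. Each environment's V(i,j) is a standard
two-well contact: a direct well on the CB–CB distance (4.5–6.5 Å) and a
mediated well (6.5–9.5 Å) whose depth interpolates between a water-mediated
and a protein-mediated matrix through the local-density switch
σ_i = ½(1 + tanh(η_σ(ρ_0 − ρ_i))), with ρ_i the direct-well-window count of
neighbors at separation ≥ 2. Switch steepness values (η_c = 5 Å⁻¹, η_σ = 7,
ρ_0 = 2.6) are the conventional ones for this family of potentials and are
configurable. With identical water/membrane matrices and k_rel = 1 the depth
weighting cancels algebraically, which the suite uses as an exact oracle.

The six 20×20 well-depth matrices are shipped as whitespace-delimited text
(alphabetical one-letter residue order). The package deliberately does not
bundle any published trained matrices; tests use synthetic (uniform,
direct-only and random-symmetric) matrices so correctness is independent of
any particular parameterization.

The burial energy is Σ_i A(σ_i) Θ(z_i, z_m) with Θ the smooth slab
indicator ½tanh[k_m(z+z_m)] + ½tanh[k_m(z_m−z)] and A the Wimley–White
octanol transfer scale (packaged TSV; neutral-His value 0.11 kcal/mol).
No value of k_m is established for this term; the default is 1 Å⁻¹ and it is
configurable.

## Saturable disulfide term

Cysteine side chains attract through α(r) = ½(tanh(κ(r − r_c)) − 1) with
κ = 10 Å⁻¹ and r_c = 4.2 Å, bracketing the 3.6–4.1 Å CB–CB range observed
for disulfides in crystal structures. Saturation — each cysteine bonds at
most once — is enforced by two switches on the smoothed cysteine
coordination density ρ_i = Σ_{|j−i|>1} ½(1 − tanh(κ(r_ij − r_c))):
θ_near turns off pairs whose densities differ by more than ≈0.4 and θ_small
turns off pairs whose densities sum past ≈2.4 (both with steepness
κ_s = 20). The thresholds printed inside the switches are 0.2 and 2.2; the
soft tanh makes the effective cutoffs roughly twice that. The pair sum runs
over unordered cysteine pairs with separation > 1 (interchain always
eligible), scaled by one overall strength k. A pairwise, always-on mode
(`saturable=False`) is provided for comparisons.

Forces are analytic, including the chain-rule terms through ρ in both
switches. At ρ_i = ρ_j the |ρ_i − ρ_j| factor has a kink; the subgradient
with sign(0) = 0 is used, which is exact on symmetric configurations.
Gradient tests compare against central finite differences (h = 10⁻⁵ Å) with
a 10⁻⁶ kcal/mol/Å force floor in the relative-error denominator, since on
fully saturated (flat) configurations both force fields vanish and the
quotient would measure roundoff only.

## Protein–DNA interface

The cross-interaction is deliberately sequence-nonspecific: screened
Coulomb energy C q_i q_j exp(−r/λ_D)/(ε_r r) between charged residue CBs
(Arg/Lys +1, Asp/Glu −1) and phosphates at −0.6 e (counterion-condensation
convention), λ_D = 10 Å (≈100 mM salt), ε_r = 78; plus a harmonic soft-core
repulsion ε(σ − r)² for r < σ = 4 Å between protein CBs and all DNA sites.
These functional forms and constants are conventions of the coarse-grained
DNA lineage this follows, not fitted values, and all are configurable.

Interface quality is measured with symmetrized native contacts: the native
set contains protein residues whose CB lies within 18 Å of any DNA
phosphate in the reference structure, and a member is preserved if it still
does in the model. The fraction preserved is flagged undefined when the
native set is empty. `scripts/with_data_checks.py` reproduces the literature
count of 135 contact residues for the Ndt80/DNA complex (PDB 1mnn) when
given a downloaded copy; the repository itself ships no crystal structures.

## Q metrics, χ and burial similarity

Q compares CA–CA internal distances over pairs with sequence separation ≥ 3:

    Q = 2/((N−2)(N−3)) Σ_{j≥i+3} exp(−(r_ij − r_ij^N)² / (2σ_ij²)),
    σ_ij = (1 + |i−j|)^0.15 Å.

`water` mode restricts to residues outside the slab and `membrane` mode to
residues inside, with σ_ij doubled in membrane mode. Region membership is
decided from the native structure's CA heights (the native defines the
reference burial pattern). χ is the fraction of residues strictly inside
|z| < z_m; θ_d is the fraction of residues whose inside/outside assignment
matches between two structures. Disulfide detection is greedy closest-first
matching of cysteine CB pairs within 4.2 Å (configurable; annealed rather
than crystallographic models may warrant a looser 4.5 Å).

## Decoy generation and Z-score optimization

Decoys misplace a membrane protein rigidly: rotation about the x axis
through the CA centroid (12 angles, 0°–165° in 15° steps) followed by a
vertical shift (20 values, −40 to +36 Å in 4 Å steps), 240 decoys per
protein. Each structure is summarized by (φ_wat, φ_mem, φ_memburial), the
water-weighted and membrane-weighted contact sums and the burial energy, and
scored with E = k·φ. The funneling measure is

    Z = (E_native − ⟨E⟩_mg) / σ(E_mg),

with decoy mean and population standard deviation weighted by 1 − θ_d, so
decoys that already sit in the native burial pattern (θ_d = 1) contribute
nothing. Training candidates are filtered to 0.2 ≤ χ ≤ 0.8 and L ≤ 2000.

Because Z is invariant to a positive rescaling of the coefficients, the
gauge is fixed at k_wat = 1 and the optimizer searches (k_mem, k_memburial)
maximizing the mean of −Z over training entries subject to the funneled
direction E_native ≤ ⟨E⟩_mg (this gauge-fixing is how "holding the decoy
energy scale constant" is realized here). A coarse grid scan (step 0.5 over
[0, 10]²) seeds a bounded L-BFGS-B polish; the result is flagged degenerate
when no coefficient direction separates natives from decoys (|Z| ≈ 0
everywhere, e.g. native at the decoy mean). Per-protein Z scores are
averaged rather than pooled into one ensemble; pooling is the main
alternative and would weight proteins by decoy count instead of equally.
Tests verify agreement with an exhaustive 0.1-step grid search and exact
recovery of planted coefficient directions (native = decoy mean − C·k with
C the empirical decoy covariance, the closed-form optimum of the ratio).

## Dynamics and annealing

The total energy is a configurable sum of the terms above plus
`backbone_springs`, an explicit surrogate for a full backbone Hamiltonian:
harmonic CA–CA virtual bonds (rest 3.8 Å) along each chain, extended with
intra-residue CA–CB (1.53 Å) and CA–O (2.0 Å) tethers so side-chain and
carbonyl sites stay attached to their residue during toy dynamics. Forces
are analytic for the disulfide and spring terms and central finite
differences for the rest; FD forces are only intended for small toys.

Annealing uses a BAOAB-splitting Langevin integrator, friction 1 ps⁻¹,
nominal 5 fs steps, uniform unit site masses (coarse-grained kinetics are
not interpreted quantitatively), with temperature interpolated linearly in
step number from 800 K to 200 K and Maxwell–Boltzmann initial velocities at
the start temperature from the run seed. Runs are deterministic in the
seed. With friction 0 the O-step disappears and the scheme reduces to
velocity Verlet; the suite checks that PE + KE then drifts by < 1 % of a
5 kcal/mol well over 10⁴ steps at dt = 0.5 fs. The full-scale protocol
(8×10⁶ steps) is a documented preset; the package default is a desk-scale
10⁵ steps, and the test suite uses a few thousand steps on toys of ~15
sites, where a bonded cysteine pair forms from 5.5 Å apart in the majority
of seeds.

## What the synthetic fixtures do and do not show

Fixtures are ideal α-helices (1.5 Å rise, 100°/residue), toy chains whose
cysteine CB sites are placed exactly, and an idealized straight B-DNA
duplex (3.38 Å rise, 36° twist, phosphates at 8.9 Å radius, 5′ termini
without P). They exercise every code path — geometry, eligibility rules,
switching functions, optimization — with exactly known answers. They do not
probe the physical realism of trained well-depth matrices (none are
bundled), real side-chain packing, DNA groove geometry, or prediction
quality on real proteins; passing tests certify the mathematics and the
implementation, not force-field accuracy.

## Numerical notes and limitations

- All switching functions are built from `tanh`; overflow-safe forms
  (1 − tanh²) are used where sech² is needed.
- The contact energy is O(L²) in memory and time per evaluation; fine for
  L ≤ a few thousand, not tuned beyond that.
- FD forces make the non-analytic terms O(L²·n_sites) per step; annealing
  with contact terms enabled is only sensible on small systems.
- The Q normalization 2/((N−2)(N−3)) counts contiguous-chain pairs; for
  region-filtered selections the pair count can differ from the
  normalization, as in the metric's standard definition.
- Greedy disulfide matching is not maximum-weight matching; for the
  near-crystallographic geometries it is meant for, the two agree.
- Zero-variance decoy energies, empty native contact sets, and all-native
  decoy sets raise or flag explicitly rather than returning NaN.
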