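# Methods

## Model

The minimal Distance Constraint Model treats a protein (or any body-bar
framework) as a Gibbs ensemble of constraint topologies.  Atoms are rigid
bodies with 6 degrees of freedom.  Constraints are bars between bodies:

* **Covalent bonds** are quenched — present in every framework, so they
  carry no thermodynamic parameters.  A generic single bond contributes 5
  bars (fixing bond length and the adjacent angles, leaving the dihedral
  rotation); bonds whose rotation is chemically forbidden — the peptide
  bond, ring bonds, and bonds to terminal atoms — carry a 6th bar.  The
  surviving 5-bar bonds are the *a-priori rotatable bonds* on which the
  flexibility index is reported (φ and ψ for the backbone; proline has no
  φ because its ring locks N–CA).
* **Hydrogen bonds** fluctuate.  Candidates are detected from local
  geometry (donor–acceptor distance ≤ 3.5 Å, D–H···A angle ≥ 100°) and
  scored with a Mayo-type empirical potential,
  E = D₀[5(R₀/R)¹² − 6(R₀/R)¹⁰]·cos²θ_DHA·cos²θ_HAA with D₀ = 8 kcal/mol
  and R₀ = 2.8 Å; candidates weaker than −0.1 kcal/mol are discarded and
  salt bridges get a fixed −10 kcal/mol.  These constants, and the linear
  entropy map γ_hb(u) = max(0, 0.4·u + 3.2), are *reconstructions*: the
  model definition fixes them "in prior work" without printing values, so
  they are exposed in `NetworkConfig`/`DCMParameters` and every
  quantitative test runs on synthetic fixtures rather than real proteins.
  An engaged H-bond places 5 bars from the donor hydrogen to the acceptor
  plus 1 bar to the acceptor antecedent.
* **Torsions** fluctuate between a *native* state (enthalpy v_nat, entropy
  weight δ_nat, one bar locking the dihedral) and a *disordered* state
  (v_dis, δ_dis, no mechanical bar).  Defaults: v_dis = 0 (reference),
  δ_dis = 1.85, δ_nat = 1.24; v_dis/δ_dis are likewise reconstructed
  constants chosen to give protein-like melting on the synthetic fixtures.

### Rigidity analysis

The (6,6) body-bar pebble game assigns 6 pebbles per body and inserts bars
in ascending order of entropy weight (quenched bars first, ties broken by
constraint id) — the order that yields the lowest upper bound on the total
conformational entropy.  A bar is independent when 7 pebbles can be
gathered across its endpoints; otherwise redundant.  Rigid clusters are
maximal sets of mutually rigid bodies (pairwise pebble test, union-find);
a rigid cluster is over-constrained when redundant bars fall inside it.
Rotatable bonds with both endpoints in one rigid cluster are locked;
surviving hinges are grouped into flexible clusters by contracting rigid
clusters and taking bridges (isolated rotors, H = A = 1) and biconnected
components (collective motions, A = internal DOF of the induced
sub-framework) of the contracted multigraph.  Every a-priori rotatable
bond lands in exactly one cluster.

Disordered torsions carry no bar, so the *mechanical* decomposition uses
covalent + engaged H-bond + native-torsion bars only.  For the entropy
bookkeeping, one bar per disordered torsion is inserted *after* the
decomposition: in a flexible region with a internal DOF, exactly a of its
disordered bars are independent, which defines q_dis (and reproduces A).
B counts redundant mechanical bars only.  For a multi-bar constraint, q is
the fraction of its bars that are independent.

Per framework, bond i gets f_i = +A/H (flexible), −min(1, B/D)
(over-constrained; the saturation keeps FI a signed density on [−1, 1] —
on heavily braced toy regions B can exceed D), or 0 (isostatic).  The pair
value f_mn equals the shared cluster's f when bonds m, n co-occur in one
cluster and 0 otherwise, including two *different* rigid clusters.

### Ensemble

The landscape is a grid over (N_nat, N_hb).  Within a macrostate,
H-bond patterns follow a conditional-Bernoulli law with per-bond enthalpy
Gibbs factors g_i = exp(−(u_i − u_sol)/RT) — equivalently, pattern weights
∝ exp(−βΣu) — and native-torsion placements are uniform.  Because the
selection weights do not depend on the independence probabilities, the
mean-field self-consistency condition is satisfied after a single update;
no iteration is needed.  Macrostates with at most `exhaustive_cutoff`
(default 4096) patterns are enumerated exactly (flagged in metadata);
larger ones are sampled with exact sequential conditional-Bernoulli draws
(elementary-symmetric-polynomial recursion), which makes the Monte-Carlo
path an unbiased estimator of the enumeration path.  Framework-level
pebble results are cached by engagement pattern, so temperature and
parameter sweeps are pure array arithmetic.

Free energy per macrostate:
G = U − T(S_mix + S_conf) with
U = ⟨Σ engaged u_hb⟩ + (N_hb_max − N_hb)u_sol + N_nat v_nat + (N_tor − N_nat)v_dis,
S_mix = R[ln C(N_tor, N_nat) + ln C(N_hb_max, N_hb)] (log-gamma, exact),
S_conf = R[Σ_i π_i q_i γ_i + q_nat N_nat δ_nat + q_dis(N_tor − N_nat)δ_dis].
With all q = 1 the sum reverts to the plain additive free-energy
decomposition; at T = 0, G is the enthalpy bracket.  Units: kcal/mol;
entropies kcal/(mol·K); R = 1.987e−3 kcal/(mol·K); the pure-number weights
γ and δ are multiplied by R.

Cp(T) = d⟨U⟩/dT by centered finite differences of the landscape-averaged
enthalpy (stabler under sampling noise than −T∂²G/∂T²; the two agree in
exact arithmetic); Tm is the Cp argmax refined by quadratic interpolation,
with a hard error when the maximum sits on a grid endpoint.  For sampled
macrostates a Cp scan draws patterns once at the median grid temperature
and reweights to the other temperatures by self-normalized importance
weights; effective sample size degrades for very wide windows, which is
why test fixtures keep the window within a factor of ~6 in temperature.

Basins are found by flooding the free-energy grid in ascending order: the
native basin is the lake draining the fully-engaged corner, the unfolded
basin drains (0,0), and the saddle is the level where the two lakes merge.
Native-basin weights ρ ∝ exp(−G/RTm) are normalized over the cells below
the saddle (cells with ρ < 1e−9 dropped).  FI and CC are ρ-weighted
averages of the per-macrostate means; per-residue FI is the mean of the
residue's φ and ψ bond values (configurable to min/max — the reduction is
not dictated by the model) and residue-level CC is the mean over the
backbone-bond pairs of the two residues.

### Parameter fitting

`fit_cp` minimizes the mean squared difference between model and data Cp
after removing the best constant baseline offset (a DSC-style nuisance;
Cp is a derivative, so a constant is the natural form).  The optimizer is
simulated annealing with Gaussian proposals reflected at the bounds,
Metropolis acceptance and geometric cooling (default 200 steps × 20
proposals, cooling 0.95, T₀ ≈ 10× the initial residual), preceded by short
exploratory restarts and followed by a cold greedy polish (the same
Metropolis machinery at near-zero temperature with narrow proposals).
`two_param` mode fixes δ_nat (default 1.24, the value shared across the
lysozyme dataset); `three_param` also fits δ_nat, bounded below δ_dis.
Default bounds: u_sol ∈ [−4, −0.5], v_nat ∈ [−1.2, −0.02],
δ_nat ∈ [0.6, 2.2].

### Response statistics

A wild-type set defines a positionwise baseline with the *population*
standard deviation (the divisor is not dictated by the procedure;
`ddof` is switchable).  z-scores against the baseline feed (i) the
normalized delta, 0 for |z| ≤ 1, sign(z)·min(|z| − 1, 1) otherwise — odd,
monotone, saturating; (ii) five bins with boundary values assigned to the
outer bin (|z| = 1 → moderate, |z| = 2 → large); (iii) a Pearson
chi-square against the standard-normal band probabilities
(2.3/13.6/68.3/13.6/2.3 %, 4 degrees of freedom).  σ = 0 positions map to
delta 0 when the value equals the mean and to saturated sign otherwise.
Stratification uses Cα–Cα distance strata [0,8), [8,16), [16,∞) Å and
excludes the mutated residue itself (an exclusion window is available but
defaults to the single site).  B-factors are normalized as
(B − median)/(1.4826·MAD) — robust, affine-invariant; zero spread centers
only and warns.

## Synthetic study systems

The generators define the study conditions:

* **Toy frameworks** (`make_toy_framework`): rotor chains, rings,
  locked triangles, over-braced pairs with closed-form ground truth, and
  random frameworks certified by the generic rigidity-matrix rank oracle
  (random generic coordinates with a minimum-separation rejection step).
  A 6-ring of 5-bar joints is isostatic under the generic (6,6) count;
  rings of n ≥ 7 provide the collective flexible case (A = n − 6).
* **Ensemble toy** (`make_ensemble_toy`): a rotor chain cross-linked by
  H-bonds with heterogeneous energies.  The two-basin fixture (5 rotors,
  3 H-bonds with u ∈ [−4.5, −3.5], u_sol = −2, v_nat = −0.3) melts near
  590 K with a genuine saddle; most other tiny parameter draws are
  single-basin because the mixing entropy smooths so coarse a grid — a
  deliberate property of desk-scale systems, not of the model.  Under
  Monte-Carlo sampling the shallow saddle is resolved in roughly 60% of
  replicates at 300 samples per macrostate; basin-dependent checks
  therefore condition on detection and report the detection rate.
* **Polymer pseudo-proteins** (`make_polymer_protein`): poly-glycine
  backbones built from ideal internal coordinates.  `helix_like`
  (φ = −57°, ψ = −47°) yields exactly n − 4 detectable i→i−4 H-bonds;
  `sheet_like` is an extended strand (no internal H-bonds, strand
  annotations); `random` draws torsions uniformly.  These emulate the
  input class — protonated all-atom structures with detectable H-bond
  networks — but not real side-chain packing, solvent structure or
  crystallographic noise, so passing tests demonstrate correctness of the
  machinery, not predictive accuracy on real proteins.
* **Synthetic calorimetry** (`make_synthetic_cp`): exact-ensemble Cp plus
  Gaussian noise scaled to the peak height.  The recovery study uses 2%
  noise, a 150–900 K window with 61 points (wide enough to contain both
  the torsion melting feature and the H-bond peak, which is what makes all
  three parameters identifiable), and 10 noise replicates; recovery errors
  are summarized as mean absolute relative error across replicates, since
  single-draw maximum-likelihood estimates sit at the identifiability
  boundary (~±10% for v_nat in three-parameter mode at this noise).
* **Null profiles** (`make_null_profiles`): positionwise Gaussian draws
  for calibrating the bin statistics.

## Numerical choices and degenerate inputs

* Rank oracle tolerance 1e−8 (relative, SVD); generic attachment points
  per bar avoid degenerate alignments.
* Pebble-game determinism: insertion order (quenched, entropy weight,
  kind, id); which bars are labelled redundant is order-dependent but the
  totals and the cluster partition are matroid properties and
  order-invariant (tested under id permutations).
* A disconnected body with no constraints is a free trivial body, not an
  error; every connected component retains 6 trivial DOF.
* `heat_capacity` requires ≥ 5 temperatures and an interior Cp maximum.
* Landscape grids can be strided (`grid_stride`) with the corner points
  always retained; the two-basin fixture keeps its basin minimum between
  stride 2 and stride 1.
* Seeds: every stochastic component takes an explicit seed and spawns
  per-macrostate streams from (seed, N_nat, N_hb, T), so identical inputs
  give bitwise-identical outputs.

## Known limitations

* The Mayo-potential constants, γ_hb map and (v_dis, δ_dis) are
  reconstructions; absolute thermodynamic numbers on real proteins would
  inherit that uncertainty even though the mechanical observables are
  robust to parameter variation.
* Desk-scale systems melt at temperatures well above real proteins (small
  systems need disproportionately strong interactions to fold at all);
  the fixtures are chosen for a clear two-state signature, not for
  matching lysozyme's Tm.
* Hydrophobic tethers are not modelled (the *minimal* DCM fluctuates
  H-bonds and torsions only); mmCIF, multi-model ensembles beyond the
  first MODEL, and insertion codes are out of scope.
* B-factor comparisons mix mobility with crystallographic disorder; the
  median normalization mitigates but does not remove this.
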