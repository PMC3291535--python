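# mdcm — a minimal Distance Constraint Model for protein rigidity

`mdcm` implements a statistical-mechanical treatment of protein network
rigidity: the **minimal Distance Constraint Model** (mDCM).  A protein is
modelled as a body-bar framework — atoms are rigid bodies with 6 degrees of
freedom, covalent bonds are quenched bars, and two kinds of interactions
fluctuate: hydrogen bonds (geometry-dependent enthalpy u_hb, entropy
γ_hb linear in u_hb) and backbone/side-chain torsion forces that are either
*native* (v_nat, δ_nat) or *disordered* (v_dis, δ_dis, with
v_nat < v_dis and δ_nat < δ_dis).  Who it is for: structural
bioinformaticians and biophysicists who want residue-level flexibility and
mechanical-coupling maps, and their change upon mutation, without running
molecular dynamics.

The ensemble is organised on a 2-D grid of order parameters
(N_nat, N_hb) — the number of engaged native torsions and hydrogen bonds.
Each macrostate carries the free energy

```
G(N_nat, N_hb) = ⟨Σ u_hb⟩ + (N_hb_max − N_hb)·u_sol + N_nat·v_nat + (N_tor − N_nat)·v_dis
                 − T·(S_mix + S_conf)

S_mix  = R [ ln C(N_tor, N_nat) + ln C(N_hb_max, N_hb) ]
S_conf = R [ Σ_i π_i q_i γ_i + q_nat N_nat δ_nat + q_dis (N_tor − N_nat) δ_dis ]
```

where the q's are conditional probabilities for a constraint to be
**independent**, measured by running the (6,6) body-bar **pebble game** on
Monte-Carlo-sampled frameworks of each macrostate (small systems are
enumerated exactly).  Entropy components are additive only over independent
constraints; attenuating them by q is what restores the usefulness of a free
energy decomposition.  The model heat capacity Cp(T) = d⟨U⟩/dT yields the
melting temperature Tm (Cp argmax), where the landscape shows a native and
an unfolded basin separated by a saddle.

Two mechanical observables are Gibbs-averaged over the native basin at Tm:

* **Flexibility index (FI)** per a-priori rotatable bond: +A/H in flexible
  regions (independent DOF per rotatable bond), −B/D in over-constrained
  regions (redundant-constraint density, saturated at −1), 0 when
  isostatic.  Positive = flexible, negative = rigid, 0 = marginally rigid.
* **Cooperativity correlation (CC)**: a symmetric bond-pair (and
  residue-pair) matrix; an entry carries the shared cluster's f when two
  bonds co-occur in one cluster and 0 when they fall in distinct clusters —
  red/positive marks correlated motions, blue/negative co-rigidity.

Model parameters {u_sol, v_nat, δ_nat} are fitted to an experimental
heat-capacity curve by simulated annealing (`two_param` mode holds
δ_nat = 1.24 fixed).  A `compare` layer turns sets of wild-type profiles
into a positionwise baseline (mean ± σ), z-scores mutant profiles against
it, classifies five response bins (no change within ±1σ, moderate 1–2σ,
large > 2σ), tests histograms against the Gaussian null
(2.3/13.6/68.2/13.6/2.3 %), stratifies responses by distance to the
mutation site and solvent-accessibility tertile, and median-normalizes
B-factors for the flexibility-versus-mobility contrast.

## Worked example

Build a small helical pseudo-protein, generate synthetic calorimetry from
known parameters, fit the model back and read off the QSFR observables:

```python
import numpy as np
from mdcm import DistanceConstraintModel, DCMParameters, AnnealingSchedule
from mdcm.synthetic import make_polymer_protein, make_synthetic_cp
from mdcm.network import build_network

atoms, annotations, n_designed = make_polymer_protein(6, "helix_like", seed=0)
params = DCMParameters(u_sol=-2.0, v_nat=-0.3)
net = build_network(atoms, params)          # 30 bodies, 12 torsions, 2 H-bonds

T, cp = make_synthetic_cp(net, params, np.linspace(150, 900, 31),
                          noise_sd=0.02, seed=1)
model = DistanceConstraintModel(net, cp_data=(T, cp), params=params)
results = model.fit(mode="two_param", seed=0,
                    schedule=AnnealingSchedule(n_steps=80, proposals_per_step=8))
print(results.summary())
```

prints

```
Minimal Distance Constraint Model results
=========================================================
bodies                              30
a-priori rotatable bonds            12
candidate H-bonds                    2
fit mode                     two_param
fit objective (MSE)          1.378e-07
fit evaluations                   1165
---------------------------------------------------------
u_sol              -2.0113              kcal/mol
v_nat              -0.3036              kcal/mol
delta_nat           1.2400
---------------------------------------------------------
Tm (Cp argmax)                   392.0 K
max Cp                          0.0209 kcal/(mol K)
native basin size                    7
basin minimum (Nnat, Nhb)       (9, 2)
mean bond FI                   -0.6442
FI range                    [-0.874, -0.111]
```

The fit recovers the generating parameters (u_sol −2.01 vs −2.0 true,
v_nat −0.304 vs −0.3) from the noisy curve.  `results.fi_residue` shows the
helix interior rigidified by its hydrogen bonds while the termini stay
closer to marginal rigidity:

```
residue 1: -0.204   residue 2: -0.855   residue 3: -0.874
residue 4: -0.874   residue 5: -0.855   residue 6: -0.204
```

`results.plot_cp()` / `results.plot_fi()` draw the fitted heat-capacity
curve and the FI profile; `results.qsfr.cc_residue` holds the
residue-by-residue cooperativity matrix.

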