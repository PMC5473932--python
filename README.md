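# mdrin

Analysis toolkit for comparing two labeled conformational ensembles of a
multi-domain protein — typically the oxidized ("ox") and reduced ("red")
MD trajectories of a redox enzyme such as human protein disulfide
isomerase (hPDI), whose four thioredoxin-like domains a–b–b′–a′ open and
close around the redox state of the a′ catalytic disulfide.

Given trajectories (multi-model PDB, or DCD/XTC plus topology), a domain
partition (residue ranges for a, b, b′, a′ and the linkers) and a state
label per trajectory, the package computes:

- **Domain geometry** per frame: the six inter-domain center distances
  R_ij (i, j ∈ {a, b, b′, a′}), the angles Θ_abb′ and Θ_bb′a′, the torsion
  Φ_abb′a′, and residue-pair Cα–Cα distances d_ij.
- **Collective motions**: Kabsch superposition on a base selection
  (e.g. the bb′ domain pair), backbone RMSD, the dynamic cross-correlation
  matrix C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), PCA of Cα Cartesian
  coordinates, eigenvector-overlap convergence checks, and free-energy
  landscapes F = −ln(p/p_max) (k_BT units) on pairs of principal
  components via Gaussian-kernel density estimation.
- **State discrimination**: the optimal single threshold V_sep on any one
  feature (exhaustive scan, both directions), an RBF-kernel SVM
  comparison, and the residue-pair discrimination-accuracy matrix over
  d_ij.
- **Dynamic residue interaction networks (DRIN)** — the core method.
  Every frame becomes a residue interaction network with five typed
  non-covalent edges (hydrogen bond, van der Waals, salt bridge, π-π,
  cation-π) from documented geometric criteria. Each pair's binary time
  series A_ij(t) is condensed into the maximum interaction lifetime

      Γ_ij = max { τ : some window of τ consecutive frames has A_ij ≡ 1 },

  one DRIN per state and interaction type. The differential network

      Δ_ij = log2((Γ_ij^ox + ε) / (Γ_ij^red + ε)),   ε > 0,

  highlights state-dominated interactions; thresholding |Δ| and merging
  the per-type graphs (keeping parallel typed edges) yields a network
  exportable as GraphML or SIF + attribute tables for standard viewers.

A synthetic-data module generates hinge trajectories, labeled feature
samples and scripted interaction schedules with known ground truth, so the
whole stack is testable without any simulation data.

## Worked example

Classify states from a single inter-domain distance and build a
differential network from two 100-frame ensembles with scripted
interactions:

```python
import numpy as np
from mdrin.synthetic import (SyntheticSpec, FeatureSpec, InteractionSchedule,
                             make_feature_samples,
                             make_scripted_interaction_trajectory)
from mdrin.classify import split_train_test, fit_linear_threshold, evaluate_svm_rbf
from mdrin.rin import build_adjacency_series
from mdrin.drin import compile_drin, differential_drin, threshold_merge

# R_b'a' ~ N(32, 2.5) in ox, N(26, 2.5) in red, 5000 snapshots per state
spec = SyntheticSpec(feature_specs=[FeatureSpec(
    "R_b'a'", {"ox": [(1.0, 32.0, 2.5)], "red": [(1.0, 26.0, 2.5)]})], seed=17)
table = make_feature_samples(spec, n_per_state=5000)
split = split_train_test(len(table), seed=17)
disc = fit_linear_threshold(table["R_b'a'"], table["state"], split=split)
svm = evaluate_svm_rbf(table["R_b'a'"], table["state"], split=split)
print(f"V_sep = {disc.threshold:.2f} A, linear {disc.test_accuracy:.1%}, SVM {svm:.1%}")

runs = {"ox": [40, 3], "red": [5, 60]}   # scripted longest runs per state
graphs = {}
for state, seed in (("ox", 1), ("red", 2)):
    sched = [InteractionSchedule((1, 4), "salt_bridge", runs[state][0]),
             InteractionSchedule((11, 14), "hbond", runs[state][1])]
    scripted = make_scripted_interaction_trajectory(100, sched, seed=seed)
    graphs[state] = compile_drin(build_adjacency_series(scripted.trajectory), state)
diffs = [differential_drin(graphs["ox"][k], graphs["red"][k], eps=1.0)
         for k in ("salt_bridge", "hbond")]
for d in diffs:
    for pair, e in sorted(d.edges.items()):
        print(f"{d.kind} {pair}: Gamma_ox={e.gamma_ox} Gamma_red={e.gamma_red} "
              f"Delta={e.delta:+.3f}")
print("edges surviving |Delta| >= 1:", threshold_merge(diffs, 1.0).number_of_edges())
```

Output:

```
V_sep = 29.01 A, linear 88.1%, SVM 88.1%
salt_bridge (1, 4): Gamma_ox=40 Gamma_red=5 Delta=+2.773
hbond (11, 14): Gamma_ox=3 Gamma_red=60 Delta=-3.931
edges surviving |Delta| >= 1: 2
```

V_sep is the distance threshold that best separates the two states (the
unimodal feature gives identical linear and SVM accuracies). The salt
bridge persists 40 consecutive frames in ox but only 5 in red
(Δ = log2(41/6) ≈ +2.77, ox-dominated); the hydrogen bond is
red-dominated; both survive the two-fold-change cutoff |Δ| ≥ 1.

The same steps are available from a shell via the `mdrin` command
(`mdrin features`, `mdrin pca`, `mdrin fel`, `mdrin classify`,
`mdrin drin`, `mdrin drin-diff`, `mdrin synth`); see `mdrin --help`.

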