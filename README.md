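# fibrilkit

Trajectory analysis of cross-β amyloid fibril assemblies.

Amyloid-β peptides stack into fibrils in which every chain repeats at
the ~0.48 nm cross-β rise along a common fibril axis.  Aβ17–42 chains
can fold either as a **U** (two β-strands joined by one turn) or as an
**S** (three β-strands joined by two turns), and the two architectures
differ markedly in how well the stack holds together under thermal
motion.  `fibrilkit` implements the analysis layer used to make that
comparison on conformational ensembles (e.g. the 300 K stream of a
replica-exchange simulation, or any multi-model PDB):

* **Fibril order parameter.**  For residue *r*, let *v_r* join the Cα
  of the first chain (A) to the Cα of the same residue in the last
  chain (E).  With *z* the fibril axis,

      ordP = (1/N_r) Σ_r ⟨v_r, z⟩ / (‖v_r‖‖z‖) = (1/N_r) Σ_r cos α_r

  ordP = 1 means a perfectly aligned fibre; lower values measure
  distortion of the stack.
* **Functional mode analysis (FMA).**  PCA of the superposed Cα
  coordinates, then a linear model of ordP on the leading principal
  components, fitted on a model-building half of the frames and
  cross-validated (Pearson r) on the held-out half.  Collapsing the
  eigenvalue-weighted coefficients back onto the eigenvectors gives the
  ensemble-weighted maximally correlated motion (**ewMCM**) — the one
  collective coordinate that drives the order-parameter fluctuation —
  plus interpolated ewMCM trajectories and the RMSF of the motion
  filtered on that vector.
* **Inter-chain statistics.**  Per-residue contact probability
  (minimum heavy-atom distance ≤ 0.45 nm, averaged over the interior
  chain pairs B-C and C-D), donor→acceptor hydrogen-bond probability
  maps (0.35 nm cutoff, optional 30° H–donor–acceptor angle), and
  non-bonded contact maps.
* **Surfaces.**  Shrake–Rupley solvent-accessible surface area with a
  deterministic golden-spiral point set, and the per-residue
  inter-chain buried surface SASA(X alone) − SASA(X∪Y), decomposed
  into hydrophobic (C, S) and hydrophilic (N, O, H) atomic channels.
* **Geometry.**  Kabsch superposition, per-residue RMSF (mean ± std
  across chains), radius of gyration, and a simplified dihedral +
  H-bond secondary-structure classifier (β / helix / coil
  probabilities).
* **Synthetic fibrils.**  A generator for ground-truth U- and S-shaped
  pentamer ensembles (26 residues per chain, numbered 17–42, exact
  0.38 nm Cα spacing, H-bond-competent backbone) with controllable
  disorder: Gaussian coordinate noise, per-chain tilt, stacking-axis
  tilt, planted collective modes with per-frame amplitudes, and
  selectively broken hydrogen-bond registers.  Every analysis above is
  testable against closed forms on these ensembles.

## Worked example

Plant a collective C-terminal fraying mode that drives the order
parameter, then recover it blindly with FMA:

```python
import numpy as np
from fibrilkit import (GeneratorParams, PlantedMode, compute_ordp, fit_pca,
                       fit_fma, generate_trajectory, sinusoid_amplitudes)
from fibrilkit.synthetic import make_cterminal_mode

planted = make_cterminal_mode(5)          # C-terminal fraying of chain E
mode = PlantedMode(directions=planted,
                   amplitudes=sinusoid_amplitudes(1000, 0.25, cycles=3,
                                                  jitter=0.01, seed=1))
traj = generate_trajectory(GeneratorParams(shape="U", n_frames=1000,
                                           noise_sigma=0.01, stack_tilt=15.0,
                                           planted_mode=mode, seed=1))
ordp = compute_ordp(traj)
print(f"ordP: mean {ordp.mean:.4f}, std {ordp.std:.4f}")

results = fit_fma(fit_pca(traj), ordp, split="half")
print(results.summary())
print(f"overlap with planted mode: "
      f"{abs(float(results.ewmcm @ planted.ravel())):.4f}")
```

which prints

```
ordP: mean 0.9657, std 0.0021
Functional Mode Analysis Results
============================================
frames (build/validation)          500/500
PCA modes used                        50
coord. variance covered               60.21%
Pearson r (build)                    0.9906
Pearson r (cross-validation)         0.9889
--------------------------------------------
leading mode coefficients:
  PC1        0.01193
  PC2        0.00167
  PC3        0.00238
  PC4        0.00315
  PC5       -0.00104
```

The order parameter fluctuates around cos 15° ≈ 0.966 (the ensemble's
baseline stacking tilt).  The cross-validated Pearson r of 0.989 says
the linear model predicts ordP on frames it never saw, and the ewMCM it
extracts overlaps the planted displacement field at 0.9993 — the
analysis found the one collective motion that was actually driving the
fibril's loss of order.

## Command line

```sh
fibrilkit generate --shape S --frames 200 --noise 0.02 --seed 1 --out s.pdb
fibrilkit ordp     --traj s.pdb --out ordp.tsv
fibrilkit contacts --traj s.pdb --out contacts.tsv
fibrilkit hbonds   --traj s.pdb --scope inter --out hbonds.tsv
fibrilkit sasa     --traj s.pdb --out sasa.tsv
fibrilkit fma      --traj s.pdb --ewmcm-pdb ewmcm.pdb
fibrilkit run      --config run.cfg          # full two-ensemble comparison
```

`run` consumes a flat `key = value` config (see
`fibrilkit.pipeline.load_config`) and writes per-ensemble TSV tables, a
side-by-side comparison table and a JSON summary, all stamped with the
config hash; results are byte-identical for a fixed config and seed.

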