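# stepmd

Enhanced-sampling molecular dynamics, at desk scale: a toolkit for the
sampling strategies used to capture a nuclease-domain docking transition —
the conformational change by which a mobile catalytic domain (think of the
HNH domain of Cas9 closing onto the scissile phosphate of its target DNA
strand) moves from a pre-catalytic to a catalytically competent pose.
Reaching such a state in unbiased simulation is a rare-event problem;
`stepmd` implements the three attack routes and the analysis workflow
around them, exercised on tunable synthetic bead systems with known
answers:

* **Accelerated MD (aMD)** — a non-negative boost that raises energy
  basins below a threshold E,

      ΔV(r) = (E − V(r))² / (α + E − V(r))   for V(r) < E,  else 0,

  in dihedral-only or dual-boost form, with threshold/acceleration
  estimation from short unbiased runs and exponential (or second-order
  cumulant) reweighting back to unbiased free-energy profiles.
* **Targeted MD (tMD)** — harmonic steering on the instantaneous best-fit
  RMSD to a target structure,

      U_tMD = ½ (k/N) [RMSD(t) − RMSD*(t)]²,

  with the spring constant k scaled down by the number N of targeted
  atoms, a linear reference schedule RMSD*(t), mass-weighted partial
  targeting, and weak positional restraints on the non-targeted scaffold.
* **Step-by-step adaptive ensembles** — cycles of unbiased replica runs,
  each cycle reseeded from the saved frame minimizing a progress metric:
  the geometric mean of the distances from the scissile-site bead to the
  two catalytic-site beads, (d₁·d₂)^½ — smaller means closer to the
  active arrangement.  No biasing force is ever applied.

The analysis module provides the companion workflow: rigid-body fitting of
trajectories to a reference over a fit selection that *excludes* the mobile
domain, coordinate-covariance PCA over the domain with projections onto the
leading modes, labeled distance-pair series (FRET-analog and
reaction-interface pairs), per-group RMSD under global-fit and self-fit
conventions, average-linkage cluster representatives (medoids), octahedral
coordination-geometry reports for a bridging ion, and a pairwise
cross-group interaction-energy decomposition.

The intended users are method developers and students of enhanced
sampling who want the algorithms, their bookkeeping, and their failure
modes in an afternoon-sized package — not a production force field.  See
`docs/methods.md` for the models, defaults, and limitations.

## Worked example

Setup arithmetic for the solvated box (a 139 × 124 × 187 Å cell at 5 mM
divalent ions, with 3 already placed at functional sites):

```
$ stepmd ions --cell 139 124 187 --mm 5 --placed 3
cell volume 3.223e+06 Å³; 5 mM needs 10 ions total, 7 extra beyond 3 placed
```

Cumulative sampling-time bookkeeping of the built-in reference run ledger:

```
$ stepmd manifest --reference --groups G1,G2,G3,G4,G10
aMD_Ed: 1.3 µs
aMD_dual: 2 µs
cMD: 11 µs
total: 14.3 µs
```

A step-by-step campaign on the ion-present docking fixture (10 replicas
per cycle, 3 000 steps each, reduced units; ~20 s on one core):

```
$ stepmd stepwise --cycles 8 --replicas 10 --steps 3000 --seed 7 --out-prefix demo
3 cycles, final metric 5.676 (converged=True) -> demo_*
```

The per-cycle minimum of the progress metric (`demo_metric.csv`) drops from
the undocked design value 9 toward the docked design value 6 and plateaus —
here 5.74 after one cycle, 5.68 after two, converged under the 5 %/2-cycle
rule:

```
cycle,min_metric
1, 5.740
2, 5.676
3, 5.676
```

`demo_seed.pdb` holds the final seed structure and `demo_manifest.tsv` the
campaign's run ledger.  The same protocol from the library:

```python
import stepmd as sm
from stepmd.engine import EngineParams

system = sm.make_domain_docking_model()          # ion-present fixture
result = sm.run_stepwise_campaign(
    system,
    EngineParams(dt=0.05, temperature=1.0, friction=1.0, seed=7, n_steps=3000),
    sm.CampaignSpec(n_cycles=8, n_replicas=10, run_length=3000,
                    selection_scope="best_so_far", master_seed=7),
)
print(result.per_cycle_min)   # non-increasing, plateaus near 6
```

Steering the same fixture in physical units with the standard protocol
(initial best-fit RMSD 10 Å, 0.25 kcal/mol/Å² per targeted atom, 100 ns
linear schedule):

```python
from stepmd.docking import make_tmd_docking_setup
from stepmd.biasing import TmdBias
from stepmd.engine import run_md, EngineParams
from stepmd.trajectory import Frame
import numpy as np

system, params = make_tmd_docking_setup()
bias = TmdBias(params, system, trace_interval=50)
ep = EngineParams(dt=0.05, temperature=310.15, friction=1.0, seed=11,
                  n_steps=2_000_000, save_interval=20_000)
run_md(system, ep, biases=[bias], initial=Frame(0.0, system.poses["undocked"]))
trace = np.array(bias.rmsd_trace)
slope = np.polyfit(trace[:, 0] / 1000, trace[:, 1], 1)[0]
print(f"{-slope:.3f} Å/ns")    # ≈ 0.093, scheduled rate 0.1
```

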