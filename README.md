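# biopsyplan

Simulation and learning toolkit for planning **targeted transperineal
template-guided prostate biopsy**. In this procedure a 13×13 brachytherapy
template (5 mm pitch) guides straight needles into the prostate, and the
clinical task is to pick five core positions that sample an MR-identified
lesion despite registration error, patient motion and organ deformation
between the pre-procedure plan and the live anatomy.

The package is aimed at researchers studying sampling strategies: it provides

* an **episodic MDP simulator** over 3D binary gland/lesion masks — state
  `s_t = (P_t, L_t, N_t, N_{t−1}, N_{t−2})` (gland, lesion and the three most
  recent needle-trajectory masks), continuous action
  `a_t = (δx, δy, δz)` with in-plane movement in (−10, +10) grid steps and a
  three-way depth/firing component, and reward

  ```
        ⎧ +10   needle fired, intersects the lesion
  R  =  ⎨  −2   needle fired, misses the lesion
        ⎪  −1   needle not fired
        ⎩  −5   needle placed outside the prostate gland
  ```

  with 20-step episodes terminating early on five hits;
* two **clinical expert policies** — π_Centre (five nodes nearest the lesion
  centroid) and π_Edge (centre node plus four nodes at the projected lesion
  boundary) — and conversion of their plans into demonstration pairs;
* **imitation learning** (behavioural cloning, MSE on demonstrated actions)
  and **reinforcement learning** (PPO with clipped surrogate, value loss and
  entropy bonus, minimising `L^{CLIP+VF+H} = E[−L^CLIP + c₁L^VF − c₂H]`),
  in pure NumPy with small pooled-feature actor–critic networks;
* **intra-procedure mismatch simulation** — rigid target registration error
  (TRE; isotropic Gaussian with RMS magnitude equal to the level in mm) and
  free-form deformation via Gaussian splines on a 10×10×10 control grid,
  parameterised by a per-step *rate* and *scale*;
* **clinical outcome metrics** — hit rate (HR), cancer core length (CCL),
  normalised CCL, needle coverage `N.Coverage = std_x·std_y·π / Area_L`, the
  lesion-size/CCL Pearson coefficient, and paired t-test comparisons;
* a **synthetic phantom generator** (ellipsoidal glands with embedded
  lesions, patient-level train/val/test splits), since clinical mask datasets
  are not redistributable.

## Worked example

```python
from biopsyplan import (generate_phantom, centre_policy, run_episode,
                        ExpertAgent, TREConfig, evaluate_policy)

# one synthetic case: 25x22x20 mm gland, 6 mm lesion offset (8, -4, 3) mm
case = generate_phantom(seed=7, gland_radii_mm=(25, 22, 20),
                        lesion_radius_mm=6.0, lesion_offset_mm=(8.0, -4.0, 3.0),
                        shape=(96, 96, 64))

plan = centre_policy(case)
print("plan nodes:", plan.nodes, "depth:", plan.entries[0][1])

res = run_episode(ExpertAgent("centre"), case)
print(f"hits {res.n_hits}/5  total reward {res.total_reward}  CCL "
      f"{sum(r.ccl_mm for r in res.records):.1f} mm")

rep = evaluate_policy(ExpertAgent("centre"), [case], tre=TREConfig(level_mm=6.0),
                      episodes_per_case=5, seed=0)
print("HR at TRE 6 mm:", round(rep.aggregate()["hr_mean"], 3))
```

prints

```
plan nodes: [(8, 5), (7, 5), (8, 6), (7, 6), (8, 4)] depth: base
hits 4/5  total reward 23  CCL 26.0 mm
HR at TRE 6 mm: 0.4
```

The lesion centroid sits between template holes, so the five nearest nodes
cluster around grid position (8, 5); four of the five cores traverse the
lesion (the fifth misses inside the gland: 4·10 + 1·(−2) − 15 no-fire steps
= 23), collecting 26 mm of cancer core length. Injecting a 6 mm registration
error between the observed and true anatomy drops the expert's hit rate
from 0.8 to 0.4 — the pre-procedure plan aims at where the lesion *appears*
to be.

## Command line

```bash
biopsyplan generate --n-patients 30 --ratios 0.7,0.1,0.2 --seed 1 --out run/cohort
biopsyplan demo     --cohort run/cohort --policy centre --out run/demos
biopsyplan train-il --cohort run/cohort --policy centre --out run/il
biopsyplan train-rl --cohort run/cohort --init-model run/il/model.npz --out run/rl
biopsyplan evaluate --cohort run/cohort --policy run/rl/model.npz \
                    --tre-levels 0,3,6,10 --out run/eval
biopsyplan compare  --report-a run/eval/percase_tre=0mm.csv \
                    --report-b run/eval/percase_tre=10mm.csv --out run/cmp.csv
```

Each stage derives its randomness from one root seed and records a
configuration hash, so a run directory is reproducible from its stored
config alone.

## Layout

| module | contents |
|---|---|
| `biopsyplan.phantoms_io` | mask volumes, phantom/cohort generation, NIfTI I/O, splits |
| `biopsyplan.geometry` | template grid, action quantization, needle rasterization, CCL |
| `biopsyplan.mismatch` | TRE sampling, Gaussian-spline free-form deformation, warping |
| `biopsyplan.environment` | the MDP: reset/step, rewards, termination, mismatch wiring |
| `biopsyplan.expert_policies` | centre/edge experts, demonstration datasets |
| `biopsyplan.learning` | behavioural cloning, PPO, policy evaluation |
| `biopsyplan.metrics` | HR, CCL, N.CCL, N.Coverage, CCL coefficient, paired t-tests |
| `biopsyplan.cli` | `biopsyplan` command-line orchestration |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
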