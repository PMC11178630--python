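# Methods

## The simulated procedure

`biopsyplan` simulates targeted transperineal prostate biopsy through a
brachytherapy template: a 13×13 grid of holes at 5 mm pitch held against the
perineum, through which straight needles are advanced along the
inferior–superior image axis. A plan consists of five core positions chosen
to sample one MR-identified lesion. The package represents anatomy as 3D
binary masks (gland and lesion) with voxel spacing in mm; all geometry is
computed in world millimetres with `world = origin + index · spacing` at
voxel centres.

The template grid is centred on the gland centroid projected onto the
transverse plane. Needles fire at one of two depths, "apex" and "base",
placed at 25% and 75% of the gland's extent along the needle axis — the
anatomy defines "near the apex/base" only qualitatively, so the quartile
planes are a package choice, exposed in configuration. The needle core is a
straight, axis-aligned, one-voxel-thick segment of configurable length
(default 20 mm, approximating a standard biopsy sampling notch), centred on
the chosen depth plane and clipped to the image.

## The decision process

Planning is an episodic Markov decision process. The state holds five
aligned mask channels: observed gland, observed lesion, and the needle
trajectories of the three most recent steps (giving the agent a short
memory of where it has sampled). The action is a continuous triple
(δx, δy, δz): in-plane movement in grid steps within (−10, +10), rounded
half-away-from-zero to whole template positions and clamped to the grid,
and a depth/firing component δz ∈ [−1, 1] split into three bands — below
−1/3 no needle is fired, the middle band fires at the apex plane, the top
band at the base plane. Interpreting (−10, +10) as grid steps (not mm)
allows movement across many template positions per action; a ±2-position
range would barely permit that on a 13-wide grid. The three-way δz encoding
is the minimal extension of the two-depth action that also admits the
"not fired" outcome the reward distinguishes.

Rewards per step: +10 for a fired needle intersecting the lesion, −2 for a
fired needle inside the gland that misses, −1 for not firing, −5 for a
needle placed entirely outside the gland (its trajectory shares no voxel
with the gland mask). Outside-gland takes precedence over miss. Episodes cap
at 20 steps and terminate early once five fired needles have hit. Repeat
visits to a node are allowed (nothing in the procedure forbids re-sampling
a hole; the coverage metric penalises redundancy naturally), and repeated
hits at the same node count toward the five-hit termination.

## Intra-procedure mismatch

Two error sources are injected between the plan and the anatomy:

* **Registration error (TRE).** A rigid translation drawn from an isotropic
  Gaussian with per-axis σ = level/√3, so the RMS displacement magnitude
  equals the configured level in mm (levels of interest: 0, 3, 6, 10 mm).
  Gland and lesion receive independent draws by default, modelling
  independent errors on anatomy and target; a flag shares one draw. The
  translation perturbs only the *observed* channels — rewards and metrics
  are judged against the true anatomy, which is exactly what makes a
  mis-registered plan miss. One draw is made per episode (a registration
  error is a per-procedure offset); a per-step resampling mode exists for
  modelling continuous patient motion.

* **Free-form deformation.** Displacements at a 10×10×10 equidistant
  control-point grid spanning the image are smoothed into a dense per-voxel
  field by Gaussian splines, u(x) = Σ_c d_c · exp(−|x−x_c|²/2σ²). Severity
  is set by a *rate* (fraction of the 1000 control points displaced per
  time step; ⌈rate·1000⌉ points chosen uniformly without replacement) and a
  *scale* (each displacement component uniform in [−scale, +scale] mm —
  "range of sampled distance" reads as a bounded range, not a Gaussian).
  The kernel has unit peak so that scale is an interpretable per-point
  displacement bound, and σ defaults to the control-point spacing
  (extent/9), the standard choice giving overlap between neighbouring basis
  functions. Because neighbouring unit-peak kernels overlap, the dense
  field's magnitude can exceed the scale by up to the product of per-axis
  kernel sums (a documented, testable bound). The dense field is evaluated
  with three separable tensor contractions — mathematically identical to
  convolving the sparse control displacements with the Gaussian kernel.
  Deformation alters the *true* anatomy each step (the lesion genuinely
  moves) and the observation shows the deformed anatomy. Fields are
  resampled fresh each step and applied to the base masks rather than
  composed cumulatively — this bounds total drift over an episode; a
  cumulative mode is available behind a flag. Masks are warped by backward
  resampling with trilinear interpolation and a 0.5 threshold.

## Expert policies and imitation learning

Two deterministic clinical strategies serve as demonstration experts. The
*centre* policy targets the five grid nodes nearest the lesion centroid
(in-plane Euclidean distance; ties broken lexicographically by
(distance, i, j); the centroid is the voxel-count-weighted mean of lesion
voxel centres). The *edge* policy targets the nearest-centroid node and
then the nodes nearest the four boundary points of the lesion's transverse
projection along ±x and ±y from the centroid; a duplicate steps outward
along its ray to the next unused node. "Edge of the lesion" has no
operational definition in clinical practice; the axis-extreme rule on the
2D projection is this package's documented choice, consistent with the
projected-area normalisation used by the coverage metric. Firing depth is
the plane nearer the lesion centroid's axial coordinate.

Rolling a plan through a zero-mismatch environment produces demonstration
pairs D = (s₀, a₀, …); each action encodes the relative displacement to
the next planned node plus the firing band (moves beyond ±10 nodes split
into a no-fire move plus a fire step). Behavioural cloning minimises the
mean squared error between demonstrated and predicted actions with Adam
(default 1000 epochs at learning rate 5e-4).

## Policy architecture and PPO

No GPU-scale network is warranted by the task, so the policy is a small
NumPy actor–critic. Observation channels are block-averaged to an 8×8×4
occupancy summary each, concatenated with the normalized grid position
(1282 features), and fed to two 64-unit tanh layers. The pooled
needle-history channels are rescaled by a gain of 50 (capped at 1): a
one-voxel-thick trajectory occupies roughly 10⁻³ of a pooling block,
orders of magnitude below the anatomy channels, and the rescale balances
the feature magnitudes so recent needle positions remain visible to the
network. The policy head
outputs a mean bounded by tanh to (−10, 10) in-plane and (−1, 1) in depth,
plus a learned state-independent log-σ per component; the value network
has the same architecture with separate weights. Sampling adds unbounded
Gaussian noise to the bounded mean (the environment's quantization clamps
stray draws); a full change-of-variables through the squashing would add
complexity without benefit at these action scales.

PPO optimises the clipped surrogate combined with a value loss (weight
c₁ = 0.5) and an entropy bonus (weight c₂ = 0.01), equivalently minimising
the negated combined objective. The value target is a state-value critic
with generalized advantage estimation (γ = 0.99, λ = 0.95) — the
conventional PPO critic, even though the objective is sometimes written
against a Q-function. Clip range 0.2; updates every 16 episodes with 4
epochs of 64-sample minibatches; advantages normalized per batch. Each
episode interacts with a freshly sampled training case. Every 100 episodes
the deterministic policy is evaluated on validation cases and a snapshot is
kept when the mean validation episode reward improves; training returns the
best checkpoint and aborts (restoring it) on a non-finite loss. The
full-scale schedule uses learning rate 5e-5 over up to 100 000 episodes;
the desk-scale runs in this repository use 2 000 episodes at 3e-4 — with
the small feature-based network, a few hundred updates at the higher rate
reach convergence on the toy tasks, whereas the full-scale rate is matched
to a much larger model and budget.

## Outcome metrics

Per episode: **HR** = hits/fired (undefined when nothing fired); **CCL** =
total needle–lesion intersection length in mm (voxel-count × axial
spacing); **N.CCL** = CCL / (5 × longest axial lesion chord), i.e.
normalised by the maximum CCL five ideally placed needles of unlimited core
could obtain (a single-needle normalisation is available via the
`n_needles` argument); **N.Coverage** = std_x·std_y·π / Area_L with
*population* standard deviations of the fired needles' world coordinates
and the lesion's transverse projected area (voxel-column union × in-plane
voxel area). Across cases, the **CCL coefficient** is the Pearson
correlation between lesion size in voxels and measured CCL. Aggregates are
reported as mean ± across-case standard deviation; policies are compared
with paired Student t-tests at α = 0.05 (no multiple-testing correction,
matching common reporting practice for these outcome tables).

## Synthetic phantoms

Clinical gland/lesion masks are not redistributable, so cohorts are
generated: ellipsoidal glands (semi-axes drawn per patient from 18–28 mm,
covering typical prostate dimensions) with ellipsoidal lesions (radii
4–9 mm, roughly one to a few grid cells) placed uniformly inside a
conservative containment region; every lesion is voxelwise inside its
gland, patients can carry several lesions (one case per lesion, all cases
of a patient in one split). Default volumes are 96×96×64 voxels at 1 mm
isotropic; the test suite and acceptance runs use 64×64×48 phantoms, which
still hold the full 60 mm template span.

What the phantoms do *not* emulate: realistic gland/lesion shape
variability (lobulated lesions, asymmetric glands), MR intensity content,
annotation noise, inter-rater variability, or the clinical lesion-size
distribution (which is unpublished for the reference cohorts; the
generator exposes the size range as a parameter instead of asserting one).
Passing tests therefore demonstrate correctness of the mechanics, learning
dynamics and metric definitions — not clinical performance on real
anatomy.

## Numerical choices and degenerate inputs

* Rounding of in-plane actions is half-away-from-zero, symmetric in sign.
* Needle voxels are those whose centres fall in the half-open interval
  [centre − L/2, centre + L/2), so a 20 mm core at 1 mm spacing covers
  exactly 20 voxels when interior.
* Non-binary input volumes are thresholded at 0.5 with a warning.
* Observation channels may be resampled to a fixed shape (default full
  resolution; 64×64×32 in the scaled RL runs) by block averaging with a
  0.25 occupancy threshold so one-voxel-thick needle channels survive;
  rewards and metrics always use full resolution.
* A deformation or TRE draw that pushes a small lesion (or gland) entirely
  out of raster support falls back to the unperturbed mask to keep the
  episode well-posed.
* Zero fired needles → HR and N.Coverage are NaN with a warning; constant
  lesion sizes or CCLs → CCL coefficient NaN with a warning; identical
  paired samples → t = 0, p = 1.
* Degenerate glands (< 2 voxels of axial extent) are rejected.

## Known limitations

Straight axis-aligned needles only (no bending, no oblique insertion, no
template-hole occlusion); one lesion per episode; the deformation model is
a general-purpose spline, not biomechanically constrained; the TRE and
deformation magnitudes are simulation parameters, not fitted to registration
studies; and the desk-scale training budgets demonstrate learning dynamics
rather than converged large-scale policies.
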