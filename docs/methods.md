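# Methods

## Thresholding model

Segmentation is posed as maximising a histogram criterion over ordered
integer cut-point vectors `TH = [th_1, …, th_m]`, `1 ≤ th_1 < … < th_m ≤ L−1`.
Classes are the half-open intensity bins `[0,th_1), [th_1,th_2), …, [th_m,L)`
— one single convention everywhere, so a pixel exactly at a threshold falls
in the class above and no intensity is double-counted.

**Otsu criterion.** With class masses `w_j = Σ_{i∈j} p_i`, class means
`μ_j = Σ_{i∈j} i·p_i / w_j` and global mean `μ_T`, the between-class variance
is `σ_B² = Σ_j w_j (μ_j − μ_T)²` (intensity² units). Empty classes carry
`w = 0` and contribute 0 rather than raising, which keeps the search space
connected for the optimizer. The implementation satisfies, and the tests
check, `Σ w_j = 1`, `Σ w_j μ_j = μ_T`, the bilevel decomposition
`σ_B² + σ_W² = σ_T²`, and invariance of `σ_B²` under a constant intensity
shift.

**Kapur criterion.** Sum over classes of the Shannon entropy of the
conditional distribution `p_i / w_j`, in nats; zero-probability bins and
empty classes contribute 0. Natural log is a free choice — any base only
rescales the objective and cannot move the argmax.

**Exhaustive oracle.** All `C(L−1, m)` vectors are enumerated (refused above
10⁷ combinations); ties break to the lexicographically smallest vector so
the oracle is deterministic. The oracle is independent of the optimizer and
anchors its correctness tests.

## EMO optimizer

Population of `N` points in the box; per iteration: charges → pairwise
forces → move → local search → selection.

* **Charge** `q_i = exp(−m (f_best − f_i)/Σ_j (f_best − f_j))` ∈ (0,1],
  maximal (=1) for the best point, monotone in fitness. An all-equal
  population receives uniform charge 1 and zero net force (avoids 0/0).
* **Force** on `i` from `j`: magnitude `q_i q_j / d²`, directed toward `j`
  when `f_j > f_i` (attraction), away otherwise. Fitness values are capped
  at 1e100 before charge computation and separations clamped below by
  `eps_sep` (default 1e-9 × box width) — both overflow guards.
* **Move**: every point except the best steps `x_d += μ_d · f̂_d · range_d`
  per coordinate, `μ_d ~ U(0,1)`, where `range_d` is the distance to the box
  wall in the force direction; a full step lands exactly on the wall. The
  "scale-to-wall" reading was chosen over plain clipping because it keeps
  every intermediate position feasible by construction. The best point is
  elitist and never moves, making the incumbent trace non-decreasing.
* **Local search**: up to `m · k_local` uniform probes within radius
  `λ_local · (u−l)` per dimension, clipped to the box; the first strict
  improvement replaces the point.
* **Integer spaces**: positions evolve continuously; every evaluation
  rounds, sorts and repairs duplicates into a strictly increasing integer
  vector (collisions incremented, overflow pulled back from the upper
  bound). Evaluations are memoised on the decoded tuple, which is what makes
  a 100-iteration run on a 256-level histogram take well under a second.
* **Anti-stagnation** (optional, off by default): when the population's
  coordinate-wise spread falls below 1% of the box width, one non-best point
  is resampled uniformly and treated as a co-best attractor for that
  iteration's forces. The trigger threshold is the package's own choice; the
  device itself only needs to guarantee that some point can re-enter
  abandoned regions.

Defaults `N = 30`, `k_max = 100`, `k_local = 10`, `λ_local = 0.25`: small
enough for sub-second runs, ample for two-threshold problems on 256-level
histograms, where the search reaches the exhaustive optimum on every tested
instance.

## Preprocessing

**Anisotropic diffusion** (Perona–Malik): explicit 4-neighbour scheme in
conservative edge-flux form `I ← I + dt · div(g(|∇I|) ∇I)` with Neumann
borders, so the global mean is conserved to machine precision and, for
`dt ≤ 0.25`, the maximum principle holds (output range inside input range)
and total variation is non-increasing. Conductance
`g = exp(−(∇/κ)²)` (or `1/(1+(∇/κ)²)`). Defaults `iterations = 15`,
`κ = 30`, `dt = 0.2` — community-standard settings for 8-bit MR slices: κ
sits well below the ≈60-level tissue contrasts, so tissue boundaries are
effectively frozen while intra-tissue noise diffuses away.

**Skull stripping**: adaptive threshold (bilevel Otsu — the package's own
thresholding machinery) → binary opening (disk r=2) → largest 8-connected
component → erosion (disk r=6) to detach residual skull → largest component
→ hole filling (recovers interior CSF) → dilation (disk r=8) → intersection
with the hole-filled pre-erosion component → largest component. Dilating two
pixels more than the erosion and then intersecting makes the mask a superset
of the detected head component's interior on smooth boundaries (the
curvature loss of an open/close pair is well under 2 px at brain-scale radii)
while never leaking outside the detected head — this is what lets a
noiseless phantom be recovered *exactly*. All radii (~1 mm/pixel scale) are
exposed as configuration.

## Pipeline

`segment_image`: diffuse → quantize to integers → strip skull → histogram
over the brain mask only → EMO with the chosen criterion (`m = 2` default)
→ pixel labeling → tissue assignment by ascending class mean
(CSF < GM < WM, T1 contrast). The off-mask background is excluded from the
histogram deliberately: the zeroed background otherwise dominates σ_B² and
one threshold is wasted separating background from head, leaving only two
tissue classes. One top-level seed drives phantom, optimizer and any other
randomness, and the full configuration is recorded in the result.

## Evaluation

Per-tissue one-vs-rest confusion counts over an optional evaluation mask;
sensitivity `TP/(TP+FN)`, specificity `TN/(FP+TN)`, accuracy
`(TP+TN)/total`. Zero-denominator metrics are reported as `None`, never as a
silent 0 or 1, so macro-averages are computed over defined entries only.
The CLI and JSON reports print percentages; the library returns fractions.
Mask overlap uses the Jaccard coefficient `|A∩B|/|A∪B|` (1.0 for two empty
masks).

## Synthetic phantom

The phantom emulates an axial T1 head slice: dark background (mean 5),
bright elliptical skull ring (230), a thin dark gap standing in for the
subarachnoid space, a GM cortical band (110) around a WM core (200) with
paired ventricles and randomized CSF pockets (50), Gaussian noise (default
SD 3% of full scale; Rician optional) and an optional low-order polynomial
bias field (default off — the method contains no bias correction, so the
default regime excludes what it cannot model). Truth labels are the
pre-noise assignments; the brain mask is CSF ∪ GM ∪ WM.

What the phantom does *not* emulate: anatomical cortical folding, partial
volume effects at tissue interfaces, spatially varying noise, and the gap
being true CSF rather than background. Its tissue modes are far better
separated (≈8 noise SDs) than real T1 data, so perfect phantom scores
demonstrate the correctness of the machinery, not clinical-grade accuracy;
on real slices the same thresholds trade off partial-volume pixels and
scores in the mid-90s (percent) are the realistic regime.

## Problem sizes and determinism

The bundled experiments use a 256×256 phantom, 64-level random histograms
for the 50-run oracle-equivalence study, and 100 random histograms for the
variance-decomposition identity; each completes in seconds. Every stochastic
component takes a `numpy` `Generator` seeded from one integer, so all
reported numbers are bit-reproducible.

## Known limitations

2-D slices only (NIfTI volumes are reduced to one axial slice on read);
single-channel T1 contrast assumed by the CSF < GM < WM ranking; no bias
-field correction; thresholds are global, so strong intensity inhomogeneity
degrades results by design; `m` must be 2 for tissue naming (other `m`
values return raw class labels).
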