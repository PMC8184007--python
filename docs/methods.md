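# Methods

`polkadots` quantifies the spatial organization of Bcl10 signaling filaments
and their interaction with autophagosomes in activated T cells, and simulates
the nucleation-limited growth and autophagy-driven degradation of those
filaments. This note records the models, the parameter choices, and the
numerical decisions, in the order of the analysis chain.

## Synthetic 3D cells (`polkadots.synth`)

Because no raw micrographs ship with the package, every imaging-side stage is
validated on synthetic volumes with exact ground truth. A cell is a filled
ellipsoid of voxels at isotropic 25 nm pitch (6 voxels = 150 nm, the
approximate resolution of the instrument the pipeline is designed for).
Filaments are tubes of radius 2 voxels (~100 nm across) dilated from
unit-step random-walk centerlines whose per-step turn is bounded
(`curvature_bound`, default 15°/step; the fidelity analyses use ≤8°/step,
i.e., a turning radius of ≥7 voxels, since Bcl10 filaments are stiff).
Near the boundary and near already-placed tubes the walk steers along the
gradient of a clearance field (Euclidean distance to the nearest disallowed
voxel, Gaussian-smoothed, σ=2), always within the curvature budget, so walks
fill crowded cells without violating the non-crossing constraint. Vesicles
are voxelized spheres of radius 2–3 voxels (diameter ≤150 nm, matching the
observation that most autophagosomes are smaller than (0.2 µm)³), pairwise
disjoint, either placed uniformly over all positions where the sphere fits,
or — with probability `q` — centered within one radius of a randomly chosen
filament endpoint (or punctum center). Ground truth records float
centerlines (arc length = step count), vesicle centers/radii/voxel counts,
and placement labels.

What the generator does *not* emulate: optics (PSF, photon noise,
deconvolution residue), anisotropic z-sampling artifacts beyond what the
resampling stage handles, multi-cell fields, and intensity variation.
Passing tests therefore demonstrate correctness of the geometry and the
statistics given a faithful segmentation, not robustness to segmentation
error on real images.

Two preset compositions are the study conditions for the resampling-null
experiments: `small_cell_config` (64³ grid, 6 filaments of 25–80 voxels,
14 uniform vesicles) for type-I calibration, sized so a cell carries a null
mean of ~5 contacts, and `medium_cell_config` (80³, 10 filaments of 30–100
voxels, 16 vesicles) for the end-bias power analysis, sized so an end-biased
cell carries ~12–18 located contacts. Two vesicles aimed at the same
endpoint always collide, so the number of biased vesicles must stay below
the endpoint count; both presets respect that with margin.

## Preprocessing (`polkadots.preprocess`)

Intensity stacks are cubic-spline resampled to an isotropic grid (z planes
at 200 nm → 25 nm), thresholded per cell and channel (an Otsu default exists
for synthetic data only), cleaned with a 3×3×3 neighborhood filter, and
denoised by removing 26-connected components below `min_voxels` (default 8,
the neighborhood-filter scale). The neighborhood filter follows the
1/27-kernel arithmetic with cutoff (2/3)³ = 8/27: a voxel is kept iff its
3×3×3 neighborhood, *center included*, holds ≥8 occupied voxels — and the
filter only ever removes voxels, so its output is a subset of the
thresholded volume. The alternative reading (≥8 among the 26 neighbors,
center excluded) is selectable via `include_center=False`; both are tested.
Components use 26-connectivity throughout: thin tubes at 25 nm pitch
fragment under 6-connectivity.

## Skeleton analysis (`polkadots.skeleton`)

Each labeled structure is thinned to a medial-axis skeleton
(`skimage.morphology.skeletonize`, Lee's method), converted to a graph on
voxel centers with 26-adjacency edges, and **simplified**: any diagonal edge
shortcut by a two-step path of strictly shorter edges is dropped. Digitized
oblique lines are riddled with such triangles; without simplification they
masquerade as junctions. Removal order (body diagonals, then face
diagonals, each requiring a surviving shorter witness path) preserves
connectivity and homotopy.

*Spur pruning* walks from each degree-one tip until the main body; terminal
branches shorter than 6 voxels (150 nm, the optical resolution) are deleted,
iterating to a fixpoint. The attachment voxel is absorbed into the spur when
its remaining neighbors stay connected within a few steps without it (a bump
that serves no connectivity purpose); when the bump carries connectivity
only because edge simplification used it as a witness, the image-adjacency
edge among its neighbors is restored and the bump removed all the same.
This makes the deleted branch exactly the injected spur in synthetic tests,
and pruning cannot disconnect a skeleton.

*Punctate classification*: a structure whose skeleton spans fewer than
6 nodes end-to-end is punctate ("P"). The extent is the geodesic diameter
(double BFS), which treats paths, loops, and lollipop-shaped skeletons
alike.

*Lengths*: thresholds stated in voxels (spur length, punctate cutoff) count
nodes, following the 6-voxel convention. Physical lengths integrate
Euclidean steps along the path **subsampled every 3 nodes**: per-step chain
summation systematically overestimates digitized oblique lines by up to
~8%, while the subsampled polyline is exact on straight axis or diagonal
paths and shortens gently curved paths negligibly. `measure_structure`
additionally subtracts a per-end cap correction, `max(r̂ − EDT(end), 0)`,
where r̂ is the mean distance-transform value along the path (the tube
radius estimate): thinning extends the skeleton into a tube's rounded end
caps by up to one radius, and the correction removes exactly the measured
overshoot without penalizing ends that thinning eroded. Together these
bring length error on 100 random tubes (20–200 voxels, ≤6°/step) to a mean
of ~0.5% with ≥95% of tubes within 10%.

*Junction untangling*: filaments do not branch, so junctions are crossing
artifacts. Mutually adjacent degree-≥3 voxels form junction clusters, and
clusters connected by chains shorter than 6 voxels are merged (two crossing
filaments whose digitizations share a stretch produce exactly such bridged
junction pairs; only the merged junction lets both continuations reclaim
the shared voxels). At each cluster the incident branches are paired to
minimize total bending energy 1/R², enumerating all maximum matchings up to
8 branches (greedy best-pair-first beyond, ties to the lexicographically
first pairing). R is the radius of the circular arc joining the two branch
stubs (5 nodes each): `R = chord / (2 sin(bend/2))`, with stub directions
from total-least-squares line fits. An algebraic sphere fit of the raw
11-voxel segment — also provided as `fit_sphere_radius`, with a
quantization-aware collinearity gate (RMS line residual ≤0.44 voxel ⇒
R = ∞) — is noticeably less reliable here because algebraic fits are biased
toward small radii on short noisy arcs; the arc estimator decides 50
random-orientation line crossings at 30–90° without error. Paired branches
are concatenated through the cluster (shortest path through the junction
voxels, which may appear in both output paths); unpaired branches terminate
at the junction. A skeleton that collapses entirely into one cluster falls
back to its geodesic diameter path. Known limitation: for *thick* tubes
crossing below ~35–40°, thinning itself fuses arms of the two filaments;
no pairing scheme can recover what the skeleton no longer contains.

*End distances* are unit-edge geodesics to the nearest degree-one node
(multi-source shortest path on the skeleton graph); pure cycles carry an
infinite sentinel and are excluded from end-distance statistics.

## Contacts (`polkadots.contacts`)

A contact is a (structure, vesicle) label pair sharing ≥1 voxel — counted
per pair, not per overlap voxel cluster. Each overlap voxel takes the end
distance of its Euclidean-nearest skeleton node (ties to the lowest node
id); the contact's end distance is the minimum over its voxels. Contacts
with punctate structures are classed "P" and carry no distance. The
rescaled distance divides by half the skeleton length *of the node's own
untangled path* (tip → 0, midpoint → 1); normalizing by the half-length
rather than the full length makes the statistic symmetric under end
relabeling, and using the per-path length keeps crossings honest.

## Resampling null (`polkadots.resample`)

The null for "are contacts more frequent / more end-localized than chance?"
rearranges the segmented vesicles inside the fixed cell boundary: each
vesicle is rotated by three uniform axis angles (voxel centers rotated
about the centroid, rounded, single-voxel holes closed), then its centroid
is placed at a uniformly drawn boundary voxel; placements leaving the
boundary or overlapping an already placed vesicle are rejected and the
*location* redrawn (rotation redraw optional), up to 10,000 tries. Overlap
with the filament channel never triggers rejection — that is what creates
null contacts. 100 trials per cell; an ensemble requires ≥90% successful
trials.

The ensemble reports two intervals: the t-based 95% CI of the mean count
(for excess-over-null comparisons) and the central-95% interval of the
trial counts. Type-I calibration is necessarily a statement about the
latter: an observation drawn from the null itself falls inside the
trial-distribution interval ~95% of the time, whereas the CI of the mean
shrinks with trial count and covers no fixed fraction. On 200 uniform
synthetic cells the observed count falls inside the trial interval in
~92–95% of cells; on 100 end-biased cells (q = 0.8) the observed
end-distance distribution differs from the pooled null (two-sample KS,
p < 0.05) in ~90%.

## Simulator (`polkadots.simulate`)

State: Carma1 nucleation sites (inactive → activated → occupied), a shared
pool of free Bcl10 monomers, filaments (length in monomers, pre/post
nucleation barrier), and autophagosomes (free/attached/consuming). Initial
conditions per cell: sites ~ Gamma(α=1.59, β=15.92), synapse fraction
~ N(0.40, 0.025), autophagosomes ~ Gamma(α=4.30, β=7.90), monomers
~ N(108,000, 3,600) (the wild-type copy number); draws truncated at zero,
counts rounded. Fixed constants: p_collide_carma = 0.1,
p_collide_bcl10 = 0.01, p_grow = 0.4, n_barrier = 50, autophagosome
collision/attachment 0.1/0.1, p_detach = 0.1. Variable: p_activate,
p_attach, p_degrade.

Each iteration applies activation, growth, then autophagosome dynamics
(entity order shuffled within each phase). Two semantics were genuinely
open and were fixed by requiring the engine to reproduce *both* benchmark
regimes (the growth-only ρ ≈ −0.56 end state **and** rise-and-decay
dynamics within the 10,000-iteration horizon) — no single reading of the
capped per-site laws does:

- **Collision scheduling** (`collision_model="monomer_pool"`, default):
  each free monomer collides with probability p_collide_bcl10 per iteration
  and lands on a uniformly chosen target (activated empty site or
  growth-enabled filament), attaching with p_attach below the barrier and
  p_grow above; several monomers may attach to one filament per iteration.
  Capped one-attachment-per-filament laws (also selectable:
  `monomer_scaled`, `bare`, `site_limited`) make the ratio of pool-depletion
  time to barrier-crossing time invariant (~540/n_sites for the wild-type
  pool), so no filament is ever stranded below the barrier and growth-only
  end states contain no puncta at all.
- **Activation** (`activation_model="single_molecule"`, default): one
  randomly chosen Carma1 oligomer is tested per iteration
  (p = p_collide_carma · synapse · p_activate), so full activation of n
  sites takes O(n/p) iterations and overlaps pool depletion; late-activating
  sites nucleate filaments that strand below the barrier — the simulated
  puncta. Independent per-site activation (selectable) finishes ~50×
  faster than depletion and yields zero puncta.

Degradation: a free autophagosome collides with probability 0.1 per
iteration with a length-weighted random filament (uniform choice
selectable; length weighting reflects surface area available for
interaction) and attaches with probability 0.1 at a uniform monomer
position. End attachments remove one monomer per degradation event
(p_degrade); interior attachments cause scission into a stable,
growth-disabled, site-attached daughter and a consumed daughter whose
autophagosome never detaches until the daughter is gone. Degraded monomers
are destroyed, never recycled. A site whose filament is fully degraded
reverts to the activated-nucleating state. Monomers obey an exact integer
ledger (free + filamentous + degraded = initial) asserted after every run
and testable per iteration from the recorded trace.

Population summaries: the same sampled 100-cell population is reused across
parameter configurations. The end-state correlation is Pearson's ρ across
cells between the trial-averaged puncta count (filaments of 1–49 monomers;
the punctum threshold equals the nucleation barrier, is nowhere near a
stated observable, and moves ρ by <0.02 over 25–100) and the pooled mean
filament length over all structures. The over-time ρ(t) correlates
*per-cell trial-averaged* punctate fraction (structure-count fraction;
monomer-fraction mode provided) with trial-averaged mean length across
cells: averaging the 10 trials first removes within-cell trial noise that
otherwise attenuates ρ(t) by ~0.2. The plateau statistic is the minimum of
a 301-iteration moving average of ρ(t), with the dwell time at or below
−0.6 reported alongside. Growth-only runs terminate at pool exhaustion
(~5,000–30,000 iterations; a 400,000-iteration safety cap guards cells with
very few sites); degradation runs stop at 10,000 iterations or total Bcl10
exhaustion. The inner loop is numba-compiled; a 100-cell × 10-trial
population runs in ~15–35 s.

Reproduced behaviors at the reference configuration (p_activate = 0.5,
p_attach = 0.1): growth-only ρ ≈ −0.51 ± 0.06 across seeds (the
experimentally calibrated reference value is −0.561);
higher p_activate → shorter filaments; degradation plateaus of
ρ(t) ≈ −0.70 to −0.76 for p_degrade ∈ {0.05, 0.10}, inside/below the
observed −0.7…−0.6 band, with rise-to-peak at ~1,400–1,600 iterations and
half-decay thousands of iterations later; higher p_degrade lowers peak
filamentous concentration. Two known behaviors of the real system are *not* reproduced, by design or
honestly noted: simulated puncta in contact with autophagosomes
do not quadruple late in the response (the real mechanism is likely more
complex — the simulator reproduces this failure), and a positive ρ away from the high-activation corner, seen in some earlier
simulation treatments, does not appear under the pooled-collision reading (ρ stays negative across the
grid, strongest at low activation).

## Statistics (`polkadots.stats`)

Pearson product-moment correlations; t-based 95% CIs of the mean; two-tailed
two-sample t, paired t, and KS tests at α = 0.05 with no multiple-testing
correction; gamma (shape–scale, location 0) and normal maximum-likelihood
fits. Undefined statistics (zero variance, too few points) propagate as NaN
sentinels, never silent zeros. A paired test on samples with constant
differences returns statistic 0 (equal samples) or ±∞ (constant offset)
rather than scipy's NaN.

## Interfaces

The library modules are the interface; the numbered scripts under
`analysis/` are thin drivers that run each study and write CSV tables under
`results/`, and `scripts/acceptance.py` recomputes the headline simulation
quantities. No separate console-script CLI is shipped — the scripts fulfil
that role. TIFF/JSON export of synthetic cells lives in `polkadots.io`.
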