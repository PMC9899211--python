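# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions used by the package, together with what the passing tests
do and do not establish about real data.

## Probabilistic territory maps

**Average method.** Subjects are grouped by the single major arterial
territory their stroke affects (ACA, MCA, PCA, VB). All masks are first
mirrored to the left hemisphere (voxel index i → dim_x − 1 − i along the
left-right axis; an involution that preserves lesion volume). The territory
map is the voxelwise lesion frequency p_s(j) = (# subjects lesioned at j) /
N_s, so every value is an exact multiple of 1/N_s. Border zones between
territories a and b are described by the ratio p_a/p_b, defined only where
both maps are positive; outside that support the ratio is stored as missing
(NaN) with an explicit support mask, never as 0 or infinity.

**Bernoulli mixture model.** Within a territory, each subject's binary mask
X_i is modelled as drawn from one of K clusters; cluster k has prior π_k and
independent per-voxel Bernoulli rates µ_{k,j}. The log-likelihood is

    Σ_i log Σ_k π_k Π_j µ_{k,j}^{x_ij} (1 − µ_{k,j})^{1−x_ij},

maximized by EM: the E-step computes responsibilities r_ik ∝ π_k P(X_i|µ_k)
in log space (log-sum-exp, so joint underflow can never divide by zero); the
M-step sets N_k = Σ_i r_ik, π_k = N_k/N and µ_k = Σ_i r_ik X_i / N_k. The
M-step normalizer is the cluster's effective count N_k — the update
consistent with the E-step and the only one under which the K = 1 model
collapses exactly to the average-method frequency map (a property the test
suite asserts to 1e-12).

Numerical choices:

- **Rate clipping** to [ε, 1−ε] with ε = 1e-6: the binary MLE hits {0,1} and
  would make the log-likelihood −∞. `unclip_rates` maps values at the bounds
  back to exact 0/1 for reporting and claiming.
- **Initialization and restarts:** responsibilities drawn from a symmetric
  Dirichlet per subject; 10 restarts by default, keeping the best final
  log-likelihood. Fits are bit-reproducible from the seed.
- **Convergence:** absolute log-likelihood improvement < 1e-6 or 500
  iterations. The trace is monotone non-decreasing (EM guarantee; asserted
  with 1e-8 slack).
- **Support reduction:** voxels never lesioned in any subject have MLE rate
  0 → ε for every cluster and contribute a cluster-independent constant to
  the log-likelihood; the fit therefore runs on the union support and the
  constant is added back to the trace. This is exact, not an approximation.
- A collapsed cluster (N_k < 1e-12) aborts the restart; if the data contain
  fewer distinct mask patterns than K, or a cluster ends with fewer than 0.5
  expected subjects, the fit is returned with a `degenerate` warning flag
  rather than failing.

**Model selection.** K is chosen as the largest value in 1..k_max for which
every fitted cluster keeps at least `min_fraction` (default 10%) of the
group. On planted mixtures with compact, well-separated footprints this
recovers the true K (asserted for K\* = 2 at n = 200 and K\* = 3 at n = 150).
A genuine limitation, verified by systematic scans during design: when a
group is homogeneous (one pattern) or small, best-of-restarts EM can split
sampling noise into balanced sub-clusters that all pass the 10% floor, so
the rule over-selects; it is *not* a consistent estimator of K under the
independent-Bernoulli model. The analysis drivers show this honestly on the
25-subject phantom groups. Practitioners should read the selected K for
small groups with caution.

**Cluster expectations.** N_k = π_k N and E[V_k] = Σ_j µ_{k,j} (voxels; ml
via the voxel volume). Comparisons to printed integer counts use
round-half-away-from-zero.

**Model moments.** E[X] = Σ_k π_k µ_k, and on a voxel subset (≤ 500, the
cost is quadratic) Cov = Σ_k π_k [diag(µ_k(1−µ_k)) + µ_k µ_kᵀ] − E[X]E[X]ᵀ;
off-diagonals are generally nonzero for K > 1, which is precisely what the
mixture adds over the average method.

## From maps to sharp atlases

**Claiming.** A voxel is claimed by a territory when at least one cluster
satisfies µ + α√(µ(1−µ)) ≥ 1. For µ in (0,1) and α > 0 this is equivalent to
µ ≥ 1/(1+α²) — exactly 0.1 at the default α = 3 — and the claimed set is
non-shrinking in α. Claiming is evaluated on unclipped rates, so a
pre-clipping rate of exactly 1 is claimed at any α ≥ 0. Claim volumes are
coded 1 ACA, 2 MCA, 3 PCA, 4 VB, 5 overlap, 6 undefined (the published
3-territory coding extended with VB, as documented in the data-record
description).

**Overlap resolution.** Voxels claimed by several territories go to the one
with the largest µ_max; exact ties are broken by the fixed priority
MCA > PCA > VB > ACA (descending cohort frequency — deterministic, since no
tie rule is otherwise defined).

**Water-spreading.** Remaining unlabelled brain voxels take the label of the
metrically nearest labelled voxel (Euclidean distance scaled by voxel size
in mm, computed by per-label exact distance transforms so that exact ties
are visible and resolved by the same priority order). The result labels
every brain voxel; agreement with a brute-force nearest-label scan is exact
on small grids.

**Smoothing.** Boundary irregularities are regularized by a single-pass
majority (modal) filter in a spherical neighborhood (default radius 1
voxel), implemented as label-indicator convolutions with priority
tie-breaks. Only labelled voxels vote, so background never invades the
brain and no new label can appear. This deterministic filter stands in for
manual cartographic boundary editing, which is out of scope.

**Hierarchy.** Level-1 parcels merge to level-2 major territories through
the lookup scheme (id, acronym, description, level2_id; written as
tab-separated text). Anatomical subdivision is a pure label-intersection:
each (territory, anatomical-parcel) pair maps to a sub-label, unmapped
intersections keep the territory label, and labelled coverage is preserved
exactly.

**Certainty index.** CI_s = P_s / Σ_s P_s on the support (Σ_s P_s > 0); CI
rows sum to 1 there and are 0 outside. Per-ROI summaries report the mean CI
in percent over ROI ∩ support; ROIs without support are reported missing,
not zero.

## Registration QC

Three strips of a stated bandwidth (default 5 voxels; distances mm-scaled)
are built by exact Euclidean distance transforms: outside/inside strips of
the brain mask (OSBM/ISBM) and the outside strip of the lateral ventricles
(OSLV). For a deformed B0 volume: γ_OSBM is the fraction of OSBM voxels
with intensity > 0, γ_ISBM the fraction of ISBM voxels with intensity = 0,
γ_OSLV the fraction of OSLV voxels brighter than λ. The cutoff λ is taken
as mean − 0.5·sd of the deformed-B0 intensities inside the template
ventricle mask — a lower CSF-intensity bound, which is the reading that
makes γ_OSLV count bright CSF-like voxels spilling outside the template
ventricles; the rule is a pluggable callable so alternative definitions can
be swapped in. Empty strips yield missing ratios, not zeros. Registration
itself (and any deformation-parameter search over real data) is out of
scope; the metrics are validated on phantoms with exactly countable
misalignment.

## Synthetic study conditions

The phantom emulates the statistical structure the pipeline assumes, not
anatomy: an ellipsoidal brain (~10k voxels at 32³), a small interior
ventricle mask, and 2–4 contiguous angular-sector territories whose
boundaries are deliberately asymmetric under the x-flip. Per territory, K\*
clusters get ellipsoidal footprints at increasing depth along the sector
axis — one compact deep cluster (~20 voxels) and broader peripheral ones
(~50–110 voxels) — with rates decaying radially from 0.55 at the centre to
≥ 0.05 at the edge. The moderate peak rate is deliberate: empirical
lesion-frequency maps are far from deterministic, and near-deterministic
rates would make every mask a near-copy of its footprint (and make the
10%-floor selection rule pathologically over-select). Planted priors are
fixed per K\* (K=2 → 0.7/0.3, K=3 → 0.5/0.3/0.2, K=4 → 0.4/0.25/0.2/0.15),
keeping every planted cluster above the selection floor. The outermost
cluster of each multi-cluster territory is angled toward a shared sector
boundary so that adjacent cohorts genuinely overlap (a planted MCA–PCA
border zone); ACA keeps a single deep cluster, so its ratio maps are empty
on the phantom — territories only have border zones where lesions co-occur.

Cohorts are drawn exactly from the generative model (cluster ∼
Categorical(π\*), voxels ∼ Bernoulli(µ\*)), with a configurable fraction of
subjects mirrored to the right hemisphere to exercise the flip stage. The
phantom B0 is piecewise-constant (background 0, tissue 100, ventricles
200), integer-shifted with zero fill so mis-deformed voxels are exactly
enumerable, with Gaussian noise applied inside the object only (the
background of a deformed magnitude image is exactly zero, which the
intensity > 0 criterion presumes).

What the phantom does **not** emulate — and hence what passing tests do not
show about real data: spatially correlated lesion shapes (real infarcts are
connected blobs; the model draws voxels independently), registration error
fields, MR contrast and intensity artefacts, anisotropic clinical voxels,
anatomical territory shapes, and the manual editing steps of published
atlases. Problem sizes were chosen for seconds-scale runs: 16³ grids for
brute-force-oracle comparisons, 32³ with 25–200 subjects per territory for
the study drivers and recovery checks.

## Known limitations

- The minimum-cluster-fraction K-selection rule over-selects on homogeneous
  or small groups (see above); reported K for the 25-subject phantom groups
  varies with the seed.
- Dice between the sharp atlas and the phantom's sector partition is ~0.7–0.9,
  not 1: lesions spill across sector boundaries by design, and
  water-spreading follows the lesions, not the generating sectors.
- The certainty index inherits the average method's sensitivity to group
  imbalance: on the phantom, the large VB peripheral cluster dominates the
  small ACA group's sector, mirroring the caveat that CIs for
  under-represented territories should not be used to trace boundaries.
- All volumes must share one grid; no resampling is provided.
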