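# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Coordinate and file conventions

Streamline coordinates are **always world millimetres** in memory; voxel
indices appear only inside ROI membership tests and metric sampling. TCK
files are written as little-endian float32 (`Float32LE`) with NaN-triplet
separators and an Inf-triplet terminator; readers accept both endiannesses
and float64. A declared/actual streamline-count mismatch is a warning (the
actual count wins); a missing magic line is a format error; a missing
terminator is a corrupt-file error. NIfTI volumes go through nibabel; when
qform and sform disagree the sform is preferred and a warning logged.
Gradient tables are read in the FSL (row bvals + 3-row bvecs) and MRtrix
(4-column) dialects; non-zero directions are renormalised, and shells are
grouped with a ±50 s/mm² tolerance because nominal b-values jitter in real
schemes.

## Phantom

The phantom is schematic geometry, not anatomy: 13 axis-aligned boxes on a
48³ grid of 2 mm voxels (configurable, ≥ 40 voxels per axis, even
left–right dimension). The mid-sagittal exclusion plane is a one-voxel
slab; left/right ROI pairs are exact mirror images across it; superior,
middle and precentral frontal boxes lie anterior to the AC coronal plane,
the parietal box posterior to the PC plane, the temporal box
posterior–inferior, and the posterior middle-frontal box (`MFg-P`) strictly
between the two commissural planes. The hand-drawn ROIs of a real protocol
have no knowable geometry; boxes keep every membership decision exactly
testable.

Bundles are cubic splines through jittered waypoint centroids (control
points get isotropic Gaussian jitter, default SD 1 mm), resampled at
~1.5 mm with the exact control points retained as vertices, and extended
6 mm beyond the terminal ROIs. The default mix holds the six SLF-like
bundles (150 streamlines each) plus two contaminants (100 each): a callosal
bundle that satisfies the left SLF II inclusion pair but crosses the
mid-sagittal slab, and an arcuate-like bundle that satisfies the left
SLF III pair but dives into the temporal box — each contaminant is removed
by exactly one "NOT" ROI, so both exclusion clauses are load-bearing.

## Streamline selection

"AND" means at least one tested point inside each include ROI, in any
order along the streamline; "NOT" means no tested point in any exclude
ROI. Tested points are the vertices plus interpolated points at most half
the smallest voxel edge apart (supersampling on by default — without it a
long segment can jump clean across the one-voxel mid-sagittal slab).
Point→voxel uses the nearest-voxel convention `i = floor(c + 0.5)` on the
continuous index `c = A⁻¹p`, i.e. voxel *i* owns `[i−0.5, i+0.5)`; points
outside the grid are simply outside every ROI. Streamlines satisfying two
bundle rules are reported in both (with a warning); an optional post-filter
resolves dorsal/ventral overlaps by mean z-coordinate, off by default.

## Multi-shell signal model

Per voxel the normalised signal is

    S/S0 = (1 − f_iso) [ ν · A_intra + (1 − ν) · A_extra ] + f_iso · exp(−b d_iso)

with ν the intra-neurite fraction (NDI), `A_intra` a stick dispersed by a
Watson distribution about the mean direction μ (concentration κ, with
ODI = (2/π)·arctan(1/κ)), and `A_extra` a zeppelin whose tensor is the
Watson average of an axially symmetric tensor with tortuosity
`d_perp = d_par (1 − ν)`. Sphere integrals use 64-point Gauss–Legendre
quadrature in cos θ and a 24-point periodic rule in azimuth, accurate to
better than 1e-6 against the erfi closed form for κ ≤ 128 (tested).
Defaults `d_par = 1.7e-3 mm²/s`, `d_iso = 3.0e-3 mm²/s` are the
conventional fixed values of the model and configurable. Rician noise is
applied per channel as |S + complex Gaussian| with σ defined on the b = 0
signal. The packaged acquisition scheme mirrors the neonatal study's
shells: b = 0/400/1000/2600 s/mm² with 20/64/88/128 Fibonacci-sphere
directions.

## Model fitting

**Tensor.** Log-linear weighted least squares: OLS start, one reweighting
pass with squared-predicted-signal weights (whether the original analysis
used OLS or WLS inside its tooling is not stated; WLS is the stable,
standard choice). Fitting uses only the b = 0 and b = 1000 shells.
Non-positive signals are excluded voxel-wise (error if fewer than 7 usable
volumes remain); negative eigenvalues are clamped to zero for metric
computation and counted. FA is clamped into [0, 1] and defined as 0 for an
all-zero tensor. Metrics: MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2,
FA = √(3/2)·‖λ − MD‖/‖λ‖.

**NODDI.** The toolbox named by the original analysis specifies no
algorithm, so the fit is a transparent two-stage search against the exact
forward model above: a coarse grid (ν and f_iso from 0 to 1 in steps of
0.05; ODI from 0.05 to 1 in steps of 0.05) followed by bounded Nelder–Mead
refinement (xatol 1e-4, ODI floor 0.01). The Watson kernel depends on ODI
only, so it is evaluated once per ODI node and the (ν, f_iso) plane is
swept algebraically. The mean direction μ is taken from the principal
eigenvector of a tensor fitted on the b ≤ 1000 shells and is not
optimised. Fits with f_iso ≥ 0.95 are flagged degenerate (ν and ODI are
unidentifiable in pure free water). Single-shell input is refused.

## Tract means and the cohort table

Values are sampled at streamline vertices by trilinear interpolation in
continuous index space (nearest-neighbour available); vertices whose
interpolation stencil leaves the grid yield NaN and are dropped and
counted — never zero-filled, which would bias means toward zero. The tract
mean is point-weighted (a plain average over all sampling points of all
streamlines, so longer streamlines weigh more); a streamline-weighted
variant is available. The cohort table carries per-hemisphere and
left/right-averaged columns; the L/R average is the arithmetic mean of the
two tract means. Subjects with an empty bundle get NaN cells and a log
entry.

## Maturation statistics

The per-branch adult reference is the sample mean and covariance
(n − 1 denominator) of the six-metric vectors of ≥ 8 adults,
eigen-decomposed. M is computed in the eigenbasis
(Σᵢ((x−μ)·vᵢ)²/λᵢ) with the direct-inverse form kept as a cross-check;
the two agree to machine precision and rescaling any metric in both data
and reference leaves M unchanged (tested to 1e-8, including general
invertible remaps of the metric space). **Degeneracy is judged on the
correlation matrix** (condition number > 1e10 → refuse, naming the most
collinear metric pair): the metrics span five orders of magnitude
(diffusivities in mm²/s against unit-free fractions), so the covariance
condition number is huge for perfectly healthy references, while the
correlation condition number is scale-free — consistent with M itself
being scale invariant.

Tests: one-sample t for lateralization indices; Pearson trends with
t = r√(n−2)/√(1−r²), df = n−2, and a significance flag at α = 0.05/6 =
0.008; pooled-variance two-sample t (df = n₁+n₂−2) with Bonferroni
p-multiplication for reported contrast p-values and Cohen's d signed
(adult − neonate)/pooled SD with |d| alongside; Wilcoxon signed-rank with
Pratt zero handling, exact null for n ≤ 25 when the differences carry no
zeros or ties, normal approximation with tie and continuity corrections
otherwise (verified against exhaustive 2ⁿ sign-flip enumeration); Spearman
rank for M vs age. Branch comparisons use α = 0.05/3 ≈ 0.01. The
Mahalanobis vectors use left/right-averaged metrics, consistent with
averaging after the null lateralization result.

## Synthetic cohorts

The generator draws 40 neonates (ages uniform on 37–44 weeks PMA by
default; a Gaussian 39.89 ± 2.08 option exists) and 40 adults (uniform
22–35 years). Uniform ages maximise trend-estimation power. Each tract
metric is

    value = intercept(bundle) + slope · (age − 40 wk) + loading · u + ε

with u a per-subject shared "maturation" factor (inducing realistic
cross-metric covariance), ε independent noise, and additional small
left/right fluctuation. Adult values use distinct means and zero slope.
Neonatal intercepts are derived from the adult means minus per-bundle
**maturation-lag fractions** (0.55 / 1.0 / 0.6 for SLF I/II/III) times a
per-metric maturation span (large for NDI, FA, MD, AD, RD; near zero for
ODI). The lags place the middle branch roughly twice as far from the adult
reference in covariance-whitened units as the other two — the asynchrony
structure the branch comparison is designed to detect — and give whitened
offsets of ≈ 17 / 32 / 19. Slopes (per week: NDI +0.010, FA +0.007,
MD −0.020e-3, RD −0.025e-3, AD −0.004e-3, ODI 0) move neonates toward the
adult state, so M shrinks with age. All values are synthetic choices, not
measured ones: the real study's branch-wise effect sizes are not public,
so passing tests demonstrate that the pipeline detects the planted
structure, not that these numbers describe real neonates.

Volume-level generation paints each bundle's corridor with the subject's
tract value plus voxel noise over a CSF-like background. The end-to-end
study driver (`pipeline.run_synthetic_study`) gives **every subject their
own tractogram realisation** and paints along the subject's own bundles,
as in a study with per-participant tractography: with a single shared
phantom, the frozen left/right asymmetries of one jitter draw repeat in
every subject and masquerade as systematic lateralization. Corridors are
dilated 3 voxels past the vertex cloud so no interpolation stencil touches
background (edge mixing is another spurious-lateralization source). The
shared-anatomy generator (`simulate_cohorts`) remains available and
deterministic for component testing.

## Problem sizes

The shipped analyses and tests use the study's cohort sizes (40 + 40),
1,100-streamline default tractograms (10,000 for the selection-oracle
check), the full 300-volume four-shell scheme, 27–75-cell NODDI recovery
grids at SNR 30, 100-replicate Monte-Carlo checks of the branch-asynchrony
pattern, and 10,000-replicate null calibrations — sizes at which every
stochastic check is stable under reseeding while the whole suite stays
quick on a single CPU.

## Known limitations

- Box ROIs and spline bundles are caricatures; no crossing fibres, no
  partial-volume gradients, no registration error, no motion or
  susceptibility artefacts.
- The NODDI fit holds μ fixed at the tensor eigenvector and omits the
  full analytic Watson solution; at very high dispersion plus noise the
  direction estimate degrades, which the recovery grids absorb but real
  crossing-fibre voxels would not.
- Cohort effect sizes are synthetic (see above); only qualitative
  patterns — trend directions, flat AD/ODI, branch ordering, M shrinking
  with age — are meaningful points of contact with the real study.
- Tractography itself (FOD estimation, streamline propagation) is out of
  scope; the pipeline consumes or synthesises tractograms.
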