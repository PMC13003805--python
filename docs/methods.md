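# Methods

## Problem and model

A volume of interest (VOI) of vascularized tissue is characterized here by
its cerebral blood volume fraction (CBV) and its vessel size distribution
(VSD): the vessel-volume-fraction-weighted histogram of per-vessel radii on
1 µm bins (40 bins, 0–40 µm), max-normalized.  An intravascular iron-oxide
contrast agent creates a susceptibility difference Δχ between blood and
tissue; the induced microscopic field inhomogeneity dephases diffusing water
spins, and the shape of the resulting multi-echo gradient/spin-echo
(GESFIDE) decay carries information about both how much vasculature there is
and how it is distributed over radii (gradient echoes are sensitive to all
perturber sizes, spin echoes peak for capillary-scale perturbers).  The
package inverts this relationship with a learned estimator and provides the
classical alternatives (dictionary matching, analytical vessel size index)
as comparators.

## Synthetic vasculature

Networks are random straight tubes (optionally with Y-branches and
sub-chord lengths) placed uniformly in position and orientation until the
rasterized blood volume hits a target within a relative tolerance (default
10%); candidates that would overshoot are rejected and redrawn, and an
unreachable target raises rather than silently clipping.  Rasterization is
the center-in rule — a voxel belongs to a tube iff its center lies within
the radius of the tube axis — applied directly (binary masks) or on a
supersampled lattice followed by block averaging (partial-volume occupancy
for coarse simulation grids).  Overlap voxels belong to the larger-radius
tube, ties to the lower index, so per-tube vvf values partition the CBV
exactly.  The optional light-sheet-like rendering draws vessels wider than a
threshold as bright walls with dark lumens (wall stains mark only the vessel
wall), blurs with a Gaussian point-spread function, and adds Gaussian noise.

Known limitations of the generator as a stand-in for real microscopy data:
tubes are straight (no tortuosity), branching is statistical rather than
hemodynamic, and radius distributions are parametric (lognormal or
two-component lognormal mixtures).  Passing tests therefore demonstrate the
correctness of the measurement/simulation/estimation machinery and the
recoverability of CBV/VSD within this family, not organ-level realism.

## Morphometry cascade

Contrast-limited adaptive histogram equalization (scikit-image), global Otsu
thresholding (threshold recorded in provenance), morphological closing with
a spherical kernel — radius 1 µm by default, floored at one voxel on coarser
grids — followed by largest-connected-component extraction; the volume
border is reflect-padded during closing so vessels cut by the VOI face close
like interior ones.  The skeleton comes from 3D thinning; voxels with more
than two skeletal 26-neighbors are junctions, the junction-free skeleton is
labeled into branches, junction voxels join their lowest-labeled incident
branch, and branches shorter than 3 points merge into their longest
neighbor.  Thinning can legally collapse a perfectly translation-symmetric
component (e.g. an exactly axis-aligned digitized cylinder) to nothing; such
components fall back to their maximal-interior-depth ridge as a centerline.

The radius at each skeletal point is estimated by star lines: 37
Fibonacci-distributed ray pairs (configurable), each ray marched on the
trilinearly interpolated mask in quarter-voxel steps with the 0.5-crossing
located by linear interpolation; the radius is half the minimum ray-pair
chord.  Thirteen ray pairs — a common choice — leave worst-case obliquity
errors above half a voxel at large radii (the minimum chord overestimates by
1/sin α when the best ray pair is α off perpendicular), so the denser
default is used and validated against a Euclidean distance-transform oracle
(±0.5 voxel on digitized cylinders of 2–11 voxel radius).  Per-vessel vvf
assigns every mask voxel to the branch of its nearest skeletal point, so
Σ vvf equals the CBV exactly.  Two mean radii are deliberately distinct: the
*true* mean is the unweighted average of per-vessel radii, while the mean
radius derived from a VSD is the vvf-weighted average of bin centers
(i + 0.5 µm); both conventions appear in the field and both are provided.

## GESFIDE simulation

The susceptibility map is Δχ inside vessels (scaled by 4π under the
`cgs_4pi` convention flag; the default `si_ppm` uses Δχ directly, the
reading consistent with the ferumoxytol calibration arithmetic of
1 ppm ↔ 0.086 mg Fe/mL at a QSM slope of 11.6 ppm·L/g Fe).  The field
offset is ΔB_z = B0·IFT[(1/3 − k_z²/|k|²)·FT[χ]] with physical wavenumbers
and the k = 0 term zeroed (the mean shift is absorbed into the rotating
frame); the domain is periodic.  Spin evolution solves the Bloch-Torrey
equation with an explicit 7-point-Laplacian diffusion update and exact local
phase accrual per step; the 180° pulse is an ideal complex conjugation at
the refocusing time (60 ms, so the spin echo forms at 120 ms); the signal is
the magnitude of the mean magnetization.  Intrinsic T1/T2 decay is excluded
because it cancels in the post/pre ratio; the pre-contrast arm is therefore
exactly 1 at every echo.  The time step obeys the stability bound
D·dt/h² ≤ 1/6, is capped at 0.5 ms by default, and is snapped to divide the
echo/refocusing time grid; a user-supplied dt violating stability is
refused.  Oracles: zero field → unit signal; D = 0 → perfect spin-echo
refocusing; uniform gradient → the closed-form cubic-phase decay
exp(−γ²G²Dt³/3) of the local magnetization within 2%; infinite cylinders
parallel/perpendicular to B0 → the known uniform/dipolar fields (the
perpendicular pattern within 5% at 2–3 radii on a partial-volume
cross-section).

ΔR2* is computed from the ratio at the 10 and 40 ms gradient echoes as
ln(ratio(10)/ratio(40))/0.030 s and ΔR2 from the spin echo as
−ln(ratio(120))/0.120 s — the standard log-ratio estimators.

## Estimator

CBVE: 18 → 2048→1024→512→256→128→64→16→8 → 1, ReLU throughout including the
output (CBV ≥ 0).  VSDE: 19 (18 echoes + predicted CBV) →
2048→1024→512→256→128→64 → 40 with a sigmoid output per bin (VSD bins in
(0,1)).  He initialization, Adam with β₁ = 0.5, β₂ = 0.9, learning rate
10⁻⁴, MSE loss, batch size 256.  "Trained until convergence" is
operationalized as early stopping on validation loss (patience 20 epochs,
max 500 by default; the scaled study uses 120/15 as its desk-scale budget).
Stage two freezes the CBVE byte-for-byte and feeds its prediction as the
19th VSDE input (a teacher-forcing flag substitutes the true CBV during
training only).  One numerical safeguard: because ratio curves are strongly
correlated across samples, a rectified output unit can start with a negative
pre-activation for *every* sample and receive zero gradient forever; at the
start of training the output bias is shifted so the median pre-activation
matches the median target (deterministic, washes out during training).
Records with CBV < 1% or > 40% are removed before splitting; the remainder
shuffles with the split seed into floor(8N/10)/floor(N/10)/remainder, which
reproduces the 25,056/3,132/3,132 bookkeeping at N = 31,320.

The networks are implemented directly in numpy (float32 weights, explicit
forward/backward/Adam); training is bit-reproducible for a fixed seed on a
given platform.

## Baselines

Dictionary matching scores a query against every training curve with
R² = 1 − SS_res/SS_tot (SS_tot about the query mean), returns the labels of
the argmax (ties to the lowest index), and falls back to least
sum-of-squares for zero-variance queries.  VSI_MRI uses the printed
constants ADC = 1 µm²/ms, B0 = 3 T, Δχ = 10⁻⁶ with the proton gyromagnetic
ratio γ = 2.675×10⁸ rad s⁻¹ T⁻¹ — a published value of
4.258×10⁻⁷ s⁻¹T⁻¹ is dimensionally implausible for this formula and is not
used — and resolves units through SI so the result is in µm.  VSI_Histo
renormalizes the VSD to unit sum and evaluates the −3/2 power mean over bin
centers; bin 0 contributes at 0.5 µm rather than being dropped.  At the
221 µm VOI scale the analytical VSI assumptions (many sparse, uniform,
randomly oriented cylinders; static dephasing) fail, so only directional
consistency between VSI_MRI and vessel size is expected, not agreement —
the worked simulation example shows VSI_MRI well below VSI_Histo.

## Evaluation conventions

The Bhattacharyya coefficient renormalizes both histograms to unit sum
(the stored VSDs are max-normalized, not probability vectors), giving
BC ∈ [0,1] with BC(p,p) = 1.  MRE is the mean absolute relative error in
percent.  Bland-Altman reports the mean of true − predicted, ±1.96·SD
limits, and the percentage of differences within the limits.  SNR is on the
amplitude scale: σ = RMS(signal)·10^(−SNR/20), applied to the ratio curves
(a flag allows noising the two arms separately).  Parametric maps broadcast
per-tile scalars to all voxels of non-overlapping tiles; edge remainders
smaller than a tile are dropped.

## The scaled replication study

Study conditions (`experiments.StudyConfig`): 5,000 VOIs of 221.4 µm
isotropic extent (the physical size of a 123³ lattice at 1.8 µm); networks
generated on 64³ lattices; susceptibility occupancy rendered onto 32³
simulation grids by 4× supersampled partial-volume rasterization (effective
1.73 µm sampling); target CBV uniform in [1.5%, 38%]; per-VOI radius
distributions lognormal with median log-uniform in [3.5, 10] µm and log-SD
uniform in [0.25, 0.55] (truncated to [1.75, 20] µm), with half the VOIs
drawing from a two-component mixture of such lognormals — real cortical
VOIs at this scale show heterogeneous, often multimodal VSDs, and this
heterogeneity is precisely what separates a learned estimator from
finite-dictionary matching; tube lengths 35–100% of their chord, 15%
Y-branching.  Simulation uses dt = 2.5 ms (well inside the stability bound
at the 6.9 µm simulation voxel); training labels are measured on the same
supersampled occupancy the simulator sees.  Training runs at most 120
epochs with patience 15.  These sizes are the package's desk-scale choice;
every knob is configurable upward.

Ground-truth labels come from the generator (exact radii, occupancy-measured
CBV/vvf), not from running morphometry on each VOI; the equivalence of the
two label paths is pinned separately by the VSD round-trip test
(BC ≥ 0.9 between generative truth and the full measurement cascade on a
123³ mask).

## Degenerate inputs and tie-breaks

Empty masks propagate as empty results (zero CBV, empty skeleton, all-zero
VSD) rather than errors; all-zero VSDs are rejected where a mean or VSI is
mathematically undefined.  Constant intensity volumes segment to an empty
mask with a warning.  Radii ≥ 40 µm clip into the last VSD bin with a
warning.  All stochastic components consume explicit integer seeds;
identical seeds give bit-identical networks, datasets, and training
histories on a given platform.
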