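# Methods

## Model of a cortical interruption

The object of interest is a connected non-bone channel through the
cortical shell joining the periosteal (outer) to the endosteal (inner)
surface. Operationally the cortex is not segmented anatomically: a
constant-thickness rind of the filled periosteal contour stands in for it
(0.33 mm by default, i.e. 4 voxels on the 0.082 mm grid and 18 voxels on
the 0.018 mm grid, matching the average cortical thickness of
metacarpophalangeal joints). This is robust but introduces a known
systematic error: where the true cortex is thinner than the mask, marrow
voxels inside the rind join the channel and inflate the measured size;
where it is thicker, the size is underestimated.

Detection is purely morphological. With `k` dilation steps the bone phase
is grown `k` times by the face-connected cross; void that survives and
still bridges the two boundaries is geodesically reconstructed inside the
original void and labeled. A gap of exactly `2k` voxels is closed from
both sides, so the enforced minimum diameter `2·k·voxel` is an exclusive
bound. Two conventions are fixed and used everywhere: the per-step
structuring element is the 6-neighborhood cross (so `k` steps span the L1
diamond of radius `k`; a Euclidean-ball mode exists as an option), and
connectivity for components and boundary adjacency is 26-neighborhood.
Components are counted after reconstruction, so seeds that reconstruct
into one region count once.

Near the cut-off, detection of a rasterized circular channel depends on
the rasterization phase: a diamond of radius `k` is guaranteed to fit for
diameters ≥ `2k + 1.5` voxels and guaranteed not to fit for ≤ `2k`
voxels; between the two, the answer depends on where the hole axis falls
relative to the lattice. Validation phantoms therefore place hole
diameters outside this half-open marginal band.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| cortical mask thickness | 0.33 mm | rind depth; rounds to 4 / 18 voxels on the two grids |
| dilation steps `k` | 1–3 (clinical grid) | exclusive minimum diameter `2·k·voxel` |
| reference cut-off | >0.10 mm (k=3 at 0.018 mm) | fixed gold-standard detection diameter |
| overlap criterion | 20 clinical voxels (0.011 mm³) | minimum voxel overlap for a cross-modality match |
| fine-grid threshold | 247‰ of max possible value | after Gaussian σ=0.8, support 1 voxel |
| coarse-grid threshold | 400‰ of filtered max | after Laplace–Hamming filtering |
| Laplace–Hamming cutoff | 0.8 × Nyquist | low-pass edge of the filter window |
| contour closing radius | 0.41 mm (pipeline) | resolution-independent periosteal gap bridging |

## Design choices where the design was open

**Periosteal contouring.** The original operator-corrected contouring
procedure is not published in algorithmic form; the stand-in here is
deterministic: isodata threshold on the raw histogram (applied to a
1-voxel Gaussian pre-smooth for noisy input; binary input is not
smoothed), slice-wise Euclidean-disk closing by distance transforms,
largest 26-connected component, slice-wise hole fill, then slice-wise
convex hull iterated to a fixpoint. Two of these steps deserve
justification. First, closing alone cannot reliably seal an interruption
wider than the cortex is thick: background "creeps" through the open
channel during the erosion half of the closing, with a safety margin of
only about half the wall thickness — which discretization consumes. The
convex hull closes any channel regardless of width; peri-articular
cross-sections are near-convex, and markedly concave anatomy should use a
manual contour instead. Second, the contour must hug the bone surface: a
contour inflated by even one voxel leaves a void ring inside the
periosteal boundary that 26-connects otherwise separate interruptions
into one component and corrupts every count.

**Laplace–Hamming filter.** The manufacturer pipeline's exact constants
are not public. The implementation multiplies the spectrum by a separable
Hamming low-pass window times a Laplacian sharpening term
`1 + s·|f|²/f_N²`. The window cutoff defaults to 0.8 × Nyquist: measured
on noise-free phantoms, a 0.4 × Nyquist window erases channels below
~0.3 mm — structures the 0.082 mm acquisition itself resolves — whereas
0.8 preserves the detection ladder while still suppressing out-of-band
noise. All constants are configuration.

**Step selection for nominal cut-offs.** Published cut-off labels are
rounded (">0.33 mm" for an enforced 0.328 mm or 0.324 mm), so
`choose_steps_for_diameter` accepts a 5% undershoot of the nominal target
before moving to the next integer step count; this reproduces every row
of the two-modality protocol table.

**Interruption surface.** No closed-form definition is published; here
the per-component surface is the number of component voxels lying in the
periosteal boundary layer times the voxel face area — the cross-section
of the cortical opening as seen from outside. Joint totals are additive
over components.

**Matching numerators.** PPV uses matched clinical-side detections over
all clinical-side detections; sensitivity uses matched reference lesions
over all reference lesions. An A-component overlapping two B-components
therefore counts once in the PPV numerator and twice on the reference
side.

**Registration.** The metric defaults to mean squares on Gaussian-
smoothed, isodata/Otsu-binarized bone maps, making the two modalities'
intensity scales irrelevant; mutual information on grayscale is an
option. The optimizer is multi-resolution Powell with full metric
sampling: long bones are nearly axisymmetric, so the axial rotation is
weakly determined, and gradient descent either stalls on it or overshoots
into a spurious symmetry basin; Powell's per-parameter line searches
recover an 8°/0.8 mm misalignment to ~0.05°/0.01 mm on phantom pairs.
Everything is deterministic — no stochastic sampling.

**Label downscaling.** Fine-to-coarse resampling assigns each coarse
voxel the majority fine label within its footprint, background included,
ties to the lowest label; coarse-to-fine or same-scale uses nearest
neighbor. Components much smaller than the overlap criterion can vanish
in downscaling, which is why matching accepts the pre-resampling
reference count as the sensitivity denominator.

**Statistics.** ICC(2,1) (two-way random effects, absolute agreement,
single measure) is computed from the two-way ANOVA mean squares with the
Shrout–Fleiss / McGraw–Wong F-bound confidence interval
(Satterthwaite-approximated denominator degrees of freedom, the SPSS
construction), fixed at 95%. It is cross-checked against an independent
implementation in the tests, never delegated to one. The Wilcoxon
signed-rank test drops zero differences, uses the exact null distribution
for up to 25 informative tie-free pairs and the tie-corrected normal
approximation otherwise; two-sided throughout. Qualitative ICC labels
("almost perfect" ≥ 0.81, etc.) are presentation only.

## The phantom: what it emulates and what it does not

The generator rasterizes an analytic object — tube, spherical shell or
slab, with cylindrical holes normal to the local surface — at both voxel
sizes. Intensity is two-level (background 0, bone 1000; the maximum
possible value is fixed at 1000 so per-mille thresholds are literal).
Partial volume comes from supersampled box-averaging
(`supersample_factor³` points per voxel, default 2³); an optional
Gaussian point-spread blur models the scanner's resolution being coarser
than its voxels (the in-vivo modality resolves ~130 µm on an 82 µm grid,
σ ≈ 0.055 mm). Noise is additive Gaussian from a seeded generator —
equal seeds give bit-identical volumes. The two outputs are related by a
stored rigid transform.

Default study conditions: outer radius 1.2 mm and wall 0.35 mm
(phalangeal scale), noise σ = 8% of the bone value (clinical-scan-like
contrast-to-noise), supersample factor 2, and a misalignment of a few
degrees/tenths of a millimetre where an experiment exercises
registration. Validation hole sets straddle each cut-off while avoiding
the phase-dependent marginal band described above.

Not emulated: trabecular texture, beam hardening, PSF anisotropy,
density calibration, and motion artifacts. Passing phantom tests
therefore demonstrates the correctness of the morphology, matching and
statistics — not segmentation robustness on pathological in-vivo data.

The thin-cortex fixture (`thin_cortex_phantom`) thins the tube wall to
~0.10 mm over a sector with the PSF model enabled: at the coarse pitch the
blurred, partial-volumed wall drops below the segmentation threshold and
a false interruption appears, while the fine grid keeps the wall intact —
the resolution artifact that motivates raising the minimum diameter.

## Numerical conventions and degenerate inputs

Arrays are (z, y, x), voxel-center 0-indexed, isotropic spacing asserted
on load (anisotropy is an error, not resampled). Threshold ties classify
as bone (`>=`). Cortical-mask erosion treats beyond-volume as inside, so
cropped anatomy grows no artificial rind at the field-of-view faces.
All-zero volumes raise an empty-contour error; a `k` large enough to
close every channel returns a valid empty set; zero between-joint
variance makes the ICC NaN with a warning; all-zero paired differences
give Wilcoxon p = 1 with a warning; zero detection counts make PPV and
sensitivity undefined errors rather than zeros.

## Problem sizes

Phantom experiments run at the true voxel sizes (0.082/0.018 mm) on a
~2.4 mm tall, 1.2 mm radius tube — about 30³ coarse and 160²×134 fine
voxels — which keeps a full two-modality experiment (generation, two
detections, registration, matching, statistics) near fifteen seconds.
Oracle-equivalence checks run on one hundred ≤20³ random grids against a
brute-force shift-loop reference implementation.

## Known limitations

The published reliability statistics of the original anatomic-specimen
study (19 joint pairs) cannot be recomputed here because those scans are
not deposited; the pipeline reproduces the protocol's parameter-derived
quantities exactly and its qualitative behavior (precision/recall
trade-off with the cut-off, thin-cortex false positives) on phantoms.
The constant-thickness mask error and the surface definition above are
the two places where absolute numbers depend most on convention.
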