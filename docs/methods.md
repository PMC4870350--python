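# Methods

## The detection model

The detector assumes microcalcifications (MCs) appear as compact bright
deposits on a slowly varying, noisy background, grouped in clusters of a few
millimeters, while the main confounders are elongated (vessels, fibrous
strands) and planar (tissue interfaces, interplane artifacts) bright
structures. Three measurements drive the chain:

- **Blob objectness** from the eigenvalues λ1 ≤ λ2 ≤ λ3 of the
  Gaussian-smoothed Hessian. Derivatives are taken in physical units
  (grey-level·mm⁻²) with per-axis smoothing σ/spacing, so the strongly
  anisotropic DBT grid (0.1 mm in-plane, 1 mm between slices) is handled
  uniformly. The response is gated to bright structures (λ3 ≤ 0) and is the
  product of a shape factor and a structureness factor
  `1 − exp(−(λ1²+λ2²+λ3²)/2γ²)`.
- **Band-pass SNR** per slice: mean over the 3×3 core minus mean over the
  annulus between the 7×7 and 15×15 windows (kernel weights +1/9 and
  −1/176, total exactly 0). The guard ring keeps pixels adjacent to a
  candidate out of its own background estimate. Negative responses carry no
  MC evidence and are clamped to 0.
- **SNR3D**, a local variance-over-mean statistic of the SNR field
  (a quasi-Fano factor). Bright compact structure inflates local variance
  much faster than the local mean, so the ratio spikes at MCs.

Candidates come from connected components: seed objects from the MOR field
(objectness × max-pooled SNR) thresholded to a target count of ~500, MC
candidates from SNR3D > 3.2. Seeds act as cluster centers; MC candidates
within 5 mm (centroid-to-centroid, mm coordinates) become members. The rule
cascade then eliminates clusters with < 9 member voxels or < 2 other seeds
within 5 mm, merges the overlapping bounding cubes of survivors, and keeps
merged cubes with ≥ `min_cube_mc_count` candidates and
≥ `min_cube_mc_volume_mm3` of candidate volume. Scoring against truth boxes
uses the strict overlap-volume > 0 criterion, and FROC analysis sweeps the
detection score (the summed member voxel count of the contributing
clusters — the same quantity the content rules threshold, so any monotone
relabeling of it yields the same curve).

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| subsample factor | 10 | – | ×10 in-plane max-pool; block max preserves point-like peaks |
| α (shape sensitivity) | 0.1 | – | standard blobness sensitivity; shape factor saturates for spheres |
| γ (structureness scale) | 3.0 | grey·mm⁻² | meaningful because phantoms normalize background noise σ to 1 |
| scales σ | 0.5, 1.0, 1.5 | mm | sub-voxel to ~3-voxel blobs on the ≈1 mm pooled grid |
| band-pass M1/M2/M3 | 15/7/3 | full-res px | 1.5/0.7/0.3 mm windows at 0.1 mm pitch |
| seed target | 500 | objects | high threshold keeping only the strongest MOR components |
| SNR3D window | 9×9×3 | voxels | ≈0.9×0.9×3 mm neighborhood on the anisotropic grid |
| SNR3D threshold | 3.2 | – | fixed binarization of the variance/mean field |
| cluster radius | 5.0 | mm | clinical MCC association distance |
| member-voxel rule | ≥ 9 | voxels | "less than 9 eliminates", boundary inclusive |
| neighbor-seed rule | ≥ 2 | seeds | corroborating seeds, own seed excluded |
| cube content rule | ≥ 80 / ≥ 140 | count / mm³ | clinical-scale defaults, resolution independent |
| fp_max | 10 | FP/volume | FROC partial-area bound |

`PipelineConfig.phantom_profile()` rescales the cube-content rule to the
phantom's statistics: a phantom cluster carries 8–15 MC analogues (versus
thousands of candidates per clinical volume), so the count floor is 4 — half
the smallest cluster, tolerating detection misses — and the volume floor
0.3 mm³ (4 candidates of ~8 full-resolution voxels at 0.01 mm³ each). These
are properties of the phantom population, fixed a priori, not tuning knobs.

Two readings of ambiguous algebra are shipped behind switches, defaults
chosen for internal consistency:

- **Objectness shape factor.** `as_printed` uses λ1²/(2α²λ2λ3), which tends
  to 1 as λ3 → 0⁻ and therefore *also* enhances lines; kept for fidelity.
  `blobness_corrected` (default) uses the conventional
  smallest-over-largest ratio λ3²/(2α²|λ1λ2|), which vanishes identically
  for ideal lines and planes — this is what makes spherical enhancement
  actually selective, and the default pipeline uses it.
- **SNR3D form.** `variance_over_mean` (default, the literal ratio σ²/m) or
  `std_over_mean` (the conventional coefficient of variation; scale
  invariant, which also makes a fixed 3.2 threshold less portable across
  grey-level scales).

## The phantom generator

Phantoms emulate the *statistics the detector measures*, not anatomy:

- background: correlated unit-σ noise (in-plane smoothed, renormalized),
  flat, or low-frequency gradient; a +10 DC offset keeps local means
  positive;
- MC analogues: isotropic Gaussian blobs, FWHM 0.2–0.8 mm, in clusters of
  8–15 within a 4 mm radius, 3 clusters per positive volume; peak contrast
  12 × noise σ *after* the depth blur;
- distractors: Gaussian-profile cylinders (FWHM 0.5 mm) transiting the full
  field of view in-plane, and a Gaussian slab, at comparable contrast.
  Fibers cross the whole volume deliberately: a segment ending inside the
  volume presents a point-like tip, which is a blob — a different object
  class than the line the distractor is meant to model;
- depth artifact: Gaussian blur along z (σ 1.5 mm), the simplest analogue of
  the interplanar smearing that limited-angle reconstruction produces.

Two numerical points matter. First, blob depth profiles are *integrated over
each slice interval* (erf differences), not point-sampled: a 0.3 mm object
point-sampled on a 1 mm slice grid would appear or vanish depending on its
sub-slice position. The profile is normalized so the post-blur peak equals
the nominal contrast, making `mc_contrast` the conspicuity in units of final
noise σ. Second, noise and signal are depth-blurred separately and the noise
alone is renormalized to unit σ, so thresholds stated in noise units (3.2,
γ = 3.0) mean the same thing in every phantom.

What passing phantom tests shows: the chain discriminates compact blobs from
lines/planes and noise, associates them into clusters, and the rule cascade
removes isolated responses, at the contrast and density regime configured
above. What it does not show: performance on anatomic backgrounds
(structured tissue texture is far richer than correlated noise), on the
clinical detector's grey-level statistics, or at clinical candidate
densities (the clinical-scale 80/140 content thresholds are never exercised
end-to-end here).

## Numerical choices

- All convolutions use reflective padding — no rim responses that would
  spawn spurious seeds.
- Hessian: smooth first, then central differences ([1,−2,1]/h² diagonals,
  two-pass [−½,0,½]/h mixed terms); eigenvalues from `eigvalsh` (ascending).
  Verified against the closed form for a smoothed Gaussian blob to 10⁻³
  relative.
- The band-pass response is computed through three separable box means
  (algebraically identical to the explicit kernel; verified to 10⁻¹⁰).
- `threshold_for_count` uses a deterministic coarse-to-fine grid search
  (4 rounds × 17 points) rather than bisection: the component-count versus
  threshold landscape is non-monotone (lowering the threshold both reveals
  and merges components) and on dense noise a bisection can walk away from
  the target. Ties prefer the higher threshold; an unreachable target
  returns the nearest count with a warning.
- ε guards: the SNR3D division uses 10⁻¹² × max(field); the objectness
  shape ratio defines 0/0 as 0 (no structure) and x/0 with x > 0 as
  saturation (as-printed mode only).
- Cube merging iterates transitive closure to a fixed point because the
  prescribed re-expansion of merged groups to cubes can create fresh
  overlaps; iteration makes the operation idempotent.
- Determinism: connected components are relabeled by first-voxel raster
  index, cluster members sorted by (distance, raster index), per-volume
  phantom seeds spawned from the master seed. Identical inputs and
  configuration give bit-identical detection tables.

## Known limitations

- **Merged cubes grow under dense candidate fields.** Re-expanding each
  merged group to a cube inflates its short axes, and on the default
  phantom (3 clusters in a 25.6 mm field) the surviving cubes frequently
  chain into one large detection. With the strict overlap criterion this
  still scores correctly, but detection boxes are much looser than the
  clusters they contain; clinical cluster densities (0–2 per volume) would
  not chain this way.
- **Survivor-count monotonicity is empirical, not a theorem.** Raising the
  member-voxel or neighbor-seed threshold removes cubes, which can fragment
  a merge chain into several surviving cubes. Under the shipped merge
  semantics and configuration the monotonicity property holds across the
  tested batches, but it is not guaranteed by construction; the cube-content
  thresholds, applied after merging, are monotone by construction.
- The SNR3D neighborhood, objectness scales, and phantom-profile content
  thresholds are package choices (the quantities are not fully pinned down
  by the method description); all are configuration fields.
- Annotations are axis-aligned boxes; voxel-mask truths are reduced to
  their bounding box on load, which the overlap>0 criterion tolerates but
  finer volumetric scoring would not.
- The FROC operating parameter is the package's detection score; systems
  with a different score ordering would trace a different curve through the
  same detections.
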