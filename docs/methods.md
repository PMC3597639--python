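# Methods

`cxplaque` quantifies astrocyte gap-junction plaques in spectral confocal
images of retinal wholemounts. This note documents the models, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## Problem and pipeline

Retinal astrocytes assemble gap junctions from four connexin isoforms
(Cx26, Cx30, Cx43, Cx45). A six-marker immunofluorescence panel labels the
four connexins plus GFAP (astrocyte cytoskeleton) and GS isolectin B4
(blood vessels) with six spectrally overlapping dyes (Alexa532, Cy3,
Alexa488, Alexa594, Cy5, AMCA respectively). Because the emission spectra
overlap, acquisition uses a lambda stack — 32 images of ~10.7 nm bandwidth
spanning 411–754 nm — and the dyes are separated computationally.

The measurement chain is:

1. **Spectral unmixing.** Each voxel's spectrum *s* ∈ ℝ³² is modeled as
   *s* = Aᵀx + ε where A is the K×Λ matrix of per-dye emission
   fingerprints (rows normalized to unit sum) and x ≥ 0 are dye
   abundances. We solve min‖s − Aᵀx‖₂ s.t. x ≥ 0 independently per voxel.
   Nonnegativity is the default because abundances are physical dye
   quantities; an unconstrained mode exists for comparison. The NNLS
   solution is computed exactly by enumerating the 2ᴷ possible active
   sets vectorized over all voxels (feasibility + KKT gradient check per
   subset), which is orders of magnitude faster than per-voxel iterative
   solvers at K ≤ 8; voxels unresolved at tolerance fall back to scipy's
   active-set NNLS. An optional spectrally flat column absorbs uniform
   background/autofluorescence.
2. **Segmentation.** Each connexin abundance map is thresholded
   (manual value or Otsu) and connected components are extracted at
   configurable 3D connectivity (default 26, merging diagonal contacts as
   surface-based tools do); components below `min_size` (default 2
   voxels) are discarded. Objects are measured in voxels, µm³, and 2D
   projected pixels.
3. **Colocalization.** Per-channel objects are merged into plaques by
   object-based colocalization: a graph links objects sharing ≥ 1 voxel
   (a centroid-distance rule is available), and each connected component
   becomes one plaque whose combination class is the union of its member
   channels — one of the 15 nonempty subsets of the four isoforms. The
   class records co-occurrence only; heteromeric vs heterotypic channel
   architecture cannot be inferred from colocalization and is not
   attempted.
4. **Compartment assignment.** A plaque is *vascular* if ≥ 50% of its
   voxels lie within 2 µm of the vessel mask (derived from the GS-lectin
   channel by Otsu thresholding with a 50-voxel minimum component size to
   suppress speckle), else *parenchymal*. This operationalizes the
   distinction between astrocytes ensheathing vessels and stellate
   parenchymal astrocytes at the level of individual plaques.
5. **Quantification.** Counts are averaged over fields of view (default
   plan: 8 fields in each of 3 retinal regions, 24 per retina),
   normalized to densities (mm⁻²) against the parenchymal field area or
   vessel surface area, scaled to totals per retina (total = density ×
   area, exact), and compared across ages as percent change. Two
   tabulations are emitted: per combination class (each plaque counted
   once) and per connexin (each plaque counted in every member isoform's
   tally).
6. **Statistics.** Per-retina totals (n = 4 per age) are compared by
   classical one-way ANOVA; pairwise comparisons use t statistics on the
   pooled ANOVA mean-square error with a Bonferroni multiplier equal to
   the number of pairs; α = 0.05.

## Percent-change printing rule

Published aging tables print percent change as a signed integer (two rows
at one decimal). Recomputing all 30 cells from their own printed totals
shows truncation toward zero reproduces 27 of them exactly (e.g. −52.67 →
−52, 422.96 → 422, 176.60 → 176, where rounding would give −53, 423, 177).
Three rows deviate: 635.69 printed as 636 and 6.276 printed as 6.3 fit
rounding rather than truncation, and one vascular pair row prints 71%
although its own totals imply 43.4%. The package standardizes on
truncation, always carries the untruncated float, and treats the three
rows as documented source inconsistencies.

## Synthetic scene model

The generator emulates a nerve-fiber-layer field of view:

- **Geometry.** Default 512×512 pixels per slice with a few z-slices;
  z-spacing 8.2 µm (the acquisition's slice thickness). The xy pixel size
  is not a published quantity; the default 0.25 µm is an assumption
  consistent with a 63×/1.4 NA objective and is configurable.
- **Vessels** are straight tubes (endpoints + radius in µm); the vessel
  mask contains voxels whose centers fall inside a tube. Vessel surface
  area is the analytic lateral area Σ2πrL, or a marching-cubes mesh area
  when only a mask is available.
- **Astrocytes** are spherical somata with thin radiating processes,
  rendered into the GFAP channel. They provide realistic spectral
  clutter; single-cell reconstruction is out of scope.
- **Plaques** are small irregular puncta: in-plane digital ellipses with
  random elongation (1–2×) and orientation, one z-slice thick (axial
  sampling is far coarser than the plaque scale), sizes drawn from a
  clipped log-normal (default median 6, σ_log 0.6, 2–30 voxels).
  Per-class counts are Poisson with configured means. Placement enforces
  pairwise disjointness with a one-voxel halo, and the planted
  compartment label is guaranteed to satisfy the same vessel-distance
  rule used at recovery (vascular plaques are placed in the ≤ 2 µm vessel
  shell, parenchymal plaques > 4 µm away, leaving a buffer so labels are
  unambiguous). A field too small or crowded raises a placement error
  after bounded retries.
- **Rendering.** Expected signal per voxel is background +
  autofluorescence (both spectrally flat) + Σₖ abundanceₖ × fingerprintₖ.
  Dye fingerprints are skewed Gaussians (steep blue edge σ=14 nm, red
  tail σ=32 nm) peaked at 448 (AMCA), 519 (Alexa488), 553 (Alexa532),
  569 (Cy3), 617 (Alexa594), 670 nm (Cy5) — a configurable model of the
  named dyes, not published curves. Noise is Poisson shot noise (gain =
  photons per intensity unit) followed by additive Gaussian read noise,
  each optional and independently seeded; with all noise off the stack is
  the exact linear mixture, which grounds the unmixing round-trip oracle.

Not modeled: PSF blur, spherical aberration, bleaching, z-extended
plaques, curved vessels, montage stitching. Passing tests therefore show
the *computational* chain is correct and well-calibrated under realistic
photon statistics and spectral overlap — not that segmentation choices
would be optimal on real optics-degraded data.

## Cohort benchmark (study conditions)

The synthetic aging cohort is a deliberately scaled-down stand-in for a
wholemount study: 2 age groups × 4 retinas × 6 fields (2 per region),
fields of 3×192×192 voxels with two crossing capillary-calibre vessels.
Baseline per-field class means put ~76 parenchymal and ~35 vascular
plaques per field, dominated by homomeric classes; at 22 months homomeric
Cx30 is multiplied 6-fold and every other class is flat. These sizes were
chosen so the Poisson sampling SE of a recovered percent change is a few
percent in the parenchyma and ~10% on the vasculature, i.e. the design is
adequately powered for recovery checks, while a full cohort runs in a few
minutes on one CPU. Imaging conditions for the cohort (plaque intensity
80, Poisson gain 4 — emulating 2-scan frame averaging — read σ 0.5,
manual threshold 40 = half the plaque intensity, flat background column
enabled) give clean separation between plaques and the
background pedestal; the manual threshold mirrors the manual intensity
thresholding used in practice. The Cy3/Alexa532 fingerprint pair is
spectrally close (569 vs 553 nm), and at low photon counts NNLS crosstalk
between them can create ghost objects — the photon-rich settings keep
ghost amplitudes several σ below threshold.

Retinal area (52 mm²) and whole-retina vessel surface area (15 mm²) are
fixed inputs used to scale densities to totals; they cancel in percent
change and ANOVA comparisons across ages.

The power check simulates per-retina totals directly (baseline at 3 and
9 months, 6-fold at 22 months, inter-retina CV 0.25, n = 4) over 500
replicates of the full ANOVA + Bonferroni procedure; image-level
rendering of 500 cohorts would add nothing to that question.

## Numerical choices and degenerate inputs

- Fingerprint matrices are validated for full row rank; a rank-deficient
  set raises an error naming the most collinear pair, and the condition
  number is exposed.
- The 32-bin grid honours the stated 411–754 nm endpoints (bin width
  343/32 ≈ 10.72 nm), taking bin centers at interval midpoints.
- Object ids are assigned by the lexicographically smallest voxel, so
  segmentation and merging are order-independent and fully deterministic.
- Zero spectra unmix to zero abundances with zero residual; empty vessel
  masks assign every plaque to the parenchyma with a logged warning and
  report zero surface area; a zero baseline makes percent change
  undefined and raises.
- All randomness flows from explicit integer seeds (scene and noise use
  separate substreams; cohorts spawn per-field seeds), so identical
  configuration + seed reproduces every artifact byte-for-byte, including
  OME-TIFFs (fixed OME UUID, no datetime tags).

## Known limitations

- The vessel-distance compartment rule is a proxy for expert judgement of
  astrocyte morphology; plaques near the 2 µm decision boundary are
  sensitive to vessel-mask errors of a pixel.
- Otsu thresholding is unreliable when foreground occupies ≪1% of a
  field (it can split the background mode); the manual threshold override
  exists for exactly this regime and is used by the cohort benchmark.
- Merged (touching) plaques of the same channel are not split — no
  watershed — matching the object-based colocalization design.
- Absolute per-retina totals depend on the retinal/vessel area inputs;
  only densities and relative changes are internally validated.
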