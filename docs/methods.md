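# Methods

## Model and assumptions

The detector is a matched filter for the foveal pit in the GCL-IPL
(ganglion cell + inner plexiform layer) en face thickness map. The
underlying anatomical assumptions are:

* the inner retinal layers retain their centrifugal foveal displacement
  (local thinning with a parafoveal ring) even in geographic atrophy,
  because atrophy primarily consumes photoreceptors and RPE;
* the pit's thickness deficit is roughly radially symmetric at the
  scale of the foveola (~0.35 mm across);
* the segmentation consumed as input is trustworthy for GCL and IPL.

When the last assumption fails — advanced degeneration distorting the
inner layers themselves — the method fails by design, and the
reliability score exists to flag exactly that case.

## Coordinate frame

Origin at the corner of the scanned area; `x` is the fast (a-scan)
axis, reported as "horizontal"; `y` is the slow (b-scan) axis, reported
as "vertical". **Which physical direction a device calls horizontal is
an assumption of this package**, since en face display convention puts
b-scans as rows. Isotropic grids are pixel-centre sampled (sample *i*
at `(i + 0.5)·res`); native volume grids are fence-post sampled
(b-scan *j* at `j·spacing`, so 49 b-scans span exactly 6 mm).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| detection grid resolution | 0.025 | mm/px | common grid all maps are resampled to |
| template σ | 7 | px | 2σ·0.025 mm = 0.35 mm ≈ foveola width |
| template size | 81 | px | ±40 px ≈ 5.7σ; truncation loses < 10⁻⁷ of the kernel mass |
| border exclusion (thinnest baseline) | 50 | native a-scan px | image borders carry acquisition artifacts; fast axis only |
| standard / dense cube | 49 / 98 b-scans over 6 mm | — | typical macular-cube presets |
| native a-scan count | 512 over 6 mm | — | common device setting; fully overridable via the JSON sidecar |

The template is the inverted isotropic Gaussian
`G(x,y) = −(1/2πσ²)·exp(−(x²+y²)/2σ²)`; its weights are all ≤ 0, sum to
≈ −1, and the unique minimum sits at the centre pixel.

## Numerical choices

* **Resampling** is bilinear on pixel centres with edge clamping —
  the minimal smooth interpolant; outputs therefore stay inside the
  input's value range, and a map already on the target grid is
  reproduced exactly.
* **Convolution** uses FFT on a reflect-padded map ("same" output
  size). Reflect padding avoids the spurious border maxima zero padding
  would create on thickness maps, and the kernel's point symmetry makes
  convolution and cross-correlation identical.
* **Argmax** is single-pixel; the claimed accuracy is one cell of the
  0.025 mm grid, not sub-pixel. Responses within a 1e-10 relative band
  of the maximum are treated as tied and resolved to the smallest
  row-major index: two analytically equal peaks (a pit centred on a
  pixel edge) differ only by ~1e-15 FFT rounding, and without the band
  that noise, not the tie rule, would pick the winner. Real competing
  peaks are separated by many orders of magnitude more.
* **Reliability** is reported raw (units mm, ≤ 0 for non-negative
  maps). No cutoff is imposed; cohort-level quantile flagging is left
  to the consumer.
* **Thickness** is voxel-count × axial pitch. For contiguous label
  runs this equals boundary-surface subtraction; non-contiguous runs
  are tolerated on load with a warning.
* Degenerate inputs: maps containing NaN are rejected at construction;
  an even template size, a resolution mismatch between map and
  template, and a border exclusion covering the whole b-scan are hard
  errors.
* The paired t test is computed in closed form on the difference
  vector; zero-variance differences return the limit (p = 1 for
  identical samples, p → 0 otherwise, with a note). Subgroup
  comparisons between *different* eyes (foveal vs extrafoveal RORA,
  standard vs dense) cannot be paired and use Welch's unpaired test,
  recorded as such in the report.

## The phantom: what it emulates, and what it does not

The generator produces label volumes (never reflectivity images — the
detector consumes segmentations) with a fixed stack RNFL / GCL / IPL /
INL / OPL / ONL / PR / RPE under a flat inner surface. Components:

* **Pit**: GCL-IPL thickness drops from a 0.09 mm parafoveal plateau to
  0 at the fovea, with spread `pit_sigma` = 0.175 mm (2σ = 0.35 mm).
  Besides the Gaussian profile, a **cosine-bowl** profile (radius
  2·pit_sigma) is provided so recovery tests do not presuppose the
  exact template shape. The outer retina (PR) thickens toward the
  fovea by 0.03 mm (spread 0.30 mm), so total retinal thickness is
  genuinely minimal at the pit in healthy phantoms.
* **RORA lesions**: circular; inside the lesion PR and RPE labels are
  removed and the ONL is reduced to a 30 % remnant scaled by a
  spatially correlated severity field (correlation length 0.4 mm,
  clipped to [0, 2]) — atrophic thinning is irregular, which is what
  defeats the thinnest-point rule. With
  `inner_layer_damage_fraction = 0` the GCL/IPL labels are bit-identical
  to the lesion-free phantom.
* **Inner-layer damage** (`inner_layer_damage_fraction` f > 0) models
  advanced degeneration *as distortion*: the GCL-IPL field inside the
  lesion is blended `(1−f)·pit + f·(parafoveal level × irregular
  field)`. Pure proportional thinning would make the map thinner and
  hence *raise* the raw convolution score while leaving a scaled pit in
  place; distortion toward an irregular parafoveal-level sheet is what
  erases the pit pattern, produces millimetre-scale errors and strictly
  lower reliability — the observed failure mode this switch exists to
  reproduce.
* **Artifacts**: a shifted b-scan is modelled by deleting the top
  `cut_fraction` of labelled voxels in every column of one b-scan,
  which slashes total thickness there (capturing the thinnest-point
  baseline) while the neighbourhood-averaging template is barely moved.
* **Noise**: zero-mean Gaussian perturbation of the GCL-IPL and PR
  column thicknesses (default SD 0.008 mm ≈ 2 axial voxels in cohort
  presets; 0 for single clean phantoms) applied before discretization.
* **Determinism**: all randomness flows from one integer seed through
  independent per-component child streams, so enabling a lesion never
  changes the noise draws of other components and equal seeds give
  bit-identical volumes.

Default geometry: 49 (or 98) b-scans × 512 a-scans × 160 axial voxels
at 3.9 µm, 6 × 6 mm.

The cohort sampler defaults describe a GA study population: fovea
scattered around the scan centre with SD 0.25 mm per axis (the
fixation error the scan-centre baseline measures), RORA areas drawn
from N(7.42, 5.06²) mm² clipped to [0.5, 15], a 32:23
foveal-to-extrafoveal split, 13/55 dense scans, and artifacts on ~10 %
of eyes.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: segmentation errors of a real layer-
segmentation network, pathologies that deform the *inner* layers
smoothly (edema, traction), eye-motion distortion within b-scans,
curved retinal geometry, and inter-grader annotation variability
(ground truth is exact). Error magnitudes on phantoms are therefore
optimistic; only orderings and invariances are meaningful, and the
evaluation asserts exactly those (template < scan-centre <
thinnest-point mean error; invariance to outer-retina pathology;
reliability-based outlier flagging).

## Problem sizes used in tests and the reproduction script

Cohort runs use n = 55 (evaluation ordering) and 40 + 5 (reliability
flagging); the recovery sweep uses a 5 × 5 grid of pit positions × 2
profiles; the convolution oracle uses 20 random 100 × 100 maps × 25
positions against a quadruple-loop double sum. One full phantom
(generate + project + resample + detect) takes ~0.25 s, the whole
reproduction script well under a minute.

## Known limitations

* The thinnest-point baseline's argmin plateaus under coarse axial
  quantisation (a 3.9 µm voxel spans several native pixels of bowl
  curvature near the pit), so agreement checks against the template
  detector are meaningful only at fine axial pitch.
* The reliability score is unnormalised; comparing it across scans
  assumes comparable parafoveal GCL-IPL thickness.
* "Horizontal"/"vertical" follow this package's axis convention (fast/
  slow); swap at the caller if a device defines them otherwise.
* Proprietary vendor formats (.e2e, DICOM OCT) are out of scope; the
  package reads TIFF label stacks with JSON geometry sidecars.
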