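# Methods

`octapipe` analyses longitudinal OCT volumes of laser-induced retinal
injury with a combined structural (orthogonal B-scan) and angiographic
(en-face OCTA) pipeline, and ships a ground-truthed synthetic generator so
every stage is testable without image downloads.  This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## The synthetic eye

**Geometry.** Volumes are `(axial, slow, fast)` grids at 1.4 um lateral and
1.9 um axial pitch by default, matching a 1000 x 1000 A-scan acquisition;
desk-scale runs reduce the lateral counts at the same pitches, and
multi-lesion "widefield" eyes use a coarser lateral pitch (2.8-11.2 um) so
that lesions of the published size fit the field.  The published mean
lesion dimensions make this unavoidable: a single day-7 CNV lesion is
~566 um wide, so four of them cannot fit any native-pitch desk-scale grid
(nor, with generous clearance, even a full 1.4 mm native-pitch field).

**Layers.** Depth maps for the ILM, ONL/OPL boundary, ELM, IS/OS band,
RPE band and choroid base are smooth surfaces (a shallow bowl, a tilt, and
a ~25 um-scale undulation of ~4 um amplitude) over a fixed stack of band
reflectivities (vitreous 0.05, inner retina 0.30, ONL 0.12, IS/OS 0.75,
RPE 0.92, choroid 0.45, arbitrary units).  No quantitative reflectivity
values are published for this system, so the constants are free parameters
chosen to give band contrasts a segmentation can work with.

**Vasculature.** Each plexus (SVP, IVP, DVP, choroid) is a set of sinuous
centerline tubes with per-vessel diameters (SVP 12-26 um, IVP/DVP 5-10 um,
choroid 12-30 um) rasterized at sub-voxel sampling into binary masks,
anchored to its host surface so lesion swelling displaces vessels with the
tissue.

**Lesions.** Per-timepoint mean dimensions follow the packaged reference
table exactly (piecewise-linear between printed days).  Lesion-to-lesion
variability is a lognormal scale per (lesion, dimension, day) with mean
exactly 1 and CV equal to the table's CV cell; a shared per-(lesion,
dimension) random effect (correlation 0.6) makes a severe lesion stay
severe over time, consistent with growth proportional to initial size.
The four dimensions are rendered so that each is geometrically
unambiguous: a flat-topped hyperreflective core between a raised ONL/OPL
boundary and the (displaced) photoreceptor band sets the ONL width (its
lateral extent) and the height (boundary-to-RPE separation at center); an
RPE surface dome sets the RPE width; an extra 26 um lift of the ELM-IS/OS
complex sets the PR width.  Lateral profiles are flat-topped with a 4 um
linear edge crossing half-amplitude exactly at the nominal width, so
full-width-at-half-maximum measurements recover the widths by
construction.  CNV lesions additionally rupture the RPE over the central
0.35 of the RPE width (outer bands destroyed, choroid signal suppressed
to 0.3x — the "void"), grow a hyporeflective sub-retinal separation when
taller than 230 um, and remove a scheduled fraction of IVP/DVP vessel
voxels inside the lesion cylinder.  The default schedule removes 80% of
in-cylinder voxels at timepoints where the lesion height is at least
200 um (days 3 and 7 for the reference means); explicit day-to-fraction
schedules override it.  Acute lesions never rupture and never lose
vessels.  An optional 1 h point repeats the day-1 values, since no
separate 1 h row is published.

**Noise.** Multiplicative lognormal speckle with mean 1, sigma/mu 0.30 and
a physical grain (lateral sigma 0.6 um ~ the 1.4 um PSF): grains span
neighbouring A-scans/B-scans, which is what makes integer-voxel B-scan
registration solvable.  Inside flowing blood the grain pattern is averaged
during the exposure, leaving 0.4x residual contrast — the spatial-speckle
cue the angiography reads.  Projection tails (1.25x imprints of
superficial vessels on the deep band), attenuation shadows under vessels
(2% per vessel voxel), an 8% static reflectivity texture and a 2% additive
floor complete the artefact model.  Motion is an integer-voxel per-B-scan
translation from a bounded mean-reverting walk (AR coefficient 0.45,
default scale ~2 voxels, clipped at 6), recorded in the metadata.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: interferometric speckle statistics and phase,
the confocal PSF, eye curvature / reference-arm geometry, flow dynamics
(no velocity information exists in the renderer), vascular remodeling
morphology (removal is voxel deletion, not re-routing), operator
variability in lesion placement, and the irregular shapes of real lesions
(the flat-topped profiles are deliberately idealized so the measurement
definitions are exact).

## Registration

Consecutive B-scans are aligned by integer-shift normalized
cross-correlation (FFT-evaluated, +-8 voxels) and chained; offsets are
re-centered at their median (mean-reverting motion prior).  No detrending
is applied by default: the jitter is integer-voxel while anatomy changes
by far less than a voxel between B-scans, so the integer chain leaves
anatomy untouched — a moving-median detrend (available as an option,
rounded to integers) would absorb the slowly-varying component of the true
motion.  On default-noise synthetic volumes the recovery is exact.

## Surface segmentation

Per-A-scan gradient/peak analysis on a lightly smoothed volume (kernel
sizes specified in micrometres so widefield pitches are not over-smoothed):
Otsu-thresholded first crossing for the ILM, brightest deep reflector for
the RPE, strongest negative inner edge for the ONL/OPL boundary, the
photoreceptor-band rise below it for ELM/IS-OS; 2D median smoothing and
ordering enforcement follow.  A column is marked invalid when its deep
reflector is much dimmer than the field median (0.65x) or sits more than
45 um above a robust quadratic "sheet" fit of the RPE — the signature of a
destroyed outer complex over a choroidal rupture.

## Angiography

The enhancement is a sequential set of localized structural iterators on
en-face (C-scan) images, applied after flattening the volume to the ILM
(C-scan planes must not graze curved layer boundaries, whose contours
mimic vessels):

1. moving-median background removal (91 um window, much larger than the
   largest vessel);
2. local contrast normalization (120 um window — it must also exceed the
   largest vessel, or large superficial vessels flatten away);
3. multiscale bright-ridge (2D Hessian eigenstructure) enhancement at
   scales matched to 5-40 um diameters, with the structureness constant
   shared across scales (a 99.5% quantile, robust to outliers);

steps 2-3 iterated twice, then an axial localization gate (negative axial
second derivative, scale-coupled to the winning in-plane scale) and a
quantile-referenced rescale to [0, 1].  Segmentation is per-C-scan
hysteresis (0.99/0.70 quantiles, absolute floor 0.03) with three
physically motivated gates: candidate voxels must be bright lumen
(>= 0.75x the median background-removed intensity of the strong seeds),
one dilation step grows the centre-weighted ridge response back over the
lumen rim, and a speckle-wash gate rejects voxels whose local speckle
contrast exceeds 1.4x that of confident vessels (static tissue is grainy,
flowing blood is washed).  Projection tails below the superficial band are
removed when the column's superficial score exceeds 1.5x the voxel's
structure score (each voxel answering with its local axial peak), and only
under convincingly detected superficial vessels.

On the 256 x 256 x 512 control cube at default noise this chain reaches
Dice 0.74 (SVP) and 0.61 (DVP, after tail rejection) against the generator
masks — numbers the acceptance suite recomputes.  Per-voxel Dice of 4-7
voxel capillaries is boundary-dominated, which is the practical ceiling
here.

## Morphometry

On the lesion-centered B-scan, each width is the full width at half
maximum of a deviation profile against a robust surround fit (two-pass
quadratic: the far surround seeds the fit, the detected deviation region
is excluded, and the fit is recomputed on all remaining valid columns —
far-surround-only extrapolation errs by 15-20 um at CNV field sizes).
Profiles: ONL — low-percentile intensity in a thin band below the boundary
fit, normalized by the same column's RPE peak (vessel shadows cancel);
RPE — elevation of the band-matched RPE depth, rupture columns counted as
disrupted via rim interpolation; PR — elevation of the IS/OS *bottom edge*
(the strongest negative axial gradient above the RPE, which lesion core
speckle cannot mimic) relative to the local RPE elevation; height — RPE
depth minus the topmost sustained core crossing (threshold midway between
inner-retina and core levels, 24 um run so displaced capillaries do not
trigger), read as the footprint median of a flat-topped profile.  FWHM
edges use the dominant above-half run with gaps up to 45 um merged
(vessel shadows notch the plateau) and the half level set from the plateau
median, not the peak.  At default noise the recovered dimensions sit
within ~1-2 voxels of truth for both conditions.

The dynamics model is exactly the self-normalized percent-change algebra:
P_t = 100 (M_t - M_0)/M_0, interval differences D1 normalized by the
baseline, D2 their consecutive differences, expansion positive.  The
steady-state rule — the package's normative reading of the
second-derivative zero-asymptote criterion — returns the earliest
timepoint strictly before the last interval after which every remaining
|D1| is at most the 5% significance threshold; requiring at least two
remaining intervals is what simultaneously reproduces the published
day-7 onset of the acute PR trace and the non-convergence of every CNV
dimension (whose final interval alone can be small).  Group statistics use
the population standard deviation and pool the per-(dimension, day) CVs by
unweighted mean; cells with zero mean are excluded and reported.

## Perfusion and phenotype

Vessel density is the positive-voxel fraction of an angiogram slab inside
a lateral ROI.  The deep-plexus density band is [boundary - 30, boundary -
6] um — stopping short of the boundary because inside a lesion that
surface is the bright core top.  A timepoint is non-perfused below 0.5x
baseline (pre-lesion scan when available, else a surround annulus at
1.5-2.5 lesion radii); consecutive non-perfused timepoints merge into
intervals and the reperfusion day is the first recovery after an interval.
The classification rule is pure in its evidence: CNV when the RPE ruptured
or the choroid shows a void, or when the lesion reached 200 um height with
deep-plexus non-perfusion; acute when no channel fires; indeterminate
otherwise.  The pipeline's evidence assembly adds robustness appropriate
to desk scale: rupture requires >45% invalid columns over the rupture-
sized core, the choroid-void slab follows a grey-closing "sheet" of the
RPE (the segmented surface dives into the rupture), non-perfusion evidence
needs an interval covering at least two timepoints, and the height
evidence is the second-highest per-day measurement.  On two simulated
four-lesion eyes (acute and CNV) the end-to-end pipeline classifies 8/8.

A desk-scale caveat, measured and worth stating: at coarse widefield
pitches the angiogram inside a lesion carries a clutter floor (~60% of
baseline density) from disrupted-tissue detections, so an 80% scheduled
removal does not present as a <50% measured drop through the full imaging
chain; the interval-detection contract is therefore certified on
generator-truth densities, while the imaged pathway backs the
classification evidence, where only the sign of the change matters.

## Problem sizes and numerical conventions

Default test and acceptance runs use 192-256 voxel lateral grids (native
pitch for control/single-lesion work, 2.8-11.2 um widefield pitch for
multi-lesion eyes), 16 lesions for group statistics, and 200 scene-only
lesions for dispersion calibration.  Voxel indices are 0-based, depth
increases with the axial index, all exported measurements are in
micrometres, slab flattening is nearest-voxel (bit-reproducible, no
interpolation), and every stochastic component is driven by explicit
integer seeds; identical parameters and seeds give bit-identical volumes.

## Known limitations

Sub-voxel motion, non-rigid motion and eye-curvature correction are out of
scope.  The angiography is single-scan spatial-statistics contrast: no
flow rates or velocities exist anywhere in the pipeline.  Boundary-
dominated Dice caps deep-capillary segmentation around 0.6 at native
pitch.  Morphometry assumes one lesion per measured B-scan with visible
surround on both sides; overlapping lesions are not handled.  The
classifier's evidence thresholds were chosen against the synthetic
artefact model and would need re-calibration on instrument data.
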