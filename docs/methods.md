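# Methods

This note records the models, numerical choices and limitations behind
`organodeath`, in the order data flows through the package.

## Acquisition model

A well is sampled as `n_fields` square fields of view, each a z-stack of
`n_planes` planes spaced `z_step` µm apart. Defaults mirror a spinning-disk
high-content setup with a 40× water-immersion objective: field area
78,974.6 µm², 15 planes, 25 µm z-step, 0.3 µm pixels. All downstream areas
are pixel counts × `pixel_size²`; the pixel grid is validated to reproduce
the nominal field area within 1% rounding. Analysis is strictly per-plane
2D: with a 25 µm z-step there is no meaningful voxel continuity between
planes, so plane intersections of one organoid are counted as separate
objects. The reported quantities are therefore *sampled* loads, not
absolute well contents — large organoids are over-counted (multiple
intersections) and edge/off-peak intersections under-estimate sizes.

## Synthetic scenes

Organoids are non-overlapping spheres (default radius 20–35 µm when not
specified by the caller) whose XY footprints are kept disjoint, so
ground-truth per-plane regions never touch. Each sphere renders per plane
as a faint uniform "body" disc in all three channels (a stand-in for
scattered light within the spheroid; default 15 a.u. against a 5 a.u.
background) — this disc *is* the ground-truth organoid label. Nuclei are
isotropic Gaussian blobs (σ = 3 px) placed on plane heights inside their
organoid's cross-section with in-plane spacing ≥ 4σ, the regime in which
seeded watershed can resolve every blob. Ground-truth nucleus labels are
2σ discs. Debris specks (default radius 2.5 µm, area ≈ 20 µm² « 250 µm²)
land outside organoid footprints. Plane depth attenuates all object
intensities linearly (2%/plane default). Background noise is additive
Gaussian (SD 2 a.u.), clipped at zero.

Dye intensities are bimodal: the "low" mode is normal
(N(50, 10) a.u.) and the "high" mode lognormal with mean 400 a.u.
(σ_log = 0.25), an 8× separation — recoverable but not trivially so.
Death mode determines which channels are high: viable low/low, apoptotic
Caspase-high, necrotic PI-high, late-apoptotic both. Intensity units are
arbitrary; nothing downstream depends on absolute scale.

`z_mode` controls organoid depth placement: `"uniform"` (default) lets
spheres straddle plane heights, producing small sub-threshold
cross-sections exactly as real sampling does; `"plane_centered"` snaps
centers to plane heights so every cross-section is a full disc — used by
exact-recovery oracles.

What a green test on this generator does *not* establish: robustness to
textured nuclei, touching organoids, optical PSF blur, photobleaching, or
intensity gradients within organoids. The generator's blobs are the
simplest shapes that exercise the segmentation logic, no more.

## Segmentation

Organoids, per plane, from the combined image (per-channel rescale to
[0, 1] by the channel maximum, then pixelwise sum; `max` is available as
an option): Gaussian blur (σ = 2 px) → log1p compression → three-class
multi-Otsu, keeping the lowest threshold → morphological closing (disk
r = 2) → region resize (erosion then dilation, disk r = 2, clipping
debris-derived fluorescence at the organoid periphery) → connected
components → area floor of 250 µm² (excludes single cells, small clumps
and debris). Two non-obvious choices:

- *Three-class Otsu on log intensities.* These planes are trimodal —
  overwhelming background, a dim organoid-body plateau, and sparse very
  bright nuclei. Two-class Otsu reliably puts its cut *above* the body
  plateau whenever dead-cell dye blobs are bright (the per-channel max
  rescale then makes the body ≈ 4% of the blob peak), losing the organoid
  entirely. The lowest of two multi-Otsu thresholds separates background
  from tissue in both the bright-blob and viable-only regimes.
- *Contrast sanity check.* Otsu always returns a split; on a plane with no
  objects it splits smoothed noise into giant fake regions. A threshold is
  accepted only if the foreground/background mean ratio is ≥ 1.5
  (`min_contrast`); otherwise the plane is declared empty. Most planes of
  a 15-plane stack contain nothing, so this check is load-bearing.

Border-touching regions are retained but flagged (`touches_border`);
excluding them would bias against large organoids, and edge intersections
are part of the sampled-load definition.

Nuclei: Gaussian blur (σ = 2 px) of the Hoechst channel, Otsu within the
organoid mask (same contrast check), peaks at ≥ 5 px separation seed a
watershed confined to the Hoechst-positive subset of the organoid mask
(so the dim body is not absorbed into nucleus regions). Each nucleus is
assigned to the organoid containing its centroid pixel; when rounding
lands the centroid on background, the nearest labelled pixel (Euclidean
distance transform) decides. Mean Caspase and PI intensities are computed
from the *raw* channels under the nucleus mask.

## Death gating

Stage 1 — viable thresholds: per channel, mean + 2·sample SD (ddof = 1) of
pooled day-0 untreated-control nuclei (pooling is per experiment, not per
well). Computed on linear intensities by default; `scale="log10"`
transforms first (values clipped at 1e-9). At least 2 nuclei are required
(SD undefined below that). Viable ⇔ at or below *both* thresholds; above
*either* threshold is dead. (The alternative "above both = dead" reading
would leave the single-positive apoptotic and necrotic populations
undefined.)

Stage 2 — death-mode wedges: for a dead nucleus, take
(Δc, Δp) = (caspase − t_caspase, pi − t_pi) with negative components
clipped to zero, and α = atan2(Δp, Δc) in degrees. α < θ_necrotic (30°)
⇒ apoptotic; α > θ_apoptotic (60°) ⇒ necrotic; otherwise late-apoptotic
(boundary angles fall into the wedge). The clipping maps single-positive
points onto the axes (α = 0 or 90°), so they classify as pure apoptotic
or necrotic regardless of the angles. The four classes partition the
intensity quadrant: every point gets exactly one label.

Angle calibration (optional): dead cells among day-10 untreated controls
give an empirical angular distribution about the anchor; the rays are set
to its ((1−q)/2, (1+q)/2) quantiles with q = 1/3 by default — the central
third of control dead cells is treated as late-apoptotic. Quantiles make
the calibration equivariant under rotation of the dead-cell cloud about
the anchor. With zero dead control cells the defaults are kept and a
warning is emitted.

Known, intended behavior: 1 − Φ(2)² ≈ 4.5% of genuinely viable nuclei lie
above a mean+2SD threshold and are gated dead. This is the operating
point of the rule, not an implementation error; recovery tests budget for
it.

The staurosporine positive control passes when the mean dead fraction of
positive-control wells exceeds the untreated mean by ≥ 0.2 (absolute,
configurable).

## Organoid-load statistics

Per-well loads (nuclei count, mean cross-section area, organoid count)
are divided by the *pooled* day-0 untreated mean to give fold changes
("tumor growth"). Each dose's day-10 fold changes are compared to the
untreated day-10 fold changes with a two-sided unpaired t-test — Welch's
unequal-variance form by default (`equal_var=True` gives the pooled
Student form) — and Bonferroni-adjusted across the doses tested per
metric: p_adj = min(1, p·n_doses). Significance is called at
p_adj < 0.05.

## Viability plate arm

Normalization divides readings by the vehicle/negative-control mean.
The 4PL is fitted by least squares with the IC50 on a log10 scale for
conditioning; initial values come from the dose-averaged response (top
and bottom from the extreme doses, IC50 from the dose nearest the
half-way response, hill = 1), with hill bounded to [0.05, 20] and the
asymptotes loosely bounded around the data. Vehicle (dose-0) wells are
used only for normalization, never in the fit; ≥ 4 distinct positive
doses are required. Flat responses and optimizer failures set
`converged = False` on the result instead of raising — an unidentifiable
fit is a reportable outcome of a screen, not a crash.

QC metrics: growth ratio = mean(day-10 untreated)/mean(day-0 untreated);
CV = sample SD/mean of day-10 negative controls (untreated + vehicle
wells — the standard screening convention when the metric's scope is
otherwise unspecified); Z′ = 1 − 3(σ₊+σ₋)/|µ₊−µ₋| between staurosporine
positives and negative controls on raw readings (affine-invariant);
DMSO effect = mean(DMSO vehicle)/mean(untreated), same plate, same day.
Verdict boundaries: growth ≥ 1.5 inclusive, CV and Z′ strict, DMSO bounds
inclusive. Missing positives or missing DMSO wells mark the respective
rule *not applicable* rather than failed; the plate passes iff every
applicable rule passes.

Plate simulation: untreated signal = baseline·growth_rate^day with
multiplicative lognormal noise of coefficient of variation `noise_cv`
(mean-one parameterization, σ² = ln(1+cv²)); treated day-10 wells are
scaled by the true 4PL response at their dose; staurosporine wells by a
near-zero survival factor (0.05). Defaults: baseline 100, growth 2× over
the 10-day exposure, cv = 0.1.

## Numerical details and edge cases

- All randomness flows from integer seeds through
  `numpy.random.SeedSequence`; layout, rendering and plate noise use
  separate spawned streams, so rendering the same scene twice is
  bit-identical.
- Empty inputs: blank planes segment to zero regions; an empty well
  summarizes to all-zero counts; `quantify_well` of zero fields, t-tests
  with < 2 wells per group, thresholds from < 2 nuclei, and zero/negative
  normalization denominators raise `ValueError`.
- Ties: nuclei on organoid boundaries go to the organoid containing the
  centroid pixel; gate-boundary angles go to the late-apoptotic wedge;
  the growth rule is inclusive at exactly 1.5.
- Tests run on scaled-down geometries (256–384 px fields, 2–3 planes,
  1 field/well) to keep the suite fast; the full-size defaults are
  exercised only through the geometry type itself.

## Limitations

No 3D reconstruction or organoid tracking over time; no brightfield
morphology; no spectral-crosstalk correction (assumed absent); no
modeling of optical PSF, photobleaching or murine-cell contamination.
Dose units are the caller's responsibility (convert to a single unit
before fitting).
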