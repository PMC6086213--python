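# Methods

`boutonflux` models the structural plasticity of en passant axonal boutons
on layer-5 pyramidal-neuron projections to layer 1 of mouse motor cortex
over a three-session imaging schedule: baseline (day 0), after four days of
rotarod training (day 4), and after four further days of home-cage rest
(day 8). Because the underlying in vivo imaging data are not publicly
deposited, every pipeline stage is driven and validated by a generative
model calibrated to the published cohort statistics of wild-type and
MECP2-duplication (Tg1) mice.

## Generative model (`synthcohort`)

Each axon segment has length L drawn from a truncated normal
(mean 138 µm, SD 73 µm, bounds 30–360 µm — the published range and
mean ± SD; the truncated normal is our choice of shape). Two bouton size
classes are seeded as independent Poisson processes along the arc with
uniform positions and a minimum spacing of 0.5 µm (our choice, keeping
neighbours resolvable at the stated optics; the source analysis never
states a spacing):

* **alpha boutons** (diameter > 2 µm; truncated normal on [2.05, 3.5] µm,
  mean 2.6, SD 0.35): density 2.7/100 µm (wild type) or 2.4/100 µm
  (mutant). Alphas are nearly immortal: per 4-day interval they survive
  with `alpha_p_survive_4d = 0.995` and are replenished by a matching
  formation intensity of 0.005 per baseline alpha per interval, keeping
  their density stationary and their emergent 4-day turnover near the
  published 0.5 %. (0.995 rather than 0.99: with the matching formation
  term, 0.99 would give ~1 % turnover, the edge of the published band.)
* **beta boutons** (diameter 1–2 µm; truncated normal on [1.0, 1.95] µm,
  mean 1.4, SD 0.25): density 4.0/100 µm (wild type) or 5.8/100 µm
  (mutant). The diameter modes were chosen to reproduce a clearly bimodal
  distribution separable at 2 µm; only the class boundary and the 1–3 µm
  range are published.

Beta dynamics per phase: a baseline bouton survives training with
`p_survive_training` and, if still present, the rest interval with
`p_survive_rest_pre`. New boutons form at the end of each phase as
Poisson(formation_intensity_phase × baseline beta count) and, once formed,
persist through the following interval with `p_stabilize_new` — newly
formed boutons are far less stable than pre-existing ones (two separate
survival laws, matching the published old-vs-new survival curves).
Mouse-level heterogeneity (a logit-normal shift of the beta survival
probabilities per mouse) is off by default and exists only to exercise the
mixed model's operating characteristics.

### Calibration

`calibrate_preset` inverts the model for a target set of seven cohort-mean
per-segment fractions. Per-segment survival and stabilization fractions are
unbiased for the underlying Bernoulli probabilities, so three parameters
follow in closed form:

    p_survive_training = survival_d4
    p_survive_rest_pre = survival_d8 / survival_d4
    p_stabilize_new    = stabilization

The two formation intensities are found by damped multiplicative
fixed-point iteration on simulated cohorts of 600 segments with common
random numbers (tolerance 0.005, typically 2–3 iterations, deterministic
given the seed). The elimination fractions use the *total-observed*
denominator (distinct lineages seen at any session) and are therefore fully
implied by the survival and formation parameters — the model has five free
dynamics parameters against seven targets. The published wild-type set is
jointly over-determined: survival 77 % pins the baseline loss at 23 % of
baseline, while formation targets of 10 % and 9 % pin the baseline share of
observed lineages at 81 %, implying a training elimination of
0.23 × 0.81 ≈ 18.6 % rather than the printed 17 %. Calibration therefore
matches survival, stabilization and formation exactly and reports the
implied elimination residuals in its `CalibrationReport` instead of
optimizing them; the implied values sit well within twice the printed SEMs.

A related, larger inconsistency: the published spontaneous 4-day beta
turnover of 23 ± 4 % cannot be reconciled with the published rest-phase
formation (9 ± 2 %) and elimination (6 ± 2 %), whose average — the stated
definition of the turnover rate — is ~7.5 %. The generator is calibrated to
the phase rates, so its emergent single-interval beta turnover is ~10 %,
and the package reports that value rather than forcing 23 %.

## Image simulation (`imagesim`)

The axon is a tube with Gaussian cross-section (FWHM = shaft diameter,
default 0.6 µm) following a smooth low-tortuosity planar curve of exactly
the segment's arc length; each bouton is a Gaussian blob with FWHM equal to
its diameter whose emission peaks at 2.5× the shaft (the detection
criterion is 2×; true emission ratios are unpublished, so the renderer
guarantees the criterion is satisfiable with margin). Boutons are composed
with the shaft by voxelwise maximum — a varicosity is a local swelling of
the axon, not a structure superimposed on it — so the transverse profile
through a bouton is the bouton's own Gaussian. The microscope blur is a
separable anisotropic Gaussian PSF (lateral FWHM 0.4 µm from the published
bead calibration; axial FWHM 2.0 µm, our choice since the analysis is
projection-based). Because every emitter is Gaussian, the PSF is folded in
analytically (variances add) and measured widths obey
FWHM_obs = √(FWHM_obj² + FWHM_psf²) exactly — the oracle used by the
bead and bouton width tests.

Geometry: 0.1 µm/pixel laterally, 1 µm z-step, ±3 µm of axial extent.
Stacks are rendered as a tight region of interest around the traced axon;
the nominal 310–420 µm field of view is carried as metadata (a full field
at this sampling would be ~10⁹ voxels per stack with no analytical
benefit). Per-slice rigid jitter (uniform, default < 1 px) and a linear
across-stack drift (default < 3 px) stay inside the published quality
gates; noise is Poisson on the signal plus Gaussian read noise (default
photon scale 100 counts at the shaft peak, background 10, read noise
SD 2). Each segment's backbone geometry is seeded from its identifier so
all imaging days share one frame — cross-day image registration is assumed
done upstream for real data and is out of scope.

## Detection (`boutondetect`)

The detector resamples the backbone at 0.1 µm arc steps, extracts the
perpendicular intensity profile from a maximum-intensity projection over
±2 µm around the axon plane, and measures peak intensity and transverse
FWHM (half-maximum crossings with linear interpolation; background is the
10th percentile of the projection). A bouton is called where the width
exceeds the local shaft reference by > 0.3 µm *and* the peak is more than
2× the local backbone reference. Numerical choices:

* **Shaft references**: rolling 25th-percentile baseline over a 20 µm
  annular window excluding the sample's ±1 µm neighbourhood. Boutons only
  push width and brightness upward, so a low quantile estimates the bare
  shaft robustly even where wide alpha boutons occupy most of a 10 µm
  window (a rolling median over 10 µm, the obvious first choice, fails in
  bouton-dense stretches). Detection is two-pass: candidate runs from the
  first pass are masked out and the references recomputed.
* **Run handling**: contiguous super-threshold runs closer than 1 µm are
  merged, runs shorter than 0.2 µm are dropped, and a merged run is split
  at prominent interior intensity peaks (prominence ≥ 0.75× the local
  reference) so a small bouton on the shoulder of a wide one is still
  called. Calls are localized at intensity peaks (the width profile
  plateaus across a bouton; intensity does not).
* **Diameter**: the raw FWHM at the call is reported alongside a
  PSF-corrected diameter √(FWHM² − FWHM_psf²); classification (alpha
  strictly above 2 µm, beta otherwise) uses the corrected value, so
  near-threshold boutons classify by their physical size rather than their
  blurred apparent size.
* **Isolation filter**: calls whose nearest neighbouring call is > 50 µm
  away are flagged and excluded from densities and turnover; a single call
  with no neighbour at all is likewise excluded (the degenerate case is
  not specified anywhere; the choice is recorded in the detection report).

On noise-free renders with boutons spaced ≥ 5 µm, detection recovers counts,
classes, and positions exactly; under default noise and motion, precision
and recall stay ≥ 0.95 for betas ≥ 1.2 µm. Boutons closer than ~4 µm to a
wide alpha can still merge into one call — a genuine resolution limit, not
a tuning artifact.

## Tracking (`boutontrack`)

Calls from consecutive days are linked by greedy nearest-neighbour matching
on arc position (closest pairs first, each call used once, default
tolerance 2 µm, distance ties broken toward the smaller arc position, which
makes the link set symmetric in the argument order). Greedy matching equals
the optimal assignment whenever within-day spacing exceeds the tolerance
and cross-day displacement is well below it — the regime the renderer and
quality gates guarantee — and the tests enforce that equivalence on small
windows; in pathological clusters the two can differ, which is why the
tolerance should be set below the minimum spacing when tracking exact
ground-truth positions (the tests use 0.4 µm there). A bouton that is
present, absent, then present again at the same site is scored as an
elimination followed by a formation of a new lineage, flagged `reappeared`
so the alternative single-lineage accounting can be reconstructed.

## Statistics (`turnoverstats`)

All statistics are per segment, then aggregated as unweighted mean ± SEM
across segments (segments are the statistical unit; pooled counts are
reported nowhere). Formation and elimination fractions divide by the number
of distinct beta lineages observed at any session; survival fractions
divide by the day-0 count, so elimination and survival deliberately do not
sum to 100 %. Rest-phase elimination defaults to the pre-existing
accounting (baseline boutons lost during rest); the alternative that also
counts losses of training-formed boutons is always computed alongside and
is provably ≥ the default. The 4-day turnover rate is
(formation + elimination)/2, reported both as a fraction and as events per
100 µm. Segments with no observed betas contribute to densities but are
excluded (as NaN) from fraction aggregation; segments with no baseline
boutons are excluded from survival; segments with no training-formed
boutons are excluded from stabilization.

## Inference (`groupstats`)

Two-group comparisons use the Mann–Whitney U test (exact null distribution
for pooled n ≤ 20 without ties, otherwise the normal approximation with
midrank tie handling and continuity correction; identical samples return
p = 1 with a degeneracy flag). The genotype × phase analysis is a linear
mixed model with genotype, phase, and their interaction as fixed effects
and random intercepts for mouse and for axon nested within mouse, fitted by
REML (Powell optimizer — it handles the variance-floor boundary that
gradient methods stall on — with an L-BFGS fallback). Whether the axon
effect should be crossed rather than nested is not stated in the source;
nesting is the physical structure (axons belong to mice) and is what the
report flags. Reference levels are fixed at wild type and the rest phase;
p-values come from the normal reference, so only |t| and p are comparable
across codings. Since the study's raw data cannot be re-tested, its
p-values are not reproduction targets; instead the module ships
operating-characteristic experiments: interaction type-I error on null
cohorts simulated from one preset (calibrated to 3.5–6.5 % at α = 0.05 over
2000 replicates), 95 % CI coverage of the known genotype × phase
elimination contrast at study scale, and power of the within-genotype
training-vs-rest comparison.

## Pipeline and problem sizes

`pipeline.run_experiment` runs either mode end to end with all stage seeds
derived from one master seed; tabular reruns are bit-identical and imaging
reruns voxel-identical. Imaging mode is capped at 100 segments per run by
default. Problem sizes used by the shipped tests and the acceptance script
are the study's own: 58 wild-type segments from 6 mice and 54 mutant
segments from 7 mice per cohort; calibration uses 600-segment cohorts;
oracle-equivalence and expectation checks use 1 200–3 000 segments
(≥ 10 000 boutons); the type-I experiment uses 2 000 replicates at study
scale.

## What the synthetic data do and do not show

The generator reproduces the published per-segment statistics, their
across-segment dispersion (via Poisson counts and Bernoulli dynamics), the
bimodal size distribution, and the acquisition geometry, PSF, noise, and
motion gates. It does not emulate: depth-dependent scattering or
photobleaching, crossing fluorescent processes and neuropil background,
terminaux boutons or axon branching, bouton size trajectories over time,
true biological mouse-to-mouse heterogeneity (off by default), or errors in
backbone tracing (traces are exact). Passing tests therefore validate the
measurement and statistics chain under the stated optical model, not
detection performance on raw in vivo data — in particular, real-data use
assumes an upstream trace and cross-day registration of comparable quality.

## Known limitations

* The published wild-type target set is internally over-determined; the
  implied training elimination is ~18.6 % against a printed 17 ± 3 %
  (within 1 SEM), and the published 23 % spontaneous beta turnover is
  incompatible with the published rest-phase rates (see Calibration).
* Sub-resolution bouton pairs (< ~4 µm around wide alphas) merge into one
  call; the generator's 0.5 µm minimum spacing permits such pairs, so
  image-mode densities run a few percent below tabular truth.
* The mixed model's p-values use the normal reference; with 6–7 mice per
  genotype a Satterthwaite or Kenward–Roger correction would be milder on
  the mouse-level terms, but the interaction inference is dominated by the
  within-mouse segment level and calibrates well empirically.
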