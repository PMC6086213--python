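# boutonflux

Quantifying the structural plasticity of **axonal boutons** — the
presynaptic varicosities of en passant synapses — from longitudinal
two-photon imaging of layer-5 pyramidal-neuron projections to layer 1 of
mouse motor cortex. The package targets the train-then-rest paradigm used
to compare wild-type mice against the MECP2-duplication (Tg1) model of
syndromic autism: each axon segment is imaged at baseline (day 0), after
four days of rotarod training (day 4), and after four days of home-cage
rest (day 8), and every bouton is scored as maintained, formed, or
eliminated in each phase.

Because the original imaging data are not publicly deposited, the package
is built around a calibrated synthetic cohort generator, so every stage of
the measurement chain is testable against known ground truth:

1. **`synthcohort`** — generative model of bouton populations and dynamics
   (alpha boutons > 2 µm, nearly immortal; beta boutons 1–2 µm, plastic),
   with `calibrate_preset` tuning latent survival/formation parameters to
   published cohort statistics;
2. **`imagesim`** — 2-photon-like image stacks (Gaussian-tube axon,
   Gaussian boutons, anisotropic PSF, Poisson + read noise, motion within
   the study's quality gates) plus the 0.1 µm bead used to calibrate the
   point-spread function;
3. **`boutondetect`** — the varicosity criteria (> 0.3 µm wider than the
   local shaft **and** > 2× brighter than the local backbone), FWHM
   diameter measurement, the 2 µm alpha/beta classification, and the 50 µm
   isolation filter;
4. **`boutontrack`** — greedy nearest-neighbour matching of calls across
   days and formed/eliminated/maintained event labels per lineage;
5. **`turnoverstats`** — the per-segment statistics: densities per 100 µm,
   formation/elimination fractions of the total observed boutons, the
   4-day turnover rate (gain + loss)/2, survival and stabilization
   fractions, aggregated as mean ± SEM across segments;
6. **`groupstats`** — Mann–Whitney U contrasts and the genotype × phase
   linear mixed model (random intercepts for mouse and axon-in-mouse),
   plus type-I/coverage/power calibration experiments;
7. **`pipeline` / `boutonflux` CLI** — end-to-end orchestration in a fast
   tabular mode or a full imaging mode.

## The statistics it computes

For each segment with bouton lineages observed over days 0/4/8 (N = number
of distinct beta boutons seen at any session):

```
formation_phase    = newly formed in phase / N
elimination_phase  = baseline boutons lost in phase / N
TOR                = (formation + elimination) / 2        (per phase)
survival_d        = baseline boutons still present at day d / baseline count
stabilization      = training-formed boutons present at day 8 / training-formed
density_class      = 100 × count / segment length (µm)
```

Cohort values are unweighted means ± SEM across segments; inference uses
Mann–Whitney U for two-group contrasts and REML mixed models for the
genotype × phase design.

## Worked example

```python
from boutonflux import synthcohort as sc, turnoverstats as ts
from boutonflux.schedule import TRAIN_REST

wt = sc.wt_preset(seed=0)          # calibrate latent parameters
cohort = sc.sample_cohort(wt, TRAIN_REST, seed=0)   # 58 segments, 6 mice
table = ts.segment_statistics(
    sc.lineage_table(cohort), sc.segments_frame(cohort)
)
agg = ts.aggregate_cohort(table).set_index("statistic")
for stat in ("elimination_training", "elimination_rest", "survival_d4",
             "stabilization_new", "density_alpha"):
    row = agg.loc[stat]
    print(f"{stat:22s} {row['mean']:.3f} ± {row['sem']:.3f} (n={row['n']:.0f})")
```

prints (seed 0):

```
elimination_training   0.180 ± 0.025 (n=58)
elimination_rest       0.085 ± 0.022 (n=58)
survival_d4            0.773 ± 0.029 (n=58)
stabilization_new      0.346 ± 0.075 (n=32)
density_alpha          2.784 ± 0.194 (n=58)
```

i.e. training roughly doubles beta-bouton elimination relative to rest
(18 % vs 8.5 % of observed boutons) while 77 % of baseline boutons survive
training, and newly formed boutons stabilize at ~35 % — the wild-type
phenotype the generator is calibrated to. Swapping in
`sc.mecp2dup_preset()` reproduces the mutant phenotype (≈ 5 % training
elimination, ≈ 95 % day-4 survival), and
`groupstats.report_contrasts(...)` on the combined table emits the full
Mann–Whitney and mixed-model battery.

The same analysis can be driven through images:

```bash
boutonflux run --mode imaging --seed 0 --out out/   # render → detect → track → stats
boutonflux detect --stack seg.tif --trace seg.swc --out calls.csv
```

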