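# Methods

## Experimental designs modeled

Two hydroponic designs, both with 10-L basins, triplicate basins per
treatment, 7-day endpoints, and per-plant measurement of root length (cm),
plant height (cm) and dry weight (g/plant):

1. **Competition intensity** — 20 target (rice) + 20 neighbor
   (barnyardgrass) seedlings per basin in alternating rows, against
   20-seedling monocultures of each species. Sowing proportions are equal,
   so the competitive-ratio density correction is 1.
2. **Two-step decomposition bioassay** — 20 donor (rice) + 10 receiver
   (weed) seedlings mixed, against a 10-seedling receiver monoculture
   (step 1, measures TB); then fresh receiver seedlings grown alone in the
   recovered mixture solution with N, P, K restored to standard Hoagland
   levels (step 2, measures AE). With competition physically removed and
   nutrients equalized, any remaining effect is attributed to released
   chemicals; RC = TB − AE follows by subtraction.

## Indices and conventions

All indices are computed from group means at full precision; rounding
(half-even, 4 dp for RCI/RNE/CR, 2 dp for IR and shares) is applied only on
display. Group means are means of basin means (basins are the randomized
units, n = 3), with a per-plant option (`unit="plant"`). The published
index table is exactly reproducible from the published group means via the
grand-mean path, which is therefore the validated default; per-replicate
index distributions are available for uncertainty instead.

Degenerate inputs raise `UndefinedIndexError` rather than returning
infinities: a dead monoculture control (performance 0) invalidates the
design rather than producing an index. Negative RC (AE measured larger
than TB) is reported and flagged `negative_rc`, never clamped — net
facilitation is a legitimate outcome, and indeed the allelopathic accession
shows negative RCI/RNE in mixture. A zero-TB row flags its share as
undefined (NaN) instead of dividing by zero.

Standard errors for TB/AE computed from raw observations pair treatment
basin *i* with control basin *i* (sorted replicate index) and take the SE
of the per-replicate inhibitory rates. The original report does not state
its pairing, so fixture-driven checks compare means only and the SE logic
is validated against synthetic data.

## Group statistics

One-way fixed-effects ANOVA (F = MS_between/MS_within) followed by Fisher's
LSD, `t(1−α/2, df_err)·sqrt(MSE·(1/n_i+1/n_j))`, two-sided, α = 0.05. The
LSD is *protected* by default (no pair flagged unless the omnibus test is
significant), which controls familywise type-I error; the unprotected
variant is a toggle. These are the textbook formulas, not a re-implementation
of any particular statistics package's behavior. Zero within-group variance
with distinct means is reported as F = ∞, p = 0 with a warning.

## Synthetic-data generator

The generator emulates both designs from a known truth: baseline
monoculture performance b per (species, trait), and per (receiver, donor)
pair a competition effect c and an allelopathy effect a expressed as
fractional reductions (negative = facilitation). Arm expectations:

| arm | additive (default) | multiplicative |
|---|---|---|
| monoculture | b | b |
| mixed | b(1−c−a) | b(1−c)(1−a) |
| residual solution | b(1−a) | b(1−a) |

The additive model is the default because the subtraction decomposition is
then exactly identifiable — a noise-free pipeline recovers TB = 100(c+a),
AE = 100a, RC = 100c. The multiplicative option exists to study
misspecification: there the subtraction recovers RC = 100·c(1−a), a
relative shortfall of c·a/(c+a−ca) (`multiplicative_rc_mismatch`),
documented and tested in closed form but not asserted as correct recovery.

Measurement noise is per-plant multiplicative lognormal with unit mean and
configurable CV (trait values are positive and published CVs are small,
roughly 2–4% of the mean); additive Gaussian noise is an option (clipped at
0). The default `noise_cv = 0.05` is a modeling choice — within-basin
variances are not published — chosen slightly above the published
between-basin CVs to be conservative. Defaults: 3 basins, 20/10 plants per
design group, effects c = 0.2, a = 0.3 in the recovery configuration.

Each (species, arm, replicate) draws from its own RNG stream derived from
the master seed by stable CRC32 hashing of the key, so extending a design
with a new arm never changes existing draws, and identical config + seed
gives byte-identical output.

What the generator does **not** emulate: growth dynamics (effects are
endpoint multipliers), nutrient-depletion feedbacks, within-basin spatial
structure, density dependence of the effects, or basin-level random
effects (plants within a basin are i.i.d.). Passing recovery tests
therefore show the *pipeline algebra and sampling behavior* are correct
under the stated model, not that real mixed-culture data satisfy the
additive separation.

## Reproduction checks and problem sizes

`report.reproduce_paper` regenerates the competition-index table and the
TB/AE decomposition from the packaged group-mean fixtures and compares
every cell with its published value at half-ulp-of-printed-precision,
|computed − printed| ≤ 0.5×10^(−d) for d printed decimals — exactly the
slack introduced by the original rounding. The qualitative neighbor-effect
verdicts (facilitation for the allelopathic accession, competition for the
other two) are checked by sign only; the published figure's bar heights are
not printed anywhere and are not asserted.

The recovery study in `analysis/03` and the test suite uses 200 runs of the
two-step design at the default sizes (3 basins × 10 receiver plants,
CV 5%), a single trait per run; this gives a Monte-Carlo SE on the mean
recovered share of ≈0.1 percentage points, ample for the ±3-point check,
and completes in seconds. The replicate grid (2/8/32 basins) demonstrates
the expected monotone RMSE decrease.

## Known limitations

- The decomposition assumes effects add on the IR scale; under
  multiplicative interference the RC component is biased (quantified
  above).
- The published TB/AE rates for the second experiment cannot be re-derived
  from the first experiment's group means (different densities, raw means
  unpublished), so the decomposition fixtures start from the published
  rates themselves.
- Residual-solution assays attribute *all* non-nutrient solution effects to
  allelochemicals; microbial or pH differences are not separable here, and
  the `nutrients_replenished=False` flag only warns about the nutrient
  confound.
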