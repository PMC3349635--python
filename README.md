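# allelosep

Tools for separating **allelopathy** (chemical interference via root
exudates) from **resource competition** in plant–plant interference, built
around target–neighbor mixed-culture experiments in hydroponics. The
motivating system is rice vs. barnyardgrass (*Echinochloa crus-galli*): an
allelopathic rice accession (PI312777) and a non-allelopathic one (Lemont)
grown with the weed, where endpoint traits (root length, plant height, dry
weight) measure how strongly each plant affects its neighbor.

Intended users: quantitative plant ecologists and weed scientists analyzing
mixed-culture / bioassay experiments, and anyone who wants the standard
interference indices with verified, reproducible numerics.

## The statistics

For a focal plant with monoculture performance $P_{mono}$ and mixed-culture
performance $P_{mix}$:

- **RCI** (relative competition intensity): $(P_{mono}-P_{mix})/P_{mono}$ —
  positive = inhibition, negative = facilitation.
- **RNE** (relative neighbor effect): $(P_{mono}-P_{mix})/\max(P_{mono},P_{mix})$
  — same sign as RCI, symmetric and bounded in $[-1,1]$.
- **CR** (competitive ratio, Willey & Rao): the ratio of the two species'
  relative yields, $\dfrac{P_{mix}^{f}/P_{mono}^{f}}{P_{mix}^{p}/P_{mono}^{p}}
  \cdot \dfrac{z_p}{z_f}$ with sowing proportions $z$; by construction
  $CR_{fp}\cdot CR_{pf}=1$.
- **IR** (inhibitory rate): $(1-\text{treatment}/\text{control})\times 100\%$.

The decomposition uses a two-step bioassay: the inhibitory rate of the
mixture on the receiver is the **total biointerference** (TB); growing the
receiver alone in the mixture's *residual solution* (nutrients replenished)
yields the **allelopathic effect** (AE), because only released chemicals
remain. Then **resource competition** is RC = TB − AE, and AE/TB is the
allelopathic share of interference.

Group summaries use basin (replicate) means; significance testing is
one-way ANOVA followed by protected LSD at the 5% level.

## Worked example

```python
>>> from allelosep import relative_competition_intensity, competitive_ratio, decompose
>>> round(relative_competition_intensity(7.32, 2.66), 4)   # weed root length vs PI
0.6366
>>> round(competitive_ratio(8.73, 10.26, 7.32, 2.66), 4)   # PI over the weed
3.2342
>>> r = decompose(tb=57.79, ae=40.88)
>>> round(r.rc, 2), round(r.ae_share, 2)
(16.91, 70.74)
```

One PI312777 plant is as competitive as ~3.2 weed plants on root length,
and 70.74% of its total interference on the weed is allelopathic rather
than resource-mediated.

The full analysis is scripted:

```sh
python analysis/01_competition_indices.py    # RCI/RNE/CR table + verdicts
python analysis/02_decompose_interference.py # TB/AE/RC split + stacked bars
python analysis/03_parameter_recovery.py     # simulation-based validation
```

`analysis/01` prints `index cells matching published values: 24/24`;
`analysis/02` prints `allelopathic shares matching published values: 6/6`
and the decomposition rows (e.g. PI/RL: TB 57.79, AE 40.88, RC 16.91, share
70.74%); `analysis/03` reports a mean recovered allelopathic share of
59.96% against a generative truth of 60% (200 noisy runs, triplicate
basins). Tables land under `results/`.

There is also a CLI (`allelosep compute-indices|decompose|simulate|
reproduce-paper|recovery-study`) and a synthetic-data generator
(`allelosep.synthetic_data`) that simulates both experimental designs from
known competition/allelopathy effect sizes — see `docs/methods.md`.

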