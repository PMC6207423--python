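# manakin

Analysis toolkit for the divergence of bearded-manakin (*Manacus*)
courtship displays and the muscle physiology underneath them. The
package covers three linked analyses plus the data plumbing and
synthetic generators needed to exercise them end to end:

1. **Ancestral range reconstruction** — species ranges are summarised
   by 12 boundary index points, embedded on the unit sphere, and
   evolved backwards along the phylogeny under Brownian motion with a
   Metropolis–Hastings sampler. Credible ancestral polygons and
   pairwise range overlap quantify whether diverging populations were
   sympatric (overlap of the smaller range above a threshold).
2. **Display divergence** — roll-snap speed (snaps/s) and length
   (snap count) from field recordings are compared across species with
   random-intercept mixed models and FDR-adjusted post-hoc contrasts,
   and the speed–length trade-off is probed with an exact
   (LP-solved) weighted quantile-regression scan across τ = 0.1–0.9:
   significantly negative upper-quantile slopes mark a performance
   constraint, and the scan reports how deep into the distribution it
   reaches.
3. **Twitch kinetics** — percent relaxation of the wing muscle
   (scapulohumeralis caudalis) under stimulation trains is fitted with
   a 4-parameter logistic frequency response (half-relaxation
   frequency f₅₀), within-train rapid fatigue is measured as the
   pulse-wise slope, and the slope-vs-frequency trend yields f*, the
   fastest sustainable contraction rate (upper confidence band
   zero-crossing).

Modules: `io_formats` (Newick trees, GeoJSON ranges, TSV tables),
`range_reconstruction`, `display_divergence`, `twitch_kinetics`,
`synthetic_data` (seeded generators with known ground truth), and
`cli_pipeline` (config-driven orchestration + `manakin` CLI).
The scientific background and model details are in
[docs/methods.md](docs/methods.md).

## Tests

```sh
pip install --no-build-isolation -e '.[test]'
python -m pytest -q tests/
```

Two tests in `tests/test_acceptance.py` score the analysis chain
against the published field datasets and fail unless
`data/Data_acoustics.txt` and `data/Data_fatigue.txt` (the original
source-data supplements) are placed under `data/`; everything else is
self-contained.

## Worked example

Simulate a study-scale display dataset and test species divergence:

```text
$ manakin simulate displays --seed 7 --out demo/sim
wrote demo/sim
$ manakin species-divergence --table demo/sim/acoustics.tsv
species effect on speed: F(3,155) = 7.323, p = 0.0001269
              a               b  estimate       se         z        p    p_adj letters
golden_collared orange_collared  3.429861 0.756569  4.533439 0.000006 0.000035     a|c
golden_collared   white_bearded  1.603948 0.553492  2.897869 0.003757 0.011271     a|b
golden_collared  white_collared  1.964028 0.735361  2.670836 0.007566 0.012348     a|b
orange_collared   white_bearded -1.825913 0.691008 -2.642392 0.008232 0.012348     c|b
orange_collared  white_collared -1.465833 0.843860 -1.737058 0.082377 0.098852     c|b
  white_bearded  white_collared  0.360080 0.667251  0.539647 0.589440 0.589440     b|b
```

The letter groups read like figure annotations: species sharing a
letter are not significantly different after FDR adjustment.

Twitch kinetics on simulated golden-collared stimulation trains:

```text
$ manakin simulate twitch --seed 7 --out demo/tw
wrote demo/tw
$ manakin twitch-analysis --fatigue demo/tw/fatigue_golden_collared.tsv \
    --phases demo/tw/twitchspeed_golden_collared.tsv --out demo/twitch.json
wrote demo/twitch.json
```

`demo/twitch.json` then contains (abridged):

```json
"frequency_response": {"golden_collared": {"f50": 93.98, "f50_se": 2.70, ...}},
"fatigue_trend":      {"golden_collared": {"gamma": -0.156, "F": 33.66,
                                           "df": [1, 6], "p": 0.00115,
                                           "fstar": 54.51, ...}}
```

i.e. the muscle's half-relaxation frequency is ~94 Hz, rapid fatigue
steepens with frequency (F(1,6) = 33.7), and the upper confidence band
of the trend crosses zero near 55 Hz — close to this species' display
speed.

The same analyses run as one pipeline from a YAML config:

```sh
manakin run --config cfg.yaml   # writes report.json + report.md
```

with keys `seed`, `output_dir`, `stages` (`ranges`, `displays`,
`twitch`), and per-stage sections (see `manakin run --help`). Given
only a seed, every stage simulates its inputs and reports estimate
vs truth recovery; the same config and seed yield a byte-identical
`report.json`.

## Reproduction

All headline quantities can be recomputed from a single seed:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This runs each stage end-to-end on generated data (~15 s) and writes a
flat JSON of named quantities — range-recovery overlaps, MCMC
acceptance rate, mixed-model F statistics, quantile-scan results,
f₅₀/f* estimates and the recovery-harness error summaries — each with
its sample size. Different seeds give statistically equivalent, not
identical, values.
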