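# stressmeta

Simulation and analysis pipeline linking stress reactivity to metacognitive
accuracy. The package generates synthetic cohorts — 2IFC (two-interval
forced choice) trials with confidence ratings, salivary cortisol panels, and
heart-rate traces — and runs the full analysis chain on them:

1. **synthetic** — signal-detection observer with a late metacognitive-noise
   stage (degrades the confidence–accuracy link without touching accuracy),
   cortisol profiles with low/medium/high peak reactivity, heart-rate traces
   with group-specific variance elevation. Fully reproducible from a single
   master seed with per-participant derived streams.
2. **staircase** — interleaved 1-up 2-down adaptive calibration with
   reversal-based threshold estimation (converges to the 70.7% point).
3. **metacognition** — type-2 ROC construction over confidence bins
   (equal-width on [0.5, 1] by default, equal-count available), trapezoidal
   AUC, calibration metrics, and a permutation null for AUC.
4. **screening** — rank-percentile classification into low/medium/high
   cortisol-reactivity groups plus the 1.1 nmol/l responder criterion.
5. **hrv** — per-minute windowed SD of heart rate, LOWESS smoothing, and a
   participant-level bootstrap two-group comparison with 95% bands and
   significance clusters.
6. **group_stats** — RT filtering, one-way ANOVA with eta², Bonferroni
   pairwise post-hocs, mixed pre/post ANOVA with partial eta², and the
   AUC-on-cortisol regression.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(staircase convergence, AUC oracle equivalence, independence nulls,
monotone degradation, parameter recovery, responder rule, HRV cluster
recovery, statistics oracles). The oracle comparisons use independent
implementations (brute-force pairwise AUC, scipy, pingouin).

## CLI

```bash
stressmeta run-all --seed 1 --out out/            # full pipeline
stressmeta simulate-cohort --seed 1 --out out/    # cohort CSVs only
stressmeta calibrate --params params.json --out out/
stressmeta score  --trials out/trials.csv --out summary.csv
stressmeta screen --cortisol out/cortisol.csv --out assignments.csv
stressmeta hrv    --heart-rate out/heart_rate.csv --assignments out/participants.csv --out hrv/
stressmeta analyze --summary summary.csv --assignments out/participants.csv --out results.json
```

All stages accept `--config config.json` (see `stressmeta.pipeline.PipelineConfig`
for the schema); `run-all` writes a manifest with the seed and a config hash,
and reruns are bit-identical.

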