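# ecogseq

Spatiotemporal analysis of event-related intracranial (ECoG) recordings,
built around high-frequency broadband power (HFB, 70–180 Hz) — a proxy for
aggregate local neuronal population spiking. The package targets studies of
self- and other-mentalizing (trait judgments about oneself vs. another
person, with an arithmetic control task) and answers *when* each cortical
region activates and how that timing relates to behavior: visual cortex
first, temporoparietal default-mode regions (TPJ, ATL, PMC) next, medial
prefrontal regions (amPFC, dmPFC, vmPFC) last, with later regions more
mentalizing-specific and more tightly coupled to the behavioral response.

It is written for electrophysiologists and computational researchers who
want the full chain as tested, reusable code rather than one-off scripts:

* **`simulate`** — ground-truthed synthetic sessions: pink-noise background
  + line noise + band-limited HFB bursts with trapezoidal envelopes,
  response times coupled to burst offsets, choices from a logistic
  valence-bias model. Every draw is reproducible from `(config, seed)`.
* **`preprocess`** — notch → common average → 5-cycle Morlet decomposition →
  per-band z → epochs [−200, 5000) ms → per-trial baseline correction →
  HFB band average → 50-ms gaussian smoothing, plus trial exclusions and
  3-scaled-MAD timepoint outlier masking.
* **`single_trial`** — the activation detector: ±10 ms sliding tests of each
  timepoint against the trial's pre-stimulus baseline (with an
  autocorrelation-aware variance so millisecond band power does not break
  the test), Benjamini–Yekutieli FDR jointly across timepoints × trials ×
  sites, a 50-ms persistence rule, and five metrics per trial: onset, peak
  and offset latency, duration, peak power.
* **`trial_averaged`** — evoked timecourses β(t) vs. baseline, site
  active/deactive/nonresponsive labels, time-window summaries, ROI grand
  averages.
* **`classify`** — mentalizing-specificity and self/other-selectivity site
  labels from the activity pattern plus bisquare-robust peak-power
  comparisons; self- vs. other-selective counts with Yates-corrected
  McNemar χ².
* **`roi`** — aggregate ROI mixed models (type / RT / choice effects per
  metric), RT-controlled pairwise ROI latency contrasts, the
  onset → specificity logistic classification, second-level
  onset-vs-effect-size models, and the mPFC offset-to-response contrast,
  behind two-stage robust outlier filtering.
* **`behavior`** — the self-positivity choice-bias model and the RT model.
* **`stats`** — the primitives: Welch's t, BY-FDR, Tukey-bisquare IRLS,
  scaled MAD, McNemar–Yates.
* **`pipeline` / CLI** — `ecogseq simulate|detect|run-all` orchestration
  with manifests; identical seeds give byte-identical tables.

## Worked example

```python
from ecogseq.pipeline import RunConfig, run_pipeline

tables = run_pipeline(RunConfig(seed=3, out_dir="results/demo"))
print(tables["pairwise_onsets"][["roi_x", "roi_y", "b", "p_adj", "sig"]]
      .head(6).to_string(index=False))
```

```
 roi_x roi_y        b  p_adj   sig
Visual   TPJ -224.586  0.000  True
Visual   ATL -246.248  0.000  True
Visual   PMC -232.417  0.000  True
Visual amPFC -394.289  0.000  True
Visual dmPFC -377.671  0.000  True
Visual vmPFC -469.274  0.000  True
```

This simulates a three-participant study (one site per ROI, 12 trials per
condition), detects single-trial activations, and fits the RT-controlled
pairwise ROI latency models. Each row is the onset-latency contrast
ROI_X − ROI_Y in milliseconds: visual cortex activates ~225 ms before TPJ
and ~470 ms before vmPFC, the BY-adjusted p-values mark which contrasts
survive FDR across the 21 ROI pairs, and the full table reproduces the
ordering Visual < {TPJ, ATL, PMC} < {amPFC, dmPFC} < vmPFC with
nonsignificant differences inside each tier. `results/demo/` also holds the
activation-metric table, site labels and specificity/selectivity profiles,
Table-1-style ROI effect estimates, behavioral model fits, and a JSON
manifest (config hash + seed + version) that makes the run reproducible.

See `docs/methods.md` for the model and algorithm details, the synthetic
generator's assumptions, and known limitations.

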