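# conflictdm

Analysis pipeline for approach–avoid decision-making under motivational
conflict on a linear track:

- **microstructure** — gap-filled tracking traces → motion segments
  (toward goal / toward start / paused), pause-resolved approach–avoid
  decisions, k-means spatial zones with silhouette scores, and log-normal
  RT summaries.
- **lba** — analytic linear ballistic accumulator race model (defective
  densities, choice probabilities, race sampler, response caution
  `b − A/2`) plus Bayesian estimation per subject × zone with
  truncated-normal priors, three-chain MCMC, and split-R̂ / effective
  sample size convergence checks.
- **photometry** — isosbestic-corrected dF/F
  (`(Ca − fitted isosbestic) / fitted isosbestic`), peri-event kernels
  (−5…+5 s, baselined to −5…−2.5 s), subject-level bootstrap CIs with the
  `√(n/(n−1))` expansion and the 1/3 s persistence rule for significant
  transients, spatial dF/F maps in 5 cm bins.
- **linkage** — joins per-(subject, zone) LBA posterior means with mean
  pause dF/F; per-parameter correlations and a standardized two-predictor
  regression of dF/F on approach/avoid drifts.
- **synth** — ground-truth-labeled synthetic cohorts (bistable
  oscillations, spatial pause hazard, zone-wise LBA decisions, two-channel
  photometry with shared multiplicative artifacts and goal-locked or
  spatially ramping signals) used to exercise everything end-to-end.

## CLI

```bash
conflictdm --seed 1 --out out/ run-all        # simulate + full analysis
conflictdm --seed 1 --out out/ simulate       # write tracking/photometry CSVs
conflictdm --out out/ segment                 # pauses + zones from CSVs
conflictdm --out out/ fit-lba                 # Bayesian LBA fits
conflictdm --out out/ photometry              # dF/F, spatial maps, pause dF/F
conflictdm --out out/ link                    # linkage table + regression
conflictdm --out out/ report                  # print the findings
```

An optional `--config path` points to a flat `key = value` file; keys
match `CohortConfig` fields (e.g. `n_subjects = 8`) and sampler fields
with a `sampler.` prefix (e.g. `sampler.iterations = 2000`). Outputs are
CSV/JSON plus a reproducibility manifest; reruns with the same seeds are
bit-identical.

## Layout

```
src/conflictdm/
  lba/core.py        analytic race model
  lba/inference.py   priors, slice MCMC, diagnostics, per-zone fits
  microstructure.py  tracking → pauses, zones, RT summaries
  photometry.py      dF/F, kernels, bootstrap, spatial maps
  synth.py           synthetic cohort generator with ground truth
  linkage.py         neural–behavioral joins, correlations, regression
  pipeline.py        end-to-end orchestration + report bundle
  cli.py             click CLI
```
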