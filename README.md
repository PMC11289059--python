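# prtddm

Simulation and analysis toolkit for the probabilistic reward task (PRT):
a generative simulator of the task and of drift-diffusion (DDM) agents, the
signal-detection response-bias/discriminability indices (log b, log d), the
standard preprocessing rules, and a hierarchical Bayesian DDM fitted by MCMC
— with parameter recovery on synthetic cohorts as the primary validation
surface.

## Modules

| module | what it does |
|---|---|
| `prtddm.task_sim` | balanced rich/lean trial schedules, skewed (75%/25%) reward-on-correct assignment, DDM agents, synthetic cohorts |
| `prtddm.wfpt` | numerically stable Wiener first-passage-time log-density (small/large-time series), phi bias mapping, parameter validation, Euler–Maruyama process sampler |
| `prtddm.hier_model` | hierarchical Bayesian DDM: group-level (feedback type × block) distributions, truncated-normal individual levels, rich/lean-specific v/a/t, complementary starting bias z(lean) = 1 − z(rich); adaptive Metropolis-within-Gibbs; split-chain R-hat |
| `prtddm.preprocess` | participant exclusion (accuracy < 50% or > 75% one button), RT window filter (0.25–2.5 s), log10 / arcsine transforms, Tukey-fence winsorization |
| `prtddm.sdt` | contingency tables, log b, log d, Δlog b reward-learning score |
| `prtddm.pipeline` | end-to-end orchestration, group summaries, and the recovery harness |

## CLI

```bash
prt simulate --n-per-group 4 --groups star,verbal,face,thumbs --seed 1 --out cohort.csv
prt preprocess --trials cohort.csv --out cohort.filtered.csv --report reports/
prt metrics --trials cohort.filtered.csv --out indices.csv
prt fit --trials cohort.filtered.csv --seed 1 --out fitdir/
prt recover --n-agents 12 --seed 1 --out recovery.json
prt report --seed 1 --out run/          # full pipeline with summary tables
prt wfpt pdf --v 1.0 --a 1.3 --t 0.3 --zraw 0 --rt 0.8 --boundary upper
```

Trial tables are long-format CSV (one row per trial: participant, group,
block, trial index, stimulus, mouth, response, correctness, reward flag, RT
in seconds, training flag); run settings are JSON.

## Notes

* Choice coding is accuracy coding: the upper boundary is the correct
  response; the response bias is expressed through the phi-mapped starting
  point z on rich-stimulus trials and 1 − z on lean-stimulus trials.
* Raw starting bias lives on [−4, 4] and is mapped to (0, 1) with the
  standard-normal CDF; boundary separation is truncated at 0 and
  non-decision time bound to [0, 1] s.
* The Euler–Maruyama sampler doubles as an independent oracle for the
  series-expansion density (normalisation, histogram, and KS agreement are
  tested).
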