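# icusurv

Discrete-time survival modelling of heterogeneous ICU event streams.

Intensive-care patients generate wildly mixed data: registry diagnosis codes
accumulated over years, free-text nursing notes, medication administrations,
lab values, and monitor vitals sampled many times per hour. `icusurv`
implements a pipeline that turns all of it into one survival model with
minimal feature engineering:

1. **Tokenization.** Every event becomes a discrete token: codes become
   tokens directly (ICD-10 history codes truncated to block level), text is
   split into words, and numeric values become `variable@percentile` symbols
   (the percentile of the value within the training distribution — 1 g of IV
   meropenem at the training median becomes `J01DH01_IV@50`). High-frequency
   signals are first aggregated to hourly min/max/median/std streams. Time is
   discretized relative to a prediction baseline (0, 24, 48 or 72 h after ICU
   admission): coarse bins before (<1, 2–7, 8–30, 31–90, 91–365, >365 days)
   and hourly slots after admission.
2. **Entity embeddings.** Each of the seven token domains gets its own
   embedding space of width `D = 6·α·V^(1/4)` for vocabulary size `V` (e.g.
   V = 10,000, α = 1 → D = 60). Embeddings are trained jointly with the rest
   of the model.
3. **Recurrent multi-label survival model.** Embedded tokens are concatenated
   per time slot, the slot sequence feeds an LSTM/GRU, the final state is
   merged with standardized age and pre-ICU hospital length of stay, and a
   sigmoid output layer emits one *conditional survival probability per
   prediction window* ([0,1), [1,7), [7,14), [14,30), [30,90), [90,365) days).
   Cumulative survival is the running product, so hazards are free to vary by
   window — no proportional-hazards assumption.
4. **Censoring-aware likelihood.** Training minimizes
   `-ℓ = -Σᵢ [log(1 + sᵢ(pᵢ-1)) + log(1 - fᵢ pᵢ)]`, where `pᵢ` is the
   predicted conditional survival of window *i* and `(sᵢ, fᵢ)` indicate
   survived/died; windows after death or censoring contribute exactly zero. A
   patient censored in the second half of a window counts as surviving it.
5. **Evaluation and explanation.** Time-dependent concordance (C^td, the
   tie-strict pairwise estimator) with 1000-resample bootstrap CIs,
   Kaplan–Meier decile calibration tables, domain-level Shapley attributions
   (nine players: seven token domains + age + LOS, with an exact
   512-coalition oracle), and a Cox proportional-hazards baseline on
   (age, sex, LOS).

Everything is exercised on synthetic cohorts with known discrete-time
hazards, generated by the built-in simulator (`icusurv.synthetic`), so every
stage is testable end to end without access to clinical data.

## Worked example

`examples/02_train_and_evaluate.py` simulates 1500 patients whose latent risk
`z ~ N(0,1)` shifts every window hazard by `γ·z` on the log-odds scale and is
carried only by the event tokens (risky diagnosis codes, shifted lab values,
doses) — never by age, sex or LOS. It then trains the model at a 24 h
baseline and prints:

```
train 971 / val 240 / test 303 admissions
stopped after 11 epochs; best val loss 1.498
window (days):            1      7     14     30     90    365
C^td recurrent model: 0.757  0.757  0.742  0.719  0.700  0.707
C^td Cox baseline:    0.396  0.432  0.447  0.473  0.474  0.474
```

C^td is the fraction of comparable patient pairs ordered correctly (0.5 =
chance). The token-based model recovers the latent risk at every horizon; the
Cox baseline, fitted on covariates that carry no risk signal, stays at
chance. The other examples demonstrate tokenization
(`01_simulate_and_tokenize.py`), calibration and life-table hazard recovery
(`03_calibration_and_hazards.py`), and Shapley attribution
(`04_explain_predictions.py`).

## Command-line pipeline

```bash
icusurv simulate --n-patients 1000 --seed 1 --out cohort.jsonl --truth truth.csv
icusurv tokenize --cohort cohort.jsonl --baseline-h 24 --out tok.json
icusurv train    --cohort cohort.jsonl --baseline-h 24 --seed 1 --out model
icusurv predict  --model model --cohort cohort.jsonl --out preds.csv
icusurv evaluate --predictions preds.csv --cohort cohort.jsonl --baseline-h 24 --out-prefix eval
icusurv explain  --model model --cohort cohort.jsonl --window 3 --out shap.csv
icusurv baseline-cox --cohort cohort.jsonl --baseline-h 24 --out cox.csv
```

Each command writes a `.manifest.json` (config hash, seeds, input digests,
timings); reruns with identical inputs and seeds are byte-identical.

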