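"""Train the recurrent survival model on a synthetic cohort and evaluate it.

Runs the full pipeline at a small scale (~2 minutes on one CPU): birthday
hold-out split, tokenizer fit on the training side only, training with early
stopping, then per-window time-dependent concordance against the Cox
baseline fitted on (age, sex, LOS) — covariates the generator keeps
independent of risk, so Cox stays near 0.5 while the token-based model does
not.
"""

import numpy as np

import icusurv as iu

BASELINE_H = 24.0

sim = iu.SimulationConfig(n_patients=1500, seed=7, post_horizon_h=BASELINE_H)
cohort, truth = iu.simulate_cohort(sim)
alive = iu.filter_alive_at_baseline(cohort, BASELINE_H)
train_all, test = iu.split_by_birthday(alive)
rng = np.random.default_rng(0)
patients = sorted(train_all.by_patient)
rng.shuffle(patients)
val_pat = set(patients[: len(patients) // 5])
tr = train_all.subset([a for a in train_all if a.patient_id not in val_pat])
va = train_all.subset([a for a in train_all if a.patient_id in val_pat])
print(f"train {len(tr)} / val {len(va)} / test {len(test)} admissions")

tok = iu.Tokenizer.fit(tr, BASELINE_H)
cfg = iu.ModelConfig(baseline_h=BASELINE_H, epochs=20, seed=0, learning_rate=3e-3,
                     dropout=0.3, recurrent_dropout=0.2, patience=4)
pad = iu.fit_padding_lengths(tok.transform_cohort(tr), cfg.padding_percentile)


def prep(c):
    labels = [iu.make_labels(a.outcome_time_d, a.event_indicator, cfg.windows,
                             BASELINE_H) for a in c]
    return iu.assemble_batch(tok.transform_cohort(c), pad, labels)


tr_b, va_b, te_b = prep(tr), prep(va), prep(test)
model = iu.build_model(cfg, tok.vocabularies, pad, iu.static_statistics(tr_b))
history = iu.train(model, tr_b, va_b, cfg)
print(f"stopped after {len(history['train_loss'])} epochs; "
      f"best val loss {min(history['val_loss']):.3f}")

S = model.predict_survival(te_b)
times = np.array([a.outcome_time_d - BASELINE_H / 24 for a in test])
events = np.array([a.event_indicator for a in test])
cs, _ = iu.c_td(S, times, events, cfg.windows)

fit = iu.fit_cox(train_all, baseline_h=BASELINE_H)
S_cox = iu.cox_survival(fit, test, cfg.windows, baseline_h=BASELINE_H)
cs_cox, _ = iu.c_td(S_cox, times, events, cfg.windows)

print("window (days):        " + "  ".join(f"{int(e):>5}" for e in cfg.windows.edges))
print("C^td recurrent model: " + "  ".join(f"{c:.3f}" for c in cs))
print("C^td Cox baseline:    " + "  ".join(f"{c:.3f}" for c in cs_cox))
# C^td is the fraction of comparable patient pairs the model orders
# correctly; 0.5 is chance. The token-based model recovers the latent risk
# that drives the simulated hazards, the covariate-only Cox model cannot.
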