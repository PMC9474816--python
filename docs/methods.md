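# Methods

## The model

Follow-up after a prediction baseline is partitioned into windows
[0,1), [1,7), [7,14), [14,30), [30,90), [90,365) days. The model emits one
conditional survival probability per window,
`p_i = P(survive window i | survived windows 1..i-1)`; cumulative survival is
`S_k = Π_{i≤k} p_i` and the discrete hazard is `1 - p_i`. Because each window
has its own output node, hazards may rise and fall freely over follow-up —
the proportional-hazards assumption is deliberately absent.

The per-admission log-likelihood is

    ℓ = Σ_i [ log(1 + s_i·(p_i − 1)) + log(1 − f_i·p_i) ]

with indicator vectors `s` (survived window i) and `f` (died in window i).
Algebraically this is `Σ_i [s_i·log p_i + f_i·log(1 − p_i)]`, a masked
binary cross-entropy: windows after death or censoring have `s_i = f_i = 0`
and contribute exactly zero, so only patients genuinely at risk in a window
back-propagate loss there. Censoring is labelled by the half-window rule: a
patient censored in the second half of a window (at or past its midpoint —
ties count as second half) is treated as surviving that window; otherwise
only the preceding windows. Follow-up is administratively censored at 365
days. The likelihood assumes non-informative censoring.

Conventions the labelling leaves open and the package fixes: window
membership uses half-open `[lower, upper)` intervals, so a death at exactly
day 7 falls in [7,14); a death recorded past the last edge is an
administratively censored survivor.

## Architecture

Per domain d, tokens are embedded in `D_d = max(1, round(6·α·V_d^(1/4)))`
dimensions (round half-up; the two reference points V = 10,000 → D = 60 and
V = 1000 → D = 34 at α = 1 hold exactly). Each (time-slot, domain) bucket is
padded/truncated to a fixed token count `L_d` — the padding percentile
(default 95) of the positive per-slot token counts in training data —
keeping the most recent tokens; embedded vectors are concatenated within the
domain and then across the seven domains into one slot vector. The slot
sequence — six pre-baseline bins oldest→newest, then hourly post-admission
slots up to the baseline — is unrolled by a GRU or LSTM. The final hidden
state, concatenated with age and pre-ICU hospital LOS standardized by
training-set mean/sd, feeds a dense layer with sigmoid outputs, one per
window. The sigmoid is required for the outputs to be probabilities; the
"conditional survival" reading of each node is what makes the likelihood
above a likelihood.

PAD (index 0) and OOV (index 1) are reserved in every vocabulary;
vocabularies are fitted on the training split only with deterministic
lexicographic index assignment, so any test-time token maps to a valid index
(real or OOV) and runs reproduce without a vocabulary seed.

The network and its gradients are implemented in numpy via a small
reverse-mode autodiff core (`icusurv._autodiff`), trained with Adam. This
keeps training CPU-deterministic under a fixed seed; gradients are verified
against finite differences in the test suite. Regularization: inverted
dropout on the final hidden state, variational (per-sequence mask) dropout
on the recurrent state, and L2 on the recurrent and output weight matrices.
The tuned search ranges (hidden units 128–384, dropout 0.1–0.8, L2
1e-4–0.1, α 0.2–2, padding percentile 90–98, cell ∈ {LSTM, GRU}) live in
`SEARCH_SPACE` and are sampled uniformly by the random-search stub;
`ModelConfig` additionally accepts 0.0 for the dropout/L2 knobs so
regularization can be switched off, e.g. when fitting the intercept-only
model whose hazards must converge to the closed-form life-table maximum
likelihood (dropout noise would bias that fit — measurably, by ~0.02 on a
hazard of 0.25).

## Tokenization details

* Numeric percentile: mid-rank empirical CDF,
  `F(v) = (#{x < v} + 0.5·#{x = v}) / n`, rounded half-up and clipped to
  [0,100]. This makes a value at the median of a symmetric training sample
  map to exactly 50.
* Hourly aggregation: per (variable, clock hour) with ≥1 observation, four
  derived events `<var>_min/_max/_median/_std` (sample std, 0 for a single
  observation so the four streams stay aligned). Each derived variable gets
  its own percentile entry.
* Words: lowercase, split on non-alphanumerics (Danish letters æøå kept);
  no stemming or negation handling.
* ICD-10 "block level" is operationalised as the 3-character category after
  stripping a Danish `D` prefix and dots (`DJ18.9` → `J18`); the truncation
  rule is a configurable argument of `code_to_token` because the exact block
  convention is an assumption. Medication tokens always combine ATC+route
  code with the dose percentile when a dose exists.
* Leakage guard: `discretize_time` raises for any event at or after the
  baseline; tokenized output is invariant to arbitrary mutation of
  post-baseline events (property-tested).

## Evaluation

* C^td: over pairs (i, j) with `T_i < T_j` and i uncensored, the fraction
  where window-specific predicted survival orders them correctly
  (`S_i < S_j`); tied predictions earn no credit. Per-window C^td by default
  truncates follow-up administratively at the window's upper edge (deaths
  beyond it count as censored there); `truncate=False` gives the
  whole-follow-up variant, under which proportional-hazards predictions
  yield exactly one constant value across windows. The implementation is
  vectorized and is tested for exact equality against an O(n²) loop oracle.
* Bootstrap CIs: percentile 2.5/97.5 over 1000 seeded resamples of subjects.
* Calibration: subjects grouped by deciles of the predicted survival for a
  window; per group, mean prediction vs the Kaplan–Meier estimate at the
  window's upper edge. Degenerate (tied) prediction distributions leave
  empty groups, which are flagged rather than silently dropped.
* Kaplan–Meier estimation delegates to lifelines (Greenwood-based CIs); the
  Cox baseline delegates to scikit-survival (Breslow ties, Breslow baseline
  hazard), checked against a hand-written partial-likelihood grid search.
* Life tables: two estimators. The label-based one (failures / contributors
  under the half-window rule) is the maximum-likelihood hazard of the
  intercept-only discrete-time model and is unbiased under uniform
  censoring; the naive deaths/at-risk-entering estimator is biased low in
  wide windows when censoring occurs inside them (e.g. 0.233 vs a true 0.25
  in [90,365) with 20% uniform censoring) and is kept for the
  censoring-free case.

## Explanation

Shapley attributions use nine players: the seven token domains plus age and
LOS. An absent token domain has its indices replaced by PAD; an absent
static feature takes the background-sample mean. Attributions are estimated
by permutation sampling (average marginal contribution over sampled player
orderings); contributions telescope within each permutation, so efficiency
`Σφ_d = f(x) − f(fully-masked reference)` holds exactly. The fully-masked
reference is the natural baseline under this masking convention; the
cohort-mean prediction over the background sample is reported alongside and
generally differs from it slightly. With nine players the exact Shapley
value is computable by 512-coalition enumeration, which serves as the
testing oracle for the efficiency, dummy and symmetry axioms. Relative
impact is `|φ_d| / Σ|φ|` per prediction; cohort summaries report median,
quartiles and 1.5·IQR whiskers per (window, domain).

## The synthetic generator

Each patient draws latent risk `z ~ N(0,1)`; window hazards are
`h_i(z) = expit(logit(h*_i) + γ_i·z)` with defaults
`h* = (0.10, 0.15, 0.08, 0.12, 0.20, 0.25)` and γ = 1 (γ may vary by
window, giving non-proportional effects). Death windows are sampled from
these hazards, death times uniformly within the window; 20% of patients
receive an early uniform censoring time, everyone else is administratively
censored at 365 days. About 18% of patients have a second admission (3% a
third), which makes patient-level splitting non-trivial. Birth days follow
calendar-month length frequencies, so the first-6-days hold-out rule
captures 72/365 ≈ 19.7% of patients.

Event streams carry the risk signal only through tokens: risky vs benign
diagnosis codes (mixture probability `expit(z)`), one drug whose log-dose
shifts with z, two lab variables with mean z, note words drawn from
risky/calm lexicons, and two vitals (sinusoid + drift + noise, mean shifted
by z) sampled 1–12 times per hour so hourly aggregation is genuinely
exercised. Age, sex and LOS are independent of z by design: the Cox baseline
fitted on them is an uninformative control, while the token-based model can
reach the latent-risk ceiling (C^td ≈ 0.70–0.76 for γ = 1).

What the generator does **not** emulate: realistic code co-occurrence or
clinical language, informative censoring, measurement artefacts,
unit heterogeneity, or inter-hospital drift. Passing tests therefore
demonstrate correctness of the machinery and recoverability of a known
signal, not clinical performance.

## Problem sizes and numerical choices

The test suite uses cohorts of 5,000–100,000 patients where only outcomes
are needed (event generation disabled) and 1,500–4,000 patients with full
event streams for training runs; the end-to-end check trains at a 24 h
baseline on ~3,400 admissions for up to 30 epochs with early stopping
(patience 5) and evaluates on the ~750-admission hold-out. The
intercept-only hazard-recovery fit uses 20,000 admissions, no dropout, and
a two-stage schedule (Adam at 2e-2, then 2e-3) to settle minibatch
oscillation below the 0.01 agreement tolerance with the life table.
Probabilities are clipped to [1e-7, 1−1e-7] inside the loss; survival-curve
products and label construction are exact. All randomness flows from
`numpy.random.default_rng` seeds carried in the configs.

## Known limitations

* The discrete-time formulation cannot predict beyond the last window edge.
* Intra-slot token order is discarded (concatenation order within a slot is
  event order, but truncation keeps only the most recent `L_d` tokens).
* The numpy implementation targets desk-scale cohorts (10³–10⁵ admissions);
  it is deterministic and exact but not GPU-fast.
* A two-level risk signal (one group token doubling all hazards) caps the
  tie-strict C^td near 0.60 even for a perfect model, because within-group
  pairs cannot be ordered; discrimination checks therefore use the
  continuous latent-risk cohort.
* The random-search stub samples the documented ranges but is not a full
  hyperparameter-optimization campaign.
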