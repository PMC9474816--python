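"""Generate a small synthetic ICU cohort and tokenize it.

Prints the cohort composition, the fitted vocabulary sizes and a few tokens
from one admission, illustrating how codes, words and numeric percentiles all
become discrete symbols.
"""

import icusurv as iu

sim = iu.SimulationConfig(n_patients=300, seed=42, post_horizon_h=24.0)
cohort, truth = iu.simulate_cohort(sim)
n_events = sum(len(a.events) for a in cohort)
deaths = sum(a.event_indicator for a in cohort)
print(f"{len(cohort)} admissions, {n_events} events, {deaths} deaths within 365 d")

baseline_h = 24.0
alive = iu.filter_alive_at_baseline(cohort, baseline_h)
tok = iu.Tokenizer.fit(alive, baseline_h)
print("vocabulary sizes per domain (PAD/OOV excluded):")
for domain, vocab in tok.vocabularies.items():
    d = iu.embedding_size(vocab.size, 1.0)
    print(f"  {domain:>16}: V = {vocab.size:4d}  ->  embedding width D = {d}")

ta = tok.transform(alive.admissions[0])
shown = 0
for domain, per_slot in ta.indices.items():
    inv = {i: s for s, i in tok.vocabularies[domain].index.items()}
    for slot, idxs in zip(ta.slots, per_slot):
        for i in idxs[:2]:
            label = slot.pre_bin if slot.kind == "pre" else f"hour {slot.post_hour}"
            print(f"  [{label:>8}] {domain}: {inv.get(i, '<OOV>')}")
            shown += 1
        if shown > 12:
            break
    if shown > 12:
        break
# Each line is one discrete token the model will embed: an ICD-10 block, a
# chart word, or a variable@percentile symbol for a numeric value.
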