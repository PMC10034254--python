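"""Simulate a ground-truth longitudinal cohort and inspect its structure.

The simulator draws baseline covariates (age, sex, comorbidity), assigns a
stratum, and walks a per-stratum Markov kernel over event types until an
absorbing terminal event, emitting per-type attributes and sojourn times.
"""

from longsynth import simulate_cohort, study_like_spec, true_transition_matrix

spec = study_like_spec(n=500, seed=0)
cohort = simulate_cohort(spec, seed=1)

print(f"{cohort.n_individuals} individuals, {len(cohort.events)} events")
print(f"mean sequence length: {cohort.sequence_lengths().mean():.2f}")
print("\nevent mix (proportion of all events per type):")
print(cohort.events.label.value_counts(normalize=True).round(3).to_string())
print("\nfirst individual's event stream (head):")
print(cohort.events[cohort.events.pid == 0].head(6).to_string(index=False))
print("\nground-truth first-order kernel, stratum 0 (rows sum to 1):")
print(true_transition_matrix(spec, 0).round(3).to_string())
# Each row is the probability of the next event type given the current one;
# DEATH is absorbing, so sequences end when it is reached.
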