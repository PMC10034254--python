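"""Run the generic utility suite on a real/synthetic cohort pair.

Reports: percent difference in mean sequence length, Hellinger distance of
the event-type distribution, per-attribute Hellinger distances, row-wise
transition-matrix distances (orders 1 and 2), a multivariate Hellinger
distance, and the random-cohort (fuzzy SQL) assessment.
"""

from longsynth import (ModelConfig, evaluate_utility, fit_and_generate,
                       simulate_cohort, small_spec)

spec = small_spec(n=800, max_length=40, seed=0)
real = simulate_cohort(spec, seed=1)
_, synthetic = fit_and_generate(real, spec.schema,
                                ModelConfig(epochs=15, hidden=32, window=40,
                                            seed=0),
                                max_length=spec.max_length, seed=0)

report = evaluate_utility(real, synthetic, spec.schema, n_queries=50, seed=0)
d = report.to_dict()
print(f"percent difference in sequence lengths: "
      f"{d['sequence_length']['percent_diff']:.2f}%")
print(f"Hellinger distance of event distribution: "
      f"{d['event_distribution_hellinger']:.4f}")
ah = d["attribute_hellinger"]["summary"]
print(f"Hellinger distance of event attributes, mean (SD): "
      f"{ah['mean']:.4f} ({ah['sd']:.4f})")
for order in ("1", "2"):
    s = d["transition_hellinger"][order]["summary"]
    print(f"transition matrices of order {order}, mean (SD): "
          f"{s['mean']:.4f} ({s['sd']:.4f})")
print(f"multivariate Hellinger distance: {d['multivariate_hellinger']:.4f}")
rc = d["random_cohort"]
print(f"random cohorts: Hellinger mean {rc['hellinger_summary']['mean']:.4f}, "
      f"normalized Euclidean mean {rc['euclidean_summary']['mean']:.4f}")
# All Hellinger values live in [0, 1]; 0 means the synthetic data is
# indistinguishable from the real data on that summary.
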