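"""Train the conditional recurrent generator and synthesize a cohort.

Pipeline: sojourn computation -> integer coding -> 120-step chunking ->
teacher-forced training of the label + attribute heads -> tree-synthesized
baseline/first-event seeds -> iterative generation with attribute masking.
"""

from longsynth import ModelConfig, fit_and_generate, simulate_cohort, small_spec

spec = small_spec(n=800, max_length=40, seed=0)
real = simulate_cohort(spec, seed=1)

config = ModelConfig(epochs=15, hidden=32, window=40, seed=0)
model, synthetic = fit_and_generate(real, spec.schema, config,
                                    max_length=spec.max_length, seed=0)

first, last = model.loss_trace[0], model.loss_trace[-1]
print(f"training loss: {first['total_loss']:.3f} (epoch 0) -> "
      f"{last['total_loss']:.3f} (epoch {last['epoch']})")
print(f"real mean sequence length: {real.sequence_lengths().mean():.2f}")
print(f"synthetic mean sequence length: "
      f"{synthetic.sequence_lengths().mean():.2f}")
print("\nreal event mix:")
print(real.events.label.value_counts(normalize=True).round(3).to_string())
print("synthetic event mix:")
print(synthetic.events.label.value_counts(normalize=True).round(3).to_string())
# A close match of the event mix and mean length indicates the recurrent
# model has learned the cohort's dynamics, not just its marginals.
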