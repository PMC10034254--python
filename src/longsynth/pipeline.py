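"""End-to-end orchestration: prepare -> train -> generate -> evaluate.

These functions are the library form of the command-line workflow; the CLI
is a thin wrapper around them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .baseline_synth import synthesize_seeds
from .cohort import Cohort, compute_sojourn, truncate_sequences
from .encoding import (EncodedCohort, EncodedSequences, chunk, encode_cohort)
from .generator import GeneratorModel, ModelConfig, generate, train
from .privacy import PrivacyConfig, PrivacyReport, assess
from .schema import CohortSchema
from .simulator import SimulationSpec, simulate_cohort
from .utility import UtilityReport, evaluate_utility


@dataclass
class Prepared:
    cohort: Cohort
    encoded: EncodedCohort
    chunks: EncodedSequences


def prepare(cohort: Cohort, schema: CohortSchema, window: int = 120,
            percentile: float | None = None, hard_cap: int | None = None
            ) -> Prepared:
    """Sojourn computation, optional truncation, encoding and chunking."""
    cohort = compute_sojourn(cohort)
    if percentile is not None:
        cohort, _ = truncate_sequences(cohort, percentile,
                                       hard_cap or len(cohort.events))
    encoded = encode_cohort(cohort, schema)
    return Prepared(cohort=cohort, encoded=encoded,
                    chunks=chunk(encoded, window=window))


def fit_and_generate(real: Cohort, schema: CohortSchema, config: ModelConfig,
                     n_synthetic: int | None = None,
                     max_length: int | None = None, seed: int | None = None,
                     temperature: float = 1.0,
                     percentile: float | None = None,
                     hard_cap: int | None = None
                     ) -> tuple[GeneratorModel, Cohort]:
    """Train on a real cohort and generate a synthetic one of the same size."""
    seed = config.seed if seed is None else seed
    prep = prepare(real, schema, window=config.window,
                   percentile=percentile, hard_cap=hard_cap)
    model = train(prep.chunks, config)
    n = n_synthetic or real.n_individuals
    seeds = synthesize_seeds(prep.encoded, n, seed=seed)
    if max_length is None:
        max_length = int(real.sequence_lengths().max())
    syn = generate(model, seeds, max_length=max_length,
                   temperature=temperature, seed=seed + 1)
    return model, syn


def end_to_end(spec: SimulationSpec, config: ModelConfig,
               seed: int = 0, n_queries: int = 50,
               privacy_config: PrivacyConfig | None = None
               ) -> dict:
    """Simulate a ground-truth cohort, synthesize it, and evaluate.

    Returns the real and synthetic cohorts, the fitted model, and the
    utility and privacy reports.
    """
    real = simulate_cohort(spec, seed=seed)
    model, syn = fit_and_generate(real, spec.schema, config,
                                  max_length=spec.max_length, seed=seed)
    utility: UtilityReport = evaluate_utility(
        real, syn, spec.schema, n_queries=n_queries, seed=seed)
    privacy: PrivacyReport = assess(real, syn, privacy_config)
    return {"real": real, "synthetic": syn, "model": model,
            "utility": utility, "privacy": privacy}
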