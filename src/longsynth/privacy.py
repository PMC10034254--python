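"""Attribution-disclosure risk assessment.

An adversary who knows an individual's quasi-identifiers (QIs — here age,
sex, and indicators for death and hospitalization derived from the event
stream) may try to match a record in one dataset against the other and, if
the match succeeds, infer a sensitive attribute they did not already know.
Both attack directions are assessed: population-to-sample (real records
attack the synthetic sample) and sample-to-population.  The implemented
estimator follows the matching structure of that attack: each attacking
record that finds a non-empty QI equivalence class in the target contributes
1 / (class size), multiplied by an indicator that the class-majority vote on
the sensitive attribute is correct ("learns something new"); the risk is the
average contribution over all attacking records.  Risks are compared to the
0.09 threshold used for public release of clinical data, which corresponds
to a minimal group size of 11 under a maximum-risk scenario.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PID, Cohort
from .schema import CohortSchema

log = logging.getLogger(__name__)

_MISSING_BAND = "__missing__"


@dataclass
class PrivacyConfig:
    """Quasi-identifiers, banding tolerances and the decision threshold."""

    quasi_identifiers: list = field(
        default_factory=lambda: ["age", "sex", "death", "hospitalization"])
    threshold: float = 0.09
    tolerances: dict = field(default_factory=lambda: {"age": 5.0})
    sensitive: str | None = None   # defaults to first non-QI baseline column
    death_label: str | None = None
    hospitalization_label: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def for_schema(cls, schema: CohortSchema) -> "PrivacyConfig":
        """Adapt the default QI set (age, sex, death, hospitalization) to a
        schema: indicators whose event label is absent are dropped."""
        base_names = [b.name for b in schema.baseline_vars]
        qis = [q for q in ("age", "sex") if q in base_names]
        kwargs = {}
        if schema.terminal_label is not None:
            qis.append("death")
            kwargs["death_label"] = schema.terminal_label
        hosp = next((l for l in schema.event_labels
                     if l.lower().startswith("hosp")), None)
        if hosp is not None:
            qis.append("hospitalization")
            kwargs["hospitalization_label"] = hosp
        return cls(quasi_identifiers=qis, **kwargs)


@dataclass
class PrivacyReport:
    population_to_sample: float
    sample_to_population: float
    threshold: float
    passed: bool
    class_size_distribution: dict
    match_counts: dict

    def to_dict(self) -> dict:
        return {
            "population_to_sample": self.population_to_sample,
            "sample_to_population": self.sample_to_population,
            "threshold": self.threshold,
            "passed": self.passed,
            "class_size_distribution": self.class_size_distribution,
            "match_counts": self.match_counts,
        }


def qi_table(cohort: Cohort, config: PrivacyConfig,
             schema: CohortSchema | None = None) -> pd.DataFrame:
    """One row per individual with QI columns plus the sensitive attribute.

    Death / hospitalization indicator QIs are derived from the presence of
    the corresponding event labels in the individual's sequence.
    """
    schema = schema or cohort.schema
    base = cohort.baseline.copy()
    out = pd.DataFrame({PID: base[PID]})
    seqs = cohort.label_sequences()
    for qi in config.quasi_identifiers:
        if qi in base.columns:
            out[qi] = base[qi].to_numpy()
        elif qi in ("death", "hospitalization"):
            if qi == "death":
                lbl = config.death_label or \
                    (schema.terminal_label if schema else None)
            else:
                lbl = config.hospitalization_label
            if lbl is None:
                raise KeyError(
                    f"QI {qi!r}: no event label configured to derive it")
            out[qi] = [int(lbl in seqs.get(pid, [])) for pid in base[PID]]
        else:
            raise KeyError(f"QI {qi!r} not found in baseline")
    sens = config.sensitive
    if sens is None:
        candidates = [c for c in base.columns
                      if c not in config.quasi_identifiers and c != PID]
        sens = candidates[0] if candidates else None
    if sens is not None:
        out["__sensitive__"] = base[sens].to_numpy() if sens in base.columns \
            else np.nan
    else:
        out["__sensitive__"] = np.nan
    return out


def _band(values: pd.Series, tol: float | None):
    if tol is None:
        keys = values.astype(object).where(values.notna(), _MISSING_BAND)
        return keys
    num = pd.to_numeric(values, errors="coerce")
    banded = np.floor(num / tol)
    keys = banded.astype(object).where(num.notna(), _MISSING_BAND)
    if num.isna().any():
        log.info("QI %s: %d missing values assigned to the missing band",
                 values.name, int(num.isna().sum()))
    return keys


def build_equivalence_classes(table: pd.DataFrame, qis: list,
                              tolerances: dict | None = None) -> dict:
    """Partition records by (banded) QI values: key -> list of row positions."""
    tolerances = tolerances or {}
    keys = pd.DataFrame({
        qi: _band(table[qi], tolerances.get(qi)) for qi in qis
    })
    classes: dict = {}
    for pos, key in enumerate(map(tuple, keys.itertuples(index=False,
                                                         name=None))):
        classes.setdefault(key, []).append(pos)
    return classes


def attribution_disclosure_risk(real: Cohort, syn: Cohort,
                                config: PrivacyConfig,
                                direction: str = "population_to_sample"
                                ) -> float:
    """Risk that an attacking record matches and learns something new.

    ``population_to_sample``: real records attack the synthetic dataset;
    ``sample_to_population``: synthetic records attack the real dataset.
    """
    rt = qi_table(real, config)
    st = qi_table(syn, config)
    if direction == "population_to_sample":
        attacker, target = rt, st
    elif direction == "sample_to_population":
        attacker, target = st, rt
    else:
        raise ValueError(f"unknown direction {direction!r}")
    qis = config.quasi_identifiers
    tol = config.tolerances
    target_classes = build_equivalence_classes(target, qis, tol)
    att_keys = pd.DataFrame({qi: _band(attacker[qi], tol.get(qi))
                             for qi in qis})
    sens_t = target["__sensitive__"].to_numpy(dtype=object)
    sens_a = attacker["__sensitive__"].to_numpy(dtype=object)

    majority: dict = {}
    for key, rows in target_classes.items():
        vals = pd.Series([sens_t[r] for r in rows]).dropna()
        majority[key] = vals.mode().iloc[0] if len(vals) else None

    total = 0.0
    n_matched = 0
    for pos, key in enumerate(map(tuple, att_keys.itertuples(index=False,
                                                             name=None))):
        rows = target_classes.get(key)
        if not rows:
            continue
        n_matched += 1
        learns = 1.0 if (majority[key] is not None
                         and majority[key] == sens_a[pos]) else 0.0
        total += learns / len(rows)
    if n_matched == 0:
        warnings.warn("no QI overlap between datasets; risk is 0",
                      stacklevel=2)
        return 0.0
    return float(total / len(attacker))


def assess(real: Cohort, syn: Cohort, config: PrivacyConfig | None = None
           ) -> PrivacyReport:
    """Run both attack directions and compare the worse risk to the threshold."""
    if config is None:
        if real.schema is None:
            raise ValueError("pass a PrivacyConfig or a cohort with a schema")
        config = PrivacyConfig.for_schema(real.schema)
    p2s = attribution_disclosure_risk(real, syn, config,
                                      "population_to_sample")
    s2p = attribution_disclosure_risk(real, syn, config,
                                      "sample_to_population")
    st = qi_table(syn, config)
    classes = build_equivalence_classes(st, config.quasi_identifiers,
                                        config.tolerances)
    sizes = pd.Series([len(v) for v in classes.values()])
    rt = qi_table(real, config)
    att = pd.DataFrame({qi: _band(rt[qi], config.tolerances.get(qi))
                        for qi in config.quasi_identifiers})
    n_matched = sum(
        1 for key in map(tuple, att.itertuples(index=False, name=None))
        if key in classes)
    return PrivacyReport(
        population_to_sample=p2s,
        sample_to_population=s2p,
        threshold=config.threshold,
        passed=bool(max(p2s, s2p) <= config.threshold),
        class_size_distribution={
            "n_classes": int(len(sizes)),
            "min": int(sizes.min()), "median": float(sizes.median()),
            "max": int(sizes.max()),
        },
        match_counts={"population_to_sample_matched": int(n_matched),
                      "population_records": int(len(rt))},
    )
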