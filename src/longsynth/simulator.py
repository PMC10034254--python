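"""Ground-truth cohort simulator.

Generates longitudinal cohorts with *known* statistical structure — baseline
covariates, a per-stratum first-order Markov kernel over event labels with an
absorbing terminal label, per-label attribute conditionals, and per-label
sojourn-time distributions — so the generative model and every evaluation
metric can be tested against an exact ground truth.  No attempt is made at
clinical realism; the point is a controllable oracle with the same shape as
administrative health data (demographics table + heterogeneous event stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import PID, Cohort
from .schema import AttributeDef, BaselineDef, CohortSchema


class SimulationSpecError(ValueError):
    pass


def _sample_dist(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    """Draw from a serializable distribution description."""
    kind = dist["type"]
    if kind == "categorical":
        return rng.choice(np.asarray(dist["categories"], dtype=object),
                          size=size, p=dist["probs"])
    if kind == "normal":
        x = rng.normal(dist["mean"], dist["sd"], size=size)
        if "min" in dist or "max" in dist:
            x = np.clip(x, dist.get("min", -np.inf), dist.get("max", np.inf))
        return x
    if kind == "lognormal":
        return rng.lognormal(dist["mean"], dist["sd"], size=size)
    if kind == "poisson":
        return rng.poisson(dist["lam"], size=size).astype(float)
    if kind == "geometric":
        # support {0, 1, 2, ...}
        return (rng.geometric(dist["p"], size=size) - 1).astype(float)
    if kind == "constant":
        return np.full(size, dist["value"])
    raise SimulationSpecError(f"unknown distribution type {kind!r}")


@dataclass
class SimulationSpec:
    """Everything needed to generate a cohort with known dynamics.

    ``kernels`` has shape [n_strata, L, L] over the schema's non-padding
    labels (terminal included); rows sum to 1 and the terminal row is
    absorbing.  ``stratum_rule`` maps a baseline variable to a stratum index:
    for a categorical variable the stratum is the category's position, for a
    continuous one the interval defined by ``cutpoints``.
    """

    schema: CohortSchema
    n_individuals: int
    baseline_models: dict           # var name -> distribution dict
    stratum_rule: dict              # {"var": name, "cutpoints": [...] (optional)}
    init_probs: np.ndarray          # [n_strata, L]
    kernels: np.ndarray             # [n_strata, L, L]
    attr_models: dict               # attr name -> {label: distribution dict}
    sojourn_models: dict            # label -> distribution dict
    max_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.init_probs = np.asarray(self.init_probs, dtype=float)
        self.kernels = np.asarray(self.kernels, dtype=float)
        L = len(self.schema.event_labels)
        if self.kernels.shape[1:] != (L, L):
            raise SimulationSpecError(
                f"kernels must be [n_strata, {L}, {L}], got {self.kernels.shape}"
            )
        if (self.kernels < 0).any() or (self.kernels > 1).any():
            raise SimulationSpecError("kernel entries must be in [0, 1]")
        if not np.allclose(self.kernels.sum(axis=2), 1.0, atol=1e-9):
            raise SimulationSpecError("kernel rows must sum to 1 (within 1e-9)")
        if not np.allclose(self.init_probs.sum(axis=1), 1.0, atol=1e-9):
            raise SimulationSpecError("init_probs rows must sum to 1")
        term = self.schema.terminal_label
        if term is not None:
            ti = self.schema.event_labels.index(term)
            absorbing = np.zeros(L)
            absorbing[ti] = 1.0
            if not np.allclose(self.kernels[:, ti, :], absorbing, atol=1e-9):
                raise SimulationSpecError("terminal label row must be absorbing")

    @property
    def n_strata(self) -> int:
        return self.kernels.shape[0]

    def stratum_of(self, baseline: pd.DataFrame) -> np.ndarray:
        var = self.stratum_rule["var"]
        vals = baseline[var].to_numpy()
        if "cutpoints" in self.stratum_rule:
            return np.searchsorted(self.stratum_rule["cutpoints"], vals,
                                   side="right")
        cats = list(self.baseline_models[var]["categories"])
        return np.array([cats.index(v) for v in vals])

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": self.schema.to_dict(),
            "n_individuals": self.n_individuals,
            "baseline_models": self.baseline_models,
            "stratum_rule": self.stratum_rule,
            "init_probs": self.init_probs.tolist(),
            "kernels": self.kernels.tolist(),
            "attr_models": self.attr_models,
            "sojourn_models": self.sojourn_models,
            "max_length": self.max_length,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        d["schema"] = CohortSchema.from_dict(d["schema"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def true_transition_matrix(spec: SimulationSpec, stratum: int) -> pd.DataFrame:
    """The exact first-order kernel used for generation (ground truth)."""
    if not (0 <= stratum < spec.n_strata):
        raise KeyError(f"unknown stratum {stratum}")
    labels = spec.schema.event_labels
    return pd.DataFrame(spec.kernels[stratum].copy(), index=labels,
                        columns=labels)


def simulate_cohort(spec: SimulationSpec, seed: int | None = None,
                    n: int | None = None) -> Cohort:
    """Generate a cohort under the spec's dynamics.

    Per individual: draw baseline, resolve the stratum, draw the first label
    from the stratum's initial distribution, then iterate the Markov kernel
    until the terminal label or ``max_length``.  Attributes are drawn from the
    per-label conditionals; irrelevant attributes stay missing.  Dates
    accumulate the drawn sojourn times (the first event has sojourn 0).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_individuals if n is None else n
    schema = spec.schema

    base_cols: dict = {PID: np.arange(n)}
    for var, dist in spec.baseline_models.items():
        base_cols[var] = _sample_dist(rng, dist, n)
    baseline = pd.DataFrame(base_cols)
    strata = spec.stratum_of(baseline)

    labels = schema.event_labels
    L = len(labels)
    term_idx = labels.index(schema.terminal_label) \
        if schema.terminal_label is not None else -1
    cum_init = np.cumsum(spec.init_probs, axis=1)
    cum_kern = np.cumsum(spec.kernels, axis=2)

    pid_col, lab_col, pos_col = [], [], []
    for i in range(n):
        s = strata[i]
        cur = int(np.searchsorted(cum_init[s], rng.random(), side="right"))
        cur = min(cur, L - 1)
        seq = [cur]
        while len(seq) < spec.max_length and cur != term_idx:
            u = rng.random()
            cur = int(np.searchsorted(cum_kern[s, cur], u, side="right"))
            cur = min(cur, L - 1)
            seq.append(cur)
        pid_col.extend([i] * len(seq))
        lab_col.extend(seq)
        pos_col.extend(range(len(seq)))

    ev = pd.DataFrame({
        PID: np.asarray(pid_col, dtype=np.int64),
        "pos": np.asarray(pos_col, dtype=np.int64),
        "label": np.asarray(labels, dtype=object)[np.asarray(lab_col)],
    })

    # sojourns: per-label distribution, first event forced to 0
    soj = np.zeros(len(ev))
    for lbl, dist in spec.sojourn_models.items():
        mask = (ev["label"] == lbl).to_numpy()
        soj[mask] = _sample_dist(rng, dist, int(mask.sum()))
    soj[(ev["pos"] == 0).to_numpy()] = 0.0
    ev["sojourn"] = soj
    ev["date"] = ev.groupby(PID)["sojourn"].cumsum()

    for a in schema.attributes:
        if a.name == "sojourn":
            continue
        col = np.full(len(ev), np.nan, dtype=object if not a.is_continuous
                      else float)
        models = spec.attr_models.get(a.name, {})
        for lbl, dist in models.items():
            if a.name not in schema.relevant_attrs(lbl):
                continue
            mask = (ev["label"] == lbl).to_numpy()
            col[mask] = _sample_dist(rng, dist, int(mask.sum()))
        ev[a.name] = col

    # The timing attribute shares the core "sojourn" column (every event type
    # carries a timing attribute, so it is relevant for all labels).
    cols = [PID, "pos", "label", "date", "sojourn"] + \
        [a for a in schema.attr_names if a != "sojourn"]
    return Cohort(baseline=baseline, events=ev[cols].copy(), schema=schema)


def small_spec(n: int = 2000, max_length: int = 60, seed: int = 0,
               terminal_hazard: float = 0.05) -> SimulationSpec:
    """A compact two-stratum cohort used throughout the tests and examples.

    Four event labels (A, B, C and an absorbing terminal EOS), two event
    attributes (binned sojourn time relevant everywhere; a categorical
    severity relevant only for A and B), and three baseline variables of
    which sex defines the stratum.  The two strata get visibly different
    kernels so conditional-generation effects are detectable at modest n.
    """
    h = terminal_hazard
    schema = CohortSchema(
        event_labels=["A", "B", "C", "EOS"],
        terminal_label="EOS",
        attributes=[
            AttributeDef(name="sojourn", n_bins=8),
            AttributeDef(name="severity", categories=["low", "med", "high"]),
        ],
        relevance={
            "A": {"sojourn", "severity"},
            "B": {"sojourn", "severity"},
            "C": {"sojourn"},
            "EOS": {"sojourn"},
        },
        baseline_vars=[
            BaselineDef(name="age", n_bins=5),
            BaselineDef(name="sex", categories=["M", "F"]),
            BaselineDef(name="comorbidity", categories=["0", "1", "2"]),
        ],
    )

    def _row(p, mult=(1.0, 1.0, 1.0)):
        # scale the non-terminal mass to leave hazard h for EOS
        p = np.asarray(p, dtype=float) * np.asarray(mult, dtype=float)
        return list(p / p.sum() * (1 - h)) + [h]

    # Stratum 1 applies a uniform multiplicative shift to the transition
    # propensities (a main-effect covariate shift, as in multinomial-logit /
    # proportional-hazards covariate models): less A, more B, slightly more C
    # from every state.
    base_rows = [[0.55, 0.25, 0.20], [0.35, 0.40, 0.25], [0.30, 0.25, 0.45]]
    m1 = (0.55, 1.9, 1.25)
    k0 = [_row(r) for r in base_rows] + [[0.0, 0.0, 0.0, 1.0]]
    k1 = [_row(r, m1) for r in base_rows] + [[0.0, 0.0, 0.0, 1.0]]
    return SimulationSpec(
        schema=schema,
        n_individuals=n,
        baseline_models={
            "age": {"type": "normal", "mean": 45.0, "sd": 18.0,
                    "min": 18.0, "max": 90.0},
            "sex": {"type": "categorical", "categories": ["M", "F"],
                    "probs": [0.51, 0.49]},
            "comorbidity": {"type": "categorical",
                            "categories": ["0", "1", "2"],
                            "probs": [0.6, 0.3, 0.1]},
        },
        stratum_rule={"var": "sex"},
        init_probs=[[0.5, 0.3, 0.2, 0.0], [0.2, 0.5, 0.3, 0.0]],
        kernels=[k0, k1],
        attr_models={
            "severity": {
                "A": {"type": "categorical",
                      "categories": ["low", "med", "high"],
                      "probs": [0.6, 0.3, 0.1]},
                "B": {"type": "categorical",
                      "categories": ["low", "med", "high"],
                      "probs": [0.2, 0.3, 0.5]},
            },
        },
        sojourn_models={
            "A": {"type": "geometric", "p": 0.25},
            "B": {"type": "poisson", "lam": 5.0},
            "C": {"type": "geometric", "p": 0.1},
            "EOS": {"type": "poisson", "lam": 10.0},
        },
        max_length=max_length,
        seed=seed,
    )


def study_like_spec(n: int = 1000, max_length: int = 80,
                    seed: int = 0) -> SimulationSpec:
    """A richer cohort shaped like administrative health data.

    Five event types (drug dispensation, ED visit, hospitalization, lab test
    and an absorbing death / last-observation label) with heterogeneous
    per-type attribute sets, for the narrative examples.
    """
    h = 0.03
    schema = CohortSchema(
        event_labels=["DRUG", "ED", "HOSP", "LAB", "DEATH"],
        terminal_label="DEATH",
        attributes=[
            AttributeDef(name="sojourn", n_bins=12),
            AttributeDef(name="drug_name",
                         categories=["morphine", "oxycodone", "antidepressant"]),
            AttributeDef(name="diag_code",
                         categories=["J18", "R07", "S72", "F32", "other"]),
            AttributeDef(name="riw", n_bins=10),
            AttributeDef(name="lab_name", categories=["ALT", "eGFR", "HCT"]),
            AttributeDef(name="lab_result", n_bins=10),
        ],
        relevance={
            "DRUG": {"sojourn", "drug_name"},
            "ED": {"sojourn", "diag_code", "riw"},
            "HOSP": {"sojourn", "diag_code", "riw"},
            "LAB": {"sojourn", "lab_name", "lab_result"},
            "DEATH": {"sojourn"},
        },
        baseline_vars=[
            BaselineDef(name="age", n_bins=8),
            BaselineDef(name="sex", categories=["M", "F"]),
            BaselineDef(name="comorbidity", categories=["0", "1", "2", "3"]),
        ],
        table_priority=["DRUG", "ED", "HOSP", "LAB", "DEATH"],
    )

    def _row(p):
        p = np.asarray(p, dtype=float)
        return list(p / p.sum() * (1 - h)) + [h]

    # low-comorbidity vs high-comorbidity dynamics
    k0 = [_row([0.60, 0.15, 0.02, 0.23]), _row([0.40, 0.25, 0.10, 0.25]),
          _row([0.35, 0.15, 0.20, 0.30]), _row([0.45, 0.10, 0.03, 0.42]),
          [0, 0, 0, 0, 1.0]]
    k1 = [_row([0.45, 0.25, 0.08, 0.22]), _row([0.30, 0.30, 0.20, 0.20]),
          _row([0.25, 0.20, 0.35, 0.20]), _row([0.35, 0.18, 0.07, 0.40]),
          [0, 0, 0, 0, 1.0]]
    return SimulationSpec(
        schema=schema,
        n_individuals=n,
        baseline_models={
            "age": {"type": "normal", "mean": 48.0, "sd": 17.0,
                    "min": 18.0, "max": 95.0},
            "sex": {"type": "categorical", "categories": ["M", "F"],
                    "probs": [0.51, 0.49]},
            "comorbidity": {"type": "categorical",
                            "categories": ["0", "1", "2", "3"],
                            "probs": [0.45, 0.30, 0.15, 0.10]},
        },
        stratum_rule={"var": "comorbidity"},
        init_probs=[[0.9, 0.05, 0.0, 0.05, 0.0]] * 4,
        kernels=[k0, k0, k1, k1],
        attr_models={
            "drug_name": {"DRUG": {"type": "categorical",
                                   "categories": ["morphine", "oxycodone",
                                                  "antidepressant"],
                                   "probs": [0.05, 0.6, 0.35]}},
            "diag_code": {
                "ED": {"type": "categorical",
                       "categories": ["J18", "R07", "S72", "F32", "other"],
                       "probs": [0.05, 0.25, 0.10, 0.15, 0.45]},
                "HOSP": {"type": "categorical",
                         "categories": ["J18", "R07", "S72", "F32", "other"],
                         "probs": [0.10, 0.15, 0.20, 0.10, 0.45]},
            },
            "riw": {
                "ED": {"type": "lognormal", "mean": -3.0, "sd": 0.7},
                "HOSP": {"type": "lognormal", "mean": 0.2, "sd": 0.9},
            },
            "lab_name": {"LAB": {"type": "categorical",
                                 "categories": ["ALT", "eGFR", "HCT"],
                                 "probs": [0.35, 0.4, 0.25]}},
            "lab_result": {"LAB": {"type": "lognormal", "mean": 3.3,
                                   "sd": 0.6}},
        },
        sojourn_models={
            "DRUG": {"type": "poisson", "lam": 20.0},
            "ED": {"type": "geometric", "p": 0.05},
            "HOSP": {"type": "geometric", "p": 0.2},
            "LAB": {"type": "poisson", "lam": 30.0},
            "DEATH": {"type": "poisson", "lam": 40.0},
        },
        max_length=max_length,
        seed=seed,
    )
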