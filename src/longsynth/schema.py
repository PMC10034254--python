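"""Cohort schema: event-label vocabulary, attribute definitions and relevance.

The schema is the single source of truth for how a longitudinal cohort is
coded.  Every vocabulary reserves index 0 for padding / missing, so that the
recurrent model can treat "no event" and "attribute not measured" uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Reserved code-0 token in the label vocabulary.
PAD_LABEL = "__pad__"
#: Reserved code-0 token in every attribute / baseline vocabulary.
MISSING = "__missing__"


@dataclass
class AttributeDef:
    """One per-event attribute.

    Exactly one of ``categories`` (ordered vocabulary, *excluding* the
    reserved missing token) or ``n_bins`` (quantile bins for an originally
    continuous value) must be given.
    """

    name: str
    categories: list[str] | None = None
    n_bins: int | None = None

    def __post_init__(self) -> None:
        if (self.categories is None) == (self.n_bins is None):
            raise ValueError(
                f"attribute {self.name!r}: give either categories or n_bins"
            )
        if self.n_bins is not None and self.n_bins < 2:
            raise ValueError(f"attribute {self.name!r}: n_bins must be >= 2")

    @property
    def is_continuous(self) -> bool:
        return self.n_bins is not None

    @property
    def cardinality(self) -> int:
        """Number of codes including the reserved missing code 0."""
        if self.categories is not None:
            return len(self.categories) + 1
        return self.n_bins + 1


@dataclass
class BaselineDef:
    """One cross-sectional (baseline) variable, coded like an attribute."""

    name: str
    categories: list[str] | None = None
    n_bins: int | None = None

    def __post_init__(self) -> None:
        if (self.categories is None) == (self.n_bins is None):
            raise ValueError(
                f"baseline var {self.name!r}: give either categories or n_bins"
            )

    @property
    def is_continuous(self) -> bool:
        return self.n_bins is not None

    @property
    def cardinality(self) -> int:
        if self.categories is not None:
            return len(self.categories) + 1
        return self.n_bins + 1


@dataclass
class CohortSchema:
    """Declares labels, attributes, relevance and baseline variables.

    Parameters
    ----------
    event_labels:
        Ordered vocabulary of event-type codes *excluding* the padding token;
        the padding token is always prepended at index 0.
    attributes:
        Per-event attribute definitions.  The sojourn-time attribute, if
        modelled, is declared here like any other attribute.
    relevance:
        Map ``event_label -> set of attribute names`` measured for that label.
        Attributes outside a label's relevance set are missing on its rows.
    baseline_vars:
        Cross-sectional variable definitions (one value per individual).
    terminal_label:
        Optional label that ends a sequence ("last observation" / death).
    table_priority:
        Tie-break order for same-day events from different source tables;
        defaults to the label order.
    """

    event_labels: list[str]
    attributes: list[AttributeDef]
    relevance: dict[str, set[str]]
    baseline_vars: list[BaselineDef]
    terminal_label: str | None = None
    table_priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if PAD_LABEL in self.event_labels:
            raise ValueError(f"{PAD_LABEL!r} is reserved; do not declare it")
        if len(set(self.event_labels)) != len(self.event_labels):
            raise ValueError("duplicate event labels")
        self.relevance = {k: set(v) for k, v in self.relevance.items()}
        attr_names = {a.name for a in self.attributes}
        for lbl, rel in self.relevance.items():
            if lbl not in self.event_labels:
                raise ValueError(f"relevance declared for unknown label {lbl!r}")
            unknown = rel - attr_names
            if unknown:
                raise ValueError(f"label {lbl!r}: unknown attributes {unknown}")
        covered = set().union(*self.relevance.values()) if self.relevance else set()
        if attr_names - covered:
            raise ValueError(
                f"attributes never relevant for any label: {attr_names - covered}"
            )
        if not self.table_priority:
            self.table_priority = list(self.event_labels)

    # -- vocabulary views -------------------------------------------------

    @property
    def label_vocab(self) -> list[str]:
        """Full label vocabulary with the padding token at index 0."""
        return [PAD_LABEL] + self.event_labels

    @property
    def n_labels(self) -> int:
        return len(self.label_vocab)

    @property
    def attr_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    @property
    def n_attrs(self) -> int:
        return len(self.attributes)

    @property
    def n_baseline(self) -> int:
        return len(self.baseline_vars)

    def label_code(self, label: str) -> int:
        return self.label_vocab.index(label)

    @property
    def terminal_code(self) -> int | None:
        if self.terminal_label is None:
            return None
        return self.label_code(self.terminal_label)

    def attribute(self, name: str) -> AttributeDef:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def relevant_attrs(self, label: str) -> set[str]:
        return self.relevance.get(label, set())

    def relevance_matrix(self) -> "np.ndarray":
        """Boolean array [n_labels, n_attrs]; row 0 (padding) is all-False."""
        import numpy as np

        mat = np.zeros((self.n_labels, self.n_attrs), dtype=bool)
        for lbl, rel in self.relevance.items():
            li = self.label_code(lbl)
            for j, a in enumerate(self.attributes):
                if a.name in rel:
                    mat[li, j] = True
        return mat

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def _vdef(d):
            out = {"name": d.name}
            if d.categories is not None:
                out["categories"] = list(d.categories)
            else:
                out["n_bins"] = d.n_bins
            return out

        return {
            "event_labels": list(self.event_labels),
            "terminal_label": self.terminal_label,
            "attributes": [_vdef(a) for a in self.attributes],
            "relevance": {k: sorted(v) for k, v in self.relevance.items()},
            "baseline_vars": [_vdef(b) for b in self.baseline_vars],
            "table_priority": list(self.table_priority),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        return cls(
            event_labels=list(d["event_labels"]),
            attributes=[AttributeDef(**a) for a in d["attributes"]],
            relevance={k: set(v) for k, v in d["relevance"].items()},
            baseline_vars=[BaselineDef(**b) for b in d["baseline_vars"]],
            terminal_label=d.get("terminal_label"),
            table_priority=list(d.get("table_priority") or []),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CohortSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
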