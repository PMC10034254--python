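"""Harmonized cohort container and multi-table preparation.

A raw extract arrives as one demographics table (one row per individual) plus
several transactional tables (dispensations, ED visits, admissions, labs, ...)
linked by a patient ID.  :func:`harmonize_tables` merges the transactional
tables into a single chronological event stream per individual; sojourn times
(days since the individual's previous event) and per-individual truncation are
computed on that stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import CohortSchema

PID = "pid"

EVENT_CORE_COLS = [PID, "pos", "label", "date", "sojourn"]


def _categorical_str(col: pd.Series) -> pd.Series:
    """Categorical vocabularies are strings; CSV may read digit-like
    categories back as numbers, so normalize non-null values to str."""
    out = col.astype(object)
    mask = col.notna()
    out[mask] = [str(int(v)) if isinstance(v, float) and float(v).is_integer()
                 else str(v) for v in col[mask]]
    return out


class ReferentialIntegrityError(ValueError):
    """An event table references a patient ID absent from demographics."""


class SchemaError(ValueError):
    """A table column cannot be mapped onto the declared schema."""


@dataclass
class EventTable:
    """One transactional source table.

    ``columns`` maps source column names to schema attribute names; the
    patient-ID and relative-date columns are named separately.  Every source
    column must be accounted for.
    """

    label: str
    frame: pd.DataFrame
    columns: dict[str, str]
    pid_col: str = PID
    date_col: str = "date"


@dataclass
class Cohort:
    """A demographics table plus one unified chronological event stream.

    ``baseline`` has one row per individual (column ``pid`` plus baseline
    variables); ``events`` has columns ``pid, pos, label, date, sojourn`` plus
    one column per schema attribute (NaN where the attribute is not relevant
    for the row's label).
    """

    baseline: pd.DataFrame
    events: pd.DataFrame
    schema: CohortSchema | None = field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return len(self.baseline)

    def sequence_lengths(self) -> pd.Series:
        """Events per individual, including zero-event individuals."""
        counts = self.events.groupby(PID).size()
        return counts.reindex(self.baseline[PID], fill_value=0)

    def label_sequences(self) -> dict:
        """Map patient ID -> list of event labels in chronological order."""
        out = {pid: [] for pid in self.baseline[PID]}
        for pid, grp in self.events.groupby(PID, sort=False):
            out[pid] = grp["label"].tolist()
        return out

    def validate(self) -> None:
        ev = self.events
        unknown = set(ev[PID]) - set(self.baseline[PID])
        if unknown:
            raise ReferentialIntegrityError(
                f"events reference unknown patient IDs: {sorted(unknown)[:5]}"
            )
        for _, grp in ev.groupby(PID):
            if not grp["date"].is_monotonic_increasing:
                raise ValueError("events not sorted by date within individual")
        if "sojourn" in ev and (ev["sojourn"].dropna() < 0).any():
            raise ValueError("negative sojourn time")
        if self.schema is not None:
            rel = self.schema.relevance
            for lbl, grp in ev.groupby("label"):
                for a in self.schema.attr_names:
                    if a in ev.columns and a not in rel.get(lbl, set()):
                        if grp[a].notna().any():
                            raise ValueError(
                                f"attribute {a!r} present on irrelevant label {lbl!r}"
                            )

    # -- persistence (two-file CSV form) ----------------------------------

    def to_csv(self, directory, delimiter: str = ",") -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(d / "baseline.csv", index=False, sep=delimiter)
        self.events.to_csv(d / "events.csv", index=False, sep=delimiter)
        if self.schema is not None:
            self.schema.save(d / "schema.yaml")

    @classmethod
    def from_csv(cls, directory, schema: CohortSchema | None = None,
                 delimiter: str = ",") -> "Cohort":
        d = Path(directory)
        baseline = pd.read_csv(d / "baseline.csv", sep=delimiter)
        events = pd.read_csv(d / "events.csv", sep=delimiter)
        if schema is None and (d / "schema.yaml").exists():
            schema = CohortSchema.load(d / "schema.yaml")
        if schema is not None:
            for a in schema.attributes:
                if not a.is_continuous and a.name in events.columns:
                    events[a.name] = _categorical_str(events[a.name])
            for b in schema.baseline_vars:
                if not b.is_continuous and b.name in baseline.columns:
                    baseline[b.name] = _categorical_str(baseline[b.name])
        return cls(baseline=baseline, events=events, schema=schema)


def to_multitable(cohort: Cohort, directory, delimiter: str = ",") -> None:
    """Write the cohort in raw multi-table form: demographics.csv plus one
    transactional CSV per event label (pid, date and the label's relevant
    attributes)."""
    schema = cohort.schema
    if schema is None:
        raise ValueError("multi-table export needs a schema")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.baseline.to_csv(d / "demographics.csv", index=False, sep=delimiter)
    for lbl in schema.event_labels:
        rows = cohort.events[cohort.events["label"] == lbl]
        cols = [PID, "date"] + sorted(schema.relevant_attrs(lbl))
        rows[cols].to_csv(d / f"{lbl}.csv", index=False, sep=delimiter)
    schema.save(d / "schema.yaml")


def from_multitable(directory, schema: CohortSchema | None = None,
                    delimiter: str = ",") -> Cohort:
    """Read the multi-table form back and harmonize it into one stream."""
    d = Path(directory)
    if schema is None:
        schema = CohortSchema.load(d / "schema.yaml")
    demographics = pd.read_csv(d / "demographics.csv", sep=delimiter)
    tables = []
    for lbl in schema.event_labels:
        path = d / f"{lbl}.csv"
        if not path.exists():
            continue
        frame = pd.read_csv(path, sep=delimiter)
        attrs = [c for c in frame.columns if c not in (PID, "date")]
        tables.append(EventTable(label=lbl, frame=frame,
                                 columns={a: a for a in attrs}))
    cohort = harmonize_tables(demographics, tables, schema)
    # re-apply the categorical string convention after CSV round-trip
    for a in schema.attributes:
        if a.categories is not None and a.name in cohort.events.columns:
            cohort.events[a.name] = _categorical_str(cohort.events[a.name])
    for b in schema.baseline_vars:
        if b.categories is not None and b.name in cohort.baseline.columns:
            cohort.baseline[b.name] = _categorical_str(
                cohort.baseline[b.name])
    return cohort


def harmonize_tables(
    demographics: pd.DataFrame,
    event_tables: list[EventTable],
    schema: CohortSchema,
) -> Cohort:
    """Interleave transactional tables into one chronological event stream.

    Events are ordered per individual by relative date; same-day ties are
    broken by the schema's table-priority order and then by source row order,
    so the result is deterministic.
    """
    known_pids = set(demographics[PID])
    attr_names = set(schema.attr_names)
    priority = {lbl: i for i, lbl in enumerate(schema.table_priority)}

    pieces = []
    for tbl in event_tables:
        if tbl.label not in schema.event_labels:
            raise SchemaError(f"event table label {tbl.label!r} not in schema")
        df = tbl.frame
        bad = set(df[tbl.pid_col]) - known_pids
        if bad:
            raise ReferentialIntegrityError(
                f"table {tbl.label!r}: unknown patient IDs {sorted(bad)[:5]}"
            )
        extra = set(df.columns) - {tbl.pid_col, tbl.date_col} - set(tbl.columns)
        if extra:
            raise SchemaError(f"table {tbl.label!r}: unmapped columns {sorted(extra)}")
        unknown_attrs = set(tbl.columns.values()) - attr_names
        if unknown_attrs:
            raise SchemaError(
                f"table {tbl.label!r}: columns map to unknown attributes "
                f"{sorted(unknown_attrs)}"
            )
        piece = pd.DataFrame({
            PID: df[tbl.pid_col].to_numpy(),
            "date": df[tbl.date_col].to_numpy(),
            "label": tbl.label,
            "_prio": priority.get(tbl.label, len(priority)),
            "_src_row": np.arange(len(df)),
        })
        for src, attr in tbl.columns.items():
            piece[attr] = df[src].to_numpy()
        pieces.append(piece)

    if pieces:
        events = pd.concat(pieces, ignore_index=True)
    else:
        events = pd.DataFrame(columns=[PID, "date", "label", "_prio", "_src_row"])
    for a in schema.attr_names:
        if a not in events.columns:
            events[a] = np.nan
    events = events.sort_values(
        [PID, "date", "_prio", "_src_row"], kind="stable"
    ).drop(columns=["_prio", "_src_row"]).reset_index(drop=True)
    events["pos"] = events.groupby(PID).cumcount()
    events["sojourn"] = np.nan
    events = events[EVENT_CORE_COLS + schema.attr_names]

    cohort = Cohort(baseline=demographics.reset_index(drop=True),
                    events=events, schema=schema)
    return cohort


def compute_sojourn(cohort: Cohort) -> Cohort:
    """Fill the sojourn column: days since the previous event, first event 0.

    Same-day consecutive events get sojourn 0.  Raises if any individual's
    dates decrease (events must already be chronological).
    """
    ev = cohort.events.copy()
    diffs = ev.groupby(PID)["date"].diff()
    if (diffs.dropna() < 0).any():
        raise ValueError("event dates decrease within an individual")
    ev["sojourn"] = diffs.fillna(0.0)
    return Cohort(baseline=cohort.baseline, events=ev, schema=cohort.schema)


@dataclass
class TruncationReport:
    cap: int
    n_truncated: int
    n_events_removed: int


def truncate_sequences(
    cohort: Cohort, percentile: float, hard_cap: int
) -> tuple[Cohort, TruncationReport]:
    """Cap per-individual event counts at the empirical percentile.

    The cap is ``min(empirical percentile of counts, hard_cap)``; individuals
    over the cap keep their chronologically earliest events.
    """
    if not (0 < percentile <= 1):
        raise ValueError("percentile must be in (0, 1]")
    if hard_cap < 1:
        raise ValueError("hard_cap must be >= 1")
    if len(cohort.events) == 0:
        return cohort, TruncationReport(cap=hard_cap, n_truncated=0,
                                        n_events_removed=0)
    counts = cohort.events.groupby(PID).size()
    cap = int(min(np.quantile(counts.to_numpy(), percentile,
                              method="inverted_cdf"), hard_cap))
    cap = max(cap, 1)
    kept = cohort.events[cohort.events["pos"] < cap].reset_index(drop=True)
    n_trunc = int((counts > cap).sum())
    report = TruncationReport(
        cap=cap, n_truncated=n_trunc,
        n_events_removed=len(cohort.events) - len(kept),
    )
    return Cohort(baseline=cohort.baseline, events=kept,
                  schema=cohort.schema), report
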