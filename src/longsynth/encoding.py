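"""Integer coding, quantile binning, and fixed-window chunking.

The generative model is wholly categorical: every label, attribute and
baseline variable is mapped to an integer code, with code 0 reserved for
padding / missing everywhere.  Originally-continuous values (lab results,
resource intensity weights, age, sojourn time) are quantile-binned; the
codebook stores bin edges and a per-bin representative (the median training
value in the bin) so codes can be decoded back to numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PID, Cohort
from .schema import AttributeDef, BaselineDef, CohortSchema


class EncodingError(ValueError):
    """A value cannot be coded under the schema (out of vocabulary)."""


@dataclass
class _ContinuousCodec:
    edges: np.ndarray          # inner bin edges, length n_bins - 1
    representatives: np.ndarray  # decoded value per bin, length n_bins

    def encode(self, values: np.ndarray) -> np.ndarray:
        # codes are 1-based; 0 stays reserved for missing
        return np.searchsorted(self.edges, values, side="right") + 1

    def decode(self, codes: np.ndarray) -> np.ndarray:
        return self.representatives[np.asarray(codes, dtype=int) - 1]


@dataclass
class _CategoricalCodec:
    categories: list

    def encode(self, values: np.ndarray) -> np.ndarray:
        lookup = {c: i + 1 for i, c in enumerate(self.categories)}
        out = np.empty(len(values), dtype=np.int64)
        bad = []
        for i, v in enumerate(values):
            code = lookup.get(v)
            if code is None:
                bad.append(v)
                code = -1
            out[i] = code
        if bad:
            raise EncodingError(f"out-of-vocabulary values: {sorted(set(map(str, bad)))}")
        return out

    def decode(self, codes: np.ndarray) -> np.ndarray:
        cats = np.asarray(self.categories, dtype=object)
        return cats[np.asarray(codes, dtype=int) - 1]


def _fit_codec(defn: AttributeDef | BaselineDef, values: np.ndarray):
    if not defn.is_continuous:
        return _CategoricalCodec(categories=list(defn.categories))
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise EncodingError(f"no observed values to bin for {defn.name!r}")
    qs = np.quantile(values, np.linspace(0, 1, defn.n_bins + 1))
    inner = np.unique(qs[1:-1])
    codec = _ContinuousCodec(edges=inner, representatives=np.zeros(len(inner) + 1))
    codes = codec.encode(values)
    reps = np.empty(len(inner) + 1)
    for b in range(len(inner) + 1):
        in_bin = values[codes == b + 1]
        if len(in_bin):
            reps[b] = float(np.median(in_bin))
        else:  # empty interior bin after edge deduplication
            lo = inner[b - 1] if b > 0 else values.min()
            hi = inner[b] if b < len(inner) else values.max()
            reps[b] = 0.5 * (lo + hi)
    codec.representatives = reps
    return codec


@dataclass
class Codebook:
    """Stores the fitted value <-> code mappings for one schema."""

    schema: CohortSchema
    attr_codecs: dict = field(default_factory=dict)
    baseline_codecs: dict = field(default_factory=dict)

    @classmethod
    def fit(cls, cohort: Cohort, schema: CohortSchema) -> "Codebook":
        cb = cls(schema=schema)
        rel = schema.relevance
        for a in schema.attributes:
            relevant_labels = [l for l, s in rel.items() if a.name in s]
            mask = cohort.events["label"].isin(relevant_labels)
            cb.attr_codecs[a.name] = _fit_codec(
                a, cohort.events.loc[mask, a.name].to_numpy()
            )
        for b in schema.baseline_vars:
            cb.baseline_codecs[b.name] = _fit_codec(
                b, cohort.baseline[b.name].to_numpy()
            )
        return cb

    def to_dict(self) -> dict:
        def _codec(c):
            if isinstance(c, _CategoricalCodec):
                return {"kind": "categorical", "categories": list(c.categories)}
            return {"kind": "continuous", "edges": c.edges.tolist(),
                    "representatives": c.representatives.tolist()}

        return {
            "schema": self.schema.to_dict(),
            "attr_codecs": {k: _codec(v) for k, v in self.attr_codecs.items()},
            "baseline_codecs": {k: _codec(v)
                                for k, v in self.baseline_codecs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        def _codec(cd):
            if cd["kind"] == "categorical":
                return _CategoricalCodec(categories=list(cd["categories"]))
            return _ContinuousCodec(
                edges=np.asarray(cd["edges"], dtype=float),
                representatives=np.asarray(cd["representatives"], dtype=float),
            )

        return cls(
            schema=CohortSchema.from_dict(d["schema"]),
            attr_codecs={k: _codec(v) for k, v in d["attr_codecs"].items()},
            baseline_codecs={k: _codec(v)
                             for k, v in d["baseline_codecs"].items()},
        )

    def attr_cardinality(self, name: str) -> int:
        codec = self.attr_codecs[name]
        if isinstance(codec, _CategoricalCodec):
            return len(codec.categories) + 1
        return len(codec.representatives) + 1

    def baseline_cardinality(self, name: str) -> int:
        codec = self.baseline_codecs[name]
        if isinstance(codec, _CategoricalCodec):
            return len(codec.categories) + 1
        return len(codec.representatives) + 1


@dataclass
class EncodedCohort:
    """Per-individual variable-length integer sequences (pre-chunking)."""

    pids: list
    labels: list          # list of int arrays [L_i]
    attrs: list           # list of int arrays [L_i, A]
    baseline: np.ndarray  # [n, B]
    codebook: Codebook

    @property
    def schema(self) -> CohortSchema:
        return self.codebook.schema


@dataclass
class EncodedSequences:
    """Fixed-window, zero-padded tensors ready for model training.

    ``labels``: [m, t] codes; ``attrs``: [m, t, A]; ``baseline``: [m, B];
    ``lengths``: true pre-padding length per chunk; ``chunk_owner``: list of
    ``(patient_id, chunk_ordinal)`` so chunks can be re-assembled.
    """

    labels: np.ndarray
    attrs: np.ndarray
    baseline: np.ndarray
    lengths: np.ndarray
    chunk_owner: list
    codebook: Codebook

    @property
    def window(self) -> int:
        return self.labels.shape[1]


def encode_cohort(
    cohort: Cohort, schema: CohortSchema, codebook: Codebook | None = None
) -> EncodedCohort:
    """Integer-code a harmonized cohort.

    Irrelevant attribute cells encode to 0 regardless of source content;
    relevant cells must be codable (out-of-vocabulary raises).
    """
    if codebook is None:
        codebook = Codebook.fit(cohort, schema)
    ev = cohort.events
    label_codes_all = np.array(
        [schema.label_code(l) for l in ev["label"]], dtype=np.int64
    ) if len(ev) else np.empty(0, dtype=np.int64)

    relev = schema.relevance_matrix()
    A = schema.n_attrs
    attr_codes_all = np.zeros((len(ev), A), dtype=np.int64)
    for j, a in enumerate(schema.attributes):
        codec = codebook.attr_codecs[a.name]
        mask = relev[label_codes_all, j] if len(ev) else np.zeros(0, dtype=bool)
        vals = ev[a.name].to_numpy()[mask]
        if isinstance(codec, _ContinuousCodec):
            vals = np.asarray(vals, dtype=float)
            if np.isnan(vals).any():
                raise EncodingError(f"missing value for relevant attribute {a.name!r}")
        attr_codes_all[mask, j] = codec.encode(vals)

    base = cohort.baseline
    B = schema.n_baseline
    baseline_codes = np.zeros((len(base), B), dtype=np.int64)
    for k, b in enumerate(schema.baseline_vars):
        baseline_codes[:, k] = codebook.baseline_codecs[b.name].encode(
            base[b.name].to_numpy()
        )

    pids = list(base[PID])
    idx_of = {pid: i for i, pid in enumerate(pids)}
    labels = [np.empty(0, dtype=np.int64) for _ in pids]
    attrs = [np.empty((0, A), dtype=np.int64) for _ in pids]
    if len(ev):
        order = ev[PID].map(idx_of).to_numpy()
        for i in range(len(pids)):
            sel = order == i
            labels[i] = label_codes_all[sel]
            attrs[i] = attr_codes_all[sel]
    return EncodedCohort(pids=pids, labels=labels, attrs=attrs,
                         baseline=baseline_codes, codebook=codebook)


def chunk(encoded: EncodedCohort, window: int = 120) -> EncodedSequences:
    """Split each individual's sequence into zero-padded windows.

    Window length 120 keeps tensors dense for long-sequence cohorts; shorter
    chunks are right-padded with code 0 in both labels and attributes.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    A = encoded.schema.n_attrs
    lab_chunks, attr_chunks, base_chunks, lengths, owners = [], [], [], [], []
    for i, pid in enumerate(encoded.pids):
        seq_l, seq_a = encoded.labels[i], encoded.attrs[i]
        n = len(seq_l)
        if n == 0:
            continue
        for ord_, start in enumerate(range(0, n, window)):
            part_l = seq_l[start:start + window]
            part_a = seq_a[start:start + window]
            L = len(part_l)
            pad_l = np.zeros(window, dtype=np.int64)
            pad_a = np.zeros((window, A), dtype=np.int64)
            pad_l[:L] = part_l
            pad_a[:L] = part_a
            lab_chunks.append(pad_l)
            attr_chunks.append(pad_a)
            base_chunks.append(encoded.baseline[i])
            lengths.append(L)
            owners.append((pid, ord_))
    m = len(lab_chunks)
    B = encoded.schema.n_baseline
    return EncodedSequences(
        labels=np.stack(lab_chunks) if m else np.empty((0, window), dtype=np.int64),
        attrs=np.stack(attr_chunks) if m else np.empty((0, window, A), dtype=np.int64),
        baseline=np.stack(base_chunks) if m else np.empty((0, B), dtype=np.int64),
        lengths=np.asarray(lengths, dtype=np.int64),
        chunk_owner=owners,
        codebook=encoded.codebook,
    )


def reassemble(chunks: EncodedSequences, baseline: np.ndarray | None = None,
               pids: list | None = None) -> EncodedCohort:
    """Concatenate chunks back into per-individual sequences (inverse of chunk
    for individuals with at least one event)."""
    per_pid: dict = {}
    base_of: dict = {}
    for idx, (pid, ord_) in enumerate(chunks.chunk_owner):
        per_pid.setdefault(pid, []).append((ord_, idx))
        base_of[pid] = chunks.baseline[idx]
    out_pids = list(per_pid) if pids is None else pids
    labels, attrs, base = [], [], []
    for pid in out_pids:
        parts = sorted(per_pid.get(pid, []))
        ls, as_ = [], []
        for _, idx in parts:
            L = chunks.lengths[idx]
            ls.append(chunks.labels[idx, :L])
            as_.append(chunks.attrs[idx, :L])
        labels.append(np.concatenate(ls) if ls
                      else np.empty(0, dtype=np.int64))
        attrs.append(np.concatenate(as_) if as_
                     else np.empty((0, chunks.attrs.shape[2]), dtype=np.int64))
        base.append(base_of.get(pid) if pid in base_of else
                    np.zeros(chunks.baseline.shape[1], dtype=np.int64))
    return EncodedCohort(pids=out_pids, labels=labels, attrs=attrs,
                         baseline=np.stack(base) if base else chunks.baseline,
                         codebook=chunks.codebook)


def decode_cohort(encoded: EncodedCohort, sojourn_attr: str = "sojourn") -> Cohort:
    """Decode integer sequences back into a Cohort.

    Categorical codes decode exactly; binned continuous codes decode to the
    bin representative.  Event dates are reconstructed by cumulating the
    decoded sojourn attribute when present.
    """
    schema = encoded.schema
    cb = encoded.codebook
    relev = schema.relevance_matrix()
    rows = []
    for i, pid in enumerate(encoded.pids):
        seq_l, seq_a = encoded.labels[i], encoded.attrs[i]
        date = 0.0
        for t in range(len(seq_l)):
            lc = int(seq_l[t])
            row = {PID: pid, "pos": t, "label": schema.label_vocab[lc]}
            soj = 0.0
            for j, a in enumerate(schema.attributes):
                code = int(seq_a[t, j])
                if relev[lc, j] and code > 0:
                    val = cb.attr_codecs[a.name].decode(np.array([code]))[0]
                    row[a.name] = val
                    if a.name == sojourn_attr:
                        soj = float(val)
                else:
                    row[a.name] = np.nan
            date += soj
            row["date"] = date
            row["sojourn"] = soj
            rows.append(row)
    cols = [PID, "pos", "label", "date", "sojourn"] + \
        [a for a in schema.attr_names if a != "sojourn"]
    events = pd.DataFrame(rows, columns=cols)
    base_cols = {PID: encoded.pids}
    for k, b in enumerate(schema.baseline_vars):
        codec = cb.baseline_codecs[b.name]
        base_cols[b.name] = codec.decode(encoded.baseline[:, k])
    baseline = pd.DataFrame(base_cols)
    return Cohort(baseline=baseline, events=events, schema=schema)
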