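"""Generic and workload-aware utility metrics.

Distribution-level comparisons use the Hellinger distance
``H(p, q) = sqrt(1 - sum_i sqrt(p_i q_i))`` (0 = identical, 1 = disjoint).
Longitudinal structure is compared through empirical k-th order Markov
transition matrices, row by row.  A single multivariate similarity number is
derived from the Gaussian Bhattacharyya distance.  The random-cohort
assessment fuzzes SELECT queries against both datasets through an embedded
SQL engine.  The workload-aware operators are standardized mean differences
and confidence-interval overlap.
"""

from __future__ import annotations

import itertools
import sqlite3
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PID, Cohort
from .schema import CohortSchema


# ---------------------------------------------------------------------------
# discrete distributions and Hellinger distance
# ---------------------------------------------------------------------------

@dataclass
class DiscreteDistribution:
    support: list
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any():
            raise ValueError("negative probabilities")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {self.probs.sum()}, not 1")

    @classmethod
    def from_counts(cls, counts: dict | pd.Series) -> "DiscreteDistribution":
        if isinstance(counts, dict):
            counts = pd.Series(counts)
        total = counts.sum()
        if total <= 0:
            raise ValueError("empty counts")
        return cls(support=list(counts.index),
                   probs=counts.to_numpy(dtype=float) / total)

    @classmethod
    def from_values(cls, values) -> "DiscreteDistribution":
        return cls.from_counts(pd.Series(values).value_counts())


def hellinger(p: DiscreteDistribution, q: DiscreteDistribution) -> float:
    """Hellinger distance on the union of supports; symmetric, in [0, 1]."""
    support = list(dict.fromkeys(list(p.support) + list(q.support)))
    pv = pd.Series(p.probs, index=p.support).reindex(support, fill_value=0.0)
    qv = pd.Series(q.probs, index=q.support).reindex(support, fill_value=0.0)
    return _hellinger_arrays(pv.to_numpy(), qv.to_numpy())


def _hellinger_arrays(p: np.ndarray, q: np.ndarray) -> float:
    # (1/sqrt 2)||sqrt p - sqrt q||_2: identical to sqrt(1 - BC) for
    # normalized inputs but exactly 0 on identical arrays
    diff = np.sqrt(np.asarray(p, dtype=float)) - np.sqrt(np.asarray(q,
                                                                    dtype=float))
    return float(min(1.0, np.sqrt(0.5 * (diff ** 2).sum())))


def summarize(values) -> dict:
    """mean / SD / median / IQR of a list of per-item metric values."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return {"mean": np.nan, "sd": np.nan, "median": np.nan, "iqr": np.nan,
                "n": 0}
    q75, q25 = np.percentile(v, [75, 25])
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1
            else 0.0, "median": float(np.median(v)), "iqr": float(q75 - q25),
            "n": int(len(v))}


# ---------------------------------------------------------------------------
# event / length / attribute comparisons
# ---------------------------------------------------------------------------

def sequence_length_report(real: Cohort, syn: Cohort,
                           n_hist_bins: int = 30) -> dict:
    """Percent difference in mean events-per-individual, plus histogram data."""
    lr = real.sequence_lengths().to_numpy(dtype=float)
    ls = syn.sequence_lengths().to_numpy(dtype=float)
    if len(lr) == 0 or len(ls) == 0:
        raise ValueError("empty cohort")
    mr, ms = lr.mean(), ls.mean()
    edges = np.histogram_bin_edges(np.concatenate([lr, ls]), bins=n_hist_bins)
    return {
        "real_mean": float(mr), "real_sd": float(lr.std(ddof=1)),
        "syn_mean": float(ms), "syn_sd": float(ls.std(ddof=1)),
        "percent_diff": float(100.0 * abs(ms - mr) / mr),
        "hist_edges": edges.tolist(),
        "hist_real": np.histogram(lr, bins=edges)[0].tolist(),
        "hist_syn": np.histogram(ls, bins=edges)[0].tolist(),
    }


def event_distribution_hellinger(real: Cohort, syn: Cohort) -> float:
    """Hellinger distance between pooled event-label distributions."""
    p = DiscreteDistribution.from_values(real.events["label"])
    q = DiscreteDistribution.from_values(syn.events["label"])
    return hellinger(p, q)


def attribute_hellinger(real: Cohort, syn: Cohort, schema: CohortSchema,
                        n_bins: int = 10) -> dict:
    """Per-attribute marginal Hellinger distances, relevance-filtered.

    Only rows whose event label is relevant for the attribute enter the
    tabulation, so padded/missing cells never distort the comparison.
    Continuous attributes are discretized on quantile bins fitted to the
    pooled real values.  Returns per-attribute distances plus a summary.
    """
    out = {}
    for a in schema.attributes:
        rel_labels = [l for l, s in schema.relevance.items() if a.name in s]
        rv = real.events.loc[real.events["label"].isin(rel_labels), a.name]
        sv = syn.events.loc[syn.events["label"].isin(rel_labels), a.name]
        rv, sv = rv.dropna(), sv.dropna()
        if len(rv) == 0 and len(sv) == 0:
            out[a.name] = np.nan
            continue
        if len(rv) == 0 or len(sv) == 0:
            out[a.name] = 1.0
            continue
        if a.is_continuous:
            edges = np.unique(np.quantile(rv.to_numpy(dtype=float),
                                          np.linspace(0, 1, n_bins + 1)[1:-1]))
            rb = np.searchsorted(edges, rv.to_numpy(dtype=float))
            sb = np.searchsorted(edges, sv.to_numpy(dtype=float))
            p = DiscreteDistribution.from_values(rb)
            q = DiscreteDistribution.from_values(sb)
        else:
            p = DiscreteDistribution.from_values(rv)
            q = DiscreteDistribution.from_values(sv)
        out[a.name] = hellinger(p, q)
    return {"per_attribute": out,
            "summary": summarize(list(out.values()))}


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Empirical k-th order transition probabilities.

    ``probs`` rows are indexed by length-k label contexts (tuples) and sum to
    1; ``counts`` holds the raw window counts.  Contexts never observed are
    simply absent — in particular any context with a terminal event in a
    non-final position, since no events follow a terminal label.
    """

    order: int
    probs: pd.DataFrame
    counts: pd.DataFrame

    @property
    def contexts(self) -> list:
        return list(self.probs.index)

    def row(self, context: tuple) -> pd.Series:
        """Transition distribution for one length-k context."""
        return self.probs.loc[[tuple(context)]].iloc[0]


def estimate_transition_matrix(cohort_or_sequences, k: int = 1,
                               labels: list | None = None) -> TransitionMatrix:
    """Count length-(k+1) windows within individuals and normalize rows.

    Accepts a Cohort or a mapping / list of label sequences.  Windows never
    cross individuals.
    """
    if k < 1:
        raise ValueError("order k must be >= 1")
    if isinstance(cohort_or_sequences, Cohort):
        seqs = list(cohort_or_sequences.label_sequences().values())
        if labels is None and cohort_or_sequences.schema is not None:
            labels = cohort_or_sequences.schema.event_labels
    elif isinstance(cohort_or_sequences, dict):
        seqs = list(cohort_or_sequences.values())
    else:
        seqs = list(cohort_or_sequences)
    counts: dict = {}
    observed = set()
    for seq in seqs:
        seq = list(seq)
        observed.update(seq)
        for t in range(len(seq) - k):
            ctx = tuple(seq[t:t + k])
            nxt = seq[t + k]
            counts.setdefault(ctx, {}).setdefault(nxt, 0)
            counts[ctx][nxt] += 1
    if not counts:
        raise ValueError(f"no windows of length {k + 1} in the data")
    if labels is None:
        labels = sorted(observed)
    ctxs = sorted(counts.keys())
    cmat = pd.DataFrame(0.0, index=pd.Index(ctxs, tupleize_cols=False),
                        columns=labels)
    for ctx, row in counts.items():
        for nxt, c in row.items():
            cmat.loc[[ctx], nxt] = float(c)
    pmat = cmat.div(cmat.sum(axis=1), axis=0)
    return TransitionMatrix(order=k, probs=pmat, counts=cmat)


def compare_transition_matrices(real: TransitionMatrix, syn: TransitionMatrix,
                                unmatched: str = "score_one") -> dict:
    """Row-wise Hellinger distances between two same-order matrices.

    Rows are matched by context over the union of contexts.  A context
    present in only one matrix scores distance 1 under ``score_one``
    (missing structure = maximal dissimilarity) or is dropped under
    ``skip``.
    """
    if real.order != syn.order:
        raise ValueError("transition matrix orders differ")
    cols = list(dict.fromkeys(list(real.probs.columns)
                              + list(syn.probs.columns)))
    rset, sset = set(real.contexts), set(syn.contexts)
    per_row = {}
    for ctx in sorted(rset | sset):
        if ctx in rset and ctx in sset:
            p = real.probs.loc[[ctx]].reindex(columns=cols,
                                              fill_value=0.0).to_numpy()[0]
            q = syn.probs.loc[[ctx]].reindex(columns=cols,
                                             fill_value=0.0).to_numpy()[0]
            # renormalize: tolerates rounded published rows
            per_row[ctx] = _hellinger_arrays(p / p.sum(), q / q.sum())
        elif unmatched == "score_one":
            per_row[ctx] = 1.0
        elif unmatched == "skip":
            continue
        else:
            raise ValueError(f"unknown unmatched policy {unmatched!r}")
    return {"per_row": per_row, "summary": summarize(per_row.values())}


# ---------------------------------------------------------------------------
# multivariate Hellinger (from the Gaussian Bhattacharyya distance)
# ---------------------------------------------------------------------------

def multivariate_hellinger(real: pd.DataFrame, syn: pd.DataFrame,
                           ridge: float = 1e-6) -> float:
    """Overall multivariate similarity of two numeric-encoded tables.

    Fits a mean vector and covariance matrix to each table, computes the
    Gaussian Bhattacharyya distance

        BD = 1/8 (mu1-mu2)' S^-1 (mu1-mu2) + 1/2 ln( det S / sqrt(det S1 det S2) )

    with S = (S1+S2)/2, and returns sqrt(1 - exp(-BD)) in [0, 1].
    Covariances get a small trace-scaled ridge on the diagonal.
    """
    if list(real.columns) != list(syn.columns):
        raise ValueError("tables must share identical columns")
    X1 = real.to_numpy(dtype=float)
    X2 = syn.to_numpy(dtype=float)
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    d = X1.shape[1]
    S1 = np.cov(X1, rowvar=False).reshape(d, d)
    S2 = np.cov(X2, rowvar=False).reshape(d, d)
    lam = ridge * (np.trace(S1) + np.trace(S2)) / (2 * d)
    S1 = S1 + lam * np.eye(d)
    S2 = S2 + lam * np.eye(d)
    S = 0.5 * (S1 + S2)
    sign, logdet_S = np.linalg.slogdet(S)
    s1, logdet_1 = np.linalg.slogdet(S1)
    s2, logdet_2 = np.linalg.slogdet(S2)
    if sign <= 0 or s1 <= 0 or s2 <= 0:
        bad = [c for i, c in enumerate(real.columns)
               if S[i, i] <= 0 or not np.isfinite(S[i, i])]
        raise np.linalg.LinAlgError(
            f"singular covariance after regularization (columns {bad})")
    diff = mu1 - mu2
    bd = 0.125 * diff @ np.linalg.solve(S, diff) \
        + 0.5 * (logdet_S - 0.5 * (logdet_1 + logdet_2))
    return float(np.sqrt(max(0.0, 1.0 - np.exp(-max(bd, 0.0)))))


def numeric_event_table(cohort: Cohort, schema: CohortSchema) -> pd.DataFrame:
    """Numeric encoding of the event stream joined with baseline covariates.

    Categorical columns map to integer codes (0 = missing), continuous ones
    stay numeric with missing as 0; used as input to multivariate_hellinger.
    """
    ev = cohort.events
    out = pd.DataFrame(index=ev.index)
    out["label"] = [schema.label_code(l) for l in ev["label"]]
    for a in schema.attributes:
        col = ev[a.name]
        if a.is_continuous:
            out[a.name] = pd.to_numeric(col, errors="coerce").fillna(0.0)
        else:
            lookup = {c: i + 1 for i, c in enumerate(a.categories)}
            out[a.name] = [lookup.get(v, 0) if not pd.isna(v) else 0
                           for v in col]
    base = cohort.baseline.set_index(PID)
    for b in schema.baseline_vars:
        col = ev[PID].map(base[b.name])
        if b.is_continuous:
            out[b.name] = pd.to_numeric(col, errors="coerce").fillna(0.0)
        else:
            lookup = {c: i + 1 for i, c in enumerate(b.categories)}
            out[b.name] = [lookup.get(v, 0) if not pd.isna(v) else 0
                           for v in col]
    return out


# ---------------------------------------------------------------------------
# random-cohort (fuzzy SQL) assessment
# ---------------------------------------------------------------------------

def normalized_euclidean(a: float, b: float) -> float:
    """|a - b| / sqrt(a^2 + b^2), defined as 0 when both are 0."""
    denom = np.sqrt(a * a + b * b)
    if denom == 0:
        return 0.0
    return float(abs(a - b) / denom)


def _flat_table(cohort: Cohort, schema: CohortSchema) -> pd.DataFrame:
    ev = cohort.events.copy()
    base = cohort.baseline.set_index(PID)
    for b in schema.baseline_vars:
        ev[b.name] = ev[PID].map(base[b.name])
    keep = ["label", "sojourn"] + \
        [a.name for a in schema.attributes if a.name != "sojourn"] + \
        [b.name for b in schema.baseline_vars]
    return ev[keep]


@dataclass
class QueryResult:
    query: str
    kind: str          # "distribution" | "aggregate"
    distance: float
    note: str = ""


def random_cohort_assessment(real: Cohort, syn: Cohort, schema: CohortSchema,
                             n_queries: int = 100, seed: int = 0,
                             max_predicates: int = 3) -> dict:
    """Fuzz random SELECT queries against both datasets and compare results.

    Each query draws up to ``max_predicates`` conjunctive predicates
    (categorical equality or numeric range, values taken from the real data)
    and either one scalar aggregate (COUNT(*) or AVG of a numeric column) or
    one categorical GROUP BY with counts.  Grouped results are compared by
    Hellinger distance on the normalized group distribution, scalar results
    by normalized Euclidean distance.  Queries empty on both sides are
    skipped; empty on exactly one side scores maximal distance 1.
    """
    rng = np.random.default_rng(seed)
    rt = _flat_table(real, schema)
    st = _flat_table(syn, schema)
    cat_cols = [c for c in rt.columns if rt[c].dtype == object]
    num_cols = [c for c in rt.columns
                if np.issubdtype(rt[c].dtype, np.number)]

    con = sqlite3.connect(":memory:")
    rt.to_sql("real_t", con, index=False)
    st.to_sql("syn_t", con, index=False)

    results: list[QueryResult] = []
    skipped = 0
    while len(results) < n_queries:
        preds = []
        for _ in range(int(rng.integers(0, max_predicates + 1))):
            if cat_cols and (not num_cols or rng.random() < 0.5):
                c = cat_cols[int(rng.integers(len(cat_cols)))]
                vals = rt[c].dropna().unique()
                v = str(vals[int(rng.integers(len(vals)))]).replace("'", "''")
                preds.append(f"\"{c}\" = '{v}'")
            elif num_cols:
                c = num_cols[int(rng.integers(len(num_cols)))]
                vals = rt[c].dropna().to_numpy(dtype=float)
                lo, hi = sorted(np.quantile(vals, rng.random(2)))
                preds.append(f"\"{c}\" BETWEEN {float(lo)} AND {float(hi)}")
        where = (" WHERE " + " AND ".join(preds)) if preds else ""

        if cat_cols and rng.random() < 0.5:
            gcol = cat_cols[int(rng.integers(len(cat_cols)))]
            sql = (f'SELECT "{gcol}", COUNT(*) FROM {{t}}{where} '
                   f'GROUP BY "{gcol}"')
            kind = "distribution"
        else:
            if num_cols and rng.random() < 0.5:
                acol = num_cols[int(rng.integers(len(num_cols)))]
                sql = f'SELECT AVG("{acol}") FROM {{t}}{where}'
            else:
                sql = f"SELECT COUNT(*) FROM {{t}}{where}"
            kind = "aggregate"

        r_rows = con.execute(sql.format(t="real_t")).fetchall()
        s_rows = con.execute(sql.format(t="syn_t")).fetchall()
        if kind == "distribution":
            rc = {k: v for k, v in r_rows if k is not None}
            sc = {k: v for k, v in s_rows if k is not None}
            if not rc and not sc:
                skipped += 1
                continue
            if not rc or not sc:
                results.append(QueryResult(sql, kind, 1.0, "one side empty"))
                continue
            d = hellinger(DiscreteDistribution.from_counts(rc),
                          DiscreteDistribution.from_counts(sc))
            results.append(QueryResult(sql, kind, d))
        else:
            ra = r_rows[0][0]
            sa = s_rows[0][0]
            if ra is None and sa is None:
                skipped += 1
                continue
            if ra is None or sa is None:
                results.append(QueryResult(sql, kind, 1.0, "one side empty"))
                continue
            results.append(QueryResult(
                sql, kind, normalized_euclidean(float(ra), float(sa))))
    con.close()
    dist = [r.distance for r in results if r.kind == "distribution"]
    aggr = [r.distance for r in results if r.kind == "aggregate"]
    return {"queries": results, "n_skipped": skipped,
            "hellinger_summary": summarize(dist),
            "euclidean_summary": summarize(aggr)}


# ---------------------------------------------------------------------------
# workload-aware operators: SMD and CI overlap
# ---------------------------------------------------------------------------

def smd_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """|m2 - m1| / sqrt((sd1^2 + sd2^2) / 2); > 0.1 flags imbalance."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    if denom == 0:
        return 0.0 if mean1 == mean2 else float("inf")
    return float(abs(mean2 - mean1) / denom)


def smd_binary(x1: int, n1: int, x2: int, n2: int) -> float:
    """SMD of two proportions x1/n1 vs x2/n2 with pooled binomial variance."""
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("need 0 <= x <= n and n > 0")
    p1, p2 = x1 / n1, x2 / n2
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if denom == 0:
        return 0.0 if p1 == p2 else float("inf")
    return float(abs(p1 - p2) / denom)


def ci_overlap(lo1: float, hi1: float, lo2: float, hi2: float) -> float:
    """Average percent of each interval covered by the intersection.

    100 * 1/2 * (L / (hi1-lo1) + L / (hi2-lo2)) with
    L = max(0, min(hi1, hi2) - max(lo1, lo2)); symmetric in the two
    intervals.  A zero-width interval contributes 1 if its point lies inside
    the other interval, else 0.
    """
    if lo1 > hi1 or lo2 > hi2:
        raise ValueError("interval bounds out of order")
    L = max(0.0, min(hi1, hi2) - max(lo1, lo2))

    def _ratio(lo, hi, other_lo, other_hi):
        w = hi - lo
        if w == 0:
            return 1.0 if other_lo <= lo <= other_hi else 0.0
        return L / w

    return float(100.0 * 0.5 * (_ratio(lo1, hi1, lo2, hi2)
                                + _ratio(lo2, hi2, lo1, hi1)))


# ---------------------------------------------------------------------------
# the full generic report
# ---------------------------------------------------------------------------

@dataclass
class UtilityReport:
    sequence_length: dict
    event_distribution_hellinger: float
    attribute_hellinger: dict
    transition_hellinger: dict      # order -> {"per_row", "summary"}
    multivariate_hellinger: float
    random_cohort: dict | None = None

    def to_dict(self) -> dict:
        def _tm(d):
            return {"summary": d["summary"],
                    "per_row": {" | ".join(map(str, k)): v
                                for k, v in d["per_row"].items()}}

        out = {
            "sequence_length": self.sequence_length,
            "event_distribution_hellinger": self.event_distribution_hellinger,
            "attribute_hellinger": self.attribute_hellinger,
            "transition_hellinger": {str(k): _tm(v) for k, v in
                                     self.transition_hellinger.items()},
            "multivariate_hellinger": self.multivariate_hellinger,
        }
        if self.random_cohort is not None:
            out["random_cohort"] = {
                "hellinger_summary": self.random_cohort["hellinger_summary"],
                "euclidean_summary": self.random_cohort["euclidean_summary"],
                "n_skipped": self.random_cohort["n_skipped"],
                "queries": [
                    {"query": q.query, "kind": q.kind,
                     "distance": q.distance, "note": q.note}
                    for q in self.random_cohort["queries"]],
            }
        return out


def evaluate_utility(real: Cohort, syn: Cohort, schema: CohortSchema,
                     orders: tuple = (1, 2), n_queries: int = 100,
                     seed: int = 0, with_random_cohorts: bool = True
                     ) -> UtilityReport:
    """Run the full generic utility suite on a real/synthetic cohort pair."""
    trans = {}
    for k in orders:
        tr = estimate_transition_matrix(real, k)
        ts = estimate_transition_matrix(syn, k)
        trans[k] = compare_transition_matrices(tr, ts)
    report = UtilityReport(
        sequence_length=sequence_length_report(real, syn),
        event_distribution_hellinger=event_distribution_hellinger(real, syn),
        attribute_hellinger=attribute_hellinger(real, syn, schema),
        transition_hellinger=trans,
        multivariate_hellinger=multivariate_hellinger(
            numeric_event_table(real, schema),
            numeric_event_table(syn, schema)),
        random_cohort=random_cohort_assessment(
            real, syn, schema, n_queries=n_queries, seed=seed)
        if with_random_cohorts else None,
    )
    return report
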