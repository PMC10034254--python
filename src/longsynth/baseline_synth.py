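"""Sequential tree-based synthesis of baseline characteristics.

Baseline variables and the values of each individual's first event are
synthesized column by column: the first variable is drawn from its empirical
marginal, and every later variable is predicted from the variables earlier in
the sequence by a fitted decision tree, sampling from the pool of real donor
values in the reached leaf.  These synthesized rows seed the recurrent
generator, which produces all subsequent events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .cohort import PID
from .encoding import EncodedCohort

log = logging.getLogger(__name__)

_NAN_TOKEN = "__nan__"


def _is_categorical(col: pd.Series, max_classes: int) -> bool:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) \
            or col.dtype == bool:
        return True
    return col.nunique(dropna=True) <= max_classes


@dataclass
class _ColumnModel:
    name: str
    categorical: bool
    marginal: np.ndarray | None = None          # first variable only
    tree: object | None = None
    donor_pools: dict = field(default_factory=dict)  # leaf id -> value array
    predictor_cats: dict = field(default_factory=dict)  # col -> category list


@dataclass
class SequentialTreeModel:
    """Fitted chain of per-variable trees with leaf-wise donor pools."""

    order: list
    columns: list  # list[_ColumnModel]
    min_leaf: int = 5


def _encode_predictors(frame: pd.DataFrame, cats: dict) -> np.ndarray:
    X = np.empty((len(frame), len(frame.columns)), dtype=float)
    for j, c in enumerate(frame.columns):
        col = frame[c]
        if c in cats:
            lookup = {v: i for i, v in enumerate(cats[c])}
            X[:, j] = [lookup.get(v, np.nan) if not _isnan(v) else np.nan
                       for v in col]
        else:
            X[:, j] = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    return X


def _isnan(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def fit_sequential_trees(
    table: pd.DataFrame,
    order: list | None = None,
    min_leaf: int = 5,
    max_classes: int = 100,
    seed: int = 0,
) -> SequentialTreeModel:
    """Fit the synthesis chain.

    ``order`` defaults to the table's column order.  For variable j > 1 a
    decision tree is fitted on variables 1..j-1; each leaf stores the real
    target values of the training rows it contains (the donor pool).  A tree
    that cannot split (constant predictors) collapses to a single leaf, which
    is exactly marginal sampling.
    """
    if len(table) == 0:
        raise ValueError("cannot fit on an empty table")
    order = list(order or table.columns)
    if set(order) != set(table.columns):
        raise ValueError("order must be a permutation of the table columns")

    cols: list[_ColumnModel] = []
    for j, name in enumerate(order):
        y = table[name]
        categorical = _is_categorical(y, max_classes)
        cm = _ColumnModel(name=name, categorical=categorical)
        if j == 0:
            cm.marginal = y.to_numpy()
        else:
            pred_cols = order[:j]
            cm.predictor_cats = {
                c: sorted(table[c].dropna().unique().tolist())
                for c in pred_cols
                if _is_categorical(table[c], max_classes)
                and table[c].dtype == object
            }
            X = _encode_predictors(table[pred_cols], cm.predictor_cats)
            if categorical:
                y_fit = y.to_numpy(dtype=object).copy()
                y_fit[[_isnan(v) for v in y_fit]] = _NAN_TOKEN
                y_fit = y_fit.astype(str)
                tree = DecisionTreeClassifier(
                    min_samples_leaf=min_leaf, random_state=seed
                )
            else:
                y_fit = pd.to_numeric(y, errors="coerce").fillna(
                    y.dropna().median() if y.notna().any() else 0.0
                ).to_numpy(dtype=float)
                tree = DecisionTreeRegressor(
                    min_samples_leaf=min_leaf, random_state=seed
                )
            tree.fit(X, y_fit)
            leaves = tree.apply(X)
            if tree.get_n_leaves() == 1:
                log.info("column %r: tree degenerated to a single leaf; "
                         "sampling from the marginal", name)
            pools: dict = {}
            y_orig = y.to_numpy()
            for leaf in np.unique(leaves):
                pools[int(leaf)] = y_orig[leaves == leaf]
            cm.tree = tree
            cm.donor_pools = pools
        cols.append(cm)
    return SequentialTreeModel(order=order, columns=cols, min_leaf=min_leaf)


def synthesize_baseline(
    model: SequentialTreeModel, n: int, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` synthetic rows from the fitted chain.

    Values only ever come from donor pools, so no categories are invented.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=range(n))
    for j, cm in enumerate(model.columns):
        if n == 0:
            out[cm.name] = pd.Series(dtype=object if cm.categorical else float)
            continue
        if j == 0:
            out[cm.name] = rng.choice(cm.marginal, size=n, replace=True)
            continue
        X = _encode_predictors(out[model.order[:j]], cm.predictor_cats)
        leaves = cm.tree.apply(X)
        values = np.empty(n, dtype=object)
        for leaf in np.unique(leaves):
            idx = np.flatnonzero(leaves == leaf)
            pool = cm.donor_pools[int(leaf)]
            values[idx] = rng.choice(pool, size=len(idx), replace=True)
        out[cm.name] = values if cm.categorical else values.astype(float)
    return out


# -- seeding the recurrent generator --------------------------------------

FIRST_LABEL = "first_label"


def seed_frame(encoded: EncodedCohort) -> pd.DataFrame:
    """Baseline + first-event codes table (one row per individual with events).

    Columns: one per baseline variable, then ``first_label`` and
    ``first_<attr>`` integer codes.  This is the training table for the
    sequential trees; synthesized rows of the same shape seed generation.
    """
    schema = encoded.schema
    rows = []
    for i, pid in enumerate(encoded.pids):
        if len(encoded.labels[i]) == 0:
            continue
        row = {b.name: int(encoded.baseline[i, k])
               for k, b in enumerate(schema.baseline_vars)}
        row[FIRST_LABEL] = int(encoded.labels[i][0])
        for j, a in enumerate(schema.attributes):
            row[f"first_{a.name}"] = int(encoded.attrs[i][0, j])
        rows.append(row)
    return pd.DataFrame(rows)


def synthesize_seeds(encoded: EncodedCohort, n: int, seed: int = 0,
                     min_leaf: int = 5) -> pd.DataFrame:
    """Fit sequential trees on the real seed table and draw n synthetic seeds."""
    table = seed_frame(encoded)
    model = fit_sequential_trees(table, min_leaf=min_leaf, seed=seed)
    syn = synthesize_baseline(model, n, seed=seed)
    return syn.astype(int)
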