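"""Training and sampling for the conditional recurrent generator.

The model is trained by teacher forcing on fixed-window chunks: events at
times {1..t-1} are inputs, events at {2..t} are targets.  The objective is

    loss_labels + lambda * loss_attributes

where ``loss_labels`` is the cross-entropy of the next event label over
non-padded positions and ``loss_attributes`` is the cross-entropy of each
attribute, counted only where the attribute is relevant for the *true* next
label.  Masking keeps the model from spending capacity predicting missing
values.

Generation starts from tree-synthesized baseline + first-event seeds, then
iterates: sample the next label from the label head, sample each attribute
relevant for that label, blank the rest, and feed the sampled event back with
the carried hidden state, until a terminal label or the maximum length.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .baseline_synth import FIRST_LABEL
from .cohort import Cohort
from .encoding import Codebook, EncodedCohort, EncodedSequences, decode_cohort
from .recurrent import CondLSTM, HiddenState, softmax
from .schema import CohortSchema


@dataclass
class ModelConfig:
    """Training hyperparameters; all sizes are embedding/width counts."""

    embed_label: int = 8
    embed_attr: int = 6
    embed_base: int = 4
    hidden: int = 48
    n_layers: int = 1
    lam: float = 1.0           # label-loss vs attribute-loss tradeoff
    batch_size: int = 64
    epochs: int = 30
    lr: float = 5e-3
    optimizer: str = "adam"
    window: int = 120
    seed: int = 0
    label_weights: list | None = None   # optional per-label loss weights
    attr_weights: list | None = None    # optional per-attribute loss weights
    include_padding_targets: bool = False  # strict-formula mode
    attr_reduction: str = "mean"        # "mean" over contributing triples | "sum"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if min(self.embed_label, self.embed_attr, self.embed_base,
               self.hidden, self.n_layers, self.batch_size, self.epochs) <= 0:
            raise ValueError("all sizes must be positive")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _ce_terms(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-position cross-entropy  -x[true] + log sum_j exp(x[j])."""
    z = logits - logits.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1)) + logits.max(axis=-1)
    true_logit = np.take_along_axis(
        logits, targets[..., None], axis=-1).squeeze(-1)
    return lse - true_logit


def label_loss(label_logits: np.ndarray, true_labels: np.ndarray,
               pad_mask: np.ndarray,
               label_weights: np.ndarray | None = None) -> float:
    """Mean next-label cross-entropy over non-padded positions.

    ``pad_mask`` is True where the position is a real (non-padding) target.
    """
    pad_mask = np.asarray(pad_mask, dtype=bool)
    if not pad_mask.any():
        raise ValueError("all positions padded: label loss undefined")
    terms = _ce_terms(label_logits, true_labels)
    if label_weights is not None:
        w = np.asarray(label_weights, dtype=float)[true_labels]
        return float((terms * w)[pad_mask].sum() / w[pad_mask].sum())
    return float(terms[pad_mask].mean())


def attribute_loss(attr_logits: list, true_labels: np.ndarray,
                   true_attrs: np.ndarray, relevance: np.ndarray,
                   pad_mask: np.ndarray, reduction: str = "mean",
                   attr_weights: np.ndarray | None = None) -> float:
    """Masked attribute cross-entropy.

    A triple (n, t, i) contributes only when attribute i is relevant for the
    true label at (n, t) and the position is not padding.  ``relevance`` is a
    boolean [C, A] matrix indexed by label code.  ``reduction`` "mean" divides
    by the number of contributing triples, "sum" divides by the number of
    non-padded positions (summing attribute terms per position).
    """
    pad_mask = np.asarray(pad_mask, dtype=bool)
    total = 0.0
    wsum = 0.0
    n_pos = float(pad_mask.sum())
    for i, logits in enumerate(attr_logits):
        mask = pad_mask & relevance[true_labels, i]
        if not mask.any():
            continue
        terms = _ce_terms(logits, true_attrs[..., i])
        w = 1.0 if attr_weights is None else float(attr_weights[i])
        total += w * terms[mask].sum()
        wsum += w * mask.sum()
    if wsum == 0:
        raise ValueError("no relevant attribute terms: attribute loss undefined")
    if reduction == "mean":
        return float(total / wsum)
    if reduction == "sum":
        return float(total / n_pos)
    raise ValueError(f"unknown reduction {reduction!r}")


def total_loss(loss_labels: float, loss_attributes: float, lam: float) -> float:
    """The lambda-weighted training objective."""
    return float(loss_labels + lam * loss_attributes)


def _label_loss_grad(logits, targets, pad_mask):
    probs = softmax(logits)
    n_valid = pad_mask.sum()
    terms = _ce_terms(logits, targets)
    loss = float(terms[pad_mask].mean())
    d = probs.copy()
    np.put_along_axis(
        d, targets[..., None],
        np.take_along_axis(d, targets[..., None], axis=-1) - 1.0, axis=-1)
    d *= pad_mask[..., None] / n_valid
    return loss, d


def _attr_loss_grad(attr_logits, true_labels, true_attrs, relevance,
                    pad_mask, reduction):
    masks = [pad_mask & relevance[true_labels, i]
             for i in range(len(attr_logits))]
    M = float(sum(m.sum() for m in masks))
    if M == 0:
        return 0.0, [np.zeros_like(l) for l in attr_logits]
    denom = M if reduction == "mean" else float(pad_mask.sum())
    loss = 0.0
    grads = []
    for i, logits in enumerate(attr_logits):
        m = masks[i]
        if m.any():
            loss += _ce_terms(logits, true_attrs[..., i])[m].sum()
        d = softmax(logits)
        tgt = true_attrs[..., i]
        np.put_along_axis(
            d, tgt[..., None],
            np.take_along_axis(d, tgt[..., None], axis=-1) - 1.0, axis=-1)
        d *= m[..., None] / denom
        grads.append(d)
    return float(loss / denom), grads


# ---------------------------------------------------------------------------
# model wrapper, training, generation
# ---------------------------------------------------------------------------

@dataclass
class GeneratorModel:
    """A fitted conditional recurrent generator bound to its codebook."""

    net: CondLSTM
    codebook: Codebook
    config: ModelConfig
    loss_trace: list = field(default_factory=list)

    @property
    def schema(self) -> CohortSchema:
        return self.codebook.schema

    def forward(self, labels, attrs, base, state: HiddenState | None = None):
        """Next-step logits for inputs at times {1..t-1} (see CondLSTM)."""
        lab, att, st, _ = self.net.forward(labels, attrs, base, state)
        return lab, att, st

    def save(self, path) -> None:
        sd = self.net.state_dict()
        arrays = {f"param::{k}": v for k, v in sd["params"].items()}
        arrays["meta_json"] = np.array(json.dumps({
            "net_meta": sd["meta"],
            "config": asdict(self.config),
            "codebook": self.codebook.to_dict(),
            "loss_trace": self.loss_trace,
        }))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "GeneratorModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            params = {k.split("::", 1)[1]: z[k] for k in z.files
                      if k.startswith("param::")}
        net = CondLSTM.from_state_dict(
            {"meta": meta["net_meta"], "params": params})
        return cls(net=net, codebook=Codebook.from_dict(meta["codebook"]),
                   config=ModelConfig(**meta["config"]),
                   loss_trace=meta["loss_trace"])


def build_net(codebook: Codebook, config: ModelConfig) -> CondLSTM:
    schema = codebook.schema
    return CondLSTM(
        n_labels=schema.n_labels,
        attr_cards=[codebook.attr_cardinality(a) for a in schema.attr_names],
        base_cards=[codebook.baseline_cardinality(b.name)
                    for b in schema.baseline_vars],
        embed_label=config.embed_label, embed_attr=config.embed_attr,
        embed_base=config.embed_base, hidden=config.hidden,
        n_layers=config.n_layers, seed=config.seed)


def train(encoded: EncodedSequences, config: ModelConfig,
          verbose: bool = False) -> GeneratorModel:
    """Fit the generator on chunked sequences by teacher forcing.

    The hidden state is reset for every chunk (windows are treated as
    independent).  Returns the fitted model with a per-epoch trace of
    (label loss, attribute loss, total loss).
    """
    codebook = encoded.codebook
    schema = codebook.schema
    net = build_net(codebook, config)
    relevance = schema.relevance_matrix()

    labels, attrs, base = encoded.labels, encoded.attrs, encoded.baseline
    lengths = encoded.lengths
    m, T = labels.shape
    in_l, in_a = labels[:, :-1], attrs[:, :-1]
    tgt_l, tgt_a = labels[:, 1:], attrs[:, 1:]
    # target at offset t is original position t+1: valid while t+1 < length
    if config.include_padding_targets:
        valid = np.ones((m, T - 1), dtype=bool)
    else:
        valid = np.arange(1, T)[None, :] < lengths[:, None]
    usable = valid.any(axis=1)
    if not usable.any():
        raise ValueError("no non-padded transitions to train on")
    idx_all = np.flatnonzero(usable)

    rng = np.random.default_rng(config.seed)
    lw = None if config.label_weights is None else \
        np.asarray(config.label_weights, dtype=float)
    trace = []
    for epoch in range(config.epochs):
        order = rng.permutation(idx_all)
        ep_lab = ep_att = ep_n = 0.0
        for start in range(0, len(order), config.batch_size):
            b = order[start:start + config.batch_size]
            ll, al, _, cache = net.forward(in_l[b], in_a[b], base[b],
                                           want_cache=True)
            vb = valid[b]
            l_lab, d_lab = _label_loss_grad(ll, tgt_l[b], vb)
            l_att, d_att = _attr_loss_grad(al, tgt_l[b], tgt_a[b],
                                           relevance, vb,
                                           config.attr_reduction)
            if lw is not None:
                # reweight label terms (renormalized weighted mean)
                l_lab = label_loss(ll, tgt_l[b], vb, lw)
                w = lw[tgt_l[b]][..., None]
                d_lab = d_lab * w * vb.sum() / (lw[tgt_l[b]][vb].sum())
            if not np.isfinite(l_lab) or not np.isfinite(l_att):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(label={l_lab}, attr={l_att}); try a lower lr")
            d_attr_scaled = [config.lam * d for d in d_att]
            grads = net.backward(cache, d_lab, d_attr_scaled)
            if config.optimizer == "adam":
                net.adam_step(grads, config.lr)
            else:
                net.sgd_step(grads, config.lr)
            nb = float(vb.sum())
            ep_lab += l_lab * nb
            ep_att += l_att * nb
            ep_n += nb
        trace.append({"epoch": epoch, "label_loss": ep_lab / ep_n,
                      "attr_loss": ep_att / ep_n,
                      "total_loss": (ep_lab + config.lam * ep_att) / ep_n})
        if verbose:
            t = trace[-1]
            print(f"epoch {epoch:3d}  label {t['label_loss']:.4f}  "
                  f"attr {t['attr_loss']:.4f}  total {t['total_loss']:.4f}")
    return GeneratorModel(net=net, codebook=codebook, config=config,
                          loss_trace=trace)


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cdf = probs.cumsum(axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random((len(probs), 1))
    return (u < cdf).argmax(axis=1)


def generate(model: GeneratorModel, seeds: pd.DataFrame, max_length: int,
             temperature: float = 1.0, seed: int = 0,
             forbid_padding: bool = True) -> Cohort:
    """Generate a synthetic cohort from baseline + first-event seeds.

    ``seeds`` columns: one integer code per baseline variable, plus
    ``first_label`` and ``first_<attr>``.  Sampling uses the softmax of each
    head (temperature <= 0 means argmax); attributes irrelevant for the
    sampled label are set to missing.  Sequences are trimmed at the first
    terminal event; dates are rebuilt by cumulating decoded sojourn values.
    """
    schema = model.schema
    net = model.net
    rng = np.random.default_rng(seed)
    n = len(seeds)
    A = schema.n_attrs
    relevance = schema.relevance_matrix()
    term_code = schema.terminal_code

    base = np.stack([seeds[b.name].to_numpy(dtype=int)
                     for b in schema.baseline_vars], axis=1) \
        if schema.baseline_vars else np.zeros((n, 0), dtype=int)
    cur_l = seeds[FIRST_LABEL].to_numpy(dtype=int)
    if (cur_l < 0).any() or (cur_l >= schema.n_labels).any():
        raise ValueError("seed labels out of vocabulary")
    cur_a = np.zeros((n, A), dtype=int)
    for j, a in enumerate(schema.attributes):
        col = f"first_{a.name}"
        if col in seeds:
            cur_a[:, j] = seeds[col].to_numpy(dtype=int)
    cur_a *= relevance[cur_l]  # enforce masking on the seeded event

    seq_l = [cur_l]
    seq_a = [cur_a]
    alive = cur_l != term_code if term_code is not None \
        else np.ones(n, dtype=bool)
    state: HiddenState | None = None
    steps = 0
    while steps < max_length - 1 and alive.any():
        ll, al, state, _ = net.forward(cur_l[:, None], cur_a[:, None, :],
                                       base, state)
        logits = ll[:, 0]
        if forbid_padding:
            logits = logits.copy()
            logits[:, 0] = -np.inf
        if temperature <= 0:
            nxt = logits.argmax(axis=1)
        else:
            nxt = _sample_rows(softmax(logits / temperature), rng)
        nxt_a = np.zeros((n, A), dtype=int)
        for j in range(A):
            lj = al[j][:, 0]
            if forbid_padding:
                lj = lj.copy()
                lj[:, 0] = -np.inf
            if temperature <= 0:
                aj = lj.argmax(axis=1)
            else:
                aj = _sample_rows(softmax(lj / temperature), rng)
            nxt_a[:, j] = aj
        nxt_a *= relevance[nxt]  # mask attributes irrelevant for the label
        seq_l.append(nxt.copy())
        seq_a.append(nxt_a)
        cur_l, cur_a = nxt, nxt_a
        if term_code is not None:
            alive &= cur_l != term_code
        steps += 1

    all_l = np.stack(seq_l, axis=1)   # [n, L]
    all_a = np.stack(seq_a, axis=1)   # [n, L, A]
    labels_out, attrs_out = [], []
    for i in range(n):
        seq = all_l[i]
        if term_code is not None:
            hits = np.flatnonzero(seq == term_code)
            end = hits[0] + 1 if len(hits) else len(seq)
        else:
            end = len(seq)
        labels_out.append(seq[:end])
        attrs_out.append(all_a[i, :end])
    enc = EncodedCohort(pids=list(range(n)), labels=labels_out,
                        attrs=attrs_out, baseline=base,
                        codebook=model.codebook)
    cohort = decode_cohort(enc)
    # the first event's sojourn is zero by convention
    first = cohort.events["pos"] == 0
    cohort.events.loc[first, "sojourn"] = 0.0
    if "sojourn" in schema.attr_names:
        cohort.events.loc[first, "sojourn"] = 0.0
    cohort.events["date"] = cohort.events.groupby("pid")["sojourn"].cumsum()
    return cohort
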