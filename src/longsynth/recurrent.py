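"""NumPy implementation of the conditional recurrent network.

Architecture: independent embedding tables for the event label, each event
attribute and each baseline variable; the embedded label and attributes are
concatenated and fed through a (possibly stacked) LSTM; each output head is a
linear map over the concatenation of the LSTM output and the embedded
baseline characteristics, so every next-step prediction is conditioned on the
individual's fixed covariates.  Receiving inputs for times {1..t-1} yields
predictions for times {2..t}.

Everything runs on CPU-sized tensors; gradients are computed by explicit
backpropagation through time and applied with Adam.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class HiddenState:
    """Opaque recurrent state; ``None`` entries mean a fresh all-zero state."""

    def __init__(self, layers: list | None = None):
        self.layers = layers  # list of (h, c) per LSTM layer

    @classmethod
    def fresh(cls) -> "HiddenState":
        return cls(layers=None)


class CondLSTM:
    """Parameters + forward/backward for the conditional LSTM.

    Parameters
    ----------
    n_labels : label vocabulary size C (including padding code 0).
    attr_cards : per-attribute class counts C_i (including missing code 0).
    base_cards : per-baseline-variable category counts.
    embed_label, embed_attr, embed_base : embedding widths.
    hidden : LSTM hidden size.  n_layers : stacked LSTM layers.
    """

    def __init__(self, n_labels: int, attr_cards: list[int],
                 base_cards: list[int], embed_label: int = 8,
                 embed_attr: int = 6, embed_base: int = 4,
                 hidden: int = 48, n_layers: int = 1, seed: int = 0):
        self.C = n_labels
        self.attr_cards = list(attr_cards)
        self.base_cards = list(base_cards)
        self.d_label, self.d_attr, self.d_base = embed_label, embed_attr, embed_base
        self.H = hidden
        self.n_layers = n_layers
        self.D_in = embed_label + embed_attr * len(attr_cards)
        self.D_base = embed_base * len(base_cards)
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        p["emb_label"] = rng.normal(0, 0.1, (self.C, embed_label))
        for j, c in enumerate(self.attr_cards):
            p[f"emb_attr_{j}"] = rng.normal(0, 0.1, (c, embed_attr))
        for k, c in enumerate(self.base_cards):
            p[f"emb_base_{k}"] = rng.normal(0, 0.1, (c, embed_base))
        for l in range(n_layers):
            d = self.D_in if l == 0 else self.H
            s = 1.0 / np.sqrt(d + self.H)
            p[f"Wx_{l}"] = rng.normal(0, s, (d, 4 * self.H))
            p[f"Wh_{l}"] = rng.normal(0, s, (self.H, 4 * self.H))
            b = np.zeros(4 * self.H)
            b[self.H:2 * self.H] = 1.0  # forget-gate bias
            p[f"b_{l}"] = b
        d_out = self.H + self.D_base
        # heads start near zero so initial predictions are near-uniform
        p["W_label"] = rng.normal(0, 0.01, (d_out, self.C))
        p["b_label"] = np.zeros(self.C)
        for j, c in enumerate(self.attr_cards):
            p[f"W_attr_{j}"] = rng.normal(0, 0.01, (d_out, c))
            p[f"b_attr_{j}"] = np.zeros(c)
        self.params = p
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0

    # -- forward ----------------------------------------------------------

    def embed_base(self, base: np.ndarray) -> np.ndarray:
        """[n, B] codes -> [n, D_base]."""
        parts = [self.params[f"emb_base_{k}"][base[:, k]]
                 for k in range(len(self.base_cards))]
        return np.concatenate(parts, axis=1) if parts else \
            np.zeros((len(base), 0))

    def _embed_inputs(self, labels: np.ndarray, attrs: np.ndarray) -> np.ndarray:
        """[n, T] and [n, T, A] codes -> [n, T, D_in]."""
        parts = [self.params["emb_label"][labels]]
        for j in range(len(self.attr_cards)):
            parts.append(self.params[f"emb_attr_{j}"][attrs[:, :, j]])
        return np.concatenate(parts, axis=2)

    def forward(self, labels: np.ndarray, attrs: np.ndarray,
                base: np.ndarray, state: HiddenState | None = None,
                want_cache: bool = False):
        """Run inputs for T steps; return logits for the *next* step each.

        Returns (label_logits [n,T,C], attr_logits list of [n,T,C_i],
        new_state, cache-or-None).
        """
        labels = np.asarray(labels)
        attrs = np.asarray(attrs)
        base = np.asarray(base)
        if labels.ndim != 2 or attrs.ndim != 3 or base.ndim != 2:
            raise ValueError("bad input ranks")
        n, T = labels.shape
        if attrs.shape[:2] != (n, T) or attrs.shape[2] != len(self.attr_cards):
            raise ValueError("attrs shape mismatch")
        if labels.max(initial=0) >= self.C or labels.min(initial=0) < 0:
            raise ValueError("label code out of range")
        x = self._embed_inputs(labels, attrs)
        H = self.H
        if state is None or state.layers is None:
            layer_state = [(np.zeros((n, H)), np.zeros((n, H)))
                           for _ in range(self.n_layers)]
        else:
            layer_state = [(h.copy(), c.copy()) for h, c in state.layers]

        caches = []  # per layer: dict of stacked step arrays
        inp = x
        for l in range(self.n_layers):
            Wx, Wh, b = (self.params[f"Wx_{l}"], self.params[f"Wh_{l}"],
                         self.params[f"b_{l}"])
            h, c = layer_state[l]
            hs = np.empty((n, T, H))
            cache_l = {"x": inp, "h_prev": [], "c_prev": [], "gates": [],
                       "c": [], "tanh_c": []} if want_cache else None
            for t in range(T):
                z = inp[:, t] @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                if want_cache:
                    cache_l["h_prev"].append(h)
                    cache_l["c_prev"].append(c)
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                hs[:, t] = h
                if want_cache:
                    cache_l["gates"].append((i, f, g, o))
                    cache_l["c"].append(c)
                    cache_l["tanh_c"].append(tc)
            layer_state[l] = (h, c)
            caches.append(cache_l)
            inp = hs

        base_emb = self.embed_base(base)
        out = np.concatenate(
            [inp, np.broadcast_to(base_emb[:, None, :], (n, T, self.D_base))],
            axis=2)
        label_logits = out @ self.params["W_label"] + self.params["b_label"]
        attr_logits = [out @ self.params[f"W_attr_{j}"] + self.params[f"b_attr_{j}"]
                       for j in range(len(self.attr_cards))]
        cache = None
        if want_cache:
            cache = {"layers": caches, "out": out, "labels": labels,
                     "attrs": attrs, "base": base, "top_h": inp}
        return label_logits, attr_logits, HiddenState(layer_state), cache

    # -- backward ---------------------------------------------------------

    def backward(self, cache: dict, d_label_logits: np.ndarray,
                 d_attr_logits: list[np.ndarray]) -> dict[str, np.ndarray]:
        """Backpropagate head-logit gradients to all parameters."""
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        out = cache["out"]          # [n, T, H + D_base]
        n, T, _ = out.shape
        H = self.H

        d_out = d_label_logits @ p["W_label"].T
        grads["W_label"] = np.einsum("ntd,ntc->dc", out, d_label_logits)
        grads["b_label"] = d_label_logits.sum(axis=(0, 1))
        for j, dal in enumerate(d_attr_logits):
            d_out += dal @ p[f"W_attr_{j}"].T
            grads[f"W_attr_{j}"] = np.einsum("ntd,ntc->dc", out, dal)
            grads[f"b_attr_{j}"] = dal.sum(axis=(0, 1))

        dh_seq = d_out[:, :, :H]            # gradient into top-layer h_t
        d_base_emb = d_out[:, :, H:].sum(axis=1)  # [n, D_base]

        for l in range(self.n_layers - 1, -1, -1):
            cl = cache["layers"][l]
            Wx, Wh = p[f"Wx_{l}"], p[f"Wh_{l}"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros_like(p[f"b_{l}"])
            dx_seq = np.empty((n, T, Wx.shape[0]))
            dh_next = np.zeros((n, H))
            dc_next = np.zeros((n, H))
            for t in range(T - 1, -1, -1):
                i, f, g, o = cl["gates"][t]
                tc = cl["tanh_c"][t]
                dh = dh_seq[:, t] + dh_next
                do = dh * tc
                dct = dh * o * (1 - tc ** 2) + dc_next
                di = dct * g
                df = dct * cl["c_prev"][t]
                dg = dct * i
                dz = np.concatenate([
                    di * i * (1 - i), df * f * (1 - f),
                    dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
                xt = cl["x"][:, t]
                dWx += xt.T @ dz
                dWh += cl["h_prev"][t].T @ dz
                db += dz.sum(axis=0)
                dh_next = dz @ Wh.T
                dc_next = dct * f
                dx_seq[:, t] = dz @ Wx.T
            grads[f"Wx_{l}"] = dWx
            grads[f"Wh_{l}"] = dWh
            grads[f"b_{l}"] = db
            dh_seq = dx_seq  # becomes gradient into layer below's h outputs

        # dx_seq at layer 0 is the gradient w.r.t. the concatenated embeddings
        dx = dh_seq
        labels, attrs = cache["labels"], cache["attrs"]
        dl = self.d_label
        np.add.at(grads["emb_label"], labels.ravel(),
                  dx[:, :, :dl].reshape(-1, dl))
        off = dl
        for j in range(len(self.attr_cards)):
            da = self.d_attr
            np.add.at(grads[f"emb_attr_{j}"], attrs[:, :, j].ravel(),
                      dx[:, :, off:off + da].reshape(-1, da))
            off += da
        base = cache["base"]
        off = 0
        for k in range(len(self.base_cards)):
            db_ = self.d_base
            np.add.at(grads[f"emb_base_{k}"], base[:, k],
                      d_base_emb[:, off:off + db_])
            off += db_
        return grads

    # -- optimizer --------------------------------------------------------

    def adam_step(self, grads: dict[str, np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8, clip: float = 5.0) -> None:
        gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = min(1.0, clip / (gnorm + 1e-12))
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            g = g * scale
            m = self._adam_m.get(k)
            if m is None:
                m = np.zeros_like(g)
                self._adam_v[k] = np.zeros_like(g)
            v = self._adam_v[k]
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            self._adam_m[k], self._adam_v[k] = m, v
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def sgd_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        for k, g in grads.items():
            self.params[k] -= lr * g

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "meta": {
                "n_labels": self.C, "attr_cards": self.attr_cards,
                "base_cards": self.base_cards, "embed_label": self.d_label,
                "embed_attr": self.d_attr, "embed_base": self.d_base,
                "hidden": self.H, "n_layers": self.n_layers,
            },
            "params": {k: v.copy() for k, v in self.params.items()},
        }

    @classmethod
    def from_state_dict(cls, sd: dict) -> "CondLSTM":
        net = cls(**sd["meta"])
        for k, v in sd["params"].items():
            net.params[k] = np.asarray(v, dtype=float)
        return net
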