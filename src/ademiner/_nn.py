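"""Minimal numpy implementation of the pluggable text encoder.

The encoder contract needed by the NER and RE stages is small: map a token
sequence to per-token states (token classification) or to a pooled pair
representation (sequence classification), and support gradient fitting.
This module provides a tiny bidirectional encoder satisfying it:

    embeddings (+ learned positions)
    -> local-context layer (window concatenation + ReLU, radius r)
    -> one softmax self-attention block (residual)
    -> position-wise feed-forward block (residual)

trained with Adam (decoupled weight decay, global-norm gradient clipping,
optional gradient accumulation, inverted dropout) under early stopping on
validation loss.  Everything is float64 numpy, seeded and single-threaded
deterministic.  A full-scale pretrained transformer is a drop-in behind the
same estimator surface.

All gradients are hand-derived and verified against numerical
differentiation in the test suite.
"""
from __future__ import annotations

import math
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["Vocab", "TokenClassifierNet", "PairClassifierNet", "Adam", "fit"]

PAD, UNK = 0, 1


class Vocab:
    """Word-level vocabulary with reserved padding/unknown slots."""

    def __init__(self, words: Sequence[str]):
        self.itos: list[str] = ["<pad>", "<unk>", *words]
        self.stoi: dict[str, int] = {w: i for i, w in enumerate(self.itos)}
        if len(self.stoi) != len(self.itos):
            raise ValueError("duplicate words in vocabulary")

    @classmethod
    def build(
        cls, token_sequences: Iterable[Sequence[str]], extra: Sequence[str] = ()
    ) -> "Vocab":
        seen: dict[str, None] = dict.fromkeys(extra)
        for seq in token_sequences:
            for tok in seq:
                seen.setdefault(tok)
        return cls(list(seen))

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, tokens: Sequence[str]) -> list[int]:
        return [self.stoi.get(t, UNK) for t in tokens]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _dropout_mask(
    rng: np.random.Generator | None, shape: tuple[int, ...], p: float
) -> np.ndarray | None:
    if rng is None or p <= 0.0:
        return None
    return (rng.random(shape) >= p) / (1.0 - p)


class _Trunk:
    """Shared encoder trunk; produces per-token hidden states."""

    def __init__(
        self,
        vocab_size: int,
        d_model: int,
        d_ff: int,
        radius: int,
        max_len: int,
        rng: np.random.Generator,
    ):
        self.d = d_model
        self.radius = radius
        self.max_len = max_len
        d, f, r = d_model, d_ff, radius
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0.0, 0.5, size=(vocab_size, d)),
            "P": rng.normal(0.0, 0.1, size=(max_len, d)),
            "Wc": _glorot(rng, (2 * r + 1) * d, d),
            "bc": np.zeros(d),
            "Wq": _glorot(rng, d, d),
            "Wk": _glorot(rng, d, d),
            "Wv": _glorot(rng, d, d),
            "Wo": _glorot(rng, d, d),
            "W1": _glorot(rng, d, f),
            "b1": np.zeros(f),
            "W2": _glorot(rng, f, d),
            "b2": np.zeros(d),
        }
        self.params["E"][PAD] = 0.0

    def forward(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        p = self.params
        B, L = ids.shape
        if L > self.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.max_len}")
        d, r = self.d, self.radius
        m = mask[..., None]  # (B, L, 1)

        X0 = p["E"][ids] + p["P"][:L]
        dm0 = _dropout_mask(rng, X0.shape, dropout)
        Xd = X0 * dm0 if dm0 is not None else X0

        # local-context layer: concatenate a (2r+1)-token window per position
        Xm = Xd * m
        Xpad = np.pad(Xm, ((0, 0), (r, r), (0, 0)))
        Z = np.concatenate([Xpad[:, j : j + L, :] for j in range(2 * r + 1)], axis=-1)
        Cpre = Z @ p["Wc"] + p["bc"]
        C = np.maximum(Cpre, 0.0)
        dmC = _dropout_mask(rng, C.shape, dropout)
        H0 = Xd + (C * dmC if dmC is not None else C)

        # single-head self-attention block
        Q, K, V = H0 @ p["Wq"], H0 @ p["Wk"], H0 @ p["Wv"]
        scale = 1.0 / math.sqrt(d)
        S = (Q @ K.transpose(0, 2, 1)) * scale
        S = S + (1.0 - mask[:, None, :]) * -1e9  # mask padded keys
        A = _softmax(S, axis=-1)
        Aatt = A @ V
        O = Aatt @ p["Wo"]
        dmO = _dropout_mask(rng, O.shape, dropout)
        H1 = H0 + (O * dmO if dmO is not None else O)

        # position-wise feed-forward block
        F1 = np.maximum(H1 @ p["W1"] + p["b1"], 0.0)
        Fo = F1 @ p["W2"] + p["b2"]
        dmF = _dropout_mask(rng, Fo.shape, dropout)
        H2 = H1 + (Fo * dmF if dmF is not None else Fo)

        cache = dict(
            ids=ids, mask=mask, m=m, dm0=dm0, dmC=dmC, dmO=dmO, dmF=dmF,
            Z=Z, Cpre=Cpre, H0=H0, Q=Q, K=K, V=V, A=A, Aatt=Aatt, H1=H1, F1=F1,
        )
        return H2, cache

    def backward(self, dH2: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        d, r = self.d, self.radius
        B, L = cache["ids"].shape
        g: dict[str, np.ndarray] = {}

        # feed-forward block
        dFo = dH2 * cache["dmF"] if cache["dmF"] is not None else dH2
        dH1 = dH2.copy()
        F1 = cache["F1"]
        g["W2"] = F1.reshape(-1, F1.shape[-1]).T @ dFo.reshape(-1, d)
        g["b2"] = dFo.sum(axis=(0, 1))
        dF1 = (dFo @ p["W2"].T) * (F1 > 0)
        H1 = cache["H1"]
        g["W1"] = H1.reshape(-1, d).T @ dF1.reshape(-1, dF1.shape[-1])
        g["b1"] = dF1.sum(axis=(0, 1))
        dH1 += dF1 @ p["W1"].T

        # attention block
        dO = dH1 * cache["dmO"] if cache["dmO"] is not None else dH1
        dH0 = dH1.copy()
        Aatt, A, V, Q, K, H0 = (
            cache["Aatt"], cache["A"], cache["V"], cache["Q"], cache["K"], cache["H0"],
        )
        g["Wo"] = Aatt.reshape(-1, d).T @ dO.reshape(-1, d)
        dAatt = dO @ p["Wo"].T
        dA = dAatt @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dAatt
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        scale = 1.0 / math.sqrt(d)
        dQ = (dS @ K) * scale
        dK = (dS.transpose(0, 2, 1) @ Q) * scale
        H0f = H0.reshape(-1, d)
        g["Wq"] = H0f.T @ dQ.reshape(-1, d)
        g["Wk"] = H0f.T @ dK.reshape(-1, d)
        g["Wv"] = H0f.T @ dV.reshape(-1, d)
        dH0 += dQ @ p["Wq"].T + dK @ p["Wk"].T + dV @ p["Wv"].T

        # local-context layer
        dC = dH0 * cache["dmC"] if cache["dmC"] is not None else dH0
        dXd = dH0.copy()
        dCpre = dC * (cache["Cpre"] > 0)
        Z = cache["Z"]
        g["Wc"] = Z.reshape(-1, Z.shape[-1]).T @ dCpre.reshape(-1, d)
        g["bc"] = dCpre.sum(axis=(0, 1))
        dZ = dCpre @ p["Wc"].T
        dXpad = np.zeros((B, L + 2 * r, d))
        for j in range(2 * r + 1):
            dXpad[:, j : j + L, :] += dZ[..., j * d : (j + 1) * d]
        dXd += dXpad[:, r : r + L, :] * cache["m"]

        # embeddings
        dX0 = dXd * cache["dm0"] if cache["dm0"] is not None else dXd
        g["P"] = np.zeros_like(p["P"])
        g["P"][:L] = dX0.sum(axis=0)
        g["E"] = np.zeros_like(p["E"])
        np.add.at(g["E"], cache["ids"], dX0)
        g["E"][PAD] = 0.0
        return g


def _ce_loss_and_dlogits(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over weighted positions; returns loss and dlogits."""
    probs = _softmax(logits, axis=-1)
    n = weights.sum()
    if n == 0:
        return 0.0, np.zeros_like(logits)
    picked = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
    loss = float(-(np.log(np.maximum(picked, 1e-12)) * weights).sum() / n)
    one_hot = np.zeros_like(logits)
    np.put_along_axis(one_hot, labels[..., None], 1.0, axis=-1)
    dlogits = (probs - one_hot) * weights[..., None] / n
    return loss, dlogits


class TokenClassifierNet:
    """Trunk + per-token softmax head (BIO tagging)."""

    def __init__(
        self,
        vocab_size: int,
        n_labels: int,
        d_model: int = 32,
        d_ff: int = 64,
        radius: int = 2,
        max_len: int = 128,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.trunk = _Trunk(vocab_size, d_model, d_ff, radius, max_len, rng)
        self.params = self.trunk.params
        self.params["Wh"] = _glorot(rng, d_model, n_labels)
        self.params["bh"] = np.zeros(n_labels)

    def loss_and_grads(
        self, batch: dict, dropout: float = 0.0, rng: np.random.Generator | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        H2, cache = self.trunk.forward(batch["ids"], batch["mask"], dropout, rng)
        logits = H2 @ self.params["Wh"] + self.params["bh"]
        loss, dlogits = _ce_loss_and_dlogits(
            logits, batch["labels"], batch["label_mask"]
        )
        d = H2.shape[-1]
        grads = {
            "Wh": H2.reshape(-1, d).T @ dlogits.reshape(-1, dlogits.shape[-1]),
            "bh": dlogits.sum(axis=(0, 1)),
        }
        dH2 = dlogits @ self.params["Wh"].T
        grads.update(self.trunk.backward(dH2, cache))
        return loss, grads

    def eval_loss(self, data: dict, batch_size: int = 64) -> float:
        total, n = 0.0, 0
        for sl in _batch_slices(len(data["ids"]), batch_size):
            batch = {k: v[sl] for k, v in data.items()}
            H2, _ = self.trunk.forward(batch["ids"], batch["mask"])
            logits = H2 @ self.params["Wh"] + self.params["bh"]
            loss, _ = _ce_loss_and_dlogits(logits, batch["labels"], batch["label_mask"])
            w = int(batch["label_mask"].sum())
            total += loss * w
            n += w
        return total / max(n, 1)

    def predict_proba(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        H2, _ = self.trunk.forward(ids, mask)
        return _softmax(H2 @ self.params["Wh"] + self.params["bh"], axis=-1)


class PairClassifierNet:
    """Trunk + entity-marker head (relation classification).

    The pair representation is the concatenation of the hidden states at the
    four entity-marker positions, a standard entity-marker pooling scheme
    for relation classification.
    """

    def __init__(
        self,
        vocab_size: int,
        n_labels: int,
        d_model: int = 32,
        d_ff: int = 64,
        radius: int = 2,
        max_len: int = 512,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.trunk = _Trunk(vocab_size, d_model, d_ff, radius, max_len, rng)
        self.params = self.trunk.params
        self.params["Wh"] = _glorot(rng, 4 * d_model, n_labels)
        self.params["bh"] = np.zeros(n_labels)

    def _pool(self, H2: np.ndarray, marker_pos: np.ndarray) -> np.ndarray:
        B = H2.shape[0]
        rows = np.arange(B)[:, None]
        return H2[rows, marker_pos].reshape(B, -1)  # (B, 4d)

    def loss_and_grads(
        self, batch: dict, dropout: float = 0.0, rng: np.random.Generator | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        H2, cache = self.trunk.forward(batch["ids"], batch["mask"], dropout, rng)
        B, L, d = H2.shape
        G = self._pool(H2, batch["marker_pos"])
        logits = G @ self.params["Wh"] + self.params["bh"]
        loss, dlogits = _ce_loss_and_dlogits(
            logits, batch["labels"], np.ones(B, dtype=float)
        )
        grads = {"Wh": G.T @ dlogits, "bh": dlogits.sum(axis=0)}
        dG = (dlogits @ self.params["Wh"].T).reshape(B, 4, d)
        dH2 = np.zeros_like(H2)
        rows = np.arange(B)[:, None]
        np.add.at(dH2, (rows, batch["marker_pos"]), dG)
        grads.update(self.trunk.backward(dH2, cache))
        return loss, grads

    def eval_loss(self, data: dict, batch_size: int = 64) -> float:
        total, n = 0.0, 0
        for sl in _batch_slices(len(data["ids"]), batch_size):
            batch = {k: v[sl] for k, v in data.items()}
            probs = self.predict_proba(batch["ids"], batch["mask"], batch["marker_pos"])
            picked = probs[np.arange(len(probs)), batch["labels"]]
            total += float(-np.log(np.maximum(picked, 1e-12)).sum())
            n += len(probs)
        return total / max(n, 1)

    def predict_proba(
        self, ids: np.ndarray, mask: np.ndarray, marker_pos: np.ndarray
    ) -> np.ndarray:
        H2, _ = self.trunk.forward(ids, mask)
        G = self._pool(H2, marker_pos)
        return _softmax(G @ self.params["Wh"] + self.params["bh"], axis=-1)


class Adam:
    """Adam with decoupled weight decay (on weight matrices) and global-norm
    gradient clipping."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        grad_clip: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.wd, self.clip = lr, weight_decay, grad_clip
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip > 0:
            norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > self.clip:
                scale = self.clip / (norm + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.wd > 0 and k.startswith("W"):
                update = update + self.wd * p
            p -= self.lr * update


def _batch_slices(n: int, batch_size: int) -> Iterator[slice]:
    for start in range(0, n, batch_size):
        yield slice(start, min(start + batch_size, n))


def fit(
    net,
    train: dict,
    val: dict,
    *,
    batch_size: int,
    learning_rate: float,
    weight_decay: float = 0.0,
    grad_clip: float = 0.0,
    grad_accumulation: int = 1,
    dropout: float = 0.0,
    max_epochs: int = 50,
    patience_steps: int | None = None,
    patience_evals: int | None = None,
    eval_every: int | None = None,
    seed: int = 0,
) -> list[dict]:
    """Train ``net`` with early stopping on validation loss.

    The validation loss is evaluated every ``eval_every`` optimizer steps
    (default: once per epoch).  Training stops when ``max_epochs`` is
    exhausted, when ``patience_steps`` optimizer steps pass without a new
    best validation loss, or after ``patience_evals`` consecutive
    non-improving evaluations.  The best-on-validation parameters are
    restored before returning.  Returns the training log: one record per
    evaluation with step, mean train loss since last evaluation, and val
    loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net.params, lr=learning_rate, weight_decay=weight_decay, grad_clip=grad_clip)
    n = len(train["ids"])
    history: list[dict] = []
    best_loss = math.inf
    best_params: dict[str, np.ndarray] | None = None
    best_step = 0
    evals_since_best = 0
    step = 0
    recent_losses: list[float] = []
    stop = False

    def evaluate() -> None:
        nonlocal best_loss, best_params, best_step, evals_since_best, stop
        val_loss = net.eval_loss(val)
        history.append(
            {
                "step": step,
                "train_loss": float(np.mean(recent_losses)) if recent_losses else None,
                "val_loss": val_loss,
            }
        )
        recent_losses.clear()
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            best_step = step
            evals_since_best = 0
        else:
            evals_since_best += 1
        if patience_evals is not None and evals_since_best > patience_evals:
            stop = True
        if patience_steps is not None and step - best_step >= patience_steps:
            stop = True

    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        micro = 0
        accum: dict[str, np.ndarray] | None = None
        for sl in _batch_slices(n, batch_size):
            idx = order[sl.start : sl.stop]
            batch = {k: v[idx] for k, v in train.items()}
            loss, grads = net.loss_and_grads(batch, dropout=dropout, rng=rng)
            recent_losses.append(loss)
            if accum is None:
                accum = grads
            else:
                for k in accum:
                    accum[k] = accum[k] + grads[k]
            micro += 1
            if micro == grad_accumulation:
                if grad_accumulation > 1:
                    accum = {k: g / grad_accumulation for k, g in accum.items()}
                opt.step(accum)
                accum, micro = None, 0
                step += 1
                if eval_every is not None and step % eval_every == 0:
                    evaluate()
                    if stop:
                        break
        if not stop and accum is not None:  # flush a trailing partial accumulation
            opt.step({k: g / micro for k, g in accum.items()})
            step += 1
        if not stop and eval_every is None:
            evaluate()
        if stop:
            break

    if best_params is not None:
        for k in net.params:
            net.params[k][...] = best_params[k]
    return history
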