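"""Recurrent amyloid classifier: embedding, Bi-LSTM/GRU/RNN, attention, head.

The architecture: token embedding (21-symbol vocabulary, dimension 100) ->
bidirectional recurrent encoder (64 hidden units per direction by default,
so per-position states are 1 x 128) -> attention pooling over positions (or
final-state pooling for the no-attention ablations) -> fully connected layer
-> 1-D batch normalization -> ReLU -> fully connected layer -> sigmoid.

Everything is implemented directly in NumPy, including backpropagation and
the Adam optimizer, so the gate equations and the attention softmax are
explicit and unit-testable.  A scalar, single-step reference LSTM cell is
provided separately from the vectorized layer so the two can be checked
against each other.

Gates of the LSTM layer follow:

    f_t = sigmoid(W_forget [h_{t-1}, x_t] + b_forget)
    i_t = sigmoid(W_input  [h_{t-1}, x_t] + b_input)
    o_t = sigmoid(W_output [h_{t-1}, x_t] + b_output)
    L_t = tanh   (W_cell   [h_{t-1}, x_t] + b_cell)
    C_t = f_t * C_{t-1} + i_t * L_t
    h_t = o_t * tanh(C_t)

and attention pooling over per-position hidden states h_1..h_n:

    u_k     = tanh(W_k h_k + b_k)
    alpha_k = softmax_k(u_k^T u_s)        (over unmasked positions)
    V       = sum_k alpha_k h_k

Padded positions are excluded from the recurrence (state carry-through),
from the attention softmax, and from the loss, so appending padding never
changes a prediction.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .io_tokenize import TokenizedBatch

CELL_TYPES = ("rnn", "gru", "lstm")


class ConfigError(ValueError):
    """Invalid model or training configuration."""


class ShapeError(ValueError):
    """Operand dimensions are mutually inconsistent."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the published architecture: vocabulary 21, embedding
    100, bidirectional LSTM with 64 units per direction (pooled width 128),
    attention pooling, and a 64-unit fully connected hidden layer.
    """

    vocab_size: int = 21
    embed_dim: int = 100
    cell: str = "lstm"
    bidirectional: bool = True
    hidden_per_direction: int = 64
    attention: bool = True
    fc_hidden: int = 64
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.cell not in CELL_TYPES:
            raise ConfigError(
                f"unknown cell {self.cell!r}; expected one of {CELL_TYPES}"
            )
        for name in ("vocab_size", "embed_dim", "hidden_per_direction",
                     "fc_hidden"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @property
    def pooled_dim(self) -> int:
        """Width of the pooled sequence representation."""
        return self.hidden_per_direction * (2 if self.bidirectional else 1)


# ---------------------------------------------------------------------------
# Reference LSTM cell (single step, explicit gate equations)
# ---------------------------------------------------------------------------

@dataclass
class LSTMCellParams:
    """Per-gate weights acting on the concatenation [h_{t-1}, x_t]."""

    W_forget: np.ndarray
    W_input: np.ndarray
    W_output: np.ndarray
    W_cell: np.ndarray
    b_forget: np.ndarray
    b_input: np.ndarray
    b_output: np.ndarray
    b_cell: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            "W_forget": self.W_forget.shape,
            "W_input": self.W_input.shape,
            "W_output": self.W_output.shape,
            "W_cell": self.W_cell.shape,
        }
        if len(set(shapes.values())) != 1:
            raise ShapeError(f"gate weight shapes differ: {shapes}")
        hidden = self.W_forget.shape[0]
        for name in ("b_forget", "b_input", "b_output", "b_cell"):
            b = getattr(self, name)
            if b.shape != (hidden,):
                raise ShapeError(
                    f"{name} has shape {b.shape}, expected ({hidden},)"
                )


@dataclass
class LSTMCellState:
    """Cell state C and hidden state h."""

    C: np.ndarray
    h: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def reference_lstm_step(
    params: LSTMCellParams, state: LSTMCellState, x: np.ndarray
) -> LSTMCellState:
    """One explicit LSTM update on a single input vector.

    Computes the forget/input/output gates and candidate cell from the
    concatenated [h_{t-1}, x_t], then the new cell and hidden states.
    """
    hidden = params.W_forget.shape[0]
    concat_dim = params.W_forget.shape[1]
    if state.h.shape != (hidden,):
        raise ShapeError(
            f"state.h has shape {state.h.shape}, expected ({hidden},)"
        )
    if state.C.shape != (hidden,):
        raise ShapeError(
            f"state.C has shape {state.C.shape}, expected ({hidden},)"
        )
    if state.h.shape[0] + x.shape[0] != concat_dim:
        raise ShapeError(
            f"x has shape {x.shape}; [h, x] length "
            f"{state.h.shape[0] + x.shape[0]} != weight columns {concat_dim}"
        )
    hx = np.concatenate([state.h, x])
    f = _sigmoid(params.W_forget @ hx + params.b_forget)
    i = _sigmoid(params.W_input @ hx + params.b_input)
    o = _sigmoid(params.W_output @ hx + params.b_output)
    cand = np.tanh(params.W_cell @ hx + params.b_cell)
    C_new = f * state.C + i * cand
    h_new = o * np.tanh(C_new)
    return LSTMCellState(C=C_new, h=h_new)


def lstm_cell_params_from_layer(W: np.ndarray, b: np.ndarray) -> LSTMCellParams:
    """Slice the vectorized layer's packed (in+H, 4H) weights into gates.

    The layer packs gates in [input, forget, output, cell] order and acts on
    [h, x] row vectors; the reference cell uses per-gate (H, H+in) matrices
    acting on column vectors.
    """
    four_h = W.shape[1]
    if four_h % 4:
        raise ShapeError(f"packed weight has {four_h} columns, not 4*H")
    H = four_h // 4
    Wi, Wf, Wo, Wc = (W[:, k * H:(k + 1) * H].T for k in range(4))
    bi, bf, bo, bc = (b[k * H:(k + 1) * H] for k in range(4))
    return LSTMCellParams(
        W_forget=Wf, W_input=Wi, W_output=Wo, W_cell=Wc,
        b_forget=bf, b_input=bi, b_output=bo, b_cell=bc,
    )


# ---------------------------------------------------------------------------
# Attention pooling (single sequence, explicit formula)
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Transform W_k/b_k and the learned context vector u_s."""

    W_k: np.ndarray
    b_k: np.ndarray
    u_s: np.ndarray

    def __post_init__(self) -> None:
        if self.W_k.shape[0] != self.u_s.shape[0]:
            raise ShapeError(
                f"u_s dim {self.u_s.shape[0]} != transformed hidden dim "
                f"{self.W_k.shape[0]}"
            )
        if self.b_k.shape != (self.W_k.shape[0],):
            raise ShapeError(
                f"b_k shape {self.b_k.shape} != ({self.W_k.shape[0]},)"
            )


def attention_pool(
    H: np.ndarray, params: AttentionParams, mask: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-position hidden states into one context vector.

    Scores are u_k^T u_s with u_k = tanh(W_k h_k + b_k); a masked softmax
    yields weights alpha (0 at masked positions, summing to 1 over the
    rest); V is the alpha-weighted sum of the raw hidden states.
    """
    n = H.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    if not mask.any():
        raise ValueError("attention_pool: mask excludes every position")
    u = np.tanh(H @ params.W_k.T + params.b_k)
    scores = u @ params.u_s
    scores = np.where(mask, scores, -np.inf)
    scores = scores - scores[mask].max()
    ex = np.where(mask, np.exp(scores), 0.0)
    alpha = ex / ex.sum()
    V = alpha @ H
    return V, alpha


# ---------------------------------------------------------------------------
# The trainable classifier
# ---------------------------------------------------------------------------

def _uniform(rng, lo, hi, shape, dtype):
    return rng.uniform(lo, hi, size=shape).astype(dtype)


class SequenceClassifier:
    """Trainable recurrent classifier over tokenized protein batches.

    Parameters live in ``self.params`` (name -> array); batch-norm running
    statistics in ``self.running``.  ``loss_and_grads`` implements full
    manual backpropagation for training; ``predict_proba`` runs in
    evaluation mode (running batch-norm statistics, deterministic).
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        H = config.hidden_per_direction
        D = config.embed_dim
        P = config.pooled_dim
        F = config.fc_hidden
        dt = self.dtype
        k_rec = 1.0 / np.sqrt(H)
        gate_mult = {"rnn": 1, "gru": 2, "lstm": 4}[config.cell]

        p: dict[str, np.ndarray] = {}
        p["embedding"] = (0.1 * rng.standard_normal((config.vocab_size, D))
                          ).astype(dt)
        p["embedding"][0] = 0.0  # pad/unknown row frozen at zero
        directions = ["fwd", "bwd"] if config.bidirectional else ["fwd"]
        for d in directions:
            p[f"W_{d}"] = _uniform(rng, -k_rec, k_rec, (H + D, gate_mult * H), dt)
            p[f"b_{d}"] = np.zeros(gate_mult * H, dtype=dt)
            if config.cell == "gru":
                # candidate weights act on [r*h, x]
                p[f"Wh_{d}"] = _uniform(rng, -k_rec, k_rec, (H + D, H), dt)
                p[f"bh_{d}"] = np.zeros(H, dtype=dt)
        if config.attention:
            k_att = 1.0 / np.sqrt(P)
            p["att_W"] = _uniform(rng, -k_att, k_att, (P, P), dt)
            p["att_b"] = np.zeros(P, dtype=dt)
            p["att_u"] = _uniform(rng, -k_att, k_att, (P,), dt)
        k1 = 1.0 / np.sqrt(P)
        p["fc1_W"] = _uniform(rng, -k1, k1, (P, F), dt)
        p["fc1_b"] = np.zeros(F, dtype=dt)
        p["bn_gamma"] = np.ones(F, dtype=dt)
        p["bn_beta"] = np.zeros(F, dtype=dt)
        k2 = 1.0 / np.sqrt(F)
        p["fc2_W"] = _uniform(rng, -k2, k2, (F, 1), dt)
        p["fc2_b"] = np.zeros(1, dtype=dt)
        self.params = p
        self.running = {
            "bn_mean": np.zeros(F, dtype=np.float64),
            "bn_var": np.ones(F, dtype=np.float64),
        }
        self.bn_momentum = 0.1
        self.bn_eps = 1e-5
        self._directions = directions

    # -- recurrent encoder --------------------------------------------------

    def _reverse_within_length(self, arr, lengths, mask):
        """Reverse each row's leading ``length`` entries (pads stay put)."""
        L = arr.shape[1]
        ar = np.arange(L)[None, :]
        src = np.clip(lengths[:, None] - 1 - ar, 0, L - 1)
        rows = np.arange(arr.shape[0])[:, None]
        out = arr[rows, src]
        if arr.ndim == 2:
            return np.where(mask, out, 0)
        return np.where(mask[:, :, None], out, 0)

    def _run_direction(self, X, mask, d):
        """Forward recurrence with state carry-through at padded positions.

        Returns per-position hidden states, the final state, and the cache
        needed for backpropagation.
        """
        cfg = self.config
        H = cfg.hidden_per_direction
        B, L, _ = X.shape
        dt = self.dtype
        W = self.params[f"W_{d}"]
        b = self.params[f"b_{d}"]
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        Hs = np.empty((B, L, H), dtype=dt)
        steps = []
        for t in range(L):
            m = mask[:, t:t + 1].astype(dt)
            xt = X[:, t, :]
            cat = np.concatenate([h, xt], axis=1)
            a = cat @ W + b
            if cfg.cell == "lstm":
                i = _sigmoid(a[:, :H])
                f = _sigmoid(a[:, H:2 * H])
                o = _sigmoid(a[:, 2 * H:3 * H])
                g = np.tanh(a[:, 3 * H:])
                c_new = f * c + i * g
                h_new = o * np.tanh(c_new)
                steps.append((h, c, i, f, o, g, c_new, m))
                c = m * c_new + (1 - m) * c
            elif cfg.cell == "gru":
                z = _sigmoid(a[:, :H])
                r = _sigmoid(a[:, H:2 * H])
                rh = r * h
                cand_in = np.concatenate([rh, xt], axis=1)
                g = np.tanh(cand_in @ self.params[f"Wh_{d}"]
                            + self.params[f"bh_{d}"])
                h_new = (1 - z) * h + z * g
                steps.append((h, z, r, g, m))
            else:  # rnn
                h_new = np.tanh(a)
                steps.append((h, h_new, m))
            h = m * h_new + (1 - m) * h
            Hs[:, t, :] = h
        return Hs, h, steps

    def _backward_direction(self, X, mask, d, dHs, dh_final, grads):
        """Backpropagate one direction; returns gradient w.r.t. X."""
        cfg = self.config
        H = cfg.hidden_per_direction
        B, L, D = X.shape
        W = self.params[f"W_{d}"]
        dW = grads[f"W_{d}"]
        db = grads[f"b_{d}"]
        dX = np.zeros_like(X)
        dh = dh_final.copy()
        dc = np.zeros((B, H), dtype=self.dtype)
        steps = self._steps_cache[d]
        for t in range(L - 1, -1, -1):
            dh = dh + dHs[:, t, :]
            xt = X[:, t, :]
            if cfg.cell == "lstm":
                h_prev, c_prev, i, f, o, g, c_new, m = steps[t]
                dh_new = m * dh
                dh_prev = (1 - m) * dh
                dc_new = m * dc
                dc_prev_skip = (1 - m) * dc
                tc = np.tanh(c_new)
                do = dh_new * tc
                dc_new = dc_new + dh_new * o * (1 - tc * tc)
                df = dc_new * c_prev
                di = dc_new * g
                dg = dc_new * i
                dc = dc_new * f + dc_prev_skip
                da = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f),
                     do * o * (1 - o), dg * (1 - g * g)], axis=1)
                cat = np.concatenate([h_prev, xt], axis=1)
                dW += cat.T @ da
                db += da.sum(axis=0)
                dcat = da @ W.T
                dh = dh_prev + dcat[:, :H]
                dX[:, t, :] = dcat[:, H:]
            elif cfg.cell == "gru":
                h_prev, z, r, g, m = steps[t]
                Wh = self.params[f"Wh_{d}"]
                dh_new = m * dh
                dh_prev = (1 - m) * dh + dh_new * (1 - z)
                dz = dh_new * (g - h_prev)
                dg = dh_new * z
                dcand = dg * (1 - g * g)
                cand_in = np.concatenate([r * h_prev, xt], axis=1)
                grads[f"Wh_{d}"] += cand_in.T @ dcand
                grads[f"bh_{d}"] += dcand.sum(axis=0)
                dcat_h = dcand @ Wh.T
                drh = dcat_h[:, :H]
                dX[:, t, :] = dcat_h[:, H:]
                dr = drh * h_prev
                dh_prev = dh_prev + drh * r
                da = np.concatenate(
                    [dz * z * (1 - z), dr * r * (1 - r)], axis=1)
                cat = np.concatenate([h_prev, xt], axis=1)
                dW += cat.T @ da
                db += da.sum(axis=0)
                dcat = da @ W.T
                dh = dh_prev + dcat[:, :H]
                dX[:, t, :] += dcat[:, H:]
            else:
                h_prev, h_new, m = steps[t]
                dh_new = m * dh
                dh_prev = (1 - m) * dh
                da = dh_new * (1 - h_new * h_new)
                cat = np.concatenate([h_prev, xt], axis=1)
                dW += cat.T @ da
                db += da.sum(axis=0)
                dcat = da @ W.T
                dh = dh_prev + dcat[:, :H]
                dX[:, t, :] = dcat[:, H:]
        return dX

    # -- full forward -------------------------------------------------------

    def _forward(self, indices, mask, training):
        cfg = self.config
        if indices.max() >= cfg.vocab_size:
            raise ValueError(
                f"token index {int(indices.max())} >= vocab_size "
                f"{cfg.vocab_size}"
            )
        B, L = indices.shape
        lengths = mask.sum(axis=1).astype(np.int64)
        if (lengths == 0).any():
            raise ValueError("every sequence must have >= 1 real position")
        E = self.params["embedding"]
        cache: dict = {"indices": indices, "mask": mask, "lengths": lengths}
        X = E[indices]
        Hs_f, h_final_f, steps_f = self._run_direction(X, mask, "fwd")
        self._steps_cache = {"fwd": steps_f}
        cache["X"] = X
        parts = [Hs_f]
        finals = [h_final_f]
        if cfg.bidirectional:
            rev_idx = self._reverse_within_length(indices, lengths, mask)
            X_rev = E[rev_idx]
            Hs_b_rev, h_final_b, steps_b = self._run_direction(
                X_rev, mask, "bwd")
            self._steps_cache["bwd"] = steps_b
            Hs_b = self._reverse_within_length(Hs_b_rev, lengths, mask)
            cache["rev_idx"] = rev_idx
            cache["X_rev"] = X_rev
            parts.append(Hs_b)
            finals.append(h_final_b)
        Hcat = np.concatenate(parts, axis=2)
        cache["Hcat"] = Hcat

        if cfg.attention:
            Wk = self.params["att_W"]
            u = np.tanh(Hcat @ Wk + self.params["att_b"])
            scores = u @ self.params["att_u"]
            neg = np.finfo(self.dtype).min / 4
            scores = np.where(mask, scores, neg)
            scores = scores - scores.max(axis=1, keepdims=True)
            ex = np.where(mask, np.exp(scores), 0.0).astype(self.dtype)
            alpha = ex / ex.sum(axis=1, keepdims=True)
            V = np.einsum("bl,blp->bp", alpha, Hcat)
            cache["u"] = u
            cache["alpha"] = alpha
        else:
            V = np.concatenate(finals, axis=1)
            alpha = None
        cache["V"] = V

        z1 = V @ self.params["fc1_W"] + self.params["fc1_b"]
        if training:
            if B < 2:
                raise ConfigError(
                    "batch normalization needs batch size >= 2 in training"
                )
            mu = z1.mean(axis=0)
            var = z1.var(axis=0)
        else:
            mu = self.running["bn_mean"].astype(self.dtype)
            var = self.running["bn_var"].astype(self.dtype)
        inv_std = 1.0 / np.sqrt(var + self.bn_eps)
        zhat = (z1 - mu) * inv_std
        bn = zhat * self.params["bn_gamma"] + self.params["bn_beta"]
        relu = np.maximum(bn, 0)
        logit = (relu @ self.params["fc2_W"] + self.params["fc2_b"])[:, 0]
        cache.update(z1=z1, mu=mu, var=var, inv_std=inv_std, zhat=zhat,
                     bn=bn, relu=relu, logit=logit, training=training)
        return logit, alpha, cache

    # -- public API ---------------------------------------------------------

    def predict_proba(self, batch: TokenizedBatch) -> np.ndarray:
        """Per-sequence amyloid probabilities, evaluation mode."""
        logit, _, _ = self._forward(batch.indices, batch.mask, training=False)
        return _sigmoid(logit.astype(np.float64))

    def attention_weights(self, batch: TokenizedBatch) -> np.ndarray:
        """Per-position attention weights (zeros at padding)."""
        if not self.config.attention:
            raise ConfigError("model was built without attention")
        _, alpha, _ = self._forward(batch.indices, batch.mask, training=False)
        return alpha

    def loss(self, batch: TokenizedBatch, y: np.ndarray,
             training: bool = False) -> float:
        logit, _, _ = self._forward(batch.indices, batch.mask, training)
        return float(_bce_from_logits(logit.astype(np.float64), y))

    def loss_and_grads(self, batch, y, update_bn_stats: bool = True):
        """Mean binary cross-entropy and gradients for every parameter."""
        indices, mask = batch.indices, batch.mask
        logit, _, cache = self._forward(indices, mask, training=True)
        B = indices.shape[0]
        if update_bn_stats:
            mom = self.bn_momentum
            n = B
            unbiased = cache["var"].astype(np.float64) * n / max(n - 1, 1)
            self.running["bn_mean"] *= (1 - mom)
            self.running["bn_mean"] += mom * cache["mu"].astype(np.float64)
            self.running["bn_var"] *= (1 - mom)
            self.running["bn_var"] += mom * unbiased
        loss = float(_bce_from_logits(logit.astype(np.float64), y))

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogit = ((_sigmoid(logit.astype(np.float64)) - y) / B).astype(
            self.dtype)
        # head
        grads["fc2_W"] += cache["relu"].T @ dlogit[:, None]
        grads["fc2_b"] += dlogit.sum(keepdims=True)
        drelu = dlogit[:, None] @ self.params["fc2_W"].T
        dbn = drelu * (cache["bn"] > 0)
        grads["bn_gamma"] += (dbn * cache["zhat"]).sum(axis=0)
        grads["bn_beta"] += dbn.sum(axis=0)
        dzhat = dbn * self.params["bn_gamma"]
        inv_std = cache["inv_std"]
        zhat = cache["zhat"]
        dz1 = (inv_std / B) * (
            B * dzhat - dzhat.sum(axis=0)
            - zhat * (dzhat * zhat).sum(axis=0)
        )
        grads["fc1_W"] += cache["V"].T @ dz1
        grads["fc1_b"] += dz1.sum(axis=0)
        dV = dz1 @ self.params["fc1_W"].T

        cfg = self.config
        H = cfg.hidden_per_direction
        Hcat = cache["Hcat"]
        if cfg.attention:
            alpha = cache["alpha"]
            u = cache["u"]
            dHcat = alpha[:, :, None] * dV[:, None, :]
            dalpha = np.einsum("bp,blp->bl", dV, Hcat)
            inner = (alpha * dalpha).sum(axis=1, keepdims=True)
            dscores = alpha * (dalpha - inner)
            dscores = np.where(mask, dscores, 0).astype(self.dtype)
            grads["att_u"] += np.einsum("bl,blp->p", dscores, u)
            du = dscores[:, :, None] * self.params["att_u"][None, None, :]
            da = du * (1 - u * u)
            B_, L_, P_ = Hcat.shape
            grads["att_W"] += Hcat.reshape(-1, P_).T @ da.reshape(-1, P_)
            grads["att_b"] += da.sum(axis=(0, 1))
            dHcat = dHcat + da @ self.params["att_W"].T
            dHf = dHcat[:, :, :H]
            dh_final_f = np.zeros((B, H), dtype=self.dtype)
            if cfg.bidirectional:
                dHb = dHcat[:, :, H:]
                dh_final_b = np.zeros((B, H), dtype=self.dtype)
        else:
            zeros = np.zeros_like(Hcat[:, :, :H])
            dHf = zeros
            dh_final_f = dV[:, :H]
            if cfg.bidirectional:
                dHb = np.zeros_like(zeros)
                dh_final_b = dV[:, H:]

        dX = self._backward_direction(
            cache["X"], mask, "fwd", dHf, dh_final_f, grads)
        dE = grads["embedding"]
        np.add.at(dE, indices, dX)
        if cfg.bidirectional:
            lengths = cache["lengths"]
            dHb_rev = self._reverse_within_length(dHb, lengths, mask)
            dX_rev = self._backward_direction(
                cache["X_rev"], mask, "bwd", dHb_rev, dh_final_b, grads)
            np.add.at(dE, cache["rev_idx"], dX_rev)
        dE[0] = 0.0  # pad/unknown embedding stays frozen
        self._steps_cache = {}
        return loss, grads

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        out = {k: v.copy() for k, v in self.params.items()}
        out.update({f"running_{k}": v.copy()
                    for k, v in self.running.items()})
        return out

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = state[k].astype(self.dtype)
        for k in self.running:
            self.running[k] = state[f"running_{k}"].astype(np.float64)

    def save(self, path) -> None:
        payload = dict(self.state_dict())
        payload["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "SequenceClassifier":
        with np.load(path) as data:
            cfg_json = bytes(data["__config__"]).decode()
            config = ModelConfig(**json.loads(cfg_json))
            model = cls(config)
            state = {k: data[k] for k in data.files if k != "__config__"}
        model.load_state_dict(state)
        return model


def build_model(config: ModelConfig) -> SequenceClassifier:
    """Construct the classifier described by ``config`` (seeded init)."""
    return SequenceClassifier(config)


def _bce_from_logits(logit: np.ndarray, y: np.ndarray) -> float:
    """Numerically stable mean binary cross-entropy."""
    return float(np.mean(np.logaddexp(0.0, logit) - y * logit))


# ---------------------------------------------------------------------------
# Adam optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= (self.lr * (self.m[k] / bc1)
                          / (np.sqrt(self.v[k] / bc2) + self.eps))
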