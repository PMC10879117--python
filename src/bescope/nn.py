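"""A small convolutional network for per-position efficiency regression,
implemented directly on NumPy.

The architecture is inception-style: parallel 1-D convolution branches
with kernel widths 1-5 over the 40-nt axis, channel concatenation, one
width-2 max-pool, and a dense head emitting a 20-long sigmoid vector
(one editing probability per protospacer position).  Training minimizes
a masked mean-squared error -- only positions whose reference base is
the editor's target base contribute -- with Adam and early stopping on
a validation split.

Keeping the network in NumPy keeps the package dependency-free and fast
on a single CPU at the problem sizes involved (a few thousand sites of
length 40); gradients are exact analytic backprop, so runs are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _im2col(x: np.ndarray, width: int) -> np.ndarray:
    """(N, L, C) -> (N, L, width*C) with zero 'same' padding."""
    n, length, c = x.shape
    left = (width - 1) // 2
    right = width // 2
    xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, width, axis=1)
    # win: (N, L, C, width) -> (N, L, width, C)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n, length, width * c)


@dataclass
class NetConfig:
    in_channels: int = 4
    length: int = 40
    out_length: int = 20
    kernel_widths: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_filters: int = 8
    learning_rate: float = 3e-3
    batch_size: int = 128
    max_epochs: int = 80
    patience: int = 10
    validation_fraction: float = 0.2
    l2: float = 1e-5


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1


class ConvEfficiencyNet:
    """Parallel-branch 1-D CNN mapping (N, 40, C) to (N, 20) in [0, 1]."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        self.params: dict[str, np.ndarray] = {}
        for w in cfg.kernel_widths:
            fan_in = w * cfg.in_channels
            self.params[f"W{w}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cfg.n_filters)
            )
            self.params[f"b{w}"] = np.zeros(cfg.n_filters)
        pooled = (cfg.length // 2) * cfg.n_filters * len(cfg.kernel_widths)
        self.params["Wd"] = rng.normal(0.0, np.sqrt(1.0 / pooled), size=(pooled, cfg.out_length))
        self.params["bd"] = np.zeros(cfg.out_length)

    # ------------------------------------------------------------------
    def _forward(self, x: np.ndarray, cache: bool = False):
        cfg = self.config
        cols, acts = {}, {}
        branches = []
        for w in cfg.kernel_widths:
            col = _im2col(x, w)
            z = col @ self.params[f"W{w}"] + self.params[f"b{w}"]
            a = np.maximum(z, 0.0)
            branches.append(a)
            if cache:
                cols[w], acts[w] = col, a
        cat = np.concatenate(branches, axis=2)            # (N, L, B*F)
        n, length, ch = cat.shape
        pairs = cat.reshape(n, length // 2, 2, ch)
        argmax = pairs.argmax(axis=2)                     # (N, L/2, ch)
        pooled = np.take_along_axis(pairs, argmax[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(n, -1)
        logits = flat @ self.params["Wd"] + self.params["bd"]
        out = _sigmoid(logits)
        if not cache:
            return out
        return out, {"x": x, "cols": cols, "acts": acts, "cat": cat,
                     "argmax": argmax, "flat": flat}

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, float))

    # ------------------------------------------------------------------
    def _loss_and_grads(self, x, y, mask):
        cfg = self.config
        out, cache = self._forward(x, cache=True)
        nmask = max(mask.sum(), 1.0)
        diff = (out - y) * mask
        loss = float((diff * diff).sum() / nmask)

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = 2.0 * diff / nmask * out * (1.0 - out)
        grads["Wd"] = cache["flat"].T @ dlogits + cfg.l2 * self.params["Wd"]
        grads["bd"] = dlogits.sum(axis=0)
        dflat = dlogits @ self.params["Wd"].T
        n = x.shape[0]
        ch = cache["cat"].shape[2]
        dpooled = dflat.reshape(n, cfg.length // 2, ch)
        dcat_pairs = np.zeros((n, cfg.length // 2, 2, ch))
        np.put_along_axis(dcat_pairs, cache["argmax"][:, :, None, :],
                          dpooled[:, :, None, :], axis=2)
        dcat = dcat_pairs.reshape(n, cfg.length, ch)

        offset = 0
        dx = np.zeros_like(x)
        for w in cfg.kernel_widths:
            da = dcat[:, :, offset : offset + cfg.n_filters]
            offset += cfg.n_filters
            dz = da * (cache["acts"][w] > 0)
            col = cache["cols"][w]
            dz2 = dz.reshape(-1, cfg.n_filters)
            grads[f"W{w}"] = col.reshape(-1, col.shape[2]).T @ dz2 \
                + cfg.l2 * self.params[f"W{w}"]
            grads[f"b{w}"] = dz2.sum(axis=0)
            dcol = (dz2 @ self.params[f"W{w}"].T).reshape(
                n, cfg.length, w, cfg.in_channels
            )
            left = (w - 1) // 2
            dxp = np.zeros((n, cfg.length + w - 1, cfg.in_channels))
            for j in range(w):
                dxp[:, j : j + cfg.length, :] += dcol[:, :, j, :]
            dx += dxp[:, left : left + cfg.length, :]
        return loss, grads, dx

    def loss(self, x, y, mask) -> float:
        out = self._forward(np.asarray(x, float))
        nmask = max(mask.sum(), 1.0)
        diff = (out - y) * mask
        return float((diff * diff).sum() / nmask)

    def gradients(self, x, y, mask):
        """Analytic parameter and input gradients of the masked MSE."""
        _, grads, dx = self._loss_and_grads(
            np.asarray(x, float), np.asarray(y, float), np.asarray(mask, float)
        )
        return grads, dx

    # ------------------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        mask: np.ndarray,
        seed: int = 0,
        x_val: Optional[np.ndarray] = None,
        y_val: Optional[np.ndarray] = None,
        mask_val: Optional[np.ndarray] = None,
    ) -> TrainingHistory:
        """Mini-batch Adam with early stopping on validation loss.

        When no validation set is supplied, ``validation_fraction`` of
        the training data is re-drawn each epoch (seeded), mirroring a
        per-epoch validation split; the best parameters seen are kept.
        """
        cfg = self.config
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        mask = np.asarray(mask, float)
        rng = np.random.default_rng(seed)
        opt = _Adam(self.params, cfg.learning_rate)
        hist = TrainingHistory()
        best = None
        best_loss = np.inf
        bad = 0
        n = x.shape[0]
        external_val = x_val is not None
        for epoch in range(cfg.max_epochs):
            if external_val:
                xi, yi, mi = x, y, mask
                xv, yv, mv = x_val, y_val, mask_val
            else:
                perm = rng.permutation(n)
                n_val = max(int(cfg.validation_fraction * n), 1)
                vi, ti = perm[:n_val], perm[n_val:]
                xi, yi, mi = x[ti], y[ti], mask[ti]
                xv, yv, mv = x[vi], y[vi], mask[vi]
            order = rng.permutation(xi.shape[0])
            losses = []
            for start in range(0, xi.shape[0], cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, grads, _ = self._loss_and_grads(xi[idx], yi[idx], mi[idx])
                opt.step(self.params, grads)
                losses.append(loss)
            val_loss = self.loss(xv, yv, mv)
            hist.train_loss.append(float(np.mean(losses)) if losses else np.nan)
            hist.val_loss.append(val_loss)
            if val_loss < best_loss - 1e-7:
                best_loss = val_loss
                best = {k: v.copy() for k, v in self.params.items()}
                hist.best_epoch = epoch
                bad = 0
            else:
                bad += 1
                if bad >= cfg.patience:
                    break
        if best is not None:
            self.params = best
        return hist

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        self.params = {k: np.asarray(v, float).copy() for k, v in state.items()}
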