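"""A funnel-shaped fully-connected regression network in pure numpy.

Architecture: for each hidden width (default 256, 128, 64, 16, 4) an
affine layer followed by batch normalization and a ReLU; then a final
affine map to a single output with no activation, since the log10
targets are signed.  Training minimizes the root-mean-squared error with
the Adam optimizer (moment decays 0.9/0.999) and early-stops on an inner
holdout carved from the training rows.

Everything is seeded and deterministic: two runs with the same data,
config and seed produce bit-identical parameters and loss traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1  # fraction of the batch statistic blended into the running stat
_ADAM_BETA1, _ADAM_BETA2, _ADAM_EPS = 0.9, 0.999, 1e-8

DEFAULT_HIDDEN_WIDTHS = (256, 128, 64, 16, 4)


def count_parameters(input_dim: int, hidden_widths=DEFAULT_HIDDEN_WIDTHS) -> int:
    """Trainable-parameter count: affine weights+biases plus 2 batch-norm
    parameters (scale, shift) per hidden unit."""
    total = 0
    fan_in = input_dim
    for w in hidden_widths:
        total += fan_in * w + w  # affine
        total += 2 * w  # batch-norm gamma, beta
        fan_in = w
    total += fan_in * 1 + 1  # output affine
    return total


@dataclass
class TrainLog:
    """Per-epoch RMSE trace on the training rows and the inner holdout."""

    train_rmse: list = field(default_factory=list)
    holdout_rmse: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class FunnelMLP:
    """The regression network; build once, train with :meth:`fit`."""

    def __init__(self, input_dim: int, hidden_widths=DEFAULT_HIDDEN_WIDTHS,
                 seed: int = 0):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        widths = list(hidden_widths)
        if any(w <= 0 for w in widths):
            raise ValueError(f"hidden widths must be positive, got {widths}")
        self.input_dim = input_dim
        self.hidden_widths = widths
        self.seed = seed
        rng = np.random.default_rng(seed)
        # float32 throughout: halves the matmul cost on CPU at a precision
        # far below the observation noise of the targets
        f32 = np.float32
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        fan_in = input_dim
        for i, w in enumerate(widths):
            # He initialization suits the ReLU nonlinearity
            self.params[f"W{i}"] = (rng.standard_normal((fan_in, w))
                                    * np.sqrt(2.0 / fan_in)).astype(f32)
            self.params[f"b{i}"] = np.zeros(w, dtype=f32)
            self.params[f"g{i}"] = np.ones(w, dtype=f32)
            self.params[f"beta{i}"] = np.zeros(w, dtype=f32)
            self.running[f"mean{i}"] = np.zeros(w, dtype=f32)
            self.running[f"var{i}"] = np.ones(w, dtype=f32)
            fan_in = w
        self.params["W_out"] = (rng.standard_normal((fan_in, 1))
                                * np.sqrt(1.0 / fan_in)).astype(f32)
        self.params["b_out"] = np.zeros(1, dtype=f32)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool):
        cache = []
        a = X
        for i in range(len(self.hidden_widths)):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if train:
                mean = z.mean(axis=0)
                var = z.var(axis=0)
                self.running[f"mean{i}"] = ((1 - _BN_MOMENTUM) * self.running[f"mean{i}"]
                                            + _BN_MOMENTUM * mean)
                self.running[f"var{i}"] = ((1 - _BN_MOMENTUM) * self.running[f"var{i}"]
                                           + _BN_MOMENTUM * var)
            else:
                mean = self.running[f"mean{i}"]
                var = self.running[f"var{i}"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mean) * inv_std
            h = self.params[f"g{i}"] * zhat + self.params[f"beta{i}"]
            out = np.maximum(h, 0.0)
            cache.append((a, zhat, inv_std, h))
            a = out
        pred = (a @ self.params["W_out"] + self.params["b_out"]).ravel()
        return pred, (cache, a)

    def _backward(self, dpred: np.ndarray, caches) -> dict[str, np.ndarray]:
        cache, a_last = caches
        grads = {}
        dpred = dpred[:, None]
        grads["W_out"] = a_last.T @ dpred
        grads["b_out"] = dpred.sum(axis=0)
        da = dpred @ self.params["W_out"].T
        for i in reversed(range(len(self.hidden_widths))):
            a_in, zhat, inv_std, h = cache[i]
            dh = da * (h > 0)
            grads[f"g{i}"] = (dh * zhat).sum(axis=0)
            grads[f"beta{i}"] = dh.sum(axis=0)
            dzhat = dh * self.params[f"g{i}"]
            m = dzhat.shape[0]
            # batch-norm backward (batch statistics depend on every row)
            dz = (inv_std / m) * (
                m * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
            )
            grads[f"W{i}"] = a_in.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            da = dz @ self.params[f"W{i}"].T
        return grads

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, *, learning_rate: float = 3e-4,
            batch_size: int = 256, max_epochs: int = 200,
            early_stop_patience: int = 10, holdout_fraction: float = 0.1,
            seed: int | None = None) -> TrainLog:
        """Train with Adam on RMSE; early-stop on an inner seeded holdout.

        The holdout is carved from the supplied rows only, so no
        information from outside the training fold reaches the stopping
        rule.  Returns the per-epoch loss trace.
        """
        if len(X) == 0:
            raise ValueError("empty training data")
        if not np.isfinite(y).all():
            raise ValueError("non-finite targets")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        n = len(X)
        n_hold = int(round(holdout_fraction * n))
        perm = rng.permutation(n)
        hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
        if len(train_idx) == 0:
            train_idx, hold_idx = perm, perm[:0]
        Xtr, ytr = X[train_idx], y[train_idx]
        Xho, yho = X[hold_idx], y[hold_idx]

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        log = TrainLog()
        best_rmse = np.inf
        best_params = None
        best_running = None
        patience_left = early_stop_patience

        epoch = -1
        for epoch in range(max_epochs):
            order = rng.permutation(len(Xtr))
            sq_sum, n_seen = 0.0, 0
            for start in range(0, len(order), batch_size):
                idx = order[start:start + batch_size]
                if len(idx) < 2:
                    continue  # batch statistics need at least 2 rows
                xb, yb = Xtr[idx], ytr[idx]
                pred, caches = self._forward(xb, train=True)
                resid = pred - yb
                mse = float(np.mean(resid ** 2))
                rmse = np.sqrt(mse)
                if not np.isfinite(rmse):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; last finite train RMSE "
                        f"{log.train_rmse[-1] if log.train_rmse else 'n/a'}"
                    )
                sq_sum += mse * len(idx)
                n_seen += len(idx)
                # d(RMSE)/d(pred); guarded for an exactly-zero loss
                dpred = resid / (len(idx) * max(rmse, 1e-12))
                grads = self._backward(dpred, caches)
                t += 1
                for key, g in grads.items():
                    m[key] = _ADAM_BETA1 * m[key] + (1 - _ADAM_BETA1) * g
                    v[key] = _ADAM_BETA2 * v[key] + (1 - _ADAM_BETA2) * g ** 2
                    mhat = m[key] / (1 - _ADAM_BETA1 ** t)
                    vhat = v[key] / (1 - _ADAM_BETA2 ** t)
                    self.params[key] -= learning_rate * mhat / (np.sqrt(vhat) + _ADAM_EPS)
            log.train_rmse.append(float(np.sqrt(sq_sum / max(n_seen, 1))))

            if len(Xho):
                ho_pred = self.predict(Xho)
                ho_rmse = float(np.sqrt(np.mean((ho_pred - yho) ** 2)))
            else:
                ho_rmse = log.train_rmse[-1]
            log.holdout_rmse.append(ho_rmse)

            if ho_rmse < best_rmse - 1e-6:
                best_rmse = ho_rmse
                best_params = {k: p.copy() for k, p in self.params.items()}
                best_running = {k: p.copy() for k, p in self.running.items()}
                log.best_epoch = epoch
                patience_left = early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        log.stopped_epoch = epoch
        if best_params is not None:
            self.params = best_params
            self.running = best_running
        return log

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions in log10 space, using the running batch-norm statistics."""
        if X.shape[1] != self.input_dim:
            raise ValueError(f"input has {X.shape[1]} features, model expects {self.input_dim}")
        pred, _ = self._forward(np.asarray(X, dtype=np.float32), train=False)
        return pred.astype(float)
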