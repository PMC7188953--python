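"""Small fully-connected tanh network trained by Levenberg-Marquardt.

The default classifier is a 20-10-7-5-2 pattern network: 20 selected feature
inputs, three tanh hidden layers and two tanh output nodes carrying the
class encoding (+1, -1) for the positive class and (-1, +1) for the negative
class.  The decision score is the difference of the two output nodes,
thresholded at 0.

Training is damped Gauss-Newton: per epoch the Jacobian of all residuals
with respect to all weights and biases is assembled by backpropagation and
the step solves (J'J + mu I) d = -J'e.  Steps that reduce the training MSE
are accepted (mu /= 10), otherwise mu *= 10 until a step is accepted or mu
overflows.  Training stops on the MSE goal, the epoch cap, mu overflow, or a
run of consecutive validation-MSE increases; the parameters with the best
validation MSE are returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_LAYERS = (20, 10, 7, 5, 2)


@dataclass
class NetworkModel:
    """Feed-forward tanh network: weights[l] is (n_out, n_in), biases[l] (n_out,)."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seed: int | None = None

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def get_params(self) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b])
                               for w, b in zip(self.weights, self.biases)])

    def set_params(self, theta: np.ndarray) -> None:
        pos = 0
        for w, b in zip(self.weights, self.biases):
            w[...] = theta[pos: pos + w.size].reshape(w.shape)
            pos += w.size
            b[...] = theta[pos: pos + b.size]
            pos += b.size

    def copy(self) -> "NetworkModel":
        return NetworkModel(self.layer_sizes, [w.copy() for w in self.weights],
                            [b.copy() for b in self.biases], self.seed)

    def to_json(self) -> str:
        return json.dumps({
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, text: str) -> "NetworkModel":
        d = json.loads(text)
        return cls(tuple(d["layer_sizes"]),
                   [np.asarray(w, float) for w in d["weights"]],
                   [np.asarray(b, float) for b in d["biases"]], d["seed"])


@dataclass
class TrainRecord:
    epochs_run: int = 0
    mse_trace: list[float] = field(default_factory=list)   # accepted steps
    val_trace: list[float] = field(default_factory=list)
    stop_reason: str = ""   # goal_reached | max_epochs | val_fail | mu_overflow
    mu: float = 1e-3


def init_network(seed: int, layer_sizes: tuple[int, ...] = DEFAULT_LAYERS
                 ) -> NetworkModel:
    """Weights and biases uniform in [-0.5, 0.5] from the seeded generator."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(n_out, n_in)))
        biases.append(rng.uniform(-0.5, 0.5, size=n_out))
    return NetworkModel(tuple(layer_sizes), weights, biases, seed)


def forward(net: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Outputs for one input vector or a (n, d) batch; tanh on every layer."""
    a = np.atleast_2d(np.asarray(x, float))
    if a.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"expected {net.layer_sizes[0]} inputs, got {a.shape[1]}"
        )
    for w, b in zip(net.weights, net.biases):
        a = np.tanh(a @ w.T + b)
    return a[0] if np.ndim(x) == 1 else a


def _forward_trace(net: NetworkModel, X: np.ndarray) -> list[np.ndarray]:
    acts = [X]
    a = X
    for w, b in zip(net.weights, net.biases):
        a = np.tanh(a @ w.T + b)
        acts.append(a)
    return acts


def jacobian(net: NetworkModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual Jacobian d(output)/d(theta) by per-output backpropagation.

    Returns (J, Y): J has one row per (sample, output node) in C order,
    matching ``get_params`` column order; Y is the (n, n_out) output batch.
    """
    acts = _forward_trace(net, X)
    n = X.shape[0]
    n_out = net.layer_sizes[-1]
    L = len(net.weights)
    # delta[l]: (n, n_out, width_l) sensitivities of each output node w.r.t.
    # the pre-activation of layer l
    dY = 1.0 - acts[-1] ** 2                       # tanh'(z_L)
    delta = np.einsum("no,op->nop", dY, np.eye(n_out))
    deltas = [None] * L
    deltas[L - 1] = delta
    for layer in range(L - 1, 0, -1):
        da = np.einsum("nop,pq->noq", deltas[layer], net.weights[layer])
        deltas[layer - 1] = da * (1.0 - acts[layer] ** 2)[:, None, :]
    blocks = []
    for layer in range(L):
        jw = np.einsum("nop,nq->nopq", deltas[layer], acts[layer])
        blocks.append(jw.reshape(n, n_out, -1))
        blocks.append(deltas[layer])
    J = np.concatenate(blocks, axis=2).reshape(n * n_out, -1)
    return J, acts[-1]


def encode_targets(labels: np.ndarray) -> np.ndarray:
    """0/1 labels -> one-hot in +-1: positive (+1,-1), negative (-1,+1)."""
    labels = np.asarray(labels, int)
    t = -np.ones((labels.size, 2))
    t[labels == 1, 0] = 1.0
    t[labels == 0, 1] = 1.0
    return t


def _mse(net: NetworkModel, X: np.ndarray, T: np.ndarray) -> float:
    return float(np.mean((forward(net, X) - T) ** 2))


def train_levenberg_marquardt(net: NetworkModel, train: tuple[np.ndarray, np.ndarray],
                              val: tuple[np.ndarray, np.ndarray] | None = None,
                              goal: float = 1e-3, max_epochs: int = 1000,
                              max_val_fail: int = 6, mu0: float = 1e-3,
                              mu_factor: float = 10.0, mu_max: float = 1e10
                              ) -> tuple[NetworkModel, TrainRecord]:
    """Levenberg-Marquardt least-squares training with validation stopping.

    ``train`` and ``val`` are (X, T) with T the +-1 one-hot targets (see
    :func:`encode_targets`).  Returns a copy of the network holding the
    parameters with the best validation MSE (or the final parameters when no
    validation set is given) plus the training record.
    """
    net = net.copy()
    X, T = np.asarray(train[0], float), np.asarray(train[1], float)
    if X.size == 0:
        raise ValueError("empty training set")
    rec = TrainRecord(mu=mu0)
    mse = _mse(net, X, T)
    best = net.copy()
    best_val = _mse(net, val[0], val[1]) if val is not None else np.inf
    val_fail = 0
    if mse < goal:
        rec.stop_reason = "goal_reached"
        rec.mse_trace.append(mse)
        return net, rec
    mu = mu0
    theta = net.get_params()
    identity = np.eye(theta.size)
    for epoch in range(1, max_epochs + 1):
        J, Y = jacobian(net, X)
        e = (Y - T).ravel()
        g = J.T @ e
        jtj = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                step = np.linalg.solve(jtj + mu * identity, -g)
            except np.linalg.LinAlgError:
                mu *= mu_factor
                continue
            net.set_params(theta + step)
            new_mse = _mse(net, X, T)
            if new_mse < mse:
                theta = theta + step
                mse = new_mse
                mu = max(mu / mu_factor, 1e-20)
                accepted = True
                break
            mu *= mu_factor
        if not accepted:
            net.set_params(theta)
            rec.stop_reason = "mu_overflow"
            break
        rec.epochs_run = epoch
        rec.mse_trace.append(mse)
        rec.mu = mu
        if val is not None:
            vmse = _mse(net, val[0], val[1])
            rec.val_trace.append(vmse)
            if vmse < best_val:
                best_val = vmse
                best = net.copy()
                val_fail = 0
            else:
                val_fail += 1
                if val_fail >= max_val_fail:
                    rec.stop_reason = "val_fail"
                    break
        if mse < goal:
            rec.stop_reason = "goal_reached"
            break
    else:
        rec.stop_reason = rec.stop_reason or "max_epochs"
    if not rec.stop_reason:
        rec.stop_reason = "max_epochs"
    result = best if (val is not None and np.isfinite(best_val)) else net
    return result, rec


def score_and_classify(net: NetworkModel, x: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Decision score f = out[positive node] - out[negative node]; label = f > 0.

    f == 0 exactly maps to the negative class (documented tie convention).
    Accepts a single vector or a batch; returns (scores, labels) arrays.
    """
    out = np.atleast_2d(forward(net, x))
    f = out[:, 0] - out[:, 1]
    labels = (f > 0).astype(int)
    if np.ndim(x) == 1:
        return f[0], labels[0]
    return f, labels
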