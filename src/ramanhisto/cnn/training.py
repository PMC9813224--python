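"""Training loop: weighted cross-entropy, Adam, per-epoch history."""

from __future__ import annotations

import numpy as np

from .network import CNNConfig, CNNModel, TrainingError, _softmax
from .splits import class_weights

__all__ = ["train", "predict"]


class _Adam:
    def __init__(self, model: CNNModel, lr: float):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n in model.parameters()]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in model.parameters()]
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, model: CNNModel) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(model.parameters()):
            g = getattr(layer, "d" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p = getattr(layer, name)
            setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class _SGD:
    def __init__(self, model: CNNModel, lr: float):
        self.lr = lr

    def step(self, model: CNNModel) -> None:
        for layer, name in model.parameters():
            setattr(layer, name, getattr(layer, name) - self.lr * getattr(layer, "d" + name))


def _standardize(model: CNNModel, X: np.ndarray) -> np.ndarray:
    if model.input_mean is None:
        return np.asarray(X, dtype=np.float32)
    return ((X - model.input_mean) / model.input_std).astype(np.float32)


def _loss_and_grad(proba, y, w):
    n = len(y)
    eps = 1e-12
    wy = w[y]
    loss = float(-(wy * np.log(proba[np.arange(n), y] + eps)).sum() / wy.sum())
    grad = proba.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (wy / wy.sum())[:, None]
    return loss, grad


def _eval_pass(model: CNNModel, X: np.ndarray, y: np.ndarray, w: np.ndarray, batch: int):
    losses, correct, total = 0.0, 0, 0
    wsum = 0.0
    for i in range(0, len(y), batch):
        xb, yb = X[i : i + batch], y[i : i + batch]
        proba = _softmax(model.logits(xb, train=False))
        wy = w[yb]
        eps = 1e-12
        losses += float(-(wy * np.log(proba[np.arange(len(yb)), yb] + eps)).sum())
        wsum += wy.sum()
        correct += int((proba.argmax(axis=1) == yb).sum())
        total += len(yb)
    return losses / wsum, correct / total


def train(
    model: CNNModel,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: CNNConfig | None = None,
    weighted: bool = True,
) -> CNNModel:
    """Train in place, minimizing (class-weighted) cross-entropy.

    Inputs are standardized per wavenumber channel with train-set statistics
    (stored on the model). Minibatches are reshuffled every epoch; per-epoch
    train and validation loss/accuracy are recorded in ``model.history``, and
    the parameters with the best validation loss are restored at the end.
    Deterministic given the model seed and a fixed thread count.
    """
    config = config or model.config
    X_train, y_train = train_set
    X_val, y_val = val_set
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)

    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0) + 1e-6
    model.input_mean = mean.astype(np.float32)
    model.input_std = std.astype(np.float32)
    Xtr = _standardize(model, X_train)
    Xva = _standardize(model, X_val)

    if weighted:
        cw = class_weights(y_train)
        w = np.array([cw.get(c, 1.0) for c in range(model.n_classes)], dtype=np.float32)
    else:
        w = np.ones(model.n_classes, dtype=np.float32)

    opt_cls = {"adam": _Adam, "sgd": _SGD}.get(config.optimizer)
    if opt_cls is None:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    opt = opt_cls(model, config.learning_rate)

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_val, best_state = np.inf, None
    rng = model.rng
    for _ in range(config.n_epochs):
        order = rng.permutation(len(y_train))
        ep_loss, ep_wsum, ep_correct = 0.0, 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = Xtr[idx], y_train[idx]
            proba = _softmax(model.logits(xb, train=True))
            loss, grad = _loss_and_grad(proba, yb, w)
            if not np.isfinite(loss):
                raise TrainingError("training loss diverged to non-finite", history)
            model.backward(grad)
            opt.step(model)
            wy = w[yb]
            ep_loss += loss * wy.sum()
            ep_wsum += wy.sum()
            ep_correct += int((proba.argmax(axis=1) == yb).sum())
        history["train_loss"].append(ep_loss / ep_wsum)
        history["train_acc"].append(ep_correct / len(y_train))
        vl, va = _eval_pass(model, Xva, y_val, w, config.batch_size)
        history["val_loss"].append(vl)
        history["val_acc"].append(va)
        if vl < best_val:
            best_val, best_state = vl, model.get_state()
    if best_state is not None:
        model.set_state(best_state)
    model.history = history
    return model


def predict(
    model: CNNModel, X: np.ndarray, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax class probabilities and hard labels (argmax, lower index wins)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.input_length:
        raise ValueError(
            f"spectra have {X.shape[1]} points; model expects {model.input_length}"
        )
    Xs = _standardize(model, X)
    probs = np.vstack(
        [
            _softmax(model.logits(Xs[i : i + batch_size], train=False))
            for i in range(0, len(Xs), batch_size)
        ]
    )
    return probs, probs.argmax(axis=1)
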