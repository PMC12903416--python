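"""Optimisation loop: AdamW, initialisation, per-epoch history.

Defaults follow the training recipe used throughout the package's
analyses: 500 epochs of minibatch size 128 with AdamW at learning rate
1e-3 and weight decay 0.01, no schedule and no early stopping.  The
output layers that produce the signal component's posterior parameters
are Xavier-normal initialised; everything else uses the engine default
(uniform +-1/sqrt(fan_in), the usual dense-layer default).

Training is plain single-threaded numpy, hence bit-deterministic for a
given seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .model import DecomposedVAE


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    seed: int = 0
    n_mc: int = 1
    log_every: int = 0  # 0: silent

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def initialize(model: DecomposedVAE, rng: np.random.Generator) -> DecomposedVAE:
    """Draw all weights; deterministic given the generator state."""
    xavier = set(model.signal_head_names())
    params: dict[str, ad.Tensor] = {}
    for name, shape in model.layer_shapes().items():
        if name in xavier:
            fan_in, fan_out = shape
            std = np.sqrt(2.0 / (fan_in + fan_out))
            arr = rng.normal(0.0, std, size=shape)
        elif name.startswith("disp/"):
            # softplus(2) ~ 2.1: a typical droplet-data dispersion; starting
            # too low lets early mean misfits hide behind heavy tails
            arr = np.full(shape, 2.0)
        elif name.endswith("/W"):
            bound = 1.0 / np.sqrt(shape[0])
            arr = rng.uniform(-bound, bound, size=shape)
        else:  # biases: uniform +-1/sqrt(fan_in) of their layer
            w_shape = model.layer_shapes()[name[:-2] + "/W"]
            bound = 1.0 / np.sqrt(w_shape[0])
            arr = rng.uniform(-bound, bound, size=shape)
        params[name] = ad.Tensor(arr, requires_grad=True)
    model.params = params
    return model


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: dict[str, ad.Tensor], lr: float = 1e-3,
                 weight_decay: float = 0.01, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


def train(model: DecomposedVAE, X: np.ndarray,
          batch_rows: pd.DataFrame | None = None,
          config: TrainConfig | None = None,
          rng: np.random.Generator | None = None):
    """Fit the model in place; returns (model, history).

    ``history`` has one entry per epoch: mean loss (-ELBO), KL and
    reconstruction terms, and wall time.
    """
    config = config or TrainConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    if X.shape[1] != model.partition.n_genes:
        raise ValueError("gene count does not match the partition")
    if not model.params:
        initialize(model, rng)
    if batch_rows is not None:
        batch_rows = batch_rows.reset_index(drop=True)
    opt = AdamW(model.params, lr=config.learning_rate,
                weight_decay=config.weight_decay)
    history: list[dict] = []
    for epoch in range(config.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        tot_loss = tot_kl = tot_rec = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            rows = batch_rows.iloc[idx] if batch_rows is not None else None
            loss, stats = model.elbo_loss(X[idx], rows, rng, epoch=epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_loss += stats["loss"]
            tot_kl += stats["kl"]
            tot_rec += stats["recon"]
            n_batches += 1
        rec = {"epoch": epoch, "loss": tot_loss / n_batches,
               "kl": tot_kl / n_batches, "recon": tot_rec / n_batches,
               "seconds": time.time() - t0}
        history.append(rec)
        if config.log_every and (epoch % config.log_every == 0):
            print(f"epoch {epoch:4d}  -elbo {rec['loss']:.3f}  "
                  f"kl {rec['kl']:.3f}  recon {rec['recon']:.3f}  "
                  f"{rec['seconds']:.2f}s")
    return model, history
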