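"""Multimodal residual multilayer perceptron for genomic prediction.

One sub-network ("tower") is built per input modality — year design,
genomic features ``Z_L Lᵀ`` and NDVI covariates — and the towers' final
hidden representations are concatenated into a single linear output neuron.
Hidden widths halve layer by layer from the first-layer width ``N1``:
``N_l = max(1, ⌊N1 / 2^(l−1)⌋)``. Consecutive hidden layers are wired as
residual blocks (dense → batch-norm → relu → dense → batch-norm, skip-add
of the block input through a bias-free projection when the widths differ,
then relu and dropout); an odd trailing layer is a plain
dense → batch-norm → relu → dropout stack.

Training minimizes mean-squared error plus L2 penalties with Adam, a
learning rate decaying as ``lr · exp(−wd · epoch)``, mini-batches of 32, a
hard cap of 128 epochs and early stopping on the training loss with
patience ``Pat``. A 10% validation split is held out and its MSE reported
per epoch; it is the objective that hyperparameter tuning minimizes.

Everything is plain numpy: forward and backward passes are written out
explicitly, which keeps runs bit-reproducible from a single integer seed on
one thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

MODALITIES = ("year", "genomic", "ndvi")


def layer_widths(N1: int, nHL: int) -> list[int]:
    """Halving width schedule ``[N1, ⌊N1/2⌋, ⌊N1/4⌋, ...]``, floored at 1."""
    if N1 < 1 or nHL < 1:
        raise ValueError("N1 and nHL must be >= 1")
    return [max(1, N1 // 2 ** l) for l in range(nHL)]


@dataclass
class MMDLConfig:
    """Architecture and optimizer hyperparameters.

    ``nHL`` and ``N1`` map modality name -> hidden-layer count / first-layer
    width; only modalities present in both the config and the data get a
    tower (the leave-one-year-out variant simply omits ``year``).
    """

    nHL: dict = field(default_factory=lambda: {"year": 1, "genomic": 2, "ndvi": 1})
    N1: dict = field(default_factory=lambda: {"year": 8, "genomic": 64, "ndvi": 8})
    l2: float = 1e-6          # λ, L2 coefficient on every dense kernel
    dropout: float = 0.0      # DO
    lr: float = 1e-3          # initial Adam learning rate
    wd: float = 1e-3          # exponential learning-decay rate
    patience: int = 16        # Pat, early-stopping patience on training loss
    batch_size: int = 32
    max_epochs: int = 128
    val_split: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.lr <= 0 or self.wd < 0 or self.l2 < 0:
            raise ValueError("lr must be > 0; wd and l2 must be >= 0")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        for q in self.nHL:
            if q not in MODALITIES:
                raise ValueError(f"unknown modality {q!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Dense:
    def __init__(self, n_in, n_out, rng, l2=0.0, bias=True):
        limit = np.sqrt(6.0 / (n_in + n_out))        # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out) if bias else None
        self.l2 = l2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None

    def forward(self, x, training):
        self._x = x if training else None
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def backward(self, g):
        self.dW = self._x.T @ g + 2.0 * self.l2 * self.W
        if self.b is not None:
            self.db = g.sum(axis=0)
        return g @ self.W.T

    def penalty(self):
        return self.l2 * float(np.sum(self.W ** 2))

    def params(self):
        yield self.W, self.dW
        if self.b is not None:
            yield self.b, self.db

    @property
    def n_params(self):
        return self.W.size + (self.b.size if self.b is not None else 0)


class BatchNorm:
    """Per-feature batch normalization with learned scale/shift."""

    def __init__(self, dim, eps=1e-3, momentum=0.9):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.run_mean = np.zeros(dim)
        self.run_var = np.ones(dim)
        self.eps, self.momentum = eps, momentum
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._istd
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.run_mean) / np.sqrt(self.run_var + self.eps) + self.beta

    def backward(self, g):
        n = g.shape[0]
        self.dgamma = np.sum(g * self._xhat, axis=0)
        self.dbeta = np.sum(g, axis=0)
        gx = self.gamma * self._istd / n * (
            n * g - self.dbeta - self._xhat * self.dgamma
        )
        return gx

    def penalty(self):
        return 0.0

    def params(self):
        yield self.gamma, self.dgamma
        yield self.beta, self.dbeta

    @property
    def n_params(self):
        return 2 * self.gamma.size


class ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def penalty(self):
        return 0.0

    def params(self):
        return iter(())

    n_params = 0


class Dropout:
    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def penalty(self):
        return 0.0

    def params(self):
        return iter(())

    n_params = 0


class ResidualBlock:
    """dense→BN→relu→dense→BN, projected skip-add, relu, dropout."""

    def __init__(self, n_in, w1, w2, rng, l2, dropout):
        self.d1 = Dense(n_in, w1, rng, l2)
        self.bn1 = BatchNorm(w1)
        self.a1 = ReLU()
        self.d2 = Dense(w1, w2, rng, l2)
        self.bn2 = BatchNorm(w2)
        self.proj = Dense(n_in, w2, rng, l2, bias=False) if n_in != w2 else None
        self.a2 = ReLU()
        self.drop = Dropout(dropout)

    def forward(self, x, training, rng=None):
        h = self.d1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.a1.forward(h, training)
        h = self.d2.forward(h, training)
        h = self.bn2.forward(h, training)
        s = self.proj.forward(x, training) if self.proj is not None else x
        out = self.a2.forward(h + s, training)
        return self.drop.forward(out, training, rng)

    def backward(self, g):
        g = self.drop.backward(g)
        g = self.a2.backward(g)
        gh = self.bn2.backward(g)
        gh = self.d2.backward(gh)
        gh = self.a1.backward(gh)
        gh = self.bn1.backward(gh)
        gx = self.d1.backward(gh)
        gs = self.proj.backward(g) if self.proj is not None else g
        return gx + gs

    @property
    def layers(self):
        ls = [self.d1, self.bn1, self.d2, self.bn2]
        if self.proj is not None:
            ls.append(self.proj)
        return ls

    def penalty(self):
        return sum(l.penalty() for l in self.layers)

    def params(self):
        for l in self.layers:
            yield from l.params()

    @property
    def n_params(self):
        return sum(l.n_params for l in self.layers)


class PlainLayer:
    """dense→BN→relu→dropout, used for an odd trailing hidden layer."""

    def __init__(self, n_in, w, rng, l2, dropout):
        self.d = Dense(n_in, w, rng, l2)
        self.bn = BatchNorm(w)
        self.a = ReLU()
        self.drop = Dropout(dropout)

    def forward(self, x, training, rng=None):
        h = self.a.forward(self.bn.forward(self.d.forward(x, training), training), training)
        return self.drop.forward(h, training, rng)

    def backward(self, g):
        return self.d.backward(self.bn.backward(self.a.backward(self.drop.backward(g))))

    def penalty(self):
        return self.d.penalty()

    def params(self):
        yield from self.d.params()
        yield from self.bn.params()

    @property
    def n_params(self):
        return self.d.n_params + self.bn.n_params


class Tower:
    """Stack of residual blocks (+ optional odd plain layer) for one modality."""

    def __init__(self, n_in, widths, rng, l2, dropout):
        self.blocks = []
        d = n_in
        i = 0
        while i + 1 < len(widths):
            self.blocks.append(ResidualBlock(d, widths[i], widths[i + 1], rng, l2, dropout))
            d = widths[i + 1]
            i += 2
        if i < len(widths):
            self.blocks.append(PlainLayer(d, widths[i], rng, l2, dropout))
            d = widths[i]
        self.out_dim = d

    def forward(self, x, training, rng=None):
        for b in self.blocks:
            x = b.forward(x, training, rng)
        return x

    def backward(self, g):
        for b in reversed(self.blocks):
            g = b.backward(g)
        return g

    def penalty(self):
        return sum(b.penalty() for b in self.blocks)

    def params(self):
        for b in self.blocks:
            yield from b.params()

    @property
    def n_params(self):
        return sum(b.n_params for b in self.blocks)


class MMDLModel:
    """Towers + linear fusion neuron. Build with :func:`build_mmdl`."""

    def __init__(self, towers: dict, fusion: Dense, config: MMDLConfig):
        self.towers = towers
        self.fusion = fusion
        self.config = config
        self.history = None

    def forward(self, blocks: dict, training=False, rng=None):
        reps = [self.towers[q].forward(blocks[q], training, rng) for q in self.towers]
        self._concat_dims = [r.shape[1] for r in reps]
        z = np.concatenate(reps, axis=1)
        return self.fusion.forward(z, training)[:, 0]

    def backward(self, g_out):
        g = self.fusion.backward(g_out[:, None])
        offs = np.cumsum([0] + self._concat_dims)
        for (q, tower), a, b in zip(self.towers.items(), offs[:-1], offs[1:]):
            tower.backward(g[:, a:b])

    def penalty(self):
        return self.fusion.penalty() + sum(t.penalty() for t in self.towers.values())

    def params(self):
        for t in self.towers.values():
            yield from t.params()
        yield from self.fusion.params()

    def count_params(self) -> int:
        return self.fusion.n_params + sum(t.n_params for t in self.towers.values())

    @property
    def fusion_in_dim(self) -> int:
        return self.fusion.W.shape[0]


def build_mmdl(input_dims: dict, config: MMDLConfig) -> MMDLModel:
    """Construct the network for the modalities present in ``input_dims``.

    ``input_dims`` maps modality name -> number of input columns. Weight
    initialization is Glorot uniform, seeded from ``config.seed``.
    """
    if not input_dims:
        raise ValueError("at least one modality is required")
    rng = np.random.default_rng(config.seed)
    towers = {}
    for q in MODALITIES:               # fixed order for reproducibility
        if q not in input_dims:
            continue
        if input_dims[q] < 1:
            raise ValueError(f"modality {q!r} has dimension {input_dims[q]}")
        widths = layer_widths(config.N1[q], config.nHL[q])
        towers[q] = Tower(input_dims[q], widths, rng, config.l2, config.dropout)
    fusion_in = sum(t.out_dim for t in towers.values())
    fusion = Dense(fusion_in, 1, rng, config.l2)
    return MMDLModel(towers, fusion, config)


class Adam:
    def __init__(self, params_shapes, beta1=0.9, beta2=0.999, eps=1e-7):
        self.m = [np.zeros(s) for s in params_shapes]
        self.v = [np.zeros(s) for s in params_shapes]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params_grads, lr):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for (p, g), m, v in zip(params_grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class TrainingDiverged(RuntimeError):
    pass


def train_mmdl(model: MMDLModel, blocks: dict, y: np.ndarray, config: MMDLConfig | None = None):
    """Fit with Adam + exponential learning-rate decay + early stopping.

    Returns ``(model, history)`` where ``history`` is a list of per-epoch
    dicts (``epoch``, ``lr``, ``loss``, ``val_loss``). The training loss is
    the epoch-average batch MSE plus L2 penalties; early stopping halts when
    it has not improved for ``patience`` consecutive epochs.
    """
    config = config or model.config
    y = np.asarray(y, dtype=float)
    n = len(y)
    for q, m in blocks.items():
        if m.shape[0] != n:
            raise ValueError(f"modality {q!r} has {m.shape[0]} rows, response has {n}")

    rng = np.random.default_rng(config.seed + 1)
    perm = rng.permutation(n)
    n_val = int(round(config.val_split * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    tr_blocks = {q: m[tr_idx] for q, m in blocks.items()}
    val_blocks = {q: m[val_idx] for q, m in blocks.items()}
    y_tr, y_val = y[tr_idx], y[val_idx]
    n_tr = len(tr_idx)

    opt = Adam([p.shape for p, _ in model.params()])
    history = []
    best = np.inf
    wait = 0
    for epoch in range(config.max_epochs):
        lr = config.lr * np.exp(-config.wd * epoch)
        order = rng.permutation(n_tr)
        batch_losses = []
        for start in range(0, n_tr, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = {q: m[idx] for q, m in tr_blocks.items()}
            yb = y_tr[idx]
            pred = model.forward(xb, training=True, rng=rng)
            err = pred - yb
            loss = float(np.mean(err ** 2)) + model.penalty()
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            batch_losses.append(loss)
            model.backward(2.0 * err / len(yb))
            opt.step(model.params(), lr)
        train_loss = float(np.mean(batch_losses))
        if n_val:
            val_pred = model.forward(val_blocks, training=False)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
        else:
            val_loss = np.nan
        history.append(
            {"epoch": epoch, "lr": float(lr), "loss": train_loss, "val_loss": val_loss}
        )
        if train_loss < best - 1e-12:
            best = train_loss
            wait = 0
        else:
            wait += 1
            if wait >= max(1, config.patience):
                break
    model.history = history
    return model, history


def predict_mmdl(model: MMDLModel, blocks: dict) -> np.ndarray:
    """Deterministic forward pass: dropout off, batch-norm in inference mode."""
    expect = set(model.towers)
    if set(blocks) != expect:
        raise ValueError(f"modalities {sorted(set(blocks))} do not match model {sorted(expect)}")
    for q, tower in model.towers.items():
        first = tower.blocks[0]
        d_in = (first.d1 if isinstance(first, ResidualBlock) else first.d).W.shape[0]
        if blocks[q].shape[1] != d_in:
            raise ValueError(f"modality {q!r}: expected {d_in} columns, got {blocks[q].shape[1]}")
    return model.forward(blocks, training=False)


def validation_mse(model: MMDLModel, history: list) -> float:
    """Tuning objective: validation MSE at the last trained epoch."""
    return history[-1]["val_loss"]
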