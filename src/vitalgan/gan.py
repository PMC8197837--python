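"""Class-conditional GAN for small tabular vital-sign data.

A generator maps (Gaussian noise ⊕ one-hot class) to a 10-dimensional
predictor vector; a discriminator maps (predictor vector ⊕ one-hot class) to
a real-vs-fake logit.  Both are compact multilayer perceptrons trained
adversarially with binary cross-entropy: per batch, one discriminator step on
real records (target real) and generator samples conditioned on the same
labels (target fake), then one generator step maximizing the discriminator's
real-belief on fresh samples.

Features are min-max scaled to [0, 1] internally and the generator output is
sigmoid-bounded, so samples respect the training envelope — with ~43 records
there is no support for unbounded extrapolation.  Sampling inverse-scales
back to physical units; a sample's label is its conditioning class.

The networks, backpropagation and Adam are implemented directly in NumPy:
at this scale (10 features, hidden widths of 64, batches of 16) dense
matrix products are all that is required, and a single seeded
``numpy.random.Generator`` drives initialization, noise and shuffling, making
training and sampling bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .metrics import frechet_distance
from .schema import (
    CLASS_HIGH,
    CLASS_LOW,
    LabeledDataset,
    ScalingTransform,
    ValidationError,
    fit_scaler,
)

#: one-hot encoding of the conditioning class
ONE_HOT = {CLASS_HIGH: (1.0, 0.0), CLASS_LOW: (0.0, 1.0)}
N_FEATURES = 10
N_CLASSES = 2


@dataclass
class GanConfig:
    """Architecture and optimization knobs.

    Defaults target the tiny-n (tens of records), low-dimension regime:
    narrow MLPs, small batches, the customary GAN Adam setting
    (lr 2e-4, beta1 0.5).
    """

    epochs: int = 2000
    noise_dim: int = 32
    gen_hidden: tuple[int, ...] = (64, 64)
    disc_hidden: tuple[int, ...] = (64, 64)
    batch_size: int = 16
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    disc_steps: int = 1
    fid_probe_every: int = 0  # 0 disables the per-epoch FID probe

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValidationError("batch_size must be >= 2")
        if self.noise_dim < 1:
            raise ValidationError("noise_dim must be >= 1")
        if any(w < 1 for w in (*self.gen_hidden, *self.disc_hidden)):
            raise ValidationError("all hidden widths must be >= 1")
        if self.disc_steps < 1:
            raise ValidationError("disc_steps must be >= 1")
        self.gen_hidden = tuple(self.gen_hidden)
        self.disc_hidden = tuple(self.disc_hidden)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


_LEAK = 0.2


class _MLP:
    """Dense leaky-ReLU network with a linear or sigmoid head."""

    def __init__(self, sizes: list[int], out_activation: str, rng: np.random.Generator):
        self.out_activation = out_activation
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # Glorot-uniform initialization
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def forward(self, X: np.ndarray):
        h = X
        pre: list[np.ndarray] = []
        acts: list[np.ndarray] = [X]
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            pre.append(z)
            if i < last:
                h = np.where(z > 0, z, _LEAK * z)
            elif self.out_activation == "sigmoid":
                h = _sigmoid(z)
            else:
                h = z
            acts.append(h)
        return h, (pre, acts)

    def backward(self, cache, d_out: np.ndarray):
        """Gradients of a scalar loss w.r.t. params and the network input.

        ``d_out`` is dL/d(output); for a linear head pass dL/d(logits).
        """
        pre, acts = cache
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        last = len(self.W) - 1
        dz = d_out
        if self.out_activation == "sigmoid":
            y = acts[-1]
            dz = d_out * y * (1.0 - y)
        for i in range(last, -1, -1):
            if i < last:
                dz = dz * np.where(pre[i] > 0, 1.0, _LEAK)
            grads_W[i] = acts[i].T @ dz
            grads_b[i] = dz.sum(axis=0)
            dz = dz @ self.W[i].T
        return grads_W + grads_b, dz


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainingLog:
    """Per-epoch adversarial losses plus optional FID probes."""

    disc_loss: list[float] = field(default_factory=list)
    gen_loss: list[float] = field(default_factory=list)
    fid_probe: dict[int, float] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.disc_loss)


@dataclass
class GeneratorModel:
    """Trained conditional generator plus everything needed to sample from it."""

    generator: _MLP
    scaler: ScalingTransform
    config: GanConfig
    one_hot: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(ONE_HOT))

    def generate(self, z: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Scaled-space samples for given noise and labels."""
        Y = np.array([self.one_hot[l] for l in labels])
        out, _ = self.generator.forward(np.hstack([z, Y]))
        return out


def _one_hot_matrix(labels: np.ndarray) -> np.ndarray:
    return np.array([ONE_HOT[l] for l in labels])


def train_cgan(real: LabeledDataset, config: GanConfig) -> tuple[GeneratorModel, TrainingLog]:
    """Adversarial training on a labeled dataset; fully seeded and reproducible.

    One epoch is one shuffled full pass over the real records.  Raises on a
    class with fewer than 2 records and aborts with a diagnostic if a loss
    becomes non-finite.
    """
    counts = real.class_counts()
    for cls, cnt in counts.items():
        if cnt < 2:
            raise ValidationError(f"class {cls!r} has {cnt} record(s); need >= 2")
    scaler = fit_scaler(real)
    X = scaler.transform(real.features)
    Y = _one_hot_matrix(real.labels)
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)

    G = _MLP([config.noise_dim + N_CLASSES, *config.gen_hidden, N_FEATURES],
             "sigmoid", rng)
    D = _MLP([N_FEATURES + N_CLASSES, *config.disc_hidden, 1], "linear", rng)
    opt_g = _Adam(G.params, config.learning_rate, config.beta1, config.beta2)
    opt_d = _Adam(D.params, config.learning_rate, config.beta1, config.beta2)

    log = TrainingLog()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            m = len(idx)

            for _ in range(config.disc_steps):
                z = rng.standard_normal((m, config.noise_dim))
                fake, _ = G.forward(np.hstack([z, yb]))
                logit_r, cache_r = D.forward(np.hstack([xb, yb]))
                logit_f, cache_f = D.forward(np.hstack([fake, yb]))
                # BCE with logits: real -> 1, fake -> 0
                d_loss = float(np.mean(_softplus(-logit_r)) + np.mean(_softplus(logit_f)))
                grads_r, _ = D.backward(cache_r, (_sigmoid(logit_r) - 1.0) / m)
                grads_f, _ = D.backward(cache_f, _sigmoid(logit_f) / m)
                opt_d.step(D.params, [gr + gf for gr, gf in zip(grads_r, grads_f)])

            z = rng.standard_normal((m, config.noise_dim))
            fake, cache_g = G.forward(np.hstack([z, yb]))
            logit, cache_d = D.forward(np.hstack([fake, yb]))
            g_loss = float(np.mean(_softplus(-logit)))  # fool D: target real
            _, d_input = D.backward(cache_d, (_sigmoid(logit) - 1.0) / m)
            grads_g, _ = G.backward(cache_g, d_input[:, :N_FEATURES])
            opt_g.step(G.params, grads_g)

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch} (D={d_loss}, G={g_loss}); "
                    "try a lower learning rate"
                )
            d_losses.append(d_loss)
            g_losses.append(g_loss)
        log.disc_loss.append(float(np.mean(d_losses)))
        log.gen_loss.append(float(np.mean(g_losses)))

        if config.fid_probe_every and (
            epoch == 0 or (epoch + 1) % config.fid_probe_every == 0
        ):
            z = rng.standard_normal((n, config.noise_dim))
            probe, _ = G.forward(np.hstack([z, Y]))
            log.fid_probe[epoch + 1] = frechet_distance(X, probe)

    model = GeneratorModel(G, scaler, replace(config))
    return model, log


def sample_synthetic(
    model: GeneratorModel, n: int, class_mix: float, seed: int = 0
) -> LabeledDataset:
    """Draw ``n`` labeled synthetic records in physical units.

    ``class_mix`` is the fraction conditioned on class ``high`` (rounded to
    the nearest count); labels are the conditioning classes and provenance is
    ``synthetic``.  Deterministic for a given model and seed.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if not 0.0 <= class_mix <= 1.0:
        raise ValidationError("class_mix must lie in [0, 1]")
    n_high = int(round(n * class_mix))
    labels = np.array([CLASS_HIGH] * n_high + [CLASS_LOW] * (n - n_high), dtype=object)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.config.noise_dim))
    scaled = model.generate(z, labels)
    features = model.scaler.inverse(scaled)
    return LabeledDataset(features, labels, provenance="synthetic")


# ---------------------------------------------------------------------------
# JSON serialization so a saved model samples self-contained

def save_model(model: GeneratorModel, path: str | Path) -> None:
    cfg = asdict(model.config)
    payload = {
        "config": cfg,
        "scaler": {
            "minimum": model.scaler.minimum.tolist(),
            "maximum": model.scaler.maximum.tolist(),
        },
        "one_hot": {k: list(v) for k, v in model.one_hot.items()},
        "weights": [w.tolist() for w in model.generator.W],
        "biases": [b.tolist() for b in model.generator.b],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> GeneratorModel:
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    cfg["gen_hidden"] = tuple(cfg["gen_hidden"])
    cfg["disc_hidden"] = tuple(cfg["disc_hidden"])
    config = GanConfig(**cfg)
    G = _MLP([config.noise_dim + N_CLASSES, *config.gen_hidden, N_FEATURES],
             "sigmoid", np.random.default_rng(0))
    G.W = [np.array(w) for w in payload["weights"]]
    G.b = [np.array(b) for b in payload["biases"]]
    scaler = ScalingTransform(
        np.array(payload["scaler"]["minimum"]), np.array(payload["scaler"]["maximum"])
    )
    model = GeneratorModel(G, scaler, config)
    model.one_hot = {k: tuple(v) for k, v in payload["one_hot"].items()}
    return model
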