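"""Raw-waveform GAN: transposed-conv generator, strided-conv critic with
phase shuffle, and WGAN-GP training with periodic checkpointing.

The topology follows the original raw-audio GAN design (kernel length
25, stride 4, ReLU/tanh generator, LeakyReLU critic with phase-shuffle
layers), parameterized by a channel multiplier ``model_size`` so a desk
preset trains on one CPU in a couple of minutes while the full-scale
``paper`` preset keeps the original geometry.  Everything runs on the package's
own autodiff engine; training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .containers import SegmentSet, SYNTHETIC_LABEL

log = logging.getLogger(__name__)


@dataclass
class GanConfig:
    """Architecture and training hyperparameters.

    ``output_len`` must equal ``base_len * stride**k`` for an integer
    number of layers ``k``.  ``iterations`` counts generator updates;
    each is preceded by ``n_critic`` critic updates.
    """

    latent_dim: int = 100
    model_size: int = 64
    output_len: int = 16384
    base_len: int = 16
    kernel_len: int = 25
    stride: int = 4
    phase_shuffle_n: int = 2
    n_critic: int = 5
    gp_lambda: float = 10.0
    batch_size: int = 64
    iterations: int = 120_000
    checkpoint_every: int = 1000
    checkpoint_samples: int = 64
    adam_lr: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    sample_rate: int = 16384
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        for name in ("latent_dim", "model_size", "output_len", "base_len",
                     "kernel_len", "stride", "iterations", "checkpoint_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ratio = self.output_len / self.base_len
        k = round(np.log(ratio) / np.log(self.stride))
        if self.stride**k * self.base_len != self.output_len:
            raise ValueError(
                f"output_len {self.output_len} must be base_len * stride^k "
                f"(base_len={self.base_len}, stride={self.stride})"
            )
        self.n_layers = int(k)


#: Scale presets.  ``paper`` is the full-scale geometry (model_size 64,
#: 16384-sample clips, 120k iterations, batch 64).  ``desk`` is the CPU
#: sizing used throughout the test harness: 1-s clips at a 1024 Hz desk
#: rate, 3 conv layers, and a training run that finishes in minutes.
PRESETS: dict[str, dict] = {
    "paper": {},
    "desk": dict(
        model_size=8, output_len=1024, base_len=16, batch_size=8,
        iterations=2000, checkpoint_every=1000, sample_rate=1024,
        adam_lr=2e-4,
    ),
}


def make_config(preset: str | None = None, **overrides) -> GanConfig:
    base = dict(PRESETS[preset]) if preset else {}
    base.update(overrides)
    return GanConfig(**base)


# ---------------------------------------------------------------------------
# layers


def _conv1d(x: Tensor, W: Tensor, b: Tensor, stride: int, pad: int, K: int) -> Tensor:
    """Strided 1-D convolution via im2col; W has shape (Cin*K, Cout)."""
    B, Cin, L = x.shape
    L_out = (L + 2 * pad - K) // stride + 1
    xp = ad.pad_last(x, pad, pad) if pad else x
    cols = ad.im2col_mat(xp, K, stride)                 # (B, L_out, Cin*K)
    cols = ad.reshape(cols, (B * L_out, Cin * K))
    y = ad.matmul(cols, W)                              # (B*L_out, Cout)
    y = ad.add(y, b)
    Cout = W.shape[1]
    return ad.transpose(ad.reshape(y, (B, L_out, Cout)), (0, 2, 1))


def _conv_transpose1d(x: Tensor, W: Tensor, b: Tensor, stride: int, K: int) -> Tensor:
    """Fractionally-strided convolution as matmul + overlap-add fold.

    ``W`` has shape (Cin, Cout*K).  Each input sample contributes a
    length-K kernel at position ``l*stride``; cropping ``pad`` from the
    left and ``K - stride - pad`` from the right makes the output
    exactly ``stride * L`` samples (pad = ceil((K-stride)/2), i.e. the
    usual kernel-25/stride-4 geometry with output padding 1).
    """
    B, Cin, L = x.shape
    Cout = W.shape[1] // K
    pad = int(np.ceil((K - stride) / 2))
    m = ad.reshape(ad.transpose(x, (0, 2, 1)), (B * L, Cin))
    p = ad.matmul(m, W)                                   # (B*L, Cout*K)
    p = ad.transpose(ad.reshape(p, (B, L, Cout, K)), (0, 2, 1, 3))
    full = ad.col2im(p, K, stride, (L - 1) * stride + K)  # (B, Cout, ...)
    y = ad.slice_last(full, pad, pad + stride * L)
    return ad.add(y, ad.reshape(b, (Cout, 1)))


def _phase_shuffle(x: Tensor, n: int, rng: np.random.Generator) -> Tensor:
    """Random circular time shift in [-n, n], independent per batch item."""
    if n <= 0:
        return x
    B, _, L = x.shape
    shifts = rng.integers(-n, n + 1, size=B)
    base = np.arange(L)
    idx = np.stack([(base - s) % L for s in shifts])[:, None, :]
    inv = np.stack([(base + s) % L for s in shifts])[:, None, :]
    return ad.shuffle_last(x, idx, inv)


def _init(rng: np.random.Generator, *shape) -> np.ndarray:
    return rng.normal(0.0, 0.02, size=shape)


class Generator:
    """Latent vectors -> waveforms in [-1, 1] (tanh output)."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        self.cfg = cfg
        k, d, K = cfg.n_layers, cfg.model_size, cfg.kernel_len
        self.channels = [d * 2 ** (k - 1 - i) for i in range(k)] + [1]
        ch0 = self.channels[0]
        self.W_dense = Tensor(_init(rng, cfg.latent_dim, ch0 * cfg.base_len), requires_grad=True)
        self.b_dense = Tensor(np.zeros(ch0 * cfg.base_len), requires_grad=True)
        self.conv_W, self.conv_b = [], []
        for cin, cout in zip(self.channels[:-1], self.channels[1:]):
            self.conv_W.append(Tensor(_init(rng, cin, cout * K), requires_grad=True))
            self.conv_b.append(Tensor(np.zeros(cout), requires_grad=True))

    @property
    def params(self) -> list[Tensor]:
        return [self.W_dense, self.b_dense] + self.conv_W + self.conv_b

    def forward(self, z: Tensor) -> Tensor:
        cfg = self.cfg
        B = z.shape[0]
        h = ad.add(ad.matmul(z, self.W_dense), self.b_dense)
        h = ad.reshape(h, (B, self.channels[0], cfg.base_len))
        h = ad.relu(h)
        for i, (W, b) in enumerate(zip(self.conv_W, self.conv_b)):
            h = _conv_transpose1d(h, W, b, cfg.stride, cfg.kernel_len)
            h = ad.tanh(h) if i == len(self.conv_W) - 1 else ad.relu(h)
        return h  # (B, 1, output_len)

    def __call__(self, z_data: np.ndarray) -> np.ndarray:
        with ad.no_grad():
            return self.forward(Tensor(z_data)).data[:, 0, :]

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.data = w.copy()


class Critic:
    """Waveform batch -> one real-valued score per clip."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        self.cfg = cfg
        k, d, K = cfg.n_layers, cfg.model_size, cfg.kernel_len
        self.channels = [1] + [d * 2**i for i in range(k)]
        self.conv_W, self.conv_b = [], []
        for cin, cout in zip(self.channels[:-1], self.channels[1:]):
            self.conv_W.append(Tensor(_init(rng, cin * K, cout), requires_grad=True))
            self.conv_b.append(Tensor(np.zeros(cout), requires_grad=True))
        flat = self.channels[-1] * cfg.base_len
        self.W_out = Tensor(_init(rng, flat, 1), requires_grad=True)
        self.b_out = Tensor(np.zeros(1), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return self.conv_W + self.conv_b + [self.W_out, self.b_out]

    def forward(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        """x: (B, 1, L) -> scores (B, 1).  ``rng`` drives phase shuffle."""
        cfg = self.cfg
        if x.shape[-1] != cfg.output_len:
            raise ValueError(
                f"critic expects clips of {cfg.output_len} samples, got {x.shape[-1]}"
            )
        pad = (cfg.kernel_len - cfg.stride + 1) // 2  # keeps L_out = L / stride
        h = x
        n_layers = len(self.conv_W)
        for i, (W, b) in enumerate(zip(self.conv_W, self.conv_b)):
            h = _conv1d(h, W, b, cfg.stride, pad, cfg.kernel_len)
            h = ad.leaky_relu(h, 0.2)
            if i < n_layers - 1:
                h = _phase_shuffle(h, cfg.phase_shuffle_n, rng)
        B = h.shape[0]
        flat = ad.reshape(h, (B, h.shape[1] * h.shape[2]))
        return ad.add(ad.matmul(flat, self.W_out), self.b_out)

    def score(self, x_data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        with ad.no_grad():
            x = Tensor(x_data[:, None, :] if x_data.ndim == 2 else x_data)
            return self.forward(x, rng).data[:, 0]


def build_generator(cfg: GanConfig, seed: int | None = None) -> Generator:
    return Generator(cfg, np.random.default_rng(cfg.seed if seed is None else seed))


def build_discriminator(cfg: GanConfig, seed: int | None = None) -> Critic:
    return Critic(cfg, np.random.default_rng(cfg.seed if seed is None else seed))


# ---------------------------------------------------------------------------
# WGAN-GP pieces


def gradient_penalty(critic_forward, real: np.ndarray, fake: np.ndarray,
                     gp_lambda: float, rng: np.random.Generator,
                     create_graph: bool = False) -> Tensor:
    """λ · E[(‖∇_x critic(x̂)‖₂ − 1)²] over per-clip uniform interpolates.

    ``critic_forward`` maps a (B, 1, L) tensor to (B, 1) scores and must
    be differentiable through the engine.  With ``create_graph`` the
    result can be backpropagated into the critic's parameters.
    """
    real = np.asarray(real, dtype=np.float64)
    fake = np.asarray(fake, dtype=np.float64)
    if real.ndim == 2:
        real, fake = real[:, None, :], fake[:, None, :]
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must have equal shapes")
    if gp_lambda == 0:
        return Tensor(0.0)
    eps = rng.uniform(size=(real.shape[0], 1, 1))
    xhat = Tensor(eps * real + (1.0 - eps) * fake, requires_grad=True)
    with ad.enable_grad():
        scores = critic_forward(xhat)
        total = ad.tsum(scores)
    (gx,) = ad.grad(total, [xhat], create_graph=True)
    sq = ad.tsum(ad.mul(gx, gx), axis=(1, 2))
    norms = ad.sqrt(sq, eps=1e-12)
    pen = ad.tmean(ad.power(ad.add(norms, Tensor(-1.0)), 2.0))
    out = ad.mul(Tensor(float(gp_lambda)), pen)
    return out if create_graph else Tensor(out.data)


class Adam:
    def __init__(self, params: list[Tensor], lr: float, b1: float, b2: float,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads: list[Tensor]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data
            m += (1 - b1) * (gd - m)
            v += (1 - b2) * (gd * gd - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# checkpoints


@dataclass
class Checkpoint:
    iteration: int
    weights: list[np.ndarray]
    samples: np.ndarray  # (checkpoint_samples, output_len)
    config: GanConfig


@dataclass
class CheckpointSeries:
    checkpoints: list[Checkpoint] = field(default_factory=list)
    losses: "np.ndarray | None" = None  # columns: iter, critic, gen, gp, wasserstein

    def __len__(self) -> int:
        return len(self.checkpoints)

    def loss_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.losses, columns=["iteration", "critic_loss", "gen_loss", "gp", "wasserstein"]
        )


def save_checkpoint(path, ckpt: Checkpoint) -> None:
    """Self-describing archive: config JSON, iteration, weights, samples."""
    payload = {f"w{i}": w for i, w in enumerate(ckpt.weights)}
    np.savez(
        Path(path), iteration=ckpt.iteration, samples=ckpt.samples,
        config=json.dumps(asdict(ckpt.config)), n_weights=len(ckpt.weights), **payload,
    )


def load_checkpoint(path) -> Checkpoint:
    with np.load(Path(path), allow_pickle=False) as z:
        raw = json.loads(str(z["config"]))
        raw.pop("n_layers", None)
        cfg = GanConfig(**raw)
        n = int(z["n_weights"])
        return Checkpoint(
            iteration=int(z["iteration"]),
            weights=[z[f"w{i}"] for i in range(n)],
            samples=z["samples"],
            config=cfg,
        )


# ---------------------------------------------------------------------------
# training


def train(data: SegmentSet, cfg: GanConfig) -> CheckpointSeries:
    """WGAN-GP training on a single-class segment set.

    Alternates ``n_critic`` critic updates and one generator update per
    iteration; every ``checkpoint_every`` iterations stores the
    generator weights plus ``checkpoint_samples`` generated clips.
    Aborts with a diagnostic if any loss goes non-finite.
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    if data.segment_len != cfg.output_len:
        raise ValueError(
            f"training clips have {data.segment_len} samples but the model "
            f"generates {cfg.output_len}"
        )
    X = np.asarray(data.segments, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg, rng)
    critic = Critic(cfg, rng)
    opt_c = Adam(critic.params, cfg.adam_lr, cfg.adam_beta1, cfg.adam_beta2)
    opt_g = Adam(gen.params, cfg.adam_lr, cfg.adam_beta1, cfg.adam_beta2)
    sample_seed = int(rng.integers(2**31 - 1))

    series = CheckpointSeries()
    losses = np.zeros((cfg.iterations, 5))

    def sample_real(B):
        return X[rng.integers(len(X), size=B)][:, None, :]

    for it in range(1, cfg.iterations + 1):
        c_loss = g_loss = gp_val = w_est = 0.0
        for _ in range(cfg.n_critic):
            real = sample_real(cfg.batch_size)
            z = rng.standard_normal((cfg.batch_size, cfg.latent_dim))
            with ad.no_grad():
                fake = gen.forward(Tensor(z)).data
            real_t, fake_t = Tensor(real), Tensor(fake)
            d_real = critic.forward(real_t, rng)
            d_fake = critic.forward(fake_t, rng)
            gp = gradient_penalty(
                lambda x: critic.forward(x, rng), real, fake,
                cfg.gp_lambda, rng, create_graph=True,
            )
            loss = ad.add(ad.add(ad.tmean(d_fake), ad.mul(Tensor(-1.0), ad.tmean(d_real))), gp)
            grads = ad.grad(loss, critic.params)
            opt_c.step(grads)
            c_loss = loss.item()
            gp_val = gp.item()
            w_est = float(d_real.data.mean() - d_fake.data.mean())

        z = rng.standard_normal((cfg.batch_size, cfg.latent_dim))
        fake = gen.forward(Tensor(z))
        d = critic.forward(fake, rng)
        loss_g = ad.mul(Tensor(-1.0), ad.tmean(d))
        grads = ad.grad(loss_g, gen.params)
        opt_g.step(grads)
        g_loss = loss_g.item()

        if not (np.isfinite(c_loss) and np.isfinite(g_loss)):
            raise RuntimeError(f"non-finite GAN loss at iteration {it}: critic={c_loss}, gen={g_loss}")
        losses[it - 1] = (it, c_loss, g_loss, gp_val, w_est)

        if it % cfg.checkpoint_every == 0:
            srng = np.random.default_rng(np.random.SeedSequence([sample_seed, it]))
            zs = srng.standard_normal((cfg.checkpoint_samples, cfg.latent_dim))
            samples = gen(zs)
            series.checkpoints.append(
                Checkpoint(iteration=it, weights=gen.get_weights(), samples=samples, config=cfg)
            )
            log.info("iteration %d: critic %.4f gen %.4f gp %.4f W %.4f",
                     it, c_loss, g_loss, gp_val, w_est)

    series.losses = losses
    return series


def generate(checkpoint: Checkpoint, n: int, seed: int = 0,
             batch: int = 64) -> SegmentSet:
    """Draw ``n`` clips from a stored generator; deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = checkpoint.config
    gen = Generator(cfg, np.random.default_rng(0))
    gen.set_weights(checkpoint.weights)
    rng = np.random.default_rng(seed)
    outs = []
    remaining = n
    while remaining > 0:
        b = min(batch, remaining)
        z = rng.standard_normal((b, cfg.latent_dim))
        outs.append(gen(z))
        remaining -= b
    clips = np.concatenate(outs, axis=0)
    return SegmentSet(
        clips, np.asarray([SYNTHETIC_LABEL] * n, dtype=object), cfg.sample_rate,
        np.asarray([f"wavegan-it{checkpoint.iteration}"] * n, dtype=object),
        np.arange(n),
    )


def select_converged(series: CheckpointSeries, ref_classifier, target_label: str):
    """Pick the checkpoint whose stored samples the reference classifier
    assigns most often to ``target_label`` (earliest iteration on ties)."""
    if len(series) == 0:
        raise ValueError("checkpoint series is empty")
    counts = []
    for ckpt in series.checkpoints:
        pred = ref_classifier.predict(ckpt.samples)
        counts.append(int(np.sum(pred == target_label)))
    best = int(np.argmax(counts))  # argmax takes the first maximum
    return series.checkpoints[best].iteration, series.checkpoints[best]


# ---------------------------------------------------------------------------
# estimator front


class WaveGAN:
    """Estimator-style front: ``fit`` on a (n, output_len) array, ``sample``.

    Parameters mirror :class:`GanConfig`; fitted attributes are
    ``series_`` (checkpoints + loss trace) and ``best_checkpoint_``
    (the last checkpoint until :meth:`select` re-ranks them).
    """

    def __init__(self, preset: str | None = None, **overrides):
        self.preset = preset
        self.overrides = overrides

    def get_params(self, deep: bool = True) -> dict:
        return {"preset": self.preset, **self.overrides}

    def set_params(self, **params):
        self.preset = params.pop("preset", self.preset)
        self.overrides.update(params)
        return self

    def config(self) -> GanConfig:
        return make_config(self.preset, **self.overrides)

    def fit(self, X, y=None, rate: float | None = None):
        cfg = self.config()
        X = np.asarray(X, dtype=np.float64)
        data = SegmentSet(
            X, np.asarray(["synthetic"] * len(X), dtype=object),
            rate or cfg.sample_rate,
        )
        self.series_ = train(data, cfg)
        self.best_checkpoint_ = self.series_.checkpoints[-1]
        return self

    def select(self, ref_classifier, target_label: str):
        it, ckpt = select_converged(self.series_, ref_classifier, target_label)
        self.best_checkpoint_ = ckpt
        self.best_iteration_ = it
        return self

    def sample(self, n: int, seed: int = 0) -> SegmentSet:
        if not hasattr(self, "series_"):
            raise RuntimeError("WaveGAN must be fitted before sampling")
        return generate(self.best_checkpoint_, n, seed=seed)
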