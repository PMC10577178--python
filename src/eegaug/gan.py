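"""Conditional Wasserstein GAN for labeled EEG frames.

The generator maps a 100-dimensional standard-normal latent vector,
concatenated with a one-hot class label, through a dense layer, a reshape to
(filters, channels, time/16), four transposed-convolution stages that each
double the time axis (LeakyReLU + batch normalization in between), one
same-size convolution and a final tanh, producing frames in (-1, 1) with the
shape of the real data.

The critic receives the frame plus a constant-valued label plane; a Gaussian
noise layer perturbs the frame during training (to keep the critic from
memorizing a small dataset), followed by convolutions with strides (2,2),
(2,2), (1,2), LeakyReLU activations, dropout and a linear dense score.

Training minimizes the Wasserstein objective: the critic loss is
mean(fake scores) - mean(real scores) with weight clipping after every
critic step, the generator loss is -mean(fake scores); the critic runs five
iterations per generator iteration. Adam uses lr 5e-4, beta1 0, beta2 0.999,
eps 1e-7. The clip bound defaults to 0.01, the conventional choice for
weight-clipped Wasserstein training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .containers import EEGError, WindowSet

LABELS = ("HC", "MDD")


@dataclass(frozen=True)
class GeneratorSpec:
    latent_dim: int = 100
    output_shape: tuple[int, int] = (13, 2000)
    upsample_stages: int = 4
    base_filters: int = 16
    leaky_slope: float = 0.2
    batch_norm: bool = True
    kernel: tuple[int, int] = (3, 5)

    def __post_init__(self) -> None:
        c, t = self.output_shape
        factor = 2**self.upsample_stages
        if t % factor != 0:
            raise EEGError(
                f"window length {t} not reachable by {self.upsample_stages} "
                f"doublings (must be divisible by {factor})"
            )
        if c < 1 or t < factor:
            raise EEGError("invalid output shape")


@dataclass(frozen=True)
class CriticSpec:
    input_shape: tuple[int, int] = (13, 2000)
    input_noise_std: float = 0.05
    conv_strides: tuple[tuple[int, int], ...] = ((2, 2), (2, 2), (1, 2))
    conv_filters: tuple[int, ...] = (16, 32, 64)
    kernel: tuple[int, int] = (3, 5)
    dropout_rate: float = 0.25
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.conv_strides):
            raise EEGError("conv_filters and conv_strides must align")


@dataclass(frozen=True)
class GanTrainingConfig:
    learning_rate: float = 5e-4
    beta1: float = 0.0
    beta2: float = 0.999
    epsilon: float = 1e-7
    critic_iters_per_gen: int = 5
    clip_value: float = 0.01
    batch_size: int = 64
    total_gen_iters: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.critic_iters_per_gen < 1:
            raise EEGError("critic_iters_per_gen must be >= 1")
        if self.clip_value <= 0:
            raise EEGError("clip_value must be positive")


class GeneratorModel:
    """Conditional generator: (latent, one-hot label) -> frame in (-1, 1)."""

    def __init__(self, spec: GeneratorSpec, n_classes: int = 2, seed: int = 0):
        self.spec = spec
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        c, t = spec.output_shape
        t0 = t // 2**spec.upsample_stages
        f = spec.base_filters
        layers: list[nn.Layer] = [
            nn.Dense(spec.latent_dim + n_classes, f * c * t0, rng=rng,
                     weight_scale=0.05),
            nn.LeakyReLU(spec.leaky_slope),
            nn.Reshape((f, c, t0)),
        ]
        for _ in range(spec.upsample_stages):
            layers.append(nn.UpsampleConv2D(f, f, spec.kernel, rng=rng,
                                            weight_scale=0.05))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            if spec.batch_norm:
                layers.append(nn.BatchNorm2d(f))
        layers.append(nn.Conv2D(f, 1, spec.kernel, (1, 1), rng=rng,
                                weight_scale=0.05))
        layers.append(nn.Tanh())
        self.seq = nn.Sequential(layers)

    def forward(self, latent: np.ndarray, label_idx: np.ndarray,
                train: bool = False) -> np.ndarray:
        latent = np.asarray(latent, dtype=nn.DTYPE)
        onehot = np.zeros((latent.shape[0], self.n_classes), dtype=nn.DTYPE)
        onehot[np.arange(latent.shape[0]), np.asarray(label_idx, dtype=int)] = 1.0
        x = np.concatenate([latent, onehot], axis=1)
        out = self.seq.forward(x, train)
        return out[:, 0]  # (N, channels, time)

    def backward(self, dframes: np.ndarray) -> None:
        self.seq.backward(dframes[:, None].astype(nn.DTYPE))

    __call__ = forward


class CriticModel:
    """Conditional critic: (frame, label plane) -> unbounded scalar score."""

    def __init__(self, spec: CriticSpec, n_classes: int = 2, seed: int = 0):
        self.spec = spec
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.noise = nn.GaussianNoise(spec.input_noise_std)
        c, t = spec.input_shape
        h, w, in_ch = c, t, 2
        layers: list[nn.Layer] = []
        for filt, stride in zip(spec.conv_filters, spec.conv_strides):
            layers.append(nn.Conv2D(in_ch, filt, spec.kernel, stride, rng=rng,
                                    weight_scale=0.05))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            h = -(-h // stride[0])
            w = -(-w // stride[1])
            in_ch = filt
        layers.append(nn.Dropout(spec.dropout_rate))
        layers.append(nn.Flatten())
        layers.append(nn.Dense(in_ch * h * w, 1, rng=rng, weight_scale=0.05))
        self.seq = nn.Sequential(layers)

    def forward(self, frames: np.ndarray, label_idx: np.ndarray,
                train: bool = False) -> np.ndarray:
        frames = np.asarray(frames, dtype=nn.DTYPE)
        if frames.shape[1:] != self.spec.input_shape:
            raise EEGError(
                f"frame shape {frames.shape[1:]} != critic input "
                f"{self.spec.input_shape}"
            )
        noisy = self.noise.forward(frames, train)
        # symmetric label encoding (-1 / +1) so both classes carry signal
        enc = 2.0 * np.asarray(label_idx, dtype=nn.DTYPE) / max(
            self.n_classes - 1, 1
        ) - 1.0
        plane = np.broadcast_to(enc[:, None, None], frames.shape)
        x = np.stack([noisy, plane], axis=1)
        return self.seq.forward(x, train)[:, 0]

    def backward(self, dscore: np.ndarray) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the input frames."""
        dx = self.seq.backward(np.asarray(dscore, dtype=nn.DTYPE)[:, None])
        return self.noise.backward(dx[:, 0])

    __call__ = forward


@dataclass
class GanBundle:
    """Trained (or untrained) generator/critic pair with full provenance."""

    generator: GeneratorModel
    critic: CriticModel
    generator_spec: GeneratorSpec
    critic_spec: CriticSpec
    config: GanTrainingConfig
    critic_loss_history: list[float] = field(default_factory=list)
    generator_loss_history: list[float] = field(default_factory=list)
    labels: tuple[str, ...] = LABELS
    channel_names: tuple[str, ...] | None = None
    sampling_rate: float = float("nan")
    window_seconds: float = float("nan")


def build_generator(spec: GeneratorSpec, n_classes: int = 2,
                    seed: int = 0) -> GeneratorModel:
    return GeneratorModel(spec, n_classes, seed)


def build_critic(spec: CriticSpec, n_classes: int = 2,
                 seed: int = 0) -> CriticModel:
    return CriticModel(spec, n_classes, seed)


def critic_loss(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """Wasserstein critic objective: mean(fake) - mean(real) (minimized)."""
    real_scores = np.asarray(real_scores, dtype=float)
    fake_scores = np.asarray(fake_scores, dtype=float)
    if real_scores.size == 0 or fake_scores.size == 0:
        raise EEGError("score lists must be non-empty")
    return float(fake_scores.mean() - real_scores.mean())


def generator_loss(fake_scores: np.ndarray) -> float:
    """Wasserstein generator objective: -mean(fake scores)."""
    fake_scores = np.asarray(fake_scores, dtype=float)
    if fake_scores.size == 0:
        raise EEGError("score list must be non-empty")
    return float(-fake_scores.mean())


def clip_weights(critic: CriticModel, clip_value: float) -> CriticModel:
    """Clamp every trainable critic parameter to [-clip_value, clip_value]."""
    if clip_value <= 0:
        raise EEGError("clip_value must be positive")
    nn.clip_params_(critic.seq.all_params, clip_value)
    return critic


def train(
    real: WindowSet,
    gspec: GeneratorSpec,
    cspec: CriticSpec,
    config: GanTrainingConfig,
    labels: tuple[str, str] = LABELS,
) -> GanBundle:
    """Alternating Wasserstein training with the 5:1 critic regimen.

    Every randomness source (initialization, minibatch order, latents,
    noise/dropout) derives from ``config.seed``. Returns a bundle whose loss
    histories have ``critic_iters_per_gen * total_gen_iters`` critic entries
    and ``total_gen_iters`` generator entries.
    """
    if not real.normalized:
        raise EEGError("GAN training expects normalized windows")
    present = set(real.groups)
    if present != set(labels):
        raise EEGError(f"training data must contain both labels; has {present}")
    n = real.n_frames
    if config.batch_size > n:
        raise EEGError(f"batch size {config.batch_size} exceeds data size {n}")
    if gspec.output_shape != real.frame_shape:
        raise EEGError("generator output shape must match the real frames")
    if cspec.input_shape != real.frame_shape:
        raise EEGError("critic input shape must match the real frames")

    ss = np.random.SeedSequence(config.seed)
    s_init_g, s_init_c, s_loop, s_stoch = ss.generate_state(4)
    generator = build_generator(gspec, len(labels), seed=int(s_init_g))
    critic = build_critic(cspec, len(labels), seed=int(s_init_c))
    rng = np.random.default_rng(int(s_loop))
    stoch = np.random.default_rng(int(s_stoch))
    generator.seq.seed_stochastic(stoch)
    critic.seq.seed_stochastic(stoch)
    critic.noise.seed(stoch)

    frames = real.frames.astype(nn.DTYPE)
    y = np.array([labels.index(g) for g in real.groups])
    b = config.batch_size
    opt_c = nn.Adam(critic.seq.all_params, config.learning_rate, config.beta1,
                    config.beta2, config.epsilon)
    opt_g = nn.Adam(generator.seq.all_params, config.learning_rate, config.beta1,
                    config.beta2, config.epsilon)

    bundle = GanBundle(
        generator, critic, gspec, cspec, config, labels=tuple(labels),
        channel_names=real.channel_names, sampling_rate=real.sampling_rate,
        window_seconds=real.window_seconds,
    )
    for _ in range(config.total_gen_iters):
        for _ in range(config.critic_iters_per_gen):
            idx = rng.choice(n, size=b, replace=False)
            z = rng.standard_normal((b, gspec.latent_dim))
            fake_y = y[rng.choice(n, size=b, replace=False)]
            fake = generator.forward(z, fake_y, train=True)
            batch = np.concatenate([frames[idx], fake])
            batch_y = np.concatenate([y[idx], fake_y])
            scores = critic.forward(batch, batch_y, train=True)
            loss_c = critic_loss(scores[:b], scores[b:])
            dscore = np.concatenate([
                np.full(b, -1.0 / b), np.full(b, 1.0 / b)
            ]).astype(nn.DTYPE)
            critic.backward(dscore)
            opt_c.step(critic.seq.all_grads)
            clip_weights(critic, config.clip_value)
            bundle.critic_loss_history.append(loss_c)
        # generator step
        z = rng.standard_normal((b, gspec.latent_dim))
        fake_y = y[rng.choice(n, size=b, replace=False)]
        fake = generator.forward(z, fake_y, train=True)
        scores = critic.forward(fake, fake_y, train=True)
        loss_g = generator_loss(scores)
        dframes = critic.backward(np.full(b, -1.0 / b, dtype=nn.DTYPE))
        generator.backward(dframes)
        opt_g.step(generator.seq.all_grads)
        bundle.generator_loss_history.append(loss_g)
    return bundle


def sample(bundle: GanBundle, n: int, label: str, seed: int = 0) -> WindowSet:
    """Draw ``n`` class-conditioned frames from the generator.

    Latents are standard normal, seeded; frames carry synthetic provenance
    ids and the requested diagnosis label.
    """
    if n < 1:
        raise EEGError("n must be >= 1")
    if label not in bundle.labels:
        raise EEGError(f"unknown label {label!r}; expected one of {bundle.labels}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, bundle.generator_spec.latent_dim))
    idx = np.full(n, bundle.labels.index(label))
    frames = np.clip(
        bundle.generator.forward(z, idx, train=False).astype(float), -1.0, 1.0
    )
    c, t = bundle.generator_spec.output_shape
    names = bundle.channel_names or tuple(f"ch{i}" for i in range(c))
    return WindowSet(
        frames=frames,
        subject_ids=np.array(
            [f"synthetic-{label.lower()}-{seed}-{i:05d}" for i in range(n)],
            dtype=object,
        ),
        groups=np.array([label] * n, dtype=object),
        dataset_ids=np.array(["synthetic"] * n, dtype=object),
        data_types=np.array(["synthetic"] * n, dtype=object),
        channel_names=names,
        sampling_rate=bundle.sampling_rate,
        window_seconds=bundle.window_seconds,
        normalized=True,
    )
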