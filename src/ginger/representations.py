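"""Generative-model representations and their similarity metrics.

Two representation families are supported, matching the two generative-model
routes the agents can use:

* a small dense beta-VAE trained on programmatically rendered visual stimuli,
  whose encoder yields diagonal-Gaussian latent posteriors compared by
  (symmetrized, exponentiated) KL divergence; and
* fixed-length text embeddings compared by cosine similarity, produced either
  by a synthetic latent-factor generator (standing in for large
  language-model sentence embeddings) or loaded from a user-supplied file.

Both similarity metrics are bounded above by 1 with self-similarity exactly
1, which is what the instance-activation mismatch term ``mu*omega*(S-1)``
expects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "GaussianRepresentation",
    "Embedding",
    "StimulusSpec",
    "BVAESpec",
    "BetaVAE",
    "render_stimulus",
    "train_bvae",
    "kl_divergence",
    "kl_similarity",
    "cosine_similarity",
    "Email",
    "generate_synthetic_emails",
    "EMAIL_FEATURES",
    "SyntheticEmbeddingProvider",
    "FileEmbeddingProvider",
]

SHAPES = ("circle", "square", "triangle")
COLORS = ("yellow", "red", "green")
TEXTURES = ("dotted", "wavy", "hatched")

_COLOR_RGB = {
    "yellow": (0.95, 0.85, 0.1),
    "red": (0.9, 0.15, 0.1),
    "green": (0.1, 0.75, 0.2),
    None: (0.55, 0.55, 0.55),  # neutral fill when color is inactive
}


@dataclass(frozen=True)
class GaussianRepresentation:
    """Diagonal-Gaussian latent posterior (the encoder's output)."""

    mean: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "logvar", np.asarray(self.logvar, dtype=float))
        if self.mean.shape != self.logvar.shape or self.mean.ndim != 1:
            raise ValueError("mean and logvar must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("non-finite representation")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def __eq__(self, other):
        if not isinstance(other, GaussianRepresentation):
            return NotImplemented
        return (np.array_equal(self.mean, other.mean)
                and np.array_equal(self.logvar, other.logvar))

    def __hash__(self):
        return hash((self.mean.tobytes(), self.logvar.tobytes()))

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "logvar": self.logvar.tolist()}


@dataclass(frozen=True)
class Embedding:
    """Fixed-length real vector representation of a textual option."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.shape[0] < 1:
            raise ValueError("embedding must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite embedding")

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def __eq__(self, other):
        if not isinstance(other, Embedding):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self):
        return hash(self.values.tobytes())

    def to_dict(self) -> dict:
        return {"values": self.values.tolist()}


@dataclass(frozen=True)
class StimulusSpec:
    """Factorial visual stimulus: shape is mandatory, color/texture optional
    (inactive factors render as a neutral solid fill, as in the early phases
    of the transfer task)."""

    shape: str
    color: str | None = None
    texture: str | None = None
    size: int = 32

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.color is not None and self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.texture is not None and self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.size < 8:
            raise ValueError("size must be >= 8 pixels")


def render_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Deterministically render a stimulus as an (H, W, 3) float array in [0,1]."""
    n = spec.size
    img = np.ones((n, n, 3), dtype=float)  # white background
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = (n - 1) / 2.0
    r = n * 0.38

    if spec.shape == "circle":
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
    elif spec.shape == "square":
        mask = (np.abs(xx - cx) <= r * 0.9) & (np.abs(yy - cy) <= r * 0.9)
    else:  # triangle (upward-pointing)
        fy = (yy - (cy - r)) / (2 * r)
        mask = (fy >= 0) & (fy <= 1) & (np.abs(xx - cx) <= fy * r)

    rgb = np.array(_COLOR_RGB[spec.color])
    img[mask] = rgb

    if spec.texture is not None:
        dark = rgb * 0.35
        if spec.texture == "dotted":
            tex = ((xx % 6 < 2) & (yy % 6 < 2))
        elif spec.texture == "wavy":
            tex = np.sin(2 * np.pi * (yy + 2.5 * np.sin(2 * np.pi * xx / 10.0)) / 8.0) > 0.3
        else:  # hatched
            tex = ((xx + yy) % 7) < 2
        img[mask & tex] = dark
    return img


@dataclass
class BVAESpec:
    """Configuration of the beta-VAE: latent size, bottleneck weight beta,
    dense layer widths, and the training budget."""

    latent_dim: int = 9
    beta: float = 1.0
    hidden_dim: int = 64
    epochs: int = 200
    learning_rate: float = 2e-3
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


class BetaVAE:
    """Dense variational autoencoder with a beta-weighted KL bottleneck.

    Encoder: flatten -> tanh(hidden) -> (mean, logvar); decoder:
    tanh(hidden) -> linear output.  Loss per sample is
    ``sum((xhat - x)^2) + beta * KL(posterior || N(0, I))``.

    Images are centered on the training-set mean before encoding; without
    this the first phase of training (fitting the shared mean image through
    the decoder bias) starves the encoder of gradient and the posterior
    collapses to a constant.
    """

    def __init__(self, input_shape: tuple, spec: BVAESpec):
        self.spec = spec
        self.input_shape = tuple(input_shape)
        D = int(np.prod(input_shape))
        self.x_mean = np.zeros(D)
        H, L = spec.hidden_dim, spec.latent_dim
        rng = np.random.default_rng(spec.seed)

        def init(n_in, n_out):
            return rng.uniform(-1, 1, (n_in, n_out)) * math.sqrt(6.0 / (n_in + n_out))

        self.W1, self.b1 = init(D, H), np.zeros(H)
        self.W2, self.b2 = init(H, L), np.zeros(L)
        self.W3, self.b3 = init(H, L), np.zeros(L)
        self.W4, self.b4 = init(L, H), np.zeros(H)
        self.W5, self.b5 = init(H, D), np.zeros(D)
        self._rng = rng
        self.loss_history: list[dict] = []

    def _params(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3,
                self.W4, self.b4, self.W5, self.b5]

    def encode(self, image: np.ndarray) -> GaussianRepresentation:
        """Deterministic posterior parameters for a single image."""
        image = np.asarray(image, dtype=float)
        if image.shape != self.input_shape:
            raise ValueError(
                f"image shape {image.shape} != training shape {self.input_shape}")
        x = image.reshape(1, -1) - self.x_mean
        h = np.tanh(x @ self.W1 + self.b1)
        mu = (h @ self.W2 + self.b2)[0]
        lv = (h @ self.W3 + self.b3)[0]
        return GaussianRepresentation(mu, lv)

    def reconstruct(self, image: np.ndarray) -> np.ndarray:
        rep = self.encode(image)
        h = np.tanh(rep.mean[None, :] @ self.W4 + self.b4)
        out = h @ self.W5 + self.b5 + self.x_mean
        return np.clip(out.reshape(self.input_shape), 0.0, 1.0)

    def _loss_and_grads(self, X: np.ndarray):
        n = X.shape[0]
        beta = self.spec.beta
        h1 = np.tanh(X @ self.W1 + self.b1)
        mu = h1 @ self.W2 + self.b2
        lv = np.clip(h1 @ self.W3 + self.b3, -10, 10)
        eps = self._rng.standard_normal(mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + std * eps
        h2 = np.tanh(z @ self.W4 + self.b4)
        xhat = h2 @ self.W5 + self.b5

        recon = np.sum((xhat - X) ** 2, axis=1)
        kl = 0.5 * np.sum(np.exp(lv) + mu ** 2 - 1.0 - lv, axis=1)
        loss = float(np.mean(recon + beta * kl))

        dxhat = 2.0 * (xhat - X) / n
        gW5 = h2.T @ dxhat
        gb5 = dxhat.sum(0)
        dh2 = (dxhat @ self.W5.T) * (1.0 - h2 ** 2)
        gW4 = z.T @ dh2
        gb4 = dh2.sum(0)
        dz = dh2 @ self.W4.T
        dmu = dz + beta * mu / n
        dlv = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(lv) - 1.0) / n
        gW2 = h1.T @ dmu
        gb2 = dmu.sum(0)
        gW3 = h1.T @ dlv
        gb3 = dlv.sum(0)
        dh1 = (dmu @ self.W2.T + dlv @ self.W3.T) * (1.0 - h1 ** 2)
        gW1 = X.T @ dh1
        gb1 = dh1.sum(0)
        grads = [gW1, gb1, gW2, gb2, gW3, gb3, gW4, gb4, gW5, gb5]
        return loss, float(np.mean(recon)), float(np.mean(kl)), grads

    def fit(self, images: Sequence[np.ndarray]) -> "BetaVAE":
        from .nn import Adam

        if len(images) == 0:
            raise ValueError("empty training set")
        X = np.stack([np.asarray(im, dtype=float).reshape(-1) for im in images])
        self.x_mean = X.mean(axis=0)
        X = X - self.x_mean
        opt = Adam(self._params(), lr=self.spec.learning_rate)
        n = X.shape[0]
        bs = max(1, min(self.spec.batch_size, n))
        for _ in range(self.spec.epochs):
            order = self._rng.permutation(n)
            ep_loss, ep_recon, ep_kl, n_batches = 0.0, 0.0, 0.0, 0
            for start in range(0, n, bs):
                batch = X[order[start:start + bs]]
                loss, recon, kl, grads = self._loss_and_grads(batch)
                opt.step(grads)
                ep_loss += loss
                ep_recon += recon
                ep_kl += kl
                n_batches += 1
            self.loss_history.append({"loss": ep_loss / n_batches,
                                      "recon": ep_recon / n_batches,
                                      "kl": ep_kl / n_batches})
        return self


def train_bvae(images: Sequence[np.ndarray], spec: BVAESpec) -> BetaVAE:
    """Train a beta-VAE on a stack of identically shaped images."""
    if len(images) == 0:
        raise ValueError("empty training set")
    model = BetaVAE(np.asarray(images[0]).shape, spec)
    return model.fit(images)


def kl_divergence(p: GaussianRepresentation, q: GaussianRepresentation) -> float:
    """Closed-form KL(p || q) between diagonal Gaussians; >= 0, 0 iff p == q."""
    if p.dim != q.dim:
        raise ValueError("dimension mismatch")
    vp, vq = np.exp(p.logvar), np.exp(q.logvar)
    return float(0.5 * np.sum(vp / vq + (q.mean - p.mean) ** 2 / vq
                              - 1.0 + q.logvar - p.logvar))


def kl_similarity(p: GaussianRepresentation, q: GaussianRepresentation,
                  scale: float = 1.0) -> float:
    """Bounded similarity exp(-KL_sym / scale) in (0, 1], symmetric,
    with KL_sym = (KL(p||q) + KL(q||p)) / 2."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    kl_sym = 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))
    return float(np.exp(-kl_sym / scale))


def cosine_similarity(u: Embedding, v: Embedding) -> float:
    """Cosine of the angle between two embeddings, clamped to [-1, 1]."""
    if u.dim != v.dim:
        raise ValueError("dimension mismatch")
    nu, nv = np.linalg.norm(u.values), np.linalg.norm(v.values)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    return float(np.clip(u.values @ v.values / (nu * nv), -1.0, 1.0))


# --------------------------------------------------------------------------
# Synthetic email corpus

EMAIL_FEATURES = (
    "mismatched_sender",
    "requesting_credentials",
    "urgent_language",
    "making_offer",
    "suspicious_subject",
    "link_mismatch",
)


@dataclass(frozen=True)
class Email:
    """One synthetic email: six binary expert-coded flags, a ham/phishing
    label, an embedding, and a text stub."""

    id: int
    features: dict
    label: str  # "ham" | "phishing"
    embedding: Embedding
    text: str = ""

    def feature_vector(self) -> np.ndarray:
        return np.array([self.features[f] for f in EMAIL_FEATURES], dtype=float)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def generate_synthetic_emails(
    n: int = 239,
    embedding_dim: int = 1536,
    phishing_fraction: float = 0.5,
    effect_strength: float = 0.4,
    noise_sd: float = 0.1,
    seed: int = 0,
    nuisance_dim: int = 4,
    nuisance_scale: float = 0.5,
) -> list[Email]:
    """Generate a labeled synthetic email corpus with class-informative
    binary features and embeddings.

    Each binary expert feature fires with probability ``0.5 + effect/2``
    under phishing and ``0.5 - effect/2`` under ham.  Embeddings follow a
    latent-factor model ``W @ [centered features, nuisance] + noise`` with
    ``W`` fixed by the seed, so embeddings of same-class emails have higher
    cosine similarity (on average) than cross-class pairs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < phishing_fraction < 1):
        raise ValueError("phishing_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_phish = _round_half_up(n * phishing_fraction)
    n_phish = min(max(n_phish, 1), n - 1)
    labels = np.array(["phishing"] * n_phish + ["ham"] * (n - n_phish))
    rng.shuffle(labels)

    p_hi = min(0.5 + effect_strength / 2.0, 1.0)
    p_lo = max(0.5 - effect_strength / 2.0, 0.0)
    k = len(EMAIL_FEATURES)
    W = rng.standard_normal((embedding_dim, k + nuisance_dim)) / math.sqrt(k + nuisance_dim)

    emails = []
    for i in range(n):
        p = p_hi if labels[i] == "phishing" else p_lo
        flags = (rng.uniform(size=k) < p).astype(int)
        nuis = nuisance_scale * rng.standard_normal(nuisance_dim)
        factors = np.concatenate([flags - 0.5, nuis])
        vec = W @ factors + noise_sd * rng.standard_normal(embedding_dim)
        emails.append(Email(
            id=i,
            features={f: int(v) for f, v in zip(EMAIL_FEATURES, flags)},
            label=str(labels[i]),
            embedding=Embedding(vec),
            text=f"synthetic email #{i} ({labels[i]})",
        ))
    return emails


# --------------------------------------------------------------------------
# Embedding providers

class SyntheticEmbeddingProvider:
    """Maps any text to a reproducible pseudo-random embedding (a stand-in
    for a sentence-embedding service; no network access)."""

    def __init__(self, dim: int = 1536, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def __call__(self, text: str) -> Embedding:
        h = abs(hash((self.seed, text))) % (2 ** 31)
        rng = np.random.default_rng(h)
        return Embedding(rng.standard_normal(self.dim))


class FileEmbeddingProvider:
    """File-backed lookup of precomputed embeddings.

    Accepts JSON ({id: [floats]}) or CSV (id, v0, v1, ...) files.
    """

    def __init__(self, path: str | Path):
        path = Path(path)
        self.table: dict[str, Embedding] = {}
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
            for key, vec in raw.items():
                self.table[str(key)] = Embedding(np.asarray(vec, dtype=float))
        else:
            for line in path.read_text().splitlines():
                if not line.strip():
                    continue
                parts = line.split(",")
                self.table[parts[0].strip()] = Embedding(
                    np.array([float(v) for v in parts[1:]]))

    def __call__(self, key: str) -> Embedding:
        if str(key) not in self.table:
            raise KeyError(f"no embedding stored for {key!r}")
        return self.table[str(key)]
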