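"""Fundus-image pipeline: denoising, PCA variance budget, CAE embeddings.

The convolutional autoencoder compresses a grayscale fundus image to a
fixed-length latent code (256 at clinical scale, smaller for desk-scale
synthetic work); the encoder output is used as a per-visit feature
vector by the forecasters. Implemented directly on the package's NumPy
autodiff core, trained with adaptive-moment gradient descent, mean
squared reconstruction loss, and early stopping on a validation split
with best-weights restore.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from . import nn
from .prep import grouped_train_val_test

__all__ = [
    "AutoencoderConfig",
    "median_filter",
    "pca_cumulative_variance",
    "components_for_variance",
    "ConvolutionalAutoencoder",
    "train_autoencoder",
    "embed",
    "load_images",
]

log = logging.getLogger(__name__)


def median_filter(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """True median filter with reflected edges; the standard salt-and-pepper remedy."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel size must be odd and >= 3")
    return ndimage.median_filter(np.asarray(image), size=kernel, mode="reflect")


def pca_cumulative_variance(images: np.ndarray) -> np.ndarray:
    """Cumulative explained-variance curve of the flattened image set.

    Nondecreasing and ending at 1.0; degenerate (zero total variance)
    input raises, since the ratio is undefined.
    """
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x.reshape(len(x), -1)
    if len(x) < 2:
        raise ValueError("need at least 2 images")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate image set: zero total variance")
    pca = PCA(svd_solver="full")
    pca.fit(x)
    return np.cumsum(pca.explained_variance_ratio_)


def components_for_variance(curve: np.ndarray, fraction: float) -> int:
    """Smallest component count whose cumulative explained variance >= fraction."""
    idx = np.searchsorted(curve, fraction - 1e-12)
    return int(min(idx, len(curve) - 1)) + 1


@dataclass
class AutoencoderConfig:
    """Training-time knobs of the convolutional autoencoder."""

    latent_dim: int = 256
    input_size: int = 64
    epochs_max: int = 200
    patience: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> "AutoencoderConfig":
        if self.latent_dim < 1 or self.latent_dim >= self.input_size**2:
            raise ValueError("latent_dim must satisfy 1 <= latent_dim < input_size^2")
        if self.input_size < 16 or self.input_size % 8 != 0:
            raise ValueError("input_size must be >= 16 and divisible by 8")
        return self


class ConvolutionalAutoencoder(BaseEstimator, TransformerMixin):
    """Convolutional encoder-decoder with a dense bottleneck.

    Encoder: three stride-2 3x3 convolution blocks (8, 16, 32 channels,
    ReLU) followed by a dense map to ``latent_dim``. Decoder mirrors them
    with nearest-neighbour x2 upsampling + convolution, ending in a
    sigmoid so reconstructions live in [0, 1]. ``transform`` returns the
    latent codes; ``inverse_transform`` decodes them.
    """

    def __init__(
        self,
        latent_dim: int = 64,
        input_size: int = 64,
        epochs_max: int = 200,
        patience: int = 10,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.latent_dim = latent_dim
        self.input_size = input_size
        self.epochs_max = epochs_max
        self.patience = patience
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    # -- architecture ---------------------------------------------------

    def _build(self, rng):
        s = self.input_size
        self._enc_convs = [
            nn.Conv(rng, 1, 8, stride=2),
            nn.Conv(rng, 8, 16, stride=2),
            nn.Conv(rng, 16, 32, stride=2),
        ]
        self._bottleneck_hw = s // 8
        flat = 32 * self._bottleneck_hw**2
        self._enc_dense = nn.Dense(rng, flat, self.latent_dim)
        self._dec_dense = nn.Dense(rng, self.latent_dim, flat)
        self._dec_convs = [
            nn.UpConv(rng, 32, 16),
            nn.UpConv(rng, 16, 8),
            nn.UpConv(rng, 8, 1),
        ]

    @property
    def _params(self):
        ps = []
        for layer in self._enc_convs + [self._enc_dense, self._dec_dense] + self._dec_convs:
            ps += layer.params
        return ps

    def _encode(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        for conv in self._enc_convs:
            h = conv(h).relu()
        h = h.reshape(h.shape[0], -1)
        return self._enc_dense(h)

    def _decode(self, z: nn.Tensor) -> nn.Tensor:
        hw = self._bottleneck_hw
        h = self._dec_dense(z).relu().reshape(-1, 32, hw, hw)
        for i, conv in enumerate(self._dec_convs):
            h = conv(h)
            h = h.sigmoid() if i == len(self._dec_convs) - 1 else h.relu()
        return h

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.max() > 1.5:
            x = x / 255.0
        if x.shape[-1] != self.input_size:
            raise ValueError(
                f"images are {x.shape[-2]}x{x.shape[-1]}, expected {self.input_size}; resize first"
            )
        return x

    # -- sklearn surface ------------------------------------------------

    def fit(self, images: np.ndarray, y=None, groups=None):
        """Train on a 60/20/20 train/validation/test split of the images."""
        cfg = AutoencoderConfig(
            self.latent_dim,
            self.input_size,
            self.epochs_max,
            self.patience,
            self.batch_size,
            self.learning_rate,
            self.seed,
        ).validate()
        x = self._as_batch(images)
        if len(x) < self.batch_size:
            raise ValueError(f"need at least batch_size={self.batch_size} images, got {len(x)}")
        rng = np.random.default_rng(cfg.seed)
        self._build(rng)
        split_groups = groups if groups is not None else np.arange(len(x))
        tr, va, te = grouped_train_val_test(split_groups, (0.6, 0.2, 0.2), seed=cfg.seed)
        opt = nn.Adam(self._params, lr=cfg.learning_rate)
        best_val, best_weights, since_best = np.inf, None, 0
        self.train_curve_, self.val_curve_ = [], []
        for _epoch in range(cfg.epochs_max):
            order = rng.permutation(tr)
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = x[order[start : start + cfg.batch_size]]
                xt = nn.Tensor(batch, requires_grad=False)
                recon = self._decode(self._encode(xt))
                loss = ((recon - xt) ** 2).mean()
                loss.backward()
                opt.step()
                losses.append(loss.data.item())
            val_mse = self._reconstruction_mse(x[va])
            self.train_curve_.append(float(np.mean(losses)))
            self.val_curve_.append(val_mse)
            if val_mse < best_val - 1e-9:
                best_val, since_best = val_mse, 0
                best_weights = [p.data.copy() for p in self._params]
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if best_weights is not None:
            for p, w in zip(self._params, best_weights):
                p.data = w
        self.val_mse_ = best_val
        self.test_mse_ = self._reconstruction_mse(x[te])
        self.n_features_in_ = x.shape[-1] * x.shape[-2]
        return self

    def _reconstruction_mse(self, x: np.ndarray) -> float:
        if len(x) == 0:
            return np.nan
        recon = self.reconstruct(x)
        return float(np.mean((recon - np.squeeze(x, 1) if x.ndim == 4 else recon - x) ** 2))

    def transform(self, images: np.ndarray) -> np.ndarray:
        """Latent codes, one row of length ``latent_dim`` per image."""
        x = self._as_batch(images)
        return self._encode(nn.Tensor(x, requires_grad=False)).data

    def inverse_transform(self, codes: np.ndarray) -> np.ndarray:
        z = nn.Tensor(np.asarray(codes, dtype=float), requires_grad=False)
        return np.squeeze(self._decode(z).data, axis=1)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        return self.inverse_transform(self.transform(images))


def train_autoencoder(
    images: np.ndarray, config: AutoencoderConfig | None = None
) -> tuple[ConvolutionalAutoencoder, dict]:
    """Fit a CAE and return it with its train/validation loss curves."""
    config = (config or AutoencoderConfig()).validate()
    model = ConvolutionalAutoencoder(
        latent_dim=config.latent_dim,
        input_size=config.input_size,
        epochs_max=config.epochs_max,
        patience=config.patience,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    model.fit(images)
    curves = {
        "train": model.train_curve_,
        "val": model.val_curve_,
        "best_val_mse": model.val_mse_,
        "test_mse": model.test_mse_,
    }
    return model, curves


def embed(
    images: np.ndarray, model: ConvolutionalAutoencoder, image_ids: list[str] | None = None
) -> pd.DataFrame:
    """Embed images to latent vectors; one row per image, columns emb_1..emb_d."""
    codes = model.transform(images)
    cols = [f"emb_{i + 1}" for i in range(codes.shape[1])]
    frame = pd.DataFrame(codes, columns=cols)
    frame.insert(0, "image_id", image_ids if image_ids is not None else np.arange(len(codes)))
    return frame


def load_images(paths: list[str | Path], size: int | None = None) -> np.ndarray:
    """Read 8-bit grayscale images, optionally resizing to size x size."""
    out = []
    for p in paths:
        img = Image.open(p).convert("L")
        if size is not None and img.size != (size, size):
            img = img.resize((size, size), Image.BILINEAR)
        out.append(np.asarray(img, dtype=float) / 255.0)
    return np.stack(out)
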