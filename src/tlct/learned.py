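"""Data-driven correction of the sensitivity artifact.

Two learned correctors are provided:

* :class:`KnownOpModel` -- a known-operator reconstruction network.  The
  analytic reconstruction pipeline (detector filtering, fixed unweighted
  back-projection, per-voxel scaling) is kept as the architecture and only
  the physically interpretable parts are trainable: the detector filter
  (initialized with the Ram-Lak kernel), a per-pixel field of normalization
  weights (initialized with ones) and a per-pixel field of voxel weights
  (initialized with the mean sensitivity, i.e. the iso-center value).  At
  initialization the network output is therefore *exactly* the
  mean-corrected FBP baseline; training moves it toward the inverse of the
  weighted Radon transform.
* :class:`UNetModel` -- a standard depth-4 U-net with 16 initial feature
  channels operating on uncorrected FBP reconstructions.

Both are trained with a mean-absolute-error loss and Adam; gradients are
computed by manual backpropagation (see :mod:`tlct.nn`), with the forward
projector serving as the exact adjoint of the embedded back-projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.fft

from .classic import apply_detector_filter, fbp_scale, ram_lak_kernel
from .geometry import GeometryConfig, SensitivityProfile
from .nn import Adam, Conv2D, ConvTranspose2, MaxPool2, ReLU
from .phantoms import TrainingSet
from .projector import Sinogram, WeightedSystem

__all__ = [
    "KnownOpParams",
    "KnownOpModel",
    "TrainConfig",
    "UNetConfig",
    "UNetModel",
    "known_op_forward",
    "train_known_op",
    "unet_correct",
    "train_unet",
]


@dataclass
class TrainConfig:
    """Shared training protocol of both networks."""

    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 4
    patience: int = 20  # early stopping on validation MAE (U-net)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# Known-operator network
# ---------------------------------------------------------------------------

@dataclass
class KnownOpParams:
    """Trainable parameters of the known-operator network.

    ``filter_kernel`` is the spatial detector filter (odd length
    ``2*n_detector - 1``, centered); ``norm_weights`` and ``voxel_weights``
    are per-image-pixel multiplicative and divisive fields.
    """

    filter_kernel: np.ndarray
    norm_weights: np.ndarray
    voxel_weights: np.ndarray

    @classmethod
    def initial(cls, geometry: GeometryConfig, profile: SensitivityProfile) -> "KnownOpParams":
        """Ram-Lak filter, unit normalization, iso-center voxel weights.

        With these values the forward pass reproduces the mean-corrected FBP
        baseline exactly.
        """
        return cls(
            filter_kernel=ram_lak_kernel(geometry.n_detector, geometry.detector_spacing),
            norm_weights=np.ones(geometry.image_shape),
            voxel_weights=np.full(geometry.image_shape, profile.iso_center_weight),
        )

    def copy(self) -> "KnownOpParams":
        return KnownOpParams(
            self.filter_kernel.copy(), self.norm_weights.copy(), self.voxel_weights.copy()
        )


def _filter_kernel_grad(rows: np.ndarray, g_rows: np.ndarray) -> np.ndarray:
    """Gradient of ``sum(g_rows * apply_detector_filter(rows, h))`` w.r.t. ``h``.

    Entry ``m`` (centered) is the cross-correlation
    ``sum_i sum_t g_rows[i, t] * rows[i, t - m]``.
    """
    n_det = rows.shape[-1]
    nfft = scipy.fft.next_fast_len(3 * n_det - 2)
    spec = scipy.fft.rfft(g_rows, nfft, axis=-1) * np.conj(scipy.fft.rfft(rows, nfft, axis=-1))
    corr = scipy.fft.irfft(spec.sum(axis=0), nfft)
    lags = np.arange(-(n_det - 1), n_det)
    return corr[lags % nfft]


class KnownOpModel:
    """Known-operator network around a fixed unweighted back-projection."""

    def __init__(self, geometry: GeometryConfig, profile: SensitivityProfile,
                 params: Optional[KnownOpParams] = None):
        self.geometry = geometry
        self.profile = profile
        self.params = params or KnownOpParams.initial(geometry, profile)
        self._system = WeightedSystem(geometry, None)  # unweighted B / B^T
        self._scale = fbp_scale(geometry)

    # -- forward ------------------------------------------------------------
    def forward(self, sino_values: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
        p = self.params
        filtered = apply_detector_filter(sino_values, p.filter_kernel)
        u = self._system.adjoint(filtered) * self._scale
        y = u * p.norm_weights / p.voxel_weights
        if cache is not None:
            cache["sino"] = sino_values
            cache["u"] = u
        return y

    def correct_sinogram(self, sinogram: Sinogram) -> np.ndarray:
        return self.forward(sinogram.values)

    # -- backward -----------------------------------------------------------
    def backward(self, g_y: np.ndarray, cache: dict, grads: dict) -> None:
        """Accumulate parameter gradients for one sample into ``grads``."""
        p = self.params
        u = cache["u"]
        grads["norm"] += g_y * u / p.voxel_weights
        grads["voxel"] += -g_y * u * p.norm_weights / p.voxel_weights**2
        g_u = g_y * p.norm_weights / p.voxel_weights
        g_filtered = self._system.forward(g_u) * self._scale
        grads["filter"] += _filter_kernel_grad(cache["sino"], g_filtered)

    def zero_grads(self) -> dict:
        return {
            "filter": np.zeros_like(self.params.filter_kernel),
            "norm": np.zeros_like(self.params.norm_weights),
            "voxel": np.zeros_like(self.params.voxel_weights),
        }

    def param_pairs(self, grads: dict):
        p = self.params
        return [
            (p.filter_kernel, grads["filter"]),
            (p.norm_weights, grads["norm"]),
            (p.voxel_weights, grads["voxel"]),
        ]

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        import h5py
        import json

        with h5py.File(path, "w") as f:
            grp = f.create_group("known_op")
            grp.create_dataset("filter_kernel", data=self.params.filter_kernel)
            grp.create_dataset("norm_weights", data=self.params.norm_weights)
            grp.create_dataset("voxel_weights", data=self.params.voxel_weights)
            grp.attrs["geometry"] = json.dumps(self.geometry.to_dict())
            grp.attrs["profile"] = json.dumps(self.profile.to_dict())

    @classmethod
    def load(cls, path: str) -> "KnownOpModel":
        import h5py
        import json

        with h5py.File(path, "r") as f:
            grp = f["known_op"]
            geometry = GeometryConfig.from_dict(json.loads(grp.attrs["geometry"]))
            profile = SensitivityProfile.from_dict(json.loads(grp.attrs["profile"]))
            params = KnownOpParams(
                filter_kernel=grp["filter_kernel"][...],
                norm_weights=grp["norm_weights"][...],
                voxel_weights=grp["voxel_weights"][...],
            )
        return cls(geometry, profile, params)


def known_op_forward(
    sinogram: Sinogram, params: KnownOpParams, geometry: Optional[GeometryConfig] = None
) -> np.ndarray:
    """Functional forward pass of the known-operator network."""
    g = sinogram.geometry if geometry is None else geometry
    model = KnownOpModel(g, SensitivityProfile(), params)
    return model.forward(sinogram.values)


def train_known_op(
    dataset: TrainingSet, config: Optional[TrainConfig] = None,
    model: Optional[KnownOpModel] = None,
    train_params: Tuple[str, ...] = ("filter", "norm", "voxel"),
) -> Tuple[KnownOpModel, List[float]]:
    """Train filter and weight fields with MAE loss and Adam.

    Inputs are the weighted sinograms, targets the ground-truth phantoms.
    ``train_params`` selects which parameter groups are optimized (freezing
    e.g. the filter keeps the remaining problem well identified).  Returns
    the trained model and the per-epoch validation-MAE history (entry 0 is
    the pre-training baseline).
    """
    config = config or TrainConfig()
    if len(dataset.train_idx) == 0:
        raise ValueError("empty training split")
    model = model or KnownOpModel(dataset.geometry, dataset.profile)
    grads = model.zero_grads()
    names = {"filter": 0, "norm": 1, "voxel": 2}
    pairs = [model.param_pairs(grads)[names[k]] for k in train_params]
    opt = Adam(pairs, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    def val_mae() -> float:
        if len(dataset.val_idx) == 0:
            return float("nan")
        errs = [
            np.mean(np.abs(model.forward(dataset.sinograms[i]) - dataset.images[i]))
            for i in dataset.val_idx
        ]
        return float(np.mean(errs))

    history = [val_mae()]
    npix = float(np.prod(dataset.geometry.image_shape))
    for _ in range(config.epochs):
        order = rng.permutation(dataset.train_idx)
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            for i in batch:
                cache: dict = {}
                y = model.forward(dataset.sinograms[i], cache)
                g_y = np.sign(y - dataset.images[i]) / (npix * len(batch))
                model.backward(g_y, cache, grads)
            opt.step()
        history.append(val_mae())
    return model, history


# ---------------------------------------------------------------------------
# U-net
# ---------------------------------------------------------------------------

@dataclass
class UNetConfig:
    """Standard U-net: two 3x3 conv + ReLU per block, 2x pooling per level."""

    depth: int = 4
    base_channels: int = 16
    residual: bool = False  # if True, the net predicts a correction added to its input
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")


class _ConvBlock:
    def __init__(self, c_in, c_out, rng):
        self.layers = [Conv2D(c_in, c_out, 3, rng=rng), ReLU(),
                       Conv2D(c_out, c_out, 3, rng=rng), ReLU()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]


class UNetModel:
    """Encoder-decoder with skip connections; output shape equals input shape.

    Inputs whose side is not divisible by ``2**depth`` are zero-padded
    symmetrically and the output is cropped back.  The final 1x1 convolution
    is zero-initialized, so an untrained network outputs zero (or, in
    residual mode, the unmodified input).
    """

    def __init__(self, config: Optional[UNetConfig] = None):
        self.config = config or UNetConfig()
        rng = np.random.default_rng(self.config.seed)
        d, b = self.config.depth, self.config.base_channels
        self.enc = []
        c_in = 1
        for lvl in range(d):
            self.enc.append(_ConvBlock(c_in, b * 2**lvl, rng))
            c_in = b * 2**lvl
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _ConvBlock(c_in, b * 2**d, rng)
        self.ups = []
        self.dec = []
        for lvl in reversed(range(d)):
            c_skip = b * 2**lvl
            self.ups.append(ConvTranspose2(2 * c_skip, c_skip, rng))
            self.dec.append(_ConvBlock(2 * c_skip, c_skip, rng))
        self.final = Conv2D(b, 1, k=1, pad=0, rng=rng, zero_init=True)

    # -- plumbing -----------------------------------------------------------
    @property
    def params(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            out.extend(blk.params)
        for up in self.ups:
            out.extend(up.params)
        out.extend(self.final.params)
        return out

    def _pad(self, x: np.ndarray) -> Tuple[np.ndarray, Tuple[int, int]]:
        m = 2**self.config.depth
        h = x.shape[-1]
        target = int(np.ceil(h / m)) * m
        lo = (target - h) // 2
        hi = target - h - lo
        if lo or hi:
            x = np.pad(x, ((0, 0), (0, 0), (lo, hi), (lo, hi)))
        return x, (lo, hi)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """``x`` has shape (batch, 1, H, W); returns the same shape."""
        x0 = x
        x, (lo, hi) = self._pad(x)
        self._pad_amounts = (lo, hi, x0.shape[-1])
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=1)
            self._skip_channels.append(skip.shape[1])
            x = dec.forward(x)
        x = self.final.forward(x)
        n = self._pad_amounts[2]
        if lo or hi:
            x = x[:, :, lo : lo + n, lo : lo + n]
        if self.config.residual:
            x = x + x0
        return x

    def backward(self, g: np.ndarray) -> None:
        lo, hi, n = self._pad_amounts
        if lo or hi:
            gp = np.zeros((g.shape[0], g.shape[1], n + lo + hi, n + lo + hi))
            gp[:, :, lo : lo + n, lo : lo + n] = g
            g = gp
        g = self.final.backward(g)
        g_skips = []
        for up, dec, c_skip in reversed(list(zip(self.ups, self.dec, self._skip_channels))):
            g = dec.backward(g)
            g_skip, g = g[:, :c_skip], g[:, c_skip:]
            g_skips.append(g_skip)
            g = up.backward(g)
        g = self.bottleneck.backward(g)
        # g_skips were collected shallow-to-deep; the encoder unwinds deep-to-shallow
        for pool, blk, g_skip in zip(reversed(self.pools), reversed(self.enc), reversed(g_skips)):
            g = pool.backward(g)
            g = blk.backward(g + g_skip)
        # gradient w.r.t. the input is not needed

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def correct_image(self, image: np.ndarray) -> np.ndarray:
        """Correct a single uncorrected FBP reconstruction."""
        out = self.forward(np.asarray(image, dtype=float)[None, None])
        return out[0, 0]

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        import h5py
        import json
        from dataclasses import asdict

        with h5py.File(path, "w") as f:
            grp = f.create_group("unet")
            grp.attrs["config"] = json.dumps(asdict(self.config))
            for i, (p, _) in enumerate(self.params):
                grp.create_dataset(f"param_{i:03d}", data=p)

    @classmethod
    def load(cls, path: str) -> "UNetModel":
        import h5py
        import json

        with h5py.File(path, "r") as f:
            grp = f["unet"]
            model = cls(UNetConfig(**json.loads(grp.attrs["config"])))
            for i, (p, _) in enumerate(model.params):
                p[...] = grp[f"param_{i:03d}"][...]
        return model


def unet_correct(image: np.ndarray, model: UNetModel) -> np.ndarray:
    """Functional wrapper: corrected reconstruction for one input image."""
    return model.correct_image(image)


def train_unet(
    dataset: TrainingSet,
    unet_config: Optional[UNetConfig] = None,
    train_config: Optional[TrainConfig] = None,
) -> Tuple[UNetModel, List[float]]:
    """Train the U-net on (uncorrected FBP -> ground truth) pairs.

    MAE loss, Adam, early stopping when the validation MAE has not improved
    for ``patience`` epochs; the best-validation weights are restored.
    Returns the model and the validation-MAE history (entry 0 is the
    untrained baseline).
    """
    train_config = train_config or TrainConfig()
    if len(dataset.train_idx) == 0:
        raise ValueError("empty training split")
    model = UNetModel(unet_config)
    opt = Adam(model.params, lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)

    inputs = dataset.fbp[:, None]  # (n, 1, H, W)
    targets = dataset.images[:, None]

    def val_mae() -> float:
        if len(dataset.val_idx) == 0:
            return float("nan")
        errs = []
        for i in dataset.val_idx:
            y = model.forward(inputs[i : i + 1])
            errs.append(np.mean(np.abs(y - targets[i : i + 1])))
        return float(np.mean(errs))

    history = [val_mae()]
    best = history[0]
    best_state = [p.copy() for p, _ in model.params]
    stall = 0
    for _ in range(train_config.epochs):
        order = rng.permutation(dataset.train_idx)
        for start in range(0, len(order), train_config.batch_size):
            batch = order[start : start + train_config.batch_size]
            x = inputs[batch]
            t = targets[batch]
            model.zero_grad()
            y = model.forward(x, train=True)
            g = np.sign(y - t) / y.size
            model.backward(g)
            opt.step()
        history.append(val_mae())
        if history[-1] < best - 1e-12:
            best = history[-1]
            best_state = [p.copy() for p, _ in model.params]
            stall = 0
        else:
            stall += 1
            if stall >= train_config.patience:
                break
    for (p, _), saved in zip(model.params, best_state):
        p[...] = saved
    return model, history
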