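"""Unsupervised characterization of the myocardium with a convolutional
auto-encoder (CAE).

The CAE is trained to reconstruct 2D in-plane (axial) patches centered
on myocardial voxels through a low-dimensional bottleneck; the
bottleneck vector is the per-voxel "encoding".  Encodings of all
myocardial voxels of a patient are later summarized into one feature
vector per patient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _nn
from .segmentation import _HU_CENTER, _HU_SCALE, _mirror

__all__ = [
    "ConvAutoencoder",
    "VoxelEncodingSet",
    "extract_axial_patches",
    "normalize_to_reference",
    "sample_training_patches",
    "train_autoencoder",
    "encode_lvm",
    "reconstruct",
]


@dataclass
class VoxelEncodingSet:
    """Per-voxel encodings of one patient's myocardium."""

    voxels: np.ndarray  # (n, 3) indices in (z, y, x)
    encodings: np.ndarray  # (n, encoding_dim)
    patient_id: str = ""
    model_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.encodings = np.asarray(self.encodings)
        if len(self.voxels) != len(self.encodings):
            raise ValueError("voxel and encoding counts differ")
        if len(np.unique(self.voxels, axis=0)) != len(self.voxels):
            raise ValueError("voxel indices must be unique")

    def __len__(self):
        return len(self.encodings)

    @property
    def encoding_dim(self):
        return self.encodings.shape[1]


def extract_axial_patches(volume, voxels, patch_size):
    """In-plane (fixed z) square patches around voxels, mirror-padded.

    For even patch sizes the target voxel sits at index patch_size // 2
    along each in-plane axis.
    """
    volume = np.asarray(volume, dtype=float)
    voxels = np.atleast_2d(np.asarray(voxels, dtype=int))
    half = patch_size // 2
    off = np.arange(patch_size) - half
    rows = _mirror(voxels[:, 1, None] + off[None, :], volume.shape[1])
    cols = _mirror(voxels[:, 2, None] + off[None, :], volume.shape[2])
    return volume[voxels[:, 0][:, None, None], rows[:, :, None], cols[:, None, :]]


# reference tissue levels the landmarks are mapped to (HU)
_REFERENCE_LANDMARKS = (-50.0, 100.0, 400.0)  # background, myocardium, blood pool


def normalize_to_reference(volume, mask):
    """Scan-level intensity standardization (piecewise-linear landmark map).

    Contrast enhancement and tissue attenuation vary between scans.
    Three robust intensity landmarks — the volume's 20th percentile
    (background), the median over the myocardial mask, and the 99th
    percentile (contrast-filled blood pool) — are mapped to fixed
    reference levels by a piecewise-linear transform with linear
    extrapolation beyond the outer landmarks.  Relative hypo-attenuation
    within the myocardium is preserved; between-patient intensity-level
    variation is removed.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("cannot normalize against an empty mask")
    anchors = np.array(
        [
            np.percentile(volume, 20),
            np.median(volume[mask > 0]),
            np.percentile(volume, 99),
        ]
    )
    if not np.all(np.diff(anchors) > 0):
        # degenerate histogram (e.g. constant volume): shift-only fallback
        return volume - (float(np.median(volume[mask > 0])) - _REFERENCE_LANDMARKS[1])
    ref = np.array(_REFERENCE_LANDMARKS)
    out = np.interp(volume, anchors, ref)
    lo, hi = volume < anchors[0], volume > anchors[2]
    slope_lo = (ref[1] - ref[0]) / (anchors[1] - anchors[0])
    slope_hi = (ref[2] - ref[1]) / (anchors[2] - anchors[1])
    out[lo] = ref[0] + (volume[lo] - anchors[0]) * slope_lo
    out[hi] = ref[2] + (volume[hi] - anchors[2]) * slope_hi
    return out


def sample_training_patches(
    volumes, masks, n_patches, seed, patch_size=16, normalize=True
):
    """Sample axial patches at masked voxels, pooled over patients."""
    rng = np.random.Generator(np.random.Philox(seed))
    pools = []
    for vol, mask in zip(volumes, masks):
        fg = np.argwhere(np.asarray(mask) > 0)
        if len(fg) == 0:
            continue
        vol = normalize_to_reference(vol, mask) if normalize else np.asarray(vol, float)
        pools.append((vol, fg))
    if not pools:
        raise ValueError("no masked voxels to sample from")
    per = _largest_split(n_patches, len(pools))
    out = []
    for (vol, fg), k in zip(pools, per):
        take = rng.integers(0, len(fg), size=k)
        out.append(extract_axial_patches(vol, fg[take], patch_size))
    return np.concatenate(out)


def _largest_split(total, parts):
    base = total // parts
    counts = [base] * parts
    for i in range(total - base * parts):
        counts[i] += 1
    return counts


class ConvAutoencoder(BaseEstimator, TransformerMixin):
    """Convolutional auto-encoder over myocardial patches.

    The encoder compresses a (patch_size, patch_size) patch to an
    ``encoding_dim`` vector through two conv + max-pool blocks and a
    dense bottleneck; the decoder mirrors it with dense, upsampling and
    conv layers.  transform() returns encodings, inverse_transform()
    reconstructions.
    """

    def __init__(
        self,
        patch_size=4,
        encoding_dim=8,
        conv_channels=8,
        epochs=15,
        batch_size=32,
        learning_rate=1e-3,
        random_state=0,
    ):
        self.patch_size = patch_size
        self.encoding_dim = encoding_dim
        self.conv_channels = conv_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _build(self):
        ps, c = self.patch_size, self.conv_channels
        if ps % 4 != 0:
            raise ValueError("patch_size must be divisible by 4")
        if self.encoding_dim >= ps * ps:
            raise ValueError(
                f"encoding_dim {self.encoding_dim} must be smaller than the "
                f"patch pixel count {ps * ps}: no compression"
            )
        q = ps // 4
        rng = np.random.Generator(np.random.Philox(self.random_state))
        self.encoder_ = _nn.Sequential(
            [
                _nn.Conv2D(1, c, 3, rng, padding="same"),
                _nn.ReLU(),
                _nn.MaxPool2D(2),
                _nn.Conv2D(c, c, 3, rng, padding="same"),
                _nn.ReLU(),
                _nn.MaxPool2D(2),
                _nn.Flatten(),
                _nn.Dense(c * q * q, self.encoding_dim, rng),
            ]
        )
        self.decoder_ = _nn.Sequential(
            [
                _nn.Dense(self.encoding_dim, c * q * q, rng),
                _nn.ReLU(),
                _nn.Reshape((c, q, q)),
                _nn.Upsample2D(2),
                _nn.Conv2D(c, c, 3, rng, padding="same"),
                _nn.ReLU(),
                _nn.Upsample2D(2),
                _nn.Conv2D(c, 1, 3, rng, padding="same"),
            ]
        )
        return rng

    def _prep(self, patches):
        x = (np.asarray(patches, dtype=float) - _HU_CENTER) / _HU_SCALE
        if x.ndim == 2:
            x = x[None]
        if x.shape[-2:] != (self.patch_size, self.patch_size):
            raise ValueError(
                f"patch shape {x.shape[-2:]} does not match model patch_size "
                f"{self.patch_size}"
            )
        return x.reshape(-1, 1, self.patch_size, self.patch_size)

    def fit(self, patches, y=None):
        """Train to reconstruct the given (n, ps, ps) HU patches."""
        x = self._prep(patches)
        if len(x) == 0:
            raise ValueError("at least one training patch is required")
        rng = self._build()
        params = self.encoder_.params + self.decoder_.params
        grads = self.encoder_.grads + self.decoder_.grads
        opt = _nn.Adam(params, grads, lr=self.learning_rate)
        trace = []
        for _ in range(self.epochs):
            order = rng.permutation(len(x))
            losses = []
            for start in range(0, len(x), self.batch_size):
                sel = order[start : start + self.batch_size]
                xb = x[sel]
                recon = self.decoder_.forward(self.encoder_.forward(xb))
                loss, dr = _nn.mse_loss(recon, xb)
                self.encoder_.backward(self.decoder_.backward(dr))
                opt.step()
                losses.append(loss)
            trace.append(float(np.mean(losses)))
        self.loss_trace_ = trace
        return self

    def initialize(self):
        """Build the untrained (randomly initialized) network in place.

        Used as the reference point when checking that training actually
        reduced reconstruction error.
        """
        self._build()
        self.loss_trace_ = []
        return self

    def _check_fitted(self):
        if not hasattr(self, "encoder_"):
            raise ValueError("auto-encoder is not fitted")

    def transform(self, patches):
        """Encodings, shape (n, encoding_dim)."""
        self._check_fitted()
        x = self._prep(patches)
        out = np.empty((len(x), self.encoding_dim))
        for start in range(0, len(x), 4096):
            out[start : start + 4096] = self.encoder_.forward(x[start : start + 4096])
        return out

    def inverse_transform(self, patches):
        """Reconstructions in HU, same shape as the input patches."""
        self._check_fitted()
        x = self._prep(patches)
        recon = self.decoder_.forward(self.encoder_.forward(x))
        return recon[:, 0] * _HU_SCALE + _HU_CENTER

    def reconstruction_error(self, patches):
        """Mean squared reconstruction error on normalized intensities."""
        x = self._prep(patches)
        self._check_fitted()
        err = 0.0
        for start in range(0, len(x), 4096):
            xb = x[start : start + 4096]
            recon = self.decoder_.forward(self.encoder_.forward(xb))
            err += float(np.sum((recon - xb) ** 2))
        return err / x.size

    def save(self, path):
        self._check_fitted()
        arrays = {
            f"w{i}": p for i, p in enumerate(self.encoder_.params + self.decoder_.params)
        }
        np.savez(
            path,
            config=json.dumps(self.get_params()),
            loss_trace=np.asarray(self.loss_trace_),
            **arrays,
        )

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        model = cls(**json.loads(str(data["config"])))
        model._build()
        for i, p in enumerate(model.encoder_.params + model.decoder_.params):
            p[...] = data[f"w{i}"]
        model.loss_trace_ = list(data["loss_trace"])
        return model


def train_autoencoder(patches, encoding_dim=16, **config):
    """Functional wrapper over ConvAutoencoder.fit."""
    return ConvAutoencoder(encoding_dim=encoding_dim, **config).fit(patches)


def encode_lvm(
    model: ConvAutoencoder, volume, mask, stride=1, patient_id="", normalize=True
):
    """Encode every masked voxel (or every stride-th along each axis)."""
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError(
            "empty myocardium mask: nothing to encode (did QC fail upstream?)"
        )
    if normalize:
        volume = normalize_to_reference(volume, mask)
    if stride > 1:
        lattice = np.zeros_like(mask, dtype=bool)
        lattice[::stride, ::stride, ::stride] = True
        sampled = mask.astype(bool) & lattice
        if not sampled.any():  # degenerate stride: fall back to all voxels
            sampled = mask.astype(bool)
    else:
        sampled = mask.astype(bool)
    voxels = np.argwhere(sampled)
    patches = extract_axial_patches(volume, voxels, model.patch_size)
    return VoxelEncodingSet(
        voxels=voxels,
        encodings=model.transform(patches),
        patient_id=patient_id,
        model_id=f"cae_seed{model.random_state}",
    )


def reconstruct(model: ConvAutoencoder, patch):
    """Reconstruct one patch (or a batch) through the bottleneck."""
    single = np.asarray(patch).ndim == 2
    out = model.inverse_transform(patch)
    return out[0] if single else out
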