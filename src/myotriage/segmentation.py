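"""Left-ventricular-myocardium segmentation from cardiac CT.

Voxelwise classification with a two-stream multiscale convolutional
network: every voxel is described by six 2D patches — axial, coronal and
sagittal planes through the voxel, each sampled at a fine and a coarse
scale — and the network labels the voxel myocardium or background.  A
small automated QC step mirrors the clinical practice of excluding scans
whose automatic segmentation failed.

Conventions: volumes are (z, y, x) arrays of HU, 0-based indexing, axial
= fixed z.  Samples falling outside the grid are mirror-reflected (the
border voxel is not repeated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import _nn

__all__ = [
    "PatchSpec",
    "extract_triplanar_patches",
    "extract_triplanar_batch",
    "TriplanarSegmenter",
    "train_segmenter",
    "segment_volume",
    "qc_segmentation",
]


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry: odd edge length and exactly two scales (fine, coarse)."""

    patch_edge: int = 25
    scales: tuple = (1.0, 3.0)

    def __post_init__(self):
        if self.patch_edge < 1 or self.patch_edge % 2 == 0:
            raise ValueError("patch_edge must be an odd positive integer")
        if len(self.scales) != 2:
            raise ValueError("exactly two scales (fine, coarse) are required")
        fine, coarse = self.scales
        if fine <= 0 or coarse <= fine:
            raise ValueError("scales must be positive with coarse > fine")


def _mirror(idx, n):
    """Mirror-reflect integer indices into [0, n) without edge repeat."""
    idx = np.asarray(idx)
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    m = np.mod(idx, period)
    return np.where(m < n, m, period - m)


# per plane: (fixed axis, row axis, col axis) in (z, y, x) order
_PLANES = ((0, 1, 2), (1, 0, 2), (2, 0, 1))  # axial, coronal, sagittal


def extract_triplanar_batch(volume, voxels, spec: PatchSpec):
    """Patches for many voxels at once: returns (n, 6, edge, edge).

    Channel order is (axial, coronal, sagittal) at the fine scale then
    the same three planes at the coarse scale.  Integer scales use a
    direct mirror-padded gather; non-integer scales sample each plane by
    linear interpolation over the scale-widened window.
    """
    volume = np.asarray(volume, dtype=float)
    voxels = np.atleast_2d(np.asarray(voxels, dtype=int))
    if voxels.shape[1] != 3:
        raise ValueError("voxels must be (n, 3) indices in (z, y, x) order")
    shape = volume.shape
    if np.any(voxels < 0) or np.any(voxels >= np.array(shape)):
        raise IndexError("voxel index outside the volume grid")

    p = spec.patch_edge
    r = (p - 1) // 2
    n = voxels.shape[0]
    out = np.empty((n, 6, p, p))
    for si, scale in enumerate(spec.scales):
        offsets = scale * (np.arange(p) - r)
        integral = float(scale).is_integer()
        for pi, (fax, rax, cax) in enumerate(_PLANES):
            ch = si * 3 + pi
            if integral:
                off = offsets.astype(int)
                rows = _mirror(voxels[:, rax, None] + off[None, :], shape[rax])
                cols = _mirror(voxels[:, cax, None] + off[None, :], shape[cax])
                idx = [None, None, None]
                idx[fax] = voxels[:, fax][:, None, None]
                idx[rax] = rows[:, :, None]
                idx[cax] = cols[:, None, :]
                out[:, ch] = volume[tuple(idx)]
            else:
                from scipy.ndimage import map_coordinates

                for k in range(n):
                    coords = np.zeros((3, p, p))
                    coords[fax] = voxels[k, fax]
                    coords[rax] = (voxels[k, rax] + offsets)[:, None]
                    coords[cax] = (voxels[k, cax] + offsets)[None, :]
                    out[k, ch] = map_coordinates(
                        volume, coords.reshape(3, -1), order=1, mode="mirror"
                    ).reshape(p, p)
    return out


def extract_triplanar_patches(volume, voxel, spec: PatchSpec):
    """Six triplanar patches (two scales) centered on one voxel."""
    return extract_triplanar_batch(volume, np.asarray(voxel)[None, :], spec)[0]


class _TwoStreamNet:
    """Two identical conv streams (fine / coarse scale) with a fused head."""

    def __init__(self, patch_edge, channels, hidden, rng):
        c1, c2 = channels

        def stream():
            layers = [
                _nn.Conv2D(3, c1, 3, rng),
                _nn.ReLU(),
                _nn.MaxPool2D(2),
                _nn.Conv2D(c1, c2, 3, rng),
                _nn.ReLU(),
            ]
            size = (patch_edge - 2) // 2 - 2
            if size < 1:
                raise ValueError(f"patch_edge {patch_edge} too small for the network")
            if size >= 2:
                layers.append(_nn.MaxPool2D(2))
                size //= 2
            layers.append(_nn.Flatten())
            return _nn.Sequential(layers), c2 * size * size

        self.fine, n_fine = stream()
        self.coarse, n_coarse = stream()
        self.head = _nn.Sequential(
            [
                _nn.Dense(n_fine + n_coarse, hidden, rng),
                _nn.ReLU(),
                _nn.Dense(hidden, 1, rng),
            ]
        )
        self._split = n_fine
        self.params = self.fine.params + self.coarse.params + self.head.params
        self.grads = self.fine.grads + self.coarse.grads + self.head.grads

    def forward(self, x):
        # x: (n, 6, p, p); channels 0-2 fine, 3-5 coarse
        hf = self.fine.forward(x[:, :3])
        hc = self.coarse.forward(x[:, 3:])
        return self.head.forward(np.concatenate([hf, hc], axis=1))

    def backward(self, grad):
        gh = self.head.backward(grad)
        self.fine.backward(gh[:, : self._split])
        self.coarse.backward(gh[:, self._split :])


# fixed affine intensity normalization (HU -> roughly unit scale)
_HU_CENTER, _HU_SCALE = 100.0, 200.0


class TriplanarSegmenter(BaseEstimator):
    """Voxel classifier for LVM segmentation (sklearn-style estimator).

    fit() takes lists of volumes and binary masks; predict_mask() labels
    every voxel of a new volume (optionally on a stride, filled by
    nearest lattice label) and applies morphological cleanup.
    """

    def __init__(
        self,
        patch_edge=25,
        scales=(1.0, 3.0),
        conv_channels=(8, 16),
        hidden=32,
        epochs=3,
        batch_size=64,
        samples_per_volume=2000,
        learning_rate=1e-3,
        stride=1,
        cleanup=True,
        fill_holes=False,
        random_state=0,
    ):
        self.patch_edge = patch_edge
        self.scales = scales
        self.conv_channels = conv_channels
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.samples_per_volume = samples_per_volume
        self.learning_rate = learning_rate
        self.stride = stride
        self.cleanup = cleanup
        self.fill_holes = fill_holes
        self.random_state = random_state

    @property
    def patch_spec(self):
        return PatchSpec(self.patch_edge, tuple(self.scales))

    def fit(self, volumes, masks, log_path=None):
        """Train on (volume, mask) pairs with class-balanced sampling."""
        volumes = [np.asarray(v, dtype=float) for v in volumes]
        masks = [np.asarray(m) for m in masks]
        if len(volumes) == 0 or len(volumes) != len(masks):
            raise ValueError("need matching non-empty volume and mask lists")
        if all(int(m.sum()) == 0 for m in masks):
            raise ValueError("all masks are empty: nothing to learn")

        spec = self.patch_spec
        rng = np.random.Generator(np.random.Philox(self.random_state))
        patches, labels = [], []
        per_class = self.samples_per_volume // 2
        for vol, mask in zip(volumes, masks):
            if vol.shape != mask.shape:
                raise ValueError("volume and mask grids differ")
            fg = np.argwhere(mask > 0)
            bg = np.argwhere(mask == 0)
            for pool, lab in ((fg, 1), (bg, 0)):
                if len(pool) == 0:
                    continue
                take = rng.integers(0, len(pool), size=per_class)
                patches.append(extract_triplanar_batch(vol, pool[take], spec))
                labels.append(np.full(per_class, lab))
        x = (np.concatenate(patches) - _HU_CENTER) / _HU_SCALE
        y = np.concatenate(labels)

        self.net_ = _TwoStreamNet(self.patch_edge, self.conv_channels, self.hidden, rng)
        opt = _nn.Adam(self.net_.params, self.net_.grads, lr=self.learning_rate)
        trace = []
        for _ in range(self.epochs):
            order = rng.permutation(len(y))
            losses = []
            for start in range(0, len(y), self.batch_size):
                sel = order[start : start + self.batch_size]
                z = self.net_.forward(x[sel])
                loss, dz = _nn.bce_with_logits(z, y[sel])
                self.net_.backward(dz)
                opt.step()
                losses.append(loss)
            trace.append(float(np.mean(losses)))
        self.loss_trace_ = trace
        self.n_training_voxels_ = len(y)
        if log_path is not None:
            with open(log_path, "w") as fh:
                fh.write("epoch\tloss\n")
                for e, l in enumerate(trace):
                    fh.write(f"{e}\t{l:.8f}\n")
        return self

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise ValueError("segmenter is not fitted")

    def decision_volume(self, volume):
        """Raw logits on the stride lattice; mainly for diagnostics."""
        self._check_fitted()
        volume = np.asarray(volume, dtype=float)
        s = int(self.stride)
        lattice = np.meshgrid(
            *[np.arange(0, n, s) for n in volume.shape], indexing="ij"
        )
        voxels = np.stack([g.ravel() for g in lattice], axis=1)
        spec = self.patch_spec
        logits = np.empty(len(voxels))
        for start in range(0, len(voxels), 4096):
            chunk = voxels[start : start + 4096]
            x = (extract_triplanar_batch(volume, chunk, spec) - _HU_CENTER) / _HU_SCALE
            logits[start : start + len(chunk)] = self.net_.forward(x).ravel()
        return logits.reshape([len(np.arange(0, n, s)) for n in volume.shape])

    def predict_mask(self, volume):
        """Binary LVM mask on the same grid as the input volume."""
        volume = np.asarray(volume, dtype=float)
        logits = self.decision_volume(volume)
        labels = (logits > 0).astype(np.uint8)
        s = int(self.stride)
        if s > 1:  # nearest-lattice fill
            for ax in range(3):
                labels = np.repeat(labels, s, axis=ax)
            labels = labels[tuple(slice(0, n) for n in volume.shape)]
        if self.cleanup and labels.any():
            comp, n_comp = ndimage.label(labels)
            if n_comp > 1:
                sizes = ndimage.sum_labels(labels, comp, index=np.arange(1, n_comp + 1))
                labels = (comp == (1 + int(np.argmax(sizes)))).astype(np.uint8)
            if self.fill_holes:
                # not the default: fills the ventricular cavity of closed shells
                labels = ndimage.binary_fill_holes(labels).astype(np.uint8)
        return labels

    def save(self, path):
        self._check_fitted()
        arrays = {f"w{i}": p for i, p in enumerate(self.net_.params)}
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
        rng = np.random.Generator(np.random.Philox(model.random_state))
        model.net_ = _TwoStreamNet(
            model.patch_edge, model.conv_channels, model.hidden, rng
        )
        for i, p in enumerate(model.net_.params):
            p[...] = data[f"w{i}"]
        model.loss_trace_ = list(data["loss_trace"])
        return model


def train_segmenter(volumes, masks, spec=None, **config):
    """Functional wrapper over TriplanarSegmenter.fit."""
    if spec is not None:
        config.setdefault("patch_edge", spec.patch_edge)
        config.setdefault("scales", spec.scales)
    return TriplanarSegmenter(**config).fit(volumes, masks)


def segment_volume(model: TriplanarSegmenter, volume):
    """Apply a trained segmenter; returns a {0,1} mask on the input grid."""
    return model.predict_mask(volume)


def qc_segmentation(
    mask,
    spacing,
    min_volume_ml=2.0,
    max_volume_ml=300.0,
    min_component_fraction=0.8,
):
    """Automated QC of a segmentation: (passed, list of failure reasons).

    Fails when the masked volume falls outside a plausible range or when
    the largest connected component holds less than a configured
    fraction of the masked voxels (fragmented segmentation).
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    reasons = []
    voxel_ml = float(np.prod(spacing)) / 1000.0
    vol_ml = float(mask.sum()) * voxel_ml
    if vol_ml < min_volume_ml:
        reasons.append(
            f"volume below minimum ({vol_ml:.2f} mL < {min_volume_ml} mL)"
        )
    if vol_ml > max_volume_ml:
        reasons.append(f"volume above maximum ({vol_ml:.2f} mL > {max_volume_ml} mL)")
    if mask.any():
        comp, n_comp = ndimage.label(mask)
        if n_comp > 1:
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
            frac = float(sizes.max()) / float(mask.sum())
            if frac < min_component_fraction:
                reasons.append(
                    f"largest connected component holds {frac:.2f} of masked "
                    f"voxels (< {min_component_fraction})"
                )
    return (len(reasons) == 0, reasons)
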