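"""Synthetic phantoms with dense ground truth and sparse annotations.

Phantoms emulate the inputs the interpolation engine sees in practice:
multi-object volumes in which each object has its own mean intensity on a
contrasting background, corrupted by additive Gaussian noise, with dense
integer ground-truth labels.  Sparse annotations are obtained by keeping
every k-th plane; annotator inconsistency is emulated by random
morphological boundary shifts of the kept planes.

All generators are pure functions of their spec and seed.  The default
phantom is 96x64x64 (z, y, x) — large enough for slice spacings up to
every 40th plane, small enough for quick runs — with two spheres stacked
along z, object contrast of 50 intensity units against a mid-gray
background, and noise of 10 units; these mirror typical contrast-to-noise
conditions of stained microCT material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, disk, erosion

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "two_object_phantom",
    "sparsify_labels",
    "perturb_labels",
]

GEOMETRIES = ("spheres", "nested-shells", "interlocking-slabs")


@dataclass
class PhantomSpec:
    """Recipe for a synthetic phantom.

    ``intensity_means`` lists the background mean first, then one mean per
    object, all in [0, 255].  ``noise_sd`` is additive Gaussian noise in
    intensity units.
    """

    shape: tuple[int, int, int] = (96, 64, 64)
    n_objects: int = 2
    geometry: str = "spheres"
    intensity_means: tuple[float, ...] = (120.0, 170.0, 70.0)
    noise_sd: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if len(self.intensity_means) != self.n_objects + 1:
            raise ValueError("need one intensity mean for background plus each object")
        if not all(0 <= m <= 255 for m in self.intensity_means):
            raise ValueError("intensity means must lie in [0, 255]")


def _sphere_labels(spec: PhantomSpec) -> np.ndarray:
    Z, Y, X = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int32)
    zz, yy, xx = np.ogrid[:Z, :Y, :X]
    radius = 0.8 * min(Z / (2.0 * spec.n_objects), Y / 2.0, X / 2.0)
    if radius < 2:
        raise ValueError(f"{spec.n_objects} spheres do not fit shape {spec.shape}")
    for i in range(spec.n_objects):
        cz = (i + 0.5) * Z / spec.n_objects
        cy, cx = (Y - 1) / 2.0, (X - 1) / 2.0
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        labels[d2 <= radius**2] = i + 1
    return labels


def _shell_labels(spec: PhantomSpec) -> np.ndarray:
    Z, Y, X = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int32)
    zz, yy, xx = np.ogrid[:Z, :Y, :X]
    c = ((Z - 1) / 2.0, (Y - 1) / 2.0, (X - 1) / 2.0)
    rmax = 0.9 * min(Z, Y, X) / 2.0
    if rmax / spec.n_objects < 2:
        raise ValueError(f"{spec.n_objects} shells do not fit shape {spec.shape}")
    d = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
    radii = [rmax * (spec.n_objects - i) / spec.n_objects
             for i in range(spec.n_objects)]
    for i, r in enumerate(radii):
        labels[d <= r] = i + 1
    return labels


def _slab_labels(spec: PhantomSpec) -> np.ndarray:
    Z, Y, X = spec.shape
    margin = 4
    if Z <= 2 * margin + spec.n_objects or Y <= 2 * margin or X <= 2 * margin:
        raise ValueError(f"slabs do not fit shape {spec.shape}")
    labels = np.zeros(spec.shape, dtype=np.int32)
    yy = np.arange(Y)[None, :, None]
    zz = np.arange(Z)[:, None, None]
    core = Z - 2 * margin
    # wavy interfaces along y interlock neighboring slabs
    amp = max(2.0, core / (6.0 * spec.n_objects))
    for i in range(spec.n_objects):
        lo = margin + core * i / spec.n_objects + amp * np.sin(
            2 * np.pi * yy / Y + i)
        hi = margin + core * (i + 1) / spec.n_objects + amp * np.sin(
            2 * np.pi * yy / Y + i + 1)
        mask = (zz >= lo) & (zz < hi)
        mask = np.broadcast_to(mask, spec.shape).copy()
        mask[:, :margin, :] = False
        mask[:, -margin:, :] = False
        mask[:, :, :margin] = False
        mask[:, :, -margin:] = False
        labels[mask] = i + 1
    return labels


def make_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume]:
    """Generate the intensity volume and dense ground-truth labels.

    Deterministic given ``spec.rng_seed``.  Intensities are clipped to
    [0, 255] and returned as a normalized 8-bit volume.
    """
    builder = {"spheres": _sphere_labels, "nested-shells": _shell_labels,
               "interlocking-slabs": _slab_labels}[spec.geometry]
    labels = builder(spec)
    means = np.asarray(spec.intensity_means, dtype=np.float64)
    img = means[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return (IntensityVolume(img, dtype_class="uint8"),
            LabelVolume(labels.astype(np.int32)))


def two_object_phantom(contrast: float = 50.0, noise_sd: float = 10.0,
                       rng_seed: int = 0,
                       shape: tuple[int, int, int] = (96, 64, 64)):
    """Two-sphere phantom with symmetric contrast around a mid-gray
    background: object means at 120 +/- ``contrast``."""
    spec = PhantomSpec(shape=shape, n_objects=2, geometry="spheres",
                       intensity_means=(120.0, 120.0 + contrast, 120.0 - contrast),
                       noise_sd=noise_sd, rng_seed=rng_seed)
    return make_phantom(spec)


def sparsify_labels(dense: LabelVolume, every_k: int, axis: str = "z",
                    offset: int = 0) -> LabelVolume:
    """Keep labels only on planes with index = offset (mod every_k)."""
    if every_k < 1:
        raise ValueError("every_k must be >= 1")
    ax = {"z": 0, "y": 1, "x": 2}[axis]
    out = np.zeros_like(dense.data)
    idx = np.arange(offset % every_k, dense.shape[ax], every_k)
    sl = [slice(None)] * 3
    sl[ax] = idx
    out[tuple(sl)] = dense.data[tuple(sl)]
    return LabelVolume(out, metadata=dict(dense.metadata), spacing=dense.spacing)


def perturb_labels(sparse: LabelVolume, magnitude: int,
                   rng_seed: int = 0) -> LabelVolume:
    """Emulate annotator inconsistency by random boundary shifts.

    On every annotated z-plane, each label region is independently dilated
    or eroded by a random disk of radius up to ``magnitude``; dilation only
    claims background so labels stay disjoint.  Deterministic given the
    seed; ``magnitude = 0`` is the identity.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    out = sparse.data.copy()
    if magnitude == 0:
        return LabelVolume(out, metadata=dict(sparse.metadata), spacing=sparse.spacing)
    rng = np.random.default_rng(rng_seed)
    planes = np.nonzero(np.any(sparse.data, axis=(1, 2)))[0]
    for p in planes:
        plane = out[p]
        for lab in np.unique(plane):
            if lab == 0:
                continue
            radius = int(rng.integers(1, magnitude + 1))
            grow = bool(rng.integers(0, 2))
            mask = plane == lab
            if grow:
                new = dilation(mask, footprint=disk(radius))
                plane[new & (plane == 0)] = lab
            else:
                new = erosion(mask, footprint=disk(radius))
                if new.any():  # never erase a label entirely
                    plane[mask & ~new] = 0
        out[p] = plane
    return LabelVolume(out, metadata=dict(sparse.metadata), spacing=sparse.spacing)
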