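"""Seed extraction and intensity-weighted Monte-Carlo random walks.

The method interpolates sparse slice annotations through a volume by
launching random walks from every annotated voxel (seed).  A walk moves on
the six-connected voxel grid; the probability of stepping from ``x`` to a
neighbor ``y`` is proportional to the Gaussian weight

    w(y) = exp(-(I(x0) - I(y))^2 / (2 * sigma^2)),

where ``I(x0)`` is the intensity at the walk's start position and ``sigma``
the root-mean-square deviation of the intensities in a small in-plane
window around it.  Walks therefore tend to stay in regions that look like
their seed's neighborhood.  Every visited voxel (including the start, and
the position after each step) registers one *hit* for the seed's label;
the per-label hit fields decide the segmentation by majority, with
never-hit voxels falling to background.

Seeds far from any competing label barely influence the contested
boundaries, so an adaptive mode launches fewer walks from seeds whose
101x101 in-plane surroundings contain no other label.

Walk randomness is counter-based and keyed per (base seed, seed index,
walk index): results are bit-identical across runs, independent of seed
ordering or scheduling, and invariant under z-block decomposition with
full ghost overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import maximum_filter

from . import _kernels
from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "Seed",
    "SeedSet",
    "WalkConfig",
    "HitField",
    "EmptyAnnotationError",
    "extract_seeds",
    "compute_sigma",
    "step_probabilities",
    "classify_interior",
    "run_walks",
    "run_blocks",
    "assign_labels",
]

#: neighbor order used everywhere: -z, +z, -y, +y, -x, +x
NEIGHBOR_OFFSETS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
    dtype=np.int64,
)

AXES = ("z", "y", "x")


class EmptyAnnotationError(ValueError):
    """Sparse label volume contains no nonzero voxel."""


@dataclass(frozen=True)
class Seed:
    """One annotated voxel: walk start position and its frozen weights."""

    position: tuple[int, int, int]
    label: int
    axis: str
    interior: bool
    sigma: float
    intensity: float


@dataclass
class SeedSet:
    """All seeds of a sparse annotation, in deterministic order.

    Order is lexicographic by (axis in z, y, x order; plane; row; column).
    Parallel arrays back the per-seed attributes so the walk kernels can
    consume them directly; ``seeds`` materializes :class:`Seed` objects.
    """

    positions: np.ndarray        # (n, 3) int64, (z, y, x)
    labels: np.ndarray           # (n,) int64
    axis_codes: np.ndarray       # (n,) int8 index into AXES
    sigmas: np.ndarray           # (n,) float64
    intensities: np.ndarray      # (n,) float64
    interior: np.ndarray         # (n,) bool
    annotated_planes: dict[str, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.positions.shape[0])

    @property
    def label_ids(self) -> tuple[int, ...]:
        return tuple(int(v) for v in np.unique(self.labels))

    @property
    def seeds(self) -> list[Seed]:
        return [
            Seed(
                position=tuple(int(c) for c in self.positions[i]),
                label=int(self.labels[i]),
                axis=AXES[self.axis_codes[i]],
                interior=bool(self.interior[i]),
                sigma=float(self.sigmas[i]),
                intensity=float(self.intensities[i]),
            )
            for i in range(len(self))
        ]

    def __iter__(self):
        return iter(self.seeds)


@dataclass
class WalkConfig:
    """Run-length and determinism parameters of the walk engine.

    ``norw`` walks per seed and ``sorw`` steps per walk default to the
    method's standard configuration (10 and 4000).  With ``adaptive`` on,
    interior seeds launch only ``interior_norw`` walks.  ``n_blocks`` > 1
    partitions the volume into z-slabs each extended by ``ghost`` slices;
    walks of a block are confined to its extended slab.
    """

    norw: int = 10
    sorw: int = 4000
    adaptive: bool = True
    interior_window: int = 101
    interior_norw: int = 1
    rng_seed: int = 0
    n_blocks: int = 1
    ghost: int = 100
    sigma_window: int = 3
    sigma_min: float = 1.0

    def __post_init__(self) -> None:
        if self.norw < 1 or self.sorw < 0:
            raise ValueError("norw must be >= 1 and sorw >= 0")
        if self.interior_window % 2 == 0 or self.sigma_window % 2 == 0:
            raise ValueError("windows must be odd")
        if not (1 <= self.interior_norw <= self.norw):
            raise ValueError("interior_norw must be in [1, norw]")
        if self.ghost < 0:
            raise ValueError("ghost must be >= 0")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass
class HitField:
    """Per-label hit counts, shape (n_labels, Z, Y, X).

    ``counts[i]`` is the field of label ``label_ids[i]``.  Counts are
    integers out of the walk engine and may become real-valued after
    smoothing.
    """

    counts: np.ndarray
    label_ids: tuple[int, ...]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.counts.shape[1:]

    def total_hits(self) -> int:
        return int(self.counts.sum())


def _plane_view(data: np.ndarray, axis: str, plane: int) -> np.ndarray:
    if axis == "z":
        return data[plane, :, :]
    if axis == "y":
        return data[:, plane, :]
    return data[:, :, plane]


def compute_sigma(img: IntensityVolume, position: tuple[int, int, int],
                  window: int = 3, axis: str = "z",
                  sigma_min: float = 1.0) -> float:
    """RMS deviation of the in-plane window intensities from the center.

    The window is axis-aligned within the annotated plane and clipped at
    the volume borders; the center voxel itself contributes a zero
    deviation.  The result is clamped below by ``sigma_min`` so constant
    neighborhoods behave like the uniform-walk limit.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    data = img.data
    z, y, x = position
    h = window // 2
    if axis == "z":
        plane = data[z]
        r, c = y, x
    elif axis == "y":
        plane = data[:, y, :]
        r, c = z, x
    else:
        plane = data[:, :, x]
        r, c = z, y
    win = plane[max(0, r - h): r + h + 1, max(0, c - h): c + h + 1]
    center = float(data[z, y, x])
    sig = float(np.sqrt(np.mean((win.astype(np.float64) - center) ** 2)))
    return max(sig, sigma_min)


def extract_seeds(sparse: LabelVolume, img: IntensityVolume,
                  axes=("z",), sigma_window: int = 3,
                  sigma_min: float = 1.0) -> SeedSet:
    """Collect every nonzero voxel of the sparse annotation as a seed.

    For each requested axis, every plane that contains a nonzero label
    contributes all its nonzero voxels with that axis tag; a voxel lying on
    annotated planes of several axes yields one seed per axis.  Each seed
    carries the frozen intensity at its position and the local sigma from
    :func:`compute_sigma`.  Interior flags start False; run
    :func:`classify_interior` to set them.
    """
    if sparse.shape != img.shape:
        raise ValueError(f"shape mismatch: labels {sparse.shape} vs image {img.shape}")
    axes = tuple(a for a in AXES if a in axes)
    if not axes:
        raise ValueError("axes must be a nonempty subset of {'z','y','x'}")
    if not np.any(sparse.data):
        raise EmptyAnnotationError("sparse label volume has no nonzero voxel")

    pos_chunks, lab_chunks, ax_chunks = [], [], []
    annotated: dict[str, list[int]] = {}
    for axis in axes:
        ax_i = AXES.index(axis)
        any_plane = np.any(sparse.data, axis=tuple(i for i in range(3) if i != ax_i))
        planes = [int(p) for p in np.nonzero(any_plane)[0]]
        annotated[axis] = planes
        for p in planes:
            view = _plane_view(sparse.data, axis, p)
            rr, cc = np.nonzero(view)
            n = rr.size
            pos = np.empty((n, 3), dtype=np.int64)
            if axis == "z":
                pos[:, 0] = p
                pos[:, 1] = rr
                pos[:, 2] = cc
            elif axis == "y":
                pos[:, 0] = rr
                pos[:, 1] = p
                pos[:, 2] = cc
            else:
                pos[:, 0] = rr
                pos[:, 1] = cc
                pos[:, 2] = p
            pos_chunks.append(pos)
            lab_chunks.append(view[rr, cc].astype(np.int64))
            ax_chunks.append(np.full(n, AXES.index(axis), dtype=np.int8))

    positions = np.concatenate(pos_chunks)
    labels = np.concatenate(lab_chunks)
    axis_codes = np.concatenate(ax_chunks)

    data = img.data
    intensities = data[positions[:, 0], positions[:, 1], positions[:, 2]].astype(np.float64)
    sigmas = np.empty(len(labels), dtype=np.float64)
    for i in range(len(labels)):
        sigmas[i] = compute_sigma(img, tuple(positions[i]), window=sigma_window,
                                  axis=AXES[axis_codes[i]], sigma_min=sigma_min)
    return SeedSet(
        positions=positions,
        labels=labels,
        axis_codes=axis_codes,
        sigmas=sigmas,
        intensities=intensities,
        interior=np.zeros(len(labels), dtype=bool),
        annotated_planes=annotated,
    )


def classify_interior(seeds: SeedSet, sparse: LabelVolume,
                      window: int = 101) -> SeedSet:
    """Flag seeds whose in-plane surroundings contain no competing label.

    A seed is *interior* iff, inside the ``window x window`` in-plane
    region centered on it (clipped at the borders), every nonzero voxel of
    its annotated plane carries the seed's own label.  Background does not
    break interiority — the rule exists to spot competition between
    labels.  Returns a new :class:`SeedSet` with updated flags.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    interior = np.zeros(len(seeds), dtype=bool)
    # group seeds by (axis, plane) so each plane is filtered once per label
    for ax_i, axis in enumerate(AXES):
        sel_ax = seeds.axis_codes == ax_i
        if not np.any(sel_ax):
            continue
        plane_idx = {"z": 0, "y": 1, "x": 2}[axis]
        planes = np.unique(seeds.positions[sel_ax, plane_idx])
        for p in planes:
            sel = sel_ax & (seeds.positions[:, plane_idx] == p)
            view = _plane_view(sparse.data, axis, int(p))
            for lab in np.unique(seeds.labels[sel]):
                other = (view != 0) & (view != lab)
                if not other.any():
                    competitor_near = None  # whole plane is clean
                else:
                    competitor_near = maximum_filter(
                        other.astype(np.uint8), size=window, mode="constant", cval=0
                    )
                sl = sel & (seeds.labels == lab)
                if competitor_near is None:
                    interior[sl] = True
                else:
                    if axis == "z":
                        rr, cc = seeds.positions[sl, 1], seeds.positions[sl, 2]
                    elif axis == "y":
                        rr, cc = seeds.positions[sl, 0], seeds.positions[sl, 2]
                    else:
                        rr, cc = seeds.positions[sl, 0], seeds.positions[sl, 1]
                    interior[sl] = competitor_near[rr, cc] == 0
    return replace(seeds, interior=interior)


def step_probabilities(img: IntensityVolume, seed: Seed,
                       x: tuple[int, int, int]) -> np.ndarray:
    """Transition probabilities to the six neighbors of ``x``.

    Order: (-z, +z, -y, +y, -x, +x).  Neighbors outside the volume get
    probability 0; the remaining Gaussian weights are normalized to sum
    to 1.
    """
    data = img.data
    shape = data.shape
    i0 = float(seed.intensity)
    inv = 1.0 / (2.0 * seed.sigma ** 2)
    w = np.zeros(6, dtype=np.float64)
    for j, off in enumerate(NEIGHBOR_OFFSETS):
        n = (x[0] + off[0], x[1] + off[1], x[2] + off[2])
        if all(0 <= n[k] < shape[k] for k in range(3)):
            d = i0 - float(data[n])
            w[j] = np.exp(-d * d * inv)
    total = w.sum()
    if total == 0.0:
        raise ValueError("degenerate geometry: no valid neighbor (1x1x1 volume?)")
    return w / total


def _walks_per_seed(seeds: SeedSet, cfg: WalkConfig) -> np.ndarray:
    n = np.full(len(seeds), cfg.norw, dtype=np.int64)
    if cfg.adaptive:
        n[seeds.interior] = cfg.interior_norw
    return n


def expected_total_hits(seeds: SeedSet, cfg: WalkConfig) -> int:
    """Exact hit budget: sum over seeds of walks(seed) * (sorw + 1)."""
    return int(_walks_per_seed(seeds, cfg).sum() * (cfg.sorw + 1))


def _validate_run(img: IntensityVolume, seeds: SeedSet) -> None:
    if len(seeds) == 0:
        raise EmptyAnnotationError("empty seed set")
    if np.any(seeds.labels == 0):
        raise ValueError("label id 0 cannot seed walks")
    if img.dtype_class not in ("uint8", "float-rescaled"):
        raise ValueError("image must be normalized (see normalize_intensities)")
    if all(s == 1 for s in img.shape):
        raise ValueError("degenerate geometry: 1x1x1 volume")


def _launch(img: IntensityVolume, seeds: SeedSet, cfg: WalkConfig,
            sel: np.ndarray, counts: np.ndarray,
            lab_to_idx: dict[int, int], zlo: int, zhi: int) -> None:
    idx = np.nonzero(sel)[0]
    if idx.size == 0:
        return
    pos = np.ascontiguousarray(seeds.positions[idx])
    gidx = idx.astype(np.int64)
    lab_idx = np.array([lab_to_idx[int(v)] for v in seeds.labels[idx]], dtype=np.int64)
    i0 = seeds.intensities[idx].astype(np.float64)
    sigma = seeds.sigmas[idx].astype(np.float64)
    nwalks = _walks_per_seed(seeds, cfg)[idx]
    base = np.uint64(cfg.rng_seed)
    if img.data.dtype == np.uint8:
        _kernels.walk_hits_u8(img.data, pos, gidx, lab_idx, i0, sigma, nwalks,
                              cfg.sorw, base, counts, zlo, zhi)
    else:
        _kernels.walk_hits_f32(img.data.astype(np.float32), pos, gidx, lab_idx,
                               i0, sigma, nwalks, cfg.sorw, base, counts,
                               zlo, zhi)


def run_walks(img: IntensityVolume, seeds: SeedSet,
              cfg: WalkConfig | None = None) -> HitField:
    """Launch all walks and accumulate the per-label hit fields.

    Each seed launches ``cfg.norw`` walks (``cfg.interior_norw`` if
    adaptive and interior) of exactly ``cfg.sorw`` steps, with the seed's
    frozen intensity and sigma.  Deterministic: keyed, counter-based RNG
    makes the result bit-identical across runs.
    """
    cfg = cfg or WalkConfig()
    _validate_run(img, seeds)
    labels = seeds.label_ids
    lab_to_idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels),) + img.shape, dtype=np.int64)
    _launch(img, seeds, cfg, np.ones(len(seeds), dtype=bool), counts,
            lab_to_idx, 0, img.shape[0])
    return HitField(counts=counts, label_ids=labels)


def run_blocks(img: IntensityVolume, seeds: SeedSet,
               cfg: WalkConfig) -> HitField:
    """Sequential z-block decomposition with ghost overlap.

    The volume is split into ``cfg.n_blocks`` near-equal z-slabs, each
    extended by ``cfg.ghost`` slices on both sides.  A block runs the walks
    of the seeds whose position lies in its core slab, confined to the
    extended slab (its edges clip like volume borders); per-label hits in
    the overlaps accumulate into the shared field.  With ``n_blocks=1`` or
    full ghost overlap this equals :func:`run_walks` exactly.
    """
    _validate_run(img, seeds)
    Z = img.shape[0]
    if cfg.n_blocks > Z:
        raise ValueError(f"n_blocks={cfg.n_blocks} exceeds z-extent {Z}")
    labels = seeds.label_ids
    lab_to_idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels),) + img.shape, dtype=np.int64)
    bounds = np.linspace(0, Z, cfg.n_blocks + 1).astype(int)
    for b in range(cfg.n_blocks):
        b0, b1 = int(bounds[b]), int(bounds[b + 1])
        zlo = max(0, b0 - cfg.ghost)
        zhi = min(Z, b1 + cfg.ghost)
        sel = (seeds.positions[:, 0] >= b0) & (seeds.positions[:, 0] < b1)
        _launch(img, seeds, cfg, sel, counts, lab_to_idx, zlo, zhi)
    return HitField(counts=counts, label_ids=labels)


def assign_labels(hits: HitField) -> LabelVolume:
    """Majority vote over the hit fields.

    Per voxel the label with the most hits wins; voxels never hit fall to
    background (0); ties break towards the smallest label id.
    """
    if hits.counts.shape[0] == 0:
        raise ValueError("empty hit field")
    best = np.argmax(hits.counts, axis=0)  # first occurrence = smallest id
    maxval = np.max(hits.counts, axis=0)
    ids = np.asarray(hits.label_ids, dtype=np.int64)
    out = ids[best]
    out[maxval <= 0] = 0
    return LabelVolume(out)
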