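"""Segmentation evaluation: Dice, average surface distance, twofold CV.

Dice aggregates all nonzero labels in a single quotient,

    Dice = 2 * sum_i |X_i ∩ X'_i| / (|X| + |X'|),

with |X| the number of *labeled* voxels, so background never inflates the
score.  The average surface distance (ASD) measures, for every boundary
point of the reference annotation (2D four-neighbor boundaries on its
annotated planes), the Euclidean distance to the nearest surface voxel of
the same label in the result (3D six-neighbor surface), averaged over all
boundary points.  A label present in the reference but missing from the
result is *lost*: ASD is then undefined and the lost-label count reported
instead.

The twofold cross-validation protocol splits the annotated planes into
two alternating sets A and B, interpolates from A, scores on B, and vice
versa; the mean of the two fold scores is the CV accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volumes import LabelVolume

__all__ = [
    "MetricsReport",
    "SliceSplit",
    "dice",
    "asd",
    "twofold_cv",
    "boundary_points_2d",
    "surface_voxels",
]


@dataclass
class MetricsReport:
    """One evaluation: Dice in [0,1], ASD in voxel units (None when any
    reference label is lost), and the lost-label count."""

    dice: float | None = None
    asd: float | None = None
    lost_labels: int = 0
    fold: str | None = None

    def to_dict(self) -> dict:
        return {"dice": self.dice, "asd": self.asd,
                "lost_labels": self.lost_labels, "fold": self.fold}


@dataclass
class SliceSplit:
    """Alternating partition of the annotated planes."""

    set_a: tuple[int, ...]
    set_b: tuple[int, ...]

    @classmethod
    def from_planes(cls, planes) -> "SliceSplit":
        planes = sorted(int(p) for p in planes)
        return cls(set_a=tuple(planes[::2]), set_b=tuple(planes[1::2]))


def _restrict(data: np.ndarray, planes) -> np.ndarray:
    idx = np.asarray(sorted(planes), dtype=np.int64)
    return data[idx]


def dice(x: LabelVolume, y: LabelVolume, restrict=None) -> float:
    """Multi-label Dice coefficient over nonzero labels.

    ``restrict``, if given, limits both volumes to those z-planes (used to
    score against held-out annotated slices).  Symmetric; 1 iff the
    labeled supports coincide label by label.
    """
    if x.shape != y.shape:
        raise ValueError("volumes must share a shape")
    a, b = x.data, y.data
    if restrict is not None:
        a, b = _restrict(a, restrict), _restrict(b, restrict)
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na + nb == 0:
        raise ValueError("Dice undefined: both volumes carry no labels")
    inter = int(np.count_nonzero((a == b) & (a != 0)))
    return 2.0 * inter / (na + nb)


def _boundary_2d(plane: np.ndarray, lab: int) -> np.ndarray:
    """In-plane 4-neighbor boundary mask of ``lab``; voxels at the plane
    edge count as boundary."""
    mask = plane == lab
    if not mask.any():
        return np.zeros_like(mask)
    inner = np.zeros_like(mask)
    inner[1:-1, 1:-1] = (
        mask[1:-1, 1:-1]
        & mask[:-2, 1:-1] & mask[2:, 1:-1]
        & mask[1:-1, :-2] & mask[1:-1, 2:]
        & (plane[:-2, 1:-1] == lab) & (plane[2:, 1:-1] == lab)
        & (plane[1:-1, :-2] == lab) & (plane[1:-1, 2:] == lab)
    )
    return mask & ~inner


def boundary_points_2d(reference: LabelVolume, lab: int,
                       planes=None) -> np.ndarray:
    """(n, 3) coordinates of the in-plane boundary points of ``lab`` on
    the reference's annotated z-planes."""
    if planes is None:
        planes = [int(p) for p in
                  np.nonzero(np.any(reference.data, axis=(1, 2)))[0]]
    pts = []
    for p in planes:
        bmask = _boundary_2d(reference.data[int(p)], lab)
        rr, cc = np.nonzero(bmask)
        if rr.size:
            coords = np.empty((rr.size, 3), dtype=np.int64)
            coords[:, 0] = int(p)
            coords[:, 1] = rr
            coords[:, 2] = cc
            pts.append(coords)
    if not pts:
        return np.empty((0, 3), dtype=np.int64)
    return np.concatenate(pts)


def surface_voxels(result: LabelVolume, lab: int) -> np.ndarray:
    """(n, 3) coordinates of the 3D surface voxels of ``lab``: labeled
    voxels with at least one six-neighbor of a different value (volume
    borders count as different)."""
    mask = result.data == lab
    if not mask.any():
        return np.empty((0, 3), dtype=np.int64)
    inner = np.zeros_like(mask)
    inner[1:-1, 1:-1, 1:-1] = (
        mask[1:-1, 1:-1, 1:-1]
        & mask[:-2, 1:-1, 1:-1] & mask[2:, 1:-1, 1:-1]
        & mask[1:-1, :-2, 1:-1] & mask[1:-1, 2:, 1:-1]
        & mask[1:-1, 1:-1, :-2] & mask[1:-1, 1:-1, 2:]
    )
    surf = mask & ~inner
    return np.argwhere(surf).astype(np.int64)


def asd(reference: LabelVolume, result: LabelVolume) -> MetricsReport:
    """Average surface distance from reference boundaries to the result.

    The reference is expected to carry labels only on its annotated
    z-planes.  For each label, in-plane boundary points are matched to the
    nearest 3D surface voxel of the same label in the result; distances
    are Euclidean in voxel units.  Any reference label with no surface in
    the result makes ASD undefined and increments ``lost_labels``.
    """
    if reference.shape != result.shape:
        raise ValueError("volumes must share a shape")
    ref_labels = reference.label_ids
    if not ref_labels:
        raise ValueError("empty reference annotation")
    planes = [int(p) for p in np.nonzero(np.any(reference.data, axis=(1, 2)))[0]]
    lost = 0
    total_d = 0.0
    total_n = 0
    for lab in ref_labels:
        bpts = boundary_points_2d(reference, lab, planes=planes)
        if bpts.shape[0] == 0:
            continue
        spts = surface_voxels(result, lab)
        if spts.shape[0] == 0:
            lost += 1
            continue
        d, _ = cKDTree(spts).query(bpts, k=1)
        total_d += float(np.sum(d))
        total_n += bpts.shape[0]
    if lost > 0:
        return MetricsReport(asd=None, lost_labels=lost)
    return MetricsReport(asd=total_d / total_n if total_n else 0.0, lost_labels=0)


def _keep_planes(sparse: LabelVolume, planes) -> LabelVolume:
    out = np.zeros_like(sparse.data)
    for p in planes:
        out[int(p)] = sparse.data[int(p)]
    return LabelVolume(out, metadata=dict(sparse.metadata), spacing=sparse.spacing)


def twofold_cv(sparse: LabelVolume, engine, img) -> dict:
    """Twofold slice cross-validation of an interpolation engine.

    ``engine(img, sparse_subset) -> LabelVolume`` is interpolated from the
    planes of set A and scored (Dice restricted to set B's planes, plus
    ASD against set B's annotation), then the roles swap.  Returns the two
    fold reports and their mean Dice/ASD.
    """
    planes = [int(p) for p in np.nonzero(np.any(sparse.data, axis=(1, 2)))[0]]
    if len(planes) < 2:
        raise ValueError("twofold CV needs at least 2 annotated planes")
    split = SliceSplit.from_planes(planes)
    reports = []
    for name, train, test in (("A->B", split.set_a, split.set_b),
                              ("B->A", split.set_b, split.set_a)):
        train_lv = _keep_planes(sparse, train)
        test_lv = _keep_planes(sparse, test)
        result = engine(img, train_lv)
        d = dice(result, test_lv, restrict=test)
        rep = asd(test_lv, result)
        rep.dice = d
        rep.fold = name
        reports.append(rep)
    mean_dice = float(np.mean([r.dice for r in reports]))
    asds = [r.asd for r in reports]
    mean_asd = float(np.mean(asds)) if all(a is not None for a in asds) else None
    return {"folds": reports, "mean_dice": mean_dice, "mean_asd": mean_asd,
            "split": split}
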