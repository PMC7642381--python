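"""End-to-end interpolation pipeline tying the modules together."""

from __future__ import annotations

import time

import numpy as np

from .engine import (
    EmptyAnnotationError,
    WalkConfig,
    assign_labels,
    classify_interior,
    extract_seeds,
    run_blocks,
    run_walks,
)
from .postprocess import (
    SmoothingConfig,
    active_contour_refine,
    compute_uncertainty,
    fill_holes,
    remove_outliers,
    smooth_hits,
)
from .volumes import IntensityVolume, LabelVolume, normalize_intensities

__all__ = ["interpolate", "augment_background"]


def _restore_annotation(result: LabelVolume, sparse: LabelVolume) -> LabelVolume:
    out = result.data.copy()
    mask = sparse.data != 0
    out[mask] = sparse.data[mask]
    return LabelVolume(out, metadata=dict(result.metadata), spacing=result.spacing)


def augment_background(sparse: LabelVolume, axes=("z",)) -> tuple[LabelVolume, int]:
    """Make the background of every annotated plane an explicit label.

    A pre-segmented plane is fully segmented: whatever the annotator left
    unlabeled there *is* background, and its voxels must seed walks of
    their own — otherwise walks escaping an object would claim the empty
    space around it unopposed.  Returns the augmented annotation and the
    temporary background label id (max existing id + 1), which the caller
    maps back to 0 after assignment.
    """
    ids = sparse.label_ids
    if not ids:
        raise EmptyAnnotationError("cannot augment an empty annotation")
    bg = max(ids) + 1
    out = sparse.data.copy()
    ax_index = {"z": 0, "y": 1, "x": 2}
    for axis in axes:
        ax = ax_index[axis]
        planes = np.nonzero(
            np.any(sparse.data, axis=tuple(i for i in range(3) if i != ax))
        )[0]
        sl = [slice(None)] * 3
        sl[ax] = planes
        view = out[tuple(sl)]
        view[view == 0] = bg
        out[tuple(sl)] = view
    return LabelVolume(out, metadata=dict(sparse.metadata),
                       spacing=sparse.spacing), bg


def _strip_background(lv: LabelVolume, bg: int) -> LabelVolume:
    out = lv.data.copy()
    out[out == bg] = 0
    return LabelVolume(out, metadata=dict(lv.metadata), spacing=lv.spacing)


def interpolate(
    img: IntensityVolume,
    sparse: LabelVolume,
    cfg: WalkConfig | None = None,
    axes=("z",),
    smooth: SmoothingConfig | None = None,
    uncertainty: bool = False,
    clean: bool = False,
    outlier_threshold: float = 0.9,
    hole_threshold: float = 0.9,
    refine: int = 0,
    strict_seeds: bool = False,
    background_seeds: bool = True,
) -> dict:
    """Interpolate a sparse slice annotation through the volume.

    Runs normalization, seed extraction, interior classification, the
    Monte-Carlo walks, and majority assignment; optional stages add the
    smoothed assignment, the uncertainty map, outlier/hole cleanup of the
    raw assignment, and active-contour refinement.  ``strict_seeds``
    restores the input labels on the annotated voxels (by default the
    walks may adjust inaccurately pre-segmented slices).

    With ``background_seeds`` (the default), the unlabeled voxels of each
    annotated plane seed an explicit background label that competes with
    the object labels and is mapped back to 0 in every returned label
    volume; see :func:`augment_background`.

    Returns a dict with the computed artifacts and per-stage timings.
    """
    if img.shape != sparse.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs labels {sparse.shape}")
    cfg = cfg or WalkConfig()
    timings: dict[str, float] = {}
    out: dict = {"timings": timings}

    t0 = time.perf_counter()
    norm = normalize_intensities(img)
    timings["normalize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    bg_label = None
    seed_source = sparse
    if background_seeds:
        seed_source, bg_label = augment_background(sparse, axes=axes)
        out["background_label"] = bg_label
    seeds = extract_seeds(seed_source, norm, axes=axes,
                          sigma_window=cfg.sigma_window, sigma_min=cfg.sigma_min)
    if cfg.adaptive:
        seeds = classify_interior(seeds, seed_source, window=cfg.interior_window)
    out["seeds"] = seeds
    timings["seeds"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if cfg.n_blocks > 1:
        hits = run_blocks(norm, seeds, cfg)
    else:
        hits = run_walks(norm, seeds, cfg)
    out["hits"] = hits
    timings["walks"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    labels = assign_labels(hits)
    if bg_label is not None:
        labels = _strip_background(labels, bg_label)
    if strict_seeds:
        labels = _restore_annotation(labels, sparse)
    labels.metadata.update(sparse.metadata)
    out["labels"] = labels
    timings["assign"] = time.perf_counter() - t0

    if smooth is not None:
        t0 = time.perf_counter()
        sm = smooth_hits(hits, smooth)
        sm_labels = assign_labels(sm)
        if bg_label is not None:
            sm_labels = _strip_background(sm_labels, bg_label)
        if strict_seeds:
            sm_labels = _restore_annotation(sm_labels, sparse)
        sm_labels.metadata.update(sparse.metadata)
        out["smoothed_hits"] = sm
        out["smoothed_labels"] = sm_labels
        timings["smooth"] = time.perf_counter() - t0

    if uncertainty:
        t0 = time.perf_counter()
        out["uncertainty"] = compute_uncertainty(hits)
        timings["uncertainty"] = time.perf_counter() - t0

    if clean:
        t0 = time.perf_counter()
        cleaned = remove_outliers(labels, threshold=outlier_threshold)
        cleaned = fill_holes(cleaned, threshold=hole_threshold)
        out["cleaned_labels"] = cleaned
        timings["clean"] = time.perf_counter() - t0

    if refine > 0:
        t0 = time.perf_counter()
        base = out.get("cleaned_labels", labels)
        out["refined_labels"] = active_contour_refine(norm, base, n_iter=refine)
        timings["refine"] = time.perf_counter() - t0

    return out
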