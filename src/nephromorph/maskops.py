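"""Compilation of independent one-vs-all structure masks into one segmentation.

Renal biopsy structures (glomeruli, tubules, peritubular capillaries,
arteries/veins, cortex/medulla) are segmented by independent per-class
models, so their binary masks may disagree: the same pixel can be claimed
by several classes, and spurious small objects survive segmentation.
This module quantifies those overlaps for QA, removes objects below a
per-class minimum area, resolves contested pixels by a configurable class
priority, and restricts the analysis to the cortex.

The most common segmentation error in this tissue — peritubular
capillaries (PTC) "detected" inside glomeruli — is corrected by removing
any PTC object whose area lies mostly within the glomerular mask.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import measure

#: Structure classes on the shared grid.
STRUCTURE_CLASSES = ("cortex", "medulla", "glomeruli", "tubules", "ptc", "arteries_veins")

#: Classes that receive a label in the compiled raster (cortex/medulla are the domain).
LABELED_CLASSES = ("glomeruli", "arteries_veins", "tubules", "ptc")

#: Compiled-label ids. 0 = residual cortex (interstitium candidate), -1 = outside cortex.
LABEL_IDS = {"glomeruli": 1, "arteries_veins": 2, "tubules": 3, "ptc": 4}
RESIDUAL = 0
OUTSIDE = -1


class MaskShapeError(ValueError):
    """Raised when per-class rasters do not share a common grid."""


@dataclass
class ClassMaskSet:
    """Per-class binary rasters from independent one-vs-all segmenters.

    Masks may overlap; compilation resolves them. All rasters share one
    shape and one physical pixel size.
    """

    masks: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise MaskShapeError(f"masks have inconsistent shapes: {sorted(shapes)}")
        for name, m in self.masks.items():
            if m.dtype != bool:
                self.masks[name] = m.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def get(self, name: str) -> np.ndarray:
        if name in self.masks:
            return self.masks[name]
        return np.zeros(self.shape, dtype=bool)


@dataclass
class ClassConfig:
    """Minimum object areas (μm²), class priority and resolution options.

    The per-class minimum areas default to the object-size floors used when
    segmenting each structure (glomeruli 500 μm², PTC 40 μm², tubules
    200 μm², arteries/veins and cortex/medulla 1000 μm²). Priority is a
    total order over structure classes used for contested pixels.
    """

    min_area_um2: dict[str, float] = field(
        default_factory=lambda: {
            "glomeruli": 500.0,
            "ptc": 40.0,
            "tubules": 200.0,
            "arteries_veins": 1000.0,
            "cortex": 1000.0,
            "medulla": 1000.0,
        }
    )
    priority: tuple[str, ...] = ("glomeruli", "arteries_veins", "tubules", "ptc")
    connectivity: int = 2  # skimage connectivity: 2 = 8-connected
    ptc_in_glom_threshold: float = 0.5
    ptc_in_glom_mode: str = "remove"  # "remove" whole objects or "trim" pixels

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.min_area_um2.values()):
            raise ValueError("minimum areas must be >= 0")
        if len(set(self.priority)) != len(self.priority):
            raise ValueError("priority must not repeat classes")
        if self.ptc_in_glom_mode not in ("remove", "trim"):
            raise ValueError("ptc_in_glom_mode must be 'remove' or 'trim'")


@dataclass
class CompiledSegmentation:
    """Single-label raster after priority resolution, restricted to cortex.

    labels: one class id per pixel (see LABEL_IDS); 0 marks residual cortex
    (candidate interstitium), -1 marks pixels outside the cortex.
    """

    labels: np.ndarray
    pixel_size_um: float
    cortex: np.ndarray
    overlap_report: pd.DataFrame
    removed_small: dict[str, int]
    removed_ptc_in_glom: int
    tubule_table: pd.DataFrame
    glomerulus_table: pd.DataFrame

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_IDS[name]

    def to_mask_set(self) -> ClassMaskSet:
        """Re-expand compiled labels into per-class masks (for idempotence checks)."""
        masks = {name: self.class_mask(name) for name in LABELED_CLASSES}
        masks["cortex"] = self.cortex.copy()
        masks["medulla"] = np.zeros_like(self.cortex)
        return ClassMaskSet(masks=masks, pixel_size_um=self.pixel_size_um)


def filter_small_objects(
    mask_set: ClassMaskSet, config: ClassConfig | None = None
) -> tuple[ClassMaskSet, dict[str, int]]:
    """Drop connected components below the per-class minimum area.

    Components are defined with ``config.connectivity`` (8-connected by
    default); the area comparison is inclusive, i.e. an object of exactly
    the minimum area is retained. Returns the filtered mask set and the
    number of removed objects per class.
    """
    config = config or ClassConfig()
    px_area = mask_set.pixel_area_um2
    removed: dict[str, int] = {}
    out: dict[str, np.ndarray] = {}
    for name, mask in mask_set.masks.items():
        thr = config.min_area_um2.get(name, 0.0)
        if thr <= 0 or not mask.any():
            out[name] = mask.copy()
            removed[name] = 0
            continue
        lab = measure.label(mask, connectivity=config.connectivity)
        counts = np.bincount(lab.ravel())
        # counts[0] is background; object kept iff area_um2 >= threshold
        keep = counts * px_area >= thr
        keep[0] = False
        out[name] = keep[lab]
        removed[name] = int((~keep[1:] & (counts[1:] > 0)).sum())
    return ClassMaskSet(masks=out, pixel_size_um=mask_set.pixel_size_um), removed


def report_overlaps(mask_set: ClassMaskSet) -> pd.DataFrame:
    """Pairwise intersection areas (μm²) between all class masks.

    Returned as a symmetric class-by-class matrix; the diagonal holds each
    class's own area. Used as segmentation QA before resolution.
    """
    names = sorted(mask_set.masks)
    px_area = mask_set.pixel_area_um2
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        mat.loc[a, a] = float(mask_set.masks[a].sum()) * px_area
    for a, b in itertools.combinations(names, 2):
        inter = float((mask_set.masks[a] & mask_set.masks[b]).sum()) * px_area
        mat.loc[a, b] = inter
        mat.loc[b, a] = inter
    return mat


def _object_table(mask: np.ndarray, pixel_size_um: float, connectivity: int) -> pd.DataFrame:
    lab = measure.label(mask, connectivity=connectivity)
    rows = []
    for p in measure.regionprops(lab):
        rows.append(
            {
                "object_id": p.label,
                "area_um2": p.area * pixel_size_um**2,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
            }
        )
    return pd.DataFrame(rows, columns=["object_id", "area_um2", "centroid_row", "centroid_col"])


def resolve_overlaps(
    mask_set: ClassMaskSet, config: ClassConfig | None = None
) -> CompiledSegmentation:
    """Compile per-class masks into one labeled raster.

    Steps, in order:

    1. cortex restriction — a cortex mask is mandatory; pixels claimed by
       both cortex and medulla count as cortex, remaining medulla pixels
       are excluded from all downstream areas;
    2. PTC error correction — any PTC object with more than
       ``ptc_in_glom_threshold`` of its area inside the glomerular mask is
       removed entirely (or trimmed pixel-wise in "trim" mode);
    3. priority resolution — each contested pixel goes to the
       highest-priority class claiming it;
    4. object tables for tubules and glomeruli are built from the final
       labels.

    Masks are assumed to be min-area filtered already (see
    :func:`filter_small_objects`).
    """
    config = config or ClassConfig()
    if "cortex" not in mask_set.masks:
        raise ValueError("cortex mask is required: analysis is restricted to cortex")
    cortex = mask_set.masks["cortex"].astype(bool)

    overlap = report_overlaps(mask_set)

    glom = mask_set.get("glomeruli")
    ptc = mask_set.get("ptc").copy()
    removed_ptc = 0
    if ptc.any() and glom.any():
        lab = measure.label(ptc, connectivity=config.connectivity)
        if config.ptc_in_glom_mode == "trim":
            before = measure.label(ptc, connectivity=config.connectivity).max()
            ptc &= ~glom
            after = measure.label(ptc, connectivity=config.connectivity).max()
            removed_ptc = int(before - after)
        else:
            total = np.bincount(lab.ravel())
            inside = np.bincount(lab[glom].ravel(), minlength=total.size)
            frac = np.zeros_like(total, dtype=float)
            np.divide(inside, total, out=frac, where=total > 0)
            drop = frac > config.ptc_in_glom_threshold
            drop[0] = False
            removed_ptc = int(drop.sum())
            ptc[drop[lab]] = False

    working = {name: mask_set.get(name) for name in LABELED_CLASSES}
    working["ptc"] = ptc

    labels = np.full(mask_set.shape, RESIDUAL, dtype=np.int16)
    assigned = np.zeros(mask_set.shape, dtype=bool)
    for name in config.priority:
        take = working[name] & ~assigned
        labels[take] = LABEL_IDS[name]
        assigned |= take
    labels[~cortex] = OUTSIDE

    tub_table = _object_table(labels == LABEL_IDS["tubules"], mask_set.pixel_size_um, config.connectivity)
    glom_table = _object_table(
        labels == LABEL_IDS["glomeruli"], mask_set.pixel_size_um, config.connectivity
    )

    return CompiledSegmentation(
        labels=labels,
        pixel_size_um=mask_set.pixel_size_um,
        cortex=cortex,
        overlap_report=overlap,
        removed_small={},
        removed_ptc_in_glom=removed_ptc,
        tubule_table=tub_table,
        glomerulus_table=glom_table,
    )


def compile_masks(
    mask_set: ClassMaskSet, config: ClassConfig | None = None
) -> CompiledSegmentation:
    """Full compilation: min-area filtering followed by overlap resolution."""
    config = config or ClassConfig()
    filtered, removed = filter_small_objects(mask_set, config)
    seg = resolve_overlaps(filtered, config)
    return replace(seg, removed_small=removed)
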