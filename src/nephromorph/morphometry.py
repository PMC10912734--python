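"""Tubulointerstitial morphometry from a compiled segmentation.

After the glomeruli, tubules, peritubular capillaries and vessels are
removed from the cortex, the residual tissue is taken to be the
interstitium. Tubular sub-compartments (lumen / epithelial cell mass /
nuclei) and interstitial phases (fibrillary collagen / non-fibrillary
matrix) are quantified either directly from ground-truth sub-compartment
labels (label mode) or from an RGB render of the stained section by
nearest-reference-color classification (color mode).

The cortical tubulointerstitial area (CTA) is defined additively as the
sum of the five compartment areas — tubular lumen, tubular cell mass,
peritubular capillaries, fibrillary collagen and non-fibrillary matrix —
so the five CTA-relative percentages sum to 100 by construction. A
subtractive cross-check (cortex minus glomeruli minus vessels) is
provided for QA only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .maskops import LABEL_IDS, RESIDUAL, CompiledSegmentation
from .synthetic import Compartment

#: CSV column order for the feature table (seven indicators + QA columns).
FEATURE_COLUMNS = [
    "case_id",
    "tLumen%",
    "tCell%",
    "iMatrix%",
    "iColl%",
    "ptc%",
    "tSize",
    "tCellDen",
    "CTA",
    "GlomN",
]

#: The seven morphometry indicators entering multivariate analysis.
FEATURES_7 = ["tLumen%", "tCell%", "iMatrix%", "iColl%", "ptc%", "tSize", "tCellDen"]


@dataclass
class CompartmentAreas:
    """Areas in μm² of the tubulointerstitial compartments of one case."""

    lumen: float
    tubule_cell: float
    ptc: float
    collagen: float
    matrix: float
    nucleus_count: int

    @property
    def cta_um2(self) -> float:
        return self.lumen + self.tubule_cell + self.ptc + self.collagen + self.matrix

    @property
    def tubular_um2(self) -> float:
        return self.lumen + self.tubule_cell


@dataclass
class FeatureRecord:
    """The seven tubulointerstitial indicators plus sampling covariates.

    The five percentage fields are fractions of CTA and sum to 100;
    ``tsize`` is the mean area per tubule instance (μm²) and ``tcellden``
    the density of tubular nuclei per mm² of tubular area.
    """

    case_id: str
    tlumen_pct: float
    tcell_pct: float
    imatrix_pct: float
    icoll_pct: float
    ptc_pct: float
    tsize: float | None
    tcellden: float | None
    cta_mm2: float
    glom_n: int
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "case_id": self.case_id,
            "tLumen%": self.tlumen_pct,
            "tCell%": self.tcell_pct,
            "iMatrix%": self.imatrix_pct,
            "iColl%": self.icoll_pct,
            "ptc%": self.ptc_pct,
            "tSize": self.tsize,
            "tCellDen": self.tcellden,
            "CTA": self.cta_mm2,
            "GlomN": self.glom_n,
        }


def records_to_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    """Feature table with the canonical column names, one row per case."""
    return pd.DataFrame([r.as_row() for r in records], columns=FEATURE_COLUMNS)


@dataclass
class SamplingCriteria:
    """Biopsy adequacy rules: minimum glomeruli and minimum CTA.

    Defaults are the internal-cohort rules (≥5 glomeruli, ≥4 mm² CTA);
    ``SamplingCriteria.external()`` relaxes CTA to 3 mm² for sections with
    less tissue.
    """

    min_glomeruli: int = 5
    min_cta_mm2: float = 4.0

    def __post_init__(self) -> None:
        if self.min_glomeruli < 0 or self.min_cta_mm2 < 0:
            raise ValueError("sampling criteria must be >= 0")

    @classmethod
    def external(cls) -> "SamplingCriteria":
        return cls(min_glomeruli=5, min_cta_mm2=3.0)


def extract_interstitium(seg: CompiledSegmentation) -> np.ndarray:
    """Residual cortical tissue after removal of all structure classes.

    Cortex pixels belonging to no structure class are presumed to
    represent the interstitium.
    """
    return (seg.labels == RESIDUAL) & seg.cortex


class PaletteError(ValueError):
    pass


def _classify_nearest(rgb: np.ndarray, refs: dict[str, tuple[int, int, int]]) -> np.ndarray:
    """Index of the nearest reference color (squared L2 in RGB) per pixel."""
    arr = rgb.astype(np.int32)
    stack = np.stack(
        [((arr - np.array(color, dtype=np.int32)) ** 2).sum(axis=-1) for color in refs.values()],
        axis=0,
    )
    return np.argmin(stack, axis=0)


def quantify_compartments(
    seg: CompiledSegmentation,
    interstitium: np.ndarray,
    truth_labels: np.ndarray | None = None,
    rgb: np.ndarray | None = None,
    palette: dict[str, tuple[int, int, int]] | None = None,
    min_nucleus_px: int = 4,
    connectivity: int = 2,
) -> CompartmentAreas:
    """Quantify tubular and interstitial compartments of a compiled case.

    Label mode (``truth_labels`` given): sub-compartment codes are read
    directly within the compiled tubule and interstitium regions.

    Color mode (``rgb`` given): tubule pixels are classified as lumen /
    cytoplasm / nuclei and interstitial pixels as collagen / matrix by
    nearest reference color from ``palette``. Nuclei are counted as
    connected components of at least ``min_nucleus_px`` pixels inside
    tubules, suppressing single-pixel color noise.

    PTC area always comes from the compiled segmentation itself.
    """
    px_area = seg.pixel_area_um2
    tubules = seg.labels == LABEL_IDS["tubules"]
    ptc_area = float((seg.labels == LABEL_IDS["ptc"]).sum()) * px_area

    if rgb is not None:
        if palette is None:
            raise PaletteError("color mode requires a reference palette")
        for key in ("lumen", "cytoplasm", "nuclei", "collagen", "matrix"):
            if key not in palette:
                raise PaletteError(f"palette missing reference color for {key!r}")
        tub_refs = {k: palette[k] for k in ("lumen", "cytoplasm", "nuclei")}
        cls_t = _classify_nearest(rgb, tub_refs)
        lumen = float(((cls_t == 0) & tubules).sum()) * px_area
        nuc_mask = (cls_t == 2) & tubules
        cell = float(((cls_t == 1) & tubules).sum()) * px_area + float(nuc_mask.sum()) * px_area
        int_refs = {k: palette[k] for k in ("collagen", "matrix")}
        cls_i = _classify_nearest(rgb, int_refs)
        coll = float(((cls_i == 0) & interstitium).sum()) * px_area
        matrix = float(((cls_i == 1) & interstitium).sum()) * px_area
    elif truth_labels is not None:
        lumen = float(((truth_labels == Compartment.LUMEN) & tubules).sum()) * px_area
        cell_px = np.isin(
            truth_labels, (Compartment.TUBULE_CELL, Compartment.TUBULE_NUCLEUS)
        ) & tubules
        cell = float(cell_px.sum()) * px_area
        nuc_mask = (truth_labels == Compartment.TUBULE_NUCLEUS) & tubules
        coll = float(((truth_labels == Compartment.COLLAGEN) & interstitium).sum()) * px_area
        matrix = float(((truth_labels == Compartment.MATRIX) & interstitium).sum()) * px_area
    else:
        raise ValueError("either truth_labels (label mode) or rgb (color mode) is required")

    lab = measure.label(nuc_mask, connectivity=connectivity)
    if lab.max():
        sizes = np.bincount(lab.ravel())[1:]
        n_nuclei = int((sizes >= min_nucleus_px).sum())
    else:
        n_nuclei = 0
    return CompartmentAreas(
        lumen=lumen, tubule_cell=cell, ptc=ptc_area, collagen=coll, matrix=matrix,
        nucleus_count=n_nuclei,
    )


def compute_features(
    areas: CompartmentAreas,
    tubule_count: int,
    glom_count: int,
    case_id: str = "case",
    compat_printed_formulas: bool = False,
) -> FeatureRecord:
    """Assemble the seven-indicator feature record from compartment areas.

    The five area fractions are percentages of the additive CTA. With no
    tubules, mean tubule size and nuclear density are undefined and the
    record is flagged instead of fabricating values.

    ``compat_printed_formulas`` switches tSize/tCellDen to the alternative
    published forms (both ×100 ratios) for cross-tool comparisons.
    """
    cta = areas.cta_um2
    if cta <= 0:
        raise ValueError("CTA is zero: nothing to quantify")
    flags: list[str] = []
    if tubule_count > 0:
        if compat_printed_formulas:
            tsize = areas.tubular_um2 / cta * 100.0
            tcellden = areas.nucleus_count / areas.tubular_um2 * 100.0
        else:
            tsize = areas.tubular_um2 / tubule_count
            tcellden = areas.nucleus_count / areas.tubular_um2 * 1e6  # per mm²
    else:
        tsize = tcellden = None
        flags.append("no_tubules")
    return FeatureRecord(
        case_id=case_id,
        tlumen_pct=areas.lumen / cta * 100.0,
        tcell_pct=areas.tubule_cell / cta * 100.0,
        imatrix_pct=areas.matrix / cta * 100.0,
        icoll_pct=areas.collagen / cta * 100.0,
        ptc_pct=areas.ptc / cta * 100.0,
        tsize=tsize,
        tcellden=tcellden,
        cta_mm2=round(cta / 1e6, 3),
        glom_n=glom_count,
        flags=flags,
    )


def extract_features(
    seg: CompiledSegmentation,
    truth_labels: np.ndarray | None = None,
    rgb: np.ndarray | None = None,
    palette: dict[str, tuple[int, int, int]] | None = None,
    case_id: str = "case",
    min_nucleus_px: int = 4,
) -> FeatureRecord:
    """Convenience wrapper: interstitium → compartments → feature record."""
    inter = extract_interstitium(seg)
    areas = quantify_compartments(
        seg, inter, truth_labels=truth_labels, rgb=rgb, palette=palette,
        min_nucleus_px=min_nucleus_px,
    )
    return compute_features(
        areas,
        tubule_count=len(seg.tubule_table),
        glom_count=len(seg.glomerulus_table),
        case_id=case_id,
    )


def cta_subtractive_mm2(seg: CompiledSegmentation) -> float:
    """QA cross-check: CTA as cortex minus glomeruli minus arteries/veins."""
    px_area = seg.pixel_area_um2
    cortex = float(seg.cortex.sum()) * px_area
    glom = float((seg.labels == LABEL_IDS["glomeruli"]).sum()) * px_area
    vess = float((seg.labels == LABEL_IDS["arteries_veins"]).sum()) * px_area
    return (cortex - glom - vess) / 1e6


def apply_sampling(
    records: list[FeatureRecord], criteria: SamplingCriteria | None = None
) -> tuple[list[FeatureRecord], list[tuple[FeatureRecord, str]]]:
    """Split records into adequate biopsies and exclusions with reasons.

    A case is kept iff it has at least ``min_glomeruli`` glomeruli AND at
    least ``min_cta_mm2`` of cortical tubulointerstitial area.
    """
    criteria = criteria or SamplingCriteria()
    kept: list[FeatureRecord] = []
    excluded: list[tuple[FeatureRecord, str]] = []
    for rec in records:
        reasons = []
        if rec.glom_n < criteria.min_glomeruli:
            reasons.append(f"glomeruli {rec.glom_n} < {criteria.min_glomeruli}")
        if rec.cta_mm2 < criteria.min_cta_mm2:
            reasons.append(f"CTA {rec.cta_mm2} mm² < {criteria.min_cta_mm2} mm²")
        if reasons:
            excluded.append((rec, "; ".join(reasons)))
        else:
            kept.append(rec)
    return kept, excluded
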