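"""Virtual renal-cortex biopsy generator with known ground truth.

Emulates a modified Picrosirius-red-stained cortical field at a
configurable pixel size (default 0.5 μm/px) using analytic geometry
primitives — tubules as lumen discs wrapped in an epithelial annulus with
nuclear dots, glomeruli and arteries as large discs, peritubular
capillaries (PTC) as small interstitial blobs — rasterized onto an
integer grid. The interstitium between structures is partitioned into
fibrillary collagen and non-fibrillary matrix as a spatially patchy
two-phase field.

Two latent factors drive each case:

* ``chronicity`` (c in [0, 1]) — interstitial fibrosis and tubular
  atrophy: more fibrillary collagen, smaller tubules, rarefied PTC,
  denser tubular nuclei;
* ``acuity`` (a in [0, 1]) — acute tubular injury: dilated lumens with
  flattened epithelium, and interstitial edema (non-fibrillary matrix
  expansion).

Each case carries a pixel-level ground-truth sub-compartment raster,
truth areas counted on it, and linked clinical metadata (Banff ci grade
coupled to c, acute-rejection status coupled to a, and a serum-creatinine
follow-up series whose reciprocal trends down with c and dips-then-
recovers with a). A fraction of PTC objects can be deliberately misplaced
inside glomeruli to exercise downstream overlap QA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .maskops import ClassMaskSet


class Compartment(IntEnum):
    """Ground-truth sub-compartment codes in the truth label raster."""

    BACKGROUND = 0
    LUMEN = 1
    TUBULE_CELL = 2
    TUBULE_NUCLEUS = 3
    PTC = 4
    COLLAGEN = 5
    MATRIX = 6
    GLOMERULUS = 7
    ARTERY = 8
    MEDULLA = 9


#: Default render palette: Picrosirius-like colors (RGB, 8-bit).
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "lumen": (250, 250, 250),
    "cytoplasm": (235, 215, 140),
    "nuclei": (55, 65, 160),
    "collagen": (200, 40, 55),
    "matrix": (240, 205, 215),
    "glomerulus": (120, 170, 110),
    "artery": (230, 140, 60),
    "medulla": (170, 200, 230),
    "background": (255, 255, 255),
}

#: Compartment code -> palette key used when rendering.
_RENDER_KEY = {
    Compartment.LUMEN: "lumen",
    Compartment.TUBULE_CELL: "cytoplasm",
    Compartment.TUBULE_NUCLEUS: "nuclei",
    Compartment.PTC: "cytoplasm",  # capillary wall renders like cytoplasm
    Compartment.COLLAGEN: "collagen",
    Compartment.MATRIX: "matrix",
    Compartment.GLOMERULUS: "glomerulus",
    Compartment.ARTERY: "artery",
    Compartment.MEDULLA: "medulla",
    Compartment.BACKGROUND: "background",
}

#: Archetype centers in (chronicity, acuity) space, mirroring the four
#: tissue phenotypes: intact tubulointerstitium, intermediate and severe
#: chronic transformation (IFTA), and acute tubular injury.
ARCHETYPES: dict[str, tuple[float, float]] = {
    "intact": (0.08, 0.12),
    "intermediate": (0.48, 0.28),
    "chronic_severe": (0.88, 0.18),
    "acute": (0.15, 0.85),
}
ARCHETYPE_SD = 0.045


class PackingError(RuntimeError):
    """Raised when the requested structures cannot be placed in the field."""


@dataclass(frozen=True)
class SyntheticParams:
    """Generative knobs for one virtual biopsy field.

    ``chronicity`` and ``acuity`` are independently settable latent factors
    in [0, 1]; the same params and seed always reproduce the identical case
    bit for bit.
    """

    chronicity: float = 0.2
    acuity: float = 0.2
    field_width_um: float = 2500.0
    field_height_um: float = 2500.0
    pixel_size_um: float = 0.5
    n_glomeruli: int = 10
    n_arteries: int = 2
    overlap_error_rate: float = 0.0
    medulla_fraction: float = 0.0
    glomerulus_radius_um: float = 90.0
    tubule_radius_um: float = 30.0
    nucleus_radius_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chronicity", "acuity", "overlap_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field size must be positive")
        if self.n_glomeruli < 0:
            raise ValueError("n_glomeruli must be >= 0")
        if not 0.0 <= self.medulla_fraction < 1.0:
            raise ValueError("medulla_fraction must be in [0, 1)")
        if self.overlap_error_rate > 0 and self.n_glomeruli == 0:
            raise ValueError("overlap_error_rate > 0 requires at least one glomerulus")


@dataclass
class CaseMetadata:
    """Clinical annotations linked to a virtual case."""

    case_id: str
    banff_ci: int
    acute_rejection: bool
    creatinine_series: list[tuple[float, float]]  # (months after biopsy, SC mg/dL)
    cohort: str = "training"

    def __post_init__(self) -> None:
        if self.banff_ci not in (0, 1, 2, 3):
            raise ValueError("banff_ci must be an ordinal in 0..3")
        times = [t for t, _ in self.creatinine_series]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("creatinine times must be strictly increasing")
        if any(sc <= 0 for _, sc in self.creatinine_series):
            raise ValueError("serum creatinine must be > 0")


@dataclass
class SyntheticCase:
    """One generated biopsy field with masks, pixel ground truth and metadata."""

    mask_set: ClassMaskSet
    truth_labels: np.ndarray  # Compartment codes per pixel
    truth_areas: dict[str, float]  # μm² per compartment
    truth_tubule_count: int
    truth_nucleus_count: int
    params: SyntheticParams
    metadata: CaseMetadata
    archetype: str | None = None
    rgb_render: np.ndarray | None = None


def _fill_disc(
    arr: np.ndarray, cy: float, cx: float, r: float, value: int, where: np.ndarray | None = None
) -> int:
    """Rasterize a disc (pixel-center inclusion) into ``arr``; returns px painted."""
    h, w = arr.shape
    y0, y1 = max(0, int(math.floor(cy - r)) - 1), min(h, int(math.ceil(cy + r)) + 2)
    x0, x1 = max(0, int(math.floor(cx - r)) - 1), min(w, int(math.ceil(cx + r)) + 2)
    if y0 >= y1 or x0 >= x1:
        return 0
    yy, xx = np.ogrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if where is not None:
        inside &= where[y0:y1, x0:x1]
    sub = arr[y0:y1, x0:x1]
    n = int(inside.sum())
    sub[inside] = value
    return n


def _place_discs(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    h_um: float,
    w_um: float,
    y_max_um: float,
    existing: list[tuple[float, float, float]],
    gap_um: float = 10.0,
    max_attempts_per: int = 400,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping disc centers; raises PackingError."""
    placed: list[tuple[float, float, float]] = []
    for i in range(n):
        r = float(radii[i])
        if 2 * r + 2 > min(w_um, y_max_um):
            raise PackingError(
                f"structure of radius {r:.0f} μm cannot fit a {w_um:.0f}×{y_max_um:.0f} μm field"
            )
        ok = False
        for _ in range(max_attempts_per):
            cy = rng.uniform(r, y_max_um - r)
            cx = rng.uniform(r, w_um - r)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + gap_um) ** 2
                for oy, ox, orad in existing + placed
            ):
                placed.append((cy, cx, r))
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place structure {i + 1}/{n} (radius {r:.0f} μm) "
                f"after {max_attempts_per} attempts: field too crowded"
            )
    return placed


def generate_case(params: SyntheticParams) -> SyntheticCase:
    """Generate one virtual biopsy field.

    Geometry is laid out in physical coordinates (μm) and rasterized at
    ``params.pixel_size_um``. Ground-truth areas are pixel counts on the
    generated sub-compartment raster times the pixel area, so they sum
    exactly to the generated cortical tubulointerstitial area.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    c, a = p.chronicity, p.acuity
    px = p.pixel_size_um
    W = int(round(p.field_width_um / px))
    H = int(round(p.field_height_um / px))
    w_um, h_um = W * px, H * px

    labels = np.zeros((H, W), dtype=np.uint8)

    # medulla strip along the bottom edge
    cortex_h_um = h_um * (1.0 - p.medulla_fraction)
    medulla_y0 = int(round(cortex_h_um / px))
    labels[medulla_y0:, :] = Compartment.MEDULLA

    # --- glomeruli and arteries -------------------------------------------
    glom_radii = np.clip(
        rng.normal(p.glomerulus_radius_um, 8.0, p.n_glomeruli),
        0.7 * p.glomerulus_radius_um,
        1.3 * p.glomerulus_radius_um,
    )
    gloms = _place_discs(rng, p.n_glomeruli, glom_radii, h_um, w_um, cortex_h_um, [])
    art_radii = np.clip(rng.normal(50.0, 8.0, p.n_arteries), 30.0, 80.0)
    try:
        arteries = _place_discs(rng, p.n_arteries, art_radii, h_um, w_um, cortex_h_um, gloms)
    except PackingError:
        arteries = []  # arteries are optional scenery; drop them if crowded
    for cy, cx, r in gloms:
        _fill_disc(labels, cy / px, cx / px, r / px, Compartment.GLOMERULUS)
    for cy, cx, r in arteries:
        _fill_disc(labels, cy / px, cx / px, r / px, Compartment.ARTERY)

    # --- tubules on a jittered hex grid -----------------------------------
    r_nom = p.tubule_radius_um * (1.0 - 0.40 * c)
    gap = 0.10 + 0.50 * c + 0.25 * a  # interstitial widening: fibrosis + edema
    s = 2.0 * r_nom * (1.0 + gap)  # center-to-center spacing
    jitter = 1.0
    r_cap = s / 2.0 - 2.0 - jitter  # tubules never touch under 8-connectivity
    row_h = s * math.sqrt(3) / 2.0
    blockers = gloms + arteries

    tubule_count = 0
    nucleus_count = 0
    tubule_centers: list[tuple[float, float]] = []
    tubule_radii: list[float] = []
    n_rows = int(cortex_h_um / row_h) + 2
    n_cols = int(w_um / s) + 2
    nr = p.nucleus_radius_um
    # case-level epithelial flattening jitter, shared by all tubules of the
    # case: trades lumen against cell mass the way acute injury does
    flatten_case = rng.normal(0.0, 0.03)
    for i in range(n_rows):
        cy0 = (i + 0.5) * row_h
        for j in range(n_cols):
            cx0 = (j + 0.5 + (0.5 if i % 2 else 0.0)) * s
            r_i = min(r_nom * rng.uniform(0.90, 1.10), r_cap)
            cy = cy0 + rng.uniform(-jitter, jitter)
            cx = cx0 + rng.uniform(-jitter, jitter)
            if cy - r_i < 1 or cy + r_i > cortex_h_um - 1 or cx - r_i < 1 or cx + r_i > w_um - 1:
                continue
            if any(
                (cy - oy) ** 2 + (cx - ox) ** 2 < (r_i + orad + 4.0) ** 2 for oy, ox, orad in blockers
            ):
                continue
            lum_f = float(
                np.clip(0.30 + 0.40 * a + flatten_case + rng.normal(0.0, 0.04), 0.12, 0.85)
            )
            lum_r = lum_f * r_i
            _fill_disc(labels, cy / px, cx / px, r_i / px, Compartment.TUBULE_CELL)
            _fill_disc(labels, cy / px, cx / px, lum_r / px, Compartment.LUMEN)
            tubule_count += 1
            tubule_centers.append((cy, cx))
            tubule_radii.append(r_i)
            # nuclei in the epithelial rim, kept separated so each stays
            # one connected component
            tub_area = math.pi * r_i**2
            density = 0.0035 * (1.0 + 0.5 * c)  # nuclei per μm² of tubular area
            target = rng.poisson(density * tub_area)
            placed: list[tuple[float, float]] = []
            # separation and edge margins scale with the pixel size so that
            # rasterized nuclei stay distinct 8-connected components
            sep2 = (2.0 * nr + 3.0 * px) ** 2
            r_lo, r_hi = lum_r + nr + 0.5, r_i - nr - 1.5 * px
            if r_hi > r_lo:
                for _ in range(int(target)):
                    for _ in range(40):
                        rho = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
                        th = rng.uniform(0.0, 2.0 * math.pi)
                        ny, nx = cy + rho * math.sin(th), cx + rho * math.cos(th)
                        if all((ny - qy) ** 2 + (nx - qx) ** 2 > sep2 for qy, qx in placed):
                            placed.append((ny, nx))
                            break
            for ny, nx in placed:
                _fill_disc(labels, ny / px, nx / px, nr / px, Compartment.TUBULE_NUCLEUS)
            nucleus_count += len(placed)

    # --- peritubular capillaries ------------------------------------------
    # small blobs squeezed between tubules; rarefied with chronicity. A
    # committed blob keeps at least the downstream minimum object area so
    # that truth PTC objects survive min-area filtering intact.
    p_keep = 0.80 * (1.0 - 0.55 * c)
    min_ptc_um2 = 45.0
    injected_ptc: list[tuple[float, float, float]] = []
    for (cy, cx), r_i in zip(tubule_centers, tubule_radii):
        for _ in range(3):
            if rng.uniform() >= p_keep:
                continue
            r_ptc = rng.uniform(5.0, 8.0)
            if rng.uniform() < p.overlap_error_rate:
                # deliberately misplace this capillary inside a glomerulus:
                # the class mask gains the object, the ground truth does not
                gy, gx, gr = gloms[rng.integers(len(gloms))]
                rho = math.sqrt(rng.uniform(0.0, max(gr - r_ptc - 1.0, 1.0) ** 2))
                th = rng.uniform(0.0, 2.0 * math.pi)
                injected_ptc.append((gy + rho * math.sin(th), gx + rho * math.cos(th), r_ptc))
                continue
            d = r_i + rng.uniform(2.0, 8.0)
            th = rng.uniform(0.0, 2.0 * math.pi)
            by, bx = (cy + d * math.sin(th)) / px, (cx + d * math.cos(th)) / px
            rp = r_ptc / px
            y0, y1 = max(0, int(by - rp) - 1), min(H, int(by + rp) + 2)
            x0, x1 = max(0, int(bx - rp) - 1), min(W, int(bx + rp) + 2)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.ogrid[y0:y1, x0:x1]
            win = labels[y0:y1, x0:x1]
            inside = ((yy - by) ** 2 + (xx - bx) ** 2 <= rp**2) & (
                win == Compartment.BACKGROUND
            )
            if inside.sum() * px**2 >= min_ptc_um2:
                win[inside] = Compartment.PTC

    # --- interstitium: collagen vs non-fibrillary matrix -------------------
    interstitium = labels == Compartment.BACKGROUND
    s_coll = float(np.clip(0.30 + 0.60 * c - 0.15 * a + rng.normal(0.0, 0.02), 0.02, 0.95))
    noise = rng.standard_normal((H, W))
    sigma_px = max(1.0, 12.0 / px)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_px)
    vals = smooth[interstitium]
    if vals.size:
        thr = np.quantile(vals, 1.0 - s_coll)
        coll = interstitium & (smooth >= thr)
        labels[coll] = Compartment.COLLAGEN
        labels[interstitium & ~coll] = Compartment.MATRIX

    # --- ground truth ------------------------------------------------------
    px_area = px**2
    counts = np.bincount(labels.ravel(), minlength=10)
    truth_areas = {
        "lumen": counts[Compartment.LUMEN] * px_area,
        "tubule_cell": (counts[Compartment.TUBULE_CELL] + counts[Compartment.TUBULE_NUCLEUS])
        * px_area,
        "ptc": counts[Compartment.PTC] * px_area,
        "collagen": counts[Compartment.COLLAGEN] * px_area,
        "matrix": counts[Compartment.MATRIX] * px_area,
        "glomeruli": counts[Compartment.GLOMERULUS] * px_area,
        "arteries": counts[Compartment.ARTERY] * px_area,
    }

    # --- one-vs-all class masks -------------------------------------------
    tub_mask = np.isin(
        labels, (Compartment.LUMEN, Compartment.TUBULE_CELL, Compartment.TUBULE_NUCLEUS)
    )
    ptc_mask = labels == Compartment.PTC
    for cy, cx, r in injected_ptc:
        blob = np.zeros_like(ptc_mask)
        _fill_disc(blob, cy / px, cx / px, r / px, 1)
        ptc_mask |= blob.astype(bool)
    medulla_mask = labels == Compartment.MEDULLA
    mask_set = ClassMaskSet(
        masks={
            "cortex": ~medulla_mask,
            "medulla": medulla_mask,
            "glomeruli": labels == Compartment.GLOMERULUS,
            "tubules": tub_mask,
            "ptc": ptc_mask,
            "arteries_veins": labels == Compartment.ARTERY,
        },
        pixel_size_um=px,
    )

    metadata = _generate_metadata(rng, c, a)
    return SyntheticCase(
        mask_set=mask_set,
        truth_labels=labels,
        truth_areas=truth_areas,
        truth_tubule_count=tubule_count,
        truth_nucleus_count=nucleus_count,
        params=p,
        metadata=metadata,
    )


def _generate_metadata(rng: np.random.Generator, c: float, a: float) -> CaseMetadata:
    """Clinical metadata coupled to the latent factors.

    Banff ci ~ Binomial(3, 0.08 + 0.8c) so its mean rises with chronicity;
    acute rejection ~ Bernoulli(0.05 + 0.75a). Reciprocal serum creatinine
    (rSC, dL/mg) starts near 1.0, declines linearly with c over follow-up,
    and in acute cases dips at biopsy then partially recovers.
    """
    ci = int(rng.binomial(3, min(0.08 + 0.80 * c, 0.97)))
    rejection = bool(rng.uniform() < 0.05 + 0.75 * a)
    n_pts = int(rng.integers(5, 9))
    times = np.sort(rng.uniform(0.5, 24.0, n_pts - 1))
    times = np.concatenate([[0.0], times])
    # enforce strict increase under rounding
    times = np.maximum.accumulate(times + np.arange(n_pts) * 1e-3)
    rsc0 = 1.0 - 0.45 * c
    rsc = rsc0 * (1.0 - 0.15 * c * times / 24.0) - 0.35 * a * np.exp(-times / 6.0)
    rsc *= np.exp(rng.normal(0.0, 0.05, n_pts))
    rsc = np.clip(rsc, 0.08, None)
    series = [(float(t), float(1.0 / r)) for t, r in zip(times, rsc)]
    return CaseMetadata(
        case_id="case", banff_ci=ci, acute_rejection=rejection, creatinine_series=series
    )


def render_rgb(
    case: SyntheticCase,
    palette: dict[str, tuple[int, int, int]] | None = None,
    noise_amplitude: int = 0,
    seed: int | None = None,
) -> np.ndarray:
    """Render the truth raster as an RGB image with an optional noise floor.

    Each pixel takes its compartment's palette color plus independent
    additive uniform noise in [-amplitude, amplitude] per channel, clipped
    to [0, 255]. Distinct compartments must map to distinct colors so the
    render stays invertible by nearest-color classification.
    """
    palette = palette or DEFAULT_PALETTE
    colors = list(palette.values())
    if len(set(colors)) != len(colors):
        raise ValueError("palette assigns the same color to multiple compartments")
    lut = np.zeros((10, 3), dtype=np.uint8)
    for comp, key in _RENDER_KEY.items():
        lut[comp] = palette[key]
    img = lut[case.truth_labels]
    if noise_amplitude:
        rng = np.random.default_rng(case.params.seed + 1 if seed is None else seed)
        noise = rng.integers(
            -noise_amplitude, noise_amplitude + 1, size=img.shape, dtype=np.int16
        )
        img = np.clip(img.astype(np.int16) + noise, 0, 255).astype(np.uint8)
    return img


def generate_cohort(
    n: int,
    design: str = "continuous",
    seed: int = 0,
    base_params: SyntheticParams | None = None,
    splits: dict[str, float] | None = None,
) -> list[SyntheticCase]:
    """Generate a cohort of virtual biopsy cases.

    ``design="continuous"`` samples (chronicity, acuity) independently
    uniform on [0, 1]; ``design="archetypes"`` samples around the four
    phenotype centers in :data:`ARCHETYPES` with within-phenotype spread
    ``ARCHETYPE_SD``, recording each case's planted archetype. ``splits``
    optionally maps cohort names to fractions (e.g. ``{"training": 0.7,
    "internal_test": 0.3}``); by default every case is labeled training.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if design not in ("continuous", "archetypes"):
        raise ValueError(f"unknown design {design!r}")
    rng = np.random.default_rng(seed)
    base = base_params or SyntheticParams()

    names = list(ARCHETYPES)
    # balanced planted design: equal archetype counts, order shuffled
    planted = [names[i % len(names)] for i in range(n)]
    rng.shuffle(planted)
    cases: list[SyntheticCase] = []
    for i in range(n):
        if design == "continuous":
            c, a = rng.uniform(), rng.uniform()
            arch = None
        else:
            arch = planted[i]
            c0, a0 = ARCHETYPES[arch]
            c = float(np.clip(rng.normal(c0, ARCHETYPE_SD), 0.0, 1.0))
            a = float(np.clip(rng.normal(a0, ARCHETYPE_SD), 0.0, 1.0))
        params = replace(
            base, chronicity=float(c), acuity=float(a), seed=int(rng.integers(2**31))
        )
        case = generate_case(params)
        case.archetype = arch
        case.metadata.case_id = f"case_{i:04d}"
        cases.append(case)

    if splits:
        total = sum(splits.values())
        bounds = np.cumsum([v / total for v in splits.values()]) * n
        names_s = list(splits)
        for i, case in enumerate(cases):
            case.metadata.cohort = names_s[int(np.searchsorted(bounds, i, side="right"))]
    return cases


#: A small field suitable for cohort-scale statistics: percentage features
#: are scale invariant, so reduced fields preserve the cohort structure.
FAST_FIELD = dict(
    field_width_um=600.0,
    field_height_um=600.0,
    pixel_size_um=2.0,
    n_glomeruli=2,
    n_arteries=1,
    glomerulus_radius_um=65.0,
)


def fast_params(**overrides) -> SyntheticParams:
    """SyntheticParams preset on a reduced 600×600 μm field at 2 μm/px."""
    kw = dict(FAST_FIELD)
    kw.update(overrides)
    return SyntheticParams(**kw)
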