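"""Fluorescent colony quantification and necrosis scoring.

Live colonies stained with calcein AM appear as bright foci on a textured
paper background.  This module detects foci, converts projected areas to
equivalent-sphere volumes, estimates doubling times from day-to-day volume
cohorts, and scores possible necrosis from orthogonal line scans.

The necrosis test rests on a chord-length projection model: a uniformly
fluorescent sphere of radius R projects intensity ``I(x) = 2*sqrt(R^2-x^2)``
along a line through its center, while a sphere whose central fraction
``f`` of the *volume* is dark (core radius ``r = f**(1/3) * R``) loses the
core chord ``2*sqrt(r^2-x^2)`` for ``|x| < r``.  The center-of-scan
intensity relative to the peak of a fully fluorescent sphere (``2R``) is
then ``1 - f**(1/3)``; for a 25%-volume dark core this is 37%, the
threshold used to flag a colony as possibly necrotic when *both*
orthogonal scans dip below it anywhere in their middle two-thirds.

Note on normalization: line scans are conventionally normalized to their
own peak, but the 37% threshold is derived against the full-sphere peak.
For a cored sphere the rim peak is below ``2R``, so self-normalization
inflates the apparent center intensity.  ``classify_necrosis`` therefore
supports both references: ``"self"`` (the conventional rule, default) and
``"sphere"`` (rim-fit estimate of the implied full-sphere peak, which
places the decision boundary exactly at f = 0.25).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import measure, transform

__all__ = [
    "FluorescenceImage",
    "LineScan",
    "ColonyRecord",
    "NecrosisClass",
    "load_image",
    "save_image",
    "subtract_background",
    "detect_foci",
    "sphere_volume_from_area",
    "doubling_time",
    "analytic_sphere_profile",
    "classify_necrosis",
    "extract_profiles",
    "expected_cell_count",
    "cloning_efficiency",
    "score_image",
]

#: default detection threshold as a fraction of the image maximum
DEFAULT_THRESHOLD_FRACTION = 0.25
#: default minimum focus area: footprint of one 10 um-radius cell, um^2
DEFAULT_MIN_AREA_UM2 = math.pi * 10.0 ** 2
#: default background median-kernel extent, um
DEFAULT_BACKGROUND_KERNEL_UM = 250.0
#: reject foci whose peak is below this many robust SDs of residual background
DEFAULT_MIN_PEAK_SNR = 15.0
#: necrosis threshold, % of peak (center intensity of a 25%-core sphere)
NECROSIS_THRESHOLD_PCT = 37.0
#: middle two-thirds of a normalized scan, positions in (100/6, 500/6)
VALLEY_WINDOW = (100.0 / 6.0, 500.0 / 6.0)


class NecrosisClass:
    NO_VALLEY = "no_valley"
    SINGLE_VALLEY_FIBER = "single_valley_fiber"
    POSSIBLY_NECROTIC = "possibly_necrotic"


@dataclass(frozen=True)
class FluorescenceImage:
    """A 2-D grayscale fluorescence image with physical pixel size."""

    pixels: np.ndarray  # non-negative intensities, arbitrary units
    pixel_size: float  # um per pixel
    acquisition_day: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if px.size and px.min() < 0:
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class LineScan:
    """A 1-pixel-wide intensity profile across a colony.

    Positions span 0-100 (scan length normalized to 100); intensities are
    normalized so the scan's own peak is 100 (unless all-zero or the scan
    was deliberately referenced to the full-sphere peak).
    """

    positions: np.ndarray  # 0..100
    intensities: np.ndarray
    axis: str = "longest"  # "longest" or "orthogonal"

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "intensities", i)
        if p.shape != i.shape or p.ndim != 1:
            raise ValueError("positions and intensities must be matching 1-D")

    def self_normalized(self) -> "LineScan":
        peak = self.intensities.max() if self.intensities.size else 0.0
        if peak <= 0:
            return self
        return replace(self, intensities=self.intensities * (100.0 / peak))


@dataclass
class ColonyRecord:
    """One detected fluorescent focus and its derived quantities."""

    label: int
    centroid: tuple[float, float]  # (row, col) px
    area: float  # um^2
    equivalent_radius: float  # um
    sphere_volume: float  # um^3
    profile_x: Optional[LineScan] = None
    profile_y: Optional[LineScan] = None
    necrosis_class: Optional[str] = None
    pixel_labels: Optional[np.ndarray] = field(default=None, repr=False)


# --- image I/O ---------------------------------------------------------------

def load_image(path: Union[str, Path], pixel_size: float,
               acquisition_day: int = 0) -> FluorescenceImage:
    """Read an 8/16-bit grayscale TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        px = tifffile.imread(path)
    else:
        from PIL import Image
        px = np.asarray(Image.open(path).convert("I"))
    return FluorescenceImage(np.asarray(px, dtype=float), pixel_size,
                             acquisition_day)


def save_image(image: FluorescenceImage, path: Union[str, Path]) -> None:
    """Write the image as 16-bit grayscale TIFF or PNG (rescaled to range)."""
    path = Path(path)
    px = image.pixels
    top = px.max() if px.size and px.max() > 0 else 1.0
    scaled = np.clip(px / top * 65535.0, 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, scaled)
    else:
        from PIL import Image
        Image.fromarray(scaled, mode="I;16").save(path)


# --- detection ---------------------------------------------------------------

def subtract_background(image: FluorescenceImage,
                        kernel_um: float = DEFAULT_BACKGROUND_KERNEL_UM,
                        downscale: int = 4) -> np.ndarray:
    """Remove slowly varying background (paper texture, flare).

    A rolling-ball-equivalent estimate: the image is decimated, median
    filtered with a kernel of physical extent ``kernel_um`` (large compared
    to a colony), and re-expanded; the clipped difference is returned.
    """
    px = image.pixels
    if px.size == 0:
        return px.copy()
    small = px[::downscale, ::downscale]
    size = int(round(kernel_um / (image.pixel_size * downscale)))
    size = max(3, size | 1)
    bg_small = ndi.median_filter(small, size=size, mode="nearest")
    bg = transform.resize(bg_small, px.shape, order=1, mode="edge",
                          anti_aliasing=False)
    return np.clip(px - bg, 0.0, None)


def _refined_component(bgsub: np.ndarray, region, threshold_fraction: float
                       ) -> np.ndarray:
    """Boolean mask of the focus re-thresholded at a fraction of its own peak.

    The global threshold (a fraction of the *image* maximum) under-segments
    dim colonies; re-thresholding each focus at the same fraction of its own
    peak makes the recovered area-to-radius relation size-independent.
    """
    r0, c0, r1, c1 = region.bbox
    pad_r = max(2, (r1 - r0) // 2)
    pad_c = max(2, (c1 - c0) // 2)
    rr0, cc0 = max(r0 - pad_r, 0), max(c0 - pad_c, 0)
    rr1 = min(r1 + pad_r, bgsub.shape[0])
    cc1 = min(c1 + pad_c, bgsub.shape[1])
    local = bgsub[rr0:rr1, cc0:cc1]
    region_mask = np.zeros_like(local, dtype=bool)
    coords = region.coords
    region_mask[coords[:, 0] - rr0, coords[:, 1] - cc0] = True
    peak = local[region_mask].max()
    local_mask = local > threshold_fraction * peak
    local_mask = ndi.binary_closing(local_mask, structure=np.ones((3, 3)))
    labels = measure.label(local_mask, connectivity=2)
    # keep the component holding the focus's brightest pixel
    flat = np.where(region_mask, local, -np.inf)
    pr, pc = np.unravel_index(np.argmax(flat), flat.shape)
    lab = labels[pr, pc]
    mask = np.zeros_like(bgsub, dtype=bool)
    if lab > 0:
        mask[rr0:rr1, cc0:cc1] = labels == lab
    else:  # degenerate: fall back to the global component
        mask[coords[:, 0], coords[:, 1]] = True
    return mask


def detect_foci(image: FluorescenceImage,
                threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                min_area: float = DEFAULT_MIN_AREA_UM2,
                background: Optional[np.ndarray] = None,
                refine: bool = True,
                min_peak_snr: float = DEFAULT_MIN_PEAK_SNR) -> list[ColonyRecord]:
    """Detect fluorescent foci and return their geometry.

    Thresholds a lightly denoised (1-px Gaussian) copy of the
    background-subtracted image at ``threshold_fraction * max``, labels
    8-connected components, then (by default) re-measures each focus at the
    same fraction of its own peak and discards those below ``min_area``
    (um^2).  Because a projected sphere thresholded at fraction ``q`` of
    its own peak keeps only the disc of radius ``R*sqrt(1-q^2)``, the
    measured area is corrected by ``1/(1-q^2)`` before the radius/volume
    conversion (refined mode only), making the size estimate unbiased under
    the chord-projection model.  Foci whose peak lies below ``min_peak_snr``
    robust standard deviations of the residual background are rejected:
    surviving paper texture peaks near 10 sigma while even a dim single
    cell exceeds ~25 sigma, so the default floor of 15 separates them.
    Two foci closer than their combined footprints merge into one
    component and are reported as a single focus; conversely, lobes of one
    colony split by a dark fiber are re-fused (their equivalent discs
    overlap).
    """
    bgsub = background if background is not None else subtract_background(image)
    if bgsub.size == 0 or bgsub.max() <= 0:
        return []
    det = ndi.gaussian_filter(bgsub, 1.0)  # suppress single-pixel shot noise
    if det.max() <= 0:
        return []
    sigma = 1.4826 * float(np.median(np.abs(det - np.median(det))))
    if det.max() < min_peak_snr * sigma:
        return []
    mask = det > threshold_fraction * det.max()
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3)))
    labels = measure.label(mask, connectivity=2)
    truncation = 1.0 - threshold_fraction ** 2 if refine else 1.0
    records: list[ColonyRecord] = []
    seen_seeds: set[tuple[int, int]] = set()
    for region in measure.regionprops(labels, intensity_image=det):
        if region.intensity_max < min_peak_snr * sigma:
            continue
        if refine:
            comp = _refined_component(det, region, threshold_fraction)
            # fragments split by a dark band re-merge on refinement; keep one
            rows_c, cols_c = np.nonzero(comp)
            flat_idx = np.argmax(det[rows_c, cols_c])
            seed = (int(rows_c[flat_idx]), int(cols_c[flat_idx]))
            if seed in seen_seeds:
                continue
            seen_seeds.add(seed)
            area_px = int(comp.sum())
            weights = np.where(comp, bgsub, 0.0)
            total = weights.sum()
            if total <= 0:
                continue
            rows, cols = np.nonzero(comp)
            centroid = (float((rows * weights[rows, cols]).sum() / total),
                        float((cols * weights[rows, cols]).sum() / total))
            comp_mask = comp
        else:
            area_px = int(region.area)
            centroid = tuple(map(float, region.centroid_weighted))
            comp_mask = np.zeros_like(bgsub, dtype=bool)
            comp_mask[region.coords[:, 0], region.coords[:, 1]] = True
        area_um2 = area_px * image.pixel_size ** 2 / truncation
        if area_um2 < min_area:
            continue
        radius = math.sqrt(area_um2 / math.pi)
        records.append(ColonyRecord(
            label=region.label, centroid=centroid, area=area_um2,
            equivalent_radius=radius,
            sphere_volume=sphere_volume_from_area(area_um2),
            pixel_labels=comp_mask))
    if refine:
        records = _merge_overlapping(records, bgsub, image.pixel_size,
                                     truncation)
    return records


def _merge_overlapping(records: list[ColonyRecord], bgsub: np.ndarray,
                       pixel_size: float, truncation: float,
                       overlap_factor: float = 0.8) -> list[ColonyRecord]:
    """Fuse detections whose equivalent discs overlap.

    A colony split by a dark fiber band appears as two abutting lobes whose
    equivalent discs overlap heavily; they are one biological object and
    are re-measured as the union of their masks.  Distinct neighbouring
    colonies have disjoint discs and are untouched.
    """
    merged = True
    while merged and len(records) > 1:
        merged = False
        for a in range(len(records)):
            for b in range(a + 1, len(records)):
                ra, rb = records[a], records[b]
                dist_um = pixel_size * math.hypot(
                    ra.centroid[0] - rb.centroid[0],
                    ra.centroid[1] - rb.centroid[1])
                if dist_um >= overlap_factor * (ra.equivalent_radius
                                                + rb.equivalent_radius):
                    continue
                comp = ra.pixel_labels | rb.pixel_labels
                area_um2 = comp.sum() * pixel_size ** 2 / truncation
                rows, cols = np.nonzero(comp)
                w = bgsub[rows, cols]
                total = w.sum() if w.sum() > 0 else len(w)
                centroid = (float((rows * w).sum() / total),
                            float((cols * w).sum() / total))
                records[a] = ColonyRecord(
                    label=ra.label, centroid=centroid, area=area_um2,
                    equivalent_radius=math.sqrt(area_um2 / math.pi),
                    sphere_volume=sphere_volume_from_area(area_um2),
                    pixel_labels=comp)
                del records[b]
                merged = True
                break
            if merged:
                break
    return records


# --- geometry and growth ------------------------------------------------------

def sphere_volume_from_area(area: float) -> float:
    """Volume of the sphere whose projected (cross-section) area is ``area``.

    ``r = sqrt(area/pi)``; ``V = 4/3 * pi * r^3``.  Units: um^2 -> um^3.
    """
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    r = math.sqrt(area / math.pi)
    return 4.0 / 3.0 * math.pi * r ** 3


def doubling_time(volumes_t0: Sequence[float], volumes_t1: Sequence[float],
                  elapsed: float) -> float:
    """Population doubling time (hours) from two volume cohorts.

    ``tau = elapsed * ln 2 / ln(mean(V_t1) / mean(V_t0))``; returns ``inf``
    when the means are equal (no growth).
    """
    v0 = np.asarray(list(volumes_t0), dtype=float)
    v1 = np.asarray(list(volumes_t1), dtype=float)
    if v0.size == 0 or v1.size == 0:
        raise ValueError("both cohorts must be non-empty")
    if np.any(v0 <= 0) or np.any(v1 <= 0):
        raise ValueError("volumes must be positive")
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    fold = float(v1.mean() / v0.mean())
    if fold == 1.0:
        return math.inf
    return elapsed * math.log(2.0) / math.log(fold)


# --- line scans and necrosis --------------------------------------------------

def analytic_sphere_profile(radius: float, core_volume_fraction: float,
                            n_points: int = 201,
                            normalization: str = "full_sphere",
                            axis: str = "longest") -> LineScan:
    """Chord-length line scan through a uniformly fluorescent sphere.

    ``I(x) = 2*sqrt(R^2 - x^2) - [|x| < r] * 2*sqrt(r^2 - x^2)`` with the
    dark-core radius ``r = f**(1/3) * R``.  ``normalization``:

    - ``"full_sphere"``: divide by the fully fluorescent peak ``2R`` and
      scale to 100, so the center value is ``100 * (1 - f**(1/3))``;
    - ``"self"``: peak of this profile = 100 (conventional);
    - ``"raw"``: chord lengths in the radius' own units.
    """
    if not 0.0 <= core_volume_fraction <= 1.0:
        raise ValueError("core volume fraction must be in [0, 1]")
    if radius <= 0:
        raise ValueError("radius must be positive")
    x = np.linspace(-radius, radius, n_points)
    r_core = core_volume_fraction ** (1.0 / 3.0) * radius
    chord = 2.0 * np.sqrt(np.clip(radius ** 2 - x ** 2, 0.0, None))
    core = np.where(np.abs(x) < r_core,
                    2.0 * np.sqrt(np.clip(r_core ** 2 - x ** 2, 0.0, None)), 0.0)
    intensity = chord - core
    positions = (x + radius) / (2.0 * radius) * 100.0
    if normalization == "full_sphere":
        intensity = intensity / (2.0 * radius) * 100.0
    elif normalization == "self":
        peak = intensity.max()
        if peak > 0:
            intensity = intensity / peak * 100.0
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return LineScan(positions, intensity, axis=axis)


def _sphere_referenced(scan: LineScan) -> np.ndarray:
    """Intensities rescaled to the implied full-sphere peak.

    Outside any core or shadow the profile of a sphere follows
    ``C * sqrt(1 - u^2)`` with ``u`` the normalized offset from the scan
    center and ``C`` the full-sphere center intensity.  Cores and fiber
    shadows only ever *depress* samples, so ``C`` is estimated as the
    maximum of ``I/sqrt(1-u^2)`` over the scan interior (``|u| <= 0.9``,
    avoiding the blur-dominated extreme edge).  Intensities are returned
    as a percentage of that estimate.
    """
    p, i = scan.positions, scan.intensities
    u = (p - 50.0) / 50.0
    interior = np.abs(u) <= 0.9
    denom = np.sqrt(np.clip(1.0 - u ** 2, 1e-9, None))
    if not np.any(interior) or i[interior].max() <= 0:
        return scan.self_normalized().intensities
    c = float(np.max(i[interior] / denom[interior]))
    if c <= 0:
        return scan.self_normalized().intensities
    return i / c * 100.0


def _has_valley(scan: LineScan, threshold_pct: float, reference: str) -> bool:
    if reference == "self":
        vals = scan.intensities
        peak = vals.max() if vals.size else 0.0
        if peak <= 0:
            return False
        if not math.isclose(peak, 100.0, rel_tol=1e-6):
            warnings.warn("profile not normalized to peak 100; normalizing",
                          stacklevel=3)
        vals = vals / peak * 100.0
    elif reference == "sphere":
        vals = _sphere_referenced(scan)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    lo, hi = VALLEY_WINDOW
    middle = (scan.positions > lo) & (scan.positions < hi)
    return bool(np.any(vals[middle] < threshold_pct))


def classify_necrosis(profile_x: LineScan, profile_y: LineScan,
                      threshold_pct: float = NECROSIS_THRESHOLD_PCT,
                      reference: str = "self") -> str:
    """Score a colony from its two orthogonal line scans.

    A 'valley' is any sample in the middle two-thirds of a scan falling
    below ``threshold_pct`` of the reference peak.  Valleys in both scans
    mark the colony *possibly necrotic*; a valley in exactly one scan is
    the signature of a paper fiber crossing the colony; none means no
    evidence of necrosis.
    """
    vx = _has_valley(profile_x, threshold_pct, reference)
    vy = _has_valley(profile_y, threshold_pct, reference)
    if vx and vy:
        return NecrosisClass.POSSIBLY_NECROTIC
    if vx or vy:
        return NecrosisClass.SINGLE_VALLEY_FIBER
    return NecrosisClass.NO_VALLEY


def extract_profiles(image: FluorescenceImage, colony: ColonyRecord,
                     background: Optional[np.ndarray] = None,
                     ) -> tuple[LineScan, LineScan]:
    """1-pixel-wide line scans along the colony's longest and orthogonal axes.

    The longest axis is the major axis of the focus's intensity-weighted
    second moments (ties break toward the image x-axis).  Scans pass
    through the weighted centroid, span the component's extent along each
    axis, sample with bilinear interpolation, are smoothed with a 3-sample
    moving average (single 1-px samples are shot-noise limited), and are
    normalized to peak 100 / length 100.  A single-pixel colony yields
    flat profiles.
    """
    bgsub = background if background is not None else subtract_background(image)
    if colony.pixel_labels is None:
        raise ValueError("colony has no pixel mask; run detect_foci first")
    mask = colony.pixel_labels
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty colony mask")
    w = bgsub[rows, cols]
    total = w.sum()
    if total <= 0:
        w = np.ones_like(w)
        total = w.sum()
    cr = (rows * w).sum() / total
    cc = (cols * w).sum() / total
    if rows.size == 1:
        flat = LineScan(np.array([0.0, 100.0]), np.array([100.0, 100.0]))
        return replace(flat, axis="longest"), replace(flat, axis="orthogonal")

    # intensity-weighted second moments -> major axis angle
    dr, dc = rows - cr, cols - cc
    mrr = (w * dr * dr).sum() / total
    mcc = (w * dc * dc).sum() / total
    mrc = (w * dr * dc).sum() / total
    # angle of the major axis measured from the image x (column) axis
    if abs(mrc) < 1e-12 and abs(mrr - mcc) < 1e-12:
        angle = 0.0  # isotropic: tie-break toward the x-axis
    else:
        angle = 0.5 * math.atan2(2.0 * mrc, mcc - mrr)
    ux, uy = math.cos(angle), math.sin(angle)  # (col, row) direction

    def scan_along(vx: float, vy: float, axis: str) -> LineScan:
        proj = dc * vx + dr * vy
        lo, hi = proj.min() - 1.0, proj.max() + 1.0
        src = (cr + lo * vy, cc + lo * vx)  # (row, col)
        dst = (cr + hi * vy, cc + hi * vx)
        prof = measure.profile_line(bgsub, src, dst, linewidth=1, order=1,
                                    mode="constant", cval=0.0,
                                    reduce_func=np.mean)
        if prof.size >= 3:
            prof = np.convolve(np.pad(prof, 1, mode="edge"),
                               np.ones(3) / 3.0, mode="valid")
        positions = np.linspace(0.0, 100.0, prof.size)
        peak = prof.max()
        intensities = prof / peak * 100.0 if peak > 0 else prof
        return LineScan(positions, intensities, axis=axis)

    return (scan_along(ux, uy, "longest"),
            scan_along(-uy, ux, "orthogonal"))


# --- seeding arithmetic -------------------------------------------------------

def expected_cell_count(density: float,
                        dims: Optional[Sequence[float]] = None,
                        volume_ul: Optional[float] = None) -> float:
    """Expected number of seeded cells in a volume.

    ``density`` is in cells/ml; the volume is given either as ``dims``
    (um x um x um) or directly as ``volume_ul``.  Round the result for the
    nearest-integer convenience value.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if (dims is None) == (volume_ul is None):
        raise ValueError("give exactly one of dims or volume_ul")
    if dims is not None:
        if len(dims) != 3:
            raise ValueError("dims must be (x, y, z) in um")
        volume_um3 = float(np.prod(np.asarray(dims, dtype=float)))
    else:
        volume_um3 = volume_ul * 1e9  # 1 ul = 1e9 um^3
    cells_per_um3 = density / 1e12  # 1 ml = 1e12 um^3
    return cells_per_um3 * volume_um3


def cloning_efficiency(n_colonies: int, n_seeded: float) -> float:
    """Percentage of seeded single cells that produced a detectable colony."""
    if n_seeded <= 0:
        raise ValueError("n_seeded must be positive")
    return 100.0 * n_colonies / n_seeded


# --- pipeline convenience -----------------------------------------------------

def score_image(image: FluorescenceImage,
                threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                min_area: float = DEFAULT_MIN_AREA_UM2,
                reference: str = "self") -> pd.DataFrame:
    """Full scoring pipeline: detect, profile, classify; one row per colony."""
    bgsub = subtract_background(image)
    records = detect_foci(image, threshold_fraction, min_area, background=bgsub)
    rows = []
    for rec in records:
        px, py = extract_profiles(image, rec, background=bgsub)
        rec.profile_x, rec.profile_y = px, py
        rec.necrosis_class = classify_necrosis(px, py, reference=reference)
        rows.append({
            "label": rec.label,
            "centroid_row_px": rec.centroid[0],
            "centroid_col_px": rec.centroid[1],
            "area_um2": rec.area,
            "equivalent_radius_um": rec.equivalent_radius,
            "sphere_volume_um3": rec.sphere_volume,
            "necrosis_class": rec.necrosis_class,
        })
    return pd.DataFrame(rows)
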