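"""Per-fiber morphometry on instance-segmented muscle cross-sections.

The segmentation (Cellpose in the original acquisition workflow; any
instance label mask is accepted, and :func:`fallback_segment` provides a
classical watershed stand-in for testing) is post-processed with a QC
filter that removes fibers touching the image border, isolated fibers,
and irregular shapes (low solidity or rough boundary).  Retained fibers
are then measured: area, minimum Feret diameter (exact rotating-calipers
width of the convex hull of the pixel outline) and internal-nuclei count
(connected DAPI components whose centroid lies deeper than a margin
inside the fiber).  Masks are organizationally divided into patches by
fiber centroid; patching never changes any per-fiber value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, cKDTree
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import segmentation as skseg

from .io import SectionImage

__all__ = [
    "QCParams",
    "qc_filter",
    "min_feret",
    "count_internal_nuclei",
    "fiber_table",
    "fallback_segment",
    "FIBER_TABLE_COLUMNS",
]

#: fixed, documented column order of the fiber table
FIBER_TABLE_COLUMNS = [
    "fiber_id",
    "patch_row",
    "patch_col",
    "area_um2",
    "min_feret_um",
    "n_internal_nuclei",
    "nuclei_per_um2",
    "solidity",
    "boundary_roughness",
    "centroid_row",
    "centroid_col",
]


@dataclass
class QCParams:
    """QC thresholds for fiber filtering (all configurable).

    Defaults are conservative: they remove segmentation artifacts (merged
    or fragmented fibers, border clips, stray isolated objects) without
    biasing the size distribution.
    """

    s_min: float = 0.85  # solidity floor (area / convex area)
    rho_max: float = 1.25  # boundary roughness ceiling (perimeter / hull perimeter)
    a_min: float = 50.0  # µm² area floor
    isolation_radius: float = 60.0  # µm; no other centroid within -> isolated
    patch_size: int = 512  # px, organizational patch side
    exclude_border: bool = True  # drop fibers clipped by the image border

    def __post_init__(self):
        if not (0 < self.s_min <= 1):
            raise ValueError("s_min must be in (0, 1]")
        if min(self.rho_max, self.a_min, self.isolation_radius, self.patch_size) <= 0:
            raise ValueError("QC parameters must be strictly positive")


_CORNERS = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])


def min_feret(region, pixel_size: float) -> float:
    """Minimum Feret diameter (µm) of a pixel region.

    The region is either a boolean mask or an (N, 2) array of pixel
    coordinates.  The outline is represented by the four corners of every
    pixel (so a 20-px-wide square at 0.5 µm/px measures exactly 10 µm);
    the minimum width of the convex hull is then exact: the minimal
    supporting-line distance is attained flush with a hull edge, so the
    minimum over hull edges of the farthest-vertex distance is returned.
    """
    if pixel_size is None or not pixel_size > 0:
        raise ValueError("pixel_size (µm/px) required")
    coords = np.argwhere(region) if np.asarray(region).dtype == bool else np.asarray(region)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("empty region")
    if coords.shape[0] == 1:
        warnings.warn("single-pixel region: min Feret is one pixel width", stacklevel=2)
        return float(pixel_size)
    pts = (coords[:, None, :] + _CORNERS[None]).reshape(-1, 2).astype(float)
    hull = ConvexHull(pts)
    v = pts[hull.vertices]  # counter-clockwise
    edges = np.roll(v, -1, axis=0) - v
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 0
    e = edges[keep] / lengths[keep, None]
    # distance of every hull vertex from each edge's supporting line
    rel = v[None, :, :] - v[keep][:, None, :]
    dists = np.abs(rel[..., 0] * e[:, None, 1] - rel[..., 1] * e[:, None, 0])
    width = dists.max(axis=1).min()
    return float(width * pixel_size)


def _region_metrics(region, pixel_size: float, shape) -> dict:
    area_um2 = region.area * pixel_size**2
    minr, minc, maxr, maxc = region.bbox
    touches = minr == 0 or minc == 0 or maxr == shape[0] or maxc == shape[1]
    per = skmeasure.perimeter_crofton(region.image, directions=4)
    hull_per = skmeasure.perimeter_crofton(region.image_convex, directions=4)
    rough = max(1.0, per / hull_per) if hull_per > 0 else 1.0
    return dict(
        fiber_id=int(region.label),
        area_um2=float(area_um2),
        solidity=float(region.solidity),
        boundary_roughness=float(rough),
        touches_border=bool(touches),
        centroid_row=float(region.centroid[0]),
        centroid_col=float(region.centroid[1]),
    )


def qc_filter(
    label_mask: np.ndarray, pixel_size: float, qc: QCParams | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove border-touching, isolated and irregular fibers.

    Returns ``(filtered_mask, report)``.  The report has one row per input
    fiber with its metrics, a ``qc_pass`` flag and, for removed fibers,
    the first rule failed (rule order: touches_border, isolated, area,
    solidity, roughness).  Label identities are preserved.  Isolation is
    pruned to a fixed point so the filter is idempotent: a fiber is
    isolated when no other *retained* fiber centroid lies within
    ``isolation_radius``.
    """
    if pixel_size is None or not pixel_size > 0:
        raise ValueError("pixel_size (µm/px) required")
    qc = qc or QCParams()
    mask = np.asarray(label_mask)
    regions = skmeasure.regionprops(mask)
    if not regions:
        return mask.copy(), pd.DataFrame(
            columns=[
                "fiber_id",
                "area_um2",
                "solidity",
                "boundary_roughness",
                "touches_border",
                "isolated",
                "qc_pass",
                "failed_rule",
            ]
        )
    rows = [_region_metrics(r, pixel_size, mask.shape) for r in regions]
    df = pd.DataFrame(rows)
    shape_ok = (
        (~df["touches_border"] | (not qc.exclude_border))
        & (df["area_um2"] >= qc.a_min)
        & (df["solidity"] >= qc.s_min)
        & (df["boundary_roughness"] <= qc.rho_max)
    ).to_numpy()

    cents = df[["centroid_row", "centroid_col"]].to_numpy() * pixel_size
    retained = shape_ok.copy()
    isolated = np.zeros(len(df), dtype=bool)
    while np.isfinite(qc.isolation_radius):  # inf disables the rule
        idx = np.flatnonzero(retained)
        if idx.size == 0:
            break
        tree = cKDTree(cents[idx])
        neigh = tree.query_ball_point(cents[idx], qc.isolation_radius)
        iso_now = np.array([len(nb) <= 1 for nb in neigh])  # only itself
        if not iso_now.any():
            break
        isolated[idx[iso_now]] = True
        retained[idx[iso_now]] = False
    df["isolated"] = isolated
    df["qc_pass"] = retained

    failed = []
    for _, row in df.iterrows():
        if row["qc_pass"]:
            failed.append("")
        elif qc.exclude_border and row["touches_border"]:
            failed.append("touches_border")
        elif row["area_um2"] < qc.a_min:
            failed.append("area")
        elif row["solidity"] < qc.s_min:
            failed.append("solidity")
        elif row["boundary_roughness"] > qc.rho_max:
            failed.append("roughness")
        else:
            failed.append("isolated")
    df["failed_rule"] = failed

    keep_labels = set(df.loc[df["qc_pass"], "fiber_id"].astype(int))
    out = np.where(np.isin(mask, list(keep_labels)), mask, 0)
    return out, df


def count_internal_nuclei(
    fiber_mask: np.ndarray,
    dapi: np.ndarray,
    pixel_size: float,
    margin: float = 2.0,
    nucleus_min_area: float = 8.0,
    threshold: float | None = None,
) -> int:
    """Count nuclei whose centroid lies deeper than ``margin`` µm inside.

    Nuclei are connected components of the thresholded DAPI channel within
    the fiber's bounding box (Otsu by default), kept when their area is at
    least ``nucleus_min_area`` µm².  Sub-sarcolemmal (peripheral) nuclei
    sit at the membrane, so a nucleus is *internal* iff its centroid falls
    inside the fiber eroded by ``margin``.
    """
    fiber_mask = np.asarray(fiber_mask, dtype=bool)
    if not fiber_mask.any():
        raise ValueError("empty fiber region")
    rs, cs = np.nonzero(fiber_mask)
    r0, r1 = rs.min(), rs.max() + 1
    c0, c1 = cs.min(), cs.max() + 1
    sub_fiber = fiber_mask[r0:r1, c0:c1]
    sub_dapi = np.asarray(dapi, dtype=float)[r0:r1, c0:c1]

    # pad with background so depth is measured to the true boundary even
    # where the fiber touches its own bounding box
    inside = (
        ndimage.distance_transform_edt(np.pad(sub_fiber, 1))[1:-1, 1:-1] * pixel_size
    )
    interior = inside > margin
    if not interior.any():
        warnings.warn(
            "margin erodes the fiber interior to nothing; returning 0", stacklevel=2
        )
        return 0
    if threshold is None:
        if np.ptp(sub_dapi) == 0:
            return 0
        threshold = skfilters.threshold_otsu(sub_dapi)
    labels, n = ndimage.label(sub_dapi > threshold)
    if n == 0:
        return 0
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    cents = ndimage.center_of_mass(np.ones_like(labels), labels, np.arange(1, n + 1))
    count = 0
    min_px = nucleus_min_area / pixel_size**2
    for area, (cy, cx) in zip(areas, cents):
        if area < min_px:
            continue
        iy, ix = int(round(cy)), int(round(cx))
        if 0 <= iy < interior.shape[0] and 0 <= ix < interior.shape[1] and interior[iy, ix]:
            count += 1
    return count


def fiber_table(
    image: SectionImage,
    label_mask: np.ndarray,
    qc: QCParams | None = None,
    *,
    margin: float = 2.0,
    nucleus_min_area: float = 8.0,
) -> pd.DataFrame:
    """QC-filter a mask and measure every retained fiber.

    Fibers are assigned to patches of ``qc.patch_size`` px by centroid;
    the patch indices are recorded but all measurements are made on the
    full-frame region, so patching is purely organizational.
    Column order is :data:`FIBER_TABLE_COLUMNS`.
    """
    qc = qc or QCParams()
    ps = image.pixel_size
    filtered, report = qc_filter(label_mask, ps, qc)
    dapi = image.channel("DAPI")
    rows = []
    for region in skmeasure.regionprops(filtered):
        fid = int(region.label)
        minr, minc, _, _ = region.bbox
        coords = region.coords
        feret = min_feret(coords, ps)
        fiber_full = filtered == fid
        n_nuc = count_internal_nuclei(
            fiber_full, dapi, ps, margin=margin, nucleus_min_area=nucleus_min_area
        )
        rep = report.loc[report["fiber_id"] == fid].iloc[0]
        area = float(rep["area_um2"])
        rows.append(
            dict(
                fiber_id=fid,
                patch_row=int(rep["centroid_row"] // qc.patch_size),
                patch_col=int(rep["centroid_col"] // qc.patch_size),
                area_um2=area,
                min_feret_um=feret,
                n_internal_nuclei=n_nuc,
                nuclei_per_um2=n_nuc / area,
                solidity=float(rep["solidity"]),
                boundary_roughness=float(rep["boundary_roughness"]),
                centroid_row=float(rep["centroid_row"]),
                centroid_col=float(rep["centroid_col"]),
            )
        )
    return pd.DataFrame(rows, columns=FIBER_TABLE_COLUMNS)


def fallback_segment(image: SectionImage, marker_depth_um: float = 1.5) -> np.ndarray:
    """Classical watershed segmentation of fibers from the boundary stain.

    A testing fallback, not a Cellpose re-implementation: fibers are the
    low-intensity interior of the (smoothed) perlecan boundary channel,
    split by a watershed on the inverted, smoothed interior distance
    transform seeded from its h-maxima (prominence ``marker_depth_um``).
    Deterministic for a given input.
    """
    perl = np.asarray(image.channel("PERLECAN"), dtype=float)
    if np.ptp(perl) == 0:
        raise ValueError("flat boundary channel: cannot segment")
    ps = image.pixel_size
    smooth = skfilters.gaussian(perl, sigma=1.0, preserve_range=True)
    interior = smooth < skfilters.threshold_otsu(smooth)
    dist = ndimage.distance_transform_edt(interior)
    dist = skfilters.gaussian(dist, sigma=4.0, preserve_range=True)
    h = max(1.0, marker_depth_um / ps)
    markers, n = ndimage.label(skmorph.h_maxima(dist, h))
    if n == 0:
        raise ValueError("no fiber seeds found")
    return skseg.watershed(-dist, markers, mask=interior).astype(np.int32)
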