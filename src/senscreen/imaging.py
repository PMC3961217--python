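"""Per-well percent-marker-positive quantification from two-channel images.

The readout contract mirrors an automated high-content analysis: the
nuclear channel determines the total cell number per image, each cell is
called marker-positive or -negative from its marker-channel mean
intensity, the percent positive is computed per image, and the per-image
percentages of a well are averaged (unweighted) into the well value.

Segmentation is deliberately simple — a between-class-variance (Otsu)
global threshold on the nuclear channel, connected components, and an
area filter — because the synthetic generator enforces nucleus
separation. Positivity is a per-cell binary call against a threshold
calibrated from uninduced scrambled-control cells (mean + k*SD of their
marker intensities); this calibration rule is this package's own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops_table
from skimage.segmentation import watershed

__all__ = [
    "DegenerateImageError",
    "segment_nuclei",
    "classify_positive",
    "calibrate_threshold",
    "quantify_well",
    "quantify_cell_table",
    "summarize_wells",
]


class DegenerateImageError(ValueError):
    """Raised when an image is constant and no threshold exists."""


def segment_nuclei(
    nuclear_image: np.ndarray,
    marker_image: np.ndarray | None = None,
    min_area: int = 15,
    max_area: int = 2000,
    split_touching: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei in the nuclear channel and measure both channels.

    Parameters
    ----------
    nuclear_image
        2-D non-negative array (the nuclear-stain channel).
    marker_image
        Optional same-shape marker channel; region mean intensities are
        measured in it when given.
    min_area, max_area
        Region-area filter in pixels; components outside the range are
        discarded.
    split_touching
        Apply a distance-transform watershed to split touching nuclei
        (off by default; the synthetic generator enforces separation).

    Returns
    -------
    labels, cells
        Label image and a per-cell table with columns (row, col,
        nuclear_intensity, marker_intensity); centroids are 0-based
        (row, col) pixel coordinates.
    """
    img = np.asarray(nuclear_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclear_image must be 2-D")
    if np.ptp(img) == 0:
        raise DegenerateImageError("constant image: no foreground threshold exists")
    thr = threshold_otsu(img)
    mask = img > thr
    if split_touching and mask.any():
        from scipy import ndimage as ndi
        from skimage.feature import peak_local_max

        dist = ndi.distance_transform_edt(mask)
        coords = peak_local_max(dist, labels=mask, min_distance=3)
        markers = np.zeros(mask.shape, dtype=int)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = watershed(-dist, markers, mask=mask)
    else:
        labels = label(mask)

    if labels.max() == 0:
        return labels, _empty_cells()

    props = regionprops_table(
        labels, intensity_image=img, properties=("label", "area", "centroid", "intensity_mean")
    )
    cells = pd.DataFrame(props).rename(
        columns={
            "centroid-0": "row",
            "centroid-1": "col",
            "intensity_mean": "nuclear_intensity",
        }
    )
    if marker_image is not None:
        mprops = regionprops_table(
            labels, intensity_image=np.asarray(marker_image, dtype=float),
            properties=("label", "intensity_mean"),
        )
        cells = cells.merge(
            pd.DataFrame(mprops).rename(columns={"intensity_mean": "marker_intensity"}),
            on="label",
        )
    else:
        cells["marker_intensity"] = np.nan

    keep = (cells["area"] >= min_area) & (cells["area"] <= max_area)
    cells = cells.loc[keep].reset_index(drop=True)
    kept = cells["label"].to_numpy()
    labels = np.where(np.isin(labels, kept), labels, 0)
    return labels, cells[["label", "area", "row", "col", "nuclear_intensity", "marker_intensity"]]


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["label", "area", "row", "col", "nuclear_intensity", "marker_intensity"]
    )


def classify_positive(
    cells: pd.DataFrame, marker_threshold: float
) -> tuple[pd.DataFrame, float]:
    """Flag marker-positive cells and compute the image percent positive.

    A cell is positive iff its marker mean intensity strictly exceeds the
    threshold. An empty cell table yields NaN (a missing value), never 0.
    """
    if not np.isfinite(marker_threshold):
        raise ValueError("marker_threshold must be finite")
    cells = cells.copy()
    cells["positive"] = cells["marker_intensity"] > marker_threshold
    if len(cells) == 0:
        return cells, float("nan")
    return cells, 100.0 * float(cells["positive"].mean())


def calibrate_threshold(control_marker_intensities, k: float = 3.0) -> float:
    """Marker-positivity threshold from uninduced-control cells.

    threshold = mean + k * SD of the pooled marker intensities of cells
    from uninduced scrambled-control wells (default k = 3).
    """
    x = np.asarray(control_marker_intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no uninduced control cells available for calibration")
    return float(x.mean() + k * x.std(ddof=1 if x.size > 1 else 0))


def quantify_well(image_percents) -> dict:
    """Aggregate per-image percent-positive values into a well value.

    The well percent positive is the unweighted mean of the per-image
    percentages (not the pooled-cell percentage); missing images (NaN)
    are excluded. If every image is missing the well is flagged missing.
    """
    p = np.asarray(image_percents, dtype=float)
    valid = np.isfinite(p)
    if not valid.any():
        return {"pct_positive": float("nan"), "n_images": int(p.size), "missing": True}
    return {
        "pct_positive": float(p[valid].mean()),
        "n_images": int(p.size),
        "missing": False,
    }


def quantify_cell_table(
    cells: pd.DataFrame, marker_threshold: float
) -> pd.DataFrame:
    """Per-image quantification of a (plate, well, field) cell table.

    Returns one row per image with columns (plate, well, field, n_cells,
    n_positive, pct_positive).
    """
    if not np.isfinite(marker_threshold):
        raise ValueError("marker_threshold must be finite")
    df = cells.copy()
    df["positive"] = df["marker_intensity"] > marker_threshold
    per_image = (
        df.groupby(["plate", "well", "field"], observed=True)
        .agg(n_cells=("marker_intensity", "size"), n_positive=("positive", "sum"))
        .reset_index()
    )
    per_image["pct_positive"] = np.where(
        per_image["n_cells"] > 0,
        100.0 * per_image["n_positive"] / per_image["n_cells"],
        np.nan,
    )
    return per_image


def summarize_wells(per_image: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-image quantification to one row per well.

    The well percent positive is the unweighted mean over its non-missing
    images, matching :func:`quantify_well`.
    """
    rows = []
    for (plate, well), grp in per_image.groupby(["plate", "well"], observed=True):
        q = quantify_well(grp["pct_positive"].to_numpy())
        rows.append(
            {
                "plate": plate,
                "well": well,
                "n_images": q["n_images"],
                "n_cells": int(grp["n_cells"].sum()),
                "pct_positive": q["pct_positive"],
                "missing": q["missing"],
            }
        )
    return pd.DataFrame(rows)
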