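"""Nuclei-mask construction: threshold, label, split, measure.

The DNA-stain channel is separated from background by a global fluorescence
intensity (FI) threshold — Otsu by default, or a user-supplied manual value,
since the original acquisition software lets the operator place it.  Pixels
strictly above the threshold are foreground; connected components become
candidate nuclei; an optional marker-controlled watershed on the distance
transform re-partitions clumps of touching nuclei.  Measurements are taken
on the raw intensities (no background subtraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import DegenerateHistogramError
from .imaging_io import Image2D, ROISpec

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class LabelMap:
    """Integer label raster: 0 = background, 1..n_objects = nuclei.

    Labels form a contiguous range ordered by the raster-scan position of
    each object's first pixel, so identical inputs always yield identical
    label assignments.
    """

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")


@dataclass
class NucleusRecord:
    """Morphometry of one segmented nucleus."""

    label: int
    area_px: int
    area_um2: float
    mean_fi: float
    centroid_um: tuple[float, float]
    touches_roi_border: bool
    is_netotic: bool | None = None
    roi_index: int | None = None


def compute_fi_threshold(
    image: Image2D, method: str = "otsu", manual_value: float | None = None
) -> float:
    """FI threshold separating background noise from stained nuclei.

    Pixels strictly above the returned value are foreground candidates.
    """
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual thresholding requires manual_value")
        if not 0 <= manual_value <= image.intensity_max:
            raise ValueError(
                f"manual_value {manual_value} outside [0, {image.intensity_max}]"
            )
        return float(manual_value)
    if method == "otsu":
        px = image.pixels
        if px.min() == px.max():
            raise DegenerateHistogramError(
                "constant image: no histogram valley for Otsu thresholding"
            )
        return float(threshold_otsu(px))
    raise ValueError(f"unknown threshold method {method!r}")


def _relabel_raster_order(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber positive labels 1..n by raster-scan order of first pixel."""
    flat = labels.ravel()
    values, first = np.unique(flat, return_index=True)
    mask = values > 0
    values, first = values[mask], first[mask]
    order = np.argsort(first)
    mapping = np.zeros(int(values.max()) + 1 if values.size else 1, dtype=labels.dtype)
    mapping[values[order]] = np.arange(1, len(values) + 1)
    return mapping[labels], len(values)


def segment_nuclei(image: Image2D, threshold: float, connectivity: int = 8) -> LabelMap:
    """Label connected foreground components (intensity > threshold)."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    foreground = image.pixels > threshold
    labeled, _ = ndi.label(foreground, structure=_STRUCTURES[connectivity])
    labeled, n = _relabel_raster_order(labeled)
    return LabelMap(labels=labeled, n_objects=n)


def split_touching_nuclei(
    labelmap: LabelMap, image: Image2D, min_peak_separation_um: float = 4.0
) -> LabelMap:
    """Re-partition clumps by watershed on the distance transform.

    Markers are local maxima of the Euclidean distance transform at least
    ``min_peak_separation_um`` apart, found independently within each object.
    Objects yielding a single marker pass through unchanged; the object count
    never decreases.  ``min_peak_separation_um = inf`` disables the stage.
    """
    if labelmap.labels.shape != image.pixels.shape:
        raise ValueError("labelmap and image shapes differ")
    if not np.isfinite(min_peak_separation_um):
        return labelmap
    if labelmap.n_objects == 0:
        return labelmap
    mask = labelmap.labels > 0
    dist = ndi.distance_transform_edt(mask, sampling=image.pixel_size_um)
    # one pixel of smoothing removes the jagged secondary maxima that a
    # rasterised boundary induces along an elongated object's medial axis
    dist = ndi.gaussian_filter(dist, sigma=1.0)  # sigma in pixels
    min_dist_px = max(1, int(round(min_peak_separation_um / image.pixel_size_um)))
    coords = peak_local_max(
        dist,
        min_distance=min_dist_px,
        labels=labelmap.labels,
        exclude_border=False,
    )
    peaks_by_label: dict[int, list[tuple[int, int]]] = {}
    for r, c in coords:
        peaks_by_label.setdefault(int(labelmap.labels[r, c]), []).append((r, c))

    # watershed only the multi-marker clumps, each within its own bounding
    # box, so single-marker objects pass through bit-identically and the
    # foreground partition is preserved exactly
    out = labelmap.labels.copy()
    next_label = labelmap.n_objects + 1
    for lab, sl in enumerate(ndi.find_objects(labelmap.labels), start=1):
        if sl is None or len(peaks_by_label.get(lab, ())) < 2:
            continue
        region = labelmap.labels[sl] == lab
        markers = np.zeros(region.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks_by_label[lab], start=1):
            markers[r - sl[0].start, c - sl[1].start] = i
        pieces = watershed(-dist[sl], markers=markers, mask=region, connectivity=2)
        for i in range(1, markers.max() + 1):
            out[sl][pieces == i] = next_label
            next_label += 1
    labels, n = _relabel_raster_order(out)
    return LabelMap(labels=labels, n_objects=n)


def measure_nuclei(labelmap: LabelMap, image: Image2D, roi: ROISpec | None = None) -> list[NucleusRecord]:
    """Per-object morphometry inside one ROI.

    ``labelmap``/``image`` are already restricted to the ROI raster; ``roi``
    supplies the physical offset of its top-left corner.  ``mean_fi`` is the
    arithmetic mean of raw pixel intensities over the object;
    ``touches_roi_border`` flags objects with any pixel on the ROI's first or
    last row/column, which the filter stage can exclude so partially captured
    cells are never measured.
    """
    if labelmap.labels.shape != image.pixels.shape:
        raise ValueError("labelmap and image shapes differ")
    if labelmap.n_objects == 0:
        return []
    s = image.pixel_size_um
    x_off = roi.x0_um if roi is not None else 0.0
    y_off = roi.y0_um if roi is not None else 0.0
    roi_index = roi.index if roi is not None else None
    n_rows, n_cols = labelmap.labels.shape
    records: list[NucleusRecord] = []
    for rp in regionprops(labelmap.labels, intensity_image=image.pixels):
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == n_rows or c1 == n_cols
        cy, cx = rp.centroid  # (row, col) in pixel index space
        records.append(
            NucleusRecord(
                label=int(rp.label),
                area_px=int(rp.area),
                area_um2=float(rp.area) * s * s,
                mean_fi=float(rp.intensity_mean),
                centroid_um=(x_off + (cx + 0.5) * s, y_off + (cy + 0.5) * s),
                touches_roi_border=bool(touches),
                roi_index=roi_index,
            )
        )
    records.sort(key=lambda r: r.label)
    return records


def records_to_csv(records: list[NucleusRecord], path) -> None:
    """Write a per-nucleus morphometry table."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "label": r.label,
                "area_px": r.area_px,
                "area_um2": r.area_um2,
                "mean_fi": r.mean_fi,
                "centroid_x_um": r.centroid_um[0],
                "centroid_y_um": r.centroid_um[1],
                "touches_roi_border": r.touches_roi_border,
            }
            for r in records
        ],
        columns=[
            "label",
            "area_px",
            "area_um2",
            "mean_fi",
            "centroid_x_um",
            "centroid_y_um",
            "touches_roi_border",
        ],
    ).to_csv(path, index=False)
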