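"""Per-plane image analysis: organoid and nucleus segmentation.

The pipeline mirrors standard high-content practice for spheroid
cultures: organoids are segmented per z-plane from the *combined*
three-channel image (so dye-positive dead cells still contribute to the
organoid footprint), debris is removed with a morphological open plus a
hard area floor (default 250 um^2, which excludes single cells and small
clumps), and nuclei are found inside organoid regions by local-maxima
seeded watershed on the Hoechst channel.  All quantification is 2D,
plane by plane; intersections of one organoid on several planes are
deliberately counted as separate objects (the sampled, not absolute,
organoid load).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, dilation, disk, erosion
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator

from .geometry import AcquisitionGeometry
from .synth import RenderedField

__all__ = [
    "ImageStack",
    "WellLoad",
    "combine_channels",
    "OrganoidSegmenter",
    "NucleusSegmenter",
    "extract_intensities",
    "segment_stack",
    "SegmentationResult",
    "quantify_well",
    "MIN_ORGANOID_AREA",
]

#: Area floor for organoid regions, um^2; objects below it are treated as
#: single cells, small clumps or debris and excluded.
MIN_ORGANOID_AREA = 250.0

CHANNEL_NAMES = ("hoechst", "caspase", "pi")


@dataclass
class ImageStack:
    """One field's 3-channel z-stack plus its acquisition geometry."""

    hoechst: np.ndarray
    caspase: np.ndarray
    pi: np.ndarray
    geometry: AcquisitionGeometry
    well_id: str = ""
    field_id: int = 0

    def __post_init__(self) -> None:
        shapes = {np.asarray(getattr(self, c)).shape for c in CHANNEL_NAMES}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValueError("channels must be (planes, rows, cols) arrays")
        for c in CHANNEL_NAMES:
            arr = np.asarray(getattr(self, c))
            if (arr < 0).any():
                raise ValueError(f"negative intensities in channel {c!r}")

    @property
    def n_planes(self) -> int:
        return self.hoechst.shape[0]

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {c: getattr(self, c) for c in CHANNEL_NAMES}

    @classmethod
    def from_rendered(
        cls, rendered: RenderedField, well_id: str = "", field_id: int = 0
    ) -> "ImageStack":
        return cls(
            hoechst=rendered.hoechst,
            caspase=rendered.caspase,
            pi=rendered.pi,
            geometry=rendered.geometry,
            well_id=well_id,
            field_id=field_id,
        )


def combine_channels(stack: ImageStack, plane: int, mode: str = "sum") -> np.ndarray:
    """Merge the three channels of one plane into a single image.

    Each channel is rescaled to a common [0, 1] dynamic range (divide by
    its own stack-plane maximum) before combining, so a dim channel is
    not drowned out by a bright one.  ``mode`` is ``"sum"`` (default) or
    ``"max"``.
    """
    if not 0 <= plane < stack.n_planes:
        raise IndexError(f"plane {plane} out of range [0, {stack.n_planes})")
    scaled = []
    for name in CHANNEL_NAMES:
        img = np.asarray(getattr(stack, name)[plane], dtype=np.float64)
        peak = img.max()
        scaled.append(img / peak if peak > 0 else img)
    if mode == "sum":
        return np.sum(scaled, axis=0)
    if mode == "max":
        return np.max(scaled, axis=0)
    raise ValueError(f"unknown combine mode {mode!r}")


def _accept_threshold(vals: np.ndarray, t: float, min_contrast: float) -> bool:
    """Reject a threshold that only splits background noise: a plane with
    no real objects has a foreground/background mean ratio near 1."""
    fg, bg = vals[vals > t], vals[vals <= t]
    if fg.size == 0 or bg.size == 0:
        return False
    bg_mean = bg.mean()
    return bg_mean <= 0 or fg.mean() / bg_mean >= min_contrast


def _contrast_threshold(
    img: np.ndarray,
    mask: np.ndarray | None,
    min_contrast: float,
    classes: int = 2,
) -> float | None:
    """Otsu threshold with a contrast sanity check; ``None`` = no objects.

    With ``classes=3`` a three-class multi-Otsu is used and the *lowest*
    threshold returned — on organoid planes the histogram is trimodal
    (background, dim organoid body, bright nuclei) and two-class Otsu
    would cut above the body plateau.
    """
    vals = img[mask] if mask is not None else img.ravel()
    if vals.size == 0 or np.ptp(vals) == 0:
        return None
    try:
        t = float(
            threshold_multiotsu(vals, classes=classes)[0]
            if classes > 2
            else threshold_otsu(vals)
        )
    except ValueError:  # fewer distinct values than classes
        t = float(threshold_otsu(vals))
    return t if _accept_threshold(vals, t, min_contrast) else None


class OrganoidSegmenter(BaseEstimator):
    """Segment organoid cross-sections from a combined-channel image.

    Stages (standard stand-ins for a high-content vendor pipeline):
    Gaussian blur -> Otsu threshold (with a contrast sanity check) ->
    morphological closing -> region resize (erosion then dilation of
    radius ``resize_radius``, clipping debris-derived fluorescence at the
    periphery) -> connected components -> area floor of ``min_area`` um^2.

    Border-touching regions are retained but flagged in the output table
    (an edge cross-section underestimates the true organoid size).

    Parameters
    ----------
    gaussian_sigma : float, default 2.0
        Blur SD in pixels; must be positive.
    closing_radius : int, default 2
        Disk radius for the closing that bridges gaps between nuclei.
    resize_radius : int, default 2
        Disk radius of the erosion/dilation pair.
    min_area : float, default 250.0
        Exclusion floor in um^2.
    min_contrast : float, default 1.5
        Minimum foreground/background mean ratio for a threshold to be
        believed; below it the plane is called empty.
    """

    def __init__(
        self,
        gaussian_sigma: float = 2.0,
        closing_radius: int = 2,
        resize_radius: int = 2,
        min_area: float = MIN_ORGANOID_AREA,
        min_contrast: float = 1.5,
    ) -> None:
        self.gaussian_sigma = gaussian_sigma
        self.closing_radius = closing_radius
        self.resize_radius = resize_radius
        self.min_area = min_area
        self.min_contrast = min_contrast

    def segment(
        self, combined: np.ndarray, geometry: AcquisitionGeometry
    ) -> tuple[np.ndarray, pd.DataFrame]:
        """Label organoid regions on one plane.

        Returns the int label image (0 = background, labels contiguous
        from 1) and a table with columns ``label``, ``area`` (um^2),
        ``centroid_x``/``centroid_y`` (um) and ``touches_border``.
        """
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        combined = np.asarray(combined, dtype=np.float64)
        smoothed = gaussian(combined, sigma=self.gaussian_sigma, preserve_range=True)
        # log compression + 3-class Otsu: the trimodal histogram
        # (background / organoid body / bright nuclei) would otherwise put
        # a 2-class threshold above the dim body plateau
        compressed = np.log1p(smoothed)
        t = _contrast_threshold(compressed, None, self.min_contrast, classes=3)
        labels = np.zeros(combined.shape, dtype=np.int32)
        cols = ["label", "area", "centroid_x", "centroid_y", "touches_border"]
        if t is None:
            return labels, pd.DataFrame(columns=cols)
        mask = compressed > t
        if self.closing_radius > 0:
            mask = closing(mask, disk(self.closing_radius))
        if self.resize_radius > 0:
            selem = disk(self.resize_radius)
            mask = dilation(erosion(mask, selem), selem)
        raw = cc_label(mask, connectivity=2)
        pixel_area = geometry.pixel_area
        min_pixels = self.min_area / pixel_area
        rows = []
        next_label = 0
        for prop in regionprops(raw):
            if prop.area < min_pixels:
                continue
            next_label += 1
            labels[raw == prop.label] = next_label
            r0, c0, r1, c1 = prop.bbox
            touches = r0 == 0 or c0 == 0 or r1 == raw.shape[0] or c1 == raw.shape[1]
            rows.append(
                {
                    "label": next_label,
                    "area": prop.area * pixel_area,
                    "centroid_x": prop.centroid[1] * geometry.pixel_size,
                    "centroid_y": prop.centroid[0] * geometry.pixel_size,
                    "touches_border": touches,
                }
            )
        return labels, pd.DataFrame(rows, columns=cols)


class NucleusSegmenter(BaseEstimator):
    """Segment nuclei on the Hoechst channel, inside organoid regions only.

    Local maxima of the blurred Hoechst image seed a watershed that is
    confined to the Hoechst-positive subset of the organoid mask, so the
    diffuse organoid body is not swallowed into nucleus regions.  Each
    nucleus is assigned to the organoid containing its centroid (or the
    nearest organoid when rounding puts the centroid on background).

    Parameters
    ----------
    gaussian_sigma : float, default 2.0
        Blur SD in pixels before peak detection.
    min_distance : int, default 5
        Minimum peak separation in pixels; two blobs closer than this
        merge into one nucleus.
    min_contrast : float, default 1.5
        Contrast sanity check for the within-organoid Otsu threshold.
    """

    def __init__(
        self,
        gaussian_sigma: float = 2.0,
        min_distance: int = 5,
        min_contrast: float = 1.5,
    ) -> None:
        self.gaussian_sigma = gaussian_sigma
        self.min_distance = min_distance
        self.min_contrast = min_contrast

    def segment(self, hoechst: np.ndarray, organoid_labels: np.ndarray) -> np.ndarray:
        """Label nuclei on one plane; 0 = background."""
        hoechst = np.asarray(hoechst, dtype=np.float64)
        if hoechst.shape != organoid_labels.shape:
            raise ValueError("hoechst and organoid label shapes differ")
        out = np.zeros(hoechst.shape, dtype=np.int32)
        region = organoid_labels > 0
        if not region.any():
            return out
        smoothed = gaussian(hoechst, sigma=self.gaussian_sigma, preserve_range=True)
        t = _contrast_threshold(smoothed, region, self.min_contrast)
        if t is None:
            return out
        fg = (smoothed > t) & region
        if not fg.any():
            return out
        peaks = peak_local_max(
            smoothed,
            min_distance=self.min_distance,
            threshold_abs=t,
            labels=cc_label(fg, connectivity=2),
            exclude_border=False,
        )
        if peaks.size == 0:
            return out
        markers = np.zeros(hoechst.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        out = watershed(-smoothed, markers=markers, mask=fg)
        return out.astype(np.int32)


def _nearest_label_map(organoid_labels: np.ndarray) -> np.ndarray:
    """Map every pixel to the label of the nearest labelled pixel."""
    if not (organoid_labels > 0).any():
        return organoid_labels
    ind = ndi.distance_transform_edt(
        organoid_labels == 0, return_distances=False, return_indices=True
    )
    return organoid_labels[tuple(ind)]


def extract_intensities(
    stack: ImageStack,
    nucleus_labels: np.ndarray,
    organoid_labels: np.ndarray,
    organoid_id_offset: dict[int, dict[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-nucleus mean dye intensities from the *raw* channel images.

    ``nucleus_labels`` and ``organoid_labels`` are (planes, rows, cols)
    volumes of per-plane labels.  ``organoid_id_offset`` optionally maps
    ``plane -> {plane-local label -> global organoid id}``.  Returns one
    row per nucleus with columns ``nucleus_id``, ``organoid_id``,
    ``well_id``, ``plane``, ``area``, ``mean_caspase``, ``mean_pi``.
    Empty label regions are skipped with a warning.
    """
    nucleus_labels = np.asarray(nucleus_labels)
    organoid_labels = np.asarray(organoid_labels)
    if nucleus_labels.shape != stack.hoechst.shape:
        raise ValueError("nucleus label volume does not match the stack")
    pixel_area = stack.geometry.pixel_area
    rows: list[dict] = []
    for k in range(stack.n_planes):
        plane_nuc = nucleus_labels[k]
        if not (plane_nuc > 0).any():
            continue
        nearest = _nearest_label_map(organoid_labels[k])
        props = regionprops(
            plane_nuc,
            intensity_image=np.stack(
                [stack.caspase[k], stack.pi[k]], axis=-1
            ),
        )
        for prop in props:
            if prop.area == 0:  # pragma: no cover - regionprops drops these
                warnings.warn(f"empty nucleus region on plane {k}; skipped")
                continue
            local = _assign_organoid_from_map(prop.centroid, organoid_labels[k], nearest)
            if organoid_id_offset is not None:
                local = organoid_id_offset.get(k, {}).get(local, 0)
            mean_c, mean_p = prop.intensity_mean
            rows.append(
                {
                    "nucleus_id": int(prop.label),
                    "organoid_id": local,
                    "well_id": stack.well_id,
                    "plane": k,
                    "area": prop.area * pixel_area,
                    "mean_caspase": float(mean_c),
                    "mean_pi": float(mean_p),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "organoid_id",
            "well_id",
            "plane",
            "area",
            "mean_caspase",
            "mean_pi",
        ],
    )


def _assign_organoid_from_map(
    centroid_rc: tuple[float, float], organoid_labels: np.ndarray, nearest: np.ndarray
) -> int:
    r = min(max(int(round(centroid_rc[0])), 0), organoid_labels.shape[0] - 1)
    c = min(max(int(round(centroid_rc[1])), 0), organoid_labels.shape[1] - 1)
    lab = int(organoid_labels[r, c])
    return lab if lab > 0 else int(nearest[r, c])


@dataclass
class SegmentationResult:
    """All outputs of one field's segmentation."""

    organoid_labels: np.ndarray  # (planes, rows, cols), global organoid ids
    nucleus_labels: np.ndarray
    organoids: pd.DataFrame  # organoid_id, well_id, field_id, plane, area, ...
    nuclei: pd.DataFrame  # nucleus_id, organoid_id, well_id, plane, area, means


def segment_stack(
    stack: ImageStack,
    organoid_segmenter: OrganoidSegmenter | None = None,
    nucleus_segmenter: NucleusSegmenter | None = None,
    combine_mode: str = "sum",
) -> SegmentationResult:
    """Run the full per-plane pipeline on one field.

    Organoid ids are made unique across planes (each plane intersection
    is its own object); nucleus records reference those global ids.
    """
    oseg = organoid_segmenter or OrganoidSegmenter()
    nseg = nucleus_segmenter or NucleusSegmenter()
    shape = stack.hoechst.shape
    organoid_vol = np.zeros(shape, dtype=np.int32)
    nucleus_vol = np.zeros(shape, dtype=np.int32)
    organoid_rows: list[pd.DataFrame] = []
    offset_maps: dict[int, dict[int, int]] = {}
    next_org = 0
    next_nuc = 0
    for k in range(stack.n_planes):
        combined = combine_channels(stack, k, mode=combine_mode)
        labels, table = oseg.segment(combined, stack.geometry)
        local_to_global = {}
        for lab in table["label"]:
            next_org += 1
            local_to_global[int(lab)] = next_org
        offset_maps[k] = local_to_global
        if local_to_global:
            lut = np.zeros(max(local_to_global) + 1, dtype=np.int32)
            for loc, glob in local_to_global.items():
                lut[loc] = glob
            organoid_vol[k] = lut[labels]
        if not table.empty:
            table = table.assign(
                organoid_id=[local_to_global[int(l)] for l in table["label"]],
                well_id=stack.well_id,
                field_id=stack.field_id,
                plane=k,
            ).drop(columns=["label"])
            organoid_rows.append(table)
        nuc = nseg.segment(stack.hoechst[k], labels)
        if (nuc > 0).any():
            nuc = nuc.astype(np.int32)
            nuc[nuc > 0] += next_nuc
            next_nuc = int(nuc.max())
            nucleus_vol[k] = nuc

    organoids = (
        pd.concat(organoid_rows, ignore_index=True)
        if organoid_rows
        else pd.DataFrame(
            columns=[
                "area",
                "centroid_x",
                "centroid_y",
                "touches_border",
                "organoid_id",
                "well_id",
                "field_id",
                "plane",
            ]
        )
    )
    # organoid ids in the volume are already global: no offset mapping needed
    nuclei = extract_intensities(stack, nucleus_vol, organoid_vol, None)
    counts = nuclei.groupby("organoid_id").size() if not nuclei.empty else pd.Series(dtype=int)
    organoids["n_nuclei"] = organoids["organoid_id"].map(counts).fillna(0).astype(int) if not organoids.empty else 0
    return SegmentationResult(
        organoid_labels=organoid_vol,
        nucleus_labels=nucleus_vol,
        organoids=organoids,
        nuclei=nuclei,
    )


@dataclass(frozen=True)
class WellLoad:
    """Sampled organoid load of one well (all fields, all planes).

    ``n_organoids`` counts plane intersections as separate objects; the
    numbers are sampled loads over ``sampled_area`` um^2, not absolute
    well contents.
    """

    well_id: str
    n_nuclei: int
    mean_area: float
    n_organoids: int
    sampled_area: float
    day: int | None = None

    def as_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "day": self.day,
            "n_nuclei": self.n_nuclei,
            "mean_area": self.mean_area,
            "n_organoids": self.n_organoids,
            "sampled_area": self.sampled_area,
        }


def quantify_well(
    results: list[SegmentationResult],
    geometry: AcquisitionGeometry,
    well_id: str = "",
    day: int | None = None,
) -> WellLoad:
    """Aggregate per-field segmentation results into one well's load.

    Nuclei and organoid counts sum over planes and fields; mean organoid
    size averages all emitted cross-section areas.  ``sampled_area`` is
    ``n_fields * field_area`` with ``n_fields`` = number of results.
    """
    if not results:
        raise ValueError("quantify_well needs at least one segmented field")
    n_nuclei = int(sum(len(r.nuclei) for r in results))
    n_organoids = int(sum(len(r.organoids) for r in results))
    areas = np.concatenate(
        [r.organoids["area"].to_numpy(dtype=float) for r in results]
    ) if n_organoids else np.array([])
    mean_area = float(areas.mean()) if areas.size else float("nan")
    return WellLoad(
        well_id=well_id,
        n_nuclei=n_nuclei,
        mean_area=mean_area,
        n_organoids=n_organoids,
        sampled_area=len(results) * geometry.field_area,
        day=day,
    )
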