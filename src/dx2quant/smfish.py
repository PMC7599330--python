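"""Two-channel smFISH quantification of exon-skipping isoform ratios.

The assay images transcripts with two RNAscope-style probe sets: a *red*
channel (C2) hybridizing exons shared by the full-length transcript and its
exon-2-skipping variant (AIMP2 and AIMP2-DX2), and a *green* channel (C1)
hybridizing only the skipped exon, hence only the full-length transcript.
DAPI (blue) marks nuclei. Each transcript appears as a diffraction-limited
focus; after thresholding and size-based noise removal, the red/green pixel
*area* ratio tracks the relative abundance of the two isoforms:

    Red/Green = alpha*([FL] + [DX2]) / (beta*[FL])
    [DX2]/[FL] = C * Red/Green - 1,   C = beta/alpha

where alpha and beta are the per-channel probe capture efficiencies. Without
a measured C the ratio is semiquantitative (relative comparisons only).

Quantification proceeds per image (pooled foci areas) and per cell, where
each focus is assigned to the nucleus with the nearest centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "MultiChannelImage",
    "FociObject",
    "Nucleus",
    "ImageQuant",
    "CellQuant",
    "CalibrationModel",
    "CalibrationError",
    "RatioStatus",
    "segment_foci",
    "detect_nuclei",
    "assign_foci_to_cells",
    "quantify_image",
    "quantify_cells",
    "isoform_ratio",
    "quantify_field",
    "summarize_cell_ratios",
]


class CalibrationError(ValueError):
    """Absolute isoform quantification requested from a relative-only model."""


class RatioStatus(str, Enum):
    OK = "ok"
    NO_GREEN = "undefined_no_green"
    EMPTY = "undefined_both_empty"


@dataclass(frozen=True)
class MultiChannelImage:
    """Registered red/green/blue rasters of one field of view.

    All three channels must share the same 2D shape and hold non-negative
    intensities (arbitrary units). ``pixel_size`` is an optional physical
    scale in micrometres per pixel; area outputs stay in px^2 regardless.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.size == 0:
                raise ValueError(f"{name} channel must be a non-empty 2D raster")
            if np.any(arr < 0):
                raise ValueError(f"{name} channel contains negative intensities")
            object.__setattr__(self, name, arr)
        if self.red.shape != self.green.shape or self.red.shape != self.blue.shape:
            raise ValueError("channel rasters must share identical dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass(frozen=True)
class FociObject:
    """One connected fluorescent object after thresholding and size filtering."""

    channel: str
    area: int
    centroid: tuple[float, float]  # (row, col)
    coords: np.ndarray = field(repr=False)  # (area, 2) int array of (row, col)


@dataclass(frozen=True)
class Nucleus:
    """A DAPI-positive connected component treated as one cell's nucleus."""

    cell_id: int
    area: int
    center: tuple[float, float]  # centroid (row, col)
    coords: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ImageQuant:
    """Image-level red/green quantification.

    ``rg_ratio`` is ``None`` when undefined (``status`` says why). In
    ``total_area`` mode the ratio is sum(red areas)/sum(green areas); in
    ``mean_object_area`` mode it is mean red object area / mean green
    object area.
    """

    n_red: int
    n_green: int
    red_total_area: int
    green_total_area: int
    rg_ratio: float | None
    status: RatioStatus
    aggregation_mode: str


@dataclass(frozen=True)
class CellQuant:
    """Per-cell foci areas and red/green ratio (undefined if green area 0)."""

    cell_id: int
    red_area: int
    green_area: int
    n_red: int
    n_green: int
    rg_ratio: float | None

    @property
    def defined(self) -> bool:
        return self.rg_ratio is not None


@dataclass(frozen=True)
class CalibrationModel:
    """Probe capture-efficiency calibration linking Red/Green to [DX2]/[FL].

    ``alpha`` is the red (pan-isoform) probe efficiency, ``beta`` the green
    (skipped-exon) probe efficiency; only their ratio C = beta/alpha enters
    the conversion. A model constructed without C is *relative-only*: raw
    red/green ratios may be compared but not converted to isoform ratios.
    """

    alpha: float | None = None
    beta: float | None = None
    C_value: float | None = None

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.C_value is not None and self.C_value <= 0:
            raise ValueError("C must be > 0")

    @classmethod
    def from_C(cls, C: float) -> "CalibrationModel":
        return cls(C_value=float(C))

    @classmethod
    def relative_only(cls) -> "CalibrationModel":
        return cls()

    @property
    def C(self) -> float | None:
        if self.C_value is not None:
            return self.C_value
        if self.alpha is not None and self.beta is not None:
            return self.beta / self.alpha
        return None

    @property
    def is_relative_only(self) -> bool:
        return self.C is None


def _binarize(image: np.ndarray, threshold_method: str | float) -> np.ndarray:
    if isinstance(threshold_method, (int, float)) and not isinstance(
        threshold_method, bool
    ):
        thr = float(threshold_method)
    elif threshold_method == "otsu":
        if image.min() == image.max():
            # no contrast: nothing above threshold
            return np.zeros(image.shape, dtype=bool)
        thr = threshold_otsu(image)
    else:
        raise ValueError(f"unknown threshold method: {threshold_method!r}")
    mask = image > thr
    if mask.mean() > 0.5:
        warnings.warn(
            "thresholded mask covers >50% of pixels; input may be saturated "
            "or the threshold too low",
            stacklevel=3,
        )
    return mask


def segment_foci(
    channel_image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_size: int = 4,
    channel: str = "red",
    connectivity: int = 2,
) -> list[FociObject]:
    """Threshold one probe channel and return size-filtered connected objects.

    Objects smaller than ``min_size`` px^2 are treated as noise and removed,
    mirroring size-based speckle rejection. ``connectivity`` follows
    scikit-image (2 = 8-connected, the bwlabel-style default).
    """
    image = np.asarray(channel_image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("channel image must be a non-empty 2D raster")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    mask = _binarize(image, threshold_method)
    labeled = label(mask, connectivity=connectivity)
    out: list[FociObject] = []
    for region in regionprops(labeled):
        if region.area >= min_size:
            out.append(
                FociObject(
                    channel=channel,
                    area=int(region.area),
                    centroid=(float(region.centroid[0]), float(region.centroid[1])),
                    coords=region.coords.copy(),
                )
            )
    return out


def detect_nuclei(
    blue_image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_area: int = 200,
    connectivity: int = 2,
) -> list[Nucleus]:
    """Segment DAPI nuclei as thresholded connected components >= ``min_area``.

    Cell ids are assigned sequentially in raster-scan order of each
    component's first pixel (the labeling order), starting at 1.
    """
    image = np.asarray(blue_image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("blue channel must be a non-empty 2D raster")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = _binarize(image, threshold_method)
    labeled = label(mask, connectivity=connectivity)
    nuclei: list[Nucleus] = []
    cell_id = 0
    for region in regionprops(labeled):
        if region.area >= min_area:
            cell_id += 1
            nuclei.append(
                Nucleus(
                    cell_id=cell_id,
                    area=int(region.area),
                    center=(float(region.centroid[0]), float(region.centroid[1])),
                    coords=region.coords.copy(),
                )
            )
    return nuclei


def assign_foci_to_cells(
    foci: Sequence[FociObject], nuclei: Sequence[Nucleus]
) -> dict[int, int]:
    """Map each focus (by list index) to the nearest nucleus center's cell id.

    Distance is Euclidean from focus centroid to nucleus centroid; exact ties
    go to the lower cell id. With no nuclei an empty mapping is returned with
    a warning (all foci unassigned).
    """
    if len(nuclei) == 0:
        warnings.warn("no nuclei available; foci left unassigned", stacklevel=2)
        return {}
    ordered = sorted(nuclei, key=lambda n: n.cell_id)
    centers = np.array([n.center for n in ordered], dtype=float)
    ids = np.array([n.cell_id for n in ordered], dtype=int)
    mapping: dict[int, int] = {}
    for i, focus in enumerate(foci):
        d2 = np.sum((centers - np.asarray(focus.centroid)) ** 2, axis=1)
        mapping[i] = int(ids[int(np.argmin(d2))])  # argmin -> first == lowest id
    return mapping


def quantify_image(
    red_foci: Sequence[FociObject],
    green_foci: Sequence[FociObject],
    aggregation_mode: str = "total_area",
) -> ImageQuant:
    """Compute the image-level red/green area ratio.

    A zero green denominator yields an undefined ratio (flag, not an
    exception); an image empty in both channels gets a distinct flag.
    """
    if aggregation_mode not in ("total_area", "mean_object_area"):
        raise ValueError(f"unknown aggregation mode: {aggregation_mode!r}")
    red_total = int(sum(f.area for f in red_foci))
    green_total = int(sum(f.area for f in green_foci))
    n_red, n_green = len(red_foci), len(green_foci)
    if n_red == 0 and n_green == 0:
        status, ratio = RatioStatus.EMPTY, None
    elif n_green == 0 or green_total == 0:
        status, ratio = RatioStatus.NO_GREEN, None
    else:
        status = RatioStatus.OK
        if aggregation_mode == "total_area":
            ratio = red_total / green_total
        else:
            ratio = (red_total / n_red) / (green_total / n_green) if n_red else 0.0
    return ImageQuant(
        n_red=n_red,
        n_green=n_green,
        red_total_area=red_total,
        green_total_area=green_total,
        rg_ratio=ratio,
        status=status,
        aggregation_mode=aggregation_mode,
    )


def quantify_cells(
    nuclei: Sequence[Nucleus],
    red_foci: Sequence[FociObject],
    green_foci: Sequence[FociObject],
    red_assignment: dict[int, int],
    green_assignment: dict[int, int],
) -> list[CellQuant]:
    """Per-cell red/green areas and ratios from foci-to-nucleus assignments.

    Every nucleus yields one CellQuant; cells with zero green area keep an
    undefined ratio and are retained (flagged, not dropped).
    """
    red_area: dict[int, int] = {n.cell_id: 0 for n in nuclei}
    green_area: dict[int, int] = {n.cell_id: 0 for n in nuclei}
    n_red: dict[int, int] = {n.cell_id: 0 for n in nuclei}
    n_green: dict[int, int] = {n.cell_id: 0 for n in nuclei}
    for idx, cid in red_assignment.items():
        red_area[cid] += red_foci[idx].area
        n_red[cid] += 1
    for idx, cid in green_assignment.items():
        green_area[cid] += green_foci[idx].area
        n_green[cid] += 1
    out = []
    for n in sorted(nuclei, key=lambda n: n.cell_id):
        cid = n.cell_id
        ratio = red_area[cid] / green_area[cid] if green_area[cid] > 0 else None
        out.append(
            CellQuant(
                cell_id=cid,
                red_area=red_area[cid],
                green_area=green_area[cid],
                n_red=n_red[cid],
                n_green=n_green[cid],
                rg_ratio=ratio,
            )
        )
    return out


def summarize_cell_ratios(cells: Sequence[CellQuant]) -> float | None:
    """Mean of the *defined* per-cell ratios (undefined cells excluded)."""
    defined = [c.rg_ratio for c in cells if c.rg_ratio is not None]
    return float(np.mean(defined)) if defined else None


def isoform_ratio(rg_ratio: float, cal: CalibrationModel) -> float:
    """Convert a red/green area ratio to the skipped/full-length isoform ratio.

    Applies [DX2]/[FL] = C * rg_ratio - 1. A negative result (rg_ratio below
    the calibration floor 1/C) is unphysical and clamped to 0 with a warning.
    """
    if cal.is_relative_only:
        raise CalibrationError(
            "calibration constant C is unknown (relative-only model); report "
            "the raw red/green ratio instead — results are semiquantitative"
        )
    if rg_ratio <= 0:
        raise ValueError("rg_ratio must be > 0")
    value = cal.C * rg_ratio - 1.0
    if value < 0:
        warnings.warn(
            "calibrated isoform ratio is negative (rg_ratio below 1/C); "
            "clamping to 0 — check the calibration constant",
            stacklevel=2,
        )
        return 0.0
    return float(value)


def quantify_field(
    image: MultiChannelImage,
    threshold_method: str | float = "otsu",
    min_size_foci: int = 4,
    min_size_nucleus: int = 200,
    aggregation_mode: str = "total_area",
    per_cell: bool = True,
    connectivity: int = 2,
) -> tuple[ImageQuant, list[CellQuant]]:
    """Full quantification of one field: segment, ratio, optional per-cell.

    Convenience wrapper chaining :func:`segment_foci`, :func:`detect_nuclei`,
    :func:`assign_foci_to_cells`, :func:`quantify_image` and
    :func:`quantify_cells`.
    """
    red = segment_foci(
        image.red, threshold_method, min_size_foci, "red", connectivity
    )
    green = segment_foci(
        image.green, threshold_method, min_size_foci, "green", connectivity
    )
    iq = quantify_image(red, green, aggregation_mode)
    cells: list[CellQuant] = []
    if per_cell:
        nuclei = detect_nuclei(image.blue, threshold_method, min_size_nucleus, connectivity)
        if nuclei:
            ra = assign_foci_to_cells(red, nuclei)
            ga = assign_foci_to_cells(green, nuclei)
            cells = quantify_cells(nuclei, red, green, ra, ga)
    return iq, cells
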