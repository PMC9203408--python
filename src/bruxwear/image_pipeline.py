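"""Colour-layer wear segmentation for multi-layer diagnostic sheets.

A worn sheet is photographed on a black background at a calibrated
resolution.  The pipeline converts that photograph into per-layer abrasion
masks and summary quantities:

1. automatic white balance anchored on the brightest low-chroma region
   (the intact white sheet surface);
2. extraction of the plate as the largest bright connected component;
3. per-layer hue/saturation/value thresholding, median filtering and
   speckle removal;
4. morphological deduplication so each abraded pixel is counted for
   exactly one (the deepest) exposed layer;
5. the layer-weighted pixel score and the abraded area / volume implied
   by the dpi calibration and the layer thicknesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color, measure, morphology

from .sheet import SheetSpec

__all__ = [
    "SheetImage",
    "PipelineParams",
    "AbrasionResult",
    "PipelineError",
    "white_balance",
    "extract_sheet_mask",
    "saturation_filter",
    "detect_layer",
    "dedupe_layers",
    "pixel_score",
    "abraded_geometry",
    "analyze_sheet",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot produce a result; names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"{stage}: {message}")


@dataclass
class SheetImage:
    """An RGB raster of a photographed sheet plus calibration metadata."""

    pixels: np.ndarray
    dpi: float = 400.0
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] == 0 or arr.shape[1] == 0:
            raise ValueError("pixels must be a nonempty H×W×3 RGB array")
        self.pixels = arr

    def as_float(self) -> np.ndarray:
        """Unit-scale float copy regardless of storage depth."""
        arr = self.pixels
        if arr.dtype == np.uint8:
            return arr.astype(np.float64) / 255.0
        if arr.dtype == np.uint16:
            return arr.astype(np.float64) / 65535.0
        return np.clip(arr.astype(np.float64), 0.0, 1.0)

    def like(self, float_pixels: np.ndarray) -> "SheetImage":
        """Re-wrap unit-scale floats in this image's storage depth."""
        arr = np.clip(float_pixels, 0.0, 1.0)
        if self.pixels.dtype == np.uint8:
            arr = np.round(arr * 255.0).astype(np.uint8)
        elif self.pixels.dtype == np.uint16:
            arr = np.round(arr * 65535.0).astype(np.uint16)
        return SheetImage(arr, dpi=self.dpi, source_path=self.source_path)


@dataclass(frozen=True)
class PipelineParams:
    """Tunables of the segmentation chain (all in pixel / unit-intensity scale)."""

    brightness_floor: float = 0.25
    white_chroma_cap: float = 0.35
    median_radius: int = 2
    dilation_radius: int = 1
    speckle_area: int = 5
    min_plate_area: int = 500


@dataclass
class AbrasionResult:
    """Segmentation output for one sheet photograph."""

    sheet_mask: np.ndarray
    layer_masks: dict[str, np.ndarray]
    layer_counts: dict[str, int]
    total_plate_area_px: int
    total_abraded_area_px: int
    pixel_score: float
    abraded_area_mm2: float
    abraded_volume_mm3: float
    source: str = "<memory>"
    params: PipelineParams = field(default_factory=PipelineParams)

    def to_record(self) -> dict:
        """JSON-serializable summary (masks omitted)."""
        return {
            "source": self.source,
            "parameters": {
                "brightness_floor": self.params.brightness_floor,
                "median_radius": self.params.median_radius,
                "dilation_radius": self.params.dilation_radius,
                "speckle_area": self.params.speckle_area,
            },
            "layer_counts": {k: int(v) for k, v in self.layer_counts.items()},
            "total_plate_area_px": int(self.total_plate_area_px),
            "total_abraded_area_px": int(self.total_abraded_area_px),
            "pixel_score": float(self.pixel_score),
            "abraded_area_mm2": float(self.abraded_area_mm2),
            "abraded_volume_mm3": float(self.abraded_volume_mm3),
        }


def _chroma(rgb: np.ndarray) -> np.ndarray:
    return rgb.max(axis=2) - rgb.min(axis=2)


def white_balance(
    image: SheetImage,
    brightness_floor: float = 0.25,
    chroma_cap: float = 0.35,
) -> SheetImage:
    """Neutralize the illuminant using the white sheet surface as reference.

    Candidate reference pixels are the bright (value above
    ``brightness_floor`` and within 60% of the image maximum), low-chroma
    pixels — on a sheet photograph that is the intact white surface.
    Per-channel gains map the reference's mean colour to neutral grey.

    Raises :class:`PipelineError` ("no sheet surface found") when no such
    region exists (all-dark or uniformly saturated images).
    """
    rgb = image.as_float()
    value = rgb.max(axis=2)
    vmax = float(value.max())
    if vmax < brightness_floor:
        raise PipelineError("white_balance", "no sheet surface found")
    bright = value >= max(brightness_floor, 0.6 * vmax)
    reference = bright & (_chroma(rgb) <= chroma_cap * np.maximum(value, 1e-9))
    if not reference.any():
        raise PipelineError("white_balance", "no sheet surface found")
    channel_means = rgb[reference].mean(axis=0)
    if np.any(channel_means <= 0):
        raise PipelineError("white_balance", "no sheet surface found")
    gains = channel_means.mean() / channel_means
    return image.like(rgb * gains[None, None, :])


def extract_sheet_mask(
    image: SheetImage,
    brightness_floor: float = 0.25,
    min_plate_area: int = 500,
) -> np.ndarray:
    """Largest bright 8-connected component, holes filled — the plate region.

    Coloured abrasion patches sit inside the plate, so hole filling keeps
    them part of the plate even when their brightness dips below the floor.
    """
    value = image.as_float().max(axis=2)
    bright = value >= brightness_floor
    labels = measure.label(bright, connectivity=2)
    if labels.max() == 0:
        raise PipelineError("extract_sheet_mask", "no sheet detected")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(counts.argmax())
    if counts[best] < min_plate_area:
        raise PipelineError("extract_sheet_mask", "no sheet detected")
    return ndimage.binary_fill_holes(labels == best)


def saturation_filter(
    image: SheetImage, sheet_mask: np.ndarray, min_saturation: float = 0.25
) -> np.ndarray:
    """Per-pixel HSV saturation inside the plate; sub-threshold pixels zeroed.

    Suppresses the neutral white surface so only exposed colour survives.
    """
    sat = color.rgb2hsv(image.as_float())[..., 1]
    out = np.where(sheet_mask & (sat >= min_saturation), sat, 0.0)
    return out


def _hue_band_mask(hue_deg: np.ndarray, band) -> np.ndarray:
    sel = np.zeros(hue_deg.shape, dtype=bool)
    for lo, hi in band:
        sel |= (hue_deg >= lo) & (hue_deg < hi)
    return sel


def detect_layer(
    image: SheetImage,
    sheet_mask: np.ndarray,
    layer,
    median_radius: int = 2,
    speckle_area: int = 5,
    hsv: np.ndarray | None = None,
) -> np.ndarray:
    """Binary mask of plate pixels showing ``layer``'s colour.

    Hue must fall in the layer's half-open band(s), saturation and value
    must clear the layer thresholds; a disk median filter (majority vote)
    smooths the selection and components smaller than ``speckle_area``
    pixels are discarded.  ``hsv`` may be passed to reuse one conversion
    across layers.
    """
    if not layer.hue_band:
        raise PipelineError("detect_layer", "white layer is not directly detectable")
    if hsv is None:
        hsv = color.rgb2hsv(image.as_float())
    hue_deg = hsv[..., 0] * 360.0
    sel = (
        _hue_band_mask(hue_deg, layer.hue_band)
        & (hsv[..., 1] >= layer.min_saturation)
        & (hsv[..., 2] >= layer.min_value)
        & sheet_mask
    )
    if median_radius > 0:
        footprint = morphology.disk(median_radius)
        # median of a binary image = majority vote over the footprint
        counts = ndimage.convolve(sel.astype(np.uint8), footprint, mode="constant")
        sel = counts > footprint.sum() // 2
    if speckle_area > 1:
        sel = morphology.remove_small_objects(sel, max_size=speckle_area - 1)
    return sel


def dedupe_layers(
    masks: list[np.ndarray], dilation_radius: int = 1
) -> list[np.ndarray]:
    """Resolve overlaps so each abraded pixel counts for exactly one layer.

    ``masks`` are ordered outermost (shallowest colour) to innermost
    (deepest).  Every pixel of the union of the raw masks is assigned to
    the deepest layer whose mask — dilated by ``dilation_radius`` to
    absorb borderline colour-transition pixels — covers it.  Outputs are
    pairwise disjoint and their union equals the input union: no pixel is
    double counted and none is missed.
    """
    if not masks:
        return []
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("layer masks have mismatched shapes")
    union = np.zeros(shape, dtype=bool)
    for m in masks:
        union |= m
    footprint = morphology.disk(dilation_radius) if dilation_radius > 0 else None
    taken = np.zeros(shape, dtype=bool)
    out: list[np.ndarray] = [None] * len(masks)  # type: ignore[list-item]
    for k in range(len(masks) - 1, -1, -1):  # deepest claims first
        reach = masks[k]
        if footprint is not None and reach.any():
            reach = morphology.dilation(reach, footprint)
        claimed = union & reach & ~taken
        out[k] = claimed
        taken |= claimed
    return out


def pixel_score(layer_counts: dict[str, int], spec: SheetSpec) -> float:
    """Layer-weighted abraded-pixel count: ``Σ_k weight_k · count_k``.

    Deeper layers carry larger weights, so the score grows with both the
    extent and the depth of the wear.
    """
    weights = {layer.name: layer.weight for layer in spec.detectable_layers}
    score = 0.0
    for name, count in layer_counts.items():
        if count < 0:
            raise ValueError(f"negative pixel count for layer {name!r}")
        score += weights.get(name, 0.0) * count
    return score


def abraded_geometry(
    layer_counts: dict[str, int], spec: SheetSpec
) -> tuple[float, float]:
    """Physical abraded area (mm²) and removed volume (mm³).

    One pixel covers ``(25.4 / dpi)²`` mm².  Volume assumes each exposed
    pixel was abraded to the midpoint of its exposed layer (the layers
    above it being fully penetrated).
    """
    px_area = spec.pixel_side_mm**2
    total_px = sum(layer_counts.values())
    area = total_px * px_area
    volume = sum(
        count * px_area * spec.exposure_depth_mm(name)
        for name, count in layer_counts.items()
    )
    return area, volume


def analyze_sheet(
    image: SheetImage,
    spec: SheetSpec | None = None,
    params: PipelineParams | None = None,
) -> AbrasionResult:
    """Run the full segmentation chain on one sheet photograph."""
    from .sheet import default_sheet_spec

    spec = spec or default_sheet_spec()
    params = params or PipelineParams()

    balanced = white_balance(
        image, brightness_floor=params.brightness_floor, chroma_cap=params.white_chroma_cap
    )
    sheet_mask = extract_sheet_mask(
        balanced,
        brightness_floor=params.brightness_floor,
        min_plate_area=params.min_plate_area,
    )
    hsv = color.rgb2hsv(balanced.as_float())
    raw_masks = []
    names = []
    for layer in spec.detectable_layers:
        raw_masks.append(
            detect_layer(
                balanced,
                sheet_mask,
                layer,
                median_radius=params.median_radius,
                speckle_area=params.speckle_area,
                hsv=hsv,
            )
        )
        names.append(layer.name)
    deduped = dedupe_layers(raw_masks, dilation_radius=params.dilation_radius)
    layer_masks = dict(zip(names, deduped))
    layer_counts = {name: int(mask.sum()) for name, mask in layer_masks.items()}
    total_abraded = sum(layer_counts.values())
    score = pixel_score(layer_counts, spec)
    area, volume = abraded_geometry(layer_counts, spec)
    return AbrasionResult(
        sheet_mask=sheet_mask,
        layer_masks=layer_masks,
        layer_counts=layer_counts,
        total_plate_area_px=int(sheet_mask.sum()),
        total_abraded_area_px=int(total_abraded),
        pixel_score=score,
        abraded_area_mm2=area,
        abraded_volume_mm3=volume,
        source=image.source_path,
        params=params,
    )
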