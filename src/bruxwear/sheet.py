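"""Specification of the multi-layer diagnostic sheet.

The sheet is a 0.5-mm thermoformed plate built from five coloured layers
(outermost first): white, blue, yellow, red, green.  Nocturnal grinding
abrades the white surface and exposes the coloured sub-layers; the deeper
the exposed colour, the more material was removed.  Each detectable
(non-white) layer carries a hue band used for segmentation, a thickness,
and a weighting factor used in the pixel score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

MM_PER_INCH = 25.4

#: Hue bands in degrees, half-open [lo, hi); red wraps around 0.
DEFAULT_HUE_BANDS: dict[str, tuple[tuple[float, float], ...]] = {
    "blue": ((190.0, 260.0),),
    "yellow": ((40.0, 75.0),),
    "red": ((330.0, 360.0), (0.0, 15.0)),
    "green": ((90.0, 160.0),),
}

#: Depth-proportional weighting factors for the pixel score.
DEFAULT_WEIGHTS = {"blue": 0.2, "yellow": 0.4, "red": 0.6, "green": 0.8}


@dataclass(frozen=True)
class LayerSpec:
    """One colour layer of the sheet.

    ``hue_band`` is a tuple of half-open intervals ``[lo, hi)`` in degrees
    on the hue circle; the white layer has an empty band (it is not a
    segmentation target — abrasion is the exposure of colour beneath it).
    """

    name: str
    hue_band: tuple[tuple[float, float], ...]
    thickness_mm: float
    weight: float
    min_saturation: float = 0.25
    min_value: float = 0.15

    def __post_init__(self) -> None:
        for lo, hi in self.hue_band:
            if not (0.0 <= lo < 360.0 and 0.0 < hi <= 360.0 and lo < hi):
                raise ValueError(f"invalid hue interval [{lo}, {hi}) for {self.name}")
        if not 0.0 <= self.min_saturation <= 1.0:
            raise ValueError("min_saturation must be in [0, 1]")
        if not 0.0 <= self.min_value <= 1.0:
            raise ValueError("min_value must be in [0, 1]")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")

    def contains_hue(self, hue_deg: float) -> bool:
        """Half-open membership: a hue exactly at ``hi`` is outside."""
        return any(lo <= hue_deg < hi for lo, hi in self.hue_band)


@dataclass(frozen=True)
class SheetSpec:
    """The full layer stack plus camera calibration.

    Layers are ordered outermost (white) to innermost (green).
    """

    layers: tuple[LayerSpec, ...]
    total_thickness_mm: float = 0.5
    dpi: float = 400.0

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        total = sum(layer.thickness_mm for layer in self.layers)
        if abs(total - self.total_thickness_mm) > 1e-6:
            raise ValueError(
                f"layer thicknesses sum to {total} mm, expected {self.total_thickness_mm} mm"
            )

    @property
    def detectable_layers(self) -> tuple[LayerSpec, ...]:
        """Colour layers that can be segmented (everything but white)."""
        return tuple(layer for layer in self.layers if layer.name != "white")

    @property
    def pixel_side_mm(self) -> float:
        return MM_PER_INCH / self.dpi

    def exposure_depth_mm(self, layer_name: str) -> float:
        """Midpoint removal depth when ``layer_name`` is the exposed colour.

        All layers above must be fully penetrated plus half of the exposed
        layer itself — an estimate, since partial within-layer abrasion is
        not observable from colour alone.
        """
        depth = 0.0
        for layer in self.layers:
            if layer.name == layer_name:
                return depth + 0.5 * layer.thickness_mm
            depth += layer.thickness_mm
        raise KeyError(f"unknown layer {layer_name!r}")


def default_sheet_spec(dpi: float = 400.0) -> SheetSpec:
    """The five-layer stack: 0.5 mm total, 0.1 mm per layer."""
    names = ["white", "blue", "yellow", "red", "green"]
    layers = tuple(
        LayerSpec(
            name=name,
            hue_band=DEFAULT_HUE_BANDS.get(name, ()),
            thickness_mm=0.1,
            weight=DEFAULT_WEIGHTS.get(name, 0.0),
        )
        for name in names
    )
    return SheetSpec(layers=layers, total_thickness_mm=0.5, dpi=dpi)


def load_sheet_spec(path) -> SheetSpec:
    """Read a sheet specification from YAML.

    Expected keys: ``layers`` (list of {name, hue_band, thickness_mm,
    weight, min_saturation, min_value}), ``total_thickness_mm``, ``dpi``.
    ``hue_band`` is a list of two-element [lo, hi) intervals (or a single
    interval) in degrees; omitted for white.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    layers = []
    for entry in raw["layers"]:
        band = entry.get("hue_band") or ()
        if band and not isinstance(band[0], (list, tuple)):
            band = (band,)
        layers.append(
            LayerSpec(
                name=entry["name"],
                hue_band=tuple(tuple(float(x) for x in iv) for iv in band),
                thickness_mm=float(entry["thickness_mm"]),
                weight=float(entry.get("weight", 0.0)),
                min_saturation=float(entry.get("min_saturation", 0.25)),
                min_value=float(entry.get("min_value", 0.15)),
            )
        )
    return SheetSpec(
        layers=tuple(layers),
        total_thickness_mm=float(raw.get("total_thickness_mm", 0.5)),
        dpi=float(raw.get("dpi", 400.0)),
    )


def save_sheet_spec(spec: SheetSpec, path) -> None:
    doc = {
        "total_thickness_mm": spec.total_thickness_mm,
        "dpi": spec.dpi,
        "layers": [
            {
                "name": layer.name,
                "hue_band": [list(iv) for iv in layer.hue_band],
                "thickness_mm": layer.thickness_mm,
                "weight": layer.weight,
                "min_saturation": layer.min_saturation,
                "min_value": layer.min_value,
            }
            for layer in spec.layers
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def with_dpi(spec: SheetSpec, dpi: float) -> SheetSpec:
    return replace(spec, dpi=dpi)
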