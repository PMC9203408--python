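"""Readers and writers for images, cohort tables and EMG event lists."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .image_pipeline import SheetImage
from .rmma import BurstEvent, RmmaEpisode

log = logging.getLogger("bruxwear")

COHORT_COLUMNS = ["subject_id", "group", "pixel_score"]
EVENT_COLUMNS = ["onset_s", "offset_s", "amplitude_frac_mvc", "grinding_sound"]


def read_sheet_image(path, dpi: float | None = None) -> SheetImage:
    """Load an RGB PNG/TIFF photograph.

    dpi is taken from file metadata when present; an explicit ``dpi``
    argument wins over metadata (with a logged warning on mismatch).
    """
    with Image.open(path) as im:
        meta_dpi = None
        info_dpi = im.info.get("dpi")
        if info_dpi:
            meta_dpi = float(info_dpi[0])
        arr = np.asarray(im.convert("RGB"))
    if dpi is not None and meta_dpi is not None and abs(dpi - meta_dpi) > 0.5:
        log.warning(
            "%s: metadata dpi %.1f differs from configured dpi %.1f; using configured",
            path, meta_dpi, dpi,
        )
    use_dpi = dpi if dpi is not None else (meta_dpi or 400.0)
    return SheetImage(arr, dpi=use_dpi, source_path=str(path))


def write_sheet_image(image: SheetImage, path) -> None:
    arr = image.pixels
    if arr.dtype != np.uint8:
        arr = np.round(np.clip(image.as_float(), 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, dpi=(image.dpi, image.dpi))


def write_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(path)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    if df.empty:
        raise ValueError("cohort table is empty")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_events_csv(path) -> list[BurstEvent]:
    df = pd.read_csv(path)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            events.append(
                BurstEvent(
                    onset_s=float(row.onset_s),
                    offset_s=float(row.offset_s),
                    amplitude_frac_mvc=float(row.amplitude_frac_mvc),
                    grinding_sound=bool(int(row.grinding_sound)),
                    excluded=bool(int(getattr(row, "excluded", 0))),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed event row {i + 2}: {exc}") from exc
    return events


def write_events_csv(events: list[BurstEvent], path) -> None:
    pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "offset_s": [e.offset_s for e in events],
            "amplitude_frac_mvc": [e.amplitude_frac_mvc for e in events],
            "grinding_sound": [int(e.grinding_sound) for e in events],
            "excluded": [int(e.excluded) for e in events],
        }
    ).to_csv(path, index=False)


def write_episodes_csv(episodes: list[RmmaEpisode], path) -> None:
    pd.DataFrame(
        {
            "start_s": [ep.start_s for ep in episodes],
            "end_s": [ep.end_s for ep in episodes],
            "kind": [ep.kind for ep in episodes],
            "n_bursts": [len(ep.bursts) for ep in episodes],
            "grinding_sound": [int(ep.has_grinding_sound) for ep in episodes],
        }
    ).to_csv(path, index=False)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
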