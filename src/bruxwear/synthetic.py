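"""Ground-truthed synthetic inputs: rendered sheet photographs, pixel-score
cohorts, and EMG burst nights.

No wear dataset ships with the method, so every downstream module is
exercised on synthetic material with known ground truth:

* :func:`render_sheet` draws an arch-shaped white plate on a black
  background, paints abrasion patches with the colour of their exposed
  layer, and optionally perturbs the result with an illumination gradient
  and Gaussian sensor noise.  The per-layer ground-truth masks are
  returned alongside the image.
* :func:`simulate_cohort` draws SB / non-SB pixel-score cohorts from
  moment-matched gamma distributions.  The defaults reproduce the study
  group moments (SB: mean 1306, SD 913, n 10; non-SB: mean 381, SD 483,
  n 35); a gamma family is used because scores are nonnegative and the
  non-SB SD exceeds its mean, which no symmetric model can produce.
* :func:`simulate_emg_night` plants phasic / tonic / mixed episodes plus
  sub-threshold distractor activity at known counts.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image_pipeline import SheetImage
from .rmma import BurstEvent
from .sheet import SheetSpec, default_sheet_spec

__all__ = [
    "Patch",
    "AbrasionScenario",
    "CohortParams",
    "EmgNightParams",
    "render_sheet",
    "random_scenario",
    "simulate_cohort",
    "simulate_emg_night",
    "arch_plate_mask",
]

LAYER_ORDER = ("blue", "yellow", "red", "green")


@dataclass(frozen=True)
class Patch:
    """One abrasion patch: ``size_px`` pixels of one exposed colour layer.

    The patch is realized as exactly the ``size_px`` pixels closest to
    ``center`` in the elliptical metric with axis ratio ``aspect``, so
    ground-truth pixel counts are exact by construction.
    """

    layer: str
    center: tuple[float, float]
    size_px: int
    aspect: float = 1.0
    angle_deg: float = 0.0
    hue_jitter_deg: float = 0.0
    saturation: float = 0.7
    value: float = 0.8


@dataclass(frozen=True)
class AbrasionScenario:
    """A renderable wear scene with known ground truth."""

    patches: tuple[Patch, ...] = ()
    image_shape: tuple[int, int] = (800, 800)
    plate: str = "arch"
    illumination_gradient: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def scaled(self, factor: float) -> "AbrasionScenario":
        """Same scene rendered at ``factor`` times the linear resolution."""
        patches = tuple(
            replace(
                p,
                center=(p.center[0] * factor, p.center[1] * factor),
                size_px=int(round(p.size_px * factor * factor)),
            )
            for p in self.patches
        )
        shape = (
            int(round(self.image_shape[0] * factor)),
            int(round(self.image_shape[1] * factor)),
        )
        return replace(self, patches=patches, image_shape=shape)


def arch_plate_mask(
    shape: tuple[int, int],
    outer_frac: float = 0.49,
    inner_frac: float = 0.175,
    arc_deg: float = 200.0,
) -> np.ndarray:
    """Horseshoe-like annular sector approximating a maxillary arch.

    The plate shape is irrelevant to the segmentation algorithms; the arch
    is used for visual realism.  Radii are fractions of ``min(shape)``.
    """
    h, w = shape
    cr, cc = 0.62 * h, 0.5 * w
    rr, cc_idx = np.mgrid[0:h, 0:w]
    dy, dx = rr - cr, cc_idx - cc
    dist = np.hypot(dy, dx)
    scale = min(h, w)
    ring = (dist >= inner_frac * scale) & (dist <= outer_frac * scale)
    # angle measured from "up" (toward row 0); the arch opens downward
    ang = np.degrees(np.arctan2(dx, -dy))
    return ring & (np.abs(ang) <= arc_deg / 2.0)


def _ellipse_plate_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - h / 2) / (0.45 * h)) ** 2 + ((cc - w / 2) / (0.45 * w)) ** 2 <= 1.0


def _plate_mask(scenario: AbrasionScenario) -> np.ndarray:
    if scenario.plate == "arch":
        return arch_plate_mask(scenario.image_shape)
    if scenario.plate == "ellipse":
        return _ellipse_plate_mask(scenario.image_shape)
    raise ValueError(f"unknown plate kind {scenario.plate!r}")


def _patch_mask(patch: Patch, shape: tuple[int, int]) -> np.ndarray:
    """Exactly ``size_px`` pixels nearest the centre in the elliptical metric.

    Works inside a bounding window around the centre for speed; the window
    comfortably covers the ellipse extent.
    """
    h, w = shape
    # metric level set m covers ~ pi*m/aspect pixels; extent sqrt(m)*max(1,1/aspect)
    m_need = patch.size_px * patch.aspect / np.pi
    radius = int(np.ceil(np.sqrt(max(m_need, 1.0)) * max(1.0, 1.0 / patch.aspect) * 1.8)) + 2
    r0 = max(0, int(patch.center[0]) - radius)
    r1 = min(h, int(patch.center[0]) + radius + 1)
    c0 = max(0, int(patch.center[1]) - radius)
    c1 = min(w, int(patch.center[1]) + radius + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    theta = np.radians(patch.angle_deg)
    dy, dx = rr - patch.center[0], cc - patch.center[1]
    u = np.cos(theta) * dy + np.sin(theta) * dx
    v = -np.sin(theta) * dy + np.cos(theta) * dx
    metric = u**2 + (v * patch.aspect) ** 2
    n = min(patch.size_px, metric.size)
    flat = np.argsort(metric, axis=None, kind="stable")[:n]
    sub = np.zeros(metric.size, dtype=bool)
    sub[flat] = True
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = sub.reshape(metric.shape)
    return mask


def _layer_hue_center(spec: SheetSpec, name: str) -> float:
    layer = next(l for l in spec.layers if l.name == name)
    lo, hi = layer.hue_band[0]
    return (lo + hi) / 2.0


def render_sheet(
    scenario: AbrasionScenario, spec: SheetSpec | None = None
) -> tuple[SheetImage, dict[str, np.ndarray]]:
    """Render a worn-sheet photograph; return it with ground-truth masks.

    Ground-truth masks are pre-deduplicated (a pixel covered by several
    patches shows, and is attributed to, the deepest layer).  The image is
    8-bit RGB; the plate is near-white on a black background.

    Raises ``ValueError`` if a patch extends outside the plate.
    """
    spec = spec or default_sheet_spec()
    rng = np.random.default_rng(scenario.seed)
    plate = _plate_mask(scenario)

    order = [l.name for l in spec.detectable_layers]
    gt: dict[str, np.ndarray] = {
        name: np.zeros(scenario.image_shape, dtype=bool) for name in order
    }
    depth = {name: i for i, name in enumerate(order)}
    claimed_depth = np.full(scenario.image_shape, -1, dtype=int)
    hues: dict[str, float] = {}
    for patch in scenario.patches:
        if patch.layer not in depth:
            raise ValueError(f"unknown layer {patch.layer!r}")
        mask = _patch_mask(patch, scenario.image_shape)
        if not np.all(plate[mask]):
            raise ValueError(f"patch on layer {patch.layer!r} extends outside the plate")
        claimed_depth[mask] = np.maximum(claimed_depth[mask], depth[patch.layer])
        jitter = rng.uniform(-patch.hue_jitter_deg, patch.hue_jitter_deg)
        hues.setdefault(patch.layer, _layer_hue_center(spec, patch.layer) + jitter)
    for name, d in depth.items():
        gt[name] = claimed_depth == d

    img = np.zeros(scenario.image_shape + (3,), dtype=np.float64)
    img[plate] = 0.88  # intact white surface, kept off-peak to avoid clipping
    sat_by_layer = {p.layer: p.saturation for p in scenario.patches}
    val_by_layer = {p.layer: p.value for p in scenario.patches}
    for name in order:
        if gt[name].any():
            rgb = colorsys.hsv_to_rgb(
                (hues[name] % 360.0) / 360.0, sat_by_layer[name], val_by_layer[name]
            )
            img[gt[name]] = rgb

    if scenario.illumination_gradient:
        g = scenario.illumination_gradient
        ramp = np.linspace(1.0 - g, 1.0 + g, scenario.image_shape[1])
        img *= ramp[None, :, None]
    if scenario.noise_sd:
        img += rng.normal(0.0, scenario.noise_sd, img.shape)

    pixels = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    image = SheetImage(pixels, dpi=spec.dpi, source_path=f"<synthetic seed={scenario.seed}>")
    return image, gt


def random_scenario(
    seed: int,
    image_size: int = 800,
    n_sites: int | None = None,
    illumination_gradient: float = 0.0,
    noise_sd: float = 0.0,
    max_blue_px: int = 4000,
) -> AbrasionScenario:
    """A realistic random wear scene: nested exposure at a few arch sites.

    Each site exposes a blue patch; with decreasing probability the wear
    penetrates further, nesting a smaller yellow / red / green patch inside
    — mimicking localized grinding facets of increasing depth.
    """
    rng = np.random.default_rng(seed)
    shape = (image_size, image_size)
    plate = arch_plate_mask(shape)
    n_sites = int(rng.integers(2, 6)) if n_sites is None else n_sites

    # candidate centres on the arch midline
    scale = image_size
    cr, cc = 0.62 * scale, 0.5 * scale
    mid_r = 0.5 * (0.49 + 0.175) * scale
    patches: list[Patch] = []
    angles = rng.uniform(-80, 80, size=n_sites)
    for ang in angles:
        a = np.radians(ang)
        center = (cr - mid_r * np.cos(a), cc + mid_r * np.sin(a))
        size = int(rng.integers(400, max_blue_px))
        aspect = float(rng.uniform(0.5, 1.0))
        nest = [("blue", size)]
        for deeper, frac_lo in (("yellow", 0.3), ("red", 0.25), ("green", 0.2)):
            if rng.random() < 0.5:
                size = max(30, int(size * rng.uniform(frac_lo, 0.6)))
                nest.append((deeper, size))
            else:
                break
        for layer, sz in nest:
            patches.append(
                Patch(
                    layer=layer,
                    center=center,
                    size_px=sz,
                    aspect=aspect,
                    angle_deg=float(rng.uniform(0, 180)),
                    saturation=float(rng.uniform(0.55, 0.85)),
                    value=float(rng.uniform(0.7, 0.85)),
                    hue_jitter_deg=8.0,
                )
            )
    # shrink any patch that falls off the plate edge rather than failing
    kept = []
    for p in patches:
        mask = _patch_mask(p, shape)
        inside = int((mask & plate).sum())
        if inside >= 30:
            kept.append(replace(p, size_px=inside) if inside < p.size_px else p)
    # re-check: keep only patches fully inside after shrinking
    final = []
    for p in kept:
        mask = _patch_mask(p, shape)
        if np.all(plate[mask]):
            final.append(p)
    return AbrasionScenario(
        patches=tuple(final),
        image_shape=shape,
        illumination_gradient=illumination_gradient,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pixel-score cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Group sizes and pixel-score moments for cohort simulation.

    Defaults are the study conditions: 10 SB subjects with mean 1306
    (SD 913) and 35 non-SB subjects with mean 381 (SD 483).
    """

    n_sb: int = 10
    n_nsb: int = 35
    sb_mean: float = 1306.0
    sb_sd: float = 913.0
    nsb_mean: float = 381.0
    nsb_sd: float = 483.0
    family: str = "gamma"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sb < 1 or self.n_nsb < 1:
            raise ValueError("group sizes must be >= 1")
        if min(self.sb_mean, self.sb_sd, self.nsb_mean, self.nsb_sd) <= 0:
            raise ValueError("means and SDs must be positive")


def _draw_scores(rng, family: str, mean: float, sd: float, n: int) -> np.ndarray:
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, size=n)
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    raise ValueError(f"unknown family {family!r}")


def simulate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Simulate a labelled pixel-score cohort.

    Returns a DataFrame with columns ``subject_id``, ``group`` (``SB`` /
    ``non-SB``) and ``pixel_score``; moment-matched within the chosen
    nonnegative family (gamma by default: shape = mean²/SD², scale =
    SD²/mean).
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    sb = _draw_scores(rng, params.family, params.sb_mean, params.sb_sd, params.n_sb)
    nsb = _draw_scores(rng, params.family, params.nsb_mean, params.nsb_sd, params.n_nsb)
    n = params.n_sb + params.n_nsb
    width = len(str(n))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "group": ["SB"] * params.n_sb + ["non-SB"] * params.n_nsb,
            "pixel_score": np.concatenate([sb, nsb]),
        }
    )


# ---------------------------------------------------------------------------
# EMG nights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmgNightParams:
    """Planted episode counts and burst geometry for one simulated night."""

    tst_h: float = 6.0
    n_phasic: int = 20
    n_tonic: int = 8
    n_mixed: int = 4
    n_grinding: int = 5
    n_distractors: int = 20
    seed: int = 0
    min_gap_s: float = 6.0  # clearance between planted items; must exceed the 3-s grouping gap


@dataclass(frozen=True)
class PlantedTruth:
    """What was planted, for exact-recovery checks."""

    n_phasic: int
    n_tonic: int
    n_mixed: int
    n_bursts: int
    n_grinding: int
    tst_h: float


def _phasic_bursts(rng, t0: float, n: int, amp, grinding: bool) -> list[BurstEvent]:
    bursts = []
    t = t0
    for _ in range(n):
        dur = float(rng.uniform(0.3, 1.5))
        bursts.append(BurstEvent(t, t + dur, amp(), grinding))
        t += dur + float(rng.uniform(0.5, 2.5))
    return bursts


def simulate_emg_night(
    params: EmgNightParams | None = None,
) -> tuple[list[BurstEvent], PlantedTruth]:
    """Simulate one night of jaw-muscle EMG burst events.

    Plants the configured numbers of phasic clusters (3–5 bursts of
    0.3–1.5 s with 0.5–2.5 s gaps), tonic bursts (2.2–6 s) and mixed
    sequences (a phasic run plus a tonic burst in one cluster), separated
    by more than the 3-s grouping gap, plus sub-threshold distractor
    activity (15% MVC bursts and 0.1-s spikes that fail the amplitude or
    duration criterion).  Grinding-sound flags are assigned to the first
    ``n_grinding`` planted episodes.

    Returns the time-sorted events and the planted ground truth.
    """
    params = params or EmgNightParams()
    rng = np.random.default_rng(params.seed)
    amp = lambda: float(rng.uniform(0.3, 0.8))
    tst_s = params.tst_h * 3600.0

    episodes: list[list[BurstEvent]] = []
    kinds: list[str] = []
    for _ in range(params.n_phasic):
        episodes.append(_phasic_bursts(rng, 0.0, int(rng.integers(3, 6)), amp, False))
        kinds.append("phasic")
    for _ in range(params.n_tonic):
        dur = float(rng.uniform(2.2, 6.0))
        episodes.append([BurstEvent(0.0, dur, amp(), False)])
        kinds.append("tonic")
    for _ in range(params.n_mixed):
        run = _phasic_bursts(rng, 0.0, 3, amp, False)
        t = run[-1].offset_s + float(rng.uniform(0.5, 2.5))
        run.append(BurstEvent(t, t + float(rng.uniform(2.2, 4.0)), amp(), False))
        episodes.append(run)
        kinds.append("mixed")

    distractors: list[BurstEvent] = []
    for _ in range(params.n_distractors):
        if rng.random() < 0.5:
            dur = float(rng.uniform(0.5, 1.5))
            distractors.append(BurstEvent(0.0, dur, 0.15, False))  # below 20% MVC
        else:
            distractors.append(BurstEvent(0.0, 0.1, 0.5, False))  # below 0.25-s minimum

    items = episodes + [[d] for d in distractors]
    if not items:
        return [], PlantedTruth(0, 0, 0, 0, 0, params.tst_h)
    durations = [it[-1].offset_s - it[0].onset_s for it in items]
    total_busy = sum(durations) + params.min_gap_s * len(items)
    if total_busy > tst_s:
        raise ValueError("night too short for the requested activity")

    for attempt in range(200):
        starts = np.sort(rng.uniform(0.0, tst_s - max(durations), size=len(items)))
        order = rng.permutation(len(items))
        ok = True
        prev_end = -params.min_gap_s
        placed_starts = np.empty(len(items))
        for slot, idx in enumerate(order):
            start = max(starts[slot], prev_end + params.min_gap_s)
            end = start + durations[idx]
            if end > tst_s:
                ok = False
                break
            placed_starts[idx] = start
            prev_end = end
        if ok:
            break
    else:
        raise RuntimeError("could not place episodes without overlap")

    order_of_episode = np.argsort([placed_starts[i] for i in range(len(episodes))])
    grinding_ids = set(order_of_episode[: params.n_grinding].tolist())

    events: list[BurstEvent] = []
    n_bursts = 0
    for i, item in enumerate(items):
        shift = placed_starts[i] - item[0].onset_s
        grind = i in grinding_ids if i < len(episodes) else False
        for b in item:
            events.append(
                BurstEvent(b.onset_s + shift, b.offset_s + shift, b.amplitude_frac_mvc,
                           grind or b.grinding_sound)
            )
        if i < len(episodes):
            n_bursts += len(item)
    events.sort(key=lambda e: e.onset_s)
    truth = PlantedTruth(
        n_phasic=params.n_phasic,
        n_tonic=params.n_tonic,
        n_mixed=params.n_mixed,
        n_bursts=n_bursts,
        n_grinding=min(params.n_grinding, len(episodes)),
        tst_h=params.tst_h,
    )
    return events, truth
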