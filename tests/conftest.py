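import numpy as np
import pytest

from bruxwear.sheet import default_sheet_spec
from bruxwear.synthetic import AbrasionScenario, Patch, random_scenario, render_sheet


@pytest.fixture(scope="session")
def spec():
    return default_sheet_spec()


@pytest.fixture(scope="session")
def single_blue_scene(spec):
    """A 300×300 plate with one 1,000-px blue patch, noiseless."""
    scenario = AbrasionScenario(
        patches=(Patch(layer="blue", center=(90.0, 150.0), size_px=1000),),
        image_shape=(300, 300),
        seed=11,
    )
    image, gt = render_sheet(scenario, spec)
    return scenario, image, gt


@pytest.fixture(scope="session")
def small_render(spec):
    """A small random multi-layer scene with ground truth."""
    scenario = random_scenario(5, image_size=300, max_blue_px=1200)
    image, gt = render_sheet(scenario, spec)
    return scenario, image, gt


def brute_force_deepest_claim(masks, radius):
    """Per-pixel oracle for layer deduplication.

    For every pixel of the union of the raw masks, walk the layers from
    deepest to shallowest and assign the pixel to the first layer with a
    mask pixel within Euclidean distance ``radius``.
    """
    shape = masks[0].shape
    union = np.zeros(shape, dtype=bool)
    for m in masks:
        union |= m
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    out = [np.zeros(shape, dtype=bool) for _ in masks]
    h, w = shape
    for r in range(h):
        for c in range(w):
            if not union[r, c]:
                continue
            for k in range(len(masks) - 1, -1, -1):
                hit = False
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and masks[k][rr, cc]:
                        hit = True
                        break
                if hit:
                    out[k][r, c] = True
                    break
    return out


def pairwise_concordance_auc(scores, labels, positive="SB"):
    """O(n²) AUC oracle: concordant positive/negative pairs, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
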