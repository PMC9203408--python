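"""Rhythmic masticatory muscle activity (RMMA) scoring and SB diagnosis.

Jaw-muscle EMG burst events from a polysomnographic night are filtered by
amplitude (≥ 20% of maximal voluntary contraction) and duration (≥ 0.25 s),
grouped into episodes by a 3-s maximum inter-burst gap, and classified:

* phasic — at least 3 bursts, each lasting 0.25 to (under) 2 s;
* tonic  — a single burst lasting at least 2 s;
* mixed  — a qualifying phasic run and a tonic burst in one episode.

Per-night indices (episodes/h, bursts/h, episodes with grinding sounds)
feed the diagnostic cut-offs: ≥ 4 episodes/h, ≥ 25 bursts/h and ≥ 1
grinding episode.  All three must be met for an SB-positive night
(conjunction; an OR rule is available for sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BurstEvent",
    "RmmaEpisode",
    "SbIndices",
    "DEFAULT_CUTOFFS",
    "filter_bursts",
    "segment_episodes",
    "classify_episode",
    "score_events",
    "compute_indices",
    "diagnose_sb",
    "select_night",
]

MVC_THRESHOLD = 0.20
MIN_BURST_S = 0.25
TONIC_MIN_S = 2.0
MAX_GAP_S = 3.0

#: Diagnostic cut-offs: episodes/h, bursts/h, grinding episodes.
DEFAULT_CUTOFFS = {"episodes_per_hour": 4.0, "bursts_per_hour": 25.0, "grinding_episodes": 1}


@dataclass(frozen=True)
class BurstEvent:
    """One EMG burst; amplitude as a fraction of maximal voluntary contraction."""

    onset_s: float
    offset_s: float
    amplitude_frac_mvc: float
    grinding_sound: bool = False
    excluded: bool = False  # wakefulness / movement artefact flag from audio-video review

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("burst offset must follow onset")
        if self.amplitude_frac_mvc < 0:
            raise ValueError("amplitude must be nonnegative")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class RmmaEpisode:
    bursts: tuple[BurstEvent, ...]
    kind: str  # phasic | tonic | mixed

    @property
    def start_s(self) -> float:
        return self.bursts[0].onset_s

    @property
    def end_s(self) -> float:
        return self.bursts[-1].offset_s

    @property
    def has_grinding_sound(self) -> bool:
        return any(b.grinding_sound for b in self.bursts)


@dataclass(frozen=True)
class SbIndices:
    episodes_per_hour: float
    bursts_per_hour: float
    grinding_episodes: int
    total_sleep_time_h: float


def filter_bursts(
    events: list[BurstEvent],
    mvc_threshold: float = MVC_THRESHOLD,
    min_duration_s: float = MIN_BURST_S,
) -> list[BurstEvent]:
    """Keep scorable bursts: amplitude ≥ threshold (inclusive), duration
    ≥ 0.25 s, not artefact-excluded; sort by onset and merge overlaps.

    Overlapping events are artefacts of event extraction; the merged burst
    spans their union, takes the maximum amplitude, and inherits any
    grinding flag.
    """
    kept = sorted(
        (
            e
            for e in events
            if not e.excluded
            and e.amplitude_frac_mvc >= mvc_threshold
            and e.duration_s >= min_duration_s
        ),
        key=lambda e: (e.onset_s, e.offset_s),
    )
    merged: list[BurstEvent] = []
    for e in kept:
        if merged and e.onset_s < merged[-1].offset_s:
            prev = merged[-1]
            merged[-1] = BurstEvent(
                prev.onset_s,
                max(prev.offset_s, e.offset_s),
                max(prev.amplitude_frac_mvc, e.amplitude_frac_mvc),
                prev.grinding_sound or e.grinding_sound,
            )
        else:
            merged.append(e)
    return merged


def segment_episodes(
    bursts: list[BurstEvent], max_gap_s: float = MAX_GAP_S
) -> list[list[BurstEvent]]:
    """Greedy left-to-right grouping by the maximum inter-burst gap.

    A burst joins the current group iff the silence between the previous
    burst's offset and its onset is at most ``max_gap_s``.
    """
    groups: list[list[BurstEvent]] = []
    for b in bursts:
        if groups and b.onset_s - groups[-1][-1].offset_s <= max_gap_s:
            groups[-1].append(b)
        else:
            groups.append([b])
    return groups


def _has_phasic_run(bursts: list[BurstEvent]) -> bool:
    """≥ 3 consecutive bursts each in the phasic duration band [0.25, 2) s."""
    run = 0
    for b in bursts:
        if MIN_BURST_S <= b.duration_s < TONIC_MIN_S:
            run += 1
            if run >= 3:
                return True
        else:
            run = 0
    return False


def classify_episode(group: list[BurstEvent]) -> RmmaEpisode | None:
    """Classify one burst group; ``None`` when it does not qualify.

    Bursts of exactly 2.0 s count as tonic, keeping the phasic duration
    band [0.25, 2) s disjoint from the tonic one.  A group holding both a
    phasic run and a tonic burst is mixed ("closely related" activity
    inside a single gap-bounded cluster).  Groups of one or two short
    bursts qualify for neither class and are rejected.
    """
    if not group:
        raise ValueError("empty burst group")
    has_tonic = any(b.duration_s >= TONIC_MIN_S for b in group)
    has_phasic = _has_phasic_run(group)
    if has_tonic and has_phasic:
        kind = "mixed"
    elif has_tonic:
        kind = "tonic"
    elif has_phasic:
        kind = "phasic"
    else:
        return None
    return RmmaEpisode(bursts=tuple(group), kind=kind)


def score_events(
    events: list[BurstEvent],
    mvc_threshold: float = MVC_THRESHOLD,
    max_gap_s: float = MAX_GAP_S,
) -> list[RmmaEpisode]:
    """Filter, segment and classify: the full per-night episode scoring."""
    bursts = filter_bursts(events, mvc_threshold=mvc_threshold)
    episodes = []
    for group in segment_episodes(bursts, max_gap_s=max_gap_s):
        ep = classify_episode(group)
        if ep is not None:
            episodes.append(ep)
    return episodes


def compute_indices(episodes: list[RmmaEpisode], tst_h: float) -> SbIndices:
    """Per-night SB indices normalized by total sleep time (hours)."""
    if tst_h <= 0:
        raise ValueError("total sleep time must be positive")
    n_bursts = sum(len(ep.bursts) for ep in episodes)
    return SbIndices(
        episodes_per_hour=len(episodes) / tst_h,
        bursts_per_hour=n_bursts / tst_h,
        grinding_episodes=sum(ep.has_grinding_sound for ep in episodes),
        total_sleep_time_h=tst_h,
    )


def diagnose_sb(
    indices: SbIndices,
    cutoffs: dict | None = None,
    rule: str = "and",
) -> tuple[bool, dict[str, bool]]:
    """Apply the diagnostic cut-offs (inclusive ≥) to one night's indices.

    Returns the diagnosis and the per-criterion breakdown.  The default
    rule requires all three criteria (matching the research criteria the
    cut-offs come from); ``rule="or"`` accepts any one.
    """
    cutoffs = cutoffs or DEFAULT_CUTOFFS
    checks = {
        "episodes_per_hour": indices.episodes_per_hour >= cutoffs["episodes_per_hour"],
        "bursts_per_hour": indices.bursts_per_hour >= cutoffs["bursts_per_hour"],
        "grinding_episodes": indices.grinding_episodes >= cutoffs["grinding_episodes"],
    }
    if rule == "and":
        positive = all(checks.values())
    elif rule == "or":
        positive = any(checks.values())
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return positive, checks


def select_night(nights: list[SbIndices]) -> SbIndices:
    """The night with the most RMMA episodes/h enters the analysis.

    Ties go to the higher bursts/h, then to the earlier night.
    """
    if not nights:
        raise ValueError("no nights provided")
    best = nights[0]
    for night in nights[1:]:
        if night.episodes_per_hour > best.episodes_per_hour or (
            night.episodes_per_hour == best.episodes_per_hour
            and night.bursts_per_hour > best.bursts_per_hour
        ):
            best = night
    return best
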