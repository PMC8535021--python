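"""Study design: duration-matched pairing and group assignment.

Each simulated (manikin) ventilation episode is paired with a real-newborn
episode of similar total PPV duration (within ±15%), allocated consecutively
from the clinical pool — the premise being that the duration of PPV needed to
establish adequate spontaneous respiration proxies the clinical condition at
birth. Pairs are then split into four analysis groups by recipient and
duration class: manikin-short (MS), baby-short (BS), manikin-long (ML),
baby-long (BL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .breath_analysis import VentilationSequence

__all__ = ["EpisodePair", "StudyGroups", "PairingError",
           "pair_by_duration", "assign_groups"]

DEFAULT_TOLERANCE = 0.15

#: Manikin scenario -> duration class of the pair.
SCENARIO_DURATION_CLASS = {"S1": "short", "S2": "short",
                           "S3": "long", "S4": "long"}


class PairingError(ValueError):
    """Raised when some episode cannot be paired; carries the orphans."""

    def __init__(self, orphans: list[str]):
        self.orphans = orphans
        super().__init__(
            "unpairable manikin episode(s): " + ", ".join(orphans))


@dataclass(frozen=True)
class EpisodePair:
    manikin_episode_id: str
    baby_episode_id: str
    manikin_duration: float  # s of PPV, pauses excluded
    baby_duration: float
    relative_difference: float  # |baby - manikin| / manikin

    def __post_init__(self) -> None:
        if self.relative_difference < 0:
            raise ValueError("relative_difference must be non-negative")


@dataclass
class StudyGroups:
    """The four analysis groups of ventilation sequences."""

    groups: dict[str, list[VentilationSequence]] = field(
        default_factory=lambda: {"MS": [], "BS": [], "ML": [], "BL": []})

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}

    def __getitem__(self, key: str) -> list[VentilationSequence]:
        return self.groups[key]


def pair_by_duration(manikin_sequences: list[VentilationSequence],
                     baby_pool: list[VentilationSequence],
                     tolerance: float = DEFAULT_TOLERANCE
                     ) -> list[EpisodePair]:
    """Pair manikin episodes with pool episodes of similar PPV duration.

    Manikin episodes are processed in order; each takes the first
    not-yet-used pool episode whose total PPV time is within ``tolerance``
    (relative to the manikin duration) — a greedy first-fit that
    operationalises consecutive allocation from the clinical pool, and is
    therefore deterministic given input order. Raises :class:`PairingError`
    listing any orphan manikin episodes.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    used = [False] * len(baby_pool)
    pairs: list[EpisodePair] = []
    orphans: list[str] = []
    for m in manikin_sequences:
        if m.total_ppv_time <= 0:
            orphans.append(m.episode_id)
            continue
        match = None
        for j, b in enumerate(baby_pool):
            if used[j]:
                continue
            rel = abs(b.total_ppv_time - m.total_ppv_time) / m.total_ppv_time
            if rel <= tolerance:
                match = (j, b, rel)
                break
        if match is None:
            orphans.append(m.episode_id)
            continue
        j, b, rel = match
        used[j] = True
        pairs.append(EpisodePair(
            manikin_episode_id=m.episode_id, baby_episode_id=b.episode_id,
            manikin_duration=m.total_ppv_time, baby_duration=b.total_ppv_time,
            relative_difference=rel))
    if orphans:
        raise PairingError(orphans)
    return pairs


def assign_groups(pairs: list[EpisodePair],
                  manikin_sequences: list[VentilationSequence],
                  baby_pool: list[VentilationSequence]) -> StudyGroups:
    """Assemble the MS/BS/ML/BL groups from duration-matched pairs.

    The duration class of a pair is fixed by the manikin member's scenario
    (S1/S2 -> short, S3/S4 -> long), not its realised duration: suboptimal
    PPV lengthens the clock, but the study design classes remain the ~30 s
    and ~90 s scenarios. Both members of a short pair go to MS/BS, of a long
    pair to ML/BL.
    """
    m_by_id = {s.episode_id: s for s in manikin_sequences}
    b_by_id = {s.episode_id: s for s in baby_pool}
    groups = StudyGroups()
    for pair in pairs:
        m = m_by_id[pair.manikin_episode_id]
        b = b_by_id[pair.baby_episode_id]
        if m.scenario not in SCENARIO_DURATION_CLASS:
            raise ValueError(f"manikin sequence {m.episode_id} has unknown "
                             f"scenario {m.scenario!r}")
        cls = SCENARIO_DURATION_CLASS[m.scenario]
        m.duration_class = cls
        b.duration_class = cls
        groups.groups["M" + cls[0].upper()].append(m)
        groups.groups["B" + cls[0].upper()].append(b)
    return groups


def pairs_to_frame(pairs: list[EpisodePair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "manikin_id": p.manikin_episode_id, "baby_id": p.baby_episode_id,
        "m_dur_s": p.manikin_duration, "b_dur_s": p.baby_duration,
        "rel_diff": p.relative_difference} for p in pairs])
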