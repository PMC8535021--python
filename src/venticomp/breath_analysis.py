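"""Breath-by-breath analysis of pressure-flow waveforms.

Mirrors what a respiratory function monitor reports during newborn
positive-pressure ventilation: individual inflations are segmented from the
pressure trace, and for each one the peak inflating pressure (PIP), positive
end-expiratory pressure (PEEP), inspired and expired tidal volumes
(flow integrated over time), weight-normalised expired tidal volume (eV_T,
mL/kg) and face-mask leak are extracted. Pauses longer than 5 s are excluded
from the total PPV time of a sequence, and upper-airway obstruction is called
when three or more consecutive inflations show minimal expired volume despite
achieving target PIP, flanked by at least one inflation with typical volumes.

Expired volume is used as the tidal-volume estimate because mask leak occurs
predominantly during inflation; leak is
``100 * (V_insp - V_exp) / V_insp``, clamped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ventsim import Episode, WaveformRecord

__all__ = [
    "BreathWindow",
    "BreathRecord",
    "VentilationSequence",
    "segment_breaths",
    "compute_pressures",
    "integrate_volumes",
    "compute_leak",
    "normalize_ev_t",
    "detect_pauses",
    "detect_obstruction",
    "assemble_sequence",
    "analyze_episode",
]

#: Maximum pause not excluded from total PPV time, seconds.
MAX_PAUSE_S = 5.0

#: Default pressure rise above baseline that starts an inflation, mbar.
DEFAULT_MIN_RISE = 5.0

#: Default "minimal volume" floor for obstruction calling, mL/kg.
DEFAULT_FLOW_FLOOR = 1.0

#: Fraction of set PIP that counts as achieving target PIP.
PIP_TARGET_FRACTION = 0.9


@dataclass(frozen=True)
class BreathWindow:
    """Sample span of one inflation-expiration cycle: [start, end)."""

    start: int
    end: int
    t_onset: float
    t_end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty breath window")


@dataclass
class BreathRecord:
    """Ventilatory parameters of one inflation."""

    index: int
    t_start: float
    t_end: float
    pip: float  # mbar
    peep: float  # mbar
    v_t_insp: float  # mL
    v_t_exp: float  # mL
    ev_t: float  # mL/kg
    leak_pct: float  # % of inspired volume, NaN when undefined
    leak_raw: float  # unclamped leak, diagnostic
    obstructed: bool = False
    reached_target_pip: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class VentilationSequence:
    """Ordered breaths of one episode, with pauses and obstruction calls."""

    episode_id: str
    recipient: str
    breaths: list[BreathRecord]
    pauses: list[tuple[float, float]]
    total_ppv_time: float
    duration_class: str | None = None
    obstruction_events: list[tuple[int, int]] = field(default_factory=list)
    scenario: str | None = None
    weight: float = 3.14

    @property
    def n_breaths(self) -> int:
        return len(self.breaths)

    @property
    def obstructed(self) -> bool:
        return len(self.obstruction_events) > 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "episode_id": self.episode_id,
            "breath_index": b.index,
            "pip_mbar": b.pip,
            "peep_mbar": b.peep,
            "vt_insp_ml": b.v_t_insp,
            "vt_exp_ml": b.v_t_exp,
            "evt_ml_kg": b.ev_t,
            "leak_pct": b.leak_pct,
            "leak_raw_pct": b.leak_raw,
            "obstructed": b.obstructed,
            "flags": ";".join(b.flags),
        } for b in self.breaths]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "episode_id": self.episode_id,
            "recipient": self.recipient,
            "scenario": self.scenario,
            "weight_kg": self.weight,
            "n_breaths": self.n_breaths,
            "total_ppv_time_s": self.total_ppv_time,
            "n_pauses": len(self.pauses),
            "duration_class": self.duration_class,
            "obstruction_events": [list(w) for w in self.obstruction_events],
        }


def _check_uniform_grid(record: WaveformRecord) -> float:
    steps = np.diff(record.time)
    if len(steps) == 0:
        raise ValueError("record too short")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform time grid")
    return float(steps[0])


def segment_breaths(record: WaveformRecord,
                    min_rise: float = DEFAULT_MIN_RISE,
                    max_window_cycles: float = 1.5) -> list[BreathWindow]:
    """Segment a pressure trace into inflation windows.

    An inflation onset is a crossing of ``baseline + min_rise``, where the
    baseline PEEP estimate is the 10th percentile of the pressure trace;
    hysteresis (return below ``baseline + min_rise/2``) guards against noise
    re-triggering. Each window runs from its onset to the next onset, capped
    at ``max_window_cycles`` times the median onset-to-onset interval so that
    a long pause is not absorbed into the preceding breath's integrals.
    """
    if min_rise <= 0:
        raise ValueError("min_rise must be positive")
    p = record.pressure
    if len(p) < 3 or np.ptp(p) < min_rise:
        return []
    dt = _check_uniform_grid(record)
    baseline = float(np.percentile(p, 10))
    hi = baseline + min_rise
    lo = baseline + 0.5 * min_rise
    onsets = []
    armed = p[0] < hi
    for i in range(1, len(p)):
        if armed and p[i] >= hi > p[i - 1]:
            onsets.append(i)
            armed = False
        elif not armed and p[i] < lo:
            armed = True
    if not onsets:
        return []
    # back the window start up slightly so the first inspiratory flow samples
    # of a fast pressure rise are not lost from the volume integrals
    backtrack = max(int(round(0.03 / dt)), 1)
    starts = []
    for j, o in enumerate(onsets):
        floor_idx = starts[-1] + 1 if starts else 0
        starts.append(max(o - backtrack, floor_idx))
    starts_arr = np.asarray(starts)
    if len(starts_arr) >= 2:
        median_gap = float(np.median(np.diff(starts_arr)))
        cap = int(round(max_window_cycles * median_gap))
    else:
        cap = len(p)
    windows = []
    for j, s in enumerate(starts):
        nxt = starts[j + 1] if j + 1 < len(starts) else len(p)
        e = min(nxt, s + cap, len(p))
        windows.append(BreathWindow(start=s, end=e,
                                    t_onset=float(record.time[s]),
                                    t_end=float(record.time[e - 1]) + dt))
    return windows


def compute_pressures(window: BreathWindow, record: WaveformRecord,
                      peep_tail_fraction: float = 0.2
                      ) -> tuple[float, float, list[str]]:
    """Extract (PIP, PEEP) for one inflation window.

    PIP is the maximum pressure in the window. PEEP is the median of the
    final ``peep_tail_fraction`` of the expiratory segment (from the pressure
    maximum onward); if that tail has not settled to a plateau, a
    ``peep_no_plateau`` quality flag is attached.
    """
    p = record.pressure[window.start:window.end]
    if len(p) == 0:
        raise ValueError("empty window")
    flags: list[str] = []
    pip = float(np.max(p))
    i_peak = int(np.argmax(p))
    expir = p[i_peak:]
    n_tail = max(int(round(len(expir) * peep_tail_fraction)), 1)
    tail = expir[-n_tail:]
    peep = float(np.median(tail))
    if len(tail) >= 3 and (np.ptp(tail) > 1.0 or tail[0] - tail[-1] > 0.5):
        flags.append("peep_no_plateau")
    return pip, peep, flags


def integrate_volumes(window: BreathWindow,
                      record: WaveformRecord) -> tuple[float, float]:
    """Trapezoidal flow integrals over one window.

    Flow is recorded in mL/min and converted to mL/s; the positive part
    integrates to the inspired volume and the magnitude of the negative part
    to the expired volume.
    """
    dt = _check_uniform_grid(record)
    q = record.flow[window.start:window.end] / 60.0  # mL/s
    v_insp = float(np.trapezoid(np.clip(q, 0.0, None), dx=dt))
    v_exp = float(np.trapezoid(np.clip(-q, 0.0, None), dx=dt))
    return v_insp, v_exp


def compute_leak(v_t_insp: float, v_t_exp: float
                 ) -> tuple[float, float, list[str]]:
    """Face-mask leak as a percentage of inspired volume.

    Returns ``(leak_pct, leak_raw, flags)``. ``leak_pct`` is
    ``100*(V_insp - V_exp)/V_insp`` clamped to [0, 100]; a zero inspired
    volume yields NaN with a ``leak_undefined`` flag, and an expired volume
    exceeding the inspired one (possible with spontaneous expiratory efforts)
    is clamped to 0 with a ``negative_leak`` flag, the raw value being kept
    for diagnostics.
    """
    if v_t_insp < 0:
        raise ValueError("v_t_insp must be non-negative")
    flags: list[str] = []
    if v_t_insp == 0:
        return float("nan"), float("nan"), ["leak_undefined"]
    raw = 100.0 * (v_t_insp - v_t_exp) / v_t_insp
    leak = raw
    if raw < 0:
        leak = 0.0
        flags.append("negative_leak")
    elif raw > 100.0:
        leak = 100.0
    return leak, raw, flags


def normalize_ev_t(v_t_exp: float, weight: float) -> float:
    """Expired tidal volume per kg body weight (manikin: 3.14 kg nominal)."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return v_t_exp / weight


def detect_pauses(windows: list[BreathWindow],
                  max_pause: float = MAX_PAUSE_S
                  ) -> list[tuple[float, float]]:
    """Find ventilation pauses longer than ``max_pause`` seconds.

    A pause is an onset-to-onset gap whose excess over the typical cycle time
    (median onset gap) exceeds ``max_pause``; it is anchored at the end of the
    typical cycle of the earlier breath.
    """
    if len(windows) < 2:
        return []
    onsets = np.array([w.t_onset for w in windows])
    gaps = np.diff(onsets)
    typical = float(np.median(gaps))
    pauses = []
    for i, g in enumerate(gaps):
        excess = g - typical
        if excess > max_pause:
            pauses.append((float(onsets[i] + typical), float(onsets[i + 1])))
    return pauses


def detect_obstruction(breaths: list[BreathRecord],
                       flow_floor: float = DEFAULT_FLOW_FLOOR,
                       pip_target: float = 30.0) -> list[tuple[int, int]]:
    """Call upper-airway obstruction windows.

    A maximal run of >= 3 consecutive breaths with ``ev_t < flow_floor``
    (mL/kg) and PIP at least ``PIP_TARGET_FRACTION * pip_target`` is reported
    iff at least one breath immediately adjacent to the run has an expired
    volume typical of the sequence (>= half the sequence median eV_T). Runs
    of low volume where PIP also collapsed are failed inflations, not
    obstruction. Returned windows are (first, last) 1-based breath indices.
    """
    if len(breaths) < 3:
        return []
    ev = np.array([b.ev_t for b in breaths])
    pip = np.array([b.pip for b in breaths])
    low = (ev < flow_floor) & (pip >= PIP_TARGET_FRACTION * pip_target)
    typical_floor = 0.5 * float(np.median(ev))
    events = []
    i = 0
    n = len(breaths)
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1]:
            j += 1
        if j - i + 1 >= 3:
            neighbours = []
            if i > 0:
                neighbours.append(ev[i - 1])
            if j < n - 1:
                neighbours.append(ev[j + 1])
            if any(v >= typical_floor for v in neighbours):
                events.append((breaths[i].index, breaths[j].index))
        i = j + 1
    return events


def assemble_sequence(record: WaveformRecord, episode_id: str = "",
                      recipient: str = "manikin", weight: float = 3.14,
                      pip_target: float = 30.0, scenario: str | None = None,
                      min_rise: float = DEFAULT_MIN_RISE,
                      flow_floor: float = DEFAULT_FLOW_FLOOR,
                      max_pause: float = MAX_PAUSE_S) -> VentilationSequence:
    """Run the full measurement pipeline on one waveform.

    Segments breaths, extracts per-inflation parameters, removes pauses
    > 5 s from the total PPV time and calls obstruction windows.
    """
    windows = segment_breaths(record, min_rise=min_rise)
    breaths: list[BreathRecord] = []
    for k, w in enumerate(windows, start=1):
        pip, peep, pflags = compute_pressures(w, record)
        v_insp, v_exp = integrate_volumes(w, record)
        leak, leak_raw, lflags = compute_leak(v_insp, v_exp)
        breaths.append(BreathRecord(
            index=k, t_start=w.t_onset, t_end=w.t_end, pip=pip, peep=peep,
            v_t_insp=v_insp, v_t_exp=v_exp,
            ev_t=normalize_ev_t(v_exp, weight),
            leak_pct=leak, leak_raw=leak_raw,
            reached_target_pip=pip >= PIP_TARGET_FRACTION * pip_target,
            flags=pflags + lflags))
    pauses = detect_pauses(windows, max_pause=max_pause)
    if windows:
        span = windows[-1].t_end - windows[0].t_onset
        total = span - sum(b - a for a, b in pauses)
    else:
        total = 0.0
    events = detect_obstruction(breaths, flow_floor=flow_floor,
                                pip_target=pip_target)
    for a, b in events:
        for br in breaths[a - 1:b]:
            br.obstructed = True
    return VentilationSequence(
        episode_id=episode_id, recipient=recipient, breaths=breaths,
        pauses=pauses, total_ppv_time=float(total),
        obstruction_events=events, scenario=scenario, weight=weight)


def analyze_episode(episode: Episode, pip_target: float | None = None,
                    **kwargs) -> VentilationSequence:
    """Convenience wrapper: analyse a simulated :class:`Episode`."""
    settings = episode.record.metadata.get("settings")
    if pip_target is None:
        pip_target = settings.set_pip if settings is not None else 30.0
    return assemble_sequence(
        episode.record, episode_id=episode.episode_id,
        recipient=episode.recipient, weight=episode.weight,
        pip_target=pip_target, scenario=episode.scenario, **kwargs)
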