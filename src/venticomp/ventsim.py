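"""Synthetic T-piece positive-pressure-ventilation waveform simulator.

Emulates the two kinds of recipient studied when benchmarking a ventilation
training manikin against real newborns: a manikin whose low lung compliance is
gated by a valve that opens abruptly after enough adequate inflations, and a
newborn whose effective compliance rises gradually over the first ~20
inflations as functional residual capacity (FRC) is established.

The lung is a single-compartment linear RC model driven by a square airway
pressure wave between the set PEEP and set PIP of a flow-driven T-piece
resuscitator:

    dV/dt = (1 - f) * (P_aw - V/C) / R

where ``f`` is the per-breath face-mask leak fraction: the flow sensor sits
between the T-piece and the mask, so a fraction ``f`` of the inspiratory flow
passing the sensor escapes at the mask seal before reaching the lung. Mask
leak is assumed to occur during inflation only, so measured expiratory flow
equals lung outflow. This makes the downstream leak formula
``100*(V_insp - V_exp)/V_insp`` recover ``100*f`` in cyclic steady state, and
makes expired volume strictly decrease with increasing leak at fixed
compliance.

All pressures are in mbar (1 mbar = 1.02 cmH2O), volumes in mL, flows as
recorded by the monitor in mL/min (positive toward the recipient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "MBAR_TO_CMH2O",
    "ResuscitatorSettings",
    "LungModel",
    "ScenarioSpec",
    "MaskLeakModel",
    "SubjectProfile",
    "WaveformRecord",
    "Episode",
    "StudyData",
    "scenario_spec",
    "simulate_breath",
    "simulate_scenario",
    "simulate_baby_episode",
    "inject_obstruction",
    "simulate_study",
]

#: Conversion constant for airway pressure units.
MBAR_TO_CMH2O = 1.02

#: Effective compliance of the valve-gated lung while the valve is closed,
#: as a fraction of its open-valve compliance. Strongly reduced, but kept
#: distinguishable from a true airway obstruction (which attenuates flow to
#: near zero).
CLOSED_VALVE_COMPLIANCE_FRACTION = 0.3

#: Flow attenuation applied to inflations affected by an injected upper-airway
#: obstruction.
OBSTRUCTION_FLOW_FACTOR = 0.02


def _check_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ResuscitatorSettings:
    """Settings of a flow-driven T-piece resuscitator (e.g. NeoPuff).

    Defaults are the standard delivery-room settings: 8 L/min gas flow,
    PIP 30 mbar (may be increased to 35), PEEP 5 mbar.
    """

    set_pip: float = 30.0  # mbar
    set_peep: float = 5.0  # mbar
    gas_flow: float = 8.0  # L/min
    inflation_rate: float = 50.0  # inflations/min
    inspiratory_fraction: float = 0.4  # fraction of the cycle spent inflating

    def __post_init__(self) -> None:
        _check_finite(
            set_pip=self.set_pip,
            set_peep=self.set_peep,
            gas_flow=self.gas_flow,
            inflation_rate=self.inflation_rate,
            inspiratory_fraction=self.inspiratory_fraction,
        )
        if not self.set_pip > self.set_peep >= 0:
            raise ValueError("require set_pip > set_peep >= 0")
        if self.gas_flow <= 0:
            raise ValueError("gas_flow must be positive")
        if not 0 < self.inspiratory_fraction < 1:
            raise ValueError("inspiratory_fraction must lie in (0, 1)")
        if self.inflation_rate <= 0:
            raise ValueError("inflation_rate must be positive")

    @property
    def cycle_time(self) -> float:
        """Duration of one inflation-expiration cycle in seconds."""
        return 60.0 / self.inflation_rate

    @property
    def inspiratory_time(self) -> float:
        return self.cycle_time * self.inspiratory_fraction


@dataclass
class LungModel:
    """Single-compartment lung: linear compliance and resistance.

    ``valve_open`` models the manikin's compliance valve: while closed, the
    effective compliance is ``compliance * CLOSED_VALVE_COMPLIANCE_FRACTION``.
    ``valve_threshold`` is the number of adequate inflations (PIP reaching at
    least 90% of the set value) needed to open it. ``frc_established_fraction``
    scales compliance during gradual FRC establishment in newborns.
    """

    compliance: float  # mL/mbar
    resistance: float = 0.30  # mbar/(mL/s), effective fill resistance (circuit + airway)
    valve_open: bool = True
    valve_threshold: int = 0
    frc_established_fraction: float = 1.0

    def __post_init__(self) -> None:
        _check_finite(compliance=self.compliance, resistance=self.resistance)
        if self.compliance < 0:
            raise ValueError("compliance must be non-negative")
        if self.resistance <= 0:
            raise ValueError("resistance must be positive")
        if self.valve_threshold < 0:
            raise ValueError("valve_threshold must be non-negative")
        if not 0 <= self.frc_established_fraction <= 1:
            raise ValueError("frc_established_fraction must lie in [0, 1]")

    @property
    def effective_compliance(self) -> float:
        c = self.compliance * self.frc_established_fraction
        if not self.valve_open:
            c *= CLOSED_VALVE_COMPLIANCE_FRACTION
        return c


@dataclass(frozen=True)
class ScenarioSpec:
    """One training scenario of the valve-gated manikin.

    S1: apnoea with normal lung compliance; 30 s of optimal PPV to baby-cry.
    S4: apnoea with low initial compliance (closed valve) and decompensated
    heart rate; 90 s of optimal PPV to baby-cry. Suboptimal PPV lengthens
    the scenario. S2/S3 are intermediate stubs.
    """

    scenario_id: Literal["S1", "S2", "S3", "S4"]
    initial_compliance: float  # mL/mbar, open-valve value
    initial_heart_rate: float  # bpm
    optimal_ppv_to_success: float  # s of effective PPV to baby-cry
    heart_rate_recovery_rate: float = 4.0  # bpm per effective inflation
    valve_gated: bool = False
    valve_threshold: int = 20

    def __post_init__(self) -> None:
        if self.optimal_ppv_to_success <= 0:
            raise ValueError("optimal_ppv_to_success must be positive")
        if self.initial_heart_rate <= 0:
            raise ValueError("initial_heart_rate must be positive")


_SCENARIOS = {
    "S1": ScenarioSpec("S1", initial_compliance=0.55, initial_heart_rate=90.0,
                       optimal_ppv_to_success=30.0),
    "S2": ScenarioSpec("S2", initial_compliance=0.60, initial_heart_rate=70.0,
                       optimal_ppv_to_success=45.0),
    "S3": ScenarioSpec("S3", initial_compliance=0.70, initial_heart_rate=55.0,
                       optimal_ppv_to_success=60.0, valve_gated=True,
                       valve_threshold=10),
    "S4": ScenarioSpec("S4", initial_compliance=0.80, initial_heart_rate=40.0,
                       optimal_ppv_to_success=90.0, valve_gated=True,
                       valve_threshold=15),
}


def scenario_spec(scenario_id: str) -> ScenarioSpec:
    """Return the built-in specification for scenario ``S1``..``S4``."""
    try:
        return _SCENARIOS[scenario_id]
    except KeyError:
        raise ValueError(f"unknown scenario id {scenario_id!r}; "
                         f"expected one of {sorted(_SCENARIOS)}") from None


@dataclass(frozen=True)
class MaskLeakModel:
    """Stochastic per-breath face-mask leak fraction.

    Realized leak for breath ``b`` (0-based) is
    ``clip(mean + drift*b + N(0, sd), 0, 0.93)``. A negative drift models
    progressively successful leak-reducing adjustments by the provider, which
    is what produces lower median leak (and hence higher expired volume) in
    long sequences.
    """

    mean_leak_fraction: float = 0.40
    per_breath_sd: float = 0.12
    drift_per_breath: float = -0.0025

    def __post_init__(self) -> None:
        if not 0 <= self.mean_leak_fraction < 1:
            raise ValueError("mean_leak_fraction must lie in [0, 1)")
        if self.per_breath_sd < 0:
            raise ValueError("per_breath_sd must be non-negative")

    def draw(self, breath_index: int, rng: np.random.Generator) -> float:
        f = (self.mean_leak_fraction
             + self.drift_per_breath * breath_index
             + rng.normal(0.0, self.per_breath_sd))
        return float(np.clip(f, 0.0, 0.93))


@dataclass(frozen=True)
class SubjectProfile:
    """Who is being ventilated.

    The manikin is rigidly reproducible: no spontaneous respiratory effort and
    an abrupt transition at scenario success. Newborns show larger
    breath-to-breath variability, occasional spontaneous-effort flow
    artefacts, and a gradual end-of-episode transition with falling delivered
    pressures and rising leak.
    """

    recipient: Literal["manikin", "baby"]
    weight: float = 3.14  # kg; manikin volumes normalised by the donor-cohort median birth weight
    parameter_jitter_scale: float = 1.0
    spontaneous_effort_rate: float = 0.0  # events/min
    end_transition: Literal["abrupt", "gradual"] = "abrupt"

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.recipient == "manikin":
            if self.spontaneous_effort_rate != 0:
                raise ValueError("manikin has no spontaneous respiratory effort")
            if self.end_transition != "abrupt":
                raise ValueError("manikin transition at success is abrupt")


def manikin_profile() -> SubjectProfile:
    return SubjectProfile(recipient="manikin", weight=3.14,
                          parameter_jitter_scale=1.0)


def baby_profile() -> SubjectProfile:
    return SubjectProfile(recipient="baby", weight=3.14,
                          parameter_jitter_scale=2.5,
                          spontaneous_effort_rate=2.0,
                          end_transition="gradual")


@dataclass
class WaveformRecord:
    """A sampled pressure-flow trace of one ventilation episode.

    time is a uniform grid in seconds, pressure in mbar, flow in mL/min with
    positive values indicating flow toward the recipient.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if not (len(self.time) == len(self.pressure) == len(self.flow)):
            raise ValueError("time, pressure, flow must have equal length")
        if len(self.time) >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")
            if steps[0] > 0.010 + 1e-12:
                raise ValueError("grid step must be <= 10 ms")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time,
                             "pressure_mbar": self.pressure,
                             "flow_ml_min": self.flow})


@dataclass
class Episode:
    """A simulated episode: waveform plus per-breath ground truth.

    ``truth`` has one row per simulated inflation with the injected leak
    fraction, effective compliance, delivered PIP/PEEP, sample boundaries and
    obstruction/adequacy flags — the reference for parameter-recovery tests.
    """

    episode_id: str
    record: WaveformRecord
    truth: pd.DataFrame
    recipient: str
    scenario: str | None = None
    weight: float = 3.14
    success_time: float | None = None  # s, elapsed ventilation time at baby-cry
    heart_rate_series: pd.DataFrame | None = None
    ppv_time: float = 0.0  # s of ventilation, pauses excluded (ground truth)

    @property
    def n_breaths(self) -> int:
        return len(self.truth)


@dataclass
class StudyData:
    """Output of :func:`simulate_study`."""

    manikin_episodes: list[Episode]
    baby_episodes: list[Episode]
    seed: int
    n_providers: int


# ---------------------------------------------------------------------------
# Waveform synthesis internals
# ---------------------------------------------------------------------------

_PRESSURE_RISE_TAU = 0.020  # s, pressurisation time constant of the T-piece circuit
_PRESSURE_FALL_TAU = 0.030  # s, release to PEEP
_PRESSURE_NOISE_SD = 0.08  # mbar
_FLOW_NOISE_SD = 30.0  # mL/min
_PIP_JITTER_SD = 0.3  # mbar at jitter scale 1 (upward excursions capped)
_PEEP_JITTER_SD = 0.2  # mbar at jitter scale 1
_PIP_JITTER_CAP = 0.5  # mbar above set PIP


def _synth_cycle(settings: ResuscitatorSettings, lung_c: float, lung_r: float,
                 leak_fraction: float, dt: float, v0: float,
                 delivered_pip: float, delivered_peep: float,
                 t_insp: float | None = None, t_cycle: float | None = None,
                 flow_factor: float = 1.0):
    """Simulate one inflation-expiration cycle without measurement noise.

    Returns (pressure, flow, v_end, v_insp_sensor, v_exp_sensor) where the
    sensor volumes are the noise-free integrals a downstream analyser should
    recover.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_finite(leak_fraction=leak_fraction, delivered_pip=delivered_pip,
                  delivered_peep=delivered_peep, v0=v0)
    if not 0 <= leak_fraction < 1:
        raise ValueError("leak_fraction must lie in [0, 1)")
    t_cycle = settings.cycle_time if t_cycle is None else t_cycle
    t_insp = settings.inspiratory_time if t_insp is None else t_insp
    n = max(int(round(t_cycle / dt)), 2)
    n_insp = int(round(t_insp / dt))
    pressure = np.empty(n)
    flow = np.empty(n)
    v = v0
    v_insp = 0.0
    v_exp = 0.0
    p_aw = delivered_peep
    for i in range(n):
        inspiring = i < n_insp
        target = delivered_pip if inspiring else delivered_peep
        tau = _PRESSURE_RISE_TAU if inspiring else _PRESSURE_FALL_TAU
        p_aw = target + (p_aw - target) * math.exp(-dt / tau)
        pressure[i] = p_aw
        if lung_c > 0:
            # exact exponential step for the RC lung (stable for any C)
            rate = (1.0 - leak_fraction) if inspiring else 1.0
            a = math.exp(-rate * dt / (lung_r * lung_c))
            dv = (lung_c * p_aw - v) * (1.0 - a)
        else:
            dv = 0.0
        if inspiring:
            dv = max(dv, 0.0)  # T-piece check: no reverse flow during inflation
            q_sensor = dv / max(1.0 - leak_fraction, 1e-9) / dt
            v_insp += q_sensor * dt
        else:
            dv = min(dv, 0.0)  # no mask leak during expiration
            q_sensor = dv / dt
            v_exp += -q_sensor * dt
        q_sensor *= flow_factor
        v = max(v + dv, 0.0)
        flow[i] = q_sensor * 60.0  # mL/s -> mL/min
    return pressure, flow, v, v_insp, v_exp


def simulate_breath(settings: ResuscitatorSettings, lung: LungModel,
                    leak: MaskLeakModel | float = 0.0, dt: float = 0.01,
                    seed: int | None = None, noise: bool = False,
                    start_volume: float | None = None) -> WaveformRecord:
    """Simulate a single inflation-expiration cycle.

    ``leak`` may be a fixed leak fraction or a :class:`MaskLeakModel` (a
    single draw is taken). The lung starts at its PEEP equilibrium volume
    unless ``start_volume`` is given, so that for a steady-state breath the
    expired volume equals ``(1 - leak) * inspired`` up to integration error.
    """
    rng = np.random.default_rng(seed)
    f = leak.draw(0, rng) if isinstance(leak, MaskLeakModel) else float(leak)
    c_eff = lung.effective_compliance
    v0 = c_eff * settings.set_peep if start_volume is None else start_volume
    pressure, flow, v_end, v_insp, v_exp = _synth_cycle(
        settings, c_eff, lung.resistance, f, dt, v0,
        settings.set_pip, settings.set_peep)
    n_lead = int(round(_LEAD_IN_S / dt))
    pressure = np.concatenate([np.full(n_lead, settings.set_peep), pressure])
    flow = np.concatenate([np.zeros(n_lead), flow])
    if noise:
        pressure = pressure + rng.normal(0.0, _PRESSURE_NOISE_SD, len(pressure))
        flow = flow + rng.normal(0.0, _FLOW_NOISE_SD, len(flow))
    time = np.arange(len(pressure)) * dt
    meta = {"leak_fraction": f, "compliance": c_eff,
            "resistance": lung.resistance, "v_insp": v_insp, "v_exp": v_exp,
            "v_end": v_end, "settings": settings, "seed": seed}
    return WaveformRecord(time, pressure, flow, meta)


def _heart_rate(initial: float, effective_inflations: float,
                recovery_rate: float, plateau: float = 160.0) -> float:
    """Logistic rise from the scenario's initial rate toward a healthy plateau,
    driven by the cumulative count of effective inflations."""
    if plateau <= initial:
        return plateau
    # logistic in "recovery units"; ~25 effective inflations at rate 4 bpm/infl
    # carry a decompensated 40 bpm most of the way to plateau
    x = effective_inflations * recovery_rate / (plateau - initial)
    frac = 1.0 / (1.0 + math.exp(-6.0 * (x - 0.5)))
    frac0 = 1.0 / (1.0 + math.exp(3.0))
    frac = (frac - frac0) / (1.0 - frac0)
    return initial + max(frac, 0.0) * (plateau - initial)


#: PEEP-level lead-in prepended to generated traces so that the first
#: inflation onset is a detectable pressure rise, seconds.
_LEAD_IN_S = 0.5


def _episode_from_breaths(breaths: list[dict], segments: list[tuple],
                          dt: float, rng: np.random.Generator,
                          noise: bool) -> tuple[WaveformRecord, pd.DataFrame]:
    """Concatenate per-breath segments (and pauses) into one waveform."""
    n_lead = int(round(_LEAD_IN_S / dt))
    lead_peep = breaths[0]["delivered_peep"]
    pressures, flows = [np.full(n_lead, lead_peep)], [np.zeros(n_lead)]
    sample_pos = n_lead
    for rec, (p_seg, q_seg) in zip(breaths, segments):
        rec["sample_start"] = sample_pos
        rec["sample_end"] = sample_pos + len(p_seg)
        pressures.append(p_seg)
        flows.append(q_seg)
        sample_pos += len(p_seg)
        if rec.get("pause_after_s", 0.0) > 0:
            n_pause = int(round(rec["pause_after_s"] / dt))
            pressures.append(np.full(n_pause, rec["delivered_peep"]))
            flows.append(np.zeros(n_pause))
            sample_pos += n_pause
    pressure = np.concatenate(pressures)
    flow = np.concatenate(flows)
    if noise:
        pressure = pressure + rng.normal(0.0, _PRESSURE_NOISE_SD, len(pressure))
        flow = flow + rng.normal(0.0, _FLOW_NOISE_SD, len(flow))
    time = np.arange(len(pressure)) * dt
    truth = pd.DataFrame(breaths)
    truth.insert(0, "breath_index", np.arange(1, len(truth) + 1))
    return WaveformRecord(time, pressure, flow), truth


def _draw_delivered_pressures(settings: ResuscitatorSettings,
                              jitter_scale: float,
                              rng: np.random.Generator) -> tuple[float, float]:
    pip_j = rng.normal(0.0, _PIP_JITTER_SD * jitter_scale)
    pip = settings.set_pip + min(pip_j, _PIP_JITTER_CAP)
    peep = settings.set_peep + rng.normal(0.0, _PEEP_JITTER_SD * jitter_scale)
    pip = max(pip, settings.set_peep + 5.0)
    peep = float(np.clip(peep, 0.5, settings.set_pip - 5.0))
    return float(pip), peep


def _spontaneous_effort(flow_seg: np.ndarray, n_insp: int, dt: float,
                        rng: np.random.Generator) -> None:
    """Superimpose a brief sinusoidal flow artefact during expiration."""
    n = len(flow_seg)
    n_eff = int(round(0.2 / dt))
    if n - n_insp <= n_eff + 2:
        return
    start = int(rng.integers(n_insp + 1, n - n_eff - 1))
    amp = rng.uniform(150.0, 450.0)  # mL/min
    wave = amp * np.sin(np.linspace(0.0, 2 * np.pi, n_eff))
    flow_seg[start:start + n_eff] += wave


def simulate_scenario(spec: ScenarioSpec | str,
                      profile: SubjectProfile | None = None,
                      settings: ResuscitatorSettings | None = None,
                      quality: Literal["optimal", "suboptimal"] = "optimal",
                      seed: int = 0,
                      dt: float = 0.01,
                      noise: bool = True,
                      leak: MaskLeakModel | None = None,
                      suboptimal_fail_fraction: float = 0.5,
                      rate_jitter: float = 0.0) -> Episode:
    """Simulate one manikin scenario run.

    The scenario clock credits only adequate inflations (delivered PIP at
    least 90% of set PIP); baby-cry is declared at the instant the cumulative
    credited PPV time reaches ``spec.optimal_ppv_to_success``, and the episode
    ends with that inflation's cycle. Under ``quality="optimal"`` every
    inflation is adequate, so ``success_time`` (elapsed ventilation time at
    cry) equals the scenario constant exactly; under ``"suboptimal"`` a
    fraction of inflations is delivered below the adequacy threshold and
    success takes longer. For valve-gated scenarios (S4) the compliance valve
    opens abruptly once ``spec.valve_threshold`` adequate inflations have been
    given, producing a step increase in expired volume.
    """
    if isinstance(spec, str):
        spec = scenario_spec(spec)
    if quality not in ("optimal", "suboptimal"):
        raise ValueError(f"quality must be 'optimal' or 'suboptimal', got {quality!r}")
    profile = manikin_profile() if profile is None else profile
    settings = ResuscitatorSettings() if settings is None else settings
    leak = MaskLeakModel() if leak is None else leak
    rng = np.random.default_rng(seed)

    rate = settings.inflation_rate * (1.0 + rng.uniform(-rate_jitter, rate_jitter))
    sim_settings = replace(settings, inflation_rate=rate)
    t_cycle = sim_settings.cycle_time
    t_insp = sim_settings.inspiratory_time

    lung_r = 0.30
    valve_open = not spec.valve_gated
    adequate_count = 0
    credited = 0.0  # s of effective PPV
    elapsed = 0.0  # s of ventilation delivered
    success_time = None
    v = None
    hr_rows = []
    breaths: list[dict] = []
    segments = []
    b = 0
    max_breaths = 2000
    while success_time is None and b < max_breaths:
        c_eff = spec.initial_compliance
        if spec.valve_gated and not valve_open:
            c_eff *= CLOSED_VALVE_COMPLIANCE_FRACTION
        if v is None:
            v = c_eff * sim_settings.set_peep
        pip_d, peep_d = _draw_delivered_pressures(
            sim_settings, profile.parameter_jitter_scale, rng)
        adequate_intent = True
        if quality == "suboptimal" and rng.random() < suboptimal_fail_fraction:
            # inadequate inflation: PIP well below the adequacy threshold
            pip_d = 0.9 * sim_settings.set_pip - rng.uniform(4.0, 8.0)
            adequate_intent = False
        f = leak.draw(b, rng)
        # valve state can change compliance between breaths; lung volume carries over
        p_seg, q_seg, v, v_insp, v_exp = _synth_cycle(
            sim_settings, c_eff, lung_r, f, dt, v, pip_d, peep_d,
            t_insp=t_insp, t_cycle=t_cycle)
        adequate = pip_d >= 0.9 * sim_settings.set_pip
        if adequate:
            adequate_count += 1
            if credited + t_cycle >= spec.optimal_ppv_to_success:
                # cry occurs partway through (or exactly at the end of) this cycle
                success_time = elapsed + (spec.optimal_ppv_to_success - credited)
            credited += t_cycle
        elapsed += t_cycle
        if spec.valve_gated and not valve_open and adequate_count >= spec.valve_threshold:
            valve_open = True
        hr = _heart_rate(spec.initial_heart_rate, adequate_count,
                         spec.heart_rate_recovery_rate)
        hr_rows.append({"time_s": elapsed, "heart_rate_bpm": hr})
        breaths.append({
            "t_start": elapsed - t_cycle, "duration_s": t_cycle,
            "delivered_pip": pip_d, "delivered_peep": peep_d,
            "leak_fraction": f, "compliance": c_eff,
            "v_insp_true": v_insp, "v_exp_true": v_exp,
            "adequate": adequate, "adequate_intent": adequate_intent,
            "obstructed": False, "valve_open": valve_open,
            "pause_after_s": 0.0,
        })
        segments.append((p_seg, q_seg))
        b += 1
    if success_time is None:
        raise RuntimeError("scenario did not reach success within the breath cap")
    record, truth = _episode_from_breaths(breaths, segments, dt, rng, noise)
    record.metadata.update({"recipient": profile.recipient,
                            "weight_kg": profile.weight,
                            "scenario": spec.scenario_id,
                            "settings": sim_settings, "seed": seed,
                            "quality": quality})
    return Episode(
        episode_id=f"{profile.recipient}-{spec.scenario_id}-seed{seed}",
        record=record, truth=truth, recipient=profile.recipient,
        scenario=spec.scenario_id, weight=profile.weight,
        success_time=float(success_time),
        heart_rate_series=pd.DataFrame(hr_rows),
        ppv_time=float(truth["duration_s"].sum()))


def simulate_baby_episode(duration_target: float,
                          settings: ResuscitatorSettings | None = None,
                          profile: SubjectProfile | None = None,
                          seed: int = 0,
                          dt: float = 0.01,
                          noise: bool = True,
                          leak: MaskLeakModel | None = None,
                          plateau_compliance: float = 0.70,
                          frc_breaths: int = 20,
                          frc_floor: float = 0.35,
                          pause_probability: float = 0.35,
                          end_transition_breaths: int = 4,
                          rate_jitter: float = 0.06,
                          compliance_jitter_sd: float = 0.18) -> Episode:
    """Simulate one real-newborn ventilation episode.

    Effective compliance ramps as ``floor + (1-floor)*(1-exp(-k*b))`` with
    ``k`` set so ~95% of the plateau is reached by ``frc_breaths`` (FRC
    establishment over the first ~20 inflations). Per-breath parameter jitter
    exceeds the manikin's by ``profile.parameter_jitter_scale``. When
    ``profile.end_transition == "gradual"``, delivered PIP and PEEP fall over
    the final few inflations while leak rises (the provider loosens the mask
    while assessing spontaneous breathing). Ventilation continues until the
    ventilated (pause-excluded) time reaches ``duration_target``; at most one
    pause longer than 5 s is inserted at a random position.
    """
    if duration_target <= 0:
        raise ValueError("duration_target must be positive")
    profile = baby_profile() if profile is None else profile
    if profile.recipient != "baby":
        raise ValueError("simulate_baby_episode requires a baby profile")
    settings = ResuscitatorSettings() if settings is None else settings
    leak = MaskLeakModel(mean_leak_fraction=0.48, per_breath_sd=0.18,
                         drift_per_breath=-0.0025) if leak is None else leak
    rng = np.random.default_rng(seed)

    rate = settings.inflation_rate * (1.0 + rng.uniform(-rate_jitter, rate_jitter))
    sim_settings = replace(settings, inflation_rate=rate)
    t_cycle = sim_settings.cycle_time
    t_insp = sim_settings.inspiratory_time
    n_breaths = max(int(round(duration_target / t_cycle)), 3)
    k = -math.log(0.05) / frc_breaths  # 95% of plateau by breath frc_breaths
    lung_r = 0.26

    pause_after = -1
    pause_dur = 0.0
    if rng.random() < pause_probability and n_breaths > 8:
        pause_after = int(rng.integers(3, n_breaths - 3))
        pause_dur = float(rng.uniform(6.0, 12.0))

    effort_prob = profile.spontaneous_effort_rate * t_cycle / 60.0
    v = None
    breaths: list[dict] = []
    segments = []
    elapsed = 0.0
    for b in range(n_breaths):
        ramp = frc_floor + (1.0 - frc_floor) * (1.0 - math.exp(-k * (b + 1)))
        # breath-to-breath lung-condition variability (tone, secretions,
        # spontaneous activity) — absent in the manikin's mechanical lung
        c_jit = math.exp(rng.normal(
            0.0, compliance_jitter_sd * profile.parameter_jitter_scale))
        c_eff = plateau_compliance * ramp * c_jit
        if v is None:
            v = c_eff * sim_settings.set_peep
        pip_d, peep_d = _draw_delivered_pressures(
            sim_settings, profile.parameter_jitter_scale, rng)
        f = leak.draw(b, rng)
        from_end = n_breaths - b  # end_transition_breaths .. 1 over the tail
        if profile.end_transition == "gradual" and from_end <= end_transition_breaths:
            fall = 1.0 - 0.3 * (end_transition_breaths - from_end + 1) / end_transition_breaths
            pip_d = max(pip_d * fall, peep_d + 4.0)
            peep_d = max(peep_d * fall, 0.5)
            f = float(np.clip(f + 0.3 * (end_transition_breaths - from_end + 1)
                              / end_transition_breaths, 0.0, 0.93))
        p_seg, q_seg, v, v_insp, v_exp = _synth_cycle(
            sim_settings, c_eff, lung_r, f, dt, v, pip_d, peep_d,
            t_insp=t_insp, t_cycle=t_cycle)
        q_seg = q_seg.copy()
        if rng.random() < effort_prob:
            _spontaneous_effort(q_seg, int(round(t_insp / dt)), dt, rng)
        elapsed += t_cycle
        breaths.append({
            "t_start": elapsed - t_cycle, "duration_s": t_cycle,
            "delivered_pip": pip_d, "delivered_peep": peep_d,
            "leak_fraction": f, "compliance": c_eff,
            "v_insp_true": v_insp, "v_exp_true": v_exp,
            "adequate": pip_d >= 0.9 * sim_settings.set_pip,
            "adequate_intent": True, "obstructed": False, "valve_open": True,
            "pause_after_s": pause_dur if b == pause_after else 0.0,
        })
        segments.append((p_seg, q_seg))
    record, truth = _episode_from_breaths(breaths, segments, dt, rng, noise)
    record.metadata.update({"recipient": "baby", "weight_kg": profile.weight,
                            "scenario": None, "settings": sim_settings,
                            "seed": seed})
    return Episode(
        episode_id=f"baby-seed{seed}", record=record, truth=truth,
        recipient="baby", scenario=None, weight=profile.weight,
        ppv_time=float(truth["duration_s"].sum()))


def inject_obstruction(episode: Episode, start_breath: int,
                       n_breaths: int) -> Episode:
    """Return a copy of ``episode`` with an upper-airway obstruction.

    Flow during the affected inflations (1-based ``start_breath`` through
    ``start_breath + n_breaths - 1``) is attenuated to near zero while the
    pressure trace is untouched, so target PIP is still achieved — the
    signature of an obstructed airway with a sealed mask. Breaths outside the
    window are unchanged.
    """
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    if start_breath < 1 or start_breath + n_breaths - 1 > episode.n_breaths:
        raise ValueError(
            f"obstruction window [{start_breath}, {start_breath + n_breaths - 1}] "
            f"exceeds episode length {episode.n_breaths}")
    truth = episode.truth.copy()
    flow = episode.record.flow.copy()
    lo = start_breath - 1
    hi = lo + n_breaths
    for _, row in truth.iloc[lo:hi].iterrows():
        s, e = int(row["sample_start"]), int(row["sample_end"])
        flow[s:e] *= OBSTRUCTION_FLOW_FACTOR
    truth.loc[truth.index[lo:hi], "obstructed"] = True
    truth.loc[truth.index[lo:hi], "v_insp_true"] *= OBSTRUCTION_FLOW_FACTOR
    truth.loc[truth.index[lo:hi], "v_exp_true"] *= OBSTRUCTION_FLOW_FACTOR
    record = WaveformRecord(episode.record.time.copy(),
                            episode.record.pressure.copy(), flow,
                            dict(episode.record.metadata))
    return Episode(episode_id=episode.episode_id, record=record, truth=truth,
                   recipient=episode.recipient, scenario=episode.scenario,
                   weight=episode.weight, success_time=episode.success_time,
                   heart_rate_series=episode.heart_rate_series,
                   ppv_time=episode.ppv_time)


def _inject_random_obstruction(episode: Episode,
                               rng: np.random.Generator) -> Episode:
    n_b = int(rng.integers(3, 6))
    margin = 3
    if episode.n_breaths < n_b + 2 * margin:
        return episode
    lo = margin + 1
    hi = episode.n_breaths - n_b - margin + 1
    # avoid the valve-gated opening phase, where volumes are already low
    if episode.scenario in ("S3", "S4"):
        lo = max(lo, scenario_spec(episode.scenario).valve_threshold + 4)
        if lo >= hi:
            return episode
    start = int(rng.integers(lo, hi + 1))
    return inject_obstruction(episode, start, n_b)


def simulate_study(n_providers: int = 18, seed: int = 0,
                   settings: ResuscitatorSettings | None = None,
                   dt: float = 0.01, noise: bool = True,
                   n_obstructed_manikin: int = 4,
                   n_obstructed_baby: int = 7,
                   duration_match_jitter: float = 0.04,
                   rate_jitter: float = 0.05) -> StudyData:
    """Simulate the full study design.

    Each of ``n_providers`` providers performs one S1 (short, ~30 s) and one
    S4 (long, ~90 s) manikin scenario, and for every manikin episode a real-
    newborn episode of matching ventilated duration (within a few percent, so
    comfortably inside the ±15% pairing tolerance) is generated into the
    clinical pool in the same order. A fixed number of episodes in each arm
    receives an injected upper-airway obstruction of 3-5 breaths. All episodes
    carry per-breath ground-truth logs.
    """
    if n_providers < 1:
        raise ValueError("n_providers must be >= 1")
    settings = ResuscitatorSettings() if settings is None else settings
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in
                   root.generate_state(4 * n_providers + 2) % (2 ** 31)]
    rng = np.random.default_rng(child_seeds[-1])

    manikin: list[Episode] = []
    babies: list[Episode] = []
    si = 0
    for p in range(n_providers):
        for scen in ("S1", "S4"):
            ep = simulate_scenario(scen, manikin_profile(), settings,
                                   quality="optimal", seed=child_seeds[si],
                                   dt=dt, noise=noise, rate_jitter=rate_jitter)
            ep.episode_id = f"M-{scen}-P{p + 1:02d}"
            si += 1
            manikin.append(ep)
            target = ep.ppv_time * (1.0 + rng.uniform(-duration_match_jitter,
                                                      duration_match_jitter))
            baby = simulate_baby_episode(target, settings,
                                         seed=child_seeds[si], dt=dt,
                                         noise=noise)
            baby.episode_id = f"B-{scen}-P{p + 1:02d}"
            si += 1
            babies.append(baby)

    obs_rng = np.random.default_rng(child_seeds[-2])
    # obstruction stays the exception: cap injections at a third of each arm
    cap = max(len(manikin) // 3, 0)
    for arm, n_obs in ((manikin, min(n_obstructed_manikin, cap)),
                       (babies, min(n_obstructed_baby, cap))):
        picks = obs_rng.choice(len(arm), size=n_obs, replace=False)
        for i in sorted(int(j) for j in picks):
            arm[i] = _inject_random_obstruction(arm[i], obs_rng)
    return StudyData(manikin_episodes=manikin, baby_episodes=babies,
                     seed=seed, n_providers=n_providers)
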