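"""Adaptive, rule-based heparin dosing engine for left-atrial ablation.

The controller maintains the activated clotting time (ACT) inside a
therapeutic window (default 300-350 s) during AF ablation.  It works in
three stages:

1. *Initialization* -- the first bolus is computed from body weight, the
   outpatient anticoagulant (which sets a units/kg rate), and how close the
   baseline ACT already sits to the goal window (the closer, the smaller
   the bolus).  The maintenance infusion starts only after the first
   post-bolus ACT.
2. *Calibration* -- the observed ACT rise per unit/kg of the first bolus
   yields a per-patient sensitivity ``S`` (seconds per unit/kg).  Every
   later (bolus, ACT) pair refines ``S`` by exponential smoothing, so the
   coefficients that generate recommendations adapt to the individual.
3. *Feedback* -- each new ACT drives a distance-to-goal rule: below the
   window, a supplemental bolus of ``weight * (center - ACT) / S`` units;
   inside or above it, a proportional infusion adjustment damped by the
   recent ACT trend; above the supratherapeutic threshold (default 400 s)
   the infusion is held at zero until the next measurement.

All gains, rate tables and clamps live in :class:`ProtocolParams`; nothing
is hard-coded, and every operation is a pure function of its inputs so that
identical state and inputs always reproduce the identical recommendation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Optional

ANTICOAGULANTS = ("apixaban", "rivaroxaban", "dabigatran", "warfarin", "none")

#: Final per-drug bolus rates, units/kg.
BOLUS_RATES = {
    "apixaban": 120.0,
    "rivaroxaban": 120.0,
    "dabigatran": 90.0,
    "warfarin": 75.0,
    "none": 120.0,
}

#: Final per-drug initial infusion rates, units/kg/h.
INFUSION_RATES = {
    "apixaban": 27.0,
    "rivaroxaban": 25.0,
    "dabigatran": 18.0,
    "warfarin": 24.0,
    "none": 24.0,
}

#: First-iteration protocol: flat 120 units/kg for any DOAC, 100 units/kg
#: without anticoagulation, and lower uniform infusions (18 DOAC / 15
#: warfarin units/kg/h).
PHASE1_BOLUS_RATES = {
    "apixaban": 120.0,
    "rivaroxaban": 120.0,
    "dabigatran": 120.0,
    "warfarin": 75.0,
    "none": 100.0,
}
PHASE1_INFUSION_RATES = {
    "apixaban": 18.0,
    "rivaroxaban": 18.0,
    "dabigatran": 18.0,
    "warfarin": 15.0,
    "none": 18.0,
}


class ValidationError(ValueError):
    """An input record violates one of its invariants."""


class ConfigurationError(ValueError):
    """A protocol/parameter document is inconsistent or incomplete."""


class PreconditionError(ValueError):
    """An operation was invoked before its state precondition held."""


def _clamp(x: float, lo: float, hi: float) -> float:
    return lo if x < lo else hi if x > hi else x


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PatientProfile:
    """Pre-procedure patient descriptors.

    Only ``anticoagulant``, ``weight`` and ``baseline_act`` enter the v1
    dose math; the remaining covariates are recorded because they are
    candidate predictors of heparin requirements, not because the engine
    uses them yet.
    """

    anticoagulant: str
    weight: float  # kg
    baseline_act: float  # seconds (ACT_0)
    hours_since_last_dose: Optional[float] = None
    sex: Optional[str] = None  # "male" | "female"
    age: Optional[float] = None  # years
    creatinine: Optional[float] = None  # mg/dL
    egfr: Optional[float] = None  # mL/min/1.73m2
    ast: Optional[float] = None  # U/L
    alt: Optional[float] = None  # U/L
    tbili: Optional[float] = None  # mg/dL
    platelets: Optional[float] = None  # 1e9/L

    def __post_init__(self) -> None:
        if self.anticoagulant not in ANTICOAGULANTS:
            raise ValidationError(
                f"unknown anticoagulant {self.anticoagulant!r}; "
                f"expected one of {ANTICOAGULANTS}"
            )
        if not self.weight > 0:
            raise ValidationError(f"weight must be > 0 kg, got {self.weight}")
        if not self.baseline_act > 0:
            raise ValidationError(
                f"baseline_act must be > 0 s, got {self.baseline_act}"
            )
        if self.hours_since_last_dose is not None and self.hours_since_last_dose < 0:
            raise ValidationError("hours_since_last_dose must be >= 0")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class GoalRange:
    """Therapeutic ACT window with its supratherapeutic ceiling."""

    low: float = 300.0
    high: float = 350.0
    center: Optional[float] = None  # defaults to the midpoint
    supra_threshold: float = 400.0

    def __post_init__(self) -> None:
        if self.center is None:
            object.__setattr__(self, "center", (self.low + self.high) / 2.0)
        if not (self.low < self.center < self.high < self.supra_threshold):
            raise ValidationError(
                "goal ordering violated: require low < center < high "
                f"< supra_threshold, got {self.low}, {self.center}, "
                f"{self.high}, {self.supra_threshold}"
            )


@dataclass
class ProtocolParams:
    """Every tunable constant of the dosing protocol.

    ``bolus_rates`` / ``infusion_rates`` are the per-anticoagulant dose
    tables (units/kg and units/kg/h).  ``reference_baseline_act`` anchors
    the proximity down-scaling ramp: a baseline ACT at (or below) this
    value receives the full table bolus, a baseline at ``goal.low``
    receives none, linear in between.  ``s_min``/``s_max`` bound the
    adapted sensitivity, ``learning_rate`` is the exponential-smoothing
    weight of each new sensitivity observation, ``infusion_gain`` converts
    seconds of goal error into units/kg/h of infusion change, and
    ``trend_damping`` subtracts a multiple of the spontaneous ACT drift
    between measurements.
    """

    bolus_rates: dict = field(default_factory=lambda: dict(BOLUS_RATES))
    infusion_rates: dict = field(default_factory=lambda: dict(INFUSION_RATES))
    reference_baseline_act: float = 120.0  # s
    min_bolus: float = 0.0  # units, supplemental-bolus floor
    max_bolus: float = 6000.0  # units, supplemental-bolus ceiling
    min_infusion: float = 0.0  # units/kg/h
    max_infusion: float = 40.0  # units/kg/h
    s_min: float = 0.3  # s per unit/kg
    s_max: float = 5.0  # s per unit/kg
    learning_rate: float = 0.5  # alpha in (0, 1]
    infusion_gain: float = 0.2  # (units/kg/h) per second of goal error
    trend_damping: float = 0.1  # (units/kg/h) per second of inter-ACT drift
    reference_sensitivity: float = 1.5  # s per unit/kg, pre-calibration prior
    initial_interval: float = 10.0  # minutes between early ACT draws
    stable_interval: float = 30.0  # minutes once 3 consecutive ACTs in goal
    bolus_round: int = 100  # round boluses to this many units (0 = off)
    scale_infusion_by_sensitivity: bool = True

    def __post_init__(self) -> None:
        for table, name in ((self.bolus_rates, "bolus_rates"),
                            (self.infusion_rates, "infusion_rates")):
            missing = [d for d in ANTICOAGULANTS if d not in table]
            if missing:
                raise ConfigurationError(f"{name} missing entries for {missing}")
            bad = [d for d, r in table.items() if not r > 0]
            if bad:
                raise ConfigurationError(f"{name} must be > 0, bad: {bad}")
        if not 0 < self.s_min <= self.s_max:
            raise ConfigurationError("require 0 < s_min <= s_max")
        if not 0 < self.learning_rate <= 1:
            raise ConfigurationError("learning_rate must be in (0, 1]")
        if self.min_bolus < 0 or self.max_bolus < self.min_bolus:
            raise ConfigurationError("require 0 <= min_bolus <= max_bolus")
        if self.min_infusion < 0 or self.max_infusion < self.min_infusion:
            raise ConfigurationError("require 0 <= min_infusion <= max_infusion")
        if self.bolus_round < 0:
            raise ConfigurationError("bolus_round must be >= 0")
        if not self.reference_baseline_act > 0:
            raise ConfigurationError("reference_baseline_act must be > 0")
        if not (self.initial_interval > 0 and self.stable_interval > 0):
            raise ConfigurationError("sampling intervals must be > 0")

    @classmethod
    def phase1(cls, **overrides) -> "ProtocolParams":
        """The pre-adaptation parameter preset (first development phase)."""
        overrides.setdefault("bolus_rates", dict(PHASE1_BOLUS_RATES))
        overrides.setdefault("infusion_rates", dict(PHASE1_INFUSION_RATES))
        return cls(**overrides)


@dataclass
class ActMeasurement:
    """One ACT draw: ``value`` seconds measured ``time`` minutes in."""

    time: float
    value: float
    index: int = 0
    flagged_suspect: bool = False

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError(f"ACT value must be > 0 s, got {self.value}")
        if self.index < 0:
            raise ValidationError("ACT index must be >= 0")


@dataclass
class DoseEvent:
    """A bolus or an infusion-rate change at ``time`` minutes."""

    time: float
    kind: str  # "bolus" | "infusion_change"
    bolus_units: float = 0.0
    new_infusion_rate: Optional[float] = None  # units/h

    def __post_init__(self) -> None:
        if self.kind not in ("bolus", "infusion_change"):
            raise ValidationError(f"unknown dose event kind {self.kind!r}")
        if self.kind == "bolus" and not self.bolus_units > 0:
            raise ValidationError("bolus events must carry bolus_units > 0")
        if self.kind == "infusion_change":
            if self.new_infusion_rate is None or self.new_infusion_rate < 0:
                raise ValidationError(
                    "infusion_change events must carry a rate >= 0"
                )


@dataclass
class EngineState:
    """Controller memory between measurements.

    ``sensitivity`` is the current estimate of ACT seconds gained per
    unit/kg of bolus; ``infusion_rate_per_kg`` is the engine's maintenance
    rate (kept through a supratherapeutic hold so the infusion resumes from
    where it left off); ``consecutive_in_goal`` feeds the sampling-cadence
    extension; ``history`` records (dose, measurement) pairs, with a
    ``None`` dose for measurement-only entries.
    """

    sensitivity: float = 1.5
    infusion_rate_per_kg: float = 0.0  # units/kg/h
    consecutive_in_goal: int = 0
    calibrated: bool = False
    prev_act_value: Optional[float] = None
    bolus_since_last_act: bool = False
    history: list = field(default_factory=list)


@dataclass
class Recommendation:
    """Engine output: what to give now and when to re-measure."""

    bolus_units: float
    infusion_rate: float  # units/h
    next_act_in: float  # minutes
    rationale: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.bolus_units) and self.bolus_units >= 0):
            raise ValidationError("bolus_units must be finite and >= 0")
        if not (math.isfinite(self.infusion_rate) and self.infusion_rate >= 0):
            raise ValidationError("infusion_rate must be finite and >= 0")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def round_bolus(units: float, params: ProtocolParams) -> float:
    """Round a bolus to the protocol's syringe increment (0 = no rounding)."""
    step = params.bolus_round
    if step == 0:
        return float(units)
    return float(step * round(units / step))


def baseline_scaling_factor(
    act0: float, goal: GoalRange, params: ProtocolParams
) -> float:
    """Down-scaling of the table bolus by baseline-ACT proximity to goal.

    Returns 1 when the baseline ACT is at or below the unanticoagulated
    reference, 0 when it already reaches the bottom of the goal window,
    and the linear interpolant in between.
    """
    if not act0 > 0:
        raise ValidationError("act0 must be > 0")
    ramp = (goal.low - act0) / (goal.low - params.reference_baseline_act)
    return _clamp(ramp, 0.0, 1.0)


def initial_bolus(
    profile: PatientProfile, goal: GoalRange, params: ProtocolParams
) -> Recommendation:
    """First bolus: per-drug rate x weight x baseline proximity scaling.

    The infusion is deliberately zero here -- it starts only after the
    first post-bolus ACT has been seen.
    """
    try:
        rate = params.bolus_rates[profile.anticoagulant]
    except KeyError:
        raise ConfigurationError(
            f"no bolus rate configured for {profile.anticoagulant!r}"
        ) from None
    scale = baseline_scaling_factor(profile.baseline_act, goal, params)
    units = round_bolus(rate * profile.weight * scale, params)
    return Recommendation(
        bolus_units=units,
        infusion_rate=0.0,
        next_act_in=params.initial_interval,
        rationale="initial_bolus",
    )


def initial_infusion(
    profile: PatientProfile, params: ProtocolParams
) -> Recommendation:
    """Starting maintenance infusion: per-drug units/kg/h x weight."""
    try:
        rate = params.infusion_rates[profile.anticoagulant]
    except KeyError:
        raise ConfigurationError(
            f"no infusion rate configured for {profile.anticoagulant!r}"
        ) from None
    return Recommendation(
        bolus_units=0.0,
        infusion_rate=rate * profile.weight,
        next_act_in=params.initial_interval,
        rationale="initial_infusion",
    )


def calibrate_sensitivity(
    state: EngineState,
    act_prev: ActMeasurement,
    act_new: ActMeasurement,
    dose: DoseEvent,
    weight: float,
    params: ProtocolParams,
) -> EngineState:
    """Update the sensitivity estimate from one (bolus, ACT rise) pair.

    The first observation sets ``S`` outright; later ones blend in with
    weight ``learning_rate`` (exponential smoothing).  A non-positive ACT
    response to a bolus is physiologically implausible, so the new
    measurement is flagged suspect (the bedside rule is to redraw it) and
    the observation is floored at ``s_min``.
    """
    if dose.kind != "bolus" or not dose.bolus_units > 0:
        raise PreconditionError("calibration requires a bolus with units > 0")
    if not act_new.time > act_prev.time:
        raise PreconditionError("act_new must be measured after act_prev")
    if not weight > 0:
        raise ValidationError("weight must be > 0")

    delta = act_new.value - act_prev.value
    if delta <= 0:
        act_new.flagged_suspect = True
        s_obs = params.s_min
    else:
        s_obs = _clamp(delta / (dose.bolus_units / weight), params.s_min, params.s_max)

    if not state.calibrated:
        s_new = s_obs
    else:
        a = params.learning_rate
        s_new = (1.0 - a) * state.sensitivity + a * s_obs
    s_new = _clamp(s_new, params.s_min, params.s_max)
    return replace(
        state,
        sensitivity=s_new,
        calibrated=True,
        history=state.history + [(dose, act_new)],
    )


def observe_act(
    state: EngineState, act: ActMeasurement, goal: GoalRange
) -> EngineState:
    """Record a measurement: update the in-goal streak and trend anchor."""
    in_goal = goal.low <= act.value <= goal.high
    return replace(
        state,
        consecutive_in_goal=state.consecutive_in_goal + 1 if in_goal else 0,
        prev_act_value=act.value,
        bolus_since_last_act=False,
        history=state.history + [(None, act)],
    )


def next_sample_interval(state: EngineState, goal: GoalRange,
                         params: Optional[ProtocolParams] = None) -> float:
    """Minutes until the next ACT draw: 30 after 3 stable in-goal ACTs."""
    params = params or ProtocolParams()
    if state.consecutive_in_goal >= 3:
        return params.stable_interval
    return params.initial_interval


def is_steady_state(state: EngineState, goal: GoalRange) -> bool:
    """Steady state once 3 consecutive ACTs sit inside the goal window."""
    return state.consecutive_in_goal >= 3


def recommend_next(
    state: EngineState,
    act_n: ActMeasurement,
    goal: GoalRange,
    profile: PatientProfile,
    params: ProtocolParams,
) -> Recommendation:
    """Distance-to-goal recommendation for one new ACT.

    Call with the state as it was *before* :func:`observe_act` consumes
    ``act_n`` (the trend term needs the previous measurement).  Branches:

    * ACT below the window: supplemental bolus ``weight * error / S``
      (clamped and rounded) plus an infusion increase;
    * ACT inside the window: bolus 0, proportional infusion adjustment
      damped by the spontaneous inter-ACT drift;
    * ACT above the window (including above the supratherapeutic
      threshold): bolus 0 and infusion suspended until the next
      measurement; the engine remembers its maintenance rate and resumes
      adjustment from it afterwards.
    """
    if not state.calibrated:
        raise PreconditionError(
            "recommend_next requires a calibrated state (first post-bolus ACT)"
        )
    v = act_n.value
    e = goal.center - v
    if state.prev_act_value is not None and not state.bolus_since_last_act:
        trend = v - state.prev_act_value
    else:
        trend = 0.0

    in_goal = goal.low <= v <= goal.high
    streak = state.consecutive_in_goal + 1 if in_goal else 0
    next_in = params.stable_interval if streak >= 3 else params.initial_interval

    if v > goal.supra_threshold:
        return Recommendation(0.0, 0.0, next_in, "supratherapeutic_hold")

    new_rate_per_kg = _clamp(
        state.infusion_rate_per_kg
        + params.infusion_gain * e
        - params.trend_damping * trend,
        params.min_infusion,
        params.max_infusion,
    )
    infusion = new_rate_per_kg * profile.weight

    if v < goal.low:
        units = _clamp(
            profile.weight * e / state.sensitivity,
            params.min_bolus,
            params.max_bolus,
        )
        units = round_bolus(units, params)
        return Recommendation(units, infusion, next_in, "below_goal_bolus")
    if in_goal:
        return Recommendation(0.0, infusion, next_in, "in_goal")
    # between goal.high and the supratherapeutic threshold: suspend the
    # infusion until the next draw (the maintenance rate is remembered and
    # resumes, gain-adjusted, once the ACT is back at goal)
    return Recommendation(0.0, 0.0, next_in, "above_goal_hold")


def apply_recommendation(
    state: EngineState, rec: Recommendation, weight: float
) -> EngineState:
    """Fold an executed recommendation back into controller memory.

    A supratherapeutic hold zeroes the pump but not the remembered
    maintenance rate; any executed bolus marks the trend anchor stale.
    """
    new = state
    if rec.rationale not in ("supratherapeutic_hold", "above_goal_hold"):
        new = replace(new, infusion_rate_per_kg=rec.infusion_rate / weight)
    if rec.bolus_units > 0:
        new = replace(new, bolus_since_last_act=True)
    return new


def start_infusion(
    state: EngineState, profile: PatientProfile, params: ProtocolParams
) -> EngineState:
    """Set the maintenance rate after the first post-bolus ACT.

    When enabled, the table rate is scaled by ``reference_sensitivity / S``
    (clamped to [0.5, 2]) so that a patient who responded weakly to the
    bolus also receives a proportionally stronger infusion -- the same
    response-scaling that governs supplemental boluses.
    """
    base = params.infusion_rates[profile.anticoagulant]
    if params.scale_infusion_by_sensitivity and state.calibrated:
        base *= _clamp(params.reference_sensitivity / state.sensitivity, 0.5, 2.0)
    base = _clamp(base, params.min_infusion, params.max_infusion)
    return replace(state, infusion_rate_per_kg=base)


@dataclass
class ReplayResult:
    """Controller state reconstructed by replaying a logged session."""

    state: EngineState
    prev_act: Optional[ActMeasurement]
    pending_bolus: Optional[DoseEvent]
    infusion_started: bool
    pump_rate: float  # units/h actually running


def replay_events(
    events: list,
    profile: PatientProfile,
    goal: GoalRange,
    params: ProtocolParams,
) -> ReplayResult:
    """Rebuild the engine state from a time-ordered event log.

    The engine is deterministic, so replaying the logged boluses, infusion
    changes and measurements recovers exactly the state it held when the
    log was written -- this is how a session is resumed.  A logged pump
    rate of zero is treated as a supratherapeutic hold (the remembered
    maintenance rate is kept).
    """
    state = EngineState(sensitivity=params.reference_sensitivity)
    prev_act: Optional[ActMeasurement] = None
    pending: Optional[DoseEvent] = None
    infusion_started = False
    pump = 0.0
    for ev in events:
        if isinstance(ev, ActMeasurement):
            if prev_act is None:
                prev_act = ev  # baseline draw, nothing to adapt from yet
                continue
            if pending is not None:
                state = calibrate_sensitivity(
                    state, prev_act, ev, pending, profile.weight, params
                )
                pending = None
            state = observe_act(state, ev, goal)
            prev_act = ev
        elif ev.kind == "bolus":
            pending = ev
            state = replace(state, bolus_since_last_act=True)
        else:
            pump = ev.new_infusion_rate
            infusion_started = True
            if pump > 0:
                state = replace(
                    state, infusion_rate_per_kg=pump / profile.weight
                )
    if not state.calibrated and prev_act is not None and pending is None \
            and infusion_started:
        state = replace(state, calibrated=True)
    return ReplayResult(state, prev_act, pending, infusion_started, pump)


def serialize_recommendation(rec: Recommendation) -> str:
    """Canonical single-line form, used for bit-level determinism checks."""
    d = dataclasses.asdict(rec)
    return (
        f"bolus_units={d['bolus_units']!r} infusion_rate={d['infusion_rate']!r} "
        f"next_act_in={d['next_act_in']!r} rationale={d['rationale']}"
    )
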