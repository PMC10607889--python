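"""Closed-loop decision logic for propofol, remifentanil and rocuronium.

The automatic policy tracks:

* propofol — effect-site TCI at esTEC-P45, modified in order by three
  safety rules: (1) when the BIS is unreliable (high EMG, low SQI or
  invalid) the target ramps upward over time; (2) when BIS rises above the
  band a temporary additive boost is applied with linear decay; (3) the
  target is clamped to an age-dependent floor (1.4 µg·mL⁻¹ below 80 years,
  1.0 µg·mL⁻¹ at 80 and above). The floor wins the rationale when it binds.

* remifentanil — effect-site TCI at esMIC₂₀, with: a fixed
  0.5 µg·kg⁻¹·min⁻¹ (ideal-body-weight) rate override at surgical incision;
  a single 50–100 µg bolus on a sudden esMIC increase; a temporary forced
  target of 4.0 ng·mL⁻¹ whenever BIS ≥ 70 (which also boosts propofol);
  and a rate-limited, gradual descent when esMIC decreases.

* rocuronium — after the induction bolus the loop waits for the first
  train-of-four count of 1, captures the concurrent modeled effect-site
  concentration as the individual reference, and thereafter regulates the
  modeled concentration at that reference by TCI.

A deliberately simplified rule-based "manual" policy reproduces the
comparator arm: stepwise plasma-TCI propofol on BIS excursions, stepwise
remifentanil on hemodynamic excursions (capped at 2 µg·kg⁻¹·min⁻¹), and
stepwise rocuronium from 7 µg·kg⁻¹·min⁻¹ to hold TOF 1, all with a human
reaction latency.

All steps are pure functions of (observation, fit, config, loop state);
identical inputs yield identical command streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import HyperbolaFit, SigmoidPDFit
from .pk import PKModel, PKState, ideal_body_weight

__all__ = [
    "ControllerConfig",
    "Command",
    "LoopState",
    "BISSample",
    "TOFSample",
    "HemoSample",
    "induction_policy",
    "propofol_step",
    "remifentanil_step",
    "rocuronium_step",
    "manual_policy_step",
    "ManualState",
]

PHASES = ("PRE_INDUCTION", "INDUCTION", "CLOSED_LOOP", "EMERGENCE")


@dataclass(frozen=True)
class BISSample:
    t: float
    bis: float
    sqi: float
    emg: float
    valid: bool = True


@dataclass(frozen=True)
class TOFSample:
    t: float
    count: int
    valid: bool = True


@dataclass(frozen=True)
class HemoSample:
    t: float
    sbp: float
    hr: float


@dataclass
class ControllerConfig:
    """All behavioral constants of the automatic policy.

    The printed clinical constants (BIS target/band, floors, rescue target,
    incision rate, bolus range) are defaults here; the unprinted magnitudes
    (ramp slopes, hold times, refractory windows) are explicit so that
    sensitivity analyses are one-flag experiments.
    """

    bis_target: float = 45.0
    bis_band: tuple[float, float] = (35.0, 55.0)
    propofol_floor_young: float = 1.4  # µg/mL, age < 80
    propofol_floor_old: float = 1.0  # µg/mL, age >= 80
    floor_age_cutoff: float = 80.0
    propofol_target_max: float = 8.0  # µg/mL safety cap
    bis_rescue_threshold: float = 70.0
    remi_rescue_target: float = 4.0  # ng/mL
    remi_rescue_hold_s: float = 180.0
    incision_remi_rate_per_kg: float = 0.5  # µg/kg(IBW)/min
    incision_hold_s: float = 120.0
    remi_bolus_range: tuple[float, float] = (50.0, 100.0)  # µg
    remi_bolus_refractory_s: float = 180.0
    esmic_jump_threshold: float = 0.5  # ng/mL between consecutive refits
    esmic_jump_full_scale: float = 1.5  # ng/mL above threshold giving max bolus
    remi_gradual_decrease_per_min: float = 0.1  # ng/mL/min
    remi_target_max: float = 12.0  # ng/mL safety cap
    delta_pct: float = 20.0
    control_interval_s: float = 10.0
    refit_interval_s: float = 30.0
    # low-signal ramp: +ramp_step per ramp_period of continuous unreliability
    low_signal_ramp_step: float = 0.2  # µg/mL
    low_signal_ramp_period_s: float = 300.0
    low_signal_ramp_cap: float = 1.0  # µg/mL above last reliable target
    bis_rise_trigger_s: float = 30.0
    bis_boost_amount: float = 0.5  # µg/mL
    bis_boost_decay_s: float = 300.0
    sqi_low_limit: float = 50.0  # controller-side reliability (evaluation uses 80)
    emg_high_limit: float = 55.0
    # induction constants
    induction_remi_rate_per_kg: float = 0.5  # µg/kg(IBW)/min
    induction_prop_bolus_per_kg: float = 0.5  # mg/kg over 10 s
    induction_prop_bolus_duration_s: float = 10.0
    induction_prop_infusion_per_kg_h: float = 10.0  # mg/kg/h after LOC
    induction_roc_bolus_per_kg: float = 0.6  # mg/kg
    induction_prop_start_s: float = 300.0
    induction_loc_grace_s: float = 120.0  # after the bolus, start the infusion anyway
    default_prop_target: float = 3.0  # µg/mL fallback before first fit
    roc_mode: str = "effect"  # "effect" (default) or "plasma" regulation
    # manual-policy constants
    manual_prop_step: float = 0.3  # µg/mL
    manual_prop_init_target: float = 3.0  # µg/mL plasma
    manual_remi_step_per_kg: float = 0.1  # µg/kg(IBW)/min
    manual_remi_max_per_kg: float = 2.0  # µg/kg/min cap
    manual_roc_init_rate_per_kg: float = 7.0  # µg/kg/min
    manual_roc_step_per_kg: float = 1.0  # µg/kg/min
    manual_latency_s: float = 30.0
    manual_cooldown_s: float = 60.0

    def __post_init__(self) -> None:
        lo, hi = self.bis_band
        if not lo < self.bis_target < hi:
            raise ValueError("bis_band must bracket bis_target")
        if self.propofol_floor_young <= 0 or self.propofol_floor_old <= 0:
            raise ValueError("propofol floors must be positive")
        blo, bhi = self.remi_bolus_range
        if not 0 < blo <= bhi:
            raise ValueError("remi_bolus_range must be ordered and positive")

    def propofol_floor(self, age: float) -> float:
        return self.propofol_floor_old if age >= self.floor_age_cutoff else self.propofol_floor_young


@dataclass(frozen=True)
class Command:
    """One controller decision for one drug at one tick."""

    drug: str
    rate: float  # mass/min (mg/min propofol+rocuronium, µg/min remifentanil)
    bolus: float = 0.0
    target: float | None = None
    rationale: str = "TRACKING"

    def __post_init__(self) -> None:
        if self.rate < 0 or self.bolus < 0:
            raise ValueError("rate and bolus must be >= 0")


@dataclass
class LoopState:
    """Mutable controller memory carried between ticks."""

    phase: str = "PRE_INDUCTION"
    prop_target: float | None = None
    remi_target: float | None = None
    tof1_reference: float | None = None
    tof_zero_seen: bool = False
    last_reliable_prop_target: float | None = None
    unreliable_since: float | None = None
    boost_started_at: float | None = None
    bis_high_since: float | None = None
    rescue_until: float = -1.0
    incision_until: float = -1.0
    last_esmic: float | None = None
    last_bolus_at: float = -1e12
    roc_last_rate: float = 0.0
    prop_boost_request: bool = False  # set by remifentanil rescue, consumed by propofol

    def advance_phase(self, phase: str) -> None:
        if PHASES.index(phase) < PHASES.index(self.phase):
            raise ValueError(f"phase may only move forward ({self.phase} -> {phase})")
        self.phase = phase


# ------------------------------------------------------------------ induction

def induction_policy(
    profile,
    t: float,
    config: ControllerConfig,
    state: LoopState,
    loc_seen: bool,
    roc_bolus_given: bool,
) -> list[Command]:
    """Scripted automatic-group induction sequence.

    Remifentanil runs at 0.5 µg·kg⁻¹·min⁻¹ (IBW) from t = 0; at t = 300 s a
    propofol bolus of 0.5 mg·kg⁻¹ is delivered over 10 s; after loss of
    consciousness propofol runs at 10 mg·kg⁻¹·h⁻¹ and rocuronium 0.6 mg·kg⁻¹
    is given. The caller transitions to CLOSED_LOOP once the first valid
    fits exist.
    """
    ibw = ideal_body_weight(profile.height)
    cmds = [
        Command("remifentanil", rate=config.induction_remi_rate_per_kg * ibw,
                rationale="INDUCTION")
    ]
    t0 = config.induction_prop_start_s
    dur = config.induction_prop_bolus_duration_s
    if t0 <= t < t0 + dur:
        # 0.5 mg/kg delivered over 10 s, expressed as an equivalent rate
        rate = config.induction_prop_bolus_per_kg * profile.weight / (dur / 60.0)
        cmds.append(Command("propofol", rate=rate, rationale="INDUCTION"))
    elif loc_seen or t >= t0 + dur + config.induction_loc_grace_s:
        # after loss of consciousness — or escalation when it is overdue
        rate = config.induction_prop_infusion_per_kg_h * profile.weight / 60.0
        cmds.append(Command("propofol", rate=rate, rationale="INDUCTION"))
    else:
        cmds.append(Command("propofol", rate=0.0, rationale="INDUCTION"))
    if loc_seen and not roc_bolus_given:
        cmds.append(Command("rocuronium", rate=0.0,
                            bolus=config.induction_roc_bolus_per_kg * profile.weight,
                            rationale="INDUCTION"))
    else:
        cmds.append(Command("rocuronium", rate=0.0, rationale="INDUCTION"))
    return cmds


# ------------------------------------------------------------------- propofol

def propofol_step(
    obs: BISSample,
    fit: SigmoidPDFit | None,
    config: ControllerConfig,
    state: LoopState,
    model: PKModel,
    pk_state: PKState,
    age: float,
) -> Command:
    """One propofol control tick in CLOSED_LOOP."""
    if state.phase != "CLOSED_LOOP":
        raise ValueError("propofol_step requires CLOSED_LOOP phase")
    t = obs.t
    floor = config.propofol_floor(age)

    if fit is None and state.prop_target is None:
        state.prop_target = config.default_prop_target

    if fit is None:
        base = state.prop_target
        rationale = "HOLD_NOT_READY"
    else:
        try:
            base = fit.invert(config.bis_target)
            rationale = "TRACKING"
        except ValueError:
            base = state.prop_target if state.prop_target is not None else config.default_prop_target
            rationale = "HOLD_NOT_READY"

    unreliable = (not obs.valid) or obs.sqi < config.sqi_low_limit or obs.emg > config.emg_high_limit

    # rule 1: low-signal upward ramp
    if unreliable:
        if state.unreliable_since is None:
            state.unreliable_since = t
            if state.last_reliable_prop_target is None:
                state.last_reliable_prop_target = base
        anchor = state.last_reliable_prop_target
        ramp = config.low_signal_ramp_step * (t - state.unreliable_since) / config.low_signal_ramp_period_s
        target = anchor + min(ramp, config.low_signal_ramp_cap)
        rationale = "LOW_SIGNAL_RAMP"
    else:
        state.unreliable_since = None
        state.last_reliable_prop_target = base
        target = base

        # rule 2: temporary boost when BIS rises above the band
        _, band_hi = config.bis_band
        if obs.bis > band_hi:
            if state.bis_high_since is None:
                state.bis_high_since = t
        else:
            state.bis_high_since = None
        trigger = (
            (state.bis_high_since is not None
             and t - state.bis_high_since >= config.bis_rise_trigger_s)
            or obs.bis >= config.bis_rescue_threshold
            or state.prop_boost_request
        )
        if trigger:
            state.boost_started_at = t
            state.prop_boost_request = False
        if state.boost_started_at is not None:
            age_s = t - state.boost_started_at
            if age_s < config.bis_boost_decay_s:
                target = target + config.bis_boost_amount * (1.0 - age_s / config.bis_boost_decay_s)
                rationale = "BIS_RISE_BOOST"
            else:
                state.boost_started_at = None

    # rule 3: age-dependent floor, applied last; it owns the rationale if it binds
    if target < floor:
        target = floor
        rationale = "FLOOR_CLAMP"
    target = min(target, config.propofol_target_max)

    state.prop_target = target
    res = model.tci_effect(pk_state, target, horizon=config.control_interval_s)
    return Command("propofol", rate=res.rate, target=target, rationale=rationale)


# --------------------------------------------------------------- remifentanil

def remifentanil_step(
    obs: BISSample,
    hfit: HyperbolaFit | None,
    config: ControllerConfig,
    state: LoopState,
    model: PKModel,
    pk_state: PKState,
    ibw: float,
    incision_now: bool = False,
) -> Command:
    """One remifentanil control tick in CLOSED_LOOP."""
    if state.phase != "CLOSED_LOOP":
        raise ValueError("remifentanil_step requires CLOSED_LOOP phase")
    t = obs.t
    bolus = 0.0
    rationale = "TRACKING"

    if hfit is None and state.last_esmic is None and state.remi_target is None:
        # nothing to track yet at all
        return Command("remifentanil", rate=0.0, rationale="HOLD_NOT_READY")

    if hfit is not None:
        current_esmic = float(np.clip(hfit.esmic(config.delta_pct),
                                      0.0, config.remi_target_max))
        # (2) sudden esMIC increase -> one proportional bolus, with refractory
        if (
            state.last_esmic is not None
            and current_esmic - state.last_esmic > config.esmic_jump_threshold
            and t - state.last_bolus_at >= config.remi_bolus_refractory_s
        ):
            lo, hi = config.remi_bolus_range
            excess = current_esmic - state.last_esmic - config.esmic_jump_threshold
            bolus = lo + (hi - lo) * min(1.0, excess / config.esmic_jump_full_scale)
            state.last_bolus_at = t
            rationale = "ESMIC_JUMP_BOLUS"
        state.last_esmic = current_esmic
    else:
        current_esmic = state.last_esmic
        if current_esmic is None:
            current_esmic = state.remi_target
        rationale = "HOLD_NOT_READY"

    if state.remi_target is None:
        state.remi_target = current_esmic

    # (4) asymmetric tracking: jump up instantly, descend at the slow rate
    if current_esmic >= state.remi_target:
        state.remi_target = current_esmic
    else:
        max_down = config.remi_gradual_decrease_per_min * config.control_interval_s / 60.0
        state.remi_target = max(current_esmic, state.remi_target - max_down)
        if rationale == "TRACKING":
            rationale = "GRADUAL_DECREASE"

    # (3) BIS >= 70 rescue: forced target, propofol boost flagged
    if obs.valid and obs.bis >= config.bis_rescue_threshold:
        state.rescue_until = t + config.remi_rescue_hold_s
        state.prop_boost_request = True
    target = state.remi_target
    if t < state.rescue_until:
        target = max(target, config.remi_rescue_target)
        state.remi_target = target
        rationale = "BIS70_RESCUE"

    # (1) incision: fixed weight-based rate overrides the TCI rate
    if incision_now:
        state.incision_until = t + config.incision_hold_s
    if t < state.incision_until:
        rate = config.incision_remi_rate_per_kg * ibw
        return Command("remifentanil", rate=rate, bolus=bolus, target=target,
                       rationale="INCISION")

    res = model.tci_effect(pk_state, target, horizon=config.control_interval_s)
    return Command("remifentanil", rate=res.rate, bolus=bolus, target=target,
                   rationale=rationale)


# ----------------------------------------------------------------- rocuronium

def rocuronium_step(
    tof: TOFSample,
    config: ControllerConfig,
    state: LoopState,
    model: PKModel,
    pk_state: PKState,
) -> Command:
    """One rocuronium control tick in CLOSED_LOOP.

    Before the reference exists the pump is off and the loop watches for the
    first TOF count of 1 as the block *recovers* after the induction bolus
    (a count of 0 must have been seen first, so the transit through 1 during
    onset is not mistaken for recovery); the concurrent modeled
    concentration (effect-site by default) becomes the individual target.
    """
    if state.phase != "CLOSED_LOOP":
        raise ValueError("rocuronium_step requires CLOSED_LOOP phase")
    regulated = pk_state.ce if config.roc_mode == "effect" else pk_state.c1

    if state.tof1_reference is None:
        if tof.valid and tof.count == 0:
            state.tof_zero_seen = True
        if tof.valid and tof.count == 1 and state.tof_zero_seen:
            state.tof1_reference = regulated
            rate = model.tci_plasma(pk_state, state.tof1_reference,
                                    horizon=config.control_interval_s)
            state.roc_last_rate = rate
            return Command("rocuronium", rate=rate, target=state.tof1_reference,
                           rationale="TRACKING")
        return Command("rocuronium", rate=0.0, rationale="HOLD_NOT_READY")

    if not tof.valid:
        # monitor invalid: hold the current rate rather than chase noise
        return Command("rocuronium", rate=state.roc_last_rate,
                       target=state.tof1_reference, rationale="HOLD_NOT_READY")

    target = state.tof1_reference
    if config.roc_mode == "effect":
        res = model.tci_effect(pk_state, target, horizon=config.control_interval_s)
        rate = res.rate
    else:
        rate = model.tci_plasma(pk_state, target, horizon=config.control_interval_s)
    state.roc_last_rate = rate
    return Command("rocuronium", rate=rate, target=target, rationale="TRACKING")


# -------------------------------------------------------------- manual policy

@dataclass
class ManualState:
    """Memory of the scripted rule-based clinician."""

    prop_target: float = 3.0
    remi_rate_per_kg: float = 0.5
    roc_rate_per_kg: float = 0.0
    bis_out_since: float | None = None
    hemo_high_since: float | None = None
    tof_high_since: float | None = None
    tof_zero_since: float | None = None
    last_prop_adjust: float = -1e12
    last_remi_adjust: float = -1e12
    last_roc_adjust: float = -1e12
    roc_started: bool = False


def manual_policy_step(
    bis: BISSample,
    hemo: HemoSample,
    tof: TOFSample,
    baseline_sbp: float,
    baseline_hr: float,
    config: ControllerConfig,
    mstate: ManualState,
    prop_model: PKModel,
    prop_state: PKState,
    weight: float,
    ibw: float,
) -> list[Command]:
    """One maintenance tick of the simplified rule-based anesthesiologist.

    Propofol plasma target steps ±0.3 µg·mL⁻¹ on sustained BIS excursions;
    remifentanil rate steps on sustained hemodynamic excursions, capped at
    2 µg·kg⁻¹·min⁻¹; rocuronium runs from 7 µg·kg⁻¹·min⁻¹ and steps to hold
    TOF count 1. Every reaction is gated by a human latency and cooldown.
    """
    t = bis.t
    lo, hi = config.bis_band

    # propofol
    if bis.valid and (bis.bis > hi or bis.bis < lo):
        if mstate.bis_out_since is None:
            mstate.bis_out_since = t
    else:
        mstate.bis_out_since = None
    if (
        mstate.bis_out_since is not None
        and t - mstate.bis_out_since >= config.manual_latency_s
        and t - mstate.last_prop_adjust >= config.manual_cooldown_s
    ):
        step = config.manual_prop_step if bis.bis > hi else -config.manual_prop_step
        mstate.prop_target = max(0.5, mstate.prop_target + step)
        mstate.last_prop_adjust = t
    prop_rate = prop_model.tci_plasma(prop_state, mstate.prop_target,
                                      horizon=config.control_interval_s)

    # remifentanil on hemodynamic excursions
    hemo_high = hemo.sbp > 1.2 * baseline_sbp and hemo.hr > 1.2 * baseline_hr
    hemo_low = hemo.sbp < 1.05 * baseline_sbp and hemo.hr < 1.05 * baseline_hr
    if hemo_high:
        if mstate.hemo_high_since is None:
            mstate.hemo_high_since = t
    else:
        mstate.hemo_high_since = None
    if (
        mstate.hemo_high_since is not None
        and t - mstate.hemo_high_since >= config.manual_latency_s
        and t - mstate.last_remi_adjust >= config.manual_cooldown_s
    ):
        mstate.remi_rate_per_kg += config.manual_remi_step_per_kg
        mstate.last_remi_adjust = t
    elif hemo_low and t - mstate.last_remi_adjust >= 5 * config.manual_cooldown_s:
        mstate.remi_rate_per_kg = max(0.05, mstate.remi_rate_per_kg - config.manual_remi_step_per_kg / 2)
        mstate.last_remi_adjust = t
    mstate.remi_rate_per_kg = min(mstate.remi_rate_per_kg, config.manual_remi_max_per_kg)
    remi_rate = mstate.remi_rate_per_kg * ibw

    # rocuronium from the initial 7 µg/kg/min, stepped to hold TOF 1
    if not mstate.roc_started:
        mstate.roc_rate_per_kg = config.manual_roc_init_rate_per_kg
        mstate.roc_started = True
    if tof.valid and tof.count >= 2:
        if mstate.tof_high_since is None:
            mstate.tof_high_since = t
    else:
        mstate.tof_high_since = None
    if tof.valid and tof.count == 0:
        if mstate.tof_zero_since is None:
            mstate.tof_zero_since = t
    else:
        mstate.tof_zero_since = None
    if (
        mstate.tof_high_since is not None
        and t - mstate.tof_high_since >= config.manual_latency_s
        and t - mstate.last_roc_adjust >= config.manual_cooldown_s
    ):
        mstate.roc_rate_per_kg += config.manual_roc_step_per_kg
        mstate.last_roc_adjust = t
    elif (
        mstate.tof_zero_since is not None
        and t - mstate.tof_zero_since >= 5 * config.manual_latency_s
        and t - mstate.last_roc_adjust >= config.manual_cooldown_s
    ):
        mstate.roc_rate_per_kg = max(0.0, mstate.roc_rate_per_kg - config.manual_roc_step_per_kg)
        mstate.last_roc_adjust = t
    roc_rate = mstate.roc_rate_per_kg * weight / 1000.0  # µg/kg/min -> mg/min

    return [
        Command("propofol", rate=prop_rate, target=mstate.prop_target, rationale="TRACKING"),
        Command("remifentanil", rate=remi_rate, rationale="TRACKING"),
        Command("rocuronium", rate=roc_rate, rationale="TRACKING"),
    ]
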