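"""Seeded virtual patients and end-to-end closed-loop simulation.

The package's test bed in place of clinical data: each patient carries an
explicit ground-truth dose–response (which the controllers never see — they
work with the nominal population PK models), sensor noise and artifact
behavior, and a surgical scenario (induction, incision, stimuli, vasoactive
events).

Truth models
------------
BIS: a Hill curve in propofol effect-site concentration whose EC50 shrinks
with remifentanil through a saturating interaction,

    EC50_eff(ce_r) = EC50 · (1 − s_max · ce_r / (ce_r + C50_r)),

so opioid spares hypnotic with diminishing returns. At a fixed BIS target
the implied propofol requirement as a function of ce_r is then exactly a
rectangular hyperbola — the construct the remifentanil estimator assumes.

TOF: the first-twitch amplitude T1 = 1 − ceᵞ/(ceᵞ + EC50ᵞ) is thresholded
into a count 0–4; the thresholds are calibrated so that ce = tof_ec50 gives
count 1 and a 0.6 mg·kg⁻¹ bolus recovers to count 1 on a clinical timescale.

Hemodynamics: baseline values scaled by surgical stimulus, attenuated by
remifentanil; vasoactive administration adds a decaying transient offset.

Model mismatch is injected by per-drug central-volume multipliers: the true
patient's V1 is ``multiplier × nominal``, so with multipliers of 1 and zero
noise the controller's nominal concentrations equal the truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .controllers import (
    BISSample,
    Command,
    ControllerConfig,
    HemoSample,
    LoopState,
    ManualState,
    TOFSample,
    induction_policy,
    manual_policy_step,
    propofol_step,
    remifentanil_step,
    rocuronium_step,
)
from .estimation import (
    BisSigmoidRegressor,
    IsoboleHyperbolaRegressor,
    NotReadyError,
)
from .pk import PKModel, PKState, ideal_body_weight, pk_params

__all__ = [
    "PatientProfile",
    "PopulationConfig",
    "Scenario",
    "sample_profile",
    "true_bis",
    "true_tof",
    "hemodynamics",
    "simulate_run",
    "simulate_rocuronium_loop",
    "RECORD_COLUMNS",
]

DRUGS = ("propofol", "remifentanil", "rocuronium")

RECORD_COLUMNS = [
    "t_s", "bis", "sqi", "emg", "sbp", "hr", "tof_count", "tof_valid",
    "rate_prop_mg_min", "rate_remi_ug_min", "rate_roc_mg_min",
    "bolus_prop_mg", "bolus_remi_ug", "bolus_roc_mg",
    "target_prop_ugml", "target_remi_ngml", "target_roc_ugml",
    "ce_prop_nominal", "ce_remi_nominal", "ce_roc_nominal",
    "ce_prop_true", "ce_remi_true", "ce_roc_true",
    "event", "rationale",
]

#: first-twitch amplitude thresholds mapping T1 to TOF counts 1..4.
#: T1 below the first value reads count 0; ce = tof_ec50 (T1 = 0.5) reads 1.
TOF_T1_THRESHOLDS = (0.3, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class PatientProfile:
    """Ground truth for one virtual patient."""

    age: float = 54.5
    sex: str = "female"
    height: float = 160.5
    weight: float = 60.4
    bis_e0: float = 93.0
    bis_emax: float = 60.0
    bis_ec50: float = 2.5  # µg/mL, at zero remifentanil
    bis_gamma: float = 2.0
    interaction_smax: float = 0.66  # maximal fractional EC50 reduction
    interaction_c50: float = 1.0  # ng/mL remifentanil at half the reduction
    tof_ec50: float = 1.2  # µg/mL rocuronium Ce at 50% twitch depression
    tof_gamma: float = 4.5
    sbp0: float = 120.0
    hr0: float = 70.0
    stim_gain_sbp: float = 0.5  # fractional rise at unit stimulus, no opioid
    stim_gain_hr: float = 0.45
    hemo_ic50_r: float = 2.0  # ng/mL remifentanil halving the stimulus response
    pk_mult_prop: float = 1.0
    pk_mult_remi: float = 1.0
    pk_mult_roc: float = 1.0

    def __post_init__(self) -> None:
        for m in (self.pk_mult_prop, self.pk_mult_remi, self.pk_mult_roc):
            if not 0.5 <= m <= 2.0:
                raise ValueError("PK multipliers must lie in [0.5, 2]")
        if self.height <= 0 or self.weight <= 0 or self.age <= 0:
            raise ValueError("demographics must be positive")


@dataclass
class PopulationConfig:
    """Sampling distributions for :func:`sample_profile`.

    Demographics follow truncated normals matched to a surgical adult
    population (age 54.5 ± 14.9 y, height 160.5 ± 8.3 cm, BMI 23.3 ± 3.8,
    70% female); PD parameters are log-normal around typical values; PK
    multipliers are log-normal, truncated to [0.5, 2].
    """

    age_mean: float = 54.5
    age_sd: float = 14.9
    age_range: tuple[float, float] = (20.0, 90.0)
    height_mean: float = 160.5
    height_sd: float = 8.3
    bmi_mean: float = 23.29
    bmi_sd: float = 3.82
    female_fraction: float = 0.70
    e0_mean: float = 93.0
    e0_sd: float = 2.0
    emax_mean: float = 60.0
    emax_sd: float = 5.0
    ec50_median: float = 2.5
    ec50_log_sd: float = 0.20
    gamma_median: float = 2.0
    gamma_log_sd: float = 0.15
    smax_median: float = 0.66
    smax_log_sd: float = 0.10
    c50r_median: float = 1.0
    c50r_log_sd: float = 0.20
    tof_ec50_median: float = 1.2
    tof_ec50_log_sd: float = 0.15
    tof_gamma_median: float = 4.5
    tof_gamma_log_sd: float = 0.10
    sbp0_mean: float = 120.0
    sbp0_sd: float = 10.0
    hr0_mean: float = 70.0
    hr0_sd: float = 8.0
    pk_mult_log_sd: float = 0.12


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return min(max(mean, lo), hi)


def sample_profile(config: PopulationConfig | None = None, seed: int = 0) -> PatientProfile:
    """Draw one reproducible virtual patient."""
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range)
    sex = "female" if rng.random() < cfg.female_fraction else "male"
    height = _trunc_normal(rng, cfg.height_mean, cfg.height_sd, 140.0, 195.0)
    bmi = _trunc_normal(rng, cfg.bmi_mean, cfg.bmi_sd, 16.0, 38.0)
    weight = bmi * (height / 100.0) ** 2

    def logn(median, log_sd, lo=0.0, hi=np.inf):
        v = median * np.exp(rng.normal(0.0, log_sd)) if log_sd > 0 else median
        return min(max(v, lo), hi)

    return PatientProfile(
        age=age, sex=sex, height=height, weight=weight,
        bis_e0=_trunc_normal(rng, cfg.e0_mean, cfg.e0_sd, 85.0, 98.0),
        bis_emax=_trunc_normal(rng, cfg.emax_mean, cfg.emax_sd, 40.0, 80.0),
        bis_ec50=logn(cfg.ec50_median, cfg.ec50_log_sd, 0.8, 8.0),
        bis_gamma=logn(cfg.gamma_median, cfg.gamma_log_sd, 1.0, 5.0),
        interaction_smax=logn(cfg.smax_median, cfg.smax_log_sd, 0.3, 0.85),
        interaction_c50=logn(cfg.c50r_median, cfg.c50r_log_sd, 0.3, 4.0),
        tof_ec50=logn(cfg.tof_ec50_median, cfg.tof_ec50_log_sd, 0.5, 3.0),
        tof_gamma=logn(cfg.tof_gamma_median, cfg.tof_gamma_log_sd, 2.0, 8.0),
        sbp0=_trunc_normal(rng, cfg.sbp0_mean, cfg.sbp0_sd, 90.0, 160.0),
        hr0=_trunc_normal(rng, cfg.hr0_mean, cfg.hr0_sd, 45.0, 110.0),
        pk_mult_prop=logn(1.0, cfg.pk_mult_log_sd, 0.5, 2.0),
        pk_mult_remi=logn(1.0, cfg.pk_mult_log_sd, 0.5, 2.0),
        pk_mult_roc=logn(1.0, cfg.pk_mult_log_sd, 0.5, 2.0),
    )


@dataclass
class Scenario:
    """Surgical timeline and sensor/noise settings for one case."""

    incision_delay_after_loc_s: float = 600.0
    maintenance_duration_s: float = 7200.0
    stimulus_intensity: float = 1.0  # sustained surgical stimulus from incision
    extra_stimuli: list[tuple[float, float, float]] = field(default_factory=list)
    #: (offset from incision, duration, added intensity)
    vasoactive_offsets_s: list[float] = field(default_factory=list)
    artifact_windows: list[tuple[float, float]] = field(default_factory=list)
    #: (start, end) offsets from incision with degraded SQI/EMG and TOF misreads
    bis_noise_sd: float = 3.0
    sbp_noise_sd: float = 4.0
    hr_noise_sd: float = 3.0
    sqi_base: float = 98.0
    sqi_artifact: float = 40.0
    emg_base: float = 30.0
    emg_artifact: float = 70.0
    tof_interval_s: float = 15.0
    tof_misread_prob: float = 0.3  # applies inside artifact windows only
    loc_bis_threshold: float = 70.0
    loc_sustain_s: float = 10.0
    roc_bolus_delay_after_loc_s: float = 60.0
    hyperbola_wait_max_s: float = 300.0  # after roc bolus, before entering the loop anyway
    max_induction_s: float = 1500.0
    vaso_sbp_offset: float = 25.0
    vaso_hr_offset: float = 10.0
    vaso_tau_s: float = 120.0


# ------------------------------------------------------------- truth models

def true_bis(profile: PatientProfile, ce_p: float, ce_r: float) -> float:
    """Ground-truth BIS at the given effect-site concentrations."""
    if ce_p < 0 or ce_r < 0:
        raise ValueError("concentrations must be >= 0")
    ec50_eff = profile.bis_ec50 * (
        1.0 - profile.interaction_smax * ce_r / (ce_r + profile.interaction_c50)
    )
    if ce_p == 0.0:
        return profile.bis_e0
    u = ce_p**profile.bis_gamma
    return profile.bis_e0 - profile.bis_emax * u / (u + ec50_eff**profile.bis_gamma)


def propofol_requirement(profile: PatientProfile, bis_target: float, ce_r) -> np.ndarray:
    """True propofol Ce giving ``bis_target`` at remifentanil Ce ``ce_r``."""
    ce_r = np.asarray(ce_r, dtype=float)
    drop = profile.bis_e0 - bis_target
    if not 0 < drop < profile.bis_emax:
        raise ValueError("target outside the attainable BIS range")
    k = (drop / (profile.bis_emax - drop)) ** (1.0 / profile.bis_gamma)
    ec50_eff = profile.bis_ec50 * (
        1.0 - profile.interaction_smax * ce_r / (ce_r + profile.interaction_c50)
    )
    return k * ec50_eff


def true_tof(profile: PatientProfile, ce_roc: float) -> int:
    """Ground-truth TOF count (0–4), non-increasing in concentration."""
    if ce_roc < 0:
        raise ValueError("ce must be >= 0")
    u = ce_roc**profile.tof_gamma
    t1 = 1.0 - u / (u + profile.tof_ec50**profile.tof_gamma)
    count = 0
    for thr in TOF_T1_THRESHOLDS:
        if t1 >= thr:
            count += 1
    return count


def hemodynamics(
    profile: PatientProfile,
    ce_r: float,
    stimulus: float,
    vaso_offset: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """Noise-free (SBP, HR) under stimulus, opioid attenuation and vasoactives."""
    if stimulus < 0:
        raise ValueError("stimulus must be >= 0")
    atten = 1.0 / (1.0 + ce_r / profile.hemo_ic50_r)
    sbp = profile.sbp0 * (1.0 + profile.stim_gain_sbp * stimulus * atten) + vaso_offset[0]
    hr = profile.hr0 * (1.0 + profile.stim_gain_hr * stimulus * atten) + vaso_offset[1]
    return sbp, hr


# --------------------------------------------------------------- simulation

class _DrugLine:
    """True + nominal PK state pair advanced by the same commands."""

    def __init__(self, drug: str, profile: PatientProfile, mult: float,
                 config: ControllerConfig):
        nominal = pk_params(drug, age=profile.age, weight=profile.weight,
                            height=profile.height, sex=profile.sex)
        truth = replace(nominal, v1=nominal.v1 * mult)
        self.nominal_model = PKModel(nominal)
        self.true_model = PKModel(truth)
        self.nominal = PKState()
        self.truth = PKState()
        self.rate = 0.0

    def advance(self, dt: float = 1.0) -> None:
        self.nominal = self.nominal_model.step(self.nominal, self.rate, dt)
        self.truth = self.true_model.step(self.truth, self.rate, dt)

    def bolus(self, dose: float) -> None:
        self.nominal = self.nominal_model.bolus(self.nominal, dose)
        self.truth = self.true_model.bolus(self.truth, dose)


def simulate_run(
    profile: PatientProfile,
    policy: str = "automatic",
    scenario: Scenario | None = None,
    seed: int = 0,
    config: ControllerConfig | None = None,
) -> pd.DataFrame:
    """Run one full case on a 1-s grid and return the Record.

    ``policy`` is ``"automatic"`` (closed loop), ``"manual"`` (rule-based
    clinician comparator) or ``"none"`` (a single induction bolus and no
    further drug — a washout control). Identical arguments yield a
    bit-identical record. Metadata (seed, policy, event times) is attached
    as ``DataFrame.attrs["meta"]``.
    """
    if policy not in ("automatic", "manual", "none"):
        raise ValueError("policy must be 'automatic', 'manual' or 'none'")
    sc = scenario or Scenario()
    cfg = config or ControllerConfig()
    rng = np.random.default_rng(seed)
    ibw = ideal_body_weight(profile.height)

    lines = {
        "propofol": _DrugLine("propofol", profile, profile.pk_mult_prop, cfg),
        "remifentanil": _DrugLine("remifentanil", profile, profile.pk_mult_remi, cfg),
        "rocuronium": _DrugLine("rocuronium", profile, profile.pk_mult_roc, cfg),
    }

    cap = int(sc.max_induction_s + sc.incision_delay_after_loc_s
              + sc.maintenance_duration_s + 60)
    cols: dict[str, list] = {c: [] for c in RECORD_COLUMNS}

    loop = LoopState()
    mstate = ManualState(prop_target=cfg.manual_prop_init_target)
    sig_est = BisSigmoidRegressor(bis_target=cfg.bis_target, warm_start=True)
    hyp_est = IsoboleHyperbolaRegressor(delta_pct=cfg.delta_pct, warm_start=True)
    sig_fit = None
    hyp_fit = None
    estec45 = None

    pair_ce: list[float] = []
    pair_bis: list[float] = []
    pair_sqi: list[float] = []
    iso_x: list[float] = []
    iso_y: list[float] = []

    loc_time: float | None = None
    below_since: float | None = None
    roc_bolus_time: float | None = None
    incision_time: float | None = None
    end_time: float | None = None
    cl_start: float | None = None
    vaso_times: list[float] = []

    prop_start = 300.0 if policy in ("automatic", "none") else 240.0
    if policy == "none":
        end_time = prop_start + sc.maintenance_duration_s

    tof_count, tof_valid = 4, True
    rationale = {"propofol": "", "remifentanil": "", "rocuronium": ""}
    last_sbp: list[float] = []
    last_hr: list[float] = []

    t = 0
    while t < cap:
        events: list[str] = []
        ce_p_true = lines["propofol"].truth.ce
        ce_r_true = lines["remifentanil"].truth.ce
        ce_n_true = lines["rocuronium"].truth.ce
        ce_p_nom = lines["propofol"].nominal.ce
        ce_r_nom = lines["remifentanil"].nominal.ce
        ce_n_nom = lines["rocuronium"].nominal.ce

        # --- sensors -------------------------------------------------------
        in_artifact = incision_time is not None and any(
            incision_time + a <= t < incision_time + b for a, b in sc.artifact_windows
        )
        sqi = sc.sqi_artifact if in_artifact else sc.sqi_base
        emg = sc.emg_artifact if in_artifact else sc.emg_base
        bis_true_now = true_bis(profile, ce_p_true, ce_r_true)
        bis_obs = float(np.clip(bis_true_now + rng.normal(0.0, sc.bis_noise_sd)
                                if sc.bis_noise_sd > 0 else bis_true_now, 0.0, 100.0))

        stim = 0.0
        if incision_time is not None and incision_time <= t < (end_time or np.inf):
            stim = sc.stimulus_intensity
            for off, dur, extra in sc.extra_stimuli:
                if incision_time + off <= t < incision_time + off + dur:
                    stim += extra
        vaso = (0.0, 0.0)
        for vt in vaso_times:
            if t >= vt:
                decay = np.exp(-(t - vt) / sc.vaso_tau_s)
                vaso = (vaso[0] + sc.vaso_sbp_offset * decay,
                        vaso[1] + sc.vaso_hr_offset * decay)
        sbp, hr = hemodynamics(profile, ce_r_true, stim, vaso)
        if sc.sbp_noise_sd > 0:
            sbp += rng.normal(0.0, sc.sbp_noise_sd)
        if sc.hr_noise_sd > 0:
            hr += rng.normal(0.0, sc.hr_noise_sd)
        last_sbp.append(sbp)
        last_hr.append(hr)

        if t % int(sc.tof_interval_s) == 0:
            tof_count = true_tof(profile, ce_n_true)
            tof_valid = True
            if in_artifact and rng.random() < sc.tof_misread_prob:
                tof_count = int(rng.integers(0, 5))

        # --- scripted events ----------------------------------------------
        if policy != "none":
            if loc_time is None and t >= prop_start:
                if bis_obs < sc.loc_bis_threshold:
                    below_since = t if below_since is None else below_since
                    if t - below_since + 1 >= sc.loc_sustain_s:
                        loc_time = t
                        incision_time = loc_time + sc.incision_delay_after_loc_s
                        end_time = incision_time + sc.maintenance_duration_s
                        for off in sc.vasoactive_offsets_s:
                            vaso_times.append(incision_time + off)
                        events.append("loc")
                else:
                    below_since = None
                if loc_time is None and t > sc.max_induction_s:
                    raise RuntimeError(
                        "no loss of consciousness within the induction window; "
                        "check profile/scenario consistency")
            if (loc_time is not None and roc_bolus_time is None
                    and t >= loc_time + sc.roc_bolus_delay_after_loc_s):
                roc_bolus_time = t
                lines["rocuronium"].bolus(cfg.induction_roc_bolus_per_kg * profile.weight)
                cols_bolus_roc = cfg.induction_roc_bolus_per_kg * profile.weight
                events.append("roc_bolus")
            else:
                cols_bolus_roc = 0.0
            if incision_time is not None and t == int(incision_time):
                events.append("incision")
                events.append("surgery_start")
        else:
            cols_bolus_roc = 0.0

        # --- pair collection ----------------------------------------------
        if policy == "automatic" and t >= prop_start and ce_p_nom > 0:
            pair_ce.append(ce_p_nom)
            pair_bis.append(bis_obs)
            pair_sqi.append(sqi)

        bolus_remi = 0.0
        tick = t % int(cfg.control_interval_s) == 0

        # --- refits --------------------------------------------------------
        if policy == "automatic" and t % int(cfg.refit_interval_s) == 0 and t > prop_start:
            try:
                sig_fit = sig_est.fit(pair_ce, pair_bis, pair_sqi).fit_result_
                estec45 = sig_fit.invert(cfg.bis_target)
                iso_x.append(ce_r_nom)
                iso_y.append(estec45)
            except (NotReadyError, ValueError):
                pass
            if len(iso_x) >= 2:
                try:
                    hyp_fit = hyp_est.fit(iso_x, iso_y).fit_result_
                except NotReadyError:
                    pass

        # --- phase transition ---------------------------------------------
        if (policy == "automatic" and loop.phase in ("PRE_INDUCTION", "INDUCTION")
                and roc_bolus_time is not None and sig_fit is not None
                and (hyp_fit is not None or t - roc_bolus_time > sc.hyperbola_wait_max_s)):
            loop.advance_phase("CLOSED_LOOP")
            cl_start = t
            events.append("closed_loop")
        if policy == "manual" and loop.phase in ("PRE_INDUCTION", "INDUCTION") \
                and roc_bolus_time is not None:
            loop.advance_phase("CLOSED_LOOP")
            cl_start = t
            events.append("maintenance")

        # --- control tick --------------------------------------------------
        if tick:
            bis_sample = BISSample(t=float(t), bis=bis_obs, sqi=sqi, emg=emg, valid=True)
            tof_sample = TOFSample(t=float(t), count=tof_count, valid=tof_valid)
            if policy == "none":
                if prop_start <= t < prop_start + cfg.induction_prop_bolus_duration_s:
                    rate = (cfg.induction_prop_bolus_per_kg * profile.weight
                            / (cfg.induction_prop_bolus_duration_s / 60.0))
                    lines["propofol"].rate = rate
                else:
                    lines["propofol"].rate = 0.0
                rationale = {d: "INDUCTION" for d in DRUGS}
            elif loop.phase != "CLOSED_LOOP":
                if loop.phase == "PRE_INDUCTION" and t >= prop_start:
                    loop.advance_phase("INDUCTION")
                if policy == "automatic":
                    cmds = induction_policy(profile, float(t), cfg, loop,
                                            loc_seen=loc_time is not None,
                                            roc_bolus_given=roc_bolus_time is not None)
                    for c in cmds:
                        if c.drug == "rocuronium":
                            continue  # the scripted bolus is applied above
                        lines[c.drug].rate = c.rate
                        rationale[c.drug] = c.rationale
                    rationale["rocuronium"] = "INDUCTION"
                else:  # manual induction
                    lines["remifentanil"].rate = cfg.induction_remi_rate_per_kg * ibw
                    if t >= prop_start:
                        lines["propofol"].rate = lines["propofol"].nominal_model.tci_plasma(
                            lines["propofol"].nominal, cfg.manual_prop_init_target,
                            horizon=cfg.control_interval_s)
                    rationale = {d: "INDUCTION" for d in DRUGS}
            else:
                if policy == "automatic":
                    cmd_p = propofol_step(bis_sample, sig_fit, cfg, loop,
                                          lines["propofol"].nominal_model,
                                          lines["propofol"].nominal, profile.age)
                    incision_now = incision_time is not None and \
                        int(incision_time) <= t < int(incision_time) + cfg.control_interval_s
                    cmd_r = remifentanil_step(bis_sample, hyp_fit, cfg, loop,
                                              lines["remifentanil"].nominal_model,
                                              lines["remifentanil"].nominal, ibw,
                                              incision_now=incision_now)
                    cmd_n = rocuronium_step(tof_sample, cfg, loop,
                                            lines["rocuronium"].nominal_model,
                                            lines["rocuronium"].nominal)
                    for c in (cmd_p, cmd_r, cmd_n):
                        lines[c.drug].rate = c.rate
                        rationale[c.drug] = c.rationale
                    if cmd_r.bolus > 0:
                        lines["remifentanil"].bolus(cmd_r.bolus)
                        bolus_remi = cmd_r.bolus
                else:
                    n = len(last_sbp)
                    b0, b1 = max(0, n - 300), max(0, n - 60)
                    if b1 > b0:
                        base_sbp = float(np.mean(last_sbp[b0:b1]))
                        base_hr = float(np.mean(last_hr[b0:b1]))
                    else:
                        base_sbp, base_hr = profile.sbp0, profile.hr0
                    hemo_sample = HemoSample(t=float(t), sbp=sbp, hr=hr)
                    cmds = manual_policy_step(bis_sample, hemo_sample, tof_sample,
                                              base_sbp, base_hr, cfg, mstate,
                                              lines["propofol"].nominal_model,
                                              lines["propofol"].nominal,
                                              profile.weight, ibw)
                    for c in cmds:
                        lines[c.drug].rate = c.rate
                        rationale[c.drug] = c.rationale

        # --- record row ----------------------------------------------------
        cols["t_s"].append(t)
        cols["bis"].append(bis_obs)
        cols["sqi"].append(sqi)
        cols["emg"].append(emg)
        cols["sbp"].append(sbp)
        cols["hr"].append(hr)
        cols["tof_count"].append(tof_count)
        cols["tof_valid"].append(int(tof_valid))
        cols["rate_prop_mg_min"].append(lines["propofol"].rate)
        cols["rate_remi_ug_min"].append(lines["remifentanil"].rate)
        cols["rate_roc_mg_min"].append(lines["rocuronium"].rate)
        cols["bolus_prop_mg"].append(0.0)
        cols["bolus_remi_ug"].append(bolus_remi)
        cols["bolus_roc_mg"].append(cols_bolus_roc if policy != "none" else 0.0)
        cols["target_prop_ugml"].append(
            loop.prop_target if policy == "automatic" else
            (mstate.prop_target if policy == "manual" else np.nan))
        cols["target_remi_ngml"].append(loop.remi_target if policy == "automatic" else np.nan)
        cols["target_roc_ugml"].append(loop.tof1_reference if policy == "automatic" else np.nan)
        cols["ce_prop_nominal"].append(ce_p_nom)
        cols["ce_remi_nominal"].append(ce_r_nom)
        cols["ce_roc_nominal"].append(ce_n_nom)
        cols["ce_prop_true"].append(ce_p_true)
        cols["ce_remi_true"].append(ce_r_true)
        cols["ce_roc_true"].append(ce_n_true)
        if end_time is not None and t == int(end_time):
            events.append("surgery_end")
        cols["event"].append("|".join(events))
        cols["rationale"].append(
            "|".join(f"{d[0].upper()}:{rationale[d]}" for d in DRUGS if rationale[d]))

        if end_time is not None and t >= int(end_time):
            break
        for line in lines.values():
            line.advance(1.0)
        t += 1

    df = pd.DataFrame(cols, columns=RECORD_COLUMNS)
    df.attrs["meta"] = {
        "policy": policy,
        "seed": int(seed),
        "loc_time": loc_time,
        "roc_bolus_time": roc_bolus_time,
        "incision_time": incision_time,
        "closed_loop_time": cl_start,
        "end_time": end_time,
        "profile": profile.__dict__.copy(),
    }
    return df


def simulate_rocuronium_loop(
    profile: PatientProfile,
    duration_s: float = 3600.0,
    config: ControllerConfig | None = None,
    tof_interval_s: float = 15.0,
) -> pd.DataFrame:
    """Run the rocuronium loop in isolation on a noise-free patient.

    The induction bolus (0.6 mg·kg⁻¹) is given at t = 0; the controller
    waits for the first TOF count of 1, captures its reference, and then
    regulates. Returns a 1-Hz frame of (t_s, tof_count, ce_true, ce_nominal,
    rate_mg_min, reference).
    """
    cfg = config or ControllerConfig()
    line = _DrugLine("rocuronium", profile, profile.pk_mult_roc, cfg)
    line.bolus(cfg.induction_roc_bolus_per_kg * profile.weight)
    loop = LoopState()
    loop.advance_phase("CLOSED_LOOP")
    n = int(duration_s)
    out = {k: np.zeros(n) for k in
           ("t_s", "tof_count", "ce_true", "ce_nominal", "rate_mg_min", "reference")}
    tof_count = 4
    for t in range(n):
        if t % int(tof_interval_s) == 0:
            tof_count = true_tof(profile, line.truth.ce)
        if t % int(cfg.control_interval_s) == 0:
            cmd = rocuronium_step(TOFSample(t=float(t), count=tof_count, valid=True),
                                  cfg, loop, line.nominal_model, line.nominal)
            line.rate = cmd.rate
        out["t_s"][t] = t
        out["tof_count"][t] = tof_count
        out["ce_true"][t] = line.truth.ce
        out["ce_nominal"][t] = line.nominal.ce
        out["rate_mg_min"][t] = line.rate
        out["reference"][t] = loop.tof1_reference if loop.tof1_reference is not None else np.nan
        line.advance(1.0)
    return pd.DataFrame(out)
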