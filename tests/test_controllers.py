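"""Closed-loop decision rules: floors, rescues, boluses, induction, manual policy."""

import pytest

from autotiva.controllers import (
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
from autotiva.estimation import HyperbolaFit, SigmoidPDFit
from autotiva.patient import PatientProfile
from autotiva.pk import PKModel, PKState, ideal_body_weight, pk_params


def bis(t=0.0, value=45.0, sqi=99.0, emg=30.0, valid=True):
    return BISSample(t=t, bis=value, sqi=sqi, emg=emg, valid=valid)


def sigmoid_fit_with_estec45(target: float) -> SigmoidPDFit:
    # invert(45) = ec50 * ((93-45)/(60-48))^(1/2) = 2*ec50
    return SigmoidPDFit(e0=93, emax=60, ec50=target / 2.0, gamma=2, n_points=50, rss=0.0)


def hyperbola_with_esmic20(x20: float) -> HyperbolaFit:
    # esmic20 = a + 5*sqrt(c); pick a = 0, c = (x20/5)^2
    return HyperbolaFit(a=0.0, b=1.5, c=(x20 / 5.0) ** 2, n_points=20, rss=0.0)


@pytest.fixture
def prop_model():
    return PKModel(pk_params("propofol", weight=60))


@pytest.fixture
def remi_model():
    return PKModel(pk_params("remifentanil", age=55, weight=60, height=160))


def closed_loop_state():
    s = LoopState()
    s.advance_phase("CLOSED_LOOP")
    return s


class TestConfig:
    def test_band_must_bracket_target(self):
        with pytest.raises(ValueError):
            ControllerConfig(bis_target=30.0)

    def test_age_dependent_floor(self):
        cfg = ControllerConfig()
        assert cfg.propofol_floor(60) == 1.4
        assert cfg.propofol_floor(83) == 1.0
        assert cfg.propofol_floor(80) == 1.0

    def test_command_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            Command("propofol", rate=-1.0)

    def test_phase_moves_only_forward(self):
        s = LoopState()
        s.advance_phase("CLOSED_LOOP")
        with pytest.raises(ValueError):
            s.advance_phase("INDUCTION")


class TestPropofolStep:
    def test_floor_clamp_young(self, prop_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        cmd = propofol_step(bis(), sigmoid_fit_with_estec45(0.8), cfg, state,
                            prop_model, PKState(), age=60)
        assert cmd.target == pytest.approx(1.4)
        assert cmd.rationale == "FLOOR_CLAMP"

    def test_floor_clamp_old(self, prop_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        cmd = propofol_step(bis(), sigmoid_fit_with_estec45(0.8), cfg, state,
                            prop_model, PKState(), age=83)
        assert cmd.target == pytest.approx(1.0)
        assert cmd.rationale == "FLOOR_CLAMP"

    def test_tracking_above_floor(self, prop_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        cmd = propofol_step(bis(), sigmoid_fit_with_estec45(3.0), cfg, state,
                            prop_model, PKState(), age=60)
        assert cmd.target == pytest.approx(3.0)
        assert cmd.rationale == "TRACKING"

    def test_low_signal_ramp_monotone(self, prop_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        fit = sigmoid_fit_with_estec45(3.0)
        targets = []
        for k in range(30):  # 5 min of continuous unreliability
            cmd = propofol_step(bis(t=10.0 * k, sqi=40.0), fit, cfg, state,
                                prop_model, PKState(), age=60)
            targets.append(cmd.target)
            assert cmd.rationale == "LOW_SIGNAL_RAMP"
        assert all(b >= a for a, b in zip(targets, targets[1:]))
        assert targets[-1] > 3.0
        assert targets[-1] == pytest.approx(3.0 + 0.2 * 290 / 300, rel=1e-6)

    def test_low_signal_ramp_capped(self, prop_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        fit = sigmoid_fit_with_estec45(3.0)
        cmd = None
        for k in range(0, 400):  # > 25 min unreliable
            cmd = propofol_step(bis(t=10.0 * k, sqi=40.0), fit, cfg, state,
                                prop_model, PKState(), age=60)
        assert cmd.target == pytest.approx(3.0 + cfg.low_signal_ramp_cap)

    def test_bis_rise_boost_decays(self, prop_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        fit = sigmoid_fit_with_estec45(3.0)
        # BIS above band for >= 30 s triggers the boost
        for k in range(4):
            cmd = propofol_step(bis(t=10.0 * k, value=60.0), fit, cfg, state,
                                prop_model, PKState(), age=60)
        assert cmd.rationale == "BIS_RISE_BOOST"
        assert cmd.target > 3.0
        boosted = cmd.target
        # once BIS is back in band the boost decays linearly
        cmd2 = propofol_step(bis(t=100.0, value=45.0), fit, cfg, state,
                             prop_model, PKState(), age=60)
        assert 3.0 < cmd2.target < boosted

    def test_no_fit_holds(self, prop_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        cmd = propofol_step(bis(), None, cfg, state, prop_model, PKState(), age=60)
        assert cmd.rationale == "HOLD_NOT_READY"
        assert cmd.target == pytest.approx(cfg.default_prop_target)

    def test_floor_dominates_whatever_fires(self, prop_model):
        # even mid-boost the emitted target never drops below the floor
        cfg, state = ControllerConfig(), closed_loop_state()
        fit = sigmoid_fit_with_estec45(0.5)
        for k in range(10):
            cmd = propofol_step(bis(t=10.0 * k, value=58.0), fit, cfg, state,
                                prop_model, PKState(), age=60)
            assert cmd.target >= 1.4


class TestRemifentanilStep:
    def test_bis70_forces_rescue_target(self, remi_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        cmd = remifentanil_step(bis(value=72.0), hyperbola_with_esmic20(3.0), cfg,
                                state, remi_model, PKState(), ibw=56.69)
        assert cmd.target == pytest.approx(4.0)
        assert cmd.rationale == "BIS70_RESCUE"

    def test_rescue_never_lowers_higher_target(self, remi_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        cmd = remifentanil_step(bis(value=72.0), hyperbola_with_esmic20(6.0), cfg,
                                state, remi_model, PKState(), ibw=56.69)
        assert cmd.target == pytest.approx(6.0)

    def test_incision_rate_on_ideal_body_weight(self, remi_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        ibw = ideal_body_weight(160.52)
        cmd = remifentanil_step(bis(), hyperbola_with_esmic20(3.0), cfg, state,
                                remi_model, PKState(), ibw=ibw, incision_now=True)
        assert cmd.rationale == "INCISION"
        assert cmd.rate == pytest.approx(0.5 * 56.69, abs=0.01)  # 28.3 µg/min

    def test_esmic_jump_bolus_bounded_and_single(self, remi_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        cmd1 = remifentanil_step(bis(t=0.0), hyperbola_with_esmic20(3.0), cfg, state,
                                 remi_model, PKState(), ibw=56.69)
        assert cmd1.bolus == 0.0
        cmd2 = remifentanil_step(bis(t=30.0), hyperbola_with_esmic20(6.0), cfg, state,
                                 remi_model, PKState(), ibw=56.69)
        assert 50.0 <= cmd2.bolus <= 100.0
        assert cmd2.rationale == "ESMIC_JUMP_BOLUS"
        # refractory: an immediate further jump emits no second bolus
        cmd3 = remifentanil_step(bis(t=60.0), hyperbola_with_esmic20(9.0), cfg, state,
                                 remi_model, PKState(), ibw=56.69)
        assert cmd3.bolus == 0.0

    def test_gradual_decrease_rate_limited(self, remi_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        remifentanil_step(bis(t=0.0), hyperbola_with_esmic20(6.0), cfg, state,
                          remi_model, PKState(), ibw=56.69)
        cmd = remifentanil_step(bis(t=10.0), hyperbola_with_esmic20(3.0), cfg, state,
                                remi_model, PKState(), ibw=56.69)
        # descent bounded at 0.1 ng/mL per min -> ~0.0167 per 10-s tick
        assert cmd.target >= 6.0 - 0.1 * 10 / 60 - 1e-12
        assert cmd.rationale == "GRADUAL_DECREASE"

    def test_step_increase_jumps_in_one_tick(self, remi_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        remifentanil_step(bis(t=0.0), hyperbola_with_esmic20(3.0), cfg, state,
                          remi_model, PKState(), ibw=56.69)
        state.last_bolus_at = 0.0  # silence the bolus pathway for this check
        cmd = remifentanil_step(bis(t=10.0), hyperbola_with_esmic20(6.0), cfg, state,
                                remi_model, PKState(), ibw=56.69)
        assert cmd.target == pytest.approx(6.0)

    def test_no_fit_no_history_holds(self, remi_model):
        cfg, state = ControllerConfig(), closed_loop_state()
        cmd = remifentanil_step(bis(), None, cfg, state, remi_model, PKState(), ibw=56.69)
        assert cmd.rationale == "HOLD_NOT_READY"
        assert cmd.rate == 0.0


class TestRocuroniumStep:
    def test_reference_captured_on_recovery_not_onset(self):
        cfg, state = ControllerConfig(), closed_loop_state()
        model = PKModel(pk_params("rocuronium", weight=60))
        # onset transit through count 1 must NOT capture
        cmd = rocuronium_step(TOFSample(t=0.0, count=1), cfg, state, model,
                              PKState(ce=1.0))
        assert state.tof1_reference is None
        assert cmd.rate == 0.0
        rocuronium_step(TOFSample(t=15.0, count=0), cfg, state, model, PKState(ce=3.0))
        cmd = rocuronium_step(TOFSample(t=30.0, count=1), cfg, state, model,
                              PKState(ce=1.45))
        assert state.tof1_reference == pytest.approx(1.45)
        assert cmd.rationale == "TRACKING"

    def test_overshoot_gives_zero_rate(self):
        cfg, state = ControllerConfig(), closed_loop_state()
        state.tof_zero_seen = True
        state.tof1_reference = 1.0
        model = PKModel(pk_params("rocuronium", weight=60))
        cmd = rocuronium_step(TOFSample(t=0.0, count=1), cfg, state, model,
                              PKState(c1=1.5, ce=1.2))
        assert cmd.rate == 0.0

    def test_invalid_monitor_holds_rate(self):
        cfg, state = ControllerConfig(), closed_loop_state()
        state.tof1_reference = 1.0
        state.roc_last_rate = 0.7
        model = PKModel(pk_params("rocuronium", weight=60))
        cmd = rocuronium_step(TOFSample(t=0.0, count=3, valid=False), cfg, state,
                              model, PKState(ce=0.5))
        assert cmd.rate == pytest.approx(0.7)
        assert cmd.rationale == "HOLD_NOT_READY"


class TestInductionPolicy:
    profile = PatientProfile(height=170.0, weight=60.0)

    def test_remifentanil_rate_on_ibw(self):
        cmds = induction_policy(self.profile, 0.0, ControllerConfig(), LoopState(),
                                loc_seen=False, roc_bolus_given=False)
        remi = next(c for c in cmds if c.drug == "remifentanil")
        assert remi.rate == pytest.approx(0.5 * 63.58, abs=0.005)  # 31.79 µg/min

    def test_propofol_infusion_after_loc(self):
        cmds = induction_policy(self.profile, 400.0, ControllerConfig(), LoopState(),
                                loc_seen=True, roc_bolus_given=True)
        prop = next(c for c in cmds if c.drug == "propofol")
        assert prop.rate == pytest.approx(10.0 * 60.0 / 60.0)  # 600 mg/h = 10 mg/min

    def test_rocuronium_bolus_dose(self):
        cmds = induction_policy(self.profile, 400.0, ControllerConfig(), LoopState(),
                                loc_seen=True, roc_bolus_given=False)
        roc = next(c for c in cmds if c.drug == "rocuronium")
        assert roc.bolus == pytest.approx(0.6 * 60.0)  # 36 mg


class TestManualPolicy:
    def run_tick(self, mstate, t=0.0, bis_value=45.0, sbp=110.0, hr=70.0, tof=1):
        model = PKModel(pk_params("propofol", weight=60))
        return manual_policy_step(
            bis(t=t, value=bis_value), HemoSample(t=t, sbp=sbp, hr=hr),
            TOFSample(t=t, count=tof), 110.0, 70.0, ControllerConfig(), mstate,
            model, PKState(), weight=60.0, ibw=56.69)

    def test_sustained_high_bis_steps_target_up(self):
        mstate = ManualState()
        for k in range(5):
            self.run_tick(mstate, t=10.0 * k, bis_value=60.0)
        assert mstate.prop_target == pytest.approx(3.3)

    def test_remifentanil_rate_capped_at_two_per_kg(self):
        mstate = ManualState(remi_rate_per_kg=2.5)
        cmds = self.run_tick(mstate)
        remi = next(c for c in cmds if c.drug == "remifentanil")
        assert remi.rate == pytest.approx(2.0 * 56.69)

    def test_initial_rocuronium_rate(self):
        mstate = ManualState()
        cmds = self.run_tick(mstate)
        roc = next(c for c in cmds if c.drug == "rocuronium")
        assert roc.rate == pytest.approx(7.0 * 60.0 / 1000.0)  # 420 µg/min as mg/min

    def test_reaction_requires_latency(self):
        mstate = ManualState()
        self.run_tick(mstate, t=0.0, bis_value=60.0)
        self.run_tick(mstate, t=10.0, bis_value=60.0)
        assert mstate.prop_target == pytest.approx(3.0)  # not yet: < 30 s sustained
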