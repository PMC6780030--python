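"""Biomarker extraction: closed-form fixtures, invariances, detectors."""

import math

import numpy as np
import pytest

import emwtrials as e
from emwtrials.biomarkers import _first_downward_crossing
from emwtrials.synthetic import linear_ap_trace, linear_ca_trace


# sample spacing of the synthetic fixtures bounds the extraction error
TOL = 0.2   # ms


def test_linear_ap_geometry(trace_fixtures):
    """Instant rise -85 -> +35 mV, linear 300 ms fall: APDxx = xx% * 300."""
    b = e.ap_biomarkers(trace_fixtures["clean"])
    assert b.APD40 == pytest.approx(120.0, abs=TOL)
    assert b.APD50 == pytest.approx(150.0, abs=TOL)
    assert b.APD90 == pytest.approx(270.0, abs=TOL)
    assert b.Tri90_40 == b.APD90 - b.APD40          # identity, exact
    assert b.Vpeak == pytest.approx(35.0, abs=1e-9)
    assert b.RMP == pytest.approx(-85.0, abs=1e-9)


def test_linear_ca_geometry(trace_fixtures):
    """Peak 1.1, diastolic 0.1, linear 500 ms decay: CTDxx = xx% * 500."""
    c = e.cat_biomarkers(trace_fixtures["clean"])
    assert c.CTD50 == pytest.approx(250.0, abs=TOL)
    assert c.CTD90 == pytest.approx(450.0, abs=TOL)


def test_emw_definition(trace_fixtures):
    b = e.extract_all(trace_fixtures["clean"])
    assert b.EMw == b.CTD90 - b.APD90               # identity, exact
    assert b.EMw == pytest.approx(180.0, abs=2 * TOL)
    # direct arithmetic cases
    s = e.BiomarkerSet(APD90=270.0, CTD90=450.0)
    assert e.emw(s) == 180.0
    s2 = e.BiomarkerSet(APD90=300.0, CTD90=300.0)
    assert e.emw(s2) == 0.0


def test_emw_undefined_when_flagged():
    s = e.BiomarkerSet(APD90=270.0, CTD90=450.0, RA=True)
    assert math.isnan(e.emw(s))
    s = e.BiomarkerSet(APD90=270.0, CTD90=math.nan)
    assert math.isnan(e.emw(s))


def test_time_shift_and_voltage_offset_invariance():
    """APDs/CTDs are invariant to shifting time and offsetting voltage."""
    base = linear_ca_trace()
    b0 = e.extract_all(base)
    shifted = e.PacedTrace(base.t + 137.0, base.v + 12.0, base.cai,
                           cl=base.cl, stim_onset=base.stim_onset + 137.0)
    b1 = e.extract_all(shifted)
    for name in ("APD40", "APD50", "APD90", "Tri90_40", "CTD50", "CTD90",
                 "EMw"):
        assert getattr(b1, name) == pytest.approx(getattr(b0, name),
                                                  abs=1e-9)
    assert b1.Vpeak == pytest.approx(b0.Vpeak + 12.0)
    assert b1.RMP == pytest.approx(b0.RMP + 12.0)


def test_crossing_matches_bruteforce_scan():
    """Interpolated threshold crossings agree with an exhaustive dense-grid
    scan to within one sample spacing."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        fall = rng.uniform(150, 400)
        tr = linear_ca_trace(fall_ms=fall, decay_ms=rng.uniform(300, 600))
        dt = np.max(np.diff(tr.t))
        # brute force: first sample at/below threshold after the peak
        for series, frac in ((tr.v, 0.9), (tr.v, 0.4), (tr.cai, 0.9),
                             (tr.cai, 0.5)):
            i_peak = int(np.argmax(series))
            thr = series[i_peak] - frac * (series[i_peak] - series[0])
            below = np.nonzero(series[i_peak:] <= thr)[0]
            t_bf = tr.t[i_peak + below[0]]
            t_interp = _first_downward_crossing(tr.t, series, thr, i_peak)
            assert abs(t_bf - t_interp) <= dt


@pytest.mark.parametrize("name,expect_ra,expect_da", [
    ("clean", False, False),
    ("noisy", False, False),
    ("ead", True, False),
    ("non_repolarising", True, False),
    ("subthreshold", False, True),
])
def test_abnormality_detection(trace_fixtures, name, expect_ra, expect_da):
    ra, da = e.detect_abnormalities(trace_fixtures[name], control_rmp=-85.0)
    assert ra == expect_ra
    assert da == expect_da


def test_noise_robustness_of_detection():
    """RA detection is stable under small-amplitude noise on a clean
    monotone repolarisation (no spurious flags)."""
    rng = np.random.default_rng(11)
    for k in range(5):
        tr = linear_ca_trace()
        tr.v = tr.v + rng.uniform(-0.09, 0.09, tr.v.size)
        ra, da = e.detect_abnormalities(tr, control_rmp=-85.0)
        assert not ra and not da


def test_no_ca_transient_invalidates_ctd():
    tr = linear_ap_trace()   # flat Ca2+ series
    c = e.cat_biomarkers(tr)
    assert math.isnan(c.CTD50) and math.isnan(c.CTD90)


def test_baseline_inside_experimental_windows(baseline_control):
    """The unmodified baseline model's nine biomarkers all sit inside the
    experimental calibration windows."""
    _, _, b = baseline_control
    inside, bad = e.CalibrationWindows().contains(b)
    assert inside, bad
    assert 180.0 <= b.APD90 <= 440.0
    assert 220.0 <= b.CTD90 <= 785.0
    assert not b.RA and not b.DA


def test_grid_refinement_convergence(baseline_control):
    """Halving all step-size controls moves APD90/CTD90 by < 1 ms."""
    _, y, _ = baseline_control
    proto = e.StimulusProtocol(n_beats=1)
    tr1, _ = e.simulate_paced(protocol=proto, initial=y)
    fine = e.SolverSettings(dt_min=0.0025, dt_max=0.125, dv_target=0.1)
    tr2, _ = e.simulate_paced(protocol=proto, initial=y, solver=fine)
    b1, b2 = e.extract_all(tr1), e.extract_all(tr2)
    assert abs(b1.APD90 - b2.APD90) < 1.0
    assert abs(b1.CTD90 - b2.CTD90) < 1.0


def test_delta_biomarkers_sign_convention():
    ctrl = e.BiomarkerSet(APD90=300.0, CTD90=500.0, EMw=200.0)
    drug = e.BiomarkerSet(APD90=330.0, CTD90=500.0, EMw=170.0)
    d = e.delta_biomarkers(drug, ctrl)
    assert d.dAPD90 == pytest.approx(10.0)
    assert d.dEMw == pytest.approx(-15.0)    # shortening is negative
    assert d.dCTD90 == pytest.approx(0.0)
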