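"""Pore-block pharmacology, trials and the block scan."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import emwtrials as e
from emwtrials.drugs import TRIAL_PROTOCOL, _summarise


class TestBlockFraction:
    def test_hill_midpoint(self):
        for h in (0.5, 1.0, 2.7):
            assert e.block_fraction(2.0, 2.0, h) == pytest.approx(0.5)

    def test_no_drug_no_block(self):
        assert e.block_fraction(0.0, 1.0, 1.0) == 0.0

    def test_direct_evaluation(self):
        assert e.block_fraction(3.0, 1.0, 1.0) == pytest.approx(0.75)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            e.block_fraction(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            e.block_fraction(1.0, 1.0, -1.0)
        with pytest.raises(ValueError):
            e.block_fraction(-1.0, 1.0, 1.0)

    @settings(deadline=None, max_examples=200)
    @given(c1=st.floats(0, 1e3), c2=st.floats(0, 1e3),
           ic50=st.floats(1e-3, 1e3), h=st.floats(0.1, 5))
    def test_monotone_in_concentration(self, c1, c2, ic50, h):
        lo, hi = sorted((c1, c2))
        b_lo = e.block_fraction(lo, ic50, h)
        b_hi = e.block_fraction(hi, ic50, h)
        assert 0.0 <= b_lo <= b_hi <= 1.0

    @settings(deadline=None, max_examples=200)
    @given(c=st.floats(1.01, 1e3), ic50=st.floats(1e-3, 1.0),
           h1=st.floats(0.1, 5), h2=st.floats(0.1, 5))
    def test_monotone_in_hill_above_ic50(self, c, ic50, h1, h2):
        lo, hi = sorted((h1, h2))
        assert (e.block_fraction(c, ic50, hi)
                >= e.block_fraction(c, ic50, lo) - 1e-12)


class TestDrugToBlocks:
    def test_inert_compound(self):
        d = e.DrugRecord("nothing", {}, eftpc_max=1.0)
        blocks = e.drug_to_blocks(d, 10.0)
        assert np.all(blocks.to_array() == 0.0)

    def test_verapamil_like(self):
        d = e.DrugRecord("verapamil_like",
                         {"IKr": e.ChannelBlockParams(9.0, 1.0),
                          "ICaL": e.ChannelBlockParams(4.5, 1.0)},
                         eftpc_max=1.0, category="NC")
        blocks = e.drug_to_blocks(d, 3.0)
        assert blocks.IKr == pytest.approx(0.25, abs=0.01)
        assert blocks.ICaL == pytest.approx(0.40, abs=0.01)

    def test_block_grows_with_multiple(self):
        d = e.DrugRecord("d", {"IKr": e.ChannelBlockParams(2.0, 1.3),
                               "INa": e.ChannelBlockParams(30.0, 0.8)},
                         eftpc_max=0.5)
        b1 = e.drug_to_blocks(d, 1.0).to_array()
        b100 = e.drug_to_blocks(d, 100.0).to_array()
        assert np.all(b100 >= b1)

    def test_record_validation(self):
        with pytest.raises(ValueError):
            e.DrugRecord("bad", eftpc_max=-1.0)
        with pytest.raises(ValueError):
            e.DrugRecord("bad", {"IFunny": e.ChannelBlockParams(1.0)})
        with pytest.raises(ValueError):
            e.ChannelBlockParams(ic50=-2.0)


def test_compendium_round_trip(tmp_path):
    drugs = e.make_compendium(seed=4, n_per_archetype=2)
    p = tmp_path / "compendium.csv"
    e.save_compendium(drugs, p)
    back = e.load_compendium(p)
    assert [d.name for d in back] == [d.name for d in drugs]
    for a, b in zip(drugs, back):
        assert a.category == b.category
        assert a.eftpc_max == pytest.approx(b.eftpc_max)
        assert set(a.channels) == set(b.channels)
        for ch in a.channels:
            assert a.channels[ch].ic50 == pytest.approx(b.channels[ch].ic50)


def test_compendium_schema_validated(tmp_path):
    p = tmp_path / "bad.csv"
    pd.DataFrame({"name": ["x"], "channel": ["IKr"]}).to_csv(p, index=False)
    with pytest.raises(ValueError, match="missing columns"):
        e.load_compendium(p)


def _one_model_population(y, biom):
    return e.Population(model_ids=["m0"],
                        scalings=[e.IonicScalings()],
                        states=[y], biomarkers={"m0": biom}, rejected={})


def test_single_model_trial_equals_direct_simulation(baseline_control):
    """A one-model population trial reproduces a direct paced simulation
    with the same block fractions, exactly."""
    _, y, biom = baseline_control
    pop = _one_model_population(y, biom)
    drug = e.DrugRecord("herg", {"IKr": e.ChannelBlockParams(1.0, 1.0)},
                        eftpc_max=1.0, category="known")
    proto = e.StimulusProtocol(n_beats=30)
    trial = e.run_drug_trial(pop, drug, multiples=(3.0,), protocol=proto)
    # oracle: direct simulation of both arms
    blocks = e.drug_to_blocks(drug, 3.0)
    tr_c, _ = e.simulate_paced(protocol=proto, initial=y)
    ctrl = e.extract_all(tr_c)
    tr_d, _ = e.simulate_paced(block=blocks, protocol=proto, initial=y)
    b = e.extract_all(tr_d, control_rmp=ctrl.RMP)
    d = e.delta_biomarkers(b, ctrl)
    row = trial.per_model.loc[(3.0, "m0")]
    assert row["dAPD90"] == pytest.approx(d.dAPD90, abs=1e-9)
    assert row["dEMw"] == pytest.approx(d.dEMw, abs=1e-9)


def test_inert_drug_changes_nothing(baseline_control):
    """No block => drug arm is bit-identical to the control arm."""
    _, y, biom = baseline_control
    pop = _one_model_population(y, biom)
    inert = e.DrugRecord("inert", {}, eftpc_max=1.0)
    proto = e.StimulusProtocol(n_beats=10)
    trial = e.run_drug_trial(pop, inert, multiples=(1.0, 100.0),
                             protocol=proto)
    for mult in (1.0, 100.0):
        s = trial.summaries[mult]
        assert s.n_ra == 0 and s.n_da == 0
        assert s.median_dEMw == 0.0
        assert s.median_dAPD90 == 0.0


def test_block_scan_control_cell_and_undefined_cells(baseline_control):
    _, y, biom = baseline_control
    pop = _one_model_population(y, biom)
    proto = e.StimulusProtocol(n_beats=10)
    grid = e.block_scan(pop, protocol=proto,
                        cells=[(0.0, 0.0, 0.0), (0.0, 1.0, 0.0)])
    ctrl = grid.loc[(0.0, 0.0, 0.0)]
    assert ctrl["median_dEMw"] == 0.0
    assert ctrl["median_dAPD90"] == 0.0
    assert ctrl["frac_ra"] == 0.0
    # full ICaL block abolishes the Ca2+ transient: EMw cell undefined
    no_cal = grid.loc[(0.0, 1.0, 0.0)]
    assert no_cal["n_valid_emw"] == 0
    assert math.isnan(no_cal["median_dEMw"])


def test_summary_counting_identity():
    """nRA + valid-EMw + (DA or otherwise invalid) partitions the
    population."""
    rows = [
        {"RA": True, "DA": False, "dEMw": math.nan, "dAPD90": math.nan,
         "dCTD90": math.nan, "control_EMw": 100.0},
        {"RA": False, "DA": True, "dEMw": math.nan, "dAPD90": math.nan,
         "dCTD90": math.nan, "control_EMw": 100.0},
        {"RA": False, "DA": False, "dEMw": -20.0, "dAPD90": 10.0,
         "dCTD90": 1.0, "control_EMw": 100.0},
        {"RA": False, "DA": False, "dEMw": 5.0, "dAPD90": 1.0,
         "dCTD90": 1.0, "control_EMw": 100.0},
    ]
    s = _summarise(rows, 4)
    assert s.n_ra + s.n_valid_emw + s.n_da == s.n_tot
    assert s.n_emw == 1
    assert s.median_dEMw == pytest.approx(-7.5)
    # degenerate control EMw excluded from the median
    rows[3]["control_EMw"] = 0.5
    s2 = _summarise(rows, 4)
    assert s2.n_valid_emw == 1
    assert s2.median_dEMw == pytest.approx(-20.0)
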