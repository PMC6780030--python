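"""AP and Ca2+-transient biomarker extraction.

Seven action-potential biomarkers (APD40/50/90, Tri90-40, dV/dtMAX, Vpeak,
RMP), two Ca2+-transient durations (CTD50/90), the electromechanical window
EMw = CTD90 - APD90, and automatic detection of repolarisation (RA) and
depolarisation (DA) abnormalities.

Conventions: both AP and Ca2+ durations are measured from the instant of
maximum upstroke velocity.  APDxx is the first downward crossing of
``Vpeak - xx% * (Vpeak - RMP)`` after the peak; CTDxx is the first time the
transient has decayed xx% of the way from its peak back to the pre-stimulus
diastolic level.  Threshold crossings are linearly interpolated between
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .ord import PacedTrace

__all__ = ["BiomarkerSet", "DeltaBiomarkers", "ap_biomarkers",
           "cat_biomarkers", "emw", "detect_abnormalities",
           "extract_all", "biomarker_table"]


# thresholds for abnormality detection; all configurable at call sites
#: minimal upstroke velocity for a beat to count as excited (V/s)
DVDT_FLOOR = 10.0
#: positive dV/dt (V/s) that counts as a repolarisation reversal (EAD)
EAD_SLOPE = 0.01
#: reversal must be sustained at least this long (ms)
EAD_SUSTAIN = 2.0
#: detection window opens this long after the upstroke (ms), skipping the
#: phase-1 notch / dome of high-Ito models
EAD_WINDOW_START = 150.0
#: diastolic voltage more than this above the control RMP flags DA (mV)
DIASTOLIC_ELEVATION = 20.0
#: minimal Ca2+ transient amplitude (fraction of diastolic) for CTDs
CA_AMP_FLOOR = 0.05

BIOMARKER_NAMES = ("APD40", "APD50", "APD90", "Tri90_40", "dVdtMAX",
                   "Vpeak", "RMP", "CTD50", "CTD90")


@dataclass
class BiomarkerSet:
    """The nine calibration biomarkers plus EMw and abnormality flags.

    Invalid entries are NaN; ``RA``/``DA`` flag repolarisation/depolarisation
    abnormalities on the underlying beat, and EMw is NaN whenever either
    flag is set or a parent biomarker is invalid.
    """

    APD40: float = math.nan
    APD50: float = math.nan
    APD90: float = math.nan
    Tri90_40: float = math.nan
    dVdtMAX: float = math.nan    # V/s
    Vpeak: float = math.nan      # mV
    RMP: float = math.nan        # mV
    CTD50: float = math.nan
    CTD90: float = math.nan
    EMw: float = math.nan        # ms
    RA: bool = False
    DA: bool = False

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def all_valid(self) -> bool:
        vals = [getattr(self, n) for n in BIOMARKER_NAMES]
        return all(np.isfinite(v) for v in vals) and not (self.RA or self.DA)


@dataclass
class DeltaBiomarkers:
    """Percent changes of a drugged beat vs the same model's control.

    Shortening is negative.  NaN when either side is invalid.
    """

    dEMw: float = math.nan
    dAPD90: float = math.nan
    dCTD90: float = math.nan


def _pct(drug: float, ctrl: float) -> float:
    if not (np.isfinite(drug) and np.isfinite(ctrl)) or ctrl == 0:
        return math.nan
    return 100.0 * (drug - ctrl) / ctrl


def delta_biomarkers(drug: BiomarkerSet, control: BiomarkerSet) -> DeltaBiomarkers:
    return DeltaBiomarkers(
        dEMw=_pct(drug.EMw, control.EMw),
        dAPD90=_pct(drug.APD90, control.APD90),
        dCTD90=_pct(drug.CTD90, control.CTD90),
    )


# ---------------------------------------------------------------------------
# crossing helpers
# ---------------------------------------------------------------------------

def _first_downward_crossing(t, x, thr, start_idx):
    """Interpolated time of the first downward crossing of thr at/after
    start_idx, or nan."""
    xs = x[start_idx:]
    ts = t[start_idx:]
    below = (xs[1:] <= thr) & (xs[:-1] > thr)
    hits = np.nonzero(below)[0]
    if hits.size == 0:
        return math.nan
    k = hits[0]
    x0, x1 = xs[k], xs[k + 1]
    t0, t1 = ts[k], ts[k + 1]
    if x1 == x0:
        return t1
    return t0 + (x0 - thr) / (x0 - x1) * (t1 - t0)


def _upstroke(trace: PacedTrace):
    """(index, time, dVdtMAX in V/s) of the fastest depolarisation."""
    dv = np.diff(trace.v) / np.diff(trace.t)
    i = int(np.argmax(dv))
    # mid-interval time of the steepest segment
    t_up = 0.5 * (trace.t[i] + trace.t[i + 1])
    return i, t_up, float(dv[i])   # mV/ms == V/s


# ---------------------------------------------------------------------------
# biomarker operations
# ---------------------------------------------------------------------------

def ap_biomarkers(trace: PacedTrace,
                  dvdt_floor: float = DVDT_FLOOR) -> BiomarkerSet:
    """AP biomarkers of one full-cycle beat (CTD fields left NaN).

    If no upstroke exceeds ``dvdt_floor`` (V/s) the beat is unexcited: AP
    durations are invalid and DA is flagged.
    """
    b = BiomarkerSet()
    i_up, t_up, dvdtmax = _upstroke(trace)
    b.RMP = float(trace.v[0])           # pre-stimulus voltage
    b.Vpeak = float(trace.v.max())
    b.dVdtMAX = dvdtmax
    if dvdtmax < dvdt_floor or b.Vpeak < 0.0:
        b.DA = True
        return b
    amp = b.Vpeak - b.RMP
    i_peak = int(np.argmax(trace.v))
    for frac, name in ((0.40, "APD40"), (0.50, "APD50"), (0.90, "APD90")):
        thr = b.Vpeak - frac * amp
        tc = _first_downward_crossing(trace.t, trace.v, thr, i_peak)
        setattr(b, name, tc - t_up if np.isfinite(tc) else math.nan)
    if np.isfinite(b.APD90) and np.isfinite(b.APD40):
        b.Tri90_40 = b.APD90 - b.APD40
    return b


def cat_biomarkers(trace: PacedTrace,
                   amp_floor: float = CA_AMP_FLOOR) -> BiomarkerSet:
    """Ca2+-transient durations of one beat (AP fields left NaN).

    The transient must rise at least ``amp_floor`` (fraction of the
    diastolic level) above diastole; otherwise (e.g. full ICaL block) the
    CTDs are invalid.
    """
    b = BiomarkerSet()
    _, t_up, _ = _upstroke(trace)
    ca = trace.cai
    dia = float(ca[0])                  # pre-stimulus diastolic level
    i_peak = int(np.argmax(ca))
    peak = float(ca[i_peak])
    if peak - dia < amp_floor * max(dia, 1e-12):
        return b
    for frac, name in ((0.50, "CTD50"), (0.90, "CTD90")):
        thr = peak - frac * (peak - dia)
        tc = _first_downward_crossing(trace.t, ca, thr, i_peak)
        setattr(b, name, tc - t_up if np.isfinite(tc) else math.nan)
    return b


def emw(bset: BiomarkerSet) -> float:
    """Electromechanical window EMw = CTD90 - APD90 (ms, may be negative)."""
    if bset.RA or bset.DA:
        return math.nan
    if not (np.isfinite(bset.CTD90) and np.isfinite(bset.APD90)):
        return math.nan
    return bset.CTD90 - bset.APD90


def detect_abnormalities(trace: PacedTrace,
                         control_rmp: float | None = None,
                         dvdt_floor: float = DVDT_FLOOR,
                         ead_slope: float = EAD_SLOPE,
                         ead_sustain: float = EAD_SUSTAIN,
                         window_start: float = EAD_WINDOW_START,
                         diastolic_elevation: float = DIASTOLIC_ELEVATION,
                         ) -> tuple[bool, bool]:
    """(RA, DA) flags for one full-cycle beat.

    RA: the voltage derivative turns positive again (> ``ead_slope`` V/s
    sustained >= ``ead_sustain`` ms) after the plateau window opens and
    before repolarisation to 90% of the amplitude, i.e. an early
    afterdepolarisation -- or the AP never repolarises below the 90% level
    before the cycle ends.

    DA: no proper upstroke (dV/dtMAX below floor or Vpeak < 0 mV), or the
    diastolic (pre-stimulus) voltage sits far above the control RMP.
    """
    t, v = trace.t, trace.v
    i_up, t_up, dvdtmax = _upstroke(trace)
    vpeak = float(v.max())
    rmp = float(v[0])

    # a beat starting far above any physiological diastolic potential means
    # the previous beat never repolarised: that is a repolarisation failure,
    # not a depolarisation abnormality
    if rmp > -60.0:
        return True, False

    da = dvdtmax < dvdt_floor or vpeak < 0.0
    if control_rmp is not None and rmp > control_rmp + diastolic_elevation:
        da = True
    if da:
        return False, True

    thr90 = vpeak - 0.9 * (vpeak - rmp)
    i_peak = int(np.argmax(v))
    t90 = _first_downward_crossing(t, v, thr90, i_peak)
    if not np.isfinite(t90):
        return True, False          # failure to repolarise before next beat

    lo = t_up + window_start
    hi = t90
    if hi <= lo:
        return False, False
    dv = np.diff(v) / np.diff(t)
    tm = 0.5 * (t[:-1] + t[1:])
    sel = (tm >= lo) & (tm <= hi)
    if not np.any(sel):
        return False, False
    rising = dv[sel] > ead_slope
    seg = np.diff(t)[sel]
    # contiguous rising time >= ead_sustain ms flags an EAD
    run = 0.0
    for k in range(rising.size):
        if rising[k]:
            run += seg[k]
            if run >= ead_sustain:
                return True, False
        else:
            run = 0.0
    return False, False


def extract_all(trace: PacedTrace,
                control_rmp: float | None = None,
                **abn_kwargs) -> BiomarkerSet:
    """Full biomarker set for one beat: AP + CTD + EMw + RA/DA flags."""
    b = ap_biomarkers(trace)
    c = cat_biomarkers(trace)
    b.CTD50, b.CTD90 = c.CTD50, c.CTD90
    ra, da = detect_abnormalities(trace, control_rmp=control_rmp, **abn_kwargs)
    b.RA = ra
    b.DA = b.DA or da
    b.EMw = emw(b)
    return b


def biomarker_table(bsets: dict[str, BiomarkerSet]) -> pd.DataFrame:
    """One row per model id; NaN encodes invalid entries."""
    rows = {mid: b.as_dict() for mid, b in bsets.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "model_id"
    return df
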