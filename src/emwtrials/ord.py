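"""O'Hara-Rudy dynamic (ORd) human ventricular cell model, endocardial variant.

The model couples membrane voltage, twelve ionic currents (with CaMKII-
phosphorylated fractions), intracellular Na+/K+/Ca2+ handling in four
compartments (myoplasm, subspace, network and junctional SR) and SR
release/uptake fluxes -- 41 state variables in total.

Two integration routes are provided:

* a numba-compiled adaptive Rush-Larsen / forward-Euler stepper
  (:func:`simulate_paced`), the workhorse for population and drug-trial runs;
  Hodgkin-Huxley gates are advanced with their exact exponential update and
  the step size tracks the voltage slope so the upstroke is resolved at
  5 us while diastole runs at coarse steps;
* the plain right-hand side (:func:`ord_rhs`) usable with any stiff ODE
  solver, kept for cross-checking the stepper against scipy's LSODA.

Maximal conductances of the nine principal currents (INa, INaL, Ito, IKr,
IKs, IK1, INCX, INaK, ICaL) can be rescaled per model (population
variability) and reduced by fractional pore block (drug action); the
effective multiplier is always ``s_X * (1 - b_X)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "IonicScalings",
    "BlockFractions",
    "StimulusProtocol",
    "PacedTrace",
    "ModelState",
    "STATE_NAMES",
    "N_STATES",
    "initial_state",
    "ord_rhs",
    "ord_currents",
    "simulate_paced",
    "SolverFailure",
]

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)
N_STATES = len(STATE_NAMES)

# Steady state of the paced (1 Hz) endocardial baseline model, used as the
# common starting point; every population model is additionally pre-paced
# from here so residual error in these digits washes out.
_Y0 = np.array([
    -87.84,        # v (mV)
    7.23,          # nai (mM)
    7.23,          # nass
    143.79,        # ki
    143.79,        # kss
    8.54e-5,       # cai
    8.43e-5,       # cass
    1.61,          # cansr
    1.56,          # cajsr
    0.0074621,     # m
    0.692591,      # hf
    0.692574,      # hs
    0.692477,      # j
    0.448501,      # hsp
    0.692413,      # jp
    0.000194015,   # mL
    0.496116,      # hL
    0.265885,      # hLp
    0.00101185,    # a
    0.999542,      # iF
    0.589579,      # iS
    0.000515567,   # ap
    0.999542,      # iFp
    0.641861,      # iSp
    2.43015e-9,    # d
    0.9999843,     # ff
    0.904947,      # fs
    0.9999844,     # fcaf
    0.9999526,     # fcas
    0.999987,      # jca
    0.002749414,   # nca
    0.9999842,     # ffp
    0.9999839,     # fcafp
    8.26608e-6,    # xrf
    0.453268,      # xrs
    0.270492,      # xs1
    0.0001963,     # xs2
    0.996801,      # xk1
    2.53943e-5,    # Jrelnp
    3.17262e-7,    # Jrelp
    0.0124065,     # CaMKt
])

# conductance multiplier order (scalings and the scan/drug machinery share it)
CHANNELS = ("INa", "INaL", "Ito", "IKr", "IKs", "IK1", "INCX", "INaK", "ICaL")
# channels that admit pore block (pumps/exchangers are not drug targets here)
BLOCKABLE = ("INa", "INaL", "Ito", "IKr", "IKs", "IK1", "ICaL")


def initial_state() -> np.ndarray:
    """Copy of the baseline paced steady-state vector."""
    return _Y0.copy()


@dataclass(frozen=True)
class IonicScalings:
    """Multiplicative factors on the nine principal maximal conductances.

    All dimensionless and >= 0; (1, 1, ..., 1) is the baseline model.
    """

    sNa: float = 1.0
    sNaL: float = 1.0
    sto: float = 1.0
    sKr: float = 1.0
    sKs: float = 1.0
    sK1: float = 1.0
    sNCX: float = 1.0
    sNaK: float = 1.0
    sCaL: float = 1.0

    def __post_init__(self):
        for name, val in asdict(self).items():
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"scaling {name} must be finite and >= 0, got {val}")

    def to_array(self) -> np.ndarray:
        return np.array([self.sNa, self.sNaL, self.sto, self.sKr, self.sKs,
                         self.sK1, self.sNCX, self.sNaK, self.sCaL])

    @classmethod
    def from_array(cls, arr) -> "IonicScalings":
        return cls(*[float(x) for x in arr])


@dataclass(frozen=True)
class BlockFractions:
    """Fractional pore block per channel, each in [0, 1]; 0 = no block."""

    INa: float = 0.0
    INaL: float = 0.0
    Ito: float = 0.0
    IKr: float = 0.0
    IKs: float = 0.0
    IK1: float = 0.0
    ICaL: float = 0.0

    def __post_init__(self):
        for name, val in asdict(self).items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"block fraction {name} must lie in [0,1], got {val}")

    def to_array(self) -> np.ndarray:
        return np.array([self.INa, self.INaL, self.Ito, self.IKr,
                         self.IKs, self.IK1, self.ICaL])


def effective_multipliers(scalings: IonicScalings | None = None,
                          block: BlockFractions | None = None) -> np.ndarray:
    """Nine-element conductance multiplier vector ``s_X * (1 - b_X)``.

    Order follows :data:`CHANNELS`; INCX and INaK carry scaling only.
    """
    s = (scalings or IonicScalings()).to_array()
    b = (block or BlockFractions()).to_array()
    mult = s.copy()
    # blockable channels sit at positions 0..5 and 8 of CHANNELS
    for bi, ci in enumerate((0, 1, 2, 3, 4, 5, 8)):
        mult[ci] = s[ci] * (1.0 - b[bi])
    return mult


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic current-clamp pacing protocol.

    Defaults: 1 Hz, -80 uA/uF for 0.5 ms at each cycle start (the baseline
    model's published stimulus).
    """

    cl: float = 1000.0          # cycle length, ms
    n_beats: int = 500          # beats to pace
    stim_amplitude: float = -80.0   # uA/uF
    stim_duration: float = 0.5      # ms

    def __post_init__(self):
        if self.cl <= 0:
            raise ValueError("cycle length must be positive")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")
        if not 0 <= self.stim_duration < self.cl:
            raise ValueError("stimulus duration must fit inside the cycle")


@dataclass
class PacedTrace:
    """Final-beat voltage and Ca2+ recording of a paced simulation.

    ``t`` is in ms relative to the stimulus onset (``stim_onset`` = 0.0), the
    grid is the solver's accepted-step grid (dense on the upstroke).  ``cai``
    units are stated in ``ca_units`` ('mM' for model output).
    """

    t: np.ndarray
    v: np.ndarray
    cai: np.ndarray
    cl: float
    stim_onset: float = 0.0
    model_id: str = ""
    ca_units: str = "mM"

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        self.cai = np.asarray(self.cai, float)
        if not (len(self.t) == len(self.v) == len(self.cai)):
            raise ValueError("time, voltage and Ca2+ series must be equally long")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    # -- delimited-table round trip (time, V, Cai) + JSON sidecar ----------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arr = np.column_stack([self.t, self.v, self.cai])
        np.savetxt(path, arr, delimiter=",", header="t_ms,v_mV,cai", comments="")
        meta = {"cl": self.cl, "stim_onset": self.stim_onset,
                "model_id": self.model_id, "ca_units": self.ca_units}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PacedTrace":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], **meta)


# ModelState is simply the raw vector plus a timestamp; a light wrapper keeps
# the invariant checks in one place.
@dataclass
class ModelState:
    y: np.ndarray
    t: float = 0.0

    def validate(self) -> None:
        y = np.asarray(self.y, float)
        if y.shape != (N_STATES,):
            raise ValueError(f"state vector must have {N_STATES} components")
        bad = np.where(~np.isfinite(y))[0]
        if bad.size:
            raise FloatingPointError(
                f"non-finite state component: {STATE_NAMES[bad[0]]}")


class SolverFailure(RuntimeError):
    """Integration blew up (non-finite state); carries model id and beat."""

    def __init__(self, model_id: str, beat: int):
        super().__init__(f"integration failed for model '{model_id}' at beat {beat}")
        self.model_id = model_id
        self.beat = beat


# ---------------------------------------------------------------------------
# model constants (endocardial)
# ---------------------------------------------------------------------------

_R, _T, _F = 8314.0, 310.0, 96485.0
_NAO, _CAO, _KO = 140.0, 1.8, 5.4

_L_CELL, _RAD = 0.01, 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L_CELL
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L_CELL
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL


@njit(cache=True, fastmath=False)
def _xdexpm1(x):
    # x / (exp(x) - 1), analytic at x = 0; cancels the GHK singularity
    if abs(x) < 1e-7:
        return 1.0 - 0.5 * x
    return x / np.expm1(x)


@njit(cache=True, fastmath=False)
def _core(y, mult, ist, dy, extra):
    """Full ORd endo right-hand side.

    mult: 9 conductance multipliers (INa, INaL, Ito, IKr, IKs, IK1, INCX,
    INaK, ICaL).  ist: stimulus current (uA/uF).  Writes derivatives into
    ``dy`` and, for the gating subset, the pair (x_inf, tau_x) into ``extra``
    so the caller may apply exact exponential (Rush-Larsen) updates.
    Returns an array of the individual currents for diagnostics.
    """
    v = y[0]
    nai = y[1]; nass = y[2]; ki = y[3]; kss = y[4]
    cai = y[5]; cass = y[6]; cansr = y[7]; cajsr = y[8]
    m = y[9]; hf = y[10]; hs = y[11]; jj = y[12]; hsp = y[13]; jp = y[14]
    mL = y[15]; hL = y[16]; hLp = y[17]
    a = y[18]; iF = y[19]; iS = y[20]; ap = y[21]; iFp = y[22]; iSp = y[23]
    d = y[24]; ff = y[25]; fs = y[26]; fcaf = y[27]; fcas = y[28]
    jca = y[29]; nca = y[30]; ffp = y[31]; fcafp = y[32]
    xrf = y[33]; xrs = y[34]; xs1 = y[35]; xs2 = y[36]; xk1 = y[37]
    Jrelnp = y[38]; Jrelp = y[39]; CaMKt = y[40]

    frt = _F / (_R * _T)
    vfrt = v * frt
    vffrt = v * _F * frt

    ENa = (1.0 / frt) * np.log(_NAO / nai)
    EK = (1.0 / frt) * np.log(_KO / ki)
    EKs = (1.0 / frt) * np.log((_KO + 0.01833 * _NAO) / (ki + 0.01833 * nai))

    # CaMKII
    KmCaMK = 0.15
    CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = 0.05 * CaMKb * (CaMKb + CaMKt) - 0.00068 * CaMKt
    fp = 1.0 / (1.0 + KmCaMK / CaMKa)   # phosphorylated fraction (shared form)

    # ---- INa (fast) ----
    mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                + 8.552 * np.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                 + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * np.exp((v + 5.730) / 56.66))
    h = 0.99 * hf + 0.01 * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * np.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    hp = 0.99 * hf + 0.01 * hsp
    tjp = 1.46 * tj
    GNa = 75.0 * mult[0]
    INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fp) * h * jj + fp * hp * jp)

    # ---- INaL ----
    mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    tmL = tm
    hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    GNaL = 0.0075 * mult[1]
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fp) * hL + fp * hLp)

    # ---- Ito ----
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1e-4 / (np.exp((v - 167.4) / 15.89)
                                  + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ip_gate = AiF * iFp + AiS * iSp
    Gto = 0.02 * mult[2]
    Ito = Gto * (v - EK) * ((1.0 - fp) * a * i_gate + fp * ap * ip_gate)

    # ---- ICaL / ICaNa / ICaK ----
    dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (3.5e-5 * np.exp(-(v + 5.0) / 4.0)
                          + 3.5e-5 * np.exp((v + 5.0) / 6.0))
    f_gate = 0.6 * ff + 0.4 * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    tffp = 2.5 * tff
    f_gate_p = 0.6 * ffp + 0.4 * fs
    tfcafp = 2.5 * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    km2n = jca * 1.0
    anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / cass) ** 4)
    dy[30] = anca * 1000.0 - nca * km2n
    # vffrt/(2 vfrt) = F/2 exactly, so the GHK fluxes stay finite at v = 0
    PhiCaL = (2.0 * _F * (cass * np.exp(2.0 * vfrt) - 0.341 * _CAO)
              * _xdexpm1(2.0 * vfrt))
    PhiCaNa = (_F * (0.75 * nass * np.exp(vfrt) - 0.75 * _NAO)
               * _xdexpm1(vfrt))
    PhiCaK = (_F * (0.75 * kss * np.exp(vfrt) - 0.75 * _KO)
              * _xdexpm1(vfrt))
    PCa = 0.0001 * mult[8]
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    ICaL = ((1.0 - fp) * PCa * PhiCaL * d * (f_gate * (1.0 - nca) + jca * fca * nca)
            + fp * PCap * PhiCaL * d * (f_gate_p * (1.0 - nca) + jca * fcap * nca))
    ICaNa = ((1.0 - fp) * PCaNa * PhiCaNa * d * (f_gate * (1.0 - nca) + jca * fca * nca)
             + fp * PCaNap * PhiCaNa * d * (f_gate_p * (1.0 - nca) + jca * fcap * nca))
    ICaK = ((1.0 - fp) * PCaK * PhiCaK * d * (f_gate * (1.0 - nca) + jca * fca * nca)
            + fp * PCaKp * PhiCaK * d * (f_gate_p * (1.0 - nca) + jca * fcap * nca))

    # ---- IKr ----
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = 1.0 / ((1.0 + np.exp((v + 55.0) / 75.0))
                 * (1.0 + np.exp((v - 10.0) / 30.0)))
    GKr = 0.046 * mult[3]
    IKr = GKr * np.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

    # ---- IKs ----
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * mult[4]
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # ---- IK1 ----
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * _KO + 144.59)
                                / (1.5692 * _KO + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * _KO) / 9.493))
    GK1 = 0.1908 * mult[5]
    IK1 = GK1 * np.sqrt(_KO) * rk1 * xk1 * (v - EK)

    # ---- INaCa (Na+/Ca2+ exchanger), myoplasmic and subspace branches ----
    kna1 = 15.0; kna2 = 5.0; kna3 = 88.12
    kasymm = 12.5; wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
    kcaon = 1.5e6; kcaoff = 5.0e3
    qna = 0.5224; qca = 0.1670
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)
    Gncx = 0.0008 * mult[6]

    # myoplasmic branch
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = _NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
    h11 = _NAO * _NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * _CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    KmCaAct = 150.0e-6
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

    # subspace branch (same scheme with nass/cass)
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo_ss = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo_ss * (JncxNa + 2.0 * JncxCa)

    # ---- INaK (Na+/K+ pump) ----
    k1p = 949.5; k1m = 182.4; k2p = 687.2; k2m = 39.4
    k3p_ = 1899.0; k3m = 79300.0; k4p_ = 639.0; k4m = 40.0
    Knai = 9.073 * np.exp(-0.1550 * vfrt / 3.0)
    Knao = 27.78 * np.exp((1.0 + 0.1550) * vfrt / 3.0)
    Kki = 0.5; Kko = 0.3582
    MgADP = 0.05; MgATP = 9.8; Kmgatp = 1.698e-7
    H_ = 1.0e-7; eP = 4.2; Khp = 1.698e-7; Knap = 224.0; Kxkur = 292.0
    P = eP / (1.0 + H_ / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (_NAO / Knao) ** 3
          / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0))
    a3 = (k3p_ * (_KO / Kko) ** 2
          / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0))
    b3 = k3m * P * H_ / (1.0 + MgATP / Kmgatp)
    a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0 * mult[7]
    INaK = Pnak * (JnakNa + JnakK)

    # ---- background and pump currents ----
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    IKb = 0.003 * xkb * (v - EK)
    INab = 3.75e-10 * _F * (nai * np.exp(vfrt) - _NAO) * _xdexpm1(vfrt)
    ICab = (2.5e-8 * 2.0 * _F * (cai * np.exp(2.0 * vfrt) - 0.341 * _CAO)
            * _xdexpm1(2.0 * vfrt))
    IpCa = 0.0005 * cai / (0.0005 + cai)

    # ---- diffusion fluxes ----
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # ---- SR release ----
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    Jrel = (1.0 - fp) * Jrelnp + fp * Jrelp

    # ---- SR uptake / leak / translocation ----
    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fp) * Jupnp + fp * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # ---- membrane potential ----
    Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + ist)
    dy[0] = -Itot

    # ---- concentrations ----
    cmdnmax = 0.05; kmcmdn = 0.00238
    trpnmax = 0.07; kmtrpn = 0.0005
    BSRmax = 0.047; KmBSR = 0.00087
    BSLmax = 1.124; KmBSL = 0.0087
    csqnmax = 10.0; kmcsqn = 0.8

    dy[1] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * _ACAP
             / (_F * _VMYO) + JdiffNa * _VSS / _VMYO)
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
    dy[3] = (-(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK) * _ACAP
             / (_F * _VMYO) + JdiffK * _VSS / _VMYO)
    dy[4] = -ICaK * _ACAP / (_F * _VSS) - JdiffK
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO)
                    - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dy[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
                     + Jrel * _VJSR / _VSS - Jdiff)
    dy[7] = Jup - Jtr * _VJSR / _VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = Bcajsr * (Jtr - Jrel)

    # ---- gate derivatives + (x_inf, tau) pairs for Rush-Larsen ----
    # extra rows: index matches the state index; col0 = x_inf, col1 = tau
    extra[9, 0] = mss;   extra[9, 1] = tm
    extra[10, 0] = hss;  extra[10, 1] = thf
    extra[11, 0] = hss;  extra[11, 1] = ths
    extra[12, 0] = jss;  extra[12, 1] = tj
    extra[13, 0] = hssp; extra[13, 1] = thsp
    extra[14, 0] = jss;  extra[14, 1] = tjp
    extra[15, 0] = mLss; extra[15, 1] = tmL
    extra[16, 0] = hLss; extra[16, 1] = thL
    extra[17, 0] = hLssp; extra[17, 1] = thLp
    extra[18, 0] = ass;  extra[18, 1] = ta
    extra[19, 0] = iss;  extra[19, 1] = tiF
    extra[20, 0] = iss;  extra[20, 1] = tiS
    extra[21, 0] = assp; extra[21, 1] = ta
    extra[22, 0] = iss;  extra[22, 1] = tiFp
    extra[23, 0] = iss;  extra[23, 1] = tiSp
    extra[24, 0] = dss;  extra[24, 1] = td
    extra[25, 0] = fss;  extra[25, 1] = tff
    extra[26, 0] = fss;  extra[26, 1] = tfs
    extra[27, 0] = fcass; extra[27, 1] = tfcaf
    extra[28, 0] = fcass; extra[28, 1] = tfcas
    extra[29, 0] = fcass; extra[29, 1] = tjca
    extra[31, 0] = fss;  extra[31, 1] = tffp
    extra[32, 0] = fcass; extra[32, 1] = tfcafp
    extra[33, 0] = xrss; extra[33, 1] = txrf
    extra[34, 0] = xrss; extra[34, 1] = txrs
    extra[35, 0] = xs1ss; extra[35, 1] = txs1
    extra[36, 0] = xs2ss; extra[36, 1] = txs2
    extra[37, 0] = xk1ss; extra[37, 1] = txk1
    extra[38, 0] = Jrel_inf; extra[38, 1] = tau_rel
    extra[39, 0] = Jrel_infp; extra[39, 1] = tau_relp

    for k in range(9, 30):
        dy[k] = (extra[k, 0] - y[k]) / extra[k, 1]
    for k in range(31, 40):
        dy[k] = (extra[k, 0] - y[k]) / extra[k, 1]
    # nca (dy[30]) and CaMKt (dy[40]) already set

    currents = np.empty(18)
    currents[0] = INa; currents[1] = INaL; currents[2] = Ito
    currents[3] = ICaL; currents[4] = ICaNa; currents[5] = ICaK
    currents[6] = IKr; currents[7] = IKs; currents[8] = IK1
    currents[9] = INaCa_i; currents[10] = INaCa_ss; currents[11] = INaK
    currents[12] = INab; currents[13] = IKb; currents[14] = IpCa
    currents[15] = ICab; currents[16] = Jrel; currents[17] = Jup
    return currents


CURRENT_NAMES = ("INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs",
                 "IK1", "INaCa_i", "INaCa_ss", "INaK", "INab", "IKb", "IpCa",
                 "ICab", "Jrel", "Jup")

# indices advanced by the exact exponential (Rush-Larsen) update
_RL_IDX = np.array(list(range(9, 30)) + list(range(31, 40)), dtype=np.int64)
# indices advanced by forward Euler (V, concentrations, nca, CaMKt)
_EU_IDX = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 30, 40], dtype=np.int64)


@njit(cache=True)
def _advance(y, mult, t_in_beat, t_end, stim_amp, stim_dur,
             dt_min, dt_max, dv_target, rec_t, rec_v, rec_ca, rec_on):
    """March the state from t_in_beat to t_end within one cycle.

    Returns (n_recorded, ok).  Steps never straddle the stimulus edges.
    """
    dy = np.empty(N_STATES)
    extra = np.empty((N_STATES, 2))
    t = t_in_beat
    n = 0
    if rec_on:
        rec_t[n] = t
        rec_v[n] = y[0]
        rec_ca[n] = y[5]
        n += 1
    while t < t_end - 1e-9:
        ist = stim_amp if t < stim_dur else 0.0
        _core(y, mult, ist, dy, extra)
        dv = abs(dy[0])
        if ist != 0.0:
            dt = dt_min
        elif dv > 1e-12:
            dt = dv_target / dv
        else:
            dt = dt_max
        if dt < dt_min:
            dt = dt_min
        if dt > dt_max:
            dt = dt_max
        # keep Ca compartment updates bounded (release transients are fast)
        for k in (6, 8):
            dk = abs(dy[k])
            if dk * dt > 0.03 * y[k]:
                dtk = 0.03 * y[k] / dk
                if dtk < dt:
                    dt = dtk
        if dt < dt_min:
            dt = dt_min
        # do not step across the stimulus-off edge or the cycle end
        if t < stim_dur and t + dt > stim_dur:
            dt = stim_dur - t
        if t + dt > t_end:
            dt = t_end - t
        for idx in _EU_IDX:
            y[idx] += dt * dy[idx]
        for idx in _RL_IDX:
            tau = extra[idx, 1]
            y[idx] = extra[idx, 0] + (y[idx] - extra[idx, 0]) * np.exp(-dt / tau)
        t += dt
        if not np.isfinite(y[0]):
            return n, False
        if rec_on:
            rec_t[n] = t
            rec_v[n] = y[0]
            rec_ca[n] = y[5]
            n += 1
    return n, True


@njit(cache=True)
def _pace(y, mult, cl, n_beats, stim_amp, stim_dur,
          dt_min, dt_max, dv_target):
    """Pace n_beats without recording; returns ok flag and beats completed."""
    dummy = np.empty(1)
    for b in range(n_beats):
        _, ok = _advance(y, mult, 0.0, cl, stim_amp, stim_dur,
                         dt_min, dt_max, dv_target, dummy, dummy, dummy, False)
        if not ok:
            return False, b
    return True, n_beats


# generous bound on recorded samples per beat (dt_min over the whole cycle)
def _max_samples(cl: float, dt_min: float) -> int:
    return int(cl / dt_min) + 16


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive-step controls for the Rush-Larsen/Euler stepper.

    ``dv_target`` (mV) caps the voltage change per step away from the
    stimulus; ``dt_min`` is used throughout the stimulus and upstroke.
    """

    dt_min: float = 0.005
    dt_max: float = 0.25
    dv_target: float = 0.2


DEFAULT_SOLVER = SolverSettings()


def simulate_paced(scalings: IonicScalings | None = None,
                   block: BlockFractions | None = None,
                   protocol: StimulusProtocol | None = None,
                   initial: np.ndarray | ModelState | None = None,
                   solver: SolverSettings = DEFAULT_SOLVER,
                   model_id: str = "",
                   ) -> tuple[PacedTrace, np.ndarray]:
    """Pace the cell and return (final-beat trace, final state vector).

    The state carries over beat to beat; only the last beat is recorded, on
    the solver's accepted-step grid (<= ``dt_min`` spacing on the upstroke).
    Raises :class:`SolverFailure` if the state goes non-finite.
    """
    protocol = protocol or StimulusProtocol()
    if isinstance(initial, ModelState):
        initial.validate()
        y = np.array(initial.y, float)
    elif initial is None:
        y = initial_state()
    else:
        y = np.array(initial, float)
        ModelState(y).validate()
    mult = effective_multipliers(scalings, block)

    if protocol.n_beats > 1:
        ok, beat = _pace(y, mult, protocol.cl, protocol.n_beats - 1,
                         protocol.stim_amplitude, protocol.stim_duration,
                         solver.dt_min, solver.dt_max, solver.dv_target)
        if not ok:
            raise SolverFailure(model_id, beat)
    nmax = _max_samples(protocol.cl, solver.dt_min)
    rec_t = np.empty(nmax)
    rec_v = np.empty(nmax)
    rec_ca = np.empty(nmax)
    n, ok = _advance(y, mult, 0.0, protocol.cl,
                     protocol.stim_amplitude, protocol.stim_duration,
                     solver.dt_min, solver.dt_max, solver.dv_target,
                     rec_t, rec_v, rec_ca, True)
    if not ok:
        raise SolverFailure(model_id, protocol.n_beats - 1)
    trace = PacedTrace(rec_t[:n].copy(), rec_v[:n].copy(), rec_ca[:n].copy(),
                       cl=protocol.cl, stim_onset=0.0, model_id=model_id)
    return trace, y


def ord_rhs(state: np.ndarray | ModelState,
            scalings: IonicScalings | None = None,
            block: BlockFractions | None = None,
            stimulus: float = 0.0) -> np.ndarray:
    """Time derivative of the full state vector (ms^-1 units per variable)."""
    if isinstance(state, ModelState):
        state.validate()
        y = np.asarray(state.y, float)
    else:
        y = np.asarray(state, float)
        ModelState(y).validate()
    mult = effective_multipliers(scalings, block)
    dy = np.empty(N_STATES)
    extra = np.empty((N_STATES, 2))
    _core(y, mult, stimulus, dy, extra)
    return dy


def ord_currents(state: np.ndarray,
                 scalings: IonicScalings | None = None,
                 block: BlockFractions | None = None) -> dict[str, float]:
    """Individual membrane currents/fluxes at a state, keyed by name."""
    y = np.asarray(state, float)
    ModelState(y).validate()
    mult = effective_multipliers(scalings, block)
    dy = np.empty(N_STATES)
    extra = np.empty((N_STATES, 2))
    cur = _core(y, mult, 0.0, dy, extra)
    return dict(zip(CURRENT_NAMES, cur))


def save_state(y: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(zip(STATE_NAMES, map(float, y)))))


def load_state(path: str | Path) -> np.ndarray:
    d = json.loads(Path(path).read_text())
    return np.array([d[k] for k in STATE_NAMES], float)
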