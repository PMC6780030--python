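"""Pore-block drug models, population drug trials and the block-grid scan.

Drug action on a channel is concentration-dependent fractional conductance
block: the remaining conductance at free concentration C is
``1 / (1 + (C / IC50)^h)`` (Hill pore block), so the block fraction is
``1 - 1/(1 + (C/IC50)^h)``.  Trials test multiples of each compound's
maximal effective free therapeutic plasma concentration (EFTPCmax).

A trial paces every calibrated model for 150 beats per concentration,
restarting from that model's control steady state, and compares the final
beat against the model's own drug-free control arm (150 beats from the same
state), yielding per-model percent changes and population summaries.  The
sensitivity scan applies fixed fractional blocks directly (no IC50 step) on
IKr/ICaL/INaL and shares all downstream machinery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ord import (BlockFractions, StimulusProtocol, SolverSettings,
                  DEFAULT_SOLVER, simulate_paced, SolverFailure)
from .biomarkers import BiomarkerSet, extract_all, delta_biomarkers
from .population import Population

__all__ = ["ChannelBlockParams", "DrugRecord", "block_fraction",
           "drug_to_blocks", "TrialResult", "run_drug_trial", "block_scan",
           "load_compendium", "save_compendium",
           "DEFAULT_MULTIPLES", "TRIAL_PROTOCOL"]

#: concentration multiples of EFTPCmax tested by default
DEFAULT_MULTIPLES = (1.0, 3.0, 10.0, 30.0, 100.0)
#: 150 beats at 1 Hz per concentration (and for the control arm)
TRIAL_PROTOCOL = StimulusProtocol(n_beats=150)

#: channels a compendium row may target (block applied via BlockFractions)
DRUG_CHANNELS = ("INa", "INaL", "Ito", "IKr", "IKs", "IK1", "ICaL")
#: risk category labels counting as torsadogenic ground truth
RISKY_CATEGORIES = ("known", "possible", "conditional")
SAFE_CATEGORIES = ("NC", "safe", "unlisted")


@dataclass(frozen=True)
class ChannelBlockParams:
    """IC50 (uM) and Hill coefficient for one drug-channel interaction."""

    ic50: float
    hill: float = 1.0

    def __post_init__(self):
        if not (self.ic50 > 0 and self.hill > 0):
            raise ValueError("IC50 and Hill coefficient must be positive")


@dataclass
class DrugRecord:
    """One compendium entry: per-channel potencies + EFTPCmax + category."""

    name: str
    channels: dict[str, ChannelBlockParams] = field(default_factory=dict)
    eftpc_max: float = 1.0      # uM
    category: str = "NC"        # known | possible | conditional | NC | unlisted

    def __post_init__(self):
        if self.eftpc_max <= 0:
            raise ValueError("EFTPCmax must be positive")
        unknown = set(self.channels) - set(DRUG_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")

    @property
    def is_risky_truth(self) -> bool:
        return self.category in RISKY_CATEGORIES


def block_fraction(concentration: float, ic50: float, hill: float) -> float:
    """Fractional block in [0, 1] of the Hill pore-block model."""
    if ic50 <= 0 or hill <= 0:
        raise ValueError("IC50 and Hill coefficient must be positive")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0.0:
        return 0.0
    return 1.0 - 1.0 / (1.0 + (concentration / ic50) ** hill)


def drug_to_blocks(drug: DrugRecord, multiple: float) -> BlockFractions:
    """Per-channel block at C = multiple x EFTPCmax (no data => no block)."""
    if multiple <= 0:
        raise ValueError("concentration multiple must be positive")
    conc = multiple * drug.eftpc_max
    blocks = {ch: block_fraction(conc, p.ic50, p.hill)
              for ch, p in drug.channels.items()}
    return BlockFractions(**blocks)


# ---------------------------------------------------------------------------
# compendium CSV (long format: one row per drug-channel pair; channel-less
# drugs keep a single row with empty channel fields)
# ---------------------------------------------------------------------------

_COMP_COLS = ["name", "channel", "ic50_uM", "hill", "eftpc_max_uM",
              "tdp_category"]


def save_compendium(drugs: list[DrugRecord], path) -> None:
    rows = []
    for d in drugs:
        if not d.channels:
            rows.append({"name": d.name, "channel": "", "ic50_uM": np.nan,
                         "hill": np.nan, "eftpc_max_uM": d.eftpc_max,
                         "tdp_category": d.category})
        for ch, p in sorted(d.channels.items()):
            rows.append({"name": d.name, "channel": ch, "ic50_uM": p.ic50,
                         "hill": p.hill, "eftpc_max_uM": d.eftpc_max,
                         "tdp_category": d.category})
    pd.DataFrame(rows, columns=_COMP_COLS).to_csv(path, index=False)


def load_compendium(path) -> list[DrugRecord]:
    df = pd.read_csv(path)
    missing = set(_COMP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"compendium missing columns: {sorted(missing)}")
    drugs = []
    for name, grp in df.groupby("name", sort=False):
        eftpc = grp["eftpc_max_uM"].unique()
        cat = grp["tdp_category"].unique()
        if len(eftpc) > 1 or len(cat) > 1:
            raise ValueError(f"inconsistent EFTPCmax/category for {name}")
        channels = {}
        for _, r in grp.iterrows():
            ch = r["channel"]
            if isinstance(ch, str) and ch:
                channels[ch] = ChannelBlockParams(float(r["ic50_uM"]),
                                                  float(r["hill"]))
        drugs.append(DrugRecord(str(name), channels, float(eftpc[0]),
                                str(cat[0])))
    return drugs


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class ConditionSummary:
    """Population aggregate at one condition (drug x multiple / scan cell)."""

    n_tot: int
    n_ra: int
    n_da: int
    n_emw: int                 # models with dEMw < the shortening threshold
    n_valid_emw: int
    median_dEMw: float
    median_dAPD90: float
    median_dCTD90: float
    frac_ra: float
    frac_emw_short: float      # fraction with dEMw below threshold
    frac_apd_long: float       # fraction with dAPD90 above +6%


@dataclass
class TrialResult:
    """Per-model and per-condition outcomes of one compound's trial."""

    drug: str
    multiples: tuple
    per_model: pd.DataFrame     # rows: (multiple, model_id) -> flags + deltas
    summaries: dict[float, ConditionSummary]
    n_tot: int


def _summarise(rows: list[dict], n_tot: int,
               emw_threshold: float = -10.0,
               apd_threshold: float = 6.0,
               min_control_emw: float = 1.0) -> ConditionSummary:
    n_ra = sum(r["RA"] for r in rows)
    n_da = sum(r["DA"] and not r["RA"] for r in rows)
    demw = np.array([r["dEMw"] for r in rows], float)
    dapd = np.array([r["dAPD90"] for r in rows], float)
    dctd = np.array([r["dCTD90"] for r in rows], float)
    # models whose control EMw is denominator-degenerate are excluded
    usable = np.isfinite(demw) & np.array(
        [abs(r["control_EMw"]) >= min_control_emw for r in rows])
    demw_ok = demw[usable]
    n_emw = int(np.sum(demw_ok < emw_threshold))
    med = float(np.median(demw_ok)) if demw_ok.size else math.nan
    dapd_ok = dapd[np.isfinite(dapd)]
    dctd_ok = dctd[np.isfinite(dctd)]
    return ConditionSummary(
        n_tot=n_tot,
        n_ra=int(n_ra),
        n_da=int(n_da),
        n_emw=n_emw,
        n_valid_emw=int(demw_ok.size),
        median_dEMw=med,
        median_dAPD90=float(np.median(dapd_ok)) if dapd_ok.size else math.nan,
        median_dCTD90=float(np.median(dctd_ok)) if dctd_ok.size else math.nan,
        frac_ra=n_ra / n_tot,
        frac_emw_short=(n_emw / demw_ok.size) if demw_ok.size else math.nan,
        frac_apd_long=(float(np.mean(dapd_ok > apd_threshold))
                       if dapd_ok.size else math.nan),
    )


def control_arm(pop: Population,
                protocol: StimulusProtocol = TRIAL_PROTOCOL,
                solver: SolverSettings = DEFAULT_SOLVER,
                ) -> dict[str, BiomarkerSet]:
    """Drug-free continuation of every model, the comparator for trials.

    Each model is paced ``protocol.n_beats`` further beats from its stored
    control steady state; the final beat's biomarkers are the 'corresponding
    control' against which drugged beats are compared.
    """
    out = {}
    for mid, sc, y in zip(pop.model_ids, pop.scalings, pop.states):
        trace, _ = simulate_paced(scalings=sc, protocol=protocol, initial=y,
                                  solver=solver, model_id=mid)
        out[mid] = extract_all(trace)
    return out


def _blocked_condition(pop: Population, blocks_of, controls,
                       protocol: StimulusProtocol,
                       solver: SolverSettings) -> list[dict]:
    """Pace every model under per-model blocks; per-model outcome rows."""
    rows = []
    for mid, sc, y in zip(pop.model_ids, pop.scalings, pop.states):
        ctrl = controls[mid]
        row = {"model_id": mid, "RA": False, "DA": False,
               "dEMw": math.nan, "dAPD90": math.nan, "dCTD90": math.nan,
               "control_EMw": ctrl.EMw, "failed": False}
        try:
            trace, _ = simulate_paced(scalings=sc, block=blocks_of(mid),
                                      protocol=protocol, initial=y,
                                      solver=solver, model_id=mid)
        except SolverFailure:
            row["failed"] = True
            row["DA"] = True        # counted invalid, never aborts the trial
            rows.append(row)
            continue
        b = extract_all(trace, control_rmp=ctrl.RMP)
        row["RA"], row["DA"] = b.RA, b.DA
        if not (b.RA or b.DA):
            d = delta_biomarkers(b, ctrl)
            row["dEMw"], row["dAPD90"], row["dCTD90"] = (d.dEMw, d.dAPD90,
                                                         d.dCTD90)
        rows.append(row)
    return rows


def run_drug_trial(pop: Population,
                   drug: DrugRecord,
                   multiples=DEFAULT_MULTIPLES,
                   protocol: StimulusProtocol = TRIAL_PROTOCOL,
                   solver: SolverSettings = DEFAULT_SOLVER,
                   controls: dict[str, BiomarkerSet] | None = None,
                   emw_threshold: float = -10.0) -> TrialResult:
    """Multi-concentration in-silico trial of one compound.

    ``controls`` (from :func:`control_arm`) can be shared across compounds;
    it is computed here when absent.
    """
    if controls is None:
        controls = control_arm(pop, protocol, solver)
    all_rows = []
    summaries = {}
    for mult in multiples:
        blocks = drug_to_blocks(drug, mult)
        rows = _blocked_condition(pop, lambda mid: blocks, controls,
                                  protocol, solver)
        for r in rows:
            r["multiple"] = mult
        all_rows.extend(rows)
        summaries[mult] = _summarise(rows, len(pop),
                                     emw_threshold=emw_threshold)
    df = pd.DataFrame(all_rows).set_index(["multiple", "model_id"])
    return TrialResult(drug.name, tuple(multiples), df, summaries, len(pop))


SCAN_LEVELS = (0.0, 0.25, 0.50, 0.75, 1.0)


def block_scan(pop: Population,
               levels=SCAN_LEVELS,
               protocol: StimulusProtocol = TRIAL_PROTOCOL,
               solver: SolverSettings = DEFAULT_SOLVER,
               controls: dict[str, BiomarkerSet] | None = None,
               cells: list[tuple[float, float, float]] | None = None,
               ) -> pd.DataFrame:
    """Exhaustive IKr x ICaL x INaL fixed-block sensitivity grid.

    Returns a tidy frame keyed by (bKr, bCaL, bNaL) with median percent
    changes of EMw/APD90 and the fractions of models showing RA, EMw
    shortening < -10% and APD90 prolongation > +6%.  Cells whose summary is
    uncomputable (e.g. RA everywhere, no Ca2+ transient under full ICaL
    block) carry NaN medians -- explicitly undefined, never silently zero.
    ``cells`` restricts the scan to selected combinations.
    """
    if controls is None:
        controls = control_arm(pop, protocol, solver)
    if cells is None:
        cells = list(itertools.product(levels, repeat=3))
    out = []
    for bkr, bcal, bnal in cells:
        blocks = BlockFractions(IKr=bkr, ICaL=bcal, INaL=bnal)
        rows = _blocked_condition(pop, lambda mid: blocks, controls,
                                  protocol, solver)
        s = _summarise(rows, len(pop))
        out.append({"bKr": bkr, "bCaL": bcal, "bNaL": bnal,
                    "median_dEMw": s.median_dEMw,
                    "median_dAPD90": s.median_dAPD90,
                    "frac_ra": s.frac_ra,
                    "frac_emw_short": s.frac_emw_short,
                    "frac_apd_long": s.frac_apd_long,
                    "n_valid_emw": s.n_valid_emw})
    return pd.DataFrame(out).set_index(["bKr", "bCaL", "bNaL"])
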