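"""Torsade-de-Pointes risk calls, the weighted TdP score and metrics.

Two classification criteria operate on a population trial:

* ``RA_only`` -- a compound is risky if it provokes repolarisation
  abnormalities in at least one model at the tested concentration;
* ``RA_plus_EMw`` -- risky if, additionally or alternatively, the median
  drug-induced EMw change falls below the shortening threshold
  (dEMw < -10%), i.e. the disjunction of the two signals.

The TdP score integrates all tested concentrations: each concentration i
contributes the fraction of models showing RA or above-threshold EMw
shortening, weighted by w_i = EFTPCmax / C_i so that effects at low
(near-therapeutic) doses weigh most:

    score = sum_i w_i (nRA_i + nEMw_i) / (n_tot sum_i w_i)   in [0, 1].

The RA-only score is the same formula with nEMw_i = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .drugs import TrialResult, RISKY_CATEGORIES

__all__ = ["ScoreInputs", "RiskCall", "ConfusionSummary", "classify",
           "tdp_score", "prediction_metrics", "log_modulus", "truth_label",
           "score_inputs_from_trial"]

EMW_THRESHOLD = -10.0       # percent; strict inequality
RA_FRACTION_CUTOFF = 0.97   # above this RA fraction a drug is risky outright


@dataclass(frozen=True)
class ScoreInputs:
    """Per-concentration counts feeding the TdP score."""

    multiples: tuple          # tested multiples of EFTPCmax (C_i / EFTPCmax)
    n_ra: tuple               # models showing RA at each concentration
    n_emw: tuple              # models with dEMw < threshold at each
    n_tot: int

    def __post_init__(self):
        if len(self.multiples) == 0:
            raise ValueError("at least one tested concentration required")
        if not (len(self.multiples) == len(self.n_ra) == len(self.n_emw)):
            raise ValueError("per-concentration arrays must align")
        if any(m <= 0 for m in self.multiples):
            raise ValueError("concentration multiples must be positive")
        for ra, em in zip(self.n_ra, self.n_emw):
            if ra < 0 or em < 0 or ra + em > self.n_tot:
                raise ValueError(
                    "nRA + nEMw must lie in [0, n_tot] (disjoint counts)")

    @property
    def weights(self) -> np.ndarray:
        """w_i = EFTPCmax / C_i == 1 / multiple."""
        return 1.0 / np.asarray(self.multiples, float)


@dataclass(frozen=True)
class RiskCall:
    drug: str
    criterion: str            # "RA_only" | "RA_plus_EMw" | "EMw_only"
    multiple: float
    risky: bool
    median_dEMw: float
    frac_ra: float


@dataclass(frozen=True)
class ConfusionSummary:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else math.nan

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else math.nan

    @property
    def accuracy(self) -> float:
        n = self.TP + self.TN + self.FP + self.FN
        return (self.TN + self.TP) / n if n else math.nan

    @property
    def ppv(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else math.nan

    @property
    def npv(self) -> float:
        return self.TN / (self.TN + self.FN) if self.TN + self.FN else math.nan


def classify(trial: TrialResult, criterion: str, multiple: float,
             emw_threshold: float = EMW_THRESHOLD,
             ra_cutoff: float = RA_FRACTION_CUTOFF) -> RiskCall:
    """Risk call for one compound at one tested concentration.

    ``RA_only``: risky iff RA in >= 1 model.  ``RA_plus_EMw``: risky iff RA
    in >= 1 model OR median dEMw < threshold (strict); when more than
    ``ra_cutoff`` of models show RA the median is not computable from <= 3
    models and the drug is risky by construction.  ``EMw_only`` (ablation):
    the median criterion alone, with the same >97%-RA escape.
    """
    if multiple not in trial.summaries:
        raise KeyError(f"multiple {multiple} not tested for {trial.drug}")
    s = trial.summaries[multiple]
    med = s.median_dEMw
    if criterion == "RA_only":
        risky = s.n_ra >= 1
    elif criterion in ("RA_plus_EMw", "EMw_only"):
        if s.frac_ra > ra_cutoff:
            risky = True
        elif not math.isfinite(med):
            if s.n_valid_emw == 0:
                raise ValueError(
                    f"degenerate trial for {trial.drug} at {multiple}x: "
                    f"no computable EMw yet RA fraction <= {ra_cutoff:.0%}")
            risky = s.n_ra >= 1
        else:
            risky = med < emw_threshold
            if criterion == "RA_plus_EMw":
                risky = risky or s.n_ra >= 1
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return RiskCall(trial.drug, criterion, multiple, bool(risky),
                    med, s.frac_ra)


def tdp_score(inputs: ScoreInputs, include_emw: bool = True) -> float:
    """Concentration-weighted TdP score in [0, 1].

    ``include_emw=False`` gives the original RA-only score (nEMw_i == 0).
    """
    w = inputs.weights
    nra = np.asarray(inputs.n_ra, float)
    nemw = np.asarray(inputs.n_emw, float) if include_emw else 0.0
    return float(np.sum(w * (nra + nemw)) / (inputs.n_tot * np.sum(w)))


def score_inputs_from_trial(trial: TrialResult,
                            emw_threshold: float = EMW_THRESHOLD,
                            ) -> ScoreInputs:
    """Collect per-concentration RA / EMw-shortening counts from a trial.

    The two counts are disjoint by construction: a model flagged RA has no
    computable EMw on that beat.
    """
    mults, nra, nemw = [], [], []
    for mult in trial.multiples:
        s = trial.summaries[mult]
        mults.append(mult)
        nra.append(s.n_ra)
        nemw.append(s.n_emw)
    return ScoreInputs(tuple(mults), tuple(nra), tuple(nemw), trial.n_tot)


def truth_label(category: str) -> bool:
    """Ground-truth mapping: known/possible/conditional -> risky (True);
    NC and unlisted compounds -> safe (False)."""
    if category in RISKY_CATEGORIES:
        return True
    if category in ("NC", "safe", "unlisted"):
        return False
    raise ValueError(f"unknown TdP risk category {category!r}")


def prediction_metrics(calls: list[RiskCall],
                       truth: dict[str, bool]) -> ConfusionSummary:
    """Confusion counts + metrics of risk calls against category truth."""
    tp = tn = fp = fn = 0
    for call in calls:
        if call.drug not in truth:
            raise KeyError(f"no truth label for drug {call.drug!r}")
        actual = truth[call.drug]
        if call.risky and actual:
            tp += 1
        elif call.risky and not actual:
            fp += 1
        elif not call.risky and actual:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(TP=tp, TN=tn, FP=fp, FN=fn)


def log_modulus(x):
    """Sign-preserving log compression L(x) = sign(x) * log10(|x| + 1)."""
    x = np.asarray(x, float)
    out = np.sign(x) * np.log10(np.abs(x) + 1.0)
    return float(out) if out.ndim == 0 else out
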