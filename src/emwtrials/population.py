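"""Experimentally calibrated populations of ventricular AP models.

A candidate population is drawn by scaling the nine principal maximal
conductances of the baseline model independently and uniformly within
stated variability ranges; each candidate is paced to (approximate) steady
state at 1 Hz and kept only if all nine AP/Ca2+ biomarkers of its final
beat fall inside experimental calibration windows with no repolarisation or
depolarisation abnormality.

The default ranges deliberately weaken repolarisation reserve (GKr, GKs,
GNaK can only go down; GCaL, GNaL, GNCX only up), so the accepted
population is biased toward pro-arrhythmic ionic profiles while every model
still looks healthy in control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ord
from .ord import (IonicScalings, BlockFractions, StimulusProtocol,
                  SolverSettings, DEFAULT_SOLVER, simulate_paced, SolverFailure)
from .biomarkers import BiomarkerSet, extract_all, BIOMARKER_NAMES

__all__ = ["SamplingRanges", "CalibrationWindows", "Population",
           "sample_population", "calibrate", "build_population"]

_SCALING_NAMES = ("sNa", "sNaL", "sto", "sKr", "sKs", "sK1", "sNCX",
                  "sNaK", "sCaL")

# variability ranges as fractions of baseline conductances
DEFAULT_RANGES = {
    "sNa": (0.30, 2.00),
    "sNaL": (1.00, 2.00),
    "sto": (0.00, 2.00),
    "sKr": (0.45, 1.00),
    "sKs": (0.00, 1.00),
    "sK1": (0.30, 2.00),
    "sNCX": (1.00, 2.00),
    "sNaK": (0.30, 1.00),
    "sCaL": (1.00, 2.00),
}

# experimental acceptance windows per biomarker (ms, V/s, mV as appropriate)
DEFAULT_WINDOWS = {
    "APD40": (85.0, 320.0),
    "APD50": (110.0, 350.0),
    "APD90": (180.0, 440.0),
    "Tri90_40": (50.0, 150.0),
    "dVdtMAX": (100.0, 1000.0),
    "Vpeak": (10.0, 55.0),
    "RMP": (-95.0, -80.0),
    "CTD50": (120.0, 420.0),
    "CTD90": (220.0, 785.0),
}


@dataclass
class SamplingRanges:
    """Per-parameter [low, high] bounds (fractions of baseline) + draw size."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))
    size: int = 150
    seed: int = 0
    method: str = "uniform"     # or "lhs" (Latin hypercube)

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("population size must be >= 1")
        for name in _SCALING_NAMES:
            lo, hi = self.bounds[name]
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid bounds for {name}: [{lo}, {hi}]")


@dataclass
class CalibrationWindows:
    """Per-biomarker [min, max] acceptance bounds."""

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))

    def __post_init__(self):
        for name in BIOMARKER_NAMES:
            lo, hi = self.windows[name]
            if not lo < hi:
                raise ValueError(f"window for {name} must satisfy min < max")

    def contains(self, bset: BiomarkerSet) -> tuple[bool, list[str]]:
        """(inside, list of violated biomarkers)."""
        bad = []
        for name in BIOMARKER_NAMES:
            lo, hi = self.windows[name]
            v = getattr(bset, name)
            if not np.isfinite(v) or not (lo <= v <= hi):
                bad.append(name)
        return (not bad), bad


def sample_population(ranges: SamplingRanges) -> list[IonicScalings]:
    """Draw conductance-scaling sets, one per candidate model.

    Each coordinate is drawn independently and uniformly inside its bounds
    (optionally by Latin-hypercube stratification); fixed seed => fixed draw.
    """
    rng = np.random.default_rng(ranges.seed)
    n = ranges.size
    cols = {}
    for name in _SCALING_NAMES:
        lo, hi = ranges.bounds[name]
        if ranges.method == "lhs":
            u = (rng.permutation(n) + rng.random(n)) / n
        else:
            u = rng.random(n)
        cols[name] = lo + (hi - lo) * u
    return [IonicScalings(**{k: float(cols[k][i]) for k in _SCALING_NAMES})
            for i in range(n)]


@dataclass
class Population:
    """Calibrated control population with per-model steady states."""

    model_ids: list[str]
    scalings: list[IonicScalings]
    states: list[np.ndarray]            # control steady state per model
    biomarkers: dict[str, BiomarkerSet]  # control biomarkers per model
    rejected: dict[str, list[str]]      # candidate id -> rejection reasons
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.model_ids)

    def subset(self, ids: list[str]) -> "Population":
        pos = {m: k for k, m in enumerate(self.model_ids)}
        idx = [pos[m] for m in ids]
        return Population(
            model_ids=list(ids),
            scalings=[self.scalings[k] for k in idx],
            states=[self.states[k] for k in idx],
            biomarkers={m: self.biomarkers[m] for m in ids},
            rejected={},
            provenance={**self.provenance, "subset_of": len(self)},
        )

    def subsample(self, n: int, seed: int = 0) -> "Population":
        """Random subset of n models (all models if n >= len)."""
        if n >= len(self):
            return self
        rng = np.random.default_rng(seed)
        ids = [self.model_ids[k]
               for k in sorted(rng.choice(len(self), n, replace=False))]
        return self.subset(ids)

    # ------------------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([asdict(s) for s in self.scalings],
                     index=self.model_ids).rename_axis("model_id") \
            .to_csv(outdir / "scalings.csv", float_format="%.17g")
        states = {m: list(map(float, y))
                  for m, y in zip(self.model_ids, self.states)}
        (outdir / "states.json").write_text(json.dumps(states))
        pd.DataFrame({m: b.as_dict() for m, b in self.biomarkers.items()}) \
            .T.rename_axis("model_id").to_csv(outdir / "biomarkers.csv")
        manifest = {"provenance": self.provenance, "rejected": self.rejected,
                    "n_accepted": len(self)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "Population":
        outdir = Path(outdir)
        sc = pd.read_csv(outdir / "scalings.csv", index_col="model_id",
                         float_precision="round_trip")
        states = json.loads((outdir / "states.json").read_text())
        bio = pd.read_csv(outdir / "biomarkers.csv", index_col="model_id")
        manifest = json.loads((outdir / "manifest.json").read_text())
        ids = list(sc.index)
        bsets = {}
        for m in ids:
            row = bio.loc[m].to_dict()
            row["RA"] = bool(row["RA"])
            row["DA"] = bool(row["DA"])
            bsets[m] = BiomarkerSet(**row)
        return cls(
            model_ids=ids,
            scalings=[IonicScalings(**sc.loc[m].to_dict()) for m in ids],
            states=[np.array(states[m]) for m in ids],
            biomarkers=bsets,
            rejected=manifest.get("rejected", {}),
            provenance=manifest.get("provenance", {}),
        )


def calibrate(candidates: list[IonicScalings],
              windows: CalibrationWindows | None = None,
              protocol: StimulusProtocol | None = None,
              solver: SolverSettings = DEFAULT_SOLVER,
              provenance: dict | None = None,
              progress: bool = False) -> Population:
    """Pace candidates to steady state and keep those inside the windows.

    Acceptance demands every biomarker valid and in range and a clean beat
    (no RA/DA).  Rejections (including solver failures) are recorded with
    reasons, never silently dropped.
    """
    windows = windows or CalibrationWindows()
    protocol = protocol or StimulusProtocol()
    ids, accepted, states, bsets = [], [], [], {}
    rejected: dict[str, list[str]] = {}
    for k, sc in enumerate(candidates):
        mid = f"m{k:04d}"
        try:
            trace, y = simulate_paced(scalings=sc, protocol=protocol,
                                      solver=solver, model_id=mid)
        except SolverFailure as err:
            rejected[mid] = [f"solver_failure_beat_{err.beat}"]
            continue
        b = extract_all(trace)
        inside, bad = windows.contains(b)
        reasons = list(bad)
        if b.RA:
            reasons.append("RA")
        if b.DA:
            reasons.append("DA")
        if inside and not (b.RA or b.DA):
            ids.append(mid)
            accepted.append(sc)
            states.append(y)
            bsets[mid] = b
        else:
            rejected[mid] = reasons
        if progress and (k + 1) % 25 == 0:
            print(f"  calibrated {k + 1}/{len(candidates)}: "
                  f"{len(ids)} accepted")
    prov = dict(provenance or {})
    prov.update(n_candidates=len(candidates),
                n_accepted=len(ids),
                acceptance_fraction=len(ids) / max(len(candidates), 1),
                protocol=asdict(protocol))
    return Population(ids, accepted, states, bsets, rejected, prov)


def build_population(ranges: SamplingRanges | None = None,
                     windows: CalibrationWindows | None = None,
                     protocol: StimulusProtocol | None = None,
                     solver: SolverSettings = DEFAULT_SOLVER,
                     progress: bool = False) -> Population:
    """sample_population + calibrate with provenance recorded."""
    ranges = ranges or SamplingRanges()
    cands = sample_population(ranges)
    return calibrate(cands, windows, protocol, solver,
                     provenance={"seed": ranges.seed, "size": ranges.size,
                                 "method": ranges.method,
                                 "bounds": {k: list(v) for k, v in
                                            ranges.bounds.items()}},
                     progress=progress)
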