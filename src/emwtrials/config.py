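"""Run configuration: one YAML-serialisable object tying the stages together.

Defaults reproduce the study conditions: Table-style sampling ranges and
calibration windows, 1 Hz pacing with 500 pre-pacing beats and 150 drug
beats, concentration multiples 1/3/10/30/100x EFTPCmax, the -10% EMw
shortening and +6% APD90 prolongation thresholds, the >=1-model RA rule and
the 97% RA cutoff.  ``fast=True`` switches to the reduced-beat desk
protocol used by the analysis scripts and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .ord import StimulusProtocol, SolverSettings
from .population import SamplingRanges, CalibrationWindows, DEFAULT_RANGES, \
    DEFAULT_WINDOWS

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # paths
    population_dir: str = "results/population"
    compendium: str = "results/compendium.csv"
    output_dir: str = "results"

    # pacing
    cl: float = 1000.0
    prepace_beats: int = 500
    drug_beats: int = 150
    stim_amplitude: float = -80.0
    stim_duration: float = 0.5

    # sampling + calibration
    population_size: int = 150
    seed: int = 12345
    sampling_method: str = "uniform"
    ranges: dict = field(default_factory=lambda: {k: list(v) for k, v in
                                                  DEFAULT_RANGES.items()})
    windows: dict = field(default_factory=lambda: {k: list(v) for k, v in
                                                   DEFAULT_WINDOWS.items()})

    # trial thresholds
    multiples: list = field(default_factory=lambda: [1.0, 3.0, 10.0, 30.0,
                                                     100.0])
    emw_threshold: float = -10.0     # percent, strict
    apd_threshold: float = 6.0       # percent
    ra_min_models: int = 1
    ra_fraction_cutoff: float = 0.97
    min_control_emw: float = 1.0     # ms, median-dEMw denominator floor

    # solver
    dt_min: float = 0.005
    dt_max: float = 0.25
    dv_target: float = 0.2

    # reduced-beat desk protocol
    fast: bool = False
    fast_prepace_beats: int = 100
    fast_drug_beats: int = 150

    def control_protocol(self) -> StimulusProtocol:
        beats = self.fast_prepace_beats if self.fast else self.prepace_beats
        return StimulusProtocol(cl=self.cl, n_beats=beats,
                                stim_amplitude=self.stim_amplitude,
                                stim_duration=self.stim_duration)

    def trial_protocol(self) -> StimulusProtocol:
        beats = self.fast_drug_beats if self.fast else self.drug_beats
        return StimulusProtocol(cl=self.cl, n_beats=beats,
                                stim_amplitude=self.stim_amplitude,
                                stim_duration=self.stim_duration)

    def solver(self) -> SolverSettings:
        return SolverSettings(dt_min=self.dt_min, dt_max=self.dt_max,
                              dv_target=self.dv_target)

    def sampling_ranges(self) -> SamplingRanges:
        return SamplingRanges(bounds={k: tuple(v) for k, v in
                                      self.ranges.items()},
                              size=self.population_size, seed=self.seed,
                              method=self.sampling_method)

    def calibration_windows(self) -> CalibrationWindows:
        return CalibrationWindows(windows={k: tuple(v) for k, v in
                                           self.windows.items()})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)
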