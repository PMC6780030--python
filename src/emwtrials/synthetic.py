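"""Synthetic drug compendia and trace fixtures.

The real trial inputs are proprietary per-channel IC50/Hill tables.  This
module generates stand-in compendia built from pharmacological archetypes
(pure hERG blocker, balanced hERG+CaL blocker, hERG blocker with late-Na
mitigation, Na-dominant blocker, inert control) whose potencies are stated
as IC50/EFTPCmax ratios, plus piecewise-linear AP/Ca2+ trace fixtures with
closed-form biomarkers for testing the extraction and abnormality
detectors.  Everything here is synthetic and labelled as such; real
compendia load through the same CSV schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .drugs import ChannelBlockParams, DrugRecord
from .ord import PacedTrace

__all__ = ["CompoundArchetype", "ARCHETYPES", "make_compendium",
           "make_trace_fixtures", "linear_ap_trace", "linear_ca_trace"]


@dataclass(frozen=True)
class CompoundArchetype:
    """Channel potency template: IC50 / EFTPCmax ratio + Hill per channel."""

    name: str
    potency_ratios: dict = field(default_factory=dict)  # channel -> IC50/EFTPC
    hills: dict = field(default_factory=dict)           # channel -> h
    category: str = "NC"      # intended truth label

    def __post_init__(self):
        if not self.potency_ratios and self.category in (
                "known", "possible", "conditional"):
            raise ValueError(
                f"archetype {self.name!r}: a risky label needs >= 1 channel")


# Potency ratios are chosen so that desk-scale populations reproduce the
# qualitative contrasts robustly:
#  - pure_hERG at 10x EFTPCmax blocks IKr 77% -> strong EMw shortening / RA;
#  - hERG_plus_CaL mirrors a verapamil-like balance (25% IKr and 40% ICaL
#    block at 3x), where ICaL block compensates the EMw;
#  - NaL_mitigated pairs the same hERG potency with late-Na block;
#  - Na_dominant mainly blocks fast Na+ with only weak hERG affinity;
#  - inert carries no channel interactions at all.
ARCHETYPES: dict[str, CompoundArchetype] = {
    "pure_hERG": CompoundArchetype(
        "pure_hERG", {"IKr": 3.0}, {"IKr": 1.0}, "known"),
    "hERG_plus_CaL": CompoundArchetype(
        "hERG_plus_CaL", {"IKr": 9.0, "ICaL": 4.5},
        {"IKr": 1.0, "ICaL": 1.0}, "NC"),
    "NaL_mitigated": CompoundArchetype(
        "NaL_mitigated", {"IKr": 3.0, "INaL": 3.0},
        {"IKr": 1.0, "INaL": 1.0}, "possible"),
    "Na_dominant": CompoundArchetype(
        "Na_dominant", {"INa": 10.0, "IKr": 100.0},
        {"INa": 1.0, "IKr": 1.0}, "unlisted"),
    "inert": CompoundArchetype("inert", {}, {}, "unlisted"),
}


def make_compendium(archetypes: list[CompoundArchetype] | None = None,
                    seed: int = 0,
                    n_per_archetype: int = 1,
                    jitter: float = 0.10,
                    eftpc_max: float = 1.0) -> list[DrugRecord]:
    """Reproducible synthetic compendium (CSV-writable via save_compendium).

    Each archetype yields ``n_per_archetype`` compounds whose IC50s are the
    template ratio times EFTPCmax, log-normally jittered by ``jitter``
    (geometric sd) under the seed.  The first compound of each archetype is
    unjittered so the template contrasts stay exact.
    """
    archetypes = list(ARCHETYPES.values()) if archetypes is None else archetypes
    rng = np.random.default_rng(seed)
    out = []
    for arch in archetypes:
        for k in range(n_per_archetype):
            channels = {}
            for ch, ratio in arch.potency_ratios.items():
                ic50 = ratio * eftpc_max
                if k > 0 and jitter > 0:
                    ic50 *= math.exp(rng.normal(0.0, math.log1p(jitter)))
                channels[ch] = ChannelBlockParams(
                    ic50=ic50, hill=arch.hills.get(ch, 1.0))
            suffix = "" if n_per_archetype == 1 else f"_{k}"
            out.append(DrugRecord(name=f"{arch.name}{suffix}",
                                  channels=channels,
                                  eftpc_max=eftpc_max,
                                  category=arch.category))
    return out


# ---------------------------------------------------------------------------
# trace fixtures with closed-form biomarkers
# ---------------------------------------------------------------------------

def linear_ap_trace(rmp: float = -85.0, vpeak: float = 35.0,
                    fall_ms: float = 300.0, cl: float = 1000.0,
                    dt: float = 0.1, rise_ms: float = 0.01,
                    pre_ms: float = 10.0) -> PacedTrace:
    """Piecewise-linear AP: rest, near-instant rise, linear fall to rest.

    Geometry: with amplitude A = vpeak - rmp and linear repolarisation over
    ``fall_ms``, APDxx = xx% * fall_ms (measured from the upstroke).
    """
    # rest segment before the stimulus keeps a pre-stimulus RMP sample
    t_pre = np.arange(-pre_ms, 0.0, dt)
    t_rise = np.array([0.0, rise_ms])
    t_fall = np.arange(rise_ms + dt, fall_ms + dt, dt)
    t_rest = np.arange(fall_ms + dt, cl - pre_ms, dt)
    t = np.concatenate([t_pre, t_rise, t_fall, t_rest])
    v = np.empty_like(t)
    v[t < 0] = rmp
    v[(t >= 0) & (t < rise_ms)] = rmp
    rising = t == rise_ms
    v[rising] = vpeak
    falling = (t > rise_ms) & (t <= fall_ms)
    v[falling] = vpeak - (vpeak - rmp) * (t[falling] - rise_ms) / (fall_ms - rise_ms)
    v[t > fall_ms] = rmp
    ca = np.full_like(t, 0.1)
    tr = PacedTrace(t - t[0], v, ca, cl=cl, stim_onset=pre_ms,
                    model_id="synthetic_linear_ap", ca_units="uM")
    return tr


def linear_ca_trace(diastolic: float = 0.1, peak: float = 1.1,
                    decay_ms: float = 500.0, **ap_kwargs) -> PacedTrace:
    """Linear-AP fixture with a triangular Ca2+ transient.

    The transient jumps to ``peak`` at the upstroke instant and decays
    linearly back to ``diastolic`` over ``decay_ms``, so CTDxx (from the
    upstroke) equals xx% * decay_ms exactly.
    """
    tr = linear_ap_trace(**ap_kwargs)
    t = tr.t - tr.stim_onset            # 0 at the upstroke
    ca = np.full_like(t, diastolic)
    dec = (t >= 0) & (t <= decay_ms)
    ca[dec] = peak - (peak - diastolic) * t[dec] / decay_ms
    tr.cai = ca
    tr.model_id = "synthetic_linear_ap_ca"
    return tr


def make_trace_fixtures(seed: int = 0) -> dict[str, PacedTrace]:
    """Named fixture set for detector tests.

    ``clean``: linear AP + triangular Ca2+ transient (APD90 = 270 ms,
    CTD50/90 = 250/450 ms, EMw = 180 ms by construction).
    ``ead``: same AP with a 15 mV secondary depolarisation bump around 80%
    repolarisation (flags RA).  ``non_repolarising``: the fall stalls above
    the 90% level until the cycle ends (flags RA).  ``subthreshold``: no
    upstroke at all (flags DA).  ``noisy``: clean plus <0.1 mV noise
    (must not flag).
    """
    rng = np.random.default_rng(seed)
    out = {}
    clean = linear_ca_trace()
    out["clean"] = clean

    ead = linear_ca_trace()
    ead.model_id = "synthetic_ead"
    t80 = ead.stim_onset + 0.8 * 300.0   # 80% repolarisation of the ramp
    bump = 15.0 * np.exp(-0.5 * ((ead.t - t80) / 8.0) ** 2)
    ead.v = ead.v + np.where((ead.t > ead.stim_onset + 60.0)
                             & (ead.t < ead.stim_onset + 300.0), bump, 0.0)
    out["ead"] = ead

    nr = linear_ca_trace()
    nr.model_id = "synthetic_non_repolarising"
    floor = -85.0 + 0.2 * 120.0          # stalls at 80% repolarisation
    nr.v = np.maximum(nr.v, floor)
    nr.v[nr.t < nr.stim_onset] = -85.0   # keep a sane pre-stimulus diastole
    out["non_repolarising"] = nr

    sub = linear_ca_trace()
    sub.model_id = "synthetic_subthreshold"
    sub.v = np.full_like(sub.v, -85.0) + 2.0 * np.exp(
        -0.5 * ((sub.t - sub.stim_onset) / 5.0) ** 2)
    sub.cai = np.full_like(sub.cai, 0.1)
    out["subthreshold"] = sub

    noisy = linear_ca_trace()
    noisy.model_id = "synthetic_noisy"
    noisy.v = noisy.v + rng.uniform(-0.05, 0.05, noisy.v.size)
    out["noisy"] = noisy
    return out
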