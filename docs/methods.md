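# Methods

## Cell model

The electrophysiology engine is the O'Hara–Rudy dynamic (ORd) human
ventricular cardiomyocyte model, endocardial variant: 41 ordinary
differential equations for membrane voltage, Hodgkin–Huxley-style gating,
Markov-type Na⁺/K⁺ pump and Na⁺/Ca²⁺ exchanger cycles, CaMKII signalling,
and Ca²⁺ handling across myoplasm, subspace, and network/junctional SR.
The endocardial subtype is used throughout: it is the model's reference
parameterisation and the one consistent with the undiseased-heart
calibration data; the cell type is not otherwise configurable.

Two intervention mechanisms multiply maximal conductances/permeabilities
of the nine principal currents (INa, INaL, Ito, IKr, IKs, IK1, INCX, INaK,
ICaL):

* **population variability** — a scaling factor `s_X` per current;
* **drug action** — a fractional pore block `b_X ∈ [0, 1]`;

combined as `G_eff = s_X (1 − b_X)`. Pumps/exchangers (INaK, INCX) carry
scaling only; they are not treated as drug targets here.

Stimulus: −80 µA/µF for 0.5 ms at each cycle start (the model's published
default; configurable). Pacing is 1 Hz throughout: 500 pre-pacing beats
for the control population (quasi-steady state) and 150 beats per drug
condition, restarting from the model's stored control state. Drugged
beats are always compared against a drug-free **control arm** (150
further beats from the same state), so any residual pacing drift cancels
from the percent changes.

### Numerics

The production integrator advances Hodgkin–Huxley gates with the exact
exponential (Rush–Larsen) update `x ← x∞ + (x − x∞) e^(−dt/τ)` and
everything else (voltage, concentrations, the ICaL `nca` gate, CaMKII) by
forward Euler. The step size tracks the voltage slope
(`dt = dv_target/|dV/dt|`, clamped to [dt_min, dt_max] = [0.005, 0.25] ms,
with dt = dt_min during the stimulus and per-step caps on relative changes
of subspace/junctional-SR Ca²⁺). GHK driving forces use an analytic
`x/expm1(x)` form so v = 0 is regular. Integration is deterministic and
bit-reproducible.

Accuracy: the stepper at accuracy settings (dt_max 0.05 ms, dv_target
0.02 mV) agrees with LSODA (rtol 1e−8) on the same right-hand side to
< 0.5 mV pointwise over a beat away from the upstroke. At the default
settings, single-beat biomarkers are converged to < 1 ms. Over hundreds of
beats, first-order integration leaves a small systematic bias through slow
Na⁺/Ca²⁺ loading: APD90 is stable to ~1 ms, but CTD90 (whose 90% decay
threshold sits on a nearly flat tail) shifts by roughly 5 ms (~1%) per
halving of the step-size controls. This is the same order of
discretisation sensitivity carried by the fixed-step integrators customary
for this model family; percent-change biomarkers are much less affected
than absolute durations because both arms share the bias. Deterministic
single-model (baseline) analyses use the tighter settings, where the
APD90 response is converged to ~0.3 percentage points.

Solver failures (non-finite state) are raised with the model id and beat
index; population and trial drivers record such models as non-viable
rather than dropping them.

## Biomarkers

Nine per-beat biomarkers: APD40/50/90 (from the instant of maximum
upstroke velocity to the first downward crossing of
`V_peak − xx%·(V_peak − RMP)`, linearly interpolated), triangulation
Tri90-40 = APD90 − APD40, dV/dt_max, V_peak, RMP (pre-stimulus voltage),
and CTD50/90 (from the upstroke instant to xx% decay of the Ca²⁺ transient
from its peak back to the pre-stimulus diastolic level — the "decay"
reading of the duration convention; for a symmetric return to baseline the
two readings coincide). EMw = CTD90 − APD90, undefined (NaN) whenever a
parent biomarker is invalid or the beat is abnormal.

Abnormality detection on the final recorded beat:

* **RA (repolarisation abnormality)** — the voltage derivative turns
  positive again (> 0.01 V/s sustained ≥ 2 ms) in a window from 150 ms
  after the upstroke until 90% repolarisation (an early
  afterdepolarisation); or the AP never reaches the 90% level before the
  next stimulus; or the beat starts above −60 mV (the previous beat never
  repolarised — cascaded failure).
* **DA (depolarisation abnormality)** — no proper upstroke
  (dV/dt_max < 10 V/s, an order of magnitude below the experimental lower
  bound, or V_peak < 0 mV), or diastolic voltage > 20 mV above the control
  RMP.

The 150 ms window start skips the phase-1 notch/dome that high-Ito
population models exhibit; with a 50 ms start those traces false-flag.
All thresholds are keyword arguments. Percent changes use each model's own
control as denominator; models whose control |EMw| < 1 ms are excluded
from median ΔEMw (denominator degeneracy) and counted in the per-condition
bookkeeping.

## Population design and calibration

Candidates are drawn independently and uniformly per conductance
(Latin-hypercube optional) inside ranges that deliberately weaken
repolarisation reserve — repolarising currents can only stay or fall
(sKr ∈ [0.45, 1], sKs ∈ [0, 1], sNaK ∈ [0.3, 1]) while depolarising
currents can only stay or rise (sCaL, sNaL, sNCX ∈ [1, 2]); sNa, sto, sK1
vary symmetrically ([0.3–2], [0–2], [0.3–2]). A candidate is accepted if
all nine biomarkers of its post-pacing beat lie inside the experimental
calibration windows (APD90 ∈ [180, 440] ms, CTD90 ∈ [220, 785] ms, RMP ∈
[−95, −80] mV, …) with no RA/DA. With 150 candidates this yields ~72%
acceptance (~108 models). Rejections are recorded with per-biomarker
reason codes. The exact random draw of the original study is unknowable;
only distributional properties (acceptance fraction, correlation
structure, block-response medians) are reproducible, which is what the
tests assert.

## Drug model and trials

Pore block per channel: `b = 1 − 1/(1 + (C/IC50)^h)` at
`C = multiple × EFTPCmax`; channels without measured IC50 are unblocked.
Default multiples: 1, 3, 10, 30, 100. The sensitivity scan applies fixed
fractional blocks to IKr/ICaL/INaL directly (no concentration step) over
the 5³ grid {0, 25, 50, 75, 100}%; scan cells whose summary is
uncomputable (RA everywhere; no Ca²⁺ transient under 100% ICaL block) are
explicit NaN, never zero.

## Risk calls, score, metrics

"RA only": risky iff ≥ 1 model shows RA. "RA + ΔEMw": risky iff ≥ 1 model
shows RA **or** the population median ΔEMw < −10% (strict inequality; a
median of exactly −10% is safe). Compounds with > 97% RA (three or fewer
models left to compute an EMw) are risky by construction. The disjunctive
reading is the primary mode because the high-RA escape only makes sense if
RA occurrence itself can force a risky call; a ΔEMw-only ablation mode is
provided. The TdP score weights each concentration by
`w_i = EFTPCmax/C_i`; it is monotone in every count, bounded in [0, 1],
and invariant to rescaling all tested concentrations. nRA and nEMw counts
are disjoint by construction (RA models have no computable EMw). Truth
mapping: known/possible/conditional risk categories → risky; not-classified
and unlisted compounds → safe. Display transform for wide-range percent
changes: log-modulus `L(x) = sign(x) log10(|x| + 1)` (base 10, the
transform's customary convention).

## Synthetic data

The archetype compendium emulates the schema and pharmacology of a real
IC50/Hill table without reproducing proprietary values: potencies are
stated as IC50/EFTPCmax ratios — pure hERG blocker (ratio 3, so 77% IKr
block at 10×), balanced hERG+CaL blocker calibrated to the verapamil
benchmark (25% IKr and 40% ICaL block at 3×), a late-Na-mitigated hERG
blocker, an Na-dominant blocker, and an inert control; log-normal jitter
(10% geometric sd) under a stated seed generates families per archetype,
with the first member left exactly on the template. What passing synthetic
trials shows: the pipeline separates the archetype classes for the stated
mechanisms (EMw shortening under unbalanced hERG block, compensation under
Ca²⁺ co-block). What it cannot show: quantitative accuracy against the
40-compound clinical panel, whose IC50s, therapeutic concentrations and
category labels are not public — users with such a table load it through
the same compendium CSV schema.

Trace fixtures are piecewise-linear APs and triangular Ca²⁺ transients
with closed-form biomarkers (APD90 = 270 ms, CTD90 = 450 ms, EMw =
180 ms), plus EAD-bump, non-repolarising, subthreshold and noise-injected
variants for the detectors.

## Known limitations

* Only conductance-mediated drug action is modelled: no state-dependent
  hERG binding kinetics, no trafficking effects, no direct effects on
  contractile machinery (positive inotropes will read as safe), no
  metabolites or PK.
* Single rate (1 Hz), single cell type, no tissue or organ coupling; the
  EMw here is a cellular surrogate, not the in-vivo pressure/QT window.
* The repolarisation-abnormality threshold of the baseline model under
  pure IKr block sits at ~94% block at 1 Hz in this implementation (and
  ~85% at a 4 s cycle length, matching the model's original publication).
  Simulator implementations of this model family are known to differ in
  exactly where this bifurcation sits; population-level RA fractions in
  the high-block corner of the sensitivity grid inherit that sensitivity,
  while APD/EMw medians, calibration yield and correlation structure do
  not.
* First-order integration leaves ~1% discretisation sensitivity in
  absolute CTD90 after long pacing (see Numerics); comparisons against a
  control arm largely cancel it.
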