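# Methods

## Scope and rationale

`mnephys` re-creates, entirely in silico, a patch-clamp study of neonatal
(P0–P5) rabbit spinal motoneurons after developmental hypoxia-ischemia
(HI): a conductance-based simulator stands in for the recordings, a feature
module measures the full electrophysiological battery (persistent inward
currents, frequency–current hysteresis, spike shape, afterhyperpolarisation,
sag, passive properties), and an assumption-gated statistics engine
compares the four injury groups (sham, HI-unaffected, HI-mild, HI-severe).
Because no raw recordings are available, the synthetic cohort is the data
source; its defaults are chosen to reproduce the *directions* of the
injured phenotype — depolarised resting potential, reduced/negative
firing hysteresis (ΔI), larger capacitance, depolarised PIC onset, higher
instantaneous firing — not the published group means themselves.

## The cell model

A single-compartment Hodgkin–Huxley-style membrane (units pF, nS, mV, pA,
ms, so no conversion constants appear):

C dV/dt = I_cmd − [ I_L + I_NaT + I_Kdr + I_NaP + I_CaL + I_H + I_AHP ]

| current | form | role |
|---|---|---|
| I_L | gL (V − EL) | leak; sets input resistance and rest |
| I_NaT | gNaT m∞(V)³ h (V − ENa) | spike upstroke; m instantaneous, h fast (0.8–10 ms bell) |
| I_Kdr | gKdr n⁴ (V − EK) | repolarisation; τ_n = 4 ms |
| I_NaP | gNaP mp∞(V) hp (V − ENa) | persistent Na⁺ PIC; hp inactivates slowly (τ_inact_NaP, may be ∞) |
| I_CaL | gCaL mc (V − ECa) | L-type Ca²⁺ PIC; slow activation (τ_CaL ≈ 100 ms), non-inactivating |
| I_H | gH r (V − EH) | hyperpolarisation-activated sag current |
| I_AHP | gAHP z (V − EK) | spike-triggered adaptation; z += 1 per spike, decays with τ_AHP |

All activation/inactivation curves are Boltzmann sigmoids. Two kinetic
choices matter and were found by analysis of the model's fixed points:

* **τ_n = 4 ms.** With a fast delayed rectifier the depolarised fixed point
  created by the Na⁺ window current is a stable focus and the cell fires a
  single spike before settling on a plateau; slowing n converts it to a
  limit cycle (repetitive firing).
* **τ_AHP = 1 s, small increments (gAHP = 0.5 nS/spike for sham).**
  Adaptation with a ~100 ms decay disappears during the long inter-spike
  intervals at the end of a descending ramp, and ΔI collapses toward zero.
  A seconds-scale "late adaptation" conductance persists to the firing
  offset and produces the robustly positive control ΔI.

Default sham values (`MNParameters()`): C = 190 pF, gL = 18 nS
(R_in ≈ 55 MΩ), EL = −62 mV, gNaT = 1600 nS, gKdr = 1400 nS, gNaP = 6 nS
(half-activation −43 mV, τ_inact = 150 ms), gCaL = 0.9 nS, gH = 2.5 nS,
reversals ENa = +50, EK = −88, ECa = +60, EH = −35 mV. These give rest
≈ −61 mV, spike threshold ≈ −36 mV, rheobase ≈ 150 pA, a quasi-steady-state
PIC of ≈ −400 pA peaking near −36 mV, and depolarisation block above
≈ 2 nA — all in the physiological range for neonatal motoneurons.

## Clamp modes and integration

Voltage clamp is ideal: V is forced to the command, gates integrate
against it, and the recorded signal is I_inj = C dV_cmd/dt + ΣI_ionic with
the command derivative taken analytically per protocol segment (so the
passive response matches the closed form exactly). Current clamp
integrates V; the adaptation variable increments on upward crossings of
0 mV. The integrator is a fixed-step explicit midpoint (RK2) scheme,
default dt = 0.025 ms, checked against 10×-finer reference integrations
(<1% on ramp responses) and a halving-dt convergence bound (<0.5% per
sample on non-spiking responses; pointwise convergence is not meaningful
across long spike trains because spike-time shifts dominate). Emitted
sweeps are decimated to 10 kHz. Recording noise is additive Gaussian on
the response only (5 pA in voltage clamp, 0.3 mV in current clamp),
seeded. `|V| > 500 mV` (or NaN) aborts with a diagnostic.

## The synthetic cohort

Cells are drawn per group from truncated normal distributions
(conductances ~12–15% relative SD, voltages ±1–2.5 mV SD); gNaT and gKdr
scale linearly with the drawn capacitance (constant channel density) —
without this, large-C cells depolarisation-block after a few spikes.
Per-cell seeds derive from the cohort seed via `SeedSequence` spawning, so
a cohort is a pure function of (spec, seed). Group sizes default to
9/12/10/8 (sham/unaffected/mild/severe).

Severe-group shifts: EL −62 → −54 mV; C +45% (with density scaling);
τ_inact_NaP 150 ms → 6 s **and** its half-voltage −45 → −36 mV
("delayed/reduced Na⁺ inactivation"); gCaL 0.9 → 6 nS with half-activation
−30 → −25 mV; NaP half-activation −43 → −38 mV; gAHP 0.5 → 0.15 nS.
Mild is roughly halfway; unaffected equals sham. The weaker severe
adaptation is required: without it the late-adaptation current at firing
offset (~400 pA) outweighs any physiologically sized sustained PIC and the
hysteresis cannot shrink.

Two genuine single-compartment limitations, found during design and
accepted:

1. **ΔI non-monotonicity in τ_inact_NaP.** Intermediate time constants
   (1–8 s) accumulate inactivation during the ~4 s firing epoch without
   recovering, yielding a *more* positive ΔI than fast quasi-static
   inactivation; sustained firing requires inactivation that is either
   effectively absent at firing voltages (the severe curve shift) or
   literally absent (τ → ∞, used in the mechanism study).
2. **The severe group mean ΔI stays positive** (~+200 pA vs sham ~+380 pA).
   Holding a standing PIC strong enough for net-negative ΔI in the same
   compartment as the spike generator either destabilises the
   hyperpolarised resting state (the cell sits at ≈ −33 mV and is excluded
   by the −45 mV rule — a small fraction of severe draws do this, echoing
   the experimental exclusions) or blocks step firing. This separation of
   PIC and spike generator is exactly why dendritic-compartment models are
   used for bistability; the phenotype here is a large, highly significant
   *reduction* in ΔI rather than a sign change.

## Feature extraction

* **Leak fit / input resistance** — least squares of current vs command on
  the ascending voltage-ramp limb over [holding+5, holding+25] mV
  (precedes PIC activation in all default cohorts); R_in = 1000/slope.
  Non-positive slopes are QC failures.
* **PIC** — response minus the fitted leak line, smoothed with a 1 ms
  boxcar. Onset: first voltage where the smoothed trace drops below
  −(5 pA + 3 × pre-ramp RMS of the same smoothed trace) and stays below
  for ≥20 ms; amplitude: most negative value; max_V: voltage there;
  negative-slope range = max_V − onset_V (held as an exact identity).
  No onset ⇒ all PIC fields NaN, never zero.
* **RMP** — command voltage at the last positive-to-negative zero crossing
  of the smoothed current on the descending ramp limb, linearly
  interpolated; read from the slowest available ramp because the
  capacitive offset C·dV/dt shifts the crossing by C|slope|/gL (≈1 mV for
  a large cell on the 36 mV/s ramp, ≈0.3 mV on the 11.25 mV/s ramp).
* **Capacitance** — single-exponential fit of the membrane transient of a
  −150 pA step (C = τ·g_total with g_total from the steady-state
  deflection); onset and offset transients are fitted and averaged. An
  ideal-clamp model has no finite voltage-clamp charging transient, so the
  amplifier's compensation readout is replaced by this membrane-time-
  constant estimate.
* **Spikes** — peaks with ≥20 mV prominence whose rising dV/dt reaches
  10 V/s; threshold is the last upward crossing of dV/dt = 10 V/s before
  the peak (crossings interpolated; the derivative lightly smoothed over 3
  samples for crossing detection only); rise/fall are the derivative
  extrema in the spike window; width at the peak–threshold midpoint.
* **F-I ramp** — I_ON / I_OFF are the command currents at the first / last
  spike threshold; ΔI = I_OFF − I_ON (positive for sham-like early
  offset, negative for self-sustained firing); F-I slope from 1/ISI vs
  current on the ascending limb, each interval attributed to its second
  spike.
* **Step firing** — instantaneous rate = 1/min ISI per sweep; steady-state
  = mean rate over the last half of the step; maxima across the family.
  Depolarisation block: silence >150 ms while the step persists with mean
  V above the last spike threshold (sustained), or such a gap followed by
  resumed firing (transient).
* **AHP** — from a 5 ms/2 nA pulse that elicits exactly one spike:
  amplitude = pre-spike baseline − post-spike minimum; half-decay = time
  from trough to half recovery. Multi-spike sweeps are rejected.
* **Sag** — hyperpolarising 1 s step: amplitude = steady (last 20%) −
  peak; ratio divides by (baseline − peak); rebound when the post-step
  potential overshoots baseline by 0.5 mV + 3×pre-step SD.
* **QC** — cells with RMP strictly more depolarised than −45 mV are
  excluded (`excluded_RMP`; the boundary value −45.0 itself is included);
  missing required protocols give `missing_protocol`. Every exclusion is
  logged with its rule and value.

## Statistics

Per variable, across injury group (age and region can be tested as
separate one-way factors with the same engine): Shapiro–Wilk on pooled
group-mean-centred residuals (handles per-group n as small as 6) and
Brown–Forsythe Levene, both at gate α = 0.05. Passing both routes to
one-way ANOVA with Tukey HSD contrasts vs the reference (sham); otherwise
Kruskal–Wallis with Dunn's tie-corrected z-tests, Holm-adjusted over all
pairwise comparisons, reference contrasts reported. All-constant input is
degenerate and routes non-parametric with a warning; levels with n < 2 are
excluded from post hocs. Missingness is casewise per variable, so each
variable uses every cell that has it (unequal N across variables is
expected). `anova_from_summary` reconstructs the omnibus F and
Tukey-Kramer reference contrasts from per-level (mean, SD, N) summaries
and agrees with raw-data ANOVA to numerical precision whenever the raw
data have those summaries.

Calibration: the omnibus stage rejects at the nominal α on null cohorts.
The reported severe-vs-sham *post hoc* p is family-wise adjusted (Tukey or
Dunn-Holm), so its per-contrast null rejection rate is deliberately
conservative — measured ≈ 0.014 at α = 0.05 with four groups. This is a
property of any FWER-controlling post hoc, not a defect; both rates are
computed by `null_calibration_study` and reported by the reproduction
script.

## Validation studies and problem sizes

`mnephys.studies` packages the self-validation experiments; sizes were
fixed in advance as the package's own study design: 50 passive cells
(recovery of R_in within 2%, EL within 1 mV, C within 5%, no spurious
PIC), 20 non-inactivating PIC cells (slow-ramp amplitude within 10% of the
analytic quasi-steady-state I–V minimum — exact in the slow-ramp limit
only when NaP does not inactivate, which is why those cells use τ → ∞),
20 paired cells for the ΔI mechanism (fast inactivation + no CaL vs no
inactivation + CaL 6 nS), 2000 null variables for calibration, and 100
cohort replicates for end-to-end phenotype detection. The phenotype study
runs the two protocols its variables need (fast voltage ramp and current
ramp, 2.5 s limbs) at dt = 0.05 ms; all single-cell accuracy studies use
the default dt = 0.025 ms.

## What the generator does and does not emulate

It emulates: protocol structure (holding −90 mV, 36 and 11.25 mV/s
triangular ramps to 0 mV, current ramps and step families, hyperpolarising
steps), 10 kHz acquisition, stationary Gaussian recording noise, and
group-level parameter shifts with realistic between-cell variability. It
does not emulate: electrode/access-resistance artefacts, drift or
non-stationary noise, channel stochasticity, dendritic cable effects,
neuromodulation, or any within-litter correlation (cells are independent,
as in the original analysis). Passing tests therefore demonstrate that the
measurement and statistics pipeline is correct and well calibrated on data
with known ground truth — not that the model parameters equal those of
real injured motoneurons.

## Known limitations

Single-compartment bistability (above); PIC onset voltages run ~10 mV
hyperpolarised of typical experimental values because the NaP activation
foot is gradual; published group means/SDs are not reproduction targets
(raw data unavailable); the acquisition rate, filtering and noise level of
the real recordings are unknown and the defaults here make no claim to
match them.
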