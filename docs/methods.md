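# Methods

## Scope and intent

`htxsim` reproduces cohort-level hemodynamics of early heart-transplant
recipients (HTxR) and age/gender-matched healthy controls, at rest and
through graded exercise up to the cohort's maximum tolerated power
(MTP; healthy 1,032 kpm/min, HTxR 522 kpm/min ≈ 50 %).  It is a
cohort model: parameters are tuned to pooled clinical data, not to any
individual patient.

## Circulation

Eight compartments: left/right atria and ventricles, systemic arterial
(aortic windkessel), systemic venous, pulmonary arterial and venous.
Units are mmHg, mL, s throughout (resistances mmHg·s/mL, compliances
mL/mmHg).  Compartment volumes are the states; pressures are algebraic.
The loop is closed, so the eight volume derivatives sum to zero exactly
and total blood volume is conserved to solver round-off (tested).

**Chambers.**  Transmural pressure is a time-varying elastance with an
exponential diastolic branch,

    P_tm = [E_min + a(t)(c·E_max − E_min)](V − V_u) + (1 − a(t))·A(e^{B(V−V_u)} − 1),

where `c` is the autonomic contractility scale.  Ventricular activation
rises as sin² to the mid-systolic peak and then decays exponentially
with a relaxation time constant τ_rel; atrial activation is a plain
sin² pulse starting at the sinoatrial beat, with the ventricle delayed
by the AV interval.  Systole, AV delay and atrial pulse durations scale
as √(RR/RR_ref).

Two deliberate features carry the cohort contrast:

* **Relaxation as an absolute time cost.**  τ_rel (0.11 s basal) does
  not shrink with RR, but it does shrink with adrenergic drive
  (lusitropy, `τ_rel ∝ 1/(1 + 3(c − 1))`).  At a denervated resting HR
  of ~94 bpm the tail consumes a large fraction of diastole, which is
  what lowers the HTxR resting end-diastolic volume (EDV ≈ 107 mL)
  relative to the healthy cohort (≈ 127 mL) at nearly equal filling
  pressures.
* **A flat diastolic P–V relation below ~130 mL** (E_min 0.055
  mmHg/mL, exponential term negligible there, steep above ~140 mL).
  The printed end-diastolic pressure/volume working points of both
  cohorts at rest and exercise are mutually consistent only with a
  compliance of this order; it also makes end-diastolic volume strongly
  preload-sensitive, which is the substrate of the Frank–Starling
  compensation the model predicts for HTxR.

**Valves** are ideal diodes with opening resistances (4–6×10⁻³); the
aortic valve drains through an additional characteristic resistance
(0.015) whose ejection pressure drop is included in the reported root
aortic pressure, widening systolic pressure at high flow without
touching the windkessel decay.

**Respiration** is a kinematic sin² waveform: intrathoracic pressure
−2 to −4.5 mmHg at rest (swing grows with the square root of tidal
volume, up to ~−12 mmHg at peak exercise), abdominal pressure +2 to
+3, lung volume FRC 2.3 L + tidal volume (0.5 L rest → 2.0 L peak),
period 5 s at rest falling linearly to 1.2 s at peak intensity.

## Sinoatrial cell

A reduced six-state Hodgkin–Huxley formulation: membrane potential,
four gates (funny-current activation y, L-type activation d and
inactivation f, delayed-rectifier activation n) and an intracellular
Ca²⁺ pool.  Currents: I_f, I_CaL (with Ca-dependent inactivation),
I_K, muscarinic I_KACh (inwardly rectifying), a small background
current and the Na/K pump.  The pacemaker clock is the slow activation
of y at diastolic potentials (τ up to ~2.9 s) against a balanced
background; deactivation at depolarized potentials is fast, so each
action potential resets the clock.

Autonomic modulation uses saturating receptor occupancies
`ach/(ach+30)` and `iso/(iso+30)` (concentrations in arbitrary model
units): ACh activates I_KACh, shifts y-activation negative and reduces
the L-type conductance; Iso shifts y-activation positive, raises the
L-type conductance, speeds gate kinetics and Ca²⁺ reuptake, and
slightly inhibits the pump.  The calibrated cell paces at 74.0 bpm with
both factors at identity (within the measured 73 ± 3 bpm of isolated
human SA cells) and spans ~39 bpm (ACh 50) to ~180 bpm (saturating Iso)
monotonically — the range the controller actually uses.

Beats are action-potential peaks (local V_m maxima above −20 mV with a
0.15 s lockout); instantaneous HR is 60/RR and the latched RR drives
chamber activation piecewise-constant per beat.

## Autonomic controller

Afferents: a saturating sigmoid of (low-pass filtered, τ = 2 s) aortic
pressure around the operating point P_set (91 mmHg rest, +90 % at peak
exercise, linear in intensity), with the standard firing range
2.52–47.78 spikes/s; pulmonary stretch firing proportional to lung
volume (11.76 spikes/s per L).  Efferents: sympathetic firing decays
exponentially in the net afferent drive; vagal firing is a rising
sigmoid of baroreceptor firing.  Central command enters additively
(sympatho-excitatory, vagal-inhibitory), and lung stretch weakly
inhibits both (vagal more), producing respiratory sinus modulation and
contributing to vagal withdrawal during hyperpnea.

Effectors are first-order blocks with logarithmic static
characteristics of sympathetic firing: peripheral resistance (τ 6 s),
venous unstressed volume (τ 20 s), ventricular contractility (τ 8 s).
The heart-period effector is replaced by neurotransmitter kinetics:
sympathetic firing maps linearly to an Iso increment (τ 2 s), vagal
firing to an ACh increment (τ 1.5 s), each added to the calibrated
basal concentration; total Iso at the SA node additionally includes
circulating catecholamines.  Pure conduction delays of the source
formulation are omitted (steady-state windows are the quantity of
interest); time constants are retained.

Exercise-specific elements, with the design reasoning:

* **Metabolic vasodilation** is a saturating function of intensity
  (63 % of its ceiling by 25 % MTP), reaching −50 % peripheral
  resistance in the healthy cohort at peak; HTxR capacity is 10 %
  lower.  A linear map cannot reconcile the HTxR peak cardiac output
  (13 L/min at 50 % MTP, MAP ≈ 116 mmHg) with the healthy peak
  vascular resistance (≈ 0.45 mmHg·s/mL at 100 %): both cohorts must be
  near-fully dilated at moderate absolute workload, which is also the
  physiologic behaviour of exercising muscle beds.
* **Adrenal catecholamines** follow a first-order system (τ 30 s)
  whose static map is zero below 15 % intensity and rises as
  `((I − 0.15)/0.85)^1.1` above it.  The threshold reproduces the
  observed division of labour: below ~20 % MTP the healthy HR response
  is dominated by vagal withdrawal, above ~30 % by adrenergic drive —
  and it is the sole HR reserve of the denervated cohort.
* **Muscle pump**: rhythmic compression of exercising-limb veins is
  expressed as a mean venous pressurization (5.3 mmHg at full
  activation, same saturating activation as vasodilation, τ 25 s).
  Without it the left ventricle cannot reach the measured peak
  end-diastolic volumes at heart rates where diastole is ~0.1 s.
* **Circulating catecholamines act on the myocardium** (inotropy and,
  through the contractility scale, lusitropy) regardless of cardiac
  innervation — β-receptors survive denervation; receptor
  supersensitivity is deliberately not modelled.
* **Arterial compliance** falls linearly with intensity (−60 % at
  peak), reproducing the systolic pressure rise of heavy exercise.

## Cohorts and calibration

The healthy configuration is the reference; `build_htxr` applies the
documented delta list exactly (vagal HR gain ×0, sympathetic HR and
elastance gains ×0.05, peripheral resistance ×1.15, systemic
compliances ×0.8, vasodilatory capacity ×0.9, peak intensity 0.5).
Every parameter carries a provenance tag in the shipped YAML:
`paper` (printed value), `cited-model` (controller/afferent constants
and standard physiologic values), `calibrated` (free parameter tuned to
the pooled cohort working points).

Basal neurotransmitter tone is set by a deterministic bisection on a
scalar tone index along a fixed ray (raise Iso if the zero-tone
closed-loop HR is below target, else raise ACh), to 0.2 bpm — a
reproducible substitute for tuning the tone by hand.  The shipped values are (ACh 0, Iso 10.16) healthy and
(ACh 0, Iso 10.94) HTxR.  The healthy ray terminates with zero *basal*
ACh because the intact closed-loop reflex already supplies ~15 units of
vagal ACh at rest.

Body surface area is not derivable from the printed demographics (BMI
only); it is shipped as a calibrated cohort parameter (1.935 m²
healthy, 2.063 m² HTxR, plausible for the reported BMIs) chosen so the
resting end-diastolic volume index matches the pooled imaging values
(65.7 / 51.9 mL/m²).

## Numerics

The coupled 23-state system is advanced by fixed-step RK4 (default
0.5 ms) in a compiled (numba) loop; sinoatrial peaks are detected
on-line and reset the activation clock between steps, so the discrete
beat events never interact with the RK stages.  The fastest time
constants of the assembled system are ~2 ms (L-type gate, valve-loaded
chambers), placing the step well inside the stability and accuracy
region: halving it changes the 300-s mean HR by < 0.05 bpm and summary
hemodynamics by ≪ 1 % (tested).  Runs are bit-reproducible.  Output is
sampled at 100 Hz.

Summary windows follow the clinical definitions: HR as the mean of
reciprocal RR intervals; MAP as the time-average of aortic pressure;
SBP/DBP as per-beat aortic extrema averaged over beats; CO as mean LV
outflow; SV as per-beat end-diastolic minus end-systolic volume; SVR as
the average controlled systemic resistance; LVEDVI as mean per-beat
end-diastolic volume over BSA.  End diastole is operationalized as the
last zero-activation sample before the ventricular upstroke (atrial
kick included): at 100 Hz and heart rates above ~160 bpm the raw
per-beat volume maximum can fall on the contraction upstroke and
corrupt the end-diastolic pressure by tens of mmHg.  Each 300-s
analysis window discards its first 60 s as transient; exercise holds
are preceded by a 120-s settling segment at the target intensity
(shortened protocol; the full 10 %-step staircase is also available and
is exercised in the test suite).

## What the simulations do and do not show

All quantities are produced by the deterministic closed loop — there is
no synthetic noise, no sampling variability, and no virtual-patient
heterogeneity.  Agreement with pooled clinical means therefore shows
that the mechanistic structure can occupy the cohort working points,
not that it captures between-patient variance (comparisons use the
pooled SD only as an acceptance band).  Known limitations: no diastolic
dysfunction (the end-diastolic P–V relation is shared by both cohorts,
i.e. a well-preserved early graft), no reinnervation dynamics, no
heart-rate variability or chemoreflex, no ventricular interaction, a
single systemic vascular bed (so regional flow redistribution is
implicit in the lumped resistance), and medication effects enter only
implicitly through the calibrated parameter values.  The healthy
peak-exercise MAP runs high against the pooled data, reflecting that
peak MAP, CO and controlled SVR cannot all be matched simultaneously in
any single-node Ohmic circuit.
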