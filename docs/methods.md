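# Methods

## Scope and state variables

`coldpath` models the intracellular relay from a cold-triggered cytosolic
Ca²⁺ signal to the expression of the cold-acclimation transcription factor
CBF3 and its feedback repressor ZAT12. The pathway state comprises 14
concentrations (nM): the CaM-activated kinases CRLK1a and CRPK1a, the
phosphorylated MAP kinases MPK6P and MPK4P, ICE1 and ICE1P, phosphorylated
(inactive) MYB15, nuclear HOS1, phosphorylated 14-3-3 (TTFP), *CBF3* mRNA,
CBF3 protein (free and phosphorylated) and *ZAT12* mRNA and protein. Time is
in hours everywhere except inside the Ca²⁺ oscillator, which runs in seconds
and converts at its interface.

Temperature never appears as a continuous variable. A cold event enters the
model in exactly three ways: its Ca²⁺ signature, the cold/warm switch of the
maximum *CBF3* mRNA degradation rate `v_d3` (0.55 vs 5.5 nM/h, the warm
value implied by the measured 7.5-min transcript half-life), and —
optionally — the circadian gate on *CBF3* transcription. Nucleo-cytoplasmic
compartments are represented only through the HOS1n and TTFP states; there
is no spatial or stochastic simulation.

## Rate laws

The kinetic forms are the canonical choices of this modeling lineage:

- CaM activation: Hill function of Ca²⁺ with fixed coefficient 4,
  half-activation `K_CaM = 500 nM` (basal 100 nM Ca²⁺ activates < 0.5% of
  CaM; the 1000-nM crest of the default shock pulse activates ~94%).
- CRLK1/CRPK1: bimolecular activation by the CaM fraction on the free form,
  first-order inactivation.
- Every phosphorylation/dephosphorylation cycle (MPK6, MPK4, MYB15, 14-3-3,
  ICE1): Michaelis–Menten conversion on a conserved total; only the modified
  form is a state variable, so conservation holds by construction.
- MPK4 antagonism: the MPK6P-catalyzed ICE1 phosphorylation flux is
  multiplied by `K_I4 / (K_I4 + MPK4P)` — the simplest realization of an
  inhibition of ICE1 activation.
- HOS1 action: ICE1P is degraded at rate
  `(v_d1·HOS1n/(K_H+HOS1n) + v_d1_basal) · ICE1P/(K_dI+ICE1P)`; the basal
  term keeps ICE1P turning over before stress, the saturable HOS1n term
  bounds the cold-enhanced degradation.
- Transcription: Hill n = 2 activation (ICE1P on *CBF3*, CBF3 protein on
  *ZAT12*) and repression (free MYB15 and ZAT12 protein on *CBF3*); mRNA and
  protein degradation are Michaelian, plus a linear term for ZAT12 protein.
- The 14th state, phosphorylated CBF3 protein, makes "marking for
  degradation" by 14-3-3 an explicit two-step process (phosphorylation, then
  faster turnover) rather than a modulated rate.

## Ca²⁺ drivers

A single cold shock is an instantaneous rise of amplitude `A = 900 nM` above
a 100 nM basal level followed by exponential decay at `k_Ca = 30/h`, so the
pulse is 95%-over in 6 min (validation enforces 2–15 min). Integration
restarts at the jump.

Spike trains come from the classic two-variable Ca²⁺-induced-Ca²⁺-release
(CICR) oscillator (cytosolic Ca²⁺ `Z`, store Ca²⁺ `Y`; pumping Hill n = 2,
release activated by `Y²` and `Z⁴`), driven by a stimulus fraction β that
jumps at the shock and decays exponentially. The parameter set is the
canonical one rescaled to nM with the basal level at exactly 100 nM
(`v0/k_out`), and all rates divided by a time-scale factor (default 25,
folded together with a fixed reference retuning) so that the interspike
interval at constant mid-range stimulus (β = 0.5) is 150 s, as observed in
plant guard cells. The oscillatory range is β ≈ 0.26–0.77, so a decaying
envelope produces a terminating train whose spike count grows as the
envelope decay slows.

Two deliberate deviations from observed spike statistics are documented
here. First, the model's spikes peak above 1 µM rather than the ~125 nM
amplitude reported for guard-cell oscillations: with calmodulin activation
shared between the pulse and train pathways (K_CaM = 500 nM, Hill 4),
125-nM spikes over a 100-nM basal level would be invisible to CaM and no
train could drive the pathway, contradicting the train-response and
AUC-equivalence behaviors; period and basal level are treated as the binding
constraints. Second, AUC equivalence — that a single pulse carrying the same
Ca²⁺ area as a train elicits a closely matching *CBF3* peak — holds within
15% for canonical few-spike trains (envelope decay ≥ 4/h). For much longer
trains (e.g. decay 2.1/h, ~12 spikes over ~0.6 h) the cascade
duration-codes the input and the train response exceeds any admissible
matched pulse (one that is over within half an hour) by ~35%. Matched
pulses default to the slowest admissible decay (6/h).

## Parameters

Directly anchored values are frozen and never calibrated: ICE1 synthesis
`v_s1 = 0.18 nM/h`, ZAT12 maximum transcription `v_s3 = 2.2 nM/h`, totals
`HOS1_t = MYB15_t = 2 nM`, and `v_d3 = 0.55 / 5.5 nM/h` (cold/warm). Mutant
lines override exactly these: *ice1* `v_s1 → 0.036`, HOS1-OX `HOS1_t → 10`,
*myb15* `MYB15_t → 0.2`, ZAT12-OX `v_s3 → 11`; ICE1-OX scales `v_s1`
five-fold (0.9 nM/h), mirroring the five-fold convention of the other
overexpression lines.

All remaining constants were chosen once, by constrained search, so that the
default set simultaneously satisfies every response window the model is
tested against: wild-type shock peak 1–6 h after the pulse, 20–500-fold
induction, 3–6 h half-width; a unique, stable unstressed steady state with
CRLK1 < 10% active, MYB15 mostly unphosphorylated and basal *CBF3* mRNA
< 5% of the shock peak; biphasic ICE1P; strict desensitization under 3-h
warm–cold cycles with full recovery at 24 h (the ICE1 pool depletes during
each response and refills with a ~11-h time constant, which is the mechanism
of desensitization — the Ca²⁺ pulses are identical by construction);
and a sustained CBF3/ZAT12 limit cycle of ~31 h period under the
oscillation-regime overrides
(`K_a2=0.55, K_I2=0.8, K_I3=0.2, K_d3=1.8, k_s1=0.25, v_d5=3.8, v_s3=3.5,
K_a3=0.8, v_d6=3.2, k_s2=0.55, v_d7=3.65, k_d7=0.1`). The joint constraint
set pins several otherwise-free choices: fast CaM-driven activation
(`k_a_crlk = 60/h`, inactivation 3/h) so the ~2-min CaM transient saturates
CRLK1a; fast MYB15 rephosphorylation/dephosphorylation so the transcription
window closes within a 90-min cold phase; a high-capacity, saturable CBF3
protein sink (`v_d5 = 14, K_d5 = 4 nM`) whose saturation under the
oscillation overrides provides the switch-like protein rise that drives the
feedback oscillation; and a near-zero-order ZAT12 protein turnover
(`K_d7 = 0.1 nM`) that supplies the delay the oscillator needs, with a
strong linear term (`k_d7 = 1/h`) in the wild type keeping the basal and
mutant states stable. `calibration.validate` re-measures every constraint;
`calibration.calibrate` reproduces the search (log-uniform proposals around
the defaults, deterministic per seed, literature-anchored values frozen).

## Circadian gate

The clock is phenomenological: `C(t) = (1 + sin 2π(t − φ)/24)/2` read out
through a Michaelian gate `g = C_0 + (1−C_0)·C/(K_c + C)` with
`K_c = 0.15` and floor `C_0 = 0.01`, multiplying `v_s2`. This form gives
small-amplitude basal *CBF3* oscillations without stress, a hard floor at
the clock trough, and a phase-confined window of responsiveness. The offset
`φ = 0.86 h` was calibrated once so the unstressed basal *CBF3* maximum
falls at ZT8, then frozen. The light–dark cycle itself is not modeled; ZT is
simulation time modulo 24 h. The phase-response scan entrains for 72 h
(three full cycles) before applying the pulse and reports the permissive
window as the phases reaching ≥ 80% of the maximal response.

## Numerics

Production integration uses LSODA with `rtol = 1e-8`, `atol = 1e-10 nM`
(overridable), restarting at every driver discontinuity (pulse onsets,
temperature-phase switches) so no jump falls inside a solver step; a failed
segment is retried once with BDF at 100-fold tighter tolerances. Negative
excursions at tolerance level are clamped to zero in reported trajectories.
Steady states are found by settling integration plus Newton polishing, and
in the multi-start search by 200 (default) log-uniform starts within
[1e-3, 1e3] × a per-variable scale, duplicates merged at 1e-6 relative
tolerance, acceptance by residual < 1e-8 nM/h. The Jacobian is central
finite differences with step `1e-6·max(|x|,1)`; eigenvalue classification
uses a 1e-9 tolerance on real parts. Limit-cycle detection integrates past a
400-h transient and classifies by peak-interval statistics (≥ 3 maxima,
interval CV < 2%, amplitude > 1e-3 of the mean; drifting amplitudes report
"transient"), which is adequate for the single-frequency cycles this model
produces; no Poincaré return maps or continuation methods are used. Peak
metrics interpolate half-height crossings linearly and resolve plateau
maxima to the earliest time. Zero or negative rate constants, totals and
Hill exponents are rejected at construction rather than simulated.

Default problem sizes keep every analysis interactive: shock runs span
40–102 h at 0.01-h output, cycle protocols 18–120 h, limit-cycle detection
800 h, and the phase-response scan samples 24 phases of ~110 h each; all
tests and the acceptance script complete in well under a minute each on one
core.

## Known limitations

- Most kinetic constants of this pathway have never been measured; the rate
  laws are canonical forms and the shipped constants are calibration outputs
  constrained by the experimentally observed response windows, not
  measurements.
- The reconstruction yields a unique steady state in the explored parameter
  regions (the negative-feedback architecture provides no bistability);
  reported multistability of low/high-CBF3 branches in this pathway is not
  reproduced, although the multi-start machinery would find and label
  coexisting states if a parameter set produced them.
- Under the ablation `K_I3 → ∞` in the oscillation regime, transcription
  exceeds the saturable mRNA degradation capacity and *CBF3* mRNA grows
  without bound — the model has no brake other than ZAT12 there; the
  detector correctly reports the absence of oscillation.
- Spike amplitude and long-train AUC equivalence trade off against each
  other as described above.
- Mutants are parameter overrides on an otherwise identical background;
  compensatory regulation, growth effects and COR-gene readouts are out of
  scope, as are vernalization and an explicit mechanistic clock.
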