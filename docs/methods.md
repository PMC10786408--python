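# Methods

`spinocereb` simulates trial-and-error motor learning of planar arm
movements by a spiking cerebellar network operating through a spinal-cord
reflex circuit onto a muscle-driven two-joint arm, all in closed loop with
biologically motivated latencies.  This note documents the models, the
numerical choices, the defaults that matter, and the limits of what the
synthetic experiments can show.

## Control loop and delays

At every 1 ms step the cerebellum receives the desired joint state
(position and velocity per joint) and the actual state of the arm, the
latter delayed by the 50 ms sensory latency of the proprioceptive pathway.
The desired reference is read at the same delayed time stamp, so a
perfectly tracking arm produces a zero teaching signal.  The cerebellar
motor commands (a flexor/extensor pair `M_f`, `M_e` per joint) travel with
a 30 ms delay to the spinal circuit, whose muscle excitations reach the
muscles after a further 30 ms (total motor delay 60 ms).  The stretch-reflex
feedback delay (30 ms) is applied inside the spinal circuit to the Ia
afferent stream only; descending-path delays are owned by the loop.

A trial is one pass over the task trajectory.  Between trials the arm is
reset to the trajectory start pose; membrane potentials, synaptic weights,
eligibility traces and all delay lines persist, as in a continuously
running nervous system.  (A consequence worth noting: consecutive
plasticity-off trials are only asymptotically identical — the neural state
approaches a limit cycle rather than being reset.)

Variants: `full` (complete spinal circuit), `sr` (stretch reflex only),
`ri` (reciprocal inhibition only) and `bypass` (cerebellar commands applied
directly as muscle excitations — the "cerebellar-only" control).

## Cerebellar network

Sizes at full scale: 80 mossy fibres (MFs), 20 000 granule cells (GCs),
200 Purkinje cells (PCs), 200 climbing fibres (CFs), 200 deep-nuclei
neurons (DCN); MF→GC 80 000 synapses, GC→PC 4 000 000, MF→DCN 16 000,
and one-to-one PC→DCN, CF→PC and CF→DCN (AMPA + NMDA) wiring.  The network
splits into one microcomplex per joint, each divided into agonist (flexor)
and antagonist (extensor) regions of the PC–CF–DCN loop.

*Input coding.*  Each of the four signals per microcomplex (desired and
actual position and velocity of its joint) is place-coded: its working
range is split into `n_mf_per_signal` half-open bins and exactly one MF per
signal is active per step, firing one spike per step while selected.
Working ranges are derived from the task trajectory (min/max padded 10 %),
which guarantees in-range coding for any task; out-of-range values clamp
to the edge bins.  Each GC receives a unique combination of one MF per
signal, so a single GC per microcomplex matches the full input combination
at any instant — a univocal sparse recoding of the sensorimotor state.

*Neurons.*  All populations are conductance-based leaky integrate-and-fire
neurons stepped at 1 ms with exponentially decaying AMPA/GABA/NMDA
conductances (NMDA is modelled as a slow excitatory conductance, without a
voltage-dependent block).  The published neuron constants were not
available, so the defaults were chosen to make each stage functional and
are all overridable:

* GC (`tau_m` 5 ms, `g_leak` 4 nS, threshold −50 mV): four coincident
  active afferents are suprathreshold, three are not, preserving the
  combinatorial selectivity of the granular layer.
* PC (`tau_m` 10 ms, `g_leak` 4.5 nS, AMPA tau 5 ms): firing rate grows
  monotonically with the GC-PC weight of its currently active parallel
  fibres, from silent (fully depressed) to ~300 Hz (weight ceiling).
* DCN (`tau_m` 10 ms, `g_leak` 2 nS, GABA tau 50 ms): tonically driven by
  the MF baseline, and gated by its PC through slow, strong inhibition, so
  Purkinje depression disinhibits the output — the classic cerebellar
  disinhibition channel.  With initial GC-PC weights (4.3–5.2 nS) the DCN
  is largely suppressed and motor commands start near zero.

Initial membrane potentials are drawn uniformly over the subthreshold
range (seeded).  This desynchronises the otherwise phase-locked spike
volleys of identical neurons, which matters: with synchronous volleys the
population rates are quantised step functions of the synaptic weight,
whereas desynchronised populations give smoothly graded rates and hence a
usable motor-command resolution.

*Teaching signal and plasticity.*  The per-joint instructive signal is
`eps = K_p (Q_d − Q_a) + K_v (Qd_d − Qd_a)` with `K_p = 3`, `K_v = 1`.
Its magnitude maps through a saturating ramp (saturation at |eps| = 1,
ceiling 10 Hz — complex-spike physiology) to a per-step CF spike
probability; its sign routes the spikes to the agonist (eps > 0) or
antagonist (eps < 0) region of the joint's microcomplex.

GC-PC synapses follow a CF-gated two-term rule: every PF spike adds a fixed
LTP quantum `alpha = 0.006 nS` to its synapses, and every CF spike at PC j
subtracts `|beta| = 0.003 nS` times an eligibility trace from all synapses
onto j.  The eligibility trace is a delayed-peak (difference of
exponentials, rise 50 ms, decay 250 ms) kernel over each GC's recent
spikes; its peak lag (~100 ms) matches the sensorimotor loop latency, so a
CF spike credits the PF activity that caused the error.  The kernel's peak
amplitude (`kernel_gain`, default 2.5 eligibility units per spike) sets the
LTD/LTP balance and thereby the residual teaching-signal rate at the
learning equilibrium; much larger values make depression outrun the slow
LTP recovery and drive the weights to the floor (maximal co-contraction),
much smaller values leave a large residual error.  Weights are clipped to
[0, 15] nS.  Initial weights are uniform-random in [4.3, 5.2] nS, or
homogeneous 4.8 nS for synaptic-adaptation comparisons.

*Output decoding.*  Per-region mean DCN firing rate, exponentially
smoothed (tau 250 ms by default) and normalised by a 250 Hz ceiling,
clipped to [0, 1]: agonist region → `M_f`, antagonist → `M_e`.  The
smoothing constant trades command bandwidth against spiking noise: with
only tens of DCN cells per region the instantaneous rate estimate is
noisy, and that noise is amplified roughly three-fold by the steep spinal
sigmoid cascade, so a long rate-estimation window lowers the closed-loop
error floor for every variant; the sensorimotor state code (which includes
the desired state) lets the learned commands compensate the added lag.

## Spinal circuit

One motoneuron (MN) per muscle and one Ia inhibitory interneuron (Ia IN)
per muscle, all leaky rate neurons `tau dr/dt = −r + sigma(sum w_i r_i(t −
tau_i))` with `tau = 1 ms` (fast-response neurons) and the on-off sigmoid
`sigma(x) = 1/(1+exp(−8(x−0.5)))`.  The update uses the exponential
integrator, which is exact for input held constant over a step.  Muscle
excitation is `u = sigma(r_MN)`.

MN inputs: the descending command (weight 1.0), the muscle's own Ia
afferent (stretch reflex, weight 1.0, delayed 30 ms), and the antagonist's
Ia interneuron (reciprocal inhibition, weight −0.5).  Antagonist Ia INs
also inhibit each other (−0.5).  Antagonist pairs cover all eight muscles
within joints: DELTant↔DELTpost, BIClong↔TRIlong, BICshort↔TRIlat,
BRA↔TRImed.  Biarticular muscles receive the mean of their two joints'
descending commands.

Ia afferents follow Prochazka's spindle model (lengths mm, velocities
mm/s): `r_Ia = sgn(v)·4.3·max(|v|, 0.01)^0.6 + 2 (l − l0) + 10`, giving the
physiological 10 Hz baseline at rest.  Rates are normalised to [0, 1] by a
per-task maximum `r_Ia,max`, computed from the task's muscle-kinematics
envelope with the velocity envelope inflated (default ×3) and 10 % padding.
The inflation reflects that actual movements overshoot the desired profile
before learning converges; it also keeps the loop gain of the delayed
stretch reflex below its oscillation threshold.  With weaker normalisation
the 30 ms-delayed velocity feedback through the steep sigmoid produces a
sustained tremor-like limit cycle.

## Arm plant

A rigid two-link pendulum in the vertical plane (hanging position is the
zero configuration, flexion positive), with standard adult segment
parameters (defaults, not ground truth) and viscous joint damping
0.5 N·m·s/rad standing in for unmodelled soft-tissue dissipation.  Eight
Hill-type muscles act through constant moment arms; muscle-tendon length is
linear in joint angle, making joint torque exactly virtual-work consistent
with the kinematics.  Muscle force is
`F_max (a·f_l(l)·f_v(v) + f_p(l)) cos(theta)` with a Gaussian force-length
curve (width 0.4 l0), a Hill force-velocity curve (max shortening 10 l0/s,
eccentric plateau 1.5), an exponential passive curve (zero at or below l0,
reaching F_max at 1.6 l0), and first-order activation dynamics with
`tau_act = 10 ms`, `tau_deact = 40 ms`.  Integration is semi-implicit Euler
at 1 ms; joint limits clamp with zeroed velocity.  External hand forces
(perturbations: 50 N for 30 ms by default) map to joint torques through
the hand-Jacobian transpose.

A note on conventions: because cerebellar output works by *disinhibition*,
a silent motor command corresponds to strong PC activity (high GC-PC
weights), not to zero weights; a zero-weight network drives the muscles
maximally.  Tests that need a passive arm therefore saturate the weights.

## Metrics

Per-trial MAE of position and velocity (joint-averaged, then
time-averaged).  Learning convergence uses the control chart: over a
sliding 200-trial window, at least 75 % (position; 73 % velocity) of trials
within mu±sigma, at most 3 % in the 2–3 sigma band, at most 2 % beyond 3
sigma, and sigma at most 0.012 rad (0.055 rad/s).  A zero-variance window
counts as stable.  Learning speed is the reciprocal of the number of trials
needed to reach 0.1 rad (0.5 rad/s) — assessed on a short 20-trial trailing
mean purely to suppress single-trial noise.  Synaptic adaptation is
quantified by the Shannon entropy of the GC-PC weight matrix treated as an
image (normalised to [0, 1] by the 15 nS bound, 256 bins) and by the
percentage of synapses that moved more than half one LTP quantum from their
initial value.  The cocontraction index per joint is
`CCI = (min/max)(min+max)` over the mean agonist-group and
antagonist-group activity (0 where both groups are silent); model CCI uses
muscle activations, with groups DELTant+BIClong / DELTpost+TRIlong
(shoulder) and BIClong+BICshort+BRA / TRIlong+TRIlat (elbow), biarticular
muscles counted at both joints.  Perturbation robustness is the mean
|MAE − baseline| over the perturbed trials.  EMG envelopes: mean removal,
full-wave rectification, zero-phase 5th-order Butterworth low-pass at 5 Hz,
optional normalisation by the identically processed maximal-voluntary-
contraction maximum.  Group comparisons: two-sample t-test for two groups;
Kruskal-Wallis followed by a hand-implemented Dunn rank post-hoc (with tie
correction, optional Holm adjustment) for four.

## Synthetic data

No human recordings ship with the package.  The benchmark tasks are
cyclic flexion-extension movements built from fifth-order minimum-jerk
segments (the standard bell-shaped-velocity model of reaching), default
endpoints shoulder 0.3→1.1 rad, elbow 0.4→1.6 rad, periods 3 / 2.3 / 1.5 s.
Synthetic EMG is a 20–450 Hz band-limited noise carrier amplitude-modulated
by Gaussian bursts locked to movement phases (default 1259.3 Hz sampling),
returned with its ground-truth modulation envelope so the envelope
extractor can be validated against a known answer.  These generators
emulate the statistical structure, not participant-specific morphology:
passing tests show the pipeline is correct and the model comparisons hold
under controlled conditions; they do not certify behaviour on real
recordings with electrode artefacts, non-stationary noise or marker
dropouts.

## Experiment scale

Closed-loop experiments in the test suite run at reduced scale — 5 MFs per
signal (1250 GCs), 40 PCs, the 2.3 s task, 300 trials, three seeds — which
keeps a full variant-comparison study within minutes on one CPU.  Model
comparisons at this scale are asserted directionally by seed majority.
Relative to the full-scale 2000-trial setting, the reduced state-space
resolution (5 bins per signal) raises the achievable error floor, and 300
trials capture only the early part of the adaptation curve.

## Known limitations

* The planar arm is a parametric stand-in: no tendon elasticity, wrapping
  geometry, or 3-D dynamics; moment arms are constant.
* NMDA kinetics are a slow exponential conductance without magnesium-block
  voltage dependence.
* CF→PC synapses carry zero conductance (their role is plasticity gating),
  so complex-spike somatic effects on PC firing are not modelled.
* The spinal circuit has no Ib (Golgi tendon) pathway, no presynaptic
  inhibition, no motoneuron pool recruitment.
* Learning equilibrium depends on the LTP/LTD balance through the
  eligibility-kernel amplitude, which is a free constant here; only its
  order of magnitude is constrained by requiring stable convergence.
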