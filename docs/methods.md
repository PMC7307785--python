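# Model and methods

## The cell

The default neuron is a chain of four cylindrical sections — axon
(500 µm × 0.1 µm), soma (15 µm × 15 µm), proximal dendrite (50 µm × 2 µm)
and distal dendrite (500 µm × 0.5 µm; 1.0 µm in the IFR-heatmap protocol)
— discretised into 10/10/10/20 compartments respectively.  Because the
two dendrites and the axon hang off opposite ends of the soma, the
compartment graph is a single unbranched chain and the implicit cable
solve is tridiagonal.  Soma dimensions, the compartment counts, the
specific capacitance (1 µF/cm²) and the axial resistivity (100 Ω·cm) are
model choices, exposed through build overrides; total section area and
volume are exactly the analytic cylinder values at any discretisation,
and refining the grid does not change them.

Membrane potential obeys `Cm·dVm/dt = −ΣI` plus axial coupling.  Each
step performs a backward-Euler tridiagonal solve for voltage with all
conductances evaluated at the already-updated gating/synaptic state
(staggered update; mechanisms are linear in V within a step), then an
explicit update of the ion mass balances.  The default step is 0.025 ms;
halving it changes a 1 s somatic trace by < 0.5 mV RMS (tested).  The
integration loop is JIT-compiled with numba.

## Currents

* **Leaks.**  Ohmic K⁺, Na⁺, Cl⁻ leaks with a fixed density ratio
  1 : 0.23 : 0.4 and a common scale fitted so that a −10 pA, 500 ms
  somatic step measures an input resistance of 365 MΩ
  (`calibration.tune_leaks`: analytic passive bracketing followed by
  secant refinement against the simulated protocol).
* **Axonal spike channels.**  `INa = m³h·gNa(V−ENa)`,
  `IK = n·gK(V−EK)` (single-exponent n gate as the model's formulation
  prints it; the classical n⁴ form is available via
  `SimulationConfig.n_exponent=4`), and an adaptation M-current
  `IM = m_M·gM(V−EK)` with a first-order gate
  (τ_max = 500 ms, Pospischil-style voltage dependence).  The rate
  functions are the standard Traub squid-derived α/β forms with threshold
  shift VT.  The kinetics behind these currents are not fully constrained
  by the source model, so VT = −63 mV, gNa = 0.1 S/cm², gK = 0.002 S/cm²,
  gM = 2×10⁻⁴ S/cm² were calibrated once against two behavioural anchors:
  the cell must spike reliably from distal drive, and the 250:300 E:I
  reference configuration at 5 Hz balanced input must fire at ≈ 5 Hz.
  With the single-exponent n gate the delayed rectifier has a sizeable
  subthreshold open fraction, which is why gK is an order of magnitude
  below textbook n⁴ densities.
* **KCC2.**  Extrusion rate `V = P·([K⁺]i[Cl⁻]i − [K⁺]o[Cl⁻]o)` per
  compartment, with P expressed as a current-type density
  (100 % = 1.9297×10⁻⁵ mA·mM⁻²·cm⁻², the conversion
  `P_current = P_conc·F·Vol/Area` over the reference whole-cell geometry
  of 1.058 pL / 529×10⁻⁸ cm²).  KCC2 transport is **electroneutral by
  default**: it moves Cl⁻ (and, in dynamic-K⁺ mode, K⁺) in the mass
  balances but carries no membrane current.  This is both the transport
  stoichiometry of the real cotransporter (1 K⁺ : 1 Cl⁻ out) and a
  consistency requirement: a Cl⁻-only extrusion current of
  ~1 µA/cm² at rest would depolarise the resting potential by ~5 mV,
  contradicting the −71.35 mV default rest.  A charge-carrying variant is
  available (`SimulationConfig.kcc2_electrogenic`).

## Chloride (and potassium) dynamics

The per-compartment balance combines (i) transmembrane Cl⁻ currents —
leak and the 4/5 Cl⁻ share of GABA_A currents — converted by
`I·Area/(F·Vol)`, (ii) KCC2 extrusion, and (iii) longitudinal diffusion
(D_Cl = 2.03 µm²/ms, free-solution value) as a conservative second-order
finite difference between compartment midpoints with sealed ends;
interface cross-sections at diameter jumps use the mean of the adjoining
areas, which keeps total Cl⁻ amount exact to round-off (tested to 10⁻⁸
over 10⁶ steps).  Signs are normalised so synaptic/leak Cl⁻ influx raises
[Cl⁻]i and a positive KCC2 bracket lowers it; a literal reading of the
combined equation would let extrusion load the cell, which contradicts
its role, so the normalised convention is used deliberately.  ECl and
EGABA are recomputed from [Cl⁻]i every step (Nernst; EHCO3 fixed, with
intracellular/extracellular bicarbonate 12/23 mM in the model and 10/25 mM
offered for analysing perforated-patch data).  `static` chloride mode
freezes every [Cl⁻]i at its initial value and computes EGABA once.

In **dynamic-K⁺ mode** [K⁺]i becomes a state: KCC2 exports one K⁺ per
Cl⁻ (zero net charge), the ionic leaks are replaced by one passive
conductance reversing at the tuned resting potential, and constant tonic
fluxes equal to the initial extrusion rate hold the rest state as a fixed
point.  Axonal K⁺ spike currents do not feed the K⁺ mass balance; the
mode captures the first-order effect of K⁺ co-transport on EK and on the
KCC2 driving product during chloride loading.

## Synapses and stimuli

Excitatory f-in synapses are mixed AMPA+NMDA (dual exponentials, unit
peak; τ 0.2/1.7 ms and 2.04/75.2 ms), g_max = 1 nS per synapse with 15 %
of it assigned to NMDA (equal-split was far too excitatory for the 5 Hz
anchor; the fraction is config-exposed), and the Mg²⁺ unblock sigmoid
`1/(1 + ([Mg]/3.57)·e^(−0.062·V))` at 1 mM Mg²⁺.  Inhibitory f-in
synapses are kinetic GABA_A receptors (α = 5 mM⁻¹ms⁻¹, β = 0.18 ms⁻¹,
g_max = 350 pS) driven by a 1 mM × 1 ms transmitter pulse per presynaptic
event; their current is split 4:1 between Cl⁻ (local, dynamic ECl) and
HCO₃⁻ (fixed EHCO3), so the Cl⁻ component feeds the mass balance.  Each
synapse receives an independent Poisson train (exponential ISIs, so the
ISI standard deviation equals the mean), seeded through a spawning
sequence so adding recorders or synapses elsewhere never perturbs a
train.  Synapses are placed at the midpoints of equal subdivisions of
their target section ("evenly distributed").

gclamp drives are Ornstein-Uhlenbeck conductances (exact one-step
updates, correlation time 10 ms), mean = 0.0001 µS × relative
conductance, CV = 0.1, emitted conductance clipped at zero.  Ten sites
per population are spread evenly over the target section; inhibitory
sites use the local dynamic EGABA with the same 4:1 anion split (a
legacy fixed −74 mV reversal is available).  When chloride is static,
EGABA is derived once from the frozen concentrations (−77.41 mV at
defaults) rather than the legacy constant, which resolves the small
tension between the two conventional values in favour of thermodynamic
consistency.

## Calibration pipeline

The recovery experiment is modelled as a Cl⁻-loaded cell relaxing toward
baseline under KCC2 extrusion against a constant tonic Cl⁻ influx that
holds the baseline.  That choice makes the recovery exactly
single-exponential with rate P·[K⁺]i — matching the single-exponential
fits applied to the recordings — and makes the extrusion-rate regression
exact: fitting `baseline + A·e^(−t/τ)`, differentiating analytically, and
regressing the rate on the bracket [K⁺]i[Cl⁻]i − [K⁺]o[Cl⁻]o yields a
slope of exactly P with the tonic influx absorbed in the free intercept.
(Modelling the leak with its full ECl dependence instead would bias the
naive slope by ~12 % and break the single-exponential form.)  The fitted
P is reported in both unit systems.  EGABA is estimated from puff
currents either by a two-potential line fit (resting g and EGABA) or by
inverting single currents at known g, and converted to [Cl⁻]i by
inverting the 4:1 weighted reversal.

Leak tuning reports the emergent rest state: with the tuned densities the
algebraic fixed point of the leak/KCC2 system sits at −71.06 mV and
4.23 mM — within 0.5 % and 0.5 % of the experimentally grounded −71.35 mV / 4.25 mM
defaults — and the model is initialised there, so 10 s unstimulated runs
drift < 0.1 mV and < 0.05 mM.

## Analyses

Output rate = axon-tip spike count (upward crossings of −20 mV with a
2 ms lockout; threshold and lockout config-exposed) over the 1000 ms
window.  IFR(t) pools spikes over K trials in a backward window
[t−Δt, t] (Δt = 20 ms, K = 5).  I/O curves plot trial-mean rate against
relative excitatory conductance; trial seeds are shared across chloride
modes so dynamic/static comparisons are paired.  x₅₀ is extracted by
piecewise-linear interpolation of the rising limb, using the
no-inhibition plateau as the reference maximum for distal-inhibition
families (distal inhibition offsets the curve without changing its
maximum).  The chloride index is `1 − a/b` with a and b the dynamic- and
static-mode x₅₀ offsets from the no-inhibition curve; ΔEGABA is the
change of the distal-dendrite spatial-mean EGABA from the start to the
end of the dynamic run.  The index sweep varies pump strength
(25–200 %), distal diameter (0.5–2 µm), inhibition level, input
resistance, distal KCC2 scaling, duration, and the dynamic-K⁺ flag, and
reports the Pearson correlation between index and ΔEGABA.

## Problem sizes and tolerances

The bundled protocols and the acceptance script use scaled-down grids
chosen to resolve the effects cleanly on a single CPU: 8-point
conductance grids (5–50 relative), one seeded trial per grid point with
paired seeds across modes, a 24-point sweep (4 pump strengths × 3
diameters × 2 inhibition levels), and 10–15 trials for the balanced-drive
reference rate (trial-to-trial SD ≈ 2 Hz).  Numerical guards: voltage
divergence (|V| > 200 mV or NaN) and [Cl⁻]i underflow (< 10⁻³ mM) abort a
run with the step and compartment reported.

## What the synthetic data do and do not emulate

Generators reproduce the *structure* of the source experiments — sparse
exponential recovery sampling with additive Gaussian noise, Ohmic puff
currents, Poisson trains, OU conductances — with ground truth embedded in
metadata.  They do not model photocurrent biophysics, series-resistance
or junction-potential artefacts, receptor desensitisation, or synaptic
short-term plasticity; passing recovery tests therefore demonstrates
estimator correctness under the stated noise model, not robustness to
every experimental artefact.

## Known limitations

* The axonal channel kinetics are a calibrated stand-in constrained only
  by printed current forms and behavioural anchors; absolute firing rates
  away from the calibrated regime (e.g. very strong drive) should be read
  qualitatively.
* A cell this electrotonically extended does not obey isopotential
  scaling laws exactly — e.g. doubling all leak densities multiplies the
  somatic input resistance by ~0.55, not 0.5 — because the thin distal
  dendrite and axon are partially decoupled by axial resistance.
* Radial (submembrane) Cl⁻ gradients, impermeant anions, extracellular
  accumulation, active dendritic conductances and networks are out of
  scope.
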