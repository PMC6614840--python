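# Methods

This note records the models implemented in fretfold, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Conformational model

The aptamer is modelled as a continuous-time Markov chain over two or three
states — unfolded **U**, ligand-free folded **F_LF**, ligand-bound folded
**F_LB** — each carrying an apparent FRET mean and width (defaults 0.32,
0.60, 0.69; σ = 0.05, the histogram peak widths of the system this package
targets).  Transition rates k(i→j) are constants or ligand-activated Hill
laws k(c) = basal + k_max·cⁿ/(K_Dⁿ + cⁿ); only docking transitions
(U→F_LB, F_LF→F_LB) are given ligand laws, because undocking is observed
to be ligand-independent in this system.  The exact form of the
rate-vs-ligand "two-state model" is implemented as this Hill law; no other
form is supported.

## Simulator

`simulate_path` is an exact event-driven (Gillespie) simulation: dwells are
exactly exponential with the state's total exit rate, successors chosen by
branching probability.  Camera effects enter only at emission
(`emit_intensities`): frames integrate the state efficiency time-weighted
within each frame (a 50 ms camera cannot resolve sub-frame events, so
transition frames are "blurred"), Gaussian noise is added per channel, and
a single exponential photobleaching time truncates the signal.  Initial
states are drawn from the stationary distribution of the generator,
emulating molecules imaged at equilibrium.

**FRET convention.**  State means are *apparent* efficiencies — the
quantity the leakage-corrected estimator E = I_A/(I_D + α·I_A) returns.
The emitter therefore inverts that map: it solves for the photon fraction
ε with (E − ℓ(1−αE))/(E + (1−ℓ)(1−αE)), emits donor = T(1−ε) and
acceptor = T·ε + ℓ·donor with ℓ = 1−α = 0.12, and a noiseless round trip
through `compute_fret` reproduces the state means to machine precision.
This closure is what anchors the simulator and the corrector to the same
α convention; with ℓ = 0 the emitter reduces to the plain donor/acceptor
split.  Apparent efficiencies below the leakage floor ℓ/(1+αℓ) ≈ 0.109
have no physical photon fraction and are clipped at ε = 0.  A raw
photon-fraction mode (`means_are_apparent=False`) is available for
modelling detection channels directly.

**Defaults not fixed by the system**: total intensity 1000 a.u. and channel
noise σ = 60 a.u. are fixture choices giving per-frame FRET noise ≈ 0.05,
comparable to the histogram widths; they are not measured values.
Photobleaching is one exponential lifetime acting on both channels
(single-step); acceptor-only bleaching, blinking and camera-specific noise
(EMCCD gain, drift) are not modelled, so tests passing on these cohorts say
nothing about those artefacts in real data.

## Trace processing

`compute_fret` implements E = I_A/(I_D + α·I_A) verbatim (α = 0.88
default) rather than the subtraction-style leakage correction; the
simulator's emission model is defined as its inverse so round trips close.
Frames with non-positive denominator or E outside (−0.2, 1.2) are flagged
invalid, never silently dropped.  Photobleaching is detected as the first
window of sustained total-intensity drop below half the initial median;
when found, the post-bleach mean of each channel is subtracted as the
background estimate (the standard estimator; the upstream protocol is
silent on background) and statistics stop at the bleach index.  Histogram
samples follow the first-ten-frames protocol: one mean per molecule;
molecules with fewer than ten valid frames are excluded and logged.
Donor-only molecule exclusion is left to the caller (no intensity-ratio
filter is applied by default).

## Occupancy and isotherm fitting

Mixture fitting is expectation–maximization on the sample list (not binned
least squares): for maximum-likelihood Gaussians the component weight
equals the normalized histogram-peak area, so weights are used directly as
occupancies.  Twenty seeded restarts with jittered means guard against
local optima; means can be box-constrained (default ±0.05) to supplied
state positions, which prevents label switching between the 0.60 and
0.66–0.69 states; components converging within 0.02 of each other are
merged and the fit repeated with one fewer component, preventing spurious
three-state fits when only one population is present.  A σ floor of 1e−4
prevents variance collapse.  BIC is reported; no further model selection
is performed.

Isotherm fits are weighted (inverse-variance when errors are supplied,
unweighted otherwise) nonlinear least squares of
floor + amplitude·cⁿ/(K_Dⁿ + cⁿ) with n bounded to [0.3, 8]; fits touching
a bound are flagged and warned.  The global two-state fit ties U = 1 − F
with shared (K_D, n) and rejects occupancy pairs summing above 1.05; the
F_LF/F_LB exchange fit shares (K_D, n) between the falling and rising
curves and treats U as a constant offset.

## Idealization and kinetics

Trajectories are idealized with a hidden Markov model whose Gaussian
emission parameters are *fixed* to the state model — states are identified
by their histogram positions first — while transition probabilities (and
the initial distribution) are re-estimated from the trace cohort by
Baum–Welch.  The idealized path is the Viterbi decode.  On traces short
enough to enumerate, Viterbi agrees exactly with brute-force maximization
over all state sequences (tested).  Traces shorter than 5 frames are
skipped with a log entry.

Dwells are one record per idealized segment, duration = frame count ×
frame time; the first and last segments of every trace are flagged
censored and excluded from rate fits — a censored record observes only
part of its dwell, biasing the dwell estimate low and the rate high.
Minimum dwell is one frame (no merging filter by default).  The default
rate estimator bins the dwells and fits A·exp(−kt), mirroring conventional
dwell-histogram analysis; the exponential MLE (left-truncated at one frame
when the frame time is supplied) is provided as the statistically
preferred alternative and used in recovery studies.  Rates for a source
state with two exits are estimated from transition-type–specific dwell
subsets; because all exits of a Markov state share one dwell distribution
this reproduces the conventional numbers, and a competing-risks estimator
(total exit rate × branching fraction) is provided for sensitivity
analysis.  Transition density plots use the idealized state means as
E_initial/E_final, rendered on a logarithmic intensity scale; the
counting identity (total transitions = segments − traces) holds by
construction.

Mechanism classification: docking is called ligand-dependent when the Hill
law beats a constant by an F-test at α = 0.05, undocking when the linear
slope differs from zero at the same level; ligand-driven docking with flat
undocking is induced fit, the converse conformational selection, both
"mixed", and fewer than three concentrations "undetermined".  The F-test
has one residual degree of freedom per concentration beyond three, so at
least five or six concentrations are needed for useful power.

## Thermodynamics

Energies are kcal/mol at 298.15 K (RT = 0.5925 kcal/mol; the imaging
temperature is not specified upstream, so room temperature is the default
and a parameter).  ΔG° = −RT·ln(k_f/k_r); ΔΔG‡ = −RT·ln(k_B/k_A) between
conditions; absolute barrier heights are deliberately not computed (they
would require an attempt frequency the data do not determine).  K_eq is
reported in the dissociation direction (k_unfold/k_fold), the convention
under which 0.037/0.27 gives the 0.14 conformational equilibrium constant,
and K_D,app = K_D,fold·K_D,bind.  Standard errors propagate to first
order and are verified against Monte-Carlo propagation in tests.  The
regulatory-regime label compares state dwell times with the transcription
window at a configurable ratio (default 3×).

## Dye accessible volumes

The AV model is deliberately simplified: a single dye-sphere radius with
straight-line reachability (grid points within the linker length of the
attachment, clash-checked against obstacle van der Waals spheres inflated
by the dye radius), no linker-path search and no three-radius dye
ellipsoid.  Defaults (linker 20 Å, width 4.5 Å kept as metadata, dye
radius 3.5 Å) follow common cyanine-dye usage and are exposed in the
configuration.  The reported distance is between mean dye positions
(R_mp); grid spacing 1 Å by default, with mean positions stable to ~0.3 Å
against 0.5 Å grids on fixtures.  Orientation factor (κ²) modelling and
dynamic dye simulations are out of scope.  PDB input is parsed from the
fixed coordinate columns of ATOM/HETATM records with line-numbered errors;
unknown elements get a 1.7 Å radius with a warning.

## Problem sizes and reproducibility

Recovery studies use cohorts of 80–200 molecules per condition at 50 ms
frames (60–200 s per molecule), 50-replicate isotherm studies, and
Baum–Welch restricted to a subsample of 30–50 traces per cohort — sizes at
which the estimators are comfortably in their asymptotic regime while a
full study runs in minutes on one CPU.  The slow-exchange occupancy cohorts
use a 50 s folded dwell so molecules are static within the 0.5 s
first-ten-frame averaging window, matching the cleanly bimodal histograms
this protocol presumes; with faster exchange the averaging window itself
broadens the apparent populations.  All randomness flows from explicit
seeds through `numpy.random.SeedSequence` spawning, so cohorts, fits and
pipeline reports are reproducible; note that multi-threaded BLAS can
perturb floating-point reductions at the last bit, which matters only for
degenerate (flat-data) fits.

## Known limitations

Two-exit rate estimates inherit the competing-risks caveat above.  The
HMM assumes Gaussian emissions with state-independent widths and no
baseline drift.  The bleach detector assumes a single irreversible
intensity step and will mislabel long blinking events.  The AV model's
straight-line reachability overestimates accessible volume behind thin
obstacles.  Hill fits with n at its bounds indicate an unresolved
cooperativity, not a measurement.
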