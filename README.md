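# fretfold

Single-molecule FRET folding kinetics for ligand-sensing RNAs, built around
the *Bacillus subtilis* lysC lysine-riboswitch aptamer: simulation of
ligand-coupled conformational dynamics, trace processing into apparent-FRET
histograms, hidden-Markov trajectory idealization, dwell-time rate fitting,
Hill binding isotherms, free-energy landscapes, and dye accessible-volume
FRET predictions.

## The science

The lysC aptamer interconverts between three conformations that report on
the P1–P5 stem distance through the apparent FRET efficiency of a Cy3/Cy5
pair: unfolded **U** (E ≈ 0.32), ligand-free folded **F_LF** (E ≈ 0.60) and
ligand-bound folded **F_LB** (E ≈ 0.66–0.69).  Mg²⁺ tunes which encounter
complex the ligand meets; lysine drives docking.  The package implements the
full analysis chain used to quantify this behaviour:

- **Apparent FRET**: E_app = I_A / (I_D + α·I_A) with α = 0.88 correcting
  12% donor→acceptor spectral leakage; population histograms take one value
  per molecule, the mean of its first ten frames.
- **Occupancies**: Gaussian-mixture fits of the histograms (component
  weights = fractional state occupancies).
- **Binding isotherms**: Hill fits, response = floor + A·cⁿ/(K_Dⁿ + cⁿ),
  including global two-curve fits of complementary occupancies.
- **Kinetics**: Viterbi idealization under a fixed-emission HMM,
  censoring-aware dwell-time extraction, mono-exponential rate fits,
  transition density plots, and rate-vs-ligand laws (straight line or
  k(c) = k_max·cⁿ/(K_Dⁿ + cⁿ)) that classify the binding mechanism as
  induced fit or conformational selection.
- **Thermodynamics**: ΔG° = −RT·ln(k_f/k_r), barrier changes
  ΔΔG‡ = −RT·ln(k_B/k_A), K_eq = k_unfold/k_fold, apparent
  K_D = K_D,fold·K_D,bind, and a kinetic-vs-thermodynamic regulatory-regime
  label against the 1–3 s transcription window.
- **Dye geometry**: grid accessible-volume clouds around attachment atoms
  and the Förster conversion E = 1/(1 + (R/R₀)⁶).

A seeded stochastic simulator (exact Gillespie paths rendered into noisy,
leakage-mixed, photobleach-truncated camera frames) generates the synthetic
cohorts that every stage is tested against.

## Worked example

Equilibrium analysis of the F_LF ↔ F_LB transition from its fitted rate
constants (`python examples/05_energy_landscape.py`):

```
K_eq (dissociation direction) = 0.137 +/- 0.041
K_D,app = K_D,fold x K_D,bind = 11.0 +/- 5.2 uM
dG0(F_LF -> F_LB) at saturation = -1.18 kcal/mol
dwell(F_LB) = 27 s, dwell(F_LF) at 300 uM lysine = 4.7 s
regulatory regime: thermodynamic-like
```

The equilibrium constant 0.137 means the docked state is ~7-fold favoured
at ligand saturation; multiplying by the 80 µM binding constant gives the
~11 µM apparent affinity of the coupled fold-and-bind transition, and a
27 s folded dwell against a 1–3 s transcription window places the switch
under thermodynamic-like control.

Each script in `examples/` is a short narrative of one capability:
dye-geometry FRET prediction (01), cohort simulation and histogram
occupancies (02), Mg²⁺ isotherm fitting (03), dwell-time kinetics and
mechanism classification (04), and the energy landscape above (05).

A thin CLI wraps the pipeline for shell use:

```bash
fretfold run-all --config examples/config.yaml
fretfold thermo --k-fold 0.27 --k-unfold 0.037 --kd-bind 80
```

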