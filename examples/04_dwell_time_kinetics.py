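"""Idealize trajectories, extract dwell times and classify the mechanism.

Two-state cohorts are simulated across a lysine titration, idealized with
the fixed-emission hidden Markov model, and per-transition rates are fitted
from uncensored dwell-time histograms.  The ligand dependence of the
docking rate versus the flat undocking rate identifies induced-fit binding.
"""

import numpy as np

from fretfold import kinetics, traces
from fretfold.simulate import (
    ConstantLaw, HillLaw, KineticScheme, Photophysics, StateModel,
    generate_cohort,
)

model = StateModel(("U", "F_LB"), (0.32, 0.69), (0.05, 0.05))
concentrations = np.array([150.0, 300.0, 600.0, 1000.0])

dock_rates, undock_rates = [], []
for i, c in enumerate(concentrations):
    scheme = KineticScheme(
        ("U", "F_LB"), np.zeros((2, 2)),
        {("U", "F_LB"): HillLaw(1.22, 310.0, 3.1),
         ("F_LB", "U"): ConstantLaw(0.18)},
        {"mg_mM": 0.5, "lysine_uM": float(c)},
    )
    cohort, _ = generate_cohort(scheme, model, 60, 0.05, 100.0,
                                Photophysics(noise_sd=60.0), seed=20 + i)
    ftr = [traces.compute_fret(t) for t in cohort]
    paths, _ = kinetics.idealize_cohort(ftr, model, n_iter=5,
                                        max_baum_welch_traces=20)
    dwells = kinetics.extract_dwells(paths)
    for state, sink in (("U", dock_rates), ("F_LB", undock_rates)):
        sub = [d for d in dwells if d.state == state and not d.censored]
        fit = kinetics.fit_dwell_rate(sub, method="histogram_lsq",
                                      frame_dt=0.05)
        sink.append(fit.rate)
    tdp = kinetics.build_tdp(paths, model)
    print(f"{c:6.0f} uM: k_dock {dock_rates[-1]:.3f} 1/s, "
          f"k_undock {undock_rates[-1]:.3f} 1/s, "
          f"{tdp.total} transitions")

hill = kinetics.fit_rate_vs_ligand(concentrations, dock_rates, model="hill")
line = kinetics.fit_rate_vs_ligand(concentrations, undock_rates,
                                   model="constant_line")
mech = kinetics.classify_mechanism(concentrations, dock_rates,
                                   concentrations, undock_rates)
print(f"docking Hill fit: k_max {hill.params['k_max']:.2f} 1/s, "
      f"K_D {hill.params['K_D']:.0f} uM, n {hill.params['n']:.1f}")
print(f"undocking straight line: {line.params['k_mean']:.3f} 1/s "
      f"(slope p = {line.params['p_slope']:.2f})")
print(f"mechanism: {mech.label}")
# A docking rate that rises with ligand while undocking stays constant is
# the kinetic signature of induced fit: lysine binds the unstructured
# aptamer and actively drives folding.
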