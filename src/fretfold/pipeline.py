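"""End-to-end orchestration: simulate -> traces -> fitting -> kinetics -> thermo.

A `RunConfig` fully specifies a run (conditions grid, kinetic scheme, state
model, analysis options and a mandatory master seed); `run_pipeline`
executes every stage, writes per-stage outputs under the run directory and
returns a consolidated report with the headline quantities: state
occupancies per condition, binding K_Ds, transition rates, the
conformational equilibrium constant, the apparent K_D and the free-energy
table, plus a ligand-binding mechanism label.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fitting, kinetics, thermo, traces as traces_mod
from .io import write_cohort, write_json, write_samples_tsv
from .simulate import (
    ConstantLaw,
    HillLaw,
    KineticScheme,
    Photophysics,
    StateModel,
    generate_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "validate_against_targets"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration; the seed is mandatory."""

    seed: int
    states: list[str]
    fret_means: list[float]
    fret_sigmas: list[float]
    base_rates: list[list[float]]
    ligand_laws: dict = field(default_factory=dict)   # "U->F_LB" -> law dict
    conditions: list[dict] = field(default_factory=list)
    n_molecules: int = 200
    frame_dt: float = 0.05
    duration: float = 60.0
    photophysics: dict = field(default_factory=dict)
    alpha: float = 0.88
    hmm_iterations: int = 10
    max_baum_welch_traces: int | None = 50
    dwell_fit_method: str = "histogram_lsq"
    temperature: float = thermo.DEFAULT_TEMPERATURE
    out_dir: str = "fretfold_run"
    make_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d or d["seed"] is None:
            raise ValueError("config must specify a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if not cfg.conditions:
            raise ValueError("config must list at least one condition")
        for c in cfg.conditions:
            if "mg_mM" not in c or "lysine_uM" not in c:
                raise ValueError(f"condition {c} must specify mg_mM and lysine_uM")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    def state_model(self) -> StateModel:
        return StateModel(tuple(self.states), tuple(self.fret_means),
                          tuple(self.fret_sigmas))

    def scheme(self, condition: dict) -> KineticScheme:
        laws = {}
        for key, spec in self.ligand_laws.items():
            a, b = key.split("->")
            kind = spec.get("type", "hill")
            if kind == "constant":
                laws[(a, b)] = ConstantLaw(spec["k"])
            elif kind == "hill":
                laws[(a, b)] = HillLaw(spec["k_max"], spec["K_D"], spec["n"],
                                       spec.get("basal", 0.0))
            else:
                raise ValueError(f"unknown rate-law type {kind!r}")
        return KineticScheme(
            states=tuple(self.states),
            base_rates=np.asarray(self.base_rates, dtype=float),
            ligand_laws=laws,
            condition=dict(condition),
        )

    def photo(self) -> Photophysics:
        return Photophysics(**self.photophysics)


def _analyze_condition(cfg: RunConfig, condition: dict, seed: int, out: Path,
                       write_outputs: bool) -> dict:
    model = cfg.state_model()
    scheme = cfg.scheme(condition)
    cohort, manifest = generate_cohort(
        scheme, model, cfg.n_molecules, cfg.frame_dt, cfg.duration,
        cfg.photo(), seed,
    )
    tag = f"mg{condition['mg_mM']:g}_lys{condition['lysine_uM']:g}"
    if write_outputs:
        write_cohort(cohort, manifest, out / f"cohort_{tag}")

    ftraces = [traces_mod.compute_fret(tr, alpha=cfg.alpha) for tr in cohort]
    samples = traces_mod.summarize_for_histogram(ftraces)
    if write_outputs:
        write_samples_tsv(samples, out / f"samples_{tag}.tsv")

    values = [s.value for s in samples]
    mix = fitting.fit_mixture(
        values,
        n_components=model.n_states,
        init_means=list(model.fret_means),
        constrain_means=0.05,
    )
    if write_outputs and cfg.make_plots:
        from .plots import plot_fret_histogram

        plot_fret_histogram(values, mix, path=out / f"histogram_{tag}.png",
                            title=tag)
    occupancies = {lbl: mix.weight_near(m)
                   for lbl, m in zip(model.labels, model.fret_means)}

    paths, transmat = kinetics.idealize_cohort(
        ftraces, model, n_iter=cfg.hmm_iterations,
        max_baum_welch_traces=cfg.max_baum_welch_traces,
    )
    dwells = kinetics.extract_dwells(paths)
    rates: dict[str, dict] = {}
    for src in model.labels:
        for dst in model.labels:
            if src == dst:
                continue
            sub = [d for d in dwells
                   if d.state == src and d.following == dst and not d.censored]
            if len(sub) >= 5:
                rf = kinetics.fit_dwell_rate(
                    sub, method=cfg.dwell_fit_method, frame_dt=cfg.frame_dt,
                )
                rates[f"{src}->{dst}"] = {
                    "rate": rf.rate, "se": rf.se, "n_dwells": rf.n_dwells,
                    "flags": rf.flags,
                }
    return {
        "condition": dict(condition),
        "n_traces": len(cohort),
        "n_samples": len(samples),
        "occupancies": occupancies,
        "mixture": {
            "means": mix.means.tolist(),
            "weights": mix.weights.tolist(),
            "bic": mix.bic,
            "converged": mix.converged,
        },
        "rates": rates,
        "n_dwells": len(dwells),
        "transition_matrix": np.asarray(transmat).tolist(),
    }


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute every stage over the condition grid; returns the run report.

    Stage failures are logged with the stage name; partial outputs are
    preserved and the report's `status` reflects the failure.
    """
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    report: dict = {"status": "ok", "stages": {}, "conditions": [],
                    "warnings": []}
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.conditions)) % (2**31)

    t0 = time.perf_counter()
    for condition, seed in zip(config.conditions, seeds):
        try:
            res = _analyze_condition(config, condition, int(seed), out,
                                     write_outputs)
            report["conditions"].append(res)
        except Exception as err:  # keep partial outputs, record the failure
            log.exception("condition stage failed for %s", condition)
            report["status"] = "stage_error"
            report["stages"][f"condition {condition}"] = f"error: {err}"
    report["stages"]["conditions_s"] = time.perf_counter() - t0

    # cross-condition analyses: occupancy isotherms and rate-vs-ligand fits
    try:
        _cross_condition_fits(config, report)
    except Exception as err:
        log.exception("cross-condition stage failed")
        report["status"] = "stage_error"
        report["stages"]["cross_condition"] = f"error: {err}"

    if write_outputs:
        write_json(report, out / "report.json")
    return report


def _cross_condition_fits(cfg: RunConfig, report: dict) -> None:
    by_lys = sorted(report["conditions"],
                    key=lambda r: r["condition"]["lysine_uM"])
    lys = np.array([r["condition"]["lysine_uM"] for r in by_lys])
    if len(by_lys) >= 4 and np.all(np.diff(lys) > 0):
        labels = cfg.states
        occ = {lbl: np.array([r["occupancies"].get(lbl, 0.0) for r in by_lys])
               for lbl in labels}
        if "U" in occ and labels[-1] in occ:
            flb = occ[labels[-1]]
            try:
                fit = fitting.fit_two_state_occupancy(
                    fitting.Isotherm(lys, occ["U"]),
                    fitting.Isotherm(lys, flb),
                )
                report["two_state_fit"] = {
                    "K_D_uM": fit.K_D, "n": fit.n,
                    "stderr": fit.stderr, "at_bound": fit.at_bound,
                }
            except ValueError as err:
                report["warnings"].append(f"two-state occupancy fit skipped: {err}")

    # ligand dependence of rates for the dominant fold/unfold transitions
    fold_key, unfold_key = None, None
    if len(cfg.states) >= 2:
        fold_key = f"{cfg.states[0]}->{cfg.states[-1]}"
        unfold_key = f"{cfg.states[-1]}->{cfg.states[0]}"
    rate_rows = [(r["condition"]["lysine_uM"], r["rates"]) for r in by_lys]
    for key, model, name in ((fold_key, "hill", "folding"),
                             (unfold_key, "constant_line", "unfolding")):
        pts = [(c, rr[key]["rate"], rr[key]["se"]) for c, rr in rate_rows
               if key in rr]
        if len(pts) >= 3:
            c, k, se = map(np.array, zip(*pts))
            lf = kinetics.fit_rate_vs_ligand(c, k, errors=se, model=model)
            report[f"{name}_rate_fit"] = {
                "model": lf.model, "params": lf.params, "flags": lf.flags,
            }
    if "folding_rate_fit" in report and "unfolding_rate_fit" in report:
        fc = [(c, rr[fold_key]["rate"]) for c, rr in rate_rows if fold_key in rr]
        uc = [(c, rr[unfold_key]["rate"]) for c, rr in rate_rows if unfold_key in rr]
        mech = kinetics.classify_mechanism(
            [p[0] for p in fc], [p[1] for p in fc],
            [p[0] for p in uc], [p[1] for p in uc],
        )
        report["mechanism"] = mech.label

        # equilibrium thermodynamics from the fitted rates
        hill = report["folding_rate_fit"]["params"]
        k_unfold = report["unfolding_rate_fit"]["params"]["k_mean"]
        k_fold = hill.get("k_max", None)
        if k_fold and k_fold > 0 and k_unfold > 0:
            keq, _ = thermo.equilibrium_constant(k_unfold, k_fold)
            kd_app, _ = thermo.apparent_kd(keq, hill["K_D"])
            report["thermo"] = {
                "K_eq": keq,
                "K_D_bind_uM": hill["K_D"],
                "K_D_app_uM": kd_app,
                "delta_g_kcal_mol": {
                    f"{c:g} uM": thermo.delta_g(
                        fitting.hill_response(c, hill["K_D"], hill["n"],
                                              0.0, k_fold),
                        k_unfold, cfg.temperature)
                    for c in [p[0] for p in fc] if c > 0
                },
            }


def validate_against_targets(report: dict, targets: dict) -> list[dict]:
    """Compare report quantities with target values at stated tolerances.

    `targets` maps a target id to {"path": dotted report key, "expected":
    value, "tol_rel": fraction} (or "tol_abs").  An unresolvable path is a
    rejection naming the target.  Returns one verdict row per target.
    """
    rows = []
    for tid, spec in targets.items():
        node = report
        try:
            for part in spec["path"].split("."):
                node = node[int(part)] if isinstance(node, list) else node[part]
        except (KeyError, IndexError, TypeError, ValueError) as err:
            raise ValueError(f"target {tid!r}: path {spec['path']!r} "
                             f"not found in report") from err
        value = float(node)
        expected = float(spec["expected"])
        if "tol_abs" in spec:
            ok = abs(value - expected) <= spec["tol_abs"]
        else:
            ok = abs(value - expected) <= spec.get("tol_rel", 0.1) * abs(expected)
        rows.append({"id": tid, "value": value, "expected": expected,
                     "pass": bool(ok)})
    return rows
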