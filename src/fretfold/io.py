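"""Plain-text archives: per-molecule TSV traces plus a JSON cohort manifest.

Layout of a cohort directory:

    manifest.json                 generation parameters and seeds
    mol00000.trace.tsv            frame, time_s, donor, acceptor
    mol00000.path.tsv             state, t_entry, t_exit (ground truth)
    ...
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import IntensityTrace, StatePath

__all__ = ["write_cohort", "read_cohort", "write_samples_tsv", "write_json"]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def write_cohort(traces: list[IntensityTrace], manifest: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(manifest, out / "manifest.json")
    for tr in traces:
        stem = tr.molecule_id or f"mol{traces.index(tr):05d}"
        df = pd.DataFrame({
            "frame": np.arange(tr.n_frames),
            "time_s": tr.times,
            "donor": tr.donor,
            "acceptor": tr.acceptor,
        })
        df.to_csv(out / f"{stem}.trace.tsv", sep="\t", index=False,
                  float_format="%.6g")
        if tr.ground_truth is not None:
            gt = pd.DataFrame(tr.ground_truth.segments,
                              columns=["state", "t_entry", "t_exit"])
            gt.to_csv(out / f"{stem}.path.tsv", sep="\t", index=False,
                      float_format="%.9g")
    return out


def read_cohort(cohort_dir) -> tuple[list[IntensityTrace], dict]:
    d = Path(cohort_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    frame_dt = float(manifest["frame_dt"])
    condition = manifest.get("condition", {})
    traces = []
    for f in sorted(d.glob("*.trace.tsv")):
        df = pd.read_csv(f, sep="\t")
        stem = f.name[: -len(".trace.tsv")]
        gt = None
        path_file = d / f"{stem}.path.tsv"
        if path_file.exists():
            pdf = pd.read_csv(path_file, sep="\t")
            gt = StatePath([(r.state, float(r.t_entry), float(r.t_exit))
                            for r in pdf.itertuples()])
        traces.append(IntensityTrace(
            frame_dt=frame_dt,
            donor=df["donor"].to_numpy(),
            acceptor=df["acceptor"].to_numpy(),
            condition=dict(condition),
            ground_truth=gt,
            molecule_id=stem,
        ))
    return traces, manifest


def write_samples_tsv(samples, path) -> None:
    """FRET histogram samples as TSV (molecule_id, e_mean, condition)."""
    df = pd.DataFrame({
        "molecule_id": [s.molecule_id for s in samples],
        "e_mean": [s.value for s in samples],
        "condition": [";".join(f"{k}={v}" for k, v in s.condition)
                      for s in samples],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
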