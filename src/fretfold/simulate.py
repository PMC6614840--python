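"""Synthetic single-molecule FRET trajectory generator.

Generates ground-truth state paths from a continuous-time Markov scheme for
riboswitch aptamer folding (states U, F_LF, F_LB), renders them into camera
frames as donor/acceptor intensity traces with spectral leakage, Gaussian
channel noise and single-step photobleaching, and produces ensemble binding
isotherms.  Every downstream analysis stage of the package can therefore be
exercised without experimental movies.

Kinetic truth and detection are deliberately separated: `simulate_path` is an
exact event-driven (Gillespie) simulation, so dwell times are exactly
exponential; camera effects (frame integration, noise, bleaching) enter only
in `emit_intensities`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConstantLaw",
    "HillLaw",
    "KineticScheme",
    "StateModel",
    "StatePath",
    "IntensityTrace",
    "Photophysics",
    "evaluate_rate_law",
    "simulate_path",
    "emit_intensities",
    "generate_cohort",
    "generate_isotherm",
    "stationary_distribution",
    "apparent_to_photon_fraction",
]


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantLaw:
    """Ligand-independent rate: k(c) = k for every concentration."""

    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"rate must be >= 0, got {self.k}")


@dataclass(frozen=True)
class HillLaw:
    """Cooperative ligand activation of a rate.

    k(c) = basal + k_max * c**n / (K_D**n + c**n)

    At c = 0 the law returns the basal rate (0 by default); at saturation it
    returns basal + k_max.  `K_D` carries whatever concentration unit `c`
    does; `n` is the Hill coefficient.
    """

    k_max: float
    K_D: float
    n: float
    basal: float = 0.0

    def __post_init__(self) -> None:
        if self.k_max < 0 or self.basal < 0:
            raise ValueError("rates must be >= 0")
        if self.K_D <= 0 or self.n <= 0:
            raise ValueError("K_D and n must be > 0")


RateLaw = ConstantLaw | HillLaw


def evaluate_rate_law(law: RateLaw, concentration: float) -> float:
    """Evaluate a transition-rate law at a ligand concentration (s^-1)."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if isinstance(law, ConstantLaw):
        return law.k
    if isinstance(law, HillLaw):
        if concentration == 0.0:
            return law.basal
        # evaluate in a ratio form that is stable for extreme c/K_D
        r = (concentration / law.K_D) ** law.n
        return law.basal + law.k_max * r / (1.0 + r)
    raise TypeError(f"unknown rate law {law!r}")


# ---------------------------------------------------------------------------
# scheme and state model
# ---------------------------------------------------------------------------

@dataclass
class KineticScheme:
    """Conformational states plus transition rates, optionally ligand-driven.

    `base_rates[i, j]` is k(i -> j) in s^-1 (diagonal ignored).  A transition
    listed in `ligand_laws` (keyed by a (from_label, to_label) pair) has its
    rate evaluated from the law at the lysine concentration of `condition`
    instead of the base matrix.
    """

    states: tuple[str, ...]
    base_rates: np.ndarray
    ligand_laws: dict[tuple[str, str], RateLaw] = field(default_factory=dict)
    condition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.base_rates = np.asarray(self.base_rates, dtype=float)
        k = len(self.states)
        if self.base_rates.shape != (k, k):
            raise ValueError("base_rates must be square over the states")
        off = self.base_rates[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("all rates must be >= 0")
        for pair in self.ligand_laws:
            if pair[0] not in self.states or pair[1] not in self.states:
                raise ValueError(f"ligand law for unknown transition {pair}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        return self.states.index(label)

    def rate_matrix(self, lysine_uM: float | None = None) -> np.ndarray:
        """Materialize k(i->j) at a lysine concentration (uM).

        Defaults to the concentration stored in `condition` (0 if absent).
        The diagonal of the returned matrix is zero.
        """
        if lysine_uM is None:
            lysine_uM = float(self.condition.get("lysine_uM", 0.0))
        k = self.base_rates.copy()
        np.fill_diagonal(k, 0.0)
        for (a, b), law in self.ligand_laws.items():
            k[self.index(a), self.index(b)] = evaluate_rate_law(law, lysine_uM)
        return k

    def generator(self, lysine_uM: float | None = None) -> np.ndarray:
        """Infinitesimal generator Q (rows sum to zero)."""
        q = self.rate_matrix(lysine_uM)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclass(frozen=True)
class StateModel:
    """Ordered conformational states with per-state apparent FRET mean/sigma.

    Means must be strictly increasing (U < F_LF < F_LB ordering) and sigmas
    in (0, 0.2).
    """

    labels: tuple[str, ...]
    fret_means: tuple[float, ...]
    fret_sigmas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.fret_means) == len(self.fret_sigmas)):
            raise ValueError("labels, means and sigmas must align")
        means = np.asarray(self.fret_means)
        if np.any(np.diff(means) <= 0):
            raise ValueError("state FRET means must be strictly increasing")
        if np.any(means < 0) or np.any(means > 1):
            raise ValueError("state FRET means must lie in [0, 1]")
        sig = np.asarray(self.fret_sigmas)
        if np.any(sig <= 0) or np.any(sig >= 0.2):
            raise ValueError("state sigmas must lie in (0, 0.2)")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def mean_of(self, label: str) -> float:
        return self.fret_means[self.labels.index(label)]


#: Default three-state model of the lysC aptamer: unfolded (U), ligand-free
#: folded (F_LF) and ligand-bound folded (F_LB) apparent efficiencies.
LYSC_STATES = StateModel(
    labels=("U", "F_LF", "F_LB"),
    fret_means=(0.32, 0.60, 0.69),
    fret_sigmas=(0.05, 0.05, 0.05),
)


@dataclass
class StatePath:
    """Ground-truth trajectory: contiguous dwells (label, t_entry, t_exit)."""

    segments: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a state path needs at least one segment")
        t = 0.0
        for _, t0, t1 in self.segments:
            if not math.isclose(t0, t, rel_tol=0, abs_tol=1e-9):
                raise ValueError("segments must be contiguous")
            if t1 <= t0:
                raise ValueError("segment durations must be > 0")
            t = t1

    @property
    def duration(self) -> float:
        return self.segments[-1][2] if self.segments else 0.0

    def state_at(self, t: float) -> str:
        for label, t0, t1 in self.segments:
            if t0 <= t < t1:
                return label
        return self.segments[-1][0]

    def occupancy(self) -> dict[str, float]:
        """Fraction of total time spent in each state."""
        tot: dict[str, float] = {}
        for label, t0, t1 in self.segments:
            tot[label] = tot.get(label, 0.0) + (t1 - t0)
        dur = self.duration
        return {k: v / dur for k, v in tot.items()}


@dataclass
class IntensityTrace:
    """Per-molecule donor/acceptor intensity time series.

    `bleach_frame` is the first frame with photobleached (background-only)
    signal, or None if the fluorophores survive the recording.
    """

    frame_dt: float
    donor: np.ndarray
    acceptor: np.ndarray
    bleach_frame: int | None = None
    condition: dict[str, float] = field(default_factory=dict)
    ground_truth: StatePath | None = None
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor must have equal length")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

def stationary_distribution(generator: np.ndarray) -> np.ndarray:
    """Stationary distribution pi of a CTMC generator (pi Q = 0, sum pi = 1)."""
    q = np.asarray(generator, dtype=float)
    k = q.shape[0]
    # append the normalization row to the transposed balance equations
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_path(
    scheme: KineticScheme,
    duration: float,
    seed: int | np.random.Generator,
    initial_state: str | None = None,
) -> StatePath:
    """Exact event-driven simulation of the scheme for `duration` seconds.

    The dwell in state i is exponential with rate sum_j k(i,j); the successor
    is chosen with probability k(i,j)/sum.  If `initial_state` is None the
    start state is drawn from the stationary distribution, emulating
    molecules imaged at equilibrium.  A state with zero exit rate is
    absorbing and yields a single dwell spanning the full duration.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if scheme.n_states < 1:
        raise ValueError("need at least one state")
    rng = np.random.default_rng(seed)
    rates = scheme.rate_matrix()
    exit_rates = rates.sum(axis=1)

    if initial_state is None:
        if scheme.n_states == 1:
            i = 0
        else:
            pi = stationary_distribution(scheme.generator())
            i = int(rng.choice(scheme.n_states, p=pi))
    else:
        i = scheme.index(initial_state)

    segments: list[tuple[str, float, float]] = []
    t = 0.0
    while t < duration:
        if exit_rates[i] <= 0.0:
            segments.append((scheme.states[i], t, duration))
            break
        dwell = rng.exponential(1.0 / exit_rates[i])
        t_end = min(t + dwell, duration)
        segments.append((scheme.states[i], t, t_end))
        t = t_end
        if t >= duration:
            break
        i = int(rng.choice(scheme.n_states, p=rates[i] / exit_rates[i]))
    return StatePath(segments)


# ---------------------------------------------------------------------------
# camera emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Photophysics:
    """Detection-channel parameters for rendering intensities.

    total_intensity : summed ideal photon count per frame (a.u.)
    noise_sd        : Gaussian noise sigma added per channel (a.u.)
    leakage_fraction: fraction of donor signal detected in the acceptor
                      channel (0.12 mirrors the alpha = 0.88 correction)
    bleach_lifetime : mean of the exponential photobleaching time (s);
                      None disables bleaching
    means_are_apparent: interpret state FRET means as leakage-corrected
                      apparent efficiencies (default) rather than raw
                      photon fractions
    """

    total_intensity: float = 1000.0
    noise_sd: float = 60.0
    leakage_fraction: float = 0.12
    bleach_lifetime: float | None = None
    means_are_apparent: bool = True

    @property
    def alpha(self) -> float:
        """Leakage-correction factor matching this emission model."""
        return 1.0 - self.leakage_fraction


def apparent_to_photon_fraction(e_app, leakage: float, alpha: float):
    """Invert the apparent-FRET map for the leakage emission model.

    Emitting donor = T(1-eps), acceptor = T*eps + leakage*donor and
    correcting with E = I_A / (I_D + alpha*I_A) returns e_app exactly when

        eps = (E - l(1 - alpha E)) / (E + (1 - l)(1 - alpha E)).

    Apparent efficiencies below the leakage floor l/(1 + alpha*l) have no
    physical photon fraction and are clipped to eps = 0.
    """
    e = np.asarray(e_app, dtype=float)
    eps = (e - leakage * (1.0 - alpha * e)) / (e + (1.0 - leakage) * (1.0 - alpha * e))
    return np.clip(eps, 0.0, 1.0)


def _frame_averaged_fret(
    path: StatePath, state_model: StateModel, frame_dt: float, n_frames: int
) -> np.ndarray:
    """Time-weighted mean state efficiency within each camera frame."""
    e = np.zeros(n_frames)
    means = {lbl: m for lbl, m in zip(state_model.labels, state_model.fret_means)}
    for label, t0, t1 in path.segments:
        f0 = int(t0 / frame_dt)
        f1 = min(int(math.ceil(t1 / frame_dt)), n_frames)
        for f in range(f0, f1):
            lo, hi = f * frame_dt, (f + 1) * frame_dt
            overlap = min(t1, hi) - max(t0, lo)
            if overlap > 0:
                e[f] += means[label] * overlap / frame_dt
    return e


def emit_intensities(
    path: StatePath,
    state_model: StateModel,
    frame_dt: float,
    photophysics: Photophysics = Photophysics(),
    seed: int | np.random.Generator = 0,
) -> IntensityTrace:
    """Render a ground-truth path into a camera-frame intensity trace.

    Frames containing a transition carry the time-weighted average of the
    state efficiencies ("blurred" frames), since sub-frame events cannot be
    resolved at 50 ms integration.  A single exponential bleaching time
    truncates the signal; frames at and after it contain background noise
    only.  Intensities are clipped at zero.
    """
    if frame_dt <= 0:
        raise ValueError("frame_dt must be > 0")
    n_frames = int(path.duration / frame_dt)
    if n_frames < 1:
        raise ValueError("path must span at least one frame")
    rng = np.random.default_rng(seed)
    p = photophysics

    e_app = _frame_averaged_fret(path, state_model, frame_dt, n_frames)
    if p.means_are_apparent and p.leakage_fraction > 0:
        eps = apparent_to_photon_fraction(e_app, p.leakage_fraction, p.alpha)
    else:
        eps = e_app
    donor = p.total_intensity * (1.0 - eps)
    acceptor = p.total_intensity * eps + p.leakage_fraction * donor

    bleach_frame: int | None = None
    if p.bleach_lifetime is not None:
        t_bleach = rng.exponential(p.bleach_lifetime)
        if t_bleach < n_frames * frame_dt:
            bleach_frame = int(t_bleach / frame_dt)
            donor = donor.copy()
            acceptor = acceptor.copy()
            donor[bleach_frame:] = 0.0
            acceptor[bleach_frame:] = 0.0

    if p.noise_sd > 0:
        donor = donor + rng.normal(0.0, p.noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0.0, p.noise_sd, n_frames)
    donor = np.clip(donor, 0.0, None)
    acceptor = np.clip(acceptor, 0.0, None)

    return IntensityTrace(
        frame_dt=frame_dt,
        donor=donor,
        acceptor=acceptor,
        bleach_frame=bleach_frame,
        ground_truth=path,
    )


# ---------------------------------------------------------------------------
# cohorts and isotherms
# ---------------------------------------------------------------------------

def generate_cohort(
    scheme: KineticScheme,
    state_model: StateModel,
    n_molecules: int,
    frame_dt: float,
    duration: float,
    photophysics: Photophysics = Photophysics(),
    seed: int = 0,
) -> tuple[list[IntensityTrace], dict]:
    """Simulate `n_molecules` independent molecules under one condition.

    Per-molecule seeds are spawned deterministically from the master seed, so
    a cohort is byte-reproducible.  Returns the traces and a manifest dict
    recording every generation parameter.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_molecules)
    traces = []
    for m, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        path = simulate_path(scheme, duration, rng)
        tr = emit_intensities(path, state_model, frame_dt, photophysics, rng)
        tr.condition = dict(scheme.condition)
        tr.molecule_id = f"mol{m:05d}"
        traces.append(tr)
    manifest = {
        "n_molecules": n_molecules,
        "frame_dt": frame_dt,
        "duration": duration,
        "seed": seed,
        "condition": dict(scheme.condition),
        "states": list(scheme.states),
        "fret_means": list(state_model.fret_means),
        "fret_sigmas": list(state_model.fret_sigmas),
        "rate_matrix": scheme.rate_matrix().tolist(),
        "photophysics": {
            "total_intensity": photophysics.total_intensity,
            "noise_sd": photophysics.noise_sd,
            "leakage_fraction": photophysics.leakage_fraction,
            "bleach_lifetime": photophysics.bleach_lifetime,
        },
    }
    return traces, manifest


def generate_isotherm(
    model: Callable[[np.ndarray], np.ndarray] | RateLaw,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Synthetic ensemble titration: response = model(c) + Gaussian noise.

    `model` is either a callable over concentration arrays or a rate law.
    Returns a `fitting.Isotherm`.
    """
    from .fitting import Isotherm  # local import to avoid a cycle

    c = np.asarray(concentrations, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 concentrations")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if isinstance(model, (ConstantLaw, HillLaw)):
        law = model
        resp = np.array([evaluate_rate_law(law, x) for x in c])
    else:
        resp = np.asarray(model(c), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, c.size)
    return Isotherm(concentrations=c, responses=resp)
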