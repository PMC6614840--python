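"""Rate constants -> equilibrium constants and free-energy landscapes.

Free energies are reported in kcal/mol at 298.15 K unless stated otherwise
(RT = 0.5925 kcal/mol at that temperature).  Only free-energy *differences*
between states (dG0 = -RT ln(k_f/k_r)) and *changes* in barrier height
between conditions (ddG = -RT ln(k_B/k_A)) are computed; absolute barrier
heights would require an attempt frequency that single-molecule dwell data
do not determine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "rt",
    "delta_g",
    "ddg_barrier",
    "equilibrium_constant",
    "apparent_kd",
    "mean_dwell_from_rates",
    "regulatory_regime",
    "EnergyLandscape",
]

#: gas constant in kcal / (mol K)
GAS_CONSTANT_KCAL = 1.987204259e-3

DEFAULT_TEMPERATURE = 298.15


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT in kcal/mol (0.5925 kcal/mol at 298.15 K)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return GAS_CONSTANT_KCAL * temperature


def _check_rates(*rates: float) -> None:
    for k in rates:
        if k <= 0:
            raise ValueError(f"rates must be > 0, got {k}")


def delta_g(k_forward: float, k_reverse: float,
            temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Standard free-energy difference dG0 = -RT ln(k_f / k_r) in kcal/mol.

    Negative values mean the destination (forward) state is favoured.
    """
    _check_rates(k_forward, k_reverse)
    return -rt(temperature) * math.log(k_forward / k_reverse)


def ddg_barrier(k_condition_b: float, k_condition_a: float,
                temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Barrier-height change between conditions: -RT ln(k_B / k_A) kcal/mol.

    Negative values mean the barrier is lower (the rate faster) in
    condition B than in the reference condition A.
    """
    _check_rates(k_condition_b, k_condition_a)
    return -rt(temperature) * math.log(k_condition_b / k_condition_a)


def equilibrium_constant(
    k_unfold: float, k_fold: float,
    se_unfold: float | None = None, se_fold: float | None = None,
) -> tuple[float, float | None]:
    """Conformational equilibrium constant in the dissociation direction.

    K_eq = k_unfold / k_fold (a.k.a. K_D,fold), so a value below one means
    the folded state is favoured.  When rate standard errors are supplied,
    the SE of K_eq follows by first-order propagation.
    """
    _check_rates(k_unfold, k_fold)
    keq = k_unfold / k_fold
    se = None
    if se_unfold is not None and se_fold is not None:
        se = keq * math.sqrt((se_unfold / k_unfold) ** 2 + (se_fold / k_fold) ** 2)
    return keq, se


def apparent_kd(
    kd_fold: float, kd_bind: float,
    se_fold: float | None = None, se_bind: float | None = None,
) -> tuple[float, float | None]:
    """Apparent dissociation constant of a coupled fold-and-bind transition.

    K_D,app = K_D,fold * K_D,bind with first-order propagated SE.
    """
    if kd_fold <= 0 or kd_bind <= 0:
        raise ValueError("dissociation constants must be > 0")
    kd = kd_fold * kd_bind
    se = None
    if se_fold is not None and se_bind is not None:
        se = kd * math.sqrt((se_fold / kd_fold) ** 2 + (se_bind / kd_bind) ** 2)
    return kd, se


def mean_dwell_from_rates(exit_rates) -> float:
    """Mean residence time 1 / sum(exit rates) in seconds."""
    k = np.atleast_1d(np.asarray(exit_rates, dtype=float))
    if np.any(k < 0):
        raise ValueError("exit rates must be >= 0")
    total = float(k.sum())
    if total <= 0:
        raise ValueError("at least one exit rate must be > 0")
    return 1.0 / total


def regulatory_regime(
    dwell_folded: float,
    dwell_unfolded: float,
    transcription_window_s: float,
    ratio: float = 3.0,
) -> str:
    """Classify riboswitch control as thermodynamic- or kinetic-like.

    A folded-state lifetime much longer than the time needed to transcribe
    the expression platform means a bound aptamer will not release before
    the regulatory decision is made (thermodynamic-like control); a
    folded-state lifetime comparable to the window puts the decision in
    kinetic competition with transcription.  `ratio` sets how much longer
    "much longer" is (default 3x).
    """
    if min(dwell_folded, dwell_unfolded, transcription_window_s) <= 0:
        raise ValueError("all inputs must be > 0")
    if dwell_folded >= ratio * transcription_window_s:
        if dwell_unfolded <= ratio * transcription_window_s:
            return "thermodynamic-like"
        return "mixed"
    return "kinetic-like"


@dataclass
class EnergyLandscape:
    """Per-transition free-energy differences at a stated temperature.

    `delta_g0[(i, j)]` is the standard free-energy difference for i -> j and
    `ddg_barrier[(i, j)]` the change in that transition's barrier relative
    to the reference condition.
    """

    temperature: float = DEFAULT_TEMPERATURE
    delta_g0: dict[tuple[str, str], float] = field(default_factory=dict)
    ddg: dict[tuple[str, str], float] = field(default_factory=dict)
    reference_condition: str = ""

    @property
    def RT(self) -> float:
        return rt(self.temperature)

    @classmethod
    def from_rates(
        cls,
        rates: dict[tuple[str, str], float],
        reference_rates: dict[tuple[str, str], float] | None = None,
        temperature: float = DEFAULT_TEMPERATURE,
        reference_condition: str = "",
    ) -> "EnergyLandscape":
        """Build a landscape from k(i->j) rate constants.

        dG0 is filled for every pair with both forward and reverse rates;
        ddG for every transition also present in `reference_rates`.
        """
        dg = {}
        for (a, b), kf in rates.items():
            kr = rates.get((b, a))
            if kr is not None:
                dg[(a, b)] = delta_g(kf, kr, temperature)
        ddg = {}
        if reference_rates:
            for pair, k_now in rates.items():
                k_ref = reference_rates.get(pair)
                if k_ref is not None:
                    ddg[pair] = ddg_barrier(k_now, k_ref, temperature)
        return cls(temperature, dg, ddg, reference_condition)

    def cycle_closure(self, cycle: list[str]) -> float:
        """Sum of dG0 around a closed state cycle (0 under detailed balance)."""
        total = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            total += self.delta_g0[(a, b)]
        return total
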