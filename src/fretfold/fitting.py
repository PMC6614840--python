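"""Population and isotherm fitting.

Two estimators live here:

* a one-dimensional Gaussian-mixture fitter (expectation-maximization on the
  per-molecule FRET samples, optionally with state means constrained near
  supplied values) whose component weights are the fractional state
  occupancies, and
* Hill-equation fitters for binding isotherms, including global two-curve
  fits for the U/F_LB two-state titration and the F_LF/F_LB population
  exchange.

Mixture fitting operates on the sample list itself rather than on binned
histograms; for maximum-likelihood Gaussians the component weight equals the
normalized area of the corresponding histogram peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "GaussianComponent",
    "MixtureFit",
    "Isotherm",
    "HillFit",
    "fit_mixture",
    "hill_response",
    "fit_hill",
    "fit_two_state_occupancy",
    "fit_flf_flb_exchange",
]

_MIN_SIGMA = 1e-4


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sigma: float
    weight: float


@dataclass
class MixtureFit:
    components: list[GaussianComponent]
    log_likelihood: float
    bic: float
    converged: bool
    n_samples: int
    notes: list[str] = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    def weight_near(self, mean: float, window: float = 0.05) -> float:
        """Total weight of components whose mean lies within `window`."""
        return float(sum(c.weight for c in self.components
                         if abs(c.mean - mean) <= window))


def _em_once(x, mu, sigma, w, mean_bounds, max_iter, tol):
    n = x.size
    prev_ll = -np.inf
    ll = prev_ll
    for _ in range(max_iter):
        # E step: responsibilities in a numerically safe log formulation
        log_comp = (
            np.log(np.maximum(w, 1e-300))[:, None]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sigma)[:, None]
            - 0.5 * ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2
        )
        log_norm = np.logaddexp.reduce(log_comp, axis=0)
        ll = float(log_norm.sum())
        r = np.exp(log_comp - log_norm[None, :])
        # M step
        nk = r.sum(axis=1)
        w = nk / n
        mu_new = (r @ x) / np.maximum(nk, 1e-300)
        if mean_bounds is not None:
            mu_new = np.clip(mu_new, mean_bounds[0], mean_bounds[1])
        var = (r * (x[None, :] - mu_new[:, None]) ** 2).sum(axis=1) / np.maximum(nk, 1e-300)
        mu = mu_new
        sigma = np.sqrt(np.maximum(var, _MIN_SIGMA**2))
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            return mu, sigma, w, ll, True
        prev_ll = ll
    return mu, sigma, w, ll, False


def fit_mixture(
    samples,
    n_components: int,
    init_means=None,
    constrain_means: float | None = None,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-10,
    merge_distance: float = 0.02,
) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture of FRET samples.

    Parameters
    ----------
    samples : per-molecule FRET values (>= 30 required)
    n_components : 1..3 mixture components
    init_means : optional component means used to seed EM (e.g. the state
        model's apparent efficiencies)
    constrain_means : if given (FRET units, e.g. 0.05), component means are
        box-constrained to within this distance of `init_means`
    n_restarts : EM restarts with jittered initializations; the best
        likelihood is kept (deterministic under `seed`)
    merge_distance : components whose converged means fall closer than this
        are merged and the fit repeated with one fewer component, preventing
        spurious split peaks

    Component weights are the fractional occupancies of the states.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise ValueError(f"need >= 30 samples, got {x.size}")
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be between 1 and 3")
    if constrain_means is not None and init_means is None:
        raise ValueError("constrain_means requires init_means")

    notes: list[str] = []
    k = n_components
    if k == 1:
        # closed-form ML solution
        mu, sd = float(x.mean()), float(max(x.std(), _MIN_SIGMA))
        ll = float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(sd)
                          - 0.5 * ((x - mu) / sd) ** 2))
        bic = -2 * ll + 2 * np.log(x.size)
        return MixtureFit([GaussianComponent(mu, sd, 1.0)], ll, bic, True, x.size)

    rng = np.random.default_rng(seed)
    if init_means is not None:
        base_mu = np.asarray(init_means, dtype=float)
        if base_mu.size != k:
            raise ValueError("init_means length must equal n_components")
    else:
        base_mu = np.quantile(x, np.linspace(0.15, 0.85, k))
    bounds = None
    if constrain_means is not None:
        bounds = (base_mu - constrain_means, base_mu + constrain_means)

    best = None
    spread = max(x.std() / k, 0.01)
    for r in range(n_restarts):
        if r == 0:
            mu0 = base_mu.copy()
        else:
            jitter = constrain_means if constrain_means is not None else spread
            mu0 = base_mu + rng.uniform(-jitter, jitter, k)
            if bounds is not None:
                mu0 = np.clip(mu0, bounds[0], bounds[1])
        sigma0 = np.full(k, spread)
        w0 = np.full(k, 1.0 / k)
        mu, sigma, w, ll, conv = _em_once(x, mu0, sigma0, w0, bounds, max_iter, tol)
        if best is None or ll > best[3]:
            best = (mu, sigma, w, ll, conv)
    mu, sigma, w, ll, conv = best

    # merge components that collapsed onto the same mean
    order = np.argsort(mu)
    mu, sigma, w = mu[order], sigma[order], w[order]
    if k >= 2 and np.any(np.diff(mu) < merge_distance):
        notes.append(f"components within {merge_distance} merged; refit with {k - 1}")
        sub = fit_mixture(x, k - 1, init_means=None, n_restarts=n_restarts,
                          seed=seed, max_iter=max_iter, tol=tol,
                          merge_distance=merge_distance)
        sub.notes = notes + sub.notes
        return sub

    if not conv:
        notes.append("EM did not reach tolerance within max_iter")
        warnings.warn("fit_mixture: EM not converged", stacklevel=2)
    n_params = 3 * k - 1
    bic = -2 * ll + n_params * np.log(x.size)
    comps = [GaussianComponent(float(m), float(s), float(wt))
             for m, s, wt in zip(mu, sigma, w)]
    return MixtureFit(comps, ll, bic, conv, x.size, notes)


# ---------------------------------------------------------------------------
# Hill isotherms
# ---------------------------------------------------------------------------

@dataclass
class Isotherm:
    """Titration curve: responses (occupancy or mean FRET) vs concentration."""

    concentrations: np.ndarray
    responses: np.ndarray
    errors: np.ndarray | None = None
    unit: str = ""

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)


@dataclass
class HillFit:
    """Result of a Hill-equation fit: response = floor + amplitude*h(c)."""

    K_D: float
    n: float
    floor: float
    amplitude: float
    stderr: dict[str, float | None]
    covar: np.ndarray | None
    at_bound: bool
    unit: str = ""
    model: str = "hill"

    def predict(self, c):
        return hill_response(c, self.K_D, self.n, self.floor, self.amplitude)


def hill_response(c, K_D: float, n: float, floor: float = 0.0,
                  amplitude: float = 1.0):
    """Hill curve floor + amplitude * c**n / (K_D**n + c**n)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(over="ignore"):
        r = np.where(c > 0, (c / K_D) ** n, 0.0)
        frac = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    out = floor + amplitude * frac
    return float(out) if out.ndim == 0 else out


_N_BOUNDS = (0.3, 8.0)


def _hill_params(c, resp, init=None, fix_floor=None, fix_amplitude=None):
    p = lmfit.Parameters()
    init = init or {}
    lo, hi = float(resp.min()), float(resp.max())
    c_pos = c[c > 0]
    half = lo + 0.5 * (hi - lo)
    k0 = init.get("K_D")
    if k0 is None:
        idx = int(np.argmin(np.abs(resp - half)))
        k0 = c[idx] if c[idx] > 0 else float(np.sqrt(c_pos.min() * c_pos.max()))
    p.add("K_D", value=float(k0), min=c_pos.min() / 1e3, max=c_pos.max() * 1e3)
    p.add("n", value=float(init.get("n", 1.0)), min=_N_BOUNDS[0], max=_N_BOUNDS[1])
    if fix_floor is None:
        p.add("floor", value=float(init.get("floor", lo)))
    else:
        p.add("floor", value=float(fix_floor), vary=False)
    if fix_amplitude is None:
        p.add("amplitude", value=float(init.get("amplitude", hi - lo)))
    else:
        p.add("amplitude", value=float(fix_amplitude), vary=False)
    return p


def _finish_hill(result, unit="", model="hill") -> HillFit:
    v = result.params.valuesdict()
    stderr = {k: (result.params[k].stderr if result.params[k].vary else None)
              for k in ("K_D", "n", "floor", "amplitude")}
    at_bound = any(
        result.params[k].vary
        and (np.isclose(result.params[k].value, result.params[k].min)
             or np.isclose(result.params[k].value, result.params[k].max))
        for k in ("K_D", "n")
    )
    if at_bound:
        warnings.warn("Hill fit converged at a parameter bound", stacklevel=3)
    return HillFit(
        K_D=float(v["K_D"]), n=float(v["n"]), floor=float(v["floor"]),
        amplitude=float(v["amplitude"]), stderr=stderr,
        covar=getattr(result, "covar", None), at_bound=at_bound,
        unit=unit, model=model,
    )


def fit_hill(isotherm: Isotherm, init: dict | None = None) -> HillFit:
    """Weighted nonlinear least-squares Hill fit of a titration curve.

    Inverse-variance weights are used when the isotherm carries response
    errors; otherwise the fit is unweighted.  The Hill coefficient is bounded
    to [0.3, 8]; hitting a bound raises a warning and flags the result.
    """
    c, resp = isotherm.concentrations, isotherm.responses
    if c.size < 4:
        raise ValueError("need >= 4 titration points")
    params = _hill_params(c, resp, init)
    weights = None
    if isotherm.errors is not None:
        weights = 1.0 / np.asarray(isotherm.errors, dtype=float)

    def residual(p):
        r = resp - hill_response(c, p["K_D"], p["n"], p["floor"], p["amplitude"])
        return r * weights if weights is not None else r

    result = lmfit.minimize(residual, params, method="leastsq")
    return _finish_hill(result, unit=isotherm.unit)


def fit_two_state_occupancy(
    isotherm_U: Isotherm, isotherm_F: Isotherm, init: dict | None = None
) -> HillFit:
    """Global two-state binding fit of falling U and rising F_LB occupancies.

    A single (K_D, n) pair is fit jointly to both curves with the two
    occupancies constrained to sum to one:  F(c) = floor + amplitude*h(c),
    U(c) = 1 - F(c).  Pairs of occupancies summing above 1.05 are rejected
    as inconsistent.
    """
    cU, cF = isotherm_U.concentrations, isotherm_F.concentrations
    if cU.shape != cF.shape or not np.allclose(cU, cF):
        raise ValueError("U and F isotherms must share the concentration grid")
    total = isotherm_U.responses + isotherm_F.responses
    if np.any(total > 1.05):
        raise ValueError("occupancy pairs sum above 1.05; not a two-state system")
    if cU.size < 4:
        raise ValueError("need >= 4 titration points")
    params = _hill_params(cF, isotherm_F.responses, init)

    def residual(p):
        f = hill_response(cF, p["K_D"], p["n"], p["floor"], p["amplitude"])
        return np.concatenate([isotherm_F.responses - f,
                               isotherm_U.responses - (1.0 - f)])

    result = lmfit.minimize(residual, params, method="leastsq")
    return _finish_hill(result, unit=isotherm_F.unit, model="two_state_global")


def fit_flf_flb_exchange(
    concentrations,
    frac_FLF,
    frac_FLB,
    init: dict | None = None,
) -> HillFit:
    """Global Hill fit of the F_LF/F_LB population exchange vs ligand.

    F_LF falls and F_LB rises with a shared (K_D, n); the U population is
    treated as a constant offset and excluded.  The fitted `amplitude` is
    the exchanged population fraction and `floor` the F_LB occupancy at
    zero ligand.
    """
    c = np.asarray(concentrations, dtype=float)
    flf = np.asarray(frac_FLF, dtype=float)
    flb = np.asarray(frac_FLB, dtype=float)
    if not (c.shape == flf.shape == flb.shape):
        raise ValueError("inputs must align")
    if c.size < 4:
        raise ValueError("need >= 4 titration points")
    if np.all(flb <= 0):
        raise ValueError("F_LB never populated; no exchange transition to fit")
    params = _hill_params(c, flb, init)
    params.add("flf0", value=float(flf.max()))

    def residual(p):
        h = hill_response(c, p["K_D"], p["n"], 0.0, 1.0)
        flb_model = p["floor"] + p["amplitude"] * h
        flf_model = p["flf0"] - p["amplitude"] * h
        return np.concatenate([flb - flb_model, flf - flf_model])

    result = lmfit.minimize(residual, params, method="leastsq")
    return _finish_hill(result, model="flf_flb_exchange")
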