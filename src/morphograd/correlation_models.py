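"""Fluorescence (cross-)correlation spectroscopy models and fitting.

FCS infers mobility and concentration from the autocorrelation of
fluorescence intensity fluctuations in a diffraction-limited observation
volume. The correlation amplitude at zero lag is the inverse of the mean
particle number N in the volume, and the correlation decays on the
timescale tau_d a particle needs to cross it, from which the diffusion
coefficient follows as D = omega0**2 / (4 * tau_d).

Implemented model family (all with an optional fast photophysical
"triplet" decay and a long-lag offset G_inf):

- 3D one-component diffusion (free ligand in the extracellular space),
- 2D one-component diffusion (membrane-anchored receptor),
- 3D two-component diffusion (mixtures of free and complexed species),
- the cross-correlation model used for dual-color FCCS, a one-component
  lateral-diffusion form without triplet term.

Fitting uses the Levenberg-Marquardt algorithm with multi-start
refinement, weighted by per-point standard errors when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "InvalidParameterError",
    "CorrelationCurve",
    "TripletDiffusionParams",
    "ObservationVolume",
    "CorrelationFit",
    "acf_3d_1c_triplet",
    "acf_2d_1c_triplet",
    "acf_3d_2c_triplet",
    "ccf_model",
    "fit_correlation",
    "diffusion_from_tau",
    "MODEL_KINDS",
]

MODEL_KINDS = ("3d1c", "2d1c", "3d2c", "ccf")

CHANNEL_KINDS = ("auto_green", "auto_red", "cross")


class InvalidParameterError(ValueError):
    """A correlation-model parameter is non-finite or out of range."""


@dataclass(frozen=True)
class ObservationVolume:
    """Confocal detection volume with 3D Gaussian profile.

    Parameters
    ----------
    omega0 : float
        Lateral 1/e**2 radius in micrometres.
    z0 : float
        Axial 1/e**2 half-length in micrometres.
    """

    omega0: float
    z0: float

    def __post_init__(self) -> None:
        if not (self.omega0 > 0 and self.z0 > 0):
            raise InvalidParameterError("omega0 and z0 must be positive")

    @property
    def v_eff(self) -> float:
        """Effective volume pi**1.5 * omega0**2 * z0 in cubic micrometres."""
        return math.pi ** 1.5 * self.omega0 ** 2 * self.z0

    @property
    def structure_ratio(self) -> float:
        """omega0 / z0, the inverse of the usual structure parameter."""
        return self.omega0 / self.z0


@dataclass
class CorrelationCurve:
    """One measured correlation function: lag times vs. amplitudes."""

    lag: np.ndarray
    g: np.ndarray
    sigma: np.ndarray | None = None
    channel_kind: str = "auto_green"

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lag.ndim != 1 or self.lag.shape != self.g.shape:
            raise ValueError("lag and g must be 1D arrays of equal length")
        if not (np.all(self.lag > 0) and np.all(np.diff(self.lag) > 0)):
            raise ValueError("lag must be strictly increasing and positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.lag.shape or not np.all(self.sigma > 0):
                raise ValueError("sigma must match lag and be positive")
        if self.channel_kind not in CHANNEL_KINDS:
            raise ValueError(f"channel_kind must be one of {CHANNEL_KINDS}")


@dataclass
class TripletDiffusionParams:
    """Parameters of the triplet-plus-diffusion correlation models.

    ``tau_d`` and ``frac`` are per-component lists; one-component models
    use a single entry with ``frac == [1.0]``. ``structure_ratio`` is
    omega0/z0 and only enters the 3D forms.
    """

    n_particles: float
    tau_d: list[float]
    frac: list[float] = field(default_factory=lambda: [1.0])
    f_trip: float = 0.0
    tau_trip: float = 1e-5
    structure_ratio: float = 0.2
    g_inf: float = 0.0

    def __post_init__(self) -> None:
        self.tau_d = [float(t) for t in np.atleast_1d(self.tau_d)]
        self.frac = [float(f) for f in np.atleast_1d(self.frac)]
        vals = [self.n_particles, self.f_trip, self.tau_trip,
                self.structure_ratio, self.g_inf, *self.tau_d, *self.frac]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("parameters must be finite")
        if self.n_particles <= 0:
            raise InvalidParameterError("n_particles must be > 0")
        if not 0 <= self.f_trip < 1:
            raise InvalidParameterError("f_trip must be in [0, 1)")
        if self.tau_trip <= 0:
            raise InvalidParameterError("tau_trip must be > 0")
        if any(t <= 0 for t in self.tau_d):
            raise InvalidParameterError("diffusion times must be > 0")
        if len(self.frac) != len(self.tau_d):
            raise InvalidParameterError("frac and tau_d lengths differ")
        if abs(sum(self.frac) - 1.0) > 1e-9:
            raise InvalidParameterError("component fractions must sum to 1")
        if not 0 < self.structure_ratio <= 1:
            raise InvalidParameterError("structure_ratio must be in (0, 1]")


@dataclass
class CorrelationFit:
    """Result of fitting a correlation model to a curve."""

    params: TripletDiffusionParams | None
    diffusion_coeff: list[float] | None
    param_errors: dict[str, float]
    residual_norm: float
    converged: bool
    model_kind: str = ""


def _triplet_factor(f_trip: float, tau_trip: float, lag: np.ndarray) -> np.ndarray:
    if f_trip == 0:
        return np.ones_like(np.asarray(lag, dtype=float))
    return 1.0 + (f_trip / (1.0 - f_trip)) * np.exp(-np.asarray(lag) / tau_trip)


def _check_lag(lag) -> np.ndarray:
    lag = np.asarray(lag, dtype=float)
    if np.any(lag <= 0) or not np.all(np.isfinite(lag)):
        raise InvalidParameterError("lag times must be positive and finite")
    return lag


def acf_3d_1c_triplet(params: TripletDiffusionParams, lag) -> np.ndarray:
    """One-component 3D diffusion autocorrelation with triplet state.

    G(tau) = (1/N) * [1 + F/(1-F) * exp(-tau/tau_trip)]
             * (1 + tau/tau_d)^-1 * [1 + (omega0/z0)^2 tau/tau_d]^-1/2
             + G_inf
    """
    lag = _check_lag(lag)
    if len(params.tau_d) != 1:
        raise InvalidParameterError("3d1c model needs exactly one component")
    x = lag / params.tau_d[0]
    g = (_triplet_factor(params.f_trip, params.tau_trip, lag)
         / params.n_particles
         / (1.0 + x)
         / np.sqrt(1.0 + params.structure_ratio ** 2 * x))
    return g + params.g_inf


def acf_2d_1c_triplet(params: TripletDiffusionParams, lag) -> np.ndarray:
    """One-component 2D (lateral) diffusion autocorrelation with triplet.

    Used for membrane-anchored species; no axial term.
    """
    lag = _check_lag(lag)
    if len(params.tau_d) != 1:
        raise InvalidParameterError("2d1c model needs exactly one component")
    g = (_triplet_factor(params.f_trip, params.tau_trip, lag)
         / params.n_particles
         / (1.0 + lag / params.tau_d[0]))
    return g + params.g_inf


def acf_3d_2c_triplet(params: TripletDiffusionParams, lag) -> np.ndarray:
    """Two-component 3D diffusion autocorrelation with shared triplet."""
    lag = _check_lag(lag)
    if len(params.tau_d) != 2:
        raise InvalidParameterError("3d2c model needs exactly two components")
    acc = np.zeros_like(lag)
    for f_i, tau_i in zip(params.frac, params.tau_d):
        x = lag / tau_i
        acc += f_i / (1.0 + x) / np.sqrt(1.0 + params.structure_ratio ** 2 * x)
    g = (_triplet_factor(params.f_trip, params.tau_trip, lag)
         / params.n_particles * acc)
    return g + params.g_inf


def ccf_model(params: TripletDiffusionParams, lag) -> np.ndarray:
    """Cross-correlation model: one component, no triplet term.

    G(tau) = (1/N) * (1 + tau/tau_d)^-1 + G_inf
    """
    lag = _check_lag(lag)
    if len(params.tau_d) != 1:
        raise InvalidParameterError("ccf model needs exactly one component")
    return 1.0 / params.n_particles / (1.0 + lag / params.tau_d[0]) + params.g_inf


_MODEL_FUNCS = {
    "3d1c": acf_3d_1c_triplet,
    "2d1c": acf_2d_1c_triplet,
    "3d2c": acf_3d_2c_triplet,
    "ccf": ccf_model,
}

# triplet bounds chosen to keep the triplet and diffusion terms from
# exchanging roles during fitting
DEFAULT_BOUNDS = {
    "n_particles": (1e-4, 1e7),
    "f_trip": (0.0, 0.5),
    "tau_trip": (1e-7, 1e-4),
    "tau_d": (1e-8, 1e2),
    "frac": (0.0, 1.0),
    "g_inf": (-0.5, 0.5),
}


def _params_to_lmfit(init: TripletDiffusionParams, model_kind: str,
                     bounds: dict | None) -> Parameters:
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    p = Parameters()
    p.add("n_particles", value=init.n_particles, min=b["n_particles"][0],
          max=b["n_particles"][1])
    # the triplet term is fitted only when the initial guess declares a
    # triplet fraction; starting from f_trip=0 pins it, preventing the
    # triplet/diffusion exchange degeneracy on photophysics-free data
    has_triplet = model_kind != "ccf" and init.f_trip > 0
    p.add("f_trip", value=init.f_trip if has_triplet else 0.0,
          min=b["f_trip"][0], max=b["f_trip"][1], vary=has_triplet)
    p.add("tau_trip", value=init.tau_trip, min=b["tau_trip"][0],
          max=b["tau_trip"][1], vary=has_triplet)
    n_comp = 2 if model_kind == "3d2c" else 1
    for i in range(n_comp):
        p.add(f"tau_d{i}", value=init.tau_d[i] if i < len(init.tau_d)
              else init.tau_d[-1] * 10,
              min=b["tau_d"][0], max=b["tau_d"][1])
    if n_comp == 2:
        p.add("frac0", value=init.frac[0], min=b["frac"][0], max=b["frac"][1])
    p.add("g_inf", value=init.g_inf, min=b["g_inf"][0], max=b["g_inf"][1])
    return p


def _lmfit_to_params(p, model_kind: str, structure_ratio: float) -> TripletDiffusionParams:
    n_comp = 2 if model_kind == "3d2c" else 1
    tau_d = [p[f"tau_d{i}"].value for i in range(n_comp)]
    if n_comp == 2:
        frac = [p["frac0"].value, 1.0 - p["frac0"].value]
        # components reported in order of ascending diffusion time
        if tau_d[0] > tau_d[1]:
            tau_d = tau_d[::-1]
            frac = frac[::-1]
    else:
        frac = [1.0]
    return TripletDiffusionParams(
        n_particles=p["n_particles"].value,
        tau_d=tau_d,
        frac=frac,
        f_trip=p["f_trip"].value if model_kind != "ccf" else 0.0,
        tau_trip=p["tau_trip"].value,
        structure_ratio=structure_ratio,
        g_inf=p["g_inf"].value,
    )


def fit_correlation(
    curve: CorrelationCurve,
    model_kind: str,
    init: TripletDiffusionParams,
    bounds: dict | None = None,
    volume: ObservationVolume | None = None,
    max_restarts: int = 5,
) -> CorrelationFit:
    """Fit a correlation model to a measured curve by Levenberg-Marquardt.

    Residuals are weighted by ``curve.sigma`` when present. If the first
    fit does not converge, up to ``max_restarts`` restarts from jittered
    initial values (deterministic sub-seeds) are attempted. Failure is
    reported through ``converged=False``, never as an exception.

    Parameters
    ----------
    curve : CorrelationCurve
    model_kind : {"3d1c", "2d1c", "3d2c", "ccf"}
    init : TripletDiffusionParams
        Starting values; its ``structure_ratio`` is used unless ``volume``
        is given.
    bounds : dict, optional
        Per-name ``(lo, hi)`` overrides of the default parameter box.
    volume : ObservationVolume, optional
        When given, per-component diffusion coefficients
        ``omega0**2 / (4 tau_d)`` are attached to the result.
    """
    if model_kind not in _MODEL_FUNCS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    structure_ratio = (volume.structure_ratio if volume is not None
                       else init.structure_ratio)
    model_func = _MODEL_FUNCS[model_kind]

    failure = CorrelationFit(params=None, diffusion_coeff=None,
                             param_errors={}, residual_norm=float("inf"),
                             converged=False, model_kind=model_kind)
    if np.ptp(curve.g) == 0:
        return failure  # constant curve carries no decay information

    weights = 1.0 / curve.sigma if curve.sigma is not None else None

    def residual(p):
        pars = _lmfit_to_params(p, model_kind, structure_ratio)
        r = model_func(pars, curve.lag) - curve.g
        return r * weights if weights is not None else r

    rng = np.random.default_rng(12345)
    best = None
    n_success = 0
    for attempt in range(max_restarts + 1):
        start = init
        if attempt > 0:
            jit = rng.lognormal(0.0, 0.3, size=1 + len(init.tau_d))
            start = replace(
                init,
                n_particles=init.n_particles * jit[0],
                tau_d=[t * j for t, j in zip(init.tau_d, jit[1:])],
            )
        try:
            out = minimize(residual, _params_to_lmfit(start, model_kind, bounds),
                           method="leastsq", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if out.success:
            n_success += 1
            if (best is None or not best.success
                    or np.sum(out.residual ** 2) < np.sum(best.residual ** 2)):
                best = out
            # a couple of agreeing starts guard against local minima
            if n_success >= 2:
                break
        elif best is None:
            best = out

    if best is None or not best.success:
        return failure

    fitted = _lmfit_to_params(best.params, model_kind, structure_ratio)
    errors = {name: (par.stderr if par.stderr is not None else float("nan"))
              for name, par in best.params.items() if par.vary}
    d = ([diffusion_from_tau(t, volume) for t in fitted.tau_d]
         if volume is not None else None)
    return CorrelationFit(
        params=fitted,
        diffusion_coeff=d,
        param_errors=errors,
        residual_norm=float(np.sum(best.residual ** 2)),
        converged=True,
        model_kind=model_kind,
    )


def diffusion_from_tau(tau_d: float, volume: ObservationVolume) -> float:
    """Diffusion coefficient from diffusion time: D = omega0**2 / (4 tau_d)."""
    if tau_d <= 0:
        raise InvalidParameterError("tau_d must be > 0")
    return volume.omega0 ** 2 / (4.0 * tau_d)
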