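"""Ligand-receptor binding: Kd estimation, equilibrium, gradient length.

Dual-color FCCS measures, in each sample, the concentrations of free
green-labeled ligand (C_g), free red-labeled binding partner (C_r) and
bound complex (C_gr). At equilibrium C_g * C_r = Kd * C_gr, so the
dissociation constant is the slope of C_g*C_r regressed on C_gr across
samples, or equivalently the center of the per-sample ln(Kd)
distribution.

The fraction of total ligand L_t bound by total receptor R_t at
dissociation constant Kd follows from mass action and conservation:

    f_bound = (Kd + L_t + R_t)/(2 L_t)
              - sqrt((Kd + L_t + R_t)**2 / (4 L_t**2) - R_t / L_t)

Transient trapping on an excess of immobile binding sites slows
transport: D_eff = D * f_free, and a source-sink gradient with constant
clearance k has decay length

    lambda = sqrt(D / k) / sqrt(R / Kd + 1)

with D the free diffusion coefficient. All concentrations are in nM
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from morphograd.correlation_models import ObservationVolume

__all__ = [
    "NoBindingError",
    "InconsistentAmplitudesError",
    "BindingMeasurement",
    "KdEstimate",
    "BindingEquilibrium",
    "TransportParams",
    "concentrations_from_amplitudes",
    "kd_by_regression",
    "kd_by_histogram",
    "bound_fraction",
    "effective_diffusion",
    "gradient_length",
    "receptor_from_gradient",
    "number_to_nanomolar",
]

#: 1 / (N_Avogadro * 1 um^3), expressed in nM: one particle per cubic
#: micrometre is 1/0.602214076 nM.
_NM_PER_PARTICLE_PER_UM3 = 1.0 / 0.602214076


class NoBindingError(ValueError):
    """No bound complex detected; Kd cannot be estimated."""


class InconsistentAmplitudesError(ValueError):
    """Cross-correlation amplitude exceeds an autocorrelation amplitude."""


@dataclass
class BindingMeasurement:
    """Free and bound concentrations (nM) from one sample/embryo."""

    c_g: float
    c_r: float
    c_gr: float
    embryo_id: str = ""

    def __post_init__(self) -> None:
        vals = (self.c_g, self.c_r, self.c_gr)
        if not all(math.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("concentrations must be finite and non-negative")


@dataclass
class KdEstimate:
    kd_regression: float
    kd_hist_mode: float
    kd_se: float
    n_points: int


@dataclass
class BindingEquilibrium:
    kd: float
    l_total: float
    r_total: float
    f_bound: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_bound <= 1:
            raise ValueError("f_bound must be in [0, 1]")


@dataclass
class TransportParams:
    """Transport summary: free, tortuosity-reduced and effective D, plus
    clearance rate and resulting gradient length."""

    d_free: float
    d_tort: float
    d_eff: float
    k_clear: float
    lambda_: float

    def __post_init__(self) -> None:
        if not (0 < self.d_eff <= self.d_tort <= self.d_free):
            raise ValueError("require 0 < d_eff <= d_tort <= d_free")
        if self.k_clear <= 0 or self.lambda_ <= 0:
            raise ValueError("k_clear and lambda_ must be positive")


def number_to_nanomolar(n: float, volume: ObservationVolume | float) -> float:
    """Convert a particle number in the effective volume to nM.

    ``volume`` is an :class:`ObservationVolume` or a volume in um^3
    (1 fL == 1 um^3).
    """
    v = volume.v_eff if isinstance(volume, ObservationVolume) else float(volume)
    return n / v * _NM_PER_PARTICLE_PER_UM3


def concentrations_from_amplitudes(
    g_auto_green0: float,
    g_auto_red0: float,
    g_cross0: float,
    volume: ObservationVolume | float,
    embryo_id: str = "",
) -> BindingMeasurement:
    """Free/bound concentrations from ideal zero-lag FCCS amplitudes.

    Total particle numbers are N_g = 1/G_g(0) and N_r = 1/G_r(0); the
    complex number is N_gr = G_x(0) / (G_g(0) * G_r(0)); free numbers
    follow by subtraction. Assumes ideal amplitudes (no spectral
    cross-talk or background correction).
    """
    if not (g_auto_green0 > 0 and g_auto_red0 > 0 and g_cross0 >= 0):
        raise ValueError("autocorrelation amplitudes must be positive")
    if g_cross0 > min(g_auto_green0, g_auto_red0) * (1 + 1e-12):
        raise InconsistentAmplitudesError(
            "cross-correlation amplitude exceeds an autocorrelation amplitude")
    n_g_total = 1.0 / g_auto_green0
    n_r_total = 1.0 / g_auto_red0
    n_gr = g_cross0 / (g_auto_green0 * g_auto_red0)
    return BindingMeasurement(
        c_g=number_to_nanomolar(max(n_g_total - n_gr, 0.0), volume),
        c_r=number_to_nanomolar(max(n_r_total - n_gr, 0.0), volume),
        c_gr=number_to_nanomolar(n_gr, volume),
        embryo_id=embryo_id,
    )


def kd_by_regression(measurements: list[BindingMeasurement]) -> KdEstimate:
    """Kd as the slope of C_g*C_r regressed on C_gr (free intercept).

    Also fills ``kd_hist_mode`` from the per-sample ln(Kd) histogram
    when at least five samples have bound complex.
    """
    ms = [m for m in measurements if m.c_gr > 0]
    if not ms:
        raise NoBindingError("no measurement has positive bound concentration")
    if len(ms) < 3:
        raise ValueError("need at least 3 measurements with c_gr > 0")
    x = np.array([m.c_gr for m in ms])
    y = np.array([m.c_g * m.c_r for m in ms])
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise NoBindingError("non-positive regression slope; no binding signal")
    per_sample = [m.c_g * m.c_r / m.c_gr for m in ms
                  if m.c_g > 0 and m.c_r > 0]
    hist_mode = float("nan")
    if len(per_sample) >= 5:
        hist_mode = kd_by_histogram(per_sample).kd_hist_mode
    return KdEstimate(
        kd_regression=float(res.slope),
        kd_hist_mode=hist_mode,
        kd_se=float(res.stderr),
        n_points=len(ms),
    )


def _gaussian(x, amp, mu, sig):
    return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)


def kd_by_histogram(per_sample_kd: list[float]) -> KdEstimate:
    """Kd as exp(mean) of a Gaussian fitted to the ln(Kd) histogram.

    Bins follow the Freedman-Diaconis rule; the Gaussian is fitted to
    bin centers vs. counts by least squares. Degenerate inputs (all
    values equal) return that value directly.
    """
    vals = np.asarray(per_sample_kd, dtype=float)
    if vals.size < 5:
        raise ValueError("need at least 5 Kd values")
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError("Kd values must be positive and finite")
    ln_kd = np.log(vals)
    if np.ptp(ln_kd) < 1e-12:  # degenerate: a single spike
        return KdEstimate(kd_regression=float("nan"),
                          kd_hist_mode=float(np.exp(np.mean(ln_kd))),
                          kd_se=0.0, n_points=vals.size)
    try:
        counts, edges = np.histogram(ln_kd, bins="fd")
    except ValueError:  # zero-IQR data defeat the FD rule
        counts, edges = np.histogram(ln_kd, bins="sturges")
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (counts.max(), float(np.mean(ln_kd)), max(float(np.std(ln_kd)), 1e-6))
    try:
        popt, pcov = optimize.curve_fit(_gaussian, centers, counts, p0=p0,
                                        maxfev=10000)
        mu, se_mu = popt[1], math.sqrt(max(pcov[1, 1], 0.0))
    except RuntimeError:
        # too few populated bins for a stable fit: fall back to moments
        mu = float(np.mean(ln_kd))
        se_mu = float(np.std(ln_kd, ddof=1) / math.sqrt(vals.size))
    kd = math.exp(mu)
    return KdEstimate(kd_regression=float("nan"), kd_hist_mode=kd,
                      kd_se=kd * se_mu, n_points=vals.size)


def bound_fraction(kd: float, l_total: float, r_total: float) -> float:
    """Bound ligand fraction from the quadratic mass-action equilibrium."""
    if not (kd > 0 and l_total > 0 and r_total > 0):
        raise ValueError("kd, l_total and r_total must be positive")
    s = (kd + l_total + r_total) / (2.0 * l_total)
    disc = s * s - r_total / l_total
    f = s - math.sqrt(max(disc, 0.0))
    return min(max(f, 0.0), 1.0)


def effective_diffusion(d_base: float, f_free: float) -> float:
    """Effective diffusion under fast-exchange trapping: D_eff = D * f_free."""
    if d_base <= 0:
        raise ValueError("d_base must be positive")
    if not 0 < f_free <= 1:
        raise ValueError("f_free must be in (0, 1]")
    return d_base * f_free


def gradient_length(d_free: float, k_clear: float, r_total: float,
                    kd: float) -> float:
    """Gradient decay length lambda = sqrt(D/k) / sqrt(R/Kd + 1) in um."""
    if min(d_free, k_clear, r_total, kd) <= 0:
        raise ValueError("all inputs must be positive")
    return math.sqrt(d_free / k_clear) / math.sqrt(r_total / kd + 1.0)


def receptor_from_gradient(lambda_: float, d_free: float, k_clear: float,
                           kd: float) -> float:
    """Receptor concentration implied by an observed gradient length.

    Inverts the gradient-length relation: R = Kd * (D / (k lambda**2) - 1).
    Binding can only shorten a gradient, so lambda must be below the
    unhindered source-sink length sqrt(D/k).
    """
    if min(lambda_, d_free, k_clear, kd) <= 0:
        raise ValueError("all inputs must be positive")
    if lambda_ >= math.sqrt(d_free / k_clear):
        raise ValueError("lambda must be < sqrt(D/k); binding cannot "
                         "lengthen a gradient")
    return kd * (d_free / (k_clear * lambda_ ** 2) - 1.0)
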