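"""Synthetic data generators with carried ground truth.

Every generator is a pure function of its parameters and seed and
returns ``(data, GroundTruth)`` so each analysis stage has a round-trip
recovery test without any external measurement:

- noisy FCS/FCCS correlation curves evaluated from the closed-form
  models, with FCS-like heteroscedastic noise (larger at short lags),
- a physical oracle that simulates Brownian particles through a 3D
  Gaussian detection profile and correlates the resulting intensity
  trace — an independent route to the same autocorrelation shape,
- per-sample free/bound concentration sets drawn from the exact
  mass-action equilibrium at a known Kd,
- exponential-gradient embryo images with autofluorescence background
  and Gaussian noise,
- protein-decay time courses with per-lane loading factors and a
  loading-control channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from morphograd.binding_affinity import BindingMeasurement
from morphograd.correlation_models import (
    CorrelationCurve,
    ObservationVolume,
    TripletDiffusionParams,
    _MODEL_FUNCS,
)
from morphograd.clearance_kinetics import DecaySeries
from morphograd.gradient_profiling import EmbryoImage

__all__ = [
    "GroundTruth",
    "DEFAULT_VOLUME",
    "default_lag_grid",
    "synth_correlation_curve",
    "brownian_photon_oracle",
    "synth_fccs_dataset",
    "synth_gradient_image",
    "synth_decay_series",
]

#: Default confocal observation volume for synthetic work
#: (lateral radius 0.25 um, axial half-length 1.25 um; structure ratio 0.2).
DEFAULT_VOLUME = ObservationVolume(omega0=0.25, z0=1.25)


@dataclass
class GroundTruth:
    """Parameters a generated dataset was produced from."""

    d_true: float | list[float] | None = None
    n_true: float | list[float] | None = None
    kd_true: float | None = None
    lambda_true: float | None = None
    k_true: float | None = None
    f_trip_true: float = 0.0
    noise_level: float = 0.0
    seed: int = 0


def default_lag_grid(n_points: int = 200) -> np.ndarray:
    """Logarithmic lag grid from 1 us to 1 s."""
    return np.logspace(-6, 0, n_points)


def synth_correlation_curve(
    truth: GroundTruth,
    model_kind: str = "3d1c",
    volume: ObservationVolume = DEFAULT_VOLUME,
    lag_grid: np.ndarray | None = None,
    tau_trip: float = 5e-6,
    channel_kind: str = "auto_green",
) -> tuple[CorrelationCurve, GroundTruth]:
    """Noisy correlation curve from a known (D, N, triplet) ground truth.

    The chosen model is evaluated on the lag grid and Gaussian noise
    with standard deviation ``noise_level * G(tau) * sqrt(tau_min/tau)``
    is added — relatively larger at short lags, as in measured FCS
    curves. The per-point noise scale is returned as ``sigma``.
    """
    if lag_grid is None:
        lag_grid = default_lag_grid()
    d = np.atleast_1d(np.asarray(truth.d_true, dtype=float))
    n = float(np.sum(np.atleast_1d(truth.n_true)))
    fracs = (np.atleast_1d(truth.n_true) / n
             if np.ndim(truth.n_true) else np.array([1.0]))
    tau_d = [volume.omega0 ** 2 / (4.0 * di) for di in d]
    params = TripletDiffusionParams(
        n_particles=n, tau_d=tau_d, frac=list(fracs),
        f_trip=truth.f_trip_true, tau_trip=tau_trip,
        structure_ratio=volume.structure_ratio, g_inf=0.0)
    g = _MODEL_FUNCS[model_kind](params, lag_grid)
    sigma = truth.noise_level * g * np.sqrt(lag_grid[0] / lag_grid)
    rng = np.random.default_rng(truth.seed)
    noisy = g + rng.normal(0.0, 1.0, size=g.shape) * sigma
    curve = CorrelationCurve(
        lag=lag_grid, g=noisy,
        sigma=sigma if truth.noise_level > 0 else None,
        channel_kind=channel_kind)
    return curve, truth


def brownian_photon_oracle(
    d: float,
    n: int,
    volume: ObservationVolume = DEFAULT_VOLUME,
    duration: float = 10.0,
    dt: float = 2e-5,
    seed: int = 0,
    box_xy: float | None = None,
    box_z: float | None = None,
    max_lag: float = 0.05,
    n_lag_points: int = 60,
) -> CorrelationCurve:
    """Autocorrelation of a simulated fluorescence intensity trace.

    ``n`` particles diffuse with coefficient ``d`` in a periodic box
    around the focus; the instantaneous intensity is the sum of the 3D
    Gaussian detection profile evaluated at each particle,
    I(t) = sum_i exp(-2 r_i^2/omega0^2 - 2 z_i^2/z0^2). The normalized
    fluctuation autocorrelation of I(t) is returned on a logarithmic
    lag grid. This route shares no code with the closed-form models and
    serves as an independent physical oracle for them.
    """
    if n < 1 or duration <= 0 or dt <= 0:
        raise ValueError("need n >= 1 and positive duration/dt")
    lx = box_xy if box_xy is not None else 10.0 * volume.omega0
    lz = box_z if box_z is not None else 6.0 * volume.z0
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    sigma_step = math.sqrt(2.0 * d * dt)

    pos = rng.uniform(-0.5, 0.5, size=(n, 3)) * np.array([lx, lx, lz])
    intensity = np.empty(n_steps)
    chunk = 20000
    i0 = 0
    while i0 < n_steps:
        k = min(chunk, n_steps - i0)
        if sigma_step > 0:
            steps = rng.normal(0.0, sigma_step, size=(k, n, 3))
            traj = pos[None, :, :] + np.cumsum(steps, axis=0)
        else:
            traj = np.broadcast_to(pos, (k, n, 3)).copy()
        # periodic wrap about the focus at the origin
        traj[..., :2] = (traj[..., :2] + lx / 2) % lx - lx / 2
        traj[..., 2] = (traj[..., 2] + lz / 2) % lz - lz / 2
        w = np.exp(-2.0 * (traj[..., 0] ** 2 + traj[..., 1] ** 2)
                   / volume.omega0 ** 2
                   - 2.0 * traj[..., 2] ** 2 / volume.z0 ** 2)
        intensity[i0:i0 + k] = w.sum(axis=1)
        if sigma_step > 0:
            pos = pos + np.cumsum(steps, axis=0)[-1]
            pos[:, :2] = (pos[:, :2] + lx / 2) % lx - lx / 2
            pos[:, 2] = (pos[:, 2] + lz / 2) % lz - lz / 2
        i0 += k

    mean_i = intensity.mean()
    fluct = intensity - mean_i
    m = 1 << int(np.ceil(np.log2(2 * n_steps)))
    spec = np.fft.rfft(fluct, m)
    acov = np.fft.irfft(spec * np.conj(spec), m)[:n_steps]
    acov /= np.arange(n_steps, 0, -1)  # unbiased normalization
    g_full = acov / mean_i ** 2

    max_idx = min(int(max_lag / dt), n_steps - 1)
    idx = np.unique(np.geomspace(1, max_idx, n_lag_points).astype(int))
    return CorrelationCurve(lag=idx * dt, g=g_full[idx],
                            channel_kind="auto_green")


def _equilibrium_complex(l_total: float, r_total: float, kd: float) -> float:
    """Bound-complex concentration from the exact mass-action quadratic."""
    s = l_total + r_total + kd
    return 0.5 * (s - math.sqrt(s * s - 4.0 * l_total * r_total))


def synth_fccs_dataset(
    kd_true: float,
    c_g_range: tuple[float, float] = (20.0, 200.0),
    c_r_range: tuple[float, float] = (20.0, 400.0),
    n_samples: int = 20,
    noise_level: float = 0.1,
    seed: int = 0,
) -> tuple[list[BindingMeasurement], GroundTruth]:
    """Per-sample free/bound concentration sets at a fixed true Kd.

    Total concentrations are drawn uniformly from the given nM ranges,
    the exact equilibrium is solved, and multiplicative log-normal
    noise of scale ``noise_level`` is applied to each reported
    concentration (emulating per-embryo calibration scatter).
    """
    if kd_true <= 0:
        raise ValueError("kd_true must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_samples):
        lt = rng.uniform(*c_g_range)
        rt = rng.uniform(*c_r_range)
        c_gr = _equilibrium_complex(lt, rt, kd_true)
        vals = np.array([lt - c_gr, rt - c_gr, c_gr])
        if noise_level > 0:
            vals = vals * rng.lognormal(0.0, noise_level, size=3)
        out.append(BindingMeasurement(c_g=vals[0], c_r=vals[1],
                                      c_gr=vals[2], embryo_id=f"synth{i:03d}"))
    truth = GroundTruth(kd_true=kd_true, noise_level=noise_level, seed=seed)
    return out, truth


def synth_gradient_image(
    lambda_true: float,
    amplitude: float = 1000.0,
    background: float = 50.0,
    noise_level: float = 0.0,
    shape_px: tuple[int, int] = (512, 512),
    pixel_size: float = 1.4,
    source_boundary: int = 32,
    seed: int = 0,
) -> tuple[EmbryoImage, GroundTruth]:
    """Exponential-gradient image with background and Gaussian noise.

    Columns left of ``source_boundary`` hold the source plateau; to the
    right the intensity decays as ``amplitude * exp(-x/lambda_true)``
    with x the distance from the boundary. Gaussian noise with standard
    deviation ``noise_level * amplitude`` is added everywhere (so an
    SNR-10 image corresponds to ``noise_level=0.1``).
    """
    if lambda_true <= 0:
        raise ValueError("lambda_true must be positive")
    h, w = shape_px
    cols = np.arange(w, dtype=float)
    x_um = np.clip(cols - source_boundary, 0.0, None) * pixel_size
    row = amplitude * np.exp(-x_um / lambda_true) + background
    img = np.tile(row, (h, 1))
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_level * amplitude, size=img.shape)
    image = EmbryoImage(pixels=img, pixel_size=pixel_size,
                        source_boundary=source_boundary,
                        background_level=background)
    truth = GroundTruth(lambda_true=lambda_true, noise_level=noise_level,
                        seed=seed)
    return image, truth


def synth_decay_series(
    k_true: float,
    timepoints_hr: list[float] = (0.0, 6.0, 12.0, 24.0),
    loading_factors: list[float] | None = None,
    noise_level: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> tuple[DecaySeries, GroundTruth]:
    """Protein-decay time course with loading-control structure.

    Each lane's band intensity is ``loading_factor * exp(-k_true * t)``
    and its control is ``loading_factor`` alone, both perturbed by
    ``(1 + noise_level * Z)`` with independent standard normals Z — so
    dividing by the control removes the loading factors exactly in the
    noise-free case.
    """
    if k_true < 0:
        raise ValueError("k_true must be non-negative")
    t_hr = np.asarray(timepoints_hr, dtype=float)
    rng = np.random.default_rng(seed)
    if loading_factors is None:
        lf = rng.lognormal(0.0, 0.2, size=t_hr.size)
    else:
        lf = np.asarray(loading_factors, dtype=float)
        if lf.shape != t_hr.shape:
            raise ValueError("loading_factors must match timepoints")
    decay = np.exp(-k_true * t_hr * 3600.0)
    intensity = lf * decay
    control = lf.copy()
    if noise_level > 0:
        intensity = intensity * (1.0 + rng.normal(0.0, noise_level,
                                                  size=t_hr.size))
        control = control * (1.0 + rng.normal(0.0, noise_level,
                                              size=t_hr.size))
    series = DecaySeries(t=t_hr, intensity=np.clip(intensity, 1e-12, None),
                         control=np.clip(control, 1e-12, None),
                         label=label, time_unit="hr")
    truth = GroundTruth(k_true=k_true, noise_level=noise_level, seed=seed)
    return series, truth
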