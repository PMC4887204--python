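"""Clearance-rate estimation from protein-decay time courses.

Secreted ligand abundance is followed over time after removing the
source (e.g. band intensities from immunoblots of conditioned medium).
Each lane is first normalized to a co-loaded control to cancel
lane-to-lane loading and recovery differences, then to the t=0 value;
the normalized series is fitted with first-order decay

    I(t) = A * exp(-k * t)

giving the clearance rate k (1/s) and half-life ln(2)/k. Slowly
degrading proteins sampled over a day decay by only a few percent, so
their rate estimates carry wide confidence intervals; ranking rates
across constructs is more robust than any single absolute value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "DecaySeries",
    "DecayFit",
    "normalize_series",
    "fit_decay",
    "compare_decay_order",
]

_SECONDS = {"s": 1.0, "hr": 3600.0, "h": 3600.0, "min": 60.0}


@dataclass
class DecaySeries:
    """Band-intensity time course with a per-lane loading control."""

    t: np.ndarray
    intensity: np.ndarray
    control: np.ndarray | None = None
    label: str = ""
    time_unit: str = "hr"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t[0] != 0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must start at 0 and be strictly increasing")
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must match")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)
            if self.control.shape != self.t.shape:
                raise ValueError("control must match t")
            if np.any(self.control <= 0):
                raise ValueError("control intensities must be positive")
        if self.time_unit not in _SECONDS:
            raise ValueError(f"time_unit must be one of {sorted(_SECONDS)}")

    @property
    def t_seconds(self) -> np.ndarray:
        return self.t * _SECONDS[self.time_unit]


@dataclass
class DecayFit:
    k_deg: float          # 1/s
    amplitude: float
    residual_norm: float
    label: str = ""

    @property
    def half_life(self) -> float:
        """Half-life ln(2)/k in seconds (inf for a non-decaying fit)."""
        return math.log(2.0) / self.k_deg if self.k_deg > 0 else math.inf


def normalize_series(series: DecaySeries) -> DecaySeries:
    """Divide by the loading control lane-wise, then by the t=0 value."""
    ratio = (series.intensity / series.control
             if series.control is not None else series.intensity.copy())
    if ratio[0] <= 0:
        raise ValueError("t=0 value must be positive after control division")
    return DecaySeries(t=series.t.copy(), intensity=ratio / ratio[0],
                       control=None, label=series.label,
                       time_unit=series.time_unit)


def fit_decay(series: DecaySeries, with_offset: bool = False) -> DecayFit:
    """Least-squares fit of A*exp(-k*t) to a normalized series.

    The amplitude is left free rather than pinned to 1 so that noise in
    the t=0 lane is absorbed instead of biasing k. An optional plateau
    term A*exp(-k*t)+C is available with ``with_offset``.
    """
    if series.t.size < 3:
        raise ValueError("need at least 3 time points")
    t = series.t_seconds
    y = series.intensity
    # log-linear start; guard against non-decaying noise
    slope = np.polyfit(t, np.log(np.clip(y, 1e-12, None)), 1)[0]
    k0 = max(-slope, 1e-12)
    try:
        if with_offset:
            popt, _ = optimize.curve_fit(
                lambda t, a, k, c: a * np.exp(-k * t) + c, t, y,
                p0=(y[0], k0, 0.0), bounds=([0, 0, -1], [np.inf, 1, 1]),
                maxfev=10000)
            a, k, c = popt
        else:
            popt, _ = optimize.curve_fit(
                lambda t, a, k: a * np.exp(-k * t), t, y,
                p0=(y[0], k0), bounds=([0, 0], [np.inf, 1]), maxfev=10000)
            a, k = popt
            c = 0.0
    except RuntimeError as exc:
        raise RuntimeError("decay fit did not converge") from exc
    if k < 0:
        raise RuntimeError("decay fit returned a negative rate")
    resid = a * np.exp(-k * t) + c - y
    return DecayFit(k_deg=float(k), amplitude=float(a),
                    residual_norm=float(np.sum(resid ** 2)),
                    label=series.label)


def compare_decay_order(fits: list[DecayFit]) -> list[tuple[str, float]]:
    """Rank fits by descending clearance rate; ties broken by label."""
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    return sorted(((f.label, f.k_deg) for f in fits),
                  key=lambda lk: (-lk[1], lk[0]))
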