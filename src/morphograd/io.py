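"""File I/O for curves, measurements, profiles, images and configs.

Plain CSV/JSON/YAML/TIFF carriers for the in-memory types; column names
follow the documented interfaces (``lag_s``, ``g``, ``sigma``,
``c_g_nM`` etc.).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from morphograd.binding_affinity import BindingMeasurement
from morphograd.clearance_kinetics import DecaySeries
from morphograd.correlation_models import CorrelationCurve, ObservationVolume
from morphograd.gradient_profiling import EmbryoImage
from morphograd.hindered_diffusion import ConcentrationProfile, SlabSimConfig

__all__ = [
    "read_curve_csv", "write_curve_csv",
    "read_curve_json", "write_curve_json",
    "read_measurements_csv", "write_measurements_csv",
    "read_profile_csv", "write_profile_csv",
    "read_decay_csv", "write_decay_csv",
    "read_image_tiff", "write_image_tiff",
    "load_slab_config",
]


def write_curve_csv(curve: CorrelationCurve, path: str | Path) -> None:
    df = pd.DataFrame({"lag_s": curve.lag, "g": curve.g})
    if curve.sigma is not None:
        df["sigma"] = curve.sigma
    df["channel_kind"] = curve.channel_kind
    df.to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> CorrelationCurve:
    df = pd.read_csv(path)
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    kind = (str(df["channel_kind"].iloc[0])
            if "channel_kind" in df.columns else "auto_green")
    return CorrelationCurve(lag=df["lag_s"].to_numpy(),
                            g=df["g"].to_numpy(), sigma=sigma,
                            channel_kind=kind)


def write_curve_json(curve: CorrelationCurve, path: str | Path,
                     volume: ObservationVolume | None = None) -> None:
    payload = {
        "lag_s": curve.lag.tolist(),
        "g": curve.g.tolist(),
        "sigma": None if curve.sigma is None else curve.sigma.tolist(),
        "channel_kind": curve.channel_kind,
        "metadata": (None if volume is None
                     else {"omega0_um": volume.omega0, "z0_um": volume.z0}),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_curve_json(path: str | Path) -> tuple[CorrelationCurve,
                                               ObservationVolume | None]:
    payload = json.loads(Path(path).read_text())
    curve = CorrelationCurve(
        lag=np.array(payload["lag_s"]), g=np.array(payload["g"]),
        sigma=None if payload.get("sigma") is None
        else np.array(payload["sigma"]),
        channel_kind=payload.get("channel_kind", "auto_green"))
    meta = payload.get("metadata")
    volume = (ObservationVolume(meta["omega0_um"], meta["z0_um"])
              if meta else None)
    return curve, volume


def write_measurements_csv(measurements: list[BindingMeasurement],
                           path: str | Path) -> None:
    pd.DataFrame(
        [{"embryo_id": m.embryo_id, "c_g_nM": m.c_g, "c_r_nM": m.c_r,
          "c_gr_nM": m.c_gr} for m in measurements]
    ).to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> list[BindingMeasurement]:
    df = pd.read_csv(path)
    return [BindingMeasurement(c_g=r.c_g_nM, c_r=r.c_r_nM, c_gr=r.c_gr_nM,
                               embryo_id=str(r.embryo_id))
            for r in df.itertuples()]


def write_profile_csv(profile: ConcentrationProfile, path: str | Path) -> None:
    pd.DataFrame({"x_um": profile.x_centers, "density": profile.counts,
                  "time_s": profile.t}).to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> ConcentrationProfile:
    df = pd.read_csv(path)
    t = float(df["time_s"].iloc[0]) if "time_s" in df.columns else float("inf")
    return ConcentrationProfile(x_centers=df["x_um"].to_numpy(),
                                counts=df["density"].to_numpy(), t=t)


def write_decay_csv(series: DecaySeries, path: str | Path) -> None:
    df = pd.DataFrame({f"t_{series.time_unit}": series.t,
                       "intensity": series.intensity})
    if series.control is not None:
        df["control"] = series.control
    df["label"] = series.label
    df.to_csv(path, index=False)


def read_decay_csv(path: str | Path) -> DecaySeries:
    df = pd.read_csv(path)
    tcol = next(c for c in df.columns if c.startswith("t_"))
    return DecaySeries(
        t=df[tcol].to_numpy(), intensity=df["intensity"].to_numpy(),
        control=df["control"].to_numpy() if "control" in df.columns else None,
        label=str(df["label"].iloc[0]) if "label" in df.columns else "",
        time_unit=tcol[2:])


def write_image_tiff(image: EmbryoImage, path: str | Path) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def read_image_tiff(path: str | Path, pixel_size: float = 1.4,
                    source_boundary: int = 0, background_level: float = 0.0,
                    channel: int | None = None) -> EmbryoImage:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError("multi-channel image: pass an explicit channel")
        arr = arr[channel]
    return EmbryoImage(pixels=np.asarray(arr, dtype=float),
                       pixel_size=pixel_size, source_boundary=source_boundary,
                       background_level=background_level)


def load_slab_config(path: str | Path, **overrides) -> SlabSimConfig:
    """Build a slab-simulation config from a YAML or JSON mapping."""
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text)) or {}
    data.update(overrides)
    names = {f.name for f in dataclasses.fields(SlabSimConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SlabSimConfig(**data)
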