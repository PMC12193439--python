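"""Readers and writers for the plain-text formats the package exchanges.

Kinetic traces, permeation readings, rheometer exports and clottability
courses travel as CSV; images as TIFF/PNG with an optional JSON sidecar
carrying the nm/pixel scale and, for synthetic data, the full parameter
echo and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clottability import ClottabilityCourse, censor_course
from .fiber_morphometry import DiameterSample, FiberImage
from .permeation import PermeationExperiment, PermeationGeometry
from .rheometry import RheoRecord
from .turbidimetry import KineticTrace

__all__ = [
    "read_traces_long",
    "read_traces_wide",
    "write_traces_long",
    "read_geometry",
    "read_permeation_csv",
    "read_rheo_csvs",
    "read_clottability_csv",
    "write_clottability_csv",
    "read_fiber_image",
    "write_fiber_image",
    "write_diameters_csv",
    "write_json",
]


def read_traces_long(
    path,
    assay_mode: str = "intrinsic",
    t_addition: float | None = None,
) -> dict[str, KineticTrace]:
    """Long-format plate export: columns series_id, time, value[, flag]."""
    df = pd.read_csv(path)
    required = {"series_id", "time", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long trace CSV needs columns {sorted(required)}")
    traces = {}
    for sid, g in df.groupby("series_id", sort=True):
        g = g.sort_values("time")
        traces[str(sid)] = KineticTrace(
            times=g["time"].to_numpy(float),
            absorbance=g["value"].to_numpy(float),
            assay_mode=assay_mode,
            t_addition=t_addition,
        )
    return traces


def read_traces_wide(
    path,
    assay_mode: str = "intrinsic",
    t_addition: float | None = None,
) -> dict[str, KineticTrace]:
    """Wide-format plate export: first column time, one column per well."""
    df = pd.read_csv(path)
    tcol = df.columns[0]
    t = df[tcol].to_numpy(float)
    return {
        str(c): KineticTrace(
            times=t,
            absorbance=df[c].to_numpy(float),
            assay_mode=assay_mode,
            t_addition=t_addition,
        )
        for c in df.columns[1:]
    }


def write_traces_long(traces: dict[str, KineticTrace], path) -> None:
    rows = []
    for sid in sorted(traces):
        tr = traces[sid]
        for t, a in zip(tr.times, tr.absorbance):
            rows.append((sid, t, a, ""))
    pd.DataFrame(rows, columns=["series_id", "time", "value", "flag"]).to_csv(path, index=False)


def read_geometry(path) -> PermeationGeometry:
    """Permeation geometry from a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return PermeationGeometry(**data)


def read_permeation_csv(path, geometry: PermeationGeometry) -> PermeationExperiment:
    """Readings CSV with columns time_min, length_mm."""
    df = pd.read_csv(path)
    if not {"time_min", "length_mm"}.issubset(df.columns):
        raise ValueError("permeation CSV needs columns time_min, length_mm")
    return PermeationExperiment(
        geometry=geometry,
        times_s=df["time_min"].to_numpy(float) * 60.0,
        lengths_mm=df["length_mm"].to_numpy(float),
    )


def read_rheo_csvs(clotting_path, ramp_path) -> RheoRecord:
    """Instrument-agnostic phase CSVs.

    Clotting phase: time_s, gprime_pa, gdoubleprime_pa.
    Ramp phase: time_s, tau_pa, gamma.
    """
    c = pd.read_csv(clotting_path)
    r = pd.read_csv(ramp_path)
    return RheoRecord(
        clot_time_s=c["time_s"].to_numpy(float),
        gprime_Pa=c["gprime_pa"].to_numpy(float),
        gdoubleprime_Pa=c["gdoubleprime_pa"].to_numpy(float),
        ramp_time_s=r["time_s"].to_numpy(float),
        tau_Pa=r["tau_pa"].to_numpy(float),
        gamma=r["gamma"].to_numpy(float),
    )


def read_clottability_csv(path) -> ClottabilityCourse:
    """Course CSV with columns digestion_min, clotting_s[, flag].

    A flag value of ``no_clot`` (or an empty clotting time) marks an
    instrument no-clot reading.
    """
    df = pd.read_csv(path)
    flags = None
    if "flag" in df.columns:
        flags = df["flag"].fillna("").astype(str).str.strip().eq("no_clot").to_numpy()
    return censor_course(
        df["digestion_min"].to_numpy(float),
        df["clotting_s"].to_numpy(float),
        no_clot_flags=flags,
    )


def write_clottability_csv(course: ClottabilityCourse, path) -> None:
    pd.DataFrame(
        {
            "digestion_min": course.digestion_times_min,
            "clotting_s": course.clotting_times_s,
            "censored": course.censored.astype(int),
            "display_s": course.display_values_s,
        }
    ).to_csv(path, index=False)


def read_fiber_image(path, nm_per_pixel: float | None = None) -> FiberImage:
    """TIFF/PNG image; nm/pixel from the argument or a ``<image>.json`` sidecar."""
    path = Path(path)
    if nm_per_pixel is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError("nm_per_pixel not given and no JSON sidecar found")
        nm_per_pixel = float(json.loads(sidecar.read_text())["nm_per_pixel"])
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    return FiberImage(pixels=np.asarray(px, dtype=float), nm_per_pixel=nm_per_pixel)


def write_fiber_image(image: FiberImage, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    px = np.clip(image.pixels, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, px)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, px)
    meta = {"nm_per_pixel": image.nm_per_pixel}
    if sidecar:
        meta.update(sidecar)
    write_json(meta, path.with_suffix(path.suffix + ".json"))


def write_diameters_csv(sample: DiameterSample, path, image_id: str = "image-0") -> None:
    pd.DataFrame(
        {
            "image_id": image_id,
            "diameter_nm": sample.diameters,
        }
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True, default=_jsonable) + "\n")
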