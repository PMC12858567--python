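"""File interchange for volumes, curves, CPMG trains and cohort tables.

Volumes go to MetaImage (.mha) through SimpleITK, or to raw
little-endian float32 with a JSON sidecar; curves and echo trains are
two-column CSV with a header; cohort tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phantoms import Calibration, CPMGSignal, LoadDisplacementCurve, VoxelVolume

__all__ = [
    "write_volume_mha", "read_volume_mha",
    "write_volume_raw", "read_volume_raw",
    "write_curve_csv", "read_curve_csv",
    "write_cpmg_csv", "read_cpmg_csv",
    "write_cohort_csv", "read_cohort_csv",
]


def write_volume_mha(vol: VoxelVolume, path: str | Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(vol.data)  # (z, y, x) preserved
    sp = vol.voxel_size * 1e-3  # SimpleITK spacing in mm
    img.SetSpacing((sp, sp, sp))
    img.SetOrigin(tuple(o * 1e-3 for o in vol.origin[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume_mha(path: str | Path) -> VoxelVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).astype(np.float32)
    sp = img.GetSpacing()
    if not np.allclose(sp, sp[0]):
        raise ValueError("only isotropic volumes are supported")
    origin_mm = img.GetOrigin()[::-1]
    return VoxelVolume(data, sp[0] * 1e3,
                       origin=tuple(o * 1e3 for o in origin_mm))


def write_volume_raw(vol: VoxelVolume, path: str | Path) -> None:
    """Raw little-endian float32 + JSON sidecar {shape, voxel_size_um, ...}."""
    path = Path(path)
    vol.data.astype("<f4").tofile(path)
    sidecar = {
        "shape": list(vol.shape),
        "voxel_size_um": vol.voxel_size,
        "origin_um": list(vol.origin),
        "calibration": {"slope": vol.calibration.slope,
                        "intercept": vol.calibration.intercept},
        "dtype": "<f4",
        "order": "zyx",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_volume_raw(path: str | Path) -> VoxelVolume:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    cal = sidecar.get("calibration", {})
    return VoxelVolume(data, sidecar["voxel_size_um"],
                       origin=tuple(sidecar.get("origin_um", (0, 0, 0))),
                       calibration=Calibration(cal.get("slope", 1.0),
                                               cal.get("intercept", 0.0)))


def write_curve_csv(curve: LoadDisplacementCurve, path: str | Path,
                    meta_path: str | Path | None = None) -> None:
    pd.DataFrame({"displacement_mm": curve.displacement,
                  "force_N": curve.force}).to_csv(path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(
            {"test_kind": curve.test_kind, "span_mm": curve.span,
             "rate_mm_min": curve.loading_rate}, indent=1))


def read_curve_csv(path: str | Path,
                   meta_path: str | Path | None = None) -> LoadDisplacementCurve:
    df = pd.read_csv(path)
    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    return LoadDisplacementCurve(
        df["displacement_mm"].to_numpy(), df["force_N"].to_numpy(),
        test_kind=meta.get("test_kind", "bend_3pt"),
        span=meta.get("span_mm", 8.0),
        loading_rate=meta.get("rate_mm_min", 3.0))


def write_cpmg_csv(signal: CPMGSignal, path: str | Path) -> None:
    pd.DataFrame({"echo_time_s": signal.echo_times,
                  "amplitude": signal.amplitudes}).to_csv(path, index=False)


def read_cpmg_csv(path: str | Path) -> CPMGSignal:
    df = pd.read_csv(path)
    t = df["echo_time_s"].to_numpy()
    return CPMGSignal(t, df["amplitude"].to_numpy(), float(t[1] - t[0]))


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
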