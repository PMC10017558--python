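"""PCAT mean attenuation inside a tube VOI.

Adipose tissue is defined as all VOI voxels whose attenuation lies in the
closed HU window [-190, -30]; PCAT_MA is their arithmetic mean. The window
is re-applied per volume after the VOI transfers across co-registered
acquisitions, so the adipose voxel set (and its count) may differ across
kVp even though the VOI geometry is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import CTVolume
from .voi import TubeVOI, transfer_voi

#: Closed adipose HU window (low, high).
DEFAULT_WINDOW = (-190.0, -30.0)


class MeasurementError(ValueError):
    pass


class NoAdiposeError(MeasurementError):
    """The VOI contains no voxel inside the adipose window: PCAT not measurable."""


@dataclass
class PCATMeasurement:
    vessel_id: str
    kvp: int | None
    recon: str | None
    adipose_voxel_count: int
    pcat_ma_hu: float
    window: tuple[float, float]
    voi_size_voxels: int
    voi_id: str | None = None
    volume_id: str | None = None
    corrected_from_kvp: int | None = None

    def __post_init__(self) -> None:
        low, high = self.window
        if low >= high:
            raise MeasurementError(f"window low must be < high, got {self.window}")
        if self.adipose_voxel_count > self.voi_size_voxels:
            raise MeasurementError("adipose voxel count exceeds VOI size")
        if self.adipose_voxel_count > 0 and self.corrected_from_kvp is None:
            if not (low <= self.pcat_ma_hu <= high):
                raise MeasurementError(
                    f"PCAT_MA {self.pcat_ma_hu} outside its own window {self.window}"
                )


def _check_window(window) -> tuple[float, float]:
    low, high = float(window[0]), float(window[1])
    if low >= high:
        raise MeasurementError(f"window low must be < high, got ({low}, {high})")
    return low, high


def adipose_mask(
    volume: CTVolume, voi: TubeVOI, window: tuple[float, float] = DEFAULT_WINDOW
) -> np.ndarray:
    """Indices of VOI voxels inside the closed HU window (may be empty)."""
    low, high = _check_window(window)
    voi = transfer_voi(voi, volume)  # validates grid binding
    idx = voi.voxel_indices
    hu = volume.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    keep = (hu >= low) & (hu <= high)
    return idx[keep]


def pcat_mean(
    volume: CTVolume, voi: TubeVOI, window: tuple[float, float] = DEFAULT_WINDOW
) -> PCATMeasurement:
    """PCAT mean attenuation of a volume inside a tube VOI.

    Raises :class:`NoAdiposeError` when no VOI voxel falls in the window —
    the analogue of a vessel in which PCAT was not measurable.
    """
    low, high = _check_window(window)
    idx = adipose_mask(volume, voi, window)
    if idx.shape[0] == 0:
        raise NoAdiposeError(
            f"no adipose voxel in [{low}, {high}] HU inside VOI {voi.vessel_id!r}: "
            "PCAT not measurable for this vessel"
        )
    hu = volume.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return PCATMeasurement(
        vessel_id=voi.vessel_id,
        kvp=volume.kvp,
        recon=volume.recon,
        adipose_voxel_count=int(idx.shape[0]),
        pcat_ma_hu=float(hu.mean()),
        window=(low, high),
        voi_size_voxels=voi.size_voxels,
        voi_id=voi.vessel_id,
        volume_id=volume.volume_id,
    )


def measure_series(
    volumes: list[CTVolume], voi: TubeVOI, window: tuple[float, float] = DEFAULT_WINDOW
) -> list[PCATMeasurement]:
    """Measure PCAT_MA on every co-registered volume of one acquisition series.

    All volumes must share the VOI's reference grid and carry a unique
    (kvp, recon) pair; the VOI is transferred by index identity and the HU
    window re-applied per volume.
    """
    seen: set[tuple] = set()
    for vol in volumes:
        key = (vol.kvp, vol.recon)
        if key in seen:
            raise MeasurementError(f"duplicate (kvp, recon) condition {key} in series")
        seen.add(key)
    return [pcat_mean(vol, voi, window) for vol in volumes]


# ---------------------------------------------------------------------------
# Tidy-table IO
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "vessel_id", "kvp", "recon", "n_adipose", "voi_size", "pcat_ma_hu",
    "window_low", "window_high", "corrected_from_kvp",
]


def measurements_to_frame(measurements: list[PCATMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "vessel_id": m.vessel_id,
            "kvp": m.kvp,
            "recon": m.recon,
            "n_adipose": m.adipose_voxel_count,
            "voi_size": m.voi_size_voxels,
            "pcat_ma_hu": m.pcat_ma_hu,
            "window_low": m.window[0],
            "window_high": m.window[1],
            "corrected_from_kvp": m.corrected_from_kvp,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_measurements_csv(measurements: list[PCATMeasurement], path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False, float_format="%.6f")


def read_measurements_csv(path) -> list[PCATMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        corrected = r.get("corrected_from_kvp")
        out.append(
            PCATMeasurement(
                vessel_id=str(r["vessel_id"]),
                kvp=int(r["kvp"]),
                recon=str(r["recon"]),
                adipose_voxel_count=int(r["n_adipose"]),
                pcat_ma_hu=float(r["pcat_ma_hu"]),
                window=(float(r["window_low"]), float(r["window_high"])),
                voi_size_voxels=int(r["voi_size"]),
                corrected_from_kvp=None if pd.isna(corrected) else int(corrected),
            )
        )
    return out
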