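"""Readers, writers and format converters.

Acoustic records go to netCDF (dimensions ping_time/depth, variable Sv in
dB, vessel metadata as attributes; classic netCDF via the scipy engine) or
to a long CSV (time_s, depth_m, sv_db). Masks are palette PNGs, echograms
grayscale PNGs with padding encoded in the alpha channel plus a JSON
metadata sidecar; events, tracks and colonies are plain CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from PIL import Image

from .classes import CLASS_PALETTE
from .preprocess import Echogram
from .simulate import GroundTruth, RawAcousticRecord


# ---------------------------------------------------------------------------
# Acoustic records
# ---------------------------------------------------------------------------


def record_to_netcdf(record: RawAcousticRecord, path) -> Path:
    path = Path(path)
    ds = xr.Dataset(
        {"Sv": (("ping_time", "depth"), record.sv.astype(np.float32))},
        coords={
            "ping_time": record.ping_times,
            "depth": record.depth_bins,
        },
        attrs={
            "vessel_id": record.vessel_id,
            "start_timestamp": str(record.start_timestamp),
            "Sv_units": "dB re 1 m-1",
        },
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def record_from_netcdf(path) -> RawAcousticRecord:
    with xr.open_dataset(path, engine="scipy") as ds:
        return RawAcousticRecord(
            ping_times=ds["ping_time"].values.astype(float),
            depth_bins=ds["depth"].values.astype(float),
            sv=ds["Sv"].values.astype(np.float32),
            vessel_id=str(ds.attrs.get("vessel_id", "UNKNOWN")),
            start_timestamp=pd.Timestamp(
                ds.attrs.get("start_timestamp", "2000-01-01")
            ),
        )


def record_to_csv(record: RawAcousticRecord, path) -> Path:
    """Long format: one row per (time_s, depth_m) sample."""
    path = Path(path)
    t = np.repeat(record.ping_times, record.depth_bins.size)
    d = np.tile(record.depth_bins, record.ping_times.size)
    df = pd.DataFrame({"time_s": t, "depth_m": d, "sv_db": record.sv.ravel()})
    header = (
        f"# vessel_id={record.vessel_id}"
        f" start_timestamp={record.start_timestamp.isoformat()}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def record_from_csv(path) -> RawAcousticRecord:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        df = pd.read_csv(path, skiprows=1)
    else:
        df = pd.read_csv(path)
    times = np.unique(df["time_s"].to_numpy())
    depths = np.unique(df["depth_m"].to_numpy())
    sv = (
        df.pivot_table(index="time_s", columns="depth_m", values="sv_db", dropna=False)
        .reindex(index=times, columns=depths)
        .to_numpy(dtype=np.float32)
    )
    return RawAcousticRecord(
        ping_times=times,
        depth_bins=depths,
        sv=sv,
        vessel_id=meta.get("vessel_id", "UNKNOWN"),
        start_timestamp=pd.Timestamp(meta.get("start_timestamp", "2000-01-01")),
    )


# ---------------------------------------------------------------------------
# Masks and echograms
# ---------------------------------------------------------------------------


def mask_to_png(mask: np.ndarray, path) -> Path:
    """Palette-coded class mask (class code = palette index)."""
    path = Path(path)
    img = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    palette = [v for rgb in CLASS_PALETTE for v in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)
    return path


def mask_from_png(path) -> np.ndarray:
    return np.array(Image.open(path), dtype=np.int8)


def echogram_to_png(echogram: Echogram, path, sidecar: bool = True) -> Path:
    """8-bit grayscale with padding as zero alpha, plus a JSON sidecar of
    window metadata. Quantization to 1/255 is the documented loss."""
    path = Path(path)
    data = echogram.data
    valid = np.isfinite(data)
    gray = np.zeros(data.shape, dtype=np.uint8)
    gray[valid] = np.round(np.clip(data[valid], 0, 1) * 255).astype(np.uint8)
    alpha = np.where(valid, 255, 0).astype(np.uint8)
    Image.fromarray(np.stack([gray, alpha], axis=-1), mode="LA").save(path)
    if sidecar:
        meta = {
            "echogram_id": echogram.echogram_id,
            "vessel_id": echogram.vessel_id,
            "start_timestamp": pd.Timestamp(echogram.start_timestamp).isoformat(),
            "time_offset_s": echogram.time_offset_s,
            "fraction_padded": echogram.fraction_padded,
            "units": echogram.units,
            "window_index": echogram.window_index,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def echogram_from_png(path) -> Echogram:
    arr = np.array(Image.open(path).convert("LA"), dtype=np.float32)
    data = arr[..., 0] / 255.0
    data[arr[..., 1] == 0] = np.nan
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Echogram(
        data=data,
        start_timestamp=pd.Timestamp(meta.get("start_timestamp", "2000-01-01")),
        vessel_id=meta.get("vessel_id", "UNKNOWN"),
        time_offset_s=meta.get("time_offset_s", 0.0),
        fraction_padded=meta.get("fraction_padded", 0.0),
        units=meta.get("units", "grayscale"),
        window_index=meta.get("window_index", 0),
    )


def truth_to_files(truth: GroundTruth, out_dir, stem: str) -> None:
    out_dir = Path(out_dir)
    mask_to_png(truth.mask, out_dir / f"{stem}_mask.png")
    truth.events.to_csv(out_dir / f"{stem}_events.csv", index=False)


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

_CONVERSIONS = {
    ("csv", "netcdf"),
    ("netcdf", "csv"),
}


def convert_formats(path, src: str, dst: str, out_path=None) -> Path:
    """Convert an Sv record between the long CSV and netCDF formats
    (lossless to float32 precision)."""
    src, dst = src.lower(), dst.lower()
    if (src, dst) not in _CONVERSIONS:
        raise ValueError(
            f"unsupported conversion {src} -> {dst}; supported: "
            + ", ".join(f"{a}->{b}" for a, b in sorted(_CONVERSIONS))
        )
    record = record_from_csv(path) if src == "csv" else record_from_netcdf(path)
    if out_path is None:
        suffix = ".nc" if dst == "netcdf" else ".csv"
        out_path = Path(path).with_suffix(suffix)
    if dst == "netcdf":
        return record_to_netcdf(record, out_path)
    return record_to_csv(record, out_path)


def grid_to_geojson(grid_df: pd.DataFrame, path) -> Path:
    """Grid-cell encounter summaries as a GeoJSON FeatureCollection of
    cell polygons (WGS84)."""
    feats = []
    for _, row in grid_df.iterrows():
        lon0, lat0, lon1, lat1 = (
            row["lon_min"], row["lat_min"], row["lon_max"], row["lat_max"]
        )
        props = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in row.items()
            if k not in ("lon_min", "lat_min", "lon_max", "lat_max")
        }
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[
                        [lon0, lat0], [lon1, lat0], [lon1, lat1],
                        [lon0, lat1], [lon0, lat0],
                    ]],
                },
                "properties": props,
            }
        )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    return path
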