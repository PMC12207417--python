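"""Standardize raw acoustic records into fixed-size grayscale echograms.

The data-preparation chain mirrors how fishing-vessel echosounder archives
are normalized before image segmentation:

1. regrid to a uniform 1 s x 0.5 m grid, linearly interpolating volume
   backscatter (in dB, along time) where the ping interval exceeds 1 s;
2. split into consecutive 10-min windows, padded to 10 min x 500 m with a
   missing sentinel (NaN) where data run short;
3. map Sv to grayscale with a fixed -90 dB -> 0.0, -20 dB -> 1.0 affine
   window, clipping outside values.

Pixel (c, r) covers [c, c+1) s x [0.5 r, 0.5 (r+1)) m, half-open; time
columns increase with time, depth rows increase downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classes import (
    BACKGROUND,
    DEPTH_STEP_M,
    SV_CEIL_DB,
    SV_FLOOR_DB,
    TIME_STEP_S,
    WINDOW_COLS,
    WINDOW_ROWS,
)
from .simulate import RawAcousticRecord


@dataclass
class RegularSvMatrix:
    """Sv on the uniform 1 s x 0.5 m grid. ``sv`` is (time, depth), NaN =
    missing. ``interpolated`` marks columns not present in the raw pings;
    ``long_gap_cols`` flags columns inside raw gaps longer than the
    configured threshold."""

    sv: np.ndarray
    start_timestamp: pd.Timestamp
    vessel_id: str
    interpolated: np.ndarray = None          # bool per time column
    long_gap_cols: np.ndarray = None         # bool per time column

    @property
    def n_times(self) -> int:
        return self.sv.shape[0]

    @property
    def n_depths(self) -> int:
        return self.sv.shape[1]


@dataclass
class Echogram:
    """One standardized window: ``data`` is (rows=depth, cols=time) with
    NaN as the padding/missing sentinel. ``units`` is ``"sv_db"`` straight
    after windowing and ``"grayscale"`` (values in [0, 1]) after
    :func:`sv_to_grayscale`."""

    data: np.ndarray
    start_timestamp: pd.Timestamp
    vessel_id: str
    time_offset_s: float = 0.0
    fraction_padded: float = 0.0
    units: str = "sv_db"
    truth_mask: np.ndarray | None = None
    window_index: int = 0

    @property
    def echogram_id(self) -> str:
        ts = pd.Timestamp(self.start_timestamp).strftime("%Y%m%dT%H%M%S")
        return f"{self.vessel_id}_{ts}_w{self.window_index:04d}"

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


def regrid_sv(record: RawAcousticRecord, max_gap_flag_s: float = 10.0) -> RegularSvMatrix:
    """Resample a raw record onto the uniform 1 s x 0.5 m grid.

    Time: values at grid instants that coincide with raw ping times are
    preserved; gaps are filled by linear interpolation of Sv in dB along
    time (per depth bin). Missing samples (NaN) are skipped as knots.
    Depth: nearest-bin-center assignment onto 0.5-m bins.

    Gaps longer than ``max_gap_flag_s`` are still interpolated but flagged
    in ``long_gap_cols``.
    """
    t = record.ping_times
    if t.size < 2:
        raise ValueError("regrid_sv needs at least 2 pings")
    if not np.all(np.diff(t) > 0):
        raise ValueError("ping_times must be strictly increasing")

    n_times = int(np.floor(t[-1] - t[0])) + 1
    grid_t = t[0] + np.arange(n_times, dtype=float) * TIME_STEP_S

    max_depth = record.depth_bins[-1] + _depth_step(record) / 2.0
    n_depths = int(round(max_depth / DEPTH_STEP_M))
    grid_d = (np.arange(n_depths) + 0.5) * DEPTH_STEP_M
    # nearest raw bin for each 0.5-m bin center
    src_idx = np.clip(
        np.searchsorted(record.depth_bins, grid_d), 0, record.depth_bins.size - 1
    )
    left = np.maximum(src_idx - 1, 0)
    closer_left = np.abs(grid_d - record.depth_bins[left]) < np.abs(
        grid_d - record.depth_bins[src_idx]
    )
    src_idx[closer_left] = left[closer_left]

    sv_depth = record.sv[:, src_idx]  # (pings, n_depths)

    out = np.full((n_times, n_depths), np.nan, dtype=np.float32)
    for j in range(n_depths):
        col = sv_depth[:, j]
        valid = np.isfinite(col)
        if valid.sum() >= 2:
            out[:, j] = np.interp(
                grid_t, t[valid], col[valid], left=np.nan, right=np.nan
            )
        elif valid.sum() == 1:
            # single knot: only the coincident grid instant gets a value
            k = np.argmin(np.abs(grid_t - t[valid][0]))
            if abs(grid_t[k] - t[valid][0]) < TIME_STEP_S / 2:
                out[k, j] = col[valid][0]

    interpolated = np.ones(n_times, dtype=bool)
    snap = np.round(t - t[0]).astype(int)
    on_grid = np.abs((t - t[0]) - snap) < 1e-6
    hit = snap[on_grid]
    interpolated[hit[(hit >= 0) & (hit < n_times)]] = False

    long_gap = np.zeros(n_times, dtype=bool)
    gaps = np.diff(t)
    for k in np.nonzero(gaps > max_gap_flag_s)[0]:
        lo = int(np.ceil(t[k] - t[0]))
        hi = int(np.floor(t[k + 1] - t[0]))
        long_gap[lo + 1: hi] = True

    return RegularSvMatrix(
        sv=out,
        start_timestamp=record.start_timestamp + pd.Timedelta(seconds=float(t[0])),
        vessel_id=record.vessel_id,
        interpolated=interpolated,
        long_gap_cols=long_gap,
    )


def _depth_step(record: RawAcousticRecord) -> float:
    d = record.depth_bins
    return float(d[1] - d[0]) if d.size > 1 else DEPTH_STEP_M


def window_echograms(
    regular: RegularSvMatrix,
    truth_mask: np.ndarray | None = None,
    window_cols: int = WINDOW_COLS,
    window_rows: int = WINDOW_ROWS,
) -> list[Echogram]:
    """Split a regular matrix into consecutive, non-overlapping 10-min,
    500-m windows anchored at the record start.

    Short or trailing-partial data are padded with NaN; depth beyond 500 m
    is truncated. ``fraction_padded`` is the padded share of each window's
    pixels. A truth mask aligned to the regular grid (depth_rows x
    time_cols) is carried through, padded with background.
    """
    n_times = regular.n_times
    if n_times == 0:
        return []
    n_depths = regular.n_depths
    n_windows = max(1, int(np.ceil(n_times / window_cols)))
    valid_rows = min(n_depths, window_rows)

    out = []
    for w in range(n_windows):
        c_lo = w * window_cols
        c_hi = min(c_lo + window_cols, n_times)
        valid_cols = c_hi - c_lo
        data = np.full((window_rows, window_cols), np.nan, dtype=np.float32)
        data[:valid_rows, :valid_cols] = regular.sv[c_lo:c_hi, :valid_rows].T
        pad_px = window_rows * window_cols - valid_rows * valid_cols
        mask_w = None
        if truth_mask is not None:
            mask_w = np.full((window_rows, window_cols), BACKGROUND, dtype=np.int8)
            mask_w[:valid_rows, :valid_cols] = truth_mask[:valid_rows, c_lo:c_hi]
        out.append(
            Echogram(
                data=data,
                start_timestamp=regular.start_timestamp
                + pd.Timedelta(seconds=c_lo * TIME_STEP_S),
                vessel_id=regular.vessel_id,
                time_offset_s=c_lo * TIME_STEP_S,
                fraction_padded=pad_px / (window_rows * window_cols),
                units="sv_db",
                truth_mask=mask_w,
                window_index=w,
            )
        )
    return out


def sv_to_grayscale_array(
    sv_db: np.ndarray,
    floor_db: float = SV_FLOOR_DB,
    ceil_db: float = SV_CEIL_DB,
) -> np.ndarray:
    """Affine map of Sv to [0, 1]: floor -> 0.0, ceil -> 1.0, values outside
    clipped; NaN (missing/padding) passes through."""
    g = (np.asarray(sv_db, dtype=np.float32) - floor_db) / (ceil_db - floor_db)
    return np.clip(g, 0.0, 1.0)


def grayscale_to_sv_array(
    g: np.ndarray,
    floor_db: float = SV_FLOOR_DB,
    ceil_db: float = SV_CEIL_DB,
) -> np.ndarray:
    """Inverse of :func:`sv_to_grayscale_array` on non-clipped pixels."""
    return np.asarray(g, dtype=np.float32) * (ceil_db - floor_db) + floor_db


def sv_to_grayscale(
    window: Echogram,
    floor_db: float = SV_FLOOR_DB,
    ceil_db: float = SV_CEIL_DB,
) -> Echogram:
    """Convert a windowed Sv echogram to grayscale units."""
    if window.units == "grayscale":
        return window
    return Echogram(
        data=sv_to_grayscale_array(window.data, floor_db, ceil_db),
        start_timestamp=window.start_timestamp,
        vessel_id=window.vessel_id,
        time_offset_s=window.time_offset_s,
        fraction_padded=window.fraction_padded,
        units="grayscale",
        truth_mask=window.truth_mask,
        window_index=window.window_index,
    )


def preprocess_record(
    record: RawAcousticRecord,
    truth_mask: np.ndarray | None = None,
    window_cols: int = WINDOW_COLS,
    window_rows: int = WINDOW_ROWS,
) -> list[Echogram]:
    """Full chain: regrid -> window -> grayscale."""
    regular = regrid_sv(record)
    windows = window_echograms(regular, truth_mask, window_cols, window_rows)
    return [sv_to_grayscale(w) for w in windows]
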