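"""Synthetic acoustic scenes with pixel-accurate ground truth.

Fishing-vessel echosounders record volume backscatter (Sv, dB) over time and
depth. Air-breathing krill predators leave two characteristic signatures in
these echograms: ascending comet-like bubble trails (penguins, fur seals;
local vertical extent up to ~2 m) and intense compact blobs from the bodies
and lung air of diving baleen whales (3 to 20+ m tall). Krill swarms appear
as diffuse horizontal blobs and the seafloor as a strong band.

This module generates such scenes phenomenologically — planted objects with
controlled geometry and intensity on top of Gaussian dB noise — together
with the per-pixel class mask and the event table that downstream stages are
supposed to recover. No sonar-equation physics (beam pattern, TVG,
absorption) is modelled; intensities are calibration knobs.

Conventions
-----------
* Mask/image arrays are (depth_rows, time_cols); row ``r`` covers depth
  ``[0.5 r, 0.5 (r+1))`` m, column ``c`` covers ``[c, c+1)`` s (half-open).
* ``RawAcousticRecord.sv`` is (ping, depth) — one row per ping.
* Missing samples carry NaN, never silent drops.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classes import (
    BACKGROUND,
    BUBBLE_TRAIL,
    CLASS_NAMES,
    CLASS_PRECEDENCE,
    DEPTH_STEP_M,
    KRILL_SWARM,
    SEAFLOOR,
    WHALE,
)

logger = logging.getLogger(__name__)

KNOT_MS = 0.514444  # 1 kn in m/s
EARTH_RADIUS_KM = 6371.0

_SPEC_CLASS_CODES = {
    "krill_swarm": KRILL_SWARM,
    "bubble_trail": BUBBLE_TRAIL,
    "whale_dive": WHALE,
    "seafloor": SEAFLOOR,
}

#: Sv floor used for "empty water" before noise is applied (dB).
SIGNAL_FLOOR_DB = -120.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PlantSpec:
    """One object to plant into a scene.

    ``shape_params`` is class-specific:

    * ``bubble_trail`` — ``width_px`` (per-column vertical width, 1-4 px,
      default 3) and ``fade_db`` (intensity drop from head to tail,
      default 10 dB).
    * ``seafloor`` — ``amplitude_m`` / ``period_s`` of a sinusoidal bottom
      profile (default flat); the band spans depth_top_m..depth_bottom_m.
    * ``krill_swarm`` / ``whale_dive`` — the blob is the ellipse inscribed
      in the time/depth bounding box.
    """

    object_class: str
    start_time_s: float
    end_time_s: float
    depth_top_m: float
    depth_bottom_m: float
    intensity_db: float
    shape_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.object_class not in _SPEC_CLASS_CODES:
            raise ValueError(
                f"unknown object_class {self.object_class!r}; "
                f"expected one of {sorted(_SPEC_CLASS_CODES)}"
            )
        if not self.end_time_s > self.start_time_s:
            raise ValueError("end_time_s must exceed start_time_s")
        if not self.depth_bottom_m > self.depth_top_m:
            raise ValueError("depth_bottom_m must exceed depth_top_m")
        if self.object_class == "whale_dive":
            if self.depth_bottom_m - self.depth_top_m < 3.0:
                raise ValueError(
                    "whale_dive vertical extent must be >= 3 m "
                    f"(got {self.depth_bottom_m - self.depth_top_m:g} m)"
                )
        if self.object_class == "bubble_trail":
            width_px = int(self.shape_params.get("width_px", 3))
            if not 1 <= width_px <= 4:
                raise ValueError(
                    "bubble_trail width_px must be 1..4 pixels (local "
                    f"vertical extent <= 2 m); got {width_px}"
                )

    @property
    def class_code(self) -> int:
        return _SPEC_CLASS_CODES[self.object_class]


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe a 10-min, 500-m window with open-water noise around
    -85 dB — quiet enough that a -68 dB krill swarm is clearly visible, as
    in real 120/200 kHz data.
    """

    duration_s: float = 600.0
    max_depth_m: float = 500.0
    ping_interval_s: float = 1.0
    noise_mean_db: float = -85.0
    noise_sd_db: float = 3.0
    object_specs: list = field(default_factory=list)
    rng_seed: int = 0
    ping_jitter_frac: float = 0.0   # uniform jitter, fraction of the interval
    dropout_prob: float = 0.0       # per-sample probability of a missing value
    vessel_id: str = "SYN-001"
    start_timestamp: str = "2022-01-15T00:00:00"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.max_depth_m <= 0:
            raise ValueError("max_depth_m must be positive")
        if self.ping_interval_s <= 0:
            raise ValueError("ping_interval_s must be positive")
        for value, name in (
            (self.noise_mean_db, "noise_mean_db"),
        ):
            if not -120.0 <= value <= 0.0:
                raise ValueError(f"{name} must lie in [-120, 0] dB")
        if self.noise_sd_db < 0:
            raise ValueError("noise_sd_db must be nonnegative")
        if not 0.0 <= self.ping_jitter_frac < 0.5:
            raise ValueError("ping_jitter_frac must lie in [0, 0.5)")

    @property
    def n_cols(self) -> int:
        return int(round(self.duration_s))

    @property
    def n_rows(self) -> int:
        return int(round(self.max_depth_m / DEPTH_STEP_M))


@dataclass
class RawAcousticRecord:
    """Irregular pings of Sv(dB) over time x depth with vessel metadata."""

    ping_times: np.ndarray          # seconds since start, strictly increasing
    depth_bins: np.ndarray          # bin centers (m), regular, increasing
    sv: np.ndarray                  # (n_pings, n_depth) dB; NaN = missing
    vessel_id: str = "UNKNOWN"
    start_timestamp: pd.Timestamp = pd.Timestamp("2022-01-15T00:00:00")
    positions: pd.DataFrame | None = None   # optional per-ping lat/lon

    def __post_init__(self) -> None:
        self.ping_times = np.asarray(self.ping_times, dtype=float)
        self.depth_bins = np.asarray(self.depth_bins, dtype=float)
        self.sv = np.asarray(self.sv, dtype=np.float32)
        self.start_timestamp = pd.Timestamp(self.start_timestamp)
        if self.sv.shape != (self.ping_times.size, self.depth_bins.size):
            raise ValueError(
                f"sv shape {self.sv.shape} does not match "
                f"{self.ping_times.size} pings x {self.depth_bins.size} depth bins"
            )
        if self.ping_times.size >= 2 and not np.all(np.diff(self.ping_times) > 0):
            raise ValueError("ping_times must be strictly increasing")


@dataclass
class GroundTruth:
    """Per-pixel class mask on the 1 s x 0.5 m grid plus planted events."""

    mask: np.ndarray                # (depth_rows, time_cols) int8 class codes
    events: pd.DataFrame            # one row per planted predator event

    @staticmethod
    def empty(n_rows: int, n_cols: int) -> "GroundTruth":
        return GroundTruth(
            mask=np.zeros((n_rows, n_cols), dtype=np.int8),
            events=_empty_events(),
        )


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": pd.Series(dtype=int),
            "object_class": pd.Series(dtype=str),
            "start_time_s": pd.Series(dtype=float),
            "duration_s": pd.Series(dtype=float),
            "height_m": pd.Series(dtype=float),
            "col_min": pd.Series(dtype=int),
            "col_max": pd.Series(dtype=int),
            "row_min": pd.Series(dtype=int),
            "row_max": pd.Series(dtype=int),
        }
    )


# ---------------------------------------------------------------------------
# Footprint geometry
# ---------------------------------------------------------------------------


def _col_span(start_s: float, end_s: float) -> tuple[int, int]:
    """Inclusive column span [c0, c1] covering [start, end) seconds."""
    c0 = int(round(start_s))
    c1 = int(round(end_s)) - 1
    return c0, max(c1, c0)


def _row_span(top_m: float, bottom_m: float) -> tuple[int, int]:
    r0 = int(round(top_m / DEPTH_STEP_M))
    r1 = int(round(bottom_m / DEPTH_STEP_M)) - 1
    return r0, max(r1, r0)


def _ellipse_footprint(spec: PlantSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c0, c1 = _col_span(spec.start_time_s, spec.end_time_s)
    r0, r1 = _row_span(spec.depth_top_m, spec.depth_bottom_m)
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    # Ellipse inscribed in the bounding box, evaluated at pixel centers.
    a = (c1 - c0 + 1) / 2.0
    b = (r1 - r0 + 1) / 2.0
    cx = c0 + a - 0.5
    cy = r0 + b - 0.5
    inside = ((cc - cx) / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0
    # Guarantee the full bounding-box rows/cols are represented: keep the
    # center row and column filled so the planted extent equals the spec span.
    inside |= np.abs(rr - cy) < 0.5
    inside |= np.abs(cc - cx) < 0.5
    rows = rr[inside]
    cols = cc[inside]
    vals = np.full(rows.size, spec.intensity_db, dtype=np.float32)
    return rows, cols, vals


def _bubble_footprint(spec: PlantSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Comet-like ascending streak: deep at the start, shallow at the end,
    intensity fading from the (recent, shallow) head back along the tail."""
    c0, c1 = _col_span(spec.start_time_s, spec.end_time_s)
    r_top, r_bot = _row_span(spec.depth_top_m, spec.depth_bottom_m)
    width_px = int(spec.shape_params.get("width_px", 3))
    fade_db = float(spec.shape_params.get("fade_db", 10.0))
    n = c1 - c0 + 1
    rows_out, cols_out, vals_out = [], [], []
    for i in range(n):
        frac = i / max(n - 1, 1)            # 0 at tail (start), 1 at head (end)
        center = r_bot + frac * (r_top - r_bot)
        half = (width_px - 1) / 2.0
        lo = int(round(center - half))
        hi = lo + width_px - 1
        lo = max(lo, r_top)
        hi = min(hi, r_bot)
        rr = np.arange(lo, hi + 1)
        rows_out.append(rr)
        cols_out.append(np.full(rr.size, c0 + i))
        vals_out.append(
            np.full(rr.size, spec.intensity_db - fade_db * (1.0 - frac), dtype=np.float32)
        )
    return (
        np.concatenate(rows_out),
        np.concatenate(cols_out),
        np.concatenate(vals_out),
    )


def _seafloor_footprint(
    spec: PlantSpec, n_rows: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c0, c1 = _col_span(spec.start_time_s, spec.end_time_s)
    amp = float(spec.shape_params.get("amplitude_m", 0.0))
    period = float(spec.shape_params.get("period_s", 300.0))
    band_m = spec.depth_bottom_m - spec.depth_top_m
    cols = np.arange(c0, c1 + 1)
    top_m = spec.depth_top_m + amp * np.sin(2 * np.pi * cols / period)
    rows_out, cols_out = [], []
    for c, t in zip(cols, top_m):
        r0, r1 = _row_span(t, t + band_m)
        r1 = min(r1, n_rows - 1)
        rr = np.arange(r0, r1 + 1)
        rows_out.append(rr)
        cols_out.append(np.full(rr.size, c))
    rows = np.concatenate(rows_out)
    cols = np.concatenate(cols_out)
    vals = np.full(rows.size, spec.intensity_db, dtype=np.float32)
    return rows, cols, vals


def _footprint(spec: PlantSpec, n_rows: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if spec.object_class == "bubble_trail":
        return _bubble_footprint(spec)
    if spec.object_class == "seafloor":
        return _seafloor_footprint(spec, n_rows)
    return _ellipse_footprint(spec)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------


def plant_object(
    record: RawAcousticRecord, truth: GroundTruth, spec: PlantSpec
) -> tuple[RawAcousticRecord, GroundTruth]:
    """Plant one object into a regular-grid record and its ground truth.

    The record must be on the standard 1 s x 0.5 m grid (the scene canvas);
    ``simulate_scene`` derives irregular-ping records afterwards. Where the
    footprint overlaps existing non-background pixels, the class precedence
    whale > bubble_trail > krill_swarm > seafloor decides which label wins;
    Sv always takes the elementwise maximum (stronger scatterer dominates).
    Returns the same objects, modified in place.
    """
    n_rows, n_cols = truth.mask.shape
    c0, c1 = _col_span(spec.start_time_s, spec.end_time_s)
    r0, r1 = _row_span(spec.depth_top_m, spec.depth_bottom_m)
    if c0 < 0 or c1 >= n_cols or r0 < 0 or (
        spec.object_class != "seafloor" and r1 >= n_rows
    ):
        raise ValueError(
            f"spec {spec.object_class} [{spec.start_time_s}-{spec.end_time_s} s, "
            f"{spec.depth_top_m}-{spec.depth_bottom_m} m] lies outside the "
            f"scene extent ({n_cols} s x {n_rows * DEPTH_STEP_M:g} m)"
        )

    rows, cols, vals = _footprint(spec, n_rows)
    code = spec.class_code
    prio = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}

    existing = truth.mask[rows, cols]
    overlap = existing != BACKGROUND
    if np.any(overlap):
        logger.warning(
            "plant_object: %s overlaps %d existing non-background pixels; "
            "precedence whale > bubble_trail > krill_swarm > seafloor applies",
            spec.object_class,
            int(overlap.sum()),
        )
    wins = np.array([prio[code] >= prio[e] for e in existing])
    truth.mask[rows[wins], cols[wins]] = code

    # Sv canvas is (ping=time, depth): transpose of image indexing.
    sv = record.sv
    sv[cols, rows] = np.maximum(sv[cols, rows], vals)

    if spec.object_class in ("bubble_trail", "whale_dive"):
        event = {
            "event_id": len(truth.events),
            "object_class": spec.object_class,
            "start_time_s": float(c0),
            "duration_s": float(c1 - c0 + 1),
            "height_m": float((rows.max() - rows.min() + 1) * DEPTH_STEP_M),
            "col_min": int(cols.min()),
            "col_max": int(cols.max()),
            "row_min": int(rows.min()),
            "row_max": int(rows.max()),
        }
        truth.events = pd.concat(
            [truth.events, pd.DataFrame([event])], ignore_index=True
        )
    return record, truth


# ---------------------------------------------------------------------------
# Scene simulation
# ---------------------------------------------------------------------------


def simulate_scene(config: SceneConfig) -> tuple[RawAcousticRecord, GroundTruth]:
    """Render a scene to an acoustic record plus pixel-accurate ground truth.

    The scene is first painted onto the standard 1 s x 0.5 m canvas (signal
    only); the output record samples that canvas at the configured ping
    times (nearest canvas column) and adds Gaussian dB noise as an
    elementwise maximum, so planted intensities are preserved exactly.
    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_rows, n_cols = config.n_rows, config.n_cols

    depth_bins = (np.arange(n_rows) + 0.5) * DEPTH_STEP_M
    canvas = RawAcousticRecord(
        ping_times=np.arange(n_cols, dtype=float),
        depth_bins=depth_bins,
        sv=np.full((n_cols, n_rows), SIGNAL_FLOOR_DB, dtype=np.float32),
        vessel_id=config.vessel_id,
        start_timestamp=config.start_timestamp,
    )
    truth = GroundTruth.empty(n_rows, n_cols)

    prio = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
    for spec in sorted(config.object_specs, key=lambda s: prio[s.class_code]):
        plant_object(canvas, truth, spec)

    # Sample the canvas at the actual ping times.
    if config.ping_interval_s == 1.0 and config.ping_jitter_frac == 0.0:
        ping_times = canvas.ping_times.copy()
        signal = canvas.sv.copy()
    else:
        base = np.arange(0.0, config.duration_s, config.ping_interval_s)
        if config.ping_jitter_frac > 0.0:
            jitter = rng.uniform(
                -config.ping_jitter_frac, config.ping_jitter_frac, base.size
            ) * config.ping_interval_s
            jitter[0] = abs(jitter[0])
            ping_times = np.clip(base + jitter, 0.0, config.duration_s - 1e-6)
            ping_times = np.maximum.accumulate(ping_times)
            ping_times += np.arange(base.size) * 1e-9  # enforce strict increase
        else:
            ping_times = base
        cols = np.clip(np.round(ping_times).astype(int), 0, n_cols - 1)
        signal = canvas.sv[cols, :]

    noise = rng.normal(
        config.noise_mean_db, config.noise_sd_db, signal.shape
    ).astype(np.float32)
    sv = np.maximum(signal, noise)

    if config.dropout_prob > 0.0:
        drop = rng.random(sv.shape) < config.dropout_prob
        sv[drop] = np.nan

    record = RawAcousticRecord(
        ping_times=ping_times,
        depth_bins=depth_bins,
        sv=sv,
        vessel_id=config.vessel_id,
        start_timestamp=config.start_timestamp,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Ready-made scene configurations
# ---------------------------------------------------------------------------

#: Default object intensities (dB). Relative prominences are the point:
#: seafloor and whale bodies are the strongest scatterers, krill the weakest.
DEFAULT_INTENSITY_DB = {
    "krill_swarm": -68.0,
    "bubble_trail": -52.0,
    "whale_dive": -42.0,
    "seafloor": -38.0,
}


def _place_nonoverlapping(
    rng: np.random.Generator,
    taken: list,
    dur: float,
    height_m: float,
    duration_s: float,
    max_depth_m: float,
    depth_lo: float,
    depth_hi: float,
    margin_s: float = 5.0,
    margin_m: float = 3.0,
    tries: int = 200,
):
    """Random bounding box that avoids previously taken boxes (with margin)."""
    for _ in range(tries):
        t0 = float(rng.integers(1, max(int(duration_s - dur - 1), 2)))
        top = float(
            rng.uniform(depth_lo, max(min(depth_hi, max_depth_m - height_m - 1), depth_lo + 0.5))
        )
        box = (t0 - margin_s, t0 + dur + margin_s, top - margin_m, top + height_m + margin_m)
        if all(
            box[1] <= o[0] or box[0] >= o[1] or box[3] <= o[2] or box[2] >= o[3]
            for o in taken
        ):
            taken.append(box)
            return t0, top
    return None


def corpus_like_config(seed: int, duration_s: float = 600.0,
                       max_depth_m: float = 500.0) -> SceneConfig:
    """A scene whose class pixel shares emulate the annotated corpus:
    ~87% background, ~10% krill swarm, ~1% bubble trails, trace whales.

    Blobs are added until each class's planted pixel budget is met
    (area-targeted placement); boxes are kept disjoint so the realized
    shares track the budgets closely.
    """
    rng = np.random.default_rng(seed)
    total_px = int(round(duration_s)) * int(round(max_depth_m / DEPTH_STEP_M))
    specs: list[PlantSpec] = []
    taken: list = []

    krill_budget = 0.10 * total_px
    planted = 0.0
    while planted < krill_budget:
        dur = float(rng.integers(80, 200))
        height = float(rng.integers(20, 60))  # 10-30 m
        rows = height / DEPTH_STEP_M
        placed = _place_nonoverlapping(
            rng, taken, dur, height, duration_s, max_depth_m, 30.0, max_depth_m - 60.0
        )
        if placed is None:
            break
        t0, top = placed
        specs.append(
            PlantSpec(
                "krill_swarm", t0, t0 + dur, top, top + height,
                DEFAULT_INTENSITY_DB["krill_swarm"] + float(rng.normal(0, 2)),
            )
        )
        planted += math.pi / 4.0 * dur * rows

    # Bubble trails are thin, so reaching a ~1% pixel share needs many
    # trails per window (trail-dense scenes, as in a corpus deliberately
    # enriched with predator examples). Trails may overlap each other and
    # krill; planting precedence sorts that out.
    bubble_budget = 0.01 * total_px
    planted = 0.0
    while planted < bubble_budget:
        dur = float(rng.integers(30, 90))
        width_px = int(rng.integers(2, 4))
        end_depth = float(rng.uniform(3.0, 60.0))
        # ascent rate capped below the trail width (px/column) so the
        # rendered streak stays 8-connected — physically, bubbles rise
        # at most ~1-1.5 m/s
        rate_m_per_s = float(rng.uniform(0.3, 0.45 * width_px))
        start_depth = end_depth + rate_m_per_s * dur
        t0 = float(rng.integers(1, int(duration_s - dur - 1)))
        specs.append(
            PlantSpec(
                "bubble_trail", t0, t0 + dur, end_depth, start_depth,
                DEFAULT_INTENSITY_DB["bubble_trail"] + float(rng.normal(0, 2)),
                {"width_px": width_px},
            )
        )
        planted += dur * width_px

    if rng.random() < 0.3:
        dur = float(rng.integers(8, 30))
        height = float(rng.uniform(4.0, 16.0))
        placed = _place_nonoverlapping(
            rng, taken, dur, height, duration_s, max_depth_m, 20.0, 150.0
        )
        if placed is not None:
            t0, top = placed
            specs.append(
                PlantSpec(
                    "whale_dive", t0, t0 + dur, top, top + height,
                    DEFAULT_INTENSITY_DB["whale_dive"],
                )
            )

    return SceneConfig(
        duration_s=duration_s,
        max_depth_m=max_depth_m,
        object_specs=specs,
        rng_seed=seed,
    )


def oracle_scene_config(
    seed: int,
    duration_s: float = 300.0,
    max_depth_m: float = 120.0,
    n_krill: int = 2,
    n_bubbles: int = 3,
    n_whales: int = 2,
    include_seafloor: bool = True,
) -> SceneConfig:
    """A noise-free scene with well-separated objects of every class, for
    exercising the rule-based reference segmenter end to end."""
    rng = np.random.default_rng(seed)
    specs: list[PlantSpec] = []
    taken: list = []

    floor_top = 0.8 * max_depth_m
    if include_seafloor:
        specs.append(
            PlantSpec("seafloor", 0.0, duration_s, floor_top, floor_top + 3.0,
                      DEFAULT_INTENSITY_DB["seafloor"])
        )
    object_depth_cap = floor_top - 12.0 if include_seafloor else max_depth_m - 10.0

    for _ in range(n_whales):
        dur = float(rng.integers(12, 30))
        height = float(rng.choice([4.0, 5.0, 9.0, 11.0, 13.0]))
        placed = _place_nonoverlapping(
            rng, taken, dur, height, duration_s, max_depth_m, 15.0,
            object_depth_cap - height, margin_s=10.0, margin_m=6.0,
        )
        if placed is None:
            continue
        t0, top = placed
        specs.append(
            PlantSpec("whale_dive", t0, t0 + dur, top, top + height,
                      DEFAULT_INTENSITY_DB["whale_dive"])
        )

    for _ in range(n_bubbles):
        dur = float(rng.integers(30, 70))
        width_px = 3
        end_depth = float(rng.uniform(3.0, 8.0))
        rate_m_per_s = float(rng.uniform(0.3, 0.45 * width_px))
        start_depth = min(end_depth + rate_m_per_s * dur, object_depth_cap)
        placed = _place_nonoverlapping(
            rng, taken, dur, start_depth - end_depth, duration_s, max_depth_m,
            end_depth, end_depth + 1.0, margin_s=10.0, margin_m=6.0,
        )
        if placed is None:
            continue
        t0, _ = placed
        specs.append(
            PlantSpec("bubble_trail", t0, t0 + dur, end_depth, start_depth,
                      DEFAULT_INTENSITY_DB["bubble_trail"],
                      {"width_px": width_px})
        )

    for _ in range(n_krill):
        dur = float(rng.integers(60, 120))
        height = float(rng.integers(8, 20))
        placed = _place_nonoverlapping(
            rng, taken, dur, height, duration_s, max_depth_m, 25.0,
            object_depth_cap - height, margin_s=10.0, margin_m=6.0,
        )
        if placed is None:
            continue
        t0, top = placed
        specs.append(
            PlantSpec("krill_swarm", t0, t0 + dur, top, top + height,
                      DEFAULT_INTENSITY_DB["krill_swarm"])
        )

    return SceneConfig(
        duration_s=duration_s,
        max_depth_m=max_depth_m,
        noise_mean_db=-120.0,
        noise_sd_db=0.0,
        object_specs=specs,
        rng_seed=seed,
    )


def training_tile_config(seed: int, size_px: int = 64) -> SceneConfig:
    """A small scene sized for one training tile (``size_px`` seconds x
    ``size_px/2`` meters), with realistic noise and a random mix of
    classes. Class frequencies are balanced far beyond the survey-corpus
    shares so a reduced network sees enough predator pixels to learn from.
    """
    rng = np.random.default_rng(seed)
    duration_s = float(size_px)
    max_depth_m = size_px * DEPTH_STEP_M
    specs: list[PlantSpec] = []

    if rng.random() < 0.5:  # krill swarm
        dur = float(rng.integers(size_px // 3, int(duration_s) - 4))
        height = float(rng.uniform(3.0, 0.3 * max_depth_m))
        t0 = float(rng.integers(1, int(duration_s - dur)))
        top = float(rng.uniform(2.0, max_depth_m - height - 2.0))
        specs.append(
            PlantSpec("krill_swarm", t0, t0 + dur, top, top + height,
                      DEFAULT_INTENSITY_DB["krill_swarm"] + float(rng.normal(0, 1.5)))
        )
    if rng.random() < 0.7:  # bubble trail
        dur = float(rng.integers(size_px // 2, int(duration_s) - 2))
        width_px = int(rng.integers(2, 4))
        end_depth = float(rng.uniform(1.5, 5.0))
        rate = float(rng.uniform(0.25, 0.45 * width_px))
        start_depth = min(end_depth + rate * dur, max_depth_m - 2.0)
        t0 = float(rng.integers(1, int(duration_s - dur)))
        specs.append(
            PlantSpec("bubble_trail", t0, t0 + dur, end_depth, start_depth,
                      DEFAULT_INTENSITY_DB["bubble_trail"] + float(rng.normal(0, 1.5)),
                      {"width_px": width_px})
        )
    if rng.random() < 0.4:  # whale dive
        dur = float(rng.integers(8, size_px // 2))
        height = float(rng.uniform(3.5, 10.0))
        t0 = float(rng.integers(1, int(duration_s - dur)))
        top = float(rng.uniform(2.0, max_depth_m - height - 2.0))
        specs.append(
            PlantSpec("whale_dive", t0, t0 + dur, top, top + height,
                      DEFAULT_INTENSITY_DB["whale_dive"] + float(rng.normal(0, 1.5)))
        )
    if rng.random() < 0.3:  # seafloor band near the bottom
        floor_top = float(rng.uniform(0.8 * max_depth_m, max_depth_m - 3.0))
        specs.append(
            PlantSpec("seafloor", 0.0, duration_s, floor_top,
                      min(floor_top + 3.0, max_depth_m),
                      DEFAULT_INTENSITY_DB["seafloor"])
        )

    return SceneConfig(
        duration_s=duration_s,
        max_depth_m=max_depth_m,
        object_specs=specs,
        rng_seed=seed,
    )


def make_training_corpus(
    n: int, seed: int = 0, size_px: int = 64
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n`` (grayscale tile, truth mask) training pairs."""
    from .preprocess import sv_to_grayscale_array  # local import: no cycle

    out = []
    for k in range(n):
        record, truth = simulate_scene(training_tile_config(seed * 1_000_003 + k, size_px))
        out.append((sv_to_grayscale_array(record.sv.T), truth.mask))
    return out


# ---------------------------------------------------------------------------
# Vessel tracks and colonies
# ---------------------------------------------------------------------------


def simulate_vessel_track(
    segments: list[tuple[float, float, float]],
    start: tuple[float, float],
    seed: int | None = None,
    start_timestamp: str | pd.Timestamp = "2022-01-15T00:00:00",
    sample_interval_s: float = 60.0,
    vessel_id: str = "SYN-001",
) -> pd.DataFrame:
    """Dead-reckon a vessel track on a sphere.

    ``segments`` is a list of ``(duration_s, speed_kn, heading_deg)``;
    heading is degrees clockwise from north. Positions are emitted every
    ``sample_interval_s``. The returned frame has columns
    (timestamp, lat, lon, speed_kn, vessel_id); activity status is derived
    downstream from speed.
    """
    lat, lon = float(start[0]), float(start[1])
    t0 = pd.Timestamp(start_timestamp)
    rows = [
        {"timestamp": t0, "lat": lat, "lon": lon,
         "speed_kn": float(segments[0][1]) if segments else 0.0}
    ]
    elapsed = 0.0
    for duration_s, speed_kn, heading_deg in segments:
        if speed_kn < 0:
            raise ValueError("segment speeds must be nonnegative")
        n_steps = int(round(duration_s / sample_interval_s))
        theta = math.radians(heading_deg)
        step_km = speed_kn * KNOT_MS * sample_interval_s / 1000.0
        for _ in range(n_steps):
            dlat = step_km / EARTH_RADIUS_KM * math.cos(theta)
            dlon = step_km / (EARTH_RADIUS_KM * math.cos(math.radians(lat))) * math.sin(theta)
            lat += math.degrees(dlat)
            lon += math.degrees(dlon)
            elapsed += sample_interval_s
            rows.append(
                {
                    "timestamp": t0 + pd.Timedelta(seconds=elapsed),
                    "lat": lat,
                    "lon": lon,
                    "speed_kn": float(speed_kn),
                }
            )
    track = pd.DataFrame(rows)
    track["vessel_id"] = vessel_id
    if not track["timestamp"].is_monotonic_increasing:
        raise RuntimeError("generated timestamps are not increasing")
    return track


def make_colony_set(
    n: int,
    region_bounds: tuple[float, float, float, float] = (-61.0, -60.0, -46.5, -44.5),
    populations=None,
    seed: int = 0,
    taxon: str = "penguin",
) -> pd.DataFrame:
    """Random predator colonies inside (lat_min, lat_max, lon_min, lon_max)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    lat_min, lat_max, lon_min, lon_max = region_bounds
    if populations is None:
        populations = np.full(n, 1e5)
    populations = np.asarray(populations, dtype=float)
    if populations.size != n:
        raise ValueError("populations must have length n")
    if np.any(populations < 0):
        raise ValueError("populations must be nonnegative")
    return pd.DataFrame(
        {
            "colony_id": [f"COL-{i:03d}" for i in range(n)],
            "lat": rng.uniform(lat_min, lat_max, n),
            "lon": rng.uniform(lon_min, lon_max, n),
            "population": populations,
            "taxon": taxon,
        }
    )
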