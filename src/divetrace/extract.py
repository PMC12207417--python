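"""Convert segmentation masks into discrete predator dive events.

Each connected component (8-connectivity) of a predator class — whale or
bubble trail — becomes one polygon; its inclusive pixel spans translate
directly into physical units on the standard grid: 1 pixel = 1 s in time
and 0.5 m in depth, so a component spanning columns 100..159 lasted 60 s
and one spanning rows 200..208 has an acoustic height of 4.5 m.

The acoustic height separates taxon groups: fur seals (body length ~2 m)
cannot produce signals taller than ~2 m, baleen whales (body diameter
3-6 m) produce signals of 3 m and more, leaving a 2-3 m ambiguous band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .classes import (
    BUBBLE_TRAIL,
    CLASS_NAMES,
    DEPTH_STEP_M,
    PREDATOR_CLASSES,
    TIME_STEP_S,
    WHALE,
)

logger = logging.getLogger(__name__)


@dataclass
class DivePolygon:
    """One connected predator component in mask pixel coordinates."""

    object_class: str               # "whale" or "bubble_trail"
    rows: np.ndarray
    cols: np.ndarray
    echogram_id: str = ""

    def __post_init__(self) -> None:
        if self.rows.size == 0:
            raise ValueError("polygon must be nonempty")

    @property
    def col_min(self) -> int:
        return int(self.cols.min())

    @property
    def col_max(self) -> int:
        return int(self.cols.max())

    @property
    def row_min(self) -> int:
        return int(self.rows.min())

    @property
    def row_max(self) -> int:
        return int(self.rows.max())

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)


def extract_dive_polygons(
    mask: np.ndarray,
    min_pixels: int = 6,
    echogram_id: str = "",
    classes=PREDATOR_CLASSES,
) -> list[DivePolygon]:
    """Connected components (8-connectivity) of each predator class,
    ordered by (col_min, row_min); components below ``min_pixels`` are
    dropped as noise."""
    mask = np.asarray(mask)
    out: list[DivePolygon] = []
    for code in classes:
        labeled = measure.label(mask == code, connectivity=2)
        for comp in measure.regionprops(labeled):
            if comp.area < min_pixels:
                continue
            out.append(
                DivePolygon(
                    object_class=CLASS_NAMES[code],
                    rows=comp.coords[:, 0].copy(),
                    cols=comp.coords[:, 1].copy(),
                    echogram_id=echogram_id,
                )
            )
    out.sort(key=lambda p: (p.col_min, p.row_min))
    return out


def classify_mammal_dive(height_m: float) -> str:
    """Taxon group from acoustic height: < 2 m seal_like, 2-3 m ambiguous,
    >= 3 m whale_like."""
    if height_m <= 0:
        raise ValueError(f"acoustic height must be positive, got {height_m}")
    if height_m < 2.0:
        return "seal_like"
    if height_m < 3.0:
        return "ambiguous"
    return "whale_like"


def measure_dive(
    polygon: DivePolygon,
    window_start: pd.Timestamp,
    track: pd.DataFrame | None = None,
    event_id: int = 0,
    n_cols: int = 600,
) -> dict:
    """Measure one polygon into a dive event.

    Duration and height use inclusive pixel spans (a single pixel is 1 s x
    0.5 m); the event timestamp is the window start plus col_min seconds;
    position is linearly interpolated from the vessel track at that
    timestamp (left empty if no track covers it).
    """
    duration_s = (polygon.col_max - polygon.col_min + 1) * TIME_STEP_S
    height_m = (polygon.row_max - polygon.row_min + 1) * DEPTH_STEP_M
    timestamp = pd.Timestamp(window_start) + pd.Timedelta(seconds=polygon.col_min)
    lat = lon = np.nan
    if track is not None and len(track) >= 2:
        t = track["timestamp"].astype("int64").to_numpy() / 1e9
        ts = timestamp.value / 1e9
        if t[0] <= ts <= t[-1]:
            lat = float(np.interp(ts, t, track["lat"].to_numpy()))
            lon = float(np.interp(ts, t, track["lon"].to_numpy()))
    if polygon.object_class == "whale":
        taxon = classify_mammal_dive(height_m)
    else:
        # Bubble trails are penguins and/or fur seals; the acoustic data
        # alone cannot separate them, only regional context can.
        taxon = "unclassified"
    return {
        "event_id": event_id,
        "echogram_id": polygon.echogram_id,
        "object_class": polygon.object_class,
        "taxon_group": taxon,
        "duration_s": duration_s,
        "duration_min": duration_s / 60.0,
        "acoustic_height_m": height_m,
        "timestamp": timestamp,
        "lat": lat,
        "lon": lon,
        "col_min": polygon.col_min,
        "col_max": polygon.col_max,
        "row_min": polygon.row_min,
        "row_max": polygon.row_max,
        "n_pixels": polygon.n_pixels,
        "window_boundary": polygon.col_min == 0 or polygon.col_max == n_cols - 1,
        "qc_flag": "kept",
    }


def extract_events(
    mask: np.ndarray,
    window_start: pd.Timestamp,
    track: pd.DataFrame | None = None,
    min_pixels: int = 6,
    echogram_id: str = "",
    id_offset: int = 0,
) -> pd.DataFrame:
    """Polygon extraction + measurement for one mask; returns the event
    table (possibly empty, always with full columns)."""
    polys = extract_dive_polygons(mask, min_pixels=min_pixels, echogram_id=echogram_id)
    rows = [
        measure_dive(p, window_start, track, event_id=id_offset + i,
                     n_cols=np.asarray(mask).shape[1])
        for i, p in enumerate(polys)
    ]
    if not rows:
        return pd.DataFrame(
            columns=list(
                measure_dive(
                    DivePolygon("whale", np.array([0]), np.array([0])),
                    pd.Timestamp("2000-01-01"),
                ).keys()
            )
        )
    return pd.DataFrame(rows)


def acoustic_height_histogram(events: pd.DataFrame, bin_m: float = 1.0) -> pd.DataFrame:
    """Counts of events per acoustic-height bin [k*bin, (k+1)*bin)."""
    if bin_m <= 0:
        raise ValueError("bin_m must be positive")
    if len(events) == 0:
        return pd.DataFrame(columns=["bin_left_m", "bin_right_m", "count"])
    h = events["acoustic_height_m"].to_numpy(dtype=float)
    top = (np.floor(h.max() / bin_m) + 1) * bin_m   # keep the top edge open
    edges = np.arange(0.0, top + bin_m / 2, bin_m)
    counts, _ = np.histogram(h, bins=edges)
    return pd.DataFrame(
        {"bin_left_m": edges[:-1], "bin_right_m": edges[1:], "count": counts}
    )


def apply_qc(events: pd.DataFrame, flags: pd.DataFrame | None) -> pd.DataFrame:
    """Apply manual-review flags: rows flagged ``remove`` keep their place
    in the table with qc_flag = "removed" but are excluded from every
    downstream rate. Unknown event ids are an error."""
    events = events.copy()
    if flags is None or len(flags) == 0:
        return events
    unknown = set(flags["event_id"]) - set(events["event_id"])
    if unknown:
        raise ValueError(f"QC flags reference unknown event ids: {sorted(unknown)}")
    removal = flags.set_index("event_id")["decision"].astype(str).str.lower()
    removed_ids = removal[removal.isin(["remove", "removed", "false_positive"])].index
    events.loc[events["event_id"].isin(removed_ids), "qc_flag"] = "removed"
    return events


def kept_events(events: pd.DataFrame) -> pd.DataFrame:
    """Events that survive QC (the only ones rates may use)."""
    if "qc_flag" not in events.columns or len(events) == 0:
        return events
    return events[events["qc_flag"] != "removed"]


def control_plot(echogram, events: pd.DataFrame, path) -> None:
    """Echogram with detection bounding boxes, for manual false-positive
    review. One PNG per echogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    img = echogram.data if hasattr(echogram, "units") else np.asarray(echogram)
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(img, cmap="viridis", aspect="auto", interpolation="nearest")
    for _, ev in events.iterrows():
        color = "red" if ev["object_class"] == "whale" else "deepskyblue"
        ax.add_patch(
            Rectangle(
                (ev["col_min"] - 0.5, ev["row_min"] - 0.5),
                ev["col_max"] - ev["col_min"] + 1,
                ev["row_max"] - ev["row_min"] + 1,
                fill=False, edgecolor=color, linewidth=1.2,
            )
        )
        ax.annotate(
            f"{ev['object_class']} #{ev['event_id']}",
            (ev["col_min"], max(ev["row_min"] - 3, 0)),
            color=color, fontsize=7,
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("depth bin (0.5 m)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
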