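"""Encounter-rate normalization and spatial/behavioral analyses.

The central statistic is the encounter rate: minutes of predator presence
beneath the vessel per hour of analyzed echogram observation, per predator
class, aggregated over time bins or lon/lat grid cells. Supporting
analyses: vessel-activity classification from track speed (fishing window
0.3-5 kn), distance-to-colony and 30-km buffer-zone exposure with a
before/after cutoff, krill-consumption equivalents, fleet synchrony
(median inter-vessel distance) and diel coverage diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .classes import PREDATOR_CLASSES, CLASS_NAMES

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
PREDATOR_CLASS_NAMES = tuple(CLASS_NAMES[c] for c in PREDATOR_CLASSES)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance (km) on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_to_nearest_colony(
    positions: pd.DataFrame, colonies: pd.DataFrame
) -> pd.DataFrame:
    """Per position: haversine distance (km) to, and id of, the nearest
    colony."""
    if len(colonies) == 0:
        raise ValueError("colony set is empty")
    lat = positions["lat"].to_numpy(dtype=float)
    lon = positions["lon"].to_numpy(dtype=float)
    d = np.stack(
        [haversine_km(lat, lon, c.lat, c.lon) for c in colonies.itertuples()],
        axis=1,
    )
    nearest = d.argmin(axis=1)
    return pd.DataFrame(
        {
            "distance_km": d[np.arange(len(lat)), nearest],
            "colony_id": colonies["colony_id"].to_numpy()[nearest],
        },
        index=positions.index,
    )


# ---------------------------------------------------------------------------
# Vessel activity
# ---------------------------------------------------------------------------


def classify_activity_by_speed(
    track: pd.DataFrame, lo_kn: float = 0.3, hi_kn: float = 5.0
) -> pd.DataFrame:
    """Label each track row stationary / fishing / steaming from its speed
    (fishing window inclusive at both bounds). Externally supplied status
    labels, where present, take precedence over the speed rule."""
    track = track.copy()
    speed = track["speed_kn"].to_numpy(dtype=float)
    if np.any(speed < 0):
        raise ValueError("negative vessel speeds are invalid")
    status = np.where(speed < lo_kn, "stationary",
                      np.where(speed > hi_kn, "steaming", "fishing"))
    if "status" in track.columns:
        supplied = track["status"].astype("object")
        keep = supplied.notna() & (supplied != "")
        status = np.where(keep, supplied, status)
    track["status"] = status
    return track


def _status_at(track: pd.DataFrame, timestamps: pd.Series) -> np.ndarray:
    """Step-function lookup: the status of each timestamp is that of the
    latest track row at or before it (outside the track -> 'unknown')."""
    t = track["timestamp"].astype("int64").to_numpy()
    s = track["status"].to_numpy()
    q = pd.to_datetime(timestamps).astype("int64").to_numpy()
    idx = np.searchsorted(t, q, side="right") - 1
    out = np.full(q.shape, "unknown", dtype=object)
    inside = (idx >= 0) & (q <= t[-1])
    out[inside] = s[idx[inside]]
    return out


def _fishing_overlap_s(track: pd.DataFrame, t0, t1) -> float:
    """Seconds of 'fishing' status inside [t0, t1), integrating the track's
    status step function."""
    t = track["timestamp"].astype("int64").to_numpy() / 1e9
    s = track["status"].to_numpy()
    a = pd.Timestamp(t0).value / 1e9
    b = pd.Timestamp(t1).value / 1e9
    edges = np.concatenate([[a], t[(t > a) & (t < b)], [b]])
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        k = np.searchsorted(t, lo, side="right") - 1
        if k >= 0 and s[k] == "fishing":
            total += hi - lo
    return total


def filter_to_fishing(
    events: pd.DataFrame,
    ledger: pd.DataFrame,
    track: pd.DataFrame,
    lo_kn: float = 0.3,
    hi_kn: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict events and observation hours to fishing periods.

    Events are kept/dropped by the status at their start timestamp; ledger
    rows have their hours scaled to the fishing overlap of their window, so
    an excluded minute leaves both the numerator and the denominator.
    """
    track = classify_activity_by_speed(track, lo_kn, hi_kn)
    if len(events):
        status = _status_at(track, events["timestamp"])
        events = events[status == "fishing"].copy()
    ledger = ledger.copy()
    fish_s = np.array(
        [_fishing_overlap_s(track, r.t_start, r.t_end) for r in ledger.itertuples()]
    )
    window_s = (
        ledger["t_end"] - ledger["t_start"]
    ).dt.total_seconds().to_numpy()
    frac = np.divide(fish_s, window_s, out=np.zeros_like(fish_s), where=window_s > 0)
    ledger["hours"] = ledger["hours"] * frac
    ledger = ledger[ledger["hours"] > 0].reset_index(drop=True)
    return events, ledger


# ---------------------------------------------------------------------------
# Observation ledger
# ---------------------------------------------------------------------------


def build_observation_ledger(
    echograms, track: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One ledger row per echogram window: vessel, window bounds, analyzed
    hours (non-padded columns only) and the vessel position at the window
    midpoint (NaN without a covering track)."""
    rows = []
    for eg in echograms:
        n_cols = eg.n_cols
        valid_cols = int(np.isfinite(eg.data).any(axis=0).sum())
        t0 = pd.Timestamp(eg.start_timestamp)
        t1 = t0 + pd.Timedelta(seconds=n_cols)
        lat = lon = np.nan
        if track is not None and len(track) >= 2:
            t = track["timestamp"].astype("int64").to_numpy() / 1e9
            mid = (t0 + (t1 - t0) / 2).value / 1e9
            if t[0] <= mid <= t[-1]:
                lat = float(np.interp(mid, t, track["lat"].to_numpy()))
                lon = float(np.interp(mid, t, track["lon"].to_numpy()))
        rows.append(
            {
                "echogram_id": eg.echogram_id,
                "vessel_id": eg.vessel_id,
                "t_start": t0,
                "t_end": t1,
                "hours": valid_cols / 3600.0,
                "lat": lat,
                "lon": lon,
            }
        )
    return pd.DataFrame(rows)


def _minutes_by_class(events: pd.DataFrame) -> dict:
    out = {}
    for name in PREDATOR_CLASS_NAMES:
        sub = events[events["object_class"] == name] if len(events) else events
        out[f"{name}_min"] = float(sub["duration_min"].sum()) if len(sub) else 0.0
    return out


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------


def _summarize(events: pd.DataFrame, hours: float) -> dict:
    row = _minutes_by_class(events)
    row["n_events"] = int(len(events))
    row["observation_hours"] = float(hours)
    for name in PREDATOR_CLASS_NAMES:
        if hours > 0:
            rate = row[f"{name}_min"] / hours
            row[f"{name}_rate_min_per_h"] = rate
            row[f"{name}_log_rate"] = float(np.log10(rate + 1.0))
        else:
            row[f"{name}_rate_min_per_h"] = np.nan
            row[f"{name}_log_rate"] = np.nan
    return row


def rate_timeseries(
    events: pd.DataFrame, ledger: pd.DataFrame, bin: str = "7D"
) -> pd.DataFrame:
    """Encounter rates per time bin and predator class.

    Minutes and hours are summed per bin (events and windows assigned by
    their start timestamp), then divided; log_rate = log10(rate + 1). Bins
    inside the ledger span with zero observation hours are emitted with
    missing (NaN) rates, not zero — no data is not the same as no
    predators.
    """
    if len(ledger) == 0:
        return pd.DataFrame()
    origin = ledger["t_start"].min().floor("D")
    span = pd.date_range(origin, ledger["t_end"].max() + pd.Timedelta(bin), freq=bin)

    def _bin_of(ts):
        return span[np.searchsorted(span.values, pd.to_datetime(ts).values, side="right") - 1]

    ledger_bins = _bin_of(ledger["t_start"])
    rows = []
    for b in span[:-1]:
        in_bin = ledger[np.asarray(ledger_bins) == b]
        hours = float(in_bin["hours"].sum())
        if len(events):
            ev_bins = _bin_of(events["timestamp"])
            ev = events[np.asarray(ev_bins) == b]
        else:
            ev = events
        row = {"bin_start": b, "bin_end": b + pd.Timedelta(bin)}
        row.update(_summarize(ev, hours))
        rows.append(row)
    out = pd.DataFrame(rows)
    # trim leading/trailing all-empty bins
    nonzero = out["observation_hours"] > 0
    if nonzero.any():
        out = out.loc[nonzero.idxmax(): nonzero[::-1].idxmax()].reset_index(drop=True)
    return out


@dataclass
class GridSpec:
    """Regular lon/lat grid; cells are half-open intervals anchored at
    integer multiples of the cell size from the origin."""

    lon_size: float
    lat_size: float
    lon_origin: float = 0.0
    lat_origin: float = 0.0
    region: str = ""

    def __post_init__(self) -> None:
        if self.lon_size <= 0 or self.lat_size <= 0:
            raise ValueError("cell sizes must be positive")

    def cell_index(self, lat, lon):
        i = np.floor((np.asarray(lon, dtype=float) - self.lon_origin) / self.lon_size)
        j = np.floor((np.asarray(lat, dtype=float) - self.lat_origin) / self.lat_size)
        return i.astype(int), j.astype(int)

    def cell_bounds(self, i: int, j: int):
        lon0 = self.lon_origin + i * self.lon_size
        lat0 = self.lat_origin + j * self.lat_size
        return lon0, lat0, lon0 + self.lon_size, lat0 + self.lat_size


#: Grid resolutions used for the three fishing regions (degrees).
REGION_GRIDS = {
    "south_georgia": 0.04,
    "south_orkneys": 0.03,
    "antarctic_peninsula": 0.075,
}


def rate_grid(
    events: pd.DataFrame, ledger: pd.DataFrame, grid: GridSpec
) -> pd.DataFrame:
    """Encounter rates per lon/lat grid cell. Cells with observations but
    no events are included (rate 0); events without a position are
    excluded with a logged count."""
    ledger = ledger[np.isfinite(ledger["lat"]) & np.isfinite(ledger["lon"])]
    if len(events):
        has_pos = np.isfinite(events["lat"]) & np.isfinite(events["lon"])
        dropped = int((~has_pos).sum())
        if dropped:
            logger.warning("rate_grid: %d events without position excluded", dropped)
        events = events[has_pos]
    li, lj = grid.cell_index(ledger["lat"], ledger["lon"])
    rows = []
    cells = set(zip(li, lj))
    if len(events):
        ei, ej = grid.cell_index(events["lat"], events["lon"])
        cells |= set(zip(ei, ej))   # conservation: no event minute may vanish
    cells = sorted(cells)
    for i, j in cells:
        sub_l = ledger[(li == i) & (lj == j)]
        sub_e = events[(ei == i) & (ej == j)] if len(events) else events
        lon0, lat0, lon1, lat1 = grid.cell_bounds(i, j)
        row = {
            "cell_i": i, "cell_j": j,
            "lon_min": lon0, "lat_min": lat0, "lon_max": lon1, "lat_max": lat1,
        }
        row.update(_summarize(sub_e, float(sub_l["hours"].sum())))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Colony exposure
# ---------------------------------------------------------------------------


def vrz_exposure(
    events: pd.DataFrame,
    ledger: pd.DataFrame,
    colonies: pd.DataFrame,
    buffer_km: float = 30.0,
    cutoff="2018-07-01",
) -> dict:
    """Buffer-zone exposure report.

    Each event and ledger window is labeled inside/outside the radial
    colony buffer (default 30 km, the approximate maximum foraging range of
    breeding penguins) and before/after the management cutoff date. Returns
    per-stratum encounter rates, the stratified tables, and the share of
    bubble-trail encounter minutes within 15 km of a colony.
    """
    cutoff = pd.Timestamp(cutoff)
    ev = events.copy()
    ld = ledger[np.isfinite(ledger["lat"]) & np.isfinite(ledger["lon"])].copy()
    if len(ev):
        ev = ev[np.isfinite(ev["lat"]) & np.isfinite(ev["lon"])].copy()
        near = distance_to_nearest_colony(ev, colonies)
        ev["distance_km"] = near["distance_km"]
        ev["nearest_colony"] = near["colony_id"]
        ev["inside_buffer"] = ev["distance_km"] <= buffer_km
        ev["period"] = np.where(ev["timestamp"] < cutoff, "before", "after")
    ld_near = distance_to_nearest_colony(ld, colonies)
    ld["distance_km"] = ld_near["distance_km"]
    ld["inside_buffer"] = ld["distance_km"] <= buffer_km
    ld["period"] = np.where(ld["t_start"] < cutoff, "before", "after")

    strata = {}
    for period in ("before", "after"):
        for inside in (True, False):
            sub_l = ld[(ld["period"] == period) & (ld["inside_buffer"] == inside)]
            if len(ev):
                sub_e = ev[(ev["period"] == period) & (ev["inside_buffer"] == inside)]
            else:
                sub_e = ev
            key = f"{period}_{'inside' if inside else 'outside'}"
            strata[key] = _summarize(sub_e, float(sub_l["hours"].sum()))

    bubble = ev[ev["object_class"] == "bubble_trail"] if len(ev) else ev
    total_min = float(bubble["duration_min"].sum()) if len(bubble) else 0.0
    within15 = (
        float(bubble.loc[bubble["distance_km"] <= 15.0, "duration_min"].sum())
        if len(bubble)
        else 0.0
    )
    return {
        "buffer_km": buffer_km,
        "cutoff": str(cutoff.date()),
        "strata": strata,
        "within_15km_share": within15 / total_min if total_min > 0 else np.nan,
        "events": ev,
        "ledger": ld,
    }


def penguin_consumption_equivalent(
    n_penguins: float, kg_per_penguin: float = 100.0
) -> float:
    """Summer krill demand of a penguin population, in tonnes (100 kg per
    penguin by default)."""
    if n_penguins < 0 or kg_per_penguin < 0:
        raise ValueError("inputs must be nonnegative")
    return n_penguins * kg_per_penguin / 1000.0


# ---------------------------------------------------------------------------
# Fleet diagnostics
# ---------------------------------------------------------------------------


def median_intervessel_distance(
    tracks: list[pd.DataFrame],
    bin: str = "1D",
    match_interval: str = "10min",
) -> pd.DataFrame:
    """Per time bin, the median over vessel pairs (and matched timestamps)
    of the haversine distance between vessels.

    Tracks are interpolated onto a common regular time grid; only
    timestamps inside every pair's coverage contribute.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 vessel tracks")
    t0 = min(tr["timestamp"].min() for tr in tracks)
    t1 = max(tr["timestamp"].max() for tr in tracks)
    grid = pd.date_range(t0.ceil(match_interval), t1, freq=match_interval)
    gsec = grid.astype("int64").to_numpy() / 1e9

    interp = []
    for tr in tracks:
        ts = tr["timestamp"].astype("int64").to_numpy() / 1e9
        inside = (gsec >= ts[0]) & (gsec <= ts[-1])
        lat = np.where(inside, np.interp(gsec, ts, tr["lat"].to_numpy()), np.nan)
        lon = np.where(inside, np.interp(gsec, ts, tr["lon"].to_numpy()), np.nan)
        interp.append((lat, lon))

    rows = []
    for a, b in combinations(range(len(tracks)), 2):
        la, lo = interp[a]
        lb, lob = interp[b]
        ok = np.isfinite(la) & np.isfinite(lb)
        d = haversine_km(la[ok], lo[ok], lb[ok], lob[ok])
        rows.append(pd.DataFrame({"timestamp": grid[ok], "pair": f"{a}-{b}",
                                  "distance_km": d}))
    all_d = pd.concat(rows, ignore_index=True)
    out = (
        all_d.set_index("timestamp")
        .resample(bin)["distance_km"]
        .median()
        .rename("median_distance_km")
        .reset_index()
    )
    return out.dropna().reset_index(drop=True)


def coverage_by_hour(ledger: pd.DataFrame, utc_offset_h: float = 0.0) -> pd.DataFrame:
    """Observation hours by local hour-of-day (24 bins, assigned by window
    start); bin sum equals the ledger total."""
    hours = np.zeros(24)
    if len(ledger):
        local = ledger["t_start"] + pd.Timedelta(hours=utc_offset_h)
        for h, v in zip(local.dt.hour, ledger["hours"]):
            hours[int(h)] += v
    return pd.DataFrame({"hour": np.arange(24), "observation_hours": hours})
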