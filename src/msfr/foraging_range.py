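"""Foraging range from telemetry: MEC windows, range GLM, stranding buffers.

A stranded predator's foraging range in the days before death is unknown, so
it is predicted from telemetry of conspecifics: tracks are regularized to a
fixed time step, split into consecutive windows of 2/4/6/8 days, and each
window is summarized by the diameter of the minimum enclosing circle (MEC)
of its positions.  A gamma GLM (log link) relates MEC diameter to timeframe,
age class, sex and season, with AIC-selected two-way interactions.  The
predicted diameter for a stranded individual's covariates becomes the
*radius* of a circular buffer centred on the stranding location — a
deliberate doubling that acknowledges the unknown direction of travel —
over which prey availability is later integrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AzimuthalEquidistant, minimum_enclosing_circle
from .glm import GammaGLMResult, ModelSearchResult, build_design, search_interactions

logger = logging.getLogger(__name__)

# region-exclusion thresholds: positions south of this latitude AND east of
# this longitude (the inner Danish waters) are dropped
LAT_MAX = 57.30
LON_MIN = 9.37

TIMEFRAMES = (2, 4, 6, 8)

CALENDAR_QUARTERS = {1: "Q1", 2: "Q1", 3: "Q1", 4: "Q2", 5: "Q2", 6: "Q2",
                     7: "Q3", 8: "Q3", 9: "Q3", 10: "Q4", 11: "Q4", 12: "Q4"}


def calendar_quarter(ts: pd.Series) -> pd.Series:
    return pd.to_datetime(ts).dt.month.map(CALENDAR_QUARTERS)


def filter_region(track: pd.DataFrame, lat_max: float = LAT_MAX,
                  lon_min: float = LON_MIN) -> pd.DataFrame:
    """Drop positions south of ``lat_max`` AND east of ``lon_min``.

    Keeps movement data representative of the open-sea study population by
    excluding the semi-enclosed waters to the south-east.
    """
    if len(track) == 0:
        return track.copy()
    drop = (track["lat"] < lat_max) & (track["lon"] > lon_min)
    return track.loc[~drop].copy()


def regularize_track(track: pd.DataFrame, step_hours: float = 6.0,
                     max_gap_hours: float = 48.0) -> pd.DataFrame:
    """Linear interpolation to a fixed time step in projected coordinates.

    Gaps longer than ``max_gap_hours`` split the track into segments (column
    ``segment``); interpolation never bridges a split.  Requires at least two
    positions.
    """
    if len(track) < 2:
        raise ValueError("regularization needs at least 2 positions")
    t = track.sort_values("timestamp").reset_index(drop=True)
    ts = pd.to_datetime(t["timestamp"])
    if ts.duplicated().any():
        t = t.loc[~ts.duplicated()].reset_index(drop=True)
        ts = pd.to_datetime(t["timestamp"])
    proj = AzimuthalEquidistant.for_points(t["lon"].to_numpy(), t["lat"].to_numpy())
    x, y = proj.forward(t["lon"].to_numpy(), t["lat"].to_numpy())
    sec = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    gaps = np.diff(sec) > max_gap_hours * 3600
    seg_id = np.concatenate([[0], np.cumsum(gaps)])

    out = []
    step_s = step_hours * 3600
    for seg in np.unique(seg_id):
        m = seg_id == seg
        if m.sum() < 2:
            continue
        s = sec[m]
        grid = np.arange(s[0], s[-1] + 1e-9, step_s)
        xi = np.interp(grid, s, x[m])
        yi = np.interp(grid, s, y[m])
        lon_i, lat_i = proj.inverse(xi, yi)
        out.append(pd.DataFrame({
            "timestamp": ts.iloc[0] + pd.to_timedelta(grid, unit="s"),
            "lon": lon_i, "lat": lat_i, "x_km": xi, "y_km": yi, "segment": seg,
        }))
    if not out:
        reg = pd.DataFrame(columns=["timestamp", "lon", "lat", "x_km", "y_km", "segment"])
    else:
        reg = pd.concat(out, ignore_index=True)
    for col in ("animal_id", "age_class", "sex"):
        if col in track.columns:
            reg[col] = track[col].iloc[0]
    return reg


@dataclass
class MECWindow:
    animal_id: str
    window_start: pd.Timestamp
    timeframe_days: int
    diameter_km: float
    center_xy: tuple[float, float]
    age_class: str
    sex: str
    quarter: str


def build_mec_windows(track: pd.DataFrame, timeframe_days: int,
                      step_hours: float = 6.0, overlap: bool = False) -> pd.DataFrame:
    """Consecutive (non-overlapping by default) MEC windows of one track.

    ``track`` must be regularized (``x_km``/``y_km`` present).  Windows with
    fewer than 2 positions are skipped with a log entry.  The window quarter
    is taken from its midpoint timestamp.
    """
    if timeframe_days not in TIMEFRAMES:
        raise ValueError(f"timeframe must be one of {TIMEFRAMES}, got {timeframe_days}")
    if "x_km" not in track.columns:
        raise ValueError("track must be regularized first (missing projected coordinates)")
    per_window = int(round(timeframe_days * 24 / step_hours))
    stride = max(per_window // 4, 1) if overlap else per_window
    rows = []
    for seg, grp in track.groupby("segment"):
        g = grp.reset_index(drop=True)
        for start in range(0, len(g) - 1, stride):
            w = g.iloc[start:start + per_window]
            if len(w) < 2:
                logger.info("skipping window with <2 positions (segment %s, start %d)", seg, start)
                continue
            if len(w) < per_window:
                break  # trailing partial window
            pts = w[["x_km", "y_km"]].to_numpy()
            (cx, cy), radius = minimum_enclosing_circle(pts)
            mid = w["timestamp"].iloc[len(w) // 2]
            rows.append({
                "animal_id": w["animal_id"].iloc[0] if "animal_id" in w else "",
                "window_start": w["timestamp"].iloc[0],
                "timeframe": str(timeframe_days),
                "diameter": 2.0 * radius,
                "center_x": cx, "center_y": cy,
                "age_class": w["age_class"].iloc[0] if "age_class" in w else "",
                "sex": w["sex"].iloc[0] if "sex" in w else "",
                "quarter": CALENDAR_QUARTERS[mid.month],
            })
    return pd.DataFrame(rows)


def windows_for_animals(tracks: pd.DataFrame, timeframes=TIMEFRAMES,
                        step_hours: float = 6.0, max_gap_hours: float = 48.0) -> pd.DataFrame:
    """Regularize every animal's track and pool MEC windows over timeframes."""
    frames = []
    for _, grp in tracks.groupby("animal_id"):
        if len(grp) < 2:
            continue
        reg = regularize_track(grp, step_hours=step_hours, max_gap_hours=max_gap_hours)
        if len(reg) < 2:
            continue
        for tf in timeframes:
            w = build_mec_windows(reg, tf, step_hours=step_hours)
            if len(w):
                frames.append(w)
    if not frames:
        return pd.DataFrame(columns=["animal_id", "window_start", "timeframe", "diameter",
                                     "center_x", "center_y", "age_class", "sex", "quarter"])
    return pd.concat(frames, ignore_index=True)


MAIN_EFFECTS = ["timeframe", "age_class", "sex", "quarter"]
REFERENCES = {"timeframe": "2", "age_class": "adult", "sex": "F", "quarter": "Q1"}


@dataclass
class RangeModel:
    """Fitted gamma GLM on MEC diameter plus the search/VIF metadata."""

    fit: GammaGLMResult
    search: ModelSearchResult
    references: dict[str, str]

    @property
    def aic(self) -> float:
        return self.fit.aic

    def predict_diameter(self, timeframe_days: int, age_class: str, sex: str,
                         quarter: str) -> float:
        df = pd.DataFrame({"timeframe": [str(timeframe_days)], "age_class": [age_class],
                           "sex": [sex], "quarter": [quarter]})
        X, names = build_design(df, self.fit.terms, self.references)
        fit_names = self.fit.names
        # a level unseen in fitting yields a column the model has no
        # coefficient for -> refuse rather than silently extrapolate
        unseen = [n for n in names if n not in fit_names]
        if unseen:
            raise ValueError(f"covariate level(s) unseen in fitting: {unseen}")
        full = np.zeros((1, len(fit_names)))
        for j, n in enumerate(names):
            full[0, fit_names.index(n)] = X[0, j]
        return float(np.exp(full @ self.fit.coef)[0])

    def prediction_grid(self, timeframes=TIMEFRAMES) -> pd.DataFrame:
        """Mean (SD) predicted diameter per timeframe x quarter x age x sex.

        SD is the delta-method standard error of the predicted mean on the
        response scale.
        """
        rows = []
        for tf in timeframes:
            for q in ("Q1", "Q2", "Q3", "Q4"):
                row = {"timeframe": f"{tf} days", "quarter": q}
                for age in ("adult", "juvenile"):
                    for sex in ("F", "M"):
                        df = pd.DataFrame({"timeframe": [str(tf)], "age_class": [age],
                                           "sex": [sex], "quarter": [q]})
                        X, names = build_design(df, self.fit.terms, self.references)
                        full = np.zeros(len(self.fit.names))
                        for j, n in enumerate(names):
                            full[self.fit.names.index(n)] = X[0, j]
                        mu = float(np.exp(full @ self.fit.coef))
                        se_eta = float(np.sqrt(full @ self.fit.cov @ full))
                        row[f"{age}_{sex}"] = f"{mu:.1f} ({mu * se_eta:.1f})"
                rows.append(row)
        return pd.DataFrame(rows)


def fit_range_glm(windows: pd.DataFrame, min_windows: int = 50,
                  vif_threshold: float = 4.0, drop_flagged: bool = False) -> RangeModel:
    """AIC-searched gamma GLM of MEC diameter on timeframe/age/sex/quarter.

    Windows with zero diameter (stationary animal) are excluded from the
    gamma fit.  Requires ``min_windows`` usable windows.
    """
    w = windows[windows["diameter"] > 0].copy()
    if len(w) < min_windows:
        raise ValueError(f"need >= {min_windows} windows with positive diameter, got {len(w)}")
    effects = [m for m in MAIN_EFFECTS if w[m].astype(str).nunique() > 1]
    search = search_interactions(
        w, w["diameter"].to_numpy(), effects,
        references={k: v for k, v in REFERENCES.items() if k in effects},
        vif_threshold=vif_threshold, drop_flagged=drop_flagged,
    )
    return RangeModel(search.best, search, {k: v for k, v in REFERENCES.items() if k in effects})


@dataclass
class ForagingBuffer:
    """Circular buffer centred on a stranding: radius = predicted MEC diameter."""

    stranding_id: object
    lon: float
    lat: float
    radius_km: float
    timeframe_days: int


def predict_buffer(model: RangeModel, stranding: pd.Series, timeframe_days: int) -> ForagingBuffer:
    """Buffer for one stranding: radius equals the predicted MEC *diameter*."""
    quarter = stranding.get("calendar_quarter")
    if quarter is None or (isinstance(quarter, float) and np.isnan(quarter)):
        quarter = CALENDAR_QUARTERS[pd.to_datetime(stranding["date"]).month]
    diameter = model.predict_diameter(timeframe_days, stranding["age_class"],
                                      stranding["sex"], quarter)
    return ForagingBuffer(
        stranding_id=stranding["id"], lon=float(stranding["lon"]),
        lat=float(stranding["lat"]), radius_km=diameter, timeframe_days=timeframe_days,
    )
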