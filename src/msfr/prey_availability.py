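"""Relative prey availability from trawl surveys, inside foraging buffers.

Survey catches (counts per standard tow, by length class) become biomass per
unit effort via a length-weight relationship evaluated at class midpoints,
restricted to consumable sizes (< 400 mm):

    BPUE = sum_{L < 400} a * ((L + 0.5 e) / 10)**b * CPUE_L

with length in mm, the midpoint converted to cm, and (a, b) the allometric
coefficients.  Log BPUE is smoothed over space and time with a penalized
additive model (depth smooth + lon/lat/year tensor product, REML); land
cells are masked rather than smoothed over.  The relative availability of a
prey to a stranded predator is the back-transformed prediction summed over
the sea cells inside its foraging buffer, with an SD from parametric
resampling of the smoother coefficients.  Sandeel, poorly caught by the
survey, instead uses an annual spawning-stock biomass index, spatially
constant within each year.  All availabilities are finally rescaled so the
maximum observed value is 100; ratios, which the functional response depends
on, are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foraging_range import ForagingBuffer
from .geometry import AzimuthalEquidistant, points_in_circle
from .smooth import PenalizedFit, fit_penalized_gaussian

MAX_LENGTH_MM = 400.0


@dataclass
class LengthWeightParams:
    species: str
    a: float
    b: float
    e: float  # length-class resolution, mm (5 or 10 depending on species)

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("allometric coefficient a must be > 0")
        if self.e not in (5, 10):
            raise ValueError(f"length resolution must be 5 or 10 mm, got {self.e}")


def compute_bpue(hauls: pd.DataFrame, lw: dict[str, LengthWeightParams]) -> pd.DataFrame:
    """Per-haul, per-species BPUE in grams.

    Length classes at or above 400 mm are excluded (consumability limit);
    the class midpoint (lower limit + half the resolution) in cm enters the
    allometry.  Raises ``KeyError`` for a species without parameters.
    """
    missing = set(hauls["species"].unique()) - set(lw)
    if missing:
        raise KeyError(f"no length-weight parameters for species: {sorted(missing)}")
    h = hauls[hauls["length_class_lower"] < MAX_LENGTH_MM].copy()
    a = h["species"].map({s: p.a for s, p in lw.items()}).to_numpy()
    b = h["species"].map({s: p.b for s, p in lw.items()}).to_numpy()
    e = h["species"].map({s: p.e for s, p in lw.items()}).to_numpy()
    mid_cm = (h["length_class_lower"].to_numpy() + 0.5 * e) / 10.0
    h["mass_g"] = a * mid_cm**b * h["cpue"].to_numpy()
    keys = [c for c in ("haul_id", "lon", "lat", "depth", "year", "quarter", "species")
            if c in h.columns]
    out = h.groupby(keys, as_index=False)["mass_g"].sum()
    return out.rename(columns={"mass_g": "bpue"})


@dataclass
class PreyField:
    """Fitted spatial BPUE surface for one species and quarter."""

    species: str
    quarter: str
    fit: PenalizedFit
    log_offset: float  # delta in log(BPUE + delta)
    years: list[int]
    # linear-predictor clamp (min/max fitted value at the training hauls):
    # keeps the exp back-transform from exploding where the tensor basis
    # extrapolates into unsurveyed corners of the grid
    linpred_range: tuple[float, float] = (-np.inf, np.inf)

    def predict_log(self, lon, lat, depth, year, coef: np.ndarray | None = None) -> np.ndarray:
        data = {
            "lon": np.asarray(lon, dtype=float), "lat": np.asarray(lat, dtype=float),
            "depth": np.asarray(depth, dtype=float),
            "year": np.asarray(year, dtype=float),
        }
        eta = self.fit.predict(data, coef=coef)
        return np.clip(eta, self.linpred_range[0], self.linpred_range[1])

    def predict_bpue(self, lon, lat, depth, year, coef: np.ndarray | None = None) -> np.ndarray:
        """Back-transformed predictions, floored at zero grams."""
        return np.maximum(np.exp(self.predict_log(lon, lat, depth, year, coef)) - self.log_offset, 0.0)


def fit_prey_field(bpue: pd.DataFrame, species: str, quarter: str,
                   k_depth: int = 6, k_space: tuple[int, int, int] = (5, 5, 3),
                   log_offset: float = 1.0, method: str = "REML",
                   min_records: int = 100) -> PreyField:
    """Penalized additive fit of log(BPUE + delta) for one species/quarter.

    Requires at least ``min_records`` records spanning at least two years.
    """
    d = bpue[(bpue["species"] == species) & (bpue["quarter"] == quarter)]
    if len(d) < min_records:
        raise ValueError(f"{species}/{quarter}: need >= {min_records} records, got {len(d)}")
    years = sorted(d["year"].unique())
    if len(years) < 2:
        raise ValueError(f"{species}/{quarter}: need records from >= 2 years")
    y = np.log(d["bpue"].to_numpy(dtype=float) + log_offset)
    data = {"lon": d["lon"].to_numpy(dtype=float), "lat": d["lat"].to_numpy(dtype=float),
            "depth": d["depth"].to_numpy(dtype=float), "year": d["year"].to_numpy(dtype=float)}
    ky = min(k_space[2], len(years))
    fit = fit_penalized_gaussian(
        data, y, spline_vars=[("depth", k_depth)],
        tensor_vars=(["lon", "lat", "year"], (k_space[0], k_space[1], ky)),
        method=method,
    )
    fitted = fit.predict(data)
    return PreyField(species=species, quarter=quarter, fit=fit,
                     log_offset=log_offset, years=[int(v) for v in years],
                     linpred_range=(float(fitted.min()), float(fitted.max())))


@dataclass
class AvailabilityEstimate:
    stranding_id: object
    species: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.mean < 0 or self.sd < 0:
            raise ValueError("availability mean and sd must be >= 0")


def integrate_buffer(field: PreyField, buffer: ForagingBuffer, grid: pd.DataFrame,
                     year: int, n_draws: int = 200, seed: int = 0) -> tuple[float, float]:
    """Total predicted BPUE over sea cells inside the buffer, with SD.

    Cell membership uses the cell-centre rule.  The SD comes from parametric
    resampling: coefficient vectors are drawn from the fitted smoother's
    posterior covariance and the buffer sum recomputed per draw.

    Raises ``ValueError`` if the buffer contains no sea cell.
    """
    proj = AzimuthalEquidistant.for_points(grid["lon"].to_numpy(), grid["lat"].to_numpy())
    if "x_km" in grid.columns:
        gx, gy = grid["x_km"].to_numpy(), grid["y_km"].to_numpy()
    else:
        gx, gy = proj.forward(grid["lon"].to_numpy(), grid["lat"].to_numpy())
    cx, cy = proj.forward(buffer.lon, buffer.lat)
    sea = grid["sea"].to_numpy() if "sea" in grid.columns else np.ones(len(grid), bool)
    inside = sea & points_in_circle(gx, gy, float(cx), float(cy), buffer.radius_km)
    if not inside.any():
        raise ValueError(
            f"buffer for stranding {buffer.stranding_id} contains no sea cell "
            f"(center {buffer.lon:.2f}E {buffer.lat:.2f}N, radius {buffer.radius_km:.0f} km)"
        )
    g = grid.loc[inside]
    depth = g["depth"].to_numpy() if "depth" in g.columns else np.full(inside.sum(), 20.0)
    lon, lat = g["lon"].to_numpy(), g["lat"].to_numpy()
    yr = np.full(len(g), float(year))
    mean = float(field.predict_bpue(lon, lat, depth, yr).sum())
    if n_draws < 2 or not np.any(field.fit.cov):
        return mean, 0.0
    rng = np.random.default_rng(seed)
    X = field.fit.design({"lon": lon, "lat": lat, "depth": depth, "year": yr})
    coefs = field.fit.sample_coefficients(n_draws, rng)  # (n_draws, p)
    eta = np.clip(coefs @ X.T, field.linpred_range[0], field.linpred_range[1])
    sums = np.maximum(np.exp(eta) - field.log_offset, 0.0).sum(axis=1)
    return mean, float(sums.std(ddof=1))


def sandeel_availability(ssb: dict[int, float] | pd.DataFrame, stranding: pd.Series,
                         cv: float = 0.0) -> tuple[float, float]:
    """Sandeel availability: the stranding year's SSB index, constant in space.

    The SD defaults to zero (no uncertainty statement accompanies the stock
    index); a coefficient of variation can be configured.
    """
    if isinstance(ssb, pd.DataFrame):
        ssb = dict(zip(ssb["year"].astype(int), ssb["ssb"].astype(float)))
    year = int(stranding["year"]) if "year" in stranding else pd.to_datetime(stranding["date"]).year
    if year not in ssb:
        raise KeyError(f"no sandeel SSB for year {year}")
    v = float(ssb[year])
    return v, cv * v


def rescale_availability(estimates: list[AvailabilityEstimate],
                         per_species: bool = False) -> list[AvailabilityEstimate]:
    """Rescale so the maximum mean is 100; SDs scale by the same factor.

    Global by default (one factor over all stranding x species values, which
    preserves cross-species ratios); ``per_species`` rescales each species to
    its own maximum of 100.  Idempotent.  Raises on all-zero input.
    """
    if not estimates:
        raise ValueError("no availability estimates to rescale")
    out = []
    if per_species:
        factors: dict[str, float] = {}
        for e in estimates:
            factors[e.species] = max(factors.get(e.species, 0.0), e.mean)
        if any(v <= 0 for v in factors.values()):
            zero = [s for s, v in factors.items() if v <= 0]
            raise ValueError(f"species with all-zero availability: {zero}")
        for e in estimates:
            f = factors[e.species] / 100.0
            out.append(AvailabilityEstimate(e.stranding_id, e.species, e.mean / f, e.sd / f))
        return out
    m = max(e.mean for e in estimates)
    if m <= 0:
        raise ValueError("all availability estimates are zero")
    f = m / 100.0
    return [AvailabilityEstimate(e.stranding_id, e.species, e.mean / f, e.sd / f)
            for e in estimates]


def availability_frame(estimates: list[AvailabilityEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"stranding_id": e.stranding_id, "species": e.species,
          "avail_mean": e.mean, "avail_sd": e.sd} for e in estimates]
    )
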