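"""Probabilistic breeding-origin mapping.

For each migrant, the fur value is inverted through the RMA calibration and
10,000 candidate precipitation values are simulated, each drawn from a
normal centred on the inverted value with an SD itself drawn from a gamma
distribution (propagating calibration uncertainty).  A kernel density over
the draws, standardized to a maximum of 1, reclassifies the isoscape into an
isotope origin-probability raster (PM_Iso).  Spring migration headings
(point-inverted autumn banding bearings) give a von Mises angular density
that scores each cell by its great-circle bearing from the sampling site
(PM_Ang).  Site maps are merged weighted by site sample size, and the
refined breeding-origin map PM_Breed is the cellwise product of PM_Iso and
PM_Ang; PM_Iso and PM_Breed are min-max standardized over unmasked cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import RMAModel, MIGRATORY
from .circular import VonMisesModel, fit_vonmises, initial_bearing, invert_bearings
from .raster import Isoscape, ProbabilityMap, Raster, minmax_standardize

__all__ = [
    "PrecipPDF",
    "simulate_precip",
    "build_precip_pdf",
    "reclassify",
    "merge_weighted",
    "bearing_grid",
    "angular_map",
    "combine",
    "run_stratified",
    "latitude_band_profile",
    "map_centroid",
]

log = logging.getLogger(__name__)


def simulate_precip(
    model: RMAModel,
    fur: float,
    n: int = 10000,
    gamma_shape: float | None = None,
    gamma_scale: float | None = None,
    gamma_cv: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Monte-Carlo delta2H_p draws for one measured fur value.

    Each draw is Normal(mean = inverted calibration value, SD = one gamma
    draw).  By default the gamma's mean equals the calibration residual SD
    expressed on the precipitation scale (residual SD / |slope|) with
    coefficient of variation ``gamma_cv``; explicit shape/scale override
    this.
    """
    if n <= 0:
        raise ValueError("need a positive number of draws")
    if model.slope == 0:
        raise ZeroDivisionError("zero calibration slope")
    rng = np.random.default_rng(rng)
    mu = float(model.invert(fur))
    if gamma_shape is None or gamma_scale is None:
        if gamma_cv <= 0:
            raise ValueError("gamma CV must be positive")
        mean_sd = model.resid_sd / abs(model.slope)
        gamma_shape = 1.0 / gamma_cv**2
        gamma_scale = mean_sd / gamma_shape
    if gamma_shape <= 0 or gamma_scale < 0:
        raise ValueError("gamma parameters must be positive")
    if gamma_scale == 0:
        return np.full(n, mu)
    sds = rng.gamma(gamma_shape, gamma_scale, size=n)
    return rng.normal(mu, sds)


@dataclass
class PrecipPDF:
    """Standardized (max = 1) kernel density over delta2H_p draws.

    Evaluated by linear interpolation on a fine grid spanning the draw range
    plus four bandwidths; a zero-variance draw set degenerates to an
    indicator of the single value.
    """

    draws: np.ndarray = field(repr=False)
    grid_x: np.ndarray = field(repr=False)
    grid_y: np.ndarray = field(repr=False)   # standardized to max 1
    point_mass: float | None = None

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)

    @property
    def argmax(self) -> float:
        if self.point_mass is not None:
            return self.point_mass
        return float(self.grid_x[np.argmax(self.grid_y)])

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.point_mass is not None:
            return np.where(np.isclose(x, self.point_mass, atol=1e-9), 1.0, 0.0) + np.where(
                np.isnan(x), np.nan, 0.0
            )
        return np.interp(x, self.grid_x, self.grid_y, left=0.0, right=0.0) + np.where(
            np.isnan(x), np.nan, 0.0
        )


def build_precip_pdf(draws, n_grid: int = 512, min_draws: int = 100) -> PrecipPDF:
    """Gaussian KDE (Silverman bandwidth) over draws, divided by its maximum."""
    d = np.asarray(draws, dtype=float)
    if d.size < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got {d.size}")
    if d.std() == 0:
        single = float(d[0])
        return PrecipPDF(
            draws=d, grid_x=np.array([single]), grid_y=np.array([1.0]),
            point_mass=single,
        )
    kde = stats.gaussian_kde(d, bw_method="silverman")
    bw = d.std(ddof=1) * kde.factor
    gx = np.linspace(d.min() - 4 * bw, d.max() + 4 * bw, n_grid)
    gy = kde(gx)
    gy = gy / gy.max()
    return PrecipPDF(draws=d, grid_x=gx, grid_y=gy)


def reclassify(isoscape: Isoscape, pdf: PrecipPDF, stratum: str = "all",
               provenance: dict | None = None) -> ProbabilityMap:
    """Evaluate the precipitation PDF at every unmasked isoscape cell."""
    vals = pdf(isoscape.values)
    return ProbabilityMap.like(
        isoscape, vals, role="PM_Iso", stratum=stratum, provenance=provenance or {}
    )


def merge_weighted(maps, weights) -> ProbabilityMap:
    """Cellwise weighted mean of aligned maps, weights normalized to sum 1.

    Provenance of the result records the normalized contribution of each
    input's sources.  Permutation-invariant and idempotent on identical
    maps.
    """
    maps = list(maps)
    w = np.asarray(weights, dtype=float)
    if len(maps) == 0 or w.size != len(maps):
        raise ValueError("need one weight per map")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    first = maps[0]
    for m in maps[1:]:
        if not first.aligned_with(m):
            raise ValueError("maps are not grid-aligned")
    wn = w / w.sum()
    out = np.zeros_like(first.values)
    for m, wi in zip(maps, wn):
        out = out + wi * m.values
    prov: dict[str, float] = {}
    for i, (m, wi) in enumerate(zip(maps, wn)):
        sub = m.provenance or {f"map{i}": 1.0}
        for k, v in sub.items():
            prov[k] = prov.get(k, 0.0) + wi * float(v)
    return first.with_values(out, provenance=prov)


def bearing_grid(site_lat: float, site_lon: float, isoscape: Isoscape) -> np.ndarray:
    """Initial great-circle bearing from the site to each unmasked cell center.

    Degrees clockwise from true north in [0, 360); masked cells and the cell
    coincident with the site come back NaN (bearing undefined).
    """
    lat, lon = isoscape.center_grids()
    b = initial_bearing(site_lat, site_lon, lat, lon)
    b = np.where(isoscape.mask, np.nan, b)
    coincident = np.isclose(lat, site_lat, atol=1e-9) & np.isclose(lon, site_lon, atol=1e-9)
    b[coincident] = np.nan
    return b


def angular_map(
    site_lat: float, site_lon: float, model: VonMisesModel, isoscape: Isoscape,
    stratum: str = "all", provenance: dict | None = None,
) -> ProbabilityMap:
    """Score each cell by the angular density at its bearing from the site."""
    b = bearing_grid(site_lat, site_lon, isoscape)
    vals = np.where(np.isnan(b), np.nan, model.density(np.nan_to_num(b)))
    return ProbabilityMap.like(
        isoscape, vals, role="PM_Ang", stratum=stratum, provenance=provenance or {}
    )


def combine(pm_iso: ProbabilityMap, pm_ang: ProbabilityMap) -> ProbabilityMap:
    """Refined breeding-origin map: cellwise product, then min-max standardized."""
    if not pm_iso.aligned_with(pm_ang):
        raise ValueError("maps are not grid-aligned")
    prod = pm_iso.values * pm_ang.values
    breed = ProbabilityMap.like(
        pm_iso, prod, role="PM_Breed", stratum=pm_iso.stratum,
        provenance=dict(pm_iso.provenance),
    )
    return minmax_standardize(breed)


def _max_standardize(pmap: ProbabilityMap) -> ProbabilityMap:
    mx = np.nanmax(pmap.values)
    if not np.isfinite(mx) or mx == 0:
        raise ValueError("cannot standardize an empty or all-zero map")
    return pmap.with_values(pmap.values / mx)


def run_stratified(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    model: RMAModel,
    isoscape: Isoscape,
    autumn_bearings,
    strata: str = "sex",
    draws: int = 10000,
    seed: int = 0,
    gamma_cv: float = 0.3,
    per_individual: bool = False,
    direction: str = "below",
    range_mask: np.ndarray | None = None,
) -> dict[str, dict[str, ProbabilityMap]]:
    """Full origin-mapping stage, per stratum.

    Only classified migrants on the requested side of the interval
    contribute ('below' = more depleted than expected locally, i.e. northern
    origins).  Individuals sharing a site have their Monte-Carlo draws
    pooled before density estimation; site maps are merged weighted by the
    site's migrant count.  Returns, per stratum, the standardized PM_Iso,
    the max-standardized merged PM_Ang and the standardized PM_Breed.

    ``range_mask``: optional boolean array aligned with the isoscape, True
    where the species' distribution range covers the cell; cells outside
    are masked in all outputs (applied last).
    """
    if "status" not in records.columns:
        raise ValueError("records are not classified (no 'status' column)")
    migrants = records[(records["status"] == MIGRATORY) & (records["side"] == direction)]
    migrants = migrants.sort_values("id").reset_index(drop=True)
    spring = invert_bearings(np.asarray(autumn_bearings, dtype=float))
    ang_model = fit_vonmises(spring)
    site_xy = sites.set_index("site_id")[["lat", "lon"]]

    if strata == "sex":
        groups = {s: migrants[migrants["sex"] == s] for s in ("female", "male")}
    elif strata == "all":
        groups = {"all": migrants}
    else:
        raise ValueError("strata must be 'sex' or 'all'")

    # deterministic per-individual seed streams, stable under stratification
    ids = migrants["id"].tolist()
    id_stream = {rid: k for k, rid in enumerate(ids)}

    out: dict[str, dict[str, ProbabilityMap]] = {}
    for name, grp in groups.items():
        if len(grp) == 0:
            log.warning("stratum '%s' has no contributing migrants; skipped", name)
            continue
        iso_maps, ang_maps, weights = [], [], []
        if per_individual:
            units = [(rid, grp[grp["id"] == rid]) for rid in grp["id"]]
        else:
            units = list(grp.groupby("site_id", sort=True))
        for key, sub in units:
            pooled = np.concatenate(
                [
                    simulate_precip(
                        model, fur, n=draws, gamma_cv=gamma_cv,
                        rng=np.random.default_rng([seed, id_stream[rid]]),
                    )
                    for rid, fur in zip(sub["id"], sub["d2h_fur"])
                ]
            )
            pdf = build_precip_pdf(pooled)
            sid = sub["site_id"].iloc[0]
            prov = {str(sid): 1.0}
            iso_maps.append(reclassify(isoscape, pdf, stratum=name, provenance=prov))
            la, lo = site_xy.loc[sid]
            ang_maps.append(
                angular_map(la, lo, ang_model, isoscape, stratum=name, provenance=prov)
            )
            weights.append(len(sub))
        pm_iso_raw = merge_weighted(iso_maps, weights)
        pm_ang = _max_standardize(merge_weighted(ang_maps, weights))
        pm_breed = combine(pm_iso_raw, pm_ang)
        pm_iso = minmax_standardize(pm_iso_raw)
        if range_mask is not None:
            outside = ~np.asarray(range_mask, dtype=bool)
            for m in (pm_iso, pm_ang, pm_breed):
                m.values[outside] = np.nan
        out[name] = {"PM_Iso": pm_iso, "PM_Ang": pm_ang, "PM_Breed": pm_breed}
    return out


def latitude_band_profile(pmap: Raster, band_width_deg: float) -> pd.DataFrame:
    """Mean unmasked map value in equal-width latitude bands (south to north)."""
    if band_width_deg <= 0:
        raise ValueError("band width must be positive")
    lat, _ = pmap.center_grids()
    lo = pmap.lat_min
    rows = []
    while lo < pmap.lat_max - 1e-9:
        hi = min(lo + band_width_deg, pmap.lat_max)
        sel = (lat >= lo) & (lat < hi) & np.isfinite(pmap.values)
        rows.append(
            {
                "lat_lo": lo,
                "lat_hi": hi,
                "mean": float(pmap.values[sel].mean()) if sel.any() else np.nan,
            }
        )
        lo = hi
    return pd.DataFrame(rows)


def map_centroid(pmap: Raster) -> tuple[float, float]:
    """Probability-weighted (lat, lon) centroid over unmasked cells."""
    lat, lon = pmap.center_grids()
    w = np.where(np.isfinite(pmap.values), pmap.values, 0.0)
    tot = w.sum()
    if tot == 0:
        raise ValueError("all-zero map has no centroid")
    return float((w * lat).sum() / tot), float((w * lon).sum() / tot)
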