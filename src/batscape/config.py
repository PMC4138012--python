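"""Configuration dataclasses for the synthetic world and the pipeline.

Both round-trip through YAML unchanged, so a run is fully described by its
config file plus the seeds recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["SyntheticConfig", "PipelineConfig"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study region and casualty sample.

    The defaults describe a mid-European scene: a 10 degree x 10 degree
    window at 10'x10' resolution with precipitation deuterium declining to
    the north at 2.5 permil per degree latitude; 45 wind-farm sites in a
    southern band holding 99 locally-moulted and 37 migrant casualties whose
    true moult origins sit in a northern latitude band; fur tracks
    precipitation linearly with ~6.3 permil residual scatter; autumn banding
    bearings cluster around 225 degrees (toward the south-west).
    """

    # isoscape grid
    lat_min: float = 50.0
    lat_max: float = 60.0
    lon_min: float = 8.0
    lon_max: float = 18.0
    cell_arcmin: float = 10.0
    gradient_slope: float = -2.5       # permil delta2H_p per degree latitude
    gradient_intercept: float = 65.0   # permil at latitude 0
    spatial_noise_sd: float = 1.5      # permil, smoothed white noise
    noise_blur_cells: float = 3.0      # Gaussian blur radius of the noise field

    # fur ~ precipitation calibration truth
    rma_slope: float = 1.3
    rma_intercept: float = -10.0       # permil
    calib_resid_sd: float = 6.3        # permil, fur-axis residual SD

    # sites and casualties
    n_sites: int = 45
    site_count_range: tuple[int, int] = (1, 16)
    site_lat_range: tuple[float, float] = (51.0, 53.5)
    site_lon_range: tuple[float, float] = (9.0, 17.0)
    n_macrochores: int = 12
    n_local: int = 99
    n_migrant: int = 37
    migrant_band: tuple[float, float] = (57.5, 60.0)   # true origin latitudes
    migrant_lon_range: tuple[float, float] = (12.0, 17.5)
    female_north_shift: float = 1.0    # deg; female origins sit this much farther north
    sex_ratio_local: float = 0.5       # fraction female among locals
    migrant_female_frac: float = 0.62
    age_probs: tuple[float, float, float] = (0.34, 0.37, 0.29)  # adult/juvenile/NA
    season_drift: float = 0.0          # permil fur per day added to migrants

    # discovery dates (day of year; July 1 .. Sep 30)
    doy_range: tuple[int, int] = (182, 273)
    year: int = 2010

    # banding bearings (autumn)
    bearing_mean: float = 225.0
    bearing_kappa: float = 4.0
    n_bearings: int = 100

    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.cell_arcmin <= 0:
            raise ValueError("cell size must be positive")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("empty grid extent")
        lo, hi = self.site_count_range
        if not (1 <= lo <= hi):
            raise ValueError("per-site count range must satisfy 1 <= lo <= hi")
        if self.n_local + self.n_migrant <= 0:
            raise ValueError("need at least one individual")
        if self.n_local < 0 or self.n_migrant < 0:
            raise ValueError("counts must be non-negative")
        if not (self.lat_min <= self.migrant_band[0] < self.migrant_band[1] <= self.lat_max):
            raise ValueError("migrant origin band must lie inside the isoscape")
        if self.bearing_kappa < 0:
            raise ValueError("bearing concentration must be >= 0")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**_retuple(cls, raw)).validate()


@dataclass
class PipelineConfig:
    """End-to-end pipeline run description (paths, parameters, seeds)."""

    out_dir: str = "out"
    records_path: str | None = None
    sites_path: str | None = None
    isoscape_path: str | None = None
    bearings_path: str | None = None
    calibration_path: str | None = None   # CSV of (precip, fur) pairs

    # externally supplied RMA parameters bypass fitting when set
    rma_slope: float | None = None
    rma_intercept: float | None = None
    rma_resid_sd: float | None = None
    rma_n: int | None = None

    classification_level: float = 0.95
    run_lmm: bool = True
    draws: int = 10000
    gamma_cv: float = 0.3
    angular: str = "vonmises"
    per_individual: bool = False
    strata: str = "sex"                 # "sex" or "all"
    range_mask_path: str | None = None
    seed: int = 0
    synthetic: SyntheticConfig | None = None  # simulate inputs when paths absent

    def to_yaml(self, path) -> None:
        raw = _plain_dict(self)
        if self.synthetic is not None:
            raw["synthetic"] = _plain_dict(self.synthetic)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("synthetic") is not None:
            raw["synthetic"] = SyntheticConfig(
                **_retuple(SyntheticConfig, raw["synthetic"])
            ).validate()
        return cls(**raw)


def _plain_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        if dataclasses.is_dataclass(v):
            continue
        out[f.name] = v
    return out


def _retuple(cls, raw: dict) -> dict:
    """YAML has no tuples; restore them per the dataclass defaults."""
    defaults = {f.name: f.default for f in dataclasses.fields(cls)}
    return {
        k: tuple(v) if isinstance(defaults.get(k), tuple) and isinstance(v, list) else v
        for k, v in raw.items()
    }
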