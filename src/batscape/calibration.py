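"""Reduced major axis (RMA) fur-precipitation calibration and classification.

The calibration relates fur keratin deuterium (delta2H_f) of sedentary bats
to the mapped mean-annual-precipitation deuterium (delta2H_p) at their site.
RMA (geometric-mean) regression is the field's standard here because both
axes carry error: slope = sign(r) * SD(fur)/SD(precip).

A carcass is classified *sedentary* when its fur value falls inside the
closed prediction interval around the expected fur value for its site at the
chosen level (default 95%), and *migratory* otherwise; the side of the
interval (below = origin in a more deuterium-depleted, i.e. typically more
northern, region) is kept for direction-aware mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RMAModel",
    "fit_rma",
    "expected_fur_interval",
    "classify",
    "classify_records",
    "invert_to_precip",
    "summarize_by_group",
    "composition_percentages",
]

SEDENTARY = "sedentary"
MIGRATORY = "migratory"


@dataclass
class RMAModel:
    """Reduced-major-axis calibration: fur = intercept + slope * precip.

    ``resid_sd`` is the SD of fur-axis residuals about the line; ``n`` and
    ``r`` may be None for externally published parameter sets, in which case
    interval half-widths use the normal rather than the t quantile.
    """

    slope: float
    intercept: float
    resid_sd: float
    n: int | None = None
    r: float | None = None

    def __post_init__(self) -> None:
        if self.resid_sd is None or self.resid_sd < 0:
            raise ValueError("residual SD must be a non-negative number")
        if self.r is not None and np.sign(self.slope) != np.sign(self.r):
            raise ValueError("slope sign must equal the sign of r")

    def predict(self, precip) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(precip, dtype=float)

    def invert(self, fur) -> np.ndarray:
        return invert_to_precip(self, fur)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "resid_sd": self.resid_sd,
            "n": self.n,
            "r": self.r,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RMAModel":
        return cls(**{k: d.get(k) for k in ("slope", "intercept", "resid_sd", "n", "r")})


def fit_rma(precip, fur) -> RMAModel:
    """Fit the RMA calibration to (delta2H_p, delta2H_f) pairs.

    Requires >= 3 pairs, positive variance on both axes and a nonzero
    correlation (the slope sign is sign(r) and undefined at r = 0).
    """
    x = np.asarray(precip, dtype=float)
    y = np.asarray(fur, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("precip and fur must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 calibration pairs, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on one axis; RMA undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        raise ValueError("correlation is exactly zero; RMA slope sign undefined")
    slope = float(np.sign(r) * sy / sx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    # fur-axis scatter about the line; 2 estimated line parameters
    resid_sd = float(np.sqrt((resid**2).sum() / max(n - 2, 1)))
    return RMAModel(slope=slope, intercept=intercept, resid_sd=resid_sd, n=n, r=r)


def _halfwidth_quantile(model: RMAModel, level: float) -> float:
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    q = 0.5 + level / 2.0
    if model.n is not None and model.n > 2:
        return float(stats.t.ppf(q, df=model.n - 2))
    return float(stats.norm.ppf(q))


def expected_fur_interval(
    model: RMAModel, site_precip: float, level: float = 0.95
) -> tuple[float, float]:
    """Closed prediction interval of fur values expected for a site.

    Centered on the calibration line at the site's delta2H_p, half-width =
    t-quantile(level, n-2) * residual SD (normal quantile when the pair
    count of an external model is unknown).
    """
    center = float(model.predict(site_precip))
    half = _halfwidth_quantile(model, level) * model.resid_sd
    return center - half, center + half


def classify(
    fur: float, site_precip: float, model: RMAModel, level: float = 0.95
) -> tuple[str, str]:
    """Classify one fur value against its site's expected interval.

    Returns ``(status, side)`` with status 'sedentary' or 'migratory' and
    side 'below'/'above'/'inside'.  Values exactly on a bound count as
    sedentary (closed-interval convention, conservative toward local origin).
    """
    if fur is None or not np.isfinite(fur):
        raise ValueError("fur isotope value missing or non-finite")
    if site_precip is None or not np.isfinite(site_precip):
        raise ValueError("site delta2H_p missing or non-finite")
    lo, hi = expected_fur_interval(model, site_precip, level)
    if lo <= fur <= hi:
        return SEDENTARY, "inside"
    return MIGRATORY, ("below" if fur < lo else "above")


def classify_records(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    model: RMAModel,
    level: float = 0.95,
) -> pd.DataFrame:
    """Vectorized classification; returns a copy with status and side columns.

    ``sites`` must carry a ``precip`` column (site delta2H_p looked up from
    the isoscape).  Order-invariant: each row is classified independently.
    """
    if "precip" not in sites.columns:
        raise ValueError("sites table lacks a 'precip' column")
    out = records.copy()
    precip = out["site_id"].map(sites.set_index("site_id")["precip"])
    if precip.isna().any():
        bad = sorted(out.loc[precip.isna(), "site_id"].unique())
        raise ValueError(f"records reference sites without delta2H_p: {bad}")
    center = model.predict(precip.to_numpy())
    half = _halfwidth_quantile(model, level) * model.resid_sd
    fur = out["d2h_fur"].to_numpy(dtype=float)
    if not np.isfinite(fur).all():
        raise ValueError("non-finite fur isotope values present")
    inside = (fur >= center - half) & (fur <= center + half)
    out["status"] = np.where(inside, SEDENTARY, MIGRATORY)
    out["side"] = np.where(inside, "inside", np.where(fur < center - half, "below", "above"))
    out["site_precip"] = precip.to_numpy()
    return out


def invert_to_precip(model: RMAModel, fur) -> np.ndarray:
    """Invert fur values through the calibration: (fur - intercept)/slope."""
    if model.slope == 0:
        raise ZeroDivisionError("zero calibration slope cannot be inverted")
    return (np.asarray(fur, dtype=float) - model.intercept) / model.slope


_AGES = ["all", "adult", "juvenile", "NA"]


def summarize_by_group(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and mean +/- SD of fur deuterium by status x age x sex.

    Rows are (status, age) with an 'all' age row per status and an 'NA' row
    for unknown age; columns hold total and per-sex counts and per-sex
    mean/SD of delta2H_f.  Works on empty input (all-zero counts).
    """
    rows = []
    statuses = [MIGRATORY, SEDENTARY]
    df = records.copy()
    if "age" in df.columns:
        df["age"] = df["age"].fillna("NA")
    for status in statuses:
        sub = df[df.get("status", pd.Series(dtype=object)) == status]
        for age in _AGES:
            grp = sub if age == "all" else sub[sub["age"] == age] if len(sub) else sub
            males = grp[grp["sex"] == "male"] if len(grp) else grp
            females = grp[grp["sex"] == "female"] if len(grp) else grp
            rows.append(
                {
                    "status": status,
                    "age": age,
                    "n": len(grp),
                    "n_male": len(males),
                    "n_female": len(females),
                    "mean_male": males["d2h_fur"].mean() if len(males) else np.nan,
                    "sd_male": males["d2h_fur"].std(ddof=1) if len(males) > 1 else np.nan,
                    "mean_female": females["d2h_fur"].mean() if len(females) else np.nan,
                    "sd_female": females["d2h_fur"].std(ddof=1) if len(females) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index(["status", "age"])


def composition_percentages(records: pd.DataFrame) -> dict:
    """Headline composition shares of a classified record table.

    Returns both raw fractions and conventionally rounded percentages: the
    migratory share, the female share among migrants, and the juvenile share
    within each status (unknown-age individuals stay in the denominator).
    """
    n = len(records)
    mig = records[records["status"] == MIGRATORY]
    sed = records[records["status"] == SEDENTARY]

    def _pct(num: int, den: int) -> tuple[float, float]:
        frac = num / den if den else np.nan
        return frac, round(100 * frac) if den else np.nan

    frac_mig, pct_mig = _pct(len(mig), n)
    frac_fem, pct_fem = _pct((mig["sex"] == "female").sum(), len(mig))
    frac_juv_m, pct_juv_m = _pct((mig["age"] == "juvenile").sum(), len(mig))
    frac_juv_s, pct_juv_s = _pct((sed["age"] == "juvenile").sum(), len(sed))
    return {
        "n_total": n,
        "n_migratory": len(mig),
        "n_sedentary": len(sed),
        "frac_migratory": frac_mig,
        "pct_migratory": pct_mig,
        "frac_female_among_migrants": frac_fem,
        "pct_female_among_migrants": pct_fem,
        "frac_juvenile_among_migrants": frac_juv_m,
        "pct_juvenile_among_migrants": pct_juv_m,
        "frac_juvenile_among_sedentary": frac_juv_s,
        "pct_juvenile_among_sedentary": pct_juv_s,
    }
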