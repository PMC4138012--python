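"""Mixed-effects covariate protocol for fur deuterium.

Implements the standard top-down model-selection strategy for grouped
ecological data: (1) collinearity screen of the predictors, (2) a three-knot
smooth per numeric covariate as a linearity diagnostic, (3) selection of the
random structure — no random effect vs a site or macrochore random
intercept — by AIC under REML with an identical full fixed part, (4)
backward elimination of fixed terms by likelihood-ratio test under ML,
respecting marginality, (5) final REML fit, and (6) a Monte-Carlo Lilliefors
normality check of the residuals.

The no-random-effect candidate's REML log-likelihood is computed in closed
form with the same convention as the mixed fits, so its AIC is comparable
(verified against nlme's gls/lme conventions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "FULL_TERMS",
    "LMMResult",
    "build_model_frame",
    "check_collinearity",
    "linearity_diagnostic",
    "fit_lmm",
    "select_random_structure",
    "select_fixed_structure",
    "fit_final",
    "lilliefors_test",
]

FULL_TERMS = ("season", "sex", "migratory", "lat", "lon", "lat:lon")

_TERM_FORMULA = {
    "season": "doy",
    "sex": "C(sex)",
    "migratory": "C(status, Treatment('sedentary'))",
    "lat": "lat",
    "lon": "lon",
    "lat:lon": "lat:lon",
}

_CATEGORICAL = {"sex": "sex", "migratory": "status"}


def build_model_frame(records: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Join classified records with site coordinates and derive day-of-year."""
    need = {"d2h_fur", "sex", "status", "date", "site_id"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    frame = records.merge(
        sites[["site_id", "lat", "lon"] + (["macrochore"] if "macrochore" in sites else [])],
        on="site_id",
        how="left",
        validate="many_to_one",
    )
    if frame["lat"].isna().any():
        bad = sorted(frame.loc[frame.lat.isna(), "site_id"].unique())
        raise ValueError(f"records reference unknown sites: {bad}")
    frame["doy"] = pd.to_datetime(frame["date"]).dt.dayofyear
    if frame["d2h_fur"].isna().any():
        raise ValueError("missing response values in model frame")
    return frame


def _formula(terms) -> str:
    rhs = " + ".join(_TERM_FORMULA[t] for t in terms) if terms else "1"
    return f"d2h_fur ~ {rhs}"


def _check_levels(frame: pd.DataFrame, terms) -> None:
    for t in terms:
        col = _CATEGORICAL.get(t)
        if col is not None and frame[col].nunique() < 2:
            raise ValueError(f"categorical covariate '{col}' has fewer than 2 levels")


def check_collinearity(
    frame: pd.DataFrame, columns=("doy", "lat", "lon"), threshold: float = 0.75
) -> pd.DataFrame:
    """Pairwise Pearson r of numeric covariates; |r| >= threshold flagged.

    A constant covariate has undefined r and is flagged degenerate rather
    than dropped silently.
    """
    cols = [c for c in columns if c in frame.columns]
    if len(cols) < 2:
        raise ValueError("need at least two numeric covariates")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            xa, xb = frame[a].to_numpy(float), frame[b].to_numpy(float)
            degenerate = xa.std() == 0 or xb.std() == 0
            r = np.nan if degenerate else float(np.corrcoef(xa, xb)[0, 1])
            rows.append(
                {
                    "var1": a,
                    "var2": b,
                    "r": r,
                    "degenerate": degenerate,
                    "flagged": degenerate or abs(r) >= threshold,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LinearityResult:
    covariate: str
    verdict: str                 # "linear" | "non-linear"
    aic_line: float
    aic_smooth: float
    smooth_x: np.ndarray = field(repr=False, default=None)
    smooth_y: np.ndarray = field(repr=False, default=None)


def linearity_diagnostic(
    frame: pd.DataFrame,
    covariate: str,
    response: str = "d2h_fur",
    aic_margin: float = 2.0,
) -> LinearityResult:
    """Three-knot smooth vs straight line as a linearity check.

    The verdict is "linear" unless the natural-cubic smooth (3 df, the
    three-knot GAM analogue) improves AIC over the straight line by more
    than ``aic_margin``.  Plottable smooth coordinates are returned.
    """
    x = frame[covariate].to_numpy(float)
    y = frame[response].to_numpy(float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct covariate values")
    line = sm.OLS(y, sm.add_constant(x)).fit()
    basis = patsy.dmatrix("cr(x, df=3)", {"x": x}, return_type="dataframe")
    smooth = sm.OLS(y, np.asarray(basis)).fit()
    grid = np.linspace(x.min(), x.max(), 100)
    grid_basis = patsy.build_design_matrices([basis.design_info], {"x": grid})[0]
    pred = np.asarray(grid_basis) @ smooth.params
    verdict = "linear" if line.aic - smooth.aic <= aic_margin else "non-linear"
    return LinearityResult(
        covariate=covariate,
        verdict=verdict,
        aic_line=float(line.aic),
        aic_smooth=float(smooth.aic),
        smooth_x=grid,
        smooth_y=np.asarray(pred),
    )


@dataclass
class LMMResult:
    """One fitted (mixed) linear model: estimates and fit statistics."""

    params: pd.DataFrame          # estimate, se, t, p per fixed term
    random: str                   # "none" | "site" | "macrochore"
    terms: tuple
    random_sd: float
    resid_sd: float
    llf: float
    k_params: int
    aic: float
    bic: float
    method: str                   # "REML" | "ML"
    n: int
    n_groups: int
    df_resid: int
    converged: bool = True
    singular: bool = False
    fitted: np.ndarray = field(default=None, repr=False)
    resid: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.params.reset_index().to_dict(orient="records"),
            "random": self.random,
            "terms": list(self.terms),
            "random_sd": self.random_sd,
            "resid_sd": self.resid_sd,
            "logLik": self.llf,
            "AIC": self.aic,
            "BIC": self.bic,
            "method": self.method,
            "n": self.n,
            "n_groups": self.n_groups,
            "df_resid": self.df_resid,
            "converged": self.converged,
            "singular": self.singular,
        }

    def report(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            f"Linear mixed-effects model fit by {self.method}",
            f"random intercept: {self.random} (SD {self.random_sd:.2f}), "
            f"residual SD {self.resid_sd:.2f}",
            f"n = {self.n}, groups = {self.n_groups}, df = {self.df_resid}",
            f"AIC = {self.aic:.1f}, BIC = {self.bic:.1f}, logLik = {self.llf:.1f}",
            "",
            f"{'term':<28}{'estimate':>10}{'SE':>8}{'t':>8}{'P':>10}",
        ]
        for name, row in self.params.iterrows():
            lines.append(
                f"{name:<28}{row.estimate:>10.2f}{row.se:>8.2f}"
                f"{row.t:>8.1f}{row.p:>10.4f}"
            )
        return "\n".join(lines)


def _reml_llf_ols(y: np.ndarray, X: np.ndarray) -> float:
    # REML log-likelihood of an iid-error linear model, nlme::gls convention
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    s2 = rss / (n - p)
    _, logdet = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(2 * np.pi * s2) + (n - p) + logdet)


def fit_lmm(
    frame: pd.DataFrame,
    terms=FULL_TERMS,
    random: str = "site",
    reml: bool = True,
) -> LMMResult:
    """Fit the fur-deuterium model with the given fixed terms and random part.

    ``random`` selects no random effect (a GLS-style iid fit), a site random
    intercept, or a macrochore random intercept.  AIC counts all estimated
    parameters (fixed + variance components).
    """
    terms = tuple(terms)
    _check_levels(frame, terms)
    formula = _formula(terms)
    y, X = patsy.dmatrices(formula, frame, return_type="dataframe")
    yv = np.asarray(y).ravel()
    Xv = np.asarray(X)
    n, p = Xv.shape
    method = "REML" if reml else "ML"

    if random == "none":
        ols = sm.OLS(yv, Xv).fit()
        llf = _reml_llf_ols(yv, Xv) if reml else float(ols.llf)
        k = p + 1
        est, se = ols.params, ols.bse
        df_resid = n - p
        tvals = est / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
        resid_sd = float(np.sqrt(ols.ssr / (n - p)))
        random_sd, n_groups = 0.0, 0
        converged, singular = True, False
        fitted = np.asarray(ols.fittedvalues)
    elif random in ("site", "macrochore"):
        group_col = "site_id" if random == "site" else "macrochore"
        if group_col not in frame.columns:
            raise ValueError(f"model frame lacks grouping column '{group_col}'")
        groups = frame[group_col].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # boundary fits (variance ~ 0) are reported via the singular flag
            warnings.filterwarnings(
                "ignore", message="Random effects covariance is singular"
            )
            res = MixedLM(yv, Xv, groups=groups).fit(reml=reml)
        llf = float(res.llf)
        k = p + 2  # fixed + random-intercept variance + residual variance
        est = np.asarray(res.params)[:p]
        se = np.asarray(res.bse)[:p]
        n_groups = len(np.unique(groups))
        # innermost-level denominator df, nlme convention
        df_resid = n - n_groups - (p - 1)
        tvals = est / se
        pvals = 2 * stats.t.sf(np.abs(tvals), max(df_resid, 1))
        random_sd = float(np.sqrt(np.asarray(res.cov_re)[0, 0]))
        resid_sd = float(np.sqrt(res.scale))
        converged = bool(res.converged)
        singular = random_sd < 1e-6 * max(resid_sd, 1e-12)
        if singular:
            warnings.warn(f"singular fit: random '{random}' variance ~ 0")
        fitted = np.asarray(res.fittedvalues)
    else:
        raise ValueError(f"unknown random structure '{random}'")

    params = pd.DataFrame(
        {"estimate": est, "se": se, "t": tvals, "p": pvals}, index=list(X.columns)
    )
    aic = -2 * llf + 2 * k
    bic = -2 * llf + k * np.log(n)
    return LMMResult(
        params=params,
        random=random,
        terms=terms,
        random_sd=random_sd,
        resid_sd=resid_sd,
        llf=llf,
        k_params=k,
        aic=float(aic),
        bic=float(bic),
        method=method,
        n=n,
        n_groups=n_groups,
        df_resid=int(df_resid),
        converged=converged,
        singular=singular,
        fitted=fitted,
        resid=yv - fitted,
    )


@dataclass
class RandomSelection:
    table: pd.DataFrame
    winner: str
    fits: dict


def select_random_structure(
    frame: pd.DataFrame, terms=FULL_TERMS, reml: bool = True
) -> RandomSelection:
    """Pick the random structure by AIC with an identical full fixed part.

    Candidates: no random effect, site random intercept, macrochore random
    intercept, all under REML by default (ML via ``reml=False``).  Exact AIC
    ties break toward the simpler model (candidate order below).
    """
    candidates = ["none", "site", "macrochore"]
    fits = {c: fit_lmm(frame, terms, random=c, reml=reml) for c in candidates}
    table = pd.DataFrame(
        {
            "random": candidates,
            "aic": [fits[c].aic for c in candidates],
            "llf": [fits[c].llf for c in candidates],
            "k": [fits[c].k_params for c in candidates],
            "singular": [fits[c].singular for c in candidates],
        }
    )
    best = min(fits, key=lambda c: (fits[c].aic, candidates.index(c)))
    return RandomSelection(table=table, winner=best, fits=fits)


def _droppable(terms) -> list:
    """Terms removable without violating marginality (interactions first)."""
    terms = list(terms)
    in_interaction = set()
    for t in terms:
        if ":" in t:
            in_interaction.update(t.split(":"))
    return [t for t in terms if ":" in t or t not in in_interaction]


@dataclass
class FixedSelection:
    final_terms: tuple
    steps: pd.DataFrame
    final: LMMResult


def select_fixed_structure(
    frame: pd.DataFrame,
    terms=FULL_TERMS,
    random: str = "site",
    alpha: float = 0.05,
) -> FixedSelection:
    """Backward elimination of fixed terms by likelihood-ratio test under ML.

    At each step every droppable term (marginality respected: the lat x lon
    interaction must leave before its main effects) is removed in turn; the
    term with the largest LRT p-value above alpha is dropped.  The final
    model is refitted under REML.
    """
    current = list(terms)
    steps = []
    while current:
        full = fit_lmm(frame, current, random=random, reml=False)
        best_p, best_term, best_stat, best_df = -np.inf, None, None, None
        for t in _droppable(current):
            reduced = fit_lmm(frame, [u for u in current if u != t], random=random, reml=False)
            stat = 2 * (full.llf - reduced.llf)
            df = full.k_params - reduced.k_params
            p = stats.chi2.sf(max(stat, 0.0), df)
            if p > best_p:
                best_p, best_term, best_stat, best_df = p, t, stat, df
        if best_term is None or best_p <= alpha:
            break
        steps.append(
            {"dropped": best_term, "lrt": best_stat, "df": best_df, "p": best_p}
        )
        current.remove(best_term)
    final = fit_lmm(frame, current, random=random, reml=True)
    return FixedSelection(
        final_terms=tuple(current),
        steps=pd.DataFrame(steps, columns=["dropped", "lrt", "df", "p"]),
        final=final,
    )


def fit_final(frame: pd.DataFrame, terms, random: str = "site") -> LMMResult:
    """Final REML fit of the selected fixed structure."""
    return fit_lmm(frame, terms, random=random, reml=True)


def _lilliefors_d(x: np.ndarray) -> float:
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


def lilliefors_test(
    residuals, n_mc: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Lilliefors-corrected Kolmogorov-Smirnov normality test.

    D is the sup distance between the empirical CDF and the normal CDF with
    mean and SD estimated from the sample; the p-value comes from a seeded
    Monte-Carlo null (standard-normal samples of the same size), which is
    exact up to simulation error and reproducible.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 residuals")
    if x.std(ddof=1) == 0:
        raise ValueError("zero-variance residuals")
    d = _lilliefors_d(x)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, n))
    sims = np.sort(
        (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True),
        axis=1,
    )
    cdf = stats.norm.cdf(sims)
    i = np.arange(1, n + 1)
    d_null = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
    p = (1 + (d_null >= d).sum()) / (n_mc + 1)
    return d, float(p)
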