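"""File formats and pipeline orchestration.

CSV is comma-separated UTF-8 with '.' decimals, dates ISO-8601 and the
sentinel "NA" for unknown age.  Coordinates are decimal degrees (WGS84).
``run_pipeline`` executes classify -> summarize -> covariate model
(optional) -> origin maps and writes a manifest with versions, seeds and
SHA-256 hashes of every input and output, so a rerun with the same config
and seeds reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    RMAModel,
    classify_records,
    composition_percentages,
    fit_rma,
    summarize_by_group,
)
from .config import PipelineConfig
from .mapping import run_stratified
from .mixedmodel import (
    build_model_frame,
    check_collinearity,
    lilliefors_test,
    select_fixed_structure,
    select_random_structure,
)
from .raster import Isoscape
from .synthetic import make_world

__all__ = [
    "read_records",
    "read_sites",
    "read_bearings",
    "read_rma",
    "write_rma",
    "run_pipeline",
]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["id", "d2h_fur", "sex", "age", "date", "site_id"]


def read_records(path) -> pd.DataFrame:
    """Read and validate a carcass record CSV.

    Requires columns id, d2h_fur, sex, age, date, site_id; accepts "NA" age;
    rejects duplicate IDs and reports the row and column of any malformed
    isotope value.  An empty file with headers yields an empty table.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype=str)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file lacks columns: {sorted(missing)}")
    if df.empty:
        out = df.copy()
        out["d2h_fur"] = pd.Series(dtype=float)
        out["date"] = pd.Series(dtype="datetime64[ns]")
        return out[RECORD_COLUMNS]
    fur = pd.to_numeric(df["d2h_fur"], errors="coerce")
    if fur.isna().any():
        row = int(fur.index[fur.isna()][0])
        raise ValueError(
            f"non-numeric isotope value in column 'd2h_fur', row {row}: "
            f"{df['d2h_fur'].iloc[row]!r}"
        )
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate record IDs: {dups}")
    out = df.copy()
    out["d2h_fur"] = fur
    out["date"] = pd.to_datetime(df["date"])
    out["age"] = df["age"].replace({"": "NA"}).fillna("NA")
    return out


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"site_id", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"sites file lacks columns: {sorted(missing)}")
    if df["site_id"].duplicated().any():
        raise ValueError("duplicate site IDs")
    return df


def read_bearings(path) -> np.ndarray:
    """Single-column CSV of bearings in degrees."""
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(dtype=float)


def write_rma(model: RMAModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def read_rma(path) -> RMAModel:
    with open(path) as fh:
        return RMAModel.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full inference chain and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}

    # ---- inputs: read from disk or simulate -----------------------------
    if cfg.records_path:
        records = read_records(cfg.records_path)
        sites = read_sites(cfg.sites_path)
        isoscape = Isoscape.from_ascii(cfg.isoscape_path)
        bearings = read_bearings(cfg.bearings_path)
        for key, p in {
            "records": cfg.records_path,
            "sites": cfg.sites_path,
            "isoscape": cfg.isoscape_path,
            "bearings": cfg.bearings_path,
        }.items():
            inputs[key] = _sha256(p)
        calib = None
        if cfg.calibration_path:
            cal = pd.read_csv(cfg.calibration_path)
            calib = (cal["precip"].to_numpy(float), cal["fur"].to_numpy(float))
            inputs["calibration"] = _sha256(cfg.calibration_path)
    elif cfg.synthetic is not None:
        world = make_world(cfg.synthetic)
        records, sites, isoscape = world.records, world.sites, world.isoscape
        bearings = world.bearings
        calib = (world.calib_precip, world.calib_fur)
        indir = out / "inputs"
        indir.mkdir(exist_ok=True)
        records.to_csv(indir / "records.csv", index=False)
        sites.to_csv(indir / "sites.csv", index=False)
        isoscape.to_ascii(indir / "isoscape.asc")
        pd.DataFrame({"bearing": bearings}).to_csv(indir / "bearings.csv", index=False)
        world.truth.to_csv(indir / "truth.csv", index=False)
        for f in indir.iterdir():
            inputs[f.stem] = _sha256(f)
    else:
        raise ValueError("config supplies neither input paths nor a synthetic world")

    if "precip" not in sites.columns:
        sites = sites.copy()
        sites["precip"] = [
            isoscape.value_at(la, lo) for la, lo in zip(sites["lat"], sites["lon"])
        ]

    # ---- calibration ----------------------------------------------------
    @_stage("calibration")
    def _calibrate():
        if cfg.rma_slope is not None:
            return RMAModel(
                slope=cfg.rma_slope, intercept=cfg.rma_intercept,
                resid_sd=cfg.rma_resid_sd, n=cfg.rma_n,
            )
        if calib is None:
            raise ValueError("no RMA parameters and no calibration pairs")
        return fit_rma(*calib)

    model = _calibrate()
    write_rma(model, out / "rma.yaml")
    outputs["rma"] = _sha256(out / "rma.yaml")

    # ---- classification and summary -------------------------------------
    @_stage("classification")
    def _classify():
        return classify_records(records, sites, model, level=cfg.classification_level)

    classified = _classify()
    classified.to_csv(out / "classified.csv", index=False)
    outputs["classified"] = _sha256(out / "classified.csv")

    summary = summarize_by_group(classified)
    summary.to_csv(out / "summary.csv")
    pcts = composition_percentages(classified)
    pcts["mean_per_site"] = len(classified) / len(sites)
    with open(out / "summary.json", "w") as fh:
        json.dump(pcts, fh, indent=2, default=float)
    outputs["summary"] = _sha256(out / "summary.csv")
    outputs["summary_json"] = _sha256(out / "summary.json")

    # ---- covariate mixed model ------------------------------------------
    lmm_info = None
    if cfg.run_lmm:
        @_stage("covariate-model")
        def _lmm():
            frame = build_model_frame(classified, sites)
            coll = check_collinearity(frame)
            rand = select_random_structure(frame)
            sel = select_fixed_structure(frame, random=rand.winner)
            d, p = lilliefors_test(sel.final.resid, seed=cfg.seed)
            return {
                "collinearity": coll.to_dict(orient="records"),
                "random_structure": rand.winner,
                "random_aic": rand.table.to_dict(orient="records"),
                "dropped": sel.steps.to_dict(orient="records"),
                "final_terms": list(sel.final_terms),
                "final": sel.final.to_dict(),
                "lilliefors_D": d,
                "lilliefors_p": p,
                "report": sel.final.report(),
            }

        lmm_info = _lmm()
        with open(out / "lmm.json", "w") as fh:
            json.dump(lmm_info, fh, indent=2, default=float)
        (out / "lmm.txt").write_text(lmm_info["report"] + "\n")
        outputs["lmm"] = _sha256(out / "lmm.json")

    # ---- origin maps -----------------------------------------------------
    @_stage("origin-maps")
    def _maps():
        return run_stratified(
            classified, sites, model, isoscape, bearings,
            strata=cfg.strata, draws=cfg.draws, seed=cfg.seed,
            gamma_cv=cfg.gamma_cv, per_individual=cfg.per_individual,
        )

    maps = _maps()
    mapdir = out / "maps"
    mapdir.mkdir(exist_ok=True)
    for stratum, roles in maps.items():
        for role, pmap in roles.items():
            p = mapdir / f"{role}_{stratum}.asc"
            pmap.to_ascii(p)
            outputs[f"{role}_{stratum}"] = _sha256(p)

    from . import __version__ as _pkg_version
    manifest = {
        "batscape_version": _pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "classification_level": cfg.classification_level,
        "draws": cfg.draws,
        "inputs_sha256": inputs,
        "outputs_sha256": outputs,
        "summary": pcts,
        "lmm_final_terms": lmm_info["final_terms"] if lmm_info else None,
        "strata_mapped": sorted(maps),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    log.info("pipeline complete: %d outputs in %s", len(outputs), out)
    return manifest
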