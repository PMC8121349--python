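"""End-to-end orchestration: ingest -> fit -> predict -> hotspots -> report.

A single RunConfig drives the whole analysis and every artifact lands in a
run directory with a manifest (config hash, seeds, versions, warnings,
file checksums).  Model fits can be serialised to JSON so the CLI stages
can hand results to each other.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .glmm import (
    DesignInfo,
    FittedModel,
    ModelSpec,
    SplineTerm,
    aic,
    fit,
    sigma_ci,
)
from .hotspots import (
    build_neighbors,
    getis_ord_gi,
    morans_i,
    persistence_score,
    pooled_percentile_flags,
    regional_summary,
)
from .ingest import CoefficientTable, ingest, read_haul_table
from .predict import mask_unsampled, predict_all_months, species_ratio, \
    monthly_regional_means
from .spde import FieldParams, SpdeMesh, build_mesh
from .splines import TprsBasis
from .synthetic import (
    default_truth,
    make_covariates,
    make_domain,
    simulate_survey,
    toy_coefficient_table,
    write_survey_csvs,
)
from .glmm import TweedieParams

logger = logging.getLogger(__name__)

PERCENTILE_NOTE = (
    "Persistence scoring defaults to the 95th-percentile threshold (Methods "
    "convention); the figure-caption convention uses the 90th. Both flag "
    "sets are written; set percentile: 0.90 to switch the persistence basis."
)

_ALLOWED_KEYS = {
    "output_dir", "seed", "hauls_csv", "coefficients_json",
    "ecosections_geojson", "groups", "variants", "n_knots", "cutoff_km",
    "d_km", "percentile", "avoidance_factor", "correct_larvae", "n_hauls",
    "years", "compute_ci", "grid_cell_km",
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    output_dir: str
    seed: int = 0
    hauls_csv: str | None = None
    coefficients_json: str | None = None
    ecosections_geojson: str | None = None
    groups: tuple = ("EP_adult", "TS_adult", "larvae")
    variants: tuple = ("null", "depth", "full")
    n_knots: int = 200
    cutoff_km: float = 10.0
    d_km: float = 10.0
    percentile: float = 0.95
    avoidance_factor: float = 1.0
    correct_larvae: bool = False
    n_hauls: int = 1609
    years: tuple = tuple(range(1993, 2020))
    compute_ci: bool = False
    grid_cell_km: float = 3.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "output_dir" not in d:
            raise ValueError("config requires output_dir")
        d = dict(d)
        if "variants" in d:  # YAML reads a bare `null` as None
            d["variants"] = ["null" if v is None else v for v in d["variants"]]
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()})
        if not (0 < cfg.percentile < 1):
            raise ValueError("percentile must be in (0, 1)")
        if cfg.avoidance_factor <= 0:
            raise ValueError("avoidance_factor must be positive")
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _data_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def compare_models(fits: list, ci: bool = True) -> pd.DataFrame:
    """Model-selection table (df, AIC, dAIC, sigma_eps with 95% CI).

    All fits must be of the same group on the same observations.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    hashes = {_data_hash(f.data[["year", "month", "biomass_mg_m2"]]) for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were made on different data (hash mismatch)")
    rows = []
    for f in fits:
        lo, hi = sigma_ci(f) if ci else (np.nan, np.nan)
        rows.append({
            "group": f.spec.group, "variant": f.spec.variant,
            "df": f.n_params, "AIC": aic(f),
            "sigma_eps": f.field_params.sigma,
            "sigma_lo": lo, "sigma_hi": hi,
            "range_km": f.field_params.range_km, "rho": f.field_params.rho,
            "phi": f.tweedie_params.phi, "p": f.tweedie_params.p,
            "marginal_nll": f.marginal_nll, "converged": f.converged,
        })
    out = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    out["dAIC"] = out["AIC"] - out["AIC"].min()
    return out


# ---------------------------------------------------------------------------
# fitted-model JSON serialisation (CLI stage hand-off)


def _tprs_to_dict(m: TprsBasis) -> dict:
    return {"knots": m.knots.tolist(), "Z": m.Z.tolist(),
            "x_center": m.x_center, "x_scale": m.x_scale,
            "col_means": m.col_means.tolist()}


def _tprs_from_dict(d: dict) -> TprsBasis:
    return TprsBasis(np.array(d["knots"]), np.array(d["Z"]),
                     d["x_center"], d["x_scale"], np.array(d["col_means"]))


def save_fit(fitted: FittedModel, path) -> None:
    d = {
        "spec": {"group": fitted.spec.group, "variant": fitted.spec.variant,
                 "terms": [[t.name, t.k, t.transform] for t in fitted.spec.terms],
                 "month_k": fitted.spec.month_k},
        "info": {
            "year_levels": list(fitted.info.year_levels),
            "month_meta": _tprs_to_dict(fitted.info.month_meta),
            "term_meta": {
                k: [v[0], v[1], v[2], _tprs_to_dict(v[3])]
                for k, v in fitted.info.term_meta.items()
            },
            "columns": list(fitted.info.columns),
        },
        "months": list(fitted.months),
        "beta": fitted.beta.tolist(),
        "u": fitted.u.tolist(),
        "field_params": vars(fitted.field_params),
        "tweedie": {"p": fitted.tweedie_params.p, "phi": fitted.tweedie_params.phi},
        "marginal_nll": fitted.marginal_nll,
        "cov_beta": fitted.cov_beta.tolist(),
        "theta": fitted.theta.tolist(),
        "converged": fitted.converged,
        "mesh": {"nodes": fitted.mesh.nodes.tolist(),
                 "triangles": fitted.mesh.triangles.tolist()},
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def load_fit(path, data: pd.DataFrame | None = None) -> FittedModel:
    from .spde import fem_matrices

    with open(path) as fh:
        d = json.load(fh)
    spec = ModelSpec(
        group=d["spec"]["group"], variant=d["spec"]["variant"],
        terms=tuple(SplineTerm(*t) for t in d["spec"]["terms"]),
        month_k=d["spec"]["month_k"],
    )
    info = DesignInfo(
        year_levels=tuple(d["info"]["year_levels"]),
        month_meta=_tprs_from_dict(d["info"]["month_meta"]),
        term_meta={k: (v[0], v[1], v[2], _tprs_from_dict(v[3]))
                   for k, v in d["info"]["term_meta"].items()},
        terms=spec.terms,
        columns=tuple(d["info"]["columns"]),
    )
    mesh = SpdeMesh(np.array(d["mesh"]["nodes"]),
                    np.array(d["mesh"]["triangles"], dtype=int))
    mesh.C, mesh.G = fem_matrices(mesh)
    return FittedModel(
        spec=spec, info=info, mesh=mesh, months=tuple(d["months"]),
        beta=np.array(d["beta"]), u=np.array(d["u"]),
        field_params=FieldParams(**d["field_params"]),
        tweedie_params=TweedieParams(**d["tweedie"]),
        marginal_nll=d["marginal_nll"], cov_beta=np.array(d["cov_beta"]),
        theta=np.array(d["theta"]), data=data, converged=d["converged"],
    )


# ---------------------------------------------------------------------------
# the pipeline


def _attach_covariates(obs: pd.DataFrame, grid) -> pd.DataFrame:
    from .synthetic import _covariates_at

    cov = _covariates_at(grid, obs["x_km"].to_numpy(), obs["y_km"].to_numpy(),
                         obs["month"].to_numpy())
    out = obs.reset_index(drop=True).copy()
    for c in cov.columns:
        out[c] = cov[c].to_numpy()
    return out


def _group_table(obs: pd.DataFrame, group: str, grid) -> pd.DataFrame:
    wide = obs.pivot_table(index="haul_id", columns="group",
                           values="biomass_mg_m2").reset_index()
    meta = obs.drop_duplicates("haul_id")[
        ["haul_id", "x_km", "y_km", "year", "month"]
    ]
    tbl = meta.merge(wide, on="haul_id")
    tbl["biomass_mg_m2"] = tbl[group]
    tbl = tbl.rename(columns={"EP_adult": "ep_adult", "TS_adult": "ts_adult"})
    return _attach_covariates(tbl, grid)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage for each configured group; returns the run dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_warnings = [PERCENTILE_NOTE]
    if config.avoidance_factor == 1.0:
        run_warnings.append(
            "avoidance_factor is 1.0: no daylight net-avoidance correction "
            "was applied (supply a gear-specific factor)."
        )

    grid = make_covariates(make_domain(cell_km=config.grid_cell_km),
                           seed=config.seed)

    # --- stage: data (simulate or read) ---
    datadir = out / "data"
    datadir.mkdir(exist_ok=True)
    if config.hauls_csv is None:
        truth = default_truth(seed=config.seed)
        truth.n_hauls = config.n_hauls
        truth.years = tuple(config.years)
        truth.avoidance_factor = config.avoidance_factor
        raw, truth_df, extras = simulate_survey(truth, grid=grid)
        write_survey_csvs(datadir, raw, truth_df, grid, truth)
        coeffs = toy_coefficient_table()
    else:
        raw = read_haul_table(config.hauls_csv)
        coeffs = (CoefficientTable.from_json(config.coefficients_json)
                  if config.coefficients_json else toy_coefficient_table())

    polygons = grid.polygons
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs, excl = ingest(raw, coeffs, config.avoidance_factor,
                           config.correct_larvae, polygons=polygons)
    obs["bioregion"] = np.where(
        obs["y_km"] >= grid.height_km / 2.0, "north", "south")
    obs.to_csv(datadir / "observations.csv", index=False)
    excl.to_csv(datadir / "exclusions.csv", index=False)

    # --- stage: mesh + fits ---
    locs = obs.drop_duplicates("haul_id")[["x_km", "y_km"]].to_numpy()
    mesh = build_mesh(locs, n_knots=config.n_knots,
                      cutoff_km=config.cutoff_km, seed=config.seed)
    fitdir = out / "fits"
    fitdir.mkdir(exist_ok=True)
    fits: dict = {}
    reports = []
    # adults first: larval full model uses observed adult biomass covariates
    order = [g for g in ("EP_adult", "TS_adult", "larvae") if g in config.groups]
    for group in order:
        tbl = _group_table(obs, group, grid)
        group_fits = []
        for variant in config.variants:
            spec = ModelSpec.for_group(group, variant)
            logger.info("fitting %s / %s", group, variant)
            f = fit(tbl, spec, mesh, seed=config.seed)
            save_fit(f, fitdir / f"{group}_{variant}.json")
            group_fits.append(f)
            fits[(group, variant)] = f
        if len(group_fits) >= 2:
            reports.append(compare_models(group_fits, ci=config.compute_ci))
    if reports:
        pd.concat(reports, ignore_index=True).to_csv(
            fitdir / "fit_report.csv", index=False)

    # --- stage: prediction ---
    best = {g: fits.get((g, "full")) or list(
        f for (gg, _), f in fits.items() if gg == g)[-1] for g in order}
    preddir = out / "predictions"
    preddir.mkdir(exist_ok=True)
    grid = mask_unsampled(grid, obs[obs["group"] == order[0]])
    surfaces, extrapolations = {}, []
    for group in order:
        if group == "larvae" and best[group].spec.variant == "full":
            _attach_adult_predictions(grid, best, surfaces)
        pred, extrap = predict_all_months(best[group], grid,
                                          collect_extrapolation=True)
        pred["group"] = group
        surfaces[group] = pred
        extrap["group"] = group
        extrapolations.append(extrap)
    pd.concat(surfaces.values(), ignore_index=True).to_csv(
        preddir / "surfaces.csv", index=False)
    pd.concat(extrapolations, ignore_index=True).to_csv(
        preddir / "extrapolation.csv", index=False)
    if {"EP_adult", "TS_adult"} <= set(order):
        species_ratio(surfaces["EP_adult"], surfaces["TS_adult"]).to_csv(
            preddir / "ratio.csv", index=False)
    pd.concat(
        [monthly_regional_means(surfaces[g], grid).assign(group=g)
         for g in order],
        ignore_index=True,
    ).to_csv(preddir / "regional_means.csv", index=False)

    # --- stage: hotspots ---
    hotdir = out / "hotspots"
    hotdir.mkdir(exist_ok=True)
    hot_groups = dict(surfaces)
    if {"EP_adult", "TS_adult"} <= set(order):
        total = (
            pd.concat([surfaces["EP_adult"], surfaces["TS_adult"]])
            .groupby(["cell_id", "month"], as_index=False)["biomass_mg_m2"]
            .sum()
        )
        total["group"] = "total_adults"
        hot_groups["total_adults"] = total
    all_z, all_flags, all_pers, all_summ, thresholds = [], [], [], [], {}
    coords = grid.cells[["x_km", "y_km"]].to_numpy()
    W_full = build_neighbors(coords, d_km=config.d_km)
    moran = {}
    for gname, pred in hot_groups.items():
        zrows = []
        for month in grid.months:
            sub = pred[pred["month"] == month]
            idx = sub["cell_id"].to_numpy()
            W = W_full[idx][:, idx]
            z = getis_ord_gi(sub["biomass_mg_m2"].to_numpy(), W)
            zrows.append(pd.DataFrame(
                {"cell_id": idx, "month": month, "z": z}))
            if month == grid.months[0]:
                moran[gname] = morans_i(sub["biomass_mg_m2"].to_numpy(), W)["z"]
        zdf = pd.concat(zrows, ignore_index=True)
        f90, t90 = pooled_percentile_flags(zdf, 0.90)
        f95, t95 = pooled_percentile_flags(zdf, 0.95)
        thresholds[gname] = {"q90": t90, "q95": t95}
        fsel = f95 if config.percentile >= 0.95 else f90
        pers = persistence_score(fsel)
        summ = regional_summary(zdf, fsel, pers, grid.cells)
        for df_, name in ((zdf, all_z), (pers, all_pers)):
            df_ = df_.copy()
            df_["group"] = gname
            name.append(df_)
        fboth = f90.rename(columns={"flag": "flag90"})
        fboth["flag95"] = f95["flag"].to_numpy()
        fboth["group"] = gname
        all_flags.append(fboth)
        summ["group"] = gname
        all_summ.append(summ)
    pd.concat(all_z, ignore_index=True).to_csv(hotdir / "z_scores.csv", index=False)
    pd.concat(all_flags, ignore_index=True).to_csv(hotdir / "flags.csv", index=False)
    pd.concat(all_pers, ignore_index=True).to_csv(
        hotdir / "persistence.csv", index=False)
    pd.concat(all_summ, ignore_index=True).to_csv(
        hotdir / "regional_summary.csv", index=False)
    with open(hotdir / "thresholds.json", "w") as fh:
        json.dump({"d_km": config.d_km, "percentile": config.percentile,
                   "thresholds": thresholds, "morans_z_april": moran}, fh,
                  indent=1)

    _write_manifest(out, config, run_warnings)
    return out


def _attach_adult_predictions(grid, best, surfaces):
    """Substitute predicted adult surfaces for the larval model's
    adult-biomass covariates at grid-prediction time."""
    for g, col in (("EP_adult", "ep_adult"), ("TS_adult", "ts_adult")):
        pred = surfaces.get(g)
        if pred is None:
            continue
        for m in grid.months:
            sub = pred[pred["month"] == m].set_index("cell_id")["biomass_mg_m2"]
            vals = sub.reindex(grid.cells["cell_id"]).fillna(0.0).to_numpy()
            grid.covariates[m][col] = vals


def _write_manifest(out: Path, config: RunConfig, run_warnings: list) -> None:
    files = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()[:16]
    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "warnings": run_warnings,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=list)
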