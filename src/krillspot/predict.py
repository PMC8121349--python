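"""Grid prediction: monthly biomass surfaces, masking, ratios, regional means.

Predictions on a 3-km grid use all fixed and random effects for each month:
mu = exp(X beta + A_grid u_month), with the year factor at its average
effect (monthly surfaces pool years).  Strata (bioregion x month) without
any survey observations are masked; masked cells never enter downstream
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import FittedModel, design_matrix
from .spde import projector


@dataclass
class PredictionGrid:
    """Regular prediction grid with per-month covariates and validity masks.

    ``cells``: DataFrame with cell_id, x_km, y_km, area_km2, ecosection,
    bioregion.  ``covariates``: month -> DataFrame (aligned with cells) of
    covariate columns.  ``valid``: month -> boolean array.
    """

    cells: pd.DataFrame
    covariates: dict
    valid: dict = field(default_factory=dict)
    polygons: list = field(default_factory=list)

    def __post_init__(self):
        for m in self.covariates:
            if m not in self.valid:
                self.valid[m] = np.ones(len(self.cells), dtype=bool)

    @property
    def months(self):
        return sorted(self.covariates)

    def frame(self, month: int) -> pd.DataFrame:
        cov = self.covariates[month]
        out = pd.concat(
            [self.cells[["cell_id", "x_km", "y_km"]].reset_index(drop=True),
             cov.reset_index(drop=True)], axis=1)
        out["month"] = month
        return out


def predict_grid(
    fitted: FittedModel, grid: PredictionGrid, month: int
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted mg/m^2 for one month (NaN at masked cells).

    Also returns the indices of valid cells whose covariates fall outside
    the training range (predictions kept, flagged as extrapolation).
    """
    if month not in grid.covariates:
        raise ValueError(f"month {month} not on the prediction grid")
    frame = grid.frame(month)
    X = design_matrix(fitted.info, frame, year_mode="mean")
    A = projector(fitted.mesh, frame[["x_km", "y_km"]].to_numpy())
    t = fitted.months.index(month)
    eta = X @ fitted.beta + A @ fitted.u[t]
    pred = np.exp(eta)
    mask = grid.valid[month]
    pred = np.where(mask, pred, np.nan)

    extrap = np.zeros(len(frame), dtype=bool)
    from .glmm import _transform

    for term in fitted.info.terms:
        transform, mean, sd, meta = fitted.info.term_meta[term.name]
        zs = (_transform(frame[term.name].to_numpy(), transform) - mean) / sd
        lo, hi = meta.knots.min(), meta.knots.max()
        extrap |= (zs < lo) | (zs > hi)
    return pred, np.where(extrap & mask)[0]


def predict_all_months(
    fitted: FittedModel, grid: PredictionGrid, collect_extrapolation: bool = False
):
    """Long table (cell_id, month, biomass_mg_m2) over valid cells only.

    With ``collect_extrapolation`` also returns a (cell_id, month) table of
    valid cells whose covariates fall outside the training range."""
    rows, flagged = [], []
    for month in grid.months:
        pred, extrap = predict_grid(fitted, grid, month)
        df = pd.DataFrame({
            "cell_id": grid.cells["cell_id"].to_numpy(),
            "month": month,
            "biomass_mg_m2": pred,
        })
        rows.append(df[np.isfinite(df["biomass_mg_m2"])])
        if len(extrap):
            flagged.append(pd.DataFrame({
                "cell_id": grid.cells["cell_id"].to_numpy()[extrap],
                "month": month,
            }))
    out = pd.concat(rows, ignore_index=True)
    if not collect_extrapolation:
        return out
    ex = (pd.concat(flagged, ignore_index=True) if flagged
          else pd.DataFrame(columns=["cell_id", "month"]))
    return out, ex


def mask_unsampled(grid: PredictionGrid, data: pd.DataFrame,
                   region_col: str = "bioregion") -> PredictionGrid:
    """Mask (region, month) strata that have no survey observations.

    Idempotent; masking only ever shrinks the valid set.  ``data`` needs
    ``month`` and a region label column (assign one from the grid polygons
    upstream if absent).
    """
    if region_col not in data.columns:
        raise ValueError(f"data lacks region column {region_col!r}")
    sampled = set(zip(data[region_col], data["month"].astype(int)))
    regions = grid.cells[region_col].to_numpy()
    for month in grid.months:
        empty = np.array([(r, month) not in sampled for r in regions])
        grid.valid[month] = grid.valid[month] & ~empty
    return grid


def species_ratio(pred_ep: pd.DataFrame, pred_ts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell E. pacifica : T. spinifera ratio with log10, by month.

    Cells where the T. spinifera prediction is exactly zero are dropped
    (count recorded in ``attrs['n_zero_denominator']``).
    """
    m = pred_ep.merge(pred_ts, on=["cell_id", "month"], suffixes=("_ep", "_ts"))
    zero = m["biomass_mg_m2_ts"] == 0
    out = m.loc[~zero].copy()
    out["ratio"] = out["biomass_mg_m2_ep"] / out["biomass_mg_m2_ts"]
    out["log10_ratio"] = np.log10(out["ratio"])
    out = out[["cell_id", "month", "ratio", "log10_ratio"]]
    out.attrs["n_zero_denominator"] = int(zero.sum())
    return out


def season_average(pred: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean over the valid (unmasked) months."""
    return (
        pred.groupby("cell_id", as_index=False)["biomass_mg_m2"]
        .mean()
        .rename(columns={"biomass_mg_m2": "season_mean_mg_m2"})
    )


def monthly_regional_means(pred: pd.DataFrame, grid: PredictionGrid,
                           region_col: str = "ecosection") -> pd.DataFrame:
    """Unweighted mean predicted biomass per (region, month), with counts.

    Masked cells are absent from ``pred`` so they never contribute; empty
    region-months are simply missing rows (not zeros).
    """
    merged = pred.merge(grid.cells[["cell_id", region_col]], on="cell_id")
    out = (
        merged.groupby([region_col, "month"])["biomass_mg_m2"]
        .agg(mean_mg_m2="mean", n_cells="size")
        .reset_index()
    )
    return out
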