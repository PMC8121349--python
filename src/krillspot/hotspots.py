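"""Getis-Ord hotspot detection, percentile flags, persistence and summaries.

Per month and group, each grid cell gets a Getis-Ord Gi Z-score measuring
local clustering of predicted biomass within a distance band (default
10 km) relative to the background mean and SD.  Thresholds are percentiles
(90th/95th) of the Z-scores pooled across the six months, so seasonal peaks
remain comparable; a cell's persistence score counts the months (0-6) it
exceeds the threshold, and a score of 6 marks a persistent hotspot.
Moran's I is available as the diagnostic used to choose the band distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

CELL_AREA_KM2 = 3.0


def build_neighbors(coords: np.ndarray, d_km: float = 10.0,
                    include_self: bool = False) -> sp.csr_matrix:
    """Symmetric binary distance-band weights on cell centroids.

    w_ij = 1 iff 0 < dist(i, j) <= d (and i = j when ``include_self``).
    """
    if d_km <= 0:
        raise ValueError("d_km must be positive")
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, float)
    tree = cKDTree(coords)
    W = tree.sparse_distance_matrix(tree, max_distance=d_km, output_type="coo_matrix")
    keep = W.row != W.col
    W = sp.csr_matrix(
        (np.ones(keep.sum()), (W.row[keep], W.col[keep])),
        shape=(len(coords), len(coords)),
    )
    if include_self:
        W = W + sp.eye(len(coords), format="csr")
    n_isolated = int(np.sum(np.asarray(W.sum(axis=1)).ravel() == 0))
    W.isolated_count = n_isolated  # attached diagnostic
    return W


def morans_i(values: np.ndarray, W: sp.spmatrix) -> dict:
    """Global Moran's I with expectation and variance under normality."""
    x = np.asarray(values, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 cells")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0:
        raise ValueError("zero variance: Moran's I undefined on a constant field")
    S0 = float(W.sum())
    if S0 == 0:
        raise ValueError("weight matrix has zero sum")
    num = float(z @ (W @ z))
    I = (n / S0) * num / den
    EI = -1.0 / (n - 1)
    Wd = W.toarray() if sp.issparse(W) else np.asarray(W, float)
    S1 = 0.5 * float(((Wd + Wd.T) ** 2).sum())
    S2 = float(((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2).sum())
    var = (n**2 * S1 - n * S2 + 3 * S0**2) / ((n**2 - 1) * S0**2) - EI**2
    return {"I": I, "E_I": EI, "Var_I": var, "z": (I - EI) / np.sqrt(var)}


def getis_ord_gi(values: np.ndarray, W: sp.spmatrix, star: bool = False) -> np.ndarray:
    """Standardized Getis-Ord statistic per cell.

    Default is Gi (self excluded): background mean/SD taken over all cells
    except i.  ``star=True`` gives Gi* (self included, global mean/SD).
    Constant fields have no defined Z; returns all-NaN with a warning.
    """
    x = np.asarray(values, float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 cells")
    if np.ptp(x) == 0:
        warnings.warn("constant field: Gi undefined, returning NaN", stacklevel=2)
        return np.full(n, np.nan)
    Wx = np.asarray(W @ x).ravel()
    Wi = np.asarray(W.sum(axis=1)).ravel()
    W2 = W.multiply(W) if sp.issparse(W) else W * W
    S1i = np.asarray(W2.sum(axis=1)).ravel()
    if star:
        xbar = x.mean()
        s = x.std()
        denom = s * np.sqrt(np.clip((n * S1i - Wi**2) / (n - 1), 0, None))
    else:
        if n < 3:
            raise ValueError("Gi (self excluded) needs at least 3 cells")
        tot, tot2 = x.sum(), (x**2).sum()
        xbar = (tot - x) / (n - 1)
        s2 = np.clip((tot2 - x**2) / (n - 1) - xbar**2, 0, None)
        s = np.sqrt(s2)
        denom = s * np.sqrt(np.clip(((n - 1) * S1i - Wi**2) / (n - 2), 0, None))
    num = Wx - xbar * Wi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / denom
    z[denom == 0] = np.nan
    return z


def pooled_percentile_flags(z: pd.DataFrame, q: float) -> tuple[pd.DataFrame, float]:
    """Flag cell-months whose Z reaches the pooled q-quantile.

    ``z`` is long format (cell_id, month, z).  One threshold per group:
    the q-quantile (linear interpolation) of all valid cell-month Z-scores
    pooled across months; ties at the threshold are flagged inclusively
    (flag = Z >= threshold).
    """
    vals = z["z"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        out = z.copy()
        out["flag"] = False
        return out, np.nan
    thr = float(np.quantile(vals, q))
    out = z.copy()
    out["flag"] = np.isfinite(z["z"]) & (z["z"] >= thr)
    return out, thr


def persistence_score(flags: pd.DataFrame, n_months: int = 6) -> pd.DataFrame:
    """Months flagged per cell (0..n_months); masked months count as
    not flagged, and cells missing any month are annotated."""
    g = flags.groupby("cell_id")
    out = g.agg(persistence=("flag", "sum"), n_valid_months=("flag", "size"))
    out = out.reset_index()
    out["persistence"] = out["persistence"].astype(int)
    out["any_masked_month"] = out["n_valid_months"] < n_months
    return out


def regional_summary(
    z: pd.DataFrame,
    flags: pd.DataFrame,
    persistence: pd.DataFrame,
    cells: pd.DataFrame,
    region_col: str = "ecosection",
    n_months: int = 6,
    cell_area_km2: float = CELL_AREA_KM2,
) -> pd.DataFrame:
    """Per-ecosection hotspot area/intensity table plus a coast-wide row.

    total area = cell_area x cells flagged in >= 1 month; persistent area =
    cell_area x cells flagged in all months; peak month/Z from the monthly
    Z-scores; ``peak_area_month`` is the month with the largest flagged area.
    """
    lab = cells[["cell_id", region_col]]
    fl = flags.merge(lab, on="cell_id")
    pers = persistence.merge(lab, on="cell_id")
    zz = z.merge(lab, on="cell_id")

    def summarize(name, f, p, zv):
        hot_cells = f.loc[f["flag"], "cell_id"].nunique()
        persist_cells = int((p["persistence"] >= n_months).sum())
        if np.isfinite(zv["z"]).any():
            peak = zv.loc[zv["z"].idxmax()]
            peak_month, peak_z = int(peak["month"]), float(peak["z"])
        else:
            peak_month, peak_z = None, np.nan
        area_by_month = f.loc[f["flag"]].groupby("month").size()
        peak_area_month = (
            int(area_by_month.idxmax()) if len(area_by_month) else None
        )
        return {
            "region": name,
            "total_area_km2": hot_cells * cell_area_km2,
            "persistent_area_km2": persist_cells * cell_area_km2,
            "peak_month": peak_month,
            "peak_z": peak_z,
            "peak_area_month": peak_area_month,
        }

    rows = []
    for name, grp in fl.groupby(region_col):
        rows.append(summarize(
            name, grp,
            pers[pers[region_col] == name],
            zz[zz[region_col] == name],
        ))
    rows.append(summarize("coastwide", fl, pers, zz))
    return pd.DataFrame(rows)
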