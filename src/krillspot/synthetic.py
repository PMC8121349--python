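"""Synthetic survey generator with known ground truth.

Emulates a multi-decade (1993–2019), April–September coastal zooplankton
survey on a rectangular shelf/slope domain: smooth bathymetry-derived
covariate surfaces, three euphausiid response groups whose biomass follows
the same spatiotemporal Tweedie GLMM the package fits (monthly Matérn GMRF
fields with AR1 correlation, spline-shaped covariate effects, year effects),
and raw net-haul tables decomposed from the simulated biomass so the whole
ingest chain is exercised.  Every dataset carries its SimulationTruth and is
bit-identical under the same seed.

The defaults are the survey conditions the analysis assumes: ~1,609
rule-conforming hauls, spatially uneven effort with no April sampling in
the northern bioregion, zero-inflated continuous biomass (point mass from
the compound Poisson–gamma law), and a configurable fraction of planted
depth-disparity violations to exercise the filters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .glmm import MONTHS
from .ingest import CoefficientTable
from .predict import PredictionGrid
from .spde import FieldParams, build_mesh, precision_from_params, sample_gmrf
from .tweedie import tweedie_rvs

# documented toy dry-weight coefficients (mg per individual); arbitrary but
# fixed — they only need to round-trip through the ingest chain
TOY_COEFFICIENTS = {
    ("E_pacifica", "S4", "female"): 6.0,
    ("E_pacifica", "S4", "male"): 4.5,
    ("T_spinifera", "S4", "female"): 9.0,
    ("T_spinifera", "S4", "male"): 7.0,
    ("E_pacifica", "eggs", None): 0.01,
    ("E_pacifica", "s1", None): 0.05,
    ("E_pacifica", "s2", None): 0.4,
}

# configured chlorophyll seasonal curve (mg/m^3 monthly spatial mean):
# spring bloom peak in May, summer decline
CHL_SEASONAL = {4: 1.8, 5: 2.6, 6: 2.0, 7: 1.3, 8: 1.0, 9: 0.9}

GROUPS = ("EP_adult", "TS_adult", "larvae")


def make_domain(width_km: float = 300.0, height_km: float = 198.0,
                cell_km: float = 3.0, seed: int = 0) -> PredictionGrid:
    """Rectangular prediction grid partitioned into toy ecosections.

    The coast is the x = 0 edge; a shelf, a slope band (split into north
    and south bioregions at mid-height) and an offshore band give five
    labelled polygons.  Deterministic (the seed is accepted for interface
    symmetry but the geometry is fixed by the dimensions).
    """
    if width_km <= 0 or height_km <= 0 or cell_km <= 0:
        raise ValueError("dimensions must be positive")
    nx = int(round(width_km / cell_km))
    ny = int(round(height_km / cell_km))
    if abs(nx * cell_km - width_km) > 1e-9 or abs(ny * cell_km - height_km) > 1e-9:
        raise ValueError("width and height must be multiples of cell_km")
    xs = (np.arange(nx) + 0.5) * cell_km
    ys = (np.arange(ny) + 0.5) * cell_km
    xx, yy = np.meshgrid(xs, ys)
    y_split = height_km / 2.0
    x_shelf, x_slope = width_km * 0.5, width_km * 0.766
    polygons = [
        ("north_shelf", box(0, y_split, x_shelf, height_km)),
        ("south_shelf", box(0, 0, x_shelf, y_split)),
        ("slope_north", box(x_shelf, y_split, x_slope, height_km)),
        ("slope_south", box(x_shelf, 0, x_slope, y_split)),
        ("offshore", box(x_slope, 0, width_km, height_km)),
    ]
    x, y = xx.ravel(), yy.ravel()
    eco = np.full(x.shape, "offshore", dtype=object)
    eco[(x < x_shelf) & (y >= y_split)] = "north_shelf"
    eco[(x < x_shelf) & (y < y_split)] = "south_shelf"
    eco[(x >= x_shelf) & (x < x_slope) & (y >= y_split)] = "slope_north"
    eco[(x >= x_shelf) & (x < x_slope) & (y < y_split)] = "slope_south"
    cells = pd.DataFrame({
        "cell_id": np.arange(x.size),
        "x_km": x, "y_km": y,
        "area_km2": 3.0,
        "ecosection": eco,
        "bioregion": np.where(y >= y_split, "north", "south"),
    })
    grid = PredictionGrid(cells=cells, covariates={}, polygons=polygons)
    grid.width_km, grid.height_km, grid.cell_km = width_km, height_km, cell_km
    return grid


def _depth_field(x, y, height_km):
    from scipy.special import expit

    center = 0.633 * 300.0 + 10.0 * np.sin(2 * np.pi * y / height_km)
    return 20.0 + 1480.0 * expit((x - center) / 25.0)


def make_covariates(grid: PredictionGrid, seed: int = 0) -> PredictionGrid:
    """Attach per-month covariate surfaces to the grid.

    Depth is a smooth shelf-to-slope sigmoid (20–1500 m) with a sinuous
    shelf break; slope its finite-difference gradient magnitude; distance
    to coast is distance to the x = 0 edge and distance to the 1000 m
    isobar is computed from the depth surface.  SST warms through the
    season and southwards; chlorophyll has a May bloom whose monthly
    spatial means follow CHL_SEASONAL exactly, enriched towards the coast.
    """
    x = grid.cells["x_km"].to_numpy()
    y = grid.cells["y_km"].to_numpy()
    H = grid.height_km
    depth = _depth_field(x, y, H)
    h = 1.0
    dz_dx = (_depth_field(x + h, y, H) - _depth_field(x - h, y, H)) / (2 * h)
    dz_dy = (_depth_field(x, y + h, H) - _depth_field(x, y - h, H)) / (2 * h)
    slope = np.hypot(dz_dx, dz_dy)
    dist_coast = x.copy()
    # 1000 m isobar x-position per cell row (from the depth model itself)
    from scipy.special import logit as _logit

    center = 0.633 * 300.0 + 10.0 * np.sin(2 * np.pi * y / H)
    x1000 = center + 25.0 * _logit((1000.0 - 20.0) / 1480.0)
    dist_1000m = np.abs(x - x1000)
    for m in MONTHS:
        frac = (m - 4) / 5.0
        # seasonal warming plus a month-shifting mesoscale anomaly: SST
        # patterns are not separable into (month) + (static space)
        sst = (
            8.0 + 6.0 * frac * (1.0 - 0.5 * y / H) - 1.5 * y / H
            + 2.0 * np.sin(2 * np.pi * (x + 12.0 * (m - 4)) / 110.0)
            * np.sin(2 * np.pi * y / 95.0)
        )
        # coastal enrichment with a drifting bloom patch; normalised so the
        # monthly spatial mean equals CHL_SEASONAL exactly
        mult = np.exp(-x / 60.0) * (
            1.0 + 0.6 * np.sin(2 * np.pi * (y + 15.0 * (m - 4)) / 140.0)
        )
        chl = CHL_SEASONAL[m] * mult / mult.mean()
        grid.covariates[m] = pd.DataFrame({
            "depth": depth, "slope": slope,
            "dist_coast": dist_coast, "dist_1000m": dist_1000m,
            "sst": sst, "chl": np.clip(chl, 1e-3, None),
        })
        grid.valid[m] = np.ones(len(grid.cells), dtype=bool)
    return grid


@dataclass
class SimulationTruth:
    """Ground-truth parameters serialised with every generated dataset."""

    field_params: dict        # group -> FieldParams
    tweedie: dict             # group -> (p, phi)
    beta0: dict               # group -> intercept
    month_amp: dict           # group -> (amplitude, peak month)
    covariate_effects: dict   # group -> {name: (linear, quadratic)}
    larval_coupling: tuple = (0.15, 0.5)   # (on EP, on TS) log1p adult mu
    year_sd: float = 0.25
    avoidance_factor: float = 1.0
    seed: int = 0
    n_hauls: int = 1609
    years: tuple = tuple(range(1993, 2020))
    sim_knots: int = 120
    violator_fraction: float = 0.03
    off_season_fraction: float = 0.02
    night_fraction: float = 0.02

    def to_json(self, path):
        d = asdict(self)
        d["field_params"] = {g: vars(fp) for g, fp in self.field_params.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=list)


def default_truth(seed: int = 0, **overrides) -> SimulationTruth:
    """The generator's default study conditions.

    Adult biomass on the mg/m^2 scale with strong zero inflation (p = 1.6,
    phi = 15 gives ~40% empty hauls at mu ~ e^4); field range 40 km,
    sigma 1, AR1 rho 0.6; quadratic depth preference, positive chlorophyll
    and slope effects; T. spinifera peaks in August, E. pacifica in
    September, larvae in June; larval biomass couples more strongly to the
    T. spinifera field than the E. pacifica field.
    """
    truth = SimulationTruth(
        field_params={
            "EP_adult": FieldParams(40.0, 1.0, 0.6),
            "TS_adult": FieldParams(40.0, 1.0, 0.6),
            "larvae": FieldParams(35.0, 0.8, 0.5),
        },
        tweedie={
            "EP_adult": (1.6, 15.0),
            "TS_adult": (1.6, 15.0),
            "larvae": (1.6, 8.0),
        },
        beta0={"EP_adult": 4.0, "TS_adult": 4.2, "larvae": 1.5},
        month_amp={"EP_adult": (0.8, 9), "TS_adult": (1.0, 8), "larvae": (0.7, 6)},
        covariate_effects={
            "EP_adult": {"depth": (0.2, -0.8), "slope": (0.3, 0.0),
                         "chl": (0.3, 0.0), "dist_1000m": (-0.3, 0.0)},
            "TS_adult": {"depth": (0.0, -0.6), "dist_coast": (-0.3, -0.1),
                         "sst": (0.2, -0.1), "chl": (0.25, 0.0)},
            "larvae": {"depth": (0.1, -0.4), "sst": (0.3, 0.0),
                       "chl": (0.35, 0.0)},
        },
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(truth, k, v)
    return truth


def _month_curve(month, amp, peak):
    return amp * np.cos((np.asarray(month, float) - peak) * np.pi / 6.0)


def _simulate_ar1_fields(Q_space, rho, n_time, rng):
    """Monthly fields u_t with stationary AR1 dynamics, N(0, Q^-1) marginals."""
    n = Q_space.shape[0]
    eps = sample_gmrf(Q_space, n_draws=n_time, rng=rng)
    u = np.empty((n_time, n))
    u[0] = eps[0]
    for t in range(1, n_time):
        u[t] = rho * u[t - 1] + np.sqrt(1.0 - rho**2) * eps[t]
    return u


def _effort_locations(rng, n, grid, months_weights, april_south_only=True):
    """Spatially uneven, month-varying haul placement (shelf-heavy effort)."""
    W, H = grid.width_km, grid.height_km
    months = np.array(MONTHS)
    m = rng.choice(months, size=n, p=months_weights)
    # effort mixture: mostly shelf, some slope, little offshore
    band = rng.choice(3, size=n, p=[0.6, 0.3, 0.1])
    x_lo = np.array([2.0, 0.5 * W, 0.766 * W])[band]
    x_hi = np.array([0.5 * W, 0.766 * W, W - 2.0])[band]
    x = rng.uniform(x_lo, x_hi)
    y = rng.uniform(2.0, H - 2.0, size=n)
    if april_south_only:
        april = m == 4
        y[april] = rng.uniform(2.0, H / 2.0 - 1.0, size=int(april.sum()))
    return x, y, m


def _covariates_at(grid: PredictionGrid, x, y, month):
    """Nearest-grid-cell covariate lookup, vectorised per month."""
    cell = grid.cell_km
    nx = int(round(grid.width_km / cell))
    ix = np.clip((x / cell).astype(int), 0, nx - 1)
    iy = np.clip((y / cell).astype(int), 0, int(round(grid.height_km / cell)) - 1)
    idx = iy * nx + ix
    out = pd.DataFrame(index=np.arange(len(x)))
    for mm in np.unique(month):
        sel = month == mm
        cov = grid.covariates[int(mm)].iloc[idx[sel]].reset_index(drop=True)
        for c in cov.columns:
            out.loc[sel, c] = cov[c].to_numpy()
    return out


def _standardized(cov: pd.DataFrame, grid: PredictionGrid):
    """Z-scores against the pooled grid distribution (the truth's scale)."""
    pooled = pd.concat([grid.covariates[m] for m in MONTHS], ignore_index=True)
    z = pd.DataFrame(index=cov.index)
    for c in cov.columns:
        v = cov[c].to_numpy(dtype=float)
        ref = pooled[c].to_numpy(dtype=float)
        if c in ("depth", "chl"):
            v, ref = np.log(v), np.log(ref)
        z[c] = (v - ref.mean()) / ref.std()
    return z


def simulate_survey(
    truth: SimulationTruth | None = None,
    n_hauls: int | None = None,
    years: tuple | None = None,
    seed: int | None = None,
    grid: PredictionGrid | None = None,
):
    """Generate a raw haul table plus per-haul ground truth.

    Returns ``(raw, truth_df, extras)``: ``raw`` is the long-format haul
    CSV table the ingest module reads; ``truth_df`` holds each haul's true
    group biomasses and planted-violation flags; ``extras`` carries the
    simulation grid, mesh and realized fields.  Planted depth-disparity
    violators, night hauls and off-season hauls are appended beyond the
    ``n_hauls`` rule-conforming hauls so the filters have work to do.
    """
    truth = truth or default_truth()
    n_hauls = n_hauls if n_hauls is not None else truth.n_hauls
    years = tuple(years) if years is not None else tuple(truth.years)
    seed = seed if seed is not None else truth.seed
    rng = np.random.default_rng(seed)

    if grid is None:
        grid = make_covariates(make_domain(), seed=seed)

    month_weights = np.array([0.06, 0.16, 0.22, 0.22, 0.18, 0.16])
    x, y, month = _effort_locations(rng, n_hauls, grid, month_weights)
    year = rng.choice(np.array(years), size=n_hauls)
    year_effects = {
        g: dict(zip(years, rng.normal(0.0, truth.year_sd, len(years))))
        for g in GROUPS
    }

    mesh = build_mesh(np.c_[x, y], n_knots=truth.sim_knots, cutoff_km=10.0,
                      seed=seed)
    from .spde import projector

    A = projector(mesh, np.c_[x, y]).toarray()
    t_idx = month.astype(int) - 4

    cov = _covariates_at(grid, x, y, month)
    z = _standardized(cov, grid)

    fields, mus, biomass = {}, {}, {}
    for g in ("EP_adult", "TS_adult"):
        fp = truth.field_params[g]
        Q = precision_from_params(mesh, fp)
        fields[g] = _simulate_ar1_fields(Q, fp.rho, len(MONTHS), rng)
        eta = truth.beta0[g] + _month_curve(month, *truth.month_amp[g])
        eta += np.array([year_effects[g][yy] for yy in year])
        for name, (b1, b2) in truth.covariate_effects[g].items():
            eta += b1 * z[name].to_numpy() + b2 * z[name].to_numpy() ** 2
        eta += np.einsum("ij,ij->i", A, fields[g][t_idx])
        mus[g] = np.exp(eta)
        p, phi = truth.tweedie[g]
        biomass[g] = tweedie_rvs(mus[g], phi, p, rng)

    g = "larvae"
    fp = truth.field_params[g]
    Q = precision_from_params(mesh, fp)
    fields[g] = _simulate_ar1_fields(Q, fp.rho, len(MONTHS), rng)
    eta = truth.beta0[g] + _month_curve(month, *truth.month_amp[g])
    eta += np.array([year_effects[g][yy] for yy in year])
    for name, (b1, b2) in truth.covariate_effects[g].items():
        eta += b1 * z[name].to_numpy() + b2 * z[name].to_numpy() ** 2
    cE, cT = truth.larval_coupling
    eta += cE * np.log1p(mus["EP_adult"]) + cT * np.log1p(mus["TS_adult"])
    eta += np.einsum("ij,ij->i", A, fields[g][t_idx])
    mus[g] = np.exp(eta)
    p, phi = truth.tweedie[g]
    biomass[g] = tweedie_rvs(mus[g], phi, p, rng)

    bottom = cov["depth"].to_numpy(dtype=float)
    sampling = np.minimum(bottom - rng.uniform(0.0, 5.0, n_hauls), 250.0)
    sampling = np.maximum(sampling, 5.0)
    volume = rng.lognormal(np.log(80.0), 0.3, n_hauls)

    hauls = pd.DataFrame({
        "haul_id": [f"H{i:05d}" for i in range(n_hauls)],
        "station_id": [f"S{i % 400:03d}" for i in range(n_hauls)],
        "year": year, "month": month.astype(int),
        "x_km": x, "y_km": y,
        "bottom_depth_m": bottom, "sampling_depth_m": sampling,
        "volume_m3": volume, "daylight": True,
    })

    extra = _planted_invalid_hauls(truth, rng, grid, years, n_hauls)
    raw = _decompose_counts(pd.concat([hauls, extra], ignore_index=True),
                            biomass, truth, rng)

    truth_df = pd.DataFrame({
        "haul_id": hauls["haul_id"],
        "EP_adult": biomass["EP_adult"],
        "TS_adult": biomass["TS_adult"],
        "larvae": biomass["larvae"],
        "planted_invalid": False,
    })
    if len(extra):
        truth_df = pd.concat([
            truth_df,
            pd.DataFrame({
                "haul_id": extra["haul_id"], "EP_adult": 0.0, "TS_adult": 0.0,
                "larvae": 0.0, "planted_invalid": True,
            }),
        ], ignore_index=True)

    extras = {"grid": grid, "mesh": mesh, "fields": fields, "mu": mus,
              "year_effects": year_effects, "hauls": hauls,
              "biomass": biomass, "z": z}
    return raw, truth_df, extras


def _planted_invalid_hauls(truth, rng, grid, years, n_valid):
    """Hauls that must be excluded: depth-disparity, night, off-season."""
    rows = []
    i0 = n_valid
    n_viol = int(round(truth.violator_fraction * n_valid))
    for k in range(n_viol):
        bottom = rng.uniform(40.0, 240.0)
        gap = (rng.uniform(31.0, 60.0) if bottom < 100 else rng.uniform(51.0, 90.0))
        rows.append({
            "haul_id": f"H{i0 + k:05d}", "station_id": "SVIO",
            "year": int(rng.choice(np.array(years))),
            "month": int(rng.choice(np.array(MONTHS))),
            "x_km": rng.uniform(5, grid.width_km - 5),
            "y_km": rng.uniform(5, grid.height_km - 5),
            "bottom_depth_m": bottom,
            "sampling_depth_m": max(bottom - gap, 1.0),
            "volume_m3": 80.0, "daylight": True,
        })
    i0 += n_viol
    n_night = int(round(truth.night_fraction * n_valid))
    n_off = int(round(truth.off_season_fraction * n_valid))
    for k in range(n_night + n_off):
        night = k < n_night
        rows.append({
            "haul_id": f"H{i0 + k:05d}", "station_id": "SOFF",
            "year": int(rng.choice(np.array(years))),
            "month": int(rng.choice(np.array(MONTHS))) if night
            else int(rng.choice([3, 10])),
            "x_km": rng.uniform(5, grid.width_km - 5),
            "y_km": rng.uniform(5, grid.height_km - 5),
            "bottom_depth_m": 150.0, "sampling_depth_m": 145.0,
            "volume_m3": 80.0, "daylight": not night,
        })
    return pd.DataFrame(rows)


def _decompose_counts(hauls: pd.DataFrame, biomass: dict, truth, rng):
    """Invert the standardization chain into a raw long count table.

    Per haul: biomass -> volumetric (/= sampling depth) -> counts via the
    toy coefficients, subsample fractions and (for adults) the avoidance
    factor, so ingest() reproduces the mg/m^2 exactly.
    """
    coeff = TOY_COEFFICIENTS
    f = truth.avoidance_factor
    n_valid = len(biomass["EP_adult"])
    subsample = rng.choice([0.25, 0.5, 1.0], size=len(hauls))
    rows = []
    for i, h in hauls.iterrows():
        vol, depth = h["volume_m3"], h["sampling_depth_m"]
        sub = subsample[i]
        b = {g: (biomass[g][i] if i < n_valid else 0.0) for g in GROUPS}

        def count_for(total_mg_m2, coeff_mg, adult):
            per_m3 = total_mg_m2 / depth
            raw_count = per_m3 * vol / coeff_mg / (f if adult else 1.0)
            return raw_count * sub

        rows += [
            dict(h, species="E_pacifica", stage="S4", sex="female",
                 count_per_haul=count_for(b["EP_adult"],
                                          coeff[("E_pacifica", "S4", "female")],
                                          True),
                 subsample_fraction=sub),
            dict(h, species="T_spinifera", stage="S4", sex="female",
                 count_per_haul=count_for(0.5 * b["TS_adult"],
                                          coeff[("T_spinifera", "S4", "female")],
                                          True),
                 subsample_fraction=sub),
            dict(h, species="T_spinifera", stage="S4", sex="male",
                 count_per_haul=count_for(0.5 * b["TS_adult"],
                                          coeff[("T_spinifera", "S4", "male")],
                                          True),
                 subsample_fraction=sub),
            dict(h, species="E_pacifica", stage="eggs", sex="",
                 count_per_haul=count_for(0.2 * b["larvae"],
                                          coeff[("E_pacifica", "eggs", None)],
                                          False),
                 subsample_fraction=sub),
            dict(h, species="E_pacifica", stage="s1", sex="",
                 count_per_haul=count_for(0.4 * b["larvae"],
                                          coeff[("E_pacifica", "s1", None)],
                                          False),
                 subsample_fraction=sub),
            dict(h, species="E_pacifica", stage="s2", sex="",
                 count_per_haul=count_for(0.4 * b["larvae"],
                                          coeff[("E_pacifica", "s2", None)],
                                          False),
                 subsample_fraction=sub),
        ]
    return pd.DataFrame(rows)


def toy_coefficient_table() -> CoefficientTable:
    return CoefficientTable(dict(TOY_COEFFICIENTS))


# ---------------------------------------------------------------------------
# recovery suite: model-level simulation on a shared analysis mesh


# preset effect shapes (on the standardized covariate scale)
RECOVERY_EFFECTS = {"depth": (0.2, -0.8)}
SELECTION_EFFECTS = {"depth": (0.2, -0.8), "sst": (0.6, 0.0), "chl": (0.5, 0.0)}


def simulate_glmm_dataset(
    mesh,
    grid: PredictionGrid,
    n_obs: int = 1200,
    years: tuple = (2016, 2017, 2018, 2019),
    field_params: FieldParams | None = None,
    p: float = 1.5,
    phi: float = 1.2,
    beta0: float = 1.0,
    seed: int = 0,
    covariate_effects: dict | None = None,
    month_amp: tuple = (0.6, 8),
    year_sd: float = 0.2,
    effort: str = "uniform",
):
    """Biomass observations simulated directly from the fitted model family.

    The latent field lives on the supplied analysis mesh (correctly
    specified discretization), so fitting the same mesh back measures pure
    estimation error.  ``effort`` is "uniform" (spatially uniform haul
    placement, equal months — the cleanest design for parameter
    identification) or "banded" (shelf-heavy, month-uneven effort as in the
    survey emulation).  Returns (observations DataFrame with covariates,
    truth dict).
    """
    fp = field_params or FieldParams(30.0, 1.0, 0.6)
    if covariate_effects is None:
        covariate_effects = dict(SELECTION_EFFECTS)
    rng = np.random.default_rng(seed)
    if effort == "uniform":
        x = rng.uniform(2.0, grid.width_km - 2.0, n_obs)
        y = rng.uniform(2.0, grid.height_km - 2.0, n_obs)
        month = rng.choice(np.arange(4, 10), size=n_obs).astype(float)
    else:
        month_weights = np.array([0.10, 0.16, 0.20, 0.20, 0.18, 0.16])
        x, y, month = _effort_locations(rng, n_obs, grid, month_weights,
                                        april_south_only=False)
    year = rng.choice(np.array(years), size=n_obs)
    year_eff = dict(zip(years, rng.normal(0.0, year_sd, len(years))))

    Q = precision_from_params(mesh, fp)
    u = _simulate_ar1_fields(Q, fp.rho, len(MONTHS), rng)
    from .spde import projector

    A = projector(mesh, np.c_[x, y]).toarray()
    cov = _covariates_at(grid, x, y, month)
    z = _standardized(cov, grid)
    eta = beta0 + _month_curve(month, *month_amp)
    eta += np.array([year_eff[yy] for yy in year])
    for name, (b1, b2) in covariate_effects.items():
        eta += b1 * z[name].to_numpy() + b2 * z[name].to_numpy() ** 2
    eta += np.einsum("ij,ij->i", A, u[month.astype(int) - 4])
    mu = np.exp(eta)
    yobs = tweedie_rvs(mu, phi, p, rng)

    data = pd.DataFrame({
        "x_km": x, "y_km": y, "year": year, "month": month.astype(int),
        "biomass_mg_m2": yobs,
    })
    for c in cov.columns:
        data[c] = cov[c].to_numpy()
    truth = {"field_params": fp, "p": p, "phi": phi, "beta0": beta0,
             "year_effects": year_eff, "u": u, "mu": mu,
             "covariate_effects": covariate_effects, "seed": seed}
    return data, truth


def make_recovery_suite(
    n_reps: int = 20,
    base_seed: int = 1000,
    mesh=None,
    grid: PredictionGrid | None = None,
    n_obs: int = 1200,
    **sim_kwargs,
):
    """Seeded replicate (dataset, truth) pairs at a fixed ground truth.

    Default study design: a 150 x 120 km domain with an 80-knot analysis
    mesh (~range/2 knot spacing, so the 30 km field is well resolved) and
    uniform effort.  Replicates share the mesh/grid and differ only by
    seed; regeneration is bit-identical.
    """
    if grid is None:
        grid = make_covariates(make_domain(150.0, 120.0, 3.0), seed=0)
    if mesh is None:
        rng = np.random.default_rng(base_seed)
        locs = np.c_[rng.uniform(5, grid.width_km - 5, 400),
                     rng.uniform(5, grid.height_km - 5, 400)]
        mesh = build_mesh(locs, n_knots=80, cutoff_km=8.0, seed=0)
    out = []
    for r in range(n_reps):
        data, truth = simulate_glmm_dataset(
            mesh, grid, n_obs=n_obs, seed=base_seed + r, **sim_kwargs
        )
        out.append((data, truth))
    return out, mesh, grid


def write_survey_csvs(outdir, raw, truth_df, grid: PredictionGrid,
                      truth: SimulationTruth):
    """Write the CSV/GeoJSON dialects the ingest module reads."""
    import os

    os.makedirs(outdir, exist_ok=True)
    raw.to_csv(os.path.join(outdir, "hauls_long.csv"), index=False)
    truth_df.to_csv(os.path.join(outdir, "haul_truth.csv"), index=False)
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": name},
             "geometry": mapping(poly)}
            for name, poly in grid.polygons
        ],
    }
    with open(os.path.join(outdir, "ecosections.geojson"), "w") as fh:
        json.dump(fc, fh)
    truth.to_json(os.path.join(outdir, "truth.json"))
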