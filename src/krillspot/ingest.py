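"""Survey-record standardization: from raw net-haul tables to biomass.

Raw zooplankton net hauls (counts per species/stage/sex, filtered volume,
depths, day/night flag) are filtered and converted to vertically integrated
dry-weight biomass (mg/m^2) for three euphausiid groups:

* ``EP_adult``  — Euphausia pacifica adults (stage S4, both sexes)
* ``TS_adult``  — Thysanoessa spinifera adults
* ``larvae``    — eggs + s1 + s2 larval stages pooled across species

Inclusion rules: daylight hauls, 1993 onwards, April–September; hauls whose
sampling depth is far off the bottom are excluded (gap > 30 m where the
bottom is shallower than 100 m, gap > 50 m for 100–250 m bottoms; deeper
stations sample to the 250 m net limit and are kept).  Daylight adult counts
may be scaled by a net-avoidance correction factor.  Conversion chain per
taxon row:  count / subsample_fraction * factor * dry-weight coefficient /
volume  (mg/m^3), then * sampling depth (mg/m^2).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

logger = logging.getLogger(__name__)

ADULT_STAGE = "S4"
LARVAL_STAGES = ("eggs", "s1", "s2")
FOCAL_SPECIES = ("E_pacifica", "T_spinifera")
GROUPS = ("EP_adult", "TS_adult", "larvae")

HAUL_COLUMNS = [
    "haul_id", "station_id", "year", "month", "x_km", "y_km",
    "bottom_depth_m", "sampling_depth_m", "volume_m3", "daylight",
]
COUNT_COLUMNS = ["species", "stage", "sex", "count_per_haul", "subsample_fraction"]


def assign_stage_group(length_mm: float, is_egg_or_nauplius: bool = False,
                       sex: str | None = None) -> str:
    """Map a measured individual to its stage group.

    eggs/nauplii < 3 mm -> ``eggs``; zoea < 5 mm -> ``s1``; juveniles
    >= 5 and < 10 mm -> ``s2``; >= 10 mm -> adults ``S4_male``/``S4_female``
    (``S4_unknown`` when sex is missing; the coefficient lookup then falls
    back to the male/female mean).
    """
    if length_mm < 0:
        raise ValueError("length must be non-negative")
    if is_egg_or_nauplius:
        if length_mm >= 3.0:
            raise ValueError("eggs/nauplii are < 3 mm by definition")
        return "eggs"
    if length_mm < 5.0:
        return "s1"
    if length_mm < 10.0:
        return "s2"
    return f"S4_{sex if sex in ('male', 'female') else 'unknown'}"


@dataclass
class CoefficientTable:
    """Dry-weight coefficients (mg per individual) by (species, stage, sex).

    Values are user-supplied (species- and stage-specific size coefficients
    from the regional literature are not bundled).  Adults of unknown sex
    use the mean of the male and female coefficients.
    """

    table: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "CoefficientTable":
        with open(path) as fh:
            raw = json.load(fh)
        tbl = {}
        for key, v in raw.items():
            species, stage, sex = (key.split("|") + [""])[:3]
            tbl[(species, stage, sex or None)] = float(v)
        return cls(tbl)

    def set(self, species, stage, coeff, sex=None):
        if coeff <= 0:
            raise ValueError("dry-weight coefficient must be positive")
        self.table[(species, stage, sex)] = float(coeff)

    def lookup(self, species, stage, sex=None) -> float:
        key = (species, stage, sex if stage == ADULT_STAGE else None)
        if key in self.table:
            return self.table[key]
        if stage == ADULT_STAGE:
            m = self.table.get((species, ADULT_STAGE, "male"))
            f = self.table.get((species, ADULT_STAGE, "female"))
            if m is not None and f is not None:
                return 0.5 * (m + f)
            both = self.table.get((species, ADULT_STAGE, None))
            if both is not None:
                return both
        raise KeyError(f"no dry-weight coefficient for {species}/{stage}/{sex}")


def read_haul_table(path) -> pd.DataFrame:
    """Read a haul CSV, auto-detecting long vs wide dialect by header.

    Long: one row per haul x species x stage x sex with a ``species``
    column.  Wide: one row per haul with ``count_<species>_<stage>[_<sex>]``
    columns (subsample fraction 1).
    """
    df = pd.read_csv(path)
    if "species" in df.columns:
        return df
    count_cols = [c for c in df.columns if c.startswith("count_")]
    if not count_cols:
        raise ValueError("unrecognised haul table: no 'species' or 'count_*' columns")
    long = df.melt(
        id_vars=[c for c in df.columns if c not in count_cols],
        value_vars=count_cols, var_name="_taxon", value_name="count_per_haul",
    )
    parts = long.pop("_taxon").str.split("_")
    long["species"] = parts.str[1:-2].str.join("_")
    # trailing tokens: <stage> or <stage>_<sex>
    long["sex"] = parts.str[-1].where(parts.str[-2] == ADULT_STAGE, "")
    long["stage"] = parts.str[-2].where(parts.str[-2] == ADULT_STAGE, parts.str[-1])
    fix = long["stage"] != ADULT_STAGE
    long.loc[fix, "species"] = parts[fix].str[1:-1].str.join("_")
    long["subsample_fraction"] = 1.0
    return long


def filter_depth_disparity(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop hauls whose sampling depth is too far off the bottom.

    Returns (survivors, exclusion log).  Rules: gap > 30 m at bottoms
    < 100 m; gap > 50 m at bottoms of 100–250 m; bottoms > 250 m always
    kept (nets stop at 250 m).  Hauls with missing depths are rejected
    with a warning rather than silently kept.
    """
    bottom = pd.to_numeric(df["bottom_depth_m"], errors="coerce")
    sampling = pd.to_numeric(df["sampling_depth_m"], errors="coerce")
    missing = bottom.isna() | sampling.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} record(s) with missing depth rejected",
            stacklevel=2,
        )
    gap = bottom - sampling
    drop = missing.copy()
    drop |= (bottom < 100) & (gap > 30)
    drop |= (bottom >= 100) & (bottom <= 250) & (gap > 50)
    excl = df.loc[drop].copy()
    excl["exclusion_reason"] = np.where(
        missing.loc[drop], "missing depth", "depth disparity"
    )
    n_hauls = excl["haul_id"].nunique() if "haul_id" in excl else len(excl)
    logger.info("depth-disparity filter removed %d haul(s)", n_hauls)
    return df.loc[~drop].copy(), excl


def filter_season_daylight(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep daylight hauls from 1993 on, April–September."""
    keep = (
        df["daylight"].astype(bool)
        & (df["year"].astype(int) >= 1993)
        & df["month"].astype(int).between(4, 9)
    )
    excl = df.loc[~keep].copy()
    excl["exclusion_reason"] = "season/daylight/era"
    return df.loc[keep].copy(), excl


def apply_net_avoidance_correction(
    df: pd.DataFrame, factor: float, correct_larvae: bool = False
) -> pd.DataFrame:
    """Scale daylight counts by the net-avoidance factor.

    Applied to adult (S4) counts; larval stages are left uncorrected unless
    ``correct_larvae``.  The factor is configuration (no default literature
    value is bundled); factor 1.0 is the identity.
    """
    if factor <= 0:
        raise ValueError("net-avoidance factor must be positive")
    out = df.copy()
    adult = out["stage"] == ADULT_STAGE
    scale = np.where(adult | correct_larvae, factor, 1.0)
    out["count_corrected"] = (
        pd.to_numeric(out["count_per_haul"]) / pd.to_numeric(out["subsample_fraction"])
    ) * scale
    return out


def _group_of(species: str, stage: str) -> str | None:
    if stage in LARVAL_STAGES:
        return "larvae"
    if stage == ADULT_STAGE:
        if species == "E_pacifica":
            return "EP_adult"
        if species == "T_spinifera":
            return "TS_adult"
        return None  # non-focal adult: excluded, logged
    return None


def standardize_biomass(
    df: pd.DataFrame,
    coefficients: CoefficientTable,
    volume_fallback: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert corrected counts to vertically integrated biomass per group.

    Per haul and group g:  mg/m^2 = sampling_depth * sum over taxa in g of
    corrected_count * coefficient / volume.  Every haul emits exactly three
    observations (zeros included — the Tweedie model needs them).  Hauls
    without a usable volume are excluded and logged.  ``volume_fallback``
    may give ``{"mouth_area_m2": ..., "tow_angle_deg": ...}`` to derive the
    volume from a ``wire_out_m`` column when the flow-meter value is absent.
    """
    if "count_corrected" not in df.columns:
        raise ValueError("run apply_net_avoidance_correction first")
    df = df.copy()
    vol = pd.to_numeric(df["volume_m3"], errors="coerce")
    if volume_fallback is not None and "wire_out_m" in df.columns:
        angle = np.deg2rad(volume_fallback.get("tow_angle_deg", 0.0))
        fallback = (
            volume_fallback["mouth_area_m2"]
            * pd.to_numeric(df["wire_out_m"], errors="coerce")
            * np.cos(angle)
        )
        vol = vol.fillna(fallback)
    df["_volume"] = vol

    rows, excluded, other_adults = [], [], 0.0
    for haul_id, h in df.groupby("haul_id", sort=True):
        meta = h.iloc[0]
        if not np.isfinite(meta["_volume"]) or meta["_volume"] <= 0:
            excluded.append({"haul_id": haul_id, "exclusion_reason": "no volume"})
            continue
        per_m3 = dict.fromkeys(GROUPS, 0.0)
        for _, r in h.iterrows():
            g = _group_of(r["species"], r["stage"])
            if g is None:
                if r["stage"] == ADULT_STAGE:
                    other_adults += float(r["count_corrected"])
                continue
            sex = r.get("sex") or None
            coeff = coefficients.lookup(r["species"], r["stage"], sex)
            per_m3[g] += float(r["count_corrected"]) * coeff / float(meta["_volume"])
        for g in GROUPS:
            rows.append(
                {
                    "haul_id": haul_id,
                    "x_km": meta["x_km"], "y_km": meta["y_km"],
                    "year": int(meta["year"]), "month": int(meta["month"]),
                    "group": g,
                    "biomass_mg_m2": per_m3[g] * float(meta["sampling_depth_m"]),
                }
            )
    if other_adults:
        logger.info("excluded %.1f corrected non-focal adult counts", other_adults)
    obs = pd.DataFrame(rows, columns=[
        "haul_id", "x_km", "y_km", "year", "month", "group", "biomass_mg_m2",
    ])
    return obs, pd.DataFrame(excluded, columns=["haul_id", "exclusion_reason"])


def read_ecosections_geojson(path) -> list[tuple[str, object]]:
    """Read an ecosection FeatureCollection -> ordered (name, polygon) list."""
    with open(path) as fh:
        fc = json.load(fh)
    return [(f["properties"]["name"], shape(f["geometry"])) for f in fc["features"]]


def assign_ecosection(x_km, y_km, polygons) -> str:
    """Point-in-polygon label; boundary points go to the first listed
    polygon (documented tie-break); outside all polygons -> ``outside``."""
    pt = Point(float(x_km), float(y_km))
    for name, poly in polygons:
        if poly.covers(pt):
            return name
    return "outside"


def assign_ecosections(df: pd.DataFrame, polygons) -> pd.Series:
    return pd.Series(
        [assign_ecosection(x, y, polygons) for x, y in zip(df["x_km"], df["y_km"])],
        index=df.index, name="ecosection",
    )


def ingest(
    df: pd.DataFrame,
    coefficients: CoefficientTable,
    avoidance_factor: float = 1.0,
    correct_larvae: bool = False,
    polygons=None,
    volume_fallback: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full standardization chain; returns (observations, exclusion log)."""
    if avoidance_factor == 1.0:
        warnings.warn(
            "net-avoidance factor is 1.0 (no correction); the survey protocol "
            "normally applies a daylight avoidance correction — set "
            "avoidance_factor from your gear calibration",
            stacklevel=2,
        )
    df1, ex1 = filter_season_daylight(df)
    df2, ex2 = filter_depth_disparity(df1)
    df3 = apply_net_avoidance_correction(df2, avoidance_factor, correct_larvae)
    obs, ex3 = standardize_biomass(df3, coefficients, volume_fallback)
    if polygons is not None:
        obs["ecosection"] = assign_ecosections(obs, polygons)
    log = pd.concat(
        [e[["haul_id", "exclusion_reason"]].drop_duplicates()
         for e in (ex1, ex2, ex3) if len(e)],
        ignore_index=True,
    ) if (len(ex1) or len(ex2) or len(ex3)) else pd.DataFrame(
        columns=["haul_id", "exclusion_reason"]
    )
    return obs, log
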