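"""Agronomic, herd and vegetation covariates derived from raw practice records.

Grazing pressure is expressed in livestock-unit days per hectare (one LU = one
dairy cow); manure nitrogen uses fixed per-type nitrogen contents (liquid
5 kg N m-3, diluted liquid 3 kg N m-3, solid 5 kg N t-1) averaged over a
3-year record window. Vegetation structure comes from Braun-Blanquet cover
codes converted to midpoint percentage covers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: kg N per m3 (liquid types) or per t (solid)
MANURE_N_CONTENT = {"liquid": 5.0, "diluted-liquid": 3.0, "solid": 5.0}

#: Braun-Blanquet code -> absolute percentage cover midpoint
BRAUN_BLANQUET_MIDPOINTS = {
    "r": 0.1,
    "+": 0.5,
    "1": 3.0,
    "2": 15.0,
    "3": 37.5,
    "4": 62.5,
    "5": 87.5,
}

MANURE_WINDOW_YEARS = 3

MILKING_PREPARATIONS = ("none", "dry", "humid")


class CovariateError(ValueError):
    pass


@dataclass
class ManureApplication:
    """One yearly manure spread: type, amount (m3 for liquids, t for solid), year index."""

    manure_type: str
    amount: float
    year: int = 0

    def __post_init__(self) -> None:
        if self.manure_type not in MANURE_N_CONTENT:
            raise CovariateError(f"unknown manure type {self.manure_type!r}")
        if self.amount < 0:
            raise CovariateError("manure amount must be non-negative")


@dataclass
class RawPracticeRecord:
    """Raw grassland/herd practice inputs for one farm."""

    farm: str
    area_ha: float
    grazing: Mapping[str, tuple[float, float]]  # season -> (LU, days)
    n_ind: float = 0.0
    p_ind: float = 0.0
    k_ind: float = 0.0
    manure: Sequence[ManureApplication] = field(default_factory=tuple)
    dairy_cows: int = 0
    milking_preparation: str = "none"
    cow_teat_care: bool = False

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise CovariateError("plot area must be positive")
        for season, (lu, days) in self.grazing.items():
            if lu < 0 or days < 0:
                raise CovariateError(f"negative grazing inputs for {season!r}")
        if self.milking_preparation not in MILKING_PREPARATIONS:
            raise CovariateError(
                f"unknown milking preparation {self.milking_preparation!r}"
            )


def grazing_pressure(lu: float, days: float, area_ha: float) -> float:
    """Seasonal grazing pressure LU*t/A in LU d ha-1."""
    if area_ha <= 0:
        raise CovariateError("plot area must be positive")
    if lu < 0 or days < 0:
        raise CovariateError("LU and days must be non-negative")
    return lu * days / area_ha


def manure_nitrogen(amount: float, manure_type: str, area_ha: float) -> float:
    """Plant-available N from one manure spread, kg N ha-1 yr-1."""
    if manure_type not in MANURE_N_CONTENT:
        raise CovariateError(f"unknown manure type {manure_type!r}")
    if amount < 0:
        raise CovariateError("amount must be non-negative")
    if area_ha <= 0:
        raise CovariateError("plot area must be positive")
    return amount * MANURE_N_CONTENT[manure_type] / area_ha


def derive_practices(raw: RawPracticeRecord) -> dict[str, float | str | bool]:
    """Derive the grassland/herd management covariates from a raw record.

    Returns Cattle_{spring,summer,autumn}, Cattle, N/P/K_ind,
    Liquid/Solid/Total_manure, Total_N_fertilization and Manure_prop (with the
    zero rule: 0 when total fertilization is 0). Manure is averaged over a
    3-year window; years missing from the record count as zero applications.
    """
    out: dict[str, float | str | bool] = {}
    seasons = ("spring", "summer", "autumn")
    for season in seasons:
        lu, days = raw.grazing.get(season, (0.0, 0.0))
        out[f"Cattle_{season}"] = grazing_pressure(lu, days, raw.area_ha)
    out["Cattle"] = sum(out[f"Cattle_{s}"] for s in seasons)

    out["N_ind"] = float(raw.n_ind)
    out["P_ind"] = float(raw.p_ind)
    out["K_ind"] = float(raw.k_ind)

    years_seen = {app.year for app in raw.manure}
    if raw.manure and len(years_seen) < MANURE_WINDOW_YEARS:
        log.warning(
            "farm %s: manure record covers %d of %d years; missing years treated as 0",
            raw.farm,
            len(years_seen),
            MANURE_WINDOW_YEARS,
        )
    liquid = sum(
        manure_nitrogen(app.amount, app.manure_type, raw.area_ha)
        for app in raw.manure
        if app.manure_type in ("liquid", "diluted-liquid")
    )
    solid = sum(
        manure_nitrogen(app.amount, app.manure_type, raw.area_ha)
        for app in raw.manure
        if app.manure_type == "solid"
    )
    out["Liquid_manure"] = liquid / MANURE_WINDOW_YEARS
    out["Solid_manure"] = solid / MANURE_WINDOW_YEARS
    out["Total_manure"] = out["Liquid_manure"] + out["Solid_manure"]
    out["Total_N_fertilization"] = out["Total_manure"] + out["N_ind"]
    out["Manure_prop"] = (
        0.0
        if out["Total_N_fertilization"] == 0
        else out["Total_manure"] / out["Total_N_fertilization"]
    )
    out["Dairy_cows"] = float(raw.dairy_cows)
    out["Milking_preparation"] = raw.milking_preparation
    out["Cow-teat_care"] = "yes" if raw.cow_teat_care else "no"
    return out


def read_practice_records(
    practices_path, manure_path=None
) -> list[RawPracticeRecord]:
    """Read raw practice records from TSV.

    ``practices_path`` columns: farm, area_ha, lu_spring, days_spring,
    lu_summer, days_summer, lu_autumn, days_autumn, n_ind, p_ind, k_ind,
    dairy_cows, milking_preparation, cow_teat_care (yes/no).
    ``manure_path`` (optional) is long-format: farm, year, type
    (liquid | diluted-liquid | solid), amount (m3 for liquids, t for solid).
    """
    import pandas as pd

    practices = pd.read_csv(practices_path, sep="\t")
    manure = (
        pd.read_csv(manure_path, sep="\t") if manure_path is not None else None
    )
    records = []
    for row in practices.itertuples(index=False):
        apps: list[ManureApplication] = []
        if manure is not None:
            for m in manure[manure["farm"] == row.farm].itertuples(index=False):
                apps.append(
                    ManureApplication(str(m.type), float(m.amount), int(m.year))
                )
        records.append(
            RawPracticeRecord(
                farm=str(row.farm),
                area_ha=float(row.area_ha),
                grazing={
                    s: (float(getattr(row, f"lu_{s}")), float(getattr(row, f"days_{s}")))
                    for s in ("spring", "summer", "autumn")
                },
                n_ind=float(row.n_ind),
                p_ind=float(row.p_ind),
                k_ind=float(row.k_ind),
                manure=apps,
                dairy_cows=int(row.dairy_cows),
                milking_preparation=str(row.milking_preparation),
                cow_teat_care=str(row.cow_teat_care).lower() == "yes",
            )
        )
    return records


def derive_covariates_table(records: Sequence[RawPracticeRecord]):
    """Practice covariates for a set of farms as a DataFrame (index = farm)."""
    import pandas as pd

    return pd.DataFrame(
        {r.farm: derive_practices(r) for r in records}
    ).T.rename_axis("farm")


def vegetation_metrics(
    bb_codes: Mapping[str, str],
    groups: Mapping[str, str],
    midpoints: Mapping[str, float] = BRAUN_BLANQUET_MIDPOINTS,
) -> dict[str, float | None]:
    """Vegetation summary from per-species Braun-Blanquet codes.

    Codes are converted to absolute cover midpoints, renormalized to relative
    covers summing to 100 %, and summarized as species richness, Pielou
    evenness J = (-sum p_i ln p_i)/ln S (None when S = 1, where J is
    undefined), and grass/forb/legume relative covers.
    """
    if not bb_codes:
        raise CovariateError("at least one species is required")
    covers = {}
    for sp, code in bb_codes.items():
        code = str(code)
        if code not in midpoints:
            raise CovariateError(f"unknown Braun-Blanquet code {code!r} for {sp!r}")
        covers[sp] = midpoints[code]
    total = sum(covers.values())
    rel = {sp: 100.0 * c / total for sp, c in covers.items()}

    s = len(rel)
    p = np.array([v / 100.0 for v in rel.values()])
    if s == 1:
        pielou: float | None = None
    else:
        shannon = -np.sum(p * np.log(p))
        pielou = float(shannon / math.log(s))

    group_cover = {"grass": 0.0, "forb": 0.0, "legume": 0.0}
    for sp, cover in rel.items():
        grp = groups.get(sp)
        if grp not in group_cover:
            raise CovariateError(f"species {sp!r} has unknown group {grp!r}")
        group_cover[grp] += cover

    return {
        "SpRichness": float(s),
        "Pielou": pielou,
        "Grass": group_cover["grass"],
        "Forb": group_cover["forb"],
        "Legume": group_cover["legume"],
    }
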