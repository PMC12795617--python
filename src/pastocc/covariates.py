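"""Grid-level site covariates and replicate-level detection covariates.

Site covariates per 5x5 km grid cell: land-cover areas (km^2) under kharif
[monsoon] cropping, double/triple [irrigated] cropping and open natural
ecosystems (ONE); major-road length (km); and livestock biomass (kg)
apportioned from village head counts.  Detection covariates per interview:
whether the respondent covered the whole grid and their years of herding
experience.

Covariates are standardized by z-score over the full district grid (sampled
and unsampled cells alike) so that fitted coefficients can be projected to
unsampled cells on the same scale, and screened pairwise for collinearity:
pairs with |Pearson r| >= 0.6 may never enter the same model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: mean body masses (kg) used to convert head counts to biomass; config, not
#: hard-wired into the arithmetic
DEFAULT_BODY_MASSES = {"cow": 250.0, "buffalo": 350.0, "sheep": 30.0, "goat": 25.0}

SMALL_BODIED = ("sheep", "goat")
LARGE_BODIED = ("cow", "buffalo")

#: covariates eligible for occupancy (psi) and detection (p) per species,
#: with the direction of effect expected a priori (reporting only; fits are
#: never constrained by sign)
SPECIES_MENUS = {
    "leopard": {
        "psi": ("biomass_total", "road", "double_triple", "one"),
        "p": ("grid_covered", "experience", "double_triple", "one"),
        "expected_sign": {
            "biomass_total": +1, "road": -1, "double_triple": +1, "one": +1,
            "grid_covered": +1, "experience": +1,
        },
    },
    "wolf": {
        "psi": ("biomass_small", "road", "kharif", "one"),
        "p": ("grid_covered", "experience", "kharif", "one"),
        "expected_sign": {
            "biomass_small": +1, "road": -1, "kharif": +1, "one": +1,
            "grid_covered": +1, "experience": +1,
        },
    },
    "hyena": {
        "psi": ("biomass_total", "road", "double_triple", "one"),
        "p": ("grid_covered", "experience", "double_triple", "one"),
        "expected_sign": {
            "biomass_total": +1, "road": -1, "double_triple": +1, "one": +1,
            "grid_covered": +1, "experience": +1,
        },
    },
    "sloth_bear": {
        "psi": ("road", "kharif", "one"),
        "p": ("grid_covered", "experience", "kharif", "one"),
        "expected_sign": {
            "road": -1, "kharif": +1, "one": +1,
            "grid_covered": +1, "experience": +1,
        },
    },
    "blackbuck": {
        "psi": ("road", "kharif", "one"),
        "p": ("grid_covered", "experience", "kharif", "one"),
        "expected_sign": {
            "road": -1, "kharif": +1, "one": +1,
            "grid_covered": +1, "experience": +1,
        },
    },
}


class ZeroVarianceError(ValueError):
    """A column with zero variance cannot be z-scored."""


@dataclass
class GridCell:
    grid_id: str
    area_kharif: float = 0.0
    area_double_triple: float = 0.0
    area_one: float = 0.0
    road_length: float = 0.0
    biomass_small: float = 0.0
    biomass_large: float = 0.0
    fraction_in_district: float = 1.0
    water_fraction: float = 0.0
    sampled: bool = True
    cell_area: float = 25.0  # km^2, 5 km x 5 km

    def __post_init__(self) -> None:
        for name in ("area_kharif", "area_double_triple", "area_one"):
            v = getattr(self, name)
            if not 0.0 <= v <= self.cell_area:
                raise ValueError(f"{self.grid_id}: {name}={v} outside [0, {self.cell_area}]")
        if self.road_length < 0 or self.biomass_small < 0 or self.biomass_large < 0:
            raise ValueError(f"{self.grid_id}: negative road length or biomass")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError(f"{self.grid_id}: water_fraction outside [0,1]")


@dataclass
class VillageRecord:
    """Village livestock census with area-overlap shares across grid cells."""

    village_id: str
    counts: dict[str, float]  # cow, buffalo, sheep, goat head counts
    overlap_fraction: dict[str, float]  # grid_id -> share of village area

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.village_id}: negative head count")
        fracs = np.array(list(self.overlap_fraction.values()), dtype=float)
        if ((fracs < 0) | (fracs > 1)).any():
            raise ValueError(f"{self.village_id}: overlap fraction outside [0,1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.village_id}: overlap fractions sum to {fracs.sum()}, not 1"
            )


def livestock_biomass(
    v: VillageRecord, masses: dict[str, float] | None = None
) -> tuple[float, float]:
    """Village biomass (kg) split into small-bodied (sheep/goat) and
    large-bodied (cow/buffalo) stock: head counts times mean body mass."""
    masses = DEFAULT_BODY_MASSES if masses is None else masses
    for lt in SMALL_BODIED + LARGE_BODIED:
        if lt in v.counts and lt not in masses:
            raise KeyError(f"no body mass configured for {lt!r}")
    small = sum(v.counts.get(lt, 0.0) * masses[lt] for lt in SMALL_BODIED if lt in masses)
    large = sum(v.counts.get(lt, 0.0) * masses[lt] for lt in LARGE_BODIED if lt in masses)
    return small, large


def apportion_to_grids(
    v: VillageRecord, masses: dict[str, float] | None = None
) -> dict[str, tuple[float, float]]:
    """Distribute a village's (small, large) biomass across the grids it
    overlaps, in proportion to the village's area share in each grid.
    Conserves total biomass exactly."""
    small, large = livestock_biomass(v, masses)
    return {
        grid: (small * f, large * f) for grid, f in v.overlap_fraction.items()
    }


def grid_biomass(
    villages: list[VillageRecord], masses: dict[str, float] | None = None
) -> pd.DataFrame:
    """Sum apportioned village biomass into per-grid totals."""
    acc: dict[str, list[float]] = {}
    for v in villages:
        for grid, (s, l) in apportion_to_grids(v, masses).items():
            cur = acc.setdefault(grid, [0.0, 0.0])
            cur[0] += s
            cur[1] += l
    df = pd.DataFrame.from_dict(
        acc, orient="index", columns=["biomass_small", "biomass_large"]
    )
    df.index.name = "grid_id"
    return df.sort_index()


def one_area(pixel_probs: np.ndarray, pixel_area: float) -> float:
    """Area (km^2) classified as open natural ecosystem: the count of pixels
    with membership probability strictly greater than 0.5, times the pixel
    area."""
    probs = np.asarray(pixel_probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("pixel probabilities must lie in [0, 1]")
    return float(np.count_nonzero(probs > 0.5) * pixel_area)


def zscore(
    table: pd.DataFrame, columns: list[str] | None = None, prefix: str = "z_"
) -> pd.DataFrame:
    """Standardize columns to mean 0, sd 1 (sample sd, ddof=1) over all rows
    of *table* — which should be the full district grid, so that predictions
    to unsampled cells use the same scale as the fit.

    Returns a copy of *table* with added ``z_``-prefixed columns.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    for col in columns:
        x = table[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ZeroVarianceError(f"column {col!r} has zero variance")
        out[prefix + col] = (x - x.mean()) / sd
    return out


def correlation_screen(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    threshold: float = 0.6,
) -> list[tuple[str, str, float]]:
    """Flag covariate pairs with |Pearson r| >= *threshold* (inclusive).

    Flagged pairs may never co-occur in one model specification; the
    selection machinery enforces this.  Symmetric: each unordered pair is
    reported once, in column order.
    """
    if len(table) < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    if columns is None:
        columns = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    corr = table[columns].corr()
    flagged = []
    for i, u in enumerate(columns):
        for v in columns[i + 1:]:
            r = corr.loc[u, v]
            if abs(r) >= threshold:
                flagged.append((u, v, float(r)))
    return flagged


def incompatible_pairs(
    flagged: list[tuple[str, str, float]]
) -> frozenset[frozenset[str]]:
    return frozenset(frozenset((u, v)) for u, v, _ in flagged)


@dataclass
class CovariateTable:
    """District-wide covariate table: raw and z-scored site covariates, plus
    the collinearity screen result."""

    table: pd.DataFrame  # indexed by grid_id; raw and z_ columns
    site_covariates: tuple[str, ...]
    incompatible: frozenset[frozenset[str]] = frozenset()
    screen_report: list[tuple[str, str, float]] = field(default_factory=list)

    def z(self, grid_ids: list[str] | None = None) -> pd.DataFrame:
        """Standardized site covariates under their plain names."""
        cols = {c: f"z_{c}" for c in self.site_covariates}
        df = self.table[list(cols.values())].rename(
            columns={v: k for k, v in cols.items()}
        )
        if grid_ids is not None:
            df = df.loc[grid_ids]
        return df


def build_covariate_table(
    grids: list[GridCell] | pd.DataFrame,
    villages: list[VillageRecord] | None = None,
    masses: dict[str, float] | None = None,
    screen_threshold: float = 0.6,
) -> CovariateTable:
    """Assemble, standardize and screen the per-grid site-covariate table.

    *grids* may be GridCell objects or an equivalent DataFrame.  When
    *villages* is given, grid biomass columns are (re)computed from the
    village census by area apportionment.
    """
    if isinstance(grids, pd.DataFrame):
        df = grids.copy()
        if df.index.name != "grid_id":
            df = df.set_index("grid_id")
    else:
        df = pd.DataFrame([vars(g) for g in grids]).set_index("grid_id")
    if villages is not None:
        bm = grid_biomass(villages, masses)
        df = df.drop(columns=["biomass_small", "biomass_large"], errors="ignore")
        df = df.join(bm, how="left").fillna(
            {"biomass_small": 0.0, "biomass_large": 0.0}
        )
    df = df.rename(
        columns={
            "area_kharif": "kharif",
            "area_double_triple": "double_triple",
            "area_one": "one",
            "road_length": "road",
        }
    )
    df["biomass_total"] = df["biomass_small"] + df["biomass_large"]
    site_covs = ("kharif", "double_triple", "one", "road", "biomass_small", "biomass_total")
    out = zscore(df, columns=list(site_covs))
    report = correlation_screen(out, columns=list(site_covs), threshold=screen_threshold)
    return CovariateTable(
        table=out,
        site_covariates=site_covs,
        incompatible=incompatible_pairs(report),
        screen_report=report,
    )


def write_covariates(cov: CovariateTable, path) -> None:
    cov.table.to_csv(path)


def write_screen_report(cov: CovariateTable, path) -> None:
    pd.DataFrame(cov.screen_report, columns=["covariate_a", "covariate_b", "r"]).to_csv(
        path, index=False
    )
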