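"""Survey-record data model: reading, validation, design summaries, date scaling.

The canonical on-disk format is a long CSV with header
``block,territory,year,julian_date,observed_state``. Observed states code the
territory condition on a single daytime visit: 1 = no owl detected, 2 = single
owl, 3 = pair without evidence of reproduction, 4 = reproducing pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STATES = (1, 2, 3, 4)
#: default survey season window, day-of-year (Mar 1 – Aug 31 of a non-leap year)
DEFAULT_DATE_WINDOW = (60, 243)

CANONICAL_COLUMNS = ("block", "territory", "year", "julian_date", "observed_state")


class SurveyDataError(ValueError):
    """Raised for malformed or invalid survey tables."""


@dataclass(frozen=True)
class SurveyRecord:
    """A single daytime visit to a territory."""

    block_id: str
    territory_id: str
    year: int
    julian_date: int
    observed_state: int

    def __post_init__(self) -> None:
        if self.observed_state not in VALID_STATES:
            raise SurveyDataError(
                f"observed_state must be in {VALID_STATES}, got {self.observed_state}"
            )


@dataclass
class StudyData:
    """Validated long-format survey records plus date-standardization state.

    Attributes
    ----------
    records
        DataFrame with the canonical columns; one row per visit. After
        :func:`standardize_dates` an extra ``jd_std`` column holds the
        centered/scaled Julian date.
    season_range
        ``{block: (first_year, last_year)}`` derived from the records.
    jd_center, jd_scale
        Mean and sample SD of the pooled Julian dates; ``None`` until
        :func:`standardize_dates` has been applied.
    """

    records: pd.DataFrame
    season_range: dict[str, tuple[int, int]] = field(default_factory=dict)
    jd_center: float | None = None
    jd_scale: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise SurveyDataError(f"records missing required columns: {missing}")
        if not self.season_range:
            self.season_range = {
                str(b): (int(g["year"].min()), int(g["year"].max()))
                for b, g in self.records.groupby("block", observed=True)
            }
        if self.jd_scale is not None and self.jd_scale <= 0:
            raise SurveyDataError("jd_scale must be > 0")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def blocks(self) -> list[str]:
        return sorted(self.season_range)

    def territories(self, block: str | None = None) -> list[str]:
        df = self.records if block is None else self.records[self.records["block"] == block]
        return sorted(df["territory"].astype(str).unique())

    def block_of(self) -> dict[str, str]:
        """Map territory id → block id (validated one-to-one at construction)."""
        return dict(
            self.records.groupby("territory", observed=True)["block"].first().astype(str)
        )


def _validate_frame(
    df: pd.DataFrame,
    date_window: tuple[int, int],
    allow_duplicates: bool,
) -> pd.DataFrame:
    bad_state = ~df["observed_state"].isin(VALID_STATES)
    if bad_state.any():
        rows = df.index[bad_state].tolist()[:20]
        vals = df.loc[bad_state, "observed_state"].unique().tolist()
        raise SurveyDataError(
            f"observed_state outside {{1,2,3,4}} (values {vals}) at rows {rows}"
        )
    lo, hi = date_window
    bad_date = (df["julian_date"] < lo) | (df["julian_date"] > hi)
    if bad_date.any():
        rows = df.index[bad_date].tolist()[:20]
        raise SurveyDataError(
            f"julian_date outside season window [{lo}, {hi}] at rows {rows}"
        )
    multi_block = df.groupby("territory", observed=True)["block"].nunique()
    offenders = multi_block[multi_block > 1].index.tolist()
    if offenders:
        raise SurveyDataError(f"territories mapped to more than one block: {offenders}")
    if not allow_duplicates:
        dup = df.duplicated(subset=["territory", "year", "julian_date"], keep=False)
        if dup.any():
            rows = df.index[dup].tolist()[:20]
            raise SurveyDataError(
                "duplicate (territory, year, julian_date) visits at rows "
                f"{rows}; pass allow_duplicates=True if intentional"
            )
    return df


def read_survey_table(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sheet: str | int = 0,
    date_window: tuple[int, int] = DEFAULT_DATE_WINDOW,
    allow_duplicates: bool = False,
) -> StudyData:
    """Read a survey table from CSV or XLSX into a validated :class:`StudyData`.

    Parameters
    ----------
    path
        File to read. Format is inferred from the suffix unless ``format``
        is given explicitly (``"csv"`` or ``"xlsx"``).
    column_map
        Mapping from the file's column names to the canonical names, e.g.
        ``{"Site": "territory", "Status": "observed_state"}``. Needed for
        deposits whose headers differ from the canonical schema.
    sheet
        Worksheet name or index for XLSX input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        raise SurveyDataError(f"unknown format {fmt!r}")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyDataError(
            f"missing required columns {missing}; present: {list(df.columns)}"
        )
    df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
    df["block"] = df["block"].astype(str)
    df["territory"] = df["territory"].astype(str)
    for col in ("year", "julian_date", "observed_state"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df = _validate_frame(df, date_window, allow_duplicates)
    return StudyData(records=df.reset_index(drop=True))


def write_survey_csv(data: StudyData, path: str | Path) -> None:
    """Write records to the canonical long CSV (standardized column dropped)."""
    data.records.loc[:, list(CANONICAL_COLUMNS)].to_csv(path, index=False)


def standardize_dates(data: StudyData) -> StudyData:
    """Center and scale Julian dates, pooled over all blocks and years.

    Uses the pooled mean and sample SD (n−1 denominator). The standardized
    value is stored in a ``jd_std`` column and the center/scale on the
    returned :class:`StudyData` so new visit dates can be placed on the same
    scale.
    """
    jd = data.records["julian_date"].to_numpy(dtype=float)
    if np.unique(jd).size < 2:
        raise SurveyDataError("cannot standardize: fewer than 2 distinct julian dates")
    center = float(jd.mean())
    scale = float(jd.std(ddof=1))
    df = data.records.copy()
    df["jd_std"] = (jd - center) / scale
    return StudyData(
        records=df,
        season_range=dict(data.season_range),
        jd_center=center,
        jd_scale=scale,
    )


@dataclass
class DesignSummary:
    """Survey-design summary statistics of a :class:`StudyData`."""

    n_territories: int
    territories_per_block: dict[str, int]
    territories_per_year: dict[int, int]
    mean_territories_per_year: float
    sd_territories_per_year: float
    range_territories_per_year: tuple[int, int]
    visits_median: float
    visits_mean: float
    visits_sd: float
    visits_range: tuple[int, int]
    median_span_days: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_territories": self.n_territories,
            "territories_per_block": self.territories_per_block,
            "territories_per_year": {str(k): v for k, v in self.territories_per_year.items()},
            "mean_territories_per_year": self.mean_territories_per_year,
            "sd_territories_per_year": self.sd_territories_per_year,
            "range_territories_per_year": list(self.range_territories_per_year),
            "visits_median": self.visits_median,
            "visits_mean": self.visits_mean,
            "visits_sd": self.visits_sd,
            "visits_range": list(self.visits_range),
            "median_span_days": self.median_span_days,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_design(data: StudyData) -> DesignSummary:
    """Summarize the survey design: effort per block, year, and territory-year."""
    df = data.records
    if df.empty:
        raise SurveyDataError("cannot summarize an empty survey table")
    per_block = (
        df.groupby("block", observed=True)["territory"].nunique().astype(int).to_dict()
    )
    per_year = (
        df.groupby("year", observed=True)["territory"].nunique().astype(int).to_dict()
    )
    py = np.array(list(per_year.values()), dtype=float)
    visits = df.groupby(["territory", "year"], observed=True).size().to_numpy(dtype=float)
    spans = (
        df.groupby(["territory", "year"], observed=True)["julian_date"]
        .agg(lambda x: x.max() - x.min())
        .to_numpy(dtype=float)
    )
    return DesignSummary(
        n_territories=int(df["territory"].nunique()),
        territories_per_block={str(k): v for k, v in per_block.items()},
        territories_per_year={int(k): v for k, v in per_year.items()},
        mean_territories_per_year=float(py.mean()),
        sd_territories_per_year=float(py.std(ddof=1)) if py.size > 1 else 0.0,
        range_territories_per_year=(int(py.min()), int(py.max())),
        visits_median=float(np.median(visits)),
        visits_mean=float(visits.mean()),
        visits_sd=float(visits.std(ddof=1)) if visits.size > 1 else 0.0,
        visits_range=(int(visits.min()), int(visits.max())),
        median_span_days=float(np.median(spans)),
    )


@dataclass
class BlockDesign:
    """Flat visit arrays for one block, ready for likelihoods and sampling.

    Latent trajectories span the block's full season range for every
    territory; seasons without visits for a territory simply contribute no
    detection terms.
    """

    block: str
    territory_ids: list[str]
    first_year: int
    n_seasons: int
    visit_terr: np.ndarray  # (V,) int32, territory index
    visit_season: np.ndarray  # (V,) int32, season index from first_year
    visit_jd: np.ndarray  # (V,) float64, standardized Julian date
    visit_y: np.ndarray  # (V,) int32, observed state 1..4
    season_offsets: np.ndarray  # (n_seasons+1,) int64 CSR offsets by season

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_seasons)

    @property
    def n_territories(self) -> int:
        return len(self.territory_ids)


def block_arrays(data: StudyData, block: str) -> BlockDesign:
    """Compile one block of a date-standardized :class:`StudyData` to arrays."""
    if data.jd_center is None or "jd_std" not in data.records.columns:
        raise SurveyDataError("standardize_dates must be applied before block_arrays")
    df = data.records[data.records["block"] == block]
    if df.empty:
        raise SurveyDataError(f"no records for block {block!r}")
    first_year, last_year = data.season_range[block]
    n_seasons = last_year - first_year + 1
    terr_ids = sorted(df["territory"].astype(str).unique())
    terr_index = {t: i for i, t in enumerate(terr_ids)}
    df = df.sort_values(["year", "territory", "julian_date"], kind="stable")
    return BlockDesign(
        block=block,
        territory_ids=terr_ids,
        first_year=first_year,
        n_seasons=n_seasons,
        visit_terr=df["territory"].map(terr_index).to_numpy(dtype=np.int32),
        visit_season=(df["year"] - first_year).to_numpy(dtype=np.int32),
        visit_jd=df["jd_std"].to_numpy(dtype=np.float64),
        visit_y=df["observed_state"].to_numpy(dtype=np.int32),
        season_offsets=np.searchsorted(
            (df["year"] - first_year).to_numpy(), np.arange(n_seasons + 1)
        ).astype(np.int64),
    )


def from_records(records: Sequence[SurveyRecord]) -> StudyData:
    """Build a :class:`StudyData` from :class:`SurveyRecord` objects."""
    df = pd.DataFrame(
        {
            "block": [r.block_id for r in records],
            "territory": [r.territory_id for r in records],
            "year": [r.year for r in records],
            "julian_date": [r.julian_date for r in records],
            "observed_state": [r.observed_state for r in records],
        }
    )
    return StudyData(records=df)
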