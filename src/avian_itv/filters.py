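"""Cleaning and inclusion rules for banding-station capture records.

The raw unit of data is one capture of one bird: band id, species, station,
coordinates, date, age/sex codes and trait measurements (body mass in grams,
wing chord in millimetres).  The cleaning pipeline, in order:

1. restrict to adult males captured inside the breeding-season window;
2. keep only the first capture of each individual within a season
   (band x species x station x year);
3. exclude gross measurement errors per station x species x trait: values
   more than ``mad_multiplier`` raw median absolute deviations from the
   group median;
4. inclusion thresholds, iterated to a fixed point: drop station x species
   groups with too few individuals, then species observed at too few
   stations or over too narrow a latitude span.

Records are never modified, only included or excluded; every exclusion is
recorded with a reason so provenance is queryable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "subset_adult_males",
    "first_capture_per_season",
    "mad_outlier_filter",
    "apply_inclusion_criteria",
    "apply_filters",
]

#: Columns a capture table must carry (trait columns may contain NaN).
CAPTURE_COLUMNS = [
    "band_id",
    "species",
    "location_id",
    "latitude",
    "longitude",
    "date",
    "age_class",
    "sex",
    "mass",
    "wing",
]


@dataclass(frozen=True)
class FilterConfig:
    min_individuals_per_location: int = 15
    min_locations_per_species: int = 5
    min_latitude_span: float = 5.0
    mad_multiplier: float = 5.0
    season_window: tuple[int, int] = (4, 8)  # start month, end month, inclusive

    def __post_init__(self) -> None:
        if (
            self.min_individuals_per_location <= 0
            or self.min_locations_per_species <= 0
            or self.min_latitude_span <= 0
            or self.mad_multiplier <= 0
        ):
            raise ValueError("all filter thresholds must be > 0")


def subset_adult_males(
    records: pd.DataFrame, season_window: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Keep adult males; optionally also restrict to the season window."""
    keep = (records["age_class"] == "adult") & (records["sex"] == "M")
    if season_window is not None:
        month = pd.to_datetime(records["date"]).dt.month
        keep &= (month >= season_window[0]) & (month <= season_window[1])
    return records.loc[keep]


def first_capture_per_season(records: pd.DataFrame) -> pd.DataFrame:
    """Earliest capture per (band, species, station, year); ties keep input order."""
    dates = pd.to_datetime(records["date"], errors="coerce")
    if dates.isna().any():
        bad = records.index[dates.isna()][0]
        raise ValueError(f"unparseable date in row {bad!r}")
    year = dates.dt.year
    order = np.lexsort(
        (np.arange(len(records)), dates.values.astype("datetime64[ns]").astype(np.int64))
    )
    sorted_df = records.iloc[order]
    key = [
        sorted_df["band_id"],
        sorted_df["species"],
        sorted_df["location_id"],
        year.iloc[order],
    ]
    keep = ~pd.MultiIndex.from_arrays(key).duplicated(keep="first")
    return sorted_df.loc[keep].sort_index()


def mad_outlier_filter(
    values: np.ndarray, multiplier: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Indices kept/removed by the raw-MAD rule.

    A value is removed when |v - median| > multiplier * MAD, where MAD is the
    raw (unscaled, no consistency constant) median of absolute deviations
    from the median.  A zero MAD (at least half the values identical) removes
    nothing and emits a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad_outlier_filter: empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("mad_outlier_filter: values must be finite")
    if multiplier <= 0:
        raise ValueError("mad_outlier_filter: multiplier must be > 0")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    idx = np.arange(v.size)
    if mad == 0:
        warnings.warn("MAD is zero; no values removed", stacklevel=2)
        return idx, idx[:0]
    removed = np.abs(v - med) > multiplier * mad
    return idx[~removed], idx[removed]


def _mad_filter_groups(records: pd.DataFrame, trait: str, multiplier: float) -> pd.Index:
    """Index of rows surviving the per (species, station) MAD rule on one trait.

    The rule is iterated within each group until no value is outside the
    threshold of the surviving sample, so the overall cleaning pipeline is
    idempotent (a single pass leaves borderline values that a re-run would
    remove, because excluding outliers shifts the median and MAD slightly).
    """
    present = records[records[trait].notna()]
    keep_idx: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, grp in present.groupby(["species", "location_id"], sort=False):
            idx = grp.index.to_numpy()
            vals = grp[trait].to_numpy()
            while vals.size:
                kept, removed = mad_outlier_filter(vals, multiplier)
                idx, vals = idx[kept], vals[kept]
                if removed.size == 0:
                    break
            keep_idx.append(idx)
    if not keep_idx:
        return pd.Index([])
    return pd.Index(np.concatenate(keep_idx)).sort_values()


def apply_inclusion_criteria(
    records: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, dict]:
    """Sample-size and spatial-coverage thresholds, iterated to a fixed point.

    Drops (station, species) groups with fewer than
    ``min_individuals_per_location`` records; then species left with fewer
    than ``min_locations_per_species`` stations or whose surviving stations
    span less than ``min_latitude_span`` degrees of latitude.  Dropping
    groups can invalidate a species' coverage, so both rules are repeated
    until nothing changes.
    """
    df = records
    steps = []
    while True:
        n0 = len(df)
        counts = df.groupby(["species", "location_id"], sort=False)["band_id"].transform("size")
        df = df.loc[counts >= cfg.min_individuals_per_location]
        after_groups = len(df)
        per_species = df.groupby("species", sort=False).agg(
            n_locations=("location_id", "nunique"),
            lat_span=("latitude", lambda s: s.max() - s.min()),
        )
        good = per_species.index[
            (per_species["n_locations"] >= cfg.min_locations_per_species)
            & (per_species["lat_span"] >= cfg.min_latitude_span)
        ]
        df = df.loc[df["species"].isin(good)]
        steps.append(
            {
                "start": n0,
                "after_group_size_rule": after_groups,
                "after_species_coverage_rule": len(df),
            }
        )
        if len(df) == n0:
            break
    report = {"steps": steps, "n_in": len(records), "n_out": len(df)}
    return df, report


def apply_filters(
    records: pd.DataFrame,
    cfg: FilterConfig = FilterConfig(),
    trait: str = "mass",
) -> tuple[pd.DataFrame, dict]:
    """Full cleaning pipeline for one trait; returns (kept records, report).

    The report carries counts per step and the band ids excluded at each
    step, so recall against known contaminants can be computed.  Records
    missing the requested trait are dropped for this trait's pipeline (they
    remain usable for the other trait).
    """
    report: dict = {"trait": trait, "n_raw": len(records)}

    step1 = subset_adult_males(records, cfg.season_window)
    report["removed_not_adult_male"] = sorted(
        set(records["band_id"]) - set(step1["band_id"])
    )
    report["n_adult_male"] = len(step1)

    step2 = first_capture_per_season(step1)
    report["n_removed_repeat_capture"] = len(step1) - len(step2)
    report["n_first_capture"] = len(step2)

    step2 = step2[step2[trait].notna()]
    keep = _mad_filter_groups(step2, trait, cfg.mad_multiplier)
    step3 = step2.loc[keep]
    report["removed_outlier_band_ids"] = sorted(
        set(step2["band_id"]) - set(step3["band_id"])
    )
    report["n_after_outlier_filter"] = len(step3)

    step4, incl = apply_inclusion_criteria(step3, cfg)
    report["inclusion"] = incl
    report["n_final"] = len(step4)
    report["n_species_final"] = int(step4["species"].nunique())
    return step4, report
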