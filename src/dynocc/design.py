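"""Study-design data model and CSV input/output.

A dynamic-occupancy survey is organised in Pollock's robust design: months
(secondary periods) nested in seasons (primary periods).  The site state may
change between seasons but is assumed closed within a season.  This module
defines the containers for detection histories, sampling effort, site
covariates and the month-to-season mapping, plus the plain-CSV readers and
writers used by the command line tools.

Missing observations (camera not deployed, malfunction, survey gap) are kept
as NaN internally and as empty fields on disk, distinct from an observed 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HABITAT_LEVELS",
    "SEASON_LABELS",
    "DataValidationError",
    "DegenerateCovariateError",
    "SeasonStructure",
    "DetectionHistory",
    "SiteCovariates",
    "Dataset",
    "build_season_structure",
    "standardize",
    "read_dataset",
    "write_dataset",
    "load_dataset",
]

#: Allowed habitat classes; the first entry is the reference level for
#: treatment (reference-cell) coding.
HABITAT_LEVELS: tuple[str, ...] = ("broadleaf", "conifer", "mixed", "human_use")

#: Season labels; "summer" is the reference level.
SEASON_LABELS: tuple[str, str] = ("summer", "winter")

#: Canonical file names used by the directory-level convenience IO.
FILE_NAMES = {
    "detections": "detections.csv",
    "effort": "effort.csv",
    "covariates": "covariates.csv",
    "seasons": "seasons.csv",
}


class DataValidationError(ValueError):
    """A dataset component violates one of the design invariants."""


class DegenerateCovariateError(DataValidationError):
    """A continuous covariate cannot be standardized (zero variance)."""


# ---------------------------------------------------------------------------
# Season structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonStructure:
    """Mapping of month columns (secondary periods) to seasons (primary periods).

    Attributes
    ----------
    labels : tuple of str
        Season label ("summer" / "winter") per primary period.
    months_per_season : tuple of int
        Number of months in each primary period.
    """

    labels: tuple[str, ...]
    months_per_season: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.months_per_season):
            raise DataValidationError("labels and months_per_season differ in length")
        if len(self.labels) == 0:
            raise DataValidationError("season structure must contain at least one season")
        for lab in self.labels:
            if lab not in SEASON_LABELS:
                raise DataValidationError(f"unknown season label {lab!r}")
        for m in self.months_per_season:
            if int(m) < 1:
                raise DataValidationError("every season needs at least one month")

    @property
    def n_seasons(self) -> int:
        return len(self.labels)

    @property
    def n_months(self) -> int:
        return int(sum(self.months_per_season))

    @property
    def month_index(self) -> dict[int, tuple[int, int]]:
        """1-based global month -> (1-based season, 1-based within-season month)."""
        out: dict[int, tuple[int, int]] = {}
        g = 1
        for s, m in enumerate(self.months_per_season, start=1):
            for j in range(1, m + 1):
                out[g] = (s, j)
                g += 1
        return out

    def season_of_month(self) -> np.ndarray:
        """0-based season index for every month column (vectorized helper)."""
        return np.repeat(np.arange(self.n_seasons), self.months_per_season)

    def winter_indicator_months(self) -> np.ndarray:
        """1.0 for months falling in a winter season, 0.0 otherwise."""
        lab = np.asarray(self.labels)[self.season_of_month()]
        return (lab == "winter").astype(float)

    def winter_indicator_seasons(self) -> np.ndarray:
        return (np.asarray(self.labels) == "winter").astype(float)


def build_season_structure(
    n_summer: int,
    n_winter: int,
    summer_len: int,
    winter_len: int,
    first: str = "summer",
) -> SeasonStructure:
    """Build an alternating summer/winter season structure.

    Parameters
    ----------
    n_summer, n_winter : int
        Number of summer and winter primary periods.  They may differ by at
        most one (seasons alternate).
    summer_len, winter_len : int
        Months per summer and per winter season.
    first : {"summer", "winter"}
        Label of the first primary period.
    """
    for name, v in {
        "n_summer": n_summer, "n_winter": n_winter,
        "summer_len": summer_len, "winter_len": winter_len,
    }.items():
        if int(v) < 1:
            raise DataValidationError(f"{name} must be a positive count, got {v}")
    if first not in SEASON_LABELS:
        raise DataValidationError(f"first season must be one of {SEASON_LABELS}")
    if abs(n_summer - n_winter) > 1:
        raise DataValidationError("alternating seasons require |n_summer - n_winter| <= 1")

    counts = {"summer": int(n_summer), "winter": int(n_winter)}
    lens = {"summer": int(summer_len), "winter": int(winter_len)}
    labels: list[str] = []
    cur = first
    while counts["summer"] + counts["winter"] > 0:
        if counts[cur] == 0:
            raise DataValidationError(
                f"cannot alternate: ran out of {cur} seasons before the other label"
            )
        labels.append(cur)
        counts[cur] -= 1
        cur = "winter" if cur == "summer" else "summer"
    months = tuple(lens[lab] for lab in labels)
    return SeasonStructure(labels=tuple(labels), months_per_season=months)


# ---------------------------------------------------------------------------
# Covariate standardization
# ---------------------------------------------------------------------------

def standardize(values: Sequence[float]) -> np.ndarray:
    """Center and scale a covariate: subtract the mean, divide by the sample
    (n-1) standard deviation.

    Raises
    ------
    DegenerateCovariateError
        If fewer than two values are given or the values are constant.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DataValidationError("standardize expects a 1-d sequence")
    if x.size < 2:
        raise DegenerateCovariateError("need at least two values to standardize")
    if not np.all(np.isfinite(x)):
        raise DataValidationError("covariate contains non-finite values")
    sd = x.std(ddof=1)
    if sd <= 0.0:
        raise DegenerateCovariateError("covariate is constant; cannot standardize")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Detection history and covariates
# ---------------------------------------------------------------------------

@dataclass
class DetectionHistory:
    """Monthly detection/non-detection matrix with per-cell trapping effort.

    ``y`` holds 0 (not detected), 1 (detected) or NaN (month not sampled);
    ``effort`` holds camera-active days (NaN where the month is missing).
    """

    site_ids: tuple[str, ...]
    y: np.ndarray
    effort: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.effort = np.asarray(self.effort, dtype=float)
        ids = tuple(str(s) for s in self.site_ids)
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise DataValidationError(f"duplicated site_id(s): {dup}")
        self.site_ids = ids
        if self.y.shape != self.effort.shape:
            raise DataValidationError(
                f"y {self.y.shape} and effort {self.effort.shape} differ in shape"
            )
        if self.y.ndim != 2 or self.y.shape[0] != len(ids):
            raise DataValidationError("y must be (n_sites, n_months)")
        obs = ~np.isnan(self.y)
        vals = self.y[obs]
        if not np.all((vals == 0.0) | (vals == 1.0)):
            raise DataValidationError("observed y values must be 0 or 1")
        eff = self.effort
        eff_obs = eff[~np.isnan(eff)]
        if np.any(eff_obs < 0):
            raise DataValidationError("effort must be non-negative")
        if np.any(eff_obs != np.round(eff_obs)):
            raise DataValidationError("effort must be whole camera-days")
        # a detection requires at least one active camera-day
        bad = obs & (self.y == 1.0) & ~(eff >= 1.0)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise DataValidationError(
                f"site {ids[i]!r}, month {j + 1}: y=1 with effort "
                f"{eff[i, j]!r} (< 1 day)"
            )
        # a missing y cell must carry no effort
        bad = ~obs & (eff > 0)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise DataValidationError(
                f"site {ids[i]!r}, month {j + 1}: missing y but effort > 0"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_months(self) -> int:
        return int(self.y.shape[1])

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.y)


@dataclass
class SiteCovariates:
    """Per-site habitat class, continuous covariates and area membership.

    Continuous covariates are stored both raw and standardized; the
    standardization constants are kept so predictions can be annotated on
    the raw scale.
    """

    site_ids: tuple[str, ...]
    habitat: tuple[str, ...]
    elevation_raw: np.ndarray
    popden_raw: np.ndarray
    area: tuple[str, ...]
    elevation_std: np.ndarray = field(default=None)  # type: ignore[assignment]
    popden_std: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.site_ids)
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicated site_id in covariates")
        self.site_ids = ids
        self.habitat = tuple(str(h) for h in self.habitat)
        self.area = tuple(str(a) for a in self.area)
        n = len(ids)
        for h in self.habitat:
            if h not in HABITAT_LEVELS:
                raise DataValidationError(
                    f"unknown habitat label {h!r}; allowed: {HABITAT_LEVELS}"
                )
        self.elevation_raw = np.asarray(self.elevation_raw, dtype=float)
        self.popden_raw = np.asarray(self.popden_raw, dtype=float)
        if not (len(self.habitat) == n == len(self.area)
                == self.elevation_raw.size == self.popden_raw.size):
            raise DataValidationError("covariate columns differ in length")
        if self.elevation_std is None:
            self.elevation_std = standardize(self.elevation_raw) if n >= 2 else np.zeros(n)
        if self.popden_std is None:
            self.popden_std = standardize(self.popden_raw) if n >= 2 else np.zeros(n)
        self.elevation_std = np.asarray(self.elevation_std, dtype=float)
        self.popden_std = np.asarray(self.popden_std, dtype=float)
        if n >= 2:
            for name, col in (("elevation_std", self.elevation_std),
                              ("popden_std", self.popden_std)):
                if abs(col.mean()) > 1e-8 or abs(col.std(ddof=1) - 1.0) > 1e-8:
                    raise DataValidationError(f"{name} is not standardized")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def area_ids(self) -> tuple[str, ...]:
        """Sorted unique area identifiers (the random-effect grouping)."""
        return tuple(sorted(set(self.area)))

    def area_index(self) -> np.ndarray:
        """0-based index into :attr:`area_ids` for every site."""
        lookup = {a: k for k, a in enumerate(self.area_ids)}
        return np.asarray([lookup[a] for a in self.area], dtype=int)

    def habitat_contrasts(self) -> np.ndarray:
        """(n_sites, 3) treatment-coded habitat indicators (reference dropped)."""
        out = np.zeros((self.n_sites, len(HABITAT_LEVELS) - 1))
        for k, lev in enumerate(HABITAT_LEVELS[1:]):
            out[:, k] = [h == lev for h in self.habitat]
        return out

    @property
    def elevation_mean(self) -> float:
        return float(self.elevation_raw.mean())

    @property
    def elevation_sd(self) -> float:
        return float(self.elevation_raw.std(ddof=1)) if self.n_sites >= 2 else 1.0

    @property
    def popden_mean(self) -> float:
        return float(self.popden_raw.mean())

    @property
    def popden_sd(self) -> float:
        return float(self.popden_raw.std(ddof=1)) if self.n_sites >= 2 else 1.0


@dataclass
class Dataset:
    """A validated bundle of detection history, covariates and season map."""

    detection_history: DetectionHistory
    covariates: SiteCovariates
    seasons: SeasonStructure

    def __post_init__(self) -> None:
        dh, cov, ss = self.detection_history, self.covariates, self.seasons
        if dh.site_ids != cov.site_ids:
            raise DataValidationError("site_ids differ between detections and covariates")
        if dh.n_months != ss.n_months:
            raise DataValidationError(
                f"detection history has {dh.n_months} month columns but the "
                f"season structure defines {ss.n_months}"
            )

    @property
    def n_sites(self) -> int:
        return self.detection_history.n_sites

    @property
    def n_seasons(self) -> int:
        return self.seasons.n_seasons

    @property
    def n_months(self) -> int:
        return self.seasons.n_months

    def __eq__(self, other: object) -> bool:  # NaN-aware equality
        if not isinstance(other, Dataset):
            return NotImplemented
        a, b = self.detection_history, other.detection_history
        same = (
            a.site_ids == b.site_ids
            and a.y.shape == b.y.shape
            and np.array_equal(a.y, b.y, equal_nan=True)
            and np.array_equal(a.effort, b.effort, equal_nan=True)
            and self.covariates.habitat == other.covariates.habitat
            and self.covariates.area == other.covariates.area
            and np.allclose(self.covariates.elevation_raw,
                            other.covariates.elevation_raw, atol=0, rtol=1e-12)
            and np.allclose(self.covariates.popden_raw,
                            other.covariates.popden_raw, atol=0, rtol=1e-12)
            and self.seasons == other.seasons
        )
        return bool(same)


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

def _month_cols(n: int) -> list[str]:
    return [f"m{j:03d}" for j in range(1, n + 1)]


def _read_matrix(path: Path, what: str) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, dtype={"site_id": str})
    if "site_id" not in df.columns:
        raise DataValidationError(f"{what} file {path} lacks a site_id column")
    ids = tuple(df["site_id"].tolist())
    mat = df.drop(columns="site_id").to_numpy(dtype=float)
    return ids, mat


def read_dataset(
    detection_path: str | Path,
    effort_path: str | Path,
    covariates_path: str | Path,
    seasons_path: str | Path,
) -> Dataset:
    """Read and validate the four study CSV files into a :class:`Dataset`."""
    det_ids, y = _read_matrix(Path(detection_path), "detection")
    eff_ids, effort = _read_matrix(Path(effort_path), "effort")
    if det_ids != eff_ids:
        raise DataValidationError("site_id order differs between detections and effort")
    if y.shape != effort.shape:
        raise DataValidationError(
            f"detections {y.shape} and effort {effort.shape} differ in shape"
        )

    cov = pd.read_csv(covariates_path, dtype={"site_id": str, "area": str})
    required = {"site_id", "habitat", "elevation", "popden", "area"}
    missing = required - set(cov.columns)
    if missing:
        raise DataValidationError(f"covariates file lacks columns: {sorted(missing)}")

    sea = pd.read_csv(seasons_path)
    if not {"month", "season_index", "season_label"} <= set(sea.columns):
        raise DataValidationError("seasons file needs month,season_index,season_label")
    sea = sea.sort_values("month")
    if list(sea["month"]) != list(range(1, len(sea) + 1)):
        raise DataValidationError("seasons file must enumerate months 1..M")
    labels: list[str] = []
    months: list[int] = []
    for s_idx, grp in sea.groupby("season_index", sort=True):
        labs = set(grp["season_label"])
        if len(labs) != 1:
            raise DataValidationError(f"season {s_idx} has mixed labels {labs}")
        labels.append(grp["season_label"].iloc[0])
        months.append(len(grp))
    seasons = SeasonStructure(labels=tuple(labels), months_per_season=tuple(months))

    if y.shape[1] != seasons.n_months:
        raise DataValidationError(
            f"detection file has {y.shape[1]} month columns but the seasons "
            f"file defines {seasons.n_months} months"
        )

    dh = DetectionHistory(site_ids=det_ids, y=y, effort=effort)
    covariates = SiteCovariates(
        site_ids=tuple(cov["site_id"].tolist()),
        habitat=tuple(cov["habitat"].tolist()),
        elevation_raw=cov["elevation"].to_numpy(dtype=float),
        popden_raw=cov["popden"].to_numpy(dtype=float),
        area=tuple(cov["area"].tolist()),
    )
    return Dataset(detection_history=dh, covariates=covariates, seasons=seasons)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four study CSVs into ``out_dir``; returns the paths written.

    Missing cells are written as empty fields so that
    ``read_dataset(write_dataset(d)) == d``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dh, cov, ss = dataset.detection_history, dataset.covariates, dataset.seasons
    cols = _month_cols(dh.n_months)

    def matrix_frame(mat: np.ndarray, as_int: bool) -> pd.DataFrame:
        df = pd.DataFrame(mat, columns=cols)
        if as_int:
            df = df.astype("Int64")  # keeps NaN as empty field, values as ints
        df.insert(0, "site_id", list(dh.site_ids))
        return df

    paths = {k: out / v for k, v in FILE_NAMES.items()}
    matrix_frame(dh.y, as_int=True).to_csv(paths["detections"], index=False)
    matrix_frame(dh.effort, as_int=True).to_csv(paths["effort"], index=False)

    pd.DataFrame({
        "site_id": list(cov.site_ids),
        "habitat": list(cov.habitat),
        "elevation": cov.elevation_raw,
        "popden": cov.popden_raw,
        "area": list(cov.area),
    }).to_csv(paths["covariates"], index=False)

    rows = []
    for g, (s, _) in ss.month_index.items():
        rows.append({"month": g, "season_index": s, "season_label": ss.labels[s - 1]})
    pd.DataFrame(rows).to_csv(paths["seasons"], index=False)
    return paths


def load_dataset(directory: str | Path) -> Dataset:
    """Read a dataset from a directory using the canonical file names."""
    d = Path(directory)
    return read_dataset(
        d / FILE_NAMES["detections"],
        d / FILE_NAMES["effort"],
        d / FILE_NAMES["covariates"],
        d / FILE_NAMES["seasons"],
    )
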