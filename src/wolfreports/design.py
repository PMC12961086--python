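"""Observed/availability design construction.

The use-availability design contrasts the locations and dates of observed
reports (case = 1) with randomly sampled availability points (case = 0):
for every observed report, ``ratio`` random locations are drawn uniformly
inside the region boundary, given uniform random dates over the year, and
tagged with the observed report's reporter identity.  Covariates (zone S,
footprint H, province) are extracted from the landscape; the footprint is
z-transformed over all rows jointly and the harmonic seasonal terms are
attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .landscape import Landscape
from .occurrence import encode_season

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = [
    "case", "report_id", "reporter_id", "province", "J",
    "sin_t", "cos_t", "S", "H", "H_z",
]


@dataclass
class DesignMatrix:
    """Observed + availability rows with encoded covariates.

    ``df`` holds one row per point; availability rows carry the
    ``report_id`` and ``reporter_id`` of their paired observed report so
    cross-validation folds can keep pairs together.  The (mean, sd) used
    for the footprint z-transform are stored so new data can be placed on
    the training scale.
    """

    df: pd.DataFrame
    ratio: int
    h_mean: float
    h_sd: float
    n_zones: int = 5

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_observed(self) -> int:
        return int((self.df["case"] == 1).sum())

    def validate(self) -> None:
        df = self.df
        n_obs = int((df["case"] == 1).sum())
        if len(df) != n_obs * (1 + self.ratio):
            raise ValueError("row count must equal n_observed * (1 + ratio)")
        per = df[df["case"] == 0].groupby("report_id").size()
        if n_obs and (len(per) != n_obs or (per != self.ratio).any()):
            raise ValueError("each observed row needs exactly `ratio` availability rows")
        pair = df.groupby("report_id")["reporter_id"].nunique()
        if (pair != 1).any():
            raise ValueError("availability rows must share their observed row's reporter_id")

    def subset(self, report_ids) -> "DesignMatrix":
        """Rows of the given observed reports (availability rows included).

        Keeps the parent's ratio and standardization scale."""
        sub = self.df[self.df["report_id"].isin(report_ids)].reset_index(drop=True)
        return DesignMatrix(sub, self.ratio, self.h_mean, self.h_sd, self.n_zones)


def sample_availability(
    boundary: Polygon, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Sample n points uniformly inside the polygon (bounding-box rejection)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if boundary.is_empty or boundary.area <= 0:
        raise ValueError("boundary polygon is degenerate")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = boundary.bounds
    frac = boundary.area / ((maxx - minx) * (maxy - miny))
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = int((n - len(pts)) / max(frac, 1e-3) * 1.2) + 16
        x = rng.uniform(minx, maxx, size=m)
        y = rng.uniform(miny, maxy, size=m)
        keep = shapely.contains_xy(boundary, x, y)
        pts = np.vstack([pts, np.column_stack([x[keep], y[keep]])])
    return pts[:n]


def assign_random_dates(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform random Julian days on the integers 1..365."""
    rng = np.random.default_rng(seed)
    return rng.integers(1, 366, size=n)


def extract_covariates(points: np.ndarray, landscape: Landscape) -> pd.DataFrame:
    """Zone S, footprint H and province of each point's containing cell.

    Raises for points outside the region boundary; points in unlabelled
    rim cells fall back to the nearest labelled cell with a logged count.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = points[:, 0], points[:, 1]
    inside = landscape.contains(x, y)
    if not inside.all():
        i = int(np.nonzero(~inside)[0][0])
        raise ValueError(f"point {i} at ({x[i]:.1f}, {y[i]:.1f}) is outside the boundary")
    H, S, prov, n_fallback = landscape.covariates_at(x, y)
    if n_fallback:
        logger.warning("%d point(s) resolved to nearest labelled cell", n_fallback)
    return pd.DataFrame({"S": S, "H": H, "province": prov})


def zscore(values) -> tuple[np.ndarray, float, float]:
    """Standardize to mean 0, sd 1 (sample sd); returns (z, mean, sd)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to standardize")
    m = float(np.mean(v))
    s = float(np.std(v, ddof=1))
    if s == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - m) / s, m, s


def build_design(
    observed: pd.DataFrame,
    landscape: Landscape,
    ratio: int = 11,
    seed: int | np.random.Generator = 0,
) -> DesignMatrix:
    """Build the observed/availability design matrix.

    For each observed report one case=1 row (its own date and location)
    plus ``ratio`` case=0 rows with fresh uniform locations and dates,
    sharing the observed report's reporter identity.  H is z-transformed
    jointly over all rows.
    """
    if int(ratio) != ratio or ratio < 1:
        raise ValueError("ratio must be an integer >= 1")
    ratio = int(ratio)
    rng = np.random.default_rng(seed)
    n_obs = len(observed)

    obs_pts = observed[["x", "y"]].to_numpy(float)
    obs_cov = extract_covariates(obs_pts, landscape)
    obs_df = pd.DataFrame(
        {
            "case": 1,
            "report_id": observed["id"].to_numpy(),
            "reporter_id": observed["reporter_id"].to_numpy(),
            "province": obs_cov["province"].to_numpy(),
            "J": observed["date"].to_numpy(int),
            "S": obs_cov["S"].to_numpy(),
            "H": obs_cov["H"].to_numpy(),
        }
    )

    n_avail = n_obs * ratio
    pts = sample_availability(landscape.boundary, n_avail, rng)
    dates = assign_random_dates(n_avail, rng)
    av_cov = extract_covariates(pts, landscape)
    av_df = pd.DataFrame(
        {
            "case": 0,
            "report_id": np.repeat(observed["id"].to_numpy(), ratio),
            "reporter_id": np.repeat(observed["reporter_id"].to_numpy(), ratio),
            "province": av_cov["province"].to_numpy(),
            "J": dates,
            "S": av_cov["S"].to_numpy(),
            "H": av_cov["H"].to_numpy(),
        }
    )

    df = pd.concat([obs_df, av_df], ignore_index=True)
    df["sin_t"], df["cos_t"] = encode_season(df["J"].to_numpy())
    hz, m, s = zscore(df["H"].to_numpy())
    df["H_z"] = hz
    return DesignMatrix(df[DESIGN_COLUMNS], ratio, m, s, landscape.n_zones)


@dataclass
class CollinearityReport:
    covariates: list[str]
    pearson: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    flagged_vif: list[tuple[str, float]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flagged_pairs and not self.flagged_vif


def screen_collinearity(
    df: pd.DataFrame,
    covariates: list[str],
    r_threshold: float = 0.7,
    vif_threshold: float = 3.0,
) -> CollinearityReport:
    """Pairwise Pearson |r| and VIF screen for the model covariates.

    Flags any pair with |r| >= 0.7 and any covariate with VIF >= 3; VIF
    is 1/(1-R^2) from regressing each covariate on the others (with
    intercept).
    """
    if len(covariates) < 2:
        raise ValueError("need at least 2 covariates to screen")
    X = df[list(covariates)].to_numpy(float)
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant covariate in collinearity screen")
    r = np.corrcoef(X, rowvar=False)
    pearson = pd.DataFrame(r, index=covariates, columns=covariates)
    flagged_pairs = [
        (covariates[i], covariates[j], float(r[i, j]))
        for i in range(len(covariates))
        for j in range(i + 1, len(covariates))
        if abs(r[i, j]) >= r_threshold
    ]
    vifs = {}
    n = len(X)
    for j, name in enumerate(covariates):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        resid = yj - Z @ np.linalg.lstsq(Z, yj, rcond=None)[0]
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        vifs[name] = 1.0 / max(1.0 - r2, 1e-12)
    vif = pd.Series(vifs)
    flagged_vif = [(k, float(v)) for k, v in vif.items() if v >= vif_threshold]
    return CollinearityReport(list(covariates), pearson, vif, flagged_pairs, flagged_vif)
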