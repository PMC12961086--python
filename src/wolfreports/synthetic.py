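"""Simulate citizen wolf reports from a known generative model.

Reports are drawn from a log-linear space-time intensity

    log lambda(x, J) = beta0 + beta_sin sin(theta) + beta_cos cos(theta)
                       + gamma[S(x)] + beta_H H(x) + beta_H2 H(x)^2,

with theta = 2 pi J / 365, S the recolonization zone and H the human
footprint of the cell containing x.  The ground-truth parameters are kept
so the fitting modules can be checked for parameter recovery.  Reporter
identities follow a truncated geometric multiplicity distribution
calibrated to a target singleton share, and valence labels come from a
logistic model with a tabulated nonlinear footprint effect g(H) plus
ordinal zone offsets, with a configurable neutral (unlabelled) fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .landscape import Landscape

REPORT_COLUMNS = ["id", "reporter_id", "date", "x", "y", "text", "channel", "valence"]


@dataclass
class GenerativeTruth:
    """True parameters of the synthetic report-generating model.

    ``gamma`` has one entry per zone with ``gamma[0] = 0`` as the
    reference (earliest-colonized zone).  ``beta_H`` / ``beta_H2`` act on
    the raw footprint index (0-50).  ``valence_shape`` tabulates the
    nonlinear footprint effect g(H) on ``valence_grid`` over the full
    footprint range; intermediate values are linearly interpolated.
    """

    beta0: float = 0.0
    beta_sin: float = 0.468
    beta_cos: float = 0.289
    gamma: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.74, 1.77, 1.56, 2.33]))
    beta_H: float = 0.105
    beta_H2: float = -0.0012
    valence_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 50.0, 101))
    valence_shape: np.ndarray = field(
        default_factory=lambda: -0.8 + 1.6 * expit((np.linspace(0.0, 50.0, 101) - 20.0) / 6.0)
    )
    valence_zone: np.ndarray = field(default_factory=lambda: np.array([0.4, 0.1, 0.0, -0.1, -0.3]))
    singleton_frac: float = 0.473
    neutral_frac: float = 0.495

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.valence_zone = np.asarray(self.valence_zone, dtype=float)
        self.valence_grid = np.asarray(self.valence_grid, dtype=float)
        self.valence_shape = np.asarray(self.valence_shape, dtype=float)
        if self.gamma[0] != 0.0:
            raise ValueError("gamma[0] must be 0 (reference zone)")
        if self.valence_grid.shape != self.valence_shape.shape:
            raise ValueError("valence_grid and valence_shape must align")

    @property
    def n_zones(self) -> int:
        return len(self.gamma)

    def g(self, H) -> np.ndarray:
        """Nonlinear valence footprint effect, interpolated from the table."""
        return np.interp(np.asarray(H, dtype=float), self.valence_grid, self.valence_shape)

    def seasonal_logterm(self, J) -> np.ndarray:
        theta = 2.0 * np.pi * np.asarray(J, dtype=float) / 365.0
        return self.beta_sin * np.sin(theta) + self.beta_cos * np.cos(theta)

    def spatial_logterm(self, H, S) -> np.ndarray:
        H = np.asarray(H, dtype=float)
        S = np.asarray(S, dtype=int)
        return self.gamma[S - 1] + self.beta_H * H + self.beta_H2 * H**2

    def log_intensity(self, H, S, J) -> np.ndarray:
        return self.beta0 + self.seasonal_logterm(J) + self.spatial_logterm(H, S)

    @property
    def seasonal_peak_day(self) -> float:
        """Julian day at which the seasonal component is maximal."""
        phase = np.arctan2(self.beta_sin, self.beta_cos)  # theta of the peak
        day = (phase % (2.0 * np.pi)) * 365.0 / (2.0 * np.pi)
        return float(day)


def default_truth(**overrides) -> GenerativeTruth:
    """The default study conditions: late-winter seasonal peak (amplitude
    ~0.55, about a threefold trough-to-peak ratio), report occurrence
    increasing across recolonization steps, and a footprint effect rising
    to a maximum in the low-to-mid 40s of the 0-50 index."""
    return GenerativeTruth(**overrides)


def simulate_reports(
    landscape: Landscape,
    truth: GenerativeTruth,
    n_reports: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw reports by rejection sampling against sup lambda.

    Proposals are uniform over (in-boundary cell, day 1..365) and accepted
    with probability lambda / sup lambda; accepted reports get a uniform
    position within their cell (re-jittered to stay inside the boundary).
    Exactly ``n_reports`` records are returned, deterministic per seed.
    """
    if n_reports < 0:
        raise ValueError("n_reports must be >= 0")
    if truth.n_zones != landscape.n_zones:
        raise ValueError(
            f"truth has {truth.n_zones} zones but landscape has {landscape.n_zones}"
        )
    rng = np.random.default_rng(seed)
    cols = ["id", "reporter_id", "date", "x", "y"]
    if n_reports == 0:
        return pd.DataFrame({c: [] for c in cols})

    inside = landscape.inside_mask()
    H = landscape.footprint[inside]
    S = landscape.zone[inside]
    cx, cy = landscape.cell_centers()
    cx, cy = cx[inside], cy[inside]
    s_spatial = truth.spatial_logterm(H, S)
    days = np.arange(1, 366)
    s_time = truth.seasonal_logterm(days)
    log_sup = s_spatial.max() + s_time.max()

    n_cells = len(H)
    accept_rate = float(np.mean(np.exp(s_spatial - s_spatial.max()))) * float(
        np.mean(np.exp(s_time - s_time.max()))
    )
    xs, ys, js = [], [], []
    remaining = n_reports
    while remaining > 0:
        m = int(remaining / max(accept_rate, 1e-3) * 1.2) + 64
        ci = rng.integers(0, n_cells, size=m)
        di = rng.integers(0, 365, size=m)
        logp = s_spatial[ci] + s_time[di] - log_sup
        keep = rng.random(m) < np.exp(logp)
        ci, di = ci[keep][:remaining], di[keep][:remaining]
        if len(ci) == 0:
            continue
        # uniform position within the accepted cell, kept inside the boundary
        half = landscape.cell_m / 2.0
        px = cx[ci] + rng.uniform(-half, half, size=len(ci))
        py = cy[ci] + rng.uniform(-half, half, size=len(ci))
        ok = landscape.contains(px, py)
        for _ in range(20):
            if ok.all():
                break
            bad = ~ok
            px[bad] = cx[ci[bad]] + rng.uniform(-half, half, size=bad.sum())
            py[bad] = cy[ci[bad]] + rng.uniform(-half, half, size=bad.sum())
            ok = landscape.contains(px, py)
        # cell centers are inside by construction; use them as a last resort
        bad = ~ok
        px[bad], py[bad] = cx[ci[bad]], cy[ci[bad]]
        xs.append(px)
        ys.append(py)
        js.append(days[di])
        remaining -= len(ci)

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    J = np.concatenate(js)
    return pd.DataFrame(
        {
            "id": [f"rep{i:06d}" for i in range(n_reports)],
            "reporter_id": [""] * n_reports,
            "date": J.astype(int),
            "x": x,
            "y": y,
        }
    )


def assign_reporters(
    reports: pd.DataFrame,
    singleton_frac: float = 0.473,
    seed: int | np.random.Generator = 0,
    max_multiplicity: int = 50,
) -> pd.DataFrame:
    """Assign reporter identities with a calibrated singleton share.

    Reporter multiplicities are drawn from a geometric distribution
    (truncated at ``max_multiplicity``) whose success parameter is chosen
    so that the expected share of *reports* contributed by single-report
    reporters equals ``singleton_frac``: for multiplicity M ~ Geom(1-q) on
    {1, 2, ...}, that share is P(M=1)/E[M] = (1-q)^2, so q = 1 - sqrt(s).
    """
    if not 0.0 < singleton_frac <= 1.0:
        raise ValueError("singleton_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(reports)
    out = reports.copy()
    if n == 0:
        out["reporter_id"] = pd.Series([], dtype=str)
        return out
    q = 1.0 - np.sqrt(singleton_frac)
    sizes: list[int] = []
    total = 0
    while total < n:
        m = int(rng.geometric(1.0 - q)) if q > 0 else 1
        m = min(m, max_multiplicity)
        sizes.append(m)
        total += m
    sizes[-1] -= total - n  # trim the last reporter to land exactly on n
    labels = np.repeat([f"obs{i:05d}" for i in range(len(sizes))], sizes)
    out["reporter_id"] = labels[rng.permutation(n)]
    return out


def simulate_valence(
    reports: pd.DataFrame,
    landscape: Landscape,
    truth: GenerativeTruth,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Label reports negative/positive/neutral from the valence model.

    A ``truth.neutral_frac`` share of reports is labelled neutral at
    random (reports without emotional content); the rest are negative
    with probability expit(g(H) + valence_zone[S]) and positive otherwise.
    """
    rng = np.random.default_rng(seed)
    out = reports.copy()
    if len(out) == 0:
        out["valence"] = pd.Series([], dtype=str)
        return out
    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    if not landscape.contains(x, y).all():
        raise ValueError("all reports must lie inside the landscape boundary")
    H, S, _, _ = landscape.covariates_at(x, y)
    p_neg = expit(truth.g(H) + truth.valence_zone[S - 1])
    neutral = rng.random(len(out)) < truth.neutral_frac
    negative = rng.random(len(out)) < p_neg
    labels = np.where(neutral, "neutral", np.where(negative, "negative", "positive"))
    out["valence"] = labels
    return out
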