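"""Penalized-spline binomial model of report valence.

The probability that a report expresses negative valence is modelled as

    logit P(negative) = f(H_z) + ordinal zone contrasts [+ s(x, y)],

where f is a penalized cubic B-spline (default basis dimension k = 25,
second-order difference penalty) standing in for an adaptive smooth, and
s is an optional low-rank thin-plate radial smoother of the report
coordinates (default k = 40) that absorbs residual spatial correlation.
The smoothing weight is chosen on a log-spaced grid by AIC with effective
degrees of freedom equal to the trace of the hat matrix.  Accuracy is
summarized by the AUC over repeated stratified 70/30 train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.special import expit
from sklearn.cluster import KMeans

from ._glmfit import irls
from .occurrence import ordinal_contrasts


@dataclass
class SplineSpec:
    """Basis and penalty configuration of the valence model.

    ``smoothing_grid`` is the set of candidate penalty weights searched
    by AIC (positive, log-spaced).  ``include_spatial`` switches the
    bivariate coordinate smoother on; ``include_zones`` the ordinal
    recolonization contrasts.
    """

    k_footprint: int = 25
    k_spatial: int = 40
    penalty_order: int = 2
    smoothing_grid: np.ndarray = field(default_factory=lambda: np.logspace(-2, 4, 7))
    include_zones: bool = True
    include_spatial: bool = False
    n_zones: int = 5

    def __post_init__(self) -> None:
        self.smoothing_grid = np.asarray(self.smoothing_grid, dtype=float)
        if self.k_footprint < 4:
            raise ValueError("k_footprint must be >= 4 (cubic B-splines)")
        if np.any(self.smoothing_grid <= 0):
            raise ValueError("smoothing_grid must be positive")


def build_spline_basis(x, k: int, penalty_order: int = 2):
    """Cubic B-spline basis on quantile-spaced knots + difference penalty.

    Returns (B, P, knots): the (n, k) basis matrix, the (k, k) penalty
    matrix D'D built from order-``penalty_order`` coefficient differences,
    and the full knot vector.  Basis rows sum to 1 (partition of unity);
    coefficient vectors linear in x lie in the null space of an order-2
    penalty.
    """
    x = np.asarray(x, dtype=float)
    if k < 4:
        raise ValueError("k must be >= 4")
    n_distinct = len(np.unique(x))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct x values ({n_distinct})")
    lo, hi = float(x.min()), float(x.max())
    n_interior = k - 4
    if n_interior > 0:
        interior = np.quantile(x, np.arange(1, n_interior + 1) / (n_interior + 1))
        interior = interior + np.linspace(0, 1e-9, n_interior)  # break exact ties
        if interior.min() <= lo or interior.max() >= hi or np.any(np.diff(interior) <= 0):
            raise ValueError("x is too discrete for the requested basis dimension")
        t = np.r_[[lo] * 4, interior, [hi] * 4]
    else:
        t = np.r_[[lo] * 4, [hi] * 4]
    B = _eval_basis(x, t)
    D = np.diff(np.eye(k), n=penalty_order, axis=0)
    return B, D.T @ D, t


def _eval_basis(x, t) -> np.ndarray:
    """Evaluate the basis at x, clipping to the knot range (no extrapolation)."""
    xc = np.clip(np.asarray(x, dtype=float), t[3], t[-4])
    return BSpline.design_matrix(xc, t, 3, extrapolate=False).toarray()


def auc(scores, labels) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Equals the probability that a random positive outscores a random
    negative, counting ties as half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


class ValenceModel:
    """Penalized-spline binomial model of negative-valence probability.

    Parameters
    ----------
    data : DataFrame with columns ``negative`` (binary response), ``H_z``
        (standardized footprint), ``S`` (zone ordinal) and, when the
        spatial smoother is enabled, coordinates ``x`` and ``y``.
    spec : SplineSpec.
    """

    def __init__(self, data: pd.DataFrame, spec: SplineSpec | None = None):
        self.spec = spec if spec is not None else SplineSpec()
        self.data = data
        y = data["negative"].to_numpy(float)
        if y.min() == y.max():
            raise ValueError("both valence classes must be present")
        self.y = y
        B, P, t = build_spline_basis(
            data["H_z"].to_numpy(float), self.spec.k_footprint, self.spec.penalty_order
        )
        self.knots = t
        self._blocks: list[np.ndarray] = [B]
        self._pens: list[np.ndarray | None] = [P]
        if self.spec.include_zones:
            C = ordinal_contrasts(self.spec.n_zones)
            S = data["S"].to_numpy(int)
            self._contrasts = C
            self._blocks.append(C[S - 1, :])
            self._pens.append(None)  # parametric terms are unpenalized
        if self.spec.include_spatial:
            coords = data[["x", "y"]].to_numpy(float)
            km = KMeans(n_clusters=self.spec.k_spatial, n_init=1, random_state=0)
            km.fit(coords)
            self._centers = km.cluster_centers_
            d = np.linalg.norm(
                self._centers[:, None, :] - self._centers[None, :, :], axis=-1
            )
            self._rbf_scale = np.median(d[d > 0])
            R = self._rbf(coords)
            self._blocks.append(R)
            self._pens.append(np.eye(self.spec.k_spatial))
        self.X = np.column_stack(self._blocks)

    def _rbf(self, coords) -> np.ndarray:
        """Thin-plate radial basis r^2 log r on the k-means centers."""
        r = np.linalg.norm(coords[:, None, :] - self._centers[None, :, :], axis=-1)
        r = r / self._rbf_scale
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(r > 0, r**2 * np.log(r), 0.0)
        return R

    def _penalty(self, lambdas) -> np.ndarray:
        S = []
        i = 0
        for block, pen in zip(self._blocks, self._pens):
            k = block.shape[1]
            if pen is None:
                S.append(np.zeros((k, k)))
            else:
                S.append(lambdas[i] * pen)
                i += 1
        out = np.zeros((self.X.shape[1], self.X.shape[1]))
        ofs = 0
        for s in S:
            k = s.shape[0]
            out[ofs : ofs + k, ofs : ofs + k] = s
            ofs += k
        return out

    def fit(self) -> "ValenceResults":
        """Penalized IRLS with AIC-guided penalty-weight selection."""
        n_smooth = sum(p is not None for p in self._pens)
        grid = self.spec.smoothing_grid
        combos = (
            [(l,) for l in grid]
            if n_smooth == 1
            else [(l1, l2) for l1 in grid for l2 in grid]
        )
        path = []
        best = None
        for lam in combos:
            res = irls(self.X, self.y, penalty=self._penalty(lam))
            aic = -2.0 * res.llf + 2.0 * res.edf
            path.append({"lambda": lam, "aic": aic, "edf": res.edf, "llf": res.llf})
            if res.converged and (best is None or aic < best[0]):
                best = (aic, lam, res)
        if best is None:
            raise RuntimeError("no penalty weight produced a converged fit")
        aic, lam, res = best
        return ValenceResults(self, res, lam, aic, pd.DataFrame(path))


class ValenceResults:
    """Fitted valence model: coefficients, AIC, smooth-curve predictions."""

    def __init__(self, model: ValenceModel, res, lambdas, aic: float, aic_path: pd.DataFrame):
        self.model = model
        self._res = res
        self.lambdas = lambdas
        self.aic = float(aic)
        self.aic_path = aic_path
        self.coef = res.coef
        self.edf = float(res.edf)
        self.llf = float(res.llf)
        self.fitted = res.fitted
        self.converged = res.converged

    @property
    def spline_coefficients(self) -> np.ndarray:
        return self.coef[: self.model.spec.k_footprint]

    @property
    def zone_effects(self) -> np.ndarray:
        k = self.model.spec.k_footprint
        if not self.model.spec.include_zones:
            return np.array([])
        return self.coef[k : k + self.model.spec.n_zones - 1]

    def smooth_curve(self, hz_grid) -> np.ndarray:
        """Footprint smooth f(H_z) on a grid (centered to mean zero)."""
        B = _eval_basis(np.asarray(hz_grid, dtype=float), self.model.knots)
        f = B @ self.spline_coefficients
        return f - f.mean()

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        """P(negative) for new reports on the training basis/centers."""
        blocks = [_eval_basis(data["H_z"].to_numpy(float), self.model.knots)]
        if self.model.spec.include_zones:
            C = self.model._contrasts
            blocks.append(C[data["S"].to_numpy(int) - 1, :])
        if self.model.spec.include_spatial:
            blocks.append(self.model._rbf(data[["x", "y"]].to_numpy(float)))
        X = np.column_stack(blocks)
        return expit(X @ self.coef)

    def summary(self) -> str:
        lam = ", ".join(f"{l:g}" for l in np.atleast_1d(self.lambdas))
        lines = [
            "Valence model (binomial penalized spline)",
            f"  n: {len(self.model.y)}   edf: {self.edf:.2f}   AIC: {self.aic:.2f}   "
            f"lambda: [{lam}]   converged: {self.converged}",
        ]
        if self.model.spec.include_zones:
            z = ", ".join(f"{v:.3f}" for v in self.zone_effects)
            lines.append(f"  zone contrasts: [{z}]")
        return "\n".join(lines)


def repeated_split_auc(
    data: pd.DataFrame,
    spec: SplineSpec | None = None,
    n_rep: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Mean +/- sd of test AUC over repeated stratified train/test splits.

    Each repetition splits the data ``train_frac``/(1 - train_frac) within
    class (so both classes appear in train and test), refits the valence
    model on the training part and evaluates the AUC on the test part.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    spec = spec if spec is not None else SplineSpec()
    rng = np.random.default_rng(seed)
    y = data["negative"].to_numpy(int)
    idx1 = np.nonzero(y == 1)[0]
    idx0 = np.nonzero(y == 0)[0]
    if min(len(idx0), len(idx1)) < 2:
        raise ValueError("each class needs at least 2 members for stratified splits")
    aucs = np.empty(n_rep)
    for r in range(n_rep):
        tr = np.concatenate(
            [
                rng.permutation(idx1)[: max(1, int(round(train_frac * len(idx1))))],
                rng.permutation(idx0)[: max(1, int(round(train_frac * len(idx0))))],
            ]
        )
        te = np.setdiff1d(np.arange(len(y)), tr)
        res = ValenceModel(data.iloc[tr], spec).fit()
        scores = res.predict_proba(data.iloc[te])
        aucs[r] = auc(scores, y[te])
    return float(aucs.mean()), float(aucs.std(ddof=1)), aucs
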