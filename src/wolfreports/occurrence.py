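"""Binomial occurrence model for the observed/availability design.

The model regresses the case indicator (1 = observed report, 0 =
availability point) on harmonic seasonal terms, orthogonal polynomial
contrasts of the ordinal recolonization step, and linear + quadratic
standardized human footprint, with a logit link.  In a use-availability
design the slope coefficients estimate the log-linear relative-occurrence
(resource-selection) function; the intercept reflects the availability
ratio and carries no ecological meaning.

Grouping structure (reporter identity, province) can be absorbed through
optional random intercepts fitted by Laplace-type penalized likelihood;
likelihood-ratio bookkeeping counts fixed-effect parameters only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._glmfit import irls, IRLSFit

_CONTRAST_SUFFIX = ["lin", "quad", "cub", "quart", "pent", "hex"]


def encode_season(J):
    """Harmonic encoding of Julian day: theta = 2*pi*J/365 -> (sin, cos)."""
    J = np.asarray(J, dtype=float)
    if np.any((J < 1) | (J > 365)):
        raise ValueError("Julian day must be in [1, 365]")
    theta = 2.0 * np.pi * J / 365.0
    return np.sin(theta), np.cos(theta)


def ordinal_contrasts(n_levels: int, scores=None) -> np.ndarray:
    """Orthonormal polynomial contrasts for an ordered factor.

    Columns are degree 1..n_levels-1 polynomial contrasts on the level
    scores (equally spaced 1..n by default; pass e.g. calendar years for
    unequal spacing).  Columns are unit-norm, sum to zero and are
    mutually orthogonal; the linear column increases with level order.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels for contrasts")
    x = np.arange(1, n_levels + 1, dtype=float) if scores is None else np.asarray(scores, float)
    if len(x) != n_levels:
        raise ValueError("scores length must equal n_levels")
    V = np.vander(x - x.mean(), N=n_levels, increasing=True)
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:]
    # sign convention: highest level loads positively on every contrast
    C = C * np.sign(C[-1, :])
    return C


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms and optional grouping factors of the model."""

    season: bool = True
    recolonization: bool = True
    footprint: bool = True
    footprint_sq: bool = True
    n_zones: int = 5
    zone_scores: tuple | None = None  # e.g. calendar recolonization years
    random_intercepts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.footprint_sq and not self.footprint:
            raise ValueError("quadratic footprint requires the linear term")

    def term_names(self) -> list[str]:
        names = ["intercept"]
        if self.season:
            names += ["sin_t", "cos_t"]
        if self.recolonization:
            names += [
                f"S_{_CONTRAST_SUFFIX[d]}" if d < len(_CONTRAST_SUFFIX) else f"S_deg{d+1}"
                for d in range(self.n_zones - 1)
            ]
        if self.footprint:
            names += ["H_z"]
        if self.footprint_sq:
            names += ["H_z2"]
        return names

    @property
    def n_params(self) -> int:
        return len(self.term_names())


def build_model_matrix(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effects model matrix from a design-row table."""
    cols = [np.ones(len(df))]
    if spec.season:
        cols += [df["sin_t"].to_numpy(float), df["cos_t"].to_numpy(float)]
    if spec.recolonization:
        C = ordinal_contrasts(spec.n_zones, spec.zone_scores)
        S = df["S"].to_numpy(int)
        if S.min() < 1 or S.max() > spec.n_zones:
            raise ValueError("zone index outside the model's ordinal range")
        cols += [C[S - 1, d] for d in range(spec.n_zones - 1)]
    if spec.footprint:
        cols += [df["H_z"].to_numpy(float)]
    if spec.footprint_sq:
        cols += [df["H_z"].to_numpy(float) ** 2]
    return np.column_stack(cols), spec.term_names()


class OccurrenceModel:
    """Binomial-logit use-availability occurrence model.

    Parameters
    ----------
    design : DesignMatrix or DataFrame with the design-row columns
        (case, J, sin_t, cos_t, S, H_z, plus grouping columns).
    spec : ModelSpec describing the fixed-effect terms and any random
        intercepts.
    """

    def __init__(self, design, spec: ModelSpec | None = None):
        from .design import DesignMatrix  # local import to avoid a cycle

        if isinstance(design, DesignMatrix):
            self.df = design.df
            self.h_mean, self.h_sd = design.h_mean, design.h_sd
        else:
            self.df = design
            self.h_mean, self.h_sd = float("nan"), float("nan")
        self.spec = spec if spec is not None else ModelSpec()
        if len(self.df) == 0:
            raise ValueError("design is empty")
        y = self.df["case"].to_numpy()
        if y.min() == y.max():
            raise ValueError("design must contain both observed and availability rows")
        self.X, self.names = build_model_matrix(self.df, self.spec)
        self.y = y.astype(float)

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> "OccurrenceResults":
        spec = self.spec
        if not spec.random_intercepts:
            res = irls(self.X, self.y, max_iter=max_iter, tol=tol)
            return OccurrenceResults(self, res, self.X.shape[1])
        return self._fit_random(max_iter, tol)

    def _fit_random(self, max_iter: int, tol: float) -> "OccurrenceResults":
        """Random intercepts by Laplace-type penalized likelihood.

        Group deviations are ridge-penalized dummy coefficients; each
        factor's variance is chosen on a log grid by coordinate descent
        on the Laplace approximation to the marginal likelihood.
        """
        Zs, sizes = [], []
        for fac in self.spec.random_intercepts:
            codes, _ = pd.factorize(self.df[fac])
            q = codes.max() + 1
            Z = np.zeros((len(self.df), q))
            Z[np.arange(len(self.df)), codes] = 1.0
            Zs.append(Z)
            sizes.append(q)
        Xfull = np.column_stack([self.X] + Zs)
        p = self.X.shape[1]
        grid = np.array([0.05, 0.2, 0.5, 1.0, 2.0])
        sigmas = np.ones(len(Zs))

        def laplace_fit(sig):
            diag = np.concatenate(
                [np.zeros(p)] + [np.full(q, 1.0 / s**2) for q, s in zip(sizes, sig)]
            )
            res = irls(Xfull, self.y, penalty=np.diag(diag), max_iter=max_iter, tol=tol)
            u = res.coef[p:]
            pen = 0.5 * float(np.sum(diag[p:] * u**2))
            # logdet(I + D Z'WZ) via the penalized-information factorization
            w = np.clip(res.fitted * (1 - res.fitted), 1e-10, None)
            Zall = Xfull[:, p:]
            ZtWZ = (Zall.T * w) @ Zall
            D = np.diag(1.0 / diag[p:])
            sign, logdet = np.linalg.slogdet(np.eye(len(u)) + D @ ZtWZ)
            crit = res.llf - pen - 0.5 * logdet
            return res, crit

        best_res, best_crit = laplace_fit(sigmas)
        for _ in range(2):
            for i in range(len(sigmas)):
                for s in grid:
                    trial = sigmas.copy()
                    trial[i] = s
                    res, crit = laplace_fit(trial)
                    if crit > best_crit:
                        best_crit, best_res, sigmas = crit, res, trial
        return OccurrenceResults(self, best_res, p, random_sd=tuple(sigmas))


class OccurrenceResults:
    """Estimates, uncertainty and diagnostics of a fitted occurrence model."""

    def __init__(
        self,
        model: OccurrenceModel,
        res: IRLSFit,
        n_fixed: int,
        random_sd: tuple[float, ...] = (),
    ):
        self.model = model
        self._res = res
        self.n_fixed = n_fixed
        self.random_sd = random_sd
        self.params = pd.Series(res.coef[:n_fixed], index=model.names)
        self.vcov = pd.DataFrame(
            res.vcov[:n_fixed, :n_fixed], index=model.names, columns=model.names
        )
        self.bse = pd.Series(np.sqrt(np.diag(self.vcov)), index=model.names)
        self.llf = res.llf
        self.df_model = n_fixed  # fixed-effect parameter count
        self.nobs = len(model.y)
        self.converged = res.converged
        self.separation = res.separation
        self.fitted = res.fitted
        if res.separation:
            warnings.warn("possible complete separation: a coefficient exceeds the bound")

    # -- inference ------------------------------------------------------------

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def dispersion(self) -> float:
        """Pearson chi-square / residual df; ~1 for a well-specified fit."""
        self._require_converged()
        mu = self.fitted
        resid_df = self.nobs - self.df_model
        if resid_df <= 0:
            raise ValueError("non-positive residual degrees of freedom")
        pearson2 = np.sum((self.model.y - mu) ** 2 / (mu * (1 - mu)))
        return float(pearson2 / resid_df)

    def _require_converged(self) -> None:
        if not self.converged:
            raise RuntimeError("fit did not converge; diagnostics unavailable")

    # -- prediction -----------------------------------------------------------

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = build_model_matrix(df, self.model.spec)
        return X @ self.params.to_numpy()

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Relative occurrence score (inverse-logit scale) for design rows."""
        return expit(self.linear_predictor(df))

    def predict_curve(self, over: str, grid=None) -> pd.DataFrame:
        """Predicted relative occurrence along one covariate.

        ``over`` is one of "season", "zone", "footprint".  Covariates not
        varied are held at reference values (seasonal mean, zone-averaged
        contrasts, mean footprint).  Returns the grid, linear predictor,
        score = expit(eta) and a 95% Wald band.
        """
        self._require_converged()
        spec = self.model.spec
        if over == "season":
            g = np.arange(1, 366) if grid is None else np.asarray(grid)
            sin_t, cos_t = encode_season(g)
            base = pd.DataFrame({"J": g, "sin_t": sin_t, "cos_t": cos_t})
            base["S"], base["H_z"] = 1, 0.0
            X, _ = build_model_matrix(base, spec)
            if spec.recolonization:  # zone-averaged contrasts are all zero
                X[:, 3 : 3 + spec.n_zones - 1] = 0.0
        elif over == "zone":
            g = np.arange(1, spec.n_zones + 1) if grid is None else np.asarray(grid)
            base = pd.DataFrame({"S": g.astype(int)})
            base["sin_t"] = base["cos_t"] = 0.0
            base["H_z"] = 0.0
            X, _ = build_model_matrix(base, spec)
        elif over == "footprint":
            if grid is None:
                h = self.model.df["H"] if "H" in self.model.df else None
                lo, hi = (h.min(), h.max()) if h is not None else (0.0, 50.0)
                g = np.linspace(lo, hi, 200)
            else:
                g = np.asarray(grid, dtype=float)
            hz = (g - self.model.h_mean) / self.model.h_sd
            tr = self.model.df["H_z"]
            if hz.min() < tr.min() - 1e-9 or hz.max() > tr.max() + 1e-9:
                warnings.warn("footprint grid extends beyond the training range")
            base = pd.DataFrame({"H_z": hz})
            base["sin_t"] = base["cos_t"] = 0.0
            base["S"] = 1
            X, _ = build_model_matrix(base, spec)
            if spec.recolonization:
                i0 = 3 if spec.season else 1
                X[:, i0 : i0 + spec.n_zones - 1] = 0.0
        else:
            raise ValueError("over must be 'season', 'zone' or 'footprint'")
        beta = self.params.to_numpy()
        eta = X @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.vcov.to_numpy(), X))
        return pd.DataFrame(
            {
                "grid": g,
                "eta": eta,
                "score": expit(eta),
                "lower": expit(eta - 1.96 * se),
                "upper": expit(eta + 1.96 * se),
            }
        )

    def summary(self) -> str:
        self_ci = self.conf_int()
        lines = [
            "Occurrence model (binomial logit, observed/availability design)",
            f"  n rows: {self.nobs}   fixed params: {self.df_model}   "
            f"logLik: {self.llf:.3f}   converged: {self.converged}",
        ]
        if self.random_sd:
            facs = ", ".join(
                f"{f} (sd={s:.3f})"
                for f, s in zip(self.model.spec.random_intercepts, self.random_sd)
            )
            lines.append(f"  random intercepts: {facs}")
        lines.append(f"{'term':>12} {'coef':>10} {'se':>9} {'z':>8} {'p':>9} "
                     f"{'[0.025':>9} {'0.975]':>9}")
        for name in self.params.index:
            lines.append(
                f"{name:>12} {self.params[name]:>10.4f} {self.bse[name]:>9.4f} "
                f"{self.zvalues[name]:>8.2f} {self.pvalues[name]:>9.3g} "
                f"{self_ci.loc[name, 'lower']:>9.4f} {self_ci.loc[name, 'upper']:>9.4f}"
            )
        return "\n".join(lines)


@dataclass
class LRTResult:
    chi2: float
    df: int
    pvalue: float


def lrt(full: OccurrenceResults, reduced: OccurrenceResults) -> LRTResult:
    """Likelihood-ratio test of nested occurrence models on the same rows."""
    if not (full.converged and reduced.converged):
        raise RuntimeError("both fits must have converged for an LRT")
    if full.nobs != reduced.nobs:
        raise ValueError("models were fitted to different numbers of rows")
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("models are not nested")
    chi2 = 2.0 * (full.llf - reduced.llf)
    if chi2 < -1e-8:
        raise ValueError(f"reduced model has higher likelihood (chi2={chi2:.3g})")
    chi2 = max(chi2, 0.0)
    df = full.df_model - reduced.df_model
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(float(chi2), int(df), p)


def lrt_ladder(design, full_spec: ModelSpec | None = None) -> pd.DataFrame:
    """Planned likelihood-ratio decomposition of the full model.

    Refits reduced models lacking, in turn, the seasonal harmonics (df 2),
    the recolonization contrasts (df 4 with five zones), both footprint
    terms (df 2) and the quadratic footprint term only (df 1), and tests
    each against the full model.
    """
    full_spec = full_spec if full_spec is not None else ModelSpec()
    full = OccurrenceModel(design, full_spec).fit()
    if not full.converged:
        raise RuntimeError("full model did not converge")
    reductions = [
        ("season", replace(full_spec, season=False)),
        ("recolonization", replace(full_spec, recolonization=False)),
        ("footprint", replace(full_spec, footprint=False, footprint_sq=False)),
        ("footprint_sq", replace(full_spec, footprint_sq=False)),
    ]
    rows = []
    for name, spec_r in reductions:
        red = OccurrenceModel(design, spec_r).fit()
        if not red.converged:
            rows.append({"factor": name, "chi2": np.nan, "df": np.nan,
                         "pvalue": np.nan, "converged": False})
            continue
        t = lrt(full, red)
        rows.append({"factor": name, "chi2": t.chi2, "df": t.df,
                     "pvalue": t.pvalue, "converged": True})
    return pd.DataFrame(rows)
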