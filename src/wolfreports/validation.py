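"""Availability-ratio sensitivity analysis and Boyce-type cross-validation.

Use-availability fits are validated with a k-fold scheme adapted to
observed/available data: observed points (with their paired availability
rows) are partitioned into folds; the model fitted on the training folds
scores the withheld rows; withheld availability scores are cut into
equal-count bins; and the area-adjusted frequency of each bin — the share
of withheld observed points divided by the share of withheld availability
points — is rank-correlated (Spearman) with the bin order.  A strongly
predictive model concentrates observed points in high-score bins, giving
rho near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, build_design
from .occurrence import ModelSpec, OccurrenceModel


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-ranked ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


@dataclass
class CVResult:
    """Per-fold Spearman rho and bin tables of a Boyce-type CV run."""

    fold_rho: list[float]
    bin_tables: list[pd.DataFrame]
    failures: list[str] = field(default_factory=list)

    @property
    def mean_rho(self) -> float:
        vals = [r for r in self.fold_rho if np.isfinite(r)]
        return float(np.mean(vals)) if vals else float("nan")


def _area_adjusted_table(scores_obs, scores_avail, n_bins: int) -> pd.DataFrame:
    """Bin availability scores into equal-count bins; adjusted frequency =
    observed share / availability share per bin (empty-denominator bins are
    merged into their lower neighbour)."""
    edges = np.quantile(scores_avail, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)  # ties can collapse bins; merge them
    edges[0], edges[-1] = -np.inf, np.inf
    if len(edges) - 1 < 2:
        raise ValueError("scores are too discrete to form bins")
    obs_counts, _ = np.histogram(scores_obs, bins=edges)
    av_counts, _ = np.histogram(scores_avail, bins=edges)
    keep = av_counts > 0
    obs_counts, av_counts = obs_counts[keep], av_counts[keep]
    obs_share = obs_counts / max(obs_counts.sum(), 1)
    av_share = av_counts / av_counts.sum()
    return pd.DataFrame(
        {
            "bin": np.arange(1, len(av_counts) + 1),
            "n_observed": obs_counts,
            "observed_share": obs_share,
            "availability_share": av_share,
            "adjusted_frequency": obs_share / av_share,
        }
    )


def boyce_crossvalidate(
    design: DesignMatrix,
    spec: ModelSpec | None = None,
    k_folds: int = 5,
    n_bins: int = 10,
    seed: int | np.random.Generator = 0,
    scores=None,
) -> CVResult:
    """Fivefold area-adjusted-frequency cross-validation.

    ``scores`` may be a callable mapping a design-row DataFrame to
    scores (e.g. a known true intensity, or an already-fitted scorer);
    by default the occurrence model given by ``spec`` is refitted on the
    training folds.  Fold assignment partitions observed reports;
    availability rows always travel with their paired observed report,
    so no withheld pair ever contributes to training.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    spec = spec if spec is not None else ModelSpec()
    rng = np.random.default_rng(seed)
    ids = design.df.loc[design.df["case"] == 1, "report_id"].to_numpy()
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k_folds)

    fold_rho: list[float] = []
    tables: list[pd.DataFrame] = []
    failures: list[str] = []
    for k, fold_idx in enumerate(folds):
        held_ids = set(ids[fold_idx])
        train_ids = [i for i in ids if i not in held_ids]
        held = design.df[design.df["report_id"].isin(held_ids)]
        assert not held["report_id"].isin(train_ids).any()  # leakage guard
        if scores is None:
            train = design.subset(train_ids)
            res = OccurrenceModel(train, spec).fit()
            if not res.converged:
                fold_rho.append(float("nan"))
                tables.append(pd.DataFrame())
                failures.append(f"fold {k + 1}: training fit did not converge")
                continue
            sc = res.linear_predictor(held)
        else:
            sc = np.asarray(scores(held), dtype=float)
        s_obs = sc[held["case"].to_numpy() == 1]
        s_av = sc[held["case"].to_numpy() == 0]
        if np.ptp(sc) == 0:
            fold_rho.append(float("nan"))
            tables.append(pd.DataFrame())
            failures.append(f"fold {k + 1}: constant scores, rho undefined")
            continue
        table = _area_adjusted_table(s_obs, s_av, n_bins)
        tables.append(table)
        try:
            fold_rho.append(spearman(table["bin"], table["adjusted_frequency"]))
        except ValueError as exc:
            fold_rho.append(float("nan"))
            failures.append(f"fold {k + 1}: {exc}")
    return CVResult(fold_rho, tables, failures)


@dataclass
class SensitivityResult:
    """Coefficient stability across candidate availability ratios."""

    ratios: list[int]
    coefficient_paths: pd.DataFrame  # mean coefficient per (ratio, term)
    coefficient_sd: pd.DataFrame
    selected_ratio: int
    flagged_ratios: list[int] = field(default_factory=list)


def ratio_sensitivity(
    observed: pd.DataFrame,
    landscape,
    spec: ModelSpec | None = None,
    ratios=(1, 2, 5, 8, 11, 15, 20),
    replicates: int = 5,
    seed: int = 0,
    stability_threshold: float = 0.05,
) -> SensitivityResult:
    """Select the availability ratio by coefficient stability.

    For each candidate ratio the design is rebuilt ``replicates`` times
    with fresh seeds and refitted; the selected ratio is the smallest one
    whose mean slope coefficients change, relative to a pooled per-term
    scale, by less than ``stability_threshold`` when moving to the next
    larger ratio.  Non-converged ratios are flagged and excluded.
    """
    ratios = sorted(int(r) for r in ratios)
    if len(ratios) < 3:
        raise ValueError("need at least 3 candidate ratios")
    spec = spec if spec is not None else ModelSpec()
    rng = np.random.default_rng(seed)
    means, sds, flagged = {}, {}, []
    for ratio in ratios:
        coefs = []
        ok = True
        for _ in range(replicates):
            design = build_design(observed, landscape, ratio=ratio, seed=rng)
            res = OccurrenceModel(design, spec).fit()
            if not res.converged:
                ok = False
                break
            coefs.append(res.params.drop("intercept"))
        if not ok:
            flagged.append(ratio)
            continue
        coefs = pd.DataFrame(coefs)
        means[ratio] = coefs.mean()
        sds[ratio] = coefs.std()
    if len(means) < 2:
        raise RuntimeError("too few converged ratios for a sensitivity analysis")
    paths = pd.DataFrame(means).T
    sds = pd.DataFrame(sds).T
    # pooled per-term scale: rms of the mean coefficients across ratios
    scale = np.sqrt((paths**2).mean(axis=0)).clip(lower=1e-3)
    usable = list(paths.index)
    selected = usable[-1]
    for i in range(len(usable) - 1):
        change = (paths.loc[usable[i + 1]] - paths.loc[usable[i]]).abs() / scale
        if float(change.max()) < stability_threshold:
            selected = usable[i]
            break
    return SensitivityResult(ratios, paths, sds, int(selected), flagged)
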