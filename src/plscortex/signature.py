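"""Cortical atrophy signatures: w-score normalization and contrast maps.

A w-score is a covariate-adjusted z-score: per region, cortical thickness is
regressed on age and sex in healthy controls, and each subject's thickness is
expressed as (observed - predicted) / control residual SD. Group differences
in w-scored thickness between a target group (e.g. a genetic form) and a
reference group (e.g. sporadic disease), adjusting for disease duration, give
a per-region t-statistic contrast map — the response vector of the
transcriptomic association stage.

Sign convention: the group indicator codes target = 1, reference = 0, so a
negative t means thinner cortex in the target group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SUBJECT_META_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "WScoreModel",
    "ContrastMap",
    "region_columns",
    "fit_wscore_model",
    "apply_wscore",
    "compute_contrast",
]


class DegenerateDesignError(ValueError):
    """Raised when the control covariate design is rank-deficient."""


def region_columns(subjects: pd.DataFrame) -> list[str]:
    """Columns of a subject table that hold regional thickness values."""
    return [c for c in subjects.columns if c not in SUBJECT_META_COLUMNS]


@dataclass
class WScoreModel:
    """Per-region control regression of thickness on intercept + age + sex.

    ``coefficients`` is a region x (intercept, age, sex) table in mm and
    mm per covariate unit; ``residual_sd`` the per-region control residual
    standard deviation (mm, n-3 denominator).
    """

    coefficients: pd.DataFrame
    residual_sd: pd.Series
    n_controls: int

    def __post_init__(self) -> None:
        if (self.residual_sd <= 0).any():
            bad = self.residual_sd.index[self.residual_sd <= 0][0]
            raise ValueError(f"non-positive residual SD in region {bad}")
        if not np.isfinite(self.coefficients.to_numpy()).all():
            raise ValueError("non-finite w-score coefficients")

    @property
    def regions(self) -> list[str]:
        return list(self.coefficients.index)

    def predict(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones_like(age, dtype=float), age, sex])
        return design @ self.coefficients.to_numpy().T


@dataclass
class ContrastMap:
    """Per-region t-statistics for a target-vs-reference group comparison."""

    t: pd.Series
    df: int
    target: str = "target"
    reference: str = "reference"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")

    @property
    def regions(self) -> list[str]:
        return list(self.t.index)

    def to_tsv(self, path) -> None:
        self.t.rename("t").to_csv(path, sep="\t", index_label="region")


def fit_wscore_model(controls: pd.DataFrame) -> WScoreModel:
    """Fit per-region OLS of thickness on intercept + age + sex in controls.

    Controls with missing age or sex are dropped with a warning. The design
    matrix is shared across regions, so a single least-squares solve covers
    all of them. Residual SD uses an n-3 denominator (three fitted
    parameters).
    """
    regions = region_columns(controls)
    keep = controls[["age", "sex"]].notna().all(axis=1)
    if (~keep).any():
        logger.warning("dropping %d controls with missing covariates", (~keep).sum())
    ctrl = controls.loc[keep]
    n = len(ctrl)
    if n < 4:
        raise ValueError("need at least 4 controls with complete covariates")

    age = ctrl["age"].to_numpy(dtype=float)
    sex = ctrl["sex"].to_numpy(dtype=float)
    for name, col in (("age", age), ("sex", sex)):
        if np.ptp(col) == 0:
            raise DegenerateDesignError(
                f"covariate '{name}' is constant across controls"
            )
    design = np.column_stack([np.ones(n), age, sex])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateDesignError("age and sex are collinear across controls")

    Y = ctrl[regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    sd = np.sqrt((resid**2).sum(axis=0) / (n - 3))

    coef = pd.DataFrame(beta.T, index=regions, columns=["intercept", "age", "sex"])
    return WScoreModel(
        coefficients=coef,
        residual_sd=pd.Series(sd, index=regions),
        n_controls=n,
    )


def apply_wscore(model: WScoreModel, subjects: pd.DataFrame) -> pd.DataFrame:
    """w = (observed - predicted(age, sex)) / control residual SD, per region.

    Returns a subjects x regions DataFrame indexed by subject_id.
    """
    regions = region_columns(subjects)
    if regions != model.regions:
        raise ValueError(
            f"region mismatch: subjects have {len(regions)} regions, "
            f"model has {len(model.regions)}"
        )
    pred = model.predict(
        subjects["age"].to_numpy(dtype=float), subjects["sex"].to_numpy(dtype=float)
    )
    obs = subjects[regions].to_numpy(dtype=float)
    w = (obs - pred) / model.residual_sd.to_numpy()
    return pd.DataFrame(w, index=subjects["subject_id"].to_numpy(), columns=regions)


def compute_contrast(
    wscores: pd.DataFrame,
    groups: pd.Series,
    duration: pd.Series,
    target_group: str,
    reference_group: str,
) -> ContrastMap:
    """Per-region t-statistic of the group term, adjusting for duration.

    For each region an OLS of the w-score on {intercept, group indicator,
    disease duration} is fit over subjects in the two groups; the t-statistic
    of the group indicator (target coded 1) is returned. The design matrix is
    shared across regions, so coefficients and their standard errors come
    from one pseudoinverse.
    """
    groups = groups.reindex(wscores.index)
    duration = duration.reindex(wscores.index)
    mask = groups.isin([target_group, reference_group]).to_numpy()
    for g in (target_group, reference_group):
        if (groups == g).sum() < 2:
            raise ValueError(f"group '{g}' has fewer than 2 subjects")
    sub = wscores.loc[mask]
    dur = duration.loc[mask]
    if dur.isna().any():
        raise ValueError("disease duration missing for some included subjects")

    n = len(sub)
    indicator = (groups.loc[mask] == target_group).to_numpy(dtype=float)
    dur_v = dur.to_numpy(dtype=float)
    if np.ptp(dur_v) == 0:
        # constant duration is collinear with the intercept; drop it and the
        # model reduces to the pooled two-sample comparison
        X = np.column_stack([np.ones(n), indicator])
    else:
        X = np.column_stack([np.ones(n), indicator, dur_v])
    k = X.shape[1]
    df = n - k
    if df <= 0:
        raise ValueError("not enough subjects for a 3-parameter model")

    W = sub.to_numpy(dtype=float)
    pinv = np.linalg.pinv(X)
    beta = pinv @ W
    resid = W - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    # var(beta_g) = sigma^2 * [(X'X)^-1]_gg
    xtx_inv_gg = (pinv @ pinv.T)[1, 1]
    se = np.sqrt(sigma2 * xtx_inv_gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)

    return ContrastMap(
        t=pd.Series(t, index=sub.columns),
        df=df,
        target=target_group,
        reference=reference_group,
        metadata={
            "n_target": int(indicator.sum()),
            "n_reference": int(n - indicator.sum()),
            "sign_convention": "positive t = thicker cortex in target group",
            "covariates": ["duration"] if k == 3 else [],
        },
    )


def contrast_pvalues(cmap: ContrastMap) -> pd.Series:
    """Two-sided p-values of the contrast t-statistics."""
    return pd.Series(
        2 * stats.t.sf(np.abs(cmap.t.to_numpy()), df=cmap.df), index=cmap.t.index
    )
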