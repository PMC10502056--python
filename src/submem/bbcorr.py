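"""Brain-behavior correlation products beyond the voxel-wise map.

Two analyses: (1) the resampling experiment on effect-size reproducibility
-- mean activation in the largest significant clusters is related to the
recall count (adjusting for age, sex and batch) in random subsamples of
log-spaced sizes (n = 26 ... 1000, 5000 draws each at paper scale),
summarizing the standardized effect size r = sign(slope) * t / sqrt(t^2 +
df) per draw; and (2) the whole-brain t-on-t regression comparing the
memorability-corrected subsequent-memory t map (predictor) with the
brain-behavior correlation t map (outcome), whose residuals localize
regions where the brain-behavior association is weaker (negative residual)
or stronger (positive) than the subsequent-memory effect predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group import GroupDesign

__all__ = [
    "EffectSizeGrid",
    "ResidualMap",
    "PAPER_SAMPLE_SIZES",
    "roi_mean_activation",
    "standardized_effect",
    "resample_effect_sizes",
    "compare_tmaps",
]

# printed verbatim in the reproducibility analysis; not re-derived from a
# rounding rule (no single rule reproduces the list)
PAPER_SAMPLE_SIZES = (26, 38, 55, 78, 113, 162, 234, 336, 483, 695, 1000)


def roi_mean_activation(stack: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Per-subject mean of the contrast stack over a region of interest."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty region of interest")
    flat = np.asarray(stack, dtype=float).reshape(stack.shape[0], -1)
    return flat[:, roi_mask.ravel()].mean(axis=1)


def standardized_effect(
    brain: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Partial correlation of brain and behavior given covariates.

    Computed on the t scale as ``sign(slope) * |t| / sqrt(t^2 + df)`` from
    the model behavior ~ brain + covariates + 1; equal to the correlation
    of the two covariate-residualized vectors.
    """
    brain = np.asarray(brain, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    n = brain.shape[0]
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float).reshape(n, -1))
    )
    p = cov.shape[1]
    if n <= p + 2:
        raise ValueError("need n > number of covariates + 2")
    x = np.column_stack([brain, cov, np.ones(n)])
    beta, *_ = np.linalg.lstsq(x, behavior, rcond=None)
    resid = behavior - x @ beta
    # rank-robust: in small subsamples a categorical dummy can be constant
    rank = np.linalg.matrix_rank(x)
    dof = n - rank
    if dof <= 0:
        raise ValueError("zero residual degrees of freedom")
    sigma2 = resid @ resid / dof
    if sigma2 == 0.0:
        return float(np.sign(beta[0]))
    cvar = np.linalg.pinv(x.T @ x)[0, 0]
    t = beta[0] / np.sqrt(sigma2 * cvar)
    return float(np.sign(beta[0]) * np.abs(t) / np.sqrt(t**2 + dof))


@dataclass
class EffectSizeGrid:
    """Resampled standardized effect sizes per ROI and sample size.

    ``effects`` is a long table (roi, n, rep, effect); ``summary``
    aggregates median, interquartile range and the rate of draws whose sign
    differs from the full-sample effect.
    """

    effects: pd.DataFrame
    summary: pd.DataFrame
    sample_sizes: tuple[int, ...]
    n_reps: int
    seed: int
    full_sample_effect: dict[int, float] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.effects.to_csv(path, sep="\t", index=False)


def resample_effect_sizes(
    stack: np.ndarray,
    phenotype: pd.DataFrame,
    rois: list[np.ndarray],
    sample_sizes: tuple[int, ...] = PAPER_SAMPLE_SIZES,
    n_reps: int = 200,
    seed: int = 0,
    covariate_design: GroupDesign | None = None,
    covariate_matrix: np.ndarray | None = None,
) -> EffectSizeGrid:
    """Subsampled brain-behavior effect sizes across sample sizes.

    For each sample size, ``n_reps`` subject subsets are drawn without
    replacement (independent across replicates); within each draw the
    standardized effect of the ROI-mean activation on the recall count,
    adjusted for the covariates, is computed per ROI.  Covariates are taken
    from ``covariate_matrix`` (subjects x covariates, no intercept column)
    or extracted from a ``covariate_design`` (all non-predictor,
    non-intercept columns).
    """
    n_subjects = len(phenotype)
    if max(sample_sizes) > n_subjects:
        raise ValueError("largest sample size exceeds the cohort")
    if covariate_matrix is None and covariate_design is not None:
        keep = [
            j
            for j, name in enumerate(covariate_design.column_names)
            if j != covariate_design.predictor_index and name != "intercept"
        ]
        covariate_matrix = covariate_design.matrix[:, keep]
    cov = (
        np.empty((n_subjects, 0))
        if covariate_matrix is None
        else np.asarray(covariate_matrix, dtype=float)
    )
    min_n = cov.shape[1] + 3
    if min(sample_sizes) < min_n:
        raise ValueError(f"smallest sample size must be >= {min_n}")

    behavior = phenotype["recall_count"].to_numpy(dtype=float)
    brain_by_roi = [roi_mean_activation(stack, roi) for roi in rois]
    full_effect = {
        r: standardized_effect(brain, behavior, cov)
        for r, brain in enumerate(brain_by_roi)
    }

    rng = np.random.default_rng(seed)
    rows = []
    for size in sample_sizes:
        for rep in range(n_reps):
            idx = rng.choice(n_subjects, size=size, replace=False)
            for r, brain in enumerate(brain_by_roi):
                eff = standardized_effect(brain[idx], behavior[idx], cov[idx])
                rows.append({"roi": r, "n": size, "rep": rep, "effect": eff})
    effects = pd.DataFrame(rows)

    def summarize(grp: pd.DataFrame) -> pd.Series:
        roi = int(grp.name[0])
        e = grp["effect"]
        ref_sign = np.sign(full_effect[roi]) or 1.0
        return pd.Series(
            {
                "median": e.median(),
                "iqr": e.quantile(0.75) - e.quantile(0.25),
                "sign_flip_rate": float((np.sign(e) == -ref_sign).mean()),
            }
        )

    summary = (
        effects.groupby(["roi", "n"], as_index=False)
        .apply(summarize, include_groups=False)
        .reset_index(drop=True)
    )
    summary[["roi", "n"]] = (
        effects.groupby(["roi", "n"], as_index=False).size()[["roi", "n"]]
    )
    summary = summary[["roi", "n", "median", "iqr", "sign_flip_rate"]]
    return EffectSizeGrid(
        effects=effects,
        summary=summary,
        sample_sizes=tuple(sample_sizes),
        n_reps=n_reps,
        seed=seed,
        full_sample_effect=full_effect,
    )


@dataclass
class ResidualMap:
    """Residuals of the t-on-t regression, on the inclusion mask only.

    Negative residuals mark voxels where the brain-behavior correlation is
    weaker than the subsequent-memory effect predicts; positive residuals,
    as strong or stronger.  NaN outside the mask.
    """

    residuals: np.ndarray
    slope: float
    intercept: float
    mask: np.ndarray


def compare_tmaps(
    predictor_tmap: np.ndarray,
    outcome_tmap: np.ndarray,
    inclusion_mask: np.ndarray,
) -> ResidualMap:
    """Regress one whole-brain t map on another and return the residuals.

    A single OLS line is fit over the included voxels (typically those with
    a significant predictor effect); residual = outcome - (intercept +
    slope * predictor).  Residuals sum to zero over the mask by the OLS
    identity.
    """
    mask = np.asarray(inclusion_mask, dtype=bool)
    if not mask.any():
        raise ValueError("inclusion mask is empty")
    xv = np.asarray(predictor_tmap, dtype=float)[mask]
    yv = np.asarray(outcome_tmap, dtype=float)[mask]
    if np.ptp(xv) == 0.0:
        raise ValueError("predictor map is constant over the inclusion mask")
    x = np.column_stack([xv, np.ones_like(xv)])
    (slope, intercept), *_ = np.linalg.lstsq(x, yv, rcond=None)
    resid = np.full(mask.shape, np.nan)
    resid[mask] = yv - (slope * xv + intercept)
    return ResidualMap(
        residuals=resid, slope=float(slope), intercept=float(intercept), mask=mask
    )
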