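"""Group-level voxel-wise inference.

Stacks per-subject contrast images and fits, at every voxel, an ordinary
least-squares model with a predictor of interest (the intercept for
mean-effect analyses such as the subsequent-memory map; the recall count
for brain-behavior analyses) plus age, sex and batch covariates.
Family-wise error is controlled by the permutation distribution of the
maximum |t| over the analysis mask (Freedman-Lane residual permutation),
two-sided at alpha = 0.05, followed by a cluster-extent filter (default
minimum 20 voxels, face connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats

__all__ = [
    "GroupDesign",
    "StatMap",
    "ThresholdResult",
    "build_group_design",
    "fit_group_model",
    "fwe_correct",
    "bonferroni_threshold",
    "cluster_table_from_map",
    "top_k_cluster_masks",
]

T_CAP = 1e6  # guard for perfect fits (zero residual variance)

_CONNECTIVITY = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class GroupDesign:
    """Subject-level design: predictor of interest + nuisance covariates.

    ``matrix`` columns are ordered [predictor, covariates..., intercept]
    unless the predictor is the intercept itself; ``predictor_index``
    points at the column tested.
    """

    matrix: np.ndarray
    column_names: list[str]
    predictor_index: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("collinear group covariates (rank-deficient design)")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return self.matrix.shape[1]


def build_group_design(
    phenotype: pd.DataFrame,
    predictor: str = "intercept",
    covariates: tuple[str, ...] = ("age", "sex", "batch_mr", "room"),
) -> GroupDesign:
    """Treatment-coded design from a phenotype table.

    ``predictor`` is ``"intercept"`` (mean-effect analysis) or a phenotype
    column (e.g. ``recall_count``; continuous predictors are z-scored).
    Categorical covariates are dummy-coded with the first level as
    reference.
    """
    n = len(phenotype)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in phenotype.columns:
            raise KeyError(f"phenotype table lacks covariate {cov!r}")
        series = phenotype[cov]
        if series.dtype.kind in "if":
            v = series.to_numpy(dtype=float)
            cols.append((v - v.mean()) / (v.std() or 1.0))
            names.append(cov)
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    if predictor == "intercept":
        matrix = np.column_stack([np.ones(n), *cols]) if cols else np.ones((n, 1))
        names = ["intercept", *names]
        pred_idx = 0
    else:
        v = phenotype[predictor].to_numpy(dtype=float)
        v = (v - v.mean()) / (v.std() or 1.0)
        matrix = np.column_stack([v, *cols, np.ones(n)])
        names = [predictor, *names, "intercept"]
        pred_idx = 0
    return GroupDesign(matrix=matrix, column_names=names, predictor_index=pred_idx)


@dataclass
class StatMap:
    """Two-sided t map with constant error df over voxels."""

    t: np.ndarray
    dof: int
    mask: np.ndarray

    def in_mask(self) -> np.ndarray:
        return self.t[self.mask]


@dataclass
class ThresholdResult:
    """FWE-corrected threshold, significant-voxel mask and cluster table.

    ``clusters`` has one row per surviving cluster: cluster_id, sign,
    n_voxels, peak_t and the 0-based peak voxel index (i, j, k).  Every
    reported cluster has at least ``min_cluster`` voxels.
    """

    t_threshold: float
    significant: np.ndarray
    clusters: pd.DataFrame
    null_max_t: np.ndarray
    alpha: float
    min_cluster: int


def _stack_to_matrix(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 4:  # subjects x X x Y x Z
        return stack.reshape(stack.shape[0], -1)[:, mask.ravel()]
    return stack


def _t_for_predictor(
    x: np.ndarray, y: np.ndarray, pred_idx: int
) -> tuple[np.ndarray, int]:
    """Vectorized per-voxel OLS t for one design column. y is N x V."""
    n, p = x.shape
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    cvar = np.linalg.inv(x.T @ x)[pred_idx, pred_idx]
    se = np.sqrt(np.maximum(sigma2 * cvar, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[pred_idx] / se
    t = np.where(np.isfinite(t), t, np.sign(beta[pred_idx]) * T_CAP)
    return np.clip(t, -T_CAP, T_CAP), dof


def fit_group_model(
    stack: np.ndarray, design: GroupDesign, mask: np.ndarray
) -> StatMap:
    """Per-voxel OLS over subjects; two-sided t for the predictor of interest.

    ``stack`` is subjects x X x Y x Z (or subjects x voxels already
    restricted to the mask).  Perfect fits are capped at |t| = 1e6.
    """
    y = _stack_to_matrix(stack, mask)
    if y.shape[0] != design.n_subjects:
        raise ValueError("contrast stack and group design are misaligned")
    t, dof = _t_for_predictor(design.matrix, y, design.predictor_index)
    tmap = np.full(mask.shape, np.nan)
    tmap[mask] = t
    return StatMap(t=tmap, dof=dof, mask=np.asarray(mask, bool))


def cluster_table_from_map(
    tmap: np.ndarray,
    threshold: float,
    mask: np.ndarray,
    min_cluster: int = 20,
    connectivity: int = 6,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label supra-threshold voxels and drop clusters below the extent cut.

    Positive and negative exceedances are labeled separately (two result
    sets from the two-sided map) and combined into one table with a sign
    column.  Returns (significant mask, cluster table).
    """
    structure = _CONNECTIVITY[connectivity]
    sig = np.zeros_like(mask, dtype=bool)
    rows = []
    cluster_id = 0
    t_clean = np.where(mask, tmap, 0.0)
    for sign, exceed in (
        (1, (t_clean > threshold)),
        (-1, (t_clean < -threshold)),
    ):
        labels, n_lab = ndimage.label(exceed, structure=structure)
        for lab in range(1, n_lab + 1):
            vox = labels == lab
            size = int(vox.sum())
            if size < min_cluster:
                continue
            cluster_id += 1
            sub_t = np.where(vox, t_clean, np.nan)
            flat_peak = np.nanargmax(sign * sub_t)
            i, j, k = np.unravel_index(flat_peak, tmap.shape)
            rows.append(
                {
                    "cluster_id": cluster_id,
                    "sign": sign,
                    "n_voxels": size,
                    "peak_t": float(tmap[i, j, k]),
                    "i": int(i),
                    "j": int(j),
                    "k": int(k),
                }
            )
            sig |= vox
    table = pd.DataFrame(
        rows, columns=["cluster_id", "sign", "n_voxels", "peak_t", "i", "j", "k"]
    )
    return sig, table


def fwe_correct(
    stack: np.ndarray,
    design: GroupDesign,
    mask: np.ndarray,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    min_cluster: int = 20,
    connectivity: int = 6,
) -> ThresholdResult:
    """Permutation max-|t| family-wise error correction, two-sided.

    Freedman-Lane scheme: the outcome is residualized against the nuisance
    covariates, residual rows are permuted, the nuisance fit is added back
    and the full model is refit; the corrected threshold is the (1 - alpha)
    quantile of the null distribution of max |t| over the mask.  Requires
    ``n_perm >= max(100, 1/alpha - 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if n_perm + 1 < 1.0 / alpha:
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha}")
    y = _stack_to_matrix(stack, mask)
    x = design.matrix
    pred = design.predictor_index
    nuis_idx = [j for j in range(x.shape[1]) if j != pred]
    rng = np.random.default_rng(seed)

    observed = fit_group_model(stack, design, mask)
    t_obs = observed.in_mask()

    if nuis_idx:
        z = x[:, nuis_idx]
        hz = z @ np.linalg.pinv(z)
        fitted = hz @ y
        resid = y - fitted
    else:
        fitted = np.zeros_like(y)
        resid = y

    null_max = np.empty(n_perm)
    n = y.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted + resid[perm]
        t_star, _ = _t_for_predictor(x, y_star, pred)
        null_max[b] = np.abs(t_star).max()

    thr = float(np.quantile(null_max, 1.0 - alpha))
    sig, table = cluster_table_from_map(
        observed.t, thr, observed.mask, min_cluster, connectivity
    )
    return ThresholdResult(
        t_threshold=thr,
        significant=sig,
        clusters=table,
        null_max_t=null_max,
        alpha=alpha,
        min_cluster=min_cluster,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test alpha under Bonferroni correction: alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def top_k_cluster_masks(
    result: ThresholdResult, labels_shape: tuple[int, int, int], k: int = 4,
    connectivity: int = 6,
) -> list[np.ndarray]:
    """Binary masks of the k largest surviving clusters (extent order).

    Implements the "largest significant clusters" region-of-interest rule
    used by the reproducibility analysis, generically on any threshold
    result.
    """
    structure = _CONNECTIVITY[connectivity]
    labels, n_lab = ndimage.label(result.significant, structure=structure)
    sizes = ndimage.sum_labels(np.ones(labels_shape), labels, range(1, n_lab + 1))
    order = np.argsort(sizes)[::-1][:k]
    return [labels == (lab + 1) for lab in order]


def partial_regression_pvalues(t: np.ndarray, dof: int) -> np.ndarray:
    """Two-sided p-values for t statistics with ``dof`` error df."""
    return 2.0 * stats.t.sf(np.abs(t), dof)
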